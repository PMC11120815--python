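"""Genotype-normalized normative CSS (nCSS) via within-genotype ECDFs.

For each common variant group, the empirical cumulative distribution of
mean predicted CSS is built from classic-diagnosis training participants.
A participant's nCSS is their percentile within their own genotype's
training distribution, divided by 100 -- i.e. the right-continuous ECDF
value (proportion of training values <= theirs), in [0, 1].  Scoring is
applied to every participant regardless of diagnosis; values outside the
training support map to 0 (below) or 1 (above).  By construction,
group-level genotype-phenotype differences collapse on the nCSS scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["GenotypeECDF", "NormativeScorer", "build_ecdfs", "ncss"]


@dataclass
class GenotypeECDF:
    """Sorted training values (multiset) for one genotype group."""

    genotype: str
    values: np.ndarray  # sorted ascending

    @property
    def n_train(self) -> int:
        return len(self.values)

    def __call__(self, value) -> np.ndarray | float:
        """Right-continuous ECDF: proportion of training values <= value."""
        v = np.asarray(value, dtype=float)
        out = np.searchsorted(self.values, v, side="right") / self.n_train
        return float(out) if np.isscalar(value) else out


def build_ecdfs(values, genotypes) -> dict[str, GenotypeECDF]:
    """One ECDF per genotype group present in the training data."""
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    if len(values) == 0:
        raise ValueError("training set is empty")
    if len(values) != len(genotypes):
        raise ValueError("values and genotypes must align")
    out = {}
    for g in pd.unique(genotypes):
        vals = np.sort(values[genotypes == g])
        out[str(g)] = GenotypeECDF(str(g), vals)
    return out


def ncss(ecdf: GenotypeECDF, value: float) -> float:
    """Normative CSS: within-genotype percentile / 100 of a mean predicted CSS."""
    return float(ecdf(float(value)))


class NormativeScorer(BaseEstimator):
    """Transformer mapping (mean predicted CSS, genotype) pairs to nCSS.

    ``fit`` ingests the classic training participants' mean predicted CSS
    and genotype labels; ``transform`` scores any participants whose
    genotype was present in training.
    """

    def fit(self, X, y=None) -> "NormativeScorer":
        """``X``: DataFrame with ``mean_predicted_css`` and ``genotype``."""
        self.ecdfs_ = build_ecdfs(
            X["mean_predicted_css"].to_numpy(dtype=float), X["genotype"].to_numpy()
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "ecdfs_"):
            raise RuntimeError("scorer is not fitted")
        vals = X["mean_predicted_css"].to_numpy(dtype=float)
        genos = X["genotype"].to_numpy()
        missing = set(genos) - set(self.ecdfs_)
        if missing:
            raise ValueError(f"no training ECDF for genotype(s): {sorted(missing)}")
        out = np.empty(len(vals))
        for g in set(genos):
            mask = genos == g
            out[mask] = self.ecdfs_[g](vals[mask])
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {
            g: list(map(float, e.values)) for g, e in self.ecdfs_.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeScorer":
        obj = cls()
        obj.ecdfs_ = {
            g: GenotypeECDF(g, np.sort(np.asarray(v, dtype=float)))
            for g, v in d.items()
        }
        return obj
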