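"""End-to-end pipeline: clean -> fit -> predict -> normalize -> [validate] -> xci.

Each stage writes its artifact into a run directory and the whole run is
recorded in a JSON manifest (package version, seed, input hashes, per-stage
outputs).  All randomness flows from the single run seed; no stage draws
from the global NumPy generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cleaning import clean_cohort
from .growth import CSSGrowthModel
from .io import read_visit_table, read_xci_table, write_visit_table
from .normative import NormativeScorer
from .predict import predict_cohort
from .crossval import loocv, summarize_rmse
from .schema import SEVERITY_MAP, ItemSchema
from .xci import cohort_mean_visit_age, fit_xci_model, grouped_correlations, nearest_visit_css

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    visits_path: str
    out_dir: str
    xci_path: str | None = None
    training_diagnosis: str = "classic"
    age_window: tuple = (2.0, 25.0)
    run_validation: bool = False
    seed: int = 0


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, returning the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = ItemSchema.default()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {"visits": _sha256(config.visits_path)},
        "stages": {},
    }
    if config.xci_path:
        manifest["inputs"]["xci"] = _sha256(config.xci_path)

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
            manifest["stages"][name] = result
            return result

        return deco

    visits = read_visit_table(config.visits_path, schema)

    @stage("clean")
    def _clean():
        revised, report = clean_cohort(visits, schema)
        write_visit_table(revised, out / "revised.csv")
        report.to_frame().to_csv(out / "cleaning_report.csv", index=False)
        return {
            "out": "revised.csv",
            "n_revised": report.total_revised,
            "n_dropped": len(report.dropped_participants),
        }

    revised = read_visit_table(out / "revised.csv", schema)

    @stage("fit")
    def _fit():
        model = CSSGrowthModel(
            training_diagnosis=config.training_diagnosis, age_window=config.age_window
        ).fit(revised)
        model.save(out / "fit.json")
        return {
            "out": "fit.json",
            "n_subjects": model.n_subjects_,
            "n_obs": model.n_obs_,
            "loglik": model.loglik_,
        }

    model = CSSGrowthModel.load(out / "fit.json")

    @stage("predict")
    def _predict():
        lo, hi = config.age_window
        in_window = revised[
            (revised["visit_age_years"] >= lo) & (revised["visit_age_years"] <= hi)
        ]
        preds = predict_cohort(model, in_window)
        preds.to_csv(out / "predictions.csv", index=False)
        return {"out": "predictions.csv", "n_participants": len(preds)}

    preds = pd.read_csv(out / "predictions.csv")

    @stage("normalize")
    def _normalize():
        train = preds[preds["diagnosis"] == config.training_diagnosis]
        scorer = NormativeScorer().fit(train)
        scored = preds.copy()
        scored["ncss"] = scorer.transform(preds)
        scored.to_csv(out / "ncss.csv", index=False)
        with open(out / "ecdfs.json", "w") as fh:
            json.dump(scorer.to_dict(), fh)
        return {"out": "ncss.csv", "n_train": len(train)}

    if config.run_validation:

        @stage("validate")
        def _validate():
            results = loocv(revised)
            results.to_csv(out / "cv.csv", index=False)
            summary = summarize_rmse(results)
            summary.to_csv(out / "cv_summary.csv", index=False)
            overall = summary.loc[summary["group"] == "overall"].iloc[0]
            return {"out": "cv.csv", "median_rmse": float(overall["median"])}

    if config.xci_path:

        @stage("xci")
        def _xci():
            xci = read_xci_table(config.xci_path)
            scored = pd.read_csv(out / "ncss.csv")
            informative = xci[xci["informative"] & xci["pxci"].notna()]
            cohort_visits = revised[
                revised["participant_id"].isin(informative["participant_id"])
            ]
            mean_age = cohort_mean_visit_age(cohort_visits)

            raw_rows = []
            for pid, sub in cohort_visits.groupby("participant_id"):
                css, age = nearest_visit_css(sub, mean_age)
                raw_rows.append(
                    {
                        "participant_id": pid,
                        "genotype": sub["genotype"].iloc[0],
                        "raw_css": css,
                        "visit_age": age,
                    }
                )
            raw = pd.DataFrame(raw_rows)

            corr_rows = []
            for score_type, frame, col in (
                ("raw_css", raw, "raw_css"),
                ("ncss", scored.rename(columns={"ncss": "score"}), "score"),
            ):
                res = grouped_correlations(frame, xci, col)
                for grp, cr in res.items():
                    corr_rows.append(
                        {
                            "score_type": score_type,
                            "group": grp,
                            "n": cr.n,
                            "r": cr.r,
                            "p": cr.p,
                            "ci_low": cr.ci95[0],
                            "ci_high": cr.ci95[1],
                        }
                    )
            pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

            merged = scored.merge(informative, on="participant_id")
            merged["sev_group"] = [SEVERITY_MAP[g] for g in merged["genotype"]]
            _, partition = fit_xci_model(merged)
            partition.to_frame().to_csv(out / "variance_partition.csv", index=False)
            return {
                "out": "correlations.csv",
                "mean_visit_age": mean_age,
                "interaction_fraction": partition.fractions["SevGroup:pXCI"],
            }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
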