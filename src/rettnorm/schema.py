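"""Item schema, genotype labels and severity groupings for the Clinical Severity Score.

The CSS is the sum of 13 clinician-rated Likert items (each 0-4 or 0-5,
totals 0-58).  Items fall into three longitudinal classes:

* ``historical`` -- fixed historical facts (e.g. age of onset of regression);
  once reported they can never legitimately change.
* ``monotone`` -- features that can only worsen or plateau over time
  (e.g. scoliosis).
* ``free`` -- items with no longitudinal constraint.

The published score does not enumerate which of the 13 items belongs to which
class, so the schema is configuration: the default below has 2 historical
items (max 4), 3 monotone items (max 5) and 8 free items, chosen so the caps
sum to 58.  The cleaning rules depend only on the class, never on item
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

ITEM_CLASSES = ("historical", "monotone", "free")

#: The eleven common MECP2 variant groupings used for model training.
GENOTYPES = (
    "R106W",
    "R133C",
    "T158M",
    "R168X",
    "R255X",
    "R270X",
    "R294X",
    "R306C",
    "large_deletion",
    "early_truncation",
    "CTT",
)

#: Group-level severity classification of the common variants.
MILD_GENOTYPES = frozenset({"R133C", "R294X", "R306C", "CTT"})
SEVERE_GENOTYPES = frozenset(set(GENOTYPES) - MILD_GENOTYPES)

#: genotype -> "mild" | "severe"
SEVERITY_MAP = {g: ("mild" if g in MILD_GENOTYPES else "severe") for g in GENOTYPES}

DIAGNOSES = ("classic", "atypical")

CSS_MAX = 58
N_ITEMS = 13


@dataclass(frozen=True)
class Item:
    """One CSS item: identity, longitudinal class and score cap."""

    item_id: str
    item_class: str
    max_score: int

    def __post_init__(self) -> None:
        if self.item_class not in ITEM_CLASSES:
            raise ValueError(
                f"item_class must be one of {ITEM_CLASSES}, got {self.item_class!r}"
            )
        if self.max_score not in (4, 5):
            raise ValueError(f"max_score must be 4 or 5, got {self.max_score}")


class ItemSchema:
    """An ordered collection of exactly 13 CSS items whose caps sum to 58."""

    def __init__(self, items: list[Item]):
        if len(items) != N_ITEMS:
            raise ValueError(f"schema needs exactly {N_ITEMS} items, got {len(items)}")
        total = sum(it.max_score for it in items)
        if total != CSS_MAX:
            raise ValueError(f"item caps must sum to {CSS_MAX}, got {total}")
        classes = {it.item_class for it in items}
        if classes != set(ITEM_CLASSES):
            raise ValueError(f"schema must contain every class in {ITEM_CLASSES}")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in schema")
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i: int) -> Item:
        return self.items[i]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def max_scores(self) -> list[int]:
        return [it.max_score for it in self.items]

    def by_class(self, item_class: str) -> list[Item]:
        return [it for it in self.items if it.item_class == item_class]

    def class_of(self, item_id: str) -> str:
        for it in self.items:
            if it.item_id == item_id:
                return it.item_class
        raise KeyError(f"unknown item_id {item_id!r}")

    @classmethod
    def default(cls) -> "ItemSchema":
        """Default 13-item schema: 2 historical (cap 4), 3 monotone (cap 5),
        8 free (5x cap 4 + 3x cap 5); caps total 58."""
        items = []
        items += [Item(f"item_{i:02d}", "historical", 4) for i in (1, 2)]
        items += [Item(f"item_{i:02d}", "monotone", 5) for i in (3, 4, 5)]
        items += [Item(f"item_{i:02d}", "free", 4) for i in (6, 7, 8, 9, 10)]
        items += [Item(f"item_{i:02d}", "free", 5) for i in (11, 12, 13)]
        return cls(items)

    def to_dict(self) -> dict:
        return {
            "items": [
                {"item_id": it.item_id, "item_class": it.item_class, "max_score": it.max_score}
                for it in self.items
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemSchema":
        return cls([Item(e["item_id"], e["item_class"], int(e["max_score"])) for e in d["items"]])


_GENOTYPE_ALIASES = {
    "large deletion": "large_deletion",
    "largedeletion": "large_deletion",
    "large_del": "large_deletion",
    "early truncation": "early_truncation",
    "earlytruncation": "early_truncation",
    "c-terminal truncation": "CTT",
    "ctt": "CTT",
}
_CANONICAL = {g.lower(): g for g in GENOTYPES}


def canonical_genotype(label: str) -> str:
    """Canonicalize a genotype label (case-insensitive, alias-aware).

    Raises ``ValueError`` listing the allowed labels if it cannot be mapped.
    """
    key = str(label).strip().lower().replace("-", "_")
    for variant in (key, key.replace("_", " ")):
        if variant in _GENOTYPE_ALIASES:
            key = _GENOTYPE_ALIASES[variant].lower()
            break
    if key in _CANONICAL:
        return _CANONICAL[key]
    raise ValueError(
        f"unknown genotype label {label!r}; allowed labels: {', '.join(GENOTYPES)}"
    )
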