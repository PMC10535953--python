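"""Correlation-weight table and the optimal descriptor DCW.

The model's only descriptor is a weighted sum over a compound's attribute
multiset: ``DCW(T, N) = sum_k CW(a_k)``, where the sum runs over token and
token-pair occurrences (plus graph invariants in the hybrid configuration).
``T`` is the rarity threshold: attributes seen in fewer than ``T`` active
training compounds are *blocked* and contribute exactly zero; ``N`` is the
optimization epoch budget carried alongside for bookkeeping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "AttributeStats",
    "CorrelationWeightTable",
    "CompoundFeatures",
    "attribute_frequencies",
    "classify_rare",
    "dcw",
]

SUBSET_LABELS = ("active", "passive", "calibration", "validation")


@dataclass(frozen=True)
class AttributeStats:
    """Presence counts of one attribute across the three modelling subsets.

    A count is the number of compounds of the subset containing the
    attribute at least once (not total occurrences), matching how promoter
    tables report feature frequencies.
    """

    code: str
    n_active: int
    n_passive: int
    n_calibration: int


@dataclass
class CompoundFeatures:
    """Attribute multiset of one compound."""

    compound_id: str
    counts: Counter[str] = field(default_factory=Counter)


@dataclass
class CorrelationWeightTable:
    """The optimizable state: attribute -> (weight, blocked flag).

    Blocked entries contribute exactly 0 to any DCW; attributes absent
    from the table (unseen at training time) also contribute 0.
    """

    weights: dict[str, float] = field(default_factory=dict)
    blocked: set[str] = field(default_factory=set)
    threshold_T: int = 1
    epochs_N: int = 1

    def __post_init__(self):
        if self.threshold_T < 1:
            raise ValueError("threshold_T must be >= 1")
        if self.epochs_N < 1:
            raise ValueError("epochs_N must be >= 1")

    def weight(self, code: str) -> float:
        if code in self.blocked:
            return 0.0
        return self.weights.get(code, 0.0)


def attribute_frequencies(
    features: list[CompoundFeatures],
    labels: dict[str, str],
    *,
    count_mode: str = "presence",
) -> list[AttributeStats]:
    """Per-attribute counts over the active/passive/calibration subsets.

    Validation compounds are never counted: they must stay blind to every
    model-building statistic.  ``count_mode='presence'`` counts compounds
    containing the attribute; ``'occurrence'`` sums multiplicities.
    """
    if count_mode not in ("presence", "occurrence"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    tallies: dict[str, list[int]] = {}
    slot = {"active": 0, "passive": 1, "calibration": 2}
    for f in features:
        label = labels.get(f.compound_id)
        if label is None or label not in SUBSET_LABELS:
            raise ValueError(f"compound {f.compound_id!r} has unknown subset label {label!r}")
        if label == "validation":
            continue
        j = slot[label]
        for code, mult in f.counts.items():
            row = tallies.setdefault(code, [0, 0, 0])
            row[j] += 1 if count_mode == "presence" else mult
    return [
        AttributeStats(code, *counts) for code, counts in sorted(tallies.items())
    ]


def classify_rare(stats: list[AttributeStats], T: int) -> set[str]:
    """Attributes blocked at threshold ``T``: active-training count < T.

    With T = 1 exactly the attributes absent from the active training set
    are blocked.  Rarity is judged on the active training set only — the
    set the model is built on.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    return {s.code for s in stats if s.n_active < T}


def dcw(features: CompoundFeatures | Counter[str], cw: CorrelationWeightTable) -> float:
    """Optimal descriptor: weight sum over the attribute multiset.

    Multiplicity counts — an attribute occurring twice contributes its
    weight twice.  Blocked and unseen attributes contribute 0.
    """
    counts = features.counts if isinstance(features, CompoundFeatures) else features
    total = 0.0
    for code, mult in counts.items():
        if code in cw.blocked:
            continue
        w = cw.weights.get(code)
        if w is not None:
            total += mult * w
    return total
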