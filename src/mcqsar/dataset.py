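"""Compound tables: the CSV-facing container shared by every stage.

A dataset is a list of (id, SMILES, endpoint) records plus an optional
subset label per compound ('active', 'passive', 'calibration',
'validation'; abbreviated a/p/c/v in files).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import FeatureConfig, extract_features
from .descriptor import SUBSET_LABELS, CompoundFeatures

__all__ = ["Compound", "Dataset", "split_dataset"]

_LABEL_ALIASES = {
    "a": "active", "p": "passive", "c": "calibration", "v": "validation",
    **{k: k for k in SUBSET_LABELS},
}


@dataclass
class Compound:
    compound_id: str
    smiles: str
    endpoint: float
    label: str | None = None


class Dataset:
    """An ordered collection of compounds with optional subset labels."""

    def __init__(self, compounds: list[Compound]):
        if len({c.compound_id for c in compounds}) != len(compounds):
            raise ValueError("duplicate compound ids")
        self.compounds = compounds

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def labels(self) -> dict[str, str]:
        out = {}
        for c in self.compounds:
            if c.label is None:
                raise ValueError(f"compound {c.compound_id!r} has no subset label")
            out[c.compound_id] = c.label
        return out

    def subset(self, label: str) -> list[Compound]:
        return [c for c in self.compounds if c.label == label]

    def apply_split(self, assignment: dict[str, str]) -> None:
        for c in self.compounds:
            c.label = assignment[c.compound_id]

    def features(self, config: FeatureConfig | None = None) -> list[CompoundFeatures]:
        """Attribute multisets of all compounds, in dataset order."""
        return [
            CompoundFeatures(c.compound_id, extract_features(c.smiles, config))
            for c in self.compounds
        ]

    # -- CSV round trip ----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        """Read a delimited table with columns id, smiles, endpoint[, split]."""
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
        required = {"id", "smiles", "endpoint"}
        if not required <= set(df.columns):
            raise ValueError(f"input must have columns {sorted(required)}")
        compounds = []
        for _, row in df.iterrows():
            label = None
            if "split" in df.columns and isinstance(row["split"], str):
                key = row["split"].strip().lower()
                if key not in _LABEL_ALIASES:
                    raise ValueError(f"unknown split label {row['split']!r}")
                label = _LABEL_ALIASES[key]
            compounds.append(
                Compound(str(row["id"]), str(row["smiles"]).strip(), float(row["endpoint"]), label)
            )
        return cls(compounds)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "id": [c.compound_id for c in self.compounds],
                "smiles": [c.smiles for c in self.compounds],
                "endpoint": [c.endpoint for c in self.compounds],
            }
        )
        if all(c.label is not None for c in self.compounds):
            df["split"] = [c.label[0] for c in self.compounds]
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df.to_csv(path, sep=sep, index=False)


def split_dataset(ids: list[str], seed: int) -> dict[str, str]:
    """Random four-way ≈25% split: seeded shuffle then round-robin labels.

    Subset sizes differ pairwise by at most 1 for every n; n = 113 yields
    sizes {29, 28, 28, 28}.  Requires n >= 8 so each subset holds at
    least 2 compounds.
    """
    if len(ids) < 8:
        raise ValueError("need at least 8 compounds to form four subsets")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[ids[idx]] = SUBSET_LABELS[pos % 4]
    return assignment
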