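"""End-to-end model building: train, evaluate, domain-check, interpret.

The workflow mirrors standard optimal-descriptor practice:

1. split the dataset into active training / passive training / calibration
   / validation quarters;
2. block attributes rarer than T in the active training set;
3. Monte Carlo-optimize the correlation weights, snapshotting at the
   calibration-set r² maximum (the overtraining stop);
4. report the full statistics battery per subset;
5. assess the applicability domain from attribute "statistical defects" —
   pairwise discrepancies of an attribute's probability across the three
   modelling subsets;
6. across three independent runs, extract *promoters*: attributes whose
   weight keeps one strict sign in every run, read as structural features
   that increase or decrease the endpoint.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import FeatureConfig, extract_features
from .dataset import Dataset
from .descriptor import (
    AttributeStats,
    CompoundFeatures,
    CorrelationWeightTable,
    attribute_frequencies,
    classify_rare,
    dcw,
)
from .metrics import PairedSeries, SetStatistics, compute_set_statistics
from .optimizer import (
    OptimizationTrace,
    TargetFunction,
    fit_line,
    line_standard_errors,
    optimize,
)

__all__ = [
    "TrainedModel",
    "RunResult",
    "Prediction",
    "PromoterRecord",
    "DomainAssessment",
    "statistical_defect",
    "compound_defect",
    "assess_domain",
    "train",
    "predict",
    "extract_promoters",
    "evaluate_model",
]

SUBSETS = ("active", "passive", "calibration", "validation")


# ---------------------------------------------------------------------------
# Applicability domain


def statistical_defect(stats: AttributeStats, set_sizes: tuple[int, int, int]) -> float:
    """Statistical defect d_k of one attribute.

    Sums |P - P'| / (N + N') over the three subset pairs, where P is the
    attribute's probability (count / subset size) and N its count.  An
    attribute distributed identically across the three modelling subsets
    has d_k = 0.  A pair with zero combined count contributes 0.
    """
    na, np_, nc = stats.n_active, stats.n_passive, stats.n_calibration
    sa, sp, sc = set_sizes
    if min(sa, sp, sc) <= 0:
        raise ValueError("set sizes must be positive")
    total = 0.0
    for (n1, s1), (n2, s2) in (((na, sa), (np_, sp)), ((na, sa), (nc, sc)), ((np_, sp), (nc, sc))):
        if n1 + n2 > 0:
            total += abs(n1 / s1 - n2 / s2) / (n1 + n2)
    return total


def compound_defect(
    features: CompoundFeatures, dk: dict[str, float], blocked: set[str]
) -> float:
    """Compound-level defect D_j: sum of d_k over non-blocked attribute occurrences."""
    total = 0.0
    for code, mult in features.counts.items():
        if code in blocked:
            continue
        total += mult * dk.get(code, 0.0)
    return total


@dataclass(frozen=True)
class DomainAssessment:
    compound_id: str
    defect: float
    threshold: float
    in_domain: bool


def assess_domain(defects: dict[str, float]) -> list[DomainAssessment]:
    """Flag compounds with D_j < 2 * mean(D_j) as in-domain.

    A wholly homogeneous dataset (every D_j = 0) is entirely in-domain:
    zero defect is the ideal case, not an exclusion.
    """
    values = np.array(list(defects.values()), dtype=float)
    d_mean = float(values.mean()) if values.size else 0.0
    threshold = 2.0 * d_mean
    return [
        DomainAssessment(cid, d, threshold, d < threshold or threshold == 0.0)
        for cid, d in defects.items()
    ]


# ---------------------------------------------------------------------------
# Trained model


@dataclass
class TrainedModel:
    """One optimized model plus everything needed to predict and domain-check."""

    cw: CorrelationWeightTable
    tf: TargetFunction
    c0: float
    c1: float
    c0_se: float
    c1_se: float
    run_seed: int
    feature_config: FeatureConfig
    dk: dict[str, float]
    d_mean: float
    split_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "format": "mcqsar-model/1",
            "weights": self.cw.weights,
            "blocked": sorted(self.cw.blocked),
            "threshold_T": self.cw.threshold_T,
            "epochs_N": self.cw.epochs_N,
            "target_function": {
                "kind": self.tf.kind,
                "iic_coefficient": self.tf.iic_coefficient,
                "cii_coefficient": self.tf.cii_coefficient,
                "disbalance_coefficient": self.tf.disbalance_coefficient,
            },
            "c0": self.c0,
            "c1": self.c1,
            "c0_se": self.c0_se,
            "c1_se": self.c1_se,
            "run_seed": self.run_seed,
            "split_seed": self.split_seed,
            "feature_config": {
                "use_atoms": self.feature_config.use_atoms,
                "use_pairs": self.feature_config.use_pairs,
                "graph_orders": sorted(self.feature_config.graph_orders),
            },
            "dk": self.dk,
            "d_mean": self.d_mean,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        tf = TargetFunction(**d["target_function"])
        fc = FeatureConfig(
            use_atoms=d["feature_config"]["use_atoms"],
            use_pairs=d["feature_config"]["use_pairs"],
            graph_orders=frozenset(d["feature_config"]["graph_orders"]),
        )
        cw = CorrelationWeightTable(
            weights={k: float(v) for k, v in d["weights"].items()},
            blocked=set(d["blocked"]),
            threshold_T=d["threshold_T"],
            epochs_N=d["epochs_N"],
        )
        return cls(
            cw=cw, tf=tf, c0=d["c0"], c1=d["c1"], c0_se=d["c0_se"], c1_se=d["c1_se"],
            run_seed=d["run_seed"], feature_config=fc,
            dk={k: float(v) for k, v in d["dk"].items()},
            d_mean=d["d_mean"], split_seed=d.get("split_seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunResult:
    """Model, per-subset statistics and the optimization trace of one run."""

    model: TrainedModel
    statistics: dict[str, SetStatistics]
    trace: OptimizationTrace
    domain: list[DomainAssessment] = field(default_factory=list)


@dataclass(frozen=True)
class Prediction:
    value: float
    in_domain: bool
    defect: float
    out_of_vocabulary: bool


@dataclass(frozen=True)
class PromoterRecord:
    code: str
    weights: tuple[float, float, float]
    n_active: int
    n_passive: int
    n_calibration: int
    dk: float
    direction: str  # 'increase' | 'decrease'


# ---------------------------------------------------------------------------
# Training


def _count_matrix(features: list[CompoundFeatures], codes: list[str]) -> np.ndarray:
    idx = {c: j for j, c in enumerate(codes)}
    X = np.zeros((len(features), len(codes)))
    for i, f in enumerate(features):
        for code, mult in f.counts.items():
            j = idx.get(code)
            if j is not None:
                X[i, j] = mult
    return X


def train(
    dataset: Dataset,
    *,
    T: int = 1,
    n_epochs: int = 15,
    tf: TargetFunction | None = None,
    run_seeds: tuple[int, ...] = (1, 2, 3),
    feature_config: FeatureConfig | None = None,
    count_mode: str = "presence",
    split_seed: int | None = None,
    step: float = 0.1,
    init: str = "symmetric",
    passes_per_epoch: int = 3,
    n_restarts: int = 6,
) -> list[RunResult]:
    """Train one model per run seed on a labelled dataset.

    Validation compounds never touch weight optimization, rarity
    classification, the regression fit, or the defect statistics; they are
    scored only at the end.
    """
    tf = tf or TargetFunction()
    feature_config = feature_config or FeatureConfig()
    features = dataset.features(feature_config)
    labels = dataset.labels
    by_label = {
        s: [f for f in features if labels[f.compound_id] == s] for s in SUBSETS
    }
    for s in SUBSETS:
        if not by_label[s]:
            raise ValueError(f"subset {s!r} is empty")

    freq = attribute_frequencies(features, labels, count_mode=count_mode)
    blocked = classify_rare(freq, T)
    codes = sorted(s.code for s in freq if s.code not in blocked)
    if not codes:
        raise ValueError("every attribute is blocked at this threshold")

    endpoint = {c.compound_id: c.endpoint for c in dataset}
    counts = {
        s: _count_matrix(by_label[s], codes)
        for s in ("active", "passive", "calibration")
    }
    y = {
        s: np.array([endpoint[f.compound_id] for f in by_label[s]])
        for s in SUBSETS
    }
    X_val = _count_matrix(by_label["validation"], codes)

    # applicability-domain reference data: split-level, identical across runs
    set_sizes = (len(by_label["active"]), len(by_label["passive"]), len(by_label["calibration"]))
    presence = attribute_frequencies(features, labels, count_mode="presence")
    dk_map = {s.code: statistical_defect(s, set_sizes) for s in presence}
    defects = {
        f.compound_id: compound_defect(f, dk_map, blocked) for f in features
    }
    d_mean = float(np.mean(list(defects.values())))

    results = []
    for seed in run_seeds:
        table, trace = optimize(
            counts, y, codes, T=T, n_epochs=n_epochs, tf=tf, seed=seed,
            step=step, init=init, passes_per_epoch=passes_per_epoch,
            n_restarts=n_restarts,
        )
        table.blocked = set(blocked)
        d_active = counts["active"] @ np.array([table.weights[c] for c in codes])
        c0, c1 = fit_line(d_active, y["active"])
        c0_se, c1_se = line_standard_errors(d_active, y["active"])
        model = TrainedModel(
            cw=table, tf=tf, c0=c0, c1=c1, c0_se=c0_se, c1_se=c1_se,
            run_seed=seed, feature_config=feature_config,
            dk=dk_map, d_mean=d_mean, split_seed=split_seed,
        )
        stats = _statistics(model, by_label, counts, X_val, y, codes)
        results.append(
            RunResult(model=model, statistics=stats, trace=trace,
                      domain=assess_domain(defects))
        )
    return results


def _statistics(model, by_label, counts, X_val, y, codes) -> dict[str, SetStatistics]:
    w = np.array([model.cw.weights[c] for c in codes])
    d = {s: counts[s] @ w for s in counts}
    d["validation"] = X_val @ w
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in SUBSETS:
            series = PairedSeries(y[s], model.c0 + model.c1 * d[s])
            out[s] = compute_set_statistics(
                series,
                descriptor=d[s],
                train_observed=y["active"] if s in ("calibration", "validation") else None,
            )
    return out


def evaluate_model(model: TrainedModel, dataset: Dataset) -> dict[str, SetStatistics]:
    """Recompute the per-subset statistics battery from a (possibly reloaded) model."""
    labels = dataset.labels
    endpoint = {c.compound_id: c.endpoint for c in dataset}
    features = dataset.features(model.feature_config)
    codes = sorted(model.cw.weights)
    by_label = {s: [f for f in features if labels[f.compound_id] == s] for s in SUBSETS}
    counts = {s: _count_matrix(by_label[s], codes) for s in ("active", "passive", "calibration")}
    X_val = _count_matrix(by_label["validation"], codes)
    y = {s: np.array([endpoint[f.compound_id] for f in by_label[s]]) for s in SUBSETS}
    return _statistics(model, by_label, counts, X_val, y, codes)


# ---------------------------------------------------------------------------
# Prediction and interpretation


def predict(model: TrainedModel, smiles: str) -> Prediction:
    """Predict the endpoint of one SMILES and check the applicability domain.

    A compound none of whose attributes carries a weight (all blocked or
    unseen) is predicted at the intercept and flagged out of domain.
    """
    feats = CompoundFeatures("query", extract_features(smiles, model.feature_config))
    value = model.c0 + model.c1 * dcw(feats, model.cw)
    defect = compound_defect(feats, model.dk, model.cw.blocked)
    covered = any(
        code in model.cw.weights and code not in model.cw.blocked
        for code in feats.counts
    )
    threshold = 2.0 * model.d_mean
    in_domain = covered and (defect < threshold or threshold == 0.0)
    return Prediction(
        value=float(value), in_domain=in_domain,
        defect=defect, out_of_vocabulary=not covered,
    )


def extract_promoters(
    runs: list[RunResult],
    stats: list[AttributeStats],
    *,
    n_active_size: int,
    prevalence: float = 0.25,
) -> list[PromoterRecord]:
    """Attributes with one strict weight sign across three runs of one split.

    Applies the prevalence filter (present in at least ``prevalence`` of
    active-training compounds by default 25%), then requires the attribute
    to be non-blocked in every run with all three weights strictly
    positive (an *increase* promoter) or strictly negative (*decrease*).
    Sorted by active-training frequency, descending, ties by code.
    """
    if len(runs) != 3:
        raise ValueError("promoter extraction needs exactly 3 runs")
    seeds = {r.model.split_seed for r in runs}
    if len(seeds) != 1:
        raise ValueError("all runs must share one split")
    by_code = {s.code: s for s in stats}
    min_count = prevalence * n_active_size
    records = []
    for code, stat in by_code.items():
        if stat.n_active < min_count:
            continue
        if any(code in r.model.cw.blocked or code not in r.model.cw.weights for r in runs):
            continue
        ws = tuple(r.model.cw.weights[code] for r in runs)
        if all(w > 0 for w in ws):
            direction = "increase"
        elif all(w < 0 for w in ws):
            direction = "decrease"
        else:
            continue
        records.append(
            PromoterRecord(
                code=code, weights=ws,
                n_active=stat.n_active, n_passive=stat.n_passive,
                n_calibration=stat.n_calibration,
                dk=runs[0].model.dk.get(code, 0.0),
                direction=direction,
            )
        )
    records.sort(key=lambda r: (-r.n_active, r.code))
    return records


def promoters_to_tsv(records: list[PromoterRecord]) -> str:
    """Promoter table in the conventional column order."""
    lines = ["code\tcw_run1\tcw_run2\tcw_run3\tn_active\tn_passive\tn_calibration\tdk\tdirection"]
    for r in records:
        w = "\t".join(f"{x:.4f}" for x in r.weights)
        lines.append(
            f"{r.code}\t{w}\t{r.n_active}\t{r.n_passive}\t{r.n_calibration}"
            f"\t{r.dk:.4f}\t{r.direction}"
        )
    return "\n".join(lines) + "\n"


def statistics_to_tsv(stats_by_run: list[dict[str, SetStatistics]]) -> str:
    """Per-set statistics rows mirroring the conventional report layout."""
    header = "run\tset\t" + "\t".join(SetStatistics.COLUMNS)
    lines = [header]
    for i, stats in enumerate(stats_by_run, start=1):
        for s in SUBSETS:
            row = "\t".join(str(v) for v in stats[s].as_row())
            lines.append(f"{i}\t{s}\t{row}")
    return "\n".join(lines) + "\n"
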