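"""Monte Carlo optimization of correlation weights.

The search is a coordinate-wise stochastic ascent.  One epoch visits every
non-blocked attribute in a freshly shuffled order; each visit proposes a
uniform perturbation of that attribute's weight and accepts it iff the
target function does not decrease.  Proposals mix two scales — mostly
small steps (U[-0.1, 0.1]) with occasional wide jumps (U[-1, 1]): the
MAE-ratio term of the IIC creates sharp ridges on which a single-scale
coordinate ascent stalls far below the attainable optimum, and the wide
jumps let the search cross them.  Three target functions are supported:

* TF0 = r_AT + r_PT - |r_AT - r_PT| * 0.1
* TF1 = TF0 + IIC_C * 0.5
* TF2 = TF1 + CII_C * 0.5

where r_AT and r_PT are the observed/calculated correlations of the active
and passive training sets, and IIC_C / CII_C are evaluated on the
calibration set.  The regression line ``endpoint = C0 + C1 * DCW`` is refit
on the active training set after every proposal, so every correlation is
measured against up-to-date calculated values.

Training keeps running but the *returned* weight table is the snapshot
from the epoch with the highest calibration r² — the point just before
overtraining sets in, identifiable only in retrospect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .descriptor import CorrelationWeightTable
from .metrics import PairedSeries, cii, iic, pearson_r

__all__ = [
    "TargetFunction",
    "EpochRecord",
    "OptimizationTrace",
    "target_value",
    "fit_line",
    "optimize",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TargetFunction:
    """Target-function kind and its coefficients.

    The disbalance coefficient multiplies |r_AT - r_PT| in TF0; the IIC and
    CII coefficients weight the calibration-set terms added by TF1 and TF2.
    Defaults are the canonical 0.1 / 0.5 / 0.5.
    """

    kind: str = "tf2"
    iic_coefficient: float = 0.5
    cii_coefficient: float = 0.5
    disbalance_coefficient: float = 0.1

    def __post_init__(self):
        if self.kind not in ("tf0", "tf1", "tf2"):
            raise ValueError(f"unknown target function kind {self.kind!r}")
        if min(self.iic_coefficient, self.cii_coefficient, self.disbalance_coefficient) < 0:
            raise ValueError("target-function coefficients must be >= 0")


def target_value(tf: TargetFunction, r_at: float, r_pt: float, calib: PairedSeries | None) -> float:
    """Evaluate the chosen target function.

    TF1 and TF2 need the calibration observed/calculated series; TF2
    includes the IIC term via TF1.
    """
    value = r_at + r_pt - abs(r_at - r_pt) * tf.disbalance_coefficient
    if tf.kind == "tf0":
        return value
    if calib is None:
        raise ValueError("TF1/TF2 require the calibration series")
    value += tf.iic_coefficient * iic(calib)
    if tf.kind == "tf2":
        value += tf.cii_coefficient * cii(calib)
    return value


def fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares intercept and slope of ``y = C0 + C1 x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 to fit the regression line")
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx < _EPS:
        raise ValueError("constant descriptor: regression line undefined")
    c1 = ((x - xm) * (y - y.mean())).sum() / sxx
    c0 = y.mean() - c1 * xm
    return float(c0), float(c1)


def line_standard_errors(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Standard errors of the univariate OLS intercept and slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    c0, c1 = fit_line(x, y)
    resid = y - (c0 + c1 * x)
    s2 = (resid * resid).sum() / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    se_c1 = np.sqrt(s2 / sxx)
    se_c0 = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return float(se_c0), float(se_c1)


@dataclass
class EpochRecord:
    epoch: int
    tf: float
    r2_active: float
    r2_passive: float
    r2_calibration: float
    iic_calibration: float
    cii_calibration: float


@dataclass
class OptimizationTrace:
    """Per-epoch history of one Monte Carlo run."""

    records: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = 0
    rng_seed: int = 0

    def to_tsv(self) -> str:
        lines = ["epoch\ttf\tr2_active\tr2_passive\tr2_calibration\tiic_c\tcii_c"]
        for r in self.records:
            lines.append(
                f"{r.epoch}\t{r.tf:.6f}\t{r.r2_active:.6f}\t{r.r2_passive:.6f}"
                f"\t{r.r2_calibration:.6f}\t{r.iic_calibration:.6f}\t{r.cii_calibration:.6f}"
            )
        return "\n".join(lines) + "\n"


class _State:
    """Dense working state: count matrices, descriptor vectors, weights."""

    def __init__(self, counts, y, codes):
        self.codes = codes
        self.X = {k: counts[k] for k in ("active", "passive", "calibration")}
        self.y = y
        self.w = np.ones(len(codes))
        self.d = {k: self.X[k] @ self.w for k in self.X}

    def shifted(self, j: int, delta: float):
        return {k: self.d[k] + delta * self.X[k][:, j] for k in self.X}

    def apply(self, j: int, delta: float, d_new):
        self.w[j] += delta
        self.d = d_new


def _evaluate(tf: TargetFunction, d: dict, y: dict):
    """Target value and fitted line for a candidate descriptor state.

    Returns None if the active-set descriptor is degenerate (all-zero or
    constant): such a state is never accepted as an improvement.
    """
    da = d["active"]
    if da.std() < 1e-9:
        return None
    c0, c1 = fit_line(da, y["active"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_at = abs(pearson_r(y["active"], da))
        sign = 1.0 if c1 >= 0 else -1.0
        r_pt = sign * pearson_r(y["passive"], d["passive"])
        calib = PairedSeries(y["calibration"], c0 + c1 * d["calibration"])
        value = target_value(tf, r_at, r_pt, calib)
    return value, c0, c1


def optimize(
    counts: dict[str, np.ndarray],
    y: dict[str, np.ndarray],
    codes: list[str],
    *,
    T: int = 1,
    n_epochs: int = 30,
    tf: TargetFunction | None = None,
    seed: int = 0,
    step: float = 0.1,
    wide_step: float = 1.0,
    wide_probability: float = 0.2,
    passes_per_epoch: int = 3,
    n_restarts: int = 6,
    init: str = "symmetric",
) -> tuple[CorrelationWeightTable, OptimizationTrace]:
    """Run the Monte Carlo ascent and return the best-calibration snapshot.

    Parameters
    ----------
    counts
        Per-subset attribute count matrices (rows = compounds, columns
        aligned with ``codes``) for 'active', 'passive', 'calibration'.
        Columns must already be restricted to non-blocked attributes.
    y
        Per-subset observed endpoint vectors (same keys).
    codes
        Attribute codes naming the columns.
    T, n_epochs
        Rarity threshold and epoch budget, stored in the returned table.
    tf
        Target function; defaults to TF2 with canonical coefficients.
    seed
        Seed of the run's own PRNG; identical inputs and seed give
        bit-identical results.
    step, wide_step, wide_probability
        Proposal scales: with probability ``wide_probability`` the
        perturbation is drawn from U[-wide_step, wide_step], otherwise
        from U[-step, step].
    passes_per_epoch
        Randomized sweeps over all attributes per epoch; the per-epoch
        bookkeeping (trace row, snapshot check) happens once per epoch
        regardless.
    n_restarts
        Independent ascents per run (sub-seeded from ``seed``).  With
        more than one restart the run returns the *ensemble* weight
        table: each restart's snapshot is calibrated to endpoint units
        (multiplied by its fitted slope C1, which also fixes the
        orientation) and the calibrated vectors are averaged.  The kinked
        IIC/CII terms leave each single ascent with an arbitrary drift
        component along weakly constrained directions; the drift is
        independent across restarts and averages out, while the
        data-supported signal is common and survives.
    init
        'symmetric' (default) draws each starting weight from U[-1, 1),
        which carries no prior sign bias; 'ones' starts every weight at
        1.0; 'uniform' draws from U[1, 2).

    Returns
    -------
    The weight table of the epoch with maximal calibration r² (not the
    final epoch) and the full per-epoch trace.
    """
    tf = tf or TargetFunction()
    if not codes:
        raise ValueError("no non-blocked attributes: nothing to optimize")
    for k in ("active", "passive", "calibration"):
        if counts[k].shape[0] == 0:
            raise ValueError(f"empty {k} subset")
        if counts[k].shape[1] != len(codes):
            raise ValueError("count matrix columns must align with codes")
    if init not in ("ones", "uniform", "symmetric"):
        raise ValueError(f"unknown init {init!r}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    seed_seq = np.random.SeedSequence(seed)
    calibrated: list[np.ndarray] = []
    best_trace: tuple[float, OptimizationTrace] | None = None
    for child in seed_seq.spawn(n_restarts):
        rng = np.random.default_rng(child)
        tf_final, w_snap, trace = _ascend(
            counts, y, codes, tf, rng, n_epochs, step, wide_step,
            wide_probability, passes_per_epoch, init,
        )
        d_active = counts["active"] @ w_snap
        if d_active.std() < 1e-9:
            continue
        # slope-calibrate: C1 * w is in endpoint units per occurrence and
        # its orientation is fixed ((w, C1) and (-w, -C1) predict alike)
        _, c1 = fit_line(d_active, y["active"])
        calibrated.append(c1 * w_snap)
        if best_trace is None or tf_final > best_trace[0]:
            best_trace = (tf_final, trace)
    if not calibrated:
        raise ValueError("every restart ended in a degenerate descriptor")
    best_w = np.mean(calibrated, axis=0)
    _, trace = best_trace
    trace.rng_seed = seed

    d_active = counts["active"] @ best_w
    if d_active.std() > 1e-9:
        _, c1 = fit_line(d_active, y["active"])
        if c1 < 0:  # can only happen for a pathological ensemble
            best_w = -best_w

    table = CorrelationWeightTable(
        weights=dict(zip(codes, map(float, best_w))),
        blocked=set(),
        threshold_T=T,
        epochs_N=n_epochs,
    )
    return table, trace


def _ascend(counts, y, codes, tf, rng, n_epochs, step, wide_step,
            wide_probability, passes_per_epoch, init):
    """One greedy ascent; returns (final TF, snapshot weights, trace)."""
    state = _State(counts, y, codes)
    if init == "uniform":
        state.w = rng.uniform(1.0, 2.0, size=len(codes))
        state.d = {k: state.X[k] @ state.w for k in state.X}
    elif init == "symmetric":
        state.w = rng.uniform(-1.0, 1.0, size=len(codes))
        state.d = {k: state.X[k] @ state.w for k in state.X}

    current = _evaluate(tf, state.d, y)
    if current is None:
        # all-ones start can be degenerate (e.g. every compound has the
        # same attribute total); nudge once with random weights
        state.w = rng.uniform(0.5, 1.5, size=len(codes))
        state.d = {k: state.X[k] @ state.w for k in state.X}
        current = _evaluate(tf, state.d, y)
    if current is None:
        raise ValueError("degenerate descriptor: no valid starting state")
    tf_cur = current[0]

    trace = OptimizationTrace()
    best_r2c = -np.inf
    best_w = state.w.copy()
    best_epoch = 0
    for epoch in range(1, n_epochs + 1):
        for _ in range(passes_per_epoch):
            for j in rng.permutation(len(codes)):
                width = wide_step if rng.random() < wide_probability else step
                delta = rng.uniform(-width, width)
                d_new = state.shifted(j, delta)
                cand = _evaluate(tf, d_new, y)
                if cand is not None and cand[0] >= tf_cur:
                    tf_cur = cand[0]
                    state.apply(j, delta, d_new)
        rec = _epoch_record(epoch, tf_cur, state, y)
        trace.records.append(rec)
        if rec.r2_calibration > best_r2c:
            best_r2c = rec.r2_calibration
            best_w = state.w.copy()
            best_epoch = epoch
    trace.best_epoch = best_epoch
    return tf_cur, best_w, trace


def _epoch_record(epoch: int, tf_value: float, state: _State, y: dict) -> EpochRecord:
    c0, c1 = fit_line(state.d["active"], y["active"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        calc = {k: c0 + c1 * state.d[k] for k in state.d}
        series = {k: PairedSeries(y[k], calc[k]) for k in state.d}
        r2 = {k: pearson_r(s.observed, s.calculated) ** 2 for k, s in series.items()}
        iic_c = iic(series["calibration"])
        cii_c = cii(series["calibration"]) if series["calibration"].n >= 4 else float("nan")
    return EpochRecord(
        epoch=epoch,
        tf=tf_value,
        r2_active=r2["active"],
        r2_passive=r2["passive"],
        r2_calibration=r2["calibration"],
        iic_calibration=iic_c,
        cii_calibration=cii_c,
    )
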