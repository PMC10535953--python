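"""Regression-quality statistics for observed/calculated endpoint series.

Beyond the standard battery (r², RMSE, MAE, Lin's CCC, LOO Q², the external
Q²F1/F2/F3 family, Fisher F), two less common indices drive the Monte Carlo
target functions:

* **IIC** — index of ideality of correlation: the signed Pearson r scaled
  by ``min(MAE-, MAE+) / max(MAE-, MAE+)``, where MAE- and MAE+ are mean
  absolute errors over negative and non-negative residuals separately.  A
  lopsided residual distribution shrinks the index even at high r.
* **CII** — correlation intensity index: ``1 - sum_k max(0, r²_{-k} - r²)``
  where ``r²_{-k}`` is the determination coefficient with point k removed.
  Each point whose removal *raises* r² lodges a "protest"; a small protest
  sum means an intense, evenly supported correlation.

All moments are population (1/n) moments.  Degenerate (constant) series
yield r² = 0 with a warning rather than an error, so an optimizer sweep
never crashes mid-search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedSeries",
    "SetStatistics",
    "pearson_r",
    "correlation_r2",
    "signed_mae",
    "iic",
    "cii",
    "ccc",
    "q2_loo",
    "q2_external",
    "fisher_f",
    "rmse_mae",
    "williams_data",
    "compute_set_statistics",
]

_EPS = 1e-300


@dataclass
class PairedSeries:
    """Observed and calculated endpoint values of one subset (same units)."""

    observed: np.ndarray
    calculated: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.calculated = np.asarray(self.calculated, dtype=float)
        if self.observed.shape != self.calculated.shape or self.observed.ndim != 1:
            raise ValueError("observed and calculated must be equal-length 1-D vectors")
        if self.observed.size < 2:
            raise ValueError("need at least 2 paired values")
        if not (np.isfinite(self.observed).all() and np.isfinite(self.calculated).all()):
            raise ValueError("missing or non-finite values are not allowed")

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def residuals(self) -> np.ndarray:
        """Delta_k = observed_k - calculated_k."""
        return self.observed - self.calculated


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Signed Pearson correlation; 0 (with a warning) for a constant series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den < _EPS:
        warnings.warn("constant series: correlation undefined, returning 0", stacklevel=2)
        return 0.0
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def correlation_r2(s: PairedSeries) -> float:
    """Squared Pearson correlation between observed and calculated, in [0, 1]."""
    r = pearson_r(s.observed, s.calculated)
    return r * r


def signed_mae(s: PairedSeries) -> tuple[float, float]:
    """Mean absolute error over negative residuals and over non-negative ones.

    Residual classes follow the strict split Delta < 0 vs Delta >= 0; an
    empty class yields 0.
    """
    d = s.residuals
    neg = d[d < 0]
    pos = d[d >= 0]
    mae_neg = float(np.abs(neg).mean()) if neg.size else 0.0
    mae_pos = float(np.abs(pos).mean()) if pos.size else 0.0
    return mae_neg, mae_pos


def iic(s: PairedSeries) -> float:
    """Index of ideality of correlation.

    ``r * min(MAE-, MAE+) / max(MAE-, MAE+)``.  A perfect fit (both MAEs
    zero) returns r itself; one empty residual class (maximally one-sided
    errors) returns 0.
    """
    mae_neg, mae_pos = signed_mae(s)
    hi = max(mae_neg, mae_pos)
    d = s.residuals
    if hi == 0.0:
        # all residuals exactly zero
        return pearson_r(s.observed, s.calculated)
    if (d < 0).sum() == 0 or (d >= 0).sum() == 0:
        return 0.0
    r = pearson_r(s.observed, s.calculated)
    return r * min(mae_neg, mae_pos) / hi


def _loo_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vector of leave-one-out r² values, one per removed point.

    Incremental update of centred sums; pre-centring keeps the running
    sums well conditioned so the result matches a from-scratch
    recomputation to ~1e-14.
    """
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = xc.sum()
    sy = yc.sum()
    sxx = (xc * xc).sum()
    syy = (yc * yc).sum()
    sxy = (xc * yc).sum()
    m = n - 1
    sx_k = sx - xc
    sy_k = sy - yc
    sxx_k = sxx - xc * xc
    syy_k = syy - yc * yc
    sxy_k = sxy - xc * yc
    num = m * sxy_k - sx_k * sy_k
    den = (m * sxx_k - sx_k * sx_k) * (m * syy_k - sy_k * sy_k)
    out = np.zeros(n)
    ok = den > _EPS
    out[ok] = num[ok] ** 2 / den[ok]
    return np.clip(out, 0.0, 1.0)


def cii(s: PairedSeries) -> float:
    """Correlation intensity index: 1 minus the summed leave-one-out protests.

    ``Protest_k = max(0, r²_{-k} - r²)``.  Requires n >= 4 so each
    leave-one-out correlation runs over at least 3 points.
    """
    if s.n < 4:
        raise ValueError("CII requires n >= 4")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r2 = correlation_r2(s)
    r2k = _loo_r2(s.observed, s.calculated)
    protests = np.maximum(0.0, r2k - r2)
    return float(1.0 - protests.sum())


def ccc(s: PairedSeries) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    o, c = s.observed, s.calculated
    vo = o.var()
    vc = c.var()
    cov = ((o - o.mean()) * (c - c.mean())).mean()
    den = vo + vc + (o.mean() - c.mean()) ** 2
    if den < _EPS:
        warnings.warn("both series constant and equal: CCC undefined, returning 0", stacklevel=2)
        return 0.0
    return float(2.0 * cov / den)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx < _EPS:
        raise ValueError("constant predictor: univariate fit is degenerate")
    b = ((x - xm) * (y - y.mean())).sum() / sxx
    a = y.mean() - b * xm
    return a, b


def q2_loo(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated determination of the univariate fit.

    ``1 - PRESS / SS_tot`` with PRESS from the leverage shortcut
    ``e_i / (1 - h_i)`` of the full-data least-squares fit; identical to n
    explicit refits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("LOO Q^2 requires n >= 4")
    a, b = _ols(x, y)
    resid = y - (a + b * x)
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    h = 1.0 / n + (x - xm) ** 2 / sxx
    if np.any(1.0 - h < 1e-12):
        raise ValueError("leave-one-out refit degenerate (leverage 1)")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot < _EPS:
        raise ValueError("constant response: Q^2 undefined")
    return 1.0 - press / ss_tot


def q2_external(calc_set: PairedSeries, train_observed: np.ndarray) -> tuple[float, float, float]:
    """External-validation family (Q²F1, Q²F2, Q²F3) against a training reference.

    F1 scales the prediction error sum by deviations from the *training*
    mean, F2 by deviations from the evaluated set's own mean, F3 compares
    per-compound mean squared errors across the two sets.
    """
    train_observed = np.asarray(train_observed, dtype=float)
    o, c = calc_set.observed, calc_set.calculated
    ybar_tr = train_observed.mean()
    press = float(((c - o) ** 2).sum())
    den_f1 = float(((o - ybar_tr) ** 2).sum())
    den_f2 = float(((o - o.mean()) ** 2).sum())
    den_f3 = float(((train_observed - ybar_tr) ** 2).sum())
    if min(den_f1, den_f2, den_f3) < _EPS:
        raise ValueError("degenerate denominator in external Q^2")
    f1 = 1.0 - press / den_f1
    f2 = 1.0 - press / den_f2
    f3 = 1.0 - (press / o.size) / (den_f3 / train_observed.size)
    return f1, f2, f3


def fisher_f(r2: float, n: int) -> float:
    """Fisher F of the univariate regression: ``r²(n-2) / (1-r²)``."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    if n < 3:
        raise ValueError("n must be >= 3")
    return r2 * (n - 2) / (1.0 - r2)


def rmse_mae(s: PairedSeries) -> tuple[float, float]:
    """Root-mean-square and mean-absolute residual (1/n)."""
    d = s.residuals
    return float(np.sqrt((d * d).mean())), float(np.abs(d).mean())


def williams_data(
    x: np.ndarray, s: PairedSeries, train_x: np.ndarray, train_rmse: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Leverage and standardized residual per compound, plus the h* warning line.

    Leverage uses the univariate hat values against the training
    descriptor; the warning leverage is ``3(p+1)/n_train`` with p = 1.
    """
    x = np.asarray(x, dtype=float)
    train_x = np.asarray(train_x, dtype=float)
    xm = train_x.mean()
    sxx = ((train_x - xm) ** 2).sum()
    if sxx < _EPS:
        raise ValueError("degenerate training descriptor spread")
    h = 1.0 / train_x.size + (x - xm) ** 2 / sxx
    std_resid = s.residuals / train_rmse
    h_star = 3.0 * 2.0 / train_x.size
    return h, std_resid, h_star


@dataclass
class SetStatistics:
    """The full statistics battery of one subset.

    Fields that need extra context (Q² needs the descriptor, the Q²F
    family needs a training reference) are None when not computed.
    """

    n: int
    r2: float
    ccc: float
    iic: float
    cii: float | None
    q2_loo: float | None
    q2_f1: float | None
    q2_f2: float | None
    q2_f3: float | None
    rmse: float
    mae: float
    fisher_f: float

    COLUMNS = (
        "n", "r2", "ccc", "iic", "cii", "q2", "q2_f1", "q2_f2", "q2_f3",
        "rmse", "mae", "f",
    )

    def as_row(self) -> list:
        """Values in the conventional report column order; F rounded to integer."""
        fmt = lambda v: "" if v is None else round(v, 4)
        return [
            self.n, fmt(self.r2), fmt(self.ccc), fmt(self.iic), fmt(self.cii),
            fmt(self.q2_loo), fmt(self.q2_f1), fmt(self.q2_f2), fmt(self.q2_f3),
            fmt(self.rmse), fmt(self.mae), round(self.fisher_f),
        ]


def compute_set_statistics(
    s: PairedSeries,
    descriptor: np.ndarray | None = None,
    train_observed: np.ndarray | None = None,
) -> SetStatistics:
    """Assemble the battery for one subset.

    ``descriptor`` enables LOO Q²; ``train_observed`` enables Q²F1/F2/F3.
    Pieces whose preconditions fail (too few points, degenerate spread)
    are reported as None rather than aborting the whole battery.
    """
    r2 = correlation_r2(s)
    rmse, mae = rmse_mae(s)
    stats = SetStatistics(
        n=s.n,
        r2=r2,
        ccc=ccc(s),
        iic=iic(s),
        cii=cii(s) if s.n >= 4 else None,
        q2_loo=None,
        q2_f1=None,
        q2_f2=None,
        q2_f3=None,
        rmse=rmse,
        mae=mae,
        fisher_f=fisher_f(min(r2, 1.0 - 1e-15), s.n) if s.n >= 3 else float("nan"),
    )
    if descriptor is not None:
        try:
            stats.q2_loo = q2_loo(descriptor, s.observed)
        except ValueError:
            pass
    if train_observed is not None:
        try:
            stats.q2_f1, stats.q2_f2, stats.q2_f3 = q2_external(s, train_observed)
        except ValueError:
            pass
    return stats
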