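"""Trajectory statistics for longitudinal cohort tables.

Implements the statistical layer tying the imaging readouts together:

* OLS interaction model ``y = b0 + b1*focal + b2*mod + b3*focal*mod``;
* Johnson-Neyman regions of significance for the conditional effect
  ``theta(m) = b1 + b3*m`` of the focal predictor across the moderator;
* fixed-knot piecewise regression as two independent fits on either side
  of the knot (default 8 months);
* four-parameter sigmoid (logistic) inflection fitting, with a
  Gaussian-CDF alternative behind ``form=``;
* LOESS (tricube-weighted local linear) trajectories with a seeded
  bootstrap pointwise band;
* cross-species overlay: z-scored LOESS curves on a normalized age axis;
* one-way ANOVA with Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import (DegenerateCurveError, InvalidArgumentError,
                         SingularDesignError)

__all__ = [
    "InteractionModelFit",
    "JNResult",
    "SigmoidFit",
    "fit_interaction_model",
    "johnson_neyman",
    "piecewise_fit",
    "sigmoid_fit",
    "loess_trajectory",
    "zscore_align",
    "anova_tukey",
]


# ---------------------------------------------------------------------------
# interaction model
# ---------------------------------------------------------------------------

@dataclass
class InteractionModelFit:
    """OLS fit of y = b0 + b1*focal + b2*moderator + b3*focal*moderator."""

    params: np.ndarray          # (4,) coefficients
    cov: np.ndarray             # (4, 4) coefficient covariance
    df_resid: int
    n: int
    pvalues: np.ndarray = field(default=None)
    bse: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.bse is None:
            self.bse = np.sqrt(np.diag(self.cov))
        if self.pvalues is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = self.params / self.bse
            self.pvalues = 2 * stats.t.sf(np.abs(t), self.df_resid)


def fit_interaction_model(table: pd.DataFrame, outcome: str, focal: str,
                          moderator: str) -> InteractionModelFit:
    """OLS with an interaction term; two-sided t p-values per coefficient."""
    cols = [outcome, focal, moderator]
    data = table[cols].dropna()
    if len(data) < 8:
        raise InvalidArgumentError("need >= 8 complete records")
    y = data[outcome].to_numpy(dtype=float)
    f = data[focal].to_numpy(dtype=float)
    m = data[moderator].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(f), f, m, f * m])
    if np.linalg.matrix_rank(X) < 4:
        raise SingularDesignError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - 4
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return InteractionModelFit(params=beta, cov=cov, df_resid=df, n=len(y))


# ---------------------------------------------------------------------------
# Johnson-Neyman
# ---------------------------------------------------------------------------

@dataclass
class JNResult:
    boundaries: list            # 0-2 moderator values, sorted
    significant_regions: list   # list of (lo, hi) intervals
    alpha: float
    t_crit: float


def _theta_se(fit: InteractionModelFit, m):
    m = np.asarray(m, dtype=float)
    b1, b3 = fit.params[1], fit.params[3]
    v11, v13, v33 = fit.cov[1, 1], fit.cov[1, 3], fit.cov[3, 3]
    theta = b1 + b3 * m
    var = v11 + m ** 2 * v33 + 2 * m * v13
    return theta, np.sqrt(np.maximum(var, 0))


def johnson_neyman(fit: InteractionModelFit, moderator_range,
                   alpha: float = 0.05) -> JNResult:
    """Closed-form Johnson-Neyman boundaries on the moderator axis.

    Boundaries are real roots in range of
    ``(b3^2 - t^2 v33) m^2 + 2 (b1 b3 - t^2 v13) m + (b1^2 - t^2 v11) = 0``
    with ``t = t_crit(alpha/2, df)``; significance of each sub-interval is
    decided by a t-test of the conditional effect at its midpoint.
    """
    lo, hi = float(moderator_range[0]), float(moderator_range[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise InvalidArgumentError("moderator range must be finite with hi > lo")
    t_crit = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    b1, b3 = fit.params[1], fit.params[3]
    v11, v13, v33 = fit.cov[1, 1], fit.cov[1, 3], fit.cov[3, 3]
    a = b3 ** 2 - t_crit ** 2 * v33
    b = 2 * (b1 * b3 - t_crit ** 2 * v13)
    c = b1 ** 2 - t_crit ** 2 * v11
    roots = []
    if abs(a) > 1e-300:
        disc = b ** 2 - 4 * a * c
        if disc >= 0:
            r = np.sqrt(disc)
            roots = [(-b - r) / (2 * a), (-b + r) / (2 * a)]
    elif abs(b) > 1e-300:
        roots = [-c / b]
    boundaries = sorted(float(r) for r in roots if lo < r < hi)

    edges = [lo] + boundaries + [hi]
    regions = []
    for a_e, b_e in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a_e + b_e)
        theta, se = _theta_se(fit, mid)
        if se > 0 and abs(theta) / se > t_crit:
            regions.append((a_e, b_e))
    # merge touching regions
    merged = []
    for reg in regions:
        if merged and np.isclose(merged[-1][1], reg[0]):
            merged[-1] = (merged[-1][0], reg[1])
        else:
            merged.append(reg)
    return JNResult(boundaries=boundaries, significant_regions=merged,
                    alpha=alpha, t_crit=t_crit)


# ---------------------------------------------------------------------------
# piecewise regression
# ---------------------------------------------------------------------------

@dataclass
class SimpleFit:
    slope: float
    intercept: float
    pvalue: float
    stderr: float
    n: int

    def slope_ci(self, alpha: float = 0.05):
        half = stats.t.ppf(1 - alpha / 2, self.n - 2) * self.stderr
        return self.slope - half, self.slope + half


def _simple_ols(x, y) -> SimpleFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    return SimpleFit(slope=float(res.slope), intercept=float(res.intercept),
                     pvalue=float(res.pvalue), stderr=float(res.stderr), n=len(x))


def piecewise_fit(table: pd.DataFrame, outcome: str, predictor: str,
                  split_var: str | None = None, knot: float = 8.0):
    """Two independent OLS fits for records at or below vs above the knot.

    The split runs on ``split_var`` (default: the predictor itself, but
    e.g. age when regressing tortuosity on CAA by age side).  A side with
    fewer than 3 records is returned as ``None``.
    """
    split_var = split_var or predictor
    cols = list(dict.fromkeys([outcome, predictor, split_var]))
    data = table[cols].dropna()
    below = data[data[split_var] <= knot]
    above = data[data[split_var] > knot]

    def fit_side(side):
        if len(side) < 3:
            return None
        return _simple_ols(side[predictor], side[outcome])

    return fit_side(below), fit_side(above)


# ---------------------------------------------------------------------------
# sigmoid inflection
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    lower: float        # A
    upper: float        # B
    rate: float         # k
    inflection: float   # t0 (the model's inflection point)
    converged: bool
    sse: float
    form: str = "logistic"
    message: str = ""


def _sigmoid(t, A, B, k, t0):
    return A + (B - A) / (1.0 + np.exp(-k * (t - t0)))


def _gauss_cdf(t, A, B, k, t0):
    return A + (B - A) * stats.norm.cdf(k * (t - t0))


def sigmoid_fit(ages, values, form: str = "logistic") -> SigmoidFit:
    """Least-squares four-parameter sigmoid fit with multi-start t0.

    Initial t0 values run over the age quartiles; the best-SSE converged
    start wins.  ``form='gaussian'`` swaps the logistic for a Gaussian CDF
    of the same parameterization (inflection still at t0).
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 6:
        raise InvalidArgumentError("need >= 6 points to fit a sigmoid")
    model = _sigmoid if form == "logistic" else _gauss_cdf
    if form not in ("logistic", "gaussian"):
        raise InvalidArgumentError("form must be 'logistic' or 'gaussian'")
    if np.ptp(y) == 0:
        return SigmoidFit(float(y[0]), float(y[0]), np.nan, np.nan, False,
                          0.0, form, "constant data: rate unidentifiable")

    rng_span = np.ptp(t) or 1.0
    k0 = 4.0 / rng_span
    best = None
    for q in (0.25, 0.5, 0.75):
        t0_init = float(np.quantile(t, q))
        p0 = (float(y.min()), float(y.max()), k0, t0_init)

        def resid(p):
            return model(t, *p) - y

        try:
            sol = optimize.least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if not sol.success:
            continue
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, False, np.inf, form,
                          "no start converged")
    sse, (A, B, k, t0) = best
    if k < 0:  # normalize orientation: positive rate, A = lower plateau
        A, B, k, t0 = B, A, -k, t0
    return SigmoidFit(float(A), float(B), float(k), float(t0), True, sse, form)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def _loess_at(x, y, x0, k):
    """Tricube-weighted local linear fit at x0 using the k nearest points."""
    d = np.abs(x - x0)
    if k >= x.size:
        w = np.ones_like(x)
    else:
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            u = np.clip(d / dmax, 0, 1)
            w = (1 - u ** 3) ** 3
    sw = w.sum()
    if sw == 0:
        return np.nan
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-14 * max(1.0, xm ** 2):
        return ym
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return ym + slope * (x0 - xm)


def loess_trajectory(x, y, span: float = 0.75, grid: np.ndarray | None = None,
                     n_grid: int = 100, n_boot: int = 500, seed: int = 0,
                     ci: float = 0.95):
    """LOESS smoother on a grid plus a seeded bootstrap pointwise band.

    At ``span=1`` the weights are uniform, so the smoother equals the
    global linear fit (documented limit convention).  Returns a DataFrame
    with columns ``x, fit, lo, hi``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise InvalidArgumentError("need >= 10 points for a LOESS trajectory")
    if not (0 < span <= 1):
        raise InvalidArgumentError("span must lie in (0, 1]")
    n = x.size
    k = int(np.ceil(span * n))
    if k < 3:
        warnings.warn("span too small for local linear fits; widened to 3 points")
        k = 3
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    fit = np.array([_loess_at(x, y, g, k) for g in grid])

    lo = np.full_like(fit, np.nan)
    hi = np.full_like(fit, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            boot[b] = [_loess_at(xb, yb, g, min(k, n)) for g in grid]
        q = (1 - ci) / 2
        lo = np.nanquantile(boot, q, axis=0)
        hi = np.nanquantile(boot, 1 - q, axis=0)
    return pd.DataFrame({"x": grid, "fit": fit, "lo": lo, "hi": hi})


# ---------------------------------------------------------------------------
# cross-species alignment
# ---------------------------------------------------------------------------

def zscore_align(curve_a, curve_b, span: float = 0.75, n_grid: int = 100,
                 labels=("a", "b")):
    """Overlay two age trajectories on a shared normalized axis.

    Each curve is LOESS-smoothed over its own age range, z-scored against
    its own smoothed values, and mapped to a normalized position
    ``(age - min) / (max - min)``.  Returns an overlay table on a shared
    [0, 1] grid with one z-scored column per curve.
    """
    shared = np.linspace(0.0, 1.0, n_grid)
    out = {"position": shared}
    for label, (ages, values) in zip(labels, (curve_a, curve_b)):
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.size < 10:
            raise InvalidArgumentError("each curve needs >= 10 points")
        rng_span = ages.max() - ages.min()
        if rng_span == 0:
            raise DegenerateCurveError("curve spans a single age")
        grid = ages.min() + shared * rng_span
        smooth = loess_trajectory(ages, values, span=span, grid=grid,
                                  n_boot=0)["fit"].to_numpy()
        sd = smooth.std()
        if sd == 0:
            raise DegenerateCurveError("zero-variance trajectory cannot be z-scored")
        out[f"z_{label}"] = (smooth - smooth.mean()) / sd
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def anova_tukey(table: pd.DataFrame, outcome: str, group_factor: str,
                alpha: float = 0.05):
    """One-way ANOVA (F, p) plus Tukey HSD pairwise comparisons.

    Groups with fewer than 2 records are dropped with a warning.  Returns
    ``(f_stat, p_value, pairwise_table)``.
    """
    data = table[[outcome, group_factor]].dropna()
    counts = data[group_factor].value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"dropping groups with < 2 records: {list(small)}")
        data = data[~data[group_factor].isin(small)]
    groups = [g[outcome].to_numpy(dtype=float)
              for _, g in data.groupby(group_factor, observed=True)]
    if len(groups) < 2:
        raise InvalidArgumentError("need >= 2 groups with >= 2 records each")
    f_stat, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(data[outcome].to_numpy(dtype=float),
                           data[group_factor].to_numpy(), alpha=alpha)
    pair = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    pair["p-adj"] = tk.pvalues  # full precision, not the rounded summary
    return float(f_stat), float(p), pair
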