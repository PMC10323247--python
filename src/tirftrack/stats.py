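"""Statistics toolbox: Mann-Whitney U, median CIs, hierarchical bootstrap
slopes, and 1:1 binding-isotherm Kd fits.

These are the four statistical procedures the TIRF dose-response analyses
rely on: nonparametric two-sample comparison of per-microtubule intensities,
distribution-free medians with 95% confidence intervals, a replicate-aware
bootstrap for dose-response slopes, and a ligand-depletion (quadratic)
isotherm fit for dissociation constants measured at probe concentrations
comparable to the Kd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

__all__ = [
    "mann_whitney_u",
    "median_ci",
    "BootstrapSlopeResult",
    "bootstrap_slope",
    "TitrationCurve",
    "KdFitResult",
    "fit_kd_quadratic",
    "fit_kd_hyperbolic",
]

EXACT_POOLED_N = 16  # exact enumeration up to this pooled sample size


def mann_whitney_u(
    a, b, alternative: str = "two-sided", method: str = "auto"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns ``(U, p)`` with U computed for sample ``a``.

    U is computed from midranks (tie-corrected).  With ``method="auto"`` the
    p-value is exact by enumeration when the pooled sample size is at most 16
    and there are no ties, and otherwise uses the normal approximation with
    tie-corrected variance and continuity correction.  An all-identical
    pooled sample returns ``p = 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return a.size * b.size / 2.0, 1.0
    if method == "auto":
        method = "exact" if (pooled.size <= EXACT_POOLED_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def median_ci(
    sample,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Median with a distribution-free confidence interval.

    For ``n >= 8`` the interval is the binomial order-statistic interval: the
    widest pair of symmetric order statistics whose binomial(n, 1/2) coverage
    is at least ``level`` (conservative).  For ``5 <= n < 8`` where the
    order-statistic interval may degenerate to the full range without
    reaching nominal coverage, a bootstrap percentile interval is used.
    Returns ``(median, ci_low, ci_high)``.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations for a median CI")
    med = float(np.median(x))
    if np.all(x == x[0]):
        return med, med, med
    alpha = 1.0 - level
    if n >= 8:
        # largest r with P(Binom(n, 1/2) <= r - 1) <= alpha/2
        r = int(sps.binom.ppf(alpha / 2.0, n, 0.5)) + 1
        while r > 1 and sps.binom.cdf(r - 1, n, 0.5) > alpha / 2.0:
            r -= 1
        while sps.binom.cdf(r, n, 0.5) <= alpha / 2.0:
            r += 1
        # 1-indexed order statistics (x_(r), x_(n+1-r))
        lo = x[r - 1] if r >= 1 else x[0]
        hi = x[n - r] if r >= 1 else x[-1]
        return med, float(lo), float(hi)
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, n), replace=True), axis=1)
    return med, float(np.quantile(meds, alpha / 2)), float(np.quantile(meds, 1 - alpha / 2))


@dataclass
class BootstrapSlopeResult:
    """Median and 95% CI of a bootstrap distribution of regression slopes."""

    slope_median: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    slopes: np.ndarray = field(repr=False, default=None)


def _as_point_arrays(data: dict) -> tuple[list, np.ndarray, list[list[np.ndarray]]]:
    """Normalize {replicate: {conc: points}} into aligned arrays."""
    reps = sorted(data.keys(), key=str)
    conc_sets = [set(map(float, data[r].keys())) for r in reps]
    concs = sorted(set.union(*conc_sets))
    if len(concs) < 2:
        raise ValueError("need at least 2 concentrations")
    pts: list[list[np.ndarray]] = []
    for r in reps:
        row = []
        lookup = {float(c): np.asarray(v, dtype=float).ravel() for c, v in data[r].items()}
        for c in concs:
            arr = lookup.get(c, np.array([]))
            if arr.size == 0:
                raise ValueError(f"replicate {r!r} has no points at concentration {c}")
            row.append(arr)
        pts.append(row)
    return reps, np.asarray(concs, dtype=float), pts


def bootstrap_slope(
    data: dict,
    n_boot: int = 1000,
    seed: int = 0,
    mode: str = "hierarchical",
) -> BootstrapSlopeResult:
    """Replicate-aware bootstrap of a dose-response regression slope.

    ``data`` maps replicate label -> {concentration (nM) -> data points}.
    Each of the ``n_boot`` iterations resamples the replicate set with
    replacement (same size), then for each drawn replicate and each
    concentration draws one data point with replacement; the pooled points
    are fit by ordinary least squares and the slope recorded.  Returned are
    the median and the 2.5/97.5 percentiles of the bootstrap slopes.

    ``mode="single_replicate"`` implements the alternative reading in which
    each iteration uses one randomly drawn replicate only.

    Deterministic for a fixed ``seed``.
    """
    if mode not in ("hierarchical", "single_replicate"):
        raise ValueError("mode must be 'hierarchical' or 'single_replicate'")
    reps, concs, pts = _as_point_arrays(data)
    m, k = len(reps), len(concs)
    rng = np.random.default_rng(seed)

    # pad ragged point lists into (m, k, max_len) for vectorized draws
    max_len = max(len(arr) for row in pts for arr in row)
    P = np.zeros((m, k, max_len))
    L = np.zeros((m, k), dtype=int)
    for i, row in enumerate(pts):
        for j, arr in enumerate(row):
            P[i, j, : len(arr)] = arr
            L[i, j] = len(arr)

    n_rep_draws = 1 if mode == "single_replicate" else m
    rep_idx = rng.integers(0, m, size=(n_boot, n_rep_draws))
    u = rng.random(size=(n_boot, n_rep_draws, k))
    pt_idx = np.floor(u * L[rep_idx]).astype(int)  # (n_boot, n_rep_draws, k)
    y = P[rep_idx[:, :, None], np.arange(k)[None, None, :], pt_idx]

    # x is the same multiset every iteration: each drawn replicate contributes
    # every concentration exactly once
    x = np.tile(concs, n_rep_draws)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    yflat = y.reshape(n_boot, n_rep_draws * k)
    slopes = (yflat - yflat.mean(axis=1, keepdims=True)) @ xc / sxx

    return BootstrapSlopeResult(
        slope_median=float(np.median(slopes)),
        ci_low=float(np.quantile(slopes, 0.025)),
        ci_high=float(np.quantile(slopes, 0.975)),
        n_boot=n_boot,
        seed=seed,
        slopes=slopes,
    )


@dataclass
class TitrationCurve:
    """A binding titration: total ligand doses vs instrument response."""

    ligand_total: np.ndarray     # nM
    response: np.ndarray         # instrument units
    fixed_partner_conc: float    # nM, the labelled species held constant

    def __post_init__(self) -> None:
        self.ligand_total = np.asarray(self.ligand_total, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.ligand_total.shape != self.response.shape:
            raise ValueError("ligand_total and response must have the same length")

    def validate_for_fit(self) -> None:
        if self.ligand_total.size < 6:
            raise ValueError("need at least 6 titration points for a fit")
        pos = self.ligand_total[self.ligand_total > 0]
        if pos.size == 0 or np.log10(pos.max() / pos.min()) < 2.0:
            raise ValueError("titration must span at least 2 decades of ligand")
        if self.fixed_partner_conc <= 0:
            raise ValueError("fixed_partner_conc must be > 0")


def bound_fraction_quadratic(L: np.ndarray, A: float, kd: float) -> np.ndarray:
    """Bound fraction of the fixed partner under 1:1 binding with depletion."""
    L = np.asarray(L, dtype=float)
    s = A + L + kd
    return (s - np.sqrt(s**2 - 4.0 * A * L)) / (2.0 * A)


@dataclass
class KdFitResult:
    """Nonlinear 1:1 isotherm fit of a titration curve."""

    kd: float           # nM
    kd_sd: float        # nM, from the parameter covariance
    r_free: float
    r_bound: float
    residual_sd: float
    model: str          # "quadratic" | "hyperbolic"
    flag: str | None = None  # None | "uninformative" | "kd_at_bound" | "failed"


def _fit_isotherm(curve: TitrationCurve, model: str) -> KdFitResult:
    curve.validate_for_fit()
    L = curve.ligand_total
    y = curve.response
    A = curve.fixed_partner_conc

    if model == "quadratic":
        def f(L, kd, r_free, r_bound):
            return r_free + (r_bound - r_free) * bound_fraction_quadratic(L, A, kd)
    else:
        def f(L, kd, r_free, r_bound):
            return r_free + (r_bound - r_free) * L / (L + kd)

    pos = L[L > 0]
    p0 = [float(np.median(pos)), float(y[np.argmin(L)]), float(y[np.argmax(L)])]
    kd_lo, kd_hi = 1e-9, 1e9
    bounds = ([kd_lo, -np.inf, -np.inf], [kd_hi, np.inf, np.inf])
    try:
        popt, pcov = optimize.curve_fit(f, L, y, p0=p0, bounds=bounds, maxfev=20000)
    except Exception:
        return KdFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, model, flag="failed")
    kd, r_free, r_bound = popt
    resid = y - f(L, *popt)
    dof = max(L.size - 3, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    kd_sd = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan

    flag = None
    if kd <= kd_lo * 10 or kd >= kd_hi / 10:
        flag = "kd_at_bound"
    else:
        frac = (
            bound_fraction_quadratic(L, A, kd) if model == "quadratic" else L / (L + kd)
        )
        amp = abs(r_bound - r_free)
        y_scale = max(np.ptp(y), abs(np.mean(y)), 1e-30)
        if frac.max() - frac.min() < 0.05 or amp <= max(3 * residual_sd, 1e-9 * y_scale):
            # the response never leaves saturation (or shows no binding
            # amplitude): Kd is not constrained by these doses
            flag = "uninformative"
    return KdFitResult(float(kd), kd_sd, float(r_free), float(r_bound), residual_sd, model, flag)


def fit_kd_quadratic(curve: TitrationCurve) -> KdFitResult:
    """1:1 binding fit with ligand depletion (quadratic isotherm).

    The default model: appropriate when the labelled partner's concentration
    is comparable to the Kd, as in microscale-thermophoresis measurements of
    low-nanomolar interactions.
    """
    return _fit_isotherm(curve, "quadratic")


def fit_kd_hyperbolic(curve: TitrationCurve) -> KdFitResult:
    """Depletion-free 1:1 binding fit, ``f = L / (L + Kd)``."""
    return _fit_isotherm(curve, "hyperbolic")
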