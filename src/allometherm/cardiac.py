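"""Cardiac thermal tolerance from maximum heart rate during acute warming.

During an acute warming trial the pharmacologically stimulated maximum
heart rate (fHmax, beats min-1) is recorded at every 1 degC step.  On the
Arrhenius axes, ln(fHmax) versus 1000/T(K), the rise is near-linear until
a breakpoint temperature T_AB where it slows; fHmax then peaks (PEAK_fHmax
at T_PEAK) and the heartbeat finally becomes arrhythmic at T_ARR.

The breakpoint is located by a continuous two-segment least-squares fit,
profiling the residual sum of squares over a dense candidate grid followed
by a finer local pass.  Whether a breakpoint is "statistically identified"
is decided by a parametric bootstrap against a single-line null, and its
confidence interval by a parametric bootstrap around the segmented fit
(resampled residual SD, refit, percentile interval on the breakpoint).
Fits whose 95% CI half-width exceeds 1.5 degC, or that are not identified,
are excluded from downstream scaling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

KELVIN_OFFSET = 273.15

CARDIAC_COLUMNS = ("temp_c", "fhmax_bpm", "fhmax_sd", "arrhythmia_flag")


@dataclass
class CardiacSeries:
    """Per-1-degC fHmax observations for one fish, ending at arrhythmia."""

    fish_id: str
    observations: pd.DataFrame  # temp_c, fhmax_bpm, fhmax_sd, arrhythmia_flag

    def __post_init__(self) -> None:
        obs = self.observations
        missing = [c for c in CARDIAC_COLUMNS if c not in obs.columns]
        if missing:
            raise DataError(f"cardiac series {self.fish_id}: missing {missing}")
        t = obs["temp_c"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise DataError(
                f"cardiac series {self.fish_id}: temperatures not increasing"
            )
        flags = obs["arrhythmia_flag"].to_numpy(bool)
        if flags[:-1].any():
            raise DataError(
                f"cardiac series {self.fish_id}: arrhythmia before final row"
            )

    def pre_arrhythmia(self) -> pd.DataFrame:
        obs = self.observations
        return obs[~obs["arrhythmia_flag"].astype(bool)]


@dataclass
class BreakpointFit:
    breakpoint_x: float         # 1000/K
    t_ab: float                 # degC
    slope_below: float          # segment below T_AB, d ln(fHmax) / d(1000/K)
    slope_above: float          # segment above T_AB
    intercept: float
    ci_halfwidth_c: float       # degC
    ci_celsius: tuple[float, float] = (float("nan"), float("nan"))
    n_boot: int = 100
    identified: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    p_value: float = float("nan")


@dataclass
class CardiacSummary:
    fish_id: str
    t_ab: Optional[float]
    t_peak: float
    peak_fhmax: float
    t_arr: Optional[float]
    t_ab_ci_halfwidth: float = float("nan")
    t_ab_excluded_reason: str = ""


def celsius_to_x(temp_c):
    """Arrhenius abscissa: 1000 / T(K)."""
    return 1000.0 / (np.asarray(temp_c, float) + KELVIN_OFFSET)


def x_to_celsius(x):
    return 1000.0 / np.asarray(x, float) - KELVIN_OFFSET


def arrhenius_transform(series: CardiacSeries) -> tuple[np.ndarray, np.ndarray]:
    """Map a cardiac series to (x, y) = (1000/T_K, ln fHmax).

    Only observations before the arrhythmic one enter the regression.
    Output is ordered by increasing temperature, i.e. decreasing x.
    """
    pre = series.pre_arrhythmia()
    if pre.empty:
        raise DataError(f"cardiac series {series.fish_id}: no pre-arrhythmia data")
    fh = pre["fhmax_bpm"].to_numpy(float)
    if np.any(fh <= 0):
        raise DataError(f"cardiac series {series.fish_id}: fhmax <= 0")
    return celsius_to_x(pre["temp_c"].to_numpy(float)), np.log(fh)


def rising_limb(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a transformed series to the rising limb of the TPC.

    The Arrhenius breakpoint characterizes the slowing of the rise of
    ln(fHmax); the post-peak decline is not Arrhenius-linear and would
    bias a single-knot fit, so the breakpoint regression uses observations
    up to and including the peak.  Input is ordered by increasing
    temperature (decreasing x); output keeps indices 0..argmax(y).
    """
    i = int(np.argmax(y))
    return x[: i + 1], y[: i + 1]


# ---------------------------------------------------------------- breakpoint

def _design(x: np.ndarray, c: float) -> np.ndarray:
    """Continuous two-segment design: y = b0 + b1*x + b2*(x - c)+ ."""
    return np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])


def _profile_rss(x: np.ndarray, y: np.ndarray,
                 cands: np.ndarray) -> np.ndarray:
    """RSS of the continuous two-segment fit at each candidate breakpoint."""
    n = len(x)
    ones = np.ones(n)
    hinge = np.maximum(x[None, :] - cands[:, None], 0.0)   # (m, n)
    m = len(cands)
    X = np.empty((m, n, 3))
    X[:, :, 0] = ones
    X[:, :, 1] = x
    X[:, :, 2] = hinge
    xtx = np.einsum("mni,mnj->mij", X, X)
    xty = np.einsum("mni,n->mi", X, y)
    # tiny ridge keeps near-singular candidate designs solvable
    xtx += 1e-12 * np.eye(3)[None, :, :]
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    fitted = np.einsum("mni,mi->mn", X, beta)
    return np.sum((y[None, :] - fitted) ** 2, axis=1)


def _candidate_grid(xs: np.ndarray, min_pts: int,
                    per_interval: int = 50) -> np.ndarray:
    """Midpoints plus uniform candidates per interval, interior only."""
    lo, hi = xs[min_pts - 1], xs[len(xs) - min_pts]
    if hi <= lo:
        return np.empty(0)
    cands = []
    for a, b in zip(xs[:-1], xs[1:]):
        a_, b_ = max(a, lo), min(b, hi)
        if b_ <= a_:
            continue
        cands.append(np.linspace(a_, b_, per_interval + 2)[1:-1])
        cands.append(np.array([0.5 * (a_ + b_)]))
    grid = np.unique(np.concatenate(cands))
    return grid[(grid > lo) & (grid < hi)]


def _fit_breakpoint_rss(x: np.ndarray, y: np.ndarray,
                        min_pts: int) -> tuple[float, np.ndarray, float]:
    """Two-stage grid search; returns (breakpoint, coefficients, rss)."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    grid = _candidate_grid(xs, min_pts)
    if grid.size == 0:
        raise DataError("no admissible breakpoint candidates")
    rss = _profile_rss(xs, ys, grid)
    i = int(np.argmin(rss))
    # refinement within one candidate spacing of the stage-1 winner
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    fine = np.linspace(lo, hi, 201)
    rss_f = _profile_rss(xs, ys, fine)
    stacked = np.concatenate([grid, fine])
    rss_all = np.concatenate([rss, rss_f])
    j = int(np.argmin(rss_all))
    c = float(stacked[j])
    beta, *_ = np.linalg.lstsq(_design(xs, c), ys, rcond=None)
    return c, beta, float(rss_all[j])


def _single_line_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _lr_stat(rss1: float, rss2: float, n: int) -> float:
    """Likelihood-ratio statistic n*ln(RSS1/RSS2) for segmented vs line.

    Scale-invariant, hence pivotal under the bootstrap null.  Degenerate
    cases: a perfect single line gives 0, a perfect segmented fit over an
    imperfect line gives +inf.
    """
    if rss1 <= 1e-14:
        return 0.0
    if rss2 <= 1e-14 * max(rss1, 1.0):
        return float("inf")
    return n * float(np.log(rss1 / rss2))


def _boot_grid_rss(xs: np.ndarray, Y: np.ndarray,
                   grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Grid-only segmented refits for a batch of response vectors.

    ``Y`` is (n, B).  Returns (breakpoints per replicate, segmented RSS per
    replicate) using orthonormal projections per candidate — equivalent to
    least squares at grid resolution, which is ample for bootstrap
    percentiles.
    """
    n, B = Y.shape
    designs = np.empty((len(grid), n, 3))
    designs[:, :, 0] = 1.0
    designs[:, :, 1] = xs
    designs[:, :, 2] = np.maximum(xs[None, :] - grid[:, None], 0.0)
    Q, _ = np.linalg.qr(designs)                 # (m, n, 3)
    proj = np.einsum("mnk,nb->mkb", Q, Y)        # (m, 3, B)
    rss = np.sum(Y**2, axis=0)[None, :] - np.sum(proj**2, axis=1)
    best = np.argmin(rss, axis=0)                # (B,)
    return grid[best], rss[best, np.arange(B)]


def _line_rss_batch(xs: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(xs), xs])
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return np.sum(Y**2, axis=0) - np.sum(proj**2, axis=0)


def fit_breakpoint(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 100,
    ci_limit_c: float = 1.5,
    min_points_per_segment: int = 3,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> BreakpointFit:
    """Arrhenius broken-stick fit with parametric-bootstrap inference.

    Returns a non-identified fit (never raises) when fewer than
    ``2 * min_points_per_segment`` points are available.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(x)
    if n < 2 * min_points_per_segment:
        return BreakpointFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                             n_boot=n_boot, identified=False, excluded=True,
                             exclusion_reason="too_few_points")
    order = np.argsort(x)
    xs, ys = x[order], y[order]

    c_hat, beta, rss2 = _fit_breakpoint_rss(xs, ys, min_points_per_segment)
    beta0_null, rss1 = _single_line_rss(xs, ys)
    stat_obs = _lr_stat(rss1, rss2, n)
    grid = _candidate_grid(xs, min_points_per_segment)

    # identification: parametric bootstrap under the single-line null
    sigma_null = np.sqrt(max(rss1, 0.0) / max(n - 2, 1))
    null_fitted = beta0_null[0] + beta0_null[1] * xs
    Yb = null_fitted[:, None] + sigma_null * rng.standard_normal((n, n_boot))
    _, rss2_b = _boot_grid_rss(xs, Yb, grid)
    rss1_b = _line_rss_batch(xs, Yb)
    stats_b = np.array([_lr_stat(r1, r2, n)
                        for r1, r2 in zip(rss1_b, rss2_b)])
    exceed = int(np.sum(stats_b >= stat_obs - 1e-12))
    p = (1 + exceed) / (n_boot + 1)
    identified = p < 0.05

    # CI: parametric bootstrap around the two-segment fit; the residual SD
    # counts the breakpoint among the estimated parameters (n - 5 df)
    sigma_alt = np.sqrt(max(rss2, 0.0) / max(n - 5, 1))
    alt_fitted = _design(xs, c_hat) @ beta
    Yb = alt_fitted[:, None] + sigma_alt * rng.standard_normal((n, n_boot))
    boots, _ = _boot_grid_rss(xs, Yb, grid)
    lo_x, hi_x = np.percentile(boots, [2.5, 97.5])
    # x decreasing in T: the low-x endpoint is the warm end
    t_lo, t_hi = sorted([x_to_celsius(lo_x), x_to_celsius(hi_x)])
    ci_halfwidth = 0.5 * (t_hi - t_lo)

    excluded, reason = False, ""
    if not identified:
        excluded, reason = True, "not_identified"
    elif ci_halfwidth > ci_limit_c:
        excluded, reason = True, "ci_exceeds_limit"
    # slope for x > c (colder than T_AB) is b1 + b2; for x < c it is b1
    return BreakpointFit(
        breakpoint_x=c_hat,
        t_ab=float(x_to_celsius(c_hat)),
        slope_below=float(beta[1] + beta[2]),
        slope_above=float(beta[1]),
        intercept=float(beta[0]),
        ci_halfwidth_c=float(ci_halfwidth),
        ci_celsius=(float(t_lo), float(t_hi)),
        n_boot=n_boot,
        identified=identified,
        excluded=excluded,
        exclusion_reason=reason,
        p_value=p,
    )


def summarize_cardiac(series: CardiacSeries,
                      fit: Optional[BreakpointFit] = None) -> CardiacSummary:
    """Collect T_AB / T_PEAK / PEAK_fHmax / T_ARR for one fish.

    PEAK_fHmax is the maximum pre-arrhythmia fHmax; T_PEAK the lowest
    temperature attaining it (earliest-peak tie break).  T_AB is reported
    only when the breakpoint fit is identified and not excluded.
    """
    pre = series.pre_arrhythmia()
    if pre.empty:
        raise DataError(f"cardiac series {series.fish_id}: no usable data")
    fh = pre["fhmax_bpm"].to_numpy(float)
    temps = pre["temp_c"].to_numpy(float)
    peak = float(fh.max())
    t_peak = float(temps[np.flatnonzero(fh == peak)[0]])
    arr = series.observations[series.observations["arrhythmia_flag"].astype(bool)]
    t_arr = float(arr["temp_c"].iloc[0]) if len(arr) else None
    t_ab = None
    ci_hw = float("nan")
    reason = ""
    if fit is not None:
        ci_hw = fit.ci_halfwidth_c
        reason = fit.exclusion_reason
        if fit.identified and not fit.excluded:
            t_ab = fit.t_ab
    return CardiacSummary(series.fish_id, t_ab, t_peak, peak, t_arr,
                          ci_hw, reason)


def read_cardiac_csv(path, fish_id: str) -> CardiacSeries:
    df = pd.read_csv(path)
    for col in CARDIAC_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing column '{col}'")
    return CardiacSeries(fish_id, df)
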