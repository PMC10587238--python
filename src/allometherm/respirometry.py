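"""Intermittent-flow respirometry: O2 traces -> MO2 series -> metabolic summaries.

A sealed respirometer alternates flush and measure phases.  During each
measure phase the dissolved-O2 concentration declines linearly; the slope
of that decline, corrected for microbial (background) respiration and
scaled by the net water volume, is the fish's oxygen uptake rate

    MO2 = (|m_fish| - |m_background|) * V_net          [mgO2 min-1]

with slopes in mg L-1 min-1 and V_net = chamber volume minus the volume
displaced by the fish (density 1 kg L-1).  Per-trial summaries follow the
standard definitions: MMR is the highest accepted MO2 (any cycle of at
least 3 min), RMR is the mean of the 10 lowest accepted MO2 values after
discarding the 5 lowest, AAS = MMR - RMR and FAS = MMR / RMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InsufficientDataError

#: density used to convert fish mass to displaced water volume, kg L-1
WATER_DENSITY_KG_PER_L = 1.0

TRACE_COLUMNS = ("time_s", "o2_mg_per_l", "phase", "cycle_index")


@dataclass
class O2Trace:
    """Raw respirometry time series for one fish at one test temperature.

    ``samples`` holds columns time_s (strictly increasing), o2_mg_per_l,
    phase ('flush'/'measure') and cycle_index (non-decreasing).
    """

    fish_id: str
    temperature: float          # degC
    chamber_volume: float       # L
    fish_mass: float            # kg
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRACE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise DataError(
                f"trace for {self.fish_id}: missing column(s) {missing}"
            )
        t = self.samples["time_s"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise DataError(f"trace for {self.fish_id}: time_s not strictly increasing")
        cyc = self.samples["cycle_index"].to_numpy()
        if len(cyc) and np.any(np.diff(cyc) < 0):
            raise DataError(f"trace for {self.fish_id}: cycle_index decreases")

    @property
    def net_volume(self) -> float:
        """Chamber volume minus fish displacement, L."""
        return self.chamber_volume - self.fish_mass / WATER_DENSITY_KG_PER_L

    def cycle_indices(self) -> list[int]:
        mask = self.samples["phase"] == "measure"
        return sorted(self.samples.loc[mask, "cycle_index"].unique().tolist())


@dataclass
class SlopeFit:
    """OLS fit of O2 (mg L-1) against time (min) over one measure phase."""

    cycle_index: int
    slope: float                # mg L-1 min-1, <= 0 expected
    intercept: float            # mg L-1
    r_squared: float            # in [0, 1]; nan when degenerate
    duration: float             # s of data used (after trimming)
    n_points: int
    t_mid: float                # s, midpoint of the used window
    status: str = "ok"          # 'ok' | 'too_short' | 'degenerate'


@dataclass
class MO2Series:
    """Per-cycle oxygen-uptake estimates with quality flags."""

    fish_id: str
    temperature: float
    records: pd.DataFrame       # cycle_index, t_mid_s, slope, r2, duration_s,
    #                             mo2, accepted, reason
    background_slope_pre: float
    background_slope_post: float
    net_volume: float

    def accepted(self) -> pd.DataFrame:
        return self.records[self.records["accepted"]]


@dataclass
class MetabolicSummary:
    fish_id: str
    temperature: float
    mmr: float                  # mgO2 min-1
    rmr: float                  # mgO2 min-1
    aas: float                  # mgO2 min-1
    fas: float                  # dimensionless
    n_accepted_cycles: int
    warnings: list[str] = field(default_factory=list)


def fit_cycle_slope(
    trace: O2Trace,
    cycle_index: int,
    trim_start: float = 60.0,
    min_duration: float = 180.0,
) -> SlopeFit:
    """Fit the O2 decline of one measure phase by ordinary least squares.

    The first ``trim_start`` seconds of the measure phase (chamber mixing)
    are discarded; cycles whose remaining span is shorter than
    ``min_duration`` seconds are flagged ``too_short`` and cycles with no
    O2 variance are flagged ``degenerate`` — neither raises.
    """
    s = trace.samples
    sel = (s["phase"] == "measure") & (s["cycle_index"] == cycle_index)
    sub = s.loc[sel]
    if sub.empty:
        raise DataError(f"cycle {cycle_index} not found in trace {trace.fish_id}")
    t = sub["time_s"].to_numpy(float)
    o2 = sub["o2_mg_per_l"].to_numpy(float)
    keep = t >= t[0] + trim_start
    t, o2 = t[keep], o2[keep]
    dur = float(t[-1] - t[0]) if len(t) > 1 else 0.0
    t_mid = float(0.5 * (t[0] + t[-1])) if len(t) else float("nan")
    if dur < min_duration or len(t) < 3:
        return SlopeFit(cycle_index, np.nan, np.nan, np.nan, dur, len(t),
                        t_mid, status="too_short")
    tm = t / 60.0  # regression is per minute
    slope, intercept = np.polyfit(tm, o2, 1)
    resid = o2 - (slope * tm + intercept)
    ss_tot = float(np.sum((o2 - o2.mean()) ** 2))
    if ss_tot == 0.0:
        return SlopeFit(cycle_index, 0.0, float(o2[0]), np.nan, dur, len(t),
                        t_mid, status="degenerate")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return SlopeFit(cycle_index, float(slope), float(intercept), r2, dur,
                    len(t), t_mid)


def _interp_background(t_mid: float, t0: float, t1: float,
                       pre: float, post: float) -> float:
    """Background slope at time t_mid, linear between trial start/end values."""
    if t1 <= t0:
        return pre
    w = np.clip((t_mid - t0) / (t1 - t0), 0.0, 1.0)
    return (1.0 - w) * pre + w * post


def extract_mo2_series(
    trace: O2Trace,
    background_pre: float,
    background_post: float,
    r2_threshold: float = 0.96,
    trim_start: float = 60.0,
    min_duration: float = 180.0,
) -> MO2Series:
    """Quality-filter all cycles and compute background-corrected MO2.

    Cycles failing the R² or duration rules are retained with
    ``accepted=False`` and a reason; MO2 is computed only for accepted
    cycles.  Background slopes come from empty-chamber measurements before
    and after the trial and are interpolated linearly in time.
    """
    v_net = trace.net_volume
    if v_net <= 0:
        raise ConfigurationError(
            f"net volume {v_net:.3f} L <= 0 for fish {trace.fish_id}"
        )
    t_all = trace.samples["time_s"].to_numpy(float)
    t0, t1 = float(t_all[0]), float(t_all[-1])
    rows = []
    for ci in trace.cycle_indices():
        fit = fit_cycle_slope(trace, ci, trim_start, min_duration)
        if fit.status == "too_short":
            acc, reason, mo2 = False, "too_short", np.nan
        elif fit.status == "degenerate":
            acc, reason, mo2 = False, "degenerate", np.nan
        elif not fit.r_squared > r2_threshold:
            acc, reason, mo2 = False, "r2_below_threshold", np.nan
        else:
            bg = _interp_background(fit.t_mid, t0, t1,
                                    background_pre, background_post)
            mo2 = (abs(fit.slope) - abs(bg)) * v_net
            acc, reason = True, ""
        rows.append(dict(cycle_index=ci, t_mid_s=fit.t_mid, slope=fit.slope,
                         r2=fit.r_squared, duration_s=fit.duration,
                         mo2=mo2, accepted=acc, reason=reason))
    records = pd.DataFrame(rows)
    if records.empty or not records["accepted"].any():
        raise DataError(
            f"no accepted cycles for fish {trace.fish_id} at "
            f"{trace.temperature} degC"
        )
    return MO2Series(trace.fish_id, trace.temperature, records,
                     background_pre, background_post, v_net)


def summarize_metabolism(
    series: MO2Series,
    mmr_min_duration: float = 180.0,
    rmr_drop_lowest: int = 5,
    rmr_keep: int = 10,
) -> MetabolicSummary:
    """Reduce an MO2 series to MMR / RMR / AAS / FAS.

    RMR is an order statistic: the accepted MO2 values are sorted
    ascending, the ``rmr_drop_lowest`` smallest discarded, and the next
    ``rmr_keep`` averaged.  If RMR >= MMR the summary is still emitted,
    carrying a warning rather than being clamped.
    """
    acc = series.accepted()
    need = rmr_drop_lowest + rmr_keep
    if len(acc) < need:
        raise InsufficientDataError(
            f"{len(acc)} accepted cycles < {need} required for fish "
            f"{series.fish_id} at {series.temperature} degC"
        )
    mo2 = acc["mo2"].to_numpy(float)
    long_enough = acc["duration_s"].to_numpy(float) >= mmr_min_duration
    if not long_enough.any():
        raise InsufficientDataError(
            f"no accepted cycle of >= {mmr_min_duration}s for MMR "
            f"(fish {series.fish_id})"
        )
    mmr = float(mo2[long_enough].max())
    ranked = np.sort(mo2)
    rmr = float(ranked[rmr_drop_lowest:rmr_drop_lowest + rmr_keep].mean())
    warnings = []
    if rmr >= mmr:
        warnings.append("rmr_ge_mmr")
    return MetabolicSummary(series.fish_id, series.temperature, mmr, rmr,
                            mmr - rmr, mmr / rmr, int(len(acc)), warnings)


def read_trace_csv(path, fish_id: str, temperature: float,
                   chamber_volume: float, fish_mass: float) -> O2Trace:
    """Load a trace CSV (schema: time_s, o2_mg_per_l, phase, cycle_index)."""
    df = pd.read_csv(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing column '{col}'")
    return O2Trace(fish_id, temperature, chamber_volume, fish_mass,
                   df[list(df.columns)])
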