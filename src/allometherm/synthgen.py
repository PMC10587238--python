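"""Synthetic study generator for the scaling / thermal-tolerance pipeline.

Emulates an acute-temperature study on a eurythermal surf-zone fish: a
cohort spanning roughly 5-700 g is repeat-tested at four acute
temperatures (12, 16, 20, 22 degC).  Whole-animal metabolic rates follow
the allometric power law ln(rate) = ln a(T) + b*ln(BM) with a per-fish
random intercept (repeated-measures structure) and lognormal residual
noise.  Respirometry traces are built from those latent rates: alternating
flush/measure phases, a linear O2 decline per measure phase whose slope is
(fish MO2 + microbial background) / net volume, an elevated-MMR episode in
the first post-chase cycle and once overnight, and optional sensor noise.
Maximum-heart-rate series rise on Arrhenius axes, slow at a mass-dependent
breakpoint T_AB, peak at T_PEAK and terminate in arrhythmia at T_ARR, all
three following power laws in body mass.  Ventricle mass is a lognormal
power law as well.

Every dataset carries its latent truth (random intercepts, per-cycle MO2,
breakpoint temperatures) so downstream estimators can be tested for
parameter recovery.  All randomness flows from ``GeneratorConfig.seed``
through named, per-fish substreams, so outputs are bit-reproducible and
independent of generation order.

Default parameter values are the study conditions themselves: the scaling
slopes/intercepts of the measured fish (MMR b=0.810, RMR b=0.809, cardiac
power laws, ventricle mass b=0.855), a background respiration level with
mean ~10% (median 6.6%) of fish respiration, and ln-scale SDs of 0.10
(individual and residual) / 0.02 (cardiac) where the source reports no
variance components.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cardiac import CardiacSeries, celsius_to_x
from .errors import ConfigurationError, DomainError
from .respirometry import O2Trace

# substream tags (second entry of the rng seed sequence)
_S_COHORT, _S_INTERCEPT, _S_TRACE, _S_CARDIAC, _S_VM, _S_OBS = range(6)

JUVENILE_MASS_KG = 0.050


def _fish_key(fish_id: str) -> int:
    """Stable 32-bit key for per-fish random substreams."""
    return zlib.crc32(fish_id.encode())


@dataclass(frozen=True)
class FishRecord:
    fish_id: str
    body_mass: float            # kg
    origin: str = "wild"        # 'wild' | 'lab_born'
    sex: str = "unknown"        # 'F' | 'M' | 'unknown'

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ConfigurationError(f"{self.fish_id}: body_mass must be > 0")

    @property
    def size_class(self) -> str:
        return "juvenile" if self.body_mass < JUVENILE_MASS_KG else "adult"


@dataclass(frozen=True)
class CardiacParams:
    """Parameters of the synthetic fHmax thermal performance curve."""

    slope_fh: float = -0.052            # mass exponent of fHmax
    intercept_fh_16c: float = 4.325     # ln(beats min-1) at 16 degC, 1 kg
    tab_slope: float = 0.030            # T_AB = exp(tab_intercept + tab_slope*lnBM)
    tab_intercept: float = 3.144        # ln(degC)
    tpeak_slope: float = 0.034
    tpeak_intercept: float = 3.304
    tarr_slope: float = 0.030
    tarr_intercept: float = 3.359
    arrhenius_slope_below: float = 6.0  # d ln(fH)/d(1000/K) below T_AB (Q10 ~ 2.0)
    arrhenius_slope_above: float = 1.6  # above T_AB (Q10 ~ 1.2 plateau)
    decline_per_c: float = 0.05         # ln-scale fall per degC past T_PEAK
    individual_sd: float = 0.05         # ln-scale random intercept SD
    noise_sd: float = 0.02              # ln-scale per-observation noise


@dataclass(frozen=True)
class GeneratorConfig:
    n_fish: int = 83
    mass_range: tuple[float, float] = (0.005, 0.700)    # kg
    temperatures: tuple[float, ...] = (12.0, 16.0, 20.0, 22.0)
    # metabolic truth: MMR and RMR power laws, ln(mgO2 min-1) intercepts
    true_slope: float = 0.810
    true_intercepts: dict[float, float] = field(
        default_factory=lambda: {12.0: 1.011, 16.0: 1.235, 20.0: 1.436, 22.0: 1.497})
    rmr_slope: float = 0.809
    rmr_intercepts: dict[float, float] = field(
        default_factory=lambda: {12.0: 0.235, 16.0: 0.59, 20.0: 0.845, 22.0: 0.97})
    individual_sd: float = 0.10         # ln-scale SD of per-fish intercepts
    residual_sd: float = 0.10           # ln-scale SD of per-cycle residuals
    background_fraction: float = 0.10   # mean background / fish respiration
    sensor_sd: float = 0.005            # mg L-1 optical O2-probe noise
    cardiac_params: CardiacParams = field(default_factory=CardiacParams)
    vm_slope: float = 0.855
    vm_intercept: float = -7.639        # ln(kg)
    vm_sd: float = 0.05
    n_cardiac: int = 30                 # fish receiving a cardiac trial
    # respirometry protocol
    flush_s: float = 540.0
    measure_s: float = 360.0
    n_cycles: int = 62
    sample_interval_s: float = 5.0
    volume_ratio: float = 40.0          # net chamber volume / fish mass (L kg-1)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mass_range
        if not (0 < lo < hi):
            raise ConfigurationError("mass_range must be positive and increasing")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ConfigurationError("temperatures must be distinct")
        for name in ("individual_sd", "residual_sd", "sensor_sd", "vm_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_fish < 0:
            raise ConfigurationError("n_fish must be >= 0")
        for t in self.temperatures:
            if t not in self.true_intercepts or t not in self.rmr_intercepts:
                raise ConfigurationError(f"no intercept configured for {t} degC")

    def zero_noise(self) -> "GeneratorConfig":
        """Copy of this config with every noise source switched off."""
        cp = dataclasses.replace(
            self.cardiac_params, individual_sd=0.0, noise_sd=0.0)
        return dataclasses.replace(
            self, individual_sd=0.0, residual_sd=0.0, sensor_sd=0.0,
            vm_sd=0.0, cardiac_params=cp)


@dataclass
class StudyDataset:
    """A full synthetic study plus its generating truth."""

    config: GeneratorConfig
    cohort: list[FishRecord]
    traces: dict[tuple[str, float], O2Trace]
    backgrounds: pd.DataFrame           # fish_id, temp_c, pre_slope, post_slope
    cardiac: dict[str, CardiacSeries]
    ventricles: pd.DataFrame            # fish_id, ventricle_mass_kg
    truth: dict


# ------------------------------------------------------------------ cohort

def generate_cohort(config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> list[FishRecord]:
    """Draw the fish cohort: body masses log-uniform over the mass range.

    Small fish (< 50 g) are a mix of wild-caught and lab-born juveniles;
    sex is recorded only for fish large enough to show dimorphism.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _S_COHORT])
    lo, hi = config.mass_range
    masses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_fish))
    fish = []
    for i, m in enumerate(masses):
        fid = f"F{i:03d}"
        if m < JUVENILE_MASS_KG:
            origin = "lab_born" if rng.random() < 0.5 else "wild"
        else:
            origin = "wild"
        if m < 0.007:
            sex = "unknown"
        else:
            sex = "F" if rng.random() < 0.5 else "M"
        fish.append(FishRecord(fid, float(m), origin, sex))
    return fish


def _fish_intercept(config: GeneratorConfig, fish: FishRecord) -> float:
    """Per-fish metabolic random intercept, stable across temperatures."""
    if config.individual_sd == 0:
        return 0.0
    rng = np.random.default_rng([config.seed, _S_INTERCEPT, _fish_key(fish.fish_id)])
    return float(config.individual_sd * rng.standard_normal())


def air_saturation_mg_per_l(temp_c: float) -> float:
    """Approximate O2 solubility of coastal seawater, mg L-1."""
    return 11.0 - 0.18 * temp_c


# ------------------------------------------------------------- respirometry

def _simulate_trace_full(fish: FishRecord, temperature: float,
                         config: GeneratorConfig) -> tuple[O2Trace, dict]:
    if temperature not in config.temperatures:
        raise DomainError(f"{temperature} degC not among configured temperatures")
    rng = np.random.default_rng(
        [config.seed, _S_TRACE, _fish_key(fish.fish_id), int(round(temperature * 10))])
    ln_bm = np.log(fish.body_mass)
    u = _fish_intercept(config, fish)
    rmr_true = np.exp(config.rmr_intercepts[temperature]
                      + config.rmr_slope * ln_bm + u)
    mmr_true = np.exp(config.true_intercepts[temperature]
                      + config.true_slope * ln_bm + u)

    n_cyc = config.n_cycles
    mo2 = rmr_true * np.exp(config.residual_sd * rng.standard_normal(n_cyc))
    # elevated-MMR episodes: first post-chase cycle and one overnight cycle
    overnight = int(rng.integers(n_cyc // 3, 2 * n_cyc // 3))
    for idx in (0, overnight):
        mo2[idx] = mmr_true * np.exp(config.residual_sd * rng.standard_normal())

    v_net = config.volume_ratio * fish.body_mass
    chamber = v_net + fish.body_mass   # displaced water at 1 kg L-1
    noisy = config.residual_sd > 0 or config.sensor_sd > 0
    if noisy:
        # lognormal trial fraction: median 0.066, mean ~ background_fraction,
        # capped so extreme draws stay physically plausible
        sigma = 0.9
        median = config.background_fraction / np.exp(0.5 * sigma**2)
        frac = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        frac = min(frac, 0.35)
    else:
        frac = config.background_fraction
    bg_mo2 = frac * rmr_true
    bg_slope = -bg_mo2 / v_net

    sat = air_saturation_mg_per_l(temperature)
    # flush:measure split within the cycle follows the protocol's menu
    # (11:4 .. 8:7 min): the longest measure whose worst-case decline
    # (elevated MO2 plus background) stays above 70% air saturation
    cycle_s = config.flush_s + config.measure_s
    worst_per_min = (1.5 * mmr_true + bg_mo2) / v_net
    measure_s = config.measure_s
    for m_min in (7.0, 6.0, 5.0, 4.0):
        measure_s = min(m_min * 60.0, config.measure_s)
        if worst_per_min * measure_s / 60.0 <= 0.28 * sat:
            break
    flush_s = cycle_s - measure_s

    dt = config.sample_interval_s
    n_flush = max(int(flush_s // dt), 1)
    n_meas = max(int(measure_s // dt), 1) + 1
    per_cycle = n_flush + n_meas
    total = n_cyc * per_cycle
    time_s = np.arange(total) * dt
    within = np.tile(np.arange(per_cycle), n_cyc)
    cycle_index = np.repeat(np.arange(n_cyc), per_cycle)
    is_meas = within >= n_flush
    elapsed_min = np.where(is_meas, (within - n_flush) * dt / 60.0, 0.0)
    slope_per_cycle = -(mo2 + bg_mo2) / v_net
    o2 = sat + np.where(is_meas, slope_per_cycle[cycle_index] * elapsed_min, 0.0)
    if config.sensor_sd > 0:
        o2 = o2 + config.sensor_sd * rng.standard_normal(total)
    samples = pd.DataFrame({
        "time_s": time_s,
        "o2_mg_per_l": o2,
        "phase": np.where(is_meas, "measure", "flush"),
        "cycle_index": cycle_index,
        "temp_c": temperature,
    })
    trace = O2Trace(fish.fish_id, temperature, chamber, fish.body_mass, samples)
    ranked = np.sort(mo2)
    truth = {
        "u": u,
        "rmr_model": float(rmr_true),
        "mmr_model": float(mmr_true),
        "mmr_realized": float(max(mo2[0], mo2[overnight])),
        "rmr_realized": float(ranked[5:15].mean()),
        "per_cycle_mo2": mo2.tolist(),
        "background_fraction": frac,
        "background_slope_pre": float(bg_slope),
        "background_slope_post": float(bg_slope),
        "net_volume": float(v_net),
    }
    return trace, truth


def simulate_o2_trace(fish: FishRecord, temperature: float,
                      config: GeneratorConfig) -> O2Trace:
    """Simulate one overnight respirometry trace (see module docstring)."""
    trace, _ = _simulate_trace_full(fish, temperature, config)
    return trace


# ------------------------------------------------------------------ cardiac

def cardiac_latents(fish: FishRecord, config: GeneratorConfig) -> dict:
    """Closed-form T_AB / T_PEAK / T_ARR for one fish (degC)."""
    p = config.cardiac_params
    ln_bm = np.log(fish.body_mass)
    t_ab = float(np.exp(p.tab_intercept + p.tab_slope * ln_bm))
    t_peak = float(np.exp(p.tpeak_intercept + p.tpeak_slope * ln_bm))
    t_arr = float(np.exp(p.tarr_intercept + p.tarr_slope * ln_bm))
    return {"t_ab": t_ab, "t_peak": t_peak, "t_arr": t_arr}


def _cardiac_curve(temps: np.ndarray, y16: float, t_ab: float,
                   t_peak: float, p: CardiacParams) -> np.ndarray:
    """Noiseless ln(fHmax) at the given temperatures (degC).

    Two Arrhenius-linear segments (slope change at ``t_ab``) up to
    ``t_peak``, then a linear-in-degC decline.
    """
    x = celsius_to_x(temps)
    x16 = celsius_to_x(16.0)
    x_ab = celsius_to_x(t_ab)
    x_peak = celsius_to_x(t_peak)
    y_ab = y16 + p.arrhenius_slope_below * (x16 - x_ab)
    y_peak = y_ab + p.arrhenius_slope_above * (x_ab - x_peak)
    y = np.where(
        temps <= t_ab,
        y16 + p.arrhenius_slope_below * (x16 - x),
        np.where(
            temps <= t_peak,
            y_ab + p.arrhenius_slope_above * (x_ab - x),
            y_peak - p.decline_per_c * (temps - t_peak),
        ),
    )
    return y


def simulate_cardiac_series(fish: FishRecord, config: GeneratorConfig
                            ) -> tuple[CardiacSeries, dict]:
    """Simulate per-1-degC fHmax from 16 degC up to arrhythmia.

    Returns the series plus its latent truth: the configured power-law
    breakpoint temperatures and the values realized on the 1-degC grid.
    The TPC peak is realized on the protocol's 1-degC grid (the nearest
    step to the latent power-law T_PEAK), so the rising limb is exactly
    two-segment on Arrhenius axes.
    """
    p = config.cardiac_params
    lat = cardiac_latents(fish, config)
    if not (16.0 < lat["t_ab"] < lat["t_peak"] < lat["t_arr"]):
        raise ConfigurationError(
            f"cardiac latents not ordered for {fish.fish_id}: {lat}")
    rng = np.random.default_rng(
        [config.seed, _S_CARDIAC, _fish_key(fish.fish_id)])
    u = p.individual_sd * rng.standard_normal() if p.individual_sd > 0 else 0.0
    y16 = p.intercept_fh_16c + p.slope_fh * np.log(fish.body_mass) + u

    t_peak_grid = float(max(round(lat["t_peak"]),
                            int(np.floor(lat["t_ab"])) + 1))
    t_arr_obs = int(max(round(lat["t_arr"]), t_peak_grid + 1))
    temps = np.arange(16.0, t_arr_obs + 1.0)
    y_clean = _cardiac_curve(temps, y16, lat["t_ab"], t_peak_grid, p)
    y = y_clean + (p.noise_sd * rng.standard_normal(len(temps))
                   if p.noise_sd > 0 else 0.0)
    fh = np.exp(y)
    flags = np.zeros(len(temps), dtype=bool)
    flags[-1] = True
    obs = pd.DataFrame({
        "temp_c": temps,
        "fhmax_bpm": fh,
        "fhmax_sd": 0.02 * fh,
        "arrhythmia_flag": flags,
    })
    series = CardiacSeries(fish.fish_id, obs)
    pre_clean = np.exp(y_clean[:-1])
    i_peak = int(np.argmax(pre_clean))
    truth = {
        **lat,
        "u_cardiac": float(u),
        "t_arr_grid": float(temps[-1]),
        "t_peak_grid": float(t_peak_grid),
        "peak_fhmax_clean": float(pre_clean[i_peak]),
    }
    return series, truth


# ------------------------------------------------- direct observation draws

def simulate_scaling_observations(
    cohort: list[FishRecord],
    slope: float,
    intercepts: dict[float, float],
    individual_sd: float,
    residual_sd: float,
    rng: np.random.Generator,
    n_obs: Optional[int] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Repeated-measures ln-response observations straight from the power law.

    One row per fish x temperature: ln_y = ln a(T) + b*ln(BM) + u_i + eps.
    When ``n_obs`` is given, a uniform random subset of that many rows is
    kept (emulating incomplete repeated measures).  Returns the data frame
    and the latent per-fish intercepts.
    """
    u = {f.fish_id: individual_sd * rng.standard_normal() for f in cohort}
    rows = []
    for f in cohort:
        for t, ln_a in intercepts.items():
            ln_y = (ln_a + slope * np.log(f.body_mass) + u[f.fish_id]
                    + residual_sd * rng.standard_normal())
            rows.append((f.fish_id, np.log(f.body_mass), t, ln_y,
                         f.origin, f.sex))
    df = pd.DataFrame(rows, columns=["fish_id", "ln_mass", "temperature",
                                     "ln_response", "origin", "sex"])
    if n_obs is not None and n_obs < len(df):
        keep = np.sort(rng.choice(len(df), size=n_obs, replace=False))
        df = df.iloc[keep].reset_index(drop=True)
    return df, u


def simulate_ventricles(cohort: list[FishRecord], config: GeneratorConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> pd.DataFrame:
    """Ventricle masses: ln(VM) = vm_intercept + vm_slope*ln(BM) + noise."""
    if rng is None:
        rng = np.random.default_rng([config.seed, _S_VM])
    rows = []
    for f in cohort:
        ln_vm = (config.vm_intercept + config.vm_slope * np.log(f.body_mass)
                 + (config.vm_sd * rng.standard_normal()
                    if config.vm_sd > 0 else 0.0))
        rows.append((f.fish_id, float(np.exp(ln_vm))))
    return pd.DataFrame(rows, columns=["fish_id", "ventricle_mass_kg"])


# -------------------------------------------------------------------- study

def generate_study(config: GeneratorConfig) -> StudyDataset:
    """Generate cohort, all respirometry traces, cardiac series, ventricle
    masses and the sidecar truth record."""
    cohort = generate_cohort(config)
    traces: dict[tuple[str, float], O2Trace] = {}
    bg_rows = []
    truth: dict = {"config_seed": config.seed, "fish": {}}
    for fish in cohort:
        ft: dict = {"body_mass_kg": fish.body_mass,
                    "u": _fish_intercept(config, fish), "traces": {}}
        for t in config.temperatures:
            trace, tr_truth = _simulate_trace_full(fish, t, config)
            traces[(fish.fish_id, t)] = trace
            ft["traces"][str(t)] = {k: v for k, v in tr_truth.items()
                                    if k != "per_cycle_mo2"}
            bg_rows.append((fish.fish_id, t,
                            tr_truth["background_slope_pre"],
                            tr_truth["background_slope_post"]))
        truth["fish"][fish.fish_id] = ft
    cardiac: dict[str, CardiacSeries] = {}
    n_cardiac = min(config.n_cardiac, len(cohort))
    cardiac_cohort = cohort[:n_cardiac]
    for fish in cardiac_cohort:
        series, c_truth = simulate_cardiac_series(fish, config)
        cardiac[fish.fish_id] = series
        truth["fish"][fish.fish_id]["cardiac"] = c_truth
    ventricles = simulate_ventricles(cardiac_cohort, config)
    truth["generating_parameters"] = {
        "true_slope": config.true_slope,
        "true_intercepts": {str(k): v for k, v in config.true_intercepts.items()},
        "rmr_slope": config.rmr_slope,
        "rmr_intercepts": {str(k): v for k, v in config.rmr_intercepts.items()},
        "vm_slope": config.vm_slope,
        "vm_intercept": config.vm_intercept,
        "cardiac": dataclasses.asdict(config.cardiac_params),
    }
    backgrounds = pd.DataFrame(
        bg_rows, columns=["fish_id", "temp_c", "pre_slope", "post_slope"])
    return StudyDataset(config, cohort, traces, backgrounds, cardiac,
                        ventricles, truth)


def write_study(study: StudyDataset, outdir) -> list[str]:
    """Write the analysis-facing CSVs plus the truth sidecar; returns the
    list of files written (relative names)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    cohort_df = pd.DataFrame(
        [(f.fish_id, f.body_mass, f.origin, f.sex) for f in study.cohort],
        columns=["fish_id", "body_mass_kg", "origin", "sex"])
    cohort_df.to_csv(out / "cohort.csv", index=False)
    written.append("cohort.csv")

    for (fid, t), trace in study.traces.items():
        name = f"trace_{fid}_{t:g}.csv"
        df = trace.samples.copy()
        df["chamber_volume_l"] = trace.chamber_volume
        df["fish_mass_kg"] = trace.fish_mass
        df.to_csv(out / name, index=False)
        written.append(name)

    study.backgrounds.to_csv(out / "background.csv", index=False)
    written.append("background.csv")

    for fid, series in study.cardiac.items():
        name = f"cardiac_{fid}.csv"
        series.observations.to_csv(out / name, index=False)
        written.append(name)

    study.ventricles.to_csv(out / "ventricles.csv", index=False)
    written.append("ventricles.csv")

    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=1)
    written.append("truth.json")
    return written
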