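"""Pipeline orchestration: simulate -> respiro -> cardiac -> scaling -> report.

Each stage reads/writes plain CSVs in the run directory so stages can also
be run individually from the CLI.  A single root seed drives every source
of randomness (the generator's substreams and the cardiac bootstrap), and
the run manifest records inputs, outputs, parameters and per-stage record
counts for one-number reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import (REF_MASS_KG, ScalingFit, fit_scaling_mixed,
                        fit_scaling_simple, scaling_fit_from_coefficients,
                        test_effects)
from .cardiac import arrhenius_transform, fit_breakpoint, read_cardiac_csv, \
    rising_limb, summarize_cardiac
from .errors import ConfigurationError, DataError, InsufficientDataError
from .respirometry import extract_mo2_series, read_trace_csv, \
    summarize_metabolism
from .synthgen import CardiacParams, GeneratorConfig, generate_study, \
    write_study
from .thermal import build_tpc_table, fick_decompose

log = logging.getLogger("allometherm")

ALL_STAGES = ("simulate", "respiro", "cardiac", "scaling", "report")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    r2_threshold: float = 0.96
    trim_start: float = 60.0
    min_duration: float = 180.0
    n_boot: int = 100
    ci_limit_c: float = 1.5
    ref_mass: float = REF_MASS_KG

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen = dict(raw.pop("generator", {}))
        if "cardiac_params" in gen:
            gen["cardiac_params"] = CardiacParams(**gen["cardiac_params"])
        for key in ("true_intercepts", "rmr_intercepts"):
            if key in gen:
                gen[key] = {float(k): float(v) for k, v in gen[key].items()}
        if "temperatures" in gen:
            gen["temperatures"] = tuple(float(t) for t in gen["temperatures"])
        if "mass_range" in gen:
            gen["mass_range"] = tuple(float(v) for v in gen["mass_range"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        seed = raw.get("seed", 0)
        gen.setdefault("seed", seed)
        try:
            config = cls(generator=GeneratorConfig(**gen), **raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        return config


# ------------------------------------------------------------------- stages

def stage_simulate(config: RunConfig, data_dir: Path) -> dict:
    study = generate_study(config.generator)
    files = write_study(study, data_dir)
    return {"files": files, "n_fish": len(study.cohort),
            "n_traces": len(study.traces), "n_cardiac": len(study.cardiac)}


def _load_cohort(data_dir: Path) -> pd.DataFrame:
    path = data_dir / "cohort.csv"
    if not path.exists():
        raise DataError(f"missing input file {path}")
    df = pd.read_csv(path)
    for col in ("fish_id", "body_mass_kg"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column '{col}'")
    return df


def stage_respiro(config: RunConfig, data_dir: Path, out_dir: Path) -> dict:
    cohort = _load_cohort(data_dir)
    bg_path = data_dir / "background.csv"
    if not bg_path.exists():
        raise DataError(f"missing input file {bg_path}")
    bg = pd.read_csv(bg_path)
    for col in ("fish_id", "temp_c", "pre_slope", "post_slope"):
        if col not in bg.columns:
            raise DataError(f"{bg_path}: missing column '{col}'")
    files, summary_rows = [], []
    for path in sorted(data_dir.glob("trace_*.csv")):
        stem = path.stem[len("trace_"):]
        fid, temp_s = stem.rsplit("_", 1)
        temp = float(temp_s)
        head = pd.read_csv(path, nrows=1)
        for col in ("chamber_volume_l", "fish_mass_kg"):
            if col not in head.columns:
                raise DataError(f"{path}: missing column '{col}'")
        trace = read_trace_csv(path, fid, temp,
                               float(head["chamber_volume_l"].iloc[0]),
                               float(head["fish_mass_kg"].iloc[0]))
        row = bg[(bg["fish_id"] == fid) & (bg["temp_c"] == temp)]
        if row.empty:
            raise DataError(f"background.csv: no entry for {fid} @ {temp} degC")
        series = extract_mo2_series(
            trace, float(row["pre_slope"].iloc[0]),
            float(row["post_slope"].iloc[0]),
            r2_threshold=config.r2_threshold,
            trim_start=config.trim_start,
            min_duration=config.min_duration)
        name = f"mo2_{fid}_{temp:g}.csv"
        series.records.to_csv(out_dir / name, index=False)
        files.append(name)
        try:
            s = summarize_metabolism(series)
        except InsufficientDataError as exc:
            log.warning("skipping summary for %s @ %s: %s", fid, temp, exc)
            continue
        summary_rows.append(dict(
            fish_id=fid, temp_c=temp, mmr=s.mmr, rmr=s.rmr, aas=s.aas,
            fas=s.fas, n_cycles=s.n_accepted_cycles,
            warnings=";".join(s.warnings)))
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "metabolic_summary.csv", index=False)
    files.append("metabolic_summary.csv")
    return {"files": files, "n_summaries": len(summary)}


def stage_cardiac(config: RunConfig, data_dir: Path, out_dir: Path) -> dict:
    rng = np.random.default_rng([config.seed, 101])
    rows = []
    for path in sorted(data_dir.glob("cardiac_*.csv")):
        fid = path.stem[len("cardiac_"):]
        series = read_cardiac_csv(path, fid)
        x, y = rising_limb(*arrhenius_transform(series))
        fit = fit_breakpoint(x, y, n_boot=config.n_boot,
                             ci_limit_c=config.ci_limit_c, rng=rng)
        s = summarize_cardiac(series, fit)
        rows.append(dict(fish_id=fid, t_ab=s.t_ab,
                         t_ab_ci_halfwidth=s.t_ab_ci_halfwidth,
                         t_ab_excluded_reason=s.t_ab_excluded_reason,
                         t_peak=s.t_peak, peak_fhmax=s.peak_fhmax,
                         t_arr=s.t_arr))
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "cardiac_summary.csv", index=False)
    return {"files": ["cardiac_summary.csv"], "n_fish": len(summary)}


def _mixed_data(summary: pd.DataFrame, cohort: pd.DataFrame,
                value_col: str) -> pd.DataFrame:
    df = summary.merge(cohort, on="fish_id")
    df = df[df[value_col] > 0]
    return pd.DataFrame({
        "fish_id": df["fish_id"],
        "ln_mass": np.log(df["body_mass_kg"]),
        "temperature": df["temp_c"],
        "ln_response": np.log(df[value_col]),
    })


def _simple_data(df: pd.DataFrame, cohort: pd.DataFrame,
                 value_col: str) -> pd.DataFrame:
    m = df.merge(cohort, on="fish_id")
    m = m[pd.to_numeric(m[value_col], errors="coerce") > 0]
    return pd.DataFrame({
        "ln_mass": np.log(m["body_mass_kg"]),
        "ln_response": np.log(m[value_col].astype(float)),
    })


def _fit_rows(fit: ScalingFit) -> list[dict]:
    rows = [dict(response=fit.response, term="slope", estimate=fit.slope,
                 se=fit.slope_se, ci_lo=fit.slope_ci[0],
                 ci_hi=fit.slope_ci[1], bic=fit.bic)]
    for t, v in fit.intercepts.items():
        rows.append(dict(response=fit.response, term=f"intercept_{t:g}",
                         estimate=v, se=fit.intercept_se.get(t, np.nan),
                         ci_lo=np.nan, ci_hi=np.nan, bic=fit.bic))
    if fit.intercept is not None:
        rows.append(dict(response=fit.response, term="intercept",
                         estimate=fit.intercept,
                         se=fit.intercept_single_se,
                         ci_lo=np.nan, ci_hi=np.nan, bic=fit.bic))
    return rows


def stage_scaling(config: RunConfig, data_dir: Path, out_dir: Path) -> dict:
    cohort = _load_cohort(data_dir)
    fit_rows, effect_rows, fitted = [], [], {}

    ms_path = out_dir / "metabolic_summary.csv"
    if ms_path.exists():
        summary = pd.read_csv(ms_path)
        for col in ("fish_id", "temp_c"):
            if col not in summary.columns:
                raise DataError(f"{ms_path}: missing column '{col}'")
        for resp in ("mmr", "rmr", "aas", "fas"):
            if resp not in summary.columns:
                continue
            data = _mixed_data(summary, cohort, resp)
            try:
                fit = fit_scaling_mixed(data, resp)
            except (DataError, InsufficientDataError) as exc:
                log.warning("scaling fit for %s failed: %s", resp, exc)
                continue
            fitted[resp] = fit
            fit_rows.extend(_fit_rows(fit))
            eff = test_effects(fit)
            for _, r in eff.terms.iterrows():
                effect_rows.append(dict(response=resp, kind="term", **r))
            for _, r in eff.contrasts.iterrows():
                effect_rows.append(dict(response=resp, kind="contrast", **r))

    # fHmax mixed fit over per-degree observations
    fh_rows = []
    for path in sorted(data_dir.glob("cardiac_*.csv")):
        fid = path.stem[len("cardiac_"):]
        series = read_cardiac_csv(path, fid)
        pre = series.pre_arrhythmia()
        fh_rows.append(pd.DataFrame({
            "fish_id": fid, "temp_c": pre["temp_c"],
            "fhmax": pre["fhmax_bpm"]}))
    if fh_rows:
        fh = pd.concat(fh_rows, ignore_index=True)
        data = _mixed_data(fh.rename(columns={"fhmax": "value"}), cohort,
                           "value")
        try:
            fit = fit_scaling_mixed(data, "fhmax")
            fitted["fhmax"] = fit
            fit_rows.extend(_fit_rows(fit))
        except (DataError, InsufficientDataError) as exc:
            log.warning("scaling fit for fhmax failed: %s", exc)

    cs_path = out_dir / "cardiac_summary.csv"
    if cs_path.exists():
        cs = pd.read_csv(cs_path)
        for resp in ("t_ab", "t_peak", "t_arr", "peak_fhmax"):
            if resp not in cs.columns:
                continue
            sub = cs[["fish_id", resp]].dropna()
            try:
                fit = fit_scaling_simple(_simple_data(sub, cohort, resp), resp)
                fitted[resp] = fit
                fit_rows.extend(_fit_rows(fit))
            except (DataError, InsufficientDataError) as exc:
                log.warning("scaling fit for %s failed: %s", resp, exc)

    vm_path = data_dir / "ventricles.csv"
    if vm_path.exists():
        vm = pd.read_csv(vm_path)
        if "ventricle_mass_kg" not in vm.columns:
            raise DataError(f"{vm_path}: missing column 'ventricle_mass_kg'")
        try:
            fit = fit_scaling_simple(
                _simple_data(vm, cohort, "ventricle_mass_kg"), "vm")
            fitted["vm"] = fit
            fit_rows.extend(_fit_rows(fit))
        except (DataError, InsufficientDataError) as exc:
            log.warning("scaling fit for vm failed: %s", exc)

    pd.DataFrame(fit_rows).to_csv(out_dir / "scaling_fits.csv", index=False)
    pd.DataFrame(effect_rows).to_csv(out_dir / "effect_tests.csv", index=False)
    return {"files": ["scaling_fits.csv", "effect_tests.csv"],
            "n_fits": len(fitted), "responses": sorted(fitted)}


def load_scaling_fits(path) -> dict[str, ScalingFit]:
    """Rebuild prediction-grade ScalingFit objects from scaling_fits.csv."""
    df = pd.read_csv(path)
    fits: dict[str, ScalingFit] = {}
    for resp, sub in df.groupby("response"):
        slope = float(sub.loc[sub["term"] == "slope", "estimate"].iloc[0])
        intercepts = {}
        for _, r in sub.iterrows():
            term = str(r["term"])
            if term.startswith("intercept_"):
                intercepts[float(term[len("intercept_"):])] = float(r["estimate"])
        fits[resp] = scaling_fit_from_coefficients(str(resp), slope, intercepts)
    return fits


def stage_report(config: RunConfig, out_dir: Path) -> dict:
    sf_path = out_dir / "scaling_fits.csv"
    if not sf_path.exists():
        raise DataError(f"missing input file {sf_path}")
    fits = load_scaling_fits(sf_path)
    mixed = {k: v for k, v in fits.items()
             if v.intercepts and k in ("mmr", "rmr", "aas", "fas")}
    cs_path = out_dir / "cardiac_summary.csv"
    cardiac = pd.read_csv(cs_path) if cs_path.exists() else None
    temps = sorted({t for f in mixed.values() for t in f.intercepts})
    means, q10s = build_tpc_table(mixed, temps, cardiac,
                                  ref_mass=config.ref_mass)
    means.to_csv(out_dir / "tpc_table.csv", index=False)
    q10s.to_csv(out_dir / "q10_table.csv", index=False)
    files = ["tpc_table.csv", "q10_table.csv"]
    if "mmr" in fits and "fhmax" in fits:
        fd = fick_decompose(fits["mmr"].slope, fits["fhmax"].slope)
        with open(out_dir / "fick.json", "w") as fh:
            json.dump(dataclasses.asdict(fd), fh, indent=1)
        files.append("fick.json")
    with open(out_dir / "run_summary.txt", "w") as fh:
        fh.write(f"allometherm {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"r2_threshold: {config.r2_threshold}\n")
        fh.write(f"min_duration_s: {config.min_duration}\n")
        fh.write(f"n_boot: {config.n_boot}\n")
        fh.write(f"ci_limit_c: {config.ci_limit_c}\n")
        fh.write(f"ref_mass_kg: {config.ref_mass}\n")
        fh.write(f"responses: {', '.join(sorted(fits))}\n")
    files.append("run_summary.txt")
    return {"files": files, "n_tpc_rows": len(means), "n_q10_rows": len(q10s)}


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in order; returns (and writes) the manifest.

    A failing stage aborts the remaining ones; the exception propagates to
    the caller (the CLI maps it to a nonzero exit status).
    """
    out = Path(config.out_dir)
    data_dir = out / "data"
    out.mkdir(parents=True, exist_ok=True)
    data_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "r2_threshold": config.r2_threshold,
            "trim_start_s": config.trim_start,
            "min_duration_s": config.min_duration,
            "n_boot": config.n_boot,
            "ci_limit_c": config.ci_limit_c,
            "ref_mass_kg": config.ref_mass,
            "generator": dataclasses.asdict(config.generator),
        },
        "stages": {},
    }
    runners = {
        "simulate": lambda: stage_simulate(config, data_dir),
        "respiro": lambda: stage_respiro(config, data_dir, out),
        "cardiac": lambda: stage_cardiac(config, data_dir, out),
        "scaling": lambda: stage_scaling(config, data_dir, out),
        "report": lambda: stage_report(config, out),
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        manifest["stages"][stage] = runners[stage]()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
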