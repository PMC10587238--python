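import numpy as np
import pandas as pd
import pytest

from allometherm import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A light study: few fish, short traces, all defaults otherwise."""
    return GeneratorConfig(n_fish=6, n_cardiac=6, n_cycles=20,
                           sample_interval_s=15.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_measure_trace(slopes_per_min, *, o2_start=8.0, dt=5.0,
                       measure_s=360.0, flush_s=60.0, chamber=2.5,
                       mass=0.5, temp=16.0, noise=None, rng=None):
    """Hand-built O2 trace with one measure phase per entry of
    ``slopes_per_min`` (mg L-1 min-1, negative = O2 decline)."""
    from allometherm.respirometry import O2Trace

    rows = []
    t = 0.0
    for ci, slope in enumerate(slopes_per_min):
        for _ in range(int(flush_s // dt)):
            rows.append((t, o2_start, "flush", ci))
            t += dt
        t_meas = 0.0
        for _ in range(int(measure_s // dt)):
            o2 = o2_start + slope * t_meas / 60.0
            if noise is not None:
                o2 += noise * rng.standard_normal()
            rows.append((t, o2, "measure", ci))
            t += dt
            t_meas += dt
    df = pd.DataFrame(rows, columns=["time_s", "o2_mg_per_l", "phase",
                                     "cycle_index"])
    return O2Trace("T01", temp, chamber, mass, df)


def make_mo2_series(values, durations=None, fish_id="T01", temp=16.0):
    """MO2Series wrapper around explicit per-cycle uptake values."""
    from allometherm.respirometry import MO2Series

    values = np.asarray(values, float)
    n = len(values)
    if durations is None:
        durations = np.full(n, 300.0)
    records = pd.DataFrame({
        "cycle_index": np.arange(n),
        "t_mid_s": np.arange(n) * 900.0 + 450.0,
        "slope": -values,
        "r2": 1.0,
        "duration_s": durations,
        "mo2": values,
        "accepted": True,
        "reason": "",
    })
    return MO2Series(fish_id, temp, records, 0.0, 0.0, 1.0)
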