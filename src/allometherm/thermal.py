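"""Thermal-sensitivity summaries: Q10, mass-normalized group means, the
Fick slope decomposition, and the combined thermal-performance table.

Q10 is the factor by which a rate changes per 10 degC,
Q10 = (R2/R1)^(10/(T2-T1)), computed from mass-normalized group means.
Group means are model-predicted values for a reference-size fish:
exp(ln a(T) + b*ln m) / m at m = 65 g.  The Fick decomposition uses the
slope arithmetic b_MR = b_Vs + b_fH on ln-ln scaling exponents: since
metabolic rate is the product of heart rate, stroke volume and blood O2
extraction, the mismatch between the metabolic and heart-rate exponents
bounds the stroke-volume exponent, b_Vs = b_MR - b_fH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .allometry import REF_MASS_KG, ScalingFit
from .errors import DomainError


@dataclass
class Q10Result:
    metric: str
    t1: float
    t2: float
    r1: float
    r2: float
    q10: float


@dataclass
class FickDecomposition:
    b_mr: float
    b_fh: float
    b_vs: float


def q10(r1: float, r2: float, t1: float, t2: float,
        metric: str = "") -> Q10Result:
    """Temperature coefficient over [t1, t2] from mean rates r1, r2."""
    if r1 <= 0 or r2 <= 0:
        raise DomainError("Q10 requires positive rates")
    if t2 <= t1:
        raise DomainError("Q10 requires T2 > T1")
    return Q10Result(metric, t1, t2, r1, r2,
                     float((r2 / r1) ** (10.0 / (t2 - t1))))


def predict_group_mean(fit: ScalingFit, temperature: float,
                       mass: float = REF_MASS_KG,
                       mass_specific: bool = True) -> float:
    """Model-predicted group mean at the given temperature for a fish of
    the given mass: exp(ln a(T) + b ln m), divided by the mass when the
    response is a whole-animal rate (``mass_specific=True``).  Ratio
    responses such as FAS keep their natural units
    (``mass_specific=False``)."""
    if mass <= 0:
        raise DomainError("mass must be > 0")
    if temperature not in fit.intercepts:
        raise DomainError(
            f"{fit.response}: no intercept fitted for {temperature} degC")
    ln_a = fit.intercepts[temperature]
    value = float(np.exp(ln_a + fit.slope * np.log(mass)))
    return value / mass if mass_specific else value


def fick_decompose(b_mr: float, b_fh: float) -> FickDecomposition:
    """Stroke-volume scaling exponent implied by metabolic and heart-rate
    exponents: b_Vs = b_MR - b_fH."""
    return FickDecomposition(b_mr, b_fh, b_mr - b_fh)


def build_tpc_table(
    fits: dict[str, ScalingFit],
    temperatures: list[float],
    cardiac_summaries: Optional[pd.DataFrame] = None,
    ref_mass: float = REF_MASS_KG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate mass-normalized group means and all pairwise interval Q10s.

    Returns ``(means, q10s)``.  ``means`` has one row per metric x
    temperature (cardiac tolerance metrics, which have no temperature
    structure, are appended as cohort means with temperature NaN);
    ``q10s`` has one row per metric per temperature pair.
    """
    ratio_metrics = {"fas"}   # dimensionless responses: no per-mass scaling
    mean_rows, q10_rows = [], []
    for metric, fit in fits.items():
        temps = [t for t in temperatures if t in fit.intercepts]
        ms = metric not in ratio_metrics
        vals = {t: predict_group_mean(fit, t, ref_mass, mass_specific=ms)
                for t in temps}
        for t in temps:
            mean_rows.append(dict(metric=metric, temp_c=t,
                                  mean_normalized=vals[t]))
        for i in range(len(temps)):
            for j in range(i + 1, len(temps)):
                t1, t2 = temps[i], temps[j]
                res = q10(vals[t1], vals[t2], t1, t2, metric)
                q10_rows.append(dict(metric=metric, t1=t1, t2=t2,
                                     q10=res.q10))
    if cardiac_summaries is not None and len(cardiac_summaries):
        for col in ("t_ab", "t_peak", "peak_fhmax", "t_arr"):
            if col in cardiac_summaries.columns:
                v = pd.to_numeric(cardiac_summaries[col], errors="coerce")
                if v.notna().any():
                    mean_rows.append(dict(metric=col, temp_c=float("nan"),
                                          mean_normalized=float(v.mean())))
    means = pd.DataFrame(mean_rows,
                         columns=["metric", "temp_c", "mean_normalized"])
    q10s = pd.DataFrame(q10_rows, columns=["metric", "t1", "t2", "q10"])
    return means, q10s
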