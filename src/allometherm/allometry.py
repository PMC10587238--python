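"""Allometric ln-ln scaling fits, model selection, effect tests and
mass-normalization.

The scaling law ln(performance) = ln a + b*ln(BM) is fitted on natural-log
axes.  Repeated-measures responses (one value per fish per acute test
temperature) use a linear mixed model with a per-individual random
intercept, temperature as a categorical fixed effect coded as absolute
per-level intercepts, and a common mass slope; estimation is maximum
likelihood so that BIC comparisons across fixed-effect structures are
valid.  One-off responses (cardiac tolerance metrics, ventricle mass) use
ordinary least squares.  Inference is large-sample: Wald chi-square tests
per term (Type II) and all-pairs temperature contrasts with a
studentized-range (Tukey) familywise adjustment.

Mass-normalization rescales a whole-animal rate measured at mass M to a
reference mass M0 along the fitted exponent and expresses it per unit
reference mass: value * (M0/M)^b / M0.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DataError, DomainError, InsufficientDataError

REF_MASS_KG = 0.065

#: residual variance below which a fixed-effect fit is treated as exact
_ZERO_RESID_TOL = 1e-12


@dataclass
class ScalingFit:
    response: str
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    intercepts: dict[float, float]          # temperature -> ln(a); {} for simple
    intercept_se: dict[float, float]
    intercept: Optional[float] = None       # single intercept (simple fits)
    intercept_single_se: Optional[float] = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    random_intercept_sd: float = float("nan")
    residual_sd: float = float("nan")
    bic: float = float("nan")
    n_individuals: int = 0
    n_observations: int = 0
    estimation: str = "ML"
    warnings: list[str] = field(default_factory=list)
    # large-sample inference state (private)
    _params: Optional[pd.Series] = None
    _cov: Optional[pd.DataFrame] = None
    _terms: dict[str, list[str]] = field(default_factory=dict)
    _df_resid: float = float("nan")


@dataclass
class ModelComparison:
    table: pd.DataFrame                     # model, bic, delta_bic, status
    selected: str
    fits: dict[str, ScalingFit]


@dataclass
class EffectTests:
    terms: pd.DataFrame                     # term, chi2, df, p
    contrasts: pd.DataFrame                 # t1, t2, estimate, se, z, p_adj


def _build_formula(include_interaction: bool,
                   covariates: Sequence[str]) -> str:
    rhs = ["0", "C(temperature)", "ln_mass"]
    if include_interaction:
        rhs.append("ln_mass:C(temperature)")
    rhs.extend(covariates)
    return "ln_response ~ " + " + ".join(rhs)


def _temp_param_name(level: float) -> str:
    return f"C(temperature)[{level}]"


def _collect_terms(param_names: Sequence[str],
                   covariates: Sequence[str]) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {"temperature": [], "ln_mass": []}
    for cov in covariates:
        terms[cov] = []
    for name in param_names:
        if ":" in name:
            terms.setdefault("ln_mass:temperature", []).append(name)
        elif name == "ln_mass":
            terms["ln_mass"].append(name)
        elif name.startswith("C(temperature)"):
            terms["temperature"].append(name)
        else:
            for cov in covariates:
                if name.startswith(cov):
                    terms[cov].append(name)
    return {k: v for k, v in terms.items() if v}


def _finalize_from_params(
    response: str,
    params: pd.Series,
    cov: pd.DataFrame,
    levels: Sequence[float],
    covariates: Sequence[str],
    *,
    random_sd: float,
    resid_sd: float,
    bic: float,
    n_ind: int,
    n_obs: int,
    df_resid: float,
    warnings: list[str],
) -> ScalingFit:
    z = stats.norm.ppf(0.975)
    slope = float(params["ln_mass"])
    slope_se = float(np.sqrt(cov.loc["ln_mass", "ln_mass"]))
    intercepts, intercept_se = {}, {}
    for lev in levels:
        name = _temp_param_name(lev)
        if name in params.index:
            intercepts[lev] = float(params[name])
            intercept_se[lev] = float(np.sqrt(cov.loc[name, name]))
    cov_effects = {n: float(params[n]) for n in params.index
                   if any(n.startswith(c) for c in covariates)}
    return ScalingFit(
        response=response,
        slope=slope,
        slope_se=slope_se,
        slope_ci=(slope - z * slope_se, slope + z * slope_se),
        intercepts=intercepts,
        intercept_se=intercept_se,
        covariate_effects=cov_effects,
        random_intercept_sd=random_sd,
        residual_sd=resid_sd,
        bic=bic,
        n_individuals=n_ind,
        n_observations=n_obs,
        warnings=warnings,
        _params=params,
        _cov=cov,
        _terms=_collect_terms(list(params.index), covariates),
        _df_resid=df_resid,
    )


def fit_scaling_mixed(
    data: pd.DataFrame,
    response_name: str = "response",
    include_interaction: bool = False,
    covariates: Sequence[str] = (),
) -> ScalingFit:
    """ML mixed-model scaling fit with per-individual random intercepts.

    ``data`` needs columns fish_id, ln_mass, temperature, ln_response
    (plus any requested covariates).  BIC uses the observation count:
    -2 llf + k ln(n_obs) with k counting fixed effects, the random
    intercept variance and the residual variance.

    Zero-residual (noiseless) data make the mixed likelihood unbounded;
    such inputs are detected via a perfect fixed-effects OLS fit and
    returned exactly, flagged ``zero_residual_degenerate``.
    """
    required = {"fish_id", "ln_mass", "temperature", "ln_response"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"scaling data: missing column(s) {sorted(missing)}")
    if not np.all(np.isfinite(data["ln_response"])):
        raise DataError("ln_response contains non-finite values "
                        "(responses must be strictly positive before logging)")
    levels = sorted(data["temperature"].unique().tolist())
    formula = _build_formula(include_interaction, covariates)
    n_obs = len(data)
    n_ind = data["fish_id"].nunique()
    warnings: list[str] = []

    ols = smf.ols(formula, data=data).fit()
    if ols.ssr / max(n_obs, 1) < _ZERO_RESID_TOL:
        warnings.append("zero_residual_degenerate")
        k = len(ols.params) + 2
        cov = pd.DataFrame(np.zeros((len(ols.params),) * 2),
                           index=ols.params.index, columns=ols.params.index)
        return _finalize_from_params(
            response_name, ols.params, cov, levels, covariates,
            random_sd=0.0, resid_sd=0.0, bic=float("-inf"),
            n_ind=n_ind, n_obs=n_obs,
            df_resid=float(ols.df_resid), warnings=warnings)

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["fish_id"])
        res = model.fit(reml=False)
    if not res.converged:
        warnings.append("not_converged")
    var_re = float(np.asarray(res.cov_re)[0, 0])
    if var_re <= 1e-10:
        warnings.append("singular_random_effect")
    k = len(res.fe_params) + 2
    bic = -2.0 * float(res.llf) + k * np.log(n_obs)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k - 2 + 0, :k - 2 + 0]
                       if False else res.cov_params())
    # restrict to fixed effects
    fe_names = list(res.fe_params.index)
    cov_fe = pd.DataFrame(res.cov_params().loc[fe_names, fe_names])
    return _finalize_from_params(
        response_name, res.fe_params, cov_fe, levels, covariates,
        random_sd=float(np.sqrt(max(var_re, 0.0))),
        resid_sd=float(np.sqrt(res.scale)),
        bic=bic, n_ind=n_ind, n_obs=n_obs,
        df_resid=float(n_obs - len(fe_names)), warnings=warnings)


def fit_scaling_simple(data: pd.DataFrame,
                       response_name: str = "response") -> ScalingFit:
    """OLS of ln_response on ln_mass for independent (one per fish) metrics."""
    required = {"ln_mass", "ln_response"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"scaling data: missing column(s) {sorted(missing)}")
    if len(data) < 3:
        raise InsufficientDataError(
            f"{response_name}: need >= 3 points, got {len(data)}")
    x = data["ln_mass"].to_numpy(float)
    if np.var(x) == 0:
        raise DataError(f"{response_name}: zero variance in ln_mass")
    res = smf.ols("ln_response ~ ln_mass", data=data).fit()
    z = stats.norm.ppf(0.975)
    slope = float(res.params["ln_mass"])
    se = float(res.bse["ln_mass"])
    fit = ScalingFit(
        response=response_name,
        slope=slope,
        slope_se=se,
        slope_ci=(slope - z * se, slope + z * se),
        intercepts={},
        intercept_se={},
        intercept=float(res.params["Intercept"]),
        intercept_single_se=float(res.bse["Intercept"]),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        bic=float(res.bic),
        n_individuals=len(data),
        n_observations=len(data),
        _params=res.params,
        _cov=pd.DataFrame(res.cov_params()),
        _terms={"ln_mass": ["ln_mass"]},
        _df_resid=float(res.df_resid),
    )
    return fit


def compare_models_bic(
    data: pd.DataFrame,
    candidates: Sequence[dict],
    response_name: str = "response",
) -> ModelComparison:
    """Fit every candidate structure by ML on the same data; lowest BIC wins.

    Each candidate is a dict with keys ``name``, ``interaction`` (bool) and
    ``covariates`` (sequence).  Ties are broken by candidate order; failed
    fits are recorded as non-candidates with the failure reason.
    """
    if len(candidates) < 2:
        raise DataError("compare_models_bic needs >= 2 candidates")
    rows, fits = [], {}
    for cand in candidates:
        name = cand["name"]
        try:
            fit = fit_scaling_mixed(
                data, response_name,
                include_interaction=bool(cand.get("interaction", False)),
                covariates=tuple(cand.get("covariates", ())))
            fits[name] = fit
            rows.append(dict(model=name, bic=fit.bic, status="ok"))
        except Exception as exc:  # noqa: BLE001 - recorded, not raised
            rows.append(dict(model=name, bic=np.nan,
                             status=f"failed: {exc}"))
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise DataError("no candidate model converged")
    best_bic = ok["bic"].min()
    # first candidate attaining the minimum wins
    selected = str(ok.loc[ok["bic"] == best_bic, "model"].iloc[0])
    table["delta_bic"] = (table["bic"] - best_bic).round(1)
    return ModelComparison(table, selected, fits)


def _wald_chi2(params: pd.Series, cov: pd.DataFrame,
               L: np.ndarray) -> tuple[float, int, float]:
    est = L @ params.to_numpy(float)
    V = L @ cov.to_numpy(float) @ L.T
    df = L.shape[0]
    if np.allclose(est, 0.0, atol=1e-10):
        return 0.0, df, 1.0
    try:
        stat = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError:
        stat = float(est @ np.linalg.pinv(V) @ est)
    if not np.isfinite(stat) or stat < 0:
        stat = float("inf")
    return stat, df, float(stats.chi2.sf(stat, df))


def test_effects(fit: ScalingFit) -> EffectTests:
    """Type II Wald chi-square per fixed term plus Tukey-adjusted all-pairs
    temperature contrasts on the per-level intercepts."""
    if fit._params is None or fit._cov is None:
        raise DataError("fit carries no inference state")
    params, cov = fit._params, fit._cov
    names = list(params.index)
    idx = {n: i for i, n in enumerate(names)}
    term_rows = []
    for term, members in fit._terms.items():
        if term == "temperature" and len(members) > 1:
            # equality of absolute per-level intercepts: k-1 differences
            L = np.zeros((len(members) - 1, len(names)))
            for r, m in enumerate(members[1:]):
                L[r, idx[members[0]]] = -1.0
                L[r, idx[m]] = 1.0
        else:
            L = np.zeros((len(members), len(names)))
            for r, m in enumerate(members):
                L[r, idx[m]] = 1.0
        chi2, df, p = _wald_chi2(params, cov, L)
        term_rows.append(dict(term=term, chi2=chi2, df=df, p=p))

    contrast_rows = []
    temps = sorted(fit.intercepts)
    k = len(temps)
    dfres = fit._df_resid if np.isfinite(fit._df_resid) else 1e6
    for i in range(k):
        for j in range(i + 1, k):
            a, b = _temp_param_name(temps[i]), _temp_param_name(temps[j])
            est = float(params[b] - params[a])
            var = float(cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b])
            se = float(np.sqrt(max(var, 0.0)))
            if se == 0.0:
                zval = 0.0 if abs(est) < 1e-10 else float("inf")
            else:
                zval = est / se
            if np.isinf(zval):
                p_adj = 0.0
            elif zval == 0.0 and se == 0.0:
                p_adj = 1.0
            else:
                p_adj = float(stats.studentized_range.sf(
                    abs(zval) * np.sqrt(2.0), k, max(dfres, 2.0)))
            contrast_rows.append(dict(t1=temps[i], t2=temps[j], estimate=est,
                                      se=se, z=zval, p_adj=p_adj))
    return EffectTests(pd.DataFrame(term_rows), pd.DataFrame(contrast_rows))


def mass_normalize(value: float, mass: float, b: float,
                   ref_mass: float = REF_MASS_KG) -> float:
    """Rescale a whole-animal rate to the reference mass along exponent b
    and express it per unit reference mass (mass-specific)."""
    if value <= 0 or mass <= 0 or ref_mass <= 0:
        raise DomainError("value, mass and ref_mass must be > 0")
    return value * (ref_mass / mass) ** b / ref_mass


def scaling_fit_from_coefficients(response: str, slope: float,
                                  intercepts: dict[float, float]
                                  ) -> ScalingFit:
    """Build a ScalingFit directly from published/known coefficients
    (slope b and per-temperature ln-intercepts), e.g. for prediction."""
    return ScalingFit(response=response, slope=slope, slope_se=float("nan"),
                      slope_ci=(float("nan"), float("nan")),
                      intercepts=dict(intercepts),
                      intercept_se={t: float("nan") for t in intercepts})
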