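"""Habitat-selection mixed models: VIF screening, random-intercept LMMs,
reductive AIC selection, and marginal/conditional R².

The model is a linear mixed model of log residency time on habitat
covariates with a random intercept per bird.  Following common practice
for variance-components reporting, marginal R² is the variance explained
by the fixed effects alone and conditional R² by fixed plus random
effects:

    R²m = var(Xβ) / (var(Xβ) + σ²_bird + σ²_resid)
    R²c = (var(Xβ) + σ²_bird) / (var(Xβ) + σ²_bird + σ²_resid)

AIC is computed from the fitted log-likelihood with
k = (#fixed effects) + 2 variance parameters.  REML is the default, as
is conventional for variance estimation; note that REML likelihoods are
not strictly comparable across different fixed-effect sets, so an
ML-based selection mode (``reml=False``) is provided.

The temporal-autocorrelation option (``ar1=True``) approximates a
continuous-time AR(1) residual on the regular daily grid by a two-stage
procedure: estimate the within-bird lag-1 residual autocorrelation from
an initial fit, pre-whiten response and design within bird, and refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["FULL_TERMS", "ModelResult", "vif", "fit_mixed_model",
           "fit_region_models"]

#: the full candidate term set of the habitat-selection model
FULL_TERMS = ("sst", "depth", "sqrt_d2eddy", "sqrt_slope", "eke", "ssh",
              "d2hill", "wind", "log_chla")


def vif(design: pd.DataFrame, covariates=None) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 - R²_k).

    R²_k comes from regressing covariate k on the remaining covariates
    (with intercept).  Perfectly collinear columns report ``inf``.  The
    conventional retention screen flags VIF >= 3 but nothing is dropped
    here.
    """
    if covariates is None:
        covariates = [c for c in design.columns
                      if pd.api.types.is_numeric_dtype(design[c])]
    if len(covariates) < 2:
        raise ValueError("vif requires at least 2 covariates")
    X = design[list(covariates)].dropna()
    out = {}
    for k in covariates:
        if X[k].nunique() <= 1:
            raise ValueError(f"covariate '{k}' is constant")
        others = sm.add_constant(X[[c for c in covariates if c != k]])
        r2 = sm.OLS(X[k], others).fit().rsquared
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class ModelResult:
    """One fitted random-intercept model."""

    region: str
    terms: tuple
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    var_random: float
    var_residual: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    converged: bool
    reml: bool
    ar1_rho: float | None = None

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "terms": list(self.terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "var_random_intercept": float(self.var_random),
            "var_residual": float(self.var_residual),
            "aic": float(self.aic),
            "df": int(len(self.params) + 2),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "n_obs": int(self.n_obs),
            "n_birds": int(self.n_groups),
            "converged": bool(self.converged),
            "reml": bool(self.reml),
            "ar1_rho": None if self.ar1_rho is None else float(self.ar1_rho),
        }


def _prewhiten(df, terms, response, group, rho) -> tuple[pd.DataFrame, str]:
    """AR(1) pre-whitening of response and design within each bird."""
    cols = [response] + list(terms)
    parts = []
    for _, g in df.groupby(group, sort=True):
        g = g.sort_values("date") if "date" in g.columns else g
        vals = g[cols].to_numpy(dtype=float)
        white = vals.copy()
        white[0] = vals[0] * np.sqrt(1.0 - rho * rho)
        white[1:] = vals[1:] - rho * vals[:-1]
        w = g.copy()
        w[cols] = white
        parts.append(w)
    return pd.concat(parts), response


def fit_mixed_model(df: pd.DataFrame, terms, response: str = "log_residency",
                    group: str = "bird_id", reml: bool = True, ar1: bool = False,
                    region: str = "all") -> ModelResult:
    """Fit a random-intercept-per-bird linear mixed model.

    ``terms`` may be empty (intercept-only; marginal R² is then 0).
    Missing rows are dropped listwise.  Raises on singular design or
    non-convergence.
    """
    terms = tuple(terms)
    cols = [response, group] + list(terms) + (["date"] if "date" in df.columns else [])
    data = df[cols].dropna()
    if data[group].nunique() < 2:
        raise ValueError(f"region {region}: need >= 2 birds, got {data[group].nunique()}")

    rho = None
    if ar1:
        base = fit_mixed_model(df, terms, response=response, group=group,
                               reml=reml, ar1=False, region=region)
        rho = _estimate_rho(data, base, terms, response, group)
        data, response = _prewhiten(data, terms, response, group, rho)

    endog = data[response].to_numpy(dtype=float)
    exog = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    model = sm.MixedLM(endog, exog, groups=data[group])
    # lbfgs is fastest but can fail on the cov_re = 0 boundary, where the
    # profiled log-likelihood turns singular or spuriously infinite;
    # powell/nm are derivative-free and stay interior
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if cand.converged and np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        raise RuntimeError(f"region {region}: singular or non-convergent "
                           f"mixed-model fit (terms={list(terms)})")

    k = len(res.fe_params) + 2  # fixed effects + random-intercept var + resid var
    aic = -2.0 * res.llf + 2.0 * k
    var_f = float(np.var(np.asarray(exog @ res.fe_params, dtype=float)))
    var_re = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    total = var_f + var_re + var_resid
    try:
        bse = pd.Series(np.asarray(res.bse_fe), index=res.fe_params.index)
        ci = np.asarray(res.conf_int())[:len(res.fe_params)]
    except (np.linalg.LinAlgError, ValueError):  # singular hessian at boundary
        bse = pd.Series(np.nan, index=res.fe_params.index)
        ci = np.full((len(res.fe_params), 2), np.nan)
    return ModelResult(
        region=region, terms=terms,
        params=res.fe_params, bse=bse,
        conf_int=pd.DataFrame(ci, index=res.fe_params.index, columns=["lo", "hi"]),
        var_random=var_re, var_residual=var_resid, aic=aic,
        r2_marginal=var_f / total, r2_conditional=(var_f + var_re) / total,
        n_obs=len(data), n_groups=data[group].nunique(),
        converged=bool(res.converged), reml=reml, ar1_rho=rho,
    )


def _estimate_rho(data, base: ModelResult, terms, response, group) -> float:
    """Within-bird lag-1 autocorrelation of residuals (consecutive days only)."""
    X = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    resid = data[response].to_numpy(dtype=float) - np.asarray(X @ base.params)
    num = den = 0.0
    for _, g in data.assign(_r=resid).groupby(group, sort=True):
        g = g.sort_values("date") if "date" in g.columns else g
        r = g["_r"].to_numpy()
        if "date" in g.columns:
            ok = np.diff(pd.DatetimeIndex(g["date"]).values
                         ).astype("timedelta64[D]").astype(int) == 1
        else:
            ok = np.ones(len(r) - 1, dtype=bool)
        num += float((r[:-1][ok] * r[1:][ok]).sum())
        den += float((r[:-1][ok] ** 2).sum())
    return 0.0 if den == 0 else float(np.clip(num / den, -0.95, 0.95))


def fit_region_models(samples: pd.DataFrame, terms=FULL_TERMS,
                      region_col: str = "region", response: str = "log_residency",
                      group: str = "bird_id", reml: bool = True, ar1: bool = False,
                      min_birds: int = 2, min_obs_per_term: int = 10,
                      exclude_regions=("outside",)) -> dict:
    """Per-region reductive-AIC model selection.

    For each region: fit the full model, then backward-eliminate — at
    each step drop the single term whose removal most lowers AIC, until
    no removal lowers it.  Regions with too few birds or observations are
    skipped with a warning.  Returns
    ``{region: {"full": ModelResult, "best": ModelResult, "trace": [...]}}``.
    """
    results = {}
    for region, df in samples.groupby(region_col, sort=True):
        if region in exclude_regions:
            continue
        data = df.dropna(subset=[response] + list(terms))
        if data[group].nunique() < min_birds:
            warnings.warn(f"region {region}: only {data[group].nunique()} birds; "
                          "skipped", stacklevel=2)
            continue
        if len(data) < min_obs_per_term * (len(terms) + 1):
            warnings.warn(f"region {region}: {len(data)} observations is too few "
                          f"for {len(terms)} candidate terms; skipped", stacklevel=2)
            continue
        try:
            full = fit_mixed_model(data, terms, response=response, group=group,
                                   reml=reml, ar1=ar1, region=str(region))
        except RuntimeError as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        current = full
        trace = [(list(full.terms), full.aic)]
        while current.terms:
            candidates = []
            for drop in current.terms:
                reduced = tuple(t for t in current.terms if t != drop)
                try:
                    cand = fit_mixed_model(data, reduced, response=response,
                                           group=group, reml=reml, ar1=ar1,
                                           region=str(region))
                except (RuntimeError, ValueError, np.linalg.LinAlgError):
                    continue
                candidates.append(cand)
            if not candidates:
                break
            best_cand = min(candidates, key=lambda m: m.aic)
            if best_cand.aic < current.aic:
                current = best_cand
                trace.append((list(current.terms), current.aic))
            else:
                break
        results[str(region)] = {"full": full, "best": current, "trace": trace}
    return results
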