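"""Interannual analysis of per-individual-year selection coefficients.

Every analysis is a linear mixed model with a random intercept per animal
(eartag), since the same individuals are tracked across 2–7 years: year
effects with Tukey-style all-pairs contrasts, regressions of a coefficient
on previous-year ANPP or growing-season temperature, lactation-status
contrasts (with optional status × climate interactions), and the
protein-vs-biomass selection relationship. All analyses are deterministic
given the input table.

Denominator degrees of freedom use a containment-style approximation
(n − rank(X) − (g − 1)); the Tukey adjustment is the Tukey–Kramer
studentized-range method on the mixed-model fixed-effect contrasts.
Significance is assessed at p < .05 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

ALPHA = 0.05


def _fit_mixedlm(formula: str, table: pd.DataFrame, groups: pd.Series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, table, groups=groups)
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True, method="powell")
    return fit


def _containment_df(n_obs: int, rank_x: int, n_groups: int) -> int:
    return max(n_obs - rank_x - (n_groups - 1), 1)


@dataclass
class YearEffectSummary:
    coefficient: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    random_intercept_var: float
    year_means: dict[int, float]
    model_fit: object = field(repr=False, default=None)
    table: pd.DataFrame = field(repr=False, default=None)


def lme_year_effect(table: pd.DataFrame, coefficient: str) -> YearEffectSummary:
    """Mixed-model F-test for among-year differences in one selection
    coefficient (fixed: year as categorical; random intercept: eartag)."""
    _require(table, [coefficient, "year", "eartag"])
    years = sorted(table["year"].unique())
    if len(years) < 2:
        raise ValueError("at least two years are required for a year effect")
    if table["eartag"].nunique() < 2:
        raise ValueError("at least two individuals are required")
    fit = _fit_mixedlm(f"{coefficient} ~ C(year)", table, table["eartag"])
    names = list(fit.fe_params.index)
    year_idx = [i for i, nm in enumerate(names) if nm.startswith("C(year)")]
    q = len(year_idx)
    L = np.zeros((q, len(names)))
    for r, i in enumerate(year_idx):
        L[r, i] = 1.0
    b = fit.fe_params.to_numpy()
    V = fit.cov_params().iloc[: len(names), : len(names)].to_numpy()
    Lb = L @ b
    LVL = L @ V @ L.T
    if not np.isfinite(LVL).all() or np.allclose(Lb, 0, atol=1e-10):
        f_stat = 0.0  # degenerate (constant response): no year effect
    else:
        f_stat = float(Lb @ np.linalg.solve(LVL, Lb) / q)
    df_den = _containment_df(len(table), len(names), table["eartag"].nunique())
    p = float(stats.f.sf(f_stat, q, df_den))
    means = table.groupby("year")[coefficient].mean().to_dict()
    re_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    return YearEffectSummary(
        coefficient=coefficient,
        f_statistic=f_stat,
        df_num=q,
        df_den=df_den,
        p_value=p,
        random_intercept_var=re_var,
        year_means={int(k): float(v) for k, v in means.items()},
        model_fit=fit,
        table=table,
    )


def tukey_years(summary: YearEffectSummary) -> pd.DataFrame:
    """All pairwise year contrasts with Tukey–Kramer family-wise adjusted p.

    Returns one row per year pair: estimate, SE, unadjusted p (t), adjusted
    p (studentized range with k = number of years).
    """
    if summary.model_fit is None:
        raise ValueError("year-effect model has not been fitted")
    fit = summary.model_fit
    table = summary.table
    years = sorted(table["year"].unique())
    k = len(years)
    names = list(fit.fe_params.index)
    b = fit.fe_params.to_numpy()
    V = fit.cov_params().iloc[: len(names), : len(names)].to_numpy()

    def year_vec(y) -> np.ndarray:
        v = np.zeros(len(names))
        v[0] = 1.0
        nm = f"C(year)[T.{y}]"
        if nm in names:
            v[names.index(nm)] = 1.0
        return v

    rows = []
    df_den = summary.df_den
    for y1, y2 in combinations(years, 2):
        c = year_vec(y2) - year_vec(y1)
        diff = float(c @ b)
        se = float(np.sqrt(c @ V @ c))
        if not np.isfinite(se) or se == 0:
            # degenerate fit (e.g. constant response): no evidence of a difference
            tval = 0.0 if abs(diff) < 1e-10 else np.inf
            se = 0.0
        else:
            tval = abs(diff) / se
        p_unadj = float(2 * stats.t.sf(tval, df_den)) if np.isfinite(tval) else 0.0
        q = tval * np.sqrt(2.0)
        p_adj = float(stats.studentized_range.sf(q, k, df_den)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "year_a": y1,
                "year_b": y2,
                "estimate": diff,
                "se": se,
                "p_unadjusted": min(p_unadj, 1.0),
                "p_adjusted": min(p_adj, 1.0),
                "significant": p_adj < ALPHA,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SlopeSummary:
    coefficient: str
    predictor: str
    slope: float
    se: float
    t_statistic: float
    df: int
    p_value: float


def regress_on_climate(
    table: pd.DataFrame,
    climate: pd.DataFrame,
    coefficient: str,
    predictor: str,
) -> SlopeSummary:
    """Mixed-model regression of a selection coefficient on one annual
    climate covariate (previous-year ANPP, 0.1 g/m², or growing-season
    temperature, °C), joined by year; eartag random intercept."""
    if predictor not in {"prev_anpp", "gs_temp"}:
        raise ValueError("predictor must be 'prev_anpp' or 'gs_temp'")
    _require(table, [coefficient, "year", "eartag"])
    _require(climate, ["year", predictor])
    missing = sorted(set(table["year"]) - set(climate["year"]))
    if missing:
        raise ValueError(f"climate table is missing year(s): {missing}")
    merged = table.merge(climate[["year", predictor]], on="year", how="left")
    if merged[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor} is constant; slope is not identifiable")
    fit = _fit_mixedlm(f"{coefficient} ~ {predictor}", merged, merged["eartag"])
    slope = float(fit.fe_params[predictor])
    se = float(fit.bse_fe[predictor])
    df = _containment_df(len(merged), 2, merged["eartag"].nunique())
    t = slope / se if se > 0 else np.inf
    return SlopeSummary(
        coefficient=coefficient,
        predictor=predictor,
        slope=slope,
        se=se,
        t_statistic=float(t),
        df=df,
        p_value=float(2 * stats.t.sf(abs(t), df)),
    )


@dataclass
class StatusContrast:
    coefficient: str
    difference: float          # lactating − non-lactating
    se: float
    p_value: float
    interactions: dict[str, float] = field(default_factory=dict)  # term → p


def status_contrast(
    table: pd.DataFrame,
    coefficient: str,
    climate: pd.DataFrame | None = None,
) -> StatusContrast:
    """Lactating vs non-lactating contrast for one selection coefficient,
    optionally testing status × climate interactions.

    ``lactating`` must be a 0/1 (or boolean) column; both statuses must be
    present."""
    _require(table, [coefficient, "eartag", "lactating"])
    status = table["lactating"].astype(int)
    if status.nunique() < 2:
        raise ValueError("both lactation statuses must be present")
    tbl = table.copy()
    tbl["lactating"] = status
    fit = _fit_mixedlm(f"{coefficient} ~ lactating", tbl, tbl["eartag"])
    diff = float(fit.fe_params["lactating"])
    se = float(fit.bse_fe["lactating"])
    df = _containment_df(len(tbl), 2, tbl["eartag"].nunique())
    t = diff / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df))
    interactions: dict[str, float] = {}
    if climate is not None:
        merged = tbl.merge(climate, on="year", how="left")
        for pred in ("prev_anpp", "gs_temp"):
            if pred not in merged.columns:
                continue
            f2 = _fit_mixedlm(f"{coefficient} ~ lactating * {pred}", merged, merged["eartag"])
            term = f"lactating:{pred}"
            ti = float(f2.fe_params[term] / f2.bse_fe[term])
            dfi = _containment_df(len(merged), 4, merged["eartag"].nunique())
            interactions[term] = float(2 * stats.t.sf(abs(ti), dfi))
    return StatusContrast(coefficient=coefficient, difference=diff, se=se, p_value=p, interactions=interactions)


def coefficient_correlation(
    table: pd.DataFrame,
    coef_x: str = "beta_biomass",
    coef_y: str = "beta_protein",
) -> SlopeSummary:
    """Slope of one selection coefficient on another (default: protein
    selection on biomass selection) with eartag random intercept.

    With a single individual the random intercept is inestimable and the
    model reduces to ordinary least squares.
    """
    _require(table, [coef_x, coef_y, "eartag"])
    if len(table) < 4:
        raise ValueError("at least 4 rows are required")
    if table["eartag"].nunique() < 2:
        res = smf.ols(f"{coef_y} ~ {coef_x}", table).fit()
        slope = float(res.params[coef_x])
        se = float(res.bse[coef_x])
        df = int(res.df_resid)
    else:
        fit = _fit_mixedlm(f"{coef_y} ~ {coef_x}", table, table["eartag"])
        slope = float(fit.fe_params[coef_x])
        se = float(fit.bse_fe[coef_x])
        df = _containment_df(len(table), 2, table["eartag"].nunique())
    t = slope / se if se > 0 else np.inf
    return SlopeSummary(
        coefficient=coef_y,
        predictor=coef_x,
        slope=slope,
        se=se,
        t_statistic=float(t),
        df=df,
        p_value=float(2 * stats.t.sf(abs(t), df)),
    )


def _require(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
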