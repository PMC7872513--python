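"""Determinant-indicator association models.

All associations are linear models with standardized betas (both the outcome
and the determinant z-scored; covariates entered raw).  Covariate rules:
sex is always a covariate, except when sex itself is the determinant — then
sex is the *outcome* of the model; the telomere indicator additionally gets
chronological age as covariate because, unlike the clock residuals, it is not
independent of age by construction.  Inference uses the t distribution with
residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DETERMINANTS, INDICATORS, InputError

__all__ = [
    "AssociationResult",
    "associate",
    "associate_all",
    "association_stats",
    "partial_spearman_matrix",
    "interaction_model",
    "longitudinal_onset",
]


@dataclass
class AssociationResult:
    indicator: str
    determinant: str
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()
    variant: str = "main"  # main | interaction | longitudinal
    beta_std: float | None = None  # fully standardized beta (longitudinal models)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise InputError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _ols_term(y: np.ndarray, X: np.ndarray, term: int):
    """OLS of y on X; returns (beta, se, t, df) for column ``term``."""
    n, k = X.shape
    df = n - k
    if df < 1:
        raise InputError(f"too few observations (n={n}) for {k} parameters")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = (resid @ resid) / df
    se = np.sqrt(max(sigma2 * XtX_inv[term, term], 0.0))
    t = beta[term] / se if se > 0 else np.inf * np.sign(beta[term])
    return float(beta[term]), float(se), float(t), df


def _p_from_t(t: float, df: int) -> float:
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def _complete_cases(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        ok &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return ok


def associate(
    indicator_values,
    determinant_values,
    covariates: pd.DataFrame | np.ndarray | None = None,
    indicator_name: str = "indicator",
    determinant_name: str = "determinant",
) -> AssociationResult:
    """Standardized-beta linear model of one indicator on one determinant.

    Complete cases only; outcome and determinant are z-scored, covariates
    entered raw.  With no covariates the beta equals the Pearson correlation.
    """
    y = np.asarray(indicator_values, dtype=float)
    x = np.asarray(determinant_values, dtype=float)
    cov_names: tuple[str, ...] = ()
    C = None
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            cov_names = tuple(covariates.columns)
            C = covariates.to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cov_names = tuple(f"cov{i}" for i in range(C.shape[1]))
    ok = _complete_cases(y, x, C)
    y, x = y[ok], x[ok]
    if C is not None:
        C = C[ok]
    if x.std(ddof=1) == 0:
        raise InputError(
            f"determinant {determinant_name!r} is constant after complete-case filtering"
        )
    design = [np.ones(len(y)), _zscore(x)]
    if C is not None:
        design.extend(C.T)
    X = np.column_stack(design)
    beta, se, t, df = _ols_term(_zscore(y), X, term=1)
    return AssociationResult(
        indicator=indicator_name,
        determinant=determinant_name,
        beta=beta,
        se=se,
        p=_p_from_t(t, df),
        n=len(y),
        covariates=cov_names,
    )


def _covariates_for(
    indicator: str, determinant: str, cohort: pd.DataFrame
) -> pd.DataFrame | None:
    """The covariate rule: sex always (unless sex is the determinant), age
    additionally for the telomere indicator."""
    cols = []
    if determinant != "sex":
        cols.append("sex")
    if indicator == "telomere":
        cols.append("age")
    return cohort[cols] if cols else None


def _model_arrays(
    ind: np.ndarray, det: np.ndarray, cov: np.ndarray | None, swap: bool
):
    """Assemble (outcome, design) for one model; swap puts the determinant
    (sex) on the outcome side."""
    ok = _complete_cases(ind, det, cov)
    y_raw = det[ok] if swap else ind[ok]
    x_raw = ind[ok] if swap else det[ok]
    if x_raw.std(ddof=1) == 0 or y_raw.std(ddof=1) == 0:
        raise InputError("constant variable after complete-case filtering")
    design = [np.ones(ok.sum()), _zscore(x_raw)]
    if cov is not None:
        design.extend(cov[ok].T)
    return _zscore(y_raw), np.column_stack(design)


def association_stats(
    indicators: pd.DataFrame,
    cohort: pd.DataFrame,
    determinants=DETERMINANTS,
    on_constant: str = "raise",
):
    """Vectorized core: betas/SEs/t/df for every (determinant, indicator) pair.

    Returns four arrays of shape (len(determinants), n_indicators) plus the
    per-cell n.  Used by both the public association table and the
    permutation loop (p-values are computed from t in one vectorized call).
    ``on_constant="null"`` records a degenerate cell (variable constant after
    complete-case filtering, e.g. a rare disease flag restricted to a small
    permuted subset) as a null result (t=0) instead of raising.
    """
    det_list = list(determinants)
    ind_list = list(indicators.columns)
    shape = (len(det_list), len(ind_list))
    beta = np.full(shape, np.nan)
    se = np.full(shape, np.nan)
    tstat = np.full(shape, np.nan)
    dof = np.zeros(shape, dtype=int)
    nobs = np.zeros(shape, dtype=int)
    ind_arr = {c: indicators[c].to_numpy(dtype=float) for c in ind_list}
    det_arr = {c: cohort[c].to_numpy(dtype=float) for c in det_list}
    sex = cohort["sex"].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    for i, det in enumerate(det_list):
        for j, ind in enumerate(ind_list):
            cov_cols = []
            if det != "sex":
                cov_cols.append(sex)
            if ind == "telomere":
                cov_cols.append(age)
            cov = np.column_stack(cov_cols) if cov_cols else None
            try:
                y, X = _model_arrays(ind_arr[ind], det_arr[det], cov, swap=det == "sex")
            except InputError:
                if on_constant == "raise":
                    raise
                beta[i, j], se[i, j], tstat[i, j] = 0.0, np.nan, 0.0
                dof[i, j] = 1
                continue
            b, s, t, df = _ols_term(y, X, term=1)
            beta[i, j], se[i, j], tstat[i, j], dof[i, j] = b, s, t, df
            nobs[i, j] = X.shape[0]
    return beta, se, tstat, dof, nobs


def associate_all(
    indicators: pd.DataFrame,
    cohort: pd.DataFrame,
    determinants=DETERMINANTS,
) -> pd.DataFrame:
    """Full association table: one row per (determinant, indicator) pair.

    ``indicators`` columns are the five layer indicators plus any composite
    columns, aligned on the cohort index.  Rows follow the determinant order,
    then the indicator column order (deterministic).
    """
    det_list = list(determinants)
    if not det_list:
        raise InputError("determinant panel is empty")
    missing = [d for d in det_list if d not in cohort.columns]
    if missing:
        raise InputError(f"determinants not in cohort table: {missing}")
    indicators = indicators.reindex(cohort.index)
    beta, se, tstat, dof, nobs = association_stats(indicators, cohort, det_list)
    p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(dof, 1))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    rows = []
    for i, det in enumerate(det_list):
        for j, ind in enumerate(indicators.columns):
            rows.append(
                {
                    "indicator": ind,
                    "determinant": det,
                    "beta": beta[i, j],
                    "se": se[i, j],
                    "p": p[i, j],
                    "n": nobs[i, j],
                }
            )
    return pd.DataFrame(rows)


def partial_spearman_matrix(
    indicators: pd.DataFrame, sex: pd.Series | np.ndarray, min_overlap: int = 10
):
    """Sex-adjusted Spearman correlations between indicator pairs.

    For each pair: rank-transform both indicators on their pairwise-complete
    subjects, residualize both rank vectors on sex (with intercept), Pearson
    correlation of the residuals.  Entries with fewer than ``min_overlap``
    complete pairs are set to NaN.  Returns (correlation, p-value) DataFrames.
    """
    import warnings as _warnings

    cols = list(indicators.columns)
    sex = np.asarray(sex, dtype=float)
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.nan, index=cols, columns=cols)
    for a_i in range(len(cols)):
        for b_i in range(a_i + 1, len(cols)):
            a, b = cols[a_i], cols[b_i]
            x = indicators[a].to_numpy(dtype=float)
            y = indicators[b].to_numpy(dtype=float)
            ok = _complete_cases(x, y, sex)
            if ok.sum() < min_overlap:
                _warnings.warn(
                    f"pair ({a}, {b}): only {int(ok.sum())} complete subjects; "
                    "correlation set to missing",
                    stacklevel=2,
                )
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                continue
            rx = stats.rankdata(x[ok])
            ry = stats.rankdata(y[ok])
            Z = np.column_stack([np.ones(ok.sum()), sex[ok]])
            coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
            coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
            ex = rx - Z @ coef_x
            ey = ry - Z @ coef_y
            r = float(np.corrcoef(ex, ey)[0, 1])
            n = int(ok.sum())
            adj = 1 if np.std(sex[ok]) > 0 else 0
            df = n - 2 - adj
            if abs(r) >= 1.0:
                p = np.nextafter(0, 1)
            else:
                t = r * np.sqrt(df / (1 - r * r))
                p = _p_from_t(t, df)
            corr.loc[a, b] = corr.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return corr, pval


def interaction_model(
    indicator_values,
    determinant_values,
    moderator,
    cohort: pd.DataFrame,
    indicator_name: str = "indicator",
    determinant_name: str = "determinant",
) -> AssociationResult:
    """Moderation model: indicator ~ determinant * moderator + covariates.

    The moderator must be binary with both levels present; the reported beta
    is the interaction coefficient on the scaled determinant.
    """
    y = np.asarray(indicator_values, dtype=float)
    x = np.asarray(determinant_values, dtype=float)
    m = np.asarray(moderator, dtype=float)
    cov = _covariates_for(indicator_name, determinant_name, cohort)
    C = cov.to_numpy(dtype=float) if cov is not None else None
    ok = _complete_cases(y, x, m, C)
    y, x, m = y[ok], x[ok], m[ok]
    if C is not None:
        C = C[ok]
    if not set(np.unique(m)) <= {0.0, 1.0}:
        raise InputError("moderator must be binary 0/1")
    if len(np.unique(m)) < 2:
        raise InputError("moderator is constant; both levels required")
    xz = _zscore(x)
    design = [np.ones(len(y)), xz, m, xz * m]
    if C is not None:
        design.extend(C.T)
    X = np.column_stack(design)
    beta, se, t, df = _ols_term(_zscore(y), X, term=3)
    return AssociationResult(
        indicator=indicator_name,
        determinant=f"{determinant_name}:moderator",
        beta=beta,
        se=se,
        p=_p_from_t(t, df),
        n=len(y),
        covariates=tuple(cov.columns) if cov is not None else (),
        variant="interaction",
    )


def longitudinal_onset(
    indicator_values,
    outcome,
    sex,
    indicator_name: str = "indicator",
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Linear probability model of a binary follow-up outcome on an indicator.

    The indicator is z-scored so ``beta`` is the change in outcome probability
    per SD; ``beta_std`` is the fully standardized coefficient (outcome also
    z-scored).  Subjects with the disease at baseline must be excluded by the
    caller for onset outcomes.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(indicator_values, dtype=float)
    s = np.asarray(sex, dtype=float)
    ok = _complete_cases(y, x, s)
    y, x, s = y[ok], x[ok], s[ok]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InputError("outcome must be binary 0/1")
    if y.sum() == 0:
        raise InputError(f"no events for outcome {outcome_name!r}")
    design = [np.ones(len(y)), _zscore(x)]
    if s.std(ddof=1) > 0:
        design.append(s)
    X = np.column_stack(design)
    beta, se, t, df = _ols_term(y, X, term=1)
    beta_std, *_ = _ols_term(_zscore(y), X, term=1)
    return AssociationResult(
        indicator=indicator_name,
        determinant=outcome_name,
        beta=beta,
        se=se,
        p=_p_from_t(t, df),
        n=len(y),
        covariates=("sex",),
        variant="longitudinal",
        beta_std=beta_std,
    )
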