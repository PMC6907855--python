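"""Mass-action incidence regression and model comparison.

The central model treats yearly snakebite incidence in district *i* as

    I_i = alpha + theta * F_i * S_i

where F_i is the district-averaged encounter frequency with the focal
venomous snake (snakes per person-hour), S_i the rural (exposed)
population, theta the conditional probability that an encounter produces
a bite, and alpha an intercept that zeroes the mean residual — which is
why, for every intercept model, the summed fitted incidence equals the
summed observed incidence and the national estimate reproduces the
reported national caseload exactly.

Five candidate structures are compared by centered R-squared and AIC:

    1. I = alpha + theta * F * S      (mass action)
    2. I = theta * F * S              (mass action, no intercept)
    3. I = alpha + theta' * S         (population only)
    4. I = alpha + theta' * F         (encounter frequency only)
    5. I = alpha + theta1*F + theta2*S  (additive, no interaction)

AIC follows the Gaussian-likelihood convention that counts the error
variance as a parameter: ``n ln(2 pi RSS / n) + n + 2 (k + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

REQUIRED_COLUMNS = ("district_id", "rural_pop", "F", "observed_incidence")

MODEL_STRUCTURES = {
    1: "I = alpha + theta*F*S",
    2: "I = theta*F*S",
    3: "I = alpha + theta*S",
    4: "I = alpha + theta*F",
    5: "I = alpha + theta1*F + theta2*S",
}

_PARAM_NAMES = {
    1: ("alpha", "theta"),
    2: ("theta",),
    3: ("alpha", "theta"),
    4: ("alpha", "theta"),
    5: ("alpha", "theta1", "theta2"),
}


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"district table missing column(s) {missing}")
    if table["district_id"].duplicated().any():
        raise ValueError("district_id values must be unique")
    for col in ("rural_pop", "F"):
        if (table[col] < 0).any():
            raise ValueError(f"column {col!r} must be non-negative")
    if (table["observed_incidence"] < 0).any():
        # Real incidence is a non-negative count; unfloored synthetic
        # draws may dip below zero in assumption-faithful simulations.
        warnings.warn("observed_incidence contains negative values")
    return table


def design_matrix(table: pd.DataFrame, model_id: int) -> tuple[np.ndarray, bool]:
    """Predictor matrix (without intercept column) and intercept flag."""
    S = table["rural_pop"].to_numpy(dtype=float)
    F = table["F"].to_numpy(dtype=float)
    if model_id == 1:
        return (F * S)[:, None], True
    if model_id == 2:
        return (F * S)[:, None], False
    if model_id == 3:
        return S[:, None], True
    if model_id == 4:
        return F[:, None], True
    if model_id == 5:
        return np.column_stack([F, S]), True
    raise ValueError(f"model_id must be 1..5, got {model_id}")


@dataclass
class FitResult:
    """One fitted candidate model with diagnostics and 99% bands."""

    model_id: int
    structure: str
    params: pd.Series
    cov_params: pd.DataFrame
    r_squared: float
    aic: float
    rss: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    k: int                      # mean parameters, incl. intercept
    has_intercept: bool
    district_id: np.ndarray
    observed: np.ndarray
    exog: np.ndarray            # full design incl. intercept column
    scale: float                # RSS / dof, the OLS sigma^2 estimate

    @property
    def dof(self) -> int:
        return self.n - self.k


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC under the Gaussian likelihood, counting sigma^2 (k+1 params).

    A perfect fit (RSS = 0) has unbounded likelihood; returns -inf with
    a warning rather than an error.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("RSS is zero; AIC is -inf (degenerate perfect fit)")
        return -np.inf
    return n * np.log(2 * np.pi * rss / n) + n + 2 * (k + 1)


def fit_model(table: pd.DataFrame, model_id: int) -> FitResult:
    """Fit one of the five candidate structures by OLS.

    R-squared is always computed against the observed mean (centered),
    including for the no-intercept Model 2, to keep the comparison table
    on one scale; no-intercept R-squared conventions differ, so that row
    is flagged in :func:`compare_models` output.
    """
    validate_table(table)
    X, intercept = design_matrix(table, model_id)
    y = table["observed_incidence"].to_numpy(dtype=float)
    n = y.size
    k = X.shape[1] + (1 if intercept else 0)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} districts for model {model_id}")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("predictors are constant; model unidentifiable")

    exog = sm.add_constant(X, has_constant="add") if intercept else X
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        corr = np.corrcoef(exog, rowvar=False)
        names = _PARAM_NAMES[model_id]
        pairs = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear: {pairs}")

    res = sm.OLS(y, exog).fit()
    fitted = res.fittedvalues
    resid = res.resid
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    names = list(_PARAM_NAMES[model_id])
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = gaussian_aic(rss, n, k)
    return FitResult(
        model_id=model_id, structure=MODEL_STRUCTURES[model_id],
        params=params, cov_params=cov, r_squared=r2, aic=aic, rss=rss,
        residuals=np.asarray(resid), fitted=np.asarray(fitted), n=n, k=k,
        has_intercept=intercept,
        district_id=table["district_id"].to_numpy(),
        observed=y, exog=np.asarray(exog), scale=float(res.scale),
    )


def intervals(fit: FitResult, level: float = 0.99) -> pd.DataFrame:
    """Per-district t-based confidence and prediction bands.

    Returns one row per district with the fitted mean, the confidence
    band on the mean, the prediction band for a new observation, and
    the band half-widths. The half-width at the mean predictor — the
    narrowest point of the confidence band — is attached as
    ``DataFrame.attrs['pi_halfwidth_at_mean']`` /
    ``['ci_halfwidth_at_mean']``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if fit.dof < 1:
        raise ValueError("no residual degrees of freedom")
    tcrit = stats.t.ppf(0.5 + level / 2, fit.dof)
    X = fit.exog
    XtX_inv = np.linalg.pinv(X.T @ X)
    lev = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    se_mean = np.sqrt(fit.scale * lev)
    se_pred = np.sqrt(fit.scale * (1.0 + lev))
    df = pd.DataFrame({
        "district_id": fit.district_id,
        "observed": fit.observed,
        "fitted": fit.fitted,
        "ci_low": fit.fitted - tcrit * se_mean,
        "ci_high": fit.fitted + tcrit * se_mean,
        "pi_low": fit.fitted - tcrit * se_pred,
        "pi_high": fit.fitted + tcrit * se_pred,
        "ci_halfwidth": tcrit * se_mean,
        "pi_halfwidth": tcrit * se_pred,
    })
    x_mean = X.mean(axis=0)
    lev_mean = float(x_mean @ XtX_inv @ x_mean)
    df.attrs["ci_halfwidth_at_mean"] = tcrit * np.sqrt(fit.scale * lev_mean)
    df.attrs["pi_halfwidth_at_mean"] = tcrit * np.sqrt(fit.scale * (1 + lev_mean))
    df.attrs["level"] = level
    return df


def residual_fitted_test(fit: FitResult) -> tuple[float, float]:
    """Pearson correlation between residuals and fitted values.

    For intercept OLS the correlation is identically zero by
    orthogonality; the test is informative for no-intercept fits, where
    curvature or misspecification shows up as nonzero correlation.
    Zero-variance residuals make the statistic undefined: returns
    (nan, nan) with a warning.
    """
    if fit.n < 3:
        raise ValueError("need at least 3 observations")
    resid_scale = max(1.0, float(np.std(fit.observed)))
    if np.std(fit.residuals) <= 1e-10 * resid_scale or np.std(fit.fitted) == 0:
        warnings.warn("degenerate residuals or fitted values; correlation undefined")
        return (np.nan, np.nan)
    r, p = stats.pearsonr(fit.residuals, fit.fitted)
    return float(r), float(p)


def confint_params(fit: FitResult, level: float = 0.99) -> pd.DataFrame:
    """t-based confidence intervals for the coefficients."""
    tcrit = stats.t.ppf(0.5 + level / 2, fit.dof)
    se = np.sqrt(np.diag(fit.cov_params.to_numpy()))
    return pd.DataFrame({
        "estimate": fit.params,
        "se": se,
        "low": fit.params - tcrit * se,
        "high": fit.params + tcrit * se,
    })


def national_incidence(fit: FitResult, level: float = 0.99
                       ) -> tuple[float, tuple[float, float]]:
    """Predicted national caseload and its confidence range.

    The total is the sum of fitted district incidences; for intercept
    models this equals the observed total exactly (residuals sum to
    zero). The range is a t interval from the coefficient covariance of
    the summed prediction.
    """
    total = float(fit.fitted.sum())
    ones_x = fit.exog.sum(axis=0)
    var_total = float(ones_x @ fit.cov_params.to_numpy() @ ones_x)
    tcrit = stats.t.ppf(0.5 + level / 2, fit.dof)
    half = tcrit * np.sqrt(max(var_total, 0.0))
    return total, (total - half, total + half)


def flag_outlier_districts(fit: FitResult, level: float = 0.99
                           ) -> tuple[list, list]:
    """Districts whose observed incidence escapes its prediction band.

    Returns ``(underestimated, overestimated)`` district ids: observed
    above the band means the model underestimates, below means it
    overestimates.
    """
    bands = intervals(fit, level=level)
    under = bands.loc[bands["observed"] > bands["pi_high"], "district_id"]
    over = bands.loc[bands["observed"] < bands["pi_low"], "district_id"]
    return list(under), list(over)


@dataclass
class ModelComparison:
    """Comparison-table rows for Models 1-5 and the AIC winner."""

    table: pd.DataFrame
    fits: dict[int, FitResult]
    best_model: int


def compare_models(table: pd.DataFrame, level: float = 0.99) -> ModelComparison:
    """Fit all five structures and rank them by AIC.

    The output mirrors the usual comparison-table layout: structure,
    centered R-squared, AIC, predicted national incidence with its
    range, one row per model in id order. Fit failures annotate the row
    rather than aborting the sweep. Model 2's national estimate is
    flagged: without an intercept its fitted total is not anchored to
    the observed total.
    """
    rows = []
    fits: dict[int, FitResult] = {}
    for mid in range(1, 6):
        try:
            fit = fit_model(table, mid)
        except ValueError as exc:
            rows.append({"model": mid, "structure": MODEL_STRUCTURES[mid],
                         "r_squared": np.nan, "aic": np.nan,
                         "national_incidence": np.nan,
                         "national_low": np.nan, "national_high": np.nan,
                         "note": f"fit failed: {exc}"})
            continue
        fits[mid] = fit
        total, (lo, hi) = national_incidence(fit, level=level)
        note = "" if fit.has_intercept else "no intercept: total not anchored"
        rows.append({"model": mid, "structure": fit.structure,
                     "r_squared": fit.r_squared, "aic": fit.aic,
                     "national_incidence": total,
                     "national_low": lo, "national_high": hi, "note": note})
    if not fits:
        raise ValueError("every candidate model failed to fit")
    df = pd.DataFrame(rows)
    best = min(fits, key=lambda m: fits[m].aic)
    return ModelComparison(table=df, fits=fits, best_model=best)


def fit_multi_species(F_matrix: pd.DataFrame, table: pd.DataFrame) -> FitResult:
    """Multi-species mass-action fit: I = alpha + sum_j theta_j*F_j*S.

    ``F_matrix`` holds one encounter-frequency column per species,
    indexed like ``table``. Each predictor is the product F_j,i * S_i;
    collinear species pairs are reported by name.
    """
    validate_table(table)
    if len(F_matrix) != len(table):
        raise ValueError("F_matrix and table have different lengths")
    species = list(F_matrix.columns)
    S = table["rural_pop"].to_numpy(dtype=float)
    X = F_matrix.to_numpy(dtype=float) * S[:, None]
    y = table["observed_incidence"].to_numpy(dtype=float)
    n, n_spec = X.shape
    if n <= n_spec + 2:
        raise ValueError(f"need more than {n_spec + 2} districts")

    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (species[i], species[j])
            for i in range(n_spec) for j in range(i + 1, n_spec)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"collinear species predictors: {pairs or species}")

    res = sm.OLS(y, exog).fit()
    names = ["alpha"] + [f"theta_{s}" for s in species]
    rss = float(res.resid @ res.resid)
    tss = float(((y - y.mean()) ** 2).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = gaussian_aic(rss, n, n_spec + 1)
    return FitResult(
        model_id=1 if n_spec == 1 else 0,
        structure="I = alpha + sum_j theta_j*F_j*S",
        params=pd.Series(res.params, index=names),
        cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
        r_squared=1.0 - rss / tss if tss > 0 else np.nan,
        aic=aic, rss=rss,
        residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
        n=n, k=n_spec + 1, has_intercept=True,
        district_id=table["district_id"].to_numpy(), observed=y,
        exog=np.asarray(exog), scale=float(res.scale),
    )
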