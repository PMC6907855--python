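"""Presence-background maximum-entropy species distribution model.

The model is the Gibbs distribution ``p(cell) = exp(lambda . f(cell)) / Z``
over background cells, with features f built from the environmental
covariates (linear and quadratic classes, standardized against the
background). Fitting maximizes the L1-penalized presence log-likelihood —
a convex problem solved with L-BFGS-B on the positive/negative weight
split. At zero regularization the optimum matches the classic maximum
entropy moment condition: expected features under the model equal the
empirical presence means.

Downstream, the fitted suitability surface is thresholded at the
zero-omission / maximum-area value (the minimum suitability over training
presences) and clipped to the species' altitudinal ceiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from vipermass.grids import LandscapeStack, OccurrenceSet, check_aligned

logger = logging.getLogger(__name__)

#: Largest grid for which every valid cell serves as training background.
FULL_BACKGROUND_CELL_LIMIT = 100_000
#: Background sample size used above that limit.
BACKGROUND_SAMPLE_SIZE = 10_000


class MaxentConvergenceError(RuntimeError):
    """Raised when the optimizer stops short of the stationarity tolerance."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class FeatureSet:
    """Feature matrix over the cells of a landscape.

    ``matrix`` has shape ``(n_cells, n_features)`` in row-major cell
    order, NaN at nodata cells. Columns are ordered covariate-major,
    linear before quadratic, and standardized by the background mean/sd
    stored in ``means`` / ``sds`` (computed on the raw feature columns).
    """

    matrix: np.ndarray
    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    classes: tuple[str, ...]
    kept_covariates: list[int]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MaxentModel:
    """Fitted Gibbs model: weights, normalizer and background reference."""

    feature_names: list[str]
    lambdas: np.ndarray
    log_normalizer: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    classes: tuple[str, ...]
    kept_covariates: list[int]
    regularization: float
    background_cells: np.ndarray
    n_iter: int = 0

    def linear_predictor(self, features: np.ndarray) -> np.ndarray:
        return features @ self.lambdas


@dataclass
class SuitabilityMap:
    """Per-cell relative occurrence rate; background cells sum to 1."""

    suitability: np.ndarray
    background_cells: np.ndarray

    @property
    def shape(self):
        return self.suitability.shape


@dataclass
class PresenceMask:
    """Boolean predicted-presence grid and the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    altitude_limit: float | None = None


def build_features(stack: LandscapeStack,
                   classes: tuple[str, ...] = ("linear", "quadratic"),
                   ) -> FeatureSet:
    """Build the standardized feature matrix over all cells of ``stack``.

    Covariates with zero variance over the valid background are dropped
    with a warning. Column order is deterministic: covariates in stack
    order, linear before quadratic within each covariate.
    """
    classes = tuple(classes)
    if not classes:
        raise ValueError("at least one feature class is required")
    unknown = set(classes) - {"linear", "quadratic"}
    if unknown:
        raise ValueError(f"unknown feature class(es) {sorted(unknown)}")
    if stack.n_covariates < 1:
        raise ValueError("stack has no covariates")

    valid = stack.valid_mask().ravel()
    raw = stack.covariates.reshape(stack.n_covariates, -1)

    kept: list[int] = []
    for k in range(stack.n_covariates):
        if np.nanstd(raw[k, valid]) == 0:
            warnings.warn(f"covariate {k} has zero variance over background; dropped")
        else:
            kept.append(k)
    if not kept:
        raise ValueError("all covariates have zero variance")

    cols, names = [], []
    for k in kept:
        if "linear" in classes:
            cols.append(raw[k])
            names.append(f"cov{k}")
        if "quadratic" in classes:
            cols.append(raw[k] ** 2)
            names.append(f"cov{k}^2")
    mat = np.column_stack(cols).astype(float)
    means = mat[valid].mean(axis=0)
    sds = mat[valid].std(axis=0)
    sds[sds == 0] = 1.0
    mat = (mat - means) / sds
    mat[~valid] = np.nan
    return FeatureSet(matrix=mat, names=names, means=means, sds=sds,
                      classes=classes, kept_covariates=kept)


def select_background(stack: LandscapeStack, seed: int = 0) -> np.ndarray:
    """Training background: every valid cell, or a uniform sample of
    10^4 cells when the grid exceeds 10^5 valid cells."""
    valid = stack.valid_indices()
    if valid.size <= FULL_BACKGROUND_CELL_LIMIT:
        return valid
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(valid, size=BACKGROUND_SAMPLE_SIZE, replace=False))


def fit_maxent(presences: OccurrenceSet, stack: LandscapeStack,
               features: FeatureSet | None = None, reg: float = 0.1,
               background: np.ndarray | None = None,
               collapse_duplicates: bool = True, max_iter: int = 1000,
               tol: float = 1e-6, seed: int = 0) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    Maximizes ``mean_presence(lambda . f) - log Z(lambda) - reg * |lambda|_1``
    where Z sums ``exp(lambda . f)`` over the background cells. The L1
    term is handled by splitting each weight into positive and negative
    parts with box constraints, keeping the problem smooth and convex.
    Stationarity is verified against the L1 subgradient condition; a fit
    that misses the tolerance raises :class:`MaxentConvergenceError`
    with the offending gradient entries attached.
    """
    if reg < 0:
        raise ValueError("reg must be non-negative")
    if features is None:
        features = build_features(stack)
    if background is None:
        background = select_background(stack, seed=seed)

    if collapse_duplicates:
        pres_cells = presences.unique_cells(stack)
    else:
        rows, cols = presences.cell_indices(stack)
        pres_cells = rows * stack.shape[1] + cols
    pres_feats = features.matrix[pres_cells]
    ok = ~np.isnan(pres_feats).any(axis=1)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} presence(s) on nodata cells excluded")
        pres_cells, pres_feats = pres_cells[ok], pres_feats[ok]
    if np.unique(pres_cells).size < 2:
        raise ValueError("need at least 2 distinct presence cells")
    if background.size < pres_cells.size:
        raise ValueError("background must be at least as large as the presence set")

    bg_feats = features.matrix[background]
    if np.isnan(bg_feats).any():
        raise ValueError("background contains nodata cells")
    p_mean = pres_feats.mean(axis=0)
    m = features.n_features

    def neg_ll_grad(lam):
        eta = bg_feats @ lam
        logz = logsumexp(eta)
        w = np.exp(eta - logz)
        e_model = w @ bg_feats
        return -(p_mean @ lam) + logz - np.log(background.size), e_model - p_mean

    def objective(uv):
        lam = uv[:m] - uv[m:]
        f, g = neg_ll_grad(lam)
        return (f + reg * uv.sum(),
                np.concatenate([g + reg, -g + reg]))

    res = minimize(objective, np.zeros(2 * m), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * m),
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    lam = res.x[:m] - res.x[m:]
    _, grad = neg_ll_grad(lam)

    # L1 stationarity: active weights need grad = -reg*sign(lam); zeros
    # need |grad| <= reg.
    viol = np.where(lam != 0, np.abs(grad + reg * np.sign(lam)),
                    np.maximum(np.abs(grad) - reg, 0.0))
    if viol.max() > tol:
        raise MaxentConvergenceError(
            f"maxent optimizer failed to reach stationarity tolerance {tol:g} "
            f"(max violation {viol.max():.3g} after {res.nit} iterations)",
            diagnostics={"violation": viol, "lambdas": lam, "nit": res.nit,
                         "message": res.message},
        )

    eta_bg = bg_feats @ lam
    return MaxentModel(
        feature_names=features.names, lambdas=lam,
        log_normalizer=float(logsumexp(eta_bg)),
        feature_means=features.means, feature_sds=features.sds,
        classes=features.classes, kept_covariates=features.kept_covariates,
        regularization=reg, background_cells=background, n_iter=res.nit,
    )


def features_for_model(model: MaxentModel, stack: LandscapeStack) -> np.ndarray:
    """Recompute the model's feature columns on ``stack`` using the
    standardization frozen at fit time."""
    valid = stack.valid_mask().ravel()
    raw = stack.covariates.reshape(stack.n_covariates, -1)
    cols = []
    for k in model.kept_covariates:
        if k >= stack.n_covariates:
            raise ValueError(f"stack lacks covariate {k} used by the model")
        if "linear" in model.classes:
            cols.append(raw[k])
        if "quadratic" in model.classes:
            cols.append(raw[k] ** 2)
    mat = np.column_stack(cols).astype(float)
    mat = (mat - model.feature_means) / model.feature_sds
    mat[~valid] = np.nan
    return mat


def predict_suitability(model: MaxentModel, stack: LandscapeStack) -> SuitabilityMap:
    """Per-cell relative occurrence rate ``exp(lambda.f - log Z)``.

    Nodata cells propagate NaN; the map sums to 1 over the model's
    background cells.
    """
    feats = features_for_model(model, stack)
    eta = feats @ model.lambdas
    suit = np.exp(eta - model.log_normalizer)
    return SuitabilityMap(suitability=suit.reshape(stack.shape),
                          background_cells=model.background_cells)


def evaluate_auc(suitability: SuitabilityMap, presences: OccurrenceSet,
                 stack: LandscapeStack, n_background: int = 1000,
                 seed: int = 0) -> float:
    """AUC of suitability against random pseudo-absence background points.

    Estimates ``P(s_presence > s_background) + 0.5 P(tie)`` via the
    rank-sum statistic, drawing ``n_background`` valid cells uniformly
    (presence cells excluded). A constant map returns 0.5 with a
    warning, matching the no-discrimination baseline.
    """
    if len(presences) < 1:
        raise ValueError("need at least one presence")
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    rows, cols = presences.cell_indices(stack)
    pres_cells = rows * stack.shape[1] + cols
    suit_flat = suitability.suitability.ravel()
    pres_s = suit_flat[pres_cells]
    keep = ~np.isnan(pres_s)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} presence(s) on nodata cells excluded")
        pres_s = pres_s[keep]
        pres_cells = pres_cells[keep]

    pool = np.setdiff1d(stack.valid_indices(), np.unique(pres_cells))
    if pool.size == 0:
        raise ValueError("no background cells available outside presences")
    rng = np.random.default_rng(seed)
    bg = rng.choice(pool, size=n_background, replace=n_background > pool.size)
    bg_s = suit_flat[bg]

    combined = np.concatenate([pres_s, bg_s])
    if np.ptp(combined) == 0:
        warnings.warn("all suitability values identical; AUC = 0.5")
        return 0.5
    ranks = rankdata(combined)
    n1 = pres_s.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * bg_s.size))


def zero_omission_threshold(suitability: SuitabilityMap,
                            presences: OccurrenceSet,
                            stack: LandscapeStack) -> float:
    """Threshold with zero training omission and maximal predicted area.

    This is the minimum suitability over presence cells: every presence
    stays predicted present, and any higher threshold would omit at
    least one while any lower one only shrinks nothing — the predicted
    area (cells at or above the threshold) is maximal among
    zero-omission choices.
    """
    rows, cols = presences.cell_indices(stack)
    s = suitability.suitability[rows, cols]
    ok = ~np.isnan(s)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} presence(s) on nodata cells excluded")
        s = s[ok]
    if s.size == 0:
        raise ValueError("no presence with valid suitability")
    return float(s.min())


def make_presence_mask(suitability: SuitabilityMap, threshold: float) -> PresenceMask:
    """Binary presence map: suitability at or above the threshold."""
    with np.errstate(invalid="ignore"):
        mask = suitability.suitability >= threshold
    mask &= ~np.isnan(suitability.suitability)
    return PresenceMask(mask=mask, threshold=float(threshold))


def apply_altitude_mask(mask: PresenceMask, elevation: np.ndarray,
                        limit: float = 1200.0) -> PresenceMask:
    """Remove predicted presence above the species' altitudinal ceiling."""
    check_aligned(mask.mask, elevation)
    new = mask.mask & ~(np.asarray(elevation, dtype=float) > limit)
    return PresenceMask(mask=new, threshold=mask.threshold, altitude_limit=limit)
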