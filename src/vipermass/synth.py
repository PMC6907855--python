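"""Synthetic landscapes, occurrences, surveys, census and incidence.

Everything downstream of this module — the niche model, the encounter
extrapolation, the incidence regression — can be exercised end to end on
data generated here with known ground truth. A single integer seed fully
determines every generated artifact.

The generator emulates the study system: spatially autocorrelated
environmental covariates, a smooth elevation field with a ridge dividing
the grid into two versants, contiguous district partitions, presence
points drawn from a log-linear suitability surface, Poisson survey
counts at known per-stratum encounter rates, log-normal rural census
counts, and district incidence following the mass-action relation
``I = alpha + theta * F * S`` plus noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from vipermass.grids import LandscapeStack, OccurrenceSet, altitude_band

logger = logging.getLogger(__name__)

# Default per-stratum encounter rates (snakes per person-hour), keyed by
# (versant, altitude band). Versant 0 is the wetter/richer slope; rates
# decline with altitude, mirroring the field pattern for the focal viper.
# The effort-weighted national pool of these values sits near 0.15.
DEFAULT_STRATUM_RATES: dict[tuple[int, int], float] = {
    (0, 0): 0.28,
    (0, 1): 0.14,
    (0, 2): 0.04,
    (1, 0): 0.18,
    (1, 1): 0.09,
    (1, 2): 0.03,
}

# Observed relative abundances used to scale non-focal detections:
# focal / all snakes ~ 0.45, focal / venomous snakes ~ 0.7.
FOCAL_OVER_ALL = 0.45
FOCAL_OVER_VENOMOUS = 0.7


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind one synthetic study.

    Parameters
    ----------
    suitability_weights
        Log-linear weights on the standardized covariates; occurrence
        probability per cell is proportional to ``exp(w . covariates)``.
    stratum_rates
        Encounter rate (snakes per person-hour) per (versant, altitude
        band) stratum.
    theta
        Conditional probability that an encounter unit produces a bite;
        the slope of the mass-action regression.
    alpha
        Baseline incidence (cases/year); the regression intercept.
    noise_sd
        Standard deviation of Gaussian incidence noise, cases/year.
    seed
        Master seed; fully determines all generated outputs.
    """

    suitability_weights: np.ndarray = field(
        default_factory=lambda: np.array([1.2, -0.8, 0.5, 0.0])
    )
    stratum_rates: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_RATES)
    )
    theta: float = 1.0e-3
    alpha: float = 0.47
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.suitability_weights = np.asarray(self.suitability_weights, dtype=float)
        if any(r < 0 for r in self.stratum_rates.values()):
            raise ValueError("stratum rates must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_landscape(seed: int, shape: tuple[int, int] = (60, 80),
                       n_covariates: int = 4, n_districts: int = 30,
                       smoothing_sigma: float = 3.0,
                       max_elevation: float = 1600.0) -> LandscapeStack:
    """Generate an aligned synthetic landscape stack.

    Covariates are white noise smoothed with a Gaussian kernel of width
    ``smoothing_sigma`` cells and then standardized to mean 0, sd 1 over
    the grid. Elevation is a smooth non-negative field rescaled to span
    ``[0, max_elevation]`` metres, shaped by a north-south ridge; the
    versant label splits each row at the ridge crest. Districts are the
    nearest-centroid (Voronoi) partition of the cells around
    ``n_districts`` random centroids, hence contiguous.
    """
    nrows, ncols = shape
    if nrows <= 0 or ncols <= 0:
        raise ValueError("grid dimensions must be positive")
    if nrows < 8 or ncols < 8:
        raise ValueError("grid must be at least 8x8")
    if n_covariates < 1:
        raise ValueError("need at least one covariate")
    if not (2 <= n_districts <= nrows * ncols) and n_districts != 1:
        raise ValueError("n_districts must be in [1, n_cells]")

    rng = np.random.default_rng(seed)

    covs = np.empty((n_covariates, nrows, ncols))
    for k in range(n_covariates):
        f = gaussian_filter(rng.standard_normal((nrows, ncols)), smoothing_sigma,
                            mode="reflect")
        covs[k] = (f - f.mean()) / f.std()

    # Ridge running down a randomly placed column band, plus smooth noise.
    ridge_col = rng.uniform(0.3, 0.7) * ncols
    cols = np.arange(ncols)
    ridge_profile = np.exp(-0.5 * ((cols - ridge_col) / (0.18 * ncols)) ** 2)
    rough = gaussian_filter(rng.standard_normal((nrows, ncols)), 2 * smoothing_sigma,
                            mode="reflect")
    rough = (rough - rough.min()) / (rough.max() - rough.min())
    elev = 0.75 * ridge_profile[None, :] + 0.25 * rough
    elev = (elev - elev.min()) / (elev.max() - elev.min()) * max_elevation

    crest = np.argmax(gaussian_filter(elev, smoothing_sigma, mode="reflect"), axis=1)
    versant = (cols[None, :] > crest[:, None]).astype(int)

    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    cells = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    if n_districts == 1:
        district = np.zeros((nrows, ncols), dtype=int)
    else:
        centroid_idx = rng.choice(nrows * ncols, size=n_districts, replace=False)
        centroids = cells[centroid_idx]
        d2 = ((cells[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        district = np.argmin(d2, axis=1).reshape(nrows, ncols).astype(int)

    # Upper-left origin at (0, nrows) so the lower-left corner sits at
    # (0, 0), matching the ASCII-grid writer's default georeference.
    return LandscapeStack(covariates=covs, elevation=elev, versant=versant,
                          district=district, origin=(0.0, float(nrows)))


def generate_occurrences(landscape: LandscapeStack, weights, n: int,
                         seed: int, replace: bool | None = None,
                         jitter: bool = True,
                         within: np.ndarray | None = None) -> OccurrenceSet:
    """Draw presence points from a log-linear suitability surface.

    Cells are sampled with probability proportional to
    ``exp(weights . covariates)``; points are jittered uniformly within
    their cell. Sampling is without replacement when ``n`` does not
    exceed the number of valid cells (override with ``replace``).
    ``within`` optionally restricts the draw to a boolean range mask —
    a species generates presence records only inside its range.
    """
    weights = np.asarray(weights, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if weights.shape[0] != landscape.n_covariates:
        raise ValueError(
            f"got {weights.shape[0]} weights for {landscape.n_covariates} covariates"
        )
    valid = landscape.valid_indices()
    if within is not None:
        within = np.asarray(within, dtype=bool)
        if within.shape != landscape.shape:
            raise ValueError("range mask misaligned with landscape")
        valid = valid[within.ravel()[valid]]
        if valid.size == 0:
            raise ValueError("range mask excludes every valid cell")
    if replace is None:
        replace = n > valid.size
    if not replace and n > valid.size:
        raise ValueError(
            f"cannot draw {n} cells without replacement from {valid.size}"
        )
    covs = landscape.covariates.reshape(landscape.n_covariates, -1)[:, valid]
    logit = weights @ covs
    logit -= logit.max()
    p = np.exp(logit)
    p /= p.sum()

    rng = np.random.default_rng(seed)
    chosen = rng.choice(valid, size=n, replace=replace, p=p)
    rows, colz = np.divmod(chosen, landscape.shape[1])
    x, y = landscape.cell_center(rows, colz)
    if jitter:
        half = 0.5 * landscape.cell_size
        x = x + rng.uniform(-half, half, size=n) * 0.999
        y = y + rng.uniform(-half, half, size=n) * 0.999
    return OccurrenceSet(points=np.column_stack([x, y]))


def generate_survey(truth: SyntheticTruth, effort_per_stratum: float = 100.0,
                    seed: int | None = None, records_per_stratum: int = 3,
                    ) -> list:
    """Simulate active-search survey records for every stratum.

    The per-stratum effort is split evenly across ``records_per_stratum``
    records. Focal counts are Poisson with mean ``rate * effort``;
    venomous and total-snake counts add independent Poisson layers
    scaled so the expected composition matches the field ratios
    (focal/venomous ~ 0.7, focal/all ~ 0.45).
    """
    from vipermass.encounter import SurveyRecord

    if effort_per_stratum <= 0:
        raise ValueError("effort_per_stratum must be positive")
    if records_per_stratum < 1:
        raise ValueError("records_per_stratum must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    land_covers = ("open", "closed_canopy", "forest")
    seasons = ("dry", "wet")
    records = []
    site = 0
    for (versant, band), rate in sorted(truth.stratum_rates.items()):
        hours = effort_per_stratum / records_per_stratum
        for j in range(records_per_stratum):
            focal = rng.poisson(rate * hours)
            extra_venom = rng.poisson(rate * (1 / FOCAL_OVER_VENOMOUS - 1) * hours)
            extra_other = rng.poisson(
                rate * (1 / FOCAL_OVER_ALL - 1 / FOCAL_OVER_VENOMOUS) * hours
            )
            records.append(SurveyRecord(
                site_id=f"site{site:02d}",
                versant=versant,
                altitude_band=band,
                land_cover=land_covers[j % len(land_covers)],
                season=seasons[j % len(seasons)],
                person_hours=hours,
                count_focal=int(focal),
                count_venomous=int(focal + extra_venom),
                count_all_snakes=int(focal + extra_venom + extra_other),
            ))
        site += 1
    return records


def generate_census(n_districts: int, seed: int, meanlog: float = 8.0,
                    sdlog: float = 1.0) -> np.ndarray:
    """Rural population per district: log-normal, positive integers."""
    if n_districts < 1:
        raise ValueError("n_districts must be >= 1")
    rng = np.random.default_rng(seed)
    pops = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_districts)
    return np.maximum(1, np.round(pops)).astype(int)


def generate_incidence(districts: pd.DataFrame, truth: SyntheticTruth,
                       noise_model: str = "gaussian",
                       seed: int | None = None,
                       floor: bool = True) -> pd.DataFrame:
    """Attach observed incidence to a district table.

    ``districts`` needs columns ``rural_pop`` (S_i) and ``F`` (mean
    encounter frequency). The mass-action mean is
    ``alpha + theta * F_i * S_i``; Gaussian noise is added and floored
    at zero (incidence is a count), or a Poisson draw is taken from the
    mean for count realism. Pass ``floor=False`` for regression studies
    that must follow the linear-Gaussian equation exactly — the floor
    censors low-incidence districts and would bias coefficient-recovery
    simulations.
    """
    for col in ("rural_pop", "F"):
        if col not in districts.columns:
            raise ValueError(f"district table missing column {col!r}")
    S = districts["rural_pop"].to_numpy(dtype=float)
    F = districts["F"].to_numpy(dtype=float)
    if (S < 0).any() or (F < 0).any():
        raise ValueError("rural_pop and F must be non-negative")
    mean = truth.alpha + truth.theta * F * S
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if noise_model == "gaussian":
        obs = mean + rng.normal(0.0, truth.noise_sd, size=mean.size)
        if floor:
            n_floored = int(np.sum(obs < 0))
            if n_floored:
                logger.info("floored %d negative incidence draw(s) at 0",
                            n_floored)
            obs = np.maximum(obs, 0.0)
    elif noise_model == "poisson":
        obs = rng.poisson(np.maximum(mean, 0.0)).astype(float)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    out = districts.copy()
    out["observed_incidence"] = obs
    return out


def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise sd that makes the regression attain a target R-squared.

    With ``var(signal)`` the variance of the mass-action mean across
    districts, Gaussian noise of variance ``var(signal) * (1 - r2) / r2``
    yields an expected coefficient of determination of ``r2``.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    sig_var = float(np.var(np.asarray(signal, dtype=float)))
    return float(np.sqrt(sig_var * (1 - r2) / r2))


def make_district_table(seed: int, n_districts: int = 200,
                        truth: SyntheticTruth | None = None,
                        target_r2: float | None = 0.66,
                        f_range: tuple[float, float] = (0.0, 0.3),
                        noise_model: str = "gaussian") -> pd.DataFrame:
    """One-call district table for regression studies.

    Draws census populations and uniform encounter frequencies, then
    generates observed incidence from the mass-action truth. When
    ``target_r2`` is given the noise sd is calibrated from the signal
    variance so the fit's expected R-squared matches it. Gaussian noise
    is left unfloored here: recovery and coverage studies probe the
    linear-Gaussian equation itself, and censoring at zero would bias
    them by construction.
    """
    truth = truth or SyntheticTruth(seed=seed)
    rng = np.random.default_rng(seed)
    S = generate_census(n_districts, seed=int(rng.integers(2**31)))
    F = rng.uniform(*f_range, size=n_districts)
    table = pd.DataFrame({
        "district_id": np.arange(n_districts),
        "rural_pop": S,
        "F": F,
    })
    if target_r2 is not None:
        signal = truth.theta * F * S
        truth = SyntheticTruth(
            suitability_weights=truth.suitability_weights,
            stratum_rates=truth.stratum_rates, theta=truth.theta,
            alpha=truth.alpha, noise_sd=noise_sd_for_r2(signal, target_r2),
            seed=truth.seed,
        )
    return generate_incidence(table, truth, noise_model=noise_model,
                              seed=int(rng.integers(2**31)),
                              floor=noise_model != "gaussian")
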