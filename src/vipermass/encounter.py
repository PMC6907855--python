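"""Encounter rates from survey effort and their spatial extrapolation.

A survey record holds the person-hours of standardized active search and
the snakes detected. Rates are pooled per stratum — total counts over
total effort, never a mean of per-record ratios — so splitting or
reordering records cannot change a stratum's rate. Strata are
(versant, altitude band) cells; altitude bands are [0,400), [400,800)
and [800, inf) metres. The rates are painted over the predicted-presence
mask and averaged per district to give the mass-action model its
encounter-frequency covariate F_i.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vipermass.grids import (ALTITUDE_BAND_LABELS, altitude_band,
                             band_label_to_index, check_aligned)
from vipermass.niche import PresenceMask

logger = logging.getLogger(__name__)

#: Count-column aliases accepted by :func:`relative_abundance`.
SPECIES_GROUPS = {
    "focal": "count_focal",
    "venomous": "count_venomous",
    "all": "count_all_snakes",
}


@dataclass
class SurveyRecord:
    """One active-search sampling session.

    ``altitude_band`` is the band index (0, 1, 2) or a label like
    ``"0-400"``. Counts must nest: focal <= venomous <= all snakes.
    """

    site_id: str
    versant: int
    altitude_band: int
    person_hours: float
    count_focal: int
    count_venomous: int
    count_all_snakes: int
    land_cover: str = "open"
    season: str = "dry"

    def __post_init__(self):
        if isinstance(self.altitude_band, str):
            self.altitude_band = band_label_to_index(self.altitude_band)
        else:
            self.altitude_band = int(self.altitude_band)
        self.versant = int(self.versant)
        if self.person_hours <= 0:
            raise ValueError("person_hours must be positive")
        if min(self.count_focal, self.count_venomous, self.count_all_snakes) < 0:
            raise ValueError("counts must be non-negative")
        if not (self.count_focal <= self.count_venomous <= self.count_all_snakes):
            raise ValueError(
                "counts must nest: focal <= venomous <= all snakes "
                f"(got {self.count_focal}, {self.count_venomous}, "
                f"{self.count_all_snakes})"
            )

    @property
    def stratum(self) -> tuple[int, int]:
        return (self.versant, self.altitude_band)


@dataclass
class StratumRates:
    """Pooled encounter rates per stratum, in snakes per person-hour.

    Retains the pooled counts and effort per stratum, the national
    pooled rate, and versant-level pooled rates used as fallback for
    strata without survey effort.
    """

    rates: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int]
    effort: dict[tuple[int, int], float]
    pooled_rate: float
    versant_rates: dict[int, float] = field(default_factory=dict)

    def rate_for(self, versant: int, band: int) -> float:
        """Rate for a stratum, falling back to the versant pool.

        Raises ``KeyError`` when neither the stratum nor its versant was
        surveyed.
        """
        key = (int(versant), int(band))
        if key in self.rates:
            return self.rates[key]
        if int(versant) in self.versant_rates:
            logger.warning(
                "stratum %s unsampled; using versant %d pooled rate %.4f",
                key, int(versant), self.versant_rates[int(versant)],
            )
            return self.versant_rates[int(versant)]
        raise KeyError(f"no rate or fallback for stratum {key}")


def stratum_encounter_rate(records: list[SurveyRecord],
                           count_attr: str = "count_focal") -> StratumRates:
    """Effort-weighted encounter rate per (versant, altitude band).

    Each stratum's rate is its pooled count divided by pooled
    person-hours — the estimate a single merged survey would give —
    not the mean of per-record ratios.
    """
    if not records:
        raise ValueError("no survey records")
    counts: dict[tuple[int, int], int] = {}
    effort: dict[tuple[int, int], float] = {}
    v_counts: dict[int, int] = {}
    v_effort: dict[int, float] = {}
    for rec in records:
        key = rec.stratum
        c = getattr(rec, count_attr)
        counts[key] = counts.get(key, 0) + c
        effort[key] = effort.get(key, 0.0) + rec.person_hours
        v_counts[rec.versant] = v_counts.get(rec.versant, 0) + c
        v_effort[rec.versant] = v_effort.get(rec.versant, 0.0) + rec.person_hours
    for key, e in effort.items():
        if e <= 0:
            raise ValueError(f"zero total effort in stratum {key}")
    rates = {k: counts[k] / effort[k] for k in counts}
    total_effort = sum(effort.values())
    pooled = sum(counts.values()) / total_effort
    versant_rates = {v: v_counts[v] / v_effort[v] for v in v_counts}
    return StratumRates(rates=rates, counts=counts, effort=effort,
                        pooled_rate=pooled, versant_rates=versant_rates)


def relative_abundance(records: list[SurveyRecord], numerator: str = "focal",
                       denominator: str = "all") -> float:
    """Proportion of detections in one species group relative to another.

    Groups are ``"focal"``, ``"venomous"`` or ``"all"``. The field
    convention reports the value truncated (not rounded) to two
    decimals; use :func:`truncate2` for the printed form.
    """
    try:
        num_col = SPECIES_GROUPS[numerator]
        den_col = SPECIES_GROUPS[denominator]
    except KeyError as exc:
        raise ValueError(f"unknown species group {exc.args[0]!r}") from None
    num = sum(getattr(r, num_col) for r in records)
    den = sum(getattr(r, den_col) for r in records)
    if den == 0:
        raise ValueError("denominator count is zero")
    return num / den


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (printed-report convention)."""
    return math.trunc(x * 100) / 100


def extrapolate_surface(rates: StratumRates, mask: PresenceMask,
                        versant: np.ndarray, elevation: np.ndarray) -> np.ndarray:
    """Paint stratum rates over the predicted-presence mask.

    Presence cells receive the rate of their (versant, altitude band)
    stratum — or the versant-level fallback — and absence cells are 0.
    Missing strata with no fallback raise an error naming every
    offending stratum.
    """
    check_aligned(mask.mask, versant, elevation)
    bands = altitude_band(elevation)
    surface = np.zeros(mask.mask.shape, dtype=float)
    present = mask.mask
    missing = []
    for v in np.unique(np.asarray(versant)[present]):
        for b in np.unique(bands[present & (versant == v)]):
            sel = present & (versant == v) & (bands == b)
            try:
                surface[sel] = rates.rate_for(int(v), int(b))
            except KeyError:
                missing.append((int(v), int(b)))
    if missing:
        raise ValueError(f"no rate or fallback for strata {sorted(missing)}")
    return surface


def district_mean_F(surface: np.ndarray, districts: np.ndarray,
                    valid: np.ndarray | None = None) -> pd.Series:
    """Spatially averaged encounter frequency per district.

    The mean runs over every valid cell of the district; cells outside
    the predicted presence contribute their zero, so F_i reflects both
    the within-range rates and the fraction of the district the species
    occupies. Districts with no valid cell get NaN and a warning.
    """
    check_aligned(surface, districts)
    surface = np.asarray(surface, dtype=float)
    districts = np.asarray(districts)
    if valid is None:
        valid = ~np.isnan(surface)
    else:
        valid = np.asarray(valid, dtype=bool) & ~np.isnan(surface)
    ids = np.unique(districts[districts >= 0])
    out = {}
    empty = []
    for d in ids:
        sel = (districts == d) & valid
        if not sel.any():
            empty.append(int(d))
            out[int(d)] = np.nan
        else:
            out[int(d)] = float(surface[sel].mean())
    if empty:
        warnings.warn(f"district(s) {empty} have no valid cells; F undefined")
    return pd.Series(out, name="F").rename_axis("district_id")


def stratum_rates_frame(rates: StratumRates) -> pd.DataFrame:
    """Tabular view of the pooled rates for CSV export."""
    rows = []
    for (v, b), r in sorted(rates.rates.items()):
        rows.append({
            "versant": v,
            "altitude_band": ALTITUDE_BAND_LABELS[b],
            "count": rates.counts[(v, b)],
            "person_hours": rates.effort[(v, b)],
            "rate": r,
        })
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[SurveyRecord]:
    """Build survey records from the standard survey CSV columns."""
    required = ["site_id", "versant", "altitude_band", "person_hours",
                "count_focal", "count_venomous", "count_all"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survey table missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SurveyRecord(
            site_id=str(row["site_id"]),
            versant=int(row["versant"]),
            altitude_band=row["altitude_band"],
            land_cover=str(row.get("land_cover", "open")),
            season=str(row.get("season", "dry")),
            person_hours=float(row["person_hours"]),
            count_focal=int(row["count_focal"]),
            count_venomous=int(row["count_venomous"]),
            count_all_snakes=int(row["count_all"]),
        ))
    return records


def records_to_frame(records: list[SurveyRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "site_id": r.site_id,
            "versant": r.versant,
            "altitude_band": ALTITUDE_BAND_LABELS[r.altitude_band],
            "land_cover": r.land_cover,
            "season": r.season,
            "person_hours": r.person_hours,
            "count_focal": r.count_focal,
            "count_venomous": r.count_venomous,
            "count_all": r.count_all_snakes,
        }
        for r in records
    ])
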