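"""End-to-end orchestration: simulate -> sdm -> encounters -> fit -> report.

Each stage reads and writes the package's standard on-disk formats
(ASCII-grid rasters, headed CSV), so a synthetic run exercises the same
I/O paths a study with real rasters would. One integer seed drives every
stochastic step through derived sub-seeds; two runs with the same config
and seed produce bit-identical CSV and raster outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vipermass import encounter, incidence, io as vio, niche, synth
from vipermass.grids import LandscapeStack, OccurrenceSet

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name, partial artifacts remain."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``synthetic=True`` the input files are generated under
    ``out_dir/inputs`` before the analysis stages run; otherwise the
    ``inputs`` mapping must point at existing rasters and tables.
    """

    seed: int = 0
    out_dir: str = "runs/out"
    synthetic: bool = True
    shape: tuple[int, int] = (60, 80)
    n_covariates: int = 4
    n_districts: int = 30
    n_occurrences: int = 150
    effort_per_stratum: float = 120.0
    target_r2: float = 0.66
    presence_quantile: float = 0.45
    reg: float = 0.1
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    altitude_limit: float = 1200.0
    n_eval_background: int = 1000
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    level: float = 0.99
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.shape = tuple(cfg.shape)
        cfg.feature_classes = tuple(cfg.feature_classes)
        cfg.models = tuple(cfg.models)
        return cfg

    def digest(self) -> str:
        # out_dir is excluded: where results land does not change what
        # is computed, and identical analyses should hash identically.
        payload = {k: list(v) if isinstance(v, tuple) else v
                   for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31, size=n)]


def simulate_inputs(config: RunConfig) -> dict[str, str]:
    """Generate and write the synthetic input files; return their paths.

    The ground-truth species range is defined as the cells whose
    log-linear suitability exceeds the ``presence_quantile`` of its own
    distribution (mirroring a species occupying roughly half the
    territory) and that sit below the altitudinal ceiling. True district
    encounter frequencies are the stratum rates averaged over that
    range, and observed incidence follows the mass-action relation with
    Gaussian noise calibrated to the target R-squared.
    """
    out = Path(config.out_dir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    s_land, s_occ, s_survey, s_census, s_inc = _subseeds(config.seed, 5)

    truth = synth.SyntheticTruth(seed=config.seed)
    if truth.suitability_weights.size != config.n_covariates:
        rng = np.random.default_rng(s_land)
        w = rng.normal(0, 1, size=config.n_covariates)
        truth = synth.SyntheticTruth(suitability_weights=w, seed=config.seed)

    land = synth.generate_landscape(s_land, shape=config.shape,
                                    n_covariates=config.n_covariates,
                                    n_districts=config.n_districts)

    # Ground-truth range: the upper tail of the log-linear suitability,
    # clipped to the altitudinal ceiling. Occurrence records are drawn
    # from within the range only — the species is absent elsewhere.
    covs = land.covariates.reshape(land.n_covariates, -1)
    eta = (truth.suitability_weights @ covs).reshape(land.shape)
    thresh = np.quantile(eta, config.presence_quantile)
    true_presence = (eta >= thresh) & (land.elevation <= config.altitude_limit)

    occ = synth.generate_occurrences(land, truth.suitability_weights,
                                     n=config.n_occurrences, seed=s_occ,
                                     within=true_presence)
    records = synth.generate_survey(truth, config.effort_per_stratum,
                                    seed=s_survey)
    rates = np.zeros(land.shape)
    from vipermass.grids import altitude_band
    bands = altitude_band(land.elevation)
    for (v, b), r in truth.stratum_rates.items():
        rates[(land.versant == v) & (bands == b)] = r
    true_surface = np.where(true_presence, rates, 0.0)
    F_true = encounter.district_mean_F(true_surface, land.district)

    pops = synth.generate_census(config.n_districts, seed=s_census)
    table = pd.DataFrame({
        "district_id": F_true.index.to_numpy(),
        "rural_pop": pops,
        "F": F_true.to_numpy(),
    })
    signal = truth.theta * table["F"] * table["rural_pop"]
    truth_cal = synth.SyntheticTruth(
        suitability_weights=truth.suitability_weights,
        stratum_rates=truth.stratum_rates, theta=truth.theta,
        alpha=truth.alpha,
        noise_sd=synth.noise_sd_for_r2(signal, config.target_r2),
        seed=config.seed,
    )
    table = synth.generate_incidence(table, truth_cal, seed=s_inc)

    paths: dict[str, str] = {}
    for k in range(land.n_covariates):
        p = out / f"covariate_{k}.asc"
        vio.write_ascii_grid(p, land.covariates[k])
        paths[f"covariate_{k}"] = str(p)
    paths["covariates"] = [paths[f"covariate_{k}"]
                           for k in range(land.n_covariates)]
    for name, layer in (("elevation", land.elevation),
                        ("versant", land.versant),
                        ("districts", land.district)):
        p = out / f"{name}.asc"
        vio.write_ascii_grid(p, np.asarray(layer, dtype=float), fmt="%.10g")
        paths[name] = str(p)
    p = out / "occurrences.csv"
    pd.DataFrame(occ.points, columns=["x", "y"]).to_csv(p, index=False)
    paths["occurrences"] = str(p)
    p = out / "survey.csv"
    encounter.records_to_frame(records).to_csv(p, index=False)
    paths["survey"] = str(p)
    p = out / "districts.csv"
    table[["district_id", "rural_pop", "observed_incidence"]].to_csv(p, index=False)
    paths["districts_table"] = str(p)
    truth_out = {
        "theta": truth_cal.theta, "alpha": truth_cal.alpha,
        "noise_sd": truth_cal.noise_sd,
        "suitability_weights": truth_cal.suitability_weights.tolist(),
        "stratum_rates": {f"{v},{b}": r
                          for (v, b), r in truth_cal.stratum_rates.items()},
    }
    vio.write_json_report(out / "truth.json", truth_out)
    paths["truth"] = str(out / "truth.json")
    return paths


def load_stack(paths: dict) -> tuple[LandscapeStack, OccurrenceSet]:
    """Read aligned input rasters and the occurrence table."""
    cov_paths = paths["covariates"]
    metas = {}
    covs = []
    for cp in cov_paths:
        arr, meta = vio.read_ascii_grid(cp)
        covs.append(arr)
        metas[str(cp)] = meta
    elev, m_e = vio.read_ascii_grid(paths["elevation"])
    vers, m_v = vio.read_ascii_grid(paths["versant"])
    dist, m_d = vio.read_ascii_grid(paths["districts"])
    metas.update({"elevation": m_e, "versant": m_v, "districts": m_d})
    common = vio.require_aligned(metas)
    covs = np.stack(covs)
    nodata = np.isnan(covs).any(axis=0) | np.isnan(elev)
    stack = LandscapeStack(
        covariates=covs, elevation=elev,
        versant=np.nan_to_num(vers, nan=-1).astype(int),
        district=np.nan_to_num(dist, nan=-1).astype(int),
        cell_size=common.cellsize, origin=common.origin_upper_left,
        nodata_mask=nodata if nodata.any() else None,
    )
    occ = OccurrenceSet(points=vio.read_occurrences(paths["occurrences"]))
    return stack, occ


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the structured run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.digest(),
                    "stages": {}}
    s_bg, s_auc = _subseeds(config.seed + 1, 2)

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise PipelineError(name, exc) from exc
            report["stages"][name] = result
            logger.info("stage %s: %s", name, result)
            return result
        return deco

    if config.synthetic:
        @stage("simulate")
        def paths():
            return simulate_inputs(config)
    else:
        paths = dict(config.inputs)
        for key in ("elevation", "versant", "districts", "occurrences",
                    "survey", "districts_table"):
            if key not in paths:
                raise PipelineError("load", ValueError(f"missing input {key!r}"))

    @stage("load")
    def loaded():
        stack, occ = load_stack(paths)
        return {"stack": stack, "occurrences": occ,
                "n_cells": stack.n_cells, "n_occurrences": len(occ)}

    stack, occ = loaded["stack"], loaded["occurrences"]

    @stage("sdm")
    def sdm():
        feats = niche.build_features(stack, classes=config.feature_classes)
        model = niche.fit_maxent(occ, stack, features=feats, reg=config.reg,
                                 seed=s_bg)
        suit = niche.predict_suitability(model, stack)
        auc = niche.evaluate_auc(suit, occ, stack,
                                 n_background=config.n_eval_background,
                                 seed=s_auc)
        thresh = niche.zero_omission_threshold(suit, occ, stack)
        mask = niche.make_presence_mask(suit, thresh)
        mask = niche.apply_altitude_mask(mask, stack.elevation,
                                         limit=config.altitude_limit)
        vio.write_ascii_grid(out / "suitability.asc", suit.suitability,
                             fmt="%.8e")
        vio.write_ascii_grid(out / "presence_mask.asc",
                             mask.mask.astype(float), fmt="%d")
        return {"model": model, "suitability": suit, "mask": mask,
                "auc": float(auc), "threshold": float(thresh),
                "presence_fraction": float(mask.mask.mean()),
                "lambdas": model.lambdas.tolist()}

    mask = sdm["mask"]

    @stage("encounters")
    def enc():
        records = encounter.records_from_frame(
            vio.read_table(paths["survey"],
                           required=("site_id", "versant", "altitude_band",
                                     "person_hours", "count_focal",
                                     "count_venomous", "count_all")))
        rates = encounter.stratum_encounter_rate(records)
        surface = encounter.extrapolate_surface(rates, mask, stack.versant,
                                                stack.elevation)
        F = encounter.district_mean_F(surface, stack.district,
                                      valid=stack.valid_mask())
        encounter.stratum_rates_frame(rates).to_csv(
            out / "stratum_rates.csv", index=False)
        vio.write_ascii_grid(out / "encounter_surface.asc", surface,
                             fmt="%.8e")
        F.reset_index().to_csv(out / "district_F.csv", index=False)
        return {"rates": rates, "surface": surface, "F": F,
                "pooled_rate": float(rates.pooled_rate),
                "relative_abundance": float(
                    encounter.relative_abundance(records))}

    @stage("fit")
    def fitted():
        census = vio.read_table(paths["districts_table"],
                                required=("district_id", "rural_pop",
                                          "observed_incidence"))
        table = census.merge(enc["F"].reset_index(), on="district_id",
                             how="inner")
        table = table.dropna(subset=["F"])
        comparison = incidence.compare_models(table, level=config.level)
        best = comparison.fits[1] if 1 in comparison.fits else \
            comparison.fits[comparison.best_model]
        bands = incidence.intervals(best, level=config.level)
        under, over = incidence.flag_outlier_districts(best,
                                                       level=config.level)
        bands["flag"] = np.where(
            bands["district_id"].isin(under), "underestimated",
            np.where(bands["district_id"].isin(over), "overestimated", ""))
        comparison.table.to_csv(out / "model_comparison.csv", index=False)
        bands.to_csv(out / "district_predictions.csv", index=False)
        r, p = incidence.residual_fitted_test(best)
        total, rng_nat = incidence.national_incidence(best,
                                                      level=config.level)
        return {"comparison": comparison, "district_table": table,
                "best_model": int(comparison.best_model),
                "theta_hat": float(best.params.get("theta", np.nan)),
                "alpha_hat": float(best.params.get("alpha", np.nan)),
                "r_squared": float(best.r_squared),
                "aic": float(best.aic),
                "national_incidence": float(total),
                "national_range": [float(rng_nat[0]), float(rng_nat[1])],
                "residual_fitted_r": float(r),
                "residual_fitted_p": float(p),
                "outliers_under": [int(d) for d in under],
                "outliers_over": [int(d) for d in over]}

    summary = {
        "seed": config.seed,
        "config_hash": report["config_hash"],
        "auc": report["stages"]["sdm"]["auc"],
        "threshold": report["stages"]["sdm"]["threshold"],
        "presence_fraction": report["stages"]["sdm"]["presence_fraction"],
        "pooled_rate": report["stages"]["encounters"]["pooled_rate"],
        "relative_abundance": report["stages"]["encounters"]["relative_abundance"],
        **{k: v for k, v in report["stages"]["fit"].items()
           if k not in ("comparison", "district_table")},
    }
    vio.write_json_report(out / "run_report.json", summary)
    report["summary"] = summary
    return report
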