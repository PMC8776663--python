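"""End-to-end analysis: load -> truncate -> MR set -> DS set -> average -> abundance.

`run_analysis` drives the whole double-observer distance-sampling analysis
from a :class:`RunConfig` and writes table-style CSVs plus a JSON summary;
`analyze_dataset` is the library entry point operating on an in-memory
:class:`SurveyDataset` and returning the results bundle as plain dicts and
DataFrames. Floating-point values in the JSON summary are rounded to six
significant digits so identical inputs yield byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from .distance_detection import DSEstimationError, DSFit, select_adjustments
from .model_averaging import ModelEstimate, akaike_weights, model_average
from .mr_detection import MRFit, mr_gof, mr_model_set
from .survey_data import SurveyDataset, binned_summary, load_survey, truncate

__all__ = ["RunConfig", "StageError", "analyze_dataset", "run_analysis"]

log = logging.getLogger("mrdsurvey")

#: the default candidate detection functions: (key, adjustment series)
DEFAULT_DS_MODELS = (
    ("uniform", "cosine"),
    ("hazard_rate", "cosine"),
    ("half_normal", "cosine"),
    ("uniform", "simple_poly"),
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Settings for a full analysis run (parsed from YAML by `from_yaml`)."""

    observations: str = "observations.csv"
    transects: str = "transects.csv"
    strata: list = field(default_factory=list)
    truncation_m: float = 1400.0
    bin_width_m: float = 200.0
    ds_models: Sequence[tuple[str, str]] = DEFAULT_DS_MODELS
    averaging_delta: float = 4.0
    exclude_models: tuple[str, ...] = ()
    extrapolation_areas: Mapping[str, float] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        cfg.ds_models = tuple(tuple(m) for m in cfg.ds_models)
        cfg.exclude_models = tuple(cfg.exclude_models)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _ds_label(key: str, adjustment: str) -> str:
    if key == "uniform":
        return "uniform_cos" if adjustment == "cosine" else "uniform_poly"
    return key


@_stage("fit-ds")
def _fit_ds_set(dataset: SurveyDataset, models, w: float, seed: int) -> list[DSFit]:
    fits: list[DSFit] = []
    labels: list[str] = []
    for key, adjustment in models:
        try:
            fit = select_adjustments(dataset.distances(), key, w, adjustment=adjustment, seed=seed)
        except DSEstimationError as exc:
            log.warning("detection function %s failed: %s", key, exc)
            continue
        fits.append(fit)
        labels.append(_ds_label(key, adjustment))
    if not fits:
        raise DSEstimationError("no detection function could be fit")
    weights = akaike_weights([f.aic for f in fits])
    best = min(f.aic for f in fits)
    for fit, wgt, label in zip(fits, weights, labels):
        fit.delta_aic = fit.aic - best
        fit.weight = float(wgt)
        fit.table_label = label  # type: ignore[attr-defined]
    fits.sort(key=lambda f: f.aic)
    return fits


def _round_sig(x, digits: int = 6):
    if isinstance(x, dict):
        return {k: _round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, digits) for v in x]
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None
        return float(f"{x:.{digits}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def analyze_dataset(
    dataset: SurveyDataset,
    truncation_m: float = 1400.0,
    bin_width_m: float = 200.0,
    ds_models: Sequence[tuple[str, str]] = DEFAULT_DS_MODELS,
    averaging_delta: float = 4.0,
    exclude_models: Sequence[str] = (),
    extrapolation_areas: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict:
    """Run the full MRDS analysis on a dataset and return a results bundle.

    The bundle contains the binned sighting table, the ranked MR and DS
    model tables, per-model and model-averaged abundance rows (with and
    without the ``exclude_models`` set), a CV decomposition, and any
    extrapolations. A single p0*, detection function set, and mean cluster
    size are shared across strata.
    """
    try:
        data = truncate(dataset, truncation_m)
    except Exception as exc:
        raise StageError(f"stage 'truncate' failed: {exc}") from exc
    if data.n_observations == 0:
        raise StageError("stage 'truncate' failed: no observations inside the truncation distance")
    w = truncation_m
    sightings = binned_summary(data, bin_width_m)

    # --- mark-recapture stage: p0* ---------------------------------------
    try:
        mr_set = mr_model_set(data, seed=seed)
    except Exception as exc:
        raise StageError(f"stage 'fit-mr' failed: {exc}") from exc
    mr_rows = []
    for f in mr_set.fits:
        try:
            chi2, dof, p = mr_gof(f, data, bin_width_m)
        except Exception:
            chi2, dof, p = np.nan, 0, np.nan
        mr_rows.append(
            {
                "model": f.label, "delta_aicc": f.delta_aicc, "weight": f.weight,
                "k": f.k, "aicc": f.aicc,
                "p0_front": f.p0_front, "se_p0_front": f.se_p0_front,
                "p0_rear": f.p0_rear, "se_p0_rear": f.se_p0_rear,
                "p0_star": f.p0_star, "se_p0_star": f.se_p0_star,
                "uninformative": f.uninformative, "identifiable": f.identifiable,
                "gof_chi2": chi2, "gof_df": dof, "gof_p": p,
            }
        )
    mr_table = pd.DataFrame(mr_rows)
    mr_avg_set = mr_set.averaging_set(averaging_delta)
    p0_avg, p0_se = model_average(
        [ModelEstimate(f.label, f.p0_star, f.se_p0_star, f.aicc, f.weight) for f in mr_avg_set]
    )

    # --- distance-sampling stage: pd --------------------------------------
    ds_fits = _fit_ds_set(data, ds_models, w, seed)
    ds_table = pd.DataFrame(
        [
            {
                "model": getattr(f, "table_label", f.label), "cvm": f.cvm_stat, "cvm_p": f.cvm_p,
                "df": f.k + 3, "delta_aic": f.delta_aic, "weight": f.weight,
                "pd": f.pd, "se_pd": f.se_pd, "aic": f.aic,
            }
            for f in ds_fits
        ]
    )
    pd_avg, pd_se = model_average(
        [
            ModelEstimate(getattr(f, "table_label", f.label), f.pd, f.se_pd, f.aic, f.weight)
            for f in ds_fits
        ]
    )

    # --- abundance ---------------------------------------------------------
    try:
        g_mean, se_g = ab.mean_group(data)
        per_model: dict[str, ab.AbundanceEstimate] = {}
        model_rows = []
        for f in ds_fits:
            label = getattr(f, "table_label", f.label)
            pa, var_pa = ab.combined_pa(p0_avg, p0_se**2, f.pd, f.se_pd**2)
            est = ab.ht_abundance(data, pa, var_pa, g_mean, se_g**2)
            per_model[label] = est
            model_rows.append(_abundance_row(label, f.weight, est))

        def _averaged(labels: list[str], tag: str) -> dict:
            ests = [
                ModelEstimate(lbl, per_model[lbl].n_total, per_model[lbl].se_n_total,
                              weight=wgt)
                for lbl, wgt in [
                    (getattr(f, "table_label", f.label), f.weight) for f in ds_fits
                ]
                if lbl in labels
            ]
            n_avg, n_se = model_average(ests)
            cv = n_se / n_avg
            lo, hi = ab.lognormal_ci(n_avg, cv)
            row = {
                "model": tag, "weight": float(sum(e.weight for e in ests)),
                "n_hat": n_avg, "se_n_hat": n_se, "cv": cv, "ci_low": lo, "ci_high": hi,
            }
            # model-averaged per-stratum densities with the same weights
            for sid in per_model[labels[0]].density_per_1000km2:
                dens = [
                    ModelEstimate(lbl, per_model[lbl].density_per_1000km2[sid][0],
                                  per_model[lbl].density_per_1000km2[sid][1], weight=e.weight)
                    for lbl, e in zip(labels, ests)
                ]
                row[f"density_{sid}"], row[f"se_density_{sid}"] = model_average(dens)
            return row

        all_labels = [getattr(f, "table_label", f.label) for f in ds_fits]
        avg_all = _averaged(all_labels, f"model_avg_{len(all_labels)}")
        kept = [l for l in all_labels if l not in exclude_models]
        avg_kept = _averaged(kept, f"model_avg_{len(kept)}") if kept != all_labels else None

        pa_avg, var_pa_avg = ab.combined_pa(p0_avg, p0_se**2, pd_avg, pd_se**2)
        est_avg = ab.ht_abundance(data, pa_avg, var_pa_avg, g_mean, se_g**2)
        cv_table = {
            lbl: ab.cv_components(per_model[lbl], p0_avg, p0_se, f.pd, f.se_pd)
            for lbl, f in zip(all_labels, ds_fits)
        }
        cv_table["model_avg"] = ab.cv_components(est_avg, p0_avg, p0_se, pd_avg, pd_se)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'abundance' failed: {exc}") from exc

    # --- extrapolation -----------------------------------------------------
    extrapolations = {}
    low_strata = [s.id for s in data.strata if "low" in (s.label or s.id)]
    if extrapolation_areas and low_strata:
        sid = low_strata[0]
        dens, se_dens = avg_all[f"density_{sid}"], avg_all[f"se_density_{sid}"]
        for name, area in extrapolation_areas.items():
            n, se, (lo, hi) = ab.extrapolate(dens, se_dens, float(area))
            extrapolations[name] = {"bears": n, "se": se, "ci_low": lo, "ci_high": hi}

    abundance_table = pd.DataFrame(
        model_rows + [avg_all] + ([avg_kept] if avg_kept else [])
    )
    return {
        "n_observations": data.n_observations,
        "sightings": sightings,
        "mr_table": mr_table,
        "mr_failures": mr_set.failures,
        "p0_star_avg": p0_avg,
        "se_p0_star_avg": p0_se,
        "ds_table": ds_table,
        "pd_avg": pd_avg,
        "se_pd_avg": pd_se,
        "pa_avg": pa_avg,
        "se_pa_avg": float(np.sqrt(var_pa_avg)),
        "mean_group_size": g_mean,
        "se_mean_group_size": se_g,
        "abundance_table": abundance_table,
        "per_model_estimates": per_model,
        "cv_components": cv_table,
        "extrapolations": extrapolations,
        "model_avg_all": avg_all,
        "model_avg_excluded": avg_kept,
    }


def _abundance_row(label: str, weight: float, est: ab.AbundanceEstimate) -> dict:
    row = {
        "model": label, "weight": weight, "n_hat": est.n_total, "se_n_hat": est.se_n_total,
        "cv": est.cv, "ci_low": est.ci_low, "ci_high": est.ci_high,
    }
    for sid, (dens, se) in est.density_per_1000km2.items():
        row[f"density_{sid}"] = dens
        row[f"se_density_{sid}"] = se
    return row


def run_analysis(config: RunConfig) -> dict:
    """Run the configured analysis and write CSV tables + a JSON summary.

    Outputs land in ``config.out_dir``: sightings.csv, mr_models.csv,
    ds_models.csv, abundance.csv, cv_components.csv and summary.json.
    Stage failures raise :class:`StageError` naming the stage; partial
    outputs written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        dataset = load_survey(config.observations, config.transects, config.strata)
    except Exception as exc:
        raise StageError(f"stage 'load' failed: {exc}") from exc
    log.info("loaded %d observations, %d transects", dataset.n_observations, len(dataset.transects))

    results = analyze_dataset(
        dataset,
        truncation_m=config.truncation_m,
        bin_width_m=config.bin_width_m,
        ds_models=config.ds_models,
        averaging_delta=config.averaging_delta,
        exclude_models=config.exclude_models,
        extrapolation_areas=config.extrapolation_areas,
        seed=config.seed,
    )
    results["sightings"].to_csv(out / "sightings.csv")
    results["mr_table"].to_csv(out / "mr_models.csv", index=False)
    results["ds_table"].to_csv(out / "ds_models.csv", index=False)
    results["abundance_table"].to_csv(out / "abundance.csv", index=False)
    pd.DataFrame(results["cv_components"]).T.to_csv(out / "cv_components.csv")

    summary = {
        "n_observations": results["n_observations"],
        "p0_star_avg": results["p0_star_avg"],
        "se_p0_star_avg": results["se_p0_star_avg"],
        "pd_avg": results["pd_avg"],
        "se_pd_avg": results["se_pd_avg"],
        "pa_avg": results["pa_avg"],
        "se_pa_avg": results["se_pa_avg"],
        "mean_group_size": results["mean_group_size"],
        "se_mean_group_size": results["se_mean_group_size"],
        "model_avg_all": results["model_avg_all"],
        "model_avg_excluded": results["model_avg_excluded"],
        "extrapolations": results["extrapolations"],
        "mr_failures": results["mr_failures"],
        "abundance_rows": results["abundance_table"].to_dict(orient="records"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(_round_sig(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["summary"] = summary
    return results
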