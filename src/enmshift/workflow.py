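"""End-to-end pipeline: clean -> thin -> screen -> calibrate -> select ->
refit replicates -> project -> threshold -> binarize -> change/centroid ->
MESS, driven by a single configuration object (optionally loaded from YAML).

Every stochastic stage consumes a named seed derived from the config seed,
so a rerun with the same config reproduces every number and output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, importance, mess as mess_mod, rangeshift, tuning
from .engine import MaxEntFitter, expand_features, logistic_output, project
from .features import FeatureSpec
from .geodata import EnvStack, Raster, cell_index_arrays, read_ascii_grid, write_ascii_grid
from .occurrences import (
    clean_occurrences,
    read_occurrences_csv,
    split_train_test,
    thin_to_grid,
)

log = logging.getLogger("enmshift")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config",
           "sample_background", "load_stack"]


@dataclass
class PipelineConfig:
    species: str = "species"
    layers_dir: str | None = None
    occurrences_csv: str | None = None
    output_dir: str | None = None
    scenario_dirs: dict = field(default_factory=dict)   # name -> layer dir

    # cleaning
    exclude_landcover: list = field(default_factory=list)
    landcover_layer: str = "LC"

    # variable screening
    screen: bool = True
    min_contrib: float = 1.0
    max_abs_corr: float = 0.8

    # calibration grid (paper-scale defaults: RM 0.1..4.0 step 0.1, 29 FCs)
    rm_values: list = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 41)])
    fc_combos: list = field(default_factory=tuning.default_fc_combinations)

    # model scale
    n_background: int = 10000
    max_iter: int = 5000
    tol: float = 1e-7
    replicates: int = 10
    fraction_train: float = 0.75
    hinge_knots: int = 30
    threshold_knots: int = 20
    clamp: bool = True
    add_presences_to_background: bool = True

    # evaluation
    alpha: float = 0.05
    or_cap: float = 0.05
    proc_boot: int = 500

    compute_mess: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    species: str
    config_hash: str
    seed: int
    cleaning: dict
    n_thinned: int
    retained_variables: list
    calibration: pd.DataFrame
    selected_fc: str
    selected_rm: float
    replicate_metrics: pd.DataFrame
    contribution: pd.Series
    thresholds: dict
    scenario_summaries: pd.DataFrame
    mess_summary: pd.DataFrame | None

    def to_json(self) -> dict:
        return {
            "species": self.species,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "cleaning": self.cleaning,
            "n_thinned": self.n_thinned,
            "retained_variables": self.retained_variables,
            "selected": {"fc": self.selected_fc, "rm": self.selected_rm},
            "replicate_metrics_mean": self.replicate_metrics.mean(numeric_only=True).to_dict(),
            "contribution_pct": self.contribution.to_dict(),
            "thresholds": self.thresholds,
            "scenarios": self.scenario_summaries.to_dict(orient="records"),
            "mess": None if self.mess_summary is None
            else self.mess_summary.to_dict(orient="records"),
        }


def load_stack(layers_dir) -> EnvStack:
    """Load every ``*.asc`` in a directory as a layer named by file stem."""
    paths = sorted(Path(layers_dir).glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc layers in {layers_dir}")
    return EnvStack({p.stem: read_ascii_grid(p) for p in paths})


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def sample_background(stack: EnvStack, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of jointly valid cells without replacement (all cells
    if fewer than n are valid); returns the per-cell variable table."""
    mask = stack.joint_mask()
    rows, cols = np.nonzero(mask)
    rng = np.random.default_rng(seed)
    if rows.size > n:
        idx = rng.choice(rows.size, size=n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return pd.DataFrame({v: stack[v].values[rows, cols] for v in stack.names})


def _presence_table(stack: EnvStack, records, variables=None) -> pd.DataFrame:
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    rows, cols, ok = cell_index_arrays(lons, lats, stack.header)
    if not ok.all():
        raise IndexError("presence records out of bounds")
    names = variables if variables is not None else stack.names
    return pd.DataFrame({v: stack[v].values[rows, cols] for v in names})


def _occurrence_cells(stack: EnvStack, records) -> list[tuple[int, int]]:
    lons = np.array([r.lon for r in records])
    lats = np.array([r.lat for r in records])
    rows, cols, _ = cell_index_arrays(lons, lats, stack.header)
    return list(zip(rows.tolist(), cols.tolist()))


def calibrate(
    records,
    stack: EnvStack,
    variables: list,
    config: PipelineConfig,
) -> tuple[list, pd.DataFrame]:
    """Evaluate the full (FC x RM) grid with a single seeded split each."""
    grid = tuning.make_candidate_grid(config.rm_values, config.fc_combos)
    train, test = split_train_test(records, config.fraction_train, config.seed + 11)
    bg = sample_background(stack.subset(variables), config.n_background, config.seed + 13)
    p_train = _presence_table(stack, train, variables)
    p_test = _presence_table(stack, test, variables)

    results = []
    for cand in grid:
        spec = FeatureSpec.from_label(
            cand.fc, hinge_knots=config.hinge_knots,
            threshold_knots=config.threshold_knots,
        )
        fitter = MaxEntFitter(
            spec, rm=cand.rm, max_iter=config.max_iter, tol=config.tol,
            add_presences_to_background=config.add_presences_to_background,
        )
        model, _ = fitter.fit(p_train, bg, variables)
        fm_tr = expand_features(p_train, model.spec, model.stats)
        fm_te = expand_features(p_test, model.spec, model.stats)
        bg_all = pd.concat([bg, p_train], ignore_index=True) \
            if config.add_presences_to_background else bg
        fm_bg = expand_features(bg_all, model.spec, model.stats)
        s_tr = logistic_output(model, fm_tr)
        s_te = logistic_output(model, fm_te)
        s_bg = logistic_output(model, fm_bg)
        met = tuning.CandidateMetrics()
        met.auc_train = tuning.auc(s_tr, s_bg)
        met.auc_test = tuning.auc(s_te, s_bg)
        met.auc_diff = met.auc_train - met.auc_test
        met.or5 = tuning.omission_rate(s_te, s_tr, q=0.05)
        met.or10 = tuning.omission_rate(s_te, s_tr, q=0.10)
        met.proc_p, met.proc_auc_ratio = tuning.partial_roc(
            s_te, s_bg, e=0.05, n_boot=config.proc_boot, seed=config.seed + 17
        )
        met.aicc = tuning.aicc(model, fm_tr, fm_bg)
        met.k_params = model.k_params
        results.append((cand, met))
        log.info("calibrated fc=%s rm=%.1f aicc=%s", cand.fc, cand.rm,
                 "nan" if met.aicc is None else f"{met.aicc:.2f}")
    return results, tuning.metrics_table(results)


def run_pipeline(
    config: PipelineConfig,
    stack: EnvStack | None = None,
    scenarios: dict | None = None,
    records=None,
) -> RunReport:
    """Execute the full pipeline; in-memory inputs override config paths."""
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if stack is None:
        if not config.layers_dir:
            raise ValueError("no layer stack: set layers_dir or pass stack")
        stack = load_stack(config.layers_dir)
    if scenarios is None:
        scenarios = {
            name: load_stack(d) for name, d in config.scenario_dirs.items()
        }
    if records is None:
        if not config.occurrences_csv:
            raise ValueError("no occurrences: set occurrences_csv or pass records")
        records = read_occurrences_csv(config.occurrences_csv)

    # ---- clean and thin -------------------------------------------------
    records, report = clean_occurrences(
        records, stack, set(config.exclude_landcover), config.landcover_layer
    )
    records, n_thin = thin_to_grid(records, stack.header, config.seed + 7)
    report.n_thinned = n_thin
    report.n_retained = len(records)
    log.info("cleaning: %s", report.to_dict())
    if len(records) < 4:
        raise ValueError("too few occurrence records after cleaning/thinning")

    # ---- variable screening --------------------------------------------
    variables = sorted(stack.names)
    if config.screen and len(variables) > 2:
        bg_screen = sample_background(stack, config.n_background, config.seed + 3)
        p_all = _presence_table(stack, records)
        spec0 = FeatureSpec.from_label("LQH", hinge_knots=config.hinge_knots)
        variables = importance.iterative_variable_screen(
            p_all, bg_screen[sorted(stack.names)], spec0,
            min_contrib=config.min_contrib, max_abs_corr=config.max_abs_corr,
            max_iter=min(config.max_iter, 2000),
        )
        log.info("screen retained: %s", variables)

    # ---- calibration and selection -------------------------------------
    cal_results, cal_table = calibrate(records, stack, variables, config)
    selected = tuning.select_best(cal_results, config.alpha, config.or_cap)
    log.info("selected fc=%s rm=%.2f", selected.fc, selected.rm)

    # ---- replicate refits ----------------------------------------------
    spec = FeatureSpec.from_label(
        selected.fc, hinge_knots=config.hinge_knots,
        threshold_knots=config.threshold_knots,
    )
    rep_rows = []
    contribs = []
    suit_sums: dict[str, np.ndarray] = {}
    mask_ref: dict[str, np.ndarray] = {}
    presence_scores_all = []
    for rep in range(config.replicates):
        rseed = config.seed + 100 + rep
        train, test = split_train_test(records, config.fraction_train, rseed)
        bg = sample_background(stack.subset(variables), config.n_background, rseed + 1)
        p_train = _presence_table(stack, train, variables)
        p_test = _presence_table(stack, test, variables)
        fitter = MaxEntFitter(
            spec, rm=selected.rm, max_iter=config.max_iter, tol=config.tol,
            add_presences_to_background=config.add_presences_to_background,
        )
        model, diag = fitter.fit(p_train, bg, variables)
        fm_tr = expand_features(p_train, model.spec, model.stats)
        fm_te = expand_features(p_test, model.spec, model.stats)
        bg_all = pd.concat([bg, p_train], ignore_index=True) \
            if config.add_presences_to_background else bg
        fm_bg = expand_features(bg_all, model.spec, model.stats)
        s_tr, s_te = logistic_output(model, fm_tr), logistic_output(model, fm_te)
        s_bg = logistic_output(model, fm_bg)
        rep_rows.append(
            {
                "replicate": rep,
                "auc_train": tuning.auc(s_tr, s_bg),
                "auc_test": tuning.auc(s_te, s_bg),
                "auc_diff": tuning.auc(s_tr, s_bg) - tuning.auc(s_te, s_bg),
                "or10": tuning.omission_rate(s_te, s_tr, q=0.10),
                "k_params": model.k_params,
            }
        )
        fm_cols = fm_tr.columns
        contribs.append(importance.percent_contribution(diag, fm_cols).contributions)
        for name, scen_stack in [("current", stack)] + list(scenarios.items()):
            rast = project(model, scen_stack.subset(variables), clamp=config.clamp)
            if name not in suit_sums:
                suit_sums[name] = np.zeros_like(rast.values)
                mask_ref[name] = rast.mask
            suit_sums[name] += np.where(rast.mask, rast.values, 0.0)
        # occurrence-cell scores under this replicate (for thresholds)
        p_all_tab = _presence_table(stack, records, variables)
        fm_all = expand_features(p_all_tab, model.spec, model.stats)
        presence_scores_all.append(logistic_output(model, fm_all))
        bg_scores = s_bg
    replicate_metrics = pd.DataFrame(rep_rows)

    suit_rasters = {
        name: Raster(
            stack.header,
            np.where(mask_ref[name], suit_sums[name] / config.replicates,
                     stack.header.nodata),
            mask_ref[name],
        )
        for name in suit_sums
    }
    contribution = (
        pd.concat(contribs, axis=1).fillna(0.0).mean(axis=1)
        .sort_values(ascending=False)
    )
    contribution = 100.0 * contribution / contribution.sum()

    # ---- thresholds and binarization ------------------------------------
    occ_cells = _occurrence_cells(stack, records)
    mean_presence_scores = np.mean(np.column_stack(presence_scores_all), axis=1)
    tstats = rangeshift.threshold_stats(
        suit_rasters["current"], occ_cells, mean_presence_scores, bg_scores
    )
    thresholds = {
        "mu": tstats.mu,
        "sigma": tstats.sigma,
        "quasi_threshold": tstats.quasi_threshold,
        "maxss_threshold": tstats.maxss_threshold,
        "final_threshold": tstats.final_threshold,
    }
    binmaps = {
        name: rangeshift.binarize(r, tstats.final_threshold)
        for name, r in suit_rasters.items()
    }

    # ---- change maps, areas, centroids ----------------------------------
    cur_centroid = rangeshift.centroid(binmaps["current"])
    scen_rows = [
        {
            "scenario": "current",
            "area_km2": rangeshift.area_km2(binmaps["current"]),
            "centroid_lon": cur_centroid.lon,
            "centroid_lat": cur_centroid.lat,
            "shift_km": 0.0,
            "bearing_deg": float("nan"),
            "retention_km2": float("nan"),
            "gain_km2": float("nan"),
            "loss_km2": float("nan"),
        }
    ]
    change_maps = {}
    for name in scenarios:
        cm = rangeshift.change_map(binmaps["current"], binmaps[name])
        change_maps[name] = cm
        cen = rangeshift.centroid(binmaps[name])
        if cen.defined and cur_centroid.defined:
            dist, bearing = rangeshift.centroid_shift(cur_centroid, cen)
        else:
            dist, bearing = float("nan"), float("nan")
        scen_rows.append(
            {
                "scenario": name,
                "area_km2": rangeshift.area_km2(binmaps[name]),
                "centroid_lon": cen.lon,
                "centroid_lat": cen.lat,
                "shift_km": dist,
                "bearing_deg": bearing,
                "retention_km2": cm.areas_km2["retention"],
                "gain_km2": cm.areas_km2["gain"],
                "loss_km2": cm.areas_km2["loss"],
            }
        )
    scenario_summaries = pd.DataFrame(scen_rows)

    # ---- MESS / MoD ------------------------------------------------------
    mess_summary = None
    mess_results = {}
    if config.compute_mess and scenarios:
        ref = _presence_table(stack, records, variables)
        envelope = mess_mod.build_envelope(ref)
        pts = [(r.lon, r.lat) for r in records]
        mess_rows = []
        for name, scen_stack in scenarios.items():
            res = mess_mod.mess_surface(scen_stack.subset(variables), envelope, pts)
            mess_results[name] = res
            mess_rows.append(
                {
                    "scenario": name,
                    "mean_mess_cells": res.mean_mess_cells,
                    "mean_mess_points": res.mean_mess_points,
                    "pct_novel_cells": float(
                        np.mean(res.mess.values[res.mess.mask] < 0) * 100.0
                    ),
                }
            )
        mess_summary = pd.DataFrame(mess_rows)

    # ---- emit artifacts --------------------------------------------------
    if out_dir:
        cal_table.to_csv(out_dir / "calibration_results.csv", index=False)
        contribution.rename("contribution_pct").to_csv(
            out_dir / "variable_importance.csv"
        )
        scenario_summaries.to_csv(out_dir / "range_change.csv", index=False)
        if mess_summary is not None:
            mess_summary.to_csv(out_dir / "mess_summary.csv", index=False)
        for name, r in suit_rasters.items():
            d = out_dir / name
            d.mkdir(exist_ok=True)
            write_ascii_grid(r, d / "suitability.asc")
            write_ascii_grid(binmaps[name].to_raster(), d / "binary.asc")
        for name, cm in change_maps.items():
            write_ascii_grid(cm.to_raster(), out_dir / name / "change.asc")
        for name, res in mess_results.items():
            write_ascii_grid(res.mess, out_dir / name / "mess.asc")
            write_ascii_grid(res.mod, out_dir / name / "mod.asc")
            pd.DataFrame(
                {"index": range(1, len(res.variables) + 1),
                 "variable": res.variables}
            ).to_csv(out_dir / name / "mod_legend.csv", index=False)
        with open(out_dir / "selected_model.json", "w") as fh:
            json.dump({"fc": selected.fc, "rm": selected.rm}, fh, indent=2)

    run_report = RunReport(
        species=config.species,
        config_hash=config.config_hash(),
        seed=config.seed,
        cleaning=report.to_dict(),
        n_thinned=n_thin,
        retained_variables=list(variables),
        calibration=cal_table,
        selected_fc=selected.fc,
        selected_rm=selected.rm,
        replicate_metrics=replicate_metrics,
        contribution=contribution,
        thresholds=thresholds,
        scenario_summaries=scenario_summaries,
        mess_summary=mess_summary,
    )
    if out_dir:
        with open(out_dir / "run_report.json", "w") as fh:
            json.dump(run_report.to_json(), fh, indent=2, default=float)
    return run_report
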