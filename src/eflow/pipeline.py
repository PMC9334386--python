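"""End-to-end pipeline: synth -> metrics -> alteration -> models -> ecology
-> uncertainty.

Each stage is a function that takes the run configuration and an artifact
directory; stages hand frames to each other in memory when run together and
read the previous stage's CSVs when run standalone (so any stage can start
from precomputed inputs).  Every output table carries a manifest, and the
run writes its resolved configuration (with hash and seed) alongside the
artifacts.  All randomness derives from the configured seed through
per-stage seed sequences, so identical config + seed reproduces every table
byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import alteration as alt
from . import ecology as eco
from . import models as mdl
from . import synthetic as syn
from . import uncertainty as unc
from .config import RunConfig
from .io import (
    read_daily_flow,
    read_table,
    save_reference_pca,
    write_daily_flow,
    write_table,
)
from .metrics import ALL_METRIC_CODES, compute_metric_vector
from .series import screen_record

log = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "stage_synth",
    "stage_metrics",
    "stage_alter",
    "stage_model",
    "stage_ecology",
    "stage_uncertainty",
]

# fixed per-stage tags so standalone stage runs reproduce the full run
_STAGE_SEEDS = {"synth": 1, "metrics": 2, "alter": 3, "model": 4, "ecology": 5}


def _seeds(cfg: RunConfig, stage: str, n: int) -> list[int]:
    ss = np.random.SeedSequence((cfg.seed, _STAGE_SEEDS[stage]))
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _out(path: str | Path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# stage 1: synthetic network, flows, covariates

def stage_synth(cfg: RunConfig, out_dir: str | Path) -> dict:
    out = _out(out_dir)
    seeds = _seeds(cfg, "synth", 2 + 2 * cfg.n_gauges)
    network = syn.generate_gauge_network(
        n_gauges=cfg.n_gauges,
        n_reaches=cfg.n_reaches,
        n_regions=cfg.n_regions,
        n_classes=cfg.n_classes,
        reference_fraction=cfg.reference_fraction,
        huc4_per_region=cfg.huc4_per_region,
        seed=seeds[0],
    )
    class_cfgs = syn.default_class_configs(network.classes)
    flows: dict[str, object] = {}
    for i, g in enumerate(network.gauges):
        ref = syn.simulate_reference_flow(
            g, n_years=cfg.n_years, seed=seeds[2 + 2 * i],
            config=class_cfgs[g.hydro_class],
        )
        obs = (
            ref
            if g.is_reference
            else syn.apply_disturbance(ref, g.disturbance, seed=seeds[3 + 2 * i])
        )
        flows[g.id] = obs
    covariates = syn.generate_covariates(
        network, noise_sd=cfg.covariate_noise_sd, seed=seeds[1]
    )
    gauges = network.gauge_frame()
    reaches = network.reach_frame()
    write_table(gauges, out / "gauges.csv", conventions={"reference": "zero disturbance"})
    write_table(reaches, out / "reaches.csv")
    write_table(covariates, out / "covariates.csv")
    if cfg.write_flows:
        flow_dir = _out(out / "flows")
        ext = "rdb" if cfg.flow_dialect == "nwis-rdb" else "csv"
        for gid, series in flows.items():
            write_daily_flow(series, flow_dir / f"{gid}.{ext}", dialect=cfg.flow_dialect)
    return {"network": network, "flows": flows, "covariates": covariates,
            "gauges": gauges, "reaches": reaches}


# ---------------------------------------------------------------------------
# stage 2: hydrologic indices at gauges

def stage_metrics(cfg: RunConfig, out_dir: str | Path, state: dict | None = None) -> dict:
    out = _out(out_dir)
    state = state or {}
    gauges = state.get("gauges")
    if gauges is None:
        gauges = read_table(out / "gauges.csv")
    flows = state.get("flows")
    if flows is None:
        flow_dir = out / "flows"
        flows = {}
        for gid in gauges.index:
            for ext, dialect in (("csv", "csv"), ("rdb", "nwis-rdb")):
                path = flow_dir / f"{gid}.{ext}"
                if path.exists():
                    flows[gid] = read_daily_flow(
                        path, dialect=dialect, gauge_id=gid,
                        drainage_area_km2=float(gauges.at[gid, "drainage_area_km2"]),
                    )
                    break
            else:
                raise FileNotFoundError(f"no flow record for gauge {gid}")
    rows = {}
    for gid, series in flows.items():
        screened, _ = screen_record(series, start_month=cfg.water_year_start_month)
        mv = compute_metric_vector(
            screened, start_month=cfg.water_year_start_month,
            n_states=cfg.colwell_states,
        )
        rows[gid] = mv.values
    metrics = pd.DataFrame.from_dict(rows, orient="index").loc[list(flows)]
    metrics = metrics[ALL_METRIC_CODES]
    metrics.index.name = "gauge_id"
    write_table(metrics, out / "metrics.csv",
                conventions={"years": "water years Oct-Sep", "units": "cfs"})
    state.update({"gauges": gauges, "metrics": metrics})
    return state


# ---------------------------------------------------------------------------
# stage 3: alteration indices

def stage_alter(cfg: RunConfig, out_dir: str | Path, state: dict | None = None) -> dict:
    out = _out(out_dir)
    state = state or {}
    gauges = state.get("gauges")
    if gauges is None:
        gauges = read_table(out / "gauges.csv")
    metrics = state.get("metrics")
    if metrics is None:
        metrics = read_table(out / "metrics.csv")
    covariates = state.get("covariates")
    if covariates is None:
        covariates = read_table(out / "covariates.csv")
    is_reference = gauges["is_reference"].astype(bool)
    classes = gauges["hydro_class"]
    natural = covariates.loc[metrics.index, syn.NATURAL_COVARIATES]
    expected = alt.estimate_reference_conditions(
        metrics,
        is_reference,
        natural,
        classes,
        unreliable_metrics=set(cfg.unreliable_metrics),
        n_trees=cfg.reference_model_trees,
        seed=_seeds(cfg, "alter", 1)[0],
    )
    alteration = alt.alteration_table(metrics, expected, is_reference)
    # seasonality: cumulative monthly deviation, zero for reference gauges
    seas_raw = pd.Series(0.0, index=metrics.index)
    for gid in metrics.index:
        if is_reference.loc[gid]:
            continue
        seas_raw.loc[gid] = alt.compute_seasonality(
            metrics.loc[gid, alt.MONTHLY_CODES],
            expected.points.loc[gid, alt.MONTHLY_CODES],
            signed=cfg.seasonality_signed,
        )
    pca = alt.fit_reference_pca(metrics, classes, is_reference)
    hai_raw = alt.hai_table(pca, metrics, classes)
    regions = gauges["region"]
    summary = pd.DataFrame(
        {
            "region": regions,
            "seasonality_raw": seas_raw,
            "hai_raw": hai_raw,
            "seasonality": alt.minmax_scale_by_region(seas_raw, regions),
            "hai": alt.minmax_scale_by_region(hai_raw, regions),
        }
    )
    write_table(alteration, out / "alteration.csv",
                conventions={"scale": "[0,1] capped |(O-E)/E|",
                             "seasonality_mode": "signed" if cfg.seasonality_signed
                             else "absolute"})
    write_table(summary, out / "alteration_summary.csv")
    save_reference_pca(pca, out / "pca_bundle")
    state.update({"alteration": alteration, "alteration_summary": summary,
                  "pca": pca, "covariates": covariates, "expected": expected})
    return state


# ---------------------------------------------------------------------------
# stage 4-5: forest models + reach extrapolation

def stage_model(cfg: RunConfig, out_dir: str | Path, state: dict | None = None) -> dict:
    out = _out(out_dir)
    state = state or {}
    gauges = state.get("gauges")
    if gauges is None:
        gauges = read_table(out / "gauges.csv")
    reaches = state.get("reaches")
    if reaches is None:
        reaches = read_table(out / "reaches.csv")
    alteration = state.get("alteration")
    if alteration is None:
        alteration = read_table(out / "alteration.csv")
    covariates = state.get("covariates")
    if covariates is None:
        covariates = read_table(out / "covariates.csv")
    is_reference = gauges["is_reference"].astype(bool)
    gauge_cov = covariates.loc[alteration.index]
    reach_cov = covariates.loc[reaches.index]
    metrics = list(alteration.columns)
    scopes = [mdl.US_SCOPE]
    if cfg.scope_policy == "regional":
        scopes += sorted(gauges["region"].unique())
    seeds = _seeds(cfg, "model", len(metrics) * len(scopes))
    bundles: dict[tuple[str, str], mdl.AlterationModelBundle] = {}
    si = 0
    for metric in metrics:
        for scope in scopes:
            ids = (
                alteration.index
                if scope == mdl.US_SCOPE
                else gauges.index[gauges["region"] == scope]
            )
            bundle = mdl.fit_alteration_model(
                gauge_cov.loc[gauge_cov.index.intersection(ids)],
                alteration.loc[alteration.index.intersection(ids), metric],
                is_reference,
                metric=metric,
                scope=scope,
                n_trees=cfg.n_trees,
                min_gauges=cfg.min_gauges_per_scope,
                mode=cfg.model_mode,
                compute_importance=(
                    scope == mdl.US_SCOPE or not cfg.importance_us_only
                ),
                seed=seeds[si],
            )
            si += 1
            if bundle is not None:
                bundles[(metric, scope)] = bundle
    pred, used = mdl.predict_reach_alteration(
        bundles, reach_cov, reaches["region"], scope_policy=cfg.scope_policy
    )
    perf = pd.DataFrame(
        [
            {
                "metric": b.metric, "scope": b.scope, "n": b.n_train,
                "oob_mse": b.oob_mse, "auc_measure1": b.auc_measure1,
                "auc_measure2": b.auc_measure2,
            }
            for b in bundles.values()
        ]
    )
    imp_rows = []
    for b in bundles.values():
        for cov, ri in b.importance_scaled.items():
            imp_rows.append(
                {"metric": b.metric, "scope": b.scope, "covariate": cov,
                 "ri_scaled": ri, "ri_raw": b.importance[cov]}
            )
    write_table(perf, out / "model_performance_auc.csv", index=False,
                conventions={"auc": "OOB rank-based, midrank ties"})
    write_table(pd.DataFrame(imp_rows), out / "variable_importance_rf.csv", index=False)
    with_imp = [b for b in bundles.values() if len(b.importance_scaled)]
    if with_imp:
        groups = mdl.importance_group_summary(with_imp, syn.COVARIATE_GROUPS)
        write_table(groups, out / "variable_importance_groups.csv",
                    conventions={"ri": "min-max scaled permutation importance"})
    pred_out = pred.copy()
    pred_out.insert(0, "comid_v2", reaches["comid_v2"])
    write_table(pred_out, out / "reach_alteration.csv",
                conventions={"clip": "[0,1]", "scope_policy": cfg.scope_policy})
    write_table(used, out / "reach_alteration_scope.csv")
    state.update({"bundles": bundles, "reach_alteration": pred, "scope_used": used,
                  "performance": perf, "reaches": reaches})
    return state


# ---------------------------------------------------------------------------
# stage 6-7: flow-ecology fits, thresholds, loss probability

def stage_ecology(cfg: RunConfig, out_dir: str | Path, state: dict | None = None) -> dict:
    out = _out(out_dir)
    state = state or {}
    reaches = state.get("reaches")
    if reaches is None:
        reaches = read_table(out / "reaches.csv")
    reach_alt = state.get("reach_alteration")
    if reach_alt is None:
        reach_alt = read_table(out / "reach_alteration.csv").drop(
            columns=["comid_v2"]
        )
    observations = syn.simulate_fish_responses(
        reach_alt,
        true_threshold=cfg.fish_true_threshold,
        max_loss=cfg.fish_max_loss,
        wedge_depth=cfg.fish_wedge_depth,
        seed=_seeds(cfg, "ecology", 1)[0],
        regions=reaches["region"],
        huc4s=reaches["huc4"],
    )
    fits, skipped = eco.fit_quantile_models(
        observations, taus=cfg.taus, min_n=cfg.min_n_quantile
    )
    huc4_to_region = dict(zip(reaches["huc4"], reaches["region"]))
    pooled = eco.pool_region_coefficients(fits, huc4_to_region)
    thresholds = eco.threshold_table(fits + pooled)
    write_table(thresholds, out / "quantile_fits.csv", index=False,
                conventions={"exceedance": "alteration >= T counts as loss",
                             "slope_se": "iid-kernel"})
    if skipped:
        write_table(pd.DataFrame(skipped), out / "quantile_skip_log.csv", index=False)
    loss_rows = []
    responses = {}
    for tau in cfg.taus:
        mats = eco.resolve_threshold_matrices(thresholds, reaches, tau)
        r = eco.classify_exceedance(reach_alt, mats["T"])
        deltas = mats["beta0"] + mats["beta1"] * reach_alt[mats["beta0"].columns]
        lp = eco.loss_probability(r, deltas)
        lp.insert(0, "tau", tau)
        lp.insert(0, "comid_v2", reaches["comid_v2"])
        loss_rows.append(lp)
        responses[tau] = {"R": r, "deltas": deltas, "mats": mats}
    fish_loss = pd.concat(loss_rows)
    fish_loss.index.name = "comid_v1"
    write_table(fish_loss, out / "fish_loss.csv",
                conventions={"p_loss": "mean of binary exceedance over defined metrics"})
    delta_frames = []
    for tau, resp in responses.items():
        d = resp["deltas"].copy()
        d.insert(0, "tau", tau)
        d.insert(0, "comid_v2", reaches["comid_v2"])
        delta_frames.append(d)
    write_table(pd.concat(delta_frames), out / "fishresponses_allmetrics.csv")
    state.update({"thresholds": thresholds, "fish_loss": fish_loss,
                  "responses": responses, "reach_alteration": reach_alt,
                  "reaches": reaches, "observations": observations})
    return state


# ---------------------------------------------------------------------------
# uncertainty propagation

def stage_uncertainty(cfg: RunConfig, out_dir: str | Path, state: dict | None = None) -> dict:
    out = _out(out_dir)
    state = state or {}
    reaches = state.get("reaches")
    if reaches is None:
        reaches = read_table(out / "reaches.csv")
    reach_alt = state.get("reach_alteration")
    if reach_alt is None:
        reach_alt = read_table(out / "reach_alteration.csv").drop(
            columns=["comid_v2"]
        )
    perf = state.get("performance")
    if perf is None:
        perf = read_table(out / "model_performance_auc.csv", index_col=None)
    used = state.get("scope_used")
    if used is None:
        used = read_table(out / "reach_alteration_scope.csv")
    thresholds = state.get("thresholds")
    if thresholds is None:
        thresholds = read_table(out / "quantile_fits.csv", index_col=None)
    fish_loss = state.get("fish_loss")
    if fish_loss is None:
        fish_loss = read_table(out / "fish_loss.csv")
    # error follows each prediction's scope tag
    mse_lookup = perf.set_index(["metric", "scope"])["oob_mse"]
    err = pd.DataFrame(np.nan, index=reach_alt.index, columns=reach_alt.columns)
    for metric in reach_alt.columns:
        for scope in used[metric].dropna().unique():
            if (metric, scope) in mse_lookup.index:
                ids = used.index[used[metric] == scope]
                err.loc[ids, metric] = mse_lookup.loc[(metric, scope)]
    ha_lo, ha_hi = unc.alteration_bounds(reach_alt, err, use_rmse=cfg.use_rmse_bounds)
    bound_rows, curve_rows = [], []
    for tau in cfg.taus:
        mats = eco.resolve_threshold_matrices(thresholds, reaches, tau)
        cols = [c for c in mats["T"].columns if c in reach_alt.columns]
        p_lo, p_hi = unc.loss_probability_bounds(
            ha_lo[cols], ha_hi[cols],
            mats["T_lo"][cols], mats["T_hi"][cols],
            literal_rule=cfg.literal_bound_rule,
        )
        point = fish_loss.loc[np.isclose(fish_loss["tau"], tau), "p_loss"]
        b = pd.DataFrame(
            {"comid_v2": reaches["comid_v2"], "tau": tau,
             "p_loss": point, "p_lower": p_lo, "p_upper": p_hi}
        )
        b.index.name = "comid_v1"
        bound_rows.append(b)
        for name, series in (("point", point), ("lower", p_lo), ("upper", p_hi)):
            curve = unc.cumulative_exceedance_curve(series.dropna())
            curve.insert(0, "bound", name)
            curve.insert(0, "tau", tau)
            curve_rows.append(curve)
    bounds = pd.concat(bound_rows)
    curves = pd.concat(curve_rows)
    write_table(bounds, out / "fish_loss_bounds.csv",
                conventions={"pairing": "literal" if cfg.literal_bound_rule
                             else "ordering-consistent",
                             "alteration_error": "rmse" if cfg.use_rmse_bounds
                             else "mse"})
    write_table(curves, out / "exceedance_curves.csv", index=False)
    state.update({"ha_bounds": (ha_lo, ha_hi), "loss_bounds": bounds,
                  "curves": curves})
    return state


_STAGES = {
    "synth": stage_synth,
    "metrics": stage_metrics,
    "alter": stage_alter,
    "model": stage_model,
    "ecology": stage_ecology,
    "uncertainty": stage_uncertainty,
}
_ORDER = ["synth", "metrics", "alter", "model", "ecology", "uncertainty"]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages in order; returns the state dict.

    Stage failures halt the run with the failing stage named.  The resolved
    configuration (with its hash) is written alongside the artifacts so
    every output directory is self-describing.
    """
    out = _out(out_dir)
    cfg.to_yaml(out / "run_config.yml")
    (out / "run_config_hash.txt").write_text(cfg.config_hash() + "\n")
    state: dict = {}
    for name in _ORDER:
        if name not in cfg.stages:
            log.info("stage %s toggled off", name)
            continue
        log.info("running stage %s", name)
        try:
            if name == "synth":
                state = stage_synth(cfg, out)
            else:
                state = _STAGES[name](cfg, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return state
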