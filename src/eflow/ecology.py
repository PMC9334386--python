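"""Flow-ecology relationships: wedge quantile regressions and tipping points.

Fish-richness residuals (observed minus expected native richness) plotted
against hydrologic alteration form a wedge: the upper envelope declines with
alteration while low residuals occur everywhere.  Linear quantile
regressions (tau = 0.50, 0.75, 0.95) of residual on alteration are fit per
hydrologic metric within each HUC-4 watershed, falling back to unweighted
region-mean coefficients where a HUC-4 lacks sample size.  The alteration at
which a fitted quantile crosses zero — the first expected loss of a native
species — is the tipping point; comparing each reach's modeled alteration to
its thresholds yields a binary exceedance vector whose mean is the
probability of fish-biodiversity loss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "QuantileFit",
    "DEFAULT_TAUS",
    "fit_quantile_models",
    "pool_region_coefficients",
    "derive_threshold",
    "threshold_table",
    "resolve_fits",
    "classify_exceedance",
    "loss_probability",
    "observations_frame",
]

DEFAULT_TAUS = (0.50, 0.75, 0.95)


@dataclass(frozen=True)
class QuantileFit:
    """Linear quantile fit of richness residual on alteration."""

    metric: str
    subregion: str  # huc4 id, or region id for pooled fallback rows
    tau: float
    beta0: float  # intercept, species
    beta1: float  # slope, species per unit alteration
    slope_se: float
    n: int
    provenance: str = "huc4"  # "huc4" | "region-mean"
    se_method: str = "iid-kernel"


def observations_frame(observations) -> pd.DataFrame:
    """Long table (location, region, huc4, metric, alteration, residual) from
    :class:`eflow.synthetic.FishObservation` records or a pre-built frame."""
    if isinstance(observations, pd.DataFrame):
        return observations
    rows = []
    for ob in observations:
        for metric, ha in ob.alterations.items():
            rows.append(
                {
                    "location_id": ob.location_id,
                    "region": ob.region,
                    "huc4": ob.huc4,
                    "metric": metric,
                    "alteration": ha,
                    "residual": ob.richness_residual,
                }
            )
    return pd.DataFrame(rows)


def fit_quantile_models(
    observations,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    min_n: int = 30,
    exclude_metrics: tuple[str, ...] = ("HAI",),
) -> tuple[list[QuantileFit], list[dict]]:
    """Fit residual ~ alteration quantile regressions per metric x HUC-4 x tau.

    Subregion/metric cells with fewer than `min_n` observations or a
    degenerate (constant) alteration gradient are skipped with a logged
    reason.  The cumulative HAI is excluded from ecological fitting by
    default (it is not a single flow component).  Slope standard errors come
    from the asymptotic iid-kernel estimate of the quantile-regression
    sparsity.

    Returns (fits, skip log).
    """
    df = observations_frame(observations)
    fits: list[QuantileFit] = []
    skipped: list[dict] = []
    for (huc4, metric), sub in df.groupby(["huc4", "metric"], sort=True):
        if metric in exclude_metrics:
            continue
        if len(sub) < min_n:
            skipped.append(
                {"subregion": huc4, "metric": metric, "reason": f"n={len(sub)}<{min_n}"}
            )
            continue
        if sub["alteration"].nunique() < 2:
            skipped.append(
                {"subregion": huc4, "metric": metric, "reason": "constant alteration"}
            )
            continue
        model = smf.quantreg("residual ~ alteration", sub)
        for tau in taus:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(q=tau, max_iter=5000)
            fits.append(
                QuantileFit(
                    metric=str(metric),
                    subregion=str(huc4),
                    tau=float(tau),
                    beta0=float(res.params["Intercept"]),
                    beta1=float(res.params["alteration"]),
                    slope_se=float(res.bse["alteration"]),
                    n=len(sub),
                )
            )
    return fits, skipped


def pool_region_coefficients(
    fits: list[QuantileFit],
    huc4_to_region: dict[str, str],
) -> list[QuantileFit]:
    """Region-mean fallback coefficients for HUC-4s without fits.

    Per metric x tau, the unweighted mean of beta0 and beta1 across the
    region's HUC-4 fits; slope SEs pool as the root-mean-square.
    """
    pooled: list[QuantileFit] = []
    by_key: dict[tuple[str, str, float], list[QuantileFit]] = {}
    for f in fits:
        region = huc4_to_region.get(f.subregion)
        if region is None:
            continue
        by_key.setdefault((region, f.metric, f.tau), []).append(f)
    for (region, metric, tau), group in sorted(by_key.items()):
        pooled.append(
            QuantileFit(
                metric=metric,
                subregion=region,
                tau=tau,
                beta0=float(np.mean([f.beta0 for f in group])),
                beta1=float(np.mean([f.beta1 for f in group])),
                slope_se=float(np.sqrt(np.nanmean([f.slope_se**2 for f in group]))),
                n=int(np.sum([f.n for f in group])),
                provenance="region-mean",
            )
        )
    return pooled


def derive_threshold(fit: QuantileFit) -> float | None:
    """Alteration tipping point: zero crossing of the fitted quantile.

    For a declining bound (beta1 < 0): ``T = -beta0/beta1`` clipped to
    [0, 1]; a negative intercept means species are already lost at zero
    alteration (T = 0).  A non-declining bound with beta0 >= 0 never crosses
    zero — the threshold is undefined (None) and the metric drops out of that
    subregion's exceedance vector.
    """
    if fit.beta0 <= 0:
        return 0.0
    if fit.beta1 >= 0:
        log.info(
            "metric %s / %s tau=%.2f: non-declining bound, threshold undefined",
            fit.metric, fit.subregion, fit.tau,
        )
        return None
    return float(np.clip(-fit.beta0 / fit.beta1, 0.0, 1.0))


def threshold_table(fits: list[QuantileFit]) -> pd.DataFrame:
    """Tipping points (with slope-SE bounds) for every fit.

    Columns: metric, subregion, tau, provenance, beta0, beta1, slope_se, n,
    T, T_lo, T_hi.  Undefined thresholds are NaN rows (kept so consumers can
    log coverage).  Bounds come from
    :func:`eflow.uncertainty.threshold_bounds`.
    """
    from .uncertainty import threshold_bounds

    cols = ["metric", "subregion", "tau", "provenance", "beta0", "beta1",
            "slope_se", "n", "T", "T_lo", "T_hi"]
    if not fits:
        return pd.DataFrame(columns=cols)
    rows = []
    for f in fits:
        t = derive_threshold(f)
        if t is None:
            lo = hi = np.nan
            t = np.nan
        else:
            lo, _, hi = threshold_bounds(f)
        rows.append(
            {
                "metric": f.metric,
                "subregion": f.subregion,
                "tau": f.tau,
                "provenance": f.provenance,
                "beta0": f.beta0,
                "beta1": f.beta1,
                "slope_se": f.slope_se,
                "n": f.n,
                "T": t,
                "T_lo": lo,
                "T_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def resolve_fits(
    fits: list[QuantileFit],
    huc4: str,
    region: str,
    tau: float,
) -> dict[str, QuantileFit]:
    """Per-metric fit covering one reach: its HUC-4's fit, else the
    region-mean fallback row."""
    out: dict[str, QuantileFit] = {}
    for f in fits:
        if f.tau != tau:
            continue
        if f.subregion == huc4:
            out[f.metric] = f
        elif f.subregion == region and f.metric not in out:
            out[f.metric] = f
    # huc4 fits win over region rows even when region row seen later
    for f in fits:
        if f.tau == tau and f.subregion == huc4:
            out[f.metric] = f
    return out


def resolve_threshold_matrices(
    thresholds: pd.DataFrame,
    reach_info: pd.DataFrame,
    tau: float,
) -> dict[str, pd.DataFrame]:
    """Per-reach coefficient/threshold matrices for one quantile.

    `thresholds` is the :func:`threshold_table` output (HUC-4 and pooled
    region rows); `reach_info` is indexed by reach id with ``huc4`` and
    ``region`` columns.  Each reach takes its HUC-4's row per metric when one
    exists, else the region-mean fallback; reaches covered by neither stay
    NaN (flagged downstream).  Returns reach x metric frames keyed
    ``"T", "T_lo", "T_hi", "beta0", "beta1"``.
    """
    sub = thresholds[np.isclose(thresholds["tau"], tau)]
    metrics = sorted(sub["metric"].unique())
    cols = ["T", "T_lo", "T_hi", "beta0", "beta1"]
    out = {c: pd.DataFrame(np.nan, index=reach_info.index, columns=metrics) for c in cols}
    huc_rows = sub[sub["provenance"] == "huc4"].set_index(["subregion", "metric"])
    reg_rows = sub[sub["provenance"] == "region-mean"].set_index(["subregion", "metric"])
    for key_col, lookup in (("huc4", huc_rows), ("region", reg_rows)):
        for key, ids in reach_info.groupby(key_col).groups.items():
            for metric in metrics:
                if (key, metric) not in lookup.index:
                    continue
                row = lookup.loc[(key, metric)]
                if key_col == "region":
                    # fallback fills only reaches whose HUC-4 had no fit at
                    # all; an undefined threshold from an existing fit stays
                    # undefined (absence of evidence, not missing coverage)
                    gap = out["beta0"].loc[ids, metric].isna()
                    ids = pd.Index(ids)[gap.to_numpy()]
                    if len(ids) == 0:
                        continue
                for c in cols:
                    out[c].loc[ids, metric] = row[c]
    return out


def classify_exceedance(
    alteration: pd.DataFrame,
    thresholds: pd.DataFrame,
) -> pd.DataFrame:
    """Binary loss indicator per reach x metric.

    `alteration` is reach x metric; `thresholds` is reach x metric of
    resolved tipping points (NaN where undefined).  R = 1 where alteration
    >= T (the boundary counts as loss); NaN where the threshold is
    undefined, excluding the metric from that reach's probability.
    """
    common = [m for m in alteration.columns if m in thresholds.columns]
    a = alteration[common]
    t = thresholds[common].reindex(a.index)
    r = (a.to_numpy() >= t.to_numpy()).astype(float)
    r[np.isnan(t.to_numpy()) | np.isnan(a.to_numpy())] = np.nan
    return pd.DataFrame(r, index=a.index, columns=common)


def loss_probability(
    exceedance: pd.DataFrame,
    deltas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-reach probability of fish-biodiversity loss and richness-delta
    summaries.

    p is the mean of the defined binary responses (NaN when no metric is
    defined for a reach, never 0).  When `deltas` (predicted richness
    residual per metric at the reach's alteration) is given, the median and
    minimum across metrics are appended.
    """
    n_def = exceedance.notna().sum(axis=1)
    p = exceedance.mean(axis=1)  # skipna mean = sum(R)/n_defined
    p[n_def == 0] = np.nan
    out = pd.DataFrame({"p_loss": p, "n_metrics": n_def})
    if deltas is not None:
        out["median_delta"] = deltas.median(axis=1)
        out["min_delta"] = deltas.min(axis=1)
    return out
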