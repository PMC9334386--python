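"""Hydrologic-alteration calculus: per-metric alteration, seasonality, HAI.

Alteration for a single index is the proportional departure of the observed
value O from its expected reference value E, ``|(O - E)/E|`` capped at 1, so
every index lands on a common [0, 1] scale; reference gauges are zero by
definition.  Two cumulative indices summarise multivariate change: a
seasonality index (cumulative proportional deviation of the 12 mean monthly
flows) and the HAI, an eigenvalue-weighted sum of a gauge's significant
principal-component score excursions outside its hydrologic class's
reference envelope.  Component significance uses the broken-stick rule;
both cumulative indices are min-max rescaled within each ecohydrologic
region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

log = logging.getLogger(__name__)

__all__ = [
    "ExpectedConditions",
    "ReferencePCA",
    "estimate_reference_conditions",
    "compute_alteration",
    "alteration_table",
    "compute_seasonality",
    "fit_reference_pca",
    "broken_stick",
    "compute_hai",
    "minmax_scale_by_region",
    "MONTHLY_CODES",
]

MONTHLY_CODES = [f"MA{i}" for i in range(12, 24)]


# ---------------------------------------------------------------------------
# expected (reference) conditions

@dataclass
class ExpectedConditions:
    """Per-gauge expected reference values: model points or class envelopes.

    ``points`` holds model-estimated E per gauge x metric (NaN where the
    metric uses the envelope fallback); ``intervals`` maps each unreliable
    metric to a (lo, hi) frame per gauge.  ``provenance`` records which route
    each metric took.
    """

    points: pd.DataFrame
    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def expected_for(self, gauge_id: str, metric: str):
        """Point E (float) or interval (lo, hi) tuple for one gauge/metric."""
        if metric in self.intervals:
            row = self.intervals[metric].loc[gauge_id]
            return (float(row["lo"]), float(row["hi"]))
        return float(self.points.at[gauge_id, metric])


def estimate_reference_conditions(
    metrics: pd.DataFrame,
    is_reference: pd.Series,
    natural_covariates: pd.DataFrame,
    classes: pd.Series,
    unreliable_metrics: set[str] = frozenset(),
    n_trees: int = 300,
    seed: int = 0,
) -> ExpectedConditions:
    """Expected reference index values at every gauge.

    For each reliable metric an ensemble-of-trees regression is fit on the
    reference gauges' *natural* covariates and used to predict E everywhere.
    Metrics flagged unreliable instead receive the central 90% interval
    (5th-95th percentile) of reference values within the gauge's hydrologic
    class.

    Parameters are tables indexed by gauge id; `classes` maps gauge -> class.
    """
    ref_ids = is_reference[is_reference].index
    if len(ref_ids) == 0:
        raise ValueError("no reference gauges available")
    X_ref = natural_covariates.loc[ref_ids]
    X_all = natural_covariates.loc[metrics.index]
    points = pd.DataFrame(index=metrics.index, columns=metrics.columns, dtype=float)
    intervals: dict[str, pd.DataFrame] = {}
    provenance: dict[str, str] = {}
    rng = np.random.SeedSequence(seed)
    for metric, child in zip(metrics.columns, rng.spawn(len(metrics.columns))):
        if metric in unreliable_metrics:
            provenance[metric] = "class-envelope"
            rows = []
            for gid in metrics.index:
                cls = classes.loc[gid]
                vals = metrics.loc[
                    ref_ids[classes.loc[ref_ids] == cls], metric
                ].dropna()
                if len(vals) == 0:
                    vals = metrics.loc[ref_ids, metric].dropna()
                    warnings.warn(
                        f"class {cls} has no reference gauges; "
                        f"global envelope used for {metric}"
                    )
                if len(vals) == 1:
                    warnings.warn(
                        f"class {cls} has a single reference gauge; "
                        f"degenerate envelope for {metric}"
                    )
                lo, hi = np.percentile(vals, [5, 95])
                rows.append((gid, lo, hi))
            intervals[metric] = pd.DataFrame(
                rows, columns=["gauge_id", "lo", "hi"]
            ).set_index("gauge_id")
        else:
            provenance[metric] = "model"
            y = metrics.loc[ref_ids, metric]
            model = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(child.generate_state(1)[0] % 2**31),
                n_jobs=1,
            )
            model.fit(X_ref.to_numpy(), y.to_numpy())
            points[metric] = model.predict(X_all.to_numpy())
    return ExpectedConditions(points=points, intervals=intervals, provenance=provenance)


# ---------------------------------------------------------------------------
# per-metric alteration

def compute_alteration(observed: float, expected) -> float:
    """Capped proportional alteration of one index value, in [0, 1].

    Point E: ``min(|(O - E)/E|, 1)``.  Interval E = (a, b): 0 when O lies
    inside, else the capped proportional distance to the nearest bound.
    E = 0 conventions (kept so intermittent-stream indices stay defined):
    O = 0 -> 0, O > 0 -> 1; both are logged when triggered.
    """
    o = float(observed)
    if isinstance(expected, tuple):
        a, b = expected
        if a <= o <= b:
            return 0.0
        nearest = a if o < a else b
        return compute_alteration(o, nearest)
    e = float(expected)
    if e == 0.0:
        if o == 0.0:
            return 0.0
        log.debug("alteration with E=0 and O>0: capped to 1")
        return 1.0
    return min(abs((o - e) / e), 1.0)


def alteration_table(
    observed: pd.DataFrame,
    expected: ExpectedConditions,
    is_reference: pd.Series,
) -> pd.DataFrame:
    """Per-gauge x per-metric alteration values in [0, 1].

    Reference gauges are zeroed for every metric, by definition of the
    reference (least-disturbed) condition.
    """
    out = pd.DataFrame(0.0, index=observed.index, columns=observed.columns)
    for gid in observed.index:
        if bool(is_reference.loc[gid]):
            continue
        for metric in observed.columns:
            out.at[gid, metric] = compute_alteration(
                observed.at[gid, metric], expected.expected_for(gid, metric)
            )
    return out


def compute_seasonality(
    observed_monthly: pd.Series | np.ndarray,
    expected_monthly: pd.Series | np.ndarray,
    signed: bool = False,
) -> float:
    """Cumulative proportional deviation of the 12 mean monthly flows.

    Default sums ``|(O_m - E_m)/E_m|`` over the 12 months, so opposite-sign
    seasonal shifts accumulate rather than cancel.  ``signed=True`` sums the
    raw signed terms instead (a literal cumulative difference, retained for
    fidelity with sign-cancelling formulations).  E_m = 0 months follow the
    :func:`compute_alteration` convention.
    """
    o = np.asarray(observed_monthly, dtype=float)
    e = np.asarray(expected_monthly, dtype=float)
    if o.shape != (12,) or e.shape != (12,):
        raise ValueError("need exactly 12 observed and 12 expected monthly means")
    terms = np.empty(12)
    for i in range(12):
        if e[i] == 0.0:
            terms[i] = 0.0 if o[i] == 0.0 else 1.0
            log.debug("seasonality month %d with E=0", i + 1)
        else:
            terms[i] = (o[i] - e[i]) / e[i]
    return float(terms.sum()) if signed else float(np.abs(terms).sum())


# ---------------------------------------------------------------------------
# PCA envelope machinery for the HAI

@dataclass
class ReferencePCA:
    """Fitted PCA of min-max-scaled indices plus per-class score envelopes.

    ``envelopes[cls]`` is a (k, 2) array of (a, b) bounds — the central 90%
    interval of reference-gauge scores per significant component.
    """

    metrics: list[str]
    col_min: pd.Series
    col_max: pd.Series
    mean: np.ndarray  # of the scaled data
    components: np.ndarray  # (n_components, n_metrics) rows = loadings
    eigenvalues: np.ndarray
    k: int
    envelopes: dict[str, np.ndarray]
    dropped_constant: list[str] = field(default_factory=list)

    def transform(self, metrics: pd.DataFrame) -> np.ndarray:
        """Project gauges onto all components (scaled + centered first)."""
        X = metrics[self.metrics].to_numpy(dtype=float)
        denom = (self.col_max - self.col_min).to_numpy()
        X = (X - self.col_min.to_numpy()) / denom
        return (X - self.mean) @ self.components.T

    def scores(self, metrics: pd.DataFrame) -> np.ndarray:
        """Scores on the k significant components only."""
        return self.transform(metrics)[:, : self.k]


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading components significant under the broken-stick rule.

    With p components, the null expected proportion of variance for rank j is
    ``b_j = (1/p) * sum_{i=j..p} 1/i``; components are significant while the
    observed proportion strictly exceeds b_j, stopping at the first failure.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(ev < 0) or np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be non-negative and non-increasing")
    total = ev.sum()
    if total == 0:
        warnings.warn("all-zero eigenvalues; no significant components")
        return 0
    p = ev.size
    props = ev / total
    inv = 1.0 / np.arange(1, p + 1)
    bs = np.cumsum(inv[::-1])[::-1] / p  # b_j = (1/p) sum_{i=j..p} 1/i
    k = 0
    for j in range(p):
        # strict inequality: a proportion exactly on the broken-stick
        # expectation is not significant (tiny eps absorbs float noise)
        if props[j] > bs[j] + 1e-12:
            k += 1
        else:
            break
    return k


def fit_reference_pca(
    metrics: pd.DataFrame,
    classes: pd.Series,
    is_reference: pd.Series,
    envelope_percentiles: tuple[float, float] = (5.0, 95.0),
) -> ReferencePCA:
    """PCA of all gauges' indices with reference-only class score envelopes.

    Each metric column is min-max scaled to [0, 1] and centered; the PCA is
    fit on reference and non-reference gauges jointly, but the per-class
    envelopes (central 90% interval per significant component) use reference
    gauges only.  Constant columns are dropped with a warning.  Loadings
    follow a fixed sign convention (largest-|loading| entry positive) so
    refits are reproducible.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 gauges for the PCA")
    col_min = metrics.min()
    col_max = metrics.max()
    keep = [m for m in metrics.columns if col_max[m] > col_min[m]]
    dropped = [m for m in metrics.columns if m not in keep]
    if dropped:
        warnings.warn(f"dropping constant metric columns: {dropped}")
    X = metrics[keep].to_numpy(dtype=float)
    X = (X - col_min[keep].to_numpy()) / (col_max[keep] - col_min[keep]).to_numpy()
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD-based PCA; eigenvalues are variances of the scores
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (len(metrics) - 1)
    for i in range(vt.shape[0]):  # fixed sign convention
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    k = broken_stick(eigenvalues)
    k = max(k, 1)  # keep at least one axis so the HAI is defined
    pca = ReferencePCA(
        metrics=keep,
        col_min=col_min[keep],
        col_max=col_max[keep],
        mean=mean,
        components=vt,
        eigenvalues=eigenvalues,
        k=k,
        envelopes={},
        dropped_constant=dropped,
    )
    scores = pca.transform(metrics)[:, :k]
    ref_mask = is_reference.loc[metrics.index].to_numpy(dtype=bool)
    lo_p, hi_p = envelope_percentiles
    global_env = np.stack(
        [
            np.percentile(scores[ref_mask], lo_p, axis=0),
            np.percentile(scores[ref_mask], hi_p, axis=0),
        ],
        axis=1,
    ) if ref_mask.any() else None
    if global_env is None:
        raise ValueError("no reference gauges: envelopes undefined")
    for cls in classes.loc[metrics.index].unique():
        in_cls = (classes.loc[metrics.index] == cls).to_numpy() & ref_mask
        if not in_cls.any():
            warnings.warn(f"class {cls}: no reference gauges; global envelope used")
            pca.envelopes[str(cls)] = global_env
            continue
        pca.envelopes[str(cls)] = np.stack(
            [
                np.percentile(scores[in_cls], lo_p, axis=0),
                np.percentile(scores[in_cls], hi_p, axis=0),
            ],
            axis=1,
        )
    return pca


def compute_hai(
    scores: np.ndarray,
    envelopes: np.ndarray,
    eigenvalues: np.ndarray,
) -> float:
    """Raw HAI for one gauge from its significant-component scores.

    Each component contributes ``|S_i - nearest violated bound| * V_i`` when
    its score falls outside the class envelope (a_i, b_i) and 0 otherwise,
    V_i being the component's eigenvalue.
    """
    s = np.asarray(scores, dtype=float)
    env = np.asarray(envelopes, dtype=float)
    v = np.asarray(eigenvalues, dtype=float)[: s.size]
    total = 0.0
    for i in range(s.size):
        a, b = env[i]
        if s[i] < a:
            total += abs(s[i] - a) * v[i]
        elif s[i] > b:
            total += abs(s[i] - b) * v[i]
    return float(total)


def hai_table(pca: ReferencePCA, metrics: pd.DataFrame, classes: pd.Series) -> pd.Series:
    """Raw HAI for every gauge in `metrics` (rows)."""
    scores = pca.scores(metrics)
    out = {}
    for i, gid in enumerate(metrics.index):
        env = pca.envelopes[str(classes.loc[gid])]
        out[gid] = compute_hai(scores[i], env, pca.eigenvalues)
    return pd.Series(out, name="hai_raw")


def minmax_scale_by_region(values: pd.Series, regions: pd.Series) -> pd.Series:
    """Min-max rescale to [0, 1] independently within each region.

    A region whose values are all equal maps to zeros (with a warning); the
    map is rank-preserving within each region.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for region in regions.loc[values.index].unique():
        mask = regions.loc[values.index] == region
        v = values[mask]
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"region {region}: constant values; scaled to 0")
            out[mask] = 0.0
        else:
            out[mask] = (v - lo) / (hi - lo)
    return out
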