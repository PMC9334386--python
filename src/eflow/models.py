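"""Ensemble-of-trees models predicting alteration from disturbance covariates.

One random-forest regression per hydrologic metric and scope (whole-US or a
single ecohydrologic region) maps the 50 disturbance/natural covariates to
the [0, 1] alteration response.  Out-of-bag (OOB) predictions provide
cross-validated error (MSE), two rank-based AUC validation measures
(reference/non-reference control, and high/low alteration at 0.5), and
permutation variable importance min-max rescaled to [0, 1].  Fitted bundles
extrapolate alteration to ungauged stream reaches, clipped to [0, 1].

The [0, 1] response is fit by regression with clipped predictions; a
classification mode on the binarised (> 0.5) response is available for
comparison since continuous alteration values carry no trials count that
would justify a strict binomial likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "AlterationModelBundle",
    "fit_alteration_model",
    "compute_auc_measures",
    "scaled_importance",
    "predict_reach_alteration",
    "importance_group_summary",
]

US_SCOPE = "US"


@dataclass
class AlterationModelBundle:
    """A fitted per-metric, per-scope alteration model with its diagnostics."""

    metric: str
    scope: str  # "US" or a region id
    model: object
    feature_names: list[str]
    oob_mse: float
    auc_measure1: float  # reference vs non-reference control (NaN if undefined)
    auc_measure2: float  # observed alteration > 0.5 control (NaN if undefined)
    importance: pd.Series  # raw permutation importance (delta OOB MSE)
    importance_scaled: pd.Series  # min-max rescaled to [0, 1]
    oob_predictions: pd.Series = field(repr=False, default=None)
    seed: int = 0
    n_train: int = 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"covariate schema mismatch; missing columns: {missing}")
        pred = self.model.predict(X[self.feature_names].to_numpy())
        return np.clip(pred, 0.0, 1.0)


def compute_auc_measures(
    predictions: pd.Series | np.ndarray,
    is_reference: pd.Series | np.ndarray,
    observed: pd.Series | np.ndarray,
    high_cut: float = 0.5,
) -> tuple[float, float]:
    """Rank-based AUCs of predicted alteration against two binary controls.

    Measure 1 scores how well predictions separate non-reference (positive)
    from reference gauges; measure 2 how well they separate observed high
    (> `high_cut`) from low alteration.  Ties are handled by midranks.  A
    measure whose control has a single class is undefined and returned as
    NaN rather than 0.
    """
    pred = np.asarray(predictions, dtype=float)
    labels1 = ~np.asarray(is_reference, dtype=bool)
    labels2 = np.asarray(observed, dtype=float) > high_cut

    def _auc(labels: np.ndarray) -> float:
        if labels.all() or not labels.any():
            return float("nan")
        return float(roc_auc_score(labels.astype(int), pred))

    return _auc(labels1), _auc(labels2)


def _oob_permutation_importance(
    model, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mean increase in MSE when each covariate is permuted.

    Permutes one column at a time and measures the rise in ensemble MSE over
    the unpermuted baseline (forest-level permutation importance).
    """
    base = float(np.mean((model.predict(X) - y) ** 2))
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
        out[j] = float(np.mean((model.predict(Xp) - y) ** 2)) - base
    return out


def scaled_importance(raw: pd.Series) -> pd.Series:
    """Min-max rescale raw importances to [0, 1] within one bundle."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("constant importances; scaled to 0")
        return raw * 0.0
    return (raw - lo) / (hi - lo)


def fit_alteration_model(
    covariates: pd.DataFrame,
    response: pd.Series,
    is_reference: pd.Series,
    metric: str,
    scope: str = US_SCOPE,
    n_trees: int = 300,
    min_gauges: int = 20,
    mode: str = "regression",
    compute_importance: bool = True,
    seed: int = 0,
) -> AlterationModelBundle | None:
    """Fit one alteration model and its OOB diagnostics.

    Returns ``None`` (with a logged reason) when fewer than `min_gauges`
    training gauges are available for the scope — under-sampled strata are
    skipped rather than fit badly.  ``mode="classification"`` fits the
    binarised (> 0.5) response instead of the continuous one.
    ``compute_importance=False`` skips the (relatively costly) permutation
    importance, leaving empty importance series.
    """
    ids = response.dropna().index
    if len(ids) < min_gauges:
        log.info(
            "scope %s / metric %s skipped: %d gauges < %d required",
            scope, metric, len(ids), min_gauges,
        )
        return None
    y = response.loc[ids].to_numpy(dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("alteration response must lie in [0, 1]")
    X = covariates.loc[ids]
    feature_names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "classification":
        model = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        model.fit(Xv, (y > 0.5).astype(int))
        oob_pred = model.oob_decision_function_[:, -1]
    elif mode == "regression":
        model = RandomForestRegressor(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        model.fit(Xv, y)
        oob_pred = model.oob_prediction_
    else:
        raise ValueError(f"unknown mode: {mode}")
    oob_pred = np.clip(oob_pred, 0.0, 1.0)
    oob_mse = float(np.mean((oob_pred - y) ** 2))
    auc1, auc2 = compute_auc_measures(oob_pred, is_reference.loc[ids], y)
    if compute_importance:
        raw_imp = pd.Series(
            _oob_permutation_importance(model, Xv, y, rng), index=feature_names
        )
    else:
        raw_imp = pd.Series(dtype=float)
    return AlterationModelBundle(
        metric=metric,
        scope=scope,
        model=model,
        feature_names=feature_names,
        oob_mse=oob_mse,
        auc_measure1=auc1,
        auc_measure2=auc2,
        importance=raw_imp,
        importance_scaled=scaled_importance(raw_imp) if len(raw_imp) else raw_imp,
        oob_predictions=pd.Series(oob_pred, index=ids),
        seed=seed,
        n_train=len(ids),
    )


def predict_reach_alteration(
    bundles: dict[tuple[str, str], AlterationModelBundle],
    reach_covariates: pd.DataFrame,
    reach_regions: pd.Series,
    scope_policy: str = "regional",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extrapolate alteration to ungauged reaches.

    `bundles` is keyed by (metric, scope).  Under the ``"regional"`` policy
    each reach uses its region's model when one exists, falling back to the
    whole-US model (logged); ``"us"`` always uses the US model.  Returns the
    reach x metric alteration table (clipped to [0, 1]) and a same-shaped
    table of the scope actually used.
    """
    if scope_policy not in ("regional", "us"):
        raise ValueError("scope_policy must be 'regional' or 'us'")
    metrics = sorted({m for m, _ in bundles})
    pred = pd.DataFrame(np.nan, index=reach_covariates.index, columns=metrics)
    used = pd.DataFrame("", index=reach_covariates.index, columns=metrics)
    regions = reach_regions.loc[reach_covariates.index]
    for metric in metrics:
        us_bundle = bundles.get((metric, US_SCOPE))
        if scope_policy == "us":
            groups = [(US_SCOPE, reach_covariates.index)]
        else:
            groups = [(r, regions.index[regions == r]) for r in regions.unique()]
        for scope, ids in groups:
            if len(ids) == 0:
                continue
            bundle = bundles.get((metric, scope))
            tag = scope
            if bundle is None:
                if us_bundle is None:
                    log.warning("metric %s: no model for scope %s nor US", metric, scope)
                    continue
                bundle = us_bundle
                tag = US_SCOPE
                if scope != US_SCOPE:
                    log.info("metric %s scope %s: falling back to US model", metric, scope)
            pred.loc[ids, metric] = bundle.predict(reach_covariates.loc[ids])
            used.loc[ids, metric] = tag
    return pred, used


def importance_group_summary(
    bundles: list[AlterationModelBundle],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Mean and standard error of scaled importance by predictor group.

    Aggregates across all bundles passed in (e.g. all metrics of one region),
    mirroring the grouped variable-importance summaries exported alongside
    the models.
    """
    rows = []
    for group, cols in groups.items():
        vals = np.concatenate(
            [b.importance_scaled.reindex(cols).dropna().to_numpy() for b in bundles]
        ) if bundles else np.array([])
        if vals.size == 0:
            continue
        rows.append(
            {
                "group": group,
                "mean_ri": float(vals.mean()),
                "se_ri": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else 0.0,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("group")
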