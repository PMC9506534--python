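"""Shapley-value interpretation of the trained BP regressor.

Attributions use the *interventional* value function: the payoff of a
coalition S for sample x is the model prediction averaged over a
background set z with the features in S fixed to x's values,

    v_x(S) = mean_z f(x_S, z_{\\bar S}),

and the Shapley value of feature j is the coalition-weighted average of
its marginal contributions.  For tree ensembles this is computed exactly
and efficiently per leaf: for a given (x, z) pair a leaf is reachable for
coalition S iff S contains every path feature where only x satisfies the
leaf's interval (set A, size a) and none where only z does (set B, size
b); features failing for both make the leaf dead.  The resulting
per-leaf Shapley weights have the closed form

    j in A:  +value * (a-1)! b! / (a+b)!
    j in B:  -value * a! (b-1)! / (a+b)!

which this module evaluates vectorized over samples x background.

Local accuracy holds by construction: the base value (mean background
prediction) plus the attribution row sum equals the model prediction.
An exact brute-force enumeration of all 2^M coalitions is provided as an
independent cross-check for small feature counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .estimation import TrainedEstimator

__all__ = [
    "ShapMatrix",
    "ImportanceReport",
    "StratumReport",
    "shap_attributions",
    "brute_force_shapley",
    "global_importance",
    "beeswarm_export",
    "dependence_export",
    "subset_reports",
    "subsample_background",
]


@dataclass
class ShapMatrix:
    """Per-sample per-feature attributions (mmHg) plus the base value."""

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_values: np.ndarray  # matching input matrix
    feature_names: list[str]
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_values = np.asarray(self.feature_values, dtype=float)
        if self.values.shape != self.feature_values.shape:
            raise ValueError("values and feature_values shapes differ")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.values.shape[0])

    @property
    def predictions(self) -> np.ndarray:
        """Model predictions implied by local accuracy."""
        return self.base_value + self.values.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "ShapMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ShapMatrix(
            values=self.values[mask],
            base_value=self.base_value,
            feature_values=self.feature_values[mask],
            feature_names=list(self.feature_names),
            sample_ids=np.asarray(self.sample_ids)[mask],
        )


def subsample_background(
    X: np.ndarray, max_rows: int = 200, seed: int = 0
) -> np.ndarray:
    """Seeded subsample of a feature matrix to use as SHAP background."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= max_rows:
        return X.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=max_rows, replace=False)
    return X[np.sort(idx)]


def _weight_tables(max_depth: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-leaf Shapley weights W_A[a, b], W_B[a, b]."""
    wa = np.zeros((max_depth + 1, max_depth + 1))
    wb = np.zeros((max_depth + 1, max_depth + 1))
    for a in range(max_depth + 1):
        for b in range(max_depth + 1):
            if a >= 1:
                wa[a, b] = (
                    math.factorial(a - 1) * math.factorial(b) / math.factorial(a + b)
                )
            if b >= 1:
                wb[a, b] = (
                    -math.factorial(a) * math.factorial(b - 1) / math.factorial(a + b)
                )
    return wa, wb


def shap_attributions(
    model: TrainedEstimator,
    samples: np.ndarray | pd.DataFrame,
    background: np.ndarray | pd.DataFrame,
) -> ShapMatrix:
    """Tree-exact interventional Shapley attributions.

    ``samples`` and ``background`` must carry the model's features in
    manifest order (DataFrames are reordered by name; a mismatch raises
    with the offending columns).
    """
    X = _check_features(model, samples)
    Z = _check_features(model, background)
    X32 = X.astype(np.float32)  # leaf-interval tests must match xgboost's
    Z32 = Z.astype(np.float32)  # float32 routing
    n, m = X.shape
    mb = Z.shape[0]
    phi = np.zeros((n, m))
    max_path = max(
        (leaf["features"].size for leaves in model.trees for leaf in leaves), default=1
    )
    wa_tab, wb_tab = _weight_tables(max(max_path, 1))
    for leaves in model.trees:
        for leaf in leaves:
            feats = leaf["features"]
            if feats.size == 0:
                continue  # constant leaf contributes equally to f(x) and base
            px = (X32[:, feats] >= leaf["lo"]) & (X32[:, feats] < leaf["hi"])  # (n, k)
            pz = (Z32[:, feats] >= leaf["lo"]) & (Z32[:, feats] < leaf["hi"])  # (mb, k)
            qx = (~px).astype(float)
            qz = (~pz).astype(float)
            pxf = px.astype(float)
            pzf = pz.astype(float)
            a_cnt = pxf @ qz.T  # only-x-passes counts, (n, mb)
            b_cnt = qx @ pzf.T
            both_fail = qx @ qz.T
            alive = both_fail == 0
            ai = a_cnt.astype(int)
            bi = b_cnt.astype(int)
            v = leaf["value"]
            ca = np.where(alive, v * wa_tab[ai, bi], 0.0)
            cb = np.where(alive, v * wb_tab[ai, bi], 0.0)
            # distribute to features: phi[i, f] += mean_j over background
            contrib = pxf * (ca @ qz) / mb + qx * (cb @ pzf) / mb  # (n, k)
            phi[:, feats] += contrib
    base = float(model.predict(Z).mean())
    names = list(model.feature_names)
    fv = X
    return ShapMatrix(values=phi, base_value=base, feature_values=fv, feature_names=names)


def _check_features(model: TrainedEstimator, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features "
            f"({model.feature_names}), got {X.shape[1]} columns"
        )
    return X


def brute_force_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    sample: np.ndarray,
    background: np.ndarray,
    max_features: int = 12,
) -> np.ndarray:
    """Exact Shapley values by enumeration of all 2^M coalitions.

    The value function is interventional: v(S) is the mean prediction over
    the background rows with the coalition's features replaced by the
    sample's values.  Weights are |S|! (M-|S|-1)! / M!.  Intended as an
    independent oracle; limited to ``max_features`` (default 12) because
    of the exponential enumeration — use the tree-exact path beyond that.
    """
    x = np.asarray(sample, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    M = x.size
    if M > max_features:
        raise ValueError(
            f"{M} features exceeds the 2^M enumeration limit ({max_features}); "
            "use the tree-exact attribution path"
        )
    mb = Z.shape[0]
    n_coal = 1 << M
    # batch-evaluate v(S) for every coalition
    big = np.repeat(Z[None, :, :], n_coal, axis=0)  # (n_coal, mb, M)
    for j in range(M):
        sel = (np.arange(n_coal) >> j) & 1
        big[sel == 1, :, j] = x[j]
    v = predict(big.reshape(n_coal * mb, M)).reshape(n_coal, mb).mean(axis=1)
    fact = [math.factorial(k) for k in range(M + 1)]
    phi = np.zeros(M)
    for S in range(n_coal):
        s_size = bin(S).count("1")
        for j in range(M):
            if S >> j & 1:
                continue
            w = fact[s_size] * fact[M - s_size - 1] / fact[M]
            phi[j] += w * (v[S | (1 << j)] - v[S])
    return phi


@dataclass
class ImportanceReport:
    """Global feature importance: mean absolute attribution per feature."""

    importances: pd.Series  # descending, index = feature names

    def __post_init__(self) -> None:
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")

    def top(self, k: int) -> list[str]:
        return list(self.importances.index[:k])

    def rank(self, feature: str) -> int:
        """1-based rank of a feature."""
        return int(np.nonzero(self.importances.index == feature)[0][0]) + 1

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.importances.items()}


def global_importance(shap: ShapMatrix) -> ImportanceReport:
    """Mean |attribution| per feature, sorted descending (ties by name)."""
    if shap.values.shape[0] == 0:
        raise ValueError("empty attribution matrix")
    imp = np.abs(shap.values).mean(axis=0)
    ser = pd.Series(imp, index=shap.feature_names)
    ser = ser.sort_index().sort_values(ascending=False, kind="stable")
    return ImportanceReport(importances=ser)


REMAINDER_LABEL = "sum_of_remaining"


def beeswarm_export(shap: ShapMatrix, top_k: int = 9) -> pd.DataFrame:
    """Long-format beeswarm table for the top-k features.

    One row per (sample, feature) for the ``top_k`` most important
    features plus one aggregate row per sample summing the remaining
    features' attributions (feature value NaN there).
    ``feature_value_rank`` is the feature value's normalized rank within
    its column (0 = smallest, 1 = largest), the quantity beeswarm plots
    encode as color.
    """
    if top_k > len(shap.feature_names):
        raise ValueError("top_k exceeds feature count")
    order = global_importance(shap).importances.index
    top = list(order[:top_k])
    rest = [f for f in shap.feature_names if f not in top]
    name_to_col = {f: i for i, f in enumerate(shap.feature_names)}
    rows = []
    n = shap.values.shape[0]
    ranks = {}
    for f in top:
        col = shap.feature_values[:, name_to_col[f]]
        r = pd.Series(col).rank(method="average", pct=True).to_numpy()
        ranks[f] = (r - 1.0 / n) / (1.0 - 1.0 / n) if n > 1 else np.full(n, 0.5)
    for i in range(n):
        sid = shap.sample_ids[i]
        for f in top:
            c = name_to_col[f]
            rows.append(
                {
                    "sample": sid,
                    "feature": f,
                    "shap_value": shap.values[i, c],
                    "feature_value": shap.feature_values[i, c],
                    "feature_value_rank": ranks[f][i],
                }
            )
        rest_sum = float(
            sum(shap.values[i, name_to_col[f]] for f in rest)
        )
        rows.append(
            {
                "sample": sid,
                "feature": REMAINDER_LABEL,
                "shap_value": rest_sum,
                "feature_value": float("nan"),
                "feature_value_rank": float("nan"),
            }
        )
    return pd.DataFrame(rows)


def dependence_export(
    shap: ShapMatrix, feature: str, trim: tuple[float, float] = (1.0, 99.0)
) -> tuple[pd.DataFrame, float]:
    """(feature value, attribution) pairs with percentile outlier trimming.

    Rows whose feature value lies outside the ``trim`` percentile band are
    removed.  Returns the table and the Spearman rank correlation of the
    retained pairs.
    """
    if feature not in shap.feature_names:
        raise ValueError(f"unknown feature {feature!r}; have {shap.feature_names}")
    from scipy.stats import spearmanr

    c = shap.feature_names.index(feature)
    fv = shap.feature_values[:, c]
    sv = shap.values[:, c]
    lo, hi = np.percentile(fv, trim)
    keep = (fv >= lo) & (fv <= hi)
    table = pd.DataFrame(
        {
            "sample": np.asarray(shap.sample_ids)[keep],
            "feature_value": fv[keep],
            "shap_value": sv[keep],
        }
    )
    if len(table) > 1 and np.ptp(table["feature_value"].to_numpy()) > 0:
        rho = float(spearmanr(table["feature_value"], table["shap_value"]).statistic)
    else:
        rho = float("nan")
    return table, rho


@dataclass
class StratumReport:
    """Importance ranking and beeswarm table of one test-set stratum."""

    name: str
    n: int
    importance: ImportanceReport | None
    beeswarm: pd.DataFrame | None
    empty: bool = False


def subset_reports(
    shap: ShapMatrix,
    predictions: np.ndarray,
    true_bp: np.ndarray,
    mae: float,
    sources: Sequence | None = None,
    top_k: int = 9,
    low_pred_factor: float = 0.8,
    high_pred_factor: float = 1.2,
) -> dict[str, StratumReport]:
    """Stratified attribution reports over the test set.

    Strata: absolute error above twice the MAE; absolute error below half
    the MAE; predictions below ``low_pred_factor`` / above
    ``high_pred_factor`` times the mean prediction (mean taken over the
    full test set before stratification); and one stratum per source
    label.  Empty strata produce a flagged report, not an exception.
    """
    predictions = np.asarray(predictions, dtype=float)
    true_bp = np.asarray(true_bp, dtype=float)
    if predictions.shape[0] != shap.values.shape[0] or true_bp.shape[0] != predictions.shape[0]:
        raise ValueError("misaligned arrays")
    err = np.abs(true_bp - predictions)
    mean_pred = predictions.mean()
    strata: dict[str, np.ndarray] = {
        "high_error": err > 2.0 * mae,
        "low_error": err < 0.5 * mae,
        "low_prediction": predictions < low_pred_factor * mean_pred,
        "high_prediction": predictions > high_pred_factor * mean_pred,
    }
    if sources is not None:
        sources = np.asarray(sources)
        for s in pd.unique(sources):
            strata[f"source:{s}"] = sources == s
    reports: dict[str, StratumReport] = {}
    for name, mask in strata.items():
        n = int(mask.sum())
        if n == 0:
            reports[name] = StratumReport(
                name=name, n=0, importance=None, beeswarm=None, empty=True
            )
            continue
        sub = shap.subset(mask)
        reports[name] = StratumReport(
            name=name,
            n=n,
            importance=global_importance(sub),
            beeswarm=beeswarm_export(sub, top_k=min(top_k, len(shap.feature_names))),
        )
    return reports
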