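"""Blood-pressure regression: subject-wise splitting, sample weighting,
gradient-boosted tree training, median post-filtering and error metrics.

The estimator is an xgboost regressor at library-default hyperparameters
on the 15 morphology features.  Data are split strictly by subject (80%
of the subjects of each source to training), because pooling beats of the
same subject across the split leaks subject identity and flatters the
error.  A pooled (beat-level) split mode reproduces that comparison.

High-pressure beats are down-weighted (weight 0.375 above half the
maximum response in the training set) to counter the imbalance of the BP
distribution.  Predictions and continuous references are median filtered
(kernel 11) per record before metrics; single-cuff sources are not
filtered.

Metrics: MAE, ME (mean of true - estimated, so negative means
overestimation), SDE (population standard deviation of the error) and
Pearson r.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "BeatDataset",
    "SplitSpec",
    "MetricsReport",
    "TrainedEstimator",
    "BloodPressureModel",
    "BloodPressureResults",
    "split_subjects",
    "sample_weights",
    "train_regressor",
    "median_postfilter",
    "compute_metrics",
]

META_COLUMNS = ["subject", "source", "record", "time_index", "response_bp"]


@dataclass
class BeatDataset:
    """Feature rows with response BP, subject, source and time order.

    Wraps a DataFrame with columns ``subject, source, record, time_index,
    response_bp`` plus the 15 features (extra ground-truth columns are
    allowed and preserved).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if self.frame["response_bp"].isna().any():
            raise ValueError("rows with missing response_bp are not allowed")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[FEATURE_NAMES].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["response_bp"].to_numpy(dtype=float)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    @property
    def sources(self) -> np.ndarray:
        return self.frame["source"].to_numpy()

    def drop_incomplete(self) -> tuple["BeatDataset", int]:
        """Remove rows with any missing (NaN) feature; returns (kept, n_dropped)."""
        ok = self.frame[FEATURE_NAMES].notna().all(axis=1)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("dropping %d rows with missing features", n_drop)
        return BeatDataset(self.frame[ok].reset_index(drop=True)), n_drop

    def subset(self, mask: np.ndarray) -> "BeatDataset":
        return BeatDataset(self.frame[np.asarray(mask, bool)].reset_index(drop=True))


@dataclass
class SplitSpec:
    """How to divide beats into training and test sets.

    ``strict`` mode assigns whole subjects (per source) to one side;
    ``pooled`` mode splits beats at random regardless of subject.
    ``co_assignment_groups`` are sets of subject ids whose records must
    share a side (e.g. repeated sessions of the same person).
    """

    mode: str = "strict"  # "strict" | "pooled"
    train_fraction: float = 0.8
    seed: int = 0
    co_assignment_groups: tuple[frozenset, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "pooled"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        self.co_assignment_groups = tuple(frozenset(g) for g in self.co_assignment_groups)


def split_subjects(dataset: BeatDataset, spec: SplitSpec) -> tuple[BeatDataset, BeatDataset]:
    """Split a dataset into training and test sets per the spec.

    Strict mode: within each source, floor(train_fraction * n_units) of
    the subject units go to training, keeping at least one unit on each
    side; co-assigned subjects form a single unit and never straddle the
    split.  Pooled mode: floor(train_fraction * n_rows) random rows train.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "pooled":
        n = len(dataset)
        perm = rng.permutation(n)
        n_train = int(math.floor(spec.train_fraction * n))
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_train]] = True
        return dataset.subset(mask), dataset.subset(~mask)

    group_of: dict = {}
    for g in spec.co_assignment_groups:
        for s in g:
            group_of[s] = g
    train_mask = np.zeros(len(dataset), dtype=bool)
    subjects = dataset.subjects
    for source in pd.unique(dataset.sources):
        src_subjects = pd.unique(subjects[dataset.sources == source])
        units: list[frozenset] = []
        seen: set = set()
        for s in src_subjects:
            u = group_of.get(s, frozenset([s]))
            if u not in seen:
                units.append(u)
                seen.add(u)
        if len(units) < 2:
            raise ValueError(
                f"source {source!r} has {len(units)} subject unit(s); strict split needs >= 2"
            )
        order = rng.permutation(len(units))
        n_train = int(math.floor(spec.train_fraction * len(units)))
        n_train = min(max(n_train, 1), len(units) - 1)
        train_subjects: set = set()
        for i in order[:n_train]:
            train_subjects |= set(units[i])
        in_src = dataset.sources == source
        train_mask |= in_src & np.isin(subjects, sorted(train_subjects))
    return dataset.subset(train_mask), dataset.subset(~train_mask)


def sample_weights(
    train: BeatDataset, threshold_fraction: float = 0.5, high_weight: float = 0.375
) -> np.ndarray:
    """Per-row training weights countering the imbalanced BP distribution.

    Rows whose response exceeds ``threshold_fraction`` of the maximum
    response in the training set get ``high_weight``; all others 1.0.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    y = train.y
    thresh = threshold_fraction * float(y.max())
    return np.where(y > thresh, high_weight, 1.0)


# ---------------------------------------------------------------------------
# Trained estimator: xgboost trees re-evaluated in float64


def _parse_booster(booster) -> tuple[list[list[dict]], float]:
    """Parse an xgboost booster into per-tree leaf interval descriptions.

    Each leaf is ``{"value": v, "features": (k,), "lo": (k,), "hi": (k,)}``
    where a sample reaches the leaf iff ``lo <= x[f] < hi`` for every
    listed feature (intervals merged over the root-to-leaf path).
    """
    df = booster.trees_to_dataframe()
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    trees: list[list[dict]] = []
    for tree_id, tdf in df.groupby("Tree", sort=True):
        nodes = {row.ID: row for row in tdf.itertuples(index=False)}
        root_id = f"{tree_id}-0"
        leaves: list[dict] = []

        def walk(node_id: str, constraints: dict) -> None:
            row = nodes[node_id]
            if row.Feature == "Leaf":
                feats = np.array(sorted(constraints), dtype=int)
                # float32 interval bounds: xgboost routes samples in float32,
                # so membership tests must use the same precision
                lo = np.array([constraints[f][0] for f in feats], dtype=np.float32)
                hi = np.array([constraints[f][1] for f in feats], dtype=np.float32)
                leaves.append(
                    {"value": float(row.Gain), "features": feats, "lo": lo, "hi": hi}
                )
                return
            f = int(str(row.Feature).lstrip("f")) if str(row.Feature).startswith("f") else None
            if f is None:  # feature names stored verbatim
                raise ValueError(f"unexpected feature label {row.Feature!r}")
            split = float(row.Split)
            lo, hi = constraints.get(f, (-np.inf, np.inf))
            # yes branch: x < split
            c_yes = dict(constraints)
            c_yes[f] = (lo, min(hi, split))
            walk(row.Yes, c_yes)
            c_no = dict(constraints)
            c_no[f] = (max(lo, split), hi)
            walk(row.No, c_no)

        walk(root_id, {})
        trees.append(leaves)
    return trees, base_score


@dataclass
class TrainedEstimator:
    """A fitted gradient-boosted BP regressor with a float64 tree evaluator.

    Predictions are computed by re-evaluating the parsed trees in float64
    (sum of reached leaf values plus the base score), which makes the
    Shapley local-accuracy identity hold to machine precision.  The
    underlying sklearn-API model is kept for serialization.
    """

    model: object
    feature_names: list[str]
    trees: list[list[dict]]
    base_score: float
    manifest: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = self._coerce(X).astype(np.float32)  # xgboost routes in float32
        pred = np.full(X.shape[0], self.base_score, dtype=float)
        for leaves in self.trees:
            for leaf in leaves:
                f, lo, hi = leaf["features"], leaf["lo"], leaf["hi"]
                if f.size:
                    sub = X[:, f]
                    mask = ((sub >= lo) & (sub < hi)).all(axis=1)
                    pred += leaf["value"] * mask
                else:
                    pred += leaf["value"]
        return pred

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing}")
            X = X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def _booster(self):
        return self.model.get_booster() if hasattr(self.model, "get_booster") else self.model

    def predict_native(self, X) -> np.ndarray:
        """Prediction through xgboost's own (float32) evaluator."""
        import xgboost as xgb

        X = self._coerce(X)
        model = self.model
        if hasattr(model, "get_booster"):
            return np.asarray(model.predict(X), dtype=float)
        return np.asarray(model.predict(xgb.DMatrix(X)), dtype=float)

    def save(self, model_path, manifest_path) -> None:
        self._booster().save_model(str(model_path))
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, model_path, manifest_path) -> "TrainedEstimator":
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(str(model_path))
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        trees, base_score = _parse_booster(booster)
        return cls(
            model=booster,
            feature_names=list(manifest["feature_names"]),
            trees=trees,
            base_score=base_score,
            manifest=manifest,
        )


def train_regressor(
    train: BeatDataset,
    weights: np.ndarray | None = None,
    response: str = "SBP",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedEstimator:
    """Fit the gradient-boosted tree regressor on the 15 features.

    Hyperparameters are the xgboost library defaults (no tuning) unless
    overridden; they are recorded verbatim in the manifest together with
    the split-independent training metadata.  A fixed seed gives a
    reproducible model.
    """
    import xgboost as xgb

    if len(train) < 100:
        raise ValueError(f"need >= 100 training rows, got {len(train)}")
    X, y = train.X, train.y
    if not np.isfinite(X).all():
        raise ValueError("non-finite features in training data; drop incomplete rows first")
    params = {"random_state": seed, "n_jobs": 1}
    if hyperparams:
        params.update(hyperparams)
    model = xgb.XGBRegressor(**params)
    model.fit(X, y, sample_weight=weights)
    trees, base_score = _parse_booster(model.get_booster())
    manifest = {
        "feature_names": list(FEATURE_NAMES),
        "response": response,
        "hyperparams": {
            k: v for k, v in model.get_params().items() if v is not None and k != "missing"
        },
        "seed": seed,
        "n_train_rows": int(len(train)),
        "weight_rule": "0.375 above half of max training response"
        if weights is not None
        else "uniform",
    }
    return TrainedEstimator(
        model=model,
        feature_names=list(FEATURE_NAMES),
        trees=trees,
        base_score=base_score,
        manifest=manifest,
    )


def median_postfilter(series: np.ndarray, kernel: int = 11) -> np.ndarray:
    """Centered running median with edge-truncated windows.

    Series shorter than the kernel are returned unchanged (with a log
    notice); the kernel must be odd.
    """
    if kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd, got {kernel}")
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < kernel:
        logger.info("series of length %d shorter than kernel %d; returned unchanged", n, kernel)
        return x.copy()
    h = kernel // 2
    return np.array([np.median(x[max(0, i - h) : min(n, i + h + 1)]) for i in range(n)])


@dataclass
class MetricsReport:
    """MAE / ME / SDE (mmHg) and Pearson r for one evaluation stratum."""

    mae: float
    me: float
    sde: float
    r: float | None
    n: int
    stratum: str = "overall"

    def as_dict(self) -> dict:
        return {
            "MAE": self.mae,
            "ME": self.me,
            "SDE": self.sde,
            "r": self.r,
            "n": self.n,
            "stratum": self.stratum,
        }


def compute_metrics(
    true_bp: np.ndarray, predicted_bp: np.ndarray, stratum: str = "overall"
) -> MetricsReport:
    """MAE, ME, SDE and Pearson r of a prediction series.

    ME uses the true-minus-estimated convention (negative ME means
    overestimation); SDE is the population (1/N) standard deviation of the
    error.  r is None when either series has zero variance.
    """
    x = np.asarray(true_bp, dtype=float)
    xh = np.asarray(predicted_bp, dtype=float)
    if x.shape != xh.shape:
        raise ValueError("series lengths differ")
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    err = x - xh
    mae = float(np.mean(np.abs(err)))
    me = float(np.mean(err))
    sde = float(np.sqrt(np.mean((err - me) ** 2)))
    sx = x - x.mean()
    sy = xh - xh.mean()
    denom = math.sqrt(float(np.sum(sx**2)) * float(np.sum(sy**2)))
    r = float(np.sum(sx * sy) / denom) if denom > 0 else None
    return MetricsReport(mae=mae, me=me, sde=sde, r=r, n=n, stratum=stratum)


# ---------------------------------------------------------------------------
# Model / Results facade


class BloodPressureModel:
    """Beat-to-beat BP regression model over a feature dataset.

    Splits the dataset, weights the training rows, fits the boosted
    ensemble and evaluates on the held-out side with per-record median
    post-filtering.

    Parameters
    ----------
    dataset : BeatDataset
        Feature rows with responses.
    response_label : str
        "SBP" or "DBP"; label only, the response column is whatever
        ``response_bp`` holds.
    split : SplitSpec
        Subject-strict by default.
    median_kernel : int
        Post-filter kernel (odd); applied per record on predictions and
        references of sources with continuous references.
    unfiltered_sources : sequence of str
        Sources with single-cuff references, excluded from median
        filtering.
    """

    def __init__(
        self,
        dataset: BeatDataset,
        response_label: str = "SBP",
        split: SplitSpec | None = None,
        hyperparams: dict | None = None,
        median_kernel: int = 11,
        weight_threshold_fraction: float = 0.5,
        high_weight: float = 0.375,
        unfiltered_sources: Sequence[str] = (),
        seed: int = 0,
    ):
        self.dataset, self.n_dropped = dataset.drop_incomplete()
        self.response_label = response_label
        self.split = split if split is not None else SplitSpec(seed=seed)
        self.hyperparams = hyperparams
        self.median_kernel = median_kernel
        self.weight_threshold_fraction = weight_threshold_fraction
        self.high_weight = high_weight
        self.unfiltered_sources = tuple(unfiltered_sources)
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "BloodPressureModel":
        return cls(BeatDataset(frame), **kwargs)

    def fit(self) -> "BloodPressureResults":
        train, test = split_subjects(self.dataset, self.split)
        w = sample_weights(
            train,
            threshold_fraction=self.weight_threshold_fraction,
            high_weight=self.high_weight,
        )
        estimator = train_regressor(
            train,
            weights=w,
            response=self.response_label,
            hyperparams=self.hyperparams,
            seed=self.seed,
        )
        estimator.manifest["split"] = {
            "mode": self.split.mode,
            "train_fraction": self.split.train_fraction,
            "seed": self.split.seed,
        }
        pred_raw = estimator.predict(test.X)

        frame = test.frame.copy()
        frame["predicted_bp_raw"] = pred_raw
        frame["true_bp_filtered"] = frame["response_bp"].astype(float)
        frame["predicted_bp_filtered"] = pred_raw
        for (_, _), idx in frame.groupby(["subject", "record"], sort=False).groups.items():
            sub = frame.loc[idx].sort_values("time_index")
            if sub["source"].iloc[0] in self.unfiltered_sources:
                continue
            frame.loc[sub.index, "predicted_bp_filtered"] = median_postfilter(
                sub["predicted_bp_raw"].to_numpy(), self.median_kernel
            )
            frame.loc[sub.index, "true_bp_filtered"] = median_postfilter(
                sub["response_bp"].to_numpy(), self.median_kernel
            )

        metrics = {
            "overall": compute_metrics(
                frame["true_bp_filtered"].to_numpy(),
                frame["predicted_bp_filtered"].to_numpy(),
                stratum="overall",
            )
        }
        for source in pd.unique(frame["source"]):
            sub = frame[frame["source"] == source]
            if len(sub) >= 2:
                metrics[str(source)] = compute_metrics(
                    sub["true_bp_filtered"].to_numpy(),
                    sub["predicted_bp_filtered"].to_numpy(),
                    stratum=str(source),
                )
        return BloodPressureResults(
            model=self,
            estimator=estimator,
            train=train,
            test=test,
            predictions=frame,
            metrics=metrics,
            train_weights=w,
        )


@dataclass
class BloodPressureResults:
    """Fit results: estimator, held-out predictions and error metrics."""

    model: BloodPressureModel
    estimator: TrainedEstimator
    train: BeatDataset
    test: BeatDataset
    predictions: pd.DataFrame
    metrics: dict[str, MetricsReport]
    train_weights: np.ndarray

    def explain(self, background_size: int = 200, seed: int = 0):
        """Shapley attributions of the test predictions (interventional,
        background subsampled from the training features)."""
        from .interpretation import shap_attributions, subsample_background

        background = subsample_background(self.train.X, background_size, seed=seed)
        return shap_attributions(self.estimator, self.test.X, background)

    def summary(self) -> str:
        m = self.metrics["overall"]
        lines = [
            f"Blood pressure estimation ({self.model.response_label})",
            f"  split: {self.model.split.mode} (train fraction "
            f"{self.model.split.train_fraction}, seed {self.model.split.seed})",
            f"  train rows: {len(self.train)}   test rows: {len(self.test)}",
            f"  MAE  = {m.mae:7.3f} mmHg",
            f"  ME   = {m.me:7.3f} mmHg",
            f"  SDE  = {m.sde:7.3f} mmHg",
            f"  r    = {m.r:7.3f}" if m.r is not None else "  r    = undefined",
        ]
        for name, rep in self.metrics.items():
            if name == "overall":
                continue
            r_txt = f"{rep.r:.3f}" if rep.r is not None else "undef"
            lines.append(
                f"    [{name}] MAE={rep.mae:.3f}  ME={rep.me:.3f}  "
                f"SDE={rep.sde:.3f}  r={r_txt}  n={rep.n}"
            )
        return "\n".join(lines)
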