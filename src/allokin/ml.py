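"""Interpretable models over conformational feature tables.

Feature tables (frames x named features, with a ``label`` column and an
optional ``group`` column identifying the source system of each frame)
are split, fitted with gradient-boosted trees or baseline models,
evaluated, and explained through per-sample additive Shapley
attributions whose mean absolute value ranks features.

Tree models use the exact TreeSHAP attributions computed natively by
XGBoost (``pred_contribs``); other models fall back to a seeded
permutation-sampling Shapley estimator. For a classifier the explained
model output is the log-odds margin, so additivity is checked against
the margin, not the probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from allokin._errors import AllokinError, InvalidParameterError

STRONG, WEAK = "strong", "weak"

#: Reference hyperparameters for the gradient-boosted model; the tree
#: count is scaled down by default (the reference setting of 10,000 is
#: available through ModelSpec.hyperparameters).
GBT_DEFAULTS = {
    "learning_rate": 0.1,
    "n_estimators": 500,
    "max_depth": 11,
    "min_child_weight": 4,
}


class SchemeError(AllokinError):
    """Feature table and learning scheme are incompatible."""


class DegenerateLabelError(AllokinError):
    """Training labels carry no signal to fit (single class)."""


class FeatureMismatchError(AllokinError):
    """Evaluation features do not match the training schema."""


# ---------------------------------------------------------------------------
# Labels and splits
# ---------------------------------------------------------------------------


def label_activity(ic50_uM: float, threshold_uM: float = 0.050) -> str:
    """Binary potency class from IC50 (uM): strictly below the
    threshold is ``strong``; at or above it ``weak`` (documented tie
    rule: the boundary value is weak)."""
    if ic50_uM <= 0:
        raise InvalidParameterError("IC50 must be positive")
    return STRONG if ic50_uM < threshold_uM else WEAK


def split_train_test(
    table: pd.DataFrame,
    fraction: float = 0.70,
    seed: int = 0,
    mode: str = "random-rows",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split.

    ``random-rows`` samples frames independently (the reference
    protocol); ``grouped`` keeps all frames of one group on one side
    (leakage-safe when frames within a system are correlated).
    """
    if table.empty:
        raise InvalidParameterError("table is empty")
    if not 0 < fraction < 1:
        raise InvalidParameterError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "random-rows":
        perm = rng.permutation(len(table))
        n_train = int(round(fraction * len(table)))
        return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]
    if mode == "grouped":
        if "group" not in table.columns or table["group"].nunique() < 2:
            raise SchemeError("grouped split needs >= 2 groups")
        groups = table["group"].unique()
        rng.shuffle(groups)
        train_groups, count = [], 0
        for g in groups:
            if count < fraction * len(table):
                train_groups.append(g)
                count += int((table["group"] == g).sum())
        mask = table["group"].isin(train_groups)
        if mask.all() or not mask.any():
            raise SchemeError("grouped split left one side empty")
        return table[mask], table[~mask]
    raise InvalidParameterError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# Model spec and fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how."""

    task: str = "classification"  # or "regression"
    algorithm: str = "gbt"  # gbt | knn | linear | rf | svm | dt
    hyperparameters: dict = field(default_factory=dict)
    split_fraction: float = 0.70
    seed: int = 0
    n_replicates: int = 1
    split_mode: str = "random-rows"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise InvalidParameterError("split fraction must be in (0,1)")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")


@dataclass
class FittedModel:
    """A fitted estimator plus its schema and task."""

    estimator: object
    feature_names: list[str]
    task: str
    algorithm: str
    classes: list[str] | None = None

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise FeatureMismatchError("feature columns differ from training")
        return X.to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame):
        arr = self._check(X)
        pred = self.estimator.predict(arr)
        if self.task == "classification":
            return np.array([self.classes[int(p)] for p in pred])
        return pred

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        """The continuous model output that attributions explain.

        Regression: the prediction. Classification: the margin
        (log-odds toward the ``strong`` class) when available,
        otherwise the positive-class probability.
        """
        arr = self._check(X)
        if self.task == "regression":
            return np.asarray(self.estimator.predict(arr), dtype=float)
        est = self.estimator
        if self.algorithm == "gbt":
            import xgboost as xgb

            booster = est.get_booster()
            return booster.predict(
                xgb.DMatrix(arr, feature_names=self.feature_names),
                output_margin=True,
            )
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(arr), dtype=float)
        return np.asarray(est.predict_proba(arr)[:, 1], dtype=float)


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    algo, task = spec.algorithm, spec.task
    if algo == "gbt":
        import xgboost as xgb

        params = {**GBT_DEFAULTS, **hp}
        cls = xgb.XGBClassifier if task == "classification" else xgb.XGBRegressor
        return cls(
            **params,
            random_state=spec.seed,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
        )
    from sklearn import (
        linear_model,
        neighbors,
        svm as sk_svm,
        tree as sk_tree,
        ensemble,
    )

    table = {
        ("knn", "classification"): lambda: neighbors.KNeighborsClassifier(**hp),
        ("knn", "regression"): lambda: neighbors.KNeighborsRegressor(**hp),
        ("linear", "classification"): lambda: linear_model.LogisticRegression(
            max_iter=1000, **hp
        ),
        ("linear", "regression"): lambda: linear_model.LinearRegression(**hp),
        ("rf", "classification"): lambda: ensemble.RandomForestClassifier(
            random_state=spec.seed, **hp
        ),
        ("rf", "regression"): lambda: ensemble.RandomForestRegressor(
            random_state=spec.seed, **hp
        ),
        ("svm", "classification"): lambda: sk_svm.SVC(**hp),
        ("svm", "regression"): lambda: sk_svm.SVR(**hp),
        ("dt", "classification"): lambda: sk_tree.DecisionTreeClassifier(
            random_state=spec.seed, **hp
        ),
        ("dt", "regression"): lambda: sk_tree.DecisionTreeRegressor(
            random_state=spec.seed, **hp
        ),
    }
    try:
        return table[(algo, task)]()
    except KeyError:
        raise InvalidParameterError(f"unknown algorithm {algo!r} for {task}")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("label", "group")]


def train_model(train: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit ``spec`` on a feature table with a ``label`` column."""
    cols = _feature_columns(train)
    X = train[cols].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    if spec.task == "classification":
        classes = sorted(set(y))
        if len(classes) < 2:
            raise DegenerateLabelError("training set has a single class")
        if set(classes) == {STRONG, WEAK}:
            classes = [WEAK, STRONG]  # encode strong = 1 (positive class)
        enc = {c: i for i, c in enumerate(classes)}
        y_fit = np.array([enc[v] for v in y])
    else:
        if len(train) < 3:
            raise InvalidParameterError("regression needs >= 3 rows")
        classes = None
        y_fit = y.astype(float)
    est = _make_estimator(spec)
    est.fit(X, y_fit)
    return FittedModel(
        estimator=est,
        feature_names=cols,
        task=spec.task,
        algorithm=spec.algorithm,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ModelMetrics:
    """Evaluation metrics; classification or regression subset is set."""

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    r_squared: float | None = None
    mse: float | None = None
    rmse: float | None = None
    mae: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def evaluate(model: FittedModel, test: pd.DataFrame) -> ModelMetrics:
    """Standard metrics on held-out data (positive class: ``strong``)."""
    if test.empty:
        raise InvalidParameterError("test set is empty")
    cols = _feature_columns(test)
    y_true = test["label"].to_numpy()
    y_pred = model.predict(test[cols])
    if model.task == "classification":
        from sklearn import metrics as skm

        return ModelMetrics(
            accuracy=float(skm.accuracy_score(y_true, y_pred)),
            precision=float(
                skm.precision_score(
                    y_true, y_pred, pos_label=STRONG, zero_division=0
                )
            ),
            recall=float(
                skm.recall_score(y_true, y_pred, pos_label=STRONG, zero_division=0)
            ),
            f1=float(
                skm.f1_score(y_true, y_pred, pos_label=STRONG, zero_division=0)
            ),
        )
    y_true = y_true.astype(float)
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    degenerate = bool(np.ptp(y_true) == 0)
    if degenerate:
        r2 = None
    else:
        from sklearn.metrics import r2_score

        r2 = float(r2_score(y_true, y_pred))
    return ModelMetrics(
        r_squared=r2,
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.mean(np.abs(resid))),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------


@dataclass
class AttributionMatrix:
    """Per-sample per-feature additive attributions."""

    values: np.ndarray  # (n_samples, n_features)
    base_values: np.ndarray  # (n_samples,)
    feature_names: list[str]

    def additivity_residual(self, model_output: np.ndarray) -> float:
        """Max |base + sum(attr) - output| over samples."""
        recon = self.base_values + self.values.sum(axis=1)
        return float(np.max(np.abs(recon - model_output)))


def attribute(
    model: FittedModel,
    samples: pd.DataFrame,
    background: pd.DataFrame | None = None,
    n_permutations: int = 128,
    seed: int = 0,
) -> AttributionMatrix:
    """Shapley attributions of the model output for each sample.

    XGBoost models use exact TreeSHAP (path-dependent); any other model
    falls back, with a warning, to a seeded permutation-sampling
    estimate against a background dataset (default: the samples
    themselves).
    """
    cols = model.feature_names
    X = samples[cols]
    if model.algorithm == "gbt":
        import xgboost as xgb

        booster = model.estimator.get_booster()
        contrib = booster.predict(
            xgb.DMatrix(X.to_numpy(dtype=float), feature_names=cols),
            pred_contribs=True,
        )
        return AttributionMatrix(
            values=np.asarray(contrib[:, :-1], dtype=float),
            base_values=np.asarray(contrib[:, -1], dtype=float),
            feature_names=cols,
        )
    warnings.warn(
        f"exact tree attribution unavailable for {model.algorithm!r}; "
        "falling back to permutation sampling",
        RuntimeWarning,
        stacklevel=2,
    )
    bg = (background if background is not None else samples)[cols].to_numpy(
        dtype=float
    )
    ref = bg.mean(axis=0)
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(dtype=float)
    n, f = arr.shape
    values = np.zeros((n, f))

    def out(rows: np.ndarray) -> np.ndarray:
        df = pd.DataFrame(rows, columns=cols)
        return model.decision_values(df)

    base = float(out(ref[None, :])[0])
    for _ in range(n_permutations):
        order = rng.permutation(f)
        # build the chain of partially-replaced rows for all samples
        cur = np.tile(ref, (n, 1))
        prev_out = out(cur)
        for j in order:
            cur[:, j] = arr[:, j]
            new_out = out(cur)
            values[:, j] += new_out - prev_out
            prev_out = new_out
    values /= n_permutations
    return AttributionMatrix(
        values=values,
        base_values=np.full(n, base),
        feature_names=cols,
    )


@dataclass
class FeatureRanking:
    """Features ordered by mean |attribution| (descending)."""

    features: list[str]
    mean_abs: np.ndarray
    positive_fraction_high: np.ndarray | None = None


def rank_features(
    attr: AttributionMatrix,
    k: int = 20,
    X: pd.DataFrame | None = None,
) -> FeatureRanking:
    """Top-k features by mean absolute attribution, ties by name.

    When sample features ``X`` are given, each feature also gets the
    fraction of positive attributions among samples whose feature value
    lies above its median (the red/high-value direction summary).
    """
    if attr.values.size == 0:
        raise InvalidParameterError("empty attribution matrix")
    mean_abs = np.abs(attr.values).mean(axis=0)
    if k > len(attr.feature_names):
        warnings.warn(
            f"k={k} exceeds {len(attr.feature_names)} features; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
        k = len(attr.feature_names)
    order = sorted(
        range(len(attr.feature_names)),
        key=lambda i: (-mean_abs[i], attr.feature_names[i]),
    )[:k]
    pos_frac = None
    if X is not None:
        pos_frac = np.empty(len(order))
        for out_i, i in enumerate(order):
            col = X[attr.feature_names[i]].to_numpy(dtype=float)
            high = col > np.median(col)
            if high.any():
                pos_frac[out_i] = float((attr.values[high, i] > 0).mean())
            else:
                pos_frac[out_i] = float("nan")
    return FeatureRanking(
        features=[attr.feature_names[i] for i in order],
        mean_abs=mean_abs[order],
        positive_fraction_high=pos_frac,
    )


# ---------------------------------------------------------------------------
# End-to-end schemes
# ---------------------------------------------------------------------------

SCHEMES = {
    "1-traj-ic50": "classification",
    "2-fingerprint-ic50": "classification",
    "3-contacts-ic50": "classification",
    "4-contacts-free-energy": "regression",
}


def run_scheme(
    table: pd.DataFrame,
    scheme: str,
    spec: ModelSpec,
    top_k: int = 20,
) -> tuple[pd.DataFrame, FeatureRanking]:
    """split -> train -> evaluate -> attribute -> rank, replicated.

    Per-replicate seeds derive from the ModelSpec seed. Returns the
    per-replicate metric table (plus mean/sd aggregate rows) and the
    ranking from attributions pooled over replicates' test sets.
    """
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}")
    required = SCHEMES[scheme]
    labels = table["label"]
    continuous = pd.api.types.is_numeric_dtype(labels)
    if required == "regression" and spec.task != "regression":
        raise SchemeError(f"{scheme} uses continuous labels; task must be regression")
    if spec.task == "regression" and not continuous:
        raise SchemeError("regression task needs numeric labels")
    if spec.task == "classification" and continuous:
        raise SchemeError("classification task needs categorical labels")

    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_replicates)
    seeds = [int(s % (2**31)) for s in seeds]
    rows = []
    pooled_abs = None
    ranking = None
    for rep, rep_seed in enumerate(seeds):
        train, test = split_train_test(
            table, spec.split_fraction, rep_seed, spec.split_mode
        )
        model = train_model(train, replace(spec, seed=rep_seed))
        metrics = evaluate(model, test)
        rows.append({"replicate": rep, **metrics.as_dict()})
        attr = attribute(model, test, seed=rep_seed)
        mean_abs = np.abs(attr.values).mean(axis=0)
        pooled_abs = mean_abs if pooled_abs is None else pooled_abs + mean_abs
        if rep == len(seeds) - 1:
            pooled = AttributionMatrix(
                values=(pooled_abs / len(seeds))[None, :],
                base_values=np.zeros(1),
                feature_names=attr.feature_names,
            )
            ranking = rank_features(pooled, k=top_k)
    df = pd.DataFrame(rows)
    agg = df.drop(columns=["replicate"]).agg(["mean", "std"])
    agg.insert(0, "replicate", ["mean", "std"])
    metrics_df = pd.concat([df, agg], ignore_index=True)
    return metrics_df, ranking
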