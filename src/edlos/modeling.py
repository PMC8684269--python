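"""Random-forest training, tuning and model comparison.

Two random-forest classifiers — one on the structured feature set, one
on the unstructured (concept) set — predict the binary long-stay class.
Each model is tuned independently by uniform random search over its
hyperparameter space, scored by mean accuracy over shared, fixed CV
folds, then refit on the full 80% training split and evaluated on the
identical held-out 20% test split.  The comparison reports the paired
metric suite (recall, specificity, precision, accuracy, F1), per-metric
deltas, prediction concordance with its 2x2 agreement table, ranked
feature importances and the selected hyperparameters, and can be
repeated on the intensive-care subgroup with its own split and tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

from .config import SearchSpace, SrfParams
from .features import FeatureBuilder, FeatureMatrix, derive_stay_features
from .synthetic import ICU_WARD

__all__ = [
    "MetricsReport",
    "ComparisonReport",
    "StratificationError",
    "split_train_test",
    "sample_params",
    "random_search_cv",
    "fit_forest",
    "evaluate",
    "concordance",
    "run_comparison",
]

logger = logging.getLogger(__name__)

METRICS = ("recall", "specificity", "precision", "accuracy", "f1")


class StratificationError(ValueError):
    """A CV fold contains a single class; enlarge the data or stratify."""


@dataclass
class MetricsReport:
    """Confusion counts and the derived metric suite (long stay = positive)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            **{m: getattr(self, m) for m in METRICS},
        }


@dataclass
class ComparisonReport:
    """Paired evaluation of the structured and unstructured models."""

    structured: MetricsReport
    unstructured: MetricsReport
    deltas: dict[str, float]
    concordance: float
    agreement_table: dict[str, int]
    best_params: dict[str, dict]
    cv_scores: dict[str, float]
    importances: dict[str, list[tuple[str, float]]]
    n_train: int
    n_test: int
    majority_rate: float
    subgroup: str = "all"
    icu: "ComparisonReport | None" = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "subgroup": self.subgroup,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "majority_rate": self.majority_rate,
            "structured": self.structured.to_dict(),
            "unstructured": self.unstructured.to_dict(),
            "deltas": self.deltas,
            "concordance": self.concordance,
            "agreement_table": self.agreement_table,
            "best_params": self.best_params,
            "cv_scores": self.cv_scores,
            "importances": {k: [[f, v] for f, v in lst] for k, lst in self.importances.items()},
        }
        if self.icu is not None:
            d["icu"] = self.icu.to_dict()
        return d


def split_train_test(
    stay_ids: list[str], fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test partition of the stay ids.

    |train| = round(fraction * n) (banker's rounding); deterministic
    under the seed.  The same partition must be reused for every model
    being compared.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(stay_ids) < 10:
        raise ValueError("need at least 10 stays to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stay_ids))
    n_train = round(fraction * len(stay_ids))
    train = [stay_ids[i] for i in sorted(order[:n_train])]
    test = [stay_ids[i] for i in sorted(order[n_train:])]
    return train, test


def sample_params(space: SearchSpace, rng: np.random.Generator) -> dict:
    """One uniform draw from the integer hyperparameter ranges."""
    return {
        "n_estimators": int(rng.integers(space.n_estimators[0], space.n_estimators[1] + 1)),
        "min_samples_split": int(
            rng.integers(space.min_samples_split[0], space.min_samples_split[1] + 1)
        ),
        "min_samples_leaf": int(
            rng.integers(space.min_samples_leaf[0], space.min_samples_leaf[1] + 1)
        ),
    }


def fit_forest(matrix: FeatureMatrix, params: dict, seed: int = 0) -> RandomForestClassifier:
    """Train the random forest on a feature matrix.

    Majority vote at 0.5, no calibration; feature importances sum to 1.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot fit on an empty matrix")
    clf = RandomForestClassifier(
        n_estimators=params["n_estimators"],
        min_samples_split=params["min_samples_split"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(matrix.values, matrix.labels)
    return clf


def random_search_cv(
    matrix: FeatureMatrix, space: SearchSpace
) -> tuple[dict, float]:
    """Tune one model by random search with fixed cross-validation folds.

    Samples ``n_iterations`` combinations uniformly, scores each by mean
    accuracy over the same ``n_folds`` folds, and returns the best
    (ties: first sampled).  Deterministic under the space seed.
    """
    space.validate()
    rng = np.random.default_rng(space.seed)
    fold_seed = int(rng.integers(2**31))
    tree_seed = int(rng.integers(2**31))
    X, y = matrix.values, matrix.labels
    folds = list(KFold(n_splits=space.n_folds, shuffle=True, random_state=fold_seed).split(X))
    for tr, va in folds:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise StratificationError(
                "a CV fold contains a single class; use more stays or stratified folds"
            )
    best_params, best_score = None, -np.inf
    for it in range(space.n_iterations):
        params = sample_params(space, rng)
        scores = []
        for tr, va in folds:
            clf = RandomForestClassifier(
                n_estimators=params["n_estimators"],
                min_samples_split=params["min_samples_split"],
                min_samples_leaf=params["min_samples_leaf"],
                random_state=tree_seed,
                n_jobs=1,
            )
            clf.fit(X[tr], y[tr])
            scores.append(float(np.mean(clf.predict(X[va]) == y[va])))
        mean_score = float(np.mean(scores))
        logger.debug("search iter %d: %s -> %.4f", it, params, mean_score)
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    return best_params, best_score


def evaluate(predictions: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Confusion counts and metric identities; long stays are positives."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    return MetricsReport(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


def concordance(preds_a: np.ndarray, preds_b: np.ndarray) -> tuple[float, dict[str, int]]:
    """Fraction of identical predictions plus the 2x2 agreement table."""
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    if preds_a.shape != preds_b.shape:
        raise ValueError("prediction vectors differ in length")
    table = {
        "a_long_b_long": int(np.sum((preds_a == 1) & (preds_b == 1))),
        "a_long_b_short": int(np.sum((preds_a == 1) & (preds_b == 0))),
        "a_short_b_long": int(np.sum((preds_a == 0) & (preds_b == 1))),
        "a_short_b_short": int(np.sum((preds_a == 0) & (preds_b == 0))),
    }
    return float(np.mean(preds_a == preds_b)), table


def _one_model(
    name: str,
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    concepts_by_stay: dict[str, set[str]] | None,
    srf_params: SrfParams,
    space: SearchSpace,
    seed: int,
):
    builder = FeatureBuilder(name, srf_params)
    builder.fit(train_df, concepts_by_stay, train_df["long_stay"].to_numpy())
    train_m = builder.transform(train_df, concepts_by_stay)
    test_m = builder.transform(test_df, concepts_by_stay)
    model_space = SearchSpace(
        n_estimators=space.n_estimators,
        min_samples_split=space.min_samples_split,
        min_samples_leaf=space.min_samples_leaf,
        n_iterations=space.n_iterations,
        n_folds=space.n_folds,
        seed=seed,
    )
    best_params, cv_score = random_search_cv(train_m, model_space)
    clf = fit_forest(train_m, best_params, seed=seed)
    preds = clf.predict(test_m.values)
    ranked = sorted(
        zip(train_m.column_names, (float(v) for v in clf.feature_importances_)),
        key=lambda fv: (-fv[1], fv[0]),
    )
    return preds, test_m.labels, best_params, cv_score, ranked


def run_comparison(
    stays: pd.DataFrame,
    concepts_by_stay: dict[str, set[str]],
    srf_params: SrfParams | None = None,
    space: SearchSpace | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    icu_subgroup: bool = False,
    subgroup: str = "all",
) -> ComparisonReport:
    """Full structured-vs-unstructured comparison on one shared split.

    Derives the engineered stay features, splits 80/20, tunes and fits
    both models on the identical training stays, and evaluates on the
    identical test stays.  With ``icu_subgroup`` the whole procedure is
    repeated from scratch within the intensive-care stays (own split,
    own tuning).
    """
    srf_params = (srf_params or SrfParams()).validate()
    space = (space or SearchSpace()).validate()
    df = stays if "long_stay" in stays.columns else derive_stay_features(stays)
    df = df.reset_index(drop=True)

    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(2**31))
    seed_structured = int(rng.integers(2**31))
    seed_unstructured = int(rng.integers(2**31))

    train_ids, test_ids = split_train_test(list(df["stay_id"]), train_fraction, split_seed)
    train_df = df[df["stay_id"].isin(set(train_ids))].reset_index(drop=True)
    test_df = df[df["stay_id"].isin(set(test_ids))].reset_index(drop=True)
    logger.info("split: %d train / %d test stays (subgroup=%s)", len(train_df), len(test_df), subgroup)

    results = {}
    for name, model_seed in (
        ("structured", seed_structured),
        ("unstructured", seed_unstructured),
    ):
        results[name] = _one_model(
            name, train_df, test_df, concepts_by_stay, srf_params, space, model_seed
        )
        logger.info("%s model: best params %s, CV accuracy %.4f", name, results[name][2], results[name][3])

    preds_s, labels, params_s, cv_s, imp_s = results["structured"]
    preds_u, _, params_u, cv_u, imp_u = results["unstructured"]
    report_s = evaluate(preds_s, labels)
    report_u = evaluate(preds_u, labels)
    conc, table = concordance(preds_s, preds_u)
    majority = float(max(np.mean(labels), 1 - np.mean(labels)))

    report = ComparisonReport(
        structured=report_s,
        unstructured=report_u,
        deltas={m: getattr(report_u, m) - getattr(report_s, m) for m in METRICS},
        concordance=conc,
        agreement_table=table,
        best_params={"structured": params_s, "unstructured": params_u},
        cv_scores={"structured": cv_s, "unstructured": cv_u},
        importances={"structured": imp_s[:25], "unstructured": imp_u[:25]},
        n_train=len(train_df),
        n_test=len(test_df),
        majority_rate=majority,
        subgroup=subgroup,
    )

    if icu_subgroup:
        icu_df = df[df["ward"] == ICU_WARD].reset_index(drop=True)
        icu_seed = int(rng.integers(2**31))
        report.icu = run_comparison(
            icu_df,
            concepts_by_stay,
            srf_params=srf_params,
            space=space,
            train_fraction=train_fraction,
            seed=icu_seed,
            icu_subgroup=False,
            subgroup="icu",
        )
    return report
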