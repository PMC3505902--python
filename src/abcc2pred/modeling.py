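"""Cost-sensitive classification of putative transporter substrates.

Organised as a model/results pair: :class:`SubstrateClassifier` holds the
training data and configuration, its :meth:`~SubstrateClassifier.fit`
returns a :class:`SubstrateClassifierResults` carrying the fitted state,
predictions and a ``summary()`` table.

Class imbalance is handled by misclassification costs: a false negative
(a true substrate predicted non-substrate) costs ``fn_cost``, the reverse
error ``fp_cost``.  Costs are realized as instance weights — substrate
instances weigh ``fn_cost``, non-substrates ``fp_cost``, rescaled to sum
to n — passed to the base learner as sample weights where supported, or
through a seeded weighted resample of size n otherwise (k-nearest
neighbours).  Bagging draws bootstrap replicates of the weighted training
set (rows sampled with probability proportional to weight) and aggregates
by majority vote, ties going to the substrate class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1

LEARNERS = ("naive_bayes", "knn", "decision_tree", "random_forest", "linear_svm")

#: learners whose fit() accepts per-instance weights
_WEIGHT_SUPPORT = {"naive_bayes", "decision_tree", "random_forest", "linear_svm"}


@dataclass(frozen=True)
class CostSpec:
    """Misclassification cost pair: fn_cost penalizes missed substrates."""

    fn_cost: float = 1.0
    fp_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.fn_cost <= 0 or self.fp_cost <= 0:
            raise ValueError("costs must be positive")

    @property
    def ratio(self) -> float:
        return self.fn_cost / self.fp_cost

    @classmethod
    def parse(cls, text: str) -> "CostSpec":
        """Parse ``"150:3.5"`` (FN : FP)."""
        fn, fp = (float(t) for t in text.split(":"))
        return cls(fn_cost=fn, fp_cost=fp)

    def __str__(self) -> str:
        return f"{self.fn_cost:g}:{self.fp_cost:g}"


#: cost pairs reported as effective for transporter-substrate data;
#: shipped as preset grid points for the cost search
PRESET_COSTS = (
    CostSpec(65, 2.5),
    CostSpec(150, 3.5),
    CostSpec(81, 1.20),
    CostSpec(80, 1.10),
)


@dataclass
class BaggingConfig:
    """Bootstrap aggregation: B replicates, majority vote."""

    n_estimators: int = 10
    bootstrap: bool = True  # False: identity replicate (diagnostics only)

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("need at least one bagging replicate")


def make_learner(kind: str, seed: int | None = None):
    """Instantiate a base learner with the package's pinned defaults."""
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if kind == "decision_tree":
        return DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=seed
        )
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        )
    if kind == "linear_svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    raise ValueError(f"unknown learner {kind!r}; choose from {LEARNERS}")


def cost_weights(y: np.ndarray, cost: CostSpec) -> np.ndarray:
    """Instance weights realizing the cost pair, rescaled to sum to n."""
    w = np.where(np.asarray(y) == 1, cost.fn_cost, cost.fp_cost).astype(float)
    return w * (len(w) / w.sum())


def _restrict(X: pd.DataFrame, features) -> pd.DataFrame:
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    return X[list(features)]


class SubstrateClassifier:
    """Cost-sensitive substrate/non-substrate classifier.

    Parameters
    ----------
    X : pandas.DataFrame
        Z-scored descriptor matrix (compounds x descriptors).
    y : sequence of int
        Binary labels, 1 = substrate.
    features : sequence of str, optional
        Descriptor subset to model on (e.g. from CFS); defaults to all
        columns.
    learner : str
        One of ``naive_bayes, knn, decision_tree, random_forest,
        linear_svm``.
    cost : CostSpec
        Misclassification cost pair (FN : FP).
    bagging : BaggingConfig, optional
        Bootstrap aggregation around the cost-sensitive base learner.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        features=None,
        learner: str = "random_forest",
        cost: CostSpec = CostSpec(),
        bagging: BaggingConfig | None = None,
    ):
        self.features = list(features) if features is not None else list(X.columns)
        self.X = _restrict(X, self.features)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        classes = np.unique(self.y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        self.learner = learner
        self.cost = cost
        self.bagging = bagging

    def fit(self, seed: int | None = 0) -> "SubstrateClassifierResults":
        rng = np.random.default_rng(seed)
        w = cost_weights(self.y, self.cost)
        Xv = self.X.to_numpy(dtype=float)
        if self.bagging is None:
            estimators = [self._fit_single(Xv, self.y, w, seed, rng)]
        else:
            estimators = []
            for b in range(self.bagging.n_estimators):
                if self.bagging.bootstrap:
                    idx = rng.choice(len(Xv), size=len(Xv), replace=True, p=w / w.sum())
                else:
                    idx = np.arange(len(Xv))
                wb = None if self.bagging.bootstrap else w
                est = self._fit_replicate(Xv[idx], self.y[idx], wb, seed, b, rng)
                estimators.append(est)
        return SubstrateClassifierResults(model=self, estimators=estimators, seed=seed)

    def _fit_single(self, Xv, y, w, seed, rng):
        est = make_learner(self.learner, seed)
        if self.learner in _WEIGHT_SUPPORT:
            est.fit(Xv, y, sample_weight=w)
        elif np.allclose(w, w[0]):
            # uniform weights: the weighted learner is the plain learner
            est.fit(Xv, y)
        else:
            idx = rng.choice(len(Xv), size=len(Xv), replace=True, p=w / w.sum())
            est.fit(Xv[idx], y[idx])
        return est

    def _fit_replicate(self, Xv, y, w, seed, b, rng):
        # replicate 0 reuses the model seed so a single identity replicate
        # reproduces the plain base learner exactly
        sub_seed = None if seed is None else (seed + 1009 * b) % (2**31)
        est = make_learner(self.learner, sub_seed)
        if w is not None and self.learner in _WEIGHT_SUPPORT:
            est.fit(Xv, y, sample_weight=w)
        else:
            est.fit(Xv, y)
        return est


@dataclass
class SubstrateClassifierResults:
    """Fitted state: predictions, evaluation and a summary table."""

    model: SubstrateClassifier
    estimators: list = field(default_factory=list)
    seed: int | None = None
    version: int = SERIALIZATION_VERSION

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Majority-vote predictions (ties -> substrate)."""
        Xv = _restrict(X, self.model.features).to_numpy(dtype=float)
        if len(Xv) == 0:
            return np.array([], dtype=int)
        votes = np.stack([est.predict(Xv) for est in self.estimators])
        pos = (votes == 1).sum(axis=0)
        return (pos * 2 >= len(self.estimators)).astype(int)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray | None:
        """Mean positive-class score where the base learner provides one."""
        Xv = _restrict(X, self.model.features).to_numpy(dtype=float)
        cols = []
        for est in self.estimators:
            if hasattr(est, "predict_proba"):
                cols.append(est.predict_proba(Xv)[:, list(est.classes_).index(1)])
            elif hasattr(est, "decision_function"):
                cols.append(est.decision_function(Xv))
            else:
                return None
        return np.mean(cols, axis=0)

    def evaluate(self, X: pd.DataFrame, y) -> MetricsReport:
        return metrics(confusion(np.asarray(y, dtype=int), self.predict(X)))

    def summary(self) -> str:
        m = self.model
        n_sub = int((m.y == 1).sum())
        lines = [
            "Substrate classification results",
            "=" * 40,
            f"learner:        {m.learner}",
            f"cost (FN:FP):   {m.cost}",
            f"bagging:        "
            + (f"{m.bagging.n_estimators} replicates" if m.bagging else "none"),
            f"features ({len(m.features)}): {', '.join(m.features)}",
            f"n train:        {len(m.y)} ({n_sub} substrates, "
            f"{len(m.y) - n_sub} non-substrates)",
            f"seed:           {self.seed}",
        ]
        train_report = self.evaluate(m.X, m.y)
        disp = train_report.round_display()
        lines += [
            "-" * 40,
            "training-set performance (resubstitution):",
            f"  sensitivity {disp['sensitivity_pct']:.2f}%  "
            f"specificity {disp['specificity_pct']:.2f}%",
            f"  G-mean {disp['g_mean']:.2f}  MCC {disp['mcc']:.2f}  "
            f"precision {disp['precision']:.2f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SubstrateClassifierResults":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain saved classifier results")
        if obj.version != SERIALIZATION_VERSION:
            raise ValueError(
                f"serialized version {obj.version} != supported {SERIALIZATION_VERSION}"
            )
        return obj


def train(
    X: pd.DataFrame,
    y,
    features=None,
    learner: str = "random_forest",
    cost: CostSpec = CostSpec(),
    bagging: BaggingConfig | None = None,
    seed: int | None = 0,
) -> SubstrateClassifierResults:
    """Functional wrapper: build and fit a :class:`SubstrateClassifier`."""
    return SubstrateClassifier(
        X, y, features=features, learner=learner, cost=cost, bagging=bagging
    ).fit(seed=seed)


def cross_validate(
    X: pd.DataFrame,
    y,
    features=None,
    learner: str = "random_forest",
    cost: CostSpec = CostSpec(),
    bagging: BaggingConfig | None = None,
    k: int = 5,
    seed: int | None = 0,
    nested_selection=None,
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled confusion matrices.

    Per-fold confusion matrices are summed before computing metrics, so
    pooled TP+FN equals the total substrate count.  ``nested_selection``,
    if given, is a callable ``(X_train, y_train) -> feature names`` re-run
    inside every fold (leakage-aware variant; the default mirrors the
    select-once-on-the-training-set protocol).
    """
    y = np.asarray(y, dtype=int)
    for cls_label in (0, 1):
        if (y == cls_label).sum() < k:
            raise ValueError(
                f"class {cls_label} has fewer than k={k} members; cannot stratify"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        feats = features
        if nested_selection is not None:
            feats = nested_selection(X.iloc[tr], y[tr])
        res = train(
            X.iloc[tr],
            y[tr],
            features=feats,
            learner=learner,
            cost=cost,
            bagging=bagging,
            seed=None if seed is None else seed + fold,
        )
        pooled = pooled + confusion(y[te], res.predict(X.iloc[te]))
    return metrics(pooled)


def cost_grid_search(
    X: pd.DataFrame,
    y,
    features=None,
    learner: str = "random_forest",
    candidates=PRESET_COSTS,
    selection_metric: str = "g_mean",
    bagging: BaggingConfig | None = None,
    k: int = 5,
    seed: int | None = 0,
) -> tuple[CostSpec, pd.DataFrame]:
    """Evaluate candidate cost pairs by cross-validation; keep the best.

    Candidates are scored with ``selection_metric`` (default G-mean, the
    natural summary for imbalanced data); ties keep the earlier candidate.
    Returns the winning :class:`CostSpec` and the full per-candidate
    report.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate cost pair")
    rows = []
    best_cost, best_score = None, -np.inf
    for cand in candidates:
        report = cross_validate(
            X, y, features=features, learner=learner, cost=cand,
            bagging=bagging, k=k, seed=seed,
        )
        score = getattr(report, selection_metric)
        rows.append({"cost": str(cand), selection_metric: score, **report.to_dict()})
        if score > best_score + 1e-12:
            best_cost, best_score = cand, score
    table = pd.DataFrame(rows)
    logger.info("cost grid: best %s (%s=%.3f)", best_cost, selection_metric, best_score)
    return best_cost, table
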