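"""Wrapper feature selection + hyperparameter tuning.

The objective balances cross-validated classification error against subset
size:

    fitness = alpha * Error + (1 - alpha) * n_selected / n_total,

with ``Error = 1 - mean stratified-CV accuracy`` of the wrapped classifier
restricted to the masked features.  The optimizer searches the joint raw box
(mask bits + hyperparameters) and the elitist best is decoded and returned
with an audit-recomputable fitness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .encoding import SolutionEncoding, build_space, decode, space_bounds
from .prep import TabularDataset
from .swarm import OptimizerConfig, optimize

__all__ = ["FitnessSpec", "SelectionResult", "build_classifier", "wrapper_fitness",
           "select_and_tune"]

MODELS = ("rf", "dt", "svm", "knn")


@dataclass(frozen=True)
class FitnessSpec:
    """Objective definition for the wrapper search.

    ``alpha`` weights classification error against subset size.  The default
    0.9 keeps accuracy dominant while giving the parsimony term
    ``(1-alpha)/n_total`` per feature enough weight to override the
    fold-level noise in cross-validated error between masks; much closer to
    1 the subset term falls below that noise floor and selection
    degenerates to error-only search, while much smaller values prune
    features whose value only shows on imbalanced held-out data.
    """

    alpha: float = 0.9
    model_id: str = "rf"
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.model_id not in MODELS:
            raise ValueError(f"unknown model {self.model_id!r}")


@dataclass
class SelectionResult:
    best_encoding: SolutionEncoding
    best_fitness: float
    cv_error: float
    trace: np.ndarray
    selected_feature_names: list[str]
    evaluations: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_mask": list(self.best_encoding.feature_mask),
                "selected_features": self.selected_feature_names,
                "hyperparams": self.best_encoding.hyperparams,
                "fitness": float(self.best_fitness),
                "cv_error": float(self.cv_error),
                "evaluations": int(self.evaluations),
                "seed": int(self.seed),
                "trace": [float(v) for v in self.trace],
            }
        )


def build_classifier(model_id: str, hyperparams: dict, seed: int = 0):
    """Instantiate the wrapped sklearn classifier from decoded hyperparameters."""
    h = dict(hyperparams)
    if model_id == "rf":
        return RandomForestClassifier(
            n_estimators=h.get("n_estimators", 100),
            max_depth=h.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if model_id == "dt":
        return DecisionTreeClassifier(
            max_depth=h.get("max_depth"),
            min_samples_split=h.get("min_samples_split", 2),
            random_state=seed,
        )
    if model_id == "svm":
        return SVC(
            C=h.get("C", 1.0), gamma=h.get("gamma", "scale"), kernel="rbf",
            probability=True, random_state=seed,
        )
    if model_id == "knn":
        return KNeighborsClassifier(
            n_neighbors=h.get("n_neighbors", 5),
            weights="distance" if h.get("distance_weighting", 0) else "uniform",
        )
    raise ValueError(f"unknown model {model_id!r}")


def wrapper_fitness(
    dataset: TabularDataset, encoding: SolutionEncoding, spec: FitnessSpec
) -> tuple[float, float]:
    """Evaluate (fitness, cv_error) for one encoding on an encoded dataset."""
    if encoding.n_selected == 0:
        raise ValueError("empty-mask: encoding selects no features")
    total = len(encoding.feature_mask)
    cols = [n for n, b in zip(dataset.feature_names, encoding.feature_mask) if b]
    X = dataset.X[cols].to_numpy(dtype=float)
    y = dataset.y.to_numpy()
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < spec.cv_folds:
        raise ValueError("degenerate-fold: a class is smaller than cv_folds")
    clf = build_classifier(spec.model_id, encoding.hyperparams, seed=spec.seed)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    accs = cross_val_score(clf, X, y, cv=cv, scoring="accuracy", n_jobs=1)
    error = 1.0 - float(np.mean(accs))
    fitness = spec.alpha * error + (1.0 - spec.alpha) * encoding.n_selected / total
    return fitness, error


def select_and_tune(
    dataset: TabularDataset,
    spec: FitnessSpec,
    opt_config: OptimizerConfig,
    algorithm: str = "psso",
    error_fn=None,
) -> SelectionResult:
    """Run the wrapper search over the joint mask + hyperparameter box.

    ``error_fn(encoding) -> error`` may replace the cross-validated error
    (used for deterministic oracle fixtures); fitness evaluations are
    memoized on the decoded encoding, so re-visited masks cost nothing.
    """
    if dataset.y.nunique() < 2 or len(dataset.feature_names) < 2:
        raise ValueError("need at least 2 classes and 2 features")
    space = build_space(dataset.feature_names, spec.model_id)
    bounds = space_bounds(space)
    total = len(dataset.feature_names)
    cache: dict[tuple, tuple[float, float]] = {}
    evaluations = 0

    def objective(position: np.ndarray) -> float:
        nonlocal evaluations
        enc = decode(position, space)
        key = enc.key()
        if key not in cache:
            evaluations += 1
            if error_fn is not None:
                error = float(error_fn(enc))
                fitness = spec.alpha * error + (1 - spec.alpha) * enc.n_selected / total
            else:
                fitness, error = wrapper_fitness(dataset, enc, spec)
            cache[key] = (fitness, error)
        return cache[key][0]

    result = optimize(objective, bounds, opt_config, algorithm)
    best = decode(result.best_position, space)
    fitness, error = cache[best.key()]
    selected = [n for n, b in zip(dataset.feature_names, best.feature_mask) if b]
    return SelectionResult(
        best_encoding=best,
        best_fitness=fitness,
        cv_error=error,
        trace=result.trace,
        selected_feature_names=selected,
        evaluations=evaluations,
        seed=opt_config.seed,
    )
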