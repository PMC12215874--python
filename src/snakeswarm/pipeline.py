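"""End-to-end study orchestration.

One :func:`run_experiment` call executes the full workflow: load or generate
data -> impute -> stratified split -> column transform (fitted on train) ->
SMOTE-ENN balance the training partition -> wrapper feature selection +
hyperparameter tuning with the chosen optimizer (or plain defaults with
``algorithm="none"``) -> refit on the balanced train -> evaluate on the
untouched test partition.  The raw test rows are checksummed before and
after optimization so leakage would be detected.

:func:`scan_protocols` repeats the experiment over a split-fraction grid or
a swarm-hyperparameter sensitivity grid (population size, inertia,
cognitive/social coefficients), reporting accuracy and feature-selection
consistency (Jaccard index across seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import smoteenn_balance
from .encoding import HYPERPARAM_SPACES
from .metrics import MetricsReport, confusion_tally, metrics_from_tally, roc_auc_ovr
from .prep import ColumnPrep, TabularDataset, clean_impute, load_csv, split_train_test
from .selection import FitnessSpec, SelectionResult, build_classifier, select_and_tune
from .swarm import OptimizerConfig
from .synthetic import GeneratorSpec, generate_thyroid_like

__all__ = ["PipelineConfig", "RunReport", "run_experiment", "scan_protocols", "jaccard"]


@dataclass(frozen=True)
class PipelineConfig:
    input_csv: str | None = None
    schema_path: str | None = None
    generator: GeneratorSpec | None = None
    model_id: str = "rf"
    algorithm: str = "none"  # none | so | pso | psso
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    alpha: float = 0.9
    cv_folds: int = 5
    split_fraction: float = 0.8
    balance_before_split: bool = False
    k_smote: int = 5
    k_enn: int = 3
    out_dir: str | None = None
    seed: int = 0


@dataclass
class RunReport:
    metrics: MetricsReport
    selection: SelectionResult | None
    trace: list[float]
    provenance: dict
    config_echo: dict
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config_echo,
                "metrics": json.loads(self.metrics.to_json()),
                "selection": None if self.selection is None else json.loads(self.selection.to_json()),
                "trace": self.trace,
                "provenance": self.provenance,
            },
            sort_keys=True,
        )


def jaccard(a, b) -> float:
    """Jaccard index of two feature-name sets (1.0 for two empty sets)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _echo_config(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj
    return enc(config)


def _load_dataset(config: PipelineConfig) -> TabularDataset:
    if config.generator is not None:
        return generate_thyroid_like(config.generator).dataset
    if config.input_csv is not None:
        return load_csv(config.input_csv, config.schema_path)
    raise ValueError("config must supply input_csv or a generator spec")


def _checksum(dataset: TabularDataset) -> str:
    payload = dataset.X.to_csv(index=False) + dataset.y.to_csv(index=False)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_experiment(
    config: PipelineConfig, dataset: TabularDataset | None = None
) -> RunReport:
    """Execute the full pipeline; ``dataset`` overrides loading/generation
    (used by the robustness scan to inject perturbed data)."""
    raw = dataset.copy() if dataset is not None else _load_dataset(config)
    clean = clean_impute(raw)
    provenance: dict = {"stages": []}
    provenance["stages"].append({"stage": "clean_impute", **clean.provenance.get("clean_impute", {})})

    if config.balance_before_split:
        # whole-dataset balancing (pre-split ordering); synthetic rows can
        # land in the test partition — supported for protocol comparison only
        prep = ColumnPrep().fit(clean)
        balanced_all = smoteenn_balance(
            prep.transform(clean), config.k_smote, config.k_enn, seed=config.seed
        )
        split = split_train_test(balanced_all, config.split_fraction, seed=config.seed)
        train_bal, test_enc = split.train, split.test
        test_checksum = _checksum(test_enc)
    else:
        split = split_train_test(clean, config.split_fraction, seed=config.seed)
        test_checksum = _checksum(split.test)
        prep = ColumnPrep().fit(split.train)
        train_enc = prep.transform(split.train)
        test_enc = prep.transform(split.test)
        train_bal = smoteenn_balance(train_enc, config.k_smote, config.k_enn, seed=config.seed)
    provenance["stages"].append(
        {
            "stage": "split",
            "fraction": config.split_fraction,
            "train_rows": split.train.n_samples,
            "test_rows": split.test.n_samples,
        }
    )
    provenance["stages"].append(
        {
            "stage": "smoteenn",
            "before": train_bal.provenance.get("counts_before_balance"),
            "after": train_bal.provenance.get("counts_after_balance"),
        }
    )

    selection: SelectionResult | None = None
    if config.algorithm == "none":
        feature_names = train_bal.feature_names
        hyperparams: dict = {}
        trace: list[float] = []
    else:
        spec = FitnessSpec(
            alpha=config.alpha, model_id=config.model_id,
            cv_folds=config.cv_folds, seed=config.seed,
        )
        opt = replace(config.optimizer, seed=config.seed)
        selection = select_and_tune(train_bal, spec, opt, algorithm=config.algorithm)
        feature_names = selection.selected_feature_names
        hyperparams = selection.best_encoding.hyperparams
        trace = [float(v) for v in selection.trace]
        provenance["stages"].append(
            {
                "stage": "select_and_tune",
                "algorithm": config.algorithm,
                "n_selected": selection.best_encoding.n_selected,
                "fitness": selection.best_fitness,
                "cv_error": selection.cv_error,
                "evaluations": selection.evaluations,
            }
        )

    clf = build_classifier(config.model_id, hyperparams, seed=config.seed)
    clf.fit(train_bal.X[feature_names].to_numpy(float), train_bal.y.to_numpy())
    if not config.balance_before_split:
        assert _checksum(split.test) == test_checksum, "test partition mutated"
    y_pred = clf.predict(test_enc.X[feature_names].to_numpy(float))
    classes = sorted(pd.unique(np.concatenate([train_bal.y.to_numpy(), test_enc.y.to_numpy()])).tolist())
    report = metrics_from_tally(confusion_tally(test_enc.y, y_pred, classes))
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(test_enc.X[feature_names].to_numpy(float))
        order = [list(clf.classes_).index(c) for c in classes if c in list(clf.classes_)]
        if len(order) == len(classes):
            auc = roc_auc_ovr(test_enc.y.to_numpy(), proba[:, order], classes)
            report.auc = {c: auc[c]["auc"] for c in classes}
    provenance["test_checksum"] = test_checksum
    provenance["selected_features"] = feature_names

    run = RunReport(
        metrics=report,
        selection=selection,
        trace=trace,
        provenance=provenance,
        config_echo=_echo_config(config),
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(run.to_json())
        if trace:
            lines = ["iteration,best_fitness"] + [f"{i},{v!r}" for i, v in enumerate(trace, 1)]
            (out / "trace.csv").write_text("\n".join(lines) + "\n")
    return run


SPLIT_GRID = (0.5, 0.6, 0.7, 0.8, 0.9)
SENSITIVITY_GRID = (
    [("population", {"n_pop": s}) for s in (20, 50, 100)]
    + [("inertia", {"inertia": w}) for w in (0.4, 0.6, 0.8)]
    + [("coefficients", {"cognitive": c, "social": c}) for c in (1.0, 2.0, 3.0)]
)


def scan_protocols(config: PipelineConfig, scan: str, n_seeds: int = 2) -> pd.DataFrame:
    """Run the split-fraction grid or the swarm-sensitivity grid.

    The sensitivity scan varies one swarm parameter per row (population size
    20/50/100, inertia 0.4/0.6/0.8, equal cognitive/social coefficients
    1/2/3) and reports mean accuracy plus feature-selection consistency
    (mean pairwise Jaccard over ``n_seeds`` seeds).
    """
    rows = []
    if scan == "splits":
        for frac in SPLIT_GRID:
            cfg = replace(config, split_fraction=frac)
            try:
                rep = run_experiment(cfg)
                rows.append(
                    rep.metrics.to_csv_row(
                        model=config.model_id, optimizer=config.algorithm, split=frac
                    )
                )
            except Exception as exc:  # scan continues per spec
                rows.append({"model": config.model_id, "split": frac, "error": str(exc)})
        return pd.DataFrame(rows)
    if scan == "sensitivity":
        for axis, overrides in SENSITIVITY_GRID:
            opt = replace(config.optimizer, **overrides)
            cfg = replace(config, optimizer=opt)
            try:
                accs, selected = [], []
                for s in range(n_seeds):
                    rep = run_experiment(replace(cfg, seed=config.seed + s))
                    accs.append(rep.metrics.accuracy)
                    selected.append(rep.provenance["selected_features"])
                jac = [
                    jaccard(selected[i], selected[j])
                    for i in range(len(selected)) for j in range(i + 1, len(selected))
                ]
                rows.append(
                    {
                        "axis": axis, **overrides,
                        "mean_accuracy": float(np.mean(accs)),
                        "accuracy_sd": float(np.std(accs)),
                        "feature_consistency": float(np.mean(jac)) if jac else 1.0,
                    }
                )
            except Exception as exc:
                rows.append({"axis": axis, **overrides, "error": str(exc)})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scan {scan!r}")
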