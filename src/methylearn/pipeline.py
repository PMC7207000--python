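"""End-to-end experiment orchestration: splits, tasks, controls, audit.

The study protocol holds out one randomly chosen genotype per provenance
— with every methylome of that genotype (both sites, both tissues,
technical replicates) — as the test set, and performs *all* data-driven
choices (imputation statistics, differential-methylation feature
selection, input standardization, hyperparameter search) on the
training samples only.  An audit log records the sample set feeding
every training-time statistic so the absence of test-set leakage can be
asserted mechanically.

Tasks are declared as classification (tissue, provenance) or regression
(biomass and other quantitative wood traits, with mean-dichotomized
differential methylation for feature selection), each with a choice of
feature source (differential with a target count, random control, or a
fixed list) and an optional tissue subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import diffmeth, nn
from .io import MethylomeMatrix, impute_missing
from .synthetic import SyntheticConfig, simulate_study

CLASSIFICATION_TASKS = ("tissue", "provenance")
REGRESSION_TASKS = ("biomass", "density", "soluble_lignin", "mannose")


class DesignError(ValueError):
    """Raised on an invalid train/test split request."""


@dataclass
class StudyDesign:
    """A train/test split of methylomes, holding out whole genotypes."""

    split_id: str
    train_ids: list[str]
    test_ids: list[str]
    rule: str

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise DesignError("train and test sets overlap")


@dataclass
class AuditLog:
    """Record of which samples fed each data-driven statistic."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, statistic: str, sample_ids: Sequence[str]) -> None:
        self.entries.append(
            {
                "stage": stage,
                "statistic": statistic,
                "sample_ids": sorted(sample_ids),
            }
        )

    def training_stages(self) -> list[dict]:
        return [e for e in self.entries if e["stage"] == "train"]

    def assert_no_leakage(self, test_ids: Sequence[str]) -> None:
        test = set(test_ids)
        for e in self.training_stages():
            leaked = test & set(e["sample_ids"])
            if leaked:
                raise AssertionError(
                    f"test samples {sorted(leaked)} fed training statistic "
                    f"{e['statistic']!r}"
                )

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w") as out:
            for e in self.entries:
                out.write(json.dumps(e) + "\n")


def make_split(
    metadata: pd.DataFrame, rule: str = "one-genotype-per-provenance", seed: int = 0
) -> StudyDesign:
    """Assign one random genotype per provenance (all its methylomes) to test.

    Provenances with a single genotype contribute no test genotype (they
    stay entirely in training; a warning notes the exception).  With
    ``rule="full-data-cv"`` every sample is a training sample and the
    test set is empty — cross-validation metrics on such a design are
    in-sample and flagged accordingly in reports.
    """
    if rule == "full-data-cv":
        return StudyDesign(
            split_id=f"full-data-seed{seed}",
            train_ids=metadata["sample_id"].tolist(),
            test_ids=[],
            rule=rule,
        )
    if rule != "one-genotype-per-provenance":
        raise DesignError(f"unknown split rule {rule!r}")
    rng = np.random.default_rng(seed)
    provenances = sorted(metadata["provenance"].unique())
    if len(provenances) < 1:
        raise DesignError("no provenances in metadata")
    test_genotypes: list[tuple[str, int]] = []
    for prov in provenances:
        genos = sorted(metadata.loc[metadata["provenance"] == prov, "genotype"].unique())
        if len(genos) < 2:
            warnings.warn(
                f"provenance {prov} has a single genotype; it contributes "
                "no test genotype"
            )
            continue
        test_genotypes.append((prov, int(rng.choice(genos))))
    if not test_genotypes:
        raise DesignError("no provenance has >= 2 genotypes; cannot form a test set")
    is_test = metadata.apply(
        lambda r: (r["provenance"], int(r["genotype"])) in set(test_genotypes), axis=1
    )
    return StudyDesign(
        split_id=f"split-seed{seed}",
        train_ids=metadata.loc[~is_test, "sample_id"].tolist(),
        test_ids=metadata.loc[is_test, "sample_id"].tolist(),
        rule=rule,
    )


@dataclass
class TaskConfig:
    """Declaration of one modelling task."""

    task: str  # tissue | provenance | biomass | density | soluble_lignin | mannose
    tissue_subset: str = "mixed"  # xylem | leaf | mixed
    feature_source: str = "differential"  # differential | random | fixed
    target_count: int = 500
    target_tolerance: int = 100
    random_n: int = 14
    fixed_positions: list[str] | None = None
    grid: list[nn.NetworkSpec] | None = None
    cv_folds: int = 7
    seed: int = 0

    def is_classification(self) -> bool:
        return self.task in CLASSIFICATION_TASKS


@dataclass
class TaskReport:
    """Everything needed to reproduce and audit one task's result."""

    task: TaskConfig
    design: StudyDesign
    selection: diffmeth.CpGSelection
    best_spec: nn.NetworkSpec
    best_model: nn.NetworkModel
    leaderboard: pd.DataFrame
    cv_metrics: dict[str, float]
    test_metrics: dict[str, float] | None
    test_predictions: pd.DataFrame | None
    confusion: pd.DataFrame | None
    importance: pd.Series
    audit: AuditLog

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.selection.to_tsv(directory / "selection.tsv")
        self.leaderboard.to_csv(directory / "leaderboard.tsv", sep="\t", index=False)
        nn.save_model(self.best_model, directory / "model.npz")
        summary = {
            "task": self.task.task,
            "tissue_subset": self.task.tissue_subset,
            "feature_source": self.task.feature_source,
            "split": self.design.split_id,
            "rule": self.design.rule,
            "n_features": len(self.selection),
            "cv_metrics": self.cv_metrics,
            "test_metrics": self.test_metrics,
            "in_sample_cv": self.design.rule == "full-data-cv",
        }
        (directory / "summary.json").write_text(json.dumps(summary, indent=2))
        if self.test_predictions is not None:
            self.test_predictions.to_csv(
                directory / "test_predictions.tsv", sep="\t", index=False
            )
        if self.confusion is not None:
            self.confusion.to_csv(directory / "confusion.tsv", sep="\t")
        self.importance.to_csv(directory / "importance.tsv", sep="\t", header=True)
        self.audit.to_jsonl(directory / "audit.jsonl")


def _tissue_filter(metadata: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "mixed":
        return metadata
    code = {"xylem": "X", "leaf": "L"}.get(subset)
    if code is None:
        raise ValueError(f"unknown tissue subset {subset!r}")
    return metadata[metadata["tissue"] == code]


def default_grid(task: str, n_inputs: int, seed: int) -> list[nn.NetworkSpec]:
    """A small default hyperparameter grid appropriate to desk-scale runs."""
    if task in CLASSIFICATION_TASKS:
        base = nn.NetworkSpec(
            n_inputs=n_inputs,
            task="classification",
            hidden_sizes=(16, 16),
            epochs=200,
            learning_rate=0.05,
            seed=seed,
        )
        return nn.expand_grid(base, activation=["tanh", "rectifier"], l2=[0.0, 5e-5])
    base = nn.NetworkSpec(
        n_inputs=n_inputs,
        task="regression",
        hidden_sizes=(16, 16),
        epochs=200,
        learning_rate=0.01,
        seed=seed,
    )
    return nn.expand_grid(base, activation=["tanh"], l2=[5e-5], hidden_dropout=[0.0, 0.2])


def _select_features(
    train_matrix: pd.DataFrame,
    labels_or_groups,
    config: TaskConfig,
    audit: AuditLog,
) -> diffmeth.CpGSelection:
    """Feature selection on the training matrix only."""
    if config.feature_source == "random":
        sel = diffmeth.random_selection(
            list(train_matrix.columns), config.random_n, seed=config.seed
        )
        audit.record("train", "random_feature_selection", list(train_matrix.index))
        return sel
    if config.feature_source == "fixed":
        if not config.fixed_positions:
            raise ValueError("fixed feature source requires fixed_positions")
        return diffmeth.CpGSelection(
            position_ids=list(config.fixed_positions), origin="fixed"
        )
    group_a, group_b = labels_or_groups
    results = diffmeth.test_all_cpg(train_matrix, group_a, group_b)
    audit.record("train", "welch_t_per_cpg", list(group_a) + list(group_b))
    sel = diffmeth.select_to_count(
        results, target=config.target_count, tolerance=config.target_tolerance
    )
    if len(sel) == 0:
        raise diffmeth.SelectionError("feature selection is empty")
    return sel


def _multiclass_groups(
    labels: pd.Series, config: TaskConfig, train_matrix: pd.DataFrame, audit: AuditLog
) -> diffmeth.CpGSelection:
    """Pooled one-vs-rest selection for multiclass problems."""
    classes = sorted(labels.unique())
    per_class = max(config.target_count // len(classes), 1)
    selections, counts = [], []
    for cls in classes:
        a = labels.index[labels == cls].tolist()
        b = labels.index[labels != cls].tolist()
        results = diffmeth.test_all_cpg(train_matrix, a, b)
        audit.record("train", f"welch_t_per_cpg[{cls} vs rest]", a + b)
        ordered = results.sort_values(["q", "p", "position_id"], kind="mergesort")
        sel = diffmeth.CpGSelection(
            position_ids=ordered["position_id"].tolist(),
            origin="differential",
            stats=results,
        )
        selections.append(sel)
        counts.append(min(per_class, len(sel)))
    pooled = diffmeth.pooled_selection(selections, counts)
    return pooled


def _impute_split(
    matrix: MethylomeMatrix,
    design: StudyDesign,
    audit: AuditLog,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Mean-impute training and test subsets with separate statistics."""
    train = impute_missing(matrix.subset_samples(design.train_ids)).data
    audit.record("train", "imputation_column_means", design.train_ids)
    test = None
    if design.test_ids:
        test = impute_missing(matrix.subset_samples(design.test_ids)).data
        audit.record("test", "imputation_column_means", design.test_ids)
    return train, test


def run_classification(
    matrix: MethylomeMatrix,
    metadata: pd.DataFrame,
    design: StudyDesign,
    config: TaskConfig,
) -> TaskReport:
    """Train and evaluate a classification task (tissue or provenance)."""
    audit = AuditLog()
    meta = _tissue_filter(metadata.set_index("sample_id"), config.tissue_subset)
    design = StudyDesign(
        split_id=design.split_id,
        train_ids=[s for s in design.train_ids if s in meta.index],
        test_ids=[s for s in design.test_ids if s in meta.index],
        rule=design.rule,
    )
    train_df, test_df = _impute_split(matrix, design, audit)

    label_col = "tissue" if config.task == "tissue" else "provenance"
    train_labels = meta.loc[design.train_ids, label_col]
    classes = sorted(train_labels.unique())
    class_index = {c: i for i, c in enumerate(classes)}
    y_train = train_labels.map(class_index).to_numpy()

    if config.feature_source == "differential" and len(classes) > 2:
        selection = _multiclass_groups(train_labels, config, train_df, audit)
    else:
        groups = (
            train_labels.index[train_labels == classes[0]].tolist(),
            train_labels.index[train_labels != classes[0]].tolist(),
        )
        selection = _select_features(train_df, groups, config, audit)

    X_train = train_df.loc[:, selection.position_ids].to_numpy()
    grid = config.grid or default_grid(
        config.task, n_inputs=len(selection), seed=config.seed
    )
    grid = [nn.replace_spec(s, n_inputs=len(selection), n_classes=len(classes)) for s in grid]
    audit.record("train", "grid_search_cv", design.train_ids)
    best_spec, best_model, leaderboard = nn.grid_search(
        grid, X_train, y_train, k=config.cv_folds
    )
    cv = nn.kfold_cv(best_spec, X_train, y_train, k=config.cv_folds)

    test_metrics = None
    test_predictions = None
    confusion = cv.confusion
    if design.test_ids and test_df is not None:
        test_labels = meta.loc[design.test_ids, label_col]
        known = test_labels.isin(classes)
        if not known.all():
            warnings.warn(
                "test samples with classes absent from training are excluded "
                "from test metrics"
            )
        eval_ids = test_labels.index[known].tolist()
        y_test = test_labels[known].map(class_index).to_numpy()
        X_test = test_df.loc[eval_ids, selection.position_ids].to_numpy()
        probs = nn.predict(best_model, X_test)
        test_metrics = nn.metrics(probs, y_test, "classification")
        p_true = probs[np.arange(len(y_test)), y_test]
        test_predictions = pd.DataFrame(
            {
                "sample_id": eval_ids,
                "true_class": [classes[i] for i in y_test],
                "predicted_class": [classes[i] for i in probs.argmax(axis=1)],
                "misclassification_probability": 1.0 - p_true,
            }
        )
        confusion = pd.crosstab(
            test_predictions["true_class"], test_predictions["predicted_class"]
        )

    ranking = importance_series = None
    from .interpret import gedeon_importance

    ranking = gedeon_importance(best_model, input_ids=selection.position_ids)
    importance_series = ranking.as_series()
    return TaskReport(
        task=config,
        design=design,
        selection=selection,
        best_spec=best_spec,
        best_model=best_model,
        leaderboard=leaderboard,
        cv_metrics=cv.metrics,
        test_metrics=test_metrics,
        test_predictions=test_predictions,
        confusion=confusion,
        importance=importance_series,
        audit=audit,
    )


def _trait_values(
    metadata: pd.DataFrame, traits: pd.DataFrame, trait: str
) -> pd.Series:
    """Per-sample trait values joined from the per-tree trait table."""
    merged = metadata.merge(
        traits, on=["provenance", "genotype", "site"], how="left", validate="many_to_one"
    )
    return pd.Series(merged[trait].to_numpy(), index=metadata["sample_id"].to_numpy())


def run_regression(
    matrix: MethylomeMatrix,
    metadata: pd.DataFrame,
    traits: pd.DataFrame,
    design: StudyDesign,
    config: TaskConfig,
) -> TaskReport:
    """Train and evaluate a quantitative-trait regression task.

    Feature selection compares training samples whose trait value lies
    strictly above the training mean against the rest (Welch's t per
    CpG), within the configured tissue subset.
    """
    audit = AuditLog()
    meta = _tissue_filter(metadata.set_index("sample_id"), config.tissue_subset)
    design = StudyDesign(
        split_id=design.split_id,
        train_ids=[s for s in design.train_ids if s in meta.index],
        test_ids=[s for s in design.test_ids if s in meta.index],
        rule=design.rule,
    )
    train_df, test_df = _impute_split(matrix, design, audit)

    values = _trait_values(metadata, traits, config.task)
    y_train_s = values.loc[design.train_ids]
    if y_train_s.isna().any():
        raise ValueError("trait missing for some training samples")
    if y_train_s.nunique() == 1:
        raise ValueError("trait is constant on the training set")

    if config.feature_source == "differential":
        high, low = diffmeth.dichotomize_at_mean(y_train_s)
        audit.record("train", "trait_mean_dichotomy", design.train_ids)
        selection = _select_features(train_df, (high, low), config, audit)
    else:
        selection = _select_features(train_df, None, config, audit)

    X_train = train_df.loc[:, selection.position_ids].to_numpy()
    y_train = y_train_s.to_numpy(dtype=float)
    grid = config.grid or default_grid(
        config.task, n_inputs=len(selection), seed=config.seed
    )
    grid = [nn.replace_spec(s, n_inputs=len(selection), task="regression") for s in grid]
    audit.record("train", "grid_search_cv", design.train_ids)
    best_spec, best_model, leaderboard = nn.grid_search(
        grid, X_train, y_train, k=config.cv_folds
    )
    cv = nn.kfold_cv(best_spec, X_train, y_train, k=config.cv_folds)

    test_metrics = None
    test_predictions = None
    if design.test_ids and test_df is not None:
        y_test_s = values.loc[design.test_ids]
        eval_ids = y_test_s.index[y_test_s.notna()].tolist()
        y_test = y_test_s.loc[eval_ids].to_numpy(dtype=float)
        X_test = test_df.loc[eval_ids, selection.position_ids].to_numpy()
        preds = nn.predict(best_model, X_test)
        test_metrics = nn.metrics(preds, y_test, "regression")
        test_predictions = pd.DataFrame(
            {"sample_id": eval_ids, "observed": y_test, "predicted": preds}
        )

    from .interpret import gedeon_importance

    ranking = gedeon_importance(best_model, input_ids=selection.position_ids)
    return TaskReport(
        task=config,
        design=design,
        selection=selection,
        best_spec=best_spec,
        best_model=best_model,
        leaderboard=leaderboard,
        cv_metrics=cv.metrics,
        test_metrics=test_metrics,
        test_predictions=test_predictions,
        confusion=None,
        importance=ranking.as_series(),
        audit=audit,
    )


def run_task(
    matrix: MethylomeMatrix,
    metadata: pd.DataFrame,
    traits: pd.DataFrame | None,
    design: StudyDesign,
    config: TaskConfig,
) -> TaskReport:
    if config.is_classification():
        return run_classification(matrix, metadata, design, config)
    if traits is None:
        raise ValueError("regression tasks require a trait table")
    return run_regression(matrix, metadata, traits, design, config)


def run_suite(config_path: str | Path, output_dir: str | Path | None = None) -> int:
    """Execute a YAML-declared batch of tasks across splits.

    Returns a process exit status: 0 if every task succeeded, 1
    otherwise (failures are recorded in the summary and the suite
    continues).  A global seed governs simulation, splitting and every
    task's stochastic stages.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(output_dir or cfg.get("output_dir", "methylearn_suite"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", seed)
        study = simulate_study(SyntheticConfig(**syn))
        matrix, metadata, traits = study.matrix, study.metadata, study.traits
    else:
        matrix = MethylomeMatrix.from_tsv(cfg["matrix"])
        metadata = pd.read_csv(cfg["metadata"], sep="\t")
        traits = pd.read_csv(cfg["traits"], sep="\t") if "traits" in cfg else None

    split_seeds = cfg.get("split_seeds", [seed])
    rule = cfg.get("split_rule", "one-genotype-per-provenance")
    rows = []
    status = 0
    for split_seed in split_seeds:
        design = make_split(metadata, rule=rule, seed=int(split_seed))
        for i, task_cfg in enumerate(cfg.get("tasks", [])):
            tc = TaskConfig(**{**task_cfg, "seed": seed})
            name = f"{design.split_id}_{tc.task}_{tc.feature_source}_{i}"
            try:
                report = run_task(matrix, metadata, traits, design, tc)
                report.save(out / name)
                rows.append(
                    {
                        "name": name,
                        "task": tc.task,
                        "split": design.split_id,
                        "status": "ok",
                        **{f"cv_{k}": v for k, v in report.cv_metrics.items()},
                        **{
                            f"test_{k}": v
                            for k, v in (report.test_metrics or {}).items()
                        },
                    }
                )
            except Exception as exc:  # noqa: BLE001 - suite keeps going
                rows.append(
                    {"name": name, "task": tc.task, "split": design.split_id,
                     "status": f"failed: {exc}"}
                )
                status = 1
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return status
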