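"""Evaluation metrics, multiclass ROC, model comparison, and the pipeline.

Accuracy for the single-label 4-class problem is the confusion-matrix
trace over the total count; micro-averaged precision, recall and F1 pool
true/false positives over the classes and — for single-label multiclass
data — all coincide with accuracy. That identity is computed here with
exact rational arithmetic so it holds bit-for-bit.

ROC analysis is one-vs-rest per class with trapezoid AUC and a
macro-averaged curve on a common false-positive-rate grid
(micro-averaging over pooled decisions is available via ``average=``).

``run_pipeline`` wires the whole method end to end: simulate a cohort,
window and normalise it, extract entropy features, train the CNN and the
two classical baselines on the same split, and evaluate on the test set
and the held-out subjects.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines as bl
from . import cnn as cnn_mod
from .entropy_features import BandScheme, feature_matrix, feature_table
from .preprocessing import (
    DatasetSplit,
    LabelScheme,
    SplitSpec,
    Window,
    extract_windows,
    split_dataset,
)
from .synthetic_semg import SimConfig, generate_cohort

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "accuracy",
    "micro_metrics",
    "roc_curves",
    "evaluate_predictions",
    "compare_models",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]

N_CLASSES = 4


@dataclass
class ConfusionMatrix:
    """Counts[i, j] = samples with true class i predicted as class j."""

    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums * 100.0, 0.0)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def confusion(
    true: np.ndarray, pred: np.ndarray, n_classes: int = N_CLASSES
) -> ConfusionMatrix:
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and predicted label arrays must match in length")
    if true.size and (
        true.min() < 0 or true.max() >= n_classes
        or pred.min() < 0 or pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the multiclass accuracy."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def micro_metrics(cm: ConfusionMatrix) -> dict[str, Fraction]:
    """Micro precision/recall/F1 from pooled per-class TP/FP/FN.

    Computed with exact rational arithmetic, independently of
    :func:`accuracy`, so the multiclass identity
    ``acc == prem == recm == f1m`` can be asserted exactly.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    tp_i = np.diag(c)
    fp_i = c.sum(axis=0) - tp_i  # predicted as i but not i
    fn_i = c.sum(axis=1) - tp_i  # truly i but missed
    tp, fp, fn = int(tp_i.sum()), int(fp_i.sum()), int(fn_i.sum())
    prem = Fraction(tp, tp + fp)
    recm = Fraction(tp, tp + fn)
    f1m = (
        Fraction(0)
        if prem + recm == 0
        else 2 * prem * recm / (prem + recm)
    )
    return {
        "acc": Fraction(tp, cm.total),
        "prem": prem,
        "recm": recm,
        "f1m": f1m,
    }


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _binary_roc(scores: np.ndarray, positive: np.ndarray):
    """Threshold-sweep ROC for one class; returns (fpr, tpr, auc)."""
    order = np.argsort(-scores, kind="stable")
    pos = positive[order].astype(float)
    n_pos = pos.sum()
    n_neg = len(pos) - n_pos
    tp = np.cumsum(pos)
    fp = np.cumsum(1.0 - pos)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(pos) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_curves(
    scores: np.ndarray,
    true: np.ndarray,
    n_classes: int = N_CLASSES,
    average: str = "macro",
    grid_points: int = 101,
) -> dict:
    """One-vs-rest ROC per class plus an averaged curve.

    Returns ``{"per_class": {c: (fpr, tpr, auc)}, "average":
    (fpr_grid, tpr, auc), "method": average}``. Classes absent from
    ``true`` (or present in every sample) are omitted with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    true = np.asarray(true, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    per_class: dict[int, tuple] = {}
    for c in range(n_classes):
        positive = true == c
        if positive.all() or not positive.any():
            warnings.warn(f"class {c} has no positives or no negatives; curve omitted")
            continue
        per_class[c] = _binary_roc(scores[:, c], positive)

    grid = np.linspace(0.0, 1.0, grid_points)
    if average == "macro":
        tprs = [np.interp(grid, fpr, tpr) for fpr, tpr, _ in per_class.values()]
        mean_tpr = np.mean(tprs, axis=0)
        avg = (grid, mean_tpr, float(np.trapezoid(mean_tpr, grid)))
    elif average == "micro":
        pooled_scores = np.concatenate([scores[:, c] for c in per_class])
        pooled_pos = np.concatenate([true == c for c in per_class])
        fpr, tpr, auc = _binary_roc(pooled_scores, pooled_pos)
        avg = (grid, np.interp(grid, fpr, tpr), auc)
    else:
        raise ValueError("average must be 'macro' or 'micro'")
    return {"per_class": per_class, "average": avg, "method": average}


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    model: str
    speed: int
    cm: ConfusionMatrix
    acc: float
    prem: float
    recm: float
    f1m: float
    roc: dict
    holdout_subject_acc: dict[str, float] = field(default_factory=dict)

    @property
    def holdout_mean(self) -> float:
        return float(np.mean(list(self.holdout_subject_acc.values())))

    @property
    def holdout_sd(self) -> float:
        """Sample standard deviation (ddof=1) across held-out subjects."""
        vals = list(self.holdout_subject_acc.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def evaluate_predictions(
    true: np.ndarray,
    pred: np.ndarray,
    scores: np.ndarray,
    model: str = "",
    speed: int = 0,
    roc_average: str = "macro",
) -> EvalReport:
    cm = confusion(true, pred)
    mm = micro_metrics(cm)
    return EvalReport(
        model=model,
        speed=speed,
        cm=cm,
        acc=float(mm["acc"]),
        prem=float(mm["prem"]),
        recm=float(mm["recm"]),
        f1m=float(mm["f1m"]),
        roc=roc_curves(scores, true, average=roc_average),
    )


def compare_models(reports: list[EvalReport]) -> pd.DataFrame:
    """Accuracy table per model x speed, ordered by descending accuracy."""
    if not reports:
        raise ValueError("at least one report is required")
    rows = []
    for r in sorted(reports, key=lambda r: -r.acc):
        row = {
            "model": r.model,
            "speed": r.speed,
            "accuracy": r.acc,
            "macro_auc": r.roc["average"][2],
        }
        if r.holdout_subject_acc:
            row["holdout_mean"] = r.holdout_mean
            row["holdout_sd"] = r.holdout_sd
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    seed: int = 0
    n_subjects: int = 64
    speed: int = 60
    sim: SimConfig | None = None
    split: SplitSpec | None = None
    label_scheme: LabelScheme = field(default_factory=LabelScheme.table2)
    band_scheme: BandScheme = field(default_factory=BandScheme)
    cnn: cnn_mod.TrainConfig | None = None
    svm: bl.SVMConfig = field(default_factory=bl.SVMConfig)
    out_dir: str | Path | None = None

    def resolved_sim(self) -> SimConfig:
        return self.sim or SimConfig(speed=self.speed, seed=self.seed)

    def resolved_split(self) -> SplitSpec:
        return self.split or SplitSpec(seed=self.seed)

    def resolved_cnn(self) -> cnn_mod.TrainConfig:
        # base rate chosen by validation loss over a grid; the iteration
        # budget covers the validation-loss minimum (~iteration 2100 on the
        # default cohort) without paying for the overfitting tail
        return self.cnn or cnn_mod.TrainConfig(
            base_rate=10.0, max_iterations=2500, seed=self.seed
        )


@dataclass
class PipelineResult:
    config: RunConfig
    split: DatasetSplit
    reports: dict[str, EvalReport]
    comparison: pd.DataFrame
    cnn_model: cnn_mod.CNNModel
    cnn_history: cnn_mod.TrainHistory
    svm_model: bl.MultiSVM
    lda_model: bl.LDAModel
    feature_table: pd.DataFrame


def _feature_split(split: DatasetSplit, table: pd.DataFrame, scheme: LabelScheme):
    """Align per-cycle feature vectors with the window split."""
    X, keys = feature_matrix(table)
    lut = {
        (row.subject, int(row.cycle)): i for i, row in keys.iterrows()
    }
    out = {}
    for name in ("train", "val", "test", "holdout"):
        ws: list[Window] = getattr(split, name)
        idx = [lut[(w.subject_id, w.cycle_index)] for w in ws]
        out[name] = (
            X[idx],
            np.array([w.label for w in ws], dtype=int),
            [w.subject_id for w in ws],
        )
    return out


def _holdout_accuracies(true, pred, subject_ids) -> dict[str, float]:
    true = np.asarray(true)
    pred = np.asarray(pred)
    subject_ids = np.asarray(subject_ids)
    return {
        str(s): float(np.mean(pred[subject_ids == s] == true[subject_ids == s]))
        for s in np.unique(subject_ids)
    }


def run_pipeline(cfg: RunConfig | None = None) -> PipelineResult:
    """Simulate, preprocess, extract features, train all three models,
    and evaluate on the test set and the held-out subjects."""
    cfg = cfg or RunConfig()
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "time": time.time()})

    try:
        stage("simulate")
        cohort = generate_cohort(cfg.resolved_sim(), cfg.n_subjects)

        stage("preprocess")
        windows: list[Window] = []
        for rec in cohort:
            windows.extend(extract_windows(rec, cfg.label_scheme))
        split = split_dataset(windows, cfg.resolved_split())

        stage("features")
        table = feature_table(cohort, cfg.band_scheme)
        feats = _feature_split(split, table, cfg.label_scheme)

        stage("train_cnn")
        Xtr, ytr = cnn_mod.windows_to_arrays(split.train)
        Xval, yval = cnn_mod.windows_to_arrays(split.val)
        arch = cnn_mod.CNNArchitecture.for_speed(cfg.speed)
        model0 = cnn_mod.init_model(arch, seed=cfg.seed)
        cnn_model, history = cnn_mod.train(
            model0, Xtr, ytr, Xval, yval, cfg.resolved_cnn()
        )

        stage("train_baselines")
        ftr_X, ftr_y, _ = feats["train"]
        fval_X, fval_y, _ = feats["val"]
        svm_model = bl.train_multisvm(ftr_X, ftr_y, cfg.svm, fval_X, fval_y)
        lda_model = bl.train_multilda(ftr_X, ftr_y)

        stage("evaluate")
        Xte, yte = cnn_mod.windows_to_arrays(split.test)
        fte_X, fte_y, _ = feats["test"]
        reports: dict[str, EvalReport] = {}

        pred, scores = cnn_mod.predict(cnn_model, Xte)
        reports["CNN"] = evaluate_predictions(yte, pred, scores, "CNN", cfg.speed)
        pred, scores = svm_model.predict(fte_X)
        reports["Multi-SVM"] = evaluate_predictions(
            fte_y, pred, scores, "Multi-SVM", cfg.speed
        )
        pred, scores = lda_model.predict(fte_X)
        reports["Multi-LDA"] = evaluate_predictions(
            fte_y, pred, scores, "Multi-LDA", cfg.speed
        )

        if split.holdout:
            Xho, yho = cnn_mod.windows_to_arrays(split.holdout)
            ho_subjects = [w.subject_id for w in split.holdout]
            pred, _ = cnn_mod.predict(cnn_model, Xho)
            reports["CNN"].holdout_subject_acc = _holdout_accuracies(
                yho, pred, ho_subjects
            )
            fho_X, fho_y, fho_subj = feats["holdout"]
            pred, _ = svm_model.predict(fho_X)
            reports["Multi-SVM"].holdout_subject_acc = _holdout_accuracies(
                fho_y, pred, fho_subj
            )
            pred, _ = lda_model.predict(fho_X)
            reports["Multi-LDA"].holdout_subject_acc = _holdout_accuracies(
                fho_y, pred, fho_subj
            )

        comparison = compare_models(list(reports.values()))
    except Exception as exc:
        failed = log[-1]["stage"] if log else "setup"
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    result = PipelineResult(
        config=cfg,
        split=split,
        reports=reports,
        comparison=comparison,
        cnn_model=cnn_model,
        cnn_history=history,
        svm_model=svm_model,
        lda_model=lda_model,
        feature_table=table,
    )
    if cfg.out_dir is not None:
        _write_artifacts(result, Path(cfg.out_dir), log)
    return result


def _write_artifacts(res: PipelineResult, out: Path, log: list[dict]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    res.feature_table.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "iteration": res.cnn_history.val_iterations,
            "val_loss": res.cnn_history.val_loss,
        }
    ).to_csv(out / "training_curve.tsv", sep="\t", index=False)
    for name, rep in res.reports.items():
        tag = name.lower().replace("-", "_")
        np.savetxt(
            out / f"confusion_{tag}.csv", rep.cm.counts, fmt="%d", delimiter=","
        )
        grid, tpr, auc = rep.roc["average"]
        pd.DataFrame({"fpr": grid, "tpr": tpr}).to_csv(
            out / f"roc_{tag}.tsv", sep="\t", index=False
        )
    cnn_mod.save_model(res.cnn_model, out / "cnn_model.npz")
    cfg = res.config
    resolved = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "speed": cfg.speed,
        "split": dataclasses.asdict(cfg.resolved_split()),
        "cnn": dataclasses.asdict(cfg.resolved_cnn()),
        "best_iteration": int(res.cnn_history.best_iteration),
        "best_val_loss": res.cnn_history.best_val_loss,
        "svm_sigma": res.svm_model.sigma,
        "svm_C": res.svm_model.C,
    }
    (out / "run_config.json").write_text(json.dumps(resolved, indent=1))
    with (out / "run_log.jsonl").open("w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
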