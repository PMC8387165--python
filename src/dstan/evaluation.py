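"""Leave-one-subject-out cross-validation, metrics and confusion matrices.

LOSOCV: all samples of one subject form the test fold and the rest train, one
fold per subject, so identity never leaks between train and test. Metrics are
accuracy (correct / total), and per-class one-vs-rest precision, recall and
F1 = 2PR/(P+R), macro-averaged over classes; zero denominators contribute 0.
Metrics are pooled over the concatenated test predictions of all folds;
per-fold accuracies are reported separately.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dstan.data import SequenceDataset
from dstan.fusion import average_fusion, concat_features, fit_svm, predict_fused
from dstan.pipeline import prepare_streams, subset_stream
from dstan.streams import StreamConfig, extract_stream_features, train_stream

logger = logging.getLogger(__name__)


@dataclass
class FoldSplit:
    test_subject: str
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray                 # (K, K) int, rows = truth
    class_order: np.ndarray
    per_class: pd.DataFrame | None = None
    per_fold: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "class_order": [int(c) for c in self.class_order],
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold.to_dict(orient="records")
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def losocv_split(dataset: SequenceDataset | pd.DataFrame) -> list[FoldSplit]:
    """One fold per subject, ordered by subject id; folds partition the data."""
    df = dataset.labels_frame() if isinstance(dataset, SequenceDataset) else dataset
    subjects = sorted(df["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError(f"LOSOCV needs >= 2 subjects, got {len(subjects)}")
    folds = []
    for subject in subjects:
        mask = df["subject_id"] == subject
        folds.append(
            FoldSplit(
                test_subject=subject,
                train_ids=df.loc[~mask, "sample_id"].tolist(),
                test_ids=df.loc[mask, "sample_id"].tolist(),
            )
        )
    return folds


def confusion(true_labels, predicted_labels, class_set) -> np.ndarray:
    """Entry (i, j): count of samples with true class i predicted as class j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError(
            f"label lists disagree in length: {true_labels.shape} vs "
            f"{predicted_labels.shape}"
        )
    classes = np.asarray(sorted(class_set))
    index = {c: i for i, c in enumerate(classes.tolist())}
    mat = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(true_labels.tolist(), predicted_labels.tolist()):
        mat[index[t], index[p]] += 1
    return mat


def compute_metrics(true_labels, predicted_labels, class_set) -> EvalReport:
    """Accuracy plus macro-averaged one-vs-rest precision/recall/F1."""
    cm = confusion(true_labels, predicted_labels, class_set)
    classes = np.asarray(sorted(class_set))
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    if np.any(tp + fp == 0):
        warnings.warn("some classes received no predicted positives; "
                      "their precision/F1 are set to 0", stacklevel=2)
    per_class = pd.DataFrame(
        {"class": classes, "precision": precision, "recall": recall, "f1": f1,
         "support": cm.sum(axis=1)}
    )
    return EvalReport(
        accuracy=accuracy,
        precision=float(precision.mean()),
        recall=float(recall.mean()),
        f1=float(f1.mean()),
        confusion=cm,
        class_order=classes,
        per_class=per_class,
    )


@dataclass
class LosocvResult:
    """Everything a full LOSOCV run produces."""

    reports: dict[str, EvalReport]
    predictions: pd.DataFrame           # one row per sample per method
    per_fold: pd.DataFrame              # subject_id, n_test, accuracy (fused)
    training_logs: dict[str, list[list[float]]] = field(default_factory=dict)

    def __eq__(self, other) -> bool:  # determinism checks compare whole results
        if not isinstance(other, LosocvResult):
            return NotImplemented
        if set(self.reports) != set(other.reports):
            return False
        for k in self.reports:
            a, b = self.reports[k], other.reports[k]
            if (a.accuracy, a.precision, a.recall, a.f1) != (b.accuracy, b.precision,
                                                             b.recall, b.f1):
                return False
            if not np.array_equal(a.confusion, b.confusion):
                return False
        return self.predictions.equals(other.predictions)


def run_losocv(dataset: SequenceDataset,
               stan_config: StreamConfig,
               stmn_config: StreamConfig,
               t: int = 9,
               frame_size: tuple[int, int] | None = None,
               estimator: str = "ilk",
               fusion_kinds: tuple[str, ...] = ("svm", "average"),
               checkpoint_dir: str | Path | None = None,
               ) -> LosocvResult:
    """Train both streams per fold, fuse, and pool test predictions.

    Every fold trains STAN-A and STMN-A from scratch on the training subjects
    only (batch-norm statistics are therefore per-fold), fits the SVM fusion
    on training-fold features, and records test predictions for the fused
    model(s) and for each single stream.
    """
    if frame_size is None:
        frame_size = stan_config.frame_size
    appearance, motion = prepare_streams(dataset, t=t, frame_size=frame_size,
                                         estimator=estimator)
    class_set = sorted(np.unique(appearance.y).tolist())
    folds = losocv_split(dataset)
    rows = []
    fold_rows = []
    logs: dict[str, list[list[float]]] = {"stan": [], "stmn": []}
    for fold in folds:
        train_subjects = {appearance.subject_ids[i]
                          for i, sid in enumerate(appearance.sample_ids)
                          if sid in set(fold.train_ids)}
        if fold.test_subject in train_subjects:
            raise AssertionError(
                f"subject leakage: {fold.test_subject} present in its own training fold"
            )
        app_train = subset_stream(appearance, fold.train_ids)
        app_test = subset_stream(appearance, fold.test_ids)
        mot_train = subset_stream(motion, fold.train_ids)
        mot_test = subset_stream(motion, fold.test_ids)

        stan = train_stream(app_train, stan_config, "appearance")
        stmn = train_stream(mot_train, stmn_config, "motion")
        logs["stan"].append(stan.training_log)
        logs["stmn"].append(stmn.training_log)
        if checkpoint_dir is not None:
            from dstan.streams import save_stream

            ckpt = Path(checkpoint_dir)
            ckpt.mkdir(parents=True, exist_ok=True)
            save_stream(stan, ckpt / f"stan_{fold.test_subject}.npz")
            save_stream(stmn, ckpt / f"stmn_{fold.test_subject}.npz")

        p_train = extract_stream_features(stan, app_train)
        q_train = extract_stream_features(stmn, mot_train)
        p_test = extract_stream_features(stan, app_test)
        q_test = extract_stream_features(stmn, mot_test)

        preds: dict[str, np.ndarray] = {
            "stan": p_test.predictions(),
            "stmn": q_test.predictions(),
        }
        if "svm" in fusion_kinds:
            svm = fit_svm(concat_features(p_train, q_train))
            preds["dstan_svm"] = predict_fused(svm, concat_features(p_test, q_test))
        if "average" in fusion_kinds:
            preds["dstan_average"] = average_fusion(
                p_test.probabilities, q_test.probabilities,
                class_order=np.asarray(class_set),
            )
        for i, sid in enumerate(p_test.sample_ids):
            row = {
                "sample_id": sid,
                "subject_id": p_test.subject_ids[i],
                "true_label": int(p_test.labels[i]),
            }
            for method, labels in preds.items():
                row[f"pred_{method}"] = int(np.asarray(class_set)[labels[i]]
                                            if method in ("stan", "stmn")
                                            else labels[i])
            for k, c in enumerate(class_set):
                row[f"proba_stan_{c}"] = float(p_test.probabilities[i, k])
                row[f"proba_stmn_{c}"] = float(q_test.probabilities[i, k])
            rows.append(row)
        headline = "dstan_svm" if "svm" in fusion_kinds else next(iter(preds))
        fold_true = p_test.labels
        fold_pred = np.asarray(
            [r[f"pred_{headline}"] for r in rows[-len(p_test.sample_ids):]]
        )
        fold_rows.append(
            {"subject_id": fold.test_subject, "n_test": len(fold_true),
             "accuracy": float((fold_pred == fold_true).mean())}
        )
        logger.info("fold %s: n=%d acc=%.3f", fold.test_subject,
                    len(fold_true), fold_rows[-1]["accuracy"])

    predictions = pd.DataFrame(rows)
    per_fold = pd.DataFrame(fold_rows)
    reports = {}
    for method in ("stan", "stmn", *(f"dstan_{k}" for k in fusion_kinds)):
        col = f"pred_{method}"
        if col in predictions:
            reports[method] = compute_metrics(
                predictions["true_label"].to_numpy(),
                predictions[col].to_numpy(), class_set,
            )
    if "dstan_svm" in reports:
        reports["dstan_svm"].per_fold = per_fold
    return LosocvResult(reports=reports, predictions=predictions,
                        per_fold=per_fold, training_logs=logs)


def save_result(result: LosocvResult, out_dir: str | Path) -> None:
    """Write report JSONs, confusion CSV grids, per-fold and prediction CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for method, report in result.reports.items():
        report.save(out / f"report_{method}.json")
        pd.DataFrame(report.confusion,
                     index=report.class_order,
                     columns=report.class_order).to_csv(out / f"confusion_{method}.csv")
    result.per_fold.to_csv(out / "per_fold.csv", index=False)
    result.predictions.to_csv(out / "predictions.csv", index=False)
    log_rows = [
        {"stream": stream, "fold": fi, "epoch": ei, "mean_loss": loss}
        for stream, fold_logs in result.training_logs.items()
        for fi, losses in enumerate(fold_logs)
        for ei, loss in enumerate(losses)
    ]
    pd.DataFrame(log_rows).to_csv(out / "training_log.csv", index=False)
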