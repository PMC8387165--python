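"""Stream integration: feature-concatenate + linear SVM, and probability averaging.

The two trained streams each emit one feature vector per sample (by default
the temporally pooled sequence feature f). DSTAN-SVM concatenates the two
vectors and trains a linear-kernel SVC (one-vs-rest, C=1, features
standardised with training-fold statistics only); DSTAN-Average instead
averages the two streams' softmax probability vectors and takes the argmax
(ties broken towards the lowest class index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from dstan.streams import StreamFeatures


class AlignmentError(ValueError):
    """Sample-id or class-set mismatch between the inputs being fused."""


@dataclass
class FusedTable:
    """Concatenated per-sample features keyed by sample id."""

    sample_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray
    features: np.ndarray  # (n, d_p + d_q)


@dataclass
class FusionModel:
    kind: str  # svm_concat | average
    class_order: np.ndarray
    svm: Pipeline | None = None
    meta: dict = field(default_factory=dict)


def concat_features(p: StreamFeatures, q: StreamFeatures) -> FusedTable:
    """Row-wise concatenation keyed by sample_id; output order follows `p`."""
    q_index = {sid: i for i, sid in enumerate(q.sample_ids)}
    missing = [sid for sid in p.sample_ids if sid not in q_index]
    extra = [sid for sid in q.sample_ids if sid not in set(p.sample_ids)]
    if missing or extra:
        raise AlignmentError(
            f"sample-id mismatch between streams; missing from q: {missing[:5]}, "
            f"extra in q: {extra[:5]}"
        )
    order = [q_index[sid] for sid in p.sample_ids]
    return FusedTable(
        sample_ids=list(p.sample_ids),
        subject_ids=list(p.subject_ids),
        labels=p.labels.copy(),
        features=np.concatenate([p.features, q.features[order]], axis=1),
    )


def fit_svm(train: FusedTable, c: float = 1.0) -> FusionModel:
    """Linear-kernel one-vs-rest SVC on standardised concatenated features."""
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError(f"SVM fusion needs >= 2 classes, got {classes.size}")
    pipeline = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", OneVsRestClassifier(SVC(kernel="linear", C=c))),
        ]
    )
    pipeline.fit(train.features, train.labels)
    return FusionModel(kind="svm_concat", class_order=classes, svm=pipeline)


def predict_fused(model: FusionModel, samples: FusedTable | np.ndarray) -> np.ndarray:
    """One predicted label per sample from the fitted SVM fusion model."""
    if model.kind != "svm_concat" or model.svm is None:
        raise ValueError("predict_fused needs a fitted svm_concat model")
    x = samples.features if isinstance(samples, FusedTable) else np.asarray(samples)
    n_expected = model.svm.named_steps["scale"].n_features_in_
    if x.shape[1] != n_expected:
        raise ValueError(f"feature dimension {x.shape[1]} != training dimension {n_expected}")
    return np.asarray(model.svm.predict(x))


def average_fusion(prob_a: np.ndarray, prob_b: np.ndarray,
                   class_order: np.ndarray | list | None = None) -> np.ndarray:
    """Argmax of the unweighted mean of two per-sample probability tables.

    np.argmax breaks ties towards the lowest class index, which is the
    documented convention.
    """
    prob_a = np.asarray(prob_a, dtype=np.float64)
    prob_b = np.asarray(prob_b, dtype=np.float64)
    if prob_a.shape != prob_b.shape:
        raise AlignmentError(
            f"probability tables disagree in shape: {prob_a.shape} vs {prob_b.shape}"
        )
    mean = 0.5 * (prob_a + prob_b)
    idx = mean.argmax(axis=1)
    if class_order is not None:
        return np.asarray(class_order)[idx]
    return idx
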