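"""Stride-sequence fall-risk classifiers with modified LOSO evaluation.

Model inputs are raw acceleration from k consecutive strides: the six
channels (chest and thigh, axes [v, ml, ap]) sliced from foot contact of the
first stride to foot contact after the k-th, concatenated in time.  A
sliding window with step one stride maximizes the number of inputs
(disjoint blocks are selectable).  The subject's balance-confidence (ABC)
score can ride along as a constant seventh channel.

Two reference architectures are provided — "LSTM2" (LSTM 290, 30% dropout,
BiLSTM 10, 40% dropout, 55 epochs) and "LSTM3" (LSTM 85/85/235 with
55/55/45% dropout, 125 epochs) — plus a reduced architecture for small
experiments; all end in a dense softmax and train with Adam.

Evaluation is a modified leave-one-subject-out: one test subject, one
validation subject chosen by fixed cyclic rotation (the next subject id),
the remainder training; a subject's data never spans sets.  Held-out
decision scores are pooled for the per-input AUC and median-aggregated per
subject for the subject-level AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierOutcome, compute_auc
from .nn import SequenceClassifier
from .types import MsgaitError, TrainingError

__all__ = [
    "ArchitectureSpec", "ARCHITECTURES", "SequenceInput", "build_stride_inputs",
    "train_sequence_model", "loso_sequence_classification",
]


@dataclass
class ArchitectureSpec:
    name: str
    layers: list  # [("lstm", units, bidirectional), ("dropout", p), ...]
    epochs: int
    lr: float = 1e-2


ARCHITECTURES = {
    "LSTM2": ArchitectureSpec(
        name="LSTM2",
        layers=[("lstm", 290, False), ("dropout", 0.30), ("lstm", 10, True), ("dropout", 0.40)],
        epochs=55,
    ),
    "LSTM3": ArchitectureSpec(
        name="LSTM3",
        layers=[("lstm", 85, False), ("dropout", 0.55), ("lstm", 85, False), ("dropout", 0.55),
                ("lstm", 235, False), ("dropout", 0.45)],
        epochs=125,
    ),
}


def reduced_architecture(hidden: int = 16, dropout: float = 0.2, epochs: int = 5,
                         lr: float = 2e-2) -> ArchitectureSpec:
    """A small single-layer architecture for CPU-scale experiments."""
    return ArchitectureSpec(
        name=f"reduced{hidden}",
        layers=[("lstm", hidden, False), ("dropout", dropout)],
        epochs=epochs,
        lr=lr,
    )


@dataclass
class SequenceInput:
    data: np.ndarray  # channels x time
    subject_id: str
    label: int
    bout_id: int = -1
    meta: dict = field(default_factory=dict)


def build_stride_inputs(bouts, cohort: pd.DataFrame, k: int = 4,
                        include_abc: bool = False, mode: str = "sliding"):
    """Cut each bout's stride sequence into k-stride model inputs.

    ``mode`` is "sliding" (step one stride; a bout with s >= k strides gives
    s - k + 1 inputs) or "disjoint" (non-overlapping blocks).  Bouts with
    fewer than k strides contribute nothing.  With ``include_abc`` the
    subject's ABC score is appended as a constant extra channel.
    """
    if k < 1:
        raise MsgaitError("k must be >= 1")
    if mode not in ("sliding", "disjoint"):
        raise MsgaitError(f"unknown mode {mode!r}")
    info = cohort.set_index("subject_id")
    inputs = []
    for bout in bouts:
        s = bout.strides
        if len(s) < k:
            continue
        label = int(info.loc[bout.subject_id, "fall_label"] == "faller")
        abc = float(info.loc[bout.subject_id, "ABC"]) if include_abc else None
        starts = range(0, len(s) - k + 1, 1 if mode == "sliding" else k)
        for start in starts:
            i0 = int(round(s[start].foot_contact_s * bout.fs))
            i1 = int(round(s[start + k - 1].next_contact_s * bout.fs))
            i1 = min(i1, bout.chest_view.shape[1])
            if i1 - i0 < 2:
                continue
            data = np.vstack([bout.chest_view[:, i0:i1], bout.thigh_view[:, i0:i1]])
            if include_abc:
                data = np.vstack([data, np.full((1, data.shape[1]), abc)])
            inputs.append(SequenceInput(data=data, subject_id=bout.subject_id,
                                        label=label, bout_id=bout.bout_id,
                                        meta={"k": k, "start": start}))
    return inputs


def train_sequence_model(inputs, arch: ArchitectureSpec, seed: int = 0,
                         epochs: int | None = None) -> SequenceClassifier:
    """Train one architecture on a list of SequenceInputs."""
    labels = [inp.label for inp in inputs]
    if len(set(labels)) < 2:
        raise TrainingError("sequence training data holds a single class")
    n_channels = inputs[0].data.shape[0]
    model = SequenceClassifier(layers=arch.layers, n_features=n_channels,
                               seed=seed, lr=arch.lr)
    seqs = [inp.data.T for inp in inputs]
    model.fit(seqs, labels, epochs=epochs if epochs is not None else arch.epochs)
    return model


def loso_sequence_classification(inputs, arch: ArchitectureSpec, seed: int = 0,
                                 epochs: int | None = None) -> ClassifierOutcome:
    """Modified LOSO: test subject out, next subject (cyclically) validates,
    the rest train.  Returns pooled and subject-median AUCs."""
    subjects = sorted({inp.subject_id for inp in inputs})
    if len(subjects) < 3:
        raise MsgaitError("modified LOSO needs at least 3 subjects")
    rows = []
    per_fold = []
    for fold, test_subj in enumerate(subjects):
        val_subj = subjects[(fold + 1) % len(subjects)]
        train_inp = [x for x in inputs if x.subject_id not in (test_subj, val_subj)]
        test_inp = [x for x in inputs if x.subject_id == test_subj]
        val_inp = [x for x in inputs if x.subject_id == val_subj]
        assert not (
            {x.subject_id for x in train_inp}
            & ({test_subj} | {val_subj})
        ), "subject leaked across partitions"
        try:
            model = train_sequence_model(train_inp, arch, seed=seed, epochs=epochs)
        except TrainingError:
            per_fold.append({"subject": test_subj, "skipped": True})
            continue
        scores = model.decision_scores([x.data.T for x in test_inp])
        for x, sc in zip(test_inp, scores):
            rows.append({"subject_id": x.subject_id, "score": float(sc),
                         "label": x.label, "fold": fold})
        fold_info = {"subject": test_subj, "validation_subject": val_subj,
                     "n_train": len(train_inp), "n_test": len(test_inp)}
        if val_inp and len({x.label for x in val_inp}) > 0:
            fold_info["val_mean_score"] = float(
                np.mean(model.decision_scores([x.data.T for x in val_inp]))
            )
        per_fold.append(fold_info)
    if not rows:
        raise MsgaitError("no held-out scores: every fold was skipped")
    scores = pd.DataFrame(rows)
    auc_input = compute_auc(scores["score"], scores["label"])
    subj = scores.groupby("subject_id").agg(score=("score", "median"),
                                            label=("label", "first"))
    auc_subject = compute_auc(subj["score"], subj["label"])
    return ClassifierOutcome(scores=scores, auc_per_input=auc_input,
                             auc_subject_median=auc_subject, per_fold=per_fold,
                             model_family=arch.name, feature_set=f"k={inputs[0].meta.get('k')}")


def run_sequence_grid(bouts, cohort: pd.DataFrame, ks, archs, seed: int = 0,
                      epochs: int | None = None, include_abc=(False, True)) -> pd.DataFrame:
    """Experiment grid over strides-per-input, architecture and ABC flag.

    Returns one row per (k, architecture, abc) with per-input and
    subject-median AUC; configurations that yield no inputs or a single class
    are recorded with NaN AUCs.
    """
    rows = []
    for k in ks:
        for abc in include_abc:
            inputs = build_stride_inputs(bouts, cohort, k=k, include_abc=abc)
            for arch in archs:
                row = {"k_strides": k, "model": arch.name, "abc": abc,
                       "n_inputs": len(inputs)}
                try:
                    out = loso_sequence_classification(inputs, arch, seed=seed, epochs=epochs)
                    row["auc_per_input"] = out.auc_per_input
                    row["auc_subject_median"] = out.auc_subject_median
                except MsgaitError:
                    row["auc_per_input"] = np.nan
                    row["auc_subject_median"] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)
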