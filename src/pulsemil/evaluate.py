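"""Evaluation: confusion-matrix metrics, attention diagnostics, ablations.

Conventions, stated in every output: confusion-matrix rows are the true
class, columns the predicted class; the positive class is "high".
Metrics with a zero denominator are defined as 0 (with a warning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sessionio
from .curriculum import predict_session
from .network import Model
from .sparsecore import shannon_entropy, softmax as np_softmax, entmax_bisect

CLASS_NAMES = ("low", "high")


@dataclass(frozen=True)
class EvaluationReport:
    confusion: np.ndarray  # rows = true, cols = predicted
    accuracy: float
    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    weighted_f1: float
    n_per_class: tuple[int, ...]
    n_total: int

    def to_dict(self) -> dict:
        return {
            "convention": "rows=true, cols=predicted; positive class = 'high'",
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": list(self.precision),
            "recall": list(self.recall),
            "f1": list(self.f1),
            "weighted_f1": self.weighted_f1,
            "n_per_class": list(self.n_per_class),
            "n_total": self.n_total,
        }


def confusion_from_predictions(
    y_true, y_pred, n_classes: int = 2
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def compute_metrics(confusion: np.ndarray) -> EvaluationReport:
    """Accuracy, per-class precision/recall/F1 and weighted F1.

    accuracy = trace / N; precision_c = TP/(TP+FP); recall_c = TP/(TP+FN);
    F1_c is their harmonic mean; weighted F1 = sum_c (N_c / N) F1_c with
    N_c the true count of class c.
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and nonempty")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be nonnegative")
    n = int(cm.sum())
    if n == 0:
        raise ValueError("confusion matrix is all zeros")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    precision, recall, f1 = [], [], []
    for c in range(cm.shape[0]):
        if tp[c] + fp[c] == 0:
            warnings.warn(f"class {c}: no predicted samples, precision set to 0")
            p = 0.0
        else:
            p = tp[c] / (tp[c] + fp[c])
        if tp[c] + fn[c] == 0:
            warnings.warn(f"class {c}: no true samples, recall set to 0")
            r = 0.0
        else:
            r = tp[c] / (tp[c] + fn[c])
        if p + r == 0:
            warnings.warn(f"class {c}: F1 undefined, set to 0")
            f = 0.0
        else:
            f = 2.0 * p * r / (p + r)
        precision.append(p)
        recall.append(r)
        f1.append(f)
    n_c = cm.sum(axis=1)
    weighted_f1 = float(np.sum(n_c / n * np.asarray(f1)))
    return EvaluationReport(
        confusion=cm.copy(),
        accuracy=float(tp.sum() / n),
        precision=tuple(precision),
        recall=tuple(recall),
        f1=tuple(f1),
        weighted_f1=weighted_f1,
        n_per_class=tuple(int(x) for x in n_c),
        n_total=n,
    )


def evaluate_model(
    model: Model,
    records: list[sessionio.SessionRecord],
    target: str = "arousal",
    alpha: float = 1.8,
    split: str | None = "test",
    mode: str | None = None,
) -> EvaluationReport:
    """Run the inference path over sessions and score the predictions."""
    y_true, y_pred = [], []
    for rec in records:
        if split is not None and rec.split != split:
            continue
        chunks = sessionio.chunk_waveform(rec.waveform).chunks.astype(np.float32)
        pred, _, _ = predict_session(model, chunks, alpha, mode)
        y_true.append(1 if rec.label(target) == "high" else 0)
        y_pred.append(pred)
    if not y_true:
        raise ValueError(f"no sessions in split {split!r}")
    return compute_metrics(confusion_from_predictions(y_true, y_pred))


def attention_report(
    model: Model,
    records: list[sessionio.SessionRecord],
    masks: dict[str, list[int]] | None = None,
    alpha: float = 1.5,
) -> list[dict]:
    """Per-session softmax vs entmax attention diagnostics.

    For each session (skipping, with a warning, any shorter than one
    chunk) the report holds both distributions over chunks, their Shannon
    entropies, and — when a saliency mask is available — the fraction of
    attention mass assigned to the implanted event chunks.
    """
    out = []
    import pulsemil.autograd as ag

    for rec in records:
        try:
            chunks = sessionio.chunk_waveform(rec.waveform).chunks.astype(np.float32)
        except ValueError:
            warnings.warn(f"session {rec.session_id}: shorter than one chunk, skipped")
            continue
        with ag.no_grad():
            h = model.encode(chunks)
            scores = model.score(h, training=False).data
        if scores.size == 1:
            soft = np.ones(1)
            sparse = np.ones(1)
        else:
            soft = np_softmax(scores)
            sparse = entmax_bisect(scores, alpha)
        entry = {
            "session_id": rec.session_id,
            "split": rec.split,
            "n_chunks": int(scores.size),
            "softmax": [float(x) for x in soft],
            "entmax": [float(x) for x in sparse],
            "softmax_entropy": float(shannon_entropy(soft)),
            "entmax_entropy": float(shannon_entropy(sparse)),
        }
        if masks is not None and rec.session_id in masks:
            mask = np.asarray(masks[rec.session_id], dtype=float)[: scores.size]
            entry["event_mass_softmax"] = float(np.sum(soft * mask))
            entry["event_mass_entmax"] = float(np.sum(sparse * mask))
            entry["n_event_chunks"] = int(mask.sum())
        out.append(entry)
    return out


def save_attention_report(path: str | Path, report: list[dict]) -> None:
    with open(path, "w") as fh:
        for entry in report:
            fh.write(json.dumps(entry) + "\n")


# ------------------------------------------------------------------ ablation
VARIANT_KINDS = {
    "pooling": ("gated", "attention", "average"),
    "branches": ("1", "2", "3", "4"),
    "curriculum": ("full", "no-topk", "no-aux", "no-supcon", "direct"),
}


def parse_variant(name: str) -> tuple[str, str]:
    if ":" not in name:
        raise ValueError(f"variant {name!r} must look like 'kind:value'")
    kind, value = name.split(":", 1)
    if kind not in VARIANT_KINDS or value not in VARIANT_KINDS[kind]:
        raise ValueError(
            f"unknown variant {name!r}; kinds and values: {VARIANT_KINDS}"
        )
    return kind, value


def ablation_suite(
    records: list[sessionio.SessionRecord],
    variants: list[str],
    seeds: list[int],
    target: str = "arousal",
    epochs: tuple[int, int, int] = (15, 15, 21),
    batch_sessions: int = 8,
) -> pd.DataFrame:
    """Train and evaluate each (variant, seed); returns rows plus medians.

    Variant names look like ``pooling:average``, ``branches:1`` or
    ``curriculum:direct``; each deviates from the canonical configuration
    in exactly that one respect.
    """
    from .curriculum import run_curriculum
    from .network import canonical_config

    rows = []
    for name in variants:
        kind, value = parse_variant(name)
        for seed in seeds:
            config = canonical_config(
                pooling_mode=value if kind == "pooling" else "gated",
                n_branches=int(value) if kind == "branches" else 3,
            )
            curriculum = value if kind == "curriculum" else "full"
            result = run_curriculum(
                records,
                target=target,
                config=config,
                epochs=epochs,
                batch_sessions=batch_sessions,
                seed=seed,
                curriculum=curriculum,
            )
            report = evaluate_model(
                result.model, records, target, alpha=result.inference_alpha
            )
            rows.append(
                {
                    "variant": name,
                    "seed": seed,
                    "accuracy": report.accuracy,
                    "weighted_f1": report.weighted_f1,
                    "is_median": False,
                }
            )
    df = pd.DataFrame(rows)
    medians = (
        df.groupby("variant")[["accuracy", "weighted_f1"]].median().reset_index()
    )
    medians["seed"] = -1
    medians["is_median"] = True
    return pd.concat([df, medians], ignore_index=True)[
        ["variant", "seed", "accuracy", "weighted_f1", "is_median"]
    ]
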