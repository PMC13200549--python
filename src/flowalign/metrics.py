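"""Evaluation of alignments against ground truth.

Two schemes:

* **LC-MS precision/recall** against peptide-identity ground truth.  Only a
  subset of detected features carries a reliable identification; a
  predicted pair is a true positive when both features share the same
  reliable label, a false positive when the labels differ *or* when exactly
  one feature is labeled and that label participates in the ground-truth
  pairing (it should have been matched to its true partner instead).
  Pairs touching no reliable feature are excluded from evaluation.

* **Extended confusion matrix** for class-labeled (clustered) spectra.
  Treating the class of the matched second-spectrum peak as the prediction
  for the first-spectrum peak gives an ordinary confusion matrix; it is
  extended with an extra column for unmatched first-spectrum peaks and an
  extra row for unmatched second-spectrum peaks, so missed peaks penalize
  accuracy, precision and recall instead of silently disappearing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lcms import MatchTable
from .spectra_io import AxisScaling, Spectrum

__all__ = [
    "GroundTruth",
    "ExtendedConfusionMatrix",
    "EvalReport",
    "lcms_precision_recall",
    "extended_confusion",
    "extended_metrics",
    "grid_search",
]


@dataclass(frozen=True)
class GroundTruth:
    """Reliable id -> label annotations for one spectrum.

    ``reliable`` restricts evaluation to confidently labeled ids; it
    defaults to every annotated id.  For LC-MS pairing each label must
    occur on at most one reliable feature per run.
    """

    id_to_label: Mapping[str, str]
    reliable: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        rel = (frozenset(self.id_to_label)
               if self.reliable is None else frozenset(self.reliable))
        object.__setattr__(self, "reliable", rel)
        missing = rel - set(self.id_to_label)
        if missing:
            raise ValueError(f"reliable ids without a label: {sorted(missing)[:5]}")

    def reliable_label(self, pid: str) -> Optional[str]:
        return self.id_to_label[pid] if pid in self.reliable else None

    def label_to_reliable_id(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pid in self.reliable:
            lab = self.id_to_label[pid]
            if lab in out:
                raise ValueError(
                    f"label {lab!r} borne by two reliable ids in one spectrum"
                )
            out[lab] = pid
        return out


@dataclass(frozen=True)
class EvalReport:
    """Alignment quality summary.

    ``precision`` is ``None`` (undefined) when no pair was evaluated.
    Extended-mode reports additionally carry accuracy and macro-averaged
    precision/recall over real classes.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: Optional[float] = None
    recall: Optional[float] = None
    accuracy: Optional[float] = None
    macro_precision: Optional[float] = None
    macro_recall: Optional[float] = None
    per_class: dict = field(default_factory=dict)


def lcms_precision_recall(m: MatchTable, gt_a: GroundTruth,
                          gt_b: GroundTruth) -> EvalReport:
    """Precision/recall of consensus pairs against peptide identities.

    The ground truth is the set of labels reliably present on both sides;
    TP + FN always equals that pair count.
    """
    by_label_a = gt_a.label_to_reliable_id()
    by_label_b = gt_b.label_to_reliable_id()
    gt_labels = set(by_label_a) & set(by_label_b)

    tp = fp = 0
    hit_labels: set[str] = set()
    for ia, ib, _, _ in m.pairs:
        la = gt_a.reliable_label(ia)
        lb = gt_b.reliable_label(ib)
        if la is not None and lb is not None:
            if la == lb:
                tp += 1
                hit_labels.add(la)
            else:
                fp += 1
        elif la is not None or lb is not None:
            lab = la if la is not None else lb
            if lab in gt_labels:
                fp += 1  # its true partner exists and was missed
            # else: excluded — nothing to compare against
        # both unlabeled: excluded from evaluation
    fn = len(gt_labels) - len(hit_labels)
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return EvalReport(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall)


@dataclass(frozen=True)
class ExtendedConfusionMatrix:
    """(K+1) x (K+1) class-assignment counts with unmatched row/column.

    Rows: true class of the first-spectrum (S1) peak, plus a final row for
    unmatched S2 peaks; columns: class of the matched S2 peak, plus a final
    column for unmatched S1 peaks.  The corner (unmatched, unmatched) cell
    is structurally zero.
    """

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.classes)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (k + 1, k + 1):
            raise ValueError("counts must be (K+1) x (K+1)")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if counts[k, k] != 0:
            raise ValueError("the (unmatched, unmatched) corner must be zero")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = list(self.classes)
        return pd.DataFrame(self.counts,
                            index=names + ["u_S2"],
                            columns=names + ["u_S1"])


def extended_confusion(m: MatchTable,
                       classes_a: Mapping[str, str],
                       classes_b: Mapping[str, str]) -> ExtendedConfusionMatrix:
    """Tally emitted pairs and unmatched peaks by class membership."""
    names = sorted(set(classes_a.values()) | set(classes_b.values()))
    idx = {c: k for k, c in enumerate(names)}
    k = len(names)
    counts = np.zeros((k + 1, k + 1), dtype=int)
    for ia, ib, _, _ in m.pairs:
        counts[idx[classes_a[ia]], idx[classes_b[ib]]] += 1
    for ia in m.unmatched_a:
        counts[idx[classes_a[ia]], k] += 1
    for ib in m.unmatched_b:
        counts[k, idx[classes_b[ib]]] += 1
    return ExtendedConfusionMatrix(classes=tuple(names), counts=counts)


def extended_metrics(c: ExtendedConfusionMatrix) -> EvalReport:
    """Accuracy and macro precision/recall from an extended matrix.

    Unmatched cells enter every denominator but never a numerator, so a
    peak lost by the alignment costs exactly as much as a misassigned one.
    Per-class values are macro-averaged over classes with a nonzero
    denominator and also reported individually.
    """
    total = c.grand_total
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = len(c.classes)
    diag = np.diag(c.counts)[:k]
    rowsum = c.counts.sum(axis=1)[:k]
    colsum = c.counts.sum(axis=0)[:k]
    per_class = {}
    precs, recs = [], []
    for i, name in enumerate(c.classes):
        p = diag[i] / colsum[i] if colsum[i] > 0 else None
        r = diag[i] / rowsum[i] if rowsum[i] > 0 else None
        per_class[name] = {"precision": p, "recall": r}
        if p is not None:
            precs.append(p)
        if r is not None:
            recs.append(r)
    return EvalReport(
        tp=int(diag.sum()),
        accuracy=float(diag.sum() / total),
        macro_precision=float(np.mean(precs)) if precs else None,
        macro_recall=float(np.mean(recs)) if recs else None,
        per_class=per_class,
    )


def grid_search(a: Spectrum, b: Spectrum,
                classes_a: Mapping[str, str], classes_b: Mapping[str, str],
                d_max_values: Sequence[float],
                delta_max_values: Sequence[float],
                scaling: AxisScaling | None = None,
                match_fraction: float = 0.5) -> pd.DataFrame:
    """Extended metrics over a full (d_max, delta_max) Cartesian grid.

    One row per parameter combination with columns ``d_max``,
    ``delta_max``, ``accuracy``, ``precision``, ``recall`` (macro).
    Deterministic for fixed inputs.
    """
    from .nmr import align_nmr  # local import: metrics stays front-end-agnostic

    d_vals = list(d_max_values)
    g_vals = list(delta_max_values)
    if not d_vals or not g_vals:
        raise ValueError("parameter ranges must be non-empty")
    rows = []
    for d_max in d_vals:
        for delta_max in g_vals:
            _, table = align_nmr(a, b, d_max, delta_max, scaling,
                                 match_fraction)
            rep = extended_metrics(extended_confusion(table, classes_a,
                                                      classes_b))
            rows.append({
                "d_max": d_max,
                "delta_max": delta_max,
                "accuracy": rep.accuracy,
                "precision": rep.macro_precision,
                "recall": rep.macro_recall,
            })
    return pd.DataFrame(rows)
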