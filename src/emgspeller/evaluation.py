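"""Scoring decoded sessions: confusion matrix, accuracy/precision/recall/F1,
and the information transfer rate (ITR) of a discrete-selection interface.

ITR (bits/min) for N commands decoded with accuracy P at T seconds per
selection:

    ITR = [log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1))] * 60 / T

which is the channel capacity of a symmetric N-ary channel; it is 0 at
chance level P = 1/N and log2(N) * 60/T bits/min at P = 1 (the P log2 P and
(1-P) terms taken at their limits).

Because a decoder can both miss true events and emit spurious ones, the
confusion matrix carries an extra "(none)" row/column when unmatched events
exist; per-class and macro metrics are computed over the command classes
only, with unmatched events feeding the FN/FP tallies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .events import COMMANDS, CommandEvent

NONE_LABEL = "(none)"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square table of (true, predicted) event counts; rows = true class."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("counts shape does not match labels")
        if np.any(arr < 0):
            raise ConfigError("negative counts")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, label: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against the rest."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_text(self) -> str:
        w = max(len(l) for l in self.labels) + 2
        head = " " * w + "".join(f"{l:>{w}}" for l in self.labels)
        rows = [head]
        for i, l in enumerate(self.labels):
            rows.append(
                f"{l:>{w}}" + "".join(f"{int(v):>{w}}" for v in self.counts[i])
            )
        return "\n".join(rows)


def confusion(
    true_events: list[CommandEvent],
    predicted_events: list[CommandEvent],
    matching_window: float = 2.0,
    labels: tuple[str, ...] = COMMANDS,
) -> ConfusionMatrix:
    """Match each true event to the nearest unmatched prediction (by onset)
    within ``matching_window`` seconds, greedily in time order; unmatched
    events land in the "(none)" row/column."""
    true_sorted = sorted(true_events, key=lambda e: e.onset)
    pred_sorted = sorted(predicted_events, key=lambda e: e.onset)
    used = [False] * len(pred_sorted)
    pairs: list[tuple[str, str]] = []
    for tev in true_sorted:
        best_j, best_d = None, None
        for j, pev in enumerate(pred_sorted):
            if used[j]:
                continue
            d = abs(pev.onset - tev.onset)
            if d <= matching_window and (best_d is None or d < best_d):
                best_j, best_d = j, d
        if best_j is None:
            pairs.append((tev.command, NONE_LABEL))
        else:
            used[best_j] = True
            pairs.append((tev.command, pred_sorted[best_j].command))
    for j, pev in enumerate(pred_sorted):
        if not used[j]:
            pairs.append((NONE_LABEL, pev.command))

    all_labels = tuple(labels)
    if any(NONE_LABEL in p for p in pairs):
        all_labels = all_labels + (NONE_LABEL,)
    index = {l: i for i, l in enumerate(all_labels)}
    counts = np.zeros((len(all_labels), len(all_labels)), dtype=np.int64)
    for t, p in pairs:
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(all_labels, counts)


@dataclass(frozen=True)
class MetricsReport:
    """Percentages; per-class values follow the one-vs-rest definitions."""

    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    macro_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    overall_accuracy: float  # trace / total

    def to_text(self) -> str:
        lines = [f"{'class':>10} {'acc':>7} {'prec':>7} {'rec':>7} {'f1':>7}"]
        for l in self.labels:
            m = self.per_class[l]
            lines.append(
                f"{l:>10} {m['accuracy']:7.1f} {m['precision']:7.1f} "
                f"{m['recall']:7.1f} {m['f1']:7.1f}"
            )
        lines.append(
            f"{'macro':>10} {self.macro_accuracy:7.1f} {self.macro_precision:7.1f} "
            f"{self.macro_recall:7.1f} {self.macro_f1:7.1f}"
        )
        lines.append(f"overall accuracy (trace/total): {self.overall_accuracy:.1f}%")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(cm: ConfusionMatrix, classes: tuple[str, ...] = COMMANDS) -> MetricsReport:
    if cm.total == 0:
        raise ConfigError("empty confusion matrix")
    present = tuple(l for l in classes if l in cm.labels)
    per_class: dict[str, dict[str, float]] = {}
    for l in present:
        tp, fp, fn, tn = cm.one_vs_rest(l)
        acc = _safe_div(tp + tn, tp + tn + fp + fn) * 100.0
        prec = _safe_div(tp, tp + fp) * 100.0
        rec = _safe_div(tp, tp + fn) * 100.0
        f1 = _safe_div(2 * prec * rec, prec + rec)
        per_class[l] = {
            "accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
        }
    macro = {
        k: float(np.mean([per_class[l][k] for l in present]))
        for k in ("accuracy", "precision", "recall", "f1")
    }
    diag = sum(
        int(cm.counts[cm.labels.index(l), cm.labels.index(l)]) for l in present
    )
    return MetricsReport(
        labels=present,
        per_class=per_class,
        macro_accuracy=macro["accuracy"],
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        overall_accuracy=diag / cm.total * 100.0,
    )


def itr(p: float, t: float, n: int = 5) -> float:
    """Information transfer rate in bits per minute.

    ``p``: classification accuracy as a probability; ``t``: average seconds
    per selection; ``n``: number of available commands.
    """
    if n < 2:
        raise ConfigError("itr needs at least 2 commands")
    if t <= 0:
        raise ConfigError("selection time must be positive")
    if p < 1.0 / n - 1e-12:
        raise ConfigError(f"accuracy {p} below chance 1/{n}; ITR undefined")
    p = min(p, 1.0)
    bits = math.log2(n)
    if p > 0:
        bits += p * math.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n - 1))
    return bits * 60.0 / t


def measure_selection_time(events: list[CommandEvent], active_duration: float) -> float:
    """Average seconds per selection over the active (non-rest) session time."""
    if not events:
        raise ConfigError("no events: selection time undefined")
    if active_duration <= 0:
        raise ConfigError("active duration must be positive")
    return active_duration / len(events)


@dataclass(frozen=True)
class SessionReport:
    name: str
    accuracy_pct: float
    itr_bits_per_min: float
    n_events: int = 0
    metrics_report: MetricsReport | None = None
    cm: ConfusionMatrix | None = None


def session_summary(reports: list[SessionReport]) -> dict[str, float]:
    """Arithmetic means of accuracy and ITR across sessions/experiments."""
    if not reports:
        raise ConfigError("no session reports to summarize")
    return {
        "mean_accuracy_pct": float(np.mean([r.accuracy_pct for r in reports])),
        "mean_itr_bits_per_min": float(
            np.mean([r.itr_bits_per_min for r in reports])
        ),
    }
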