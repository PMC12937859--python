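"""Metrics, precision-recall curves, and throughput/occupancy accounting.

The accounting turns gate statistics into the system-level efficiency
numbers: with the hardware gate shutting a fraction ``s0`` of the session
and a fraction ``low`` of the remaining time handled at the low-resolution
configuration (whose bit rate is a fraction ``b`` cheaper than full
resolution),

    occupancy        = s0 + (1 - s0) * low          (ultra-low-power time)
    total_reduction  = s0 + b * low * (1 - s0)      (data-volume saving)

against a full-precision reference of 12 bit x 2 kHz = 24 kbps/channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .cascade import DecisionTrace

__all__ = [
    "ThroughputReport",
    "classification_metrics",
    "pr_curve",
    "throughput_report",
    "measure_gate_statistics",
    "bit_rate_saving",
    "FULLRES_KBPS",
]

#: 12 bit x 2 kHz full-precision reference, kbps per channel.
FULLRES_KBPS = 24.0


@dataclass
class ThroughputReport:
    """System-level efficiency summary; all fractions in [0, 1]."""

    s0_frac: float
    lowres_frac: float
    bit_reduction: float
    occupancy: float
    algorithmic_reduction: float
    total_reduction: float
    fullres_kbps: float
    effective_kbps: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        return (
            f"hardware-gated (S0) time        : {self.s0_frac:7.2%}\n"
            f"low-res share of remaining time : {self.lowres_frac:7.2%}\n"
            f"low-res bit-rate saving         : {self.bit_reduction:7.2%}\n"
            f"ultra-low-power occupancy       : {self.occupancy:7.2%}\n"
            f"algorithmic data reduction      : {self.algorithmic_reduction:7.2%}\n"
            f"total data reduction            : {self.total_reduction:7.2%}\n"
            f"per-channel rate                : {self.fullres_kbps:.1f} -> "
            f"{self.effective_kbps:.2f} kbps\n"
        )


def classification_metrics(
    pred: np.ndarray, truth: np.ndarray, scores: np.ndarray | None = None
) -> dict[str, float]:
    """F1 / precision / recall (positive class), AUC from scores if given.

    Raises on a single-class truth when AUC is requested (the ROC is
    undefined there); the threshold metrics remain defined.
    """
    from sklearn.metrics import precision_score, recall_score, f1_score, roc_auc_score

    pred = np.asarray(pred).ravel().astype(int)
    truth = np.asarray(truth).ravel().astype(int)
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("pred and truth must be non-empty and equal length")
    out = {
        "precision": float(precision_score(truth, pred, zero_division=0)),
        "recall": float(recall_score(truth, pred, zero_division=0)),
        "f1": float(f1_score(truth, pred, zero_division=0)),
    }
    if scores is not None:
        if np.unique(truth).size < 2:
            raise ValueError("AUC undefined for single-class truth")
        out["auc"] = float(roc_auc_score(truth, np.asarray(scores).ravel()))
    return out


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Exhaustive precision-recall sweep over the distinct score values.

    Returns an array of (threshold, precision, recall) rows ordered by
    increasing threshold, with the decision rule score >= threshold; recall
    is non-increasing along the rows.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if not labels.any():
        raise ValueError("pr_curve needs at least one positive label")
    n_pos = labels.sum()
    rows = []
    for thr in np.unique(scores):
        sel = scores >= thr
        tp = np.sum(sel & labels)
        prec = tp / sel.sum() if sel.any() else 1.0
        rows.append((float(thr), float(prec), float(tp / n_pos)))
    return np.array(rows)


def bit_rate_saving(bits_low: int, rate_low: float, bits_high: int,
                    rate_high: float) -> float:
    """Relative bit-rate saving of the low-res stream vs the high-res one:
    1 - (6*1000)/(12*2000) = 0.75 for the default configurations."""
    full = bits_high * rate_high
    if full <= 0:
        raise ValueError("high-res bit rate must be positive")
    return 1.0 - (bits_low * rate_low) / full


def throughput_report(
    s0_frac: float,
    lowres_frac: float,
    bit_reduction: float,
    fullres_kbps: float = FULLRES_KBPS,
) -> ThroughputReport:
    """Combine gate statistics into the system efficiency report."""
    for name, v in (("s0_frac", s0_frac), ("lowres_frac", lowres_frac),
                    ("bit_reduction", bit_reduction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if fullres_kbps <= 0:
        raise ValueError("fullres_kbps must be positive")
    occupancy = s0_frac + (1.0 - s0_frac) * lowres_frac
    algo = bit_reduction * lowres_frac * (1.0 - s0_frac)
    total = s0_frac + algo
    return ThroughputReport(
        s0_frac=s0_frac,
        lowres_frac=lowres_frac,
        bit_reduction=bit_reduction,
        occupancy=occupancy,
        algorithmic_reduction=algo,
        total_reduction=total,
        fullres_kbps=fullres_kbps,
        effective_kbps=fullres_kbps * (1.0 - total),
    )


def measure_gate_statistics(trace: DecisionTrace) -> tuple[float, float]:
    """Empirical (s0_frac, lowres_frac) from a cascade decision trace.

    ``s0_frac`` is the gated share of all windows; ``lowres_frac`` the
    share of non-gated windows that stayed at the low-resolution
    configuration (screened rest plus windows whose escalation GRU2
    rejected). All-gated traces return lowres_frac = 0 by convention.
    """
    n = trace.stage.size
    if n == 0:
        raise ValueError("empty decision trace")
    counts = trace.counts()
    s0 = counts["gated_S0"] / n
    non_gated = n - counts["gated_S0"]
    if non_gated == 0:
        return float(s0), 0.0
    low = (counts["screened_rest"] + counts["confirmed_reject"]) / non_gated
    return float(s0), float(low)
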