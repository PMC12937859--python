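"""Four-state labels (S0/S1/S2/S3) and the sliding-window dataset.

States:

* S0 — distinct rest: below the silence-detector threshold, near the noise
  floor. The hardware gate handles these alone.
* S1 — indistinguishable rest: above-threshold interference (EMG, blinks,
  non-motor fluctuations) with no pre-movement temporal structure.
* S2 — transition: the preparation span of length T_pre tracing back from
  the movement trigger (switch release).
* S3 — fully active: from the trigger until the end of the trial.

Event-defined states (S2/S3) take priority over the detector split
(S1 vs S0). A window "belongs" to an interval iff its last sample falls in
the half-open interval [start, end) — decisions are stamped at window end,
keeping the labeling causal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrialEvents", "WindowDataset", "make_windows", "label_states", "STATES"]

STATES = ("S0", "S1", "S2", "S3")

#: Default preparation span: four analysis windows of 512 ms.
DEFAULT_T_PRE = 4 * 0.512


@dataclass
class TrialEvents:
    """Per-trial behavioral timestamps in seconds.

    ``t_release`` marks movement onset (the physical trigger); the trial
    runs until ``t_trial_end``. ``t_pre`` is the trace-back span that
    defines the transition state before each release.
    """

    t_release: np.ndarray
    t_trial_end: np.ndarray
    t_pre: float = DEFAULT_T_PRE

    def __post_init__(self) -> None:
        self.t_release = np.atleast_1d(np.asarray(self.t_release, dtype=np.float64))
        self.t_trial_end = np.atleast_1d(np.asarray(self.t_trial_end, dtype=np.float64))
        if self.t_release.shape != self.t_trial_end.shape:
            raise ValueError("t_release and t_trial_end must have equal length")
        if np.any(self.t_trial_end <= self.t_release):
            raise ValueError("each trial must end after its release event")
        order = np.argsort(self.t_release)
        self.t_release = self.t_release[order]
        self.t_trial_end = self.t_trial_end[order]
        if np.any(self.t_release[1:] < self.t_trial_end[:-1]):
            raise ValueError("trials must not overlap")
        if self.t_pre < 0:
            raise ValueError("t_pre must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.t_release.size


@dataclass
class WindowDataset:
    """Sliding windows over a signal: 512 ms field of view, 16 ms stride.

    Window ``i`` covers samples ``[i*stride, i*stride + win)`` of the
    reference (high-rate) timeline; consecutive windows share
    ``win - stride`` samples. ``t_last[i]`` is the timestamp of the
    window's final sample, at which the decision for that window is issued.
    """

    x: np.ndarray
    fs: float
    win: int
    stride: int
    labels: np.ndarray | None = None
    x_low: np.ndarray | None = None  # time-aligned low-rate stream
    fs_low: float | None = None

    @property
    def n_windows(self) -> int:
        return (len(self.x) - self.win) // self.stride + 1

    @property
    def t_last(self) -> np.ndarray:
        starts = np.arange(self.n_windows) * self.stride
        return (starts + self.win - 1) / self.fs

    def window(self, i: int) -> np.ndarray:
        s = i * self.stride
        return self.x[s : s + self.win]

    def windows_highres(self) -> np.ndarray:
        """All windows of the high-rate stream, shape (n_windows, win)."""
        starts = np.arange(self.n_windows)[:, None] * self.stride
        return self.x[starts + np.arange(self.win)]

    def windows_lowres(self) -> np.ndarray:
        """Time-aligned windows of the low-rate stream."""
        if self.x_low is None or self.fs_low is None:
            raise ValueError("dataset has no low-rate view")
        factor = self.fs / self.fs_low
        win_lo = int(round(self.win / factor))
        stride_lo = self.stride / factor
        starts = np.rint(np.arange(self.n_windows) * stride_lo).astype(int)[:, None]
        return self.x_low[starts + np.arange(win_lo)]


def make_windows(
    x: np.ndarray,
    fs: float,
    win_ms: float = 512.0,
    stride_ms: float = 16.0,
    x_low: np.ndarray | None = None,
    fs_low: float | None = None,
) -> WindowDataset:
    """Cut a signal into trailing (causal) fixed-length windows.

    n_windows = floor((n_samples - win) / stride) + 1.
    """
    x = np.asarray(x)
    win = int(round(win_ms * fs / 1000.0))
    stride = int(round(stride_ms * fs / 1000.0))
    if len(x) < win:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {win}-sample window"
        )
    return WindowDataset(x=x, fs=fs, win=win, stride=stride, x_low=x_low, fs_low=fs_low)


def label_states(
    windows: WindowDataset,
    events: TrialEvents | None,
    gate_flags: np.ndarray,
) -> np.ndarray:
    """Assign one of S0/S1/S2/S3 to every window.

    Priority S3 > S2 > (S1|S0): windows whose last sample falls in
    [t_release, t_trial_end) are S3; in [t_release - t_pre, t_release) are
    S2; the rest split into S1 (gate open) vs S0 (gate shut) by the
    detector flags, which must align one-to-one with the windows.
    """
    n = windows.n_windows
    gate_flags = np.asarray(gate_flags, dtype=bool)
    if gate_flags.shape != (n,):
        raise ValueError(f"expected {n} gate flags, got {gate_flags.shape}")
    t = windows.t_last
    labels = np.where(gate_flags, "S1", "S0").astype("<U2")
    if events is not None and events.n_trials > 0:
        duration = len(windows.x) / windows.fs
        if np.any(events.t_release < 0) or np.any(events.t_trial_end > duration + 1e-9):
            raise ValueError("trial events fall outside the recording span")
        for rel in events.t_release:
            labels[(t >= rel - events.t_pre) & (t < rel)] = "S2"
        # S3 assigned last so it wins over a following trial's trace-back
        for rel, end in zip(events.t_release, events.t_trial_end):
            labels[(t >= rel) & (t < end)] = "S3"
    windows.labels = labels
    return labels
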