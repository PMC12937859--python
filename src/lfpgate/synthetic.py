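"""Synthetic four-state LFP sessions with ground truth.

The generator emulates the state semantics the pipeline is built around,
not the biophysics of cortex:

* S0 (distinct rest) — Gaussian noise at the background-noise amplitude;
  occupies most of the session.
* S1 (indistinguishable rest) — the same noise plus randomly timed
  high-amplitude broadband bursts (EMG/blink-like artifacts, 100-300 ms,
  5-10x the noise floor) with no pre-movement temporal structure.
* S2 (transition) — a linear amplitude ramp of the active oscillation from
  the resting baseline into the burst, spanning T_pre before each release.
* S3 (fully active) — sustained band-limited oscillations (beta 22 Hz +
  high-gamma 80 Hz by default, the bands carrying motor intent) until the
  trial ends.

Trials are laid out so the requested S2/S3 occupancies are met by
construction; S1 bursts are placed into the remaining rest until their
sample budget is spent. All channels share the oscillatory/artifact signal
plus a configurable fraction of common noise; everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import LfpRecording, downsample, quantize, QuantizedStream
from .labeling import TrialEvents, DEFAULT_T_PRE

__all__ = ["SynthConfig", "generate_session", "generate_grid_variants",
           "STATE_CODES"]

STATE_CODES = {"S0": 0, "S1": 1, "S2": 2, "S3": 3}


@dataclass
class SynthConfig:
    """Session recipe. Amplitudes in uV, durations in seconds."""

    fs: float = 2000.0
    duration_s: float = 60.0
    n_channels: int = 4
    noise_sd: float = 5.0
    # occupancy targets as fractions of session time (S0 is the remainder)
    frac_s1: float = 0.15
    frac_s2: float = 0.10
    frac_s3: float = 0.12
    t_pre: float = DEFAULT_T_PRE
    artifact_amp_range: tuple[float, float] = (5.0, 10.0)  # x noise_sd
    artifact_dur_range: tuple[float, float] = (0.1, 0.3)   # seconds
    ramp: str = "linear"  # or "sigmoid"
    ramp_onset_level: float = 0.25  # envelope at preparation onset (x full amp)
    osc_freqs: tuple[float, ...] = (22.0, 80.0)
    osc_amps: tuple[float, ...] = (20.0, 15.0)
    channel_correlation: float = 0.8
    seed: int = 20260128

    def __post_init__(self) -> None:
        fr = (self.frac_s1, self.frac_s2, self.frac_s3)
        if any(f < 0 for f in fr) or sum(fr) > 1.0:
            raise ValueError("occupancy fractions must be >= 0 and sum to <= 1")
        if self.fs <= 2 * max(self.osc_freqs, default=0.0):
            raise ValueError("fs must exceed twice the highest oscillation frequency")
        if len(self.osc_freqs) != len(self.osc_amps):
            raise ValueError("osc_freqs and osc_amps must have equal length")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ValueError("channel_correlation must lie in [0, 1]")


def _layout_trials(cfg: SynthConfig, rng: np.random.Generator):
    """Place trials so that S2/S3 sample budgets are hit exactly."""
    if cfg.frac_s3 == 0.0:
        return np.empty(0), np.empty(0)
    n_trials = max(1, int(round(cfg.frac_s2 * cfg.duration_s / cfg.t_pre))) \
        if cfg.t_pre > 0 and cfg.frac_s2 > 0 else \
        max(1, int(round(cfg.frac_s3 * cfg.duration_s / 2.0)))
    active_dur = cfg.frac_s3 * cfg.duration_s / n_trials
    trial_len = cfg.t_pre + active_dur
    rest_total = cfg.duration_s - n_trials * trial_len
    if rest_total < 0:
        raise ValueError("requested S2/S3 occupancy does not fit in the session")
    # even gaps with mild jitter; first gap before trial 1, last after trial n
    gaps = np.full(n_trials + 1, rest_total / (n_trials + 1))
    if n_trials > 1:
        jitter = rng.uniform(-0.2, 0.2, size=n_trials + 1) * gaps
        jitter -= jitter.mean()
        gaps = gaps + jitter
    t = 0.0
    releases, ends = [], []
    for k in range(n_trials):
        t += gaps[k]
        releases.append(t + cfg.t_pre)
        t += trial_len
        ends.append(t)
    return np.array(releases), np.array(ends)


def generate_session(
    cfg: SynthConfig,
) -> tuple[LfpRecording, TrialEvents, np.ndarray]:
    """Build one session.

    Returns the multichannel recording, the trial events, and the
    per-sample ground-truth state codes (0..3 for S0..S3).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    truth = np.zeros(n, dtype=np.int8)

    releases, ends = _layout_trials(cfg, rng)
    events = TrialEvents(releases, ends, t_pre=cfg.t_pre) if releases.size else \
        TrialEvents(np.empty(0), np.empty(0), t_pre=cfg.t_pre)

    # oscillation envelope: 0 in rest, ramp over S2, 1 during S3
    env = np.zeros(n)
    for rel, end in zip(releases, ends):
        i0 = int(round((rel - cfg.t_pre) * cfg.fs))
        i1 = int(round(rel * cfg.fs))
        i2 = min(int(round(end * cfg.fs)), n)
        ramp = np.linspace(0.0, 1.0, max(i1 - i0, 1), endpoint=False)
        if cfg.ramp == "sigmoid":
            ramp = 1.0 / (1.0 + np.exp(-10.0 * (ramp - 0.5)))
        # preparation onset is itself a burst onset: the envelope steps to a
        # detectable level immediately, then climbs to the active amplitude
        ramp = cfg.ramp_onset_level + (1.0 - cfg.ramp_onset_level) * ramp
        env[max(i0, 0):i1] = ramp[: i1 - max(i0, 0)]
        env[i1:i2] = 1.0
        truth[max(i0, 0):i1] = STATE_CODES["S2"]
        truth[i1:i2] = STATE_CODES["S3"]

    osc = np.zeros(n)
    for f, a in zip(cfg.osc_freqs, cfg.osc_amps):
        osc += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    shared = osc * env

    # S1 artifacts: broadband bursts dropped into rest until the budget is spent
    budget = int(round(cfg.frac_s1 * n))
    placed = 0
    attempts = 0
    while placed < budget and attempts < 10_000:
        attempts += 1
        dur = int(rng.uniform(*cfg.artifact_dur_range) * cfg.fs)
        start = int(rng.uniform(0, n - dur))
        seg = slice(start, start + dur)
        if np.any(truth[seg] != STATE_CODES["S0"]):
            continue
        amp = rng.uniform(*cfg.artifact_amp_range) * cfg.noise_sd
        burst = rng.normal(0.0, amp, size=dur)
        # soft edges so bursts are not discontinuous
        edge = min(dur // 8, int(0.01 * cfg.fs))
        if edge > 0:
            w = np.ones(dur)
            w[:edge] = np.linspace(0, 1, edge)
            w[-edge:] = np.linspace(1, 0, edge)
            burst *= w
        shared[seg] += burst
        truth[seg] = STATE_CODES["S1"]
        placed += dur

    rho = cfg.channel_correlation
    common_noise = rng.normal(0.0, cfg.noise_sd, size=n)
    chans = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        own = rng.normal(0.0, cfg.noise_sd, size=n)
        chans[c] = shared + np.sqrt(rho) * common_noise + np.sqrt(1 - rho) * own
    rec = LfpRecording(samples=chans, fs=cfg.fs,
                       channel_ids=[f"ch{i}" for i in range(cfg.n_channels)])
    return rec, events, truth


def truth_window_labels(truth: np.ndarray, win: int, stride: int) -> np.ndarray:
    """Ground-truth state (code) of each trailing window = state at its
    last sample, matching the causal decision-stamp convention."""
    n_windows = (len(truth) - win) // stride + 1
    last = np.arange(n_windows) * stride + win - 1
    return truth[last]


def generate_grid_variants(
    vc: np.ndarray,
    fs: float,
    full_scale: float,
    rates: tuple[float, ...] = (500.0, 1000.0, 2000.0),
    bits: tuple[int, ...] = (4, 6, 8, 12),
) -> dict[tuple[float, int], QuantizedStream]:
    """Resampled/requantized views of one virtual channel, time-aligned.

    One view per (rate, bit-depth) pair, for sweeping the trade-off
    between input fidelity and transmission cost.
    """
    out: dict[tuple[float, int], QuantizedStream] = {}
    for r in rates:
        if r > fs:
            raise ValueError(f"grid rate {r} exceeds source rate {fs}")
        xr = downsample(vc, fs, r)
        for b in bits:
            out[(r, b)] = quantize(xr, b, full_scale, fs=r)
    return out
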