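"""Level-1 silence gate: windowed strength features and the wake-up decision.

The gate computes the windowed mean-absolute-value (MAV) signal strength

    E[n] = sum_{k=n-Tw+1}^{n} |x_vc[k]|

over a short trailing window of Tw samples and compares it against a
threshold Vth calibrated as a low quantile of the strength distribution
during confirmed-active epochs. Windows with E < Vth are classified as
distinct rest (S0) and nothing downstream sees them; E >= Vth wakes the
next stage. Calibrating on the *active* distribution rather than the noise
floor makes the gate a high-recall brain switch: by construction (1 - q) of
active strengths clear the threshold.

Besides MAV the module provides the three comparison features used to rank
window-level strength detectors (median absolute deviation, winsorized
average, Teager nonlinear energy operator) and a bit-accurate integer model
of the hardware datapath (absolute-value accumulate + compare).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorConfig",
    "StrengthSeries",
    "FixedPointConfig",
    "mav_strength",
    "mad_strength",
    "wa_strength",
    "neo_strength",
    "strength",
    "calibrate_threshold",
    "gate",
    "interception_at_fixed_miss",
    "fixed_point_detect",
]

FEATURES = ("MAV", "MAD", "WA", "NEO")


@dataclass
class DetectorConfig:
    """Silence-detector parameters.

    Tw : window length in samples (default 32 = 16 ms at 2 kHz, matching
        the pipeline's decision cadence).
    q : calibration quantile on the active strength distribution (0.03
        keeps 97% of active windows above threshold).
    Vth : threshold in strength units; 0 until calibrated.
    step : samples between strength evaluations (default = Tw).
    """

    Tw: int = 32
    q: float = 0.03
    Vth: float = 0.0
    step: int | None = None

    def __post_init__(self) -> None:
        if self.Tw < 1:
            raise ValueError("Tw must be >= 1")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must be in (0, 1)")
        if self.Vth < 0:
            raise ValueError("Vth must be >= 0")
        if self.step is None:
            self.step = self.Tw
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class StrengthSeries:
    """Windowed strength values evaluated every ``step`` samples.

    ``values[i]`` is the feature over the trailing window ending at source
    sample ``Tw - 1 + i*step``.
    """

    values: np.ndarray
    step: int
    feature: str = "MAV"


@dataclass
class FixedPointConfig:
    """Integer datapath widths for the hardware detector model."""

    input_bits: int = 12
    acc_bits: int = 17
    rounding: str = "truncate"

    def validate(self, Tw: int) -> None:
        need = self.input_bits + math.ceil(math.log2(Tw)) if Tw > 1 else self.input_bits
        if self.acc_bits < need:
            raise OverflowError(
                f"accumulator width {self.acc_bits} < {need} bits required for "
                f"Tw={Tw} windows of {self.input_bits}-bit codes"
            )


def _window_starts(n: int, Tw: int, step: int) -> np.ndarray:
    if n < Tw:
        raise ValueError(f"series of length {n} shorter than window Tw={Tw}")
    return np.arange(0, n - Tw + 1, step)


def _window_view(x: np.ndarray, Tw: int, step: int) -> np.ndarray:
    starts = _window_starts(len(x), Tw, step)
    return x[starts[:, None] + np.arange(Tw)]


def mav_strength(x: np.ndarray, cfg: DetectorConfig) -> StrengthSeries:
    """Windowed sum of absolute values (multiplier-free strength feature)."""
    x = np.asarray(x, dtype=np.float64)
    starts = _window_starts(len(x), cfg.Tw, cfg.step)
    csum = np.concatenate(([0.0], np.cumsum(np.abs(x))))
    values = csum[starts + cfg.Tw] - csum[starts]
    return StrengthSeries(values=values, step=cfg.step, feature="MAV")


def mad_strength(x: np.ndarray, cfg: DetectorConfig) -> StrengthSeries:
    """Per-window median absolute deviation from the window median."""
    w = _window_view(np.asarray(x, dtype=np.float64), cfg.Tw, cfg.step)
    med = np.median(w, axis=1, keepdims=True)
    values = np.median(np.abs(w - med), axis=1)
    return StrengthSeries(values=values, step=cfg.step, feature="MAD")


def wa_strength(
    x: np.ndarray, cfg: DetectorConfig, limits: tuple[float, float] = (0.05, 0.95)
) -> StrengthSeries:
    """Winsorized mean of the rectified window, robust to outliers.

    Within each window of |x| the lowest ``floor(limits[0]*Tw)`` samples
    are replaced by the smallest retained order statistic and the highest
    ``floor((1-limits[1])*Tw)`` by the largest retained one, then the
    window is averaged. Rectification makes this a signal-strength
    estimate (a trimmed cousin of the windowed MAV) rather than a mean
    level, which for zero-mean field potentials would be ~0 regardless of
    amplitude.
    """
    w = _window_view(np.abs(np.asarray(x, dtype=np.float64)), cfg.Tw, cfg.step)
    k_lo = int(np.floor(limits[0] * cfg.Tw + 1e-9))
    k_hi = int(np.floor((1.0 - limits[1]) * cfg.Tw + 1e-9))
    s = np.sort(w, axis=1)
    if k_lo > 0:
        s[:, :k_lo] = s[:, [k_lo]]
    if k_hi > 0:
        s[:, -k_hi:] = s[:, [-k_hi - 1]]
    values = np.mean(s, axis=1)
    return StrengthSeries(values=values, step=cfg.step, feature="WA")


def neo_strength(x: np.ndarray, cfg: DetectorConfig) -> StrengthSeries:
    """Window mean of the Teager energy psi[n] = x[n]^2 - x[n-1]*x[n+1].

    psi needs one sample of context on each side, so the series must be at
    least Tw + 2 long and windows shorter than 3 are rejected.
    """
    x = np.asarray(x, dtype=np.float64)
    if cfg.Tw < 3:
        raise ValueError("NEO window must be at least 3 samples")
    if len(x) < cfg.Tw + 2:
        raise ValueError("series too short for NEO (needs Tw + 2 samples)")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    # psi[i] corresponds to source sample i+1; interior window = Tw - 2 psis
    inner = DetectorConfig(Tw=cfg.Tw - 2, q=cfg.q, step=cfg.step)
    w = _window_view(psi, inner.Tw, inner.step)
    values = np.mean(w, axis=1)
    return StrengthSeries(values=values, step=cfg.step, feature="NEO")


_FEATURE_FUNCS = {
    "MAV": mav_strength,
    "MAD": mad_strength,
    "WA": wa_strength,
    "NEO": neo_strength,
}


def strength(x: np.ndarray, cfg: DetectorConfig, feature: str = "MAV") -> StrengthSeries:
    """Dispatch to one of the window strength features by name."""
    try:
        fn = _FEATURE_FUNCS[feature.upper()]
    except KeyError:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")
    return fn(x, cfg)


def calibrate_threshold(active_strengths: np.ndarray, q: float = 0.03) -> float:
    """Threshold = lower empirical q-quantile of active-state strengths.

    Convention: the ceil(q*n)-th order statistic, no interpolation — a
    hardware-realizable rule under which, for distinct values, at least
    (1 - q) of the calibration strengths strictly exceed Vth.
    """
    v = np.asarray(active_strengths, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty strength set")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    k = math.ceil(q * v.size)  # 1-based order statistic
    return float(np.partition(v, k - 1)[k - 1])


def gate(E: StrengthSeries | np.ndarray, Vth: float) -> np.ndarray:
    """Transmit flags: True where strength >= Vth (ties transmit).

    False means the window is classified S0 and downstream stages must see
    no data for that step.
    """
    if Vth < 0:
        raise ValueError("Vth must be >= 0")
    values = E.values if isinstance(E, StrengthSeries) else np.asarray(E)
    return values >= Vth


def interception_at_fixed_miss(
    rest_strengths: np.ndarray, active_strengths: np.ndarray, miss: float = 0.03
) -> float:
    """Fraction of rest windows rejected when the active miss rate is pinned.

    The threshold is the lower ``miss``-quantile of the active distribution
    (same order-statistic convention as calibration); the returned
    interception rate is the fraction of rest strengths strictly below it.
    """
    rest = np.asarray(rest_strengths, dtype=np.float64).ravel()
    active = np.asarray(active_strengths, dtype=np.float64).ravel()
    if rest.size == 0 or active.size == 0:
        raise ValueError("both strength sets must be non-empty")
    if not 0.0 < miss < 1.0:
        raise ValueError("miss must be in (0, 1)")
    thr = calibrate_threshold(active, miss)
    return float(np.count_nonzero(rest < thr) / rest.size)


def fixed_point_detect(
    codes: np.ndarray,
    vth_int: int,
    cfg: DetectorConfig,
    fx: FixedPointConfig | None = None,
) -> np.ndarray:
    """Bit-accurate model of the hardware MAV datapath.

    Absolute values of integer codes are accumulated over Tw samples in an
    ``acc_bits``-wide register and compared against an integer threshold.
    The accumulator width must satisfy acc_bits >= input_bits +
    ceil(log2(Tw)) so the all-rail worst case cannot overflow; violating
    that raises at construction. Decisions are exactly those of the
    floating-point gate on the same integers.
    """
    if fx is None:
        fx = FixedPointConfig()
    fx.validate(cfg.Tw)
    codes = np.asarray(codes)
    if not np.issubdtype(codes.dtype, np.integer):
        raise TypeError("fixed-point detector expects integer codes")
    if int(np.max(np.abs(codes), initial=0)) > (1 << (fx.input_bits - 1)):
        raise OverflowError(f"codes exceed {fx.input_bits}-bit input range")
    if vth_int < 0 or vth_int >= (1 << fx.acc_bits):
        raise OverflowError("integer threshold outside accumulator range")
    starts = _window_starts(len(codes), cfg.Tw, cfg.step)
    acc_mask = (1 << fx.acc_bits) - 1
    abscodes = np.abs(codes.astype(np.int64))
    csum = np.concatenate(([0], np.cumsum(abscodes)))
    acc = (csum[starts + cfg.Tw] - csum[starts]) & acc_mask
    return acc >= vth_int
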