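"""Level-2 DualGRU cascade: screen cheap, confirm expensive.

GRU1 consumes the low-resolution stream (6 bit / 1 kHz) and separates Rest
from Potential-Active at a high-recall operating point; GRU2 re-examines
only the windows GRU1 passes, on the high-resolution stream (12 bit /
2 kHz), to filter GRU1's false positives. The back-end decoder wakes only
when GRU2 confirms. Combined with the Level-1 silence gate this yields the
monotone decision chain

    ACTIVE  ⊆  PotentialActive  ⊆  gate-open windows.

Each 512 ms window is presented to a GRU as 32 frames of 16 ms — one frame
per decision step — rather than one sample per timestep: the recurrence
then spans the decision cadence instead of thousands of raw samples, which
keeps backpropagation-through-time short and well-conditioned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .gru import GRUClassifier
from .gate import DetectorConfig, mav_strength, gate as gate_op
from .labeling import WindowDataset

__all__ = [
    "GruSpec",
    "TrainConfig",
    "CascadeModel",
    "DecisionTrace",
    "FoldMetrics",
    "frame_windows",
    "MODEL_REGISTRY",
    "register_model",
    "train_gru",
    "gru1_screen",
    "gru2_confirm",
    "select_operating_point",
    "noise_floor_gain",
    "fit_cascade",
    "window_strengths",
    "cascade_decide",
    "crossval",
    "fold_sd",
    "save_model",
    "load_model",
]

N_FRAMES = 32  # 512 ms field of view / 16 ms decision step

ACTIVE_STATES = ("S2", "S3")  # cascade positives; negatives are S0/S1

#: Sequence-classifier registry: any entry must accept
#: (input_size, hidden_size, seed) and expose fit/predict_proba with the
#: GRUClassifier signatures. Lets alternative recurrent architectures be
#: benchmarked through the same training/CV harness.
MODEL_REGISTRY: dict[str, type] = {"gru": GRUClassifier}


def register_model(name: str, cls: type) -> None:
    MODEL_REGISTRY[name] = cls


@dataclass
class GruSpec:
    """Input contract and architecture of one cascade stage.

    ``input_gain`` rescales the code-normalized frames so the background
    noise sits near unit variance (estimated robustly from the training
    stream); raw 6- or 12-bit codes occupy only a sliver of [-1, 1] and
    would otherwise produce vanishing early gradients.
    """

    input_bits: int = 6
    input_rate: float = 1000.0
    hidden_units: int = 32
    layers: int = 1
    input_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.layers != 1:
            raise NotImplementedError("only single-layer GRUs are supported")

    @property
    def frame_size(self) -> int:
        # samples of the stage's stream inside one 16 ms frame
        return int(round(self.input_rate * 0.016))


@dataclass
class TrainConfig:
    """Optimization and cross-validation settings.

    Defaults follow the training recipe used throughout: Adam at learning
    rate 3e-4, at most 300 epochs with early stopping (patience 20,
    monitoring validation F1, best weights restored), five trial-blocked
    folds. ``train_stride_factor`` thins the 16 ms-stride training windows
    (consecutive windows overlap ~97%, so a 64 ms training stride loses
    almost nothing and cuts epoch cost 4x); evaluation always uses the
    full-resolution stride.
    """

    lr: float = 3e-4
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 64
    folds: int = 5
    seed: int = 20260128
    target_recall: float = 0.97
    theta2: float = 0.5
    val_fraction: float = 0.2
    train_stride_factor: int = 4

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class CascadeModel:
    """Both trained stages plus their operating thresholds."""

    gru1: GRUClassifier
    gru2: GRUClassifier
    spec1: GruSpec
    spec2: GruSpec
    theta1: float = 0.5
    theta2: float = 0.5

    def __post_init__(self) -> None:
        for name, th in (("theta1", self.theta1), ("theta2", self.theta2)):
            if not 0.0 <= th <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {th}")


@dataclass
class DecisionTrace:
    """Per-window cascade outcome and the transmitted-bit ledger.

    ``stage[i]`` is one of gated_S0 / screened_rest / confirmed_reject /
    ACTIVE; ``bits[i]`` the bits the implant had to send for that step:
    0 when gated, the low-res step cost when GRU1 handled it, low + high
    when the window escalated to GRU2.
    """

    stage: np.ndarray
    bits: np.ndarray
    gate_flags: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    STAGES = ("gated_S0", "screened_rest", "confirmed_reject", "ACTIVE")

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.stage == s)) for s in self.STAGES}

    @property
    def total_bits(self) -> float:
        return float(self.bits.sum())

    @property
    def active_mask(self) -> np.ndarray:
        return self.stage == "ACTIVE"


@dataclass
class FoldMetrics:
    """Per-fold scores with mean and the n-1-denominator spread.

    ``screen_recall`` is GRU1's recall of S2/S3 windows at its calibrated
    operating point on the held-out fold — the quantity that bounds
    wake-up latency.
    """

    f1: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: np.ndarray
    screen_recall: np.ndarray | None = None

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        names = ("f1", "precision", "recall", "auc")
        if self.screen_recall is not None:
            names = names + ("screen_recall",)
        for name in names:
            v = getattr(self, name)
            out[name] = {"mean": float(np.mean(v)), "sd": fold_sd(v),
                         "folds": [float(x) for x in v]}
        return out


def fold_sd(values: np.ndarray) -> float:
    """Sample standard deviation across folds: sqrt(sum (x-x̄)² / (n-1))."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        return 0.0
    return float(np.sqrt(np.sum((v - v.mean()) ** 2) / (v.size - 1)))


# --------------------------------------------------------------------- framing

def frame_windows(W: np.ndarray, bits: int, gain: float = 1.0,
                  n_frames: int = N_FRAMES) -> np.ndarray:
    """(n_windows, win_samples) codes -> (n, n_frames, frame) GRU input.

    Codes are scaled to [-1, 1) by the bit depth, then multiplied by
    ``gain`` (see :func:`noise_floor_gain`).
    """
    W = np.asarray(W, dtype=np.float64)
    n, win = W.shape
    if win % n_frames != 0:
        raise ValueError(f"window of {win} samples not divisible into {n_frames} frames")
    scale = float(1 << (bits - 1))
    return (W * (gain / scale)).reshape(n, n_frames, win // n_frames)


def noise_floor_gain(codes: np.ndarray, bits: int) -> float:
    """Gain that maps the stream's background noise to ~unit variance.

    Noise sigma is estimated as median(|codes|)/0.6745 — the robust
    estimator conventional in neural signal thresholding, insensitive to
    the sparse high-amplitude active/artifact epochs.
    """
    med = float(np.median(np.abs(np.asarray(codes, dtype=np.float64))))
    if med <= 0:
        return 1.0
    sigma_norm = (med / 0.6745) / float(1 << (bits - 1))
    return 1.0 / sigma_norm


def _check_resolution(X: np.ndarray, spec: GruSpec, stage: str) -> None:
    if X.ndim != 3 or X.shape[1] != N_FRAMES or X.shape[2] != spec.frame_size:
        raise ValueError(
            f"{stage}: window view shape {X.shape} does not match spec "
            f"({N_FRAMES} frames x {spec.frame_size} samples at "
            f"{spec.input_rate:g} Hz)"
        )


# -------------------------------------------------------------------- training

def train_gru(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    spec: GruSpec,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int | None = None,
    arch: str = "gru",
):
    """Train one cascade stage; returns (model, history).

    Deterministic given the seed. Raises if the training labels are
    single-class (a GRU cannot learn a discriminant from one class).
    ``arch`` names an entry in :data:`MODEL_REGISTRY`.
    """
    X = np.asarray(X, dtype=np.float64)
    _check_resolution(X, spec, "train_gru")
    seed = cfg.seed if seed is None else seed
    model = MODEL_REGISTRY[arch](input_size=spec.frame_size,
                                 hidden_size=spec.hidden_units, seed=seed)
    history = model.fit(
        X, y, X_val=X_val, y_val=y_val,
        lr=cfg.lr, max_epochs=cfg.max_epochs, batch_size=cfg.batch_size,
        patience=cfg.patience, class_weight="balanced", seed=seed,
    )
    return model, history


def gru1_screen(X_low: np.ndarray, model: CascadeModel) -> tuple[np.ndarray, np.ndarray]:
    """Stage-1 screen on low-res views: (PotentialActive flags, scores)."""
    _check_resolution(np.asarray(X_low), model.spec1, "gru1_screen")
    p = model.gru1.predict_proba(X_low)
    return p >= model.theta1, p


def gru2_confirm(X_high: np.ndarray, model: CascadeModel) -> tuple[np.ndarray, np.ndarray]:
    """Stage-2 confirmation on high-res views: (Active flags, scores)."""
    _check_resolution(np.asarray(X_high), model.spec2, "gru2_confirm")
    p = model.gru2.predict_proba(X_high)
    return p >= model.theta2, p


def select_operating_point(
    scores: np.ndarray, labels: np.ndarray, target_recall: float = 0.97
) -> float:
    """Largest threshold whose recall meets the floor.

    Maximizes precision subject to recall >= target_recall: the threshold
    is the ceil(target * n_pos)-th largest positive score, so exactly that
    many positives sit at or above it. A recall floor of 1.0 returns the
    minimum positive score.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    pos = scores[labels]
    if pos.size == 0:
        raise ValueError("operating point needs at least one positive example")
    if not 0.0 < target_recall <= 1.0:
        raise ValueError("target_recall must be in (0, 1]")
    k = int(np.ceil(target_recall * pos.size))
    return float(np.sort(pos)[::-1][k - 1])


# -------------------------------------------------------------------- decision

def window_strengths(ds: WindowDataset, detector: DetectorConfig) -> np.ndarray:
    """MAV strength of the trailing Tw samples ending at each window's last
    sample — the quantity the Level-1 gate thresholds, one per window."""
    offset = ds.win - detector.Tw
    if offset < 0:
        raise ValueError("detector window Tw longer than the analysis window")
    cfg = DetectorConfig(Tw=detector.Tw, q=detector.q, step=ds.stride)
    return mav_strength(ds.x[offset:], cfg).values[: ds.n_windows]


def _gate_flags_per_window(ds: WindowDataset, detector: DetectorConfig,
                           vth: float) -> np.ndarray:
    return gate_op(window_strengths(ds, detector), vth)


def cascade_decide(
    ds: WindowDataset,
    model: CascadeModel,
    detector: DetectorConfig,
    vth: float,
) -> DecisionTrace:
    """Run the full hierarchy over a windowed session.

    Stage order is strict: a window the silence gate shuts never reaches
    GRU1, and GRU2 only sees windows GRU1 passed. The bit ledger charges
    each 16 ms step with the bits its deepest stage required.
    """
    n = ds.n_windows
    flags = _gate_flags_per_window(ds, detector, vth)

    stage = np.full(n, "gated_S0", dtype="<U16")
    p1 = np.zeros(n)
    p2 = np.zeros(n)

    open_idx = np.flatnonzero(flags)
    if open_idx.size:
        X_low = frame_windows(ds.windows_lowres()[open_idx],
                              model.spec1.input_bits, model.spec1.input_gain)
        passed, scores1 = gru1_screen(X_low, model)
        p1[open_idx] = scores1
        stage[open_idx[~passed]] = "screened_rest"
        esc_idx = open_idx[passed]
        if esc_idx.size:
            X_high = frame_windows(ds.windows_highres()[esc_idx],
                                   model.spec2.input_bits,
                                   model.spec2.input_gain)
            confirmed, scores2 = gru2_confirm(X_high, model)
            p2[esc_idx] = scores2
            stage[esc_idx[confirmed]] = "ACTIVE"
            stage[esc_idx[~confirmed]] = "confirmed_reject"

    stride_s = ds.stride / ds.fs
    low_bits = model.spec1.input_bits * model.spec1.input_rate * stride_s
    high_bits = model.spec2.input_bits * model.spec2.input_rate * stride_s
    bits = np.zeros(n)
    bits[stage == "screened_rest"] = low_bits
    escalated = (stage == "confirmed_reject") | (stage == "ACTIVE")
    bits[escalated] = low_bits + high_bits

    return DecisionTrace(stage=stage, bits=bits, gate_flags=flags, p1=p1, p2=p2)


# ---------------------------------------------------------------- fitting

def fit_cascade(
    X_low: np.ndarray,
    X_high: np.ndarray,
    y: np.ndarray,
    fit_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: TrainConfig,
    spec1: GruSpec,
    spec2: GruSpec,
    seed: int,
) -> CascadeModel:
    """Train both stages and pick the GRU1 operating point.

    GRU1 trains on the low-res views of ``fit_idx`` (thinned by the
    training stride factor) with early stopping on ``val_idx``; theta1 is
    then chosen on the validation scores to meet the target recall. GRU2
    trains on the high-res views of all positives plus the negatives GRU1
    passes at theta1 (its false positives); if GRU1 passes none, all
    negatives are used so training stays two-class.
    """
    fit_idx = np.asarray(fit_idx)[:: cfg.train_stride_factor]
    val_idx = np.asarray(val_idx)

    m1, _ = train_gru(X_low[fit_idx], y[fit_idx], cfg, spec1,
                      X_val=X_low[val_idx], y_val=y[val_idx], seed=seed + 1)
    p1_val = m1.predict_proba(X_low[val_idx])
    theta1 = select_operating_point(p1_val, y[val_idx], cfg.target_recall)

    p1_fit = m1.predict_proba(X_low[fit_idx])
    keep = (y[fit_idx] == 1) | (p1_fit >= theta1)
    if np.unique(y[fit_idx][keep]).size < 2:
        keep = np.ones(fit_idx.size, dtype=bool)
    g2_idx = fit_idx[keep]
    val_keep = (y[val_idx] == 1) | (p1_val >= theta1)
    if np.unique(y[val_idx][val_keep]).size < 2:
        val_keep = np.ones(val_idx.size, dtype=bool)
    g2_val_idx = val_idx[val_keep]

    m2, _ = train_gru(X_high[g2_idx], y[g2_idx], cfg, spec2,
                      X_val=X_high[g2_val_idx], y_val=y[g2_val_idx], seed=seed + 2)
    return CascadeModel(gru1=m1, gru2=m2, spec1=spec1, spec2=spec2,
                        theta1=theta1, theta2=cfg.theta2)


# ---------------------------------------------------------------- cross-validation

def _trial_blocks(ds: WindowDataset, trial_ends: np.ndarray) -> np.ndarray:
    """Block id per window: windows up to each trial's end share a block,
    so the ~97%-overlapping windows of one trial can never straddle folds."""
    return np.searchsorted(np.asarray(trial_ends), ds.t_last, side="right")


def crossval(
    ds: WindowDataset,
    labels: np.ndarray,
    trial_ends: np.ndarray,
    cfg: TrainConfig,
) -> tuple[FoldMetrics, list[CascadeModel]]:
    """Trial-blocked k-fold CV of the full cascade (Active vs Rest).

    Per fold: stages are trained on the other folds (with an inner,
    seeded trial-blocked validation split for early stopping and the GRU1
    operating point; GRU2 trains on GRU1-passing negatives — its job is
    GRU1's false positives), then the model cascade (screen at theta1,
    confirm at theta2) is scored on the held-out fold. This measures the
    DualGRU itself; the Level-1 silence gate belongs to the deployment
    chain (:func:`cascade_decide`) and its throughput accounting, where a
    below-threshold window is by definition S0. AUC uses the combined
    score p1*p2.

    Returns the per-fold metrics and the per-fold fitted models.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    y = np.isin(labels, ACTIVE_STATES).astype(float)
    blocks = _trial_blocks(ds, trial_ends)
    uniq = np.unique(blocks)
    if uniq.size < cfg.folds:
        raise ValueError(f"{uniq.size} trial blocks < {cfg.folds} folds")
    rng = np.random.default_rng(cfg.seed)
    block_fold = dict(zip(uniq, rng.permutation(uniq.size) % cfg.folds))
    fold_of = np.array([block_fold[b] for b in blocks])

    g1 = noise_floor_gain(ds.x_low, 6)
    g2 = noise_floor_gain(ds.x, 12)
    X_low_all = frame_windows(ds.windows_lowres(), 6, g1)
    X_high_all = frame_windows(ds.windows_highres(), 12, g2)
    spec1 = GruSpec(input_bits=6, input_rate=ds.fs_low or 1000.0, input_gain=g1)
    spec2 = GruSpec(input_bits=12, input_rate=ds.fs, input_gain=g2)

    f1s, precs, recs, aucs, srecs, models = [], [], [], [], [], []
    for fold in range(cfg.folds):
        test_mask = fold_of == fold
        train_blocks = np.unique(blocks[~test_mask])
        inner_rng = np.random.default_rng(cfg.seed + 1000 + fold)
        n_val = max(1, int(round(cfg.val_fraction * train_blocks.size)))
        val_blocks = inner_rng.choice(train_blocks, size=n_val, replace=False)
        val_mask = np.isin(blocks, val_blocks) & ~test_mask
        fit_mask = ~test_mask & ~val_mask

        fit_idx = np.flatnonzero(fit_mask)
        val_idx = np.flatnonzero(val_mask)

        model = fit_cascade(X_low_all, X_high_all, y, fit_idx, val_idx,
                            cfg, spec1, spec2, seed=cfg.seed + 10 * fold)
        models.append(model)
        m1, m2, theta1 = model.gru1, model.gru2, model.theta1

        # held-out evaluation of the model cascade
        te = np.flatnonzero(test_mask)
        p1_te = m1.predict_proba(X_low_all[te])
        p2_te = m2.predict_proba(X_high_all[te])
        screened = p1_te >= theta1
        pred = screened & (p2_te >= cfg.theta2)
        yt = y[te]
        tp = np.sum(pred & (yt == 1))
        fp = np.sum(pred & (yt == 0))
        fn = np.sum(~pred & (yt == 1))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        score = p1_te * p2_te
        auc = roc_auc_score(yt, score) if np.unique(yt).size > 1 else np.nan
        srec = np.sum(screened & (yt == 1)) / max(np.sum(yt == 1), 1)
        f1s.append(f1); precs.append(prec); recs.append(rec)
        aucs.append(auc); srecs.append(srec)

    metrics = FoldMetrics(f1=np.array(f1s), precision=np.array(precs),
                          recall=np.array(recs), auc=np.array(aucs),
                          screen_recall=np.array(srecs))
    return metrics, models


# ------------------------------------------------------------------ persistence

def save_model(model: CascadeModel, path: str | Path) -> None:
    """Model bundle: weights in .npz, spec + thresholds in JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "gru1.npz", **model.gru1.get_weights())
    np.savez(path / "gru2.npz", **model.gru2.get_weights())
    meta = {
        "spec1": asdict(model.spec1),
        "spec2": asdict(model.spec2),
        "theta1": model.theta1,
        "theta2": model.theta2,
    }
    (path / "cascade.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> CascadeModel:
    path = Path(path)
    meta = json.loads((path / "cascade.json").read_text())
    spec1 = GruSpec(**meta["spec1"])
    spec2 = GruSpec(**meta["spec2"])
    g1 = GRUClassifier(spec1.frame_size, spec1.hidden_units)
    g2 = GRUClassifier(spec2.frame_size, spec2.hidden_units)
    with np.load(path / "gru1.npz") as z:
        g1.set_weights(dict(z))
    with np.load(path / "gru2.npz") as z:
        g2.set_weights(dict(z))
    return CascadeModel(gru1=g1, gru2=g2, spec1=spec1, spec2=spec2,
                        theta1=meta["theta1"], theta2=meta["theta2"])
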