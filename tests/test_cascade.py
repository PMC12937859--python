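import numpy as np
import pytest

from lfpgate import (
    GruSpec, TrainConfig, CascadeModel, DetectorConfig,
    frame_windows, select_operating_point, gru1_screen, gru2_confirm,
    cascade_decide, crossval, fold_sd, save_model, load_model,
    make_windows, GRUClassifier, noise_floor_gain,
)
from lfpgate.cascade import N_FRAMES, _trial_blocks


def _model(theta1=0.5, theta2=0.5, seed=0, zero_init=False):
    spec1 = GruSpec(input_bits=6, input_rate=1000.0)
    spec2 = GruSpec(input_bits=12, input_rate=2000.0)
    g1 = GRUClassifier(spec1.frame_size, 8, seed=seed, zero_init=zero_init)
    g2 = GRUClassifier(spec2.frame_size, 8, seed=seed + 1, zero_init=zero_init)
    return CascadeModel(gru1=g1, gru2=g2, spec1=spec1, spec2=spec2,
                        theta1=theta1, theta2=theta2)


def _dataset(n_s=4.0, seed=0):
    rng = np.random.default_rng(seed)
    hi = rng.integers(-2048, 2048, size=int(2000 * n_s))
    lo = rng.integers(-32, 32, size=int(1000 * n_s))
    return make_windows(hi, 2000.0, x_low=lo, fs_low=1000.0)


class TestFraming:
    def test_shapes_and_scaling(self):
        W = np.full((3, 512), 16.0)
        X = frame_windows(W, 6)
        assert X.shape == (3, N_FRAMES, 16)
        assert np.all(X == 0.5)

    def test_gain_is_applied(self):
        W = np.full((1, 512), 16.0)
        np.testing.assert_allclose(frame_windows(W, 6, gain=2.0), 1.0)

    def test_indivisible_window_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            frame_windows(np.zeros((2, 100)), 6)

    def test_noise_floor_gain_maps_noise_to_unit_scale(self):
        rng = np.random.default_rng(0)
        codes = np.rint(rng.normal(0, 4.0, 100_000))
        g = noise_floor_gain(codes, 6)
        framed = frame_windows(codes[None, :99_840], 6, g)
        assert 0.7 < framed.std() < 1.4


class TestOperatingPoint:
    def test_full_recall_returns_min_positive_score(self):
        s = np.array([0.9, 0.2, 0.6, 0.4])
        y = np.array([1, 0, 1, 1])
        assert select_operating_point(s, y, 1.0) == 0.4

    def test_enumerated_example(self):
        s = np.array([0.9, 0.8, 0.7, 0.1, 0.6, 0.2])
        y = np.array([1, 1, 1, 1, 0, 0])
        assert select_operating_point(s, y, 0.75) == 0.7

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            select_operating_point(np.array([0.5]), np.array([0]))

    def test_achieved_recall_meets_floor(self):
        rng = np.random.default_rng(1)
        s = rng.random(500)
        y = rng.random(500) > 0.7
        for target in (0.5, 0.9, 0.97):
            th = select_operating_point(s, y, target)
            assert np.mean(s[y] >= th) >= target


class TestScreenConfirm:
    def test_zero_threshold_passes_everything(self):
        model = _model(theta1=0.0)
        X = frame_windows(np.zeros((5, 512)), 6)
        passed, _ = gru1_screen(X, model)
        assert passed.all()

    def test_threshold_one_passes_nothing(self):
        model = _model(theta1=1.0)
        X = frame_windows(np.random.default_rng(0).normal(size=(5, 512)), 6)
        passed, _ = gru1_screen(X, model)
        assert not passed.any()

    def test_resolution_mismatch_rejected(self):
        model = _model()
        X_high = frame_windows(np.zeros((2, 1024)), 12)
        with pytest.raises(ValueError, match="does not match"):
            gru1_screen(X_high, model)
        X_low = frame_windows(np.zeros((2, 512)), 6)
        with pytest.raises(ValueError, match="does not match"):
            gru2_confirm(X_low, model)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="theta1"):
            _model(theta1=1.5)


class TestCascadeDecide:
    def test_all_zero_signal_fully_gated_zero_bits(self):
        ds = make_windows(np.zeros(8000, dtype=np.int64), 2000.0,
                          x_low=np.zeros(4000, dtype=np.int64), fs_low=1000.0)
        trace = cascade_decide(ds, _model(), DetectorConfig(), vth=1.0)
        assert (trace.stage == "gated_S0").all()
        assert trace.total_bits == 0.0

    def test_stage_inclusion_chain_on_random_configurations(self):
        ds = _dataset(seed=2)
        rng = np.random.default_rng(3)
        strengths_sorted = None
        for _ in range(20):
            model = _model(theta1=float(rng.random()),
                           theta2=float(rng.random()), seed=int(rng.integers(99)))
            vth = float(rng.uniform(0, 3000))
            trace = cascade_decide(ds, model, DetectorConfig(), vth)
            active = trace.stage == "ACTIVE"
            screened_plus = active | (trace.stage == "confirmed_reject")
            assert not np.any(active & ~screened_plus)
            assert not np.any(screened_plus & ~trace.gate_flags)
            counts = trace.counts()
            assert sum(counts.values()) == ds.n_windows

    def test_bit_ledger_hand_computed(self):
        # force three stages with degenerate thresholds: zero-init GRUs
        # output exactly 0.5 everywhere
        ds = _dataset(n_s=2.0, seed=4)
        det = DetectorConfig()
        model = _model(theta1=0.4, theta2=0.6, zero_init=True)
        vth = float(np.median(np.abs(ds.x)) * det.Tw)  # some gated, some open
        trace = cascade_decide(ds, model, det, vth)
        n_open = int(trace.gate_flags.sum())
        # p1 = 0.5 >= 0.4 -> all open windows escalate; p2 = 0.5 < 0.6 -> reject
        assert (trace.stage[trace.gate_flags] == "confirmed_reject").all()
        # per 16 ms step: low = 6*1000*0.016 = 96 bits, high = 12*2000*0.016 = 384
        assert trace.total_bits == n_open * (96 + 384)

    def test_raising_theta1_never_increases_highres_bits(self):
        ds = _dataset(seed=5)
        highres = []
        for th in (0.0, 0.3, 0.6, 0.9, 1.0):
            model = _model(theta1=th, theta2=0.5, seed=11)
            trace = cascade_decide(ds, model, DetectorConfig(), vth=0.0)
            esc = np.isin(trace.stage, ("confirmed_reject", "ACTIVE")).sum()
            highres.append(esc)
        assert all(a >= b for a, b in zip(highres, highres[1:]))


class TestFoldSd:
    def test_identical_folds_have_zero_sd(self):
        assert fold_sd(np.full(5, 0.93)) == 0.0

    def test_known_example(self):
        assert fold_sd(np.array([0.9, 1.1, 1.0, 0.95, 1.05])) == pytest.approx(
            0.07905694150420949)

    def test_matches_two_pass_variance(self):
        v = np.random.default_rng(6).random(5)
        mean = sum(v) / 5
        expected = (sum((x - mean) ** 2 for x in v) / 4) ** 0.5
        assert fold_sd(v) == pytest.approx(expected, rel=1e-12)


class TestCrossval:
    def test_fewer_trial_blocks_than_folds_rejected(self, windowed_session):
        ds, events, det, strengths, vth, labels = windowed_session
        with pytest.raises(ValueError, match="folds"):
            crossval(ds, labels, events.t_trial_end[:1],
                     TrainConfig(folds=5))

    def test_blocks_keep_all_windows_of_a_trial_together(self, windowed_session):
        ds, events, *_ = windowed_session
        blocks = _trial_blocks(ds, events.t_trial_end)
        # block boundaries occur only at trial ends
        changes = np.flatnonzero(np.diff(blocks))
        for c in changes:
            t = ds.t_last[c + 1]
            assert np.any(events.t_trial_end <= t)


class TestModelRegistry:
    def test_registered_architecture_is_used_by_train_gru(self):
        from lfpgate.cascade import register_model, train_gru

        calls = []

        class Dummy:
            def __init__(self, input_size, hidden_size, seed):
                calls.append((input_size, hidden_size, seed))

            def fit(self, X, y, **kw):
                return None

            def predict_proba(self, X):
                return np.full(len(X), 0.5)

        register_model("dummy", Dummy)
        X = frame_windows(np.zeros((8, 512)), 6)
        y = np.array([0, 1] * 4, float)
        model, _ = train_gru(X, y, TrainConfig(), GruSpec(6, 1000.0),
                             seed=3, arch="dummy")
        assert isinstance(model, Dummy)
        assert calls == [(16, 32, 3)]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = _model(theta1=0.42, theta2=0.77, seed=13)
        model.spec1.input_gain = 9.5
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        assert loaded.theta1 == 0.42 and loaded.theta2 == 0.77
        assert loaded.spec1.input_gain == 9.5
        X = frame_windows(np.random.default_rng(7).normal(size=(4, 512)), 6)
        np.testing.assert_array_equal(model.gru1.predict_proba(X),
                                      loaded.gru1.predict_proba(X))
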