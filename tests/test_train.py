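"""Training: correlation loss and gradient, chunking, splitting, the fit loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from s2spike.network import S2SConfig, build_network
from s2spike.targets import GaussianTargetSpec
from s2spike.train import (
    TrainConfig,
    _backward_chunk,
    _forward_chunk,
    chunk_recordings,
    correlation_loss,
    correlation_loss_grad,
    fit,
    split_train_val,
)


def textbook_pearson(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


class TestCorrelationLoss:
    def test_self_correlation_is_minus_one(self, rng):
        x = rng.normal(size=100)
        assert correlation_loss(x, x) == pytest.approx(-1.0, abs=1e-6)

    def test_anticorrelation_is_plus_one(self, rng):
        x = rng.normal(size=100)
        assert correlation_loss(x, -x) == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_guarded_pearson(self, rng):
        # the loss is the guarded form -cov/((sd+eps)(sd+eps)); compare to a
        # direct computation of the same expression, and loosely to plain r
        eps = 1e-8
        for _ in range(20):
            a, b = rng.normal(size=(2, 50))
            ac, bc = a - a.mean(), b - b.mean()
            direct = -np.mean(ac * bc) / ((ac.std() + eps) * (bc.std() + eps))
            assert correlation_loss(a, b) == pytest.approx(direct, abs=1e-12)
            assert correlation_loss(a, b) == pytest.approx(
                -textbook_pearson(a, b), abs=1e-6
            )

    def test_constant_signal_is_guarded_not_nan(self):
        loss = correlation_loss(np.ones(10), np.arange(10.0))
        assert np.isfinite(loss) and abs(loss) < 1e-3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_loss(np.zeros(3), np.zeros(4))

    @settings(deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=100.0),
        st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_invariant_under_positive_affine_transforms(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 60))
        base = correlation_loss(x, y)
        assert correlation_loss(a * x + b, y) == pytest.approx(base, abs=1e-6)
        assert correlation_loss(x, a * y + b) == pytest.approx(base, abs=1e-6)


class TestGradients:
    def test_loss_gradient_matches_finite_differences(self, rng):
        p = rng.normal(size=40)
        t = rng.poisson(1.0, size=40).astype(float)
        g = correlation_loss_grad(p, t)
        eps = 1e-6
        for k in rng.choice(40, size=10, replace=False):
            dp = np.zeros(40)
            dp[k] = eps
            fd = (correlation_loss(p + dp, t) - correlation_loss(p - dp, t)) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_backprop_matches_finite_differences(self, rng):
        cfg = S2SConfig(w_seq=12, nFilt_in=5, n_hidden=2, nhu=4, seed=1)
        params = build_network(cfg)
        # lift biases so activations are alive and away from ReLU kinks
        params.analysis_b += 0.3
        for _, b in params.hidden:
            b += 0.3
        x = rng.normal(size=40)
        t = rng.poisson(1.0, size=40).astype(float)
        est, frames, acts, pad_left = _forward_chunk(params, x)
        assert est.std() > 0
        grads = _backward_chunk(
            params, frames, acts, pad_left, correlation_loss_grad(est, t)
        )

        def loss():
            e, *_ = _forward_chunk(params, x)
            return correlation_loss(e, t)

        eps = 1e-6
        for arr, grad in zip(params.flat_arrays(), grads):
            flat = arr.ravel()
            for k in rng.choice(arr.size, size=min(6, arr.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp = loss()
                flat[k] = orig - eps
                lm = loss()
                flat[k] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad.ravel()[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestChunking:
    def test_chunk_arithmetic(self, rng):
        from s2spike.io import Recording

        rec = Recording(
            trace=rng.normal(size=2500), spikes=np.zeros(2500, dtype=int)
        )
        chunks = chunk_recordings([rec], 1000, None, w_seq=100)
        assert [len(x) for x, _ in chunks] == [1000, 1000, 500]

    def test_short_recording_yields_no_chunks(self, rng):
        from s2spike.io import Recording

        rec = Recording(trace=rng.normal(size=50), spikes=np.zeros(50, dtype=int))
        assert chunk_recordings([rec], 1000, None, w_seq=100) == []

    def test_boundaries_match_naive_slicing(self, rng):
        from s2spike.io import Recording
        from s2spike.network import standardize

        trace = rng.normal(size=730)
        rec = Recording(trace=trace, spikes=np.zeros(730, dtype=int))
        chunks = chunk_recordings([rec], 200, None, w_seq=50)
        z = standardize(trace)
        expected = [z[s : s + 200] for s in range(0, 730, 200)]
        expected = [e for e in expected if len(e) >= 50]
        assert len(chunks) == len(expected)
        for (x, _), e in zip(chunks, expected):
            np.testing.assert_array_equal(x, e)

    def test_chunk_len_below_frame_length_rejected(self):
        with pytest.raises(ValueError):
            chunk_recordings([], 50, None, w_seq=100)


class TestSplit:
    def test_sizes_and_partition(self, tiny_recordings):
        train, val = split_train_val(tiny_recordings, 0.2, seed=4)
        assert len(val) == max(1, round(0.2 * len(tiny_recordings)))
        ids = lambda recs: {r.neuron_id for r in recs}
        assert ids(train) | ids(val) == ids(tiny_recordings)
        assert ids(train) & ids(val) == set()

    def test_deterministic_for_fixed_seed(self, tiny_recordings):
        a = split_train_val(tiny_recordings, 0.2, seed=9)
        b = split_train_val(tiny_recordings, 0.2, seed=9)
        assert [r.neuron_id for r in a[0]] == [r.neuron_id for r in b[0]]

    def test_fewer_than_two_recordings_rejected(self, tiny_recordings):
        with pytest.raises(ValueError):
            split_train_val(tiny_recordings[:1], 0.2, seed=0)


@pytest.fixture(scope="module")
def fitted(tiny_recordings):
    cfg = S2SConfig(w_seq=50, nFilt_in=8, n_hidden=1, nhu=8, seed=2)
    tcfg = TrainConfig(
        chunk_len=500,
        max_epochs=8,
        batch_size=4,
        seed=5,
        target_spec=GaussianTargetSpec(),
    )
    return cfg, tcfg, fit(cfg, tcfg, tiny_recordings)


class TestFit:
    def test_history_shapes_and_best_epoch(self, fitted):
        _, tcfg, (params, hist) = fitted
        assert hist.n_epochs <= tcfg.max_epochs
        assert 1 <= hist.epoch_of_best_validation <= hist.n_epochs
        best = hist.val_loss[hist.epoch_of_best_validation - 1]
        assert best <= hist.val_loss[0]
        assert best == min(hist.val_loss)

    def test_training_reduces_loss(self, fitted):
        _, _, (params, hist) = fitted
        assert hist.val_loss[-1] < hist.val_loss[0]

    def test_same_seed_reproduces_history_exactly(self, fitted, tiny_recordings):
        cfg, tcfg, (_, hist) = fitted
        _, hist2 = fit(cfg, tcfg, tiny_recordings)
        assert hist.train_loss == hist2.train_loss
        assert hist.val_loss == hist2.val_loss

    def test_returned_params_are_best_epoch_weights(self, fitted, tiny_recordings):
        cfg, tcfg, (params, hist) = fitted
        from s2spike.train import _mean_loss

        val = [r for r in tiny_recordings]
        # recompute the validation loss of the returned weights: must equal the best
        train_recs, val_recs = split_train_val(val, tcfg.val_fraction, tcfg.seed)
        val_chunks = chunk_recordings(
            val_recs, tcfg.chunk_len, tcfg.target_spec, cfg.w_seq
        )
        assert _mean_loss(params, val_chunks) == pytest.approx(
            min(hist.val_loss), abs=1e-12
        )

    def test_unusable_recordings_rejected(self, rng):
        from s2spike.io import Recording

        short = [
            Recording(trace=rng.normal(size=60), spikes=np.zeros(60, dtype=int)),
            Recording(trace=rng.normal(size=60), spikes=np.zeros(60, dtype=int)),
        ]
        with pytest.raises(ValueError, match="chunk"):
            fit(S2SConfig(w_seq=100, n_hidden=0, seed=0), TrainConfig(seed=0), short)
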