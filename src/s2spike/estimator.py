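"""Scikit-learn-style estimator wrapping the full training pipeline.

``SpikeSignalRegressor`` is the package's primary surface: ``fit`` takes
lists of fluorescence traces and spike-count sequences (one pair per
neuron, lengths may differ across neurons), ``predict`` returns a
same-length spike-signal estimate per trace, and ``score`` reports the
mean Pearson correlation at the 25 Hz evaluation rate.  It follows the
scikit-learn estimator contract (``get_params``/``set_params``, cloning,
trailing-underscore fitted attributes), so it composes with
``sklearn.model_selection`` utilities that accept list-like X.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from . import evaluation, train as _train
from .io import Recording
from .network import NetworkParams, S2SConfig, count_parameters, forward
from .targets import GaussianTargetSpec

__all__ = ["SpikeSignalRegressor"]


class SpikeSignalRegressor(BaseEstimator):
    """Spike-signal estimation from calcium fluorescence traces.

    An analysis-synthesis network (stride-1 convolutional encoder, 0-3
    time-distributed dense hidden layers, bias-free convolutional
    decoder with overlap-add) trained to maximize the Pearson
    correlation between its output and the — optionally
    Gaussian-smoothed — ground-truth spike signal.

    Parameters
    ----------
    frame_len : int, default 100
        Input frame length in samples (1 s at 100 Hz); also the number of
        output samples synthesized per frame.
    n_analysis_filters : int, default 30
        Number of analysis-layer kernels.
    n_hidden_layers : int, default 3
        Hidden-stack depth (0-3).
    hidden_units : int, default 30
        Units per hidden layer.
    smooth_targets : bool, default True
        Convolve the spike targets with a unit-sum Gaussian window.
    target_width, target_std : window shape in samples, default (11, 5).
    learning_rate, batch_size, patience, max_epochs, chunk_len,
    val_fraction : optimization schedule (Adam, patience-based early
        stopping on a recording-level validation split).
    random_state : int or None
        Seeds initialization, splitting, and shuffling.

    Attributes
    ----------
    params_ : NetworkParams
        Weights of the best-validation epoch.
    history_ : TrainHistory
        Per-epoch losses and the early-stopping outcome.
    n_parameters_ : int
        Trainable-scalar count of the fitted network.
    """

    def __init__(
        self,
        frame_len: int = 100,
        n_analysis_filters: int = 30,
        n_hidden_layers: int = 3,
        hidden_units: int = 30,
        smooth_targets: bool = True,
        target_width: int = 11,
        target_std: float = 5.0,
        learning_rate: float = 0.001,
        batch_size: int = 20,
        patience: int = 6,
        min_delta: float = 1e-3,
        max_epochs: int = 100,
        chunk_len: int = 1000,
        val_fraction: float = 0.2,
        random_state: int | None = None,
    ):
        self.frame_len = frame_len
        self.n_analysis_filters = n_analysis_filters
        self.n_hidden_layers = n_hidden_layers
        self.hidden_units = hidden_units
        self.smooth_targets = smooth_targets
        self.target_width = target_width
        self.target_std = target_std
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.min_delta = min_delta
        self.max_epochs = max_epochs
        self.chunk_len = chunk_len
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _network_config(self, seed: int) -> S2SConfig:
        return S2SConfig(
            w_seq=self.frame_len,
            nFilt_in=self.n_analysis_filters,
            n_hidden=self.n_hidden_layers,
            nhu=self.hidden_units,
            seed=seed,
        )

    @staticmethod
    def _as_recordings(X, y) -> list[Recording]:
        if y is None or len(X) != len(y):
            raise ValueError("X and y must be matched lists of sequences")
        return [
            Recording(trace=np.asarray(x), spikes=np.asarray(s), neuron_id=str(j))
            for j, (x, s) in enumerate(zip(X, y))
        ]

    def fit(self, X, y):
        """Fit on lists of traces ``X`` and spike-count sequences ``y``."""
        recordings = self._as_recordings(X, y)
        rng = check_random_state(self.random_state)
        init_seed, train_seed = rng.randint(0, 2**31 - 1, size=2)
        tcfg = _train.TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            patience=self.patience,
            min_delta=self.min_delta,
            max_epochs=self.max_epochs,
            chunk_len=self.chunk_len,
            val_fraction=self.val_fraction,
            seed=int(train_seed),
            target_spec=GaussianTargetSpec(
                width=self.target_width,
                std=self.target_std,
                enabled=self.smooth_targets,
            ),
        )
        config = self._network_config(int(init_seed))
        self.params_, self.history_ = _train.fit(config, tcfg, recordings)
        self.n_parameters_ = self.params_.n_parameters
        assert self.n_parameters_ == count_parameters(config)
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Spike-signal estimate for each trace, same length as the input."""
        check_is_fitted(self, "params_")
        return [forward(self.params_, np.asarray(x)).values for x in X]

    def score(self, X, y) -> float:
        """Mean Pearson correlation with the ground truth at 25 Hz bins."""
        recordings = self._as_recordings(X, y)
        estimates = self.predict(X)
        result = evaluation.evaluate(estimates, recordings, evaluation.EvalConfig())
        return result.grand_mean["pearson"]
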