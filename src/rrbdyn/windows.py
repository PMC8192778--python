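"""Tapered sliding-window correlation estimation for network time series.

Dynamic functional connectivity is estimated as a sequence of weighted
Pearson correlation matrices, one per window position.  The default taper is
an exponentially decaying kernel (largest weight on the most recent sample
of the window); a rectangular kernel reduces the estimator to the ordinary
sample correlation and is provided as a robustness alternative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateWindowError, InputError, ParameterError, ValidationError

#: Canonical network channel order used throughout the package.
DEFAULT_NETWORKS = ("SN", "lCEN", "rCEN", "DMN", "cMN", "sMN")

_VAR_TOL = 1e-12


@dataclass(frozen=True)
class NetworkTimeSeries:
    """One subject's multivariate series with named network channels.

    Parameters
    ----------
    subject_id : str
    network_names : tuple of str
        Channel names, one per column of ``values``.
    values : ndarray of shape (T, K)
        Standardized (or at least finite) channel values.
    tr_seconds : float
        Sampling interval of the series in seconds.
    """

    subject_id: str
    network_names: tuple
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "network_names", tuple(self.network_names))
        if values.ndim != 2:
            raise ValidationError("values must be a 2-D (time x channel) array")
        if values.shape[1] != len(self.network_names):
            raise ValidationError(
                f"{values.shape[1]} columns but {len(self.network_names)} network names"
            )
        if not np.all(np.isfinite(values)):
            bad = int(np.argwhere(~np.isfinite(values))[0, 0])
            raise ValidationError(f"non-finite value at row {bad}")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TaperKernel:
    """Normalized window weights (sum to one, oldest sample first)."""

    weights: np.ndarray
    shape: str
    window_samples: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 1 or w.size != self.window_samples:
            raise ParameterError("weights must be 1-D of length window_samples")
        if np.any(w < 0):
            raise ParameterError("taper weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("taper weights must sum to 1")


@dataclass(frozen=True)
class WindowedConnectivity:
    """Ordered per-window correlation matrices for one subject."""

    subject_id: str
    network_names: tuple
    window_onsets: np.ndarray  # sample index of each window's first sample
    matrices: np.ndarray  # (n_windows, K, K)
    kernel: TaperKernel

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]


def make_taper(window_samples: int, shape: str = "exponential",
               decay_rate: float | None = None) -> TaperKernel:
    """Build a sliding-window taper.

    For the exponential shape the raw weight at offset ``j`` (``j = 0`` oldest,
    ``W-1`` newest) is ``exp(-decay_rate * (W - 1 - j))``, normalized to sum
    one, so the newest sample in the window carries the largest weight.
    ``decay_rate`` defaults to ``3 / W`` (about 95% of the mass inside the
    window).  The rectangular shape is uniform ``1/W``.
    """
    if window_samples < 2:
        raise ParameterError("window_samples must be >= 2")
    if shape == "rectangular":
        w = np.full(window_samples, 1.0 / window_samples)
    elif shape == "exponential":
        if decay_rate is None:
            decay_rate = 3.0 / window_samples
        if decay_rate <= 0:
            raise ParameterError("decay_rate must be > 0 for the exponential taper")
        j = np.arange(window_samples)
        raw = np.exp(-decay_rate * (window_samples - 1 - j))
        w = raw / raw.sum()
    else:
        raise ParameterError(f"unknown taper shape {shape!r}")
    return TaperKernel(weights=w, shape=shape, window_samples=window_samples)


def weighted_correlation(values: np.ndarray, kernel: TaperKernel,
                         channel_names=None) -> np.ndarray:
    """Weighted Pearson correlation of one window.

    Uses the weighted population covariance
    ``C = sum_j w_j (x_j - mu_w)(x_j - mu_w)^T`` with ``mu_w`` the weighted
    mean, then normalizes to a correlation matrix with an exact unit diagonal.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ParameterError("window values must be 2-D")
    if x.shape[0] != kernel.window_samples:
        raise ParameterError(
            f"window has {x.shape[0]} rows, kernel expects {kernel.window_samples}"
        )
    w = kernel.weights
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    var = np.diag(cov).copy()
    if np.any(var <= _VAR_TOL):
        ch = int(np.argmax(var <= _VAR_TOL))
        name = channel_names[ch] if channel_names is not None else f"channel {ch}"
        raise DegenerateWindowError(str(name))
    d = np.sqrt(var)
    corr = cov / np.outer(d, d)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _batched_weighted_correlation(values: np.ndarray, kernel: TaperKernel,
                                  step: int, channel_names=None):
    """All windows at once.  Mathematically identical to calling
    :func:`weighted_correlation` per window; vectorized for speed."""
    W = kernel.window_samples
    w = kernel.weights
    # (n_windows, K, W): windows along axis 0, channels axis 1
    wins = sliding_window_view(values, W, axis=0)[::step]
    mu = wins @ w  # (n, K)
    xc = wins - mu[:, :, None]
    cov = np.einsum("niw,njw,w->nij", xc, xc, w, optimize=True)
    var = np.einsum("nii->ni", cov)
    bad = var <= _VAR_TOL
    if np.any(bad):
        n_idx, ch = map(int, np.argwhere(bad)[0])
        name = channel_names[ch] if channel_names is not None else f"channel {ch}"
        raise DegenerateWindowError(str(name), onset=n_idx * step)
    d = np.sqrt(var)
    corr = cov / (d[:, :, None] * d[:, None, :])
    corr = np.clip((corr + corr.transpose(0, 2, 1)) / 2.0, -1.0, 1.0)
    idx = np.arange(corr.shape[1])
    corr[:, idx, idx] = 1.0
    return corr


def sliding_window_connectivity(ts: NetworkTimeSeries, kernel: TaperKernel,
                                step: int = 1) -> WindowedConnectivity:
    """Correlation matrices at window onsets ``0, step, 2*step, ...``.

    Emits ``floor((T - W) / step) + 1`` windows; requires ``T >= W``.
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    T = ts.n_timepoints
    W = kernel.window_samples
    if T < W:
        raise InputError(
            f"series of length {T} shorter than window of {W} samples"
        )
    matrices = _batched_weighted_correlation(ts.values, kernel, step,
                                             channel_names=ts.network_names)
    onsets = np.arange(0, T - W + 1, step)
    return WindowedConnectivity(
        subject_id=ts.subject_id,
        network_names=ts.network_names,
        window_onsets=onsets,
        matrices=matrices,
        kernel=kernel,
    )


class SlidingWindowConnectivity(TransformerMixin, BaseEstimator):
    """Transformer mapping network time series to windowed correlations.

    Parameters
    ----------
    window_seconds : float, default 30.0
        Window length in seconds; converted per subject to samples by
        rounding ``window_seconds / tr`` to the nearest integer >= 2.
    shape : {"exponential", "rectangular"}
    decay_rate : float or None
        Exponential decay constant; ``None`` means ``3 / W``.
    step : int, default 1
        Window onset increment in samples (maximally overlapping windows).
    """

    def __init__(self, window_seconds: float = 30.0, shape: str = "exponential",
                 decay_rate: float | None = None, step: int = 1):
        self.window_seconds = window_seconds
        self.shape = shape
        self.decay_rate = decay_rate
        self.step = step

    def fit(self, X=None, y=None):
        if self.window_seconds <= 0:
            raise ParameterError("window_seconds must be > 0")
        self.n_features_in_ = 0
        return self

    def window_samples(self, tr_seconds: float) -> int:
        return max(2, int(round(self.window_seconds / tr_seconds)))

    def transform(self, X):
        """Transform one :class:`NetworkTimeSeries` or a sequence of them."""
        self.fit()
        single = isinstance(X, NetworkTimeSeries)
        series = [X] if single else list(X)
        out = []
        for ts in series:
            kernel = make_taper(self.window_samples(ts.tr_seconds), self.shape,
                                self.decay_rate)
            out.append(sliding_window_connectivity(ts, kernel, self.step))
        return out[0] if single else out
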