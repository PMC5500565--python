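"""Single-trial sliding-window regularized Fisher discrimination of
epoched sensor data.

For each 60 ms training window centered at tau (default -100..600 ms in
10 ms steps relative to outcome onset) a spatial weight vector

    w(tau) = S_c^{-1} (m2 - m1)

is estimated, where S_c is the average of the two shrinkage-regularized
class covariance matrices S~_i = (1-lambda) S_i + lambda nu I (nu =
trace(S_i)/D, the average eigenvalue).  Projecting window-averaged trials
onto w yields single-trial discriminant amplitudes y; discrimination
performance is the leave-one-out cross-validated ROC area (Az), its
significance a label-permutation null, and the scalp coupling of the
component the forward model a = X y / (y^T y).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

__all__ = [
    "EpochArray",
    "WindowSpec",
    "DiscriminantResult",
    "ForwardModel",
    "PermutationNull",
    "window_average",
    "regularized_cov",
    "fisher_weights",
    "discriminant_amplitudes",
    "loo_az",
    "sliding_discrimination",
    "optimize_lambda",
    "permutation_threshold",
    "forward_model",
    "project_unseen",
    "SlidingFisherDiscriminant",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.0, 0.001, 0.01, 0.028, 0.05, 0.1, 0.3, 1.0)


@dataclass
class EpochArray:
    """Epoched sensor data: trials x channels x samples.

    t0 is the time (s) of the first sample relative to outcome onset.
    """

    data: np.ndarray
    sfreq: float
    t0: float
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not np.isfinite(self.data).all():
            raise ValueError("epochs contain non-finite values")
        if self.channel_names is None:
            self.channel_names = tuple(
                f"ch{i:02d}" for i in range(self.data.shape[1])
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to outcome onset."""
        return self.t0 + np.arange(self.data.shape[2]) / self.sfreq

    def __getitem__(self, idx) -> "EpochArray":
        return EpochArray(self.data[idx], self.sfreq, self.t0, self.channel_names)

    def save(self, path: str | Path) -> None:
        """Array + JSON metadata sidecar."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "sfreq": self.sfreq,
            "t0": self.t0,
            "channel_names": list(self.channel_names),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "EpochArray":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data, meta["sfreq"], meta["t0"],
                   tuple(meta["channel_names"]))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding training windows: centers (ms) and width (ms)."""

    centers: tuple[float, ...] = tuple(float(c) for c in range(-100, 601, 10))
    width: float = 60.0


@dataclass
class DiscriminantResult:
    w: np.ndarray             # windows x channels
    y: np.ndarray             # windows x trials (training-set amplitudes)
    az: np.ndarray            # windows (LOO cross-validated)
    lambda_: float
    labels: np.ndarray
    windows: WindowSpec
    peak_window: float        # center (ms) of max Az, earliest on ties
    forward_models: np.ndarray  # windows x channels

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.az == self.az.max()))


@dataclass
class ForwardModel:
    a: np.ndarray


@dataclass
class PermutationNull:
    az_samples: np.ndarray
    threshold: float
    n_perm: int
    p: float


def _window_mask(epochs: EpochArray, center_ms: float, width_ms: float) -> np.ndarray:
    t_ms = epochs.times * 1000.0
    lo, hi = center_ms - width_ms / 2.0, center_ms + width_ms / 2.0
    mask = (t_ms >= lo - 1e-9) & (t_ms < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"window {center_ms} ms lies outside the epoch")
    if t_ms[0] > lo + 1e-9 or t_ms[-1] < hi - 1.0 / epochs.sfreq * 1000.0 - 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] ms not fully inside epoch "
            f"[{t_ms[0]:.1f}, {t_ms[-1]:.1f}] ms"
        )
    return mask


def window_average(
    epochs: EpochArray, center_ms: float, width_ms: float = 60.0
) -> np.ndarray:
    """Per-trial mean over the samples falling in the window (half-open
    upper bound), trials x channels."""
    mask = _window_mask(epochs, center_ms, width_ms)
    return epochs.data[:, :, mask].mean(axis=2)


def regularized_cov(X: np.ndarray, lambda_: float) -> np.ndarray:
    """Shrinkage-regularized covariance (1-lambda) S + lambda nu I with
    nu = trace(S)/D; trace-preserving for every lambda."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 trials for a covariance estimate")
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    nu = np.trace(S) / S.shape[0]
    return (1.0 - lambda_) * S + lambda_ * nu * np.eye(S.shape[0])


def fisher_weights(
    Xa: np.ndarray,
    Xb: np.ndarray,
    lambda_: float = 0.0,
    invert: bool = True,
) -> np.ndarray:
    """Regularized Fisher discriminant weights.

    w = S~_c^{-1} (m_b - m_a), with S~_c the average of the two
    regularized class covariances; class B (the positive/high class)
    projects to positive amplitudes.  ``invert=False`` gives the
    inverse-free variant w = S~_c (m_b - m_a) for comparison.
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    Sc = 0.5 * (regularized_cov(Xa, lambda_) + regularized_cov(Xb, lambda_))
    diff = mb - ma
    if not invert:
        return Sc @ diff
    try:
        return np.linalg.solve(Sc, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "common covariance is singular; increase the regularization "
            "lambda above 0"
        ) from exc


def discriminant_amplitudes(
    epochs: EpochArray, w: np.ndarray, center_ms: float, width_ms: float = 60.0
) -> np.ndarray:
    """Single-trial amplitudes y_i = w^T x_i averaged over the window."""
    w = np.asarray(w, dtype=float)
    if w.size != epochs.n_channels:
        raise ValueError("weight length must equal the channel count")
    return window_average(epochs, center_ms, width_ms) @ w


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must be binary 0/1 with both classes present")
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each class needs at least 2 trials")
    return labels


def loo_az(
    epochs: EpochArray,
    labels: Sequence[int],
    center_ms: float,
    lambda_: float = 0.0,
    width_ms: float = 60.0,
    return_y: bool = False,
):
    """Leave-one-out cross-validated ROC area (Az) for one window.

    Each trial is scored by a discriminant trained on all other trials
    (full retrain per fold; no shortcut).
    """
    labels = _check_labels(np.asarray(labels))
    Xw = window_average(epochs, center_ms, width_ms)
    n = Xw.shape[0]
    y = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xa = Xw[keep & (labels == 0)]
        Xb = Xw[keep & (labels == 1)]
        w = fisher_weights(Xa, Xb, lambda_)
        y[i] = Xw[i] @ w
    az = float(roc_auc_score(labels, y))
    if return_y:
        return az, y
    return az


def sliding_discrimination(
    epochs: EpochArray,
    labels: Sequence[int],
    windows: WindowSpec | None = None,
    lambda_: float = 0.0,
) -> DiscriminantResult:
    """Train the discriminant in every sliding window.

    Per window: full-sample weights w (used for amplitudes and forward
    model) and the LOO-cross-validated Az.  The peak window is the
    earliest center attaining the maximal Az.
    """
    if windows is None:
        windows = WindowSpec()
    labels = _check_labels(np.asarray(labels))
    n_win = len(windows.centers)
    W = np.empty((n_win, epochs.n_channels))
    Y = np.empty((n_win, epochs.n_trials))
    A = np.empty(n_win)
    FM = np.empty((n_win, epochs.n_channels))
    for k, c in enumerate(windows.centers):
        Xw = window_average(epochs, c, windows.width)
        w = fisher_weights(Xw[labels == 0], Xw[labels == 1], lambda_)
        y = Xw @ w
        W[k] = w
        Y[k] = y
        A[k] = loo_az(epochs, labels, c, lambda_, windows.width)
        FM[k] = _forward_from_matrix(Xw, y)
    peak = windows.centers[int(np.argmax(A == A.max()))]
    return DiscriminantResult(
        w=W, y=Y, az=A, lambda_=lambda_, labels=labels, windows=windows,
        peak_window=peak, forward_models=FM,
    )


def optimize_lambda(
    epochs: EpochArray,
    labels: Sequence[int],
    windows: WindowSpec | None = None,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> float:
    """Shrinkage strength maximizing mean LOO Az over post-outcome windows
    (centers > 0 ms); ties resolved toward the smaller lambda."""
    if windows is None:
        windows = WindowSpec()
    labels = _check_labels(np.asarray(labels))
    post = [c for c in windows.centers if c > 0]
    if not post:
        raise ValueError("no post-outcome windows to optimize over")
    best_lam, best_score = None, -np.inf
    for lam in sorted(grid):
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda grid values must lie in [0, 1]")
        try:
            score = float(
                np.mean([loo_az(epochs, labels, c, lam, windows.width) for c in post])
            )
        except np.linalg.LinAlgError:
            continue  # singular at lambda=0 on rank-deficient data
        if score > best_score + 1e-12:
            best_lam, best_score = lam, score
    if best_lam is None:
        raise np.linalg.LinAlgError("no lambda on the grid was estimable")
    return best_lam


def permutation_threshold(
    epochs: EpochArray,
    labels: Sequence[int],
    center_ms: float,
    n_perm: int = 1000,
    p: float = 0.01,
    rng: np.random.Generator | None = None,
    lambda_: float = 0.0,
    width_ms: float = 60.0,
) -> PermutationNull:
    """Null distribution of LOO Az under random label permutation;
    threshold is the empirical (1-p) quantile."""
    if rng is None:
        rng = np.random.default_rng()
    labels = _check_labels(np.asarray(labels))
    null = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(labels)
        while perm.sum() in (0, len(perm)):  # pragma: no cover - degenerate
            perm = rng.permutation(labels)
        null[j] = loo_az(epochs, perm, center_ms, lambda_, width_ms)
    thr = float(np.quantile(null, 1.0 - p))
    return PermutationNull(az_samples=null, threshold=thr, n_perm=n_perm, p=p)


def _forward_from_matrix(Xw: np.ndarray, y: np.ndarray) -> np.ndarray:
    denom = float(y @ y)
    if denom <= 0:
        raise ValueError("amplitudes are all zero; forward model undefined")
    return (Xw.T @ y) / denom


def forward_model(
    epochs: EpochArray, y: np.ndarray, center_ms: float, width_ms: float = 60.0
) -> ForwardModel:
    """Scalp coupling pattern a = X y / (y^T y) for window-averaged data
    X (channels x trials)."""
    y = np.asarray(y, dtype=float)
    Xw = window_average(epochs, center_ms, width_ms)
    if y.size != Xw.shape[0]:
        raise ValueError("y length must equal the trial count")
    return ForwardModel(a=_forward_from_matrix(Xw, y))


def project_unseen(
    epochs_unseen: EpochArray,
    w_peak: np.ndarray,
    center_ms: float,
    bins: Sequence[str],
    width_ms: float = 60.0,
    bin_order: Sequence[str] = ("very_low", "low", "medium", "high", "very_high"),
) -> "pd.Series":
    """Mean discriminant amplitude of held-out trials per surprise bin.

    The peak-window weights are applied to trials never used in training;
    empty bins yield NaN.
    """
    import pandas as pd

    y = discriminant_amplitudes(epochs_unseen, w_peak, center_ms, width_ms)
    bins = np.asarray(bins)
    if bins.size != y.size:
        raise ValueError("bins length must equal the trial count")
    means = {
        b: (float(y[bins == b].mean()) if (bins == b).any() else np.nan)
        for b in bin_order
    }
    return pd.Series(means, name="mean_amplitude")


class SlidingFisherDiscriminant(BaseEstimator):
    """Sliding-window regularized Fisher discriminant as an estimator.

    Parameters
    ----------
    sfreq, tmin : sampling rate (Hz) and first-sample time (s) used when
        ``fit`` receives a plain 3-D array instead of an EpochArray.
    window_centers_ms, window_width_ms : training windows.
    shrinkage : float in [0,1], or "auto" to optimize over shrinkage_grid
        by mean post-outcome LOO Az.
    n_permutations, alpha : label-permutation null at the peak window
        (set n_permutations=0 to skip).

    Attributes (after ``fit``)
    --------------------------
    filters_ : windows x channels backward weights.
    patterns_ : windows x channels forward models.
    scores_ : per-window LOO Az.
    lambda_ : shrinkage actually used.
    peak_window_ms_, peak_az_ : best window and its Az.
    threshold_ : permutation Az threshold at the peak window (if computed).
    """

    def __init__(
        self,
        sfreq: float = 250.0,
        tmin: float = -0.2,
        window_centers_ms: Sequence[float] | None = None,
        window_width_ms: float = 60.0,
        shrinkage: float | str = "auto",
        shrinkage_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
        n_permutations: int = 0,
        alpha: float = 0.01,
        random_state: int | None = None,
    ):
        self.sfreq = sfreq
        self.tmin = tmin
        self.window_centers_ms = window_centers_ms
        self.window_width_ms = window_width_ms
        self.shrinkage = shrinkage
        self.shrinkage_grid = shrinkage_grid
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def _as_epochs(self, X) -> EpochArray:
        if isinstance(X, EpochArray):
            return X
        return EpochArray(np.asarray(X), self.sfreq, self.tmin)

    def _windows(self) -> WindowSpec:
        if self.window_centers_ms is None:
            return WindowSpec(width=self.window_width_ms)
        return WindowSpec(
            centers=tuple(float(c) for c in self.window_centers_ms),
            width=self.window_width_ms,
        )

    def fit(self, X, y):
        epochs = self._as_epochs(X)
        labels = _check_labels(np.asarray(y))
        windows = self._windows()
        if self.shrinkage == "auto":
            lam = optimize_lambda(epochs, labels, windows, self.shrinkage_grid)
        else:
            lam = float(self.shrinkage)
        res = sliding_discrimination(epochs, labels, windows, lam)
        self.result_ = res
        self.filters_ = res.w
        self.patterns_ = res.forward_models
        self.scores_ = res.az
        self.amplitudes_ = res.y
        self.lambda_ = lam
        self.peak_window_ms_ = res.peak_window
        self.peak_az_ = float(res.az.max())
        y_peak = res.y[res.peak_index]
        # class-mean midpoint: the projection carries no bias term
        self.decision_threshold_ = 0.5 * (
            y_peak[labels == 0].mean() + y_peak[labels == 1].mean()
        )
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            self.null_ = permutation_threshold(
                epochs, labels, res.peak_window, self.n_permutations,
                self.alpha, rng, lam, windows.width,
            )
            self.threshold_ = self.null_.threshold
        return self

    def decision_function(self, X) -> np.ndarray:
        """Peak-window amplitudes for (possibly unseen) epochs."""
        epochs = self._as_epochs(X)
        k = self.result_.peak_index
        return discriminant_amplitudes(
            epochs, self.filters_[k], self.peak_window_ms_, self.window_width_ms
        )

    def transform(self, X) -> np.ndarray:
        """Amplitudes in every window, trials x windows."""
        epochs = self._as_epochs(X)
        return np.column_stack(
            [
                discriminant_amplitudes(
                    epochs, self.filters_[k], c, self.window_width_ms
                )
                for k, c in enumerate(self.result_.windows.centers)
            ]
        )

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > self.decision_threshold_).astype(int)
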