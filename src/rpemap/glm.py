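"""EEG-informed BOLD general linear models.

Event regressors (100 ms boxcars locked to outcome or stimulus onset,
optionally amplitude-modulated by single-trial EEG discriminant
amplitudes or model-derived surprise) are convolved with a canonical
double-gamma hemodynamic response, sampled at the TR and fit voxelwise by
ordinary least squares.  Statistical maps are thresholded with a
resampling procedure that permutes the parametric amplitude sequences,
refits, and derives a joint |Z| / cluster-size threshold; spatial overlap
of the valence and surprise maps is assessed by conjunction.  Percent
signal change around each outcome feeds a trial-wise regression of value
updating on ROI activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .task import SessionData

__all__ = [
    "EventRegressor",
    "DesignMatrix",
    "VolumeSeries",
    "GLMResult",
    "ClusterThreshold",
    "PSCTrace",
    "Cluster",
    "double_gamma_hrf",
    "build_regressor",
    "build_design_glm1",
    "fit_glm",
    "group_level",
    "extract_clusters",
    "resample_cluster_threshold",
    "conjunction",
    "psc",
    "psc_value_update_regression",
    "roi_bin_profile",
    "VoxelGLM",
]

DEFAULT_TR = 2.5
DEFAULT_Z_THRESH = 2.57
EVENT_DURATION = 0.1  # 100 ms boxcars


@dataclass
class EventRegressor:
    """Events of one condition: onsets (s), durations (s), amplitudes."""

    onsets: np.ndarray
    amplitudes: np.ndarray | None = None
    durations: np.ndarray | float = EVENT_DURATION
    name: str = "events"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be sorted")
        if self.amplitudes is None:
            self.amplitudes = np.ones_like(self.onsets)
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.shape != self.onsets.shape:
                raise ValueError("amplitudes must align with onsets")
        if np.isscalar(self.durations):
            self.durations = np.full_like(self.onsets, float(self.durations))
        if np.any(np.asarray(self.durations) <= 0):
            raise ValueError("durations must be positive")


@dataclass
class DesignMatrix:
    X: np.ndarray            # volumes x regressors
    names: tuple[str, ...]
    TR: float = DEFAULT_TR

    @property
    def n_volumes(self) -> int:
        return self.X.shape[0]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.names))

    def column(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class VolumeSeries:
    """4-D voxel time series (x, y, z, volumes)."""

    data: np.ndarray
    TR: float = DEFAULT_TR
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be x,y,z,volumes")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the mask")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def flat(self) -> np.ndarray:
        """volumes x in-mask voxels."""
        return self.data[self.mask].T

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Map per-voxel values back into a 3-D volume."""
        out = np.full(self.data.shape[:3], fill)
        out[self.mask] = values
        return out

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path, TR: float = DEFAULT_TR) -> "VolumeSeries":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), TR=TR)


@dataclass
class GLMResult:
    beta: np.ndarray         # regressors x voxels
    z: np.ndarray            # regressors x voxels
    residual_df: int
    names: tuple[str, ...]

    def beta_map(self, name: str, vol: VolumeSeries) -> np.ndarray:
        return vol.unflatten(self.beta[self.names.index(name)])

    def z_map(self, name: str, vol: VolumeSeries) -> np.ndarray:
        return vol.unflatten(self.z[self.names.index(name)])


@dataclass
class Cluster:
    size: int
    sign: int
    indices: np.ndarray      # voxel coordinates, n x 3


@dataclass
class ClusterThreshold:
    z_thresh: float
    min_cluster_voxels: int
    null_sizes: np.ndarray
    p: float
    n_iter: int


@dataclass
class PSCTrace:
    psc: np.ndarray          # trials x timepoints (percent)
    window_offsets: np.ndarray  # volume offsets relative to the outcome volume
    baseline: np.ndarray     # per-trial baseline signal
    run_mean: float
    kept_trials: np.ndarray  # indices of trials inside the run


def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``dt`` s.

    Difference of two gamma densities (positive lobe peaking near 5 s,
    undershoot scaled by 1/6), truncated at 32 s, normalized to unit peak.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    h = stats.gamma.pdf(t, peak_delay) - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay
    )
    return h / h.max()


def build_regressor(
    events: EventRegressor,
    TR: float,
    n_volumes: int,
    hrf: np.ndarray | None = None,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved event column sampled at volume times t = k*TR.

    Amplitude-scaled boxcars are laid on a fine grid (default 100 ms, the
    event duration), convolved with the double-gamma kernel, and read out
    at acquisition times.
    """
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    run_len = n_volumes * TR
    if events.onsets.size and events.onsets.max() >= run_len:
        raise ValueError("event onset beyond the end of the run")
    n_fine = int(np.ceil(run_len / dt)) + hrf.size
    fine = np.zeros(n_fine)
    for onset, dur, amp in zip(events.onsets, events.durations, events.amplitudes):
        i0 = int(np.round(onset / dt))
        i1 = max(i0 + 1, int(np.round((onset + dur) / dt)))
        fine[i0:i1] += amp
    conv = np.convolve(fine, hrf)[:n_fine]
    vol_t = np.arange(n_volumes) * TR
    fine_t = np.arange(n_fine) * dt
    return np.interp(vol_t, fine_t, conv)


def _center(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c = a - a.mean()
    if np.allclose(c, 0.0):
        warnings.warn(
            f"parametric regressor {name!r} has no amplitude variance after "
            "mean-centering; it is collinear with the unmodulated regressor"
        )
    return c


def build_design_glm1(
    session: SessionData,
    y_late_val: Sequence[float],
    model_surprise: Sequence[float],
    y_late_sur: Sequence[float],
    y_early_val: Sequence[float],
    motion: np.ndarray | None = None,
    lost_onsets: Sequence[float] = (),
    block: int = 0,
    TR: float = DEFAULT_TR,
    n_volumes: int | None = None,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """Outcome-phase EEG-informed design (single run).

    Task columns: UM (unmodulated outcome events), EEG_LateVal, MODEL_Sur,
    EEG_LateSur, EEG_EarlyVal (parametric, mean-centered before
    convolution), LOST (dropped with a warning when empty) and DEC
    (unmodulated events at stimulus presentation), plus motion nuisance
    columns.
    """
    trials = session.block_trials(block)
    if not trials:
        raise ValueError(f"session has no trials in block {block}")
    outcome_onsets = np.array([t.outcome_onset_s for t in trials])
    stim_onsets = np.array([t.onset_s for t in trials])
    n_ev = outcome_onsets.size
    for name, a in (
        ("EEG_LateVal", y_late_val),
        ("MODEL_Sur", model_surprise),
        ("EEG_LateSur", y_late_sur),
        ("EEG_EarlyVal", y_early_val),
    ):
        if len(a) != n_ev:
            raise ValueError(f"{name} has {len(a)} amplitudes for {n_ev} events")
    if n_volumes is None:
        n_volumes = int(np.ceil((outcome_onsets.max() + 20.0) / TR))

    cols, names = [], []

    def add(name: str, onsets, amplitudes=None):
        ev = EventRegressor(onsets=np.asarray(onsets), amplitudes=amplitudes,
                            name=name)
        cols.append(build_regressor(ev, TR, n_volumes, hrf=hrf))
        names.append(name)

    add("UM", outcome_onsets)
    add("EEG_LateVal", outcome_onsets, _center(y_late_val, "EEG_LateVal"))
    add("MODEL_Sur", outcome_onsets, _center(model_surprise, "MODEL_Sur"))
    add("EEG_LateSur", outcome_onsets, _center(y_late_sur, "EEG_LateSur"))
    add("EEG_EarlyVal", outcome_onsets, _center(y_early_val, "EEG_EarlyVal"))
    if len(lost_onsets):
        add("LOST", np.asarray(lost_onsets))
    else:
        warnings.warn("no lost trials; LOST regressor dropped")
    add("DEC", stim_onsets)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion nuisance rows must equal n_volumes")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion_{j}")

    return DesignMatrix(X=np.column_stack(cols), names=tuple(names), TR=TR)


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Signed t -> Z through matched tail probabilities (numerically safe)."""
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(np.abs(t), df)
    p = np.clip(p, 1e-300, 1.0)
    z = stats.norm.isf(p)
    return np.sign(t) * np.clip(z, 0.0, 40.0)


def fit_glm(Y: VolumeSeries | np.ndarray, X: DesignMatrix) -> GLMResult:
    """Voxelwise ordinary least squares with per-regressor t -> Z maps.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    if isinstance(Y, VolumeSeries):
        data = Y.flat()
    else:
        data = np.asarray(Y, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
    Xm = np.column_stack([X.X, np.ones(X.n_volumes)])  # implicit intercept
    names = tuple(X.names) + ("intercept",)
    if data.shape[0] != Xm.shape[0]:
        raise ValueError("time-series length does not match the design")
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name offending columns via vanishing R diagonal
        _, R = np.linalg.qr(Xm)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (columns: {bad})")

    beta, _, _, _ = np.linalg.lstsq(Xm, data, rcond=None)
    resid = data - Xm @ beta
    df = Xm.shape[0] - Xm.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    z = _t_to_z(tvals, df)
    return GLMResult(beta=beta[:-1], z=z[:-1], residual_df=df,
                     names=tuple(X.names))


def group_level(subject_betas: Sequence[np.ndarray]) -> np.ndarray:
    """One-sample t across subjects per voxel, returned as a Z map.

    A documented simplification of a full mixed-effects group model:
    subjects enter as a random sample, within-subject variance is ignored.
    """
    B = np.stack([np.asarray(b, dtype=float) for b in subject_betas])
    if B.shape[0] < 2:
        raise ValueError("group level needs at least 2 subjects")
    t, _ = stats.ttest_1samp(B, 0.0, axis=0)
    return _t_to_z(np.nan_to_num(t), B.shape[0] - 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def extract_clusters(
    z_map: np.ndarray, z_thresh: float = DEFAULT_Z_THRESH, connectivity: int = 26
) -> list[Cluster]:
    """Connected components of |Z| > z_thresh, labelled separately by sign."""
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    out: list[Cluster] = []
    struct = _structure(connectivity)
    for sign, mask in ((1, z_map > z_thresh), (-1, z_map < -z_thresh)):
        lab, n = ndimage.label(mask, structure=struct)
        for k in range(1, n + 1):
            idx = np.argwhere(lab == k)
            out.append(Cluster(size=idx.shape[0], sign=sign, indices=idx))
    return sorted(out, key=lambda c: -c.size)


def resample_cluster_threshold(
    Y: VolumeSeries,
    design_builder: Callable[[Mapping[str, np.ndarray]], DesignMatrix],
    amplitude_sets: Mapping[str, np.ndarray],
    contrast_names: Sequence[str] | None = None,
    n_iter: int = 100,
    z_thresh: float = DEFAULT_Z_THRESH,
    p: float = 0.05,
    rng: np.random.Generator | None = None,
    connectivity: int = 26,
) -> ClusterThreshold:
    """Joint |Z| / cluster-size threshold from amplitude resampling.

    Per iteration each parametric amplitude vector is permuted across its
    trials (the amplitude distribution is preserved, the trial sequence is
    randomized), the design rebuilt via ``design_builder``, the GLM refit,
    and the largest supra-threshold cluster recorded over the permuted
    regressors and both signs.  The minimum cluster size is the smallest
    size exceeding the (1-p) quantile of those null maxima.
    """
    if rng is None:
        rng = np.random.default_rng()
    if contrast_names is None:
        contrast_names = list(amplitude_sets)
    null_max = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        permuted = {k: rng.permutation(np.asarray(v)) for k, v in amplitude_sets.items()}
        X = design_builder(permuted)
        res = fit_glm(Y, X)
        m = 0
        for name in contrast_names:
            zm = Y.unflatten(res.z[res.names.index(name)])
            for c in extract_clusters(zm, z_thresh, connectivity):
                m = max(m, c.size)
        null_max[it] = m
    q = np.quantile(null_max, 1.0 - p)
    min_size = int(np.floor(q)) + 1
    return ClusterThreshold(
        z_thresh=z_thresh, min_cluster_voxels=min_size, null_sizes=null_max,
        p=p, n_iter=n_iter,
    )


def apply_cluster_threshold(
    z_map: np.ndarray, thr: ClusterThreshold, connectivity: int = 26
) -> np.ndarray:
    """Mask of voxels in clusters meeting both the |Z| and size criteria."""
    mask = np.zeros(z_map.shape, dtype=bool)
    for c in extract_clusters(z_map, thr.z_thresh, connectivity):
        if c.size >= thr.min_cluster_voxels:
            mask[tuple(c.indices.T)] = True
    return mask


def conjunction(*masks: np.ndarray) -> np.ndarray:
    """Voxelwise intersection of surviving-voxel masks."""
    if len(masks) < 2:
        raise ValueError("conjunction needs at least two masks")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("mask grids do not match")
        out = out & m
    return out


def psc(
    ts: np.ndarray,
    onsets: Sequence[float],
    TR: float = DEFAULT_TR,
    window: tuple[float, float] = (-5.0, 10.0),
) -> PSCTrace:
    """Outcome-locked percent signal change traces.

    PSC_i(t) = 100 * (X_i(t) - X_i^b) / Xbar, with baseline X_i^b the mean
    of the 2 volumes preceding the outcome volume and Xbar the run mean.
    Trials whose window falls off the run are skipped with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    k0 = int(np.round(window[0] / TR))
    k1 = int(np.round(window[1] / TR))
    offsets = np.arange(k0, k1 + 1)
    run_mean = float(ts.mean())
    traces, baselines, kept = [], [], []
    for i, onset in enumerate(onsets):
        iv = int(np.round(onset / TR))
        if iv + k0 < 0 or iv + k1 >= ts.size:
            warnings.warn(f"trial at {onset:.1f}s too close to run edge; skipped")
            continue
        base = float(ts[iv - 2 : iv].mean())
        traces.append(100.0 * (ts[iv + offsets] - base) / run_mean)
        baselines.append(base)
        kept.append(i)
    return PSCTrace(
        psc=np.asarray(traces),
        window_offsets=offsets,
        baseline=np.asarray(baselines),
        run_mean=run_mean,
        kept_trials=np.asarray(kept, dtype=int),
    )


def psc_summary(trace: PSCTrace) -> np.ndarray:
    """Per-trial scalar: mean PSC over volumes 2-4 after onset (the 5-10 s
    plateau around the hemodynamic peak)."""
    sel = (trace.window_offsets >= 2) & (trace.window_offsets <= 4)
    return trace.psc[:, sel].mean(axis=1)


def psc_value_update_regression(
    psc_per_subject: Sequence[np.ndarray],
    value_update_per_subject: Sequence[np.ndarray],
) -> tuple[np.ndarray, float, float]:
    """Per-subject OLS slope of value update on PSC, with a group-level
    one-tailed t-test (mean slope > 0).

    Returns (slopes, t, p).  Zero-variance PSC yields a NaN slope for that
    subject (excluded from the group test).
    """
    slopes = []
    for x, y in zip(psc_per_subject, value_update_per_subject):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("PSC and value-update lengths differ")
        if np.ptp(x) == 0:
            slopes.append(np.nan)
            continue
        slopes.append(stats.linregress(x, y).slope)
    slopes = np.asarray(slopes)
    valid = slopes[~np.isnan(slopes)]
    if valid.size < 2:
        return slopes, float("nan"), float("nan")
    t, p = stats.ttest_1samp(valid, 0.0, alternative="greater")
    return slopes, float(t), float(p)


def _tercile_labels(amps: np.ndarray) -> np.ndarray:
    """low/medium/high by the 33rd/66th percentiles of the amplitudes."""
    e1, e2 = np.percentile(amps, [100 / 3.0, 200 / 3.0])
    out = np.where(amps <= e1, "low", np.where(amps <= e2, "medium", "high"))
    return out


def roi_bin_profile(
    session: SessionData,
    y_surprise: Sequence[float],
    valence_labels: Sequence[int],
    Y: VolumeSeries,
    roi_masks: Mapping[str, np.ndarray],
    block: int = 0,
    TR: float = DEFAULT_TR,
    n_volumes: int | None = None,
    motion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Six-bin (valence x surprise tercile) ROI response profile.

    Trials are split into positive/negative RPE and, within each valence
    class, into terciles of the EEG surprise amplitudes (0-33, 33-66,
    66-100 percentiles).  Six unmodulated outcome-locked event regressors
    (plus DEC) are fit and the mean beta per ROI per bin tabulated; empty
    bins are reported as NaN.
    """
    trials = session.block_trials(block)
    y_surprise = np.asarray(y_surprise, dtype=float)
    valence = np.asarray(valence_labels, dtype=int)
    if y_surprise.size != len(trials) or valence.size != len(trials):
        raise ValueError("amplitudes must align with the block's trials")
    onsets = np.array([t.outcome_onset_s for t in trials])
    stim_onsets = np.array([t.onset_s for t in trials])
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets.max() + 20.0) / TR))

    sur_lab = np.empty(len(trials), dtype=object)
    for val in (1, -1):
        m = valence == val
        if m.any():
            sur_lab[m] = _tercile_labels(y_surprise[m])

    cols, names = [], []
    for val, vname in ((1, "pos"), (-1, "neg")):
        for s in ("low", "medium", "high"):
            m = (valence == val) & (sur_lab == s)
            name = f"{vname}_{s}"
            names.append(name)
            if m.any():
                ev = EventRegressor(onsets=np.sort(onsets[m]), name=name)
                cols.append(build_regressor(ev, TR, n_volumes))
            else:
                cols.append(None)
    present = [i for i, c in enumerate(cols) if c is not None]
    Xcols = [cols[i] for i in present]
    Xnames = [names[i] for i in present]
    Xcols.append(build_regressor(EventRegressor(onsets=stim_onsets, name="DEC"),
                                 TR, n_volumes))
    Xnames.append("DEC")
    if motion is not None:
        for j in range(motion.shape[1]):
            Xcols.append(motion[:, j])
            Xnames.append(f"motion_{j}")
    X = DesignMatrix(X=np.column_stack(Xcols), names=tuple(Xnames), TR=TR)
    res = fit_glm(Y, X)

    rows = []
    for name in names:
        val, s = name.split("_")
        row = {"valence": val, "surprise": s}
        for roi, mask in roi_masks.items():
            if name in res.names:
                bmap = Y.unflatten(res.beta[res.names.index(name)])
                row[roi] = float(bmap[np.asarray(mask, dtype=bool)].mean())
            else:
                row[roi] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class VoxelGLM(BaseEstimator):
    """Voxelwise OLS GLM as a thin sklearn-style estimator.

    ``fit(Y, X)`` with Y a VolumeSeries (or volumes x voxels array) and X
    a DesignMatrix; fitted attributes ``beta_``, ``z_``, ``names_``,
    ``residual_df_``.
    """

    def fit(self, Y, X: DesignMatrix):
        res = fit_glm(Y, X)
        self.result_ = res
        self.beta_ = res.beta
        self.z_ = res.z
        self.names_ = res.names
        self.residual_df_ = res.residual_df
        return self

    def predict(self, X: DesignMatrix) -> np.ndarray:
        """Fitted task-signal time courses, volumes x voxels."""
        return X.X @ self.beta_
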