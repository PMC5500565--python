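"""Synthetic data with planted ground truth for every pipeline stage.

Generates (i) reversal-learning behaviour from a softmax RL agent,
(ii) EEG epochs carrying a categorical valence component (~308 ms) and a
parametric surprise component (~320 ms) with distinct scalp patterns over
spatially correlated noise, and (iii) BOLD volumes whose voxels load on
HRF-convolved trial amplitudes in valence-only, surprise-only, overlap
(linear superposition) and null regions.  Ground-truth latents are
returned alongside every dataset so recovery tests never re-derive them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import rl
from .eeg import EpochArray
from .glm import EventRegressor, VolumeSeries, build_regressor, double_gamma_hrf
from .task import SessionData, TaskConfig, TrialContext, run_session

__all__ = [
    "EEGGenConfig",
    "BOLDGenConfig",
    "SoftmaxRLAgent",
    "gen_behavior",
    "gen_rts",
    "gen_eeg",
    "gen_bold",
    "gen_fixture_suite",
]


class SoftmaxRLAgent:
    """Choice policy: delta-rule value learning + softmax decisions.

    Keeps its own value state in sync with the trial history the task
    simulator passes in; never reads the ground-truth contingency.
    """

    def __init__(self, params: rl.RLParams):
        self.params = params
        self._values: dict[str, float] = {}
        self._n_seen = 0

    def _v(self, s: str) -> float:
        return self._values.get(s, rl.V0)

    def __call__(self, ctx: TrialContext, rng: np.random.Generator) -> str:
        # absorb outcomes observed since the last call
        for t in ctx.history[self._n_seen:]:
            delta = t.outcome - self._v(t.choice)
            self._values[t.choice] = rl.update_value_mf(
                self._v(t.choice), delta, self.params.alpha
            )
            self._n_seen += 1
        a, b = ctx.pair[0], ctx.pair[1]
        p_a = rl.choice_prob(self._v(a), self._v(b), self.params.beta,
                             self.params.phi)
        return a if rng.random() < p_a else b


def gen_behavior(
    params: rl.RLParams,
    config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SessionData, rl.LatentTrace]:
    """Simulate a session with a softmax RL agent and return it together
    with the latent trace at the generating parameters."""
    if config is None:
        config = TaskConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    session = run_session(config, SoftmaxRLAgent(params), rng)
    trace = rl.latent_trace(params, session, "mf")
    return session, trace


def gen_rts(
    trace: rl.LatentTrace,
    rng: np.random.Generator,
    base: float = 0.65,
    effect: float = 0.12,
    noise_sd: float = 0.08,
) -> np.ndarray:
    """Synthetic response times (s): the RT following a surprising positive
    RPE speeds up and following a surprising negative RPE slows down."""
    n = trace.delta.size
    rts = base + noise_sd * rng.standard_normal(n)
    rts[1:] -= effect * trace.delta[:-1]  # sign(delta)*|delta| = delta
    return np.clip(rts, 0.2, 1.25)


# ----------------------------------------------------------------- EEG


@dataclass
class EEGGenConfig:
    """Ground-truth EEG generator settings.

    Two temporally overlapping components: a categorical valence component
    (default latency 308 ms) and a parametric surprise component (default
    320 ms), with near-orthogonal unit-norm scalp patterns, Gaussian
    temporal envelopes, and spatially correlated sensor noise.  ``snr``
    scales component amplitude against unit-variance noise.
    """

    n_channels: int = 64
    sfreq: float = 250.0
    epoch_span_ms: tuple[float, float] = (-200.0, 700.0)
    valence_latency_ms: float = 308.0
    surprise_latency_ms: float = 320.0
    component_width_ms: float = 60.0
    snr: float = 1.0
    valence_jitter: float = 0.25
    noise_spatial_corr: float = 0.3
    seed: int | None = None
    max_pattern_corr: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.epoch_span_ms
        for lat in (self.valence_latency_ms, self.surprise_latency_ms):
            if not (lo < lat < hi):
                raise ValueError("component latency outside the epoch span")
        if not (0.0 <= self.noise_spatial_corr < 1.0):
            raise ValueError("noise_spatial_corr must lie in [0, 1)")


def _near_orthogonal_patterns(
    n_channels: int, max_corr: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-norm channel patterns with |correlation| below max_corr."""
    for _ in range(100):
        a = rng.standard_normal(n_channels)
        b = rng.standard_normal(n_channels)
        a /= np.linalg.norm(a)
        b -= (a @ b) * a * 0.8  # partial deflation keeps some overlap
        b /= np.linalg.norm(b)
        r = np.corrcoef(a, b)[0, 1]
        if abs(r) < max_corr:
            return a, b
    raise RuntimeError("failed to draw near-orthogonal patterns")


def _spatial_mixing(n_channels: int, corr: float) -> np.ndarray:
    """First-order neighbour mixing kernel along the channel axis."""
    if corr == 0.0:
        return np.eye(n_channels)
    M = np.eye(n_channels)
    idx = np.arange(n_channels - 1)
    M[idx, idx + 1] = corr
    M[idx + 1, idx] = corr
    # renormalize rows to preserve unit noise variance
    M /= np.sqrt((M**2).sum(axis=1, keepdims=True))
    return M


def gen_eeg(
    trace: rl.LatentTrace,
    config: EEGGenConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EpochArray, dict]:
    """One epoch per trial with planted valence and surprise components.

    epoch_i(ch, t) = snr * [ a_val(i) g(t - t_val) P_val(ch)
                           + a_sur(i) g(t - t_sur) P_sur(ch) ] + noise,
    with a_val = sign(delta) * (1 + jitter) (categorical; independent of
    |delta| by construction) and a_sur = |delta| - mean|delta|
    (parametric).  Returns the epochs and the planted per-trial amplitudes
    and patterns.
    """
    if config is None:
        config = EEGGenConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_trials = trace.delta.size
    lo, hi = config.epoch_span_ms
    t_ms = np.arange(lo, hi, 1000.0 / config.sfreq)
    n_samples = t_ms.size

    p_val, p_sur = _near_orthogonal_patterns(
        config.n_channels, config.max_pattern_corr, rng
    )
    sd = config.component_width_ms / 2.355  # FWHM -> sd
    g_val = np.exp(-0.5 * ((t_ms - config.valence_latency_ms) / sd) ** 2)
    g_sur = np.exp(-0.5 * ((t_ms - config.surprise_latency_ms) / sd) ** 2)

    a_val = np.sign(trace.delta) * (
        1.0 + config.valence_jitter * rng.standard_normal(n_trials)
    )
    a_sur = trace.surprise - trace.surprise.mean()

    M = _spatial_mixing(config.n_channels, config.noise_spatial_corr)
    noise = np.einsum(
        "cd,ndt->nct", M, rng.standard_normal((n_trials, config.n_channels, n_samples))
    )
    signal = config.snr * (
        a_val[:, None, None] * p_val[None, :, None] * g_val[None, None, :]
        + a_sur[:, None, None] * p_sur[None, :, None] * g_sur[None, None, :]
    )
    epochs = EpochArray(
        data=signal + noise, sfreq=config.sfreq, t0=lo / 1000.0
    )
    truth = {
        "valence_amp": a_val,
        "surprise_amp": a_sur,
        "pattern_valence": p_val,
        "pattern_surprise": p_sur,
        "valence_latency_ms": config.valence_latency_ms,
        "surprise_latency_ms": config.surprise_latency_ms,
    }
    return epochs, truth


# ---------------------------------------------------------------- BOLD


@dataclass
class BOLDGenConfig:
    """Ground-truth BOLD generator settings.

    Disjoint cubic ROIs load on the HRF-convolved valence amplitude, the
    surprise amplitude, their sum (linear superposition) or nothing;
    everything sits on a constant baseline plus white Gaussian noise with
    optional spatial smoothing.
    """

    grid: tuple[int, int, int] = (32, 32, 12)
    TR: float = 2.5
    n_volumes: int = 463
    roi_size: int = 4            # cubes of roi_size^3 voxels
    effect_amplitude: float = 1.0
    baseline: float = 100.0
    noise_sd: float = 1.0
    smoothness: float = 0.0      # Gaussian sd in voxels; 0 = none
    seed: int | None = None

    def default_rois(self) -> dict[str, np.ndarray]:
        nx, ny, nz = self.grid
        s = self.roi_size
        masks = {}
        corners = {
            "valence_only": (2, 2, 2),
            "surprise_only": (nx - s - 2, 2, 2),
            "overlap": (2, ny - s - 2, nz - s - 2),
            "null": (nx - s - 2, ny - s - 2, nz - s - 2),
        }
        for name, (x, y, z) in corners.items():
            m = np.zeros(self.grid, dtype=bool)
            m[x : x + s, y : y + s, z : z + s] = True
            masks[name] = m
        return masks


def gen_bold(
    outcome_onsets: np.ndarray,
    valence_amp: np.ndarray,
    surprise_amp: np.ndarray,
    config: BOLDGenConfig | None = None,
    rng: np.random.Generator | None = None,
    rois: Mapping[str, np.ndarray] | None = None,
) -> tuple[VolumeSeries, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Volumes whose ROI voxels load on the planted trial amplitudes.

    Returns (volumes, roi truth masks, the regressor time courses the
    voxels actually load on).
    """
    if config is None:
        config = BOLDGenConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if rois is None:
        rois = config.default_rois()
    onsets = np.asarray(outcome_onsets, dtype=float)
    val = np.asarray(valence_amp, dtype=float)
    sur = np.asarray(surprise_amp, dtype=float)
    if not (onsets.size == val.size == sur.size):
        raise ValueError("onsets and amplitude vectors must align")

    hrf = double_gamma_hrf(0.1)
    r_val = build_regressor(
        EventRegressor(onsets=onsets, amplitudes=val - val.mean(), name="val"),
        config.TR, config.n_volumes, hrf=hrf,
    )
    r_sur = build_regressor(
        EventRegressor(onsets=onsets, amplitudes=sur - sur.mean(), name="sur"),
        config.TR, config.n_volumes, hrf=hrf,
    )

    data = config.baseline + config.noise_sd * rng.standard_normal(
        config.grid + (config.n_volumes,)
    )
    a = config.effect_amplitude
    loadings = {
        "valence_only": a * r_val,
        "surprise_only": a * r_sur,
        "overlap": a * (r_val + r_sur),
        "null": np.zeros(config.n_volumes),
    }
    for name, mask in rois.items():
        data[np.asarray(mask, dtype=bool)] += loadings.get(name, 0.0)
    if config.smoothness > 0:
        from scipy.ndimage import gaussian_filter

        for k in range(config.n_volumes):
            data[..., k] = gaussian_filter(data[..., k], config.smoothness)

    vols = VolumeSeries(data=data, TR=config.TR)
    return vols, dict(rois), {"valence": r_val, "surprise": r_sur}


# ------------------------------------------------------------- fixtures


def gen_fixture_suite(
    seed: int,
    out_dir: str | Path,
    n_trials_per_block: int = 60,
    n_channels: int = 16,
    grid: tuple[int, int, int] = (12, 12, 6),
    n_volumes: int | None = None,
) -> dict[str, Path]:
    """Small deterministic fixture bundle (behaviour, epochs, volumes,
    ground truth) written to ``out_dir``; byte-stable for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    cfg = TaskConfig(n_blocks=2, trials_per_block=n_trials_per_block, seed=seed)
    params = rl.RLParams(alpha=0.3, beta=5.0, phi=0.0)
    session, trace = gen_behavior(params, cfg, rng)
    paths: dict[str, Path] = {}

    session.to_tsv(out / "trials.tsv")
    paths["trials"] = out / "trials.tsv"
    rts = gen_rts(trace, rng)
    table = rl.build_behavioral_table(session, trace, rts)
    table.to_csv(out / "behavior.tsv", sep="\t", index=False)
    paths["behavior"] = out / "behavior.tsv"

    eeg_cfg = EEGGenConfig(n_channels=n_channels, seed=seed)
    epochs, eeg_truth = gen_eeg(trace, eeg_cfg, rng)
    epochs.save(out / "epochs")
    paths["epochs"] = out / "epochs.npy"

    block0 = session.block_trials(0)
    onsets = np.array([t.outcome_onset_s for t in block0])
    n0 = len(block0)
    if n_volumes is None:
        # cover the last outcome plus the hemodynamic tail
        n_volumes = int(np.ceil((onsets.max() + 20.0) / BOLDGenConfig.TR))
    bold_cfg = BOLDGenConfig(grid=grid, n_volumes=n_volumes, roi_size=3, seed=seed)
    vols, rois, _ = gen_bold(
        onsets, eeg_truth["valence_amp"][:n0], eeg_truth["surprise_amp"][:n0],
        bold_cfg, rng,
    )
    vols.to_nifti(out / "bold.nii.gz")
    paths["bold"] = out / "bold.nii.gz"
    for name, mask in rois.items():
        np.save(out / f"roi_{name}.npy", mask)

    truth = pd.DataFrame(
        {
            "delta": trace.delta,
            "surprise": trace.surprise,
            "valence_amp": eeg_truth["valence_amp"],
            "surprise_amp": eeg_truth["surprise_amp"],
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    meta = {
        "seed": seed,
        "alpha": params.alpha,
        "beta": params.beta,
        "phi": params.phi,
        "valence_latency_ms": eeg_cfg.valence_latency_ms,
        "surprise_latency_ms": eeg_cfg.surprise_latency_ms,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    paths["meta"] = out / "meta.json"
    return paths
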