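"""Reinforcement-learning models of reversal-learning choice behaviour.

Three models, all sharing a softmax decision rule
``P_first = sigma(beta * (v_first - v_second) - phi)``:

* ``"mf"``   — model-free delta rule with a fixed learning rate:
               ``v(i+1) = v(i) + alpha * delta(i)``, ``delta = r - v``.
* ``"dyn"``  — same delta rule with a dynamic learning rate modulated by
               the slope of the exponentially smoothed unsigned RPE.
* ``"mb"``   — model-based stimulus-outcome contingency learner: a 3x2
               contingency matrix is updated for the (chosen symbol,
               outcome-type) entry and the chosen symbol's value is read
               out as its probability of a rewarding outcome.

Fitting is maximum likelihood in unconstrained space (logit for alpha,
log for beta and gamma) from multiple random starts, with BIC-based model
comparison.  The per-trial latent traces (values, signed RPE "valence",
unsigned RPE "surprise", learning rate, value update) feed the EEG and
fMRI stages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .task import SessionData

__all__ = [
    "RLParams",
    "LatentTrace",
    "ModelFit",
    "rpe",
    "update_value_mf",
    "update_dynamic_alpha",
    "smoothed_surprise_slope",
    "update_so_mb",
    "choice_prob",
    "neg_log_likelihood",
    "fit_mle",
    "bic",
    "latent_trace",
    "surprise_bins",
    "build_behavioral_table",
    "RescorlaWagner",
    "DynamicRescorlaWagner",
    "StimulusOutcomeModel",
]

PROB_FLOOR = 1e-12
V0 = 0.5  # uninformative initial expected value / contingency

MODEL_NAMES = ("mf", "dyn", "mb")
_N_FREE = {"mf": 3, "dyn": 4, "mb": 3}

SURPRISE_BIN_LABELS = ("very_low", "low", "medium", "high", "very_high")
SURPRISE_BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RLParams:
    """Natural-space model parameters.

    alpha: learning rate in (0,1).  beta: inverse temperature (> 0).
    phi: indecision offset.  gamma: stiffness of the dynamic learning rate
    (log-space free parameter; high gamma freezes the rate).  smooth_const:
    exponential smoothing constant for the unsigned-RPE trace (dynamic
    model only; fixed, not fitted).
    """

    alpha: float
    beta: float
    phi: float = 0.0
    gamma: float | None = None
    smooth_const: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not (0.0 < self.smooth_const <= 1.0):
            raise ValueError("smooth_const must lie in (0, 1]")


@dataclass
class LatentTrace:
    """Per-trial model latents for a session run through a model."""

    v: np.ndarray            # n_trials x n_symbols values *before* the update
    delta: np.ndarray        # signed RPE (valence carrier)
    surprise: np.ndarray     # |delta|
    alpha_t: np.ndarray      # effective learning rate on each trial
    value_update: np.ndarray  # v_chosen(i+1) - v_chosen(i)
    choice_p: np.ndarray     # probability assigned to the observed choice
    symbols: tuple[str, ...]
    SO: np.ndarray | None = None  # final contingency matrix (model-based)

    @property
    def valence(self) -> np.ndarray:
        return np.sign(self.delta)


@dataclass
class ModelFit:
    params: RLParams
    logL: float              # normalized log-likelihood (per-class means summed)
    bic: float
    n_trials: int
    model_name: str
    n_starts: int
    converged: bool


def rpe(v: float, r: int) -> float:
    """Signed reward prediction error delta = r - v."""
    if r not in (0, 1):
        raise ValueError("outcome r must be 0 or 1")
    return r - v


def update_value_mf(v: float, delta: float, alpha: float) -> float:
    """Fixed-rate delta-rule update v' = v + alpha * delta."""
    return v + alpha * delta


def _slope_transfer(m: float, gamma: float) -> float:
    """Monotone transfer of the smoothed-|RPE| slope into [0, 1).

    f(m) = |m| / (|m| + exp(gamma)): f(0)=0, saturating in |m|, and
    negligible for large gamma, which freezes the dynamic learning rate.
    """
    am = abs(m)
    return am / (am + math.exp(gamma))


def update_dynamic_alpha(alpha_prev: float, m: float, gamma: float) -> float:
    """Dynamic learning-rate update.

    Positive slopes of the smoothed unsigned RPE push alpha toward 1
    (speed learning up after surprising stretches); negative slopes shrink
    alpha toward 0 (slow learning down as outcomes become predictable).
    """
    f = _slope_transfer(m, gamma)
    if m > 0:
        return alpha_prev + f * (1.0 - alpha_prev)
    if m < 0:
        return alpha_prev - f * alpha_prev
    return alpha_prev


def smoothed_surprise_slope(
    surprise_history: Sequence[float], smooth_const: float
) -> np.ndarray:
    """Per-trial slope m(i) of the exponentially smoothed |RPE| trace.

    s(i) = s(i-1) + smooth_const * (|delta(i)| - s(i-1)), initialized at the
    first observation; m(i) = s(i) - s(i-1) (m(0) = 0).
    """
    h = np.asarray(surprise_history, dtype=float)
    if h.size == 0:
        raise ValueError("surprise history must be non-empty")
    s_prev = h[0]
    m = np.zeros_like(h)
    for i in range(1, h.size):
        s = s_prev + smooth_const * (h[i] - s_prev)
        m[i] = s - s_prev
        s_prev = s
    return m


def update_so_mb(
    SO: np.ndarray, s: int, r: int, alpha: float
) -> tuple[np.ndarray, float]:
    """Stimulus-outcome contingency update for the chosen entry only.

    delta_SO = 1 - SO[s, r]; SO'[s, r] = SO[s, r] + alpha * delta_SO.
    Returns the new matrix and the refreshed chosen-symbol value SO'[s, 1].
    """
    out = SO.copy()
    out[s, r] += alpha * (1.0 - out[s, r])
    return out, float(out[s, 1])


def choice_prob(v_a: float, v_b: float, beta: float, phi: float) -> float:
    """Softmax probability of choosing the first-listed symbol of the pair."""
    z = beta * (v_a - v_b) - phi
    # logistic, numerically stable
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _run_model(
    params: RLParams, data: SessionData, model: str
) -> LatentTrace:
    """Forward pass of a model through a session, recording latents."""
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    if model == "dyn" and params.gamma is None:
        raise ValueError("the dynamic-rate model requires gamma")
    symbols = data.config.symbols
    sym_idx = {s: i for i, s in enumerate(symbols)}
    n = len(data.trials)

    v = np.full(len(symbols), V0)
    SO = np.full((len(symbols), 2), V0) if model == "mb" else None
    alpha = params.alpha
    s_prev = None  # smoothed |delta| state (dynamic model)

    v_hist = np.empty((n, len(symbols)))
    delta_hist = np.empty(n)
    alpha_hist = np.empty(n)
    dv_hist = np.empty(n)
    p_hist = np.empty(n)

    for i, t in enumerate(data.trials):
        a, b = t.pair[0], t.pair[1]
        ia, ib = sym_idx[a], sym_idx[b]
        ic = sym_idx[t.choice]
        v_hist[i] = v

        p_first = choice_prob(v[ia], v[ib], params.beta, params.phi)
        p_hist[i] = p_first if t.choice == a else 1.0 - p_first

        delta = t.outcome - v[ic]
        delta_hist[i] = delta

        if model == "dyn":
            ad = abs(delta)
            if s_prev is None:
                s_prev, m = ad, 0.0
            else:
                s = s_prev + params.smooth_const * (ad - s_prev)
                m = s - s_prev
                s_prev = s
            alpha = update_dynamic_alpha(alpha, m, params.gamma)
        alpha_hist[i] = alpha

        v_old = v[ic]
        if model == "mb":
            SO, v_new = update_so_mb(SO, ic, t.outcome, alpha)
            v[ic] = v_new
        else:
            v[ic] = update_value_mf(v[ic], delta, alpha)
        dv_hist[i] = v[ic] - v_old

    return LatentTrace(
        v=v_hist,
        delta=delta_hist,
        surprise=np.abs(delta_hist),
        alpha_t=alpha_hist,
        value_update=dv_hist,
        choice_p=p_hist,
        symbols=symbols,
        SO=SO,
    )


def neg_log_likelihood(
    params: RLParams, data: SessionData, model: str = "mf"
) -> float:
    """Negative normalized log-likelihood of the observed choices.

    The log-likelihood is computed per choice class (the three symbols):
    each class's summed log choice probability is divided by that class's
    choice count, and the class terms are summed.  Classes with no choices
    contribute zero.  Choice probabilities are floored at PROB_FLOOR.
    """
    if len(data.trials) == 0:
        raise ValueError("session has no trials")
    trace = _run_model(params, data, model)
    p = np.maximum(trace.choice_p, PROB_FLOOR)
    if np.any(trace.choice_p <= PROB_FLOOR):
        warnings.warn("choice probabilities floored at %g" % PROB_FLOOR)
    logp = np.log(p)
    chosen = np.array([t.choice for t in data.trials])
    total = 0.0
    for s in trace.symbols:
        mask = chosen == s
        n_s = int(mask.sum())
        if n_s:
            total += logp[mask].sum() / n_s
    return -total


def bic(logL: float, d: int, n: int) -> float:
    """Bayesian information criterion: -2 logL + d log n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * logL + d * math.log(n)


# ------------------------------------------------------------- fitting

_LOGIT = lambda x: math.log(x / (1.0 - x))
_EXPIT = lambda z: 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z))


def _to_params(theta: np.ndarray, model: str, smooth_const: float) -> RLParams:
    alpha = min(max(_EXPIT(theta[0]), 1e-9), 1 - 1e-9)
    beta = math.exp(min(theta[1], 30.0))
    phi = theta[2]
    gamma = theta[3] if model == "dyn" else None
    return RLParams(alpha=alpha, beta=beta, phi=phi, gamma=gamma,
                    smooth_const=smooth_const)


def _random_start(model: str, rng: np.random.Generator) -> np.ndarray:
    theta = [
        _LOGIT(rng.uniform(0.1, 0.9)),        # logit alpha
        math.log(rng.uniform(0.5, 15.0)),     # log beta
        rng.normal(0.0, 0.5),                 # phi
    ]
    if model == "dyn":
        theta.append(rng.normal(2.0, 1.0))    # gamma (log-space free param)
    return np.asarray(theta)


def fit_mle(
    data: SessionData,
    model: str = "mf",
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
    smooth_const: float = 0.1,
) -> ModelFit:
    """Maximum-likelihood fit in unconstrained space from random starts.

    alpha is logit-transformed and beta (and gamma's exponent) enter as
    free reals, preserving natural bounds.  Returns the best of
    ``n_starts`` Nelder-Mead runs.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        rng = np.random.default_rng()

    def objective(theta: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                return neg_log_likelihood(
                    _to_params(theta, model, smooth_const), data, model
                )
            except (OverflowError, ValueError):
                return 1e12

    best = None
    any_converged = False
    failures = []
    for _ in range(n_starts):
        x0 = _random_start(model, rng)
        try:
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-8})
        except Exception as exc:  # pragma: no cover - optimizer crash
            failures.append(str(exc))
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            "all optimization starts failed: " + "; ".join(failures)
        )

    params = _to_params(best.x, model, smooth_const)
    logL = -best.fun
    n = len(data.trials)
    d = _N_FREE[model]
    return ModelFit(
        params=params,
        logL=logL,
        bic=bic(logL, d, n),
        n_trials=n,
        model_name=model,
        n_starts=n_starts,
        converged=any_converged,
    )


def latent_trace(
    params: RLParams, data: SessionData, model: str = "mf"
) -> LatentTrace:
    """Per-trial latents (values, RPE, |RPE|, learning rate, value update)
    for fitted or generating parameters."""
    return _run_model(params, data, model)


def surprise_bins(
    surprise: Sequence[float],
    edges: Sequence[float] = SURPRISE_BIN_EDGES,
) -> np.ndarray:
    """Five-level surprise labels from |RPE| values.

    Bins are [0, .2], (.2, .4], (.4, .6], (.6, .8], (.8, 1]: boundary
    values fall into the lower bin, except that 1.0 is very_high.
    """
    x = np.asarray(surprise, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("surprise values must lie in [0, 1]")
    idx = np.digitize(x, np.asarray(edges)[1:-1], right=True)
    return np.asarray(SURPRISE_BIN_LABELS)[idx]


def build_behavioral_table(
    data: SessionData,
    trace: LatentTrace,
    rts: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Trial-level design table for behavioural regressions.

    Columns: valence (sign of RPE), surprise (|RPE|), stay (next choice of
    the same symbol when the same pair is offered again; missing
    otherwise/at the last trial), and delta_rt = RT(t+1) - RT(t) when RTs
    are supplied.
    """
    n = len(data.trials)
    if len(trace.delta) != n:
        raise ValueError("trace and session lengths differ")
    if rts is not None and len(rts) != n:
        raise ValueError("rts length must match the session")

    stay = np.full(n, np.nan)
    for i in range(n - 1):
        t, t1 = data.trials[i], data.trials[i + 1]
        if set(t1.pair) == set(t.pair):
            stay[i] = float(t1.choice == t.choice)
    out = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in data.trials],
            "valence": np.sign(trace.delta),
            "surprise": trace.surprise,
            "stay": stay,
        }
    )
    if rts is not None:
        rts = np.asarray(rts, dtype=float)
        drt = np.full(n, np.nan)
        drt[:-1] = rts[1:] - rts[:-1]
        out["rt"] = rts
        out["delta_rt"] = drt
    return out


# ------------------------------------------------ sklearn-style wrappers


class RescorlaWagner(BaseEstimator):
    """Fixed-learning-rate model-free RL model as an sklearn-style estimator.

    Parameters
    ----------
    n_starts : random optimizer restarts for the ML fit.
    random_state : seed for the restart draws.

    Attributes (after ``fit``)
    --------------------------
    params_ : RLParams with the ML estimates.
    alpha_, beta_, phi_ : convenience scalars.
    logL_, bic_ : normalized log-likelihood and BIC.
    fit_ : the full ModelFit record.
    """

    model_name = "mf"

    def __init__(self, n_starts: int = 10, random_state: int | None = None,
                 smooth_const: float = 0.1):
        self.n_starts = n_starts
        self.random_state = random_state
        self.smooth_const = smooth_const

    def fit(self, session: SessionData, y=None):
        rng = np.random.default_rng(self.random_state)
        self.fit_ = fit_mle(session, self.model_name, self.n_starts, rng,
                            smooth_const=self.smooth_const)
        self.params_ = self.fit_.params
        self.alpha_ = self.params_.alpha
        self.beta_ = self.params_.beta
        self.phi_ = self.params_.phi
        self.logL_ = self.fit_.logL
        self.bic_ = self.fit_.bic
        return self

    def latent_trace(self, session: SessionData,
                     params: RLParams | None = None) -> LatentTrace:
        if params is None:
            params = self.params_
        return latent_trace(params, session, self.model_name)

    def predict_proba(self, session: SessionData) -> np.ndarray:
        """Probability assigned to each observed choice under the fit."""
        return self.latent_trace(session).choice_p

    def score(self, session: SessionData, y=None) -> float:
        """Normalized log-likelihood at the fitted parameters."""
        return -neg_log_likelihood(self.params_, session, self.model_name)


class DynamicRescorlaWagner(RescorlaWagner):
    """Model-free RL with a dynamic learning rate driven by the slope of
    the smoothed unsigned RPE (free stiffness parameter gamma)."""

    model_name = "dyn"

    def fit(self, session: SessionData, y=None):
        super().fit(session)
        self.gamma_ = self.params_.gamma
        return self


class StimulusOutcomeModel(RescorlaWagner):
    """Model-based stimulus-outcome contingency learner."""

    model_name = "mb"


def compare_models(
    sessions: Sequence[SessionData],
    models: Sequence[str] = MODEL_NAMES,
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fit each model to each session and tabulate summed BIC per model.

    One row per (session, model); the model with the lowest summed BIC
    across sessions is the selected model.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for j, sess in enumerate(sessions):
        for m in models:
            f = fit_mle(sess, m, n_starts, rng)
            rows.append(
                {
                    "subject": j,
                    "model": m,
                    "alpha": f.params.alpha,
                    "beta": f.params.beta,
                    "phi": f.params.phi,
                    "gamma": f.params.gamma,
                    "logL": f.logL,
                    "bic": f.bic,
                }
            )
    return pd.DataFrame(rows)
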