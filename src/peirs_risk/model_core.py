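"""Risk-sensitive reinforcement-learning model (PEIRS) and its nested baseline (RW).

The learner tracks, for every stimulus, a running estimate of the mean
reward (Q) and of the spread of rewards (S).  Q is updated with the
classic delta rule; S is updated toward the unsigned reward prediction
error, so that in the long run it approaches the mean absolute deviation
of the reward distribution.  Choice utilities combine the two:

    U = Q + gamma0 * S + gamma1 * delta_context * S

where ``delta_context`` is the difference between the average Q of the
stimuli offered on the current trial and the average Q over all stimuli
of the active stimulus set.  A positive ``gamma0`` expresses a baseline
taste for variance (risk-seeking); a positive ``gamma1`` makes the
learner risk-seeking in rich contexts and risk-averse in poor ones.
With both gammas at zero the model reduces to plain Rescorla-Wagner
value learning (utility = Q).

Choices between two options follow a softmax (logistic) rule with
inverse temperature beta.  Forced single-option trials update the latent
state but contribute no choice likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "PeirsParams",
    "LatentState",
    "Q_INIT",
    "S_INIT",
    "update_q",
    "update_s",
    "delta_context",
    "utility",
    "choice_probability",
    "log_choice_probability",
    "session_loglik",
    "replay_latent_trace",
    "trials_to_arrays",
    "STIMULUS_IDS",
]

#: Initial estimates for every stimulus (points).
Q_INIT = 50.0
S_INIT = 5.0

#: Canonical stimulus labels: set 1 = A-D (blocks 1-2), set 2 = E-H (blocks 3-4).
STIMULUS_IDS = ("A", "B", "C", "D", "E", "F", "G", "H")
_STIM_INDEX = {sid: i for i, sid in enumerate(STIMULUS_IDS)}


@dataclass(frozen=True)
class PeirsParams:
    """The five PEIRS parameters on the natural (bounded) scale.

    alpha_q, alpha_s in (0, 1); beta >= 0; gamma0, gamma1 unbounded.
    gamma0 = gamma1 = 0 gives the nested RW model.
    """

    alpha_q: float
    alpha_s: float
    beta: float
    gamma0: float = 0.0
    gamma1: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_q < 1.0):
            raise ValueError(f"alpha_q must lie in (0, 1), got {self.alpha_q}")
        if not (0.0 < self.alpha_s < 1.0):
            raise ValueError(f"alpha_s must lie in (0, 1), got {self.alpha_s}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")

    @property
    def is_rw(self) -> bool:
        return self.gamma0 == 0.0 and self.gamma1 == 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha_q, self.alpha_s, self.beta, self.gamma0, self.gamma1]
        )


@dataclass
class LatentState:
    """Per-stimulus value (q) and spread (s) estimates, keyed like STIMULUS_IDS."""

    q: np.ndarray
    s: np.ndarray

    @classmethod
    def initial(cls, n_stimuli: int = len(STIMULUS_IDS)) -> "LatentState":
        return cls(q=np.full(n_stimuli, Q_INIT), s=np.full(n_stimuli, S_INIT))


def update_q(q: float, reward: float, alpha_q: float) -> float:
    """Delta-rule update of the mean estimate of the chosen stimulus."""
    return q + alpha_q * (reward - q)


def update_s(s: float, q: float, reward: float, alpha_s: float) -> float:
    """Update the spread estimate toward the unsigned prediction error.

    With i.i.d. rewards the fixed point is E|r - q|, the mean absolute
    deviation of the reward distribution (sigma * sqrt(2/pi) for a
    normal distribution once q has converged).
    """
    return s + alpha_s * (abs(reward - q) - s)


def delta_context(q_presented: Sequence[float], q_all: Sequence[float]) -> float:
    """Context signal: mean Q of offered stimuli minus mean Q of the whole set.

    Positive in rich (high-reward) contexts, negative in poor ones. For
    forced trials and single-stimulus ratings ``q_presented`` holds the
    single stimulus.
    """
    q_presented = np.asarray(q_presented, dtype=float)
    if q_presented.size == 0:
        raise DataError("delta_context requires at least one presented stimulus")
    return float(np.mean(q_presented) - np.mean(np.asarray(q_all, dtype=float)))


def utility(q: float, s: float, delta: float, params: PeirsParams) -> float:
    """Mean-variance utility with context-weighted risk term."""
    return q + params.gamma0 * s + params.gamma1 * delta * s


def _log_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    # log(1 / (1 + exp(-x))) without overflow for large |x|
    return -np.logaddexp(0.0, -np.asarray(x, dtype=float))


def choice_probability(u_chosen: float, u_unchosen: float, beta: float) -> float:
    """Softmax probability of the chosen option in a two-option trial."""
    return float(np.exp(_log_sigmoid(beta * (u_chosen - u_unchosen))))


def log_choice_probability(u_chosen: float, u_unchosen: float, beta: float) -> float:
    return float(_log_sigmoid(beta * (u_chosen - u_unchosen)))


# ---------------------------------------------------------------------------
# Session likelihood
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("trial", "block", "stim_set", "trial_type", "option_left",
                     "option_right", "chosen", "reward")


def trials_to_arrays(trials: pd.DataFrame) -> dict:
    """Convert a completed trial log to the flat arrays the likelihood uses.

    Returns chosen/other stimulus indices (other = -1 on forced trials),
    rewards, and the base index of the active stimulus set (0 for A-D,
    4 for E-H).
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise DataError(f"trial log is missing columns: {missing}")
    n = len(trials)
    chosen = np.empty(n, dtype=np.int64)
    other = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=np.float64)
    set_base = np.empty(n, dtype=np.int64)
    for t, row in enumerate(trials.itertuples(index=False)):
        ch = row.chosen
        if not isinstance(ch, str) or ch not in _STIM_INDEX:
            raise DataError(f"trial {row.trial}: invalid chosen stimulus {ch!r}")
        if pd.isna(row.reward):
            raise DataError(f"trial {row.trial}: missing reward for taken action")
        c = _STIM_INDEX[ch]
        left, right = row.option_left, row.option_right
        if isinstance(right, str) and right in _STIM_INDEX:
            o = _STIM_INDEX[left] if _STIM_INDEX[left] != c else _STIM_INDEX[right]
            if c not in (_STIM_INDEX[left], _STIM_INDEX[right]):
                raise DataError(f"trial {row.trial}: chosen not among offered")
        else:
            o = -1
            if c != _STIM_INDEX[left]:
                raise DataError(f"trial {row.trial}: forced choice mismatch")
        chosen[t] = c
        other[t] = o
        reward[t] = float(row.reward)
        set_base[t] = 0 if int(row.stim_set) == 1 else 4
    return {"chosen": chosen, "other": other, "reward": reward,
            "set_base": set_base}


def session_loglik(
    params: PeirsParams,
    trials: pd.DataFrame | dict,
    model: str = "peirs",
) -> float:
    """Log-likelihood of all two-option choices in one session.

    A single forward pass from Q=50, S=5: every trial (forced included)
    updates the latent state with its observed outcome; only two-option
    trials contribute log choice-probability terms.  ``model='rw'``
    evaluates the nested baseline (utility = Q, gammas ignored).
    """
    from ._kernels import session_loglik_kernel

    arrays = trials if isinstance(trials, dict) else trials_to_arrays(trials)
    use_gamma = model.lower() == "peirs"
    if model.lower() not in ("peirs", "rw"):
        raise ValueError(f"unknown model {model!r}")
    ll = session_loglik_kernel(
        params.alpha_q, params.alpha_s, params.beta,
        params.gamma0 if use_gamma else 0.0,
        params.gamma1 if use_gamma else 0.0,
        use_gamma,
        arrays["chosen"], arrays["other"], arrays["reward"], arrays["set_base"],
    )
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite session log-likelihood")
    return float(ll)


def replay_latent_trace(
    params: PeirsParams, trials: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Replay observed choices/rewards; return pre-trial Q and S traces.

    Row t holds the state *before* trial t's update, so row 0 is the
    initial state.  Shapes (n_trials, 8), columns ordered as
    STIMULUS_IDS.  Pure-python reference path, also used to cross-check
    the compiled likelihood.
    """
    arrays = trials_to_arrays(trials) if isinstance(trials, pd.DataFrame) else trials
    n = arrays["chosen"].shape[0]
    q = np.full(len(STIMULUS_IDS), Q_INIT)
    s = np.full(len(STIMULUS_IDS), S_INIT)
    q_trace = np.empty((n, q.size))
    s_trace = np.empty((n, s.size))
    for t in range(n):
        q_trace[t] = q
        s_trace[t] = s
        c = arrays["chosen"][t]
        r = arrays["reward"][t]
        pe = r - q[c]
        s[c] = update_s(s[c], q[c], r, params.alpha_s)
        q[c] = q[c] + params.alpha_q * pe
    return q_trace, s_trace
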