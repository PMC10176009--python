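"""Hierarchical empirical-Bayes (EM) fitting of the RW and PEIRS models.

Subject parameters live on an unconstrained "Gaussian" scale — logit
for the learning rates, log for the softmax inverse temperature,
identity for the gamma parameters — where the population distribution
is an independent Gaussian per parameter.  The E-step computes each
subject's maximum-a-posteriori (MAP) estimate under the current
population prior, with a Laplace (curvature-based) approximation of the
posterior variance; the M-step re-estimates the prior mean and variance
from the cohort's posterior moments.  Iterating to convergence yields
empirically regularized subject fits, which feed per-subject BIC model
comparison and the parameter-recovery harness.

The RW baseline is PEIRS with both gammas pinned at zero.  It is fitted
over (alpha_q, alpha_s, beta); its choice likelihood does not depend on
alpha_s, which therefore stays at its prior — it is carried so the two
models share a parameter space, and the BIC penalty uses k = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import pearsonr

from . import agents as ag
from . import task_design as td
from .errors import DataError, FitError
from .model_core import PeirsParams, session_loglik, trials_to_arrays

__all__ = [
    "MODELS",
    "free_param_names",
    "n_free_params",
    "transform",
    "inverse_transform",
    "PopulationPrior",
    "SubjectFit",
    "FitConfig",
    "map_fit_subject",
    "em_fit_population",
    "bic",
    "compare_models",
    "ModelComparison",
    "RecoveryReport",
    "parameter_recovery",
]

MODELS = ("rw", "peirs")

_FREE = {"peirs": ("alpha_q", "alpha_s", "beta", "gamma0", "gamma1"),
         "rw": ("alpha_q", "alpha_s", "beta")}
#: BIC parameter counts: the RW likelihood has no gamma terms.
_K = {"peirs": 5, "rw": 3}

_VAR_FLOOR = 1e-6


def _check_model(model: str) -> str:
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    return model


def free_param_names(model: str) -> Tuple[str, ...]:
    return _FREE[_check_model(model)]


def n_free_params(model: str) -> int:
    return _K[_check_model(model)]


def transform(v: Sequence[float], model: str = "peirs") -> PeirsParams:
    """Unconstrained vector -> natural-scale parameters.

    Logistic for learning rates, exp for beta, identity for gammas.
    For RW the 3-vector maps to (alpha_q, alpha_s, beta) with gammas 0.
    """
    model = _check_model(model)
    v = np.asarray(v, dtype=float)
    if v.shape != (len(_FREE[model]),):
        raise ValueError(f"expected a {len(_FREE[model])}-vector for {model}")
    g0, g1 = (float(v[3]), float(v[4])) if model == "peirs" else (0.0, 0.0)
    # keep the image strictly inside the open bounds under float rounding
    tiny = 1e-12
    return PeirsParams(
        alpha_q=float(np.clip(expit(v[0]), tiny, 1.0 - 1e-13)),
        alpha_s=float(np.clip(expit(v[1]), tiny, 1.0 - 1e-13)),
        beta=float(np.exp(min(v[2], 50.0))), gamma0=g0, gamma1=g1)


def inverse_transform(p: PeirsParams, model: str = "peirs") -> np.ndarray:
    """Natural-scale parameters -> unconstrained vector (errors on boundaries)."""
    model = _check_model(model)
    for name, val in (("alpha_q", p.alpha_q), ("alpha_s", p.alpha_s)):
        if not (0.0 < val < 1.0):
            raise ValueError(f"{name}={val} has no finite unconstrained image")
    if p.beta <= 0.0:
        raise ValueError("beta must be strictly positive to invert")
    head = [float(logit(p.alpha_q)), float(logit(p.alpha_s)), float(np.log(p.beta))]
    if model == "peirs":
        return np.array(head + [p.gamma0, p.gamma1])
    return np.array(head)


@dataclass
class PopulationPrior:
    """Independent per-parameter Gaussian on the unconstrained scale."""

    mean: np.ndarray
    var: np.ndarray
    model: str = "peirs"
    n_iter: int = 0
    converged: bool = False
    #: per-iteration total penalized objective (sum over subjects of MAP
    #: loglik + log prior density at the MAP), for monitoring EM progress
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @classmethod
    def default(cls, model: str = "peirs") -> "PopulationPrior":
        """Weakly informative starting prior: mean 0, SD 2.5 per parameter."""
        k = n_free_params(model)
        return cls(mean=np.zeros(k), var=np.full(k, 2.5**2), model=model)

    def log_density(self, v: np.ndarray) -> float:
        z = (v - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + np.log(2 * np.pi * self.var)))


@dataclass
class SubjectFit:
    subject: int
    model: str
    map_unconstrained: np.ndarray
    map_params: PeirsParams
    loglik: float  # likelihood term only, at the MAP
    posterior_var: np.ndarray  # Laplace approximation, per parameter
    bic: float
    n_choice_trials: int
    converged: bool = True


@dataclass
class FitConfig:
    n_starts: int = 10
    n_starts_later: int = 3  # E-steps after the first reuse the previous MAP
    max_em_iter: int = 100
    em_tol: float = 1e-3
    optimizer_tol: float = 1e-9
    seed: int = 0


def _n_choice_trials(arrays: dict) -> int:
    return int(np.sum(arrays["other"] >= 0))


def bic(loglik: float, model: str, n_choice_trials: int) -> float:
    """Per-subject BIC = -2 loglik + k ln(n), n = two-option trials."""
    if n_choice_trials <= 0:
        raise DataError("BIC requires at least one choice trial")
    return -2.0 * loglik + n_free_params(model) * np.log(n_choice_trials)


def map_fit_subject(
    trials: pd.DataFrame | dict,
    prior: PopulationPrior,
    model: str = "peirs",
    config: Optional[FitConfig] = None,
    subject: int = 0,
    extra_starts: Optional[List[np.ndarray]] = None,
    n_starts: Optional[int] = None,
) -> SubjectFit:
    """MAP fit of one subject under a Gaussian population prior.

    Maximizes session log-likelihood plus log-prior on the unconstrained
    scale with multistart L-BFGS-B (prior mean plus prior draws, plus
    any ``extra_starts`` such as warm starts).  Stores the
    likelihood-only value and the diagonal Laplace posterior variance.
    """
    model = _check_model(model)
    config = config or FitConfig()
    arrays = trials if isinstance(trials, dict) else trials_to_arrays(trials)
    rng = np.random.default_rng(config.seed + 1000003 * subject)

    def objective(v: np.ndarray) -> float:
        ll = session_loglik(transform(v, model), arrays, model)
        return -(ll + prior.log_density(v))

    k = n_free_params(model)
    n_st = n_starts if n_starts is not None else config.n_starts
    starts = [prior.mean.copy()]
    if extra_starts:
        starts.extend(np.asarray(x, dtype=float) for x in extra_starts)
    while len(starts) < n_st:
        starts.append(rng.normal(prior.mean, np.sqrt(prior.var)))

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                bounds=[(-25.0, 25.0)] * k,
                options={"ftol": config.optimizer_tol, "maxiter": 500})
        except FloatingPointError:
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_ok == 0:
        raise FitError(f"all {len(starts)} starts failed for subject {subject} ({model})")

    v_map = best.x
    ll = session_loglik(transform(v_map, model), arrays, model)
    post_var = _laplace_posterior_var(objective, v_map, prior)
    n_choice = _n_choice_trials(arrays)
    return SubjectFit(
        subject=subject, model=model, map_unconstrained=v_map,
        map_params=transform(v_map, model), loglik=ll,
        posterior_var=post_var, bic=bic(ll, model, n_choice),
        n_choice_trials=n_choice, converged=bool(best.success))


def _laplace_posterior_var(objective, v: np.ndarray, prior: PopulationPrior,
                           h: float = 1e-3) -> np.ndarray:
    """Laplace posterior variances: diagonal of the inverse Hessian of the
    negative log-posterior, by central finite differences.

    If the Hessian is not positive definite (flat or mis-converged
    directions) the per-parameter fallback is the diagonal-curvature
    reciprocal, then the prior variance — the exact posterior variance
    for a likelihood-flat parameter.
    """
    k = v.size
    f0 = objective(v)
    H = np.empty((k, k))
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        fp[i] = objective(v + e)
        fm[i] = objective(v - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = objective(v + ei + ej)
            fmm = objective(v - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                 - fm[i] - fm[j] + fmm) / (2.0 * h**2)
    var = np.empty(k)
    try:
        L = np.linalg.cholesky(H)  # PD check
        inv = np.linalg.inv(H)
        var = np.diag(inv).copy()
    except np.linalg.LinAlgError:
        for i in range(k):
            var[i] = 1.0 / H[i, i] if H[i, i] > 1e-10 else prior.var[i]
    bad = ~np.isfinite(var) | (var <= 0)
    var[bad] = prior.var[bad]
    return np.minimum(var, prior.var * 1e3)


def _as_arrays_list(datasets) -> List[dict]:
    out = []
    for d in datasets:
        trials = d.trials if hasattr(d, "trials") else d
        out.append(trials_to_arrays(trials) if isinstance(trials, pd.DataFrame) else trials)
    return out


def em_fit_population(
    datasets: Sequence,
    model: str = "peirs",
    config: Optional[FitConfig] = None,
    prior0: Optional[PopulationPrior] = None,
) -> Tuple[PopulationPrior, List[SubjectFit]]:
    """Empirical-Bayes EM over a cohort (run per condition by the caller).

    Alternates MAP fits with Laplace posterior variances (E) and
    prior-moment updates (M): mean = cohort mean of the MAPs, variance =
    mean of (MAP^2 + posterior var) minus squared mean, floored at 1e-6.
    Stops when the largest absolute change in prior mean or variance
    drops below ``em_tol``, or at ``max_em_iter`` with converged=False.
    """
    model = _check_model(model)
    config = config or FitConfig()
    if len(datasets) < 2:
        raise DataError("EM needs at least two subjects")
    arrays_list = _as_arrays_list(datasets)
    prior = prior0 or PopulationPrior.default(model)
    fits: List[SubjectFit] = []
    prev_maps: Optional[List[np.ndarray]] = None
    converged = False
    history: List[float] = []
    it = 0
    for it in range(1, config.max_em_iter + 1):
        fits = []
        for i, arrays in enumerate(arrays_list):
            extra = [prev_maps[i]] if prev_maps is not None else None
            n_st = config.n_starts if prev_maps is None else config.n_starts_later
            fits.append(map_fit_subject(
                arrays, prior, model, config, subject=i,
                extra_starts=extra, n_starts=n_st))
        m = np.stack([f.map_unconstrained for f in fits])
        v = np.stack([f.posterior_var for f in fits])
        history.append(float(sum(
            f.loglik + prior.log_density(f.map_unconstrained) for f in fits)))
        new_mean = m.mean(axis=0)
        new_var = np.maximum((m**2 + v).mean(axis=0) - new_mean**2, _VAR_FLOOR)
        delta = max(np.max(np.abs(new_mean - prior.mean)),
                    np.max(np.abs(new_var - prior.var)))
        prior = PopulationPrior(mean=new_mean, var=new_var, model=model, n_iter=it)
        prev_maps = [f.map_unconstrained for f in fits]
        if delta < config.em_tol:
            converged = True
            break
    prior.converged = converged
    prior.n_iter = it
    prior.history = history
    for f, ds in zip(fits, datasets):
        if hasattr(ds, "subject"):
            f.subject = ds.subject
    return prior, fits


@dataclass
class ModelComparison:
    """Per-subject BIC comparison of RW vs PEIRS on identical data."""

    delta_bic: np.ndarray  # BIC_rw - BIC_peirs per subject; > 0 favors PEIRS
    n_prefer_peirs: int
    n_subjects: int
    total_bic_rw: float
    total_bic_peirs: float

    @property
    def fraction_prefer_peirs(self) -> float:
        return self.n_prefer_peirs / self.n_subjects


def compare_models(fits_rw: Sequence[SubjectFit],
                   fits_peirs: Sequence[SubjectFit]) -> ModelComparison:
    if len(fits_rw) != len(fits_peirs):
        raise DataError("model comparison requires matched subject sets")
    for fr, fp in zip(fits_rw, fits_peirs):
        if fr.subject != fp.subject or fr.n_choice_trials != fp.n_choice_trials:
            raise DataError("model comparison requires identical datasets per subject")
    d = np.array([fr.bic - fp.bic for fr, fp in zip(fits_rw, fits_peirs)])
    return ModelComparison(
        delta_bic=d,
        n_prefer_peirs=int(np.sum(d > 0)),
        n_subjects=len(d),
        total_bic_rw=float(sum(f.bic for f in fits_rw)),
        total_bic_peirs=float(sum(f.bic for f in fits_peirs)),
    )


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """True-vs-recovered correlations on the unconstrained scale."""

    r_matrix: np.ndarray  # (5, 5): true parameter i vs recovered parameter j
    param_names: Tuple[str, ...]
    n_subjects: int
    n_failed: int
    seed: int
    true_unconstrained: np.ndarray
    recovered_unconstrained: np.ndarray

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.r_matrix)

    @property
    def max_abs_off_diagonal(self) -> float:
        off = self.r_matrix[~np.eye(self.r_matrix.shape[0], dtype=bool)]
        return float(np.max(np.abs(off)))


def parameter_recovery(
    population: Optional[ag.PopulationSpec] = None,
    n_subjects: int = 32,
    seed: int = 0,
    schedule_config: Optional[td.ExperienceConfig] = None,
    fit_config: Optional[FitConfig] = None,
) -> RecoveryReport:
    """Simulate known PEIRS agents, refit hierarchically, correlate.

    Samples ``n_subjects`` parameter vectors from the population,
    simulates each on its own experience schedule, runs the EM fit, and
    returns the full 5x5 Pearson matrix between generating and recovered
    unconstrained parameters (diagonal = recovery quality, off-diagonal
    = leakage between parameters).
    """
    population = population or ag.DEFAULT_RECOVERY
    root = np.random.SeedSequence(seed)
    pop_seq, cohort_seq, fit_seq = root.spawn(3)
    params_list, u_true = ag.sample_population(
        population, np.random.default_rng(pop_seq), n_subjects)
    datasets = ag.simulate_cohort(
        population, seed=int(np.random.default_rng(cohort_seq).integers(2**31)),
        n_subjects=n_subjects, config=schedule_config, params_list=params_list)
    fit_config = fit_config or FitConfig()
    fit_config = replace(fit_config,
                         seed=int(np.random.default_rng(fit_seq).integers(2**31)))
    failed: List[int] = []
    _, fits = em_fit_population(datasets, model="peirs", config=fit_config)
    u_rec = np.stack([f.map_unconstrained for f in fits])
    k = u_true.shape[1]
    r = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            r[i, j] = pearsonr(u_true[:, i], u_rec[:, j])[0]
    return RecoveryReport(
        r_matrix=r, param_names=ag.PARAM_NAMES, n_subjects=n_subjects,
        n_failed=len(failed), seed=seed,
        true_unconstrained=u_true, recovered_unconstrained=u_rec)
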