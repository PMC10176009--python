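"""Behavioral risk-preference statistics.

Risk is the outcome variance of an option.  For the experience task the
risk preference per context is the fraction of matched-mean choice
trials on which the high-SD stimulus was chosen, computed over the
second half of each 144-trial stimulus set (learning has stabilized by
then); mixed-trial accuracy (fraction choosing the higher-mean
stimulus, all mixed trials) is the comprehension control.  For the
description task, p(risky) comes from the EV-matched gambles 9 (low
context) and 10 (high context) over all trials, and accuracy from
gambles 1-8 (fraction choosing the higher-EV side).

Inference helpers mirror the reporting conventions of within-subject
designs: a 2x2 repeated-measures ANOVA built from per-subject
difference-score contrasts (exact for a fully-within 2x2: each F is the
square of the corresponding paired t), paired t with Cohen's d_z, and
the Wilcoxon signed-rank Z with normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import task_design as td
from .errors import DataError
from .model_core import PeirsParams

__all__ = [
    "RiskPreference",
    "AnovaResult",
    "risk_preference_experience",
    "risk_preference_description",
    "rm_anova_2x2",
    "paired_t",
    "wilcoxon_signed_rank",
    "stimulus_utility",
    "dataset_stimulus_utilities",
]


@dataclass
class RiskPreference:
    subject: int
    condition: str
    task: str  # experience | description
    p_risky_high: float  # NaN if the cell is empty
    p_risky_low: float
    accuracy_mixed: float
    n_high: int
    n_low: int
    n_mixed: int


def _proportion(hits: int, n: int) -> float:
    return hits / n if n > 0 else float("nan")


def risk_preference_experience(
    trials: pd.DataFrame,
    stimuli: Optional[Tuple[List[td.StimulusSpec], List[td.StimulusSpec]]] = None,
    subject: int = 0,
    condition: str = "",
) -> RiskPreference:
    """Context-wise risk preference from a completed experience log.

    Per stimulus set, only the second half of that set's trials (by
    presentation order) enter the context proportions; mixed-trial
    accuracy uses all mixed trials.
    """
    stimuli = stimuli or td.default_stimulus_sets()
    by_id = {s.id: s for s in stimuli[0] + stimuli[1]}
    mean_all = np.mean([s.mean for s in stimuli[0]])
    sd_thresh = np.mean([s.sd for s in stimuli[0]])

    risky_hits = {"high_context": 0, "low_context": 0}
    risky_n = {"high_context": 0, "low_context": 0}
    mixed_hits = 0
    mixed_n = 0
    for set_id, sub in trials.groupby("stim_set"):
        half_start = len(sub) // 2
        second_half = sub.iloc[half_start:]
        for row in second_half.itertuples(index=False):
            if row.trial_type in ("high_context", "low_context") and row.option_right:
                risky_n[row.trial_type] += 1
                if by_id[row.chosen].sd > sd_thresh:
                    risky_hits[row.trial_type] += 1
    for row in trials.itertuples(index=False):
        if row.trial_type == "mixed" and row.option_right:
            mixed_n += 1
            if by_id[row.chosen].mean > mean_all:
                mixed_hits += 1
    return RiskPreference(
        subject=subject, condition=condition, task="experience",
        p_risky_high=_proportion(risky_hits["high_context"], risky_n["high_context"]),
        p_risky_low=_proportion(risky_hits["low_context"], risky_n["low_context"]),
        accuracy_mixed=_proportion(mixed_hits, mixed_n),
        n_high=risky_n["high_context"], n_low=risky_n["low_context"],
        n_mixed=mixed_n)


def risk_preference_description(
    trials: pd.DataFrame,
    gambles: Optional[Sequence[td.GambleSpec]] = None,
    subject: int = 0,
    condition: str = "",
) -> RiskPreference:
    """p(risky) from gambles 9 (low) and 10 (high); accuracy from gambles 1-8.

    All trials count (no learning in this task).  On equal-EV mixed
    gambles (none in the default set) neither option is "correct" and
    the trial is excluded from accuracy.
    """
    gambles = gambles if gambles is not None else td.default_gambles()
    by_id = {g.id: g for g in gambles}
    risky_hits = {"high_reward": 0, "low_reward": 0}
    risky_n = {"high_reward": 0, "low_reward": 0}
    acc_hits = 0
    acc_n = 0
    for row in trials.itertuples(index=False):
        g = by_id[int(row.gamble_id)]
        if g.context in ("high_reward", "low_reward"):
            risky_n[g.context] += 1
            if row.chosen == "risky":
                risky_hits[g.context] += 1
        else:
            ev_safe, ev_risky = td.gamble_expected_values(g)
            if ev_safe == ev_risky:
                continue
            acc_n += 1
            better = "risky" if ev_risky > ev_safe else "safe"
            if row.chosen == better:
                acc_hits += 1
    return RiskPreference(
        subject=subject, condition=condition, task="description",
        p_risky_high=_proportion(risky_hits["high_reward"], risky_n["high_reward"]),
        p_risky_low=_proportion(risky_hits["low_reward"], risky_n["low_reward"]),
        accuracy_mixed=_proportion(acc_hits, acc_n),
        n_high=risky_n["high_reward"], n_low=risky_n["low_reward"], n_mixed=acc_n)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: Tuple[int, int]
    p: float
    partial_eta_sq: float
    undefined: bool = False  # zero-variance contrast


def paired_t(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Paired t-test with Cohen's d_z (mean difference / SD of differences)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise DataError("paired t needs at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": float("nan"), "df": n - 1, "p": float("nan"),
                "d_z": float("nan")}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p),
            "d_z": float(d.mean() / sd)}


def _contrast_f(contrast: np.ndarray, effect: str) -> AnovaResult:
    n = contrast.size
    sd = contrast.std(ddof=1)
    if sd == 0:
        return AnovaResult(effect, float("nan"), (1, n - 1), float("nan"),
                           float("nan"), undefined=True)
    t = contrast.mean() / (sd / np.sqrt(n))
    F = t**2
    p = stats.f.sf(F, 1, n - 1)
    return AnovaResult(effect, float(F), (1, n - 1), float(p),
                       float(F / (F + (n - 1))))


def rm_anova_2x2(
    cells: np.ndarray,
    factor_names: Tuple[str, str] = ("hunger", "context"),
) -> List[AnovaResult]:
    """Fully within-subject 2x2 ANOVA from difference-score contrasts.

    ``cells`` has shape (n_subjects, 2, 2), axis 1 = first factor,
    axis 2 = second factor.  For each effect the within-subject contrast
    is t-tested against zero; F = t^2 with df = (1, n-1), which is
    exact for this design.  Partial eta squared = F / (F + df2).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise DataError("expected per-subject cells of shape (n, 2, 2)")
    if np.isnan(cells).any():
        raise DataError("missing cell means; every subject needs all four cells")
    n = cells.shape[0]
    if n < 2:
        raise DataError("ANOVA needs at least two subjects")
    main_a = cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)
    main_b = cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1)
    inter = (cells[:, 0, 0] - cells[:, 0, 1]) - (cells[:, 1, 0] - cells[:, 1, 1])
    return [
        _contrast_f(main_a, factor_names[0]),
        _contrast_f(main_b, factor_names[1]),
        _contrast_f(inter, f"{factor_names[0]} x {factor_names[1]}"),
    ]


def wilcoxon_signed_rank(
    x: Sequence[float], y: Optional[Sequence[float]] = None
) -> Tuple[float, float]:
    """Signed-rank Z and two-sided p (normal approximation).

    Zero differences are dropped, ties get midranks, the z-score carries
    a 0.5 continuity correction toward the null mean and the variance a
    tie correction.  Sign of Z follows the sign of the rank sum
    displacement (positive when x tends to exceed y).
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DataError("all differences are zero; signed-rank undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        raise DataError("degenerate signed-rank variance (all ranks tied at zero)")
    diff = w_plus - mu
    correction = 0.5 * np.sign(diff)
    z = (diff - correction) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Model-derived stimulus utilities
# ---------------------------------------------------------------------------


def stimulus_utility(
    q_final: Sequence[float], s_final: Sequence[float], params: PeirsParams
) -> np.ndarray:
    """Utility of each stimulus from final Q/S, single-stimulus context signal.

    For a lone (rated) stimulus the context signal is its own Q minus
    the mean Q of the set, so u_i = q_i + g0 s_i + g1 (q_i - mean q) s_i.
    """
    q = np.asarray(q_final, dtype=float)
    s = np.asarray(s_final, dtype=float)
    delta = q - q.mean()
    return q + params.gamma0 * s + params.gamma1 * delta * s


def dataset_stimulus_utilities(dataset) -> Dict[str, np.ndarray]:
    """Per-set and set-averaged stimulus utilities at the end of learning.

    Uses the latent state after the last trial of each stimulus set.
    Returns utilities ordered by the within-set stimulus order
    (A-D / E-H, i.e. (35,5), (35,20), (65,5), (65,20) by default).
    """
    trials = dataset.trials
    out: Dict[str, np.ndarray] = {}
    per_set = []
    for set_id in sorted(trials["stim_set"].unique()):
        last_pos = int(np.where(trials["stim_set"].to_numpy() == set_id)[0][-1])
        # state *after* the set's final trial = state before the next one,
        # or the final state replayed past the end
        q, s = _state_after(dataset, last_pos)
        base = 0 if int(set_id) == 1 else 4
        u = stimulus_utility(q[base:base + 4], s[base:base + 4], dataset.params)
        out[f"set{int(set_id)}"] = u
        per_set.append(u)
    out["mean"] = np.mean(per_set, axis=0)
    return out


def _state_after(dataset, t: int) -> Tuple[np.ndarray, np.ndarray]:
    """Latent state after trial index t (0-based), from the stored trace."""
    q = dataset.q_trace[t].copy()
    s = dataset.s_trace[t].copy()
    row = dataset.trials.iloc[t]
    from .model_core import _STIM_INDEX  # stable private mapping

    c = _STIM_INDEX[row["chosen"]]
    r = float(row["reward"])
    pe = r - q[c]
    s[c] += dataset.params.alpha_s * (abs(pe) - s[c])
    q[c] += dataset.params.alpha_q * pe
    return q, s
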