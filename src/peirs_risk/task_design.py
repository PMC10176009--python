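"""Trial schedules and reward generation for the two risk tasks.

Experience task: four stimuli whose rewards follow approximately normal
distributions in a 2x2 design (mean 35 or 65 points, SD 5 or 20).  A
session has 4 blocks of 72 trials: per block 18 high-context trials
(the two mean-65 stimuli), 18 low-context (the two mean-35 stimuli),
24 mixed trials (one of each mean), and 12 forced single-stimulus
trials (3 per stimulus).  A forced trial showing stimulus X never
immediately precedes a high/low-context trial offering X.  Stimulus
identities are reset after two blocks: blocks 1-2 use set A-D, blocks
3-4 use the structurally identical set E-H.

Description task: 10 fixed two-option gambles, 4 blocks of 20 trials,
each gamble played 8 times.  Gambles 1-8 pit a 50:50 +/-10 gamble
(EV 0) against a risky option from the 2x2x2 cross of win probability
{0.6, 0.4} x win {30, 70} x loss {30, 70} (EV spanning -30..+30).
Gambles 9 and 10 are EV-matched safe-vs-risky pairs in a pure-loss
(low) and pure-gain (high) context, valence mirrors of one another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

__all__ = [
    "StimulusSpec",
    "GambleOption",
    "GambleSpec",
    "ExperienceConfig",
    "DescriptionConfig",
    "default_stimulus_sets",
    "default_gambles",
    "make_experience_schedule",
    "make_description_schedule",
    "sample_reward",
    "quantize_reward",
    "pregenerate_block_rewards",
    "BlockRewards",
    "gamble_expected_values",
    "option_ev",
    "option_sd",
    "ordering_violations",
    "TRIAL_TYPES",
]

TRIAL_TYPES = ("high_context", "low_context", "mixed", "forced")

REWARD_MIN = 0
REWARD_MAX = 100


@dataclass(frozen=True)
class StimulusSpec:
    """A stimulus and its true reward distribution (points)."""

    id: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def default_stimulus_sets() -> Tuple[List[StimulusSpec], List[StimulusSpec]]:
    """The 2x2 mean x SD cross, twice (set 1 = A-D, set 2 = E-H)."""
    design = [(35, 5), (35, 20), (65, 5), (65, 20)]
    set1 = [StimulusSpec(i, m, s) for i, (m, s) in zip("ABCD", design)]
    set2 = [StimulusSpec(i, m, s) for i, (m, s) in zip("EFGH", design)]
    return set1, set2


@dataclass(frozen=True)
class GambleOption:
    """One side of a described gamble: win `win` with p_win, else lose `lose`."""

    p_win: float
    win: float
    lose: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_win <= 1.0):
            raise ValueError("p_win must lie in [0, 1]")


@dataclass(frozen=True)
class GambleSpec:
    id: int
    context: str  # mixed | low_reward | high_reward
    safe_option: GambleOption
    risky_option: GambleOption


def option_ev(opt: GambleOption) -> float:
    return opt.p_win * opt.win - (1.0 - opt.p_win) * opt.lose


def option_sd(opt: GambleOption) -> float:
    """Outcome standard deviation of a two-outcome gamble."""
    return float(np.sqrt(opt.p_win * (1 - opt.p_win)) * (opt.win + opt.lose))


def gamble_expected_values(g: GambleSpec) -> Tuple[float, float]:
    return option_ev(g.safe_option), option_ev(g.risky_option)


def default_gambles() -> List[GambleSpec]:
    """The 10-gamble set.

    Gambles 9/10 point values are design defaults (equal-EV,
    valence-mirrored): low = certain -40 vs 50:50 {-80, 0}; high =
    certain +40 vs 50:50 {+80, 0}.
    """
    gambles = []
    safe_mixed = GambleOption(0.5, 10, 10)
    combos = itertools.product((0.6, 0.4), (30, 70), (30, 70))
    for gid, (p, win, lose) in enumerate(combos, start=1):
        gambles.append(GambleSpec(gid, "mixed", safe_mixed, GambleOption(p, win, lose)))
    gambles.append(GambleSpec(9, "low_reward",
                              GambleOption(0.0, 0, 40), GambleOption(0.5, 0, 80)))
    gambles.append(GambleSpec(10, "high_reward",
                              GambleOption(1.0, 40, 0), GambleOption(0.5, 80, 0)))
    return gambles


# ---------------------------------------------------------------------------
# Experience schedule
# ---------------------------------------------------------------------------


@dataclass
class ExperienceConfig:
    n_blocks: int = 4
    trials_per_block: int = 72
    p_context: float = 0.5
    p_mixed: float = 1 / 3
    p_forced: float = 1 / 6
    reset_after_blocks: int = 2
    max_attempts: int = 10_000

    def counts(self) -> Tuple[int, int, int]:
        """Per-block (context, mixed, forced) counts; must be exact integers."""
        tpb = self.trials_per_block
        n_ctx = self.p_context * tpb
        n_mix = self.p_mixed * tpb
        n_forced = self.p_forced * tpb
        counts = []
        for name, x in (("context", n_ctx), ("mixed", n_mix), ("forced", n_forced)):
            r = round(x)
            if abs(x - r) > 1e-9:
                raise ConfigurationError(
                    f"{name} proportion does not give an integer count per block "
                    f"({x:.3f} of {tpb} trials)")
            counts.append(r)
        n_ctx, n_mix, n_forced = counts
        if n_ctx % 2:
            raise ConfigurationError(
                f"context count per block must be even to split high/low, got {n_ctx}")
        if n_ctx + n_mix + n_forced != tpb:
            raise ConfigurationError(
                f"trial-type counts {counts} do not sum to {tpb} trials per block")
        return n_ctx, n_mix, n_forced


def _block_stimuli(config: ExperienceConfig, block: int,
                   sets: Tuple[List[StimulusSpec], List[StimulusSpec]]):
    set_id = 1 if block <= config.reset_after_blocks else 2
    return set_id, sets[set_id - 1]


def _build_block_trials(config: ExperienceConfig, stimuli: Sequence[StimulusSpec],
                        rng: np.random.Generator) -> List[dict]:
    n_ctx, n_mix, n_forced = config.counts()
    high = [s.id for s in stimuli if s.mean > np.mean([t.mean for t in stimuli])]
    low = [s.id for s in stimuli if s.id not in high]
    if len(high) != 2 or len(low) != 2:
        raise ConfigurationError("experience task requires two high- and two low-mean stimuli")
    trials: List[dict] = []
    for _ in range(n_ctx // 2):
        trials.append({"trial_type": "high_context", "offered": tuple(high)})
        trials.append({"trial_type": "low_context", "offered": tuple(low)})
    # mixed pairs: cycle the 2x2 cross so each pairing is equally frequent
    pairs = list(itertools.product(high, low))
    for k in range(n_mix):
        trials.append({"trial_type": "mixed", "offered": pairs[k % len(pairs)]})
    # forced: round-robin so every stimulus is sampled equally often
    order = [s.id for s in stimuli]
    for k in range(n_forced):
        trials.append({"trial_type": "forced", "offered": (order[k % len(order)],)})
    return trials


def _violates(prev: Optional[dict], cur: dict) -> bool:
    """Forced trial on X must not immediately precede a context trial offering X."""
    if prev is None or prev["trial_type"] != "forced":
        return False
    if cur["trial_type"] not in ("high_context", "low_context"):
        return False
    return prev["offered"][0] in cur["offered"]


def _arrange_block(trials: List[dict], prev_last: Optional[dict],
                   rng: np.random.Generator, max_attempts: int,
                   block: int) -> List[dict]:
    """Shuffle with local swap repair; rejection-resample as fallback."""
    attempts = 0
    order = list(trials)
    while attempts < max_attempts:
        rng.shuffle(order)
        ok = True
        for _ in range(10 * len(order)):
            bad = None
            for i in range(len(order)):
                prev = order[i - 1] if i > 0 else prev_last
                if _violates(prev, order[i]):
                    bad = i
                    break
            if bad is None:
                break
            j = int(rng.integers(len(order)))
            order[bad], order[j] = order[j], order[bad]
            attempts += 1
            if attempts >= max_attempts:
                break
        else:
            ok = False
        bad = any(
            _violates(order[i - 1] if i > 0 else prev_last, order[i])
            for i in range(len(order))
        )
        if ok and not bad:
            return order
        attempts += 1
    raise GenerationError(
        f"could not satisfy the forced-trial ordering constraint in block {block}")


def make_experience_schedule(
    config: Optional[ExperienceConfig] = None,
    seed: int = 0,
    stimulus_sets: Optional[Tuple[List[StimulusSpec], List[StimulusSpec]]] = None,
) -> pd.DataFrame:
    """Generate an (unchosen) experience-task schedule.

    Deterministic given ``seed``.  Columns: trial (1-based), block,
    stim_set, trial_type, option_left, option_right (empty string on
    forced trials).
    """
    config = config or ExperienceConfig()
    sets = stimulus_sets or default_stimulus_sets()
    rng = np.random.default_rng(seed)
    rows = []
    prev_last: Optional[dict] = None
    trial_no = 1
    for block in range(1, config.n_blocks + 1):
        set_id, stimuli = _block_stimuli(config, block, sets)
        trials = _build_block_trials(config, stimuli, rng)
        ordered = _arrange_block(trials, prev_last, rng, config.max_attempts, block)
        for tr in ordered:
            offered = list(tr["offered"])
            if len(offered) == 2 and rng.random() < 0.5:
                offered = offered[::-1]
            rows.append({
                "trial": trial_no,
                "block": block,
                "stim_set": set_id,
                "trial_type": tr["trial_type"],
                "option_left": offered[0],
                "option_right": offered[1] if len(offered) == 2 else "",
            })
            trial_no += 1
        prev_last = ordered[-1]
    return pd.DataFrame(rows)


def ordering_violations(schedule: pd.DataFrame) -> int:
    """Count forced->context same-stimulus adjacencies over the whole schedule."""
    count = 0
    rows = schedule.to_dict("records")
    for prev, cur in zip(rows, rows[1:]):
        if prev["trial_type"] != "forced":
            continue
        if cur["trial_type"] not in ("high_context", "low_context"):
            continue
        if prev["option_left"] in (cur["option_left"], cur["option_right"]):
            count += 1
    return count


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------


def quantize_reward(value: float) -> int:
    """Round to the nearest integer point and clip to the 0-100 display scale."""
    return int(np.clip(np.rint(value), REWARD_MIN, REWARD_MAX))


def sample_reward(stimulus: StimulusSpec, rng: np.random.Generator) -> int:
    """One reward draw from the stimulus distribution, quantized."""
    return quantize_reward(rng.normal(stimulus.mean, stimulus.sd))


@dataclass
class BlockRewards:
    """Pre-drawn per-stimulus reward sequences for one block.

    ``raw`` holds the standardized pre-rounding values (empirical mean
    and SD exactly equal to the stimulus spec); ``take`` delivers them
    in order, quantized to integer points.
    """

    raw: Dict[str, np.ndarray]
    _cursor: Dict[str, int] = field(default_factory=dict)

    def take(self, stimulus_id: str) -> int:
        i = self._cursor.get(stimulus_id, 0)
        seq = self.raw[stimulus_id]
        if i >= len(seq):
            raise RuntimeError(f"reward sequence exhausted for stimulus {stimulus_id}")
        self._cursor[stimulus_id] = i + 1
        return quantize_reward(seq[i])


def pregenerate_block_rewards(
    n_trials: int,
    stimuli: Sequence[StimulusSpec],
    seed: int | np.random.Generator,
) -> BlockRewards:
    """Draw and standardize one reward sequence per stimulus for a block.

    Each sequence is long enough to cover every possible selection in
    the block (one value per trial) and is affinely rescaled so its
    empirical mean and SD equal the stimulus spec exactly, implementing
    the "intended reward distribution per block" contract.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw: Dict[str, np.ndarray] = {}
    for st in stimuli:
        x = rng.normal(st.mean, st.sd, size=n_trials)
        if st.sd == 0 or n_trials < 2:
            x = np.full(n_trials, float(st.mean))
        else:
            sd = x.std(ddof=0)
            if sd == 0:  # astronomically unlikely; keep the draw centered
                x = np.full(n_trials, float(st.mean))
            else:
                x = (x - x.mean()) / sd * st.sd + st.mean
        raw[st.id] = x
    return BlockRewards(raw=raw)


# ---------------------------------------------------------------------------
# Description schedule
# ---------------------------------------------------------------------------


@dataclass
class DescriptionConfig:
    n_blocks: int = 4
    trials_per_block: int = 20


def make_description_schedule(
    config: Optional[DescriptionConfig] = None,
    seed: int = 0,
    gambles: Optional[List[GambleSpec]] = None,
) -> Tuple[pd.DataFrame, List[GambleSpec]]:
    """Generate the described-gamble schedule (order is a function of seed only).

    Every gamble appears equally often within every block, so the
    default 4 x 20 layout plays each of the 10 gambles 8 times with
    context trials (gambles 9-10) making up one fifth of trials.
    """
    config = config or DescriptionConfig()
    gambles = gambles if gambles is not None else default_gambles()
    n_g = len(gambles)
    per_block, rem = divmod(config.trials_per_block, n_g)
    if rem or per_block < 1:
        raise ConfigurationError(
            f"{config.trials_per_block} trials per block cannot repeat "
            f"{n_g} gambles a whole number of times")
    rng = np.random.default_rng(seed)
    rows = []
    trial_no = 1
    ids = [g.id for g in gambles]
    for block in range(1, config.n_blocks + 1):
        order = np.repeat(ids, per_block)
        rng.shuffle(order)
        for gid in order:
            rows.append({"trial": trial_no, "block": block, "gamble_id": int(gid)})
            trial_no += 1
    return pd.DataFrame(rows), gambles
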