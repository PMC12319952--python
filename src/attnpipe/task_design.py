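"""Experimental design: dot-field composition, trial schedules, adaptive staircases.

The task is single-interval detection of a color-coherence signal: a field of
240 colored dots drawn from 5 of 7 possible colors. A *noise* field contains
48 dots of each color (proportion 0.2 per color); a *target* field
over-represents one color. Coherence is the proportion P_t of the
over-represented color, related to the equal proportion P_n of each of the
four other colors by

    coherence = P_t = 1 - 4 * P_n

so coherence 0.2 is pure noise (P_t = P_n = 0.2) and 1.0 is a single-color
field. Before each stimulus, 0-3 color cues indicate which color(s) may carry
the coherence signal.

Three schedulers mirror the experiment's three phases:

* threshold session — 7 interleaved 2-down-1-up staircases, one per color,
  over 5 runs of 84 trials (60 trials per staircase);
* practice session — no/one/two/three-cue conditions blocked, 8 blocks of 84
  trials (168 trials per condition: 126 target + 42 noise);
* EEG session — alternating one-cue and two-cue blocks, 10 blocks of 84
  trials (per condition: 315 target = 45 per color, 105 noise = 15 per color),
  cue-to-stimulus interval jittered in [0.8, 1.1] s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import PALETTE

CUE_CONDITIONS = ("no", "one", "two", "three")
N_CUES = {"no": 0, "one": 1, "two": 2, "three": 3}

#: Stimulus timing (seconds).
CUE_DURATION = 0.5
STIM_DURATION = 0.15
RESPONSE_WINDOW = 1.5
ITI_RANGE = (1.0, 1.5)
PRACTICE_CUE_TO_STIM = 0.8
EEG_JITTER_RANGE = (0.8, 1.1)

#: Coherence of a pure-noise field (every proportion equals 0.2).
NOISE_COHERENCE = 0.2

#: Group-mean coherence threshold used as the default per-color signal level.
DEFAULT_THRESHOLD = 0.44


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotFieldSpec:
    """Composition of one dot-field frame."""

    colors: tuple[str, ...]          # the 5 displayed colors
    counts: tuple[int, ...]          # dots per color, same order
    n_dots: int
    target_color: str | None
    coherence: float                 # P_t, in [0.2, 1]
    is_target: bool

    def __post_init__(self) -> None:
        if len(self.colors) != 5 or len(set(self.colors)) != 5:
            raise ValueError("a dot field shows exactly 5 distinct colors")
        if sum(self.counts) != self.n_dots:
            raise ValueError("dot counts must sum to n_dots")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the cued detection task."""

    block_index: int
    cue_condition: str               # no | one | two | three
    cued_colors: tuple[str, ...]     # ordered; first entry is the target cue
    target_color: str
    is_target: bool
    display_colors: frozenset[str]
    coherence: float                 # P_t on target trials, 0.2 on noise trials
    cue_to_stim_interval: float      # seconds between cue offset and stimulus
    cue_positions: tuple[float, ...]  # angles (deg) on the 1.5-deg cue circle
    onset: float                     # cue onset, seconds from record start

    def __post_init__(self) -> None:
        if self.cue_condition != "no" and self.target_color not in self.cued_colors:
            raise ValueError("target color must be cued on cued trials")
        if len(self.display_colors) != 5:
            raise ValueError("display must contain 5 colors")
        if self.target_color not in self.display_colors:
            raise ValueError("target color must appear in the display")
        nontarget_cues = set(self.cued_colors) - {self.target_color}
        if nontarget_cues & self.display_colors:
            raise ValueError("cued but non-target colors cannot be displayed")

    @property
    def stim_onset(self) -> float:
        return self.onset + CUE_DURATION + self.cue_to_stim_interval


@dataclass
class TrialSchedule:
    """Ordered trial records plus tabular (TSV) round-trip."""

    trials: list[TrialRecord]
    session: str = "unknown"

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def subset(self, predicate: Callable[[TrialRecord], bool]) -> "TrialSchedule":
        return TrialSchedule([t for t in self.trials if predicate(t)], self.session)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "onset": t.onset,
                "block": t.block_index,
                "cue_condition": t.cue_condition,
                "cued_colors": ",".join(t.cued_colors),
                "target_color": t.target_color,
                "is_target": int(t.is_target),
                "display_colors": ",".join(sorted(t.display_colors)),
                "coherence": t.coherence,
                "jitter": t.cue_to_stim_interval,
                "cue_positions": ",".join(f"{a:.3f}" for a in t.cue_positions),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, session: str = "unknown") -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t")
        trials = []
        for _, r in df.iterrows():
            cued = tuple(str(r["cued_colors"]).split(",")) if str(r["cued_colors"]) not in ("", "nan") else ()
            pos = tuple(float(x) for x in str(r["cue_positions"]).split(",")) if str(r["cue_positions"]) not in ("", "nan") else ()
            trials.append(TrialRecord(
                block_index=int(r["block"]),
                cue_condition=str(r["cue_condition"]),
                cued_colors=cued,
                target_color=str(r["target_color"]),
                is_target=bool(int(r["is_target"])),
                display_colors=frozenset(str(r["display_colors"]).split(",")),
                coherence=float(r["coherence"]),
                cue_to_stim_interval=float(r["jitter"]),
                cue_positions=pos,
                onset=float(r["onset"]),
            ))
        return cls(trials, session)


# ---------------------------------------------------------------------------
# Dot-field composition
# ---------------------------------------------------------------------------

def compose_dot_field(
    target_color: str,
    coherence: float,
    display_colors: Iterable[str],
    n_dots: int = 240,
) -> DotFieldSpec:
    """Integer dot counts realizing a coherence level.

    The target color receives a proportion ``coherence`` of the ``n_dots``
    dots and each of the four non-target colors receives (1 - coherence) / 4.
    Non-integer ideal counts are resolved by largest-remainder apportionment
    (floor everything, then hand out the leftover dots in order of fractional
    part, target first on ties) so the counts always sum to ``n_dots``.
    """
    display = tuple(display_colors)
    if not (NOISE_COHERENCE <= coherence <= 1.0):
        raise ValueError(f"coherence must lie in [0.2, 1], got {coherence}")
    if target_color not in display:
        raise ValueError(f"target color {target_color!r} not among display colors")
    if n_dots < 5:
        raise ValueError("need at least 5 dots")
    if len(display) != 5 or len(set(display)) != 5:
        raise ValueError("display must contain exactly 5 distinct colors")

    # order: target first, then remaining display colors in given order
    ordered = (target_color,) + tuple(c for c in display if c != target_color)
    p_n = (1.0 - coherence) / 4.0
    ideal = np.array([coherence * n_dots] + [p_n * n_dots] * 4)
    counts = np.floor(ideal + 1e-9).astype(int)
    remainder = n_dots - counts.sum()
    # largest fractional part first; ties broken by position (target first)
    frac = ideal - np.floor(ideal + 1e-9)
    order = np.argsort(-frac, kind="stable")
    for i in range(remainder):
        counts[order[i % 5]] += 1
    is_target = coherence > NOISE_COHERENCE
    return DotFieldSpec(
        colors=ordered,
        counts=tuple(int(c) for c in counts),
        n_dots=n_dots,
        target_color=target_color if is_target else None,
        coherence=coherence,
        is_target=is_target,
    )


def select_display_colors(
    cued_colors: Iterable[str],
    target_color: str,
    palette: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> frozenset[str]:
    """Choose the 5 display colors for a trial.

    The display always contains the target color plus 4 colors drawn without
    replacement from the palette, excluding every cued color — cued but
    non-target colors never appear in the display.
    """
    palette = PALETTE if palette is None else list(palette)
    rng = np.random.default_rng() if rng is None else rng
    cued = set(cued_colors)
    if len(palette) != 7 or len(set(palette)) != 7:
        raise ValueError("palette must contain 7 distinct colors")
    if cued and target_color not in cued:
        raise ValueError("target color must be one of the cued colors")
    pool = sorted((set(palette) - cued) - {target_color})
    if len(pool) < 4:
        raise ValueError("fewer than 4 eligible non-target colors")
    chosen = rng.choice(pool, size=4, replace=False)
    return frozenset({target_color} | set(chosen))


def _cue_positions(n_cues: int, rng: np.random.Generator) -> tuple[float, ...]:
    """Cue angles: random rotation, maximal angular separation (metadata only)."""
    if n_cues == 0:
        return ()
    rot = float(rng.uniform(0.0, 360.0))
    sep = 360.0 / n_cues
    return tuple((rot + i * sep) % 360.0 for i in range(n_cues))


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _make_trial(
    block: int,
    condition: str,
    is_target: bool,
    onset: float,
    jitter: float,
    rng: np.random.Generator,
    thresholds: Mapping[str, float],
    target_color: str | None = None,
) -> TrialRecord:
    n_cues = N_CUES[condition]
    if target_color is None:
        target_color = str(rng.choice(PALETTE))
    if n_cues == 0:
        cued: tuple[str, ...] = ()
    else:
        others = rng.choice(sorted(set(PALETTE) - {target_color}),
                            size=n_cues - 1, replace=False)
        cued = (target_color,) + tuple(str(c) for c in others)
    display = select_display_colors(cued, target_color, rng=rng)
    coherence = float(thresholds[target_color]) if is_target else NOISE_COHERENCE
    return TrialRecord(
        block_index=block,
        cue_condition=condition,
        cued_colors=cued,
        target_color=target_color,
        is_target=is_target,
        display_colors=display,
        coherence=coherence,
        cue_to_stim_interval=jitter,
        cue_positions=_cue_positions(n_cues, rng),
        onset=onset,
    )


def _trial_span(jitter: float, rng: np.random.Generator) -> float:
    iti = float(rng.uniform(*ITI_RANGE))
    return CUE_DURATION + jitter + STIM_DURATION + RESPONSE_WINDOW + iti


def build_practice_schedule(
    rng: np.random.Generator,
    thresholds: Mapping[str, float] | None = None,
) -> TrialSchedule:
    """Practice session: 2 superblocks x random order of 4 block types x 84 trials.

    Each cue condition fills exactly 2 blocks (168 trials), each block 75%
    target / 25% noise (126 target + 42 noise per condition). Cue-to-stimulus
    interval fixed at 0.8 s.
    """
    thresholds = dict.fromkeys(PALETTE, DEFAULT_THRESHOLD) if thresholds is None else thresholds
    block_types: list[str] = []
    for _ in range(2):
        block_types.extend(rng.permutation(CUE_CONDITIONS))
    trials: list[TrialRecord] = []
    onset = 5.0
    for block, condition in enumerate(block_types):
        flags = np.array([True] * 63 + [False] * 21)
        rng.shuffle(flags)
        for is_target in flags:
            trials.append(_make_trial(block, condition, bool(is_target), onset,
                                      PRACTICE_CUE_TO_STIM, rng, thresholds))
            onset += _trial_span(PRACTICE_CUE_TO_STIM, rng)
        onset += 2.0  # inter-block pause
    return TrialSchedule(trials, session="practice")


def build_eeg_schedule(
    rng: np.random.Generator,
    thresholds: Mapping[str, float] | None = None,
    conditions: Sequence[str] = ("one", "two"),
    n_blocks_per_cond: int = 5,
) -> TrialSchedule:
    """EEG session: 10 alternating one-cue/two-cue blocks of 84 trials.

    Per condition the color marginals are exact: 45 target and 15 noise trials
    per color (315 target + 105 noise), realized as 9 target + 3 noise per
    color per block. The cue-to-stimulus interval is drawn uniformly from
    [0.8, 1.1] s on every trial.
    """
    thresholds = dict.fromkeys(PALETTE, DEFAULT_THRESHOLD) if thresholds is None else thresholds
    order: list[str] = []
    first = conditions[int(rng.integers(len(conditions)))] if len(conditions) > 1 else conditions[0]
    second = [c for c in conditions if c != first]
    for i in range(n_blocks_per_cond * len(conditions)):
        if len(conditions) == 1:
            order.append(conditions[0])
        else:
            order.append(first if i % 2 == 0 else second[0])
    trials: list[TrialRecord] = []
    onset = 5.0
    for block, condition in enumerate(order):
        per_block: list[tuple[str, bool]] = []
        for color in PALETTE:
            per_block += [(color, True)] * 9 + [(color, False)] * 3
        idx = rng.permutation(len(per_block))
        for i in idx:
            color, is_target = per_block[i]
            jitter = float(rng.uniform(*EEG_JITTER_RANGE))
            trials.append(_make_trial(block, condition, is_target, onset,
                                      jitter, rng, thresholds, target_color=color))
            onset += _trial_span(jitter, rng)
        onset += 2.0
    return TrialSchedule(trials, session="eeg")


# ---------------------------------------------------------------------------
# Adaptive staircase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseState:
    """State of one 2-down-1-up staircase.

    Two consecutive correct responses lower coherence by one step; any error
    raises it by one step. This rule converges on the stimulus level yielding
    sqrt(0.5) ~ 70.7% correct. Coherence is clamped to (0.2, 1.0]: the lower
    clamp is 0.2 + step because 0.2 is pure noise.
    """

    coherence: float
    step: float = 0.04
    consecutive_correct: int = 0
    n_trials: int = 0
    n_reversals: int = 0
    history: tuple[tuple[float, bool], ...] = ()
    reversal_levels: tuple[float, ...] = ()
    last_direction: int = 0  # +1 up, -1 down, 0 none yet


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance a 2-down-1-up staircase by one (target-trial) response."""
    history = state.history + ((state.coherence, bool(correct)),)
    coherence = state.coherence
    n_rev = state.n_reversals
    rev_levels = state.reversal_levels
    last_dir = state.last_direction

    if correct:
        cc = state.consecutive_correct + 1
        if cc >= 2:
            direction = -1
            new_coh = max(NOISE_COHERENCE + state.step, coherence - state.step)
            if last_dir == +1:
                n_rev += 1
                rev_levels = rev_levels + (coherence,)
            coherence, cc, last_dir = new_coh, 0, direction
    else:
        cc = 0
        direction = +1
        new_coh = min(1.0, coherence + state.step)
        if last_dir == -1:
            n_rev += 1
            rev_levels = rev_levels + (coherence,)
        coherence, last_dir = new_coh, direction

    return replace(
        state,
        coherence=coherence,
        consecutive_correct=cc,
        n_trials=state.n_trials + 1,
        n_reversals=n_rev,
        history=history,
        reversal_levels=rev_levels,
        last_direction=last_dir,
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    color: str
    threshold: float
    converged: bool
    n_reversals: int
    final_state: StaircaseState


def run_threshold_session(
    observer: Callable[[str, float], float],
    rng: np.random.Generator,
    n_runs: int = 5,
    trials_per_run: int = 84,
    step: float = 0.04,
    start: float = 0.8,
    average_last_reversals: int = 4,
) -> dict[str, ThresholdEstimate]:
    """Seven interleaved per-color staircases over ``n_runs`` x ``trials_per_run``.

    Each run assigns trials_per_run / 7 trials to each color (75% target, 25%
    noise), giving 60 trials per staircase under the defaults. ``observer``
    maps (color, coherence) to P(correct) on target trials; noise trials carry
    no coherence level and do not update the staircase. The threshold is the
    mean of the last ``average_last_reversals`` reversal coherences, which
    discards the initial descent from the starting level. A staircase whose
    level pins at the 1.0 ceiling is flagged non-converged (the
    participant-exclusion rule).
    """
    per_color = trials_per_run // len(PALETTE)
    n_target = round(per_color * 0.75)
    n_noise = per_color - n_target
    states = {c: StaircaseState(coherence=start, step=step) for c in PALETTE}
    ceiling_hits = dict.fromkeys(PALETTE, 0)

    for _ in range(n_runs):
        trial_list: list[tuple[str, bool]] = []
        for color in PALETTE:
            trial_list += [(color, True)] * n_target + [(color, False)] * n_noise
        for i in rng.permutation(len(trial_list)):
            color, is_target = trial_list[i]
            if is_target:
                p = float(observer(color, states[color].coherence))
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"observer returned probability {p} outside [0, 1]")
                correct = bool(rng.random() < p)
                states[color] = staircase_update(states[color], correct)
                if states[color].coherence >= 1.0 - 1e-12:
                    ceiling_hits[color] += 1
            else:
                rng.random()  # noise trial: response simulated, no update

    out: dict[str, ThresholdEstimate] = {}
    for color, st in states.items():
        levels = st.reversal_levels[-average_last_reversals:]
        pinned = ceiling_hits[color] >= 5 or st.coherence >= 1.0 - 1e-12
        threshold = float(np.mean(levels)) if levels else st.coherence
        out[color] = ThresholdEstimate(
            color=color,
            threshold=threshold,
            converged=not pinned and len(levels) > 0,
            n_reversals=st.n_reversals,
            final_state=st,
        )
    return out


def two_down_one_up_convergence_point(
    p_correct: Callable[[float], float],
    lo: float = NOISE_COHERENCE,
    hi: float = 1.0,
) -> float:
    """Coherence at which a monotone psychometric function crosses sqrt(0.5).

    Bisection; independent of the staircase machinery, used as an oracle for
    staircase convergence.
    """
    target = math.sqrt(0.5)
    f_lo, f_hi = p_correct(lo) - target, p_correct(hi) - target
    if f_lo * f_hi > 0:
        raise ValueError("psychometric function does not cross 70.7% in range")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if (p_correct(mid) - target) * f_lo <= 0:
            hi = mid
        else:
            lo, f_lo = mid, p_correct(mid) - target
    return 0.5 * (lo + hi)
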