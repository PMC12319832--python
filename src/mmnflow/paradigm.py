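"""Oddball-with-volatility paradigm: probability schedules, tone sequences,
standard/deviant trial labels and stable/volatile phase masks.

The paradigm presents a long sequence of binary tones (1 = high 528 Hz,
0 = low 440 Hz) whose generative probability ``p_high`` is piecewise
constant. Periods where ``p_high`` stays constant for at least
``stable_min_len`` trials (default 90) are *stable*; everything else is
*volatile*. Trial types follow local run structure: a *deviant* follows at
least 5 repetitions of the other tone, a *standard* is exactly the 6th
consecutive repetition of the same tone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToneSchedule",
    "ToneSequence",
    "TrialLabels",
    "make_schedule",
    "default_schedule",
    "sample_sequence",
    "label_trials",
    "phase_crosstab",
    "read_design_tsv",
    "write_design_tsv",
]

STABLE_MIN_LEN = 90


@dataclass(frozen=True)
class ToneSchedule:
    """Generative schedule: per-trial probability of the high tone and phase.

    Phase labels live on the schedule (they are a property of the generative
    probability, not of the realised draws).
    """

    p_high: np.ndarray          # (n_trials,) float in [0, 1]
    phase: np.ndarray           # (n_trials,) str, "stable" | "volatile"
    segment_bounds: np.ndarray  # 0-based trial indices where p_high changes

    @property
    def n_trials(self) -> int:
        return self.p_high.shape[0]

    def __post_init__(self):
        if self.p_high.shape != self.phase.shape:
            raise ValueError("p_high and phase must have equal length")
        if np.any((self.p_high < 0) | (self.p_high > 1)):
            raise ValueError("p_high values must lie in [0, 1]")


@dataclass(frozen=True)
class ToneSequence:
    """A realised binary tone sequence drawn from a :class:`ToneSchedule`."""

    u: np.ndarray  # (n_trials,) int in {0, 1}
    seed: int | None = None

    def __post_init__(self):
        if not np.isin(self.u, (0, 1)).all():
            raise ValueError("tone identities must be binary (0/1)")

    def __len__(self) -> int:
        return self.u.shape[0]


@dataclass(frozen=True)
class TrialLabels:
    """Per-trial type ('standard' | 'deviant' | 'other') and phase."""

    trial_type: np.ndarray
    phase: np.ndarray


def make_schedule(
    segments: Sequence[tuple[int, float]],
    stable_min_len: int = STABLE_MIN_LEN,
) -> ToneSchedule:
    """Build a piecewise-constant probability schedule.

    Parameters
    ----------
    segments
        Sequence of ``(length, p_high)`` pairs. Lengths must be positive and
        probabilities in [0, 1]. Adjacent segments with equal probability are
        merged before phase labelling, since stability is defined by maximal
        runs of constant probability.
    stable_min_len
        Minimum length (in trials) of a constant-probability run for its
        trials to be labelled stable.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("schedule needs at least one segment")
    lengths = np.array([s[0] for s in segments], dtype=int)
    probs = np.array([s[1] for s in segments], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("segment probabilities must lie in [0, 1]")

    p_high = np.repeat(probs, lengths)
    # maximal runs of constant probability (merges equal adjacent segments)
    change = np.flatnonzero(np.diff(p_high) != 0) + 1
    bounds = np.concatenate(([0], change, [p_high.size]))
    phase = np.empty(p_high.size, dtype=object)
    for a, b in zip(bounds[:-1], bounds[1:]):
        phase[a:b] = "stable" if (b - a) >= stable_min_len else "volatile"
    return ToneSchedule(p_high=p_high, phase=phase.astype("U8"),
                        segment_bounds=bounds[1:-1].copy())


def default_schedule(n_trials: int = 1800,
                     stable_min_len: int = STABLE_MIN_LEN) -> ToneSchedule:
    """Template volatility schedule.

    Long high/low-probability blocks (>= ``stable_min_len`` trials, so they
    are stable by construction) alternate with short volatile stretches
    (paired sub-``stable_min_len`` segments whose probability changes
    rapidly and averages about 0.5), totalling ``n_trials``. The pattern
    composes for any ``n_trials`` >= ``stable_min_len``; a deposited design
    TSV can be loaded instead via :func:`read_design_tsv`.
    """
    if n_trials < stable_min_len:
        raise ValueError(
            f"n_trials must be at least stable_min_len ({stable_min_len})")
    stable_len = max(120, stable_min_len)
    stable_ps = [0.90, 0.10, 0.85, 0.15]
    # volatile block: rapid switches between extreme probabilities, with a
    # short stochastic (p ~ 0.5) stretch; every segment < 90 trials
    vol_blocks = [
        [(25, 0.15), (30, 0.80), (20, 0.50), (15, 0.85)],
        [(30, 0.85), (25, 0.20), (20, 0.50), (15, 0.10)],
        [(25, 0.80), (30, 0.10), (20, 0.50), (15, 0.90)],
        [(30, 0.20), (25, 0.85), (20, 0.50), (15, 0.15)],
    ]
    vol_len = 90
    segments: list[tuple[int, float]] = []
    remaining, i = n_trials, 0
    while remaining > 0:
        if remaining < stable_len + vol_len:
            if remaining >= stable_min_len:
                segments.append((remaining, stable_ps[i % len(stable_ps)]))
            else:  # short tail: volatile stochastic stretch
                segments.append((remaining, 0.5))
            break
        segments.append((stable_len, stable_ps[i % len(stable_ps)]))
        segments.extend(vol_blocks[i % len(vol_blocks)])
        remaining -= stable_len + vol_len
        i += 1
    return make_schedule(segments, stable_min_len=stable_min_len)


def sample_sequence(schedule: ToneSchedule, seed: int) -> ToneSequence:
    """Draw tones independently: ``u(k) ~ Bernoulli(p_high(k))``."""
    rng = np.random.default_rng(seed)
    u = (rng.random(schedule.n_trials) < schedule.p_high).astype(np.int8)
    return ToneSequence(u=u, seed=seed)


def label_trials(seq: ToneSequence | np.ndarray) -> TrialLabels:
    """Label each trial standard / deviant / other from local run structure.

    A trial is *deviant* iff its tone differs from its predecessor and the
    preceding >= 5 trials were all that other tone. A trial is *standard* iff
    it is exactly the 6th consecutive occurrence of the same tone (the 7th and
    later repetitions are 'other'). The first 5 trials are never standard or
    deviant.
    """
    u = seq.u if isinstance(seq, ToneSequence) else np.asarray(seq)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("tone identities must be binary (0/1)")
    n = u.shape[0]
    trial_type = np.full(n, "other", dtype="U8")
    run = 1  # length of the run of identical tones ending at trial k
    for k in range(1, n):
        prev_run = run
        if u[k] == u[k - 1]:
            run += 1
            if run == 6:
                trial_type[k] = "standard"
        else:
            if prev_run >= 5:
                trial_type[k] = "deviant"
            run = 1
    return TrialLabels(trial_type=trial_type, phase=np.full(n, "", dtype="U8"))


def attach_phase(labels: TrialLabels, schedule: ToneSchedule) -> TrialLabels:
    if labels.trial_type.shape[0] != schedule.n_trials:
        raise ValueError("labels and schedule lengths differ")
    return TrialLabels(trial_type=labels.trial_type.copy(),
                       phase=schedule.phase.copy())


def phase_crosstab(labels: TrialLabels, schedule: ToneSchedule) -> pd.DataFrame:
    """Cross-tabulate trial_type x phase (counts)."""
    if labels.trial_type.shape[0] != schedule.n_trials:
        raise ValueError("labels and schedule lengths differ")
    df = pd.DataFrame({"trial_type": labels.trial_type,
                       "phase": schedule.phase})
    tab = pd.crosstab(df["trial_type"], df["phase"])
    for tt in ("standard", "deviant", "other"):
        if tt not in tab.index:
            tab.loc[tt] = 0
    for ph in ("stable", "volatile"):
        if ph not in tab.columns:
            tab[ph] = 0
    return tab.loc[["standard", "deviant", "other"], ["stable", "volatile"]]


def write_design_tsv(path, schedule: ToneSchedule, seq: ToneSequence) -> None:
    """Write a design table: trial (1-based), tone, p_high, phase."""
    pd.DataFrame({
        "trial": np.arange(1, schedule.n_trials + 1),
        "tone": seq.u.astype(int),
        "p_high": schedule.p_high,
        "phase": schedule.phase,
    }).to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> tuple[ToneSchedule, ToneSequence]:
    """Load a design TSV (columns: trial, tone, p_high, phase).

    Accepts a deposited design file when the columns map; phase labels are
    taken from the file as-is (they are part of the design).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"trial", "tone", "p_high", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file missing columns: {sorted(missing)}")
    df = df.sort_values("trial")
    p = df["p_high"].to_numpy(float)
    change = np.flatnonzero(np.diff(p) != 0) + 1
    sched = ToneSchedule(p_high=p,
                         phase=df["phase"].to_numpy(str).astype("U8"),
                         segment_bounds=change)
    seq = ToneSequence(u=df["tone"].to_numpy(int).astype(np.int8))
    return sched, seq
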