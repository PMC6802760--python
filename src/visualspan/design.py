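"""Experimental design and trial scoring for the trigram character-recognition task.

The task presents three-character strings (trigrams) briefly at varying
horizontal eccentricities around fixation while the participant reports all
three characters. Each character's correctness is scored at the character
position it occupied, and per-position percent-correct profiles ("visual-span
profiles") are accumulated per participant and pattern-complexity level.

Positions are integers: 0 is fixation, negative is left of fixation, positive
is right; adjacent positions are one character width (~1 degree) apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteProfileError, InvalidTrialError

AGE_GROUPS = ("young", "older")
COMPLEXITY_LEVELS = ("low", "medium", "high")
ROLES = ("first", "middle", "last")
#: offset of each trigram role from the trigram's center position
ROLE_OFFSETS = {"first": -1, "middle": 0, "last": 1}

#: canonical column order for trial tables (response columns are optional)
TRIAL_COLUMNS = [
    "participant_id", "age_group", "complexity", "block", "center",
    "stim1", "stim2", "stim3", "correct1", "correct2", "correct3",
]


@dataclass(frozen=True)
class SessionDesign:
    """Parameters of one participant's trigram session.

    Parameters
    ----------
    center_positions
        Trigram center positions, symmetric about 0 and contiguous.
    n_complexity_levels, blocks_per_level, reps_per_center_per_block
        Factorial structure: each complexity level is run in
        ``blocks_per_level`` blocks, and within a block every center appears
        ``reps_per_center_per_block`` times.
    set_size
        Number of characters in each complexity-matched stimulus set.
    scored_range
        Inclusive interval of positions at which accuracy is assessed;
        characters falling outside it are shown but not scored.
    """

    center_positions: tuple[int, ...] = tuple(range(-8, 9))
    n_complexity_levels: int = 3
    blocks_per_level: int = 3
    reps_per_center_per_block: int = 3
    set_size: int = 26
    scored_range: tuple[int, int] = (-7, 7)

    def __post_init__(self) -> None:
        centers = self.center_positions
        if len(centers) < 1:
            raise ValueError("center_positions must be non-empty")
        if sorted(centers) != list(range(min(centers), max(centers) + 1)):
            raise ValueError("center_positions must be contiguous integers")
        if min(centers) != -max(centers):
            raise ValueError("center_positions must be symmetric about 0")
        if self.set_size < 2:
            raise ValueError("set_size must be at least 2")
        lo, hi = self.scored_range
        if lo > hi:
            raise ValueError("scored_range must be an ordered interval")

    @property
    def trials_per_participant(self) -> int:
        return (len(self.center_positions) * self.n_complexity_levels
                * self.blocks_per_level * self.reps_per_center_per_block)

    @property
    def scored_positions(self) -> np.ndarray:
        lo, hi = self.scored_range
        return np.arange(lo, hi + 1)

    @property
    def displayed_positions(self) -> np.ndarray:
        """All positions at which any character is displayed."""
        return np.arange(min(self.center_positions) - 1,
                         max(self.center_positions) + 2)

    def coverage(self) -> dict[int, list[tuple[int, str]]]:
        """Map each scored position to the (center, role) pairs covering it."""
        cov: dict[int, list[tuple[int, str]]] = {
            int(x): [] for x in self.scored_positions}
        for c in self.center_positions:
            for role, off in ROLE_OFFSETS.items():
                x = c + off
                if x in cov:
                    cov[x].append((c, role))
        return cov

    def expected_obs_per_position(self) -> int:
        """Scored observations per position per complexity under balance."""
        n_centers_covering = 3  # first/middle/last of three adjacent centers
        return (n_centers_covering * self.blocks_per_level
                * self.reps_per_center_per_block)


def default_design() -> SessionDesign:
    """The standard session: 17 centers x 3 complexities x 3 blocks x 3 reps.

    459 trials per participant; characters appear at positions -9..+9 but
    accuracy is scored only at -7..+7.
    """
    return SessionDesign()


@dataclass(frozen=True)
class TrigramTrial:
    """One trigram presentation with per-character correctness."""

    participant_id: str
    age_group: str
    complexity: str
    block_index: int
    center: int
    stimulus: tuple[int, int, int]
    correct: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if len(set(self.stimulus)) != 3:
            raise InvalidTrialError(
                f"stimulus characters must be distinct, got {self.stimulus}")


@dataclass(frozen=True)
class PositionScore:
    """Binary correctness of one character at one scored position."""

    position: int
    score: int
    role: str


@dataclass
class SpanProfile:
    """Percent-correct by position for one participant x complexity."""

    participant_id: str
    age_group: str
    complexity: str
    positions: np.ndarray
    accuracy: np.ndarray  # percent, aligned with positions
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if not (len(self.positions) == len(self.accuracy) == len(self.n_obs)):
            raise ValueError("profile arrays must be aligned")
        if np.any((self.accuracy < 0) | (self.accuracy > 100)):
            raise ValueError("accuracy must lie in [0, 100] percent")
        if np.any(self.n_obs < 1):
            raise ValueError("every scored position needs >= 1 observation")

    def accuracy_at(self, position: int) -> float:
        idx = np.flatnonzero(self.positions == position)
        if idx.size == 0:
            raise KeyError(position)
        return float(self.accuracy[idx[0]])


def score_trial(trial: TrigramTrial, design: SessionDesign) -> list[PositionScore]:
    """Score one trial: one PositionScore per character inside the scored range.

    The first character sits at center-1, the middle at center, the last at
    center+1; characters landing outside ``design.scored_range`` are dropped.
    """
    if trial.center not in design.center_positions:
        raise InvalidTrialError(
            f"trial center {trial.center} is not a design center position")
    lo, hi = design.scored_range
    out = []
    for role, flag in zip(ROLES, trial.correct):
        x = trial.center + ROLE_OFFSETS[role]
        if lo <= x <= hi:
            out.append(PositionScore(position=x, score=int(bool(flag)), role=role))
    return out


def _require_trial_frame(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise InvalidTrialError(f"trial table missing columns: {missing}")


def score_trials(trials: pd.DataFrame, design: SessionDesign) -> pd.DataFrame:
    """Vectorised scoring of a trial table.

    Returns a long table with one row per scored character:
    participant_id, age_group, complexity, position, role, score.
    """
    _require_trial_frame(trials)
    bad = ~trials["center"].isin(design.center_positions)
    if bad.any():
        rows = trials.index[bad].tolist()[:5]
        raise InvalidTrialError(
            f"trials with centers outside the design at rows {rows}")
    lo, hi = design.scored_range
    parts = []
    for role, col in zip(ROLES, ("correct1", "correct2", "correct3")):
        pos = trials["center"].to_numpy() + ROLE_OFFSETS[role]
        keep = (pos >= lo) & (pos <= hi)
        part = trials.loc[keep, ["participant_id", "age_group", "complexity"]].copy()
        part["position"] = pos[keep]
        part["role"] = role
        part["score"] = trials.loc[keep, col].astype(bool).astype(int).to_numpy()
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def build_profiles(trials: pd.DataFrame, design: SessionDesign) -> list[SpanProfile]:
    """Accumulate per-position accuracy profiles per participant x complexity.

    Raises
    ------
    IncompleteProfileError
        If any scored position has zero observations for some cell (including
        the degenerate empty-input case).
    """
    if len(trials) == 0:
        raise IncompleteProfileError("no trials: every scored position is empty")
    scores = score_trials(trials, design)
    positions = design.scored_positions
    profiles = []
    grouped = scores.groupby(["participant_id", "complexity"], sort=True)
    for (pid, comp), grp in grouped:
        counts = grp.groupby("position")["score"].agg(["sum", "count"])
        missing = [int(x) for x in positions if x not in counts.index]
        if missing:
            raise IncompleteProfileError(
                f"participant {pid!r}, complexity {comp!r}: no observations "
                f"at position(s) {missing}")
        counts = counts.reindex(positions)
        profiles.append(SpanProfile(
            participant_id=str(pid),
            age_group=str(grp["age_group"].iloc[0]),
            complexity=str(comp),
            positions=positions.copy(),
            accuracy=100.0 * counts["sum"].to_numpy() / counts["count"].to_numpy(),
            n_obs=counts["count"].to_numpy(),
        ))
    return profiles


def profiles_to_frame(profiles: Iterable[SpanProfile]) -> pd.DataFrame:
    """Tidy long-format view of profiles (one row per position)."""
    rows = []
    for p in profiles:
        for x, acc, n in zip(p.positions, p.accuracy, p.n_obs):
            rows.append((p.participant_id, p.age_group, p.complexity,
                         int(x), int(n), float(acc)))
    return pd.DataFrame(rows, columns=[
        "participant_id", "age_group", "complexity",
        "position", "n_obs", "accuracy_pct"])


def profiles_from_frame(frame: pd.DataFrame) -> list[SpanProfile]:
    profiles = []
    for (pid, comp), grp in frame.groupby(["participant_id", "complexity"], sort=True):
        grp = grp.sort_values("position")
        profiles.append(SpanProfile(
            participant_id=str(pid),
            age_group=str(grp["age_group"].iloc[0]),
            complexity=str(comp),
            positions=grp["position"].to_numpy(),
            accuracy=grp["accuracy_pct"].to_numpy(),
            n_obs=grp["n_obs"].to_numpy(),
        ))
    return profiles


def center_role_accuracy(trials: pd.DataFrame, design: SessionDesign) -> pd.DataFrame:
    """Accuracy at fixation (position 0) by trigram role x complexity x age group.

    Only the three centers -1, 0, +1 place a character at position 0; this
    table separates crowded (middle) from partially-flanked (first/last)
    presentations at fixation. Cells with no observations get NaN accuracy and
    n = 0, never 0%.
    """
    scores = score_trials(trials, design)
    at0 = scores[scores["position"] == 0]
    agg = at0.groupby(["age_group", "complexity", "role"])["score"].agg(
        n="count", accuracy_pct=lambda s: 100.0 * s.mean())
    groups = sorted(trials["age_group"].unique())
    comps = sorted(trials["complexity"].unique())
    full = pd.MultiIndex.from_product(
        [groups, comps, list(ROLES)],
        names=["age_group", "complexity", "role"])
    agg = agg.reindex(full)
    agg["n"] = agg["n"].fillna(0).astype(int)
    return agg.reset_index()
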