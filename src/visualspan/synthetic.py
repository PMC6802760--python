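"""Synthetic trigram-session and reading-record generator.

Real participant data for this paradigm is rarely shared, so the generator
produces trial-level data with the statistical structure the analysis
assumes, letting every pipeline stage be exercised end to end and letting
recovery of known ground truth be measured.

The latent model for one participant and complexity level is an asymmetric
Gaussian accuracy function over character position x:

    base(x) = chance + (peak - chance) * exp(-(x - shift)^2 / (2 sigma(x)^2))

with sigma = sigma_left for x < shift and sigma_right otherwise, and
chance = 1/set_size (uniform guessing over the stimulus set). Characters in
the middle trigram slot are flanked on both sides and suffer extra crowding:
their above-chance component is multiplied by ``middle_penalty``. Because a
scored position receives first/middle/last characters equally often, the
observable profile is the role mixture with effective amplitude
(2 + middle_penalty)/3 * (peak - chance); the closed-form true span used for
calibration and recovery checks is the width of that mixture curve at the
criterion.

Default cell parameters are calibrated so the group-level true spans equal
the study's reported span means per age group x complexity, middle-slot
accuracy at fixation matches the reported 76% (older) / 89% (young) for high
complexity, and rightward asymmetry is ~0.5 characters for young and ~0.25
for older adults. Reading speed is linear in a participant's mean true span
with Gaussian participant noise, calibrated to group means of 485 cpm
(young) and 260 cpm (older).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (AGE_GROUPS, COMPLEXITY_LEVELS, ROLE_OFFSETS, ROLES,
                     SessionDesign, default_design)
from .errors import ConfigError


@dataclass(frozen=True)
class CellParams:
    """Latent profile parameters for one age group x complexity cell.

    peak: first/last-role accuracy at the profile peak (proportion).
    sigma_left / sigma_right: profile spread (positions) left/right of the
        peak; right > left yields a rightward span asymmetry.
    peak_shift: rightward displacement of the profile peak (positions).
    middle_penalty: multiplicative crowding factor in (0, 1] on the
        above-chance accuracy of middle-slot characters.
    between_participant_sd: SD (characters) of the participant-level shift
        applied to the cell's true span.
    """

    peak: float
    sigma_left: float
    sigma_right: float
    peak_shift: float
    middle_penalty: float
    between_participant_sd: float


@dataclass(frozen=True)
class ReadingParams:
    """Linear span -> reading-speed model: cpm = intercept[group] + slope*span + noise."""

    intercepts: Mapping[str, float]
    slope: float = 20.0
    noise_sd: float = 120.0
    n_sentences: int = 20
    min_characters: int = 17
    max_characters: int = 25
    floor_cpm: float = 60.0


# Calibrated defaults: group true spans of 7.2/6.5/5.5 (young) and
# 7.1/6.4/3.1 (older) characters for low/medium/high complexity.
# Between-participant SDs target the OBSERVED (estimated-span) spread —
# the reported SE x sqrt(21) per cell, and for the high-complexity cells the
# more precisely printed contrast effect size d = 1.36 (pooled observed SD
# 2.4/1.36 = 1.77) — deconvolved for the pipeline's own span-estimation
# noise (~0.7 characters SD at 27 observations/position), since the
# reported spreads describe estimated, not latent, spans.
_DEFAULT_CELLS: dict[tuple[str, str], CellParams] = {
    ("young", "low"): CellParams(0.990, 5.3280, 5.7113, 0.1250, 0.970, 1.09),
    ("young", "medium"): CellParams(0.985, 4.8918, 5.2831, 0.1250, 0.960, 1.18),
    ("young", "high"): CellParams(0.960, 4.5689, 5.0041, 0.1250, 0.924, 1.62),
    ("older", "low"): CellParams(0.990, 5.3901, 5.5833, 0.0625, 0.960, 2.19),
    ("older", "medium"): CellParams(0.980, 5.0193, 5.2193, 0.0625, 0.950, 2.15),
    ("older", "high"): CellParams(0.950, 3.2122, 3.4821, 0.0625, 0.790, 1.62),
}

_DEFAULT_READING = ReadingParams(intercepts={"young": 357.0, "older": 149.3})


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    n_per_group: int = 21
    seed: int = 0
    set_size: int = 26
    criterion: float = 0.8
    cells: Mapping[tuple[str, str], CellParams] = field(
        default_factory=lambda: dict(_DEFAULT_CELLS))
    reading: ReadingParams = _DEFAULT_READING

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.set_size < 2:
            raise ConfigError("set_size must be >= 2")
        if not 0.0 < self.criterion < 1.0:
            raise ConfigError("criterion must lie in (0, 1)")
        chance = 1.0 / self.set_size
        for key in ((g, c) for g in AGE_GROUPS for c in COMPLEXITY_LEVELS):
            if key not in self.cells:
                raise ConfigError(f"cells missing entry for {key}")
            cell = self.cells[key]
            if not chance < cell.peak <= 1.0:
                raise ConfigError(f"cells[{key}].peak must be in (chance, 1]")
            if cell.sigma_left <= 0 or cell.sigma_right <= 0:
                raise ConfigError(f"cells[{key}].sigma_* must be > 0")
            if not 0.0 < cell.middle_penalty <= 1.0:
                raise ConfigError(f"cells[{key}].middle_penalty must be in (0, 1]")
            if cell.between_participant_sd < 0:
                raise ConfigError(
                    f"cells[{key}].between_participant_sd must be >= 0")
        for g in AGE_GROUPS:
            if g not in self.reading.intercepts:
                raise ConfigError(f"reading.intercepts missing group {g!r}")
        if self.reading.noise_sd < 0:
            raise ConfigError("reading.noise_sd must be >= 0")


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def cell_true_span(cell: CellParams, set_size: int = 26,
                   criterion: float = 0.8) -> float:
    """Closed-form width of the role-mixed latent curve at the criterion.

    The mixture amplitude is m*(peak - chance) with m = (2 + penalty)/3; the
    criterion crossing on each side sits k*sigma from the peak with
    k = sqrt(2 ln(amplitude / (criterion - chance))), so the width is
    (sigma_left + sigma_right) * k (the peak shift moves, but does not widen,
    the supra-criterion interval). Zero if the mixture peak never reaches the
    criterion.
    """
    chance = 1.0 / set_size
    amp = (2.0 + cell.middle_penalty) / 3.0 * (cell.peak - chance)
    if amp <= criterion - chance:
        return 0.0
    k = math.sqrt(2.0 * math.log(amp / (criterion - chance)))
    return (cell.sigma_left + cell.sigma_right) * k


@dataclass(frozen=True)
class LatentParticipant:
    """Ground truth for one simulated participant."""

    participant_id: str
    age_group: str
    cells: Mapping[str, CellParams]  # keyed by complexity, after perturbation
    true_spans: Mapping[str, float]  # characters, per complexity

    @property
    def mean_true_span(self) -> float:
        return float(np.mean(list(self.true_spans.values())))


#: minimum realized true span (characters) after participant perturbation
_SPAN_FLOOR = 0.2


def sample_participants(config: GeneratorConfig,
                        seed: int | None = None) -> list[LatentParticipant]:
    """Draw the cohort: group-mean parameters plus participant perturbation.

    Each participant gets a single standard-normal ability draw u shifting
    their true span in every complexity cell by between_participant_sd * u
    (floored just above zero); the latent sigmas are rescaled accordingly.
    A shared draw makes spans correlated across complexity levels, as they
    are for real observers. Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    participants = []
    for group in AGE_GROUPS:
        for i in range(config.n_per_group):
            u = rng.standard_normal()
            cells: dict[str, CellParams] = {}
            spans: dict[str, float] = {}
            for comp in COMPLEXITY_LEVELS:
                cell = config.cells[(group, comp)]
                base_span = cell_true_span(cell, config.set_size,
                                           config.criterion)
                target = max(base_span + cell.between_participant_sd * u,
                             _SPAN_FLOOR)
                f = target / base_span if base_span > 0 else 1.0
                cells[comp] = replace(cell, sigma_left=f * cell.sigma_left,
                                      sigma_right=f * cell.sigma_right)
                spans[comp] = target if base_span > 0 else 0.0
            participants.append(LatentParticipant(
                participant_id=f"{group}{i + 1:02d}", age_group=group,
                cells=cells, true_spans=spans))
    return participants


def latent_accuracy(participant: LatentParticipant, complexity: str,
                    x, role: str, set_size: int = 26):
    """Probability of reporting a character correctly at position(s) x."""
    cell = participant.cells[complexity]
    x = np.asarray(x, dtype=float)
    chance = 1.0 / set_size
    sigma = np.where(x < cell.peak_shift, cell.sigma_left, cell.sigma_right)
    base = chance + (cell.peak - chance) * np.exp(
        -((x - cell.peak_shift) ** 2) / (2.0 * sigma ** 2))
    if role == "middle":
        base = chance + cell.middle_penalty * (base - chance)
    elif role not in ROLES:
        raise ValueError(f"unknown trigram role {role!r}")
    return np.clip(base, chance, 1.0)


def _distinct_triples(rng: np.random.Generator, n: int,
                      set_size: int) -> np.ndarray:
    """n rows of 3 distinct character indices in 1..set_size, uniform."""
    u = rng.random((n, set_size))
    return np.argpartition(u, 2, axis=1)[:, :3] + 1


def simulate_session(participant: LatentParticipant,
                     design: SessionDesign | None = None,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate one participant's full trigram session as a trial table.

    Within each block the center x repetition schedule is shuffled. Each
    character is reported correctly with its latent probability; on an error
    a response is drawn uniformly from the remaining set (recorded in
    resp1..resp3 for realism; scoring uses the correctness flags).
    """
    design = design or default_design()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    set_size = design.set_size
    frames = []
    for comp in COMPLEXITY_LEVELS[:design.n_complexity_levels]:
        for block in range(design.blocks_per_level):
            centers = np.repeat(np.asarray(design.center_positions),
                                design.reps_per_center_per_block)
            centers = rng.permutation(centers)
            n = len(centers)
            stim = _distinct_triples(rng, n, set_size)
            correct = np.empty((n, 3), dtype=bool)
            resp = stim.copy()
            for j, role in enumerate(ROLES):
                pos = centers + ROLE_OFFSETS[role]
                p = latent_accuracy(participant, comp, pos, role, set_size)
                correct[:, j] = rng.random(n) < p
                wrong = ~correct[:, j]
                offs = rng.integers(1, set_size, size=n)
                resp[wrong, j] = ((stim[wrong, j] - 1 + offs[wrong])
                                  % set_size) + 1
            frames.append(pd.DataFrame({
                "participant_id": participant.participant_id,
                "age_group": participant.age_group,
                "complexity": comp,
                "block": block,
                "center": centers,
                "stim1": stim[:, 0], "stim2": stim[:, 1], "stim3": stim[:, 2],
                "correct1": correct[:, 0], "correct2": correct[:, 1],
                "correct3": correct[:, 2],
                "resp1": resp[:, 0], "resp2": resp[:, 1], "resp3": resp[:, 2],
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_reading(participant: LatentParticipant, config: GeneratorConfig,
                     seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Simulate sentence-reading records for one participant.

    Sentence lengths are uniform on [min_characters, max_characters]; the
    participant's underlying speed is linear in mean true span plus Gaussian
    noise, floored at ``floor_cpm``, and per-sentence times follow from it.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rp = config.reading
    lengths = rng.integers(rp.min_characters, rp.max_characters + 1,
                           size=rp.n_sentences)
    speed = (rp.intercepts[participant.age_group]
             + rp.slope * participant.mean_true_span
             + rng.normal(0.0, rp.noise_sd))
    speed = max(speed, rp.floor_cpm)
    return pd.DataFrame({
        "participant_id": participant.participant_id,
        "sentence_id": np.arange(1, rp.n_sentences + 1),
        "n_characters": lengths,
        "reading_time_s": 60.0 * lengths / speed,
    })


def simulate_experiment(config: GeneratorConfig | None = None,
                        seed: int | None = None,
                        design: SessionDesign | None = None
                        ) -> tuple[list[LatentParticipant], pd.DataFrame, pd.DataFrame]:
    """Simulate the whole experiment: cohort, trial table, reading table.

    All randomness derives from a single seed via spawned child streams, so
    identical (config, seed) reproduces identical outputs.
    """
    config = config or GeneratorConfig()
    design = design or default_design()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_total = 2 * config.n_per_group
    streams = root.spawn(1 + 2 * n_total)
    participants = sample_participants(
        config, seed=np.random.default_rng(streams[0]).integers(2 ** 31))
    trial_frames, reading_frames = [], []
    for i, part in enumerate(participants):
        trial_frames.append(simulate_session(
            part, design, np.random.default_rng(streams[1 + 2 * i])))
        reading_frames.append(simulate_reading(
            part, config, np.random.default_rng(streams[2 + 2 * i])))
    return (participants,
            pd.concat(trial_frames, ignore_index=True),
            pd.concat(reading_frames, ignore_index=True))


def config_to_dict(config: GeneratorConfig) -> dict:
    d = {
        "n_per_group": config.n_per_group,
        "seed": config.seed,
        "set_size": config.set_size,
        "criterion": config.criterion,
        "cells": {f"{g}:{c}": asdict(config.cells[(g, c)])
                  for g in AGE_GROUPS for c in COMPLEXITY_LEVELS},
        "reading": {**asdict(config.reading),
                    "intercepts": dict(config.reading.intercepts)},
    }
    return d


def config_from_dict(d: Mapping) -> GeneratorConfig:
    try:
        cells = {}
        for key, val in d.get("cells", {}).items():
            g, c = key.split(":")
            cells[(g, c)] = CellParams(**val)
        reading = d.get("reading")
        kwargs = {k: d[k] for k in ("n_per_group", "seed", "set_size",
                                    "criterion") if k in d}
        if cells:
            kwargs["cells"] = cells
        if reading:
            kwargs["reading"] = ReadingParams(**reading)
        return GeneratorConfig(**kwargs)
    except (TypeError, ValueError, KeyError) as exc:
        raise ConfigError(f"invalid generator config: {exc}") from exc


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def manifest(config: GeneratorConfig, seed: int | None = None) -> dict:
    """Reproducibility manifest: the config, the seed used, and a config hash."""
    return {
        "config": config_to_dict(config),
        "seed": config.seed if seed is None else seed,
        "config_sha256": config_hash(config),
    }
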