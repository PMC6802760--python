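"""Sentence reading speed and its join with span estimates.

Reading speed is expressed in characters per minute (cpm):
60 * n_characters / reading_time_seconds per sentence, averaged per
participant (mean of per-sentence speeds by default; a total-characters over
total-time mode is also available since the two differ whenever sentence
speeds vary).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

log = logging.getLogger(__name__)

READING_COLUMNS = ["participant_id", "sentence_id", "n_characters",
                   "reading_time_s"]


def compute_speed(records: pd.DataFrame,
                  mode: str = "mean_of_speeds") -> pd.DataFrame:
    """Per-participant reading speed (cpm) from per-sentence records.

    ``mode='mean_of_speeds'`` averages per-sentence cpm;
    ``mode='total'`` divides total characters by total time.
    """
    missing = [c for c in READING_COLUMNS if c not in records.columns]
    if missing:
        raise InvalidRecordError(f"reading table missing columns: {missing}")
    if len(records) == 0:
        raise InvalidRecordError("no reading records")
    bad_t = records["reading_time_s"] <= 0
    if bad_t.any():
        raise InvalidRecordError(
            f"non-positive reading_time_s at rows {records.index[bad_t].tolist()[:5]}")
    bad_n = records["n_characters"] < 1
    if bad_n.any():
        raise InvalidRecordError(
            f"n_characters < 1 at rows {records.index[bad_n].tolist()[:5]}")
    if mode == "mean_of_speeds":
        per = 60.0 * records["n_characters"] / records["reading_time_s"]
        out = per.groupby(records["participant_id"]).mean()
    elif mode == "total":
        g = records.groupby("participant_id")
        out = 60.0 * g["n_characters"].sum() / g["reading_time_s"].sum()
    else:
        raise ValueError(f"unknown speed mode {mode!r}")
    log.info("computed reading speeds for %d participants (mode=%s)",
             len(out), mode)
    return out.rename("cpm").reset_index()


def span_speed_join(spans: pd.DataFrame, speeds: pd.DataFrame,
                    pooling: str = "participant_mean",
                    complexity: str | None = None) -> pd.DataFrame:
    """Pair span estimates with reading speeds for correlation.

    ``pooling='participant_mean'`` averages each participant's span across
    complexity levels; ``pooling='per_complexity'`` keeps only the named
    ``complexity`` level (one pair per participant either way). Participants
    present in one table but not the other are excluded with a warning.
    """
    if pooling == "participant_mean":
        agg = spans.groupby("participant_id")["span_chars"].mean()
    elif pooling == "per_complexity":
        if complexity is None:
            raise ValueError("per_complexity pooling requires a complexity level")
        sub = spans[spans["complexity"] == complexity]
        agg = sub.set_index("participant_id")["span_chars"]
    else:
        raise ValueError(f"unknown pooling mode {pooling!r}")
    agg = agg.rename("span").reset_index()
    sp = set(agg["participant_id"])
    sv = set(speeds["participant_id"])
    unmatched = sorted(sp.symmetric_difference(sv))
    if unmatched:
        warnings.warn(f"excluding {len(unmatched)} unmatched participant(s): "
                      f"{unmatched[:10]}", stacklevel=2)
    return agg.merge(speeds[["participant_id", "cpm"]], on="participant_id",
                     how="inner")
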