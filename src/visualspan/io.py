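"""CSV/JSON reading and writing for pipeline tables.

All files are UTF-8 with mandatory headers. Positions serialize as signed
integers and accuracies as percent with two decimals; span sizes are rounded
to one decimal place only in the written span table — in-memory values keep
full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .design import TRIAL_COLUMNS, AGE_GROUPS, COMPLEXITY_LEVELS
from .errors import InvalidRecordError, InvalidTrialError
from .reading import READING_COLUMNS
from .spanfit import ProfileFit

PROFILE_COLUMNS = ["participant_id", "age_group", "complexity", "position",
                   "n_obs", "accuracy_pct"]
SPAN_COLUMNS = ["participant_id", "age_group", "complexity", "model",
                "span_chars", "left_extent", "right_extent", "asymmetry",
                "span_bits", "criterion"]


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = TRIAL_COLUMNS + [c for c in trials.columns if c not in TRIAL_COLUMNS]
    out = trials[cols].copy()
    for c in ("correct1", "correct2", "correct3"):
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidTrialError(f"{path}: missing columns {missing}")
    bad_group = ~df["age_group"].isin(AGE_GROUPS)
    if bad_group.any():
        raise InvalidTrialError(
            f"{path}: invalid age_group at data row(s) "
            f"{(df.index[bad_group] + 2).tolist()[:5]}")
    bad_comp = ~df["complexity"].isin(COMPLEXITY_LEVELS)
    if bad_comp.any():
        raise InvalidTrialError(
            f"{path}: invalid complexity at data row(s) "
            f"{(df.index[bad_comp] + 2).tolist()[:5]}")
    for c in ("correct1", "correct2", "correct3"):
        bad = ~df[c].isin((0, 1))
        if bad.any():
            raise InvalidTrialError(
                f"{path}: {c} must be 0/1 at data row(s) "
                f"{(df.index[bad] + 2).tolist()[:5]}")
        df[c] = df[c].astype(bool)
    return df


def write_profiles(profiles_frame: pd.DataFrame, path) -> None:
    out = profiles_frame[PROFILE_COLUMNS].copy()
    out["accuracy_pct"] = out["accuracy_pct"].round(2)
    out.to_csv(path, index=False, encoding="utf-8")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidRecordError(f"{path}: missing columns {missing}")
    return df


def write_spans(spans: pd.DataFrame, path) -> None:
    out = spans[SPAN_COLUMNS].copy()
    out["span_chars"] = out["span_chars"].round(1)  # reported precision
    for c in ("left_extent", "right_extent", "asymmetry", "span_bits"):
        out[c] = out[c].round(4)
    out.to_csv(path, index=False, encoding="utf-8")


def read_spans(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in SPAN_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidRecordError(f"{path}: missing columns {missing}")
    return df


def write_reading(records: pd.DataFrame, path) -> None:
    records[READING_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_reading(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidRecordError(f"{path}: missing columns {missing}")
    return df


def fit_to_dict(fit: ProfileFit, seed: int | None = None) -> dict:
    d = asdict(fit)
    d["params"] = list(d["params"])
    d["multistart_seed"] = seed
    return d


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable), encoding="utf-8")


def _jsonable(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
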