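"""TSV readers/writers for track and frequency tables.

Dialects (UTF-8, tab-separated, '.' decimal):

* track table — header ``track_id  age_at_start_h  observed_duration_h
  detached  event_time_h``; ``detached`` is 0/1 and ``event_time_h`` is
  empty on censored rows;
* frequency table — header ``adult_day  n_nuclei  n_blebs``; the
  per-100-nuclei frequency is always recomputed from the counts, never
  read from the file.

Malformed rows are rejected with their line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .kinetics import BlebTrack, ValidationError
from .trajectory import FrequencyObservation

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_frequency_obs",
    "write_frequency_obs",
    "TRACK_COLUMNS",
    "FREQUENCY_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "age_at_start_h", "observed_duration_h", "detached", "event_time_h"]
FREQUENCY_COLUMNS = ["adult_day", "n_nuclei", "n_blebs"]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file, no tracks or observations") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing} (header: {list(df.columns)})")
    return df


def _parse_float(value: str, path: Path, line: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"{path}:{line}: non-numeric {col} value {value!r}") from None


def read_tracks(path: str | Path) -> list[BlebTrack]:
    """Read and validate a track table; raises on any malformed row."""
    path = Path(path)
    df = _read_table(path, TRACK_COLUMNS)
    if len(df) == 0:
        raise ValidationError(f"{path}: no tracks")
    tracks, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            detached_raw = str(row.detached).strip()
            if detached_raw not in {"0", "1"}:
                raise ValidationError(
                    f"{path}:{line}: detached must be 0 or 1, got {detached_raw!r}"
                )
            detached = detached_raw == "1"
            event_raw = str(row.event_time_h).strip()
            if detached and event_raw == "":
                raise ValidationError(
                    f"{path}:{line}: detached row for track {row.track_id!r} "
                    "has empty event_time_h"
                )
            if not detached and event_raw != "":
                raise ValidationError(
                    f"{path}:{line}: censored row for track {row.track_id!r} "
                    f"carries event_time_h {event_raw!r}"
                )
            tracks.append(
                BlebTrack(
                    track_id=str(row.track_id),
                    age_at_start=_parse_float(row.age_at_start_h, path, line, "age_at_start_h"),
                    observed_duration=_parse_float(
                        row.observed_duration_h, path, line, "observed_duration_h"
                    ),
                    detached=detached,
                    event_time=_parse_float(event_raw, path, line, "event_time_h")
                    if detached
                    else None,
                )
            )
        except ValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError("invalid track rows:\n" + "\n".join(problems))
    return tracks


def write_tracks(tracks: Sequence[BlebTrack], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "track_id": [t.track_id for t in tracks],
            "age_at_start_h": [repr(t.age_at_start) for t in tracks],
            "observed_duration_h": [repr(t.observed_duration) for t in tracks],
            "detached": [int(t.detached) for t in tracks],
            "event_time_h": [repr(t.event_time) if t.detached else "" for t in tracks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_frequency_obs(path: str | Path) -> list[FrequencyObservation]:
    """Read and validate a cross-sectional frequency table."""
    path = Path(path)
    df = _read_table(path, FREQUENCY_COLUMNS)
    if len(df) == 0:
        raise ValidationError(f"{path}: no observations")
    obs, problems = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            day = _parse_float(row.adult_day, path, line, "adult_day")
            try:
                n_nuclei = int(row.n_nuclei)
                n_blebs = int(row.n_blebs)
            except ValueError:
                raise ValidationError(
                    f"{path}:{line}: n_nuclei and n_blebs must be integers, "
                    f"got {row.n_nuclei!r}, {row.n_blebs!r}"
                ) from None
            obs.append(FrequencyObservation(adult_day=day, n_nuclei=n_nuclei, n_blebs=n_blebs))
        except ValidationError as exc:
            problems.append(str(exc))
    if problems:
        raise ValidationError("invalid frequency rows:\n" + "\n".join(problems))
    return obs


def write_frequency_obs(obs: Sequence[FrequencyObservation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "adult_day": [repr(float(o.adult_day)) for o in obs],
            "n_nuclei": [o.n_nuclei for o in obs],
            "n_blebs": [o.n_blebs for o in obs],
        }
    )
    df.to_csv(path, sep="\t", index=False)
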