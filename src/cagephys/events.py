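"""Event data model and CSV I/O for automated home-cage experiments.

The raw data of an IntelliCage-style experiment form a three-level event
hierarchy: RFID-identified *visits* to one of four operant corners, the
*nosepokes* made at the left/right door of the visited corner, and the
*licks* registered at the opened bottle.  This module defines the on-disk
CSV dialect, validates its invariants, and reduces the hierarchy to visit
classes (plain visit / nosepoke visit / lick visit).

Tables are held as :class:`pandas.DataFrame` with fixed column schemas:

``visits``
    ``visit_id, animal_tag, corner, start_time_s, end_time_s, module_label``
``nosepokes``
    ``visit_id, side, time_s, door_opened, lick_count, lick_duration_s,
    contact_time_s``

Times are seconds since experiment start (t=0 at cage activation); the
companion ``metadata.json`` carries ``t0_clock`` (ISO-8601 wall-clock time
of t=0) and the animal roster with group labels, so wall-clock task
windows can be mapped onto the relative time axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "VISIT_COLUMNS",
    "NOSEPOKE_COLUMNS",
    "PLAIN_VISIT",
    "NP_VISIT",
    "L_VISIT",
    "SchemaError",
    "IntegrityError",
    "ExperimentMetadata",
    "read_event_log",
    "write_event_log",
    "validate_events",
    "classify_visits",
    "read_metadata",
    "write_metadata",
]

VISIT_COLUMNS = [
    "visit_id",
    "animal_tag",
    "corner",
    "start_time_s",
    "end_time_s",
    "module_label",
]
NOSEPOKE_COLUMNS = [
    "visit_id",
    "side",
    "time_s",
    "door_opened",
    "lick_count",
    "lick_duration_s",
    "contact_time_s",
]

SIDES = ("LEFT", "RIGHT")

# visit classes
PLAIN_VISIT = "PLAIN_VISIT"
NP_VISIT = "NP_VISIT"
L_VISIT = "L_VISIT"


class SchemaError(ValueError):
    """A CSV file does not conform to the expected column schema."""


class IntegrityError(ValueError):
    """Cross-table referential integrity or a record invariant is violated."""


@dataclass
class ExperimentMetadata:
    """Sidecar metadata: absolute clock of t=0 and the animal roster.

    Parameters
    ----------
    t0_clock
        Wall-clock datetime corresponding to ``start_time_s == 0``.
    roster
        Mapping of animal tag -> group label (e.g. genotype).
    """

    t0_clock: datetime
    roster: dict[str, str] = field(default_factory=dict)

    @property
    def t0_hour(self) -> float:
        """Wall-clock hour-of-day of experiment start, fractional."""
        t = self.t0_clock
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def clock_hour(self, time_s: float | np.ndarray) -> float | np.ndarray:
        """Map seconds-since-start to wall-clock hour-of-day in [0, 24)."""
        return (self.t0_hour + np.asarray(time_s) / 3600.0) % 24.0


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_events(visits: pd.DataFrame, nosepokes: pd.DataFrame) -> None:
    """Check every record-level and cross-table invariant.

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        On duplicated visit ids, negative durations, corners outside 1-4,
        overlapping visits of one animal, orphan nosepokes, pokes outside
        their visit interval, or licks with zero count but nonzero duration.
    """
    _require_columns(visits, VISIT_COLUMNS, "visits")
    _require_columns(nosepokes, NOSEPOKE_COLUMNS, "nosepokes")

    if visits["visit_id"].duplicated().any():
        dup = visits.loc[visits["visit_id"].duplicated(), "visit_id"].tolist()
        raise IntegrityError(f"duplicated visit_id(s): {dup}")
    bad = visits["end_time_s"] < visits["start_time_s"]
    if bad.any():
        raise IntegrityError(
            f"end_time < start_time for visit_id(s): "
            f"{visits.loc[bad, 'visit_id'].tolist()}"
        )
    bad_corner = ~visits["corner"].isin([1, 2, 3, 4])
    if bad_corner.any():
        raise IntegrityError(
            f"corner outside 1-4 for visit_id(s): "
            f"{visits.loc[bad_corner, 'visit_id'].tolist()}"
        )
    # visits of one animal must not overlap in time
    for tag, sub in visits.sort_values("start_time_s").groupby("animal_tag"):
        starts = sub["start_time_s"].to_numpy()
        ends = sub["end_time_s"].to_numpy()
        if len(sub) > 1 and (starts[1:] < ends[:-1]).any():
            raise IntegrityError(f"overlapping visits for animal {tag!r}")

    if len(nosepokes):
        known = set(visits["visit_id"])
        orphan = sorted(set(nosepokes["visit_id"]) - known)
        if orphan:
            raise IntegrityError(f"nosepokes reference unknown visit_id(s): {orphan}")
        bad_side = ~nosepokes["side"].isin(SIDES)
        if bad_side.any():
            raise IntegrityError(
                f"invalid nosepoke side(s): "
                f"{sorted(nosepokes.loc[bad_side, 'side'].unique())}"
            )
        merged = nosepokes.merge(
            visits[["visit_id", "start_time_s", "end_time_s"]], on="visit_id"
        )
        outside = (merged["time_s"] < merged["start_time_s"]) | (
            merged["time_s"] > merged["end_time_s"]
        )
        if outside.any():
            raise IntegrityError(
                f"nosepoke outside its visit interval for visit_id(s): "
                f"{sorted(merged.loc[outside, 'visit_id'].unique())}"
            )
        lick_bad = (nosepokes["lick_count"] == 0) & (nosepokes["lick_duration_s"] > 0)
        if lick_bad.any():
            raise IntegrityError(
                "lick_duration > 0 with lick_count == 0 for visit_id(s): "
                f"{sorted(nosepokes.loc[lick_bad, 'visit_id'].unique())}"
            )
        if (nosepokes["lick_count"] < 0).any():
            raise IntegrityError("negative lick_count")


def read_event_log(
    visits_path: str | Path, nosepokes_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a visits/nosepokes CSV pair.

    Returns the two tables sorted by time with referential integrity
    checked.  An empty file with only the header row yields an empty,
    correctly-typed table.
    """
    visits = pd.read_csv(visits_path)
    nosepokes = pd.read_csv(nosepokes_path)
    _require_columns(visits, VISIT_COLUMNS, str(visits_path))
    _require_columns(nosepokes, NOSEPOKE_COLUMNS, str(nosepokes_path))
    visits = visits[VISIT_COLUMNS].astype(
        {
            "visit_id": np.int64,
            "animal_tag": str,
            "corner": np.int64,
            "start_time_s": float,
            "end_time_s": float,
            "module_label": str,
        }
    )
    nosepokes = nosepokes[NOSEPOKE_COLUMNS].astype(
        {
            "visit_id": np.int64,
            "side": str,
            "time_s": float,
            "door_opened": bool,
            "lick_count": np.int64,
            "lick_duration_s": float,
            "contact_time_s": float,
        }
    )
    validate_events(visits, nosepokes)
    visits = visits.sort_values("start_time_s", kind="stable").reset_index(drop=True)
    nosepokes = nosepokes.sort_values("time_s", kind="stable").reset_index(drop=True)
    return visits, nosepokes


def write_event_log(
    visits: pd.DataFrame,
    nosepokes: pd.DataFrame,
    visits_path: str | Path,
    nosepokes_path: str | Path,
) -> None:
    """Write the table pair in the canonical CSV dialect (UTF-8, '.' decimal)."""
    validate_events(visits, nosepokes)
    visits[VISIT_COLUMNS].to_csv(visits_path, index=False)
    nosepokes[NOSEPOKE_COLUMNS].to_csv(nosepokes_path, index=False)


def classify_visits(visits: pd.DataFrame, nosepokes: pd.DataFrame) -> pd.Series:
    """Assign each visit its class: lick, nosepoke-only, or plain.

    A visit with any licks is ``L_VISIT``; with at least one nosepoke but
    no licks it is ``NP_VISIT`` ("unnecessary" exploratory pokes); with no
    nosepokes at all it is ``PLAIN_VISIT``.  The three classes partition
    the visits.

    Returns
    -------
    pandas.Series
        Indexed by ``visit_id``, values in
        ``{PLAIN_VISIT, NP_VISIT, L_VISIT}``.
    """
    agg = nosepokes.groupby("visit_id").agg(
        n_pokes=("visit_id", "size"), n_licks=("lick_count", "sum")
    )
    agg = agg.reindex(visits["visit_id"], fill_value=0)
    cls = np.where(
        agg["n_licks"] > 0, L_VISIT, np.where(agg["n_pokes"] > 0, NP_VISIT, PLAIN_VISIT)
    )
    return pd.Series(cls, index=agg.index, name="visit_class")


def write_metadata(meta: ExperimentMetadata, path: str | Path) -> None:
    payload = {"t0_clock": meta.t0_clock.isoformat(), "roster": meta.roster}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_metadata(path: str | Path) -> ExperimentMetadata:
    payload = json.loads(Path(path).read_text())
    return ExperimentMetadata(
        t0_clock=datetime.fromisoformat(payload["t0_clock"]),
        roster=dict(payload.get("roster", {})),
    )
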