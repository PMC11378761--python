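"""Embedded per-subject study tables.

The study that motivates this package deposited no raw recordings, but it
printed every per-subject value: demographics, trial durations, peak
angular velocities and roll angles, traditional Procrustes dissimilarities,
and the expanding-Procrustes dissimilarity/percent-similarity pairs for
inter- and intra-limb comparisons.  Those tables are shipped here as
plain-text fixtures so the group statistics can be recomputed exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["GroupTable", "SubjectInfo", "load_fixture", "available_tables"]

_DATA_PACKAGE = "expanding_procrustes.data"


class FixtureLookupError(KeyError):
    """Unknown table identifier."""


@dataclass
class GroupTable:
    """One printed per-subject table, with group membership per row."""

    table_id: str
    title: str
    frame: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def group(self, g: int) -> pd.DataFrame:
        """Rows for group 1 (younger) or group 2 (older)."""
        return self.frame[self.frame["group"] == g]


@dataclass
class SubjectInfo:
    subject_id: str
    group: int
    age: float
    arm_length: float
    eye_height: float


def _index() -> dict:
    text = resources.files(_DATA_PACKAGE).joinpath("index.json").read_text()
    return json.loads(text)


def available_tables() -> list[str]:
    return sorted(_index())


def load_fixture(table_id: str) -> GroupTable:
    """Load one embedded table by id (``table1`` ... ``table8``, ``tableA1`` ... ``tableA4``)."""
    idx = _index()
    if table_id not in idx:
        raise FixtureLookupError(
            f"unknown table id {table_id!r}; valid ids: {sorted(idx)}"
        )
    entry = idx[table_id]
    with resources.files(_DATA_PACKAGE).joinpath(entry["file"]).open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return GroupTable(table_id=table_id, title=entry["title"], frame=frame)


def load_subjects() -> list[SubjectInfo]:
    """Demographic records; warns if a row violates the group age bands
    (group 1 under 30 years, group 2 between 35 and 75)."""
    table = load_fixture("table1")
    subjects = []
    for _, row in table.frame.iterrows():
        age = float(row["age_years"])
        group = int(row["group"])
        if group == 1 and not age < 30:
            warnings.warn(f"{row['subject']}: group 1 but age {age} >= 30")
        if group == 2 and not (35 <= age <= 75):
            warnings.warn(f"{row['subject']}: group 2 but age {age} outside [35, 75]")
        subjects.append(
            SubjectInfo(
                subject_id=str(row["subject"]),
                group=group,
                age=age,
                arm_length=float(row["arm_length_cm"]),
                eye_height=float(row["eye_height_cm"]),
            )
        )
    return subjects
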