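"""Domain types and readers/writers for food-diary entry tables.

A diary entry records one food/drink intake event as reported through one
of two channels: a voice assistant ("alexa") or a web form ("web").  Each
entry carries two timestamps — the *intake* timestamp (when the participant
said they ate or drank) and the *submission* timestamp (when the record was
entered) — plus one or more free-text item descriptions.  Voice attempts
that were never submitted are kept as ``status="partial"`` records.

Timestamps are naive local times at minute resolution; seconds present on
input are truncated.  On disk a dataset is a CSV with a fixed column order
(items joined with ``|``) or a JSON list of objects (items as a native
list).  Both round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

__all__ = [
    "DiaryEntry",
    "DiaryDataset",
    "read_diary",
    "write_diary",
    "parse_timestamp",
    "format_timestamp",
    "CSV_COLUMNS",
    "ITEM_DELIMITER",
]

SOURCES = ("alexa", "web")
STATUSES = ("submitted", "partial")
CSV_COLUMNS = [
    "entry_id",
    "participant_id",
    "source",
    "intake_ts",
    "submission_ts",
    "status",
    "items",
]
ITEM_DELIMITER = "|"
_TS_FORMAT = "%Y-%m-%dT%H:%M"


def parse_timestamp(value: str | datetime, *, context: str = "") -> datetime:
    """Parse a timestamp and truncate it to minute resolution.

    Accepts a ``datetime`` or any ISO-8601-like string pandas can parse.
    Raises ``ValueError`` naming ``context`` (e.g. row/field) on failure.
    """
    if isinstance(value, datetime):
        return value.replace(second=0, microsecond=0)
    try:
        ts = pd.Timestamp(value)
        if pd.isna(ts):
            raise ValueError("missing")
    except Exception as exc:
        where = f" ({context})" if context else ""
        raise ValueError(f"unparseable timestamp {value!r}{where}") from exc
    if ts.tzinfo is not None:
        ts = ts.tz_localize(None)
    return ts.to_pydatetime().replace(second=0, microsecond=0)


def format_timestamp(ts: datetime) -> str:
    return ts.strftime(_TS_FORMAT)


@dataclass(frozen=True)
class DiaryEntry:
    """One submitted or partial diary record from one source."""

    entry_id: str
    participant_id: str
    source: Literal["alexa", "web"]
    intake_ts: datetime
    submission_ts: datetime
    items: tuple[str, ...]
    status: Literal["submitted", "partial"] = "submitted"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"entry {self.entry_id}: unknown source {self.source!r}")
        if self.status not in STATUSES:
            raise ValueError(f"entry {self.entry_id}: unknown status {self.status!r}")
        object.__setattr__(self, "items", tuple(self.items))
        if self.status == "submitted" and not self.items:
            raise ValueError(f"entry {self.entry_id}: submitted entry must have items")
        if any(not it for it in self.items):
            raise ValueError(f"entry {self.entry_id}: empty item text")
        object.__setattr__(
            self, "intake_ts", parse_timestamp(self.intake_ts, context=self.entry_id)
        )
        object.__setattr__(
            self,
            "submission_ts",
            parse_timestamp(self.submission_ts, context=self.entry_id),
        )


@dataclass
class DiaryDataset:
    """A collection of diary entries with free-text provenance metadata."""

    entries: list[DiaryEntry] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.entry_id in seen:
                raise ValueError(f"duplicate entry_id {e.entry_id!r}")
            seen.add(e.entry_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self) -> dict[str, DiaryEntry]:
        return {e.entry_id: e for e in self.entries}

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.participant_id, None)
        return list(seen)

    def submitted(self) -> list[DiaryEntry]:
        return [e for e in self.entries if e.status == "submitted"]


def _entry_from_row(row: dict, row_no: int, items: Iterable[str]) -> DiaryEntry:
    for col in CSV_COLUMNS[:-1]:  # items handled separately (may be empty)
        if row.get(col) in (None, ""):
            raise ValueError(f"row {row_no}: missing value for column {col!r}")
    return DiaryEntry(
        entry_id=str(row["entry_id"]),
        participant_id=str(row["participant_id"]),
        source=str(row["source"]),
        intake_ts=parse_timestamp(
            row["intake_ts"], context=f"row {row_no}, field intake_ts"
        ),
        submission_ts=parse_timestamp(
            row["submission_ts"], context=f"row {row_no}, field submission_ts"
        ),
        items=tuple(items),
        status=str(row["status"]),
    )


def read_diary(path: str | Path, format: str | None = None) -> DiaryDataset:
    """Read a diary table from ``path`` (CSV or JSON; inferred from suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    entries: list[DiaryEntry] = []
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        for row_no, row in enumerate(df.to_dict(orient="records"), start=1):
            raw_items = row["items"]
            items = (
                tuple(raw_items.split(ITEM_DELIMITER)) if raw_items != "" else ()
            )
            entries.append(_entry_from_row(row, row_no, items))
    elif fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        for row_no, row in enumerate(records, start=1):
            missing = [c for c in CSV_COLUMNS if c not in row]
            if missing:
                raise ValueError(
                    f"row {row_no}: missing required column(s): {', '.join(missing)}"
                )
            entries.append(_entry_from_row(row, row_no, row["items"]))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return DiaryDataset(entries=entries, provenance=str(path))


def write_diary(data: DiaryDataset, path: str | Path, format: str | None = None) -> None:
    """Write ``data`` to ``path`` so that :func:`read_diary` reproduces it.

    CSV items are joined with ``|``; item text containing the delimiter is
    rejected rather than escaped so fixtures stay greppable.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for e in data.entries:
        if fmt == "csv" and any(ITEM_DELIMITER in it for it in e.items):
            raise ValueError(
                f"entry {e.entry_id}: item text contains the delimiter {ITEM_DELIMITER!r}"
            )
        rows.append(
            {
                "entry_id": e.entry_id,
                "participant_id": e.participant_id,
                "source": e.source,
                "intake_ts": format_timestamp(e.intake_ts),
                "submission_ts": format_timestamp(e.submission_ts),
                "status": e.status,
                "items": ITEM_DELIMITER.join(e.items) if fmt == "csv" else list(e.items),
            }
        )
    if fmt == "csv":
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
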