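"""Clinical item vocabulary and flat event tables.

The data model is deliberately "OMOP-lite": events live in a single flat
delimited table keyed by opaque concept identifiers with a domain tag
(condition / measurement / procedure / medication), rather than a full
relational common-data-model instance.  Numeric lab results are turned into
categorical vocabulary items ("TSH"/"high" is a different item from
"TSH"/"low"), and items seen in fewer than ``min_support`` distinct patients
are dropped from the vocabulary before any modelling.

``events.csv`` schema (UTF-8, header required)::

    patient_id, concept_id, domain, event_date, numeric_value, ref_low, ref_high

``event_date`` is ISO-8601 (YYYY-MM-DD); the last three columns may be blank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidRangeError, RowParseError, SchemaError

logger = logging.getLogger(__name__)

DOMAINS = ("condition", "measurement", "procedure", "medication")
QUALIFIERS = ("none", "normal", "high", "low")

#: columns of events.csv, in order
EVENT_COLUMNS = (
    "patient_id",
    "concept_id",
    "domain",
    "event_date",
    "numeric_value",
    "ref_low",
    "ref_high",
)


@dataclass(frozen=True, eq=False)
class ClinicalItem:
    """One vocabulary entry.

    Identity is ``(concept_id, qualifier)``: a categorized lab result is its
    own item, so ``TSH/high`` and ``TSH/low`` are distinct.  ``domain`` tags
    the item but does not participate in identity or ordering.
    """

    concept_id: str
    domain: str = "condition"
    qualifier: str = "none"

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")
        if self.qualifier != "none" and self.domain != "measurement":
            raise ValueError(
                f"qualifier {self.qualifier!r} is only valid for measurements, "
                f"got domain {self.domain!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.concept_id, self.qualifier)

    def __eq__(self, other):
        if not isinstance(other, ClinicalItem):
            return NotImplemented
        return self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __lt__(self, other: "ClinicalItem"):
        return self.key < other.key

    def __repr__(self):
        q = "" if self.qualifier == "none" else f"/{self.qualifier}"
        return f"<{self.concept_id}{q} [{self.domain}]>"

    def stripped(self) -> "ClinicalItem":
        """The same concept with no abnormality qualifier (order identity)."""
        if self.qualifier == "none":
            return self
        return replace(self, qualifier="none")


@dataclass(frozen=True)
class EventRecord:
    """One row of the patient event table."""

    patient_id: str
    item: ClinicalItem
    event_date: date
    numeric_value: float | None = None
    ref_low: float | None = None
    ref_high: float | None = None

    def __post_init__(self):
        if self.numeric_value is not None and self.item.domain != "measurement":
            raise ValueError("numeric_value is only valid for measurement events")
        if (
            self.ref_low is not None
            and self.ref_high is not None
            and self.ref_low > self.ref_high
        ):
            raise InvalidRangeError(
                f"ref_low {self.ref_low} > ref_high {self.ref_high} "
                f"for {self.item.concept_id}"
            )


@dataclass
class Vocabulary:
    """Retained item set with per-item distinct-patient support counts."""

    items: set[ClinicalItem]
    patient_support: dict[ClinicalItem, int]

    def __contains__(self, item: ClinicalItem) -> bool:
        return item in self.items

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "concept_id": it.concept_id,
                "qualifier": it.qualifier,
                "domain": it.domain,
                "patient_support": self.patient_support[it],
            }
            for it in sorted(self.items)
        ]
        return pd.DataFrame(rows, columns=["concept_id", "qualifier", "domain", "patient_support"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def categorize_measurement(value: float, ref_low: float, ref_high: float) -> str:
    """Categorize a numeric lab value against its reference range.

    Returns ``"low"`` if strictly below ``ref_low``, ``"high"`` if strictly
    above ``ref_high``, else ``"normal"``.  Values equal to a bound are
    ``"normal"``: flags fire strictly outside the range, matching common
    laboratory flagging conventions.
    """
    if ref_low > ref_high:
        raise InvalidRangeError(f"ref_low {ref_low} > ref_high {ref_high}")
    if value < ref_low:
        return "low"
    if value > ref_high:
        return "high"
    return "normal"


def categorize_events(events: Iterable[EventRecord]) -> list[EventRecord]:
    """Assign normal/high/low qualifiers to measurement events.

    Measurements lacking a numeric value or a complete reference range keep
    qualifier ``none`` (they remain vocabulary items rather than being
    dropped).
    """
    out = []
    for ev in events:
        if (
            ev.item.domain == "measurement"
            and ev.numeric_value is not None
            and ev.ref_low is not None
            and ev.ref_high is not None
        ):
            q = categorize_measurement(ev.numeric_value, ev.ref_low, ev.ref_high)
            out.append(replace(ev, item=replace(ev.item, qualifier=q)))
        else:
            out.append(ev)
    return out


def filter_rare_items(
    events: list[EventRecord], min_support: int = 10
) -> tuple[list[EventRecord], Vocabulary]:
    """Drop items observed in fewer than ``min_support`` distinct patients.

    Support is counted per patient: duplicate events of an item within one
    patient count once.  Returns the filtered event list and the retained
    vocabulary with its support counts.
    """
    if not events:
        raise ValueError("events must be non-empty")
    patients_by_item: dict[ClinicalItem, set[str]] = {}
    for ev in events:
        patients_by_item.setdefault(ev.item, set()).add(ev.patient_id)
    support = {it: len(pats) for it, pats in patients_by_item.items()}
    kept = {it for it, n in support.items() if n >= min_support}
    filtered = [ev for ev in events if ev.item in kept]
    n_dropped = len(support) - len(kept)
    if n_dropped:
        logger.info(
            "filter_rare_items: dropped %d/%d items below support %d",
            n_dropped, len(support), min_support,
        )
    vocab = Vocabulary(items=kept, patient_support={it: support[it] for it in kept})
    return filtered, vocab


def _parse_float(raw, field: str, line: int) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowParseError(f"unparseable {field} value {raw!r}", line=line) from None


def read_events(path: str | Path, delimiter: str = ",") -> list[EventRecord]:
    """Read an events table; malformed rows raise with their file line number."""
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype={"patient_id": "string", "concept_id": "string", "domain": "string"},
        keep_default_na=True,
    )
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    records: list[EventRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        for field in ("patient_id", "concept_id", "domain"):
            val = getattr(row, field)
            if pd.isna(val) or val == "":
                raise RowParseError(f"missing {field}", line=line)
        if row.domain not in DOMAINS:
            raise RowParseError(f"unknown domain {row.domain!r}", line=line)
        raw_date = row.event_date
        if pd.isna(raw_date) or raw_date == "":
            raise RowParseError("missing event_date", line=line)
        try:
            event_date = date.fromisoformat(str(raw_date))
        except ValueError:
            raise RowParseError(
                f"unparseable event_date {raw_date!r}", line=line
            ) from None
        records.append(
            EventRecord(
                patient_id=str(row.patient_id),
                item=ClinicalItem(concept_id=str(row.concept_id), domain=str(row.domain)),
                event_date=event_date,
                numeric_value=_parse_float(row.numeric_value, "numeric_value", line),
                ref_low=_parse_float(row.ref_low, "ref_low", line),
                ref_high=_parse_float(row.ref_high, "ref_high", line),
            )
        )
    return records


def events_to_frame(events: Iterable[EventRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": ev.patient_id,
            "concept_id": ev.item.concept_id,
            "domain": ev.item.domain,
            "event_date": ev.event_date.isoformat(),
            "numeric_value": ev.numeric_value,
            "ref_low": ev.ref_low,
            "ref_high": ev.ref_high,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def write_events(events: Iterable[EventRecord], path: str | Path) -> None:
    """Write events.csv; inverse of :func:`read_events` for uncategorized records."""
    events_to_frame(events).to_csv(path, index=False)
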