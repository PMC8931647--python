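"""Referral episodes and the temporal train/test split.

A referral episode is the unit of analysis: one referral order paired with the
patient's first specialty visit no more than ``max_wait_days`` later.  The
query side of the episode is every distinct clinical item on the chart in the
closed window ``[referral_date - lookback_days, referral_date]``; the target
side is the set of laboratory and imaging orders (domains measurement and
procedure) placed on the visit date, with any abnormality qualifier stripped
(an order has no result yet).

Six months is fixed as 183 days for both the lookback and the maximum wait, so
episode construction is bit-reproducible; each patient contributes at most one
episode, anchored at their earliest qualifying referral.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ehr_model import ClinicalItem, EventRecord
from .errors import ConfigurationError, RowParseError, SchemaError

logger = logging.getLogger(__name__)

TARGET_DOMAINS = ("measurement", "procedure")


@dataclass
class ReferralEpisode:
    """One patient's referral: query item set plus first-visit target orders."""

    patient_id: str
    referral_date: date
    specialty_visit_date: date
    query_items: frozenset[ClinicalItem]
    target_items: frozenset[ClinicalItem]

    def __post_init__(self):
        wait = (self.specialty_visit_date - self.referral_date).days
        if wait < 0:
            raise ValueError("specialty visit precedes referral")
        for it in self.target_items:
            if it.domain not in TARGET_DOMAINS:
                raise ValueError(f"target item {it!r} is not a lab/imaging order")


def _read_dated_table(path: str | Path, date_col: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": "string"})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    dates = []
    for i, raw in enumerate(df[date_col]):
        try:
            dates.append(date.fromisoformat(str(raw)))
        except ValueError:
            raise RowParseError(f"unparseable {date_col} {raw!r}", line=i + 2) from None
    df[date_col] = dates
    return df


def read_referrals(path: str | Path) -> pd.DataFrame:
    """referrals.csv: patient_id, referral_date, encounter_id (optional)."""
    return _read_dated_table(path, "referral_date", ["patient_id", "referral_date"])


def read_visits(path: str | Path) -> pd.DataFrame:
    """visits.csv: patient_id, visit_date."""
    return _read_dated_table(path, "visit_date", ["patient_id", "visit_date"])


def build_episodes(
    events: Iterable[EventRecord],
    referrals: pd.DataFrame,
    visits: pd.DataFrame,
    lookback_days: int = 183,
    max_wait_days: int = 183,
) -> list[ReferralEpisode]:
    """Pair referrals with first subsequent specialty visits into episodes.

    For each patient, referral orders are scanned in date order and the
    earliest referral with a specialty visit in ``[referral, referral +
    max_wait_days]`` forms that patient's (single) episode.  Patients whose
    referrals all lack a qualifying visit are excluded.
    """
    if len(referrals) == 0:
        logger.warning("build_episodes: empty referral table, no episodes built")
        return []

    events_by_patient: dict[str, list[EventRecord]] = {}
    for ev in events:
        events_by_patient.setdefault(ev.patient_id, []).append(ev)
    visits_by_patient: dict[str, list[date]] = {}
    for row in visits.itertuples(index=False):
        visits_by_patient.setdefault(str(row.patient_id), []).append(row.visit_date)
    for vd in visits_by_patient.values():
        vd.sort()

    episodes: list[ReferralEpisode] = []
    wait = timedelta(days=max_wait_days)
    lookback = timedelta(days=lookback_days)
    grouped = referrals.groupby("patient_id", sort=True)["referral_date"]
    for patient_id, ref_dates in grouped:
        patient_id = str(patient_id)
        pvisits = visits_by_patient.get(patient_id, [])
        match: tuple[date, date] | None = None
        for ref_date in sorted(ref_dates):
            visit = next((v for v in pvisits if ref_date <= v <= ref_date + wait), None)
            if visit is not None:
                match = (ref_date, visit)
                break
        if match is None:
            continue
        ref_date, visit_date = match
        pevents = events_by_patient.get(patient_id, [])
        query = frozenset(
            ev.item for ev in pevents if ref_date - lookback <= ev.event_date <= ref_date
        )
        targets = frozenset(
            ev.item.stripped()
            for ev in pevents
            if ev.event_date == visit_date and ev.item.domain in TARGET_DOMAINS
        )
        episodes.append(
            ReferralEpisode(
                patient_id=patient_id,
                referral_date=ref_date,
                specialty_visit_date=visit_date,
                query_items=query,
                target_items=targets,
            )
        )
    logger.info(
        "build_episodes: %d referrals for %d patients -> %d episodes",
        len(referrals), referrals["patient_id"].nunique(), len(episodes),
    )
    return episodes


def split_by_year(
    episodes: Sequence[ReferralEpisode], test_year: int = 2020
) -> tuple[list[ReferralEpisode], list[ReferralEpisode]]:
    """Temporal split: referral years before ``test_year`` train, equal test.

    An episode dated after the test year indicates a misconfigured split and
    raises; an empty train partition is permitted but logged.
    """
    train, test = [], []
    for ep in episodes:
        year = ep.referral_date.year
        if year < test_year:
            train.append(ep)
        elif year == test_year:
            test.append(ep)
        else:
            raise ConfigurationError(
                f"episode for {ep.patient_id} dated {ep.referral_date} is after "
                f"test year {test_year}"
            )
    if episodes and not train:
        logger.warning("split_by_year: empty training partition (all referrals in %d)", test_year)
    return train, test


def _item_to_list(item: ClinicalItem) -> list[str]:
    return [item.concept_id, item.domain, item.qualifier]


def _item_from_list(lst: Sequence[str]) -> ClinicalItem:
    return ClinicalItem(concept_id=lst[0], domain=lst[1], qualifier=lst[2])


def write_episodes(episodes: Iterable[ReferralEpisode], path: str | Path) -> None:
    """Serialize episodes as JSON lines (one object per episode)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ep in episodes:
            obj = {
                "patient_id": ep.patient_id,
                "referral_date": ep.referral_date.isoformat(),
                "specialty_visit_date": ep.specialty_visit_date.isoformat(),
                "query_items": sorted(_item_to_list(i) for i in ep.query_items),
                "target_items": sorted(_item_to_list(i) for i in ep.target_items),
            }
            fh.write(json.dumps(obj) + "\n")


def read_episodes(path: str | Path) -> list[ReferralEpisode]:
    episodes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            episodes.append(
                ReferralEpisode(
                    patient_id=obj["patient_id"],
                    referral_date=date.fromisoformat(obj["referral_date"]),
                    specialty_visit_date=date.fromisoformat(obj["specialty_visit_date"]),
                    query_items=frozenset(_item_from_list(i) for i in obj["query_items"]),
                    target_items=frozenset(_item_from_list(i) for i in obj["target_items"]),
                )
            )
    return episodes
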