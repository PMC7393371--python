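"""Domain types and I/O for scored mating-behaviour observations.

Observations come from 2-h videos filmed at 1 frame per second, so all times
are integer seconds (= frame indices).  Two behaviours are scored: the
*copulation* (two worms tightly interlinked, ventral tail-plate contact) and
the postcopulatory *suck* (a worm placing its pharynx over its own female
genital opening).  An interlinked event counts as a copulation only if it
lasts at least 5 s; shorter events are rejected at ingest with a warning.

Two experimental units exist:

* a **pair** — two worms of known pairing type (conspecific *M. lignano*,
  conspecific *M. janickei*, or heterospecific) observed alone; and
* a **drop** — a 3-µl arena holding two worms of each species, where one
  species is dyed so every copulation can be typed LL / LJ / JJ.

Durations use the half-open convention [start, end): duration = end - start,
and the 5-s rule is ``end - start >= 5``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, Union

logger = logging.getLogger(__name__)

MIN_COPULATION_S = 5

PairingType = Literal["lignano", "hetero", "janickei"]
CopulationType = Literal["LL", "LJ", "JJ", "NA"]

PAIRING_TYPES = ("lignano", "hetero", "janickei")
COPULATION_TYPES = ("LL", "LJ", "JJ", "NA")

EVENT_LOG_COLUMNS = [
    "record_id",
    "record_kind",
    "pairing_type_or_blank",
    "event_kind",
    "actor_a",
    "actor_b",
    "start_s",
    "end_s",
    "copulation_type",
    "preceding_copulation_index",
]

DROP_META_COLUMNS = ["drop_id", "chamber_id", "excluded", "exclusion_reason"]


class EventValidationError(ValueError):
    """Raised when an event or record violates a structural invariant."""


class EventParseError(ValueError):
    """Raised when an event-log row cannot be parsed; names the row."""


@dataclass(frozen=True)
class CopulationEvent:
    """One copulation, [start_s, end_s) in integer seconds."""

    pair_or_drop_id: str
    actor_a: str
    actor_b: str
    start_s: int
    end_s: int
    copulation_type: CopulationType = "NA"

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise EventValidationError(
                f"{self.pair_or_drop_id}: negative start_s {self.start_s}"
            )
        if self.end_s < self.start_s:
            raise EventValidationError(
                f"{self.pair_or_drop_id}: end_s {self.end_s} precedes "
                f"start_s {self.start_s}"
            )
        if self.duration_s < MIN_COPULATION_S:
            raise EventValidationError(
                f"{self.pair_or_drop_id}: copulation of {self.duration_s} s "
                f"is below the {MIN_COPULATION_S} s minimum"
            )
        if self.copulation_type not in COPULATION_TYPES:
            raise EventValidationError(
                f"unknown copulation_type {self.copulation_type!r}"
            )

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SuckEvent:
    """One suck; optionally linked to the copulation it follows (0-based)."""

    pair_or_drop_id: str
    start_s: int
    end_s: int
    preceding_copulation_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise EventValidationError(
                f"{self.pair_or_drop_id}: negative start_s {self.start_s}"
            )
        if self.end_s <= self.start_s:
            raise EventValidationError(
                f"{self.pair_or_drop_id}: suck must have end_s > start_s "
                f"(got {self.start_s}..{self.end_s})"
            )

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


Event = Union[CopulationEvent, SuckEvent]


def _check_pair_events(
    record_id: str,
    copulations: Sequence[CopulationEvent],
    sucks: Sequence[SuckEvent],
    window_s: Optional[int],
) -> None:
    cops = sorted(copulations, key=lambda e: e.start_s)
    for a, b in zip(cops, cops[1:]):
        if b.start_s < a.end_s:
            raise EventValidationError(
                f"{record_id}: copulations overlap at "
                f"[{a.start_s},{a.end_s}) and [{b.start_s},{b.end_s})"
            )
    for s in sucks:
        for c in cops:
            if s.start_s < c.end_s and c.start_s < s.end_s:
                raise EventValidationError(
                    f"{record_id}: suck [{s.start_s},{s.end_s}) overlaps "
                    f"copulation [{c.start_s},{c.end_s})"
                )
        if s.preceding_copulation_index is not None:
            i = s.preceding_copulation_index
            if not 0 <= i < len(cops):
                raise EventValidationError(
                    f"{record_id}: suck links to copulation {i} "
                    f"but only {len(cops)} copulations exist"
                )
            if s.start_s < cops[i].end_s:
                raise EventValidationError(
                    f"{record_id}: suck starts before its linked copulation ends"
                )
    if window_s is not None:
        for e in list(cops) + list(sucks):
            if e.end_s > window_s:
                raise EventValidationError(
                    f"{record_id}: event ends at {e.end_s} s, beyond the "
                    f"{window_s} s observation window"
                )


@dataclass
class PairRecord:
    """All scored events for one mating pair, plus optional fecundity.

    ``offspring_counts`` holds the 14-day offspring tally of each maternal
    individual that was isolated after filming: one entry for conspecific
    pairs (one randomly chosen worm isolated), two for heterospecific pairs
    (both worms isolated; downstream analysis averages them).
    """

    pair_id: str
    pairing_type: PairingType
    chamber_id: str = ""
    observation_day: int = 0
    copulations: list[CopulationEvent] = field(default_factory=list)
    sucks: list[SuckEvent] = field(default_factory=list)
    offspring_counts: Optional[tuple[int, ...]] = None
    window_s: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pairing_type not in PAIRING_TYPES:
            raise EventValidationError(
                f"{self.pair_id}: unknown pairing_type {self.pairing_type!r}"
            )
        self.copulations = sorted(self.copulations, key=lambda e: e.start_s)
        self.sucks = sorted(self.sucks, key=lambda e: e.start_s)
        _check_pair_events(self.pair_id, self.copulations, self.sucks, self.window_s)
        if self.offspring_counts is not None:
            if any(c < 0 for c in self.offspring_counts):
                raise EventValidationError(
                    f"{self.pair_id}: negative offspring count"
                )

    @property
    def n_copulations(self) -> int:
        return len(self.copulations)


@dataclass
class DropRecord:
    """All typed copulations in one 2+2 mate-choice drop."""

    drop_id: str
    chamber_id: str = ""
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    copulations: list[CopulationEvent] = field(default_factory=list)
    window_s: Optional[int] = None

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise EventValidationError(
                f"{self.drop_id}: excluded drop must carry a reason"
            )
        self.copulations = sorted(self.copulations, key=lambda e: e.start_s)
        if not self.excluded:
            for e in self.copulations:
                if e.copulation_type == "NA":
                    raise EventValidationError(
                        f"{self.drop_id}: included drop has an untyped copulation"
                    )
        if self.window_s is not None:
            for e in self.copulations:
                if e.end_s > self.window_s:
                    raise EventValidationError(
                        f"{self.drop_id}: event beyond observation window"
                    )

    @property
    def n_copulations(self) -> int:
        return len(self.copulations)

    def first_copulation_type(self) -> Optional[str]:
        """Type of the earliest copulation (ties broken by row order)."""
        if not self.copulations:
            return None
        return self.copulations[0].copulation_type


def _parse_int(value: str, column: str, row_num: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise EventParseError(
            f"row {row_num}: cannot parse {column}={value!r} as integer"
        ) from exc


def read_event_log(
    path,
    schema: Literal["pair", "drop"],
    pairing_types: Optional[dict[str, str]] = None,
    window_s: Optional[int] = None,
) -> list[PairRecord] | list[DropRecord]:
    """Read a scored event log (CSV or TSV) into typed records.

    The file must carry the documented header (``EVENT_LOG_COLUMNS``).
    Sub-5-second "copulations" are rejected with a logged warning and do not
    enter the dataset.  Malformed rows raise :class:`EventParseError` naming
    the row; end < start raises :class:`EventValidationError`.
    """
    path = str(path)
    delimiter = "\t" if path.endswith((".tsv", ".txt")) else ","
    rows_by_record: dict[str, dict] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None or set(EVENT_LOG_COLUMNS) - set(
            reader.fieldnames
        ):
            raise EventParseError(
                f"{path}: header must contain columns {EVENT_LOG_COLUMNS}"
            )
        for row_num, row in enumerate(reader, start=2):
            rid = row["record_id"]
            kind = row["record_kind"]
            if kind != schema:
                raise EventParseError(
                    f"row {row_num}: record_kind {kind!r} does not match "
                    f"requested schema {schema!r}"
                )
            start = _parse_int(row["start_s"], "start_s", row_num)
            end = _parse_int(row["end_s"], "end_s", row_num)
            if end < start:
                raise EventValidationError(
                    f"row {row_num}: end_s {end} precedes start_s {start}"
                )
            if rid not in rows_by_record:
                rows_by_record[rid] = {
                    "pairing_type": row["pairing_type_or_blank"] or None,
                    "copulations": [],
                    "sucks": [],
                }
                order.append(rid)
            rec = rows_by_record[rid]
            if row["event_kind"] == "copulation":
                if end - start < MIN_COPULATION_S:
                    logger.warning(
                        "row %d (%s): event of %d s rejected — below %d s "
                        "minimum for a copulation",
                        row_num,
                        rid,
                        end - start,
                        MIN_COPULATION_S,
                    )
                    continue
                rec["copulations"].append(
                    CopulationEvent(
                        pair_or_drop_id=rid,
                        actor_a=row["actor_a"],
                        actor_b=row["actor_b"],
                        start_s=start,
                        end_s=end,
                        copulation_type=row["copulation_type"] or "NA",
                    )
                )
            elif row["event_kind"] == "suck":
                link = row.get("preceding_copulation_index") or ""
                rec["sucks"].append(
                    SuckEvent(
                        pair_or_drop_id=rid,
                        start_s=start,
                        end_s=end,
                        preceding_copulation_index=(
                            _parse_int(link, "preceding_copulation_index", row_num)
                            if link
                            else None
                        ),
                    )
                )
            else:
                raise EventParseError(
                    f"row {row_num}: unknown event_kind {row['event_kind']!r}"
                )

    if schema == "pair":
        records_p: list[PairRecord] = []
        for rid in order:
            rec = rows_by_record[rid]
            ptype = rec["pairing_type"]
            if pairing_types and rid in pairing_types:
                ptype = pairing_types[rid]
            if ptype is None:
                raise EventParseError(
                    f"record {rid}: pairing_type missing for pair schema"
                )
            records_p.append(
                PairRecord(
                    pair_id=rid,
                    pairing_type=ptype,
                    copulations=rec["copulations"],
                    sucks=rec["sucks"],
                    window_s=window_s,
                )
            )
        return records_p

    records_d: list[DropRecord] = []
    for rid in order:
        rec = rows_by_record[rid]
        if rec["sucks"]:
            raise EventParseError(f"record {rid}: suck events in a drop log")
        records_d.append(
            DropRecord(drop_id=rid, copulations=rec["copulations"], window_s=window_s)
        )
    return records_d


def write_event_log(records: Iterable[Union[PairRecord, DropRecord]], path) -> None:
    """Write records back to the documented CSV event-log format."""
    path = str(path)
    delimiter = "\t" if path.endswith((".tsv", ".txt")) else ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(EVENT_LOG_COLUMNS)
        for rec in records:
            if isinstance(rec, PairRecord):
                rid, kind, ptype = rec.pair_id, "pair", rec.pairing_type
                events: list[Event] = list(rec.copulations) + list(rec.sucks)
            else:
                rid, kind, ptype = rec.drop_id, "drop", ""
                events = list(rec.copulations)
            for e in sorted(events, key=lambda ev: (ev.start_s, ev.end_s)):
                if isinstance(e, CopulationEvent):
                    writer.writerow(
                        [rid, kind, ptype, "copulation", e.actor_a, e.actor_b,
                         e.start_s, e.end_s, e.copulation_type, ""]
                    )
                else:
                    writer.writerow(
                        [rid, kind, ptype, "suck", "", "", e.start_s, e.end_s,
                         "NA",
                         "" if e.preceding_copulation_index is None
                         else e.preceding_copulation_index]
                    )


def read_drop_metadata(path) -> dict[str, dict]:
    """Read the drop metadata CSV (drop_id, chamber_id, excluded, reason)."""
    meta: dict[str, dict] = {}
    with open(str(path), newline="") as fh:
        reader = csv.DictReader(
            row for row in fh if not row.startswith("#")
        )
        if reader.fieldnames is None or set(DROP_META_COLUMNS) - set(
            reader.fieldnames
        ):
            raise EventParseError(
                f"{path}: header must contain columns {DROP_META_COLUMNS}"
            )
        for row_num, row in enumerate(reader, start=2):
            excluded = row["excluded"].strip()
            if excluded not in ("0", "1"):
                raise EventParseError(
                    f"row {row_num}: excluded must be 0 or 1, got {excluded!r}"
                )
            meta[row["drop_id"]] = {
                "chamber_id": row["chamber_id"],
                "excluded": excluded == "1",
                "exclusion_reason": row["exclusion_reason"] or None,
            }
    return meta


def apply_drop_metadata(
    drops: Sequence[DropRecord], meta: dict[str, dict]
) -> list[DropRecord]:
    """Attach chamber ids and exclusion flags from a metadata table."""
    out = []
    for d in drops:
        m = meta.get(d.drop_id)
        if m is None:
            out.append(d)
        else:
            out.append(
                replace(
                    d,
                    chamber_id=m["chamber_id"],
                    excluded=m["excluded"],
                    exclusion_reason=m["exclusion_reason"],
                )
            )
    return out


def filter_drops(drops: Sequence[DropRecord]) -> list[DropRecord]:
    """Drop excluded replicates, logging the exclusion tally by reason.

    Idempotent: the retained records all have the excluded flag unset.
    """
    reasons: dict[str, int] = {}
    kept = []
    for d in drops:
        if d.excluded:
            reasons[d.exclusion_reason or "other"] = (
                reasons.get(d.exclusion_reason or "other", 0) + 1
            )
        else:
            kept.append(d)
    if reasons:
        tally = ", ".join(f"{k}: {v}" for k, v in sorted(reasons.items()))
        logger.info(
            "excluded %d of %d drops (%s); %d retained",
            len(drops) - len(kept), len(drops), tally, len(kept),
        )
    return kept
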