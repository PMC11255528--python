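"""Date-keyed alignment of viral-load series from the two sources.

Up to three (value, date) viral-load entries are abstracted per source,
position 1 being the most recent.  Positional comparison is misleading
when the EHR lags the paper chart by one result — the EHR's newest entry
then equals the paper chart's *second* newest.  Aligning on the recorded
date instead pairs entries that refer to the same lab result; an entry
whose date appears in only one source counts as missing in the other.

Two derived views are produced: "all viral loads" (per-pair match flags
over the date-aligned series) and "at least one viral load" (does the
EHR's most recent value match any of the <=3 paper values).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

from .normalization import vl_values_match

__all__ = ["VLEntry", "AlignedPair", "AlignedVLSeries", "align_vl",
           "vl_pair_match", "at_least_one_vl"]

logger = logging.getLogger(__name__)

MAX_ENTRIES = 3


@dataclass(frozen=True)
class VLEntry:
    """One viral-load record from one source.

    ``position`` is 1..3 with 1 the most recent; ``value`` in copies/mL
    and ``date`` may each be missing (None).
    """

    value: float | None
    date: datetime.date | None
    source: str  # "paper" | "ehr"
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MAX_ENTRIES:
            raise ValueError(f"position must be 1..{MAX_ENTRIES}")
        if self.source not in ("paper", "ehr"):
            raise ValueError("source must be 'paper' or 'ehr'")


@dataclass(frozen=True)
class AlignedPair:
    """A date-keyed pair; one side may be absent (entry missing there)."""

    paper: VLEntry | None
    ehr: VLEntry | None

    def __post_init__(self) -> None:
        if self.paper is None and self.ehr is None:
            raise ValueError("a pair needs at least one present side")
        if (self.paper is not None and self.ehr is not None
                and self.paper.date != self.ehr.date):
            raise ValueError("two-sided pairs must share a date")

    @property
    def complete(self) -> bool:
        return self.paper is not None and self.ehr is not None

    @property
    def date(self) -> datetime.date | None:
        side = self.paper if self.paper is not None else self.ehr
        return side.date


@dataclass(frozen=True)
class AlignedVLSeries:
    """Result of :func:`align_vl` plus the derived match flags."""

    pairs: tuple[AlignedPair, ...]
    #: per-pair flags: True/False for complete pairs with both values,
    #: None where a side (or a value) is absent — "all viral loads" view
    all_viral_loads: tuple[bool | None, ...]
    #: "at least one viral load": EHR's newest value matches any paper value
    at_least_one: bool

    @property
    def n_unpaired_paper(self) -> int:
        return sum(1 for p in self.pairs if p.ehr is None)

    @property
    def n_unpaired_ehr(self) -> int:
        return sum(1 for p in self.pairs if p.paper is None)

    @property
    def most_recent_pair(self) -> AlignedPair | None:
        """The pair with the newest date (dated pairs only)."""
        dated = [p for p in self.pairs if p.date is not None]
        return dated[0] if dated else None


def vl_pair_match(pair: AlignedPair) -> bool | None:
    """Match flag for a pair: None when not applicable (one-sided pair
    or a missing value), else value agreement within 1 copy/mL."""
    if not pair.complete:
        return None
    if pair.paper.value is None or pair.ehr.value is None:
        return None
    return vl_values_match(pair.paper.value, pair.ehr.value)


def _most_recent_value(entries: list[VLEntry]) -> float | None:
    """Newest non-missing value: by date where dated, else by position."""
    valued = [e for e in entries if e.value is not None]
    if not valued:
        return None
    dated = [e for e in valued if e.date is not None]
    if dated:
        return max(dated, key=lambda e: e.date).value
    return min(valued, key=lambda e: e.position).value


def at_least_one_vl(paper_entries: list[VLEntry],
                    ehr_entries: list[VLEntry]) -> bool:
    """Whether the EHR's most recent value matches any paper value."""
    newest = _most_recent_value(ehr_entries)
    if newest is None:
        return False
    return any(e.value is not None and vl_values_match(newest, e.value)
               for e in paper_entries)


def _check_entries(entries: list[VLEntry], source: str) -> None:
    if len(entries) > MAX_ENTRIES:
        raise ValueError(f"more than {MAX_ENTRIES} {source} entries")
    positions = [e.position for e in entries]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate positions in {source} entries")
    for e in entries:
        if e.source != source:
            raise ValueError(f"entry {e} is not from source {source!r}")


def align_vl(paper_entries: list[VLEntry],
             ehr_entries: list[VLEntry]) -> AlignedVLSeries:
    """Pair the two viral-load series on exact calendar date.

    Entries pair iff their dates are equal; unpaired entries (including
    all undated ones) become one-sided pairs, i.e. missing in the other
    source.  Pairs are ordered by date descending, undated entries last.
    Duplicate same-source dates are paired deterministically in position
    order with a logged warning.  Every input entry appears in exactly
    one pair.
    """
    _check_entries(paper_entries, "paper")
    _check_entries(ehr_entries, "ehr")

    by_pos = lambda e: e.position
    paper_dated = sorted((e for e in paper_entries if e.date is not None), key=by_pos)
    ehr_dated = sorted((e for e in ehr_entries if e.date is not None), key=by_pos)

    for name, dated in (("paper", paper_dated), ("ehr", ehr_dated)):
        dates = [e.date for e in dated]
        if len(set(dates)) != len(dates):
            logger.warning(
                "duplicate %s-source viral-load dates %s; pairing by position",
                name, sorted(d.isoformat() for d in dates),
            )

    pairs: list[AlignedPair] = []
    ehr_pool = list(ehr_dated)
    for p in paper_dated:
        mate = next((e for e in ehr_pool if e.date == p.date), None)
        if mate is not None:
            ehr_pool.remove(mate)
        pairs.append(AlignedPair(paper=p, ehr=mate))
    pairs.extend(AlignedPair(paper=None, ehr=e) for e in ehr_pool)

    pairs.sort(key=lambda pr: pr.date, reverse=True)
    pairs.extend(AlignedPair(paper=e, ehr=None)
                 for e in paper_entries if e.date is None)
    pairs.extend(AlignedPair(paper=None, ehr=e)
                 for e in ehr_entries if e.date is None)

    flags = tuple(vl_pair_match(pr) for pr in pairs)
    return AlignedVLSeries(
        pairs=tuple(pairs),
        all_viral_loads=flags,
        at_least_one=at_least_one_vl(paper_entries, ehr_entries),
    )
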