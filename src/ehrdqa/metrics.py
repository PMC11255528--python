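"""Completeness, matching, concordance scores and LQAS classification.

These are the dataset- and facility-level audit metrics:

* **completeness** — fraction of records with a non-missing value for a
  variable in one source ("number of fields filled divided by all
  fields");
* **matching** — among records non-missing in *both* sources, the
  fraction whose standardized values are equal;
* **concordance score** — per record, the count (0-15) of designated
  variables that either match or are missing in both sources;
* **LQAS classification** — each metric is flagged "high quality" at a
  >=85% threshold, following the lot-quality-assurance-sampling audit
  design in which 48-76 randomly sampled charts per facility suffice to
  classify the facility against that threshold.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .normalization import (
    DEFAULT_MISSINGNESS,
    MissingnessConfig,
    RawValue,
    is_missing,
    values_match,
    vl_values_match,
)
from .variables import (
    CONCORDANCE_VARIABLES,
    SPEC_BY_NAME,
    VARIABLE_NAMES,
    VariableKind,
    VariableSpec,
    get_spec,
)
from .vl_alignment import MAX_ENTRIES, AlignedVLSeries, VLEntry, align_vl

__all__ = [
    "QUALITY_THRESHOLD",
    "RecordPair",
    "MetricResult",
    "Concordance",
    "ConcordanceResult",
    "completeness",
    "matching",
    "concordance_score",
    "date_error_profile",
    "facility_summary",
    "lqas_sample_size",
]

#: LQAS quality threshold: a metric at or above 85% is "high quality".
QUALITY_THRESHOLD = 0.85


@dataclass
class RecordPair:
    """One patient's 28-variable record abstracted from both sources."""

    patient_id: str
    facility_id: str
    values: dict[str, tuple[RawValue, RawValue]]  # name -> (paper, ehr)
    missingness: MissingnessConfig = field(default=DEFAULT_MISSINGNESS)
    _vl_series: AlignedVLSeries | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        absent = [n for n in VARIABLE_NAMES if n not in self.values]
        if absent:
            raise ValueError(f"record {self.patient_id!r} lacks variables {absent}")

    def paper(self, name: str) -> RawValue:
        return self.values[name][0]

    def ehr(self, name: str) -> RawValue:
        return self.values[name][1]

    def value(self, name: str, source: str) -> RawValue:
        idx = 0 if source == "paper" else 1
        return self.values[name][idx]

    def _entries(self, source: str) -> list[VLEntry]:
        cfg = self.missingness
        out: list[VLEntry] = []
        for pos in range(1, MAX_ENTRIES + 1):
            vspec = get_spec(f"vl{pos}_value")
            dspec = get_spec(f"vl{pos}_date")
            vraw = self.value(f"vl{pos}_value", source)
            draw = self.value(f"vl{pos}_date", source)
            value = None if is_missing(vraw, vspec, cfg) else float(vraw.parsed)
            date = None if is_missing(draw, dspec, cfg) else draw.parsed
            if value is not None or date is not None:
                out.append(VLEntry(value=value, date=date, source=source,
                                   position=pos))
        return out

    @property
    def vl_series(self) -> AlignedVLSeries:
        """Date-aligned viral-load series (built lazily, cached)."""
        if self._vl_series is None:
            self._vl_series = align_vl(self._entries("paper"),
                                       self._entries("ehr"))
        return self._vl_series

    @property
    def record_date(self) -> datetime.date | None:
        """Anchor date for post-intervention filtering: the last-visit
        date (paper chart, falling back to the EHR)."""
        for source in ("paper", "ehr"):
            raw = self.value("date_last_visit", source)
            if not is_missing(raw, get_spec("date_last_visit"), self.missingness):
                return raw.parsed
        return None


@dataclass(frozen=True)
class MetricResult:
    """A (numerator, denominator, fraction, quality-flag) bundle."""

    variable: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")

    @property
    def fraction(self) -> float | None:
        """Proportion in [0,1]; None (not applicable) when the
        denominator is zero, as happens for variables with no data."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def high_quality(self) -> bool | None:
        f = self.fraction
        return None if f is None else f >= QUALITY_THRESHOLD

    @property
    def percent(self) -> float | None:
        f = self.fraction
        return None if f is None else 100.0 * f


class Concordance(enum.Enum):
    MATCH = "concordant_match"
    BOTH_MISSING = "concordant_both_missing"
    DISCORDANT = "discordant"


@dataclass(frozen=True)
class ConcordanceResult:
    patient_id: str
    per_variable: Mapping[str, Concordance]

    @property
    def score(self) -> int:
        """0..15: count of variables that match or are missing in both."""
        return sum(1 for c in self.per_variable.values()
                   if c is not Concordance.DISCORDANT)


def completeness(records: Sequence[RecordPair], variable: str,
                 source: str) -> MetricResult:
    """Fraction of records with a non-missing value in one source."""
    if not records:
        raise ValueError("empty record collection")
    if source not in ("paper", "ehr"):
        raise ValueError("source must be 'paper' or 'ehr'")
    spec = get_spec(variable)
    n = sum(1 for r in records
            if not is_missing(r.value(variable, source), spec, r.missingness))
    return MetricResult(variable=variable, numerator=n, denominator=len(records))


def matching(records: Sequence[RecordPair], variable: str) -> MetricResult:
    """Among records complete in both sources, the fraction matching."""
    if not records:
        raise ValueError("empty record collection")
    spec = get_spec(variable)
    denom = num = 0
    for r in records:
        p, e = r.values[variable]
        if is_missing(p, spec, r.missingness) or is_missing(e, spec, r.missingness):
            continue
        denom += 1
        if values_match(p, e, spec, r.missingness):
            num += 1
    return MetricResult(variable=variable, numerator=num, denominator=denom)


def _concordance_cell(record: RecordPair, spec: VariableSpec,
                      use_aligned_vl: bool) -> Concordance:
    name = spec.name
    cfg = record.missingness
    if use_aligned_vl and name in ("vl1_value", "vl1_date"):
        pair = record.vl_series.most_recent_pair
        if name == "vl1_value":
            pv = pair.paper.value if pair and pair.paper else None
            ev = pair.ehr.value if pair and pair.ehr else None
            if pv is None and ev is None:
                return Concordance.BOTH_MISSING
            if pv is None or ev is None:
                return Concordance.DISCORDANT
            return (Concordance.MATCH if vl_values_match(pv, ev)
                    else Concordance.DISCORDANT)
        pd_ = pair.paper.date if pair and pair.paper else None
        ed = pair.ehr.date if pair and pair.ehr else None
        if pd_ is None and ed is None:
            return Concordance.BOTH_MISSING
        if pd_ is None or ed is None:
            return Concordance.DISCORDANT
        return Concordance.MATCH if pd_ == ed else Concordance.DISCORDANT
    p, e = record.values[name]
    pm, em = is_missing(p, spec, cfg), is_missing(e, spec, cfg)
    if pm and em:
        return Concordance.BOTH_MISSING
    if pm or em:
        return Concordance.DISCORDANT
    return (Concordance.MATCH if values_match(p, e, spec, cfg)
            else Concordance.DISCORDANT)


def concordance_score(record: RecordPair,
                      specs: Iterable[VariableSpec] = CONCORDANCE_VARIABLES,
                      use_aligned_vl: bool = True) -> ConcordanceResult:
    """Per-record concordance over the 15 designated variables.

    A variable is concordant if the standardized values match *or* the
    field is missing in both sources; missing in exactly one source, or
    present-but-unequal, is discordant.  With ``use_aligned_vl`` the
    most-recent viral-load value/date comes from the date-aligned pair
    rather than the positional slot.
    """
    per = {s.name: _concordance_cell(record, s, use_aligned_vl) for s in specs}
    return ConcordanceResult(patient_id=record.patient_id, per_variable=per)


def date_error_profile(records: Sequence[RecordPair], variable: str,
                       month_days: int = 30,
                       quarter_days: int = 90) -> dict[str, float]:
    """Distribution of |paper - EHR| among mismatching dates.

    Restricted to records complete in both sources whose dates differ;
    returns bucket fractions for <=1 month (30 days), 1-3 months and
    >3 months, plus the cumulative within-1/3-month shares.  Empty dict
    when there are no mismatches.
    """
    spec = get_spec(variable)
    if spec.kind is not VariableKind.DATE:
        raise ValueError(f"{variable!r} is not a date variable")
    diffs: list[int] = []
    for r in records:
        p, e = r.values[variable]
        if is_missing(p, spec, r.missingness) or is_missing(e, spec, r.missingness):
            continue
        if p.parsed != e.parsed:
            diffs.append(abs((p.parsed - e.parsed).days))
    if not diffs:
        return {}
    n = len(diffs)
    le_month = sum(d <= month_days for d in diffs)
    le_quarter = sum(d <= quarter_days for d in diffs)
    return {
        "n_mismatches": n,
        "within_1_month": le_month / n,
        "1_to_3_months": (le_quarter - le_month) / n,
        "beyond_3_months": (n - le_quarter) / n,
        "cum_within_1_month": le_month / n,
        "cum_within_3_months": le_quarter / n,
    }


def facility_summary(records: Sequence[RecordPair],
                     facility_ids: Iterable[str],
                     use_aligned_vl: bool = True) -> pd.DataFrame:
    """Per-facility table of record counts, mean concordance and
    per-variable matching fractions.

    The dataset-level mean concordance equals the record-weighted mean
    of the facility rows.  Raises if any record references a facility
    absent from ``facility_ids``.
    """
    known = set(facility_ids)
    orphans = sorted({r.facility_id for r in records} - known)
    if orphans:
        raise ValueError(f"records reference unknown facilities: {orphans}")

    rows: dict[str, dict] = {}
    by_fac: dict[str, list[RecordPair]] = {}
    for r in records:
        by_fac.setdefault(r.facility_id, []).append(r)
    for fac, recs in sorted(by_fac.items()):
        scores = [concordance_score(r, use_aligned_vl=use_aligned_vl).score
                  for r in recs]
        mean_score = sum(scores) / len(scores)
        row = {
            "n_records": len(recs),
            "mean_concordance": mean_score,
            "concordance_fraction": mean_score / len(CONCORDANCE_VARIABLES),
        }
        row["high_quality"] = row["concordance_fraction"] >= QUALITY_THRESHOLD
        for name in VARIABLE_NAMES:
            m = matching(recs, name)
            row[f"match_{name}"] = math.nan if m.fraction is None else m.fraction
        rows[fac] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "facility_id"
    return df


def lqas_sample_size(patient_volume: int, min_size: int = 48,
                     max_size: int = 76, lo_volume: int = 100,
                     hi_volume: int = 1000) -> int:
    """Charts to sample at a facility under the LQAS audit design.

    Monotone nondecreasing in patient volume: the minimum sample (48)
    below ``lo_volume``, the maximum (76) above ``hi_volume``, linear
    interpolation between, always clamped to ``[min_size,
    min(volume, max_size)]`` (a facility cannot contribute more charts
    than it has patients).
    """
    if patient_volume < 1:
        raise ValueError("patient volume must be >= 1")
    if patient_volume <= lo_volume:
        size = min_size
    elif patient_volume >= hi_volume:
        size = max_size
    else:
        frac = (patient_volume - lo_volume) / (hi_volume - lo_volume)
        size = round(min_size + frac * (max_size - min_size))
    return min(size, patient_volume, max_size)
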