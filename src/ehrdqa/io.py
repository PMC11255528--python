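"""File schemas: record-pair tables, facility tables, run configuration.

The record-pair file is delimited text with one row per patient and a
fixed, versioned header: ``patient_id``, ``facility_id``, then a
``paper_<variable>`` / ``ehr_<variable>`` column pair for each of the
28 variables (58 columns total).  Dates are ISO-8601 ``YYYY-MM-DD`` in
files regardless of the source dialect; a day-first option converts
``DD/MM/YYYY`` input at read time.  Round-tripping a dataset through
write/read is lossless.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .association import FacilityProfile
from .metrics import QUALITY_THRESHOLD, RecordPair
from .normalization import DEFAULT_MISSINGNESS, MissingnessConfig, RawValue
from .simulate import GroundTruth
from .variables import SPEC_BY_NAME, VARIABLE_NAMES, VariableKind

__all__ = [
    "SCHEMA_VERSION", "RECORD_COLUMNS", "RunConfig",
    "read_record_pairs", "write_record_pairs",
    "read_facilities", "write_facilities", "write_ground_truth",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

RECORD_COLUMNS: tuple[str, ...] = ("patient_id", "facility_id") + tuple(
    f"{source}_{name}" for name in VARIABLE_NAMES for source in ("paper", "ehr")
)

FACILITY_COLUMNS = ("facility_id", "arm", "alert_tier", "ehr_availability",
                    "tech_experience", "years_ehr_use")

_DAYFIRST_RE = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on besides its input files."""

    threshold: float = QUALITY_THRESHOLD
    cutoff_date: datetime.date = datetime.date(2018, 7, 1)
    continuity: bool = True
    bootstrap_reps: int = 2000
    bonferroni_m: int = 3
    use_aligned_vl: bool = True
    seed: int = 0
    missingness: MissingnessConfig = field(default=DEFAULT_MISSINGNESS)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        if self.bootstrap_reps < 1 or self.bonferroni_m < 1:
            raise ValueError("bootstrap_reps and bonferroni_m must be >= 1")

    def to_dict(self) -> dict:
        m = self.missingness
        return {
            "schema_version": SCHEMA_VERSION,
            "threshold": self.threshold,
            "cutoff_date": self.cutoff_date.isoformat(),
            "continuity": self.continuity,
            "bootstrap_reps": self.bootstrap_reps,
            "bonferroni_m": self.bonferroni_m,
            "use_aligned_vl": self.use_aligned_vl,
            "seed": self.seed,
            "missingness": {
                "collection_date": m.collection_date.isoformat(),
                "hiv_epoch": m.hiv_epoch.isoformat(),
                "sentinel_dates": sorted(d.isoformat() for d in m.sentinel_dates),
                "na_codes": sorted(m.na_codes),
                "dob_floor": m.dob_floor.isoformat(),
                "regimen_synonyms": dict(m.regimen_synonyms),
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        data.pop("schema_version", None)
        if "missingness" in data:
            m = data["missingness"]
            data["missingness"] = MissingnessConfig(
                collection_date=datetime.date.fromisoformat(m["collection_date"]),
                hiv_epoch=datetime.date.fromisoformat(m["hiv_epoch"]),
                sentinel_dates=frozenset(
                    datetime.date.fromisoformat(d) for d in m["sentinel_dates"]),
                na_codes=frozenset(m["na_codes"]),
                dob_floor=datetime.date.fromisoformat(m["dob_floor"]),
                regimen_synonyms=dict(m.get("regimen_synonyms", {})),
            )
        if isinstance(data.get("cutoff_date"), str):
            data["cutoff_date"] = datetime.date.fromisoformat(data["cutoff_date"])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _maybe_dayfirst(text: str) -> str:
    m = _DAYFIRST_RE.match(text.strip())
    if not m:
        return text
    day, month, year = (int(g) for g in m.groups())
    try:
        return datetime.date(year, month, day).isoformat()
    except ValueError:
        return text


def write_record_pairs(records: Sequence[RecordPair], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "facility_id": r.facility_id}
        for name in VARIABLE_NAMES:
            p, e = r.values[name]
            row[f"paper_{name}"] = p.text
            row[f"ehr_{name}"] = e.text
        rows.append(row)
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(path, index=False)


def read_record_pairs(
    path: str | Path,
    missingness: MissingnessConfig = DEFAULT_MISSINGNESS,
    dayfirst: bool = False,
) -> list[RecordPair]:
    """Load a record-pair file.

    Malformed typed cells (unparseable dates or viral loads) load as
    missing; each is logged and counted in a single summary warning.
    Raises on missing columns or an empty data section.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    absent = [c for c in RECORD_COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")
    if df.empty:
        raise ValueError(f"{path}: empty data section")

    records: list[RecordPair] = []
    n_malformed = 0
    for _, row in df.iterrows():
        values: dict[str, tuple[RawValue, RawValue]] = {}
        for name in VARIABLE_NAMES:
            kind = SPEC_BY_NAME[name].kind
            pair = []
            for source in ("paper", "ehr"):
                text = str(row[f"{source}_{name}"])
                if dayfirst and kind is VariableKind.DATE:
                    text = _maybe_dayfirst(text)
                rv = RawValue(text, kind)
                if (kind in (VariableKind.DATE, VariableKind.VIRAL_LOAD)
                        and text.strip() and rv.parsed is None):
                    n_malformed += 1
                    logger.warning(
                        "malformed %s cell %r (%s, patient %s); treated as missing",
                        kind.value, text, f"{source}_{name}", row["patient_id"],
                    )
                pair.append(rv)
            values[name] = (pair[0], pair[1])
        records.append(RecordPair(patient_id=str(row["patient_id"]),
                                  facility_id=str(row["facility_id"]),
                                  values=values, missingness=missingness))
    if n_malformed:
        logger.warning("%s: %d malformed cell(s) treated as missing",
                       path, n_malformed)
    return records


def write_facilities(facilities: Iterable[FacilityProfile],
                     path: str | Path) -> None:
    rows = [dataclasses.asdict(f) for f in facilities]
    pd.DataFrame(rows, columns=list(FACILITY_COLUMNS)).to_csv(path, index=False)


def read_facilities(path: str | Path) -> list[FacilityProfile]:
    df = pd.read_csv(path)
    absent = [c for c in FACILITY_COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(f"{path}: missing required columns {absent}")
    if df.empty:
        raise ValueError(f"{path}: empty data section")
    return [
        FacilityProfile(
            facility_id=str(row.facility_id), arm=str(row.arm),
            alert_tier=int(row.alert_tier),
            ehr_availability=int(row.ehr_availability),
            tech_experience=int(row.tech_experience),
            years_ehr_use=float(row.years_ehr_use),
        )
        for row in df.itertuples()
    ]


def write_ground_truth(truth: GroundTruth, truth_path: str | Path,
                       labels_path: str | Path) -> None:
    truth.truth.to_csv(truth_path)
    truth.labels.to_csv(labels_path)
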