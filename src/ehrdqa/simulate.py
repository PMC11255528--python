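"""Study-shaped synthetic dual-source datasets with known error processes.

The generator emulates the structure of a facility-level chart audit:
50 facilities (half in the intervention arm of a trial of EHR clinical
alerts, a nested subset of those receiving the missing-viral-load
alert), 48-76 randomly sampled charts per facility, and 28 variables
abstracted from both the paper chart and the EHR.  Observed values in
both sources derive from a single ground truth through independent,
labelled error processes:

* per-cell missingness (blank, coded-NA, or a sentinel 1980-01-01 date);
* date transcription errors with a small-offset mixture (most errors of
  "one-off" dates fall within a month of the truth; repeated dates err
  by larger gaps);
* a series-level viral-load lag in which the EHR misses the newest
  paper result, shifting its entries by one position;
* drug-regimen separator variants ("A + B and C") that canonicalize
  identically, and viral-load decimal-precision variants within
  1 copy/mL;
* an alert effect multiplying the EHR's entry and date-correctness
  probabilities for viral-load and pickup variables at alert facilities
  after the rollout date;
* facility covariates (EHR availability, technology experience) that
  scale the EHR error rates, giving the concordance-covariate
  correlations a known sign.

Every observed-vs-truth discrepancy carries exactly one error label in
the returned :class:`GroundTruth` sidecar.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import FacilityProfile
from .metrics import RecordPair, completeness, lqas_sample_size, matching
from .normalization import MissingnessConfig, RawValue
from .variables import SPEC_BY_NAME, VARIABLE_NAMES, VariableKind

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset",
           "recover_parameters", "expected_completeness", "expected_matching"]

DAY = datetime.timedelta(days=1)

# Default per-variable marginal missingness (paper, ehr), emulating a
# mature HIV-care EHR deployment: demographics and one-off dates nearly
# complete, repeated lab results much less complete electronically.
DEFAULT_MISSING: dict[str, tuple[float, float]] = {
    "date_of_birth": (0.001, 0.0005),
    "gender": (0.0075, 0.0),
    "district": (0.0, 0.0),
    "sector": (0.0, 0.0),
    "facility_name": (0.0, 0.0),
    "date_last_visit": (0.001, 0.0006),
    "date_first_positive_test": (0.218, 0.344),
    "date_enrollment": (0.003, 0.003),
    "date_first_art": (0.001, 0.024),
    "who_stage": (0.010, 0.058),
    "regimen1_start_date": (0.018, 0.024),
    "regimen1_drugs": (0.016, 0.045),
    "pickup1_date": (0.0003, 0.0006),
    "pickup1_drugs": (0.0003, 0.045),
    "pickup2_date": (0.010, 0.024),
    "pickup2_drugs": (0.010, 0.068),
    "pickup3_date": (0.021, 0.058),
    "pickup3_drugs": (0.020, 0.099),
}

# EHR date-transcription error probability per variable (before the
# facility-covariate multiplier); repeated dates are rarely kept up to
# date in the EHR, one-off enrollment-era dates mostly suffer small
# transcription slips.
DEFAULT_DATE_ERROR_EHR: dict[str, float] = {
    "date_of_birth": 0.064,
    "date_last_visit": 0.70,
    "date_first_positive_test": 0.40,
    "date_enrollment": 0.25,
    "date_first_art": 0.28,
    "regimen1_start_date": 0.28,
    "regimen2_start_date": 0.46,
    "regimen3_start_date": 0.46,
    "pickup1_date": 0.72,
    "pickup2_date": 0.79,
    "pickup3_date": 0.83,
    "vl1_date": 0.868, "vl2_date": 0.868, "vl3_date": 0.868,
}

# Offset mixture for corrupted dates: P(<=30 d), P(31-90 d), P(>90 d).
ONE_OFF_OFFSET_WEIGHTS = (0.36, 0.20, 0.44)
REPEATED_OFFSET_WEIGHTS = (0.12, 0.20, 0.68)

# Mismatch probability for non-date, non-VL values entered in the EHR.
DEFAULT_VALUE_ERROR_EHR: dict[str, float] = {
    "gender": 0.034,
    "district": 0.004,
    "sector": 0.04,
    "facility_name": 0.0,
    "who_stage": 0.15,
    "regimen1_drugs": 0.18,
    "regimen2_drugs": 0.40,
    "regimen3_drugs": 0.40,
    "pickup1_drugs": 0.16,
    "pickup2_drugs": 0.16,
    "pickup3_drugs": 0.16,
}

FIRST_LINE_REGIMENS = (
    "Tenofovir (300) + Lamivudine (300) + Efavirenz (600)",
    "Tenofovir (300) + Lamivudine (300) + Dolutegravir (50)",
    "Zidovudine (300) + Lamivudine (150) + Nevirapine (200)",
    "Abacavir (600) + Lamivudine (300) + Efavirenz (600)",
)
SECOND_LINE_REGIMENS = (
    "Zidovudine (300) + Lamivudine (150) + Lopinavir (200)",
    "Tenofovir (300) + Lamivudine (300) + Atazanavir (300)",
    "Abacavir (600) + Lamivudine (300) + Lopinavir (200)",
)
WHO_STAGES = ("Stage I", "Stage II", "Stage III", "Stage IV")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study-shaped conditions."""

    n_facilities: int = 50
    intervention_fraction: float = 0.5
    vl_alert_fraction_of_intervention: float = 11 / 25
    tier3_fraction_of_alert: float = 0.5
    charts_per_facility_range: tuple[int, int] = (48, 76)
    #: lognormal patient-volume model feeding the LQAS size table;
    #: median/sigma chosen to put the mean sample near 69 charts
    volume_log_median: float = math.log(1100.0)
    volume_log_sigma: float = 1.1
    collection_date: datetime.date = datetime.date(2018, 12, 1)
    cutoff_date: datetime.date = datetime.date(2018, 7, 1)

    missing_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MISSING))
    date_error_ehr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DATE_ERROR_EHR))
    value_error_ehr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VALUE_ERROR_EHR))
    date_error_paper: float = 0.01
    value_error_paper: float = 0.01
    sentinel_date_rate: float = 0.25
    na_code_rate: float = 0.10

    # second/third-line regimens: truth presence, then per-source entry
    regimen2_truth_prob: float = 0.04
    regimen2_entry_probs: tuple[float, float] = (0.97, 0.62)  # (paper, ehr)
    regimen3_truth_prob: float = 0.0005
    regimen3_entry_probs: tuple[float, float] = (0.0, 0.6)

    # viral-load series
    vl_count_probs: tuple[float, float, float, float] = (0.05, 0.09, 0.16, 0.70)
    ehr_vl_lag_prob: float = 0.25
    ehr_vl_entry_probs: tuple[float, float, float] = (0.82, 0.64, 0.62)
    vl_value_error_ehr: float = 0.05
    vl_decimal_prob: float = 0.30
    regimen_split_prob: float = 0.15

    alert_effect: float = 2.24
    covariate_effects: tuple[float, float] = (0.12, -0.08)  # availability, tech
    availability_probs: tuple[float, ...] = (0.05, 0.10, 0.20, 0.35, 0.30)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.intervention_fraction,
                 self.vl_alert_fraction_of_intervention,
                 self.tier3_fraction_of_alert, self.sentinel_date_rate,
                 self.na_code_rate, self.ehr_vl_lag_prob,
                 self.vl_value_error_ehr, self.vl_decimal_prob,
                 self.regimen_split_prob, self.date_error_paper,
                 self.value_error_paper, self.regimen2_truth_prob,
                 self.regimen3_truth_prob,
                 *self.vl_count_probs, *self.ehr_vl_entry_probs,
                 *self.availability_probs,
                 *self.regimen2_entry_probs, *self.regimen3_entry_probs,
                 *(r for pair in self.missing_rates.values() for r in pair),
                 *self.date_error_ehr.values(), *self.value_error_ehr.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.vl_count_probs), 1.0, abs_tol=1e-9):
            raise ValueError("vl_count_probs must sum to 1")
        if not math.isclose(sum(self.availability_probs), 1.0, abs_tol=1e-9):
            raise ValueError("availability_probs must sum to 1")
        lo, hi = self.charts_per_facility_range
        if not 1 <= lo <= hi:
            raise ValueError("charts_per_facility_range must be a nonempty range")
        if self.alert_effect <= 0:
            raise ValueError("alert_effect must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def noiseless(cls, **kw) -> "SimulationConfig":
        """Zero-error limit: every truth field present, no missingness
        or corruption in either source — both sources render the truth
        identically, so every metric is 100% and every concordance
        score is 15."""
        base = dict(
            missing_rates={k: (0.0, 0.0) for k in DEFAULT_MISSING},
            date_error_ehr={k: 0.0 for k in DEFAULT_DATE_ERROR_EHR},
            value_error_ehr={k: 0.0 for k in DEFAULT_VALUE_ERROR_EHR},
            date_error_paper=0.0, value_error_paper=0.0,
            sentinel_date_rate=0.0, na_code_rate=0.0,
            regimen2_truth_prob=1.0, regimen2_entry_probs=(1.0, 1.0),
            regimen3_truth_prob=1.0, regimen3_entry_probs=(1.0, 1.0),
            vl_count_probs=(0.0, 0.0, 0.0, 1.0),
            ehr_vl_lag_prob=0.0, ehr_vl_entry_probs=(1.0, 1.0, 1.0),
            vl_value_error_ehr=0.0, vl_decimal_prob=0.0,
            regimen_split_prob=0.0, alert_effect=1.0,
            covariate_effects=(0.0, 0.0),
        )
        base.update(kw)
        return cls(**base)

    @property
    def missingness(self) -> MissingnessConfig:
        return MissingnessConfig(collection_date=self.collection_date)


@dataclass
class GroundTruth:
    """True values plus a per-cell error label for every discrepancy.

    ``labels`` holds one column per (source, variable) cell with an
    empty string where the observed text renders the truth faithfully,
    else exactly one of ``missing``, ``sentinel``, ``na_code``,
    ``transcribed``, ``lagged``, ``split``, ``precision`` or ``wrong_value``.
    """

    truth: pd.DataFrame
    labels: pd.DataFrame


def _covariate_error_multiplier(cfg: SimulationConfig, availability: int,
                                tech: int) -> float:
    """EHR error-rate multiplier from facility covariates: 1 at neutral
    covariates, <1 for high availability, >1 for high tech-experience
    (whose slope is negative on quality)."""
    a_slope, t_slope = cfg.covariate_effects
    eta = a_slope * (availability - 3) + t_slope * (tech - 2)
    return 2.0 / (1.0 + math.exp(eta))


def _rand_date(rng: np.random.Generator, lo: datetime.date,
               hi: datetime.date) -> datetime.date:
    span = (hi - lo).days
    return lo + int(rng.integers(0, span + 1)) * DAY


def _offset_days(rng: np.random.Generator, weights: tuple[float, ...]) -> int:
    bucket = rng.choice(3, p=weights)
    if bucket == 0:
        mag = int(rng.integers(1, 31))
    elif bucket == 1:
        mag = int(rng.integers(31, 91))
    else:
        mag = int(rng.integers(91, 721))
    return mag if rng.random() < 0.5 else -mag


def _corrupt_date(rng: np.random.Generator, true: datetime.date,
                  repeated: bool, lo: datetime.date,
                  hi: datetime.date) -> datetime.date:
    """Transcription error: offset the true date, staying inside the
    plausibility window [lo, hi] (a corrupted date that looked
    impossible would be classed missing, not mismatching)."""
    w = REPEATED_OFFSET_WEIGHTS if repeated else ONE_OFF_OFFSET_WEIGHTS
    offset = _offset_days(rng, w)
    cand = true + offset * DAY
    if not lo <= cand <= hi:
        cand = true - offset * DAY
    if not lo <= cand <= hi:
        mag = abs(offset)
        room_up, room_down = (hi - true).days, (true - lo).days
        if room_up >= room_down:
            cand = true + max(1, min(mag, room_up)) * DAY
        else:
            cand = true - max(1, min(mag, room_down)) * DAY
    return cand


def _split_regimen(raw: str) -> str:
    head, sep, tail = raw.rpartition(" + ")
    return f"{head} and {tail}" if sep else raw


def _render_missing(rng: np.random.Generator, cfg: SimulationConfig,
                    kind: VariableKind) -> tuple[str, str]:
    if kind is VariableKind.DATE and rng.random() < cfg.sentinel_date_rate:
        return "1980-01-01", "sentinel"
    if kind not in (VariableKind.DATE, VariableKind.VIRAL_LOAD) \
            and rng.random() < cfg.na_code_rate:
        return "unknown", "na_code"
    return "", "missing"


class _RecordSimulator:
    """Draws one patient's truth and renders both observed sources."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator,
                 facility: FacilityProfile, facility_fields: dict[str, str]):
        self.cfg = cfg
        self.rng = rng
        self.fac = facility
        self.fac_fields = facility_fields
        self.err_mult = _covariate_error_multiplier(
            cfg, facility.ehr_availability, facility.tech_experience)

    # ---- truth -----------------------------------------------------

    def draw_truth(self) -> dict[str, object]:
        cfg, rng = self.cfg, self.rng
        t: dict[str, object] = dict(self.fac_fields)
        t["date_of_birth"] = _rand_date(rng, datetime.date(1950, 1, 1),
                                        datetime.date(2000, 12, 31))
        t["gender"] = "F" if rng.random() < 0.6 else "M"
        enroll = _rand_date(rng, datetime.date(2005, 1, 1),
                            datetime.date(2017, 12, 31))
        t["date_enrollment"] = enroll
        t["date_first_positive_test"] = enroll - int(rng.integers(0, 366)) * DAY
        first_art = enroll + int(rng.integers(0, 181)) * DAY
        t["date_first_art"] = first_art
        t["who_stage"] = WHO_STAGES[rng.choice(4, p=[0.35, 0.3, 0.25, 0.1])]
        t["regimen1_start_date"] = first_art + int(rng.integers(0, 31)) * DAY
        t["regimen1_drugs"] = FIRST_LINE_REGIMENS[
            int(rng.integers(len(FIRST_LINE_REGIMENS)))]
        for line, prob in ((2, cfg.regimen2_truth_prob),
                           (3, cfg.regimen3_truth_prob)):
            if rng.random() < prob:
                switch = t["regimen1_start_date"] + int(rng.integers(180, 2001)) * DAY
                t[f"regimen{line}_start_date"] = min(
                    switch, cfg.collection_date)
                t[f"regimen{line}_drugs"] = SECOND_LINE_REGIMENS[
                    int(rng.integers(len(SECOND_LINE_REGIMENS)))]
            else:
                t[f"regimen{line}_start_date"] = None
                t[f"regimen{line}_drugs"] = None
        last_visit = cfg.collection_date - int(rng.integers(0, 271)) * DAY
        t["date_last_visit"] = last_visit
        pickup = last_visit
        for pos in (1, 2, 3):
            t[f"pickup{pos}_date"] = pickup
            t[f"pickup{pos}_drugs"] = t["regimen1_drugs"]
            pickup = pickup - int(rng.integers(28, 95)) * DAY
        n_vl = int(rng.choice(4, p=cfg.vl_count_probs))
        vl_date = cfg.collection_date - int(rng.integers(30, 366)) * DAY
        for pos in (1, 2, 3):
            if pos <= n_vl:
                value = float(round(10 ** rng.uniform(math.log10(20), 6)))
                t[f"vl{pos}_date"] = vl_date
                t[f"vl{pos}_value"] = value
                vl_date = vl_date - int(rng.integers(90, 366)) * DAY
            else:
                t[f"vl{pos}_date"] = None
                t[f"vl{pos}_value"] = None
        return t

    # ---- observation processes -------------------------------------

    def _ehr_boost(self) -> float:
        """Alert-effect multiplier active for this record (post-rollout
        records at facilities with the missing-VL alert)."""
        return self.cfg.alert_effect if self.fac.has_vl_alert else 1.0

    def _date_window(self, name: str) -> tuple[datetime.date, datetime.date]:
        spec = SPEC_BY_NAME[name]
        m = self.cfg.missingness
        if name == "date_of_birth":
            return m.dob_floor, m.collection_date
        lo = m.hiv_epoch if spec.hiv_epoch_bound else m.dob_floor
        return lo, m.collection_date

    def _observe_date(self, name: str, true: datetime.date | None,
                      source: str, miss_prob: float,
                      err_prob: float) -> tuple[str, str]:
        rng, cfg = self.rng, self.cfg
        if true is None or rng.random() < miss_prob:
            text, label = _render_missing(rng, cfg, VariableKind.DATE)
            return text, (label if true is not None else
                          (label if text else ""))
        if rng.random() < err_prob:
            lo, hi = self._date_window(name)
            corrupted = _corrupt_date(rng, true, SPEC_BY_NAME[name].repeated,
                                      lo, hi)
            return corrupted.isoformat(), "transcribed"
        return true.isoformat(), ""

    def _observe_value(self, name: str, true: object, source: str,
                       miss_prob: float, err_prob: float) -> tuple[str, str]:
        rng, cfg = self.rng, self.cfg
        kind = SPEC_BY_NAME[name].kind
        if true is None or rng.random() < miss_prob:
            text, label = _render_missing(rng, cfg, kind)
            return text, (label if true is not None else (label if text else ""))
        if rng.random() < err_prob:
            if kind is VariableKind.DRUG_REGIMEN:
                pool = [r for r in FIRST_LINE_REGIMENS + SECOND_LINE_REGIMENS
                        if r != true]
                return pool[int(rng.integers(len(pool)))], "wrong_value"
            if name == "gender":
                return ("M" if true == "F" else "F"), "wrong_value"
            if name == "who_stage":
                pool = [s for s in WHO_STAGES if s != true]
                return pool[int(rng.integers(len(pool)))], "wrong_value"
            return f"{true} (alt)", "wrong_value"
        if kind is VariableKind.DRUG_REGIMEN and source == "ehr" \
                and rng.random() < cfg.regimen_split_prob:
            return _split_regimen(str(true)), "split"
        return str(true), ""

    def observe(self, truth: dict[str, object], post_cutoff: bool
                ) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
        cfg, rng = self.cfg, self.rng
        paper: dict[str, str] = {}
        ehr: dict[str, str] = {}
        labels: dict[str, str] = {}
        boost = self._ehr_boost() if post_cutoff else 1.0

        for name in VARIABLE_NAMES:
            if name.startswith("vl") or name.startswith("regimen2") \
                    or name.startswith("regimen3"):
                continue
            spec = SPEC_BY_NAME[name]
            true = truth[name]
            miss_p, miss_e = cfg.missing_rates.get(name, (0.0, 0.0))
            if name.startswith("pickup"):
                miss_e = max(0.0, 1.0 - (1.0 - miss_e) * boost)
            if spec.kind is VariableKind.DATE:
                err_e = min(0.98, cfg.date_error_ehr.get(name, 0.0) * self.err_mult)
                if name.startswith("pickup"):
                    err_e = 1.0 - min(1.0, (1.0 - err_e) * boost)
                paper[name], labels[f"paper_{name}"] = self._observe_date(
                    name, true, "paper", miss_p, cfg.date_error_paper)
                ehr[name], labels[f"ehr_{name}"] = self._observe_date(
                    name, true, "ehr", miss_e, err_e)
            else:
                err_e = min(0.98, cfg.value_error_ehr.get(name, 0.0) * self.err_mult)
                paper[name], labels[f"paper_{name}"] = self._observe_value(
                    name, true, "paper", miss_p, cfg.value_error_paper)
                ehr[name], labels[f"ehr_{name}"] = self._observe_value(
                    name, true, "ehr", miss_e, err_e)

        self._observe_second_line(truth, paper, ehr, labels)
        self._observe_vl(truth, paper, ehr, labels, boost)
        return paper, ehr, labels

    def _observe_second_line(self, truth, paper, ehr, labels) -> None:
        cfg, rng = self.cfg, self.rng
        for line in (2, 3):
            p_entry, e_entry = getattr(cfg, f"regimen{line}_entry_probs")
            present = truth[f"regimen{line}_drugs"] is not None
            on_paper = present and rng.random() < p_entry
            on_ehr = present and rng.random() < e_entry
            for suffix in ("start_date", "drugs"):
                name = f"regimen{line}_{suffix}"
                true = truth[name]
                for source, keep, out in (("paper", on_paper, paper),
                                          ("ehr", on_ehr, ehr)):
                    key = f"{source}_{name}"
                    if not keep:
                        out[name] = ""
                        labels[key] = "missing" if present else ""
                        continue
                    if suffix == "start_date":
                        err = (cfg.date_error_paper if source == "paper" else
                               min(0.98, cfg.date_error_ehr[name] * self.err_mult))
                        out[name], labels[key] = self._observe_date(
                            name, true, source, 0.0, err)
                    else:
                        err = (cfg.value_error_paper if source == "paper" else
                               min(0.98, cfg.value_error_ehr[name] * self.err_mult))
                        out[name], labels[key] = self._observe_value(
                            name, true, source, 0.0, err)

    def _observe_vl(self, truth, paper, ehr, labels, boost: float) -> None:
        cfg, rng = self.cfg, self.rng
        entries = [(truth[f"vl{p}_date"], truth[f"vl{p}_value"])
                   for p in (1, 2, 3) if truth[f"vl{p}_value"] is not None]

        # paper chart: faithful, except decimal-precision variants
        for pos in (1, 2, 3):
            dname, vname = f"vl{pos}_date", f"vl{pos}_value"
            if pos <= len(entries):
                date, value = entries[pos - 1]
                paper[dname] = date.isoformat()
                labels[f"paper_{dname}"] = ""
                if rng.random() < cfg.vl_decimal_prob:
                    paper[vname] = f"{value + round(rng.uniform(0.1, 0.9), 1):.1f}"
                    labels[f"paper_{vname}"] = "precision"
                else:
                    paper[vname] = f"{value:.0f}"
                    labels[f"paper_{vname}"] = ""
            else:
                paper[dname] = paper[vname] = ""
                labels[f"paper_{dname}"] = labels[f"paper_{vname}"] = ""

        # EHR: series-level lag, per-slot inclusion, date/value errors.
        # A lag drops the newest paper result from the EHR, shifting the
        # rest up one slot; each surviving entry is then independently
        # entered (or not) at its slot.
        lag_prob = min(1.0, cfg.ehr_vl_lag_prob / boost)
        lagged = bool(entries) and rng.random() < lag_prob
        remaining = entries[1:] if lagged else list(entries)
        date_err = min(0.98, cfg.date_error_ehr["vl1_date"] * self.err_mult)
        date_err = 1.0 - min(1.0, (1.0 - date_err) * boost)
        for slot in (1, 2, 3):
            dname, vname = f"vl{slot}_date", f"vl{slot}_value"
            if slot > len(remaining):
                ehr[dname] = ehr[vname] = ""
                miss = "lagged" if (lagged and slot <= len(entries)) else ""
                labels[f"ehr_{dname}"] = labels[f"ehr_{vname}"] = miss
                continue
            keep = min(1.0, cfg.ehr_vl_entry_probs[slot - 1] * boost)
            if rng.random() >= keep:
                ehr[dname] = ehr[vname] = ""
                labels[f"ehr_{dname}"] = labels[f"ehr_{vname}"] = "missing"
                continue
            date, value = remaining[slot - 1]
            if rng.random() < date_err:
                lo, hi = self._date_window(dname)
                ehr[dname] = _corrupt_date(rng, date, repeated=True,
                                           lo=lo, hi=hi).isoformat()
                labels[f"ehr_{dname}"] = "transcribed"
            else:
                ehr[dname] = date.isoformat()
                labels[f"ehr_{dname}"] = "lagged" if lagged else ""
            if rng.random() < cfg.vl_value_error_ehr:
                ehr[vname] = f"{float(round(10 ** rng.uniform(math.log10(20), 6))):.0f}"
                labels[f"ehr_{vname}"] = "wrong_value"
            else:
                ehr[vname] = f"{value:.0f}"
                labels[f"ehr_{vname}"] = "lagged" if lagged else ""


def _make_facilities(cfg: SimulationConfig,
                     rng: np.random.Generator) -> list[FacilityProfile]:
    n = cfg.n_facilities
    n_int = round(n * cfg.intervention_fraction)
    n_alert = round(n_int * cfg.vl_alert_fraction_of_intervention)
    n_tier3 = round(n_alert * cfg.tier3_fraction_of_alert)
    tiers = ([3] * n_tier3 + [2] * (n_alert - n_tier3)
             + [1] * (n_int - n_alert) + [0] * (n - n_int))
    rng.shuffle(tiers)
    out = []
    for i, tier in enumerate(tiers):
        out.append(FacilityProfile(
            facility_id=f"HF{i + 1:03d}",
            arm="intervention" if tier >= 1 else "control",
            alert_tier=tier,
            ehr_availability=int(rng.choice(5, p=cfg.availability_probs)) + 1,
            tech_experience=int(rng.binomial(4, 0.5)),
            years_ehr_use=float(round(rng.uniform(1.0, 10.0), 1)),
        ))
    return out


def generate_dataset(
    cfg: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
) -> tuple[list[RecordPair], list[FacilityProfile], GroundTruth]:
    """Generate a study-shaped dual-source dataset.

    Deterministic given the seed (``seed`` overrides ``cfg.rng_seed``).
    Returns the record pairs, the facility profiles and the
    :class:`GroundTruth` sidecar.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    facilities = _make_facilities(cfg, rng)
    miss_cfg = cfg.missingness

    records: list[RecordPair] = []
    truth_rows: dict[str, dict] = {}
    label_rows: dict[str, dict] = {}
    lo, hi = cfg.charts_per_facility_range
    for i, fac in enumerate(facilities):
        volume = max(1, int(round(math.exp(
            rng.normal(cfg.volume_log_median, cfg.volume_log_sigma)))))
        n_charts = lqas_sample_size(volume, min_size=lo, max_size=hi)
        fac_fields = {
            "district": f"District {i % 10 + 1}",
            "sector": f"Sector {i % 20 + 1}",
            "facility_name": f"Facility {fac.facility_id}",
        }
        sim = _RecordSimulator(cfg, rng, fac, fac_fields)
        for j in range(n_charts):
            pid = f"{fac.facility_id}-P{j + 1:03d}"
            truth = sim.draw_truth()
            post = truth["date_last_visit"] >= cfg.cutoff_date
            paper, ehr, labels = sim.observe(truth, post)
            values = {
                name: (RawValue(paper[name], SPEC_BY_NAME[name].kind),
                       RawValue(ehr[name], SPEC_BY_NAME[name].kind))
                for name in VARIABLE_NAMES
            }
            records.append(RecordPair(patient_id=pid,
                                      facility_id=fac.facility_id,
                                      values=values, missingness=miss_cfg))
            truth_rows[pid] = {
                k: (v.isoformat() if isinstance(v, datetime.date) else
                    ("" if v is None else
                     (f"{v:g}" if isinstance(v, float) else str(v))))
                for k, v in truth.items()
            }
            label_rows[pid] = labels

    truth_df = pd.DataFrame.from_dict(truth_rows, orient="index")
    truth_df.index.name = "patient_id"
    labels_df = pd.DataFrame.from_dict(label_rows, orient="index").fillna("")
    labels_df.index.name = "patient_id"
    return records, facilities, GroundTruth(truth=truth_df, labels=labels_df)


# --- analytic expectations & parameter recovery -------------------------

def _covariate_grid(cfg: SimulationConfig):
    """Joint distribution of (availability, tech) with probabilities."""
    tech_probs = [math.comb(4, k) * 0.5 ** 4 for k in range(5)]
    for a, pa in enumerate(cfg.availability_probs, start=1):
        for k, pt in enumerate(tech_probs):
            yield a, k, pa * pt


def expected_completeness(cfg: SimulationConfig, variable: str,
                          source: str) -> float:
    """Closed-form completeness implied by the generator config.

    Valid for configurations with ``alert_effect = 1`` (the alert
    multiplier makes EHR viral-load/pickup completeness depend on the
    facility mix, which this helper does not average over).
    """
    if cfg.alert_effect != 1.0 and source == "ehr" and (
            variable.startswith("vl") or variable.startswith("pickup")):
        raise ValueError("expected_completeness for VL/pickup EHR cells "
                         "requires alert_effect == 1")
    idx = 0 if source == "paper" else 1
    if variable.startswith("regimen2") or variable.startswith("regimen3"):
        line = variable[7]
        truth_p = getattr(cfg, f"regimen{line}_truth_prob")
        entry_p = getattr(cfg, f"regimen{line}_entry_probs")[idx]
        return truth_p * entry_p
    if variable.startswith("vl"):
        pos = int(variable[2])
        p = cfg.vl_count_probs
        if source == "paper":
            return sum(p[n] for n in range(pos, 4))
        lag = cfg.ehr_vl_lag_prob
        # P(at least `pos` entries remain in the EHR after the lag drop)
        p_remaining = sum(
            p[n] * ((1 - lag) if n == pos else 1.0)
            for n in range(pos, 4)
        )
        return p_remaining * cfg.ehr_vl_entry_probs[pos - 1]
    miss = cfg.missing_rates.get(variable, (0.0, 0.0))[idx]
    return 1.0 - miss


def expected_matching(cfg: SimulationConfig, variable: str) -> float:
    """Closed-form match fraction (among complete-in-both records)
    implied by the config, averaging the facility-covariate error
    multiplier over its distribution.  Supports plain (non-VL,
    non-second-line) variables."""
    spec = SPEC_BY_NAME[variable]
    if variable.startswith("vl") or variable.startswith("regimen2") \
            or variable.startswith("regimen3"):
        raise ValueError("analytic matching covers plain variables only")
    if spec.kind is VariableKind.DATE:
        base = cfg.date_error_ehr.get(variable, 0.0)
        p_ok_paper = 1.0 - cfg.date_error_paper
    else:
        base = cfg.value_error_ehr.get(variable, 0.0)
        p_ok_paper = 1.0 - cfg.value_error_paper
    if variable.startswith("pickup") and cfg.alert_effect != 1.0:
        raise ValueError("pickup matching requires alert_effect == 1")
    total = 0.0
    for a, k, p in _covariate_grid(cfg):
        mult = _covariate_error_multiplier(cfg, a, k)
        total += p * (1.0 - min(0.98, base * mult))
    return p_ok_paper * total


def expected_vl_match_rate(cfg: SimulationConfig, alert: bool) -> float:
    """Closed-form post-rollout viral-load match rate per EHR entry
    (date-aligned value agreement), for configs with zero covariate
    slopes: the paper chart holds every true entry with a faithful
    date, so an EHR entry matches iff its date survived transcription
    and neither value was corrupted."""
    if cfg.covariate_effects != (0.0, 0.0):
        raise ValueError("analytic VL match rate requires zero covariate slopes")
    d_err = cfg.date_error_ehr["vl1_date"]
    boost = cfg.alert_effect if alert else 1.0
    p_date_ok = min(1.0, (1.0 - d_err) * boost)
    return p_date_ok * (1.0 - cfg.vl_value_error_ehr)


def recover_parameters(records: list[RecordPair]) -> pd.DataFrame:
    """Estimate per-variable completeness and matching from a dataset
    using the pipeline's own metrics (truth-free validation harness)."""
    rows = []
    for name in VARIABLE_NAMES:
        cp = completeness(records, name, "paper")
        ce = completeness(records, name, "ehr")
        m = matching(records, name)
        rows.append({
            "variable": name,
            "paper_complete": cp.fraction,
            "ehr_complete": ce.fraction,
            "match": m.fraction,
            "n_complete_both": m.denominator,
        })
    return pd.DataFrame(rows).set_index("variable")
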