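"""Associations between data quality and facility characteristics.

Two families of analysis:

* Pearson correlation (with Bonferroni adjustment) between per-record
  concordance scores and facility-level covariates from the user survey
  (EHR availability/uptime Likert 1-5, technology-experience score 0-4,
  mean years of EHR use), broadcast from facility to its records.
* 2x2 contingency analysis of the clinical-alert effect: post-rollout
  record-entries are cross-classified as match/no-match by whether the
  facility received the missing-viral-load alert, tested by chi-square
  (Yates continuity correction by default) with the phi coefficient as
  effect size — for a 2x2 table phi equals the Pearson contingency
  coefficient and Cramer's V.
"""

from __future__ import annotations

import datetime
import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import RecordPair, concordance_score
from .normalization import is_missing, values_match
from .variables import get_spec
from .vl_alignment import MAX_ENTRIES

__all__ = [
    "FacilityProfile",
    "ContingencyTable2x2",
    "CorrelationResult",
    "AlertEffectResult",
    "concordance_covariate_correlation",
    "chi_square_2x2",
    "phi_coefficient",
    "alert_effect_table",
]


@dataclass(frozen=True)
class FacilityProfile:
    """Facility identity, trial arm/alert tier and survey covariates.

    Alert tiers nest: tier 0 = control arm, tier 1 = treatment-start
    alert only, tier >= 2 adds the missing-viral-load alert, tier 3 adds
    the high-viral-load alert.
    """

    facility_id: str
    arm: str  # "intervention" | "control"
    alert_tier: int
    ehr_availability: int  # Likert 1..5
    tech_experience: int  # 0..4
    years_ehr_use: float

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "control"):
            raise ValueError("arm must be 'intervention' or 'control'")
        if not 0 <= self.alert_tier <= 3:
            raise ValueError("alert_tier must be 0..3")
        if (self.alert_tier >= 1) != (self.arm == "intervention"):
            raise ValueError("alert_tier >= 1 iff arm is intervention")
        if not 1 <= self.ehr_availability <= 5:
            raise ValueError("ehr_availability must be Likert 1..5")
        if not 0 <= self.tech_experience <= 4:
            raise ValueError("tech_experience must be 0..4")

    @property
    def has_vl_alert(self) -> bool:
        return self.alert_tier >= 2


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows {alert, no-alert} and columns {match, no-match}."""

    a: int  # alert, match
    b: int  # alert, no match
    c: int  # no alert, match
    d: int  # no alert, no match

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: float


def concordance_covariate_correlation(
    scores: Sequence[float],
    covariate: Sequence[float],
    m_comparisons: int = 1,
) -> CorrelationResult:
    """Pearson correlation of per-record concordance with a covariate.

    Returns r with a Fisher-z 95% CI, the t statistic on n-2 df, the raw
    p-value and the Bonferroni-adjusted p = min(1, m * p_raw).  Raises on
    zero variance (the correlation is undefined).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and covariate must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p_raw = stats.pearsonr(x, y)
    r = float(r)
    df = n - 2
    if abs(r) == 1.0:
        t_stat = math.inf if r > 0 else -math.inf
        ci_low = ci_high = r
    else:
        t_stat = r * math.sqrt(df / (1.0 - r * r))
        z = math.atanh(r)
        half = stats.norm.ppf(0.975) / math.sqrt(n - 3)
        ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return CorrelationResult(
        r=r, ci_low=ci_low, ci_high=ci_high, t_stat=float(t_stat), df=df,
        p_raw=float(p_raw),
        p_adjusted=min(1.0, m_comparisons * float(p_raw)),
    )


def chi_square_2x2(table: ContingencyTable2x2,
                   continuity: bool = True) -> tuple[float, int, float]:
    """Chi-square test of association on a 2x2 table (1 df).

    With ``continuity`` the Yates-corrected statistic
    ``N (|ad-bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))`` (floored at 0 when
    the correction exceeds |ad-bc|); without it the uncorrected
    ``N (ad-bc)^2 / (...)``.  Raises on a zero marginal.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in table.marginals:
        raise ValueError("zero marginal: chi-square undefined")
    n = table.n
    cross = abs(a * d - b * c)
    if continuity:
        cross = max(0.0, cross - n / 2.0)
    denom = math.prod(table.marginals)
    chi2 = n * cross * cross / denom
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p


def phi_coefficient(table: ContingencyTable2x2, ci_method: str = "bootstrap",
                    n_boot: int = 2000,
                    seed: int | None = 0) -> tuple[float, float, float]:
    """Phi effect size, sqrt(chi2_uncorrected / N), with a 95% CI.

    ``ci_method="bootstrap"`` resamples the four cell counts
    multinomially (percentile CI, seeded); ``"fisher"`` uses the
    Fisher-z approximation treating phi like a correlation.
    """
    chi2, _, _ = chi_square_2x2(table, continuity=False)
    phi = math.sqrt(chi2 / table.n)
    if ci_method == "fisher":
        z = math.atanh(min(phi, 1 - 1e-12))
        half = stats.norm.ppf(0.975) / math.sqrt(table.n - 3)
        return phi, math.tanh(z - half), math.tanh(z + half)
    if ci_method != "bootstrap":
        raise ValueError("ci_method must be 'bootstrap' or 'fisher'")
    rng = np.random.default_rng(seed)
    counts = np.array([table.a, table.b, table.c, table.d])
    probs = counts / table.n
    draws = rng.multinomial(table.n, probs, size=n_boot)
    phis = np.empty(n_boot)
    for i, (a, b, c, d) in enumerate(draws):
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if 0 in (r1, r2, c1, c2):
            phis[i] = 0.0
            continue
        phis[i] = abs(a * d - b * c) / math.sqrt(r1 * r2 * c1 * c2)
    lo, hi = np.percentile(phis, [2.5, 97.5])
    return phi, float(lo), float(hi)


class VariableFamily(enum.Enum):
    VL_MATCH = "vl_match"
    PICKUP_MATCH = "pickup_match"


def _vl_entry_outcomes(record: RecordPair) -> list[bool]:
    """Per EHR viral-load entry: did it date-align and value-match the
    paper chart?  One outcome per valued EHR entry."""
    out = []
    for pair in record.vl_series.pairs:
        if pair.ehr is None or pair.ehr.value is None:
            continue
        out.append(bool(pair.complete and pair.paper.value is not None
                        and abs(pair.paper.value - pair.ehr.value) <= 1.0))
    return out


def _pickup_entry_outcomes(record: RecordPair) -> list[bool]:
    """Per EHR pickup entry (by date): does the paper chart record the
    same pickup date?"""
    out = []
    for pos in range(1, MAX_ENTRIES + 1):
        name = f"pickup{pos}_date"
        spec = get_spec(name)
        p, e = record.values[name]
        if is_missing(e, spec, record.missingness):
            continue
        out.append((not is_missing(p, spec, record.missingness))
                   and values_match(p, e, spec, record.missingness))
    return out


@dataclass(frozen=True)
class AlertEffectResult:
    table: ContingencyTable2x2
    family: VariableFamily
    cutoff_date: datetime.date
    n_records: int
    #: per-facility match percentages ranked descending, for plotting
    facility_percentages: pd.DataFrame

    @property
    def alert_match_pct(self) -> float:
        return 100.0 * self.table.a / (self.table.a + self.table.b)

    @property
    def control_match_pct(self) -> float:
        return 100.0 * self.table.c / (self.table.c + self.table.d)


def alert_effect_table(
    records: Sequence[RecordPair],
    facilities: Iterable[FacilityProfile] | Mapping[str, FacilityProfile],
    family: VariableFamily | str = VariableFamily.VL_MATCH,
    cutoff_date: datetime.date = datetime.date(2018, 7, 1),
) -> AlertEffectResult:
    """Cross-classify post-rollout EHR entries by alert status and match.

    Records dated (last visit) before ``cutoff_date`` predate the alert
    rollout and are excluded.  Entries are EHR-present viral-load values
    (``vl_match``, matched via date alignment) or EHR-present drug-pickup
    dates (``pickup_match``, matched exactly to the paper chart).  Raises
    if either facility group is empty after filtering.
    """
    family = VariableFamily(family)
    if not isinstance(facilities, Mapping):
        facilities = {f.facility_id: f for f in facilities}
    outcome_fn = (_vl_entry_outcomes if family is VariableFamily.VL_MATCH
                  else _pickup_entry_outcomes)

    cells = {True: [0, 0], False: [0, 0]}  # alert -> [match, no-match]
    per_fac: dict[str, list[int]] = {}
    n_records = 0
    for r in records:
        rd = r.record_date
        if rd is None or rd < cutoff_date:
            continue
        fac = facilities.get(r.facility_id)
        if fac is None:
            raise ValueError(f"record {r.patient_id!r} references unknown "
                             f"facility {r.facility_id!r}")
        n_records += 1
        outcomes = outcome_fn(r)
        slot = per_fac.setdefault(r.facility_id, [0, 0])
        for ok in outcomes:
            cells[fac.has_vl_alert][0 if ok else 1] += 1
            slot[0 if ok else 1] += 1

    for label, alert in (("alert", True), ("no-alert", False)):
        if sum(cells[alert]) == 0:
            raise ValueError(
                f"no {family.value} entries in the {label} group after "
                f"filtering at {cutoff_date.isoformat()}"
            )

    table = ContingencyTable2x2(a=cells[True][0], b=cells[True][1],
                                c=cells[False][0], d=cells[False][1])
    rows = []
    for fid, (m, nm) in per_fac.items():
        total = m + nm
        rows.append({
            "facility_id": fid,
            "has_vl_alert": facilities[fid].has_vl_alert,
            "n_entries": total,
            "n_matches": m,
            "match_pct": 100.0 * m / total if total else math.nan,
        })
    df = (pd.DataFrame(rows)
          .sort_values("match_pct", ascending=False, ignore_index=True))
    return AlertEffectResult(table=table, family=family,
                             cutoff_date=cutoff_date, n_records=n_records,
                             facility_percentages=df)


def records_concordance_covariates(
    records: Sequence[RecordPair],
    facilities: Iterable[FacilityProfile] | Mapping[str, FacilityProfile],
    use_aligned_vl: bool = True,
) -> pd.DataFrame:
    """Record-level frame of concordance scores with facility covariates
    broadcast to each record — the input to the correlation analyses."""
    if not isinstance(facilities, Mapping):
        facilities = {f.facility_id: f for f in facilities}
    rows = []
    for r in records:
        fac = facilities.get(r.facility_id)
        if fac is None:
            raise ValueError(f"record {r.patient_id!r} references unknown "
                             f"facility {r.facility_id!r}")
        rows.append({
            "patient_id": r.patient_id,
            "facility_id": r.facility_id,
            "concordance": concordance_score(r, use_aligned_vl=use_aligned_vl).score,
            "ehr_availability": fac.ehr_availability,
            "tech_experience": fac.tech_experience,
            "years_ehr_use": fac.years_ehr_use,
        })
    return pd.DataFrame(rows)
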