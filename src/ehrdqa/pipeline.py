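"""End-to-end report generation tying the audit stages together.

:func:`run_pipeline` takes loaded record pairs, facility profiles and a
:class:`~ehrdqa.io.RunConfig` and produces a :class:`ReportBundle`
holding the completeness table (per source), the matching table
(complete-in-both + matches), the per-facility concordance table, the
covariate-correlation statistics table, the alert-effect contingency
analyses and a machine-readable summary.  Identical inputs and config
yield identical bundles; every printed percentage is recomputable from
the printed counts in the same table.
"""

from __future__ import annotations

import dataclasses
import json
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .association import (
    AlertEffectResult,
    FacilityProfile,
    alert_effect_table,
    chi_square_2x2,
    concordance_covariate_correlation,
    phi_coefficient,
    records_concordance_covariates,
)
from .io import RunConfig
from .metrics import (
    RecordPair,
    completeness,
    concordance_score,
    facility_summary,
    matching,
)
from .variables import SPEC_BY_NAME, VARIABLE_NAMES

__all__ = ["ReportBundle", "run_pipeline"]

COVARIATES = ("ehr_availability", "tech_experience", "years_ehr_use")


def _pct(fraction: float | None) -> float | None:
    return None if fraction is None else round(100.0 * fraction, 2)


@dataclass
class ReportBundle:
    completeness_table: pd.DataFrame
    matching_table: pd.DataFrame
    facility_table: pd.DataFrame
    correlation_table: pd.DataFrame
    alert_vl: AlertEffectResult | None
    alert_pickup: AlertEffectResult | None
    alert_stats: pd.DataFrame
    summary: dict
    config: RunConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.completeness_table.to_csv(out / "completeness.csv", index=False)
        self.matching_table.to_csv(out / "matching.csv", index=False)
        self.facility_table.to_csv(out / "facility_concordance.csv")
        self.correlation_table.to_csv(out / "correlations.csv", index=False)
        self.alert_stats.to_csv(out / "alert_effect_stats.csv", index=False)
        for name, res in (("vl", self.alert_vl), ("pickup", self.alert_pickup)):
            if res is not None:
                res.facility_percentages.to_csv(
                    out / f"alert_effect_{name}_facilities.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


def _completeness_table(records: Sequence[RecordPair]) -> pd.DataFrame:
    rows = []
    for name in VARIABLE_NAMES:
        cp = completeness(records, name, "paper")
        ce = completeness(records, name, "ehr")
        rows.append({
            "variable": name,
            "in_concordance": SPEC_BY_NAME[name].in_concordance,
            "paper_filled": cp.numerator,
            "paper_pct": _pct(cp.fraction),
            "paper_high_quality": cp.high_quality,
            "ehr_filled": ce.numerator,
            "ehr_pct": _pct(ce.fraction),
            "ehr_high_quality": ce.high_quality,
            "n_records": cp.denominator,
        })
    return pd.DataFrame(rows)


def _matching_table(records: Sequence[RecordPair]) -> pd.DataFrame:
    rows = []
    n = len(records)
    for name in VARIABLE_NAMES:
        m = matching(records, name)
        rows.append({
            "variable": name,
            "complete_both": m.denominator,
            "complete_both_pct": _pct(m.denominator / n),
            "matches": m.numerator,
            "match_pct": _pct(m.fraction),
            "high_quality": m.high_quality,
        })
    return pd.DataFrame(rows)


def _correlations(records, facilities, cfg: RunConfig) -> pd.DataFrame:
    frame = records_concordance_covariates(records, facilities,
                                           use_aligned_vl=cfg.use_aligned_vl)
    rows = []
    for cov in COVARIATES:
        row = {"parameter_1": "concordance_score", "parameter_2": cov}
        try:
            res = concordance_covariate_correlation(
                frame["concordance"], frame[cov],
                m_comparisons=cfg.bonferroni_m)
        except ValueError as exc:  # zero variance: undefined correlation
            row["note"] = str(exc)
        else:
            row.update({
                "r": round(res.r, 4),
                "ci_low": round(res.ci_low, 4),
                "ci_high": round(res.ci_high, 4),
                "t_stat": round(res.t_stat, 2), "df": res.df,
                "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _alert_stats(results: dict[str, AlertEffectResult | None],
                 cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for family, res in results.items():
        if res is None:
            continue
        t = res.table
        row = {
            "family": family,
            "a_alert_match": t.a, "b_alert_nomatch": t.b,
            "c_control_match": t.c, "d_control_nomatch": t.d,
            "alert_match_pct": round(res.alert_match_pct, 2),
            "control_match_pct": round(res.control_match_pct, 2),
        }
        try:
            chi_c, df, p_c = chi_square_2x2(t, continuity=True)
            chi_u, _, p_u = chi_square_2x2(t, continuity=False)
            phi, lo, hi = phi_coefficient(t, n_boot=cfg.bootstrap_reps,
                                          seed=cfg.seed)
        except ValueError as exc:  # zero marginal: test undefined
            row["note"] = str(exc)
        else:
            row.update({
                "chi2_yates": round(chi_c, 2), "p_yates": p_c,
                "chi2_uncorrected": round(chi_u, 2), "p_uncorrected": p_u,
                "df": df,
                "phi": round(phi, 4),
                "phi_ci_low": round(lo, 4), "phi_ci_high": round(hi, 4),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(records: Sequence[RecordPair],
                 facilities: Sequence[FacilityProfile],
                 config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> ReportBundle:
    """Run the full audit: metrics, facility breakdown, associations.

    The alert-effect analyses are skipped (with ``None`` results) when a
    group is empty after the post-rollout filter — e.g. a dataset with
    no alert facilities; any other stage error propagates with the
    stage named.
    """
    config = config or RunConfig()
    if not records:
        raise ValueError("pipeline: empty record collection")

    fac_ids = [f.facility_id for f in facilities]
    try:
        fac_table = facility_summary(records, fac_ids,
                                     use_aligned_vl=config.use_aligned_vl)
    except ValueError as exc:
        raise ValueError(f"facility-summary stage: {exc}") from exc

    scores = [concordance_score(r, use_aligned_vl=config.use_aligned_vl).score
              for r in records]

    alert_results: dict[str, AlertEffectResult | None] = {}
    for family in ("vl_match", "pickup_match"):
        try:
            alert_results[family] = alert_effect_table(
                records, facilities, family=family,
                cutoff_date=config.cutoff_date)
        except ValueError:
            alert_results[family] = None

    n = len(records)
    summary = {
        "n_records": n,
        "n_facilities": len(fac_ids),
        "n_variables": len(VARIABLE_NAMES),
        "total_data_cells": n * len(VARIABLE_NAMES) * 2,
        "mean_records_per_facility": round(n / len(fac_ids), 2),
        "mean_concordance": round(statistics.fmean(scores), 2),
        "sd_concordance": round(statistics.stdev(scores), 2) if n > 1 else 0.0,
        "n_facilities_high_quality": int(fac_table["high_quality"].sum()),
        "config": config.to_dict(),
    }

    bundle = ReportBundle(
        completeness_table=_completeness_table(records),
        matching_table=_matching_table(records),
        facility_table=fac_table,
        correlation_table=_correlations(records, facilities, config),
        alert_vl=alert_results["vl_match"],
        alert_pickup=alert_results["pickup_match"],
        alert_stats=_alert_stats(alert_results, config),
        summary=summary,
        config=config,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
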