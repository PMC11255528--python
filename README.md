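# ehrdqa — dual-source EHR data-quality assessment

`ehrdqa` implements a facility-level **data-quality audit** comparing
patient records abstracted twice — once from the paper chart and once
from the electronic health record (EHR) — over a fixed set of 28
variables covering HIV-care enrollment, antiretroviral regimens, drug
pickups and viral-load (VL) results. It is written for health-informatics
researchers and implementers who need to quantify how faithfully an EHR
deployment mirrors the primary paper documentation, and to test whether
facility characteristics or clinical-decision-support alerts move those
metrics.

## The metrics

For a variable $v$ and source $s \in \{\text{paper}, \text{ehr}\}$ over
$N$ audited records:

- **Completeness** $C_{v,s} = n_{\text{filled}} / N$ — the fraction of
  records with a non-missing value. A field is *missing* if blank,
  coded "not available", or an implausible date: a sentinel
  (1980-01-01), a date after chart abstraction, or an HIV-treatment
  date before HIV care existed in the country.
- **Matching** $M_v = n_{\text{match}} / n_{\text{both}}$ — among
  records non-missing in *both* sources, the fraction whose
  standardized values are equal. Standardization canonicalizes drug
  regimens to an order-free component multiset, allows ±1 copy/mL on
  viral loads, and requires exact calendar-date equality for dates.
- **Concordance score** — per record, the count (0–15) of 15 designated
  variables that either match or are missing in both sources.
- **LQAS classification** — following the lot-quality-assurance-sampling
  audit design, 48–76 randomly sampled charts per facility classify it
  against an 85% quality threshold: a metric is "high quality" iff it is
  ≥ 0.85.

Viral loads are recorded as the last three (value, date) entries per
source and are **aligned by date** before comparison: an EHR that runs
one result behind the chart would otherwise look discordant at every
position. Association analyses use record-level Pearson correlations
(Fisher-z CIs, Bonferroni adjustment) between concordance and facility
survey covariates, and a 2×2 chi-square (Yates-corrected by default)
with the phi coefficient, $\phi = \sqrt{\chi^2 / N}$, for the effect of
missing-VL alerts on post-rollout matching.

Because real audit records are not redistributable, the package ships a
**synthetic-data generator** that reproduces the audit's structure — 50
facilities, intervention/control arms, nested alert tiers, per-variable
missingness, sentinel dates, date-transcription error mixtures, the
EHR's one-result VL lag, regimen-separator and VL-decimal variants, an
alert effect, and covariate-coupled error rates — with a labelled
ground truth for every injected error.

## Worked example

```python
from ehrdqa import (SimulationConfig, generate_dataset, alert_effect_table,
                    chi_square_2x2, phi_coefficient)

records, facilities, truth = generate_dataset(SimulationConfig(), seed=1)
res = alert_effect_table(records, facilities, family="vl_match")
chi2, df, p = chi_square_2x2(res.table, continuity=True)
print(res.alert_match_pct, res.control_match_pct, chi2)
```

Running `python examples/04_alert_effect.py` prints:

```
vl_match:
  alert facilities:     414/ 1116 (37.1%) matched
  control facilities:   384/ 2458 (15.6%) matched
  chi2(1) = 202.9, p = 5e-46, phi = 0.24 (95% CI 0.20-0.27)
```

i.e. of the 1116 post-rollout EHR viral-load entries at facilities with
the missing-VL alert, 414 date-aligned and value-matched the paper
chart, against 15.6% at facilities without the alert — a decisive
association (the generator injects this effect, so the pipeline should
find it). The other scripts in `examples/` walk through simulation
(`01`), the core audit metrics (`02`, printing e.g. a mean concordance
of 9.77, SD 1.62, out of 15), date-keyed VL alignment (`03`) and
covariate correlations (`05`, availability r = +0.18, technology
experience r = −0.07, years of use r ≈ 0).

A thin CLI wraps the same pipeline:

```sh
ehrdqa simulate --out-dir data --seed 1
ehrdqa report --input data/record_pairs.csv \
              --facilities data/facilities.csv --out-dir report
```

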