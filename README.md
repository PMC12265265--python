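# clinaudit

Counterfactual social-bias auditing for clinical language models.

## The problem

Language models deployed in clinical workflows — writing teaching cases,
suggesting differential diagnoses and treatments, assessing patient needs —
can absorb and reproduce societal biases against patients of a given sex,
ethnicity, educational attainment, income level, or health-insurance status.
`clinaudit` implements a three-scenario audit of such a model as a reusable,
tested pipeline:

1. **Case generation.** The model is asked to write teaching cases for
   diseases with well-documented epidemiology (hypertension, diabetes,
   hepatitis B). The demographic distribution of the generated patients is
   compared against reference (national survey) prevalence with chi-square
   goodness-of-fit tests: demographic parity means generated cases mirror
   who actually has the disease.
2. **Diagnosis and treatment.** Clinical vignettes are held fixed while the
   patient's five sociodemographic attributes are varied over the full
   2^5 = 32 counterfactual factorial. Returned diagnosis lists are coded
   against each vignette's expert-preferred differential list (an unmatched
   or missing diagnosis is coded 11) and compared across subgroups on three
   indicators — mean rank of the expert-preferred primary diagnosis, its
   top-3 inclusion rate, and the mean rank of every expert diagnosis —
   plus referral and advanced-imaging (CT/MRI/ultrasound) recommendation
   rates.
3. **Needs assessment.** The model rates 22 Likert statements (patient
   honesty, understanding, relationships, pain treatment, other treatment)
   for the same counterfactual patients; self-contradictory answers
   (verbal disagreement with a numeric 5, and the symmetric case) are
   excluded before per-statement subgroup comparison.

Subgroup contrasts use Mann–Whitney rank-sum tests for ranks and ratings
and chi-square / Fisher exact tests for binary outcomes, with
Benjamini–Hochberg false-discovery-rate correction applied within each
(indicator × case) or per-statement family; significance is flagged at
FDR-adjusted p < 0.05 and p ≤ 0.001.

Because audits of live commercial model APIs are not reproducible offline,
the package ships a **seedable synthetic responder** with an explicit,
injectable bias model (demographic sampling distributions, additive
diagnosis rank shifts, referral/imaging propensities per attribute level,
Likert mean shifts, contradiction injection). Its zero-bias *null*
configuration calibrates the audit's false-discovery behaviour; injected
effects verify the pipeline recovers known biases with high power. Any
component satisfying the `(task) -> ResponseRecord` contract — e.g. a live
API adapter — can be plugged in instead.

## Worked example

Inject a referral-propensity gap by insurance status (10.0% insured vs
14.5% uninsured) and run the full diagnosis audit — 19 vignettes × 32
profiles × 25 replicates × 3 model tags = 45,600 responses:

```python
import dataclasses
from clinaudit import (AuditConfig, SyntheticResponder, default_fixtures,
                       make_null_config, run_audit)

fixtures = default_fixtures()
null = make_null_config("llm-a", fixtures)
biased = dataclasses.replace(
    null,
    diagnosis=dataclasses.replace(
        null.diagnosis,
        referral_probs={("insurance", "insured"): 0.10,
                        ("insurance", "uninsured"): 0.145},
    ),
)
config = AuditConfig(fixtures=fixtures, replicates=25)
report = run_audit("diagnosis", config, SyntheticResponder(biased), master_seed=1)

print("tasks executed:", report.task_count)
rates = report.indicators.query(
    "indicator == 'referral_rate' and subgroup.str.startswith('insurance')")
print(rates.groupby("subgroup")
      .apply(lambda g: (g.value * g.n).sum() / g.n.sum(), include_groups=False)
      .round(4))
row = report.tests.query(
    "indicator == 'referral_rate_pooled' and contrast.str.startswith('insurance')"
).iloc[0]
print(f"pooled insured-vs-uninsured: chi2={row.statistic:.1f}, "
      f"adjusted p={row.p_adjusted:.3g}, flagged={row.significant_05}")
```

Output:

```
tasks executed: 45600
subgroup
insurance=insured      0.1011
insurance=uninsured    0.1484
dtype: float64
pooled insured-vs-uninsured: chi2=233.0, adjusted p=6.77e-52, flagged=True
```

The audit recovers the injected 4.5-percentage-point gap (10.1% vs 14.8%
observed) and the pooled insurance contrast is flagged at FDR-adjusted
p ≪ 0.001. `export_report(report, "out/")` writes the indicator, test,
and deviation tables as CSV plus run metadata (master seed and a config
digest) so the bundle is exactly reproducible.

A `clinaudit` console command wraps the same library:

```bash
clinaudit plan -a diagnosis --seed 1          # 45600 tasks
clinaudit run -a needs --seed 1 -o out/needs  # null-responder audit + export
clinaudit report -d out/needs --alpha 0.05
```

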