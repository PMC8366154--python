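# prospmatch

A study-design engine for **prospective matching to guide enrollment** in
comparative-effectiveness studies of care models. It is written for
biostatisticians and trial designers who want to pre-register, stress-test or
adapt a design in which patients who transfer into a treatment care model are
matched — *before* anyone is contacted — to similar patients who stayed in
usual care, and recruitment then works outward from the closest matches.

The engine covers the full design loop on synthetic multi-facility cohorts:

1. **Synthetic cohorts** with a confounded transfer mechanism: selection into
   the treatment model follows a logistic model on observed covariates (age,
   CAN score, JFI score, dementia, prior hospitalization), so unmatched arms
   are imbalanced by construction.
2. **Eligibility** from visit histories: ≥ 2 usual-care visits and no
   treatment-clinic visits in the pre-exposure year, plus either a clean
   transfer (≥ 2 treatment-clinic visits, no usual-care visits in the exposure
   year) or clean continuation, applied through quarterly rolling data pulls
   and a facility volume filter.
3. **Matching**: coarsened-exact keys (facility, race, sex, advance directive,
   dementia, any prior hospitalization) with an age caliper (|Δage| ≤ 5 y),
   refined by a Mahalanobis distance over standardized (age, hospitalization
   count, CAN, JFI); treated patients need ≥ 5 candidates to be recruitable.
4. **Recruitment simulation**: a weekly discrete-event model that enrolls a
   treated patient, contacts candidates in priority tiers (distance < 0.1,
   < 0.25, < 0.5, …), escalates tiers every 2 weeks, and closes the window
   after 5 weeks; each contact enrolls with probability 0.2 by default.
5. **Balance diagnostics**: standardized mean differences
   `SMD = (x̄₂ − x̄₁) / √((s₁² + s₂²)/2)` (binary: variances p(1−p)), with
   |SMD| < 0.2 as the conventional balance threshold.
6. **Power**: Monte-Carlo power for zero-inflated Poisson / negative-binomial
   outcomes ("days not at home"), with marginal arm means matched exactly
   (λ = μ/(1−π)), facility-level frailty clustering, and a zero-inflated count
   regression with cluster-robust arm-effect test.

## Worked example

```python
import prospmatch as pm

cfg = pm.StudyConfig().validate()          # 6 facilities x 1500 patients
report = pm.run_full_study(cfg, seed=7)

stats = report["pool_statistics"]
rec = report["recruitment"]
print(f"treated eligible:    {report['n_treated_eligible']}")
print(f"lacking >=5 matches: {stats['n_lacking_min_matches']} "
      f"({100 * stats['fraction_lacking']:.1f}%)")
print(f"dyads formed:        {rec['n_dyads']} of {rec['n_treated_enrolled']} "
      f"treated enrolled")
```

prints

```
treated eligible:    1199
lacking >=5 matches: 163 (13.6%)
dyads formed:        275 of 1036 treated enrolled
```

Of 1,199 patients who cleanly transferred, 13.6% had fewer than five
exact-compatible controls and were never approached; recruitment then reached
its 275-dyad target. The balance report shows what the matching bought:

```
SMD age        pre -0.34  post -0.02
SMD can_score  pre -0.67  post -0.02
SMD jfi_score  pre -0.65  post -0.03
SMD dementia   pre -0.14  post +0.00
```

Covariates driving transfer are badly imbalanced between the unmatched arms
(|SMD| up to 0.67) and balanced among enrolled dyads (all |SMD| < 0.05);
exact-matched covariates balance to exactly zero. A command-line interface
mirrors each stage (`prospmatch run-all --seed 7 --out out/`, plus
`generate-cohort`, `classify`, `match`, `simulate-recruitment`, `balance`,
`power`).

The power module answers the sample-size question directly:

```python
res = pm.estimate_power(pm.PowerSpec(seed=1))   # ZIP, 275 dyads, 5.5 vs 4.0
print(res.summary())
# power = 1.000 (MC SE 0.000, 1000 replicates, 0 fit failures excluded)
```

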