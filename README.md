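# sizevarpart

Quantify how much of the year-to-year variation in an exploited fish stock's
**size structure** — the full length-frequency composition, not a single
summary number — is explained by fishing, by temperature, and by their
overlap, and compare many stocks in a meta-analysis.

Size-selective fishing truncates the large end of a length distribution;
warming acts mostly through recruitment and perturbs the small end with a
delay. Classical monitoring reduces each year to a univariate size-based
indicator (SBI: the 95th length percentile L95, mean length, Shannon
diversity, Pielou evenness, skewness) and regresses it on the forcings.
`sizevarpart` instead treats the whole composition matrix as the response.

## The method

For one stock, let **Y** be the *n*-years × *m*-length-classes matrix of
annual proportions, *f* the annual fishing mortality (yr⁻¹) and *T* the
annual temperature, optionally lagged. Redundancy analysis (RDA) summarizes
a fit by R² = ‖P_X **Y**‖² / ‖**Y**‖² (column-centered Frobenius sums of
squares, P_X the projection onto the predictor space), corrected for sample
size with Ezekiel's adjustment adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1).
Two-set variation partitioning differences three adjusted fits:

    [a] pure fishing      = adjR²(f + T) − adjR²(T)
    [c] pure temperature  = adjR²(f + T) − adjR²(f)
    [b] shared            = adjR²(f) + adjR²(T) − adjR²(f + T)
    residual              = 1 − adjR²(f + T)

The pure fractions are tested by permuting reduced-model residuals
(Freedman–Lane) with the partial pseudo-F statistic; the shared fraction is
not testable. The temperature lag (0/1/3 years for annual surveys, 0/2/3
for multi-year surveys) is chosen per stock by the largest total adjusted
R². Exploitation rates μ are converted to instantaneous F via the type II
fishery relation μ = F(1 − e^{−(F+M)})/(F + M). Across stocks, the fractions
are compared by ANOVA/Tukey HSD, regressed on life-history traits and on
long-term forcing indices (mean and CV of F/M and of temperature; OLS and a
habitat-random-intercept mixed model with Satterthwaite degrees of freedom),
and the partition's p-values are matched against SBI-regression p-values
with an exact binomial test.

A seeded age-structured simulator (von Bertalanffy growth, logistic
selectivity, temperature-forced lognormal recruitment, multinomial survey
sampling) generates stocks with known truth for validation.

## Worked example

```python
import sizevarpart as svp

stocks = svp.simulate_fleet(8, seed=5)                 # synthetic batch
cfg = svp.RunConfig(n_perm=199, seed=1)
results, failures = svp.analyze_stocks(stocks, cfg)
out = svp.run_meta(results, cfg)
print(out.summary)
print(out.efficiency)
```

prints (seed 5, 8 stocks):

```
{'n_stocks': 8, 'mean_fishing_pct': 26.895155643042834,
 'mean_shared_pct': 4.318253302635366, 'mean_temperature_pct': 2.7525649165841286,
 'max_total_adj_r2_pct': 77.95899520442482,
 'n_fishing_significant': 8, 'n_temperature_significant': 2}
        effect  prob_success   binom_p  n_pairs  n_success
0      fishing         0.350  0.980761       40         14
1  temperature         0.625  0.076930       40         25
```

Fishing explains on average 27% of the size-structure variance in this
simulated fleet (all 8 stocks significant at α = 0.05) against 2.8% for
temperature — as built into the generator, whose default fleet ramps F while
keeping recruitment forcing moderate. The efficiency table counts how often
the partition's permutation p beats the matching indicator-regression p
(25 of 40 temperature pairs here) with a one-sided exact binomial p.

The same pipeline runs from the shell:

```bash
sizevarpart simulate --n-stocks 8 --seed 5 --out stocks/
sizevarpart meta stocks/ --seed 1 --n-perm 999 --out results/
sizevarpart fixture --out fixture_out/   # published-table statistics
```

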