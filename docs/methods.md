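# Methods

## Response matrix

The unit of analysis is one stock's annual length composition: counts per
half-open length class [lower, upper) in cm, one row per survey year. Rows
are converted to proportions before ordination, which removes survey-effort
differences between years; a Hellinger transform (square root of
proportions) is available behind `transform="hellinger"` but is off by
default, since proportions are the most literal reading of "composition of
size classes" and the two give very similar partitions on compositions
without long zero tails. Length classes empty across all years are dropped —
they carry no variance and would distort evenness denominators. Years with
a zero total are rejected at load: an empty survey year is missing data,
not a observation of emptiness.

Alignment pairs the composition row at year *t* with fishing mortality
F(*t*) — never lagged; fishing removes standing biomass immediately — and
temperature T(*t* − lag), the delay standing in for recruitment-mediated
effects. Years missing any of the three are dropped; at least 8 aligned
years are required (`min_years`), below which a 3-predictor-equivalent fit
has too few residual degrees of freedom to be meaningful.

## Partition and inference

RDA is implemented directly: column-center, project onto the predictor
column space (thin SVD; ranks below the declared predictor count raise a
collinearity error unless explicitly allowed), and report explained over
total sum of squares. Partial fits residualize both response and predictors
on the conditioning set but keep the *total* SS denominator, so marginal
and partial fractions are commensurable. Predictor columns whose norm
collapses under residualization (fully absorbed by the conditioning set)
are zeroed rather than projected onto floating-point noise.

The two-set partition uses differences of Ezekiel-adjusted R² values, the
standard unbiased construction; fractions are left unclamped internally
(the shared fraction is routinely negative with correlated-but-opposed
predictors) and clamped at zero only in report tables, whose totals still
come from the unclamped arithmetic. Significance of each pure fraction uses
the Freedman–Lane scheme: hold the reduced-model fit, permute its residual
rows, recompute the partial pseudo-F
(SS_explained/p)/(SS_residual/(n − p − q − 1)), and count exceedances with
the add-one correction p = (#{F\* ≥ F_obs} + 1)/(n_perm + 1). 1000
permutations by default. The permutation loop is vectorized (all draws as
one tensor contraction), so the default costs milliseconds at survey-series
sizes. The shared fraction has no permutation distribution and is never
tested.

Lag selection fits the partition at each candidate (0/1/3 years for annual
surveys; 0/2/3 when the survey interval exceeds one year, with a switch to
restrict to {2, 3}) and keeps the largest total adjusted R², ties to the
smaller lag (parsimony). Permutation tests are run only at the winning lag.
**Known limitation:** selecting the lag by maximum adjusted R² and then
testing at that lag inflates the realized false-positive rate of the
temperature test above the nominal α — in the null simulations the test
itself rejects at 3–6% while the select-then-test chain rejects at roughly
8–16%. The validation suite therefore characterizes the test's size at a
fixed lag, and the acceptance report states both numbers.

## Mortality conversion and fishing indices

Exploitation rates are converted assuming a type II fishery (fishing and
natural mortality concurrent through the year): μ = F·A/Z with Z = F + M
and A = 1 − e^{−Z}. The inverse is a Brent root find on a doubling upper
bracket, tolerance 1e-10 in μ; round trips are exact to ~1e-8 in F over
F ∈ [0, 5], M ∈ [0.05, 1]. Cross-stock fishing pressure is the mortality
ratio F/M, summarized by its long-term mean and CV (sample sd over mean,
n − 1 denominator; the choice is a convention, stated here because no
single standard exists).

## Indicators

Moment indicators (mean length, skewness) use bin midpoints as the length
of every fish in the bin; skewness is the population-moment form with no
small-sample correction. Shannon H uses natural logs over nonzero classes;
Pielou J divides by ln S with S the classes occupied at *stock* level, held
constant across years so J is comparable through time. L95 interpolates
linearly inside the bin where the cumulative proportion crosses 0.95 —
equivalent to assuming uniform lengths within a bin. A year with all mass
in one class gets H = 0 and missing skewness with a warning.

Indicator regressions (`SBI ~ T + F + T×F`) z-score both predictors before
forming the product, making the interaction coefficient scale-free; marginal
p-values are unaffected, the product term's would otherwise depend on
measurement units. A constant indicator returns zero slopes with p = 1.

## Cross-stock models

The three effect columns (clamped, as reported in tables) are compared by a
one-way ANOVA with Tukey's HSD — the construction that reproduces the
published comparison p-values from the printed per-stock table; pairwise
two-sided paired t-tests are kept as an alternative (`method="paired_t"`,
p = 1 when the differences have zero variance). Groupings smaller than 3
stocks are skipped with a warning. No multiple-testing correction is
applied anywhere beyond Tukey's own familywise adjustment, matching the
source analysis.

Covariate models per covariate: univariate OLS of the fraction on the
covariate, then a linear mixed model with the same fixed effect and a
random intercept by habitat. The LMM is fitted by REML (statsmodels
MixedLM); the fixed-slope p-value uses a t distribution with Satterthwaite
degrees of freedom computed from the closed-form REML likelihood of the
random-intercept model (finite-difference gradient of the contrast variance
and observed information; agrees with lmerTest to ~4 decimals in the df on
balanced test data). A singular fit (random-intercept variance numerically
zero) or a single habitat falls back to OLS with a flag.

The efficiency comparison matches, per stock and per effect, the
partition's permutation p against each of the five indicator regressions'
corresponding-term p. Success is *strict* inequality (ties count against
the partition), the success probability is reported over all pairs, and the
test is an exact one-sided binomial against 0.5.

## Synthetic stocks

The generator is a deterministic cohort model observed through a noisy
survey. Defaults describe a generic demersal stock: L∞ = 60 cm, K = 0.35
yr⁻¹, a₀ = −0.5 yr, 12% CV of length at age, M = 0.25 yr⁻¹ (A_max set so
that survivorship to the oldest age is below 1%, capped at 40), logistic
fishing selectivity centred at 32 cm, temperature an AR(1) around 8 °C
(ρ = 0.6, sd 0.6 °C), recruitment lognormal (σ_R = 0.3, −σ²/2 mean
correction so β_T = 0 leaves mean recruitment stationary) responding to the
temperature anomaly one year back at β_T = 0.25 °C⁻¹, F ramping 0.1 → 0.6
yr⁻¹ with a small reflected random walk, and 5000 fish per survey year
binned at 2 cm. Survey vulnerability reuses the fishing selectivity unless
a separate curve is configured — the simplest mechanism that lets fishing
truncation show in the observed composition. 35-year series match the
multi-decade span of the real assessments.

Three frozen scenarios exercise the analysis:

* **fishing ramp** (F 0.1 → 0.8, β_T = 0): the fishing fraction should be
  detected; observed power ≈ 99–100% over 100 replicates.
* **temperature null** (constant F, β_T = 0, σ_R = 0): any temperature
  detection is a false positive; the fixed-lag test rejects at 3–6%, and
  the mean reported temperature fraction is below 0.005.
* **lag recovery** (β_T = 0.8 under white-noise temperature, survey seeing
  age-0 fish so the echo arrives at exactly the recruitment lag): the
  selected lag matches the true 1- or 3-year lag in essentially all of 50
  replicates.

What the simulator does *not* emulate: density-dependent recruitment,
evolutionary or growth responses to fishing or warming, spatial structure,
gear changes, ageing error, or effort-varying surveys. Passing these
scenarios shows the estimator recovers the signals its linear model
assumes; it does not validate those assumptions for real stocks, where the
response may be nonlinear or size-class specific.

## Numerical conventions

Rank decisions use a 1e-10 relative singular-value threshold; residualized
predictor columns below 1e-8 of their original norm count as absorbed.
Proportions sum to 1 within 1e-12; the partition identity
[a] + [b] + [c] = total adjusted R² holds to 1e-10 on random inputs. All
randomness flows through explicit integer seeds (numpy Generator /
SeedSequence); per-stock analysis seeds are derived from the run seed and a
CRC of the stock id, so batch order does not affect results, and identical
configurations reproduce output CSVs byte for byte.
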