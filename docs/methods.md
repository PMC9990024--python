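# Methods

`sitqc` analyses the three quality-control assays used to judge whether
chilling (immobilisation at ~4 °C before transport and release) damages
mass-reared sterile male *Aedes aegypti*: survival, escape ability from
a flight-test device, and sexual competitiveness against fertile males.
This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the package's own validation
demonstrates.

## Survival

Lifespans are analysed per treatment (control, one 25-min chill, and
two-chill schedules 25+25, 25+50, 25+100 min) with the Kaplan–Meier
product-limit estimator; deaths are processed before censorings at tied
times (the standard convention). The headline summary is the restricted
mean survival time — the area under S(t) up to the largest observed
time. The assay runs until every male is dead, so follow-up is complete
and the restricted mean equals the arithmetic mean lifespan; the
restricted form is kept so that censored data (e.g. truncated assays)
are handled correctly.

Groups are compared with pairwise log-rank tests (chi-square with 1 df)
rather than a proportional-hazards fit: the quantities of interest —
mean survival times and significance groupings — do not require hazard
modelling, and the log-rank test makes no shape assumption. Familywise
error across the 10 pairs is controlled with Holm's step-down
adjustment, and the result is displayed as compact letters. Replicates
(rearing batches) are pooled within treatment; no batch-level frailty is
modelled.

Kaplan–Meier estimation, the restricted mean and the log-rank statistic
are computed with `lifelines`; the package's tests check them against
hand-computed product-limit examples and a brute-force enumeration of
the hypergeometric observed-minus-expected sums.

## Escape ability

Each flight trial loads 50 males into a vertical flight-test device and
records how many escape within 2 h; the escape rate is escaped/loaded.
Treatments are summarised by the mean ± SE of per-replicate rates
(11 replicates per treatment), compared with the tie-corrected
Kruskal–Wallis test (H referred to chi-square with k−1 df; if all
observations are tied, H = 0 and p = 1 by convention), and grouped with
an LSD-style criterion on mean ranks (Conover): pair (i, j) separates
when |R̄ᵢ − R̄ⱼ| exceeds t₁₋α/₂,N₋k · √(S²·(N−1−H)/(N−k)·(1/nᵢ+1/nⱼ)).
The procedure is protected: no pair is declared different unless the
global test is significant. LSD makes no multiplicity adjustment by
design; it is the liberal end of the post-hoc spectrum and is reported
as such.

The duration effect is modelled as a binomial GLM on the treatments
with a second chill exposure (25, 50, 100 min): logit(p) = β₀ +
β₁·duration, β₁ in logit units per minute. The fit is by iteratively
reweighted least squares, converged when the relative deviance change
falls below 1e-8 (50 iterations maximum); standard errors come from
(XᵀWX)⁻¹. Complete separation is detected (fitted linear predictor
beyond ±15, i.e. fitted probabilities at machine 0/1) and reported as
`converged=False` rather than returning divergent estimates. Replicates
enter as separate binomial observations by default; a pooled-per-duration
option exists because either convention is defensible. An optional
influence-mitigation step adds one indicator column per observation
whose absolute Pearson residual exceeds 3 in a first pass; it is off by
default and the added columns are always reported. Controls and the
single-chill treatment are excluded from the regression — they have no
second-chill duration — and the single-chill treatment sits at duration
0 on the treatment line in the generator.

## Sexual competitiveness

Five cage arms, each with 50 fertile females: *Hn* (+50 fertile males),
*Hs* (+50 sterile males), and three competition arms *Ho*, *Ho_1_25*,
*Ho_2_25* (+50 fertile +50 sterile males; sterile males unchilled,
chilled once, or chilled twice). From pooled hatch rates, Fried's index
C = (Hn−Ho)/(Ho−Hs)·(N/S) and induced sterility IS = (1−Ho/Hn)·100.
C may legitimately be negative when the competition cage out-hatches the
fertile control; C is undefined at Ho = Hs, and Ho < Hs lies outside
Fried's mixture model (flagged with a warning, never silently returned
as infinity).

**Resampling.** Variability is a stratified nonparametric bootstrap:
cages are resampled with replacement within each arm, and pooled rates,
C and IS recomputed per replicate (B = 5000 default). The cage is the
resampling unit because it is the independent experimental unit;
resampling eggs would ignore the cage-level correlation and understate
variance. The control arms are resampled once per replicate and shared
across competition arms, so the resample vectors are paired and the
arm-comparison tests inherit the shared-control correlation. Replicates
with undefined or out-of-domain C (Ho_b ≤ Hs_b) are counted, reported,
and excluded from the moments, with a warning when they exceed 1% of B.
Intervals are percentile CIs; point estimates are egg-weighted pooled
hatch rates by default, with an unweighted per-cage-mean option since
published analyses do not always state which convention they use.

**Overdispersion.** Between-cage heterogeneity of hatch counts is
quantified per arm by beta-binomial maximum likelihood: cage hatch
probability ~ Beta with mean μ and intraclass correlation ρ, so ρ = 0
collapses to the binomial. The likelihood is maximised with L-BFGS-B
from three starts (method-of-moments ρ plus two fixed starts), and
standard errors come from the finite-difference observed information.
ρ is unidentifiable from a single cage (an error), and boundary fits
(all-zero or all-hatched counts) are rejected rather than returned. No
random-effect integration is needed: arm is the only fixed effect and
cage the only grouping level, so independent per-arm ML is the exact
likelihood for this design.

**Arm comparison.** Pairwise differences of C (and IS) use the paired
bootstrap difference distributions: two-sided bootstrap p-values
(floored at 1/B), Holm-adjusted across pairs, displayed as compact
letters. A studentized-range (Tukey) procedure on the 5000 resamples
would treat resamples as independent replicates — pseudo-replication —
so the Holm-adjusted bootstrap test is used instead.

## Synthetic-data generator

The generator exists so every estimator can be validated by parameter
recovery. Defaults are the published study conditions:

| parameter | default | meaning |
|---|---|---|
| `hatch_fertile` | 0.3766 | hatch rate of fertile-mated eggs |
| `hatch_sterile` | 0.006 × 0.3766 | residual hatch after a 50 Gy dose (99.4% sterility) |
| `c_true_by_arm` | Ho 1.16, Ho_1_25 0.32, Ho_2_25 0.0 | true competitiveness per arm |
| `n_females`, `n_fertile_males`, `n_sterile_males` | 50 | cage composition |
| `eggs_per_female_mean` | 50 | Poisson clutch mean (declared default; not reported in the assay description) |
| `cage_overdispersion` | 0.0 | Beta ICC of cage hatch probabilities; 0 = pure binomial |
| `n_cages_per_arm` | 4 | replicates per arm |
| `flight_n_loaded`, `flight_replicates` | 50, 11 | flight-trial design |
| `escape_logit_intercept`, `escape_logit_slope` | −2.405, −0.0287 /min | logit line through the published escape rates at durations 0/25/50/100 |
| `escape_control_logit` | logit(0.281) | separate control intercept (mean of the published control rates) |
| `lifespan_shape` | 4 | Weibull shape (declared default) |
| `lifespan_scale_by_treatment` | means 67/56/56/55/54 d | per-treatment Weibull scales via mean = scale·Γ(1+1/shape) |
| survival cohort | 100 males × 4 replicates | per treatment |

Mechanisms: each female mates exactly once — a fertile male with
probability N/(N + C·S) — which is precisely the mixture Fried's index
inverts; remating would make C unidentifiable from hatch data alone.
Eggs are Poisson per female; hatch probabilities are drawn per
(cage × mate type) from a Beta with the configured mean and ICC.
Lifespans are Weibull with shared shape and per-treatment scale,
rounded up to whole days to match daily mortality recording, complete
follow-up. Escape counts are binomial on the logit line, with a
separate control intercept because unchilled controls are off the
duration line. All generators draw from a single seeded
`numpy.random.Generator`; identical (config, seed) gives bit-identical
tables.

The paper's Ho_2_25 estimate is negative (−0.11), but a generative C
must be non-negative — negative estimates arise as sampling noise
around a competitiveness of zero — so the default for that arm is 0.

What the generator does **not** emulate: temperature physiology and
recovery dynamics, remating and insemination biology, rearing-batch
effects beyond the cage level, day-to-day egg-collection structure, or
any spatial/release process. Passing recovery tests therefore shows the
estimators are correct for data of this structure, not that real
experiments satisfy the single-mating or Weibull assumptions.

A known inconsistency in the published summary values: the printed
Hn = 37.66%, C = 1.16 and IS = 41.35% cannot all hold under pooled
plug-in arithmetic (the mixture identity forces IS ≈ 53.4% when
C = 1.16, or C ≈ 0.71 when IS = 41.35%), which suggests a different
averaging convention behind the printed means. Both pooled and
per-cage conventions are implemented; resolving which matches requires
the original cage-level datasets.

## Validation scales and numerical choices

The test suite validates at desk scale, chosen to keep the full run in
minutes on one CPU: competitiveness recovery at the study design
(4 cages × 50 females × Poisson(50) eggs, B = 5000), Monte-Carlo SEs
from 40–50 outer replicates; GLM recovery at 200 flight replicates;
beta-binomial recovery at 200 cages of ~2500 eggs; CI calibration over
300 outer simulations with B = 1000.

Known limitation, measured by that calibration run: with only 4 cages
per arm the stratified cage bootstrap has 4 clusters per stratum, and
the nonparametric bootstrap's (n−1)/n variance shrinkage at n = 4 makes
the percentile CI markedly anti-conservative — observed coverage of the
nominal 95% interval is ≈ 80% at the study conditions, rising to ≈ 93%
at 12 cages per arm. This is a property of cluster bootstraps at tiny
cluster counts, not of the implementation; bootstrap SEs and CIs from
4-cage experiments should be read as lower bounds on uncertainty.

Other numerical conventions: ties in ranks are mean-ranked; the
Kruskal–Wallis tie correction divides by 1 − Σ(t³−t)/(N³−N); compact
letters use the insert-and-absorb algorithm (deterministic given group
order, not guaranteed minimal); JSON reports serialise with sorted keys
and no timestamps so identical runs are byte-identical; non-finite
numbers serialise as null.
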