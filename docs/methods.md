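# Methods

This note documents the statistical procedures implemented in `cardiorenal`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## The phenotyping model

The analysis treats each adult participant as a point in a 10-dimensional
risk-factor space — height (cm), BMI (kg m⁻²), waist-to-height ratio, SBP
(mmHg), DBP (mmHg), resting heart rate (bpm), HDL (mmol L⁻¹), non-HDL
(mmol L⁻¹), HbA1c (%), eGFR (ml/min/1.73 m²) — and partitions the joint
distribution with k-means. k-means assumes roughly spherical clusters in the
*standardized* space and hard membership; it estimates cluster means but not
covariances, so it is a restricted Gaussian-mixture model. Men and women are
clustered separately on rounds pooled across the survey era, each sex with
its own standardization (per-feature z-scores).

### Derived measures

BMI, WHtR and non-HDL are exact ratios/differences of raw fields. Kidney
function uses the CKD-EPI creatinine equation; the 2009 coefficients are the
default because the analysis era predates the 2021 race-free refit, the race
multiplier is **off** by default, and the 2021 variant is selectable
(`egfr_ckdepi(..., version="2021")`). The equation is a piecewise power law,
continuous at the sex-specific knot κ and strictly decreasing in creatinine,
so it inverts in closed form; the generator uses that inverse to back-derive
serum creatinine. Serum creatinine passes through a configurable linear
calibration map (default identity: the published cross-method calibration
coefficients are external data).

## Cleaning

Stages run in this order, with each record attributed to the first rule that
removes it:

1. **BP summarization** — discard the first reading (it is systematically
   inflated), average the rest; fewer than two readings leaves the summary
   missing (configurable to use a single reading).
2. **Plausibility ranges** — per-variable bounds on natural scales (height
   100–250 cm, SBP 70–270, DBP 30–150, BMI 10–80, TC 1.75–20, HDL 0.4–5,
   HbA1c 3–18 %, RHR 30–200, creatinine 0.2–15 mg/dL, ...). These defaults
   are this package's own table, fully overridable by config.
3. **Internal consistency** — SBP > DBP and TC ≥ HDL; an offending pair is
   set missing as a pair.
4. **Pairwise Mahalanobis screen** — applied to every pair among the five
   anthropometric variables, the BP pair and the lipid pair; all members
   log-transformed except height and DBP. The cutoff is on the *squared*
   distance: d² > χ²₂ at cumulative probability 1 − 2(1 − Φ(6)) ≈ 40.09,
   i.e. a two-sided univariate 6-SD tail mapped to two dimensions (the
   unsquared equivalent would be ≈ 6.33). Parameters are estimated per sex
   on pooled rounds, matching the sex-stratified clustering. The estimate is
   refreshed after excluding flagged pairs and iterated to a stable flag set
   (at most 10 passes): extreme pairs inflate a one-shot covariance enough
   to mask one another, while on clean data the first pass flags nothing and
   the iteration is a no-op. Flagged pairs have both members set missing
   (dropping the whole record immediately is available by flag); the
   complete-case restriction then removes the participant.
5. **Analysis set** — age ≥ 20 with a complete 10-feature vector.

The stack is idempotent, affine-equivariant on the log scale (rescaling a
variable does not change flags), and removes nothing from an error-free
synthetic cohort beyond the under-age/incomplete rules (the null tail
probability per pair is ~2×10⁻⁹).

## Clustering

Lloyd iterations with Euclidean distance; initialization draws k distinct
data points per start (k-means++ available by flag but not default);
assignment ties break to the lowest cluster index; an emptied cluster is
reseeded at the point farthest from its center so k stays fixed; convergence
when assignments are stable or the maximum center shift is < 10⁻⁶
standardized units (max 300 iterations); the best of `n_starts` (default 50)
random starts by total within-cluster sum of squares is returned. The
implementation is validated against an exhaustive-partition oracle at tiny n
and against an independent library implementation on random data.

Diagnostics report the elbow curve (wcss) and mean silhouette width per k
over a 5–12 default range; a singleton's silhouette is defined as 0.

**Profiling and naming.** Clusters are summarized by per-feature medians
positioned as percentiles of the whole-sample empirical distribution,
risk-oriented (reversed for height, HDL and eGFR, where lower values mean
higher risk). Names come from a priority-ordered deterministic rule set on
these positions — a formalization of the inspection-based naming that such
analyses traditionally use, needed here so tests can assert names:

| priority | name | rule (risk-oriented percentile positions) |
|---|---|---|
| 1 | severe hyperglycemia | HbA1c ≥ P95 |
| 2 | severe obesity | BMI ≥ P92 |
| 3 | high blood pressure | SBP ≥ P90 |
| 4 | high cholesterol | non-HDL ≥ P90 |
| 5 | high heart rate | RHR ≥ P90 |
| 6 | low DBP, low eGFR | DBP ≤ P25 and eGFR ≤ P25 (natural scale) |
| 7 | low risk | every non-height position ≤ P40 |
| 8 | low BMI, high HDL | BMI ≤ P25 and HDL position ≤ P25 |
| — | mid risk tall / short | fallback, split by height median vs sample median |

Two thresholds deserve comment. The obesity rule sits at P92 rather than
P95 because a cluster holding ~10 % of the sample caps its own median near
P95 by construction; the hyperglycemia cluster is small (~3 %) so P95 works
there. Height is excluded from the low-risk rule because stature is not a
modifiable risk factor and the low-risk phenotype is defined by near-optimal
*levels*, not by being tall. All thresholds are configurable.

Cluster correspondence across runs uses the per-pair Jaccard matrix and an
optimal one-to-one (rectangular) assignment; flow tables across k are plain
contingency counts. Intra/inter-cluster distances are exact all-pairs
average Euclidean distances (chunked, not approximated); a singleton's intra
distance is 0 with a warning.

## Stability

For B subsamples (default 1,000; the bundled acceptance run uses 50) of
fraction 0.5 drawn without replacement, the subsample is re-clustered at the
reference k and each reference cluster records its **maximum** Jaccard
against any replicate cluster — the standard clusterwise-stability choice; a
global one-to-one matching is available (`matching="assignment"`) and is
never larger. Replicate re-clustering uses 10 starts (vs 50 for the
reference fit) for tractability, stays in the full-sample standardized space
(per-subsample re-standardization behind a flag), and draws an independent
child seed per replicate from one master seed.

The null calibration applies the identical procedure to n iid draws from an
uncorrelated standard normal in the same dimension: k-means happily cuts one
Gaussian blob into k arbitrary slabs, but the slabs move between subsamples,
so every per-cluster average stays low (≤ 0.30 at n = 30,180, dim = 10,
k = 10). Separated synthetic mixtures score ≥ 0.90, so the two regimes are
cleanly distinguishable.

**Subperiod consistency** re-clusters each calendar subperiod with its own
standardization, profiles the result, and matches period clusters to the
pooled reference by the root-mean-square difference of percentile positions
— computed against the *pooled* distribution, because within-period ranks
renormalize and would mask an archetype that is absent from a period.
Matches with RMS distance above 12 percentile points (default, configurable)
are reported as unmatched; in simulations genuine matches sit below ~7 while
blob-splitting artifacts sit above ~17.

## Survey-weighted analysis

Weight preparation: (1) within each round, weights are rescaled to a common
total — the mean per-round sample size — so every round contributes the same
effective sample size; (2) within each round, 5-year age-band multipliers
(20–24 … 85+) post-stratify the weighted age distribution to a reference.
The reference table of record (census counts) is external, user-supplied
data; the shipped default is the pooled empirical band distribution
restricted to bands populated in every round (a uniform-over-bands reference
is provided for stylized tests). A band with zero weighted mass but positive
reference mass is an error, not a silent renormalization.

Prevalence series are weighted cluster shares per round — age-standardized
(post-stratified weights) or crude (rescaled weights only). Trend models are
one weighted logistic regression per cluster: membership on continuous
calendar year plus age-band indicators, fitted by IRLS with frequency-style
weights, reported as percent change in odds per year with a two-sided
large-sample Wald p (no multiple-testing adjustment). The pre-specified
periods are 1988–2000, 2000–2010 and 2010–2018, boundary years inclusive on
both ends (they overlap deliberately, matching the pre-specification).
Predictor models regress membership on age band (reference 20–24), year per
decade, ethnicity (reference non-Hispanic White), education (reference below
high school), smoking (reference never), four medication flags and three
disease-history flags. Design-based (strata/PSU) variance estimation is out
of scope: SEs treat the weights as frequency weights and should be read as
such. Wilson score intervals accompany binomial proportions; they are exact
0/1 at empty/full counts.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes — no more:

- each sex is a mixture of phenotype archetypes, each a multivariate normal
  on natural scales truncated to plausibility bounds by resampling (the
  Euclidean/k-means geometry the method expects; not log-normal);
- mixture weights evolve on the log-odds scale per round
  (`weight_trend_per_round`), emulating rising/falling phenotype prevalence;
- raw fields are back-derived so that derived measures are true functions of
  raw data: weight = BMI·(height/100)², waist = WHtR·height,
  TC = non-HDL + HDL, creatinine by inverting the eGFR equation at the drawn
  age and sex, three BP readings = drawn value + iid N(0, 2²) noise with the
  first reading biased +3 mmHg (so the averaging rule matters);
- survey weights are log-normal (σ = 0.5 default), independent of archetype;
- ages are drawn per archetype from a truncated-normal distribution
  discretized over the 5-year bands;
- optional binary covariate effects shift one archetype's membership
  log-odds (for predictor-recovery experiments), and an artifact injector
  plants implausible values, discordant BP pairs (≥ 8 SDs along the
  discordant direction of the (log SBP, DBP) distribution while each value
  stays individually plausible), consistency violations and missing fields,
  returning the altered ids as ground truth.

The default library has 10 sex-specific archetypes whose mixture shares and
defining levels follow published per-phenotype summaries (e.g. hyperglycemia
median HbA1c 9.9/9.8 %, severe-obesity BMI 41.1/38.2 kg m⁻², high-BP SBP
159 mmHg, mid-risk heights 155/167 cm women, 168/182 cm men); within-cluster
covariances are **not** published anywhere and are this package's own
illustrative choices (diagonal, with realistic SDs). Consequently synthetic
prevalence and characteristic tables are *not* estimates of any real
population, and passing tests demonstrate that the machinery recovers known
structure — not that real survey data contain that structure. The generator
also omits real-data features that the analysis does not rely on: multistage
stratified sampling, oversampling, nonresponse adjustment, questionnaire
skip logic, measurement-era drift and within-person correlation.

## Numerical choices and problem sizes

- All randomness flows through `numpy` SeedSequence spawning; identical
  (config, seed) reproduces outputs bit-for-bit.
- k-means tolerance 10⁻⁶ standardized units, max 300 iterations; empty
  clusters reseeded rather than allowed to vanish.
- Percentile positions use the midrank convention (ties count half).
- The test suite and the acceptance script run the null stability
  calibration at n = 30,180, dim = 10, k = 10 with 10 starts and B = 50
  half-subsamples, and the mixture-recovery checks at n = 2,000 per sex with
  B = 50 — sizes chosen so the whole suite completes in minutes while the
  Monte-Carlo error on every asserted quantity stays an order of magnitude
  below its margin (e.g. moving from B = 1,000 to 50 shifts per-cluster
  average Jaccards by well under 0.05).

## Known limitations

- Variance estimation ignores the survey's design effect (no strata/PSU
  linearization); p values are large-sample Wald.
- The Mahalanobis screen assumes approximate bivariate log-normality; very
  heavy-tailed variables would need a robust (e.g. MCD) variant.
- Cluster naming is a deterministic surrogate for expert inspection; on real
  data the rule thresholds would deserve review against the actual profile
  distributions.
- The generator's archetype covariances are stipulated, so absolute
  prevalence levels in synthetic outputs carry no external meaning.
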