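# Methods

## Background and scope

The Implicit Association Test (IAT) infers an implicit preference from the
latency difference between two "critical" block pairings: a *compatible*
assignment of categories to response keys and an *incompatible* one. A
*scoring algorithm* turns a subject's raw trial record (latencies plus
error flags) into one number. `iatkit` implements a combinatorial family
of such algorithms, built from four orthogonal parameters:

1. **Extreme-latency treatment** (6 options): no treatment; fixed-value
   trimming (drop < 400 ms); fixed-value winsorizing (clip to
   [300, 3000] ms); 10% statistical trimming; 10% statistical
   winsorizing; 10% inverse trimming (drop the values adjacent to the
   median). Latencies above 10 s are always removed first, for correct
   and error trials alike.
2. **Error treatment** (5 options): ignore (pool errors with correct
   trials), exclude, recode to the block's correct mean + 2 SD, treat
   correct and error latencies separately, recode to correct mean + 600 ms.
3. **Score formula** (7 options): D (mean difference over the inclusive
   SD); G (difference of mean Gaussian ranks); the Worst Performance Rule
   (difference of 90th percentiles over the inclusive SD); mini
   differences (mean over SD of all pairwise incompatible − compatible
   differences), plus trimmed, winsorized and inverse-trimmed variants of
   the mini-difference distribution.
4. **Practice/test handling** (2 options): pool the critical trials, or
   score practice and test subsets separately and average.

The full cross is 6 × 5 × 7 × 2 = 420 algorithms. Ignore and Separate are
mathematically identical whenever the latency treatment does not depend on
the empirical distribution (options none / fixed trim / fixed winsor), so
the deduplicated set has 420 − 3·7·2 = 378 unique algorithms. The package
keeps the Ignore-coded spec as the canonical representative of each merged
pair; a property test asserts the merged twins produce bit-identical score
columns (treated scored sets are returned sorted so that logically
equivalent paths are bitwise equal, not merely equal up to float summation
order).

Named presets: `D2` = (fixed trim, ignore, D, distinction), `D5` and `D6`
swap the error treatment for the 2 SD and 600 ms recodes; the `*_improved`
variants replace the latency treatment with statistical winsorizing and
drop the practice/test distinction, leaving the error treatment unchanged.
`G_standard` is defined here as (no treatment, ignore, G, no distinction):
the G score is rank-based, so no extreme-latency pretreatment is its
natural baseline.

## Numerical conventions

- **Tail count** for statistical trimming/winsorizing: k = ⌊p·n⌋ per tail
  (default p = 0.10), computed on the vector the option operates on. This
  is deterministic and never removes fractional trials.
- **Winsorizing replacement** is the most extreme retained order statistic
  (standard winsorizing).
- **Inverse trimming** sorts ascending and removes the k values on each
  side of the center: for even n, the two central order statistics and
  outward; for odd n the median itself is retained and its k neighbours on
  each side are removed. This keeps the removed count at exactly 2k for
  every n; the odd-n tie-break is a package decision (definitions in the
  literature only say "the 10% above and below the median").
- **Recode baselines** (mean, SD for the 2 SD / 600 ms penalties) are
  computed on the *treated* correct latencies of the same block, mirroring
  the D-score tradition in which extreme-latency handling precedes error
  replacement; recoded values are not re-subjected to the latency
  treatment, but they are capped at the 10 s ceiling so that no scored
  value ever exceeds it.
- **SD** is the sample (n − 1) standard deviation throughout.
- **Quantiles** (Worst Performance Rule) use linear interpolation between
  order statistics (the "type 7" convention; `numpy.quantile` default).
- **G score ranks**: midranks for ties, fractional rank (r − 0.5)/N,
  Gaussian rank = standard-normal quantile. The convention is isolated in
  one function (`scoring.gaussian_ranks`).
- **Minimum-data rule**: a block (or phase subset under Distinction) must
  retain ≥ 2 scored latencies after all treatments, otherwise the
  subject's score for that algorithm is missing with a coded reason
  (`too_few_trials`, `zero_pooled_sd`, `recode_baseline_needs_2_correct`,
  …) recorded in the score matrix's JSON sidecar.

## Psychometric evaluation

Per dataset, each algorithm gets an indicator table:

- **Split-half reliability**: trials are split odd/even by within-block
  presentation order, each half is scored with the complete pipeline, the
  across-subject Pearson r is Spearman–Brown corrected (2r/(1+r)) and
  clamped to [−1, 1]. The split scheme is a package decision and is
  isolated in `psychometrics.split_halves` so alternates (first/second
  half, random split) can be swapped in.
- **Test–retest**: Pearson r of scores across two sessions.
- **Validity**: Pearson r of scores with each criterion measure, tagged
  direct / indirect / behavioral via the panel's role sidecar. Criteria
  are pre-oriented so that higher = stronger target-consistent preference,
  hence higher correlations are better. Correlations are pairwise-deleted
  and require ≥ 3 complete pairs.

Indicators are converted to **rank scores**: within each indicator the
algorithms are midranked, the highest rank going to the best performance;
ranks are averaged within property; *overall validity* is the unweighted
mean of the direct/indirect/predictive property rank scores present in the
dataset, and *reliability* the mean of the reliability properties present.

## Rank-based inference

The comparison layer treats (algorithm × dataset) rank scores as analysis
units and asks whether one option of a parameter outperforms another.

- **ANOVA-type statistic (ATS)**: global midranks; cell relative effects
  p̂ = (mean cell rank − 0.5)/N; for a hypothesis projection T the
  statistic is F = N·p̂′Tp̂ / tr(TV̂) with V̂ = N·diag(σ̂²ᵢ/nᵢ), referred to
  an F distribution with Box-approximated fractional degrees of freedom
  f₁ = tr(TV̂)²/tr(TV̂TV̂) and f₂ = tr(TV̂)²/Σ tᵢᵢ²v̂ᵢᵢ²/(nᵢ−1), following
  the Brunner–Dette–Munk construction. The partial-η² reported alongside
  is derived as f₁F/(f₁F + f₂) and is labelled an approximation in the
  output. A Monte Carlo study (2000 null replicates, run by both the test
  suite and the acceptance script) checks the 5% level.
- **Simultaneous contrasts**: per-group global relative effects with an
  analytic influence-function covariance estimate (own-group term
  (Ĥ(Xᵢₖ) − p̂ᵢ)/nᵢ plus the cross term (ĉᵢⱼ − F̂ᵢ(Xⱼₖ))/N that accounts
  for estimating the pooled cdf). Simultaneous two-sided intervals use the
  equicoordinate quantile of max|Z| for a multivariate normal with the
  contrasts' estimated correlation, computed by seeded Monte Carlo
  (200 000 draws; Bonferroni fallback when the correlation matrix is not
  usable). Intervals are large-sample (normal-based); a null-simulation
  coverage study guards calibration.
- **Patel–Hoel 2×2 interaction**: within each level of factor B the
  dominance probability P(A₁ < A₂) (ties half) is estimated from midrank
  placements with the Brunner–Munzel variance; Δ is the difference of the
  two estimates with a normal-approximation CI.
- **T-graphs**: a directed edge winner → loser for every significant
  contrast, then transitive reduction (reachability is preserved; a cycle
  among significant relations raises an error because the contrasts'
  transitivity excludes it). Exported as DOT and node-link JSON.

## Synthetic data generator

The generator emulates the critical-block structure of a classic 7-block
IAT: 20 practice + 40 test trials per pairing (60 per critical block).
Latencies are ex-Gaussian — the standard positively skewed reaction-time
family — with defaults μ = 600 ms, σ = 100 ms, τ = 150 ms, plus a
per-subject general-speed offset (SD 80 ms). Each subject's latent
preference θ ~ N(0, 1) shifts the incompatible and compatible blocks by
±(δ·θ)/2 with δ = 150 ms, a typical magnitude for a clearly measurable
implicit effect. Errors occur at 5% base rate, +3% in the incompatible
pairing; under the built-in-penalty mode each error latency additionally
contains a positive correction time (300 ms + Exp(150 ms)), reproducing
the empirical signature that error trials are slower than correct ones in
every block. Contamination injects 2% fast guesses (120–295 ms) and 1%
lapses (4–11 s, so the 10 s ceiling is exercised). Criterion measures are
loading·θ + N(0, 1) noise with loadings 0.3–0.5 across two direct, two
indirect and one behavioral measure; a second session redraws trial noise
around θ′ = ρθ + √(1−ρ²)ε with stability ρ = 0.8. The six-dataset study
layout (`default_study_configs`) is three built-in datasets with a retest
session and three no-built-in single-session datasets, so that crossing
with the 378 unique algorithms yields 2268 analysis units.

What the generator does *not* model: stimulus-level crossed random
effects, block-order effects, strategic recoding/faking, practice-related
drift within a session, and subject-level exclusion criteria. One
consequence worth spelling out: practice and test trials are drawn from
the same process, so the practice/test-distinction parameter has no true
effect built into the synthetic study beyond the noise-weighting penalty
of averaging a short practice-block score — the direction of its contrast
in the shipped six-dataset demo is therefore seed-dependent and should be
read as a pipeline demonstration, not a finding. The calibration
(type-I, coverage) and recovery quantities, by contrast, are stable
across seeds. Passing
tests therefore show that the machinery is correct and calibrated under a
realistic-but-idealized data-generating process, not that any particular
algorithm is best for real populations.

## Problem sizes used in the shipped analyses

The acceptance script runs the full six-dataset study at 40 subjects per
dataset with all 378 unique algorithms (2268 units through the complete
scoring → indicators → ranks → ATS pipeline), a 2000-replicate null study
for the ATS level, a 400-replicate coverage study for the contrast
intervals, and 10 recovery replicates at 200 subjects. These sizes keep
the whole run in the low minutes on one core while leaving Monte Carlo
error small relative to the effects checked.

## Known limitations

- Contrast and Patel–Hoel intervals are normal-approximation intervals;
  small-group coverage can dip slightly below nominal (the coverage study
  tracks this).
- η²ₚ for the ATS has no canonical definition; the conversion used here is
  a labelled approximation.
- The analysis units (algorithm × dataset rank scores) are treated as
  independent by the inference layer, as in the study design the package
  reproduces; algorithms scored on the same subjects are in truth
  positively dependent, which makes the significance tests liberal in
  absolute terms. The layer is intended for comparing options on a common
  footing, not for population inference.
- Test–retest requires a second session in the input; the generator only
  produces it for built-in-style configurations by default.
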