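# Methods

This note documents the models and procedures `macromate` implements, the
defaults it ships, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Event model

Observations are scored at 1 frame s⁻¹, so all times are integer seconds.
Intervals are half-open `[start, end)` and a duration is `end − start`;
the minimum-copulation rule is therefore `end − start ≥ 5` (we read the
5-s threshold as inclusive). Two worms form either a *pair* (one pairing
type: conspecific *M. lignano*, conspecific *M. janickei*, or
heterospecific) observed alone for 2 h, or share a *drop* with two worms
of each species, where dyeing one species lets every copulation be typed
LL / LJ / JJ. In pair logs the copulation type is `NA` — the two species
cannot be told apart under transmitted light — and species-level typing is
only required in drop logs. Copulations of one pair may not overlap in
time, and a suck (a postcopulatory self-directed behaviour) may not
overlap a copulation; both are validation errors at ingest. Sub-5-s
"copulations" are rejected with a logged warning rather than silently
dropped, so scoring errors stay visible.

An event table can only represent records that have events; replicates
that never copulated re-enter the analysis through the trait-table roster
and are flagged `excluded_no_copulations` there.

## Behavioural traits

Six traits are derived per pair from the first five copulations only
(fixing the observation effort per pair):

| trait | definition | undefined when |
|---|---|---|
| copulation latency | start of first copulation | no copulations |
| mean copulation duration | mean of `end − start` | no copulations |
| mean copulation interval | mean gap end→next start | < 2 copulations |
| mean time until suck | mean delay copulation-end → suck-start | no attributed suck |
| mean suck duration | mean suck length | no attributed suck |
| number of sucks | count of attributed sucks | < 5 copulations |

A suck is attributed to a copulation if it is the first suck starting at
or after that copulation's end and before the next copulation's start;
sucks after the fifth copulation are ignored. Undefined traits are typed
missing values, never zeros. Fecundity is the 14-day offspring count of
the isolated maternal individual(s), averaged over both for heterospecific
pairs.

Group comparisons use one-way ANOVA on natural-log-transformed data
followed by Tukey HSD for the five timed traits (time-until-suck gets +1
before the log because a suck can start the frame its copulation ends),
and Kruskal–Wallis followed by pairwise Mann–Whitney tests with Bonferroni
factor 3 for suck counts and offspring numbers. All logs are natural: the
log-normal CV formula `CV = 100·√(exp(σ²)−1)` is exact only for base *e*.
Standard deviations are sample (n−1) throughout. Compact letter displays
are computed at α = 0.05 from maximal cliques of the
not-significantly-different graph.

## Mate-choice statistics

With two worms per species in a drop, the random-mating null for
copulation types is 0.25 : 0.50 : 0.25 — the Hardy–Weinberg-style
expectation from drawing the two *participations* of a copulation
independently from a species pool at equal rates. (Counting the six
distinct pairs of four worms instead gives 1/6 : 4/6 : 1/6; the field's
convention, which we follow, is the participation null, and the
rate-adjusted machinery below is only self-consistent under it.)

* **First-copulation test** — Pearson χ² of the per-drop first copulation
  types against (0.25, 0.50, 0.25), df = 2. Ties in start second are
  broken by event-row order (deterministic and logged in the record
  ordering).
* **Repeated G-tests** — per-drop G = 2·Σ oᵢ ln(oᵢ/eᵢ) (0·ln 0 = 0) with
  Bonferroni over the included drops; a heterogeneity G computed as the
  independence-table G on the drops × 3 table, df = (R−1)(C−1) (59 drops →
  df = 116); a pooled G on the summed counts; and the total G = Σ per-drop
  G with the identity total = pooled + heterogeneity used as a numerical
  cross-check, not as the definition. When the heterogeneity G is
  significant the pooled test is reported but flagged not interpretable
  and conclusions rest on the per-drop tests. All-zero category columns
  are dropped from the independence table (with df following the retained
  table) and empty drops are excluded with a logged note. No Williams or
  Yates corrections are applied.
* **Mating rates and the rate-adjusted null** — p = (2m_LL + m_LJ)/(2m_T),
  q = 1 − p; expected counts (p², 2pq, q²)·m_T; per-drop Pearson χ² with
  Bonferroni. The default df is 1 (three categories, one constraint, one
  parameter estimated from the same counts — the Hardy–Weinberg-test
  analogy); df = 2 is available since the convention differs between
  sources, and both are reported by the CLI. On ideal multinomial draws
  from the null the df = 1 test rejects at ≈ the nominal rate while df = 2
  is conservative (the suite checks the df = 1 calibration). If q = 0 then
  m_LJ = m_JJ = 0 necessarily, so zero-expectation categories can never
  hold observations; they contribute nothing.

## Morphometrics

Each stylet carries 60 ordered landmarks: ordinals 1 and 30 fix the tip
and base of the curve on the side far from the seminal vesicle, 31 and 60
the near side, with 28 sliding semilandmarks between each pair. Ordinals
are 1-based in files and documentation, 0-based internally.

* **GPA** centres each configuration, scales to unit centroid size and
  rotates to an iterated consensus; rotation is solved by SVD with the
  determinant constrained to +1 — reflections are never allowed, chirality
  is handled only by explicit mirroring (x-negation) upstream, matching
  how specimens imaged dorsally vs ventrally are standardised. The
  consensus is iterated to 10⁻¹⁰ (max 100 iterations) and the result is
  put in a canonical orientation (principal axis on x, 180° ambiguity
  fixed by the sign of the third moment), which makes the output invariant
  to input order and to similarity transforms of any input.
* **Semilandmark sliding** moves each semilandmark along the chord between
  its curve neighbours to minimise, per specimen, the thin-plate-spline
  bending energy of the consensus-to-specimen deformation (default) or
  the Procrustes distance (`chord`). The bending-energy step solves the
  tangent-restricted quadratic exactly, then scales the whole step so no
  landmark moves more than half the distance to its nearest curve
  neighbour — any fraction of the Newton step of a convex quadratic still
  descends, and the cap keeps the tangent linearisation (and the curve
  geometry) valid; without it the unconstrained step can run away along
  near-affine directions of the bending-energy matrix. After each pass the
  set is re-superimposed and the consensus updated; iteration stops at a
  relative objective change of 10⁻⁸, after 20 passes, or as soon as a pass
  no longer improves the objective (the best state is kept, making the
  recorded trace non-increasing by construction). Consensus re-estimation
  is not guaranteed to reduce the sliding objective, hence the explicit
  early stop.
* **Relative warps** at α = 0 are the principal components of the
  flattened aligned coordinates about their mean — the only setting in
  which RWS1 is a plain principal component, and the default. α ≠ 0
  reweights the non-affine eigendirections of the consensus bending-energy
  matrix by λ^(−α/2) for parity with the classic tps-software family.
  Warps with singular value below 10⁻⁸ of the largest are treated as zero;
  n generic specimens yield n − 1 nonzero warps (72 → 71), bounded by
  min(n − 1, 2·60 − 4).
* **Thin-plate splines** use the U(r) = r² log r² kernel; the interpolant
  is exact at the landmarks, affine targets have zero bending energy, and
  degenerate (collinear) landmark systems raise.

Group tests on centroid size and RWS1 are one-way ANOVA + Tukey HSD on the
raw scale (shape scores can be negative; no log transform).

## Synthetic generators

The generators define the study conditions the tests run under; one global
seed fans out to independent substreams (pairs / drops / stylets) so any
dataset regenerates alone.

**Pair logs.** Latency, copulation duration, interval, suck delay and suck
duration are log-normal per species. The log-scale sd defaults are set
from the stereotypy each behaviour shows in conspecific pairings via the
exact CV relation (e.g. a latency CV near 86% ↔ σ_log ≈ 0.745, duration
CV 27% ↔ 0.265); the medians, which the summary statistics do not pin
down, are plausible field values: *M. lignano* median copulation ~100 s
and *M. janickei* ~480 s (≈ 5× longer on the mean scale), latencies of
10–15 min, intervals of 5–10 min, near-immediate *M. lignano* sucks
(median 2 s) vs delayed *M. janickei* sucks (median 60 s), suck
probability per copulation 0.9 / 0.7 / 0.3 (lignano / janickei / hetero).
Heterospecific pairs average the species' log-medians and inflate the
log-sd by 1.4 (the partners disagree about timing, so realised behaviour
is noisier). Fecundity: Poisson mean 15 offspring for conspecific pairs
(one maternal individual isolated); heterospecific pairs succeed with
probability 0.2 and then exactly one randomly chosen partner produces
1 + Poisson(3) offspring — never both. Because events are drawn i.i.d.
within a pair with no between-pair random effect, traits that average
over five copulations show smaller pair-level CVs than single-event
traits like latency; the generator emulates distributional shape and
species contrasts, not the full between-pair variance structure of real
data, and passing tests should be read accordingly.

**Drops.** Each drop holds L1, L2, J1, J2 with six candidate pairs under
competing exponential clocks. The hazard of pair (i, j) is
propensityᵢ·propensityⱼ/3600 s⁻¹, times the preference multiplier for
conspecific pairs, times a homotypic factor 2 for conspecific pairs. The
factor 2 makes the no-preference copulation-type *rates* exactly
(p², 2pq, q²) with p = prop_L/(prop_L + prop_J) — i.e. the generator's
null case is precisely the participation null the statistics test, for
any propensity values (a bare product over the six pairs would instead
give the 1:4:1 pair-count proportions and contradict the analysis's null).
Defaults: propensity 3.0 vs 1.5 (the two-fold rate difference between the
species), preference 1, a 7200-s window, 68 drops of which 5 are flagged
injured and 4 dim-lighting (leaving 59 analysable). Drawn durations use
the species distributions (LL → lignano, JJ → janickei, LJ → mixture).

By default copulating individuals are *blocked* until their copulation
ends (`busy_blocking=True`, the physical model; no refractory period
beyond that, as none is documented). Blocking has a real statistical
consequence: while the LL pair copulates only the JJ pair is free, and
vice versa, so the copulation sequence is positively correlated
homotypically and full-window counts drift away from (p², 2pq, q²) even
with no preference — the arena itself produces apparently assortative
counts, and the per-drop rate-adjusted test then rejects well above its
nominal level. This is a violation of the null's independence assumption
by the data-generating mechanism, not a miscalibration of the test, and
the suite demonstrates both facts: calibration is verified with blocking
off (the regime where participations are independent), and a companion
test shows blocking inflates rejections. First-copulation statistics are
unaffected by blocking. Under strong preference (×10) the test's power
exceeds 0.8 at m_T ≥ 50.

**Stylets.** The two species means are packaged hand-drawn 60-point
polylines — a tapering tube around a centerline whose heading turns
gently (*M. lignano*, nearly straight tip) or sharply near the tip
(*M. janickei*, hooked) — synthetic fixtures qualitatively matching the
species' habitus, not tracings of any image. The hybrid mean interpolates
the GPA-aligned species means (weight 0.5) and is scaled 1.15× in
centroid size (the observed larger hybrid stylets have no mechanistic
explanation; this is a knob, not a model). Specimens are the group mean
plus isotropic Gaussian landmark noise (sd 0.8 image units against a
stylet length of ~60); group sizes default to 25 / 29 / 18.

## Problem sizes and numerical choices

Calibration and recovery tests run at 150–400 simulated drops, 200 trait
replicates, and 200 pairs per species — sizes at which binomial/SE bounds
are already tight enough to detect the failure modes they guard against.
The acceptance script uses 10,000 drops (first copulation only) and the
full 72-specimen shape set. GPA tolerance 10⁻¹⁰ (max 100 iterations);
sliding tolerance 10⁻⁸ (max 20 passes); relative-warp variance floor
10⁻⁸ of the leading singular value; G/χ² additivity verified to 10⁻⁸
relative.

## Known limitations

* The arena simulator has no spatial component; encounter rates are
  implicit in the propensities.
* The generator is not fitted to any deposited dataset; it reproduces
  structure (distribution families, rate ratios, design counts), not
  empirical parameter values, and per-pair behavioural correlations are
  absent (see above).
* Relative warps with α ≠ 0 follow the standard reweighting but are
  provided for parity only; all shipped analyses use α = 0.
* The TPS reader accepts the common tpsDig dialect (LM=, ID=, SCALE=,
  IMAGE=, CRLF tolerated); it does not implement the full TPS-file zoo
  (curves, links, 3-D).
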