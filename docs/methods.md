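# Methods

This note records the models, numerical choices and known limitations behind
`saltqtl`, in the order the pipeline runs them.

## Synthetic doubled-haploid trial data

The simulator exists so that every stage of the analysis can be exercised
and falsified at desk scale; it is first-class, tested code, not a fixture.

**Genotypes.** A DH line is fully homozygous, so each marker carries one of
two parental alleles (`E`/`K`).  Along a linkage group the allele sequence
is a two-state Markov chain: the first marker is a fair coin, and the switch
probability between adjacent markers is the inverse-Kosambi recombination
fraction r = ½ tanh(2d) of their cM distance.  No crossover interference is
modelled beyond what the Kosambi function implies pairwise between adjacent
markers — the simplest process consistent with a Kosambi-scale map.  Missing
calls are injected i.i.d. after genotype generation.  The default scale is
212 lines and five 120 cM groups at 5 cM spacing (126 positions of a 1 cM
walk per group): a deliberate desk-scale stand-in for a real wheat map with
thousands of markers, which changes runtime only, not logic.  Group labels
reuse wheat chromosome names (1A, 2B, 5A, 6A, 7A) purely for readability.

**Traits.** Additive architecture only: with s = +1 (E) or −1 (K) at each
causal locus, value = µ + Σ a·s + N(0, σ²).  The causal genotype is read
from the marker nearest the requested position rather than a hidden locus;
at the default 5 cM spacing the discretization is at most 2.5 cM, which
keeps recovery experiments interpretable.  Because DH allele classes are
balanced, the expected single-locus variance share is a²/(a² + σ²), and
`effect_for_target_r2` inverts this to plant a locus at a chosen share
(15 % by default, the size of a solid but not overwhelming growth QTL).
Missing calls at the causal marker are resolved by a fair coin so the trait
is defined for every line.  Dominance is impossible in DH material and
epistasis is out of scope.

**Growth.** Shoot growth on the imaged window (day −4 to +10 around salt
application) is exponential: control PSA(t) = A₀·exp(g·t); salt-treated
plants grow at rate g before day 0 and g·π after, with a per-line penalty
factor π.  Defaults: g = 0.18 d⁻¹ and A₀ = 20 kpixels, plausible magnitudes
for young wheat on an imaging platform; penalties drawn uniformly on
[0.6, 1.1] reproduce the observed spread of the tolerance index (roughly
0.66–1.09, a few lines growing slightly faster under salt).  Penalties may
exceed 1 for that reason, so the spec-level restriction to (0, 1] is relaxed
to "positive".  Measurement noise is a mean-one multiplicative lognormal
(pixel areas are positive; error scales with size) whose log-sd ≈ the
coefficient of variation (0.05 by default).  Each replicate produces a
paired control and salt plant per line, mirroring a split-plot main plot.

**Field trials.** A rows × ranges grid (10 × 12 by default, three replicates
of up to 40 entries) with plot value = line mean + row effect + range effect
+ noise, effects drawn independently per trait.  Assignment is a complete
randomization constrained to the replicate count per line; resolvable
row–column designs are not reproduced.

**What the simulator does not emulate** — and hence what green tests do not
establish about real data: genotyping error, segregation distortion from
selection, interference beyond Kosambi, non-exponential growth (tillering,
senescence), skewed ion-trait distributions arising from major-gene
segregation, genotype-by-environment interaction, and spatial correlation
structure richer than additive row/column trends.

## Growth phenotyping

PSA is the sum of one top and two side pixel counts, in kpixels.  For each
plant a cubic smoothing spline is fitted to **ln(PSA)** against day with the
effective degrees of freedom pinned at 4 (trace of the smoother hat matrix;
the smoothing parameter is found by bisection, and since the trace depends
only on the day grid, the search is cached per imaging schedule — one search
serves all plants).  Fitting the log rather than the raw scale is a
deliberate choice where the procedure's description is ambiguous: RGR is
defined as d ln A / dt, and on the log scale a noiseless exponential is the
penalty-free fixed point of the smoother, so the interval RGR returns the
generating rate to machine precision — a contract the raw-scale variant
cannot make.  Daily RGR is the unit-day difference of the smoothed log
curve (matching a difference-quotient definition with dt = 1 day); the
analytic derivative is also exposed.

The tolerance index of a replicate pair is RGR_salt/RGR_control over days
1–5; the line value averages the per-pair ratios (`ratio_method="paired"`),
with the ratio-of-mean-RGRs alternative behind a switch since published
descriptions support either reading.  Pairs with non-positive control RGR
are excluded and logged — the index is meaningless for a shrinking control
plant — and unpaired plants are dropped.  Line trait values are plain
replicate means; the original split-plot REML adjustment is intentionally
out of scope.  One consequence of df = 4 smoothing worth knowing: the salt
trajectory has a rate kink at day 0 which the spline rounds off, so on
noiseless data the tolerance index deviates from the generating penalty by
up to ~0.03; the paired-exponential case remains exact.

## Map curation and construction

Filters run missingness → distortion → crossovers and are idempotent.  The
distortion rule is conjunctive — frequency outside [0.40, 0.60] **and**
exact binomial p < 0.05 — the conservative reading of an ambiguous
published parenthetical (it removes the fewest markers).  Crossovers are
counted between consecutive non-missing calls so a run of missing data
contributes at most one switch; the threshold (100, global across groups)
is the published value.  Recombination fractions are line fractions among
lines informative at both markers, capped at 0.4999 so Kosambi distances
stay finite; capped pairs are effectively unlinked candidates.  Map
positions are cumulative Kosambi distances of adjacent-marker fractions,
each group anchored at 0 cM.

Marker ordering re-specifies the RECORD idea as explicit COUNT minimization
(total observed recombination events under an order, missing-skipped):
greedy insertion seeded by the tightest-linked pair, then segment-reversal
and single-relocation passes until no move improves COUNT, with the
guarantee that the returned order never exceeds the input order's COUNT.
Orders are identified up to reversal.  Assignment of markers to linkage
groups is taken as input; de novo grouping is out of scope.

## Composite interval mapping

The scan is Haley–Knott regression on the expected genotype score rather
than the EM mixture likelihood of classical CIM — a deliberate deviation:
for a two-class DH population at dense marker spacing the LOD profiles are
near-identical, and the regression form is simpler, deterministic and fast
enough to permute honestly.  At each 1 cM walk position the score is
g = 2·P(E) − 1, with P(E) conditioned on the nearest non-missing flanking
markers through the DH two-state Markov model (hard 0/1 at a genotyped
marker, 0.5 with no informative flank; missing genotypes are never imputed
to hard calls).  The model is trait ~ 1 + g + cofactors, with the 5
forward-stepwise cofactors (largest RSS reduction per step, ties to the
lower marker index) excluded when within 10 cM of the test position on its
group.  LOD = (n/2)·log₁₀(RSS_reduced/RSS_full) with the reduced model
dropping g; the additive effect is the coefficient of g (half the E−K
class-mean difference, positive when E raises the trait); R² (%) is the
RSS drop over the total trait sum of squares — one of several defensible
definitions, chosen for additivity with the cofactor fit.

Numerics: designs are orthonormalized by modified Gram–Schmidt with a
rank tolerance, collinear cofactors dropped with a warning; positions with
no genotype variance get LOD 0; a perfect fit yields LOD = ∞ rather than an
arbitrary cap.  The engine precomputes the score matrices once per
(map, genotype, trait-completeness) combination, so each permutation costs
a few matrix products; complete-case lines per trait.

Permutation thresholds shuffle trait values across lines with genotypes
fixed, re-select cofactors inside every permutation (selection is part of
the procedure; switchable off for speed), and take the empirical (1 − α)
type-7 quantile of the genome-wide maximum LOD.  Fewer than 20 permutations
is refused.  The procedure's measured operating characteristics at the
default desk scale (212 lines, 605 walk positions, 200 permutations):
planted-QTL detection ≈ 90 % at a 15 % variance share, median peak error
≈ 1 cM, and genome-wide type-I error slightly below the nominal 0.05
(each null trait is compared against its own permutation quantile, which
is mildly conservative).  Occasional chance exceedances on unlinked groups
are expected at α = 0.05.

Peaks are LOD-profile local maxima at or above threshold; maxima within
15 cM on a group merge keeping the higher (the unique-locus rule, also
applied across traits by single-linkage clustering).  Support intervals are
the contiguous walk stretch within k LOD of the peak, k = 1 and 2.  Names
follow the wheat convention Q\<trait\>.\<lab\>-\<chromosome\>[.\<n\>], the
ordinal used only when a trait has two or more QTL on one chromosome.

## Field validation

EM38 apparent conductivity (mS/m) is calibrated to EC₁:₅ (dS/m) by ordinary
least squares (slope, intercept, R², two-sided slope p); predictions are
floored at zero.  Soil-solution salinity is EC₁:₅ × 5000 / gravimetric water
content with the water content on the **percentage** scale by default: the
published formula nominally says g/g, but only percent-scale division
reproduces field magnitudes of a few hundred mM (0.79 dS/m at 8.9 % ↔
≈ 444 mM); the fraction scale is supported as an option.

Spatial adjustment is an explicit stand-in for an out-of-scope REML model
with autocorrelated rows and columns: a two-way median polish of the
row × range plot matrix per trial, each line summarized as the mean of
overall + residual over its plots.  It removes additive trends exactly and
beats raw means under simulated trend + noise, but models no within-row
correlation.  Allele effects default to raw line means (the adjusted
variant is a flag) so that noiseless constructions are recovered exactly;
the percentage difference uses the non-beneficial group's mean as
denominator (the published choice is unstated), and concordance is strict
sign agreement with the glasshouse expectation — lower leaf Na⁺ for
exclusion alleles, higher leaf K⁺ or yield for accumulation alleles — with
no significance filter, so a 0 % difference is non-concordant.

## Pipeline

Stage seeds are SHA-256 hashes of (master seed, stage name) reduced below
2³¹, so runs are reproducible end to end and byte-identical under a fixed
config; the manifest digests config, seeds, outputs and file hashes and
carries stage-level counts (lines/markers retained, peaks found).  Stage
failure aborts with a stage-named error and renames partial outputs with a
`.partial` suffix.

## Problem sizes used in the checks

The recovery and error-rate experiments run at the default desk scale —
20 population replicates and 200 permutations for detection, 100 null
traits for type-I error, 500 lines for ordering recovery, 2000 lines for
the recombination-fraction check — sizes at which binomial noise on the
reported rates is a few percent.  The reproduction script
(`scripts/acceptance.py`) uses the same sizes and finishes in about two
minutes on one CPU.

## Known limitations

Single-QTL regression scans only (no multiple-QTL model, no epistasis);
no de novo linkage grouping or map joining; no mixed-model/REML machinery
anywhere (replicate means and median polish stand in); the R² and support
conventions match this package's own definitions, not any particular
legacy program; and conclusions from synthetic data transfer to real
populations only to the extent the generators above capture them.
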