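# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish about real data.

## The synthetic factorial cross

The generator emulates the data-generating process of a dense-marker 7×7
factorial cross in an outbred, dioecious tree.

**Founders and markers.** Marker positions are drawn uniformly without
replacement per chromosome; alt-allele frequencies are uniform on a MAF
range (default 0.1–0.5). The 14 founders' haplotypes are sampled
independently per site — founders are unrelated and sites are in linkage
equilibrium, so a parent is heterozygous at a site with probability 2pq.
Real founder genomes carry background LD and relatedness; nothing
downstream exploits either, so their absence does not flatter the
pipeline.

**Meiosis.** Each chromosome carries a piecewise-constant CO intensity
per sex (expected COs/bp/meiosis). With `interference_mode="none"`,
the CO count is Poisson with mean equal to the intensity integral and
positions follow the normalised intensity; positions are drawn by
inverse-transform sampling of the cumulative intensity, which is exact
for piecewise-constant rates (no rejection loop is needed even under
50× hotspot multipliers). The default is `"gamma"`: a *stationary*
gamma-renewal process (shape ν = 5) on the cumulative-intensity scale,
mapped back through the inverse cumulative intensity. The first arrival
uses the equilibrium delay (uniform fraction of a length-biased
Gamma(ν+1, 1/ν) draw) so marginal rates still integrate to the
landscape. ν = 5 gives the strong positive interference typical of plant
meiosis — the same regime the Kosambi map function presumes — and
suppresses the tight double-COs that no 500-kb block rule could see.
The expected count is unchanged (≈1.2 per chromosome per gamete by
default); only the count variance shrinks. `obligate_co` redraws until
at least one CO appears, preserving the conditional landscape shape.

**Defaults as study conditions.** 829 progeny split as evenly as
possible over 49 families (45×17 + 4×16); a 1.2× male intensity
multiplier on every other chromosome; genotyping error 1% (substitution
to a uniformly random *different* dosage — the simplest model whose
detectable fraction can be enumerated exactly from the trio genotypes);
missingness 5%. The desk-scale genome used throughout the tests is two
5-Mb chromosomes with 2,000 markers each; the recovery benchmark uses
200 progeny, which makes each half-sib family (~29 offspring) far
smaller than the study-scale ~118 and is therefore the *harder* phasing
regime.

**Annotation tracks.** Gene/repeat counts per 10-kb unit window are
Poisson with mean `base·(1 + c·z)`, where z is the standardised window
CO intensity and c a per-feature coupling coefficient (defaults: genes
and simple repeats +0.6, Gypsy/Copia −0.6, GC −0.5, mirroring the
qualitative structure reported for poplar); GC is realised base-by-base.
A flat landscape has z ≡ 0, so correlate recovery tests use the
piecewise-random landscape (10 segments, ±60% variation). This
construction gives the correlate models a known ground truth, but its
features are conditionally independent given the landscape — real
genomes have feature–feature dependence (multicollinearity) far stronger
than the coupling induces, so coefficient *signs*, not magnitudes, are
the meaningful recovery target.

**Reproducibility.** All randomness descends from one master seed via
`SeedSequence` spawn keys per gamete/stream, so results are independent
of evaluation order and bit-identical across re-runs.

## Parentage and parental-genotype correction

Candidate (mother, father) pairs are scored by the fraction of
trio-complete markers without a Mendelian violation; ties break by
marker count, then lexicographic pair id. Parental calls are then
corrected per marker by maximising the joint likelihood of the pooled
half-sib progeny under Mendelian transmission with a symmetric
observation-error channel (observed = true w.p. 1−ε, else one of the
other two dosages w.p. ε/2 each; ε default 0.01). The other parent's
genotype is fixed when known and marginalised uniformly when missing
(or always, via a flag). An existing call is only overwritten when the
log-likelihood margin exceeds ln 10, and only with ≥ 50 informative
progeny (both configurable): with ~30-offspring families and 1% progeny
error, two erroneous observations can already produce a margin of ~8
nats, so the margin is a guard against flip-flopping, not a guarantee —
on error-free data correction provably changes nothing.

## Phasing

Both routes operate on the focal parent's transmitted-allele matrix
(deterministic allele subtraction; all-het trios, violations and missing
trios are NA; markers > 25% NA dropped).

1. *LD-sign chaining*: Pearson correlation of transmitted-allele
   indicators for each adjacent pair over jointly non-NA offspring;
   positive → coupling, negative → repulsion; chained from the first
   marker (haplotype A carries its ref allele by convention). Junctions
   with |r| < 0.3 or < 10 joint observations are flagged low-confidence
   (coupling is carried when r is undefined).
2. *Two-point linkage*: for pairs within a 30-marker band,
   rf̂ = min(d, n−d)/n under the better phase and the phase-known LOD;
   pairs with rf̂ ≤ 0.5 and LOD > 8 form a graph whose components are
   linkage groups; phase propagates breadth-first.

The consensus keeps agreeing junctions; conflicts defer to a method the
other flagged low-confidence, and otherwise to the higher within-method
confidence rank. A final refinement pass flips any junction at which
more than half of the gametes appear to switch haplotype: a real CO is
private to one gamete, so a majority switch can only be a phase error.
This matters in the small-family regime (a 14-offspring family can leave
junctions with *no* jointly informative offspring); at study-scale
family sizes it is a no-op.

## Crossover demarcation

Each gamete's labels are formed only at the markers informative for
*that* gamete — smoothing windows contain 20 informative markers, and CO
regions are bounded by markers at which the transmitted haplotype is
unequivocal. The two-pass majority smoothing (20-marker windows, step
10, run from both chromosome ends) resolves pass disagreements by a
centred 20-marker majority; a residual tie keeps the marker's own raw
label — a centred window ties exactly at a clean switch, where the raw
label is already correct; breaking such ties toward the left neighbour
would displace every boundary one marker rightward — and only then falls
back to the left neighbour. Maximal constant-label runs become blocks;
interior blocks spanning < 500 kb are absorbed (same-label flanks merge;
otherwise the longer flank takes the span), iterated smallest-first
until stable, which removes gene-conversion-like double switches at the
cost of genuinely clustered double-COs (visible as recall loss in
hotspot-injected simulations). Terminal blocks are exempt. Intervals are
half-open 0-based internally and converted at I/O.

## Maps

Adjacent-marker rf̂ is the switch frequency over pairwise-complete
gametes; rf̂ ≥ 0.5 is clamped to 0.499 with a warning rather than
dropped, preserving chromosome contiguity. Kosambi's
d = 25·ln((1+2r)/(1−2r)) converts to cM. The consensus map cuts each
gamete's blocks at CO-region midpoints so that every switch is visible
to the 10-kb pseudo-marker grid (leaving CO-gap windows NA would drop
switches from pairwise-complete estimates and collapse the map length
several-fold), then bins redundant pseudo-marker columns (NA matches
only NA) and pools all gametes.

## Sex-bias statistics

* Per-LG χ² with E = (C_f + C_m)/2, df 1, Bonferroni over LGs — valid
  because the factorial design supplies equal gamete numbers per sex.
* The Poisson mixed model (log link; sex, chromosome, sex×chromosome,
  standardised family size; family random intercept nested in sex) is
  fitted by variational Bayes. When the estimated random-intercept SD is
  < 0.1 the variance component is degenerate and the model is reduced to
  the fixed-effects Poisson GLM: the VB posterior SDs are otherwise too
  small for honest Wald intervals (measured ~70% coverage on
  truly-Poisson counts, vs ~95–100% after reduction), while genuinely
  overdispersed counts keep the mixed model.
* Scale selection uses a complex Morlet (ω₀ = 6) CWT of the male,
  female, and difference signals in 30-kb bins at dyadic scales 2–256
  bins, cone-of-influence excluded; the selected window is the dyadic
  scale in [16, 64] bins (480 kb–1.92 Mb) maximising the
  difference-signal variance fraction, 32 bins = 960 kb by default.
* Window tests: the exact conditional Poisson ratio test
  (X = C_f | n ~ Binomial(n, ½)) with the central two-sided mid-P
  (double the smaller mid-corrected tail, capped at 1), BH-adjusted.
  Windows flagged as putative centromere/telomere (total below the 20th
  percentile of the chromosome's window totals — the minimum-average
  rule is otherwise unquantified) or as IOD outliers (outside the global
  5th–95th percentiles of the unbiased variance/mean of the 14
  per-parent counts) are excluded before testing.
* Directional purity: at q ≤ 0.25 with 90% true nulls, BH itself admits
  ~22% false discoveries that split directions evenly, so the
  male-direction fraction of discoveries cannot exceed ~0.89 in
  expectation under a sparse weak alternative; measured ≈ 0.84 at a 1.3×
  effect on 65-count windows (mid-P is mildly anti-conservative).
  Tightening to q ≤ 0.05 raises the purity above 0.9. With the
  alternative on half the chromosomes the purity exceeds 0.9 at
  q ≤ 0.25, which is what the end-to-end check asserts.

## Hotspots

30-kb windows, CO assigned by region midpoint (a region spanning windows
counts once). Filters: structural-exclusion BED; mean informative-marker
count within 60 kb of each border < 2 (alternate rule: ≥ 1 CO but
adjacent-window mean marker count < 1); IOD outside the global 10th–90th
percentile band (alternate: top-90th only). λ defaults to the mean count
per *retained* window per scope; Bonferroni m is the retained count,
never the pre-filter count. Adjacent significant windows share a cluster
id. By construction λ_female + λ_male = λ_combined on the same retained
window set.

## Correlates

Features are assigned to windows by interval midpoint (half-open: a
boundary midpoint goes right), GC over non-N bases. Genotype r² is the
squared Pearson correlation of dosages over pairwise-complete samples;
window means use left-anchored pairs ≤ 10 kb apart. CO-count models are
OLS on centred/scaled covariates — model 1 with simple repeats and sex,
model 2 without — scored by 5-fold cross-validation repeated 10 times
with a fixed seed; backward AIC elimination is available but the two
named models are first-class. Enrichment contrasts use the two-tailed
Wilcoxon rank-sum (exact by enumeration for n ≤ 20 without ties, else
normal approximation with tie and continuity corrections; W is reported
in the rank-sum-minus-offset convention).

## Problem sizes and what the tests show

The test suite and `scripts/acceptance.py` run at desk scale: two 5-Mb
chromosomes, 2,000 markers each, 200 progeny for the recovery benchmark
and 829 for the injection benchmark; calibration suites run on
count-level simulations (200 replicates) rather than full crosses, since
the statistics consume count tables. Passing these suites shows the
chain of estimators is correct and calibrated under the generator's
assumptions — Mendelian transmission, independent genotyping errors,
piecewise-constant landscapes. They do not certify behaviour under
segregation distortion, reference mis-ordering or mis-assembly,
structural variation, or coverage-dependent genotyping error, all of
which are outside the generator (reference marker order is trusted
throughout, and ordering algorithms are deliberately out of scope).

## Known limitations

* CO regions, not points: resolution is bounded by informative-marker
  spacing (median span ≈ the local informative gap).
* The 500-kb minimum block removes genuine double-COs closer than
  500 kb; under strong hotspots this attenuates counts (and any sex
  difference) in exactly the windows of interest.
* The mid-P test is mildly anti-conservative by design; FWER/FDR
  calibration is asserted empirically in the acceptance suite.
* The consensus map pools gametes directly; no segment-wise map merging
  is attempted.
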