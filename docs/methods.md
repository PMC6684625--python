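# Methods

## The problem

Long-range linkage disequilibrium (LRLD) — non-random association between
alleles at loci at least 5 Mb apart on the same chromosome — can arise from
genetic drift, gene–gene interactions, population substructure, or simply from
sampling noise when minor allele frequencies are small relative to the sample.
`lrldscan` implements the full analysis chain for studying it: the two-locus
testing theory that says when LRLD is detectable at all, a chromosome-wide scan
over phased multi-population panels, annotation and structural-variant overlap
statistics for the hits, and a case-control simulator quantifying how LRLD
partners corrupt odds-ratio-based disease-variant identification.

## Two-locus model (`ld`)

For a variant pair with designated major alleles A and B, sample haplotype
frequencies give

    D = p_AB − p_A p_B,
    X² = 2n D² / (p_A(1−p_A) p_B(1−p_B)),

with `n` the number of diploid individuals (2n phased haplotypes).  X² equals
`2n r²` exactly, where `r` is the Pearson correlation of the two allele
indicator vectors, and equals the generic Pearson chi-square of the 2×2
haplotype table; both identities are asserted in the tests.  D′ divides D by
its maximum attainable magnitude given the margins (`min(p_A(1−p_B), (1−p_A)p_B)`
for D > 0, `min(p_A p_B, (1−p_A)(1−p_B))` for D < 0), and is defined as 0 at
D = 0.  The exact alternative is the one-tailed Fisher test: the hypergeometric
tail over tables at least as extreme toward the observed sign of D with margins
fixed.  The tail direction is decided from integer counts
(`n_AB·2n − n_A·n_B`), not from the floating-point D, so exactly balanced
tables deterministically take the `greater` tail.

The major–major haplotype frequency is confined to
`[1 − p_a − p_b, 1 − max(p_a, p_b)]` (p_a, p_b minor allele frequencies) with
the equilibrium point `(1−p_a)(1−p_b)` sitting asymmetrically inside the
interval.  The closer the equilibrium sits to a boundary — i.e. the rarer the
alleles — the more often small samples land on high-|D′| tables by chance;
this is why the scan restricts itself to common variants.

Haplotypes are read directly from phase (`|` separator).  There is no EM
reconstruction from unphased genotypes: records with unphased or missing calls
are rejected and counted.  Monomorphic margins are a precondition violation in
`estimate_ld`, not a silent zero — the scan filters them beforehand.

## Detection theory (`theory`)

`detection_profile(n, p_a, p_b, alpha)` fixes integer allele counts
`round(2n·p)` and walks every admissible major–major haplotype count,
evaluating both tests.  Both are compared *one-tailed at level α* in the
direction of the implied disequilibrium: Fisher natively, the chi-square via
its signed root (one-sided p = upper-tail(X²)/2).  This is the design choice
behind the reported ordering — the exact test's discreteness makes it declare
equilibrium over at least as wide a range of haplotype frequencies as the
chi-square at every sample size; under a two-sided chi-square reading the
ordering breaks at n = 500, so the one-tailed reading is used for the profile.
The genome scan (below) is a different setting and keeps the standard
two-sided 1-df chi-square p-value.

Map functions convert physical distance to recombination fraction assuming a
uniform 1.15 cM/Mb: Haldane `r = (1−e^(−2d))/2` (no interference) and Kosambi
`r = tanh(2d)/2` (with interference).  The 5 Mb scan threshold corresponds to
r = 0.0543 and 0.0572 respectively.

Pooling two subpopulations that are each at internal linkage equilibrium
creates disequilibrium `D = w(1−w)(p_A1−p_A2)(p_B1−p_B2)` (w the proportion of
subpopulation 2).  `substructure_significance_grid` evaluates both tests on
the *expected* haplotype table of the pooled population: the chi-square on the
unrounded expected frequencies, Fisher on nearest-integer-rounded cells (the
rounded table's margins define the test; the total may come out odd by ±1).
The default grid mode couples the loci ("both loci share the same frequency
within each subpopulation"), the worst case for spurious LD.

## Sampling simulation (`sampling`)

`simulate_detection_rate` draws 2n haplotypes multinomially at fixed true
haplotype frequencies, applies both tests at level α to each replicate and
reports rejection fractions with Monte-Carlo standard errors
`sqrt(rate(1−rate)/n_reps)`.  Replicates that come out monomorphic at either
locus (possible at small n) count as non-detections rather than being redrawn;
redrawing would bias rates upward.  Default 10,000 replicates.  All tests are
evaluated vectorized (hypergeometric tails for Fisher), so 10,000 replicates
run in well under a second.

## Genome scan (`scan`)

Input is one phased panel per population over a shared variant universe.
Variants enter only if their analysis-allele frequency lies in [0.1, 0.9] in
*every* population (equivalently MAF ≥ 0.1; the conservative common-variant
cutoff that suppresses chance LRLD).  All intra-chromosomal pairs at distance
≥ 5 Mb (inclusive threshold) are tested per population with the two-locus
chi-square.  P-values are adjusted by Benjamini–Hochberg per chromosome per
population by default (`fdr_scope="genome_wide"` pools chromosomes within a
population), and records with q < 0.05 are reported with D, D′, X², p and q.

Pair statistics are computed from a single co-occurrence matrix product
`MᵀM/2n` of the major-coded haplotype matrix, so a chromosome with a few
hundred filtered variants scans in well under a second.  The `workers` setting
only partitions the pair list into contiguous chunks; results are concatenated
and canonically sorted (population, chromosome, pos_a, pos_b), so output is
bitwise independent of the worker count — asserted by a test.

Downstream helpers: `apply_centromere_filter` flags records with either
position inside the closed interval centromere ± 5 Mb (reduced meiotic
recombination there inflates LD and dominates cross-population intersections);
`population_intersections` counts pairs significant in each population subset,
with and without centromere-flagged records; `expected_intersections` computes
the independence expectation per chromosome, `E[X∩Y] = n_X n_Y / N` and
`E[all] = Πn / N^(k−1)` with N the chromosome's tested-pair count;
`find_hotspots` lists variants participating in ≥ `min_pairs` significant
pairs per population (default 2, the weakest reading of "hotspot").

## Annotation statistics (`annotation`)

Positions classify into ten mutually exclusive codes: 1 CDS, 2 5′UTR, 3 3′UTR,
4 noncoding gene, 5 intron, 6/7 within 1 kb upstream/downstream of a gene,
8/9 within 5 kb upstream/downstream, 10 remaining nongenic.  Where features
overlap the lowest code wins (CDS strongest), making classification a total,
order-independent function.  Upstream/downstream windows respect strand when
the annotation provides it and fall back to genome orientation otherwise.
`region_proportions` reports per-class code proportions (rows sum to 1);
`sv_overlap` reports counts and percentages of variants inside
deletion/inversion intervals and on insertion positions, plus per-SV tallies
with length statistics.  Structural variants are recognized in VCF input by
identifiers beginning `esv` (with SVTYPE/END) or supplied as a typed BED.

## Disease model (`disease`)

A sufficient-cause model with two disjoint causes: a purely environmental one
of population frequency E = 0.03, and a gene–environment interaction whose
environmental component has frequency E_G = 0.05 and requires carrying the
interacting allele (dominant: ≥ 1 copy).  Penetrances add:
P(case|carrier) = E + E_G, P(case|non-carrier) = E, lifetime incidence
K = E + c·E_G at carrier frequency c (so K = 0.08 at c = 1).  Case and control
genotype frequencies follow by Bayes' rule and the disease variant's dominant
odds ratio converges to (E+E_G)(1−E)/(E(1−E−E_G)) ≈ 2.812 regardless of
allele frequency.  The additive (disjoint-cause) penetrance is used rather
than the complementary-risk form 1−(1−E)(1−E_G); only the additive form gives
incidence exactly 0.08 at full carrier frequency.

`simulate_case_control` resamples panel individuals with replacement, draws
case status per individual from its carrier state at the designated disease
variant, fills the case and control pools (controls are drawn from the
unaffected, the standard case-control design) and computes a dominant odds
ratio for every variant in the configured regions (default ± 10 kb around the
disease variant; region windows are overridable, e.g. ± 30 kb).  Any zero cell
gets the Haldane–Anscombe +0.5 correction.  `detection_error_rate` replicates
the study and calls a replicate an error when any other variant's OR is at
least the disease variant's — the true variant must be *strictly* top-ranked,
so an exact-LD partner forces an error every time.  Defaults are 1,000 cases,
1,000 controls and 1,000 replicates, all configurable; the convergence test
uses 2,000 per arm because at 1,000 the finite-sample upward bias of the odds
ratio is comparable to the Monte-Carlo error of the mean.

## Synthetic panels (`synth`)

The generator reproduces the study conditions downstream code expects without
any external data: three populations ("AFR", "EUR", "EAS") of 500 diploids,
300 common variants on a 200 Mb chromosome, allele frequencies uniform in
[0.1, 0.9] with per-population Gaussian divergence (sd 0.05, clipped to the
band — the order of the observed mean continental subpopulation frequency
differences), block-like local LD, and plantable long-range pairs.

Local LD uses a block-mosaic: within each `block_length` (default 100 kb)
window, a haplotype either copies one of 16 founder haplotypes (probability
`within_block_dprime`, default 0.8) or draws its alleles independently.  This
gives block-structured correlation without a coalescent dependency; variants
in different blocks are independent in expectation.  `within_block_dprime`
controls the *strength* of block LD monotonically but is not a calibrated D′
value; the contract tested is independence at 0 and strong LD near 1.  After
the draw each column is repaired to exactly `round(2n p)` analysis-allele
copies, so realized frequencies respect the configured band to 1/(2n).

Planting rewrites exactly two columns: the anchor column is set to its target
frequency (once, so several plants may share a hotspot anchor), and the
partner is resampled conditional on the anchor to hit
`p_ab = p_a p_b + D′·min(p_a(1−p_b), (1−p_a)p_b)`.  Unachievable targets fail
loudly naming the violated bound; populations not named keep both columns
untouched.  Admixed panels draw two within-equilibrium subpopulations at the
requested mixing ratio, so their expected pooled D equals the closed form
above; the non-equilibrium variant is deliberately unsupported.

Annotation tracks place non-overlapping gene models in disjoint slots
(~80% coding with UTR/CDS/intron structure), one centromere per chromosome
(3 Mb at the midpoint), and SV intervals with lengths uniform in 310–60,000 bp
— the observed length range of common structural variants.  Everything flows
from a single integer seed per call and is byte-reproducible.

What the generator does *not* emulate: realistic demography (bottlenecks,
growth), recombination-rate variation, allele-frequency spectra, X/Y
chromosomes, or genuine biological LRLD mechanisms.  Passing tests therefore
demonstrate that the statistics behave as designed under known signal and
null conditions — not that real panels contain any particular amount of LRLD.

## Problem sizes and numerical choices

Tests and the acceptance script use 500 diploids × 300 variants per
population (≈ 43,000 long-range pairs per chromosome per population), 10,000
simulation replicates, 20 null-scan seeds, and 50,000 cases/controls for the
odds-ratio convergence check; each stage runs in seconds.  Significance uses
p ≤ α for the level-α tests and q < α for FDR discovery ("FDR less than
0.05").  The distance threshold and the centromere pad are closed (boundary
points count).  BED input (0-based half-open) converts to the internal
1-based closed convention at the boundary; multi-allelic sites are recoded to
the alternate allele with the largest pooled minor allele frequency before
analysis, keeping all other alleles as the reference class so no samples are
dropped.

## Known limitations

* Composite genotypic disequilibrium and multi-allelic LD are out of scope;
  only the dominant disease model is implemented (recessive/additive behave
  similarly in this model family).
* FDR scope (per chromosome vs genome-wide) is a configuration choice; the
  default is per chromosome per population.
* The scan holds each chromosome's filtered variant set in memory; it targets
  desk-scale panels and fixtures, not biobank matrices.
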