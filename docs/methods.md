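# Methods

This note records the models, parameter choices and numerical conventions
behind `mirnet`, and what the synthetic benchmarks do and do not establish
about behaviour on real data.

## Duplex alignment and the six screening rules

A target site is scored by pairing the miRNA 5′→3′ against a transcript
window read 3′→5′. Pair states are Watson–Crick (A:U, G:C), G:U wobble,
mismatch, or gap; the alignment score is `#MM + 0.5·#GU + #GAP`. Windows of
the miRNA length ±1 are scanned at step 1 (`max_gaps = 1`; `max_gaps = 0`
gives a pure ungapped scan). The length difference fixes the gap side — a
longer window bulges one transcript base, a shorter one leaves a miRNA
position unpaired — and among placements the one maximizing the
Watson–Crick count wins, ties going to the leftmost gap in duplex order.

Positions are 1-based from the miRNA 5′ end. A transcript bulge falls
*between* miRNA positions and is assigned the half-integer coordinate in
between, so a bulge inside the 2–12 or 10–11 span is caught by the span
rules; gaps count as mismatches in all positional rules and as 1.0 toward
the score. The "adjacent mismatches ≤ 2" rule is read as: the number of
adjacent-mismatch *pairs* over the whole duplex is at most 2 (a run of
three consecutive mismatches contains two such pairs). This coexists with
the separate rule banning any adjacent mismatch inside positions 2–12; the
two are applied as independent conjunctive filters.

**Energy model.** The ≥ 74% minimum-free-energy criterion needs duplex
energies, and no folding engine is part of the screening rules; a
stacking-free per-pair model is used: G:C = −3, A:U = −2, G:U = −1,
MM/GAP = 0 (arbitrary units). The criterion is a *ratio* to the
perfect-complement duplex of the same miRNA, which makes it dimensionless
and largely insensitive to affine rescaling of the pair energies; the 74%
threshold is applied to that ratio. This keeps criterion 1 deterministic
and unit-testable.

Overlapping passing windows of one (miRNA, transcript) pair collapse to the
best-scoring window (ties: lowest score, then smallest start, then smallest
end). The scanner is vectorized over windows but is required — by test — to
agree exactly with a plain brute-force enumeration of every window and gap
placement.

## Degradome validation

Tag 5′-end counts are accumulated per transcript position; the expected
cleavage position of a predicted site is the transcript base paired with
miRNA position 10. The site count `s` is classified against the transcript
profile: category 4 if `s = 1`; else 0 if `s` equals a unique maximum, 1 if
the maximum is shared, 2 if `s` is above the median of *non-zero* positions,
3 otherwise; zero counts give no call. The median is taken over non-zero
positions only because degradome profiles are sparse — a position-wide
median would almost always be 0 and category 3 could never occur. The keep
rule is category ≤ 2 plus score ≤ 4 plus intact 10–11 pairing; the category
threshold is configurable because published validated-target tables
sometimes list category-3/4 sites alongside a stated 0–2 rule — the stricter
text rule is the default and the tension is simply surfaced here. A ±1-nt
cleavage-position tolerance exists but is off by default.

## Differential screen

Counts are normalized by median-of-ratios size factors (column totals,
scaled to geometric mean 1, when no entity is positive everywhere). The
log2 fold change uses pseudocount 0.5 on group means. Per-entity
method-of-moments NB dispersions (`(var − mean)/mean²`, floored at 1e-4)
are noisy at three replicates, so they are shrunk toward the across-entity
median with `prior_df = 4` pseudo-replicates — the empirical-Bayes device
of limma/DESeq — and the Wald statistic is referred to a Student t with
`n_a + n_b − 2 + prior_df` degrees of freedom. Under a null NB simulation
(2000 genes, 3 vs 3, dispersion 0.05) the screen's size is ≈ 0.03–0.05 at
α = 0.05; a plain normal reference was anti-conservative (≈ 0.11–0.12) and
an unmoderated t(4) was calibrated but materially underpowered for 4–8-fold
planted effects. Gene calls use strict `|log2FC| > 1.5` with adjusted
P < 0.05; miRNA calls use `|log2FC| ≥ 1` with FDR < 0.05, as is conventional
for these data.

## Co-expression pipeline

The expression filter (value ≥ 2 in ≥ 70% of samples, SD > 0.25) is applied
on the FPKM/TPM scale; correlations are then computed on `log2(x + 1)`
(variance stabilization — raw-scale Pearson correlations of lognormal-like
expression under-state the latent co-regulation and drag down eigengene
fidelity). The network is unsigned (`|r|^β`); a signed option exists.
Average-linkage clustering of `1 − TOM` is cut at a static height (default
0.99) — a deterministic stand-in for dynamic tree cutting, with the module
size rule (≥ 50) and eigengene-merging step (≥ 0.8) retained.

Two membership refinements follow the cut, both standard ideas from the
dynamic-tree-cut family: (i) a kME screen — members correlating < 0.7 with
their module eigengene move to the unassigned pool, and modules falling
below the minimum size dissolve (0.7 is approximately the p ≈ 0.01 null
quantile of a correlation at 12 samples, so unstructured genes that the
static cut happens to agglomerate do not survive as fake modules); (ii) a
reassignment pass — every entity joins the module whose core eigengene it
matches best, if that kME reaches the same threshold. Eigengenes are the
first principal component of the standardized member profiles, unit
variance, oriented so the mean member correlation is non-negative. Module
labels come from a fixed color palette ordered by decreasing size; hub
selection takes the `ceil(0.001 · size)` top-kME members (always ≥ 1, ties
lexicographic).

## Enrichment, phenology

Enrichment uses the upper-tail hypergeometric probability
`P = 1 − Σ_{i<m} C(M,i)·C(N−M,n−i)/C(N,n)` with Benjamini–Hochberg control
across tested terms; terms with zero candidate overlap are excluded from
testing (they are untestable and would only dilute the correction), the
background defaults to the annotation universe, and no ontology-graph
propagation is applied — annotations are flat sets. The FDR cut is ≤ 0.05.

Chilling hours count hourly readings with `0 < T ≤ 7.2 °C` — exclusive at
zero so frozen hours do not accumulate chill; both bounds are arguments.
Missing hours are skipped and reported, never interpolated. Endodormancy
release is the earliest survey date with bud break rate ≥ 50%. The qPCR
utility is the plain `2^−ΔΔCt` ratio without efficiency correction.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a four-stage × three-replicate
bud break study. Module genes share a latent per-sample factor on the log2
scale (`√ρ·f + √(1−ρ)·ε`, pairwise correlation ρ, default 0.8); the latent
factors are orthogonalized in-sample because planted modules are independent
by construction and, at a dozen samples, raw Gaussian factors correlate
enough by chance to blur the planted blocks. The trait equals the trait
module's factor plus noise at 10% of its SD. Counts are negative-binomial
(default dispersion 0.05 — a conventional bulk-RNA-seq value, not
study-derived, as are the 8–12 M library sizes) around means derived from
latent FPKM, gene length and library size; the emitted FPKM is recomputed
from the realized counts with the *true* lengths and library sizes.
Normalizing by realized totals instead would couple every gene to the
planted modules compositionally (150 of 600 genes swinging two-fold moves
the total), an artifact that a realistic 20k-gene transcriptome barely
shows. Planted DE genes (default 50, log2FC 2 between the first two stages)
are drawn from the module-free pool; planted DE miRNAs default to log2FC 3,
reflecting the large stage swings typical of miRNAs, among 150 miRNAs
(roughly the number of known miRNAs such studies profile — also enough for
median-of-ratios normalization to be robust to the planted fraction).

Planted duplex sites embed the reverse complement of a miRNA in a uniform
random background and then impose an exact mismatch/wobble pattern; the
truth table's compliance flags are computed by *literal* application of the
six rules to the pattern, independent of the scanner, so they serve as an
oracle. The violator benchmark cycles six single-criterion violation
patterns (with miRNA base composition constrained so exactly the intended
criterion fails) and is evaluated with an ungapped scan: truth labels are
defined on the planted register, and a one-bulge realignment can otherwise
legitimately rescue a violator into a different, passing duplex — gapped
scanning is validated separately against the brute-force oracle. Degradome
simulation puts a configurable peak at each compliant site's cleavage
position over per-position Poisson noise.

Benchmark conditions are fixed once: module recovery uses 600 genes /
3 × 150-gene modules / 150 noise genes / 12 samples / ρ = 0.8 with no DE
planting (planted DE genes share a stage profile and legitimately form
their own module, which is a different question from module recovery). Hub
recovery uses ρ = 0.4, a loading-1.0 well-expressed hub per module,
dispersion 0.01 and six replicates per stage: identifying the single
top-loading member among 150 by sample kME is statistically marginal at
12 samples for *any* method (the sample eigengene itself tilts toward
chance directions), so the property is tested where it is well-posed.

Passing these benchmarks shows the machinery is correct under its own
model: independent block-structured modules, exact planted duplex patterns,
clean degradome peaks, NB counts. Real data add batch effects, correlated
modules, isoform ambiguity, adapter artifacts and compositional
normalization issues that the generator deliberately omits; results on real
studies depend on those, and the thresholds above, not on the code paths
validated here.

## Orchestration

The `mirnet` CLI and `mirnet.pipeline` chain the stages in study order
(simulate → quantify → DE → predict → degradome-validate → co-expression →
enrichment → network), each stage writing to its own subdirectory. All
paper-convention thresholds live in one named profile (`pmume2022`) so every
number is auditable in one place; the manifest records the configuration
hash, seed, and SHA-256 of every output, and re-running with the same seed
reproduces identical checksums. The acceptance script scales every
simulation to desk size (200 oracle pairs, 100 planted sites, 600-gene
networks, 1000-replicate nulls) — sizes chosen so the whole run completes
in minutes on one CPU while keeping each estimate's Monte-Carlo error well
inside the margins being asserted.

## Known limitations

- The energy model is deliberately minimal; sites judged by true folding
  energies (e.g. RNAduplex) can differ near the 74% boundary.
- Static-height tree cutting plus kME refinement approximates, but is not,
  the Dynamic Hybrid algorithm; very close or nested modules may split
  differently.
- The DE screen is a screening tool with conventional thresholds, not a
  reimplementation of any specific DE engine; absolute DEG counts are not
  comparable across engines.
- GO annotations are taken as flat sets; no parent-term propagation.
- Network assembly treats co-expression edges as undirected context around
  validated miRNA → TF edges; no TF → downstream direction is inferred.
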