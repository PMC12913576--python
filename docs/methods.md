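# Methods

This note records the models, conventions and numerical choices behind
`plastcub`, and what the synthetic-data generator does and does not emulate.

## Coding-sequence quality control

All codon statistics operate on spliced, strand-corrected coding sequences
extracted from annotated genomes. A CDS is retained only if its length is
divisible by three and it contains no internal stop codon; translation uses
NCBI table 11 (bacterial/plant plastid), which assigns the same amino acids
as the standard code for all sense codons, so the choice is a naming
convention rather than a numerical one. Terminal stop codons are stripped
before any statistic; a CDS annotated without one is kept (plastid
annotations frequently omit it) with a logged note. Codons containing
ambiguous bases are dropped from all counts, and a CDS with more than 5% of
such codons is discarded outright.

Genes duplicated by the inverted repeat are extracted twice; per-genome
statistics deduplicate by (gene name, identical nucleotide sequence) so IR
genes are not double-weighted in RSCU/ENC. Whether to count IR duplicates
once or twice is genuinely open in the comparative literature; deduplication
was chosen because it keeps per-genome gene counts in the range typical of
slipper-orchid plastomes and treats the IR as one evolutionary unit.
Coordinates are 0-based half-open internally; GenBank's 1-based closed
convention exists only at the I/O boundary.

## Codon-usage statistics

**RSCU.** For codon *c* in a synonymous family *F*,
RSCU(c) = count(c)·|F| / Σ_F counts. Families with zero total are reported
missing rather than zero; the single-codon families (Met, Trp) are carried
as 1 when present for display parity with standard RSCU heatmaps.

**ENC.** Wright's effective number of codons is computed from
class-averaged family homozygosities,
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, over the degeneracy classes of
table 11 (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold families; Met
and Trp contribute the constant 2). Per-family homozygosity is Σp² without
the finite-sample correction and (nΣp² − 1)/(n − 1) with it (the default);
corrected families need n ≥ 2 and are excluded when the corrected value is
non-positive. An empty three-fold class is imputed as F̄₃ ≈ (F̄₂ + F̄₄)/2
(Wright's recommendation, matching common codonW behaviour); any other empty
class rescales the result from the available classes. Estimates are capped
to [20, 61] because the corrected estimator can exceed 61 on small uniform
samples; the cap keeps the interpretive range meaningful.

**Expected ENC.** The compositional expectation is evaluated exactly as
ENC\* = 2 + s + 29/(s² + (1 − s)²) with s = GC3s (G+C at third positions of
degenerate families, Met/Trp/stops excluded). Genes below the curve indicate
selection on synonymous codon choice beyond compositional pressure; the
module reports per-gene deviation and the fraction of genes below the curve.

**PR2.** Parity-rule-2 coordinates are computed over the eight codon blocks
whose third position is fully degenerate (Ala, Arg CGN, Gly, Leu CTN, Pro,
Ser TCN, Thr, Val): A₃/(A₃+T₃) and G₃/(G₃+C₃). This is the standard Sueoka
formulation; restricting to fourfold sites removes amino-acid composition
from the comparison. Coordinates with empty denominators are missing.

**GC12** is the arithmetic mean of GC1 and GC2, not the GC over pooled
positions 1+2; the two differ only when codon counts differ between
positions, which cannot happen here, so the choice is cosmetic.

## Neutrality analysis

The neutrality plot regresses per-gene GC12 on GC3 by ordinary least
squares. Under mutation-driven evolution all positions feel the same
compositional pressure and the slope approaches 1; under selection GC12 is
pinned by the encoded protein while GC3 floats, and the slope approaches 0.
The slope × 100 is reported as the percent contribution of mutational
pressure (selection = 100 − value). This equation of slope with a variance
share is an interpretive convention of the field, not a formal variance
decomposition, and the package reproduces the interpretation as such. OLS
(not total least squares) is used because the slope/R² semantics reported in
comparative plastome studies are OLS semantics. Fits require at least three
genes with defined coordinates; a constant response yields slope 0 with
R² = 0.

## Ka/Ks (Nei–Gojobori 1986)

Site counting: each codon position contributes a synonymous-site fraction
(synonymous single-nucleotide changes / allowed single-nucleotide changes),
where changes creating stop codons are excluded from numerator and
denominator alike, and the nonsynonymous fraction is the complement — so
S + N = 3 × codons exactly. Sites are averaged over the two sequences of a
pair.

Difference counting: codons differing at k positions are scored by the
unweighted mean of synonymous/nonsynonymous step counts over the k!
substitution orderings, discarding orderings that pass through a stop codon;
a codon pair whose orderings are all blocked is skipped and logged. These
conventions match the original counting method and the NG mode of the
commonly used calculators.

Rates are Jukes–Cantor corrected, d = −¾·ln(1 − 4p/3). A proportion p ≥ 3/4
is reported as saturated: the rate is missing and the pair retained with a
flag. The ratio is missing when Ks = 0. Category thresholds: strong
purifying < 0.5, relaxed purifying 0.5–1 (both boundaries inclusive),
positive > 1; missing ratios are "undefined". Ratios above 10 are treated as
outliers and excluded from all aggregates. Orthologs are aligned codon-aware
with a simple Needleman–Wunsch on the translated proteins (match/mismatch/gap
= 1/−1/−2) back-translated to codons; for the near-identical orthologs this
pipeline targets, alignment choice is not load-bearing.

## SSR scanning

Only perfect tandem repeats are reported, unit lengths 1–10 bp with minimum
copy numbers 10 (mono), 6 (di), 5 (tri–penta) and 3 (hexa–deca). Every
reported locus is maximal (not extendable by a full unit either way),
primitive (its motif is not a tandem of a shorter unit), and exact (the span
is a verbatim tandem, never containing N). Reports contained within a longer
report of the same run (phase shifts, non-primitive multiples) are
suppressed, so each repeat region is reported once. Motifs are orientation-
and phase-sensitive (AT ≠ TA, no reverse-complement canonicalization), which
matches how cross-species motif presence/absence panels are usually drawn.
Compartment classification (CDS exon / intron / intergenic) uses the locus
midpoint; loci crossing a boundary keep the midpoint call and are flagged.
tRNA/rRNA exon positions fall into the intergenic class under the strict
trichotomy. Circular genomes are scanned with a 1 kb wrapped extension and
deduplicated so origin-crossing runs are found. Unit lengths 7–10 exceed the
classical MISA range but are first-class here; compound (interrupted) SSRs
are out of scope.

## Quadripartite structure

The inverted repeats are located as the maximal pair of disjoint, exactly
reverse-complementary repeats (≥ `min_ir`, default 1000 bp) on the circle,
found by 25-mer seed-and-extend between the doubled sequence and its reverse
complement — linear-time and sufficient for the near-identical IRs of real
plastomes; mismatch tolerance is a possible future extension. The longer
single-copy gap is labelled LSC; IRb is the copy immediately downstream of
the LSC, making the junction labels (JLB, JSB, JSA, JLA) deterministic.
Equal-length candidate pairs are broken by leftmost start. Genomes without a
qualifying repeat return a logged "no-IR" structure with the whole circle as
LSC. Detected structures always satisfy |LSC| + |SSC| + 2·|IR| = genome
length and IRa = revcomp(IRb); note that published region lengths for real
accessions do not always sum to the published genome length, so the tiling
invariant is enforced on computed structures only.

Genome descriptors: size, GC, AT skew (A−T)/(A+T), GC skew, gene density
(unique gene names per kb), coding ratio (union of CDS exons over genome
length), tRNA feature count, IR length, and GC1/2/3 over the concatenated
deduplicated CDS set. A lineage's evolutionary rate (root-to-tip branch
length sums) requires a phylogeny and is accepted as an externally supplied
number, never computed here.

Gene-order comparison is annotation-based synteny on shared single-copy
gene names: the fraction of adjacent pairs preserved strand-aware, and all
maximal reversed blocks (contiguous runs appearing contiguously in the other
genome in reversed order with every strand flipped), detected by a linear
scan of the signed permutation and verified in tests against brute-force
block enumeration.

## Statistical kernel

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(k − 1 df) even at small group sizes — adequate for the 6–30-member groups
the pipeline compares; an exact permutation KW is not implemented. Dunn's
post-hoc compares mean ranks with tie-corrected pooled variance and
Bonferroni over the k(k−1)/2 pairs. The Wilcoxon rank-sum test uses exact
enumeration for small tie-free samples (both n < 8) and the
continuity-and-tie-corrected normal approximation otherwise. Cohen's d uses
the (n−1)-weighted pooled SD. Pearson matrices use pairwise-complete
observations (≥ 3) with two-tailed t tests. All p-values are two-sided;
degenerate inputs (constant data, zero variance) return H = 0/p = 1 or
missing values rather than raising. Null calibration of each test is part of
the acceptance suite (rejection rate at α = 0.05 within [0.04, 0.06] over
4,000 seeded replicates).

## Synthetic data: what it emulates, and what it does not

All generators draw from numpy's PCG64 with `SeedSequence([seed, stream])`
substreams (one fixed stream constant per component), so identical `SimSpec`
inputs are byte-identical across runs and platforms.

**Usage regimes** (default 80 genes × 300 codons, GC pressure
θ ~ Uniform(0.2, 0.8) — gene counts typical of a plastome and a pressure
range wide enough to identify the regression). *Mutation*: every base drawn
with P(G/C) = θ_g, stop codons rejection-sampled away, so GC12 ≈ GC3 ≈ θ_g
and the expected neutrality slope is ≈ 1 (attenuated a few percent by
binomial noise in GC3 — visible in the worked example). *Selection*: one
fixed random amino-acid sequence reused by every gene, each amino acid
encoded through its largest synonymous block sharing a two-base prefix, so
GC12 is pinned exactly while third positions are drawn with P(G/C) = θ_g;
expected slope ≈ 0.

**Divergence.** `evolve` applies uniform single-nucleotide proposals until
`round(divergence × length)` acceptances: stop-creating proposals always
rejected, synonymous always accepted, nonsynonymous accepted with
probability ω — so the NG86 ratio of the pair estimates ω, and ω = 1 is
neutral. Proposals are uncapped in rate, so multiple hits at one site occur
and are what the Jukes–Cantor correction absorbs. When aggregating replicate
simulations the package reports the pooled ratio (mean Ka over mean Ks): the
per-replicate ratio Ka/Ks has a small-sample upward bias of a few percent
(Jensen's inequality on the noisy Ks denominator, CV² ≈ 1/Sd) that the
ratio-of-means avoids.

**Plastomes.** `make_plastome` assembles LSC + IRb + SSC from screened
random background (GC 0.35, the AT-rich composition typical of these
genomes) with genes laid head-to-tail in the LSC, an optional two-exon gene
(intron), an optional gene planted across JLB or JSB, and planted SSRs per
compartment; IRa is the exact reverse complement of IRb, computed after all
edits. Default region lengths are proportioned like a reference
slipper-orchid plastome (expanded IR, strongly contracted SSC); desk-scale
tests pass smaller values explicitly. Screening uses an independent
regex-based tandem-run scanner (deliberately separate from the package's own
SSR detector, so recovery tests are not circular) to remove accidental
qualifying runs; the four bases flanking the IR copies are set so the
planted repeat pair cannot be extended; and a k-mer check rejects assemblies
with any accidental reverse-complement repeat at anchor resolution,
regenerating deterministically from a derived seed. Planted SSR flanks are
chosen to break periodicity, making planted loci maximal exactly as planted.
A CDS-planted motif whose tandem encodes a stop in reading frame leaves that
gene QC-filtered downstream; tests use frame-safe motifs.

What the generator does **not** emulate: phylogenetic structure (no trees,
no shared ancestry between genomes), among-site rate variation, indels,
transition/transversion bias, IR mismatches, gene content variation,
pseudogenes, and base composition heterogeneity along the genome. Passing
recovery tests therefore demonstrates correctness of the algorithms under
their stated assumptions (exact IRs, perfect SSRs, independent genes), not
robustness to every idiosyncrasy of real accessions.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen to exercise every code
path with comfortable statistical power: 80 × 300-codon gene sets over 20
seeds for regime discrimination, 500-codon × 50-replicate divergence
simulations, 1,000 SSR syntheses, 100 structure syntheses at
5 kb / 2 kb / 1 kb region lengths, and 4,000-replicate null calibrations.

## Known limitations

- IR detection is exact-match only; a genome whose IRs differ by even one
  substitution will be reported with the longest exact sub-repeat.
- Origin-spanning genes are handled for extraction (split exons) but the
  junction report treats a feature's span as its min–max extent, which
  overstates spans for genes split across the sequence origin.
- The ENC empty-class rescaling (for classes other than the three-fold one)
  maps uniform usage to 61 but maps extreme bias to slightly above 20.
- `rscu_group_test` applies Bonferroni across codons; the comparative
  literature usually reports uncorrected per-codon tests, so both raw and
  adjusted p-values are returned.
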