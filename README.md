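# plastcub

Codon-usage bias and structural analysis of plastid (chloroplast) genomes,
for researchers in comparative organellar genomics and molecular evolution.

Chloroplast genomes are compact, largely single-copy circles with a
conserved quadripartite architecture (large single-copy region, two inverted
repeats, small single-copy region). Their protein-coding genes show strongly
non-random synonymous codon usage, shaped by some mixture of mutational
pressure (which acts on all codon positions alike) and natural selection
(which constrains codon choice for translational efficiency while leaving
third positions otherwise free). `plastcub` implements the standard toolkit
for asking *which force dominates* and *how the genome's architecture
varies*:

- **Codon-usage metrics** — codon counts; relative synonymous codon usage
  (RSCU = observed count / mean count of the synonymous family); positional
  GC content (GC1, GC2, GC3, GC12 = (GC1+GC2)/2, and GC3s over synonymous
  third positions); Wright's effective number of codons
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, spanning 20 (one codon per amino
  acid) to 61 (uniform usage); and parity-rule-2 coordinates
  A₃/(A₃+T₃) vs G₃/(G₃+C₃) at fourfold-degenerate third positions.
- **Mutation-vs-selection partitioning** — the neutrality plot (per-gene
  OLS of GC12 on GC3: slope ≈ 1 reads as mutation-driven, ≈ 0 as
  selection-dominated, slope × 100 as the percent contribution of mutational
  pressure) and deviation from the expected-ENC curve
  `ENC* = 2 + GC3s + 29/[GC3s² + (1−GC3s)²]`.
- **Ka/Ks selection analysis** — the Nei–Gojobori (1986) counting method
  with Jukes–Cantor correction: synonymous/nonsynonymous site fractions per
  codon (stop-creating changes excluded), pathway-averaged difference
  counts, and classification into strong purifying (Ka/Ks < 0.5), relaxed
  purifying (0.5–1) and positive (> 1) selection, with functional-category
  aggregation (Wilcoxon rank-sum, Cohen's d, one-sample *t* vs 1,
  Bonferroni; ratios > 10 excluded as outliers).
- **Perfect microsatellite (SSR) profiling** — maximal, primitive tandem
  repeats of unit length 1–10 bp at the thresholds mono ≥ 10, di ≥ 6,
  tri–penta ≥ 5, hexa–deca ≥ 3 copies, classified by compartment
  (CDS / intron / intergenic) and summarized as cross-species
  presence/absence matrices.
- **Quadripartite structure** — exact inverted-repeat detection by
  seed-and-extend, junction reporting (JLB, JSB, JSA, JLA), genome
  descriptors (size, GC, skews, gene density, coding ratio, tRNA count, IR
  length) and annotation-based gene-order comparison (conserved adjacencies,
  reversed blocks).
- **Group statistics** — Kruskal–Wallis with Dunn's post-hoc,
  Pearson correlation matrices with two-tailed *t* tests.
- **Synthetic data** — a fully deterministic generator of quadripartite
  plastomes, codon-usage regimes (mutation-driven vs selection-dominated),
  neutral/purifying sequence divergence and planted SSRs, each with complete
  machine-readable ground truth. All simulation-based tests run against it.

## Worked example

```python
from plastcub import (SimSpec, make_plastome, simulate_usage_regime, evolve,
                      detect_quadripartite, usage_profile,
                      neutrality_regression, mutation_contribution, ng86_pair)
from plastcub.ssr_scan import scan_plastome
from plastcub.codon_metrics import positional_gc

# a synthetic quadripartite genome with two planted intergenic SSRs
spec = SimSpec(seed=11, n_genes=6, codons_per_gene=120,
               region_lengths=(12000, 3000, 1500),
               ssr_plan=(("AT", 6, "IGS"), ("A", 10, "IGS")))
genome, truth = make_plastome(spec)
s = detect_quadripartite(genome.sequence, min_ir=1000)
print(f"genome {genome.length} bp | LSC {s.lsc[1]} | IR {s.ir_length} | SSC {s.ssc[1]}")
print("junctions:", s.junctions)

# neutrality analysis under the two simulated regimes
for regime in ("mutation", "selection"):
    genes, _ = simulate_usage_regime(SimSpec(seed=1, regime=regime))
    fit = neutrality_regression([(positional_gc(g)[2], positional_gc(g)[3]) for g in genes])
    print(f"{regime:9s} regime: slope {fit.slope:.4f} (R^2 {fit.r_squared:.4f}) "
          f"-> mutation {mutation_contribution(fit):.1f}%")

# per-gene usage profile and a purifying-selection Ka/Ks estimate
genes, _ = simulate_usage_regime(SimSpec(seed=1, regime="selection"))
p = usage_profile(genes[0], corrected_enc=False)
print(f"gene001: ENC {p.enc:.2f}, GC3s {p.gc3s:.3f}, PR2 ({p.pr2_at:.3f}, {p.pr2_gc:.3f})")
derived = evolve(genes[0], divergence=0.05, omega=0.3, seed=4)
r = ng86_pair(genes[0], derived)
print(f"Ka/Ks: Ka {r.ka:.4f}, Ks {r.ks:.4f}, ratio {r.ratio:.3f} -> {r.category}")

print("SSRs:", [(l.motif, l.copies, l.compartment) for l in scan_plastome(genome)])
```

prints

```
genome 19500 bp | LSC 12000 | IR 3000 | SSC 1500
junctions: {'JLB': 12000, 'JSB': 15000, 'JSA': 16500, 'JLA': 0}
mutation  regime: slope 0.9579 (R^2 0.9492) -> mutation 95.8%
selection regime: slope 0.0000 (R^2 0.0000) -> mutation 0.0%
gene001: ENC 47.11, GC3s 0.416, PR2 (0.543, 0.471)
Ka/Ks: Ka 0.0361, Ks 0.0889, ratio 0.406 -> strong_purifying
SSRs: [('AT', 6, 'IGS'), ('A', 10, 'IGS')]
```

Reading the output: the detector recovered the planted region lengths
exactly, and the four junction coordinates follow the canonical
LSC→IRb→SSC→IRa order. Under the mutation-driven regime the per-gene GC12
tracks GC3 almost one-to-one (slope ≈ 0.96 — the residual shortfall is
binomial sampling noise in GC3 attenuating the regression), while under the
selection regime the protein sequence pins GC12 and the slope collapses to
0. The evolved gene pair, simulated with a nonsynonymous acceptance
probability of 0.3, is correctly recovered as strongly purifying
(Ka/Ks ≈ 0.4 at this short divergence). Both planted SSRs are found with
their exact spans and intergenic location.

A `plastcub` console script exposes the same operations on files
(`extract-cds`, `structure`, `rscu`, `enc`, `neutrality`, `pr2`, `ssr`,
`kaks`, `compare-groups`, `simulate`, `run-all`); see `plastcub --help`.

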