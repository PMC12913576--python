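"""Quadripartite detection, junction reporting, descriptors and synteny."""

import itertools

import numpy as np
import pytest

from plastcub.genetic_code import revcomp
from plastcub.genome_structure import (
    compare_gene_order,
    detect_quadripartite,
    genes_by_region,
    genome_stats,
    junction_report,
    reassemble,
)
from plastcub.plastome_io import GeneFeature, Plastome
from plastcub.synthetic_data import SimSpec, make_plastome


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def build_genome(seed=0, lsc=5000, ir=2000, ssc=1000):
    rng = np.random.default_rng(seed)
    lsc_s, irb_s, ssc_s = random_seq(rng, lsc), random_seq(rng, ir), random_seq(rng, ssc)
    return lsc_s + irb_s + ssc_s + revcomp(irb_s), (lsc, ir, ssc)


class TestDetect:
    def test_constructed_genome_recovered(self):
        # hand-constructed LSC + IRb + SSC + revcomp(IRb); flanks may extend
        # the repeat by chance, so compare against the planted lengths
        p, truth = make_plastome(SimSpec(seed=5, n_genes=1, codons_per_gene=30,
                                         region_lengths=(5000, 2000, 1000)))
        s = detect_quadripartite(p.sequence, min_ir=1000)
        assert s == truth.structure
        assert s.ir_length == 2000
        assert s.junctions == {"JLB": 5000, "JSB": 7000, "JSA": 8000, "JLA": 0}

    def test_rotation_invariance_of_region_lengths(self):
        p, truth = make_plastome(SimSpec(seed=6, n_genes=1, codons_per_gene=30,
                                         region_lengths=(5000, 2000, 1000)))
        seq = p.sequence
        rotated = seq[1234:] + seq[:1234]
        s = detect_quadripartite(rotated, min_ir=1000)
        assert (s.lsc[1], s.irb[1], s.ssc[1], s.ira[1]) == (5000, 2000, 1000, 2000)

    def test_no_ir_genome(self):
        rng = np.random.default_rng(1)
        s = detect_quadripartite(random_seq(rng, 8000), min_ir=1000)
        assert not s.has_ir
        assert s.lsc == (0, 8000)
        assert s.ir_length == 0

    def test_tiling_and_revcomp_invariants(self):
        for seed in range(5):
            p, _ = make_plastome(SimSpec(seed=seed, n_genes=1, codons_per_gene=30,
                                         region_lengths=(4000, 1500, 900)))
            s = detect_quadripartite(p.sequence, min_ir=1000)
            assert s.lsc[1] + s.ssc[1] + 2 * s.ir_length == s.genome_length
            seq = p.sequence
            irb = seq[s.irb[0] : s.irb[0] + s.irb[1]]
            ira = seq[s.ira[0] : s.ira[0] + s.ira[1]]
            assert revcomp(ira) == irb

    def test_self_consistency_on_reassembled_sequence(self):
        p, _ = make_plastome(SimSpec(seed=8, n_genes=1, codons_per_gene=30,
                                     region_lengths=(4000, 1500, 900)))
        rotated = p.sequence[2222:] + p.sequence[:2222]
        s1 = detect_quadripartite(rotated, min_ir=1000)
        canonical = reassemble(rotated, s1)
        s2 = detect_quadripartite(canonical, min_ir=1000)
        assert s2.lsc == (0, s1.lsc[1])
        assert (s2.irb[1], s2.ssc[1]) == (s1.irb[1], s1.ssc[1])

    def test_region_of(self):
        p, truth = make_plastome(SimSpec(seed=5, n_genes=1, codons_per_gene=30,
                                         region_lengths=(5000, 2000, 1000)))
        s = truth.structure
        assert s.region_of(0) == "LSC"
        assert s.region_of(5000) == "IRB"
        assert s.region_of(7500) == "SSC"
        assert s.region_of(9999) == "IRA"


class TestJunctions:
    def _genome(self):
        return make_plastome(
            SimSpec(seed=11, n_genes=3, codons_per_gene=50,
                    region_lengths=(5000, 1500, 1200), junction_gene="JSB")
        )

    def test_gene_across_jsb_flagged_as_spanning(self):
        p, truth = self._genome()
        report = junction_report(truth.structure, p)
        jsb = next(j for j in report if j.junction == "JSB")
        assert jsb.spans
        assert jsb.distance == 0
        assert jsb.gene == "gene003"

    def test_gene_inside_region_not_flagged(self):
        p, truth = self._genome()
        regions = genes_by_region(truth.structure, p)
        assert "gene001" in regions["LSC"]
        assert "gene003" not in sum(regions.values(), [])  # spans, listed nowhere

    def test_empty_annotation(self):
        p, truth = self._genome()
        bare = Plastome(id="bare", sequence=p.sequence)
        report = junction_report(truth.structure, bare)
        assert all(j.gene is None for j in report)


class TestGenomeStats:
    def test_balanced_at_skew_zero(self):
        p = Plastome(id="x", sequence="AATT" * 250)
        st = genome_stats(p)
        assert st.at_skew == 0.0
        assert st.gc == 0.0

    def test_gene_density_arithmetic(self):
        feats = [
            GeneFeature(f"g{i}", "CDS", "+", ((i * 400, i * 400 + 90),))
            for i in range(20)
        ]
        p = Plastome(id="x", sequence="ACGT" * 2500, features=feats)  # 10 kb
        st = genome_stats(p)
        assert st.gene_density == pytest.approx(2.0)
        assert st.coding_ratio == pytest.approx(20 * 90 / 10000)

    def test_overlapping_cds_exons_merged(self):
        feats = [
            GeneFeature("a", "CDS", "+", ((100, 220),)),
            GeneFeature("b", "CDS", "+", ((160, 300),)),
        ]
        p = Plastome(id="x", sequence="ACGT" * 250, features=feats)
        assert genome_stats(p).coding_ratio == pytest.approx(200 / 1000)

    def test_no_cds_missing_positional_gc(self):
        p = Plastome(id="x", sequence="ACGT" * 250)
        st = genome_stats(p)
        assert st.coding_ratio == 0.0
        assert st.gc1 is None and st.gc3 is None

    def test_trna_count(self):
        feats = [GeneFeature(f"trn{i}", "tRNA", "+", ((i * 100, i * 100 + 70),))
                 for i in range(5)]
        p = Plastome(id="x", sequence="ACGT" * 250, features=feats)
        assert genome_stats(p).trna_count == 5


def _mk(order, length=3000):
    feats = []
    pos = 10
    for name, strand in order:
        feats.append(GeneFeature(name, "CDS", strand, ((pos, pos + 30),)))
        pos += 50
    return Plastome(id="x", sequence="A" * length, features=feats)


def brute_force_reversed_blocks(order_a, order_b):
    """Oracle: test every contiguous block of a for reversed+flipped
    contiguous appearance in b; keep the maximal ones."""
    pos_b = {g: i for i, (g, _) in enumerate(order_b)}
    strand_b = {g: s for g, s in order_b}
    hits = []
    n = len(order_a)
    for i in range(n):
        for j in range(i + 1, n):
            block = order_a[i : j + 1]
            positions = [pos_b[g] for g, _ in block]
            reversed_contig = positions == list(
                range(positions[0], positions[0] - len(block), -1)
            )
            flipped = all(strand_b[g] != s for g, s in block)
            if reversed_contig and flipped:
                hits.append((i, j))
    return [
        (order_a[i][0], order_a[j][0])
        for i, j in hits
        if not any((i2 <= i and j <= j2) and (i2, j2) != (i, j) for i2, j2 in hits)
    ]


class TestGeneOrder:
    def test_single_inversion(self):
        a = _mk([(g, "+") for g in "ABCDE"])
        b = _mk([("A", "+"), ("D", "-"), ("C", "-"), ("B", "-"), ("E", "+")])
        r = compare_gene_order(a, b)
        assert r.reversed_blocks == (("B", "D"),)
        assert r.adjacency_conservation == pytest.approx(0.5)

    def test_identical_genomes(self):
        a = _mk([(g, "+") for g in "ABCDEF"])
        r = compare_gene_order(a, a)
        assert r.adjacency_conservation == 1.0
        assert r.reversed_blocks == ()

    def test_disjoint_gene_sets_empty_report(self):
        a = _mk([(g, "+") for g in "ABC"])
        b = _mk([(g, "+") for g in "XYZ"])
        r = compare_gene_order(a, b)
        assert r.shared_genes == 0
        assert r.adjacency_conservation is None

    def test_agrees_with_brute_force_on_random_permutations(self):
        rng = np.random.default_rng(17)
        genes = list("ABCDEFGH")
        order_a = [(g, "+") for g in genes]
        a = _mk(order_a)
        for _ in range(40):
            perm = list(genes)
            rng.shuffle(perm)
            order_b = [(g, rng.choice(["+", "-"])) for g in perm]
            b = _mk(order_b)
            got = set(compare_gene_order(a, b).reversed_blocks)
            expected = set(brute_force_reversed_blocks(order_a, order_b))
            assert got == expected, (order_b, got, expected)
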