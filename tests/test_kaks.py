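"""NG86 site counting, pathway averaging, rate estimation and aggregation.

The test-side oracle re-derives site fractions and pathway averages from
scratch with Biopython's translation, independently of the implementation's
cached tables and recursion order.
"""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcub.genetic_code import SENSE_CODONS
from plastcub.kaks import (
    KaKsResult,
    OUTLIER_RATIO,
    aggregate_by_category,
    align_codons,
    categorize,
    category_contrasts,
    gene_pair_kaks,
    ng86_codon_differences,
    ng86_pair,
    ng86_sites,
    read_axt,
)
from plastcub.plastome_io import CodingSequence

AA = {c: str(Seq(c).translate(table=11)) for c in SENSE_CODONS}
STOPS = {"TAA", "TAG", "TGA"}


def oracle_sites(codon):
    s = 0.0
    for pos in range(3):
        syn = allowed = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                continue
            allowed += 1
            syn += AA[mut] == AA[codon]
        s += syn / allowed if allowed else 0.0
    return s, 3.0 - s


def oracle_differences(a, b):
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if AA[nxt] == AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


class TestSites:
    @pytest.mark.parametrize(
        "codon, s",
        [("TTT", 1 / 3), ("TTA", 2 / 3), ("ATG", 0.0)],
    )
    def test_hand_enumerated_examples(self, codon, s):
        sv, nv = ng86_sites(codon)
        assert sv == pytest.approx(s)
        assert sv + nv == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert ng86_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPathwayAveraging:
    def test_all_codon_pairs_match_brute_force(self):
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                got = ng86_codon_differences(a, b)
                expected = oracle_differences(a, b)
                if expected is None:
                    assert got is None, (a, b)
                else:
                    assert got == pytest.approx(expected), (a, b)

    def test_some_pair_exercises_blocked_pathways(self):
        """At least one sense-codon pair has a stop-blocked pathway, so the
        averaging really is over a strict subset of the k! orderings."""
        n_partial = 0
        for a, b in itertools.product(SENSE_CODONS, repeat=2):
            diffs = sum(x != y for x, y in zip(a, b))
            if diffs < 2:
                continue
            paths = oracle_differences(a, b)
            full = oracle_differences_count(a, b)
            if full < math.factorial(diffs):
                n_partial += 1
        assert n_partial > 0


def oracle_differences_count(a, b):
    diffs = [i for i in range(3) if a[i] != b[i]]
    n = 0
    for order in itertools.permutations(diffs):
        cur, ok = a, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            cur = nxt
        n += ok
    return n


class TestPairwise:
    def test_identical_sequences(self):
        a = CodingSequence("g", "ATGAAATTTGGG")
        r = ng86_pair(a, a)
        assert (r.Sd, r.Nd, r.ka, r.ks) == (0.0, 0.0, 0.0, 0.0)
        assert r.ratio is None
        assert r.category == "undefined"

    def test_single_codon_hand_example(self):
        r = ng86_pair(CodingSequence("g", "TTT"), CodingSequence("g", "TTA"))
        assert r.S == pytest.approx(0.5)
        assert r.N == pytest.approx(2.5)
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.pn == pytest.approx(0.4)
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert r.ks == 0.0
        assert r.ratio is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ng86_pair(CodingSequence("g", "ATGAAA"), CodingSequence("g", "ATG"))

    def test_gap_and_ambiguous_columns_excluded(self):
        a = CodingSequence("g", "ATG---AAANNN")
        b = CodingSequence("g", "ATGCCCAAATTT")
        r = ng86_pair(a, b)
        assert r.n_codons == 2  # only ATG and AAA columns comparable

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_symmetry_and_site_conservation(self, codons, rnd):
        a = CodingSequence("a", "".join(codons))
        shuffled = [rnd.choice(SENSE_CODONS) if rnd.random() < 0.3 else c for c in codons]
        b = CodingSequence("b", "".join(shuffled))
        r_ab, r_ba = ng86_pair(a, b), ng86_pair(b, a)
        assert r_ab.S + r_ab.N == pytest.approx(3 * r_ab.n_codons)
        for field in ("S", "N", "Sd", "Nd", "ka", "ks"):
            va, vb = getattr(r_ab, field), getattr(r_ba, field)
            if va is None:
                assert vb is None
            else:
                assert va == pytest.approx(vb)


class TestCategorize:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.113, "strong_purifying"),
            (0.4999, "strong_purifying"),
            (0.5, "relaxed_purifying"),
            (1.0, "relaxed_purifying"),
            (1.2, "positive"),
            (None, "undefined"),
        ],
    )
    def test_thresholds(self, ratio, expected):
        assert categorize(ratio) == expected


def _result(gene, ratio):
    return KaKsResult(gene, ("s1", "s2"), 100, 75, 225, 1, 1, 0.01, 0.004,
                      ks=0.01, ka=0.01 * ratio if ratio is not None else None,
                      ratio=ratio)


class TestAggregation:
    def test_mean_per_category(self):
        rows = [_result("rbcL", r) for r in (0.1, 0.2, 0.3)]
        df = aggregate_by_category(rows)
        rubisco = df[df.category == "Rubisco"].iloc[0]
        assert rubisco["mean_ratio"] == pytest.approx(0.2)
        assert rubisco["frac_strong"] == 1.0

    def test_outlier_excluded(self):
        rows = [_result("psbA", 0.2), _result("psbA", 12.0)]
        df = aggregate_by_category(rows)
        assert df[df.category == "photosystem II"].iloc[0]["n"] == 1
        assert OUTLIER_RATIO == 10.0

    def test_identical_categories_null_contrast(self):
        rows = [_result("psbA", r) for r in (0.1, 0.2, 0.3)] + [
            _result("rbcL", r) for r in (0.1, 0.2, 0.3)
        ]
        df = category_contrasts(rows)
        row = df.iloc[0]
        assert row["p_raw"] > 0.9
        assert row["cohens_d"] == pytest.approx(0.0)


class TestAlignment:
    def test_identical_alignment_passthrough(self):
        a = CodingSequence("g", "ATGAAATTTGGG")
        aa, bb = align_codons(a, a)
        assert aa.nt == bb.nt == a.nt

    def test_codon_deletion_gapped(self):
        a = CodingSequence("g", "ATGAAATTTGGGCCC")
        b = CodingSequence("g", "ATGAAAGGGCCC")  # TTT codon missing
        aa, bb = align_codons(a, b)
        assert len(aa.nt) == len(bb.nt) == 15
        assert bb.nt.count("-") == 3
        r = gene_pair_kaks(a, b)
        assert r.n_codons == 4
        assert r.Sd == r.Nd == 0.0


def test_read_axt(tmp_path):
    path = tmp_path / "pairs.axt"
    path.write_text("block1 1 9\nATGAAATTT\nATGAAATTA\n\nblock2 1 3\nGGG\nGGC\n")
    blocks = read_axt(path)
    assert [b[0] for b in blocks] == ["block1", "block2"]
    r = ng86_pair(blocks[0][1], blocks[0][2])
    assert r.n_codons == 3


class TestSimulationRecovery:
    def test_neutral_evolution_ratio_near_one(self):
        from plastcub.synthetic_data import SimSpec, evolve, simulate_usage_regime

        genes, _ = simulate_usage_regime(
            SimSpec(seed=7, n_genes=1, codons_per_gene=500, gc_pressure_range=(0.5, 0.5))
        )
        ratios = []
        for seed in range(5):
            derived = evolve(genes[0], divergence=0.1, omega=1.0, seed=seed)
            ratios.append(ng86_pair(genes[0], derived).ratio)
        assert 0.9 <= float(np.mean(ratios)) <= 1.1

    def test_purifying_evolution_recovers_omega(self):
        from plastcub.synthetic_data import SimSpec, evolve, simulate_usage_regime

        genes, _ = simulate_usage_regime(
            SimSpec(seed=9, n_genes=1, codons_per_gene=500, gc_pressure_range=(0.5, 0.5))
        )
        ratios = []
        for seed in range(5):
            derived = evolve(genes[0], divergence=0.08, omega=0.3, seed=seed)
            ratios.append(ng86_pair(genes[0], derived).ratio)
        assert abs(float(np.mean(ratios)) - 0.3) <= 0.1
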