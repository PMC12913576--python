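"""Quadripartite plastome structure, junction reports, genome descriptors
and gene-order comparison.

The canonical plastid genome is a circle tiled by four regions: the large
single-copy region (LSC), inverted repeat b (IRb), the small single-copy
region (SSC) and inverted repeat a (IRa), with IRa the exact reverse
complement of IRb.  The four junctions are named JLB (LSC/IRb), JSB
(IRb/SSC), JSA (SSC/IRa) and JLA (IRa/LSC).

Detection finds the maximal pair of disjoint, exactly reverse-complementary
repeats of at least ``min_ir`` bp on the circle, by seed-and-extend on
25-mer anchors between the doubled sequence and its reverse complement.
The longer single-copy gap is labelled LSC.  Genomes without a qualifying
repeat are returned as a "no-IR" structure covering the whole circle.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genetic_code import revcomp
from .plastome_io import GeneFeature, Plastome, dedupe_cds, extract_cds

log = logging.getLogger(__name__)

ANCHOR_K = 25


@dataclass(frozen=True)
class QuadripartiteStructure:
    """Region intervals on the circular genome, each as (start, length).

    ``start`` is a position in [0, genome_length); regions may wrap the
    origin.  ``has_ir`` is False for the degenerate no-IR result, where the
    whole genome is reported as LSC.
    """

    genome_length: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    has_ir: bool = True

    @property
    def ir_length(self) -> int:
        return self.irb[1]

    @property
    def junctions(self) -> dict[str, int]:
        """JLB, JSB, JSA, JLA positions (the start of the downstream region)."""
        L = self.genome_length
        return {
            "JLB": self.irb[0] % L,
            "JSB": self.ssc[0] % L,
            "JSA": self.ira[0] % L,
            "JLA": self.lsc[0] % L,
        }

    def region_of(self, pos: int) -> str:
        L = self.genome_length
        pos %= L
        for name in ("lsc", "irb", "ssc", "ira"):
            start, length = getattr(self, name)
            if (pos - start) % L < length:
                return name.upper() if name != "lsc" else "LSC"
        raise AssertionError("position outside the tiling")  # pragma: no cover


def _interval_slice(seq: str, start: int, length: int) -> str:
    L = len(seq)
    start %= L
    if start + length <= L:
        return seq[start : start + length]
    return seq[start:] + seq[: (start + length) % L]


def _max_rc_repeat_pair(
    seq: str, min_len: int, k: int = ANCHOR_K
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Largest pair of disjoint reverse-complementary repeats on the circle.

    Returns ((start_a, length), (start_b, length)) in circle coordinates or
    None.  Exact matches only; anchors are k-mers shared between the doubled
    sequence and the doubled reverse complement, merged along diagonals and
    verified by direct extension.
    """
    L = len(seq)
    if L <= k:
        return None
    S = seq + seq
    R = revcomp(seq)
    R2 = R + R

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L):  # starts in the first copy are enough: matches wrap
        index[S[i : i + k]].append(i)

    # group anchor hits by alignment diagonal (i - j)
    diagonals: dict[int, set[int]] = defaultdict(set)
    for j in range(L):
        for i in index.get(R2[j : j + k], ()):
            diagonals[i - j].add(i)

    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    seen: set[tuple[int, int, int]] = set()
    for diag, starts in diagonals.items():
        ordered = sorted(starts)
        run_start = ordered[0]
        prev = ordered[0]
        runs = []
        for i in ordered[1:]:
            if i > prev + k:  # gap too large: separate anchor run
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a0, a1 in runs:
            i, j = a0, a0 - diag
            # extend left/right by direct comparison (bounded by the doubling)
            left = 0
            while i - left - 1 >= 0 and j - left - 1 >= 0 and S[i - left - 1] == R2[j - left - 1]:
                left += 1
            m = a1 - a0 + k
            right = 0
            while (
                i + m + right < len(S)
                and j + m + right < len(R2)
                and S[i + m + right] == R2[j + m + right]
            ):
                right += 1
            start_i = i - left
            length = m + left + right
            if length < min_len:
                continue
            length = min(length, L)  # a repeat cannot exceed the circle
            a_start = start_i % L
            j_start = (a0 - diag - left) % L
            b_start = (L - j_start - length) % L
            key = tuple(sorted(((a_start, length), (b_start, length)))[0] + (length,))
            if key in seen:
                continue
            seen.add(key)
            # the two copies must be disjoint on the circle
            if _circular_overlap(a_start, b_start, length, L):
                continue
            if 2 * length > L:
                continue
            cand_key = (length, -min(a_start, b_start))
            if best is None or cand_key > (best[0], -min(best[1][0], best[2][0])):
                a, b = sorted([(a_start, length), (b_start, length)])
                best = (length, a, b)
    if best is None:
        return None
    return best[1], best[2]


def _circular_overlap(a_start: int, b_start: int, length: int, L: int) -> bool:
    gap_ab = (b_start - (a_start + length)) % L
    gap_ba = (a_start - (b_start + length)) % L
    return gap_ab + gap_ba + 2 * length != L or a_start == b_start


def detect_quadripartite(
    sequence: str, min_ir: int = 1000, k: int = ANCHOR_K
) -> QuadripartiteStructure:
    """Locate LSC / IRb / SSC / IRa on a circular genome.

    The maximal disjoint reverse-complementary repeat pair of length >=
    ``min_ir`` defines the IRs; the longer of the two single-copy gaps is
    the LSC.  IRb is the repeat copy immediately downstream of the LSC, so
    the canonical order LSC -> IRb -> SSC -> IRa holds going clockwise from
    the LSC start.  Without a qualifying repeat, a logged no-IR structure
    with the whole genome as LSC is returned.
    """
    seq = sequence.upper()
    L = len(seq)
    pair = _max_rc_repeat_pair(seq, min_ir, k=k) if L > 2 * min_ir else None
    if pair is None:
        log.info("no inverted repeat >= %d bp found (genome %d bp)", min_ir, L)
        return QuadripartiteStructure(
            genome_length=L,
            lsc=(0, L), irb=(0, 0), ssc=(0, 0), ira=(0, 0),
            has_ir=False,
        )
    (a_start, m), (b_start, _) = pair
    gap_ab = ((b_start - (a_start + m)) % L, (a_start + m) % L)  # (len, start)
    gap_ba = ((a_start - (b_start + m)) % L, (b_start + m) % L)
    (lsc_len, lsc_start), (ssc_len, ssc_start) = sorted(
        [gap_ab, gap_ba], reverse=True
    )
    # IRb = the IR copy that starts where the LSC ends
    irb_start = (lsc_start + lsc_len) % L
    ira_start = a_start if irb_start == b_start else b_start
    assert irb_start in (a_start, b_start)
    return QuadripartiteStructure(
        genome_length=L,
        lsc=(lsc_start, lsc_len),
        irb=(irb_start, m),
        ssc=(ssc_start, ssc_len),
        ira=(ira_start, m),
    )


def reassemble(seq: str, s: QuadripartiteStructure) -> str:
    """Rotate the genome to canonical orientation (LSC starting at 0)."""
    k = s.lsc[0] % len(seq)
    return seq[k:] + seq[:k]


# ---------------------------------------------------------------------------
# junction report

@dataclass(frozen=True)
class JunctionGene:
    junction: str
    position: int
    gene: str | None
    distance: int | None  # signed bp from gene start to the junction; 0 if spanning
    spans: bool


def junction_report(s: QuadripartiteStructure, p: Plastome) -> list[JunctionGene]:
    """Nearest/overlapping gene at each junction (JLB, JSB, JSA, JLA).

    ``spans`` marks genes whose span covers the junction point; otherwise
    ``distance`` is the signed circular distance from the junction to the
    nearest gene edge (positive downstream).  Empty annotation yields
    entries with no gene.
    """
    L = s.genome_length
    out = []
    for name, pos in s.junctions.items():
        # (abs distance, spans is preferred, gene name) -> pick the minimum
        best: tuple[int, int, str, int, bool] | None = None
        for f in p.features:
            lo, hi = f.span
            if lo <= pos < hi:
                cand = (0, 0, f.name, 0, True)
            else:
                d_down = (lo - pos) % L  # junction -> gene start, clockwise
                d_up = (pos - hi) % L + 1  # gene end -> junction
                d = d_down if d_down <= d_up else -d_up
                cand = (abs(d), 1, f.name, d, False)
            if best is None or cand[:3] < best[:3]:
                best = cand
        if best is None:
            out.append(JunctionGene(name, pos, None, None, False))
        else:
            out.append(JunctionGene(name, pos, best[2], best[3], best[4]))
    return out


def genes_by_region(s: QuadripartiteStructure, p: Plastome) -> dict[str, list[str]]:
    """Genes wholly inside each region (spanning genes excluded)."""
    out: dict[str, list[str]] = {"LSC": [], "IRB": [], "SSC": [], "IRA": []}
    for f in p.features:
        lo, hi = f.span
        regions = {s.region_of(lo), s.region_of(hi - 1)}
        if len(regions) == 1:
            out[regions.pop()].append(f.name)
    return out


# ---------------------------------------------------------------------------
# genome-level descriptors

@dataclass
class GenomeStats:
    size: int
    gc: float
    gc1: float | None
    gc2: float | None
    gc3: float | None
    at_skew: float
    gc_skew: float
    gene_density: float  # unique gene names per kb
    coding_ratio: float
    trna_count: int
    ir_length: int


def genome_stats(p: Plastome, s: QuadripartiteStructure | None = None) -> GenomeStats:
    """Descriptors used in multi-genus comparisons.

    GC1/2/3 are computed over the concatenated QC-passed CDS set
    (IR-duplicate gene copies deduplicated); coding_ratio merges overlapping
    CDS exons before measuring coverage; gene density counts unique gene
    names per kb.
    """
    from .codon_metrics import positional_gc

    seq = p.sequence
    n = {b: seq.count(b) for b in "ACGT"}
    at = n["A"] + n["T"]
    gc_n = n["G"] + n["C"]
    cds = dedupe_cds(extract_cds(p))
    gc1, gc2, gc3, _ = positional_gc(cds) if cds else (None, None, None, None)

    intervals = sorted(
        (start, end) for f in p.genes("CDS") for start, end in f.exons
    )
    covered = 0
    cur_s, cur_e = None, None
    for a, b in intervals:
        if cur_e is None or a > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = a, b
        else:
            cur_e = max(cur_e, b)
    if cur_e is not None:
        covered += cur_e - cur_s

    return GenomeStats(
        size=p.length,
        gc=gc_n / len(seq),
        gc1=gc1, gc2=gc2, gc3=gc3,
        at_skew=(n["A"] - n["T"]) / at if at else 0.0,
        gc_skew=(n["G"] - n["C"]) / gc_n if gc_n else 0.0,
        gene_density=len({f.name for f in p.features}) / (p.length / 1000.0),
        coding_ratio=covered / p.length,
        trna_count=sum(1 for f in p.features if f.kind == "tRNA"),
        ir_length=s.ir_length if s is not None and s.has_ir else 0,
    )


def stats_table(stats_by_id: dict[str, GenomeStats]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        [{"id": k, **vars(v)} for k, v in stats_by_id.items()]
    ).set_index("id")


# ---------------------------------------------------------------------------
# gene-order comparison (annotation-based synteny)

@dataclass(frozen=True)
class SyntenyReport:
    shared_genes: int
    adjacency_conservation: float | None
    reversed_blocks: tuple[tuple[str, str], ...]  # (first gene, last gene) in a's order


def _ordered_unique_genes(p: Plastome) -> list[tuple[str, str]]:
    """(name, strand) in genomic order, restricted to single-copy names."""
    from collections import Counter

    counts = Counter(f.name for f in p.features)
    feats = sorted(p.features, key=lambda f: f.span)
    return [(f.name, f.strand) for f in feats if counts[f.name] == 1]


def compare_gene_order(a: Plastome, b: Plastome) -> SyntenyReport:
    """Strand-aware gene-order comparison on shared single-copy genes.

    Reports the fraction of adjacent shared-gene pairs of ``a`` preserved
    in ``b`` (same order and strands, or reversed order with both strands
    flipped), and all maximal reversed blocks: contiguous runs of ``a``'s
    order that appear in ``b`` contiguously, in reversed order, with every
    strand flipped.  Fewer than two shared genes yields an empty report.
    """
    order_a = _ordered_unique_genes(a)
    order_b = _ordered_unique_genes(b)
    shared = {g for g, _ in order_a} & {g for g, _ in order_b}
    seq_a = [(g, st) for g, st in order_a if g in shared]
    seq_b = [(g, st) for g, st in order_b if g in shared]
    if len(shared) < 2:
        return SyntenyReport(len(shared), None, ())

    pos_b = {g: i for i, (g, _) in enumerate(seq_b)}
    strand_b = {g: st for g, st in seq_b}

    preserved = 0
    n_pairs = len(seq_a) - 1
    for (g1, s1), (g2, s2) in zip(seq_a, seq_a[1:]):
        i, j = pos_b[g1], pos_b[g2]
        same = j == i + 1 and strand_b[g1] == s1 and strand_b[g2] == s2
        flipped = i == j + 1 and strand_b[g1] != s1 and strand_b[g2] != s2
        preserved += same or flipped

    # signed positions of a's genes in b: sign flips when strand differs
    signed = []
    for g, st in seq_a:
        sign = 1 if strand_b[g] == st else -1
        signed.append(sign * (pos_b[g] + 1))  # 1-based to keep sign meaningful

    blocks: list[tuple[int, int]] = []
    i = 0
    while i < len(signed) - 1:
        # maximal run where consecutive entries are flipped and descending by 1
        j = i
        while (
            j + 1 < len(signed)
            and signed[j] < 0
            and signed[j + 1] < 0
            and signed[j + 1] == signed[j] + 1
        ):
            j += 1
        if j > i:
            blocks.append((i, j))
            i = j + 1
        else:
            i += 1
    names = tuple((seq_a[i][0], seq_a[j][0]) for i, j in blocks)
    return SyntenyReport(
        shared_genes=len(shared),
        adjacency_conservation=preserved / n_pairs if n_pairs else None,
        reversed_blocks=names,
    )
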