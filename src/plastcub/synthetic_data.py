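"""Synthetic plastomes and codon-evolution regimes with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_usage_regime` draws gene sets under the two hypotheses the
  neutrality analysis discriminates.  In the *mutation* regime a per-gene
  GC pressure theta ~ Uniform(gc_pressure_range) acts identically on all
  three codon positions (stop codons rejection-sampled away), so GC12 and
  GC3 both track theta and the expected neutrality slope is ~1.  In the
  *selection* regime one fixed amino-acid sequence is reused for every gene
  (each amino acid encoded by a fixed two-base prefix), pinning GC12, while
  synonymous third positions are drawn with per-gene G/C probability theta,
  so the expected slope is ~0.

* :func:`evolve` diverges a coding sequence under uniform single-nucleotide
  substitution with nonsynonymous acceptance probability ``omega``
  (synonymous proposals always accepted, stop-creating proposals always
  rejected), so the NG86 Ka/Ks of the pair estimates ``omega``.

* :func:`make_plastome` assembles a circular quadripartite genome
  (LSC + IRb + SSC + IRa, IRa the exact reverse complement of IRb) with
  annotated genes, optional introns and junction-spanning genes, and
  planted perfect SSRs.  Single-copy backgrounds are screened (with an
  independent regex scanner, not the package's own SSR detector) so that no
  unplanned qualifying SSR run and no unplanned reverse-complement repeat
  of anchor size exists; boundary bases are set so the planted IR pair
  cannot be extended.  Complete machine-readable ground truth is returned.

All randomness flows through numpy's PCG64 generator seeded from
``SeedSequence([seed, stream])`` with a fixed stream constant per
component, so identical SimSpec inputs give identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genetic_code import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    revcomp,
    translate,
)
from .genome_structure import ANCHOR_K, QuadripartiteStructure
from .plastome_io import CodingSequence, GeneFeature, Plastome
from .ssr_scan import DEFAULT_THRESHOLDS, SSRLocus

log = logging.getLogger(__name__)

_STREAM_USAGE = 1
_STREAM_EVOLVE = 2
_STREAM_PLASTOME = 3

_BASES = np.array(list("ACGT"))
_STOP_IDX = {48, 50, 56}  # TAA, TAG, TGA as 16*b1 + 4*b2 + b3 with A,C,G,T=0..3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one synthetic data set.

    Defaults mirror the study conditions the analyses assume: ~80 genes per
    genome, 300 codons per gene, GC pressure spanning 0.2-0.8, and region
    lengths proportioned like a Paphiopedilum reference plastome (expanded
    IRs, strongly contracted SSC).
    """

    seed: int = 0
    n_genes: int = 80
    codons_per_gene: int = 300
    regime: str = "mutation"  # mutation | selection
    gc_pressure_range: tuple[float, float] = (0.2, 0.8)
    omega: float = 1.0
    divergence: float = 0.1
    region_lengths: tuple[int, int, int] = (91_989, 33_436, 4_363)  # lsc, ir, ssc
    ssr_plan: tuple[tuple[str, int, str], ...] = ()  # (motif, copies, compartment)
    intron_gene: bool = False
    junction_gene: str | None = None  # "JLB" | "JSB": plant a gene across it

    def __post_init__(self):
        lo, hi = self.gc_pressure_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("gc_pressure_range must be within [0, 1]")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if any(x <= 0 for x in self.region_lengths):
            raise ValueError("region lengths must be positive")


# ---------------------------------------------------------------------------
# codon-usage regimes

def _random_codons_gc(rng: np.random.Generator, n_codons: int, theta: float) -> str:
    """n_codons random codons with per-base P(G or C) = theta; stops
    rejection-sampled away."""
    p = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
    idx = rng.choice(4, size=(n_codons, 3), p=p)
    code = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
    bad = np.isin(code, list(_STOP_IDX))
    while bad.any():
        idx[bad] = rng.choice(4, size=(int(bad.sum()), 3), p=p)
        code = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
        bad = np.isin(code, list(_STOP_IDX))
    return "".join(_BASES[idx].reshape(-1))


# per-amino-acid codon block with a fixed two-base prefix (the largest
# synonymous block sharing its first two bases), split by third-base G/C
_AA_PREFIX: dict[str, str] = {}
_AA_THIRDS_GC: dict[str, str] = {}
_AA_THIRDS_AT: dict[str, str] = {}
for _aa, _fam in SYNONYMOUS_FAMILIES.items():
    _by_prefix: dict[str, list[str]] = {}
    for _c in _fam:
        _by_prefix.setdefault(_c[:2], []).append(_c)
    _prefix = max(sorted(_by_prefix), key=lambda p: len(_by_prefix[p]))
    _AA_PREFIX[_aa] = _prefix
    _thirds = sorted(c[2] for c in _by_prefix[_prefix])
    _AA_THIRDS_GC[_aa] = "".join(b for b in _thirds if b in "GC")
    _AA_THIRDS_AT[_aa] = "".join(b for b in _thirds if b in "AT")

_AA_LIST = sorted(SYNONYMOUS_FAMILIES)


def simulate_usage_regime(spec: SimSpec) -> tuple[list[CodingSequence], np.ndarray]:
    """Gene set under the requested regime plus the true per-gene theta."""
    if spec.n_genes < 1:
        raise ValueError("empty gene set")
    if spec.regime not in ("mutation", "selection"):
        raise ValueError(f"unknown regime {spec.regime!r}")
    rng = _rng(spec.seed, _STREAM_USAGE)
    lo, hi = spec.gc_pressure_range
    thetas = rng.uniform(lo, hi, spec.n_genes)
    genes: list[CodingSequence] = []
    if spec.regime == "mutation":
        for g, theta in enumerate(thetas):
            nt = _random_codons_gc(rng, spec.codons_per_gene, float(theta))
            genes.append(CodingSequence(gene=f"gene{g + 1:03d}", nt=nt, species="sim"))
    else:
        protein = rng.choice(_AA_LIST, size=spec.codons_per_gene)
        for g, theta in enumerate(thetas):
            use_gc = rng.random(spec.codons_per_gene) < theta
            codons = []
            for aa, gc in zip(protein, use_gc):
                thirds = _AA_THIRDS_GC[aa] if gc else _AA_THIRDS_AT[aa]
                if not thirds:  # family has no third base on that side
                    thirds = _AA_THIRDS_AT[aa] or _AA_THIRDS_GC[aa]
                third = thirds[rng.integers(len(thirds))] if len(thirds) > 1 else thirds
                codons.append(_AA_PREFIX[aa] + third)
            genes.append(
                CodingSequence(gene=f"gene{g + 1:03d}", nt="".join(codons), species="sim")
            )
    return genes, thetas


# ---------------------------------------------------------------------------
# pairwise divergence

def evolve(
    cds: CodingSequence,
    divergence: float,
    omega: float = 1.0,
    seed: int = 0,
) -> CodingSequence:
    """Diverged copy of a coding sequence.

    Uniform random single-nucleotide proposals are applied until
    ``round(divergence * len(nt))`` substitutions have been accepted.
    Proposals creating a stop codon are always rejected; synonymous
    proposals always accepted; nonsynonymous proposals accepted with
    probability ``omega``.  The NG86 Ka/Ks of (original, evolved) therefore
    estimates omega.
    """
    rng = _rng(seed, _STREAM_EVOLVE)
    nt = list(cds.nt.upper())
    n_target = int(round(divergence * len(nt)))
    accepted = 0
    proposals = 0
    cap = 1000 * max(n_target, 1) + 10_000
    while accepted < n_target and proposals < cap:
        proposals += 1
        pos = int(rng.integers(len(nt)))
        old = nt[pos]
        new = "ACGT".replace(old, "")[int(rng.integers(3))]
        c0 = 3 * (pos // 3)
        codon = nt[c0 : c0 + 3]
        new_codon = "".join(codon[: pos - c0] + [new] + codon[pos - c0 + 1 :])
        if new_codon in STOP_CODONS:
            continue
        old_codon = "".join(codon)
        if CODON_TO_AA[new_codon] != CODON_TO_AA[old_codon] and rng.random() >= omega:
            continue
        nt[pos] = new
        accepted += 1
    if accepted < n_target:  # pragma: no cover - only with omega ~ 0
        log.warning("evolve: reached proposal cap at %d/%d substitutions", accepted, n_target)
    return CodingSequence(gene=cds.gene, nt="".join(nt), species=cds.species + "_derived")


# ---------------------------------------------------------------------------
# plastome assembly

# independent regex screen for qualifying SSR runs (kept separate from the
# package's own scanner so planted-SSR recovery tests are not circular)
_SSR_PATTERNS = {
    u: re.compile(r"(.{%d})\1{%d,}" % (u, c - 1))
    for u, c in DEFAULT_THRESHOLDS.items()
}


def qualifying_runs(seq: str) -> list[tuple[int, int]]:
    """Spans of tandem runs meeting the detection thresholds (regex-based)."""
    spans = []
    for pattern in _SSR_PATTERNS.values():
        spans.extend(m.span() for m in pattern.finditer(seq))
    return sorted(spans)


def _screened_background(rng: np.random.Generator, n: int, gc: float = 0.35) -> list[str]:
    """Random AT-rich background free of qualifying SSR runs."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list("".join(_BASES[rng.choice(4, size=n, p=p)]))
    for _ in range(50):
        runs = qualifying_runs("".join(seq))
        if not runs:
            return seq
        for a, b in runs:
            mid = (a + b) // 2
            current = seq[mid]
            seq[mid] = str(rng.choice([c for c in "ACGT" if c != current]))
    raise RuntimeError("could not screen background of qualifying SSR runs")


@dataclass
class PlastomeTruth:
    """Machine-readable ground truth accompanying a synthetic plastome."""

    structure: QuadripartiteStructure
    ssrs: list[SSRLocus] = field(default_factory=list)
    gene_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    thetas: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        s = self.structure
        return json.dumps(
            {
                "genome_length": s.genome_length,
                "regions": {k: list(getattr(s, k)) for k in ("lsc", "irb", "ssc", "ira")},
                "junctions": s.junctions,
                "ssrs": [
                    {"motif": l.motif, "copies": l.copies, "start": l.start,
                     "end": l.end, "compartment": l.compartment}
                    for l in self.ssrs
                ],
                "gene_spans": self.gene_spans,
                "thetas": self.thetas,
            },
            indent=1,
        )


def _breaking_base(
    arr: list[str], idx: int, avoid: set[str], gene_spans: dict[str, tuple[int, int]]
) -> str:
    """A base for position idx avoiding the given characters and avoiding
    the creation of a stop codon when idx falls inside an annotated gene."""
    for base in "ACGT":
        if base in avoid:
            continue
        for span in gene_spans.values():
            lo, hi = span
            if lo <= idx < hi:
                c0 = lo + 3 * ((idx - lo) // 3)
                codon = "".join(arr[c0 : c0 + 3])
                codon = codon[: idx - c0] + base + codon[idx - c0 + 1 :]
                if codon in STOP_CODONS:
                    break
        else:
            return base
    return next(b for b in "ACGT" if b not in avoid)  # pragma: no cover


def _plant_ssr(
    arr: list[str],
    pos: int,
    motif: str,
    copies: int,
    gene_spans: dict[str, tuple[int, int]],
) -> SSRLocus:
    """Write a perfect tandem at pos and break both flanks so the run is
    maximal exactly as planted."""
    run = motif * copies
    arr[pos : pos + len(run)] = list(run)
    if pos > 0:
        arr[pos - 1] = _breaking_base(arr, pos - 1, {motif[-1]}, gene_spans)
    end = pos + len(run)
    if end < len(arr):
        arr[end] = _breaking_base(arr, end, {motif[0]}, gene_spans)
    return SSRLocus(motif=motif, copies=copies, start=pos, end=end)


def make_plastome(spec: SimSpec) -> tuple[Plastome, PlastomeTruth]:
    """Assemble a synthetic quadripartite plastome with full ground truth.

    Genes from :func:`simulate_usage_regime` are laid head-to-tail in the
    LSC (the first becomes a two-exon gene when ``spec.intron_gene``); an
    extra gene is planted across the requested junction; SSRs from
    ``spec.ssr_plan`` are planted by compartment (IGS after the gene block,
    CDS inside the last gene, intron inside the intron).  A CDS-planted
    motif whose tandem encodes a stop in reading frame will leave that gene
    QC-filtered downstream; choose frame-safe motifs when that matters.

    Raises ValueError when the plan does not fit the region lengths.
    """
    lsc_len, ir_len, ssc_len = spec.region_lengths
    if ir_len < ANCHOR_K + 1:
        raise ValueError(f"IR length must exceed the anchor size ({ANCHOR_K})")
    rng = _rng(spec.seed, _STREAM_PLASTOME)

    genes, thetas = simulate_usage_regime(spec)
    junction_cds: CodingSequence | None = None
    if spec.junction_gene:
        if spec.junction_gene not in ("JLB", "JSB"):
            raise ValueError("junction_gene must be 'JLB' or 'JSB'")
        junction_cds = genes.pop()  # reserve the last simulated gene
        if not genes and spec.ssr_plan and any(c == "CDS" for _, _, c in spec.ssr_plan):
            raise ValueError("CDS SSR plan needs at least one LSC gene")

    lsc = _screened_background(rng, lsc_len)
    irb = _screened_background(rng, ir_len)
    ssc = _screened_background(rng, ssc_len)

    features: list[GeneFeature] = []
    gene_spans: dict[str, tuple[int, int]] = {}
    truth_thetas: dict[str, float] = {}

    # --- genes head-to-tail in the LSC ------------------------------------
    intron_len = 0
    if spec.ssr_plan and spec.intron_gene:
        longest_intron_ssr = max(
            (len(m) * c for m, c, comp in spec.ssr_plan if comp == "intron"), default=0
        )
        intron_len = max(120, longest_intron_ssr + 40)
    elif spec.intron_gene:
        intron_len = 120

    pos = 100
    intron_span: tuple[int, int] | None = None
    for i, g in enumerate(genes):
        stop = "TAA"
        body = g.nt + stop
        if i == 0 and spec.intron_gene:
            half = 3 * (len(body) // 6)
            exon1 = body[:half]
            exon2 = body[half:]
            intron = "".join(_screened_background(rng, intron_len))
            lsc[pos : pos + len(body) + intron_len] = list(exon1 + intron + exon2)
            exons = ((pos, pos + half), (pos + half + intron_len, pos + len(body) + intron_len))
            intron_span = (pos + half, pos + half + intron_len)
            features.append(GeneFeature(g.gene, "CDS", "+", exons))
            gene_spans[g.gene] = (pos, pos + len(body) + intron_len)
            pos += len(body) + intron_len + 60
        else:
            lsc[pos : pos + len(body)] = list(body)
            features.append(GeneFeature(g.gene, "CDS", "+", ((pos, pos + len(body)),)))
            gene_spans[g.gene] = (pos, pos + len(body))
            pos += len(body) + 60
        truth_thetas[g.gene] = float(thetas[i])
    igs_cursor = pos + 40
    if pos + 100 > lsc_len:
        raise ValueError("gene plan does not fit in the LSC")

    # --- assemble LSC + IRb + SSC; IRa appended after all edits ------------
    arr = lsc + irb + ssc
    jlb, jsb = lsc_len, lsc_len + ir_len
    jsa = lsc_len + ir_len + ssc_len

    if junction_cds is not None:
        body = junction_cds.nt + "TAA"
        junction_pos = jlb if spec.junction_gene == "JLB" else jsb
        start = junction_pos - min(30, len(body) - 3)
        end = start + len(body)
        if end > jsa - 2 or (spec.junction_gene == "JLB" and end > jsb - 2):
            raise ValueError("junction gene does not fit")
        arr[start:end] = list(body)
        features.append(GeneFeature(junction_cds.gene, "CDS", "+", ((start, end),)))
        gene_spans[junction_cds.gene] = (start, end)

    # --- planted SSRs ------------------------------------------------------
    planted: list[SSRLocus] = []
    for motif, copies, compartment in spec.ssr_plan:
        motif = motif.upper()
        run_len = len(motif) * copies
        if compartment == "IGS":
            if igs_cursor + run_len + 20 > lsc_len:
                raise ValueError(f"IGS SSR {motif}x{copies} does not fit in the LSC")
            locus = _plant_ssr(arr, igs_cursor, motif, copies, gene_spans)
            igs_cursor += run_len + 20
        elif compartment == "CDS":
            host = genes[-1].gene if genes else None
            if host is None:
                raise ValueError("CDS SSR plan needs an LSC gene")
            lo, hi = gene_spans[host]
            start = lo + 30 - (lo + 30 - lo) % 3  # codon-aligned offset
            if start + run_len + 4 > hi:
                raise ValueError(f"CDS SSR {motif}x{copies} does not fit in gene {host}")
            locus = _plant_ssr(arr, start, motif, copies, gene_spans)
        elif compartment == "intron":
            if intron_span is None:
                raise ValueError("intron SSR plan requires intron_gene=True")
            lo, hi = intron_span
            if lo + 10 + run_len + 2 > hi:
                raise ValueError(f"intron SSR {motif}x{copies} does not fit the intron")
            locus = _plant_ssr(arr, lo + 10, motif, copies, gene_spans)
        else:
            raise ValueError(f"unknown compartment {compartment!r}")
        planted.append(
            SSRLocus(motif=locus.motif, copies=locus.copies, start=locus.start,
                     end=locus.end, compartment=compartment)
        )

    # --- IRa, boundary-extension breaking, final screening ------------------
    comp = dict(zip("ACGT", "TGCA"))
    for _ in range(60):
        ira = list(revcomp("".join(arr[jlb:jsb])))
        full = arr + ira
        L = len(full)
        changed = False
        # planted IR pair must not be extendable into the single-copy regions
        if full[jlb - 1] == comp[full[0]]:
            full[jlb - 1] = _breaking_base(full, jlb - 1, {full[jlb - 1]}, gene_spans)
            changed = True
        if full[jsb] == comp[full[jsa - 1]]:
            full[jsb] = _breaking_base(full, jsb, {full[jsb]}, gene_spans)
            changed = True
        # no unplanned qualifying SSR run anywhere on the circle
        doubled = "".join(full) + "".join(full[: min(L, 200)])
        for a, b in qualifying_runs(doubled):
            if a >= L:  # duplicate view of a run already seen in the first copy
                continue
            if any(p.start - 1 <= a and b <= p.end + 1 for p in planted):
                continue
            mid = ((a + b) // 2) % L
            if mid >= jsa:  # inside IRa: patch the mirrored IRb base instead
                mid = jlb + (L - 1 - mid)
            full[mid] = _breaking_base(full, mid, {full[mid]}, gene_spans)
            changed = True
        if not changed:
            break
        arr = full[:jsa]  # keep edits; IRa is rebuilt from IRb next round
    else:  # pragma: no cover
        raise RuntimeError("could not stabilize synthetic plastome")

    sequence = "".join(full)
    if not _ir_pair_is_unique(sequence, jlb, jsb, jsa):
        bumped = int(spec.seed) * 1009 + 7919  # new attempt, still deterministic
        log.info("accidental repeat detected; regenerating with derived seed")
        return make_plastome(
            SimSpec(**{**spec.__dict__, "seed": bumped})
        )

    structure = QuadripartiteStructure(
        genome_length=len(sequence),
        lsc=(0, lsc_len),
        irb=(jlb, ir_len),
        ssc=(jsb, ssc_len),
        ira=(jsa, ir_len),
    )
    plastome = Plastome(
        id=f"SYN{spec.seed:06d}",
        sequence=sequence,
        features=sorted(features, key=lambda f: f.span),
        species=f"Synthetica plastoma {spec.seed}",
        genus="Synthetica",
    )
    truth = PlastomeTruth(
        structure=structure,
        ssrs=planted,
        gene_spans=gene_spans,
        thetas=truth_thetas,
    )
    return plastome, truth


def make_ssr_fixture(
    seed: int,
    copies_delta: int = 0,
    thresholds: dict[int, int] | None = None,
    gap: int = 25,
) -> tuple[str, list[SSRLocus]]:
    """A screened random sequence with one planted SSR per unit length 1-10.

    Each unit length u gets a random primitive motif planted at
    ``threshold[u] + copies_delta`` copies (``copies_delta=-1`` plants
    sub-threshold runs, and the returned locus list is then empty).  The
    assembled sequence is verified with the independent regex screen: every
    qualifying run is a planted span and nothing else qualifies.  Fully
    deterministic in the seed.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    rng = _rng(seed, _STREAM_PLASTOME + 1)
    for attempt in range(40):
        total = sum(u * (c + copies_delta) + gap for u, c in thresholds.items())
        arr = _screened_background(rng, 200 + total + 200)
        planted: list[SSRLocus] = []
        spans: list[tuple[int, int]] = []
        pos = 100
        for u in sorted(thresholds):
            copies = thresholds[u] + copies_delta
            while True:
                motif = "".join(_BASES[rng.integers(4, size=u)])
                from .ssr_scan import is_primitive

                if is_primitive(motif):
                    break
            locus = _plant_ssr(arr, pos, motif, copies, {})
            spans.append((locus.start, locus.end))
            if copies >= thresholds[u]:
                planted.append(locus)
            pos = locus.end + gap
        runs = qualifying_runs("".join(arr))
        expected = {(l.start, l.end) for l in planted}
        if {tuple(r) for r in runs} == expected or (
            not planted and not runs
        ):
            return "".join(arr), planted
    raise RuntimeError("could not assemble a clean SSR fixture")  # pragma: no cover


def _ir_pair_is_unique(seq: str, jlb: int, jsb: int, jsa: int, k: int = ANCHOR_K) -> bool:
    """True when every reverse-complement k-mer match on the circle maps one
    planted IR copy onto the other (no accidental inverted repeats)."""
    L = len(seq)
    doubled = seq + seq
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i : i + k], []).append(i)
    rc = revcomp(seq)
    rc2 = rc + rc

    def in_irb(x: int) -> bool:
        return jlb <= x and x + k <= jsb

    def in_ira(x: int) -> bool:
        return jsa <= x and x + k <= L

    for j in range(L):
        for i in index.get(rc2[j : j + k], ()):
            src = (L - j - k) % L
            if (in_irb(i) and in_ira(src)) or (in_ira(i) and in_irb(src)):
                continue
            return False
    return True


def write_fixture(
    plastome: Plastome, truth: PlastomeTruth, directory: str | Path
) -> dict[str, Path]:
    """Write GenBank + FASTA + JSON ground-truth sidecar for a synthesis."""
    from .plastome_io import write_genbank, write_genome_fasta

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": directory / f"{plastome.id}.gb",
        "fasta": directory / f"{plastome.id}.fasta",
        "truth": directory / f"{plastome.id}.truth.json",
    }
    write_genbank(plastome, paths["genbank"])
    write_genome_fasta(plastome, paths["fasta"])
    paths["truth"].write_text(truth.to_json())
    return paths
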