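"""Perfect microsatellite (SSR) detection and compartment classification.

Only perfect tandem repeats are reported, for unit lengths 1-10 bp with the
per-unit minimum copy numbers used throughout the analysis: mono >= 10,
di >= 6, tri- to penta- >= 5, hexa- to deca- >= 3.  Every reported locus is

* maximal: it cannot be extended by one full unit in either direction;
* primitive: the motif is not itself a tandem of a shorter unit (a run of
  ``ATATAT...`` is one di-SSR, never a tetra-SSR with unit ``ATAT``);
* exact: the spanned sequence is a verbatim tandem of the motif, never
  containing N.

Motifs are orientation- and phase-sensitive: AT and TA are distinct motifs,
and no reverse-complement canonicalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .plastome_io import Plastome

#: unit length -> minimum copy number for a reportable perfect SSR
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5,
                                      6: 3, 7: 3, 8: 3, 9: 3, 10: 3}

COMPARTMENT_CDS = "CDS"
COMPARTMENT_INTRON = "intron"
COMPARTMENT_IGS = "IGS"

CATEGORY_NAMES = {1: "MonoSSR", 2: "DiSSR", 3: "TriSSR", 4: "TetraSSR",
                  5: "PentaSSR", 6: "HexaSSR", 7: "HeptaSSR", 8: "OctaSSR",
                  9: "NonaSSR", 10: "DecaSSR"}


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    copies: int
    start: int
    end: int
    compartment: str | None = None
    spans_boundary: bool = False

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def category(self) -> str:
        return CATEGORY_NAMES[self.unit_len]


def is_primitive(motif: str) -> bool:
    """True when the motif is not a tandem repeat of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect SSRs of unit length 1-10 meeting the thresholds.

    A run qualifying under several unit lengths is reported once, with its
    primitive (shortest) unit; shorter reports fully contained in a longer
    report of the same run are suppressed.  Runs containing N are rejected.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = sequence.upper()
    L = len(seq)
    candidates: list[SSRLocus] = []
    for u, min_copies in sorted(thresholds.items()):
        if u < 1:
            raise ValueError(f"invalid unit length {u}")
        i = 0
        while i + u * min_copies <= L:
            motif = seq[i : i + u]
            if "N" in motif or not is_primitive(motif):
                i += 1
                continue
            # count full-unit copies to the right
            j = i + u
            while j + u <= L and seq[j : j + u] == motif:
                j += u
            copies = (j - i) // u
            if copies >= min_copies:
                candidates.append(SSRLocus(motif=motif, copies=copies, start=i, end=i + u * copies))
                i = i + u * copies - (u - 1)  # allow overlapping phases just past the run
            else:
                i += 1
    # suppress reports strictly contained in another report (same run seen
    # in a different phase or as a non-primitive multiple)
    out = []
    for c in candidates:
        contained = any(
            o is not c and o.start <= c.start and c.end <= o.end
            and (o.end - o.start) > (c.end - c.start)
            for o in candidates
        )
        if not contained:
            out.append(c)
    return sorted(set(out), key=lambda s: (s.start, s.unit_len))


def classify_compartment(loci: Sequence[SSRLocus], p: Plastome) -> list[SSRLocus]:
    """Assign each locus a genomic compartment by its midpoint.

    Midpoint inside a CDS exon -> CDS; inside an intron (between exons of an
    annotated gene, any kind) -> intron; everywhere else -> IGS.  A locus
    whose span crosses a compartment boundary keeps the midpoint call and is
    flagged ``spans_boundary``.
    """
    def compartment_of(pos: int) -> str:
        intron = False
        for f in p.features:
            in_exon = any(s <= pos < e for s, e in f.exons)
            if in_exon and f.kind == "CDS":
                return COMPARTMENT_CDS
            lo, hi = f.span
            if lo <= pos < hi and not in_exon:
                intron = True
        # tRNA/rRNA exon positions fall through to IGS: the compartment
        # scheme is a strict CDS / intron / intergenic trichotomy
        return COMPARTMENT_INTRON if intron else COMPARTMENT_IGS

    out = []
    for locus in loci:
        mid = (locus.start + locus.end) // 2
        comp = compartment_of(mid)
        spans = compartment_of(locus.start) != compartment_of(locus.end - 1)
        out.append(replace(locus, compartment=comp, spans_boundary=spans))
    return out


def scan_plastome(
    p: Plastome, thresholds: Mapping[int, int] | None = None
) -> list[SSRLocus]:
    """Scan a circular genome: origin-crossing runs are found by scanning
    the sequence extended with a 1 kb prefix copy and deduplicating."""
    pad = min(len(p.sequence), 1000)
    extended = p.sequence + p.sequence[:pad]
    loci = find_ssrs(extended, thresholds)
    L = len(p.sequence)
    seen = set()
    out = []
    for locus in loci:
        if locus.start >= L:  # fully inside the padded copy
            continue
        key = (locus.motif, locus.start % L, locus.copies)
        if key in seen:
            continue
        seen.add(key)
        out.append(locus)
    return classify_compartment(out, p)


def presence_absence_matrix(
    loci_by_species: Mapping[str, Iterable[SSRLocus]],
) -> "pandas.DataFrame":  # noqa: F821
    """Binary motif x species matrix (1 = motif present in that species).

    Motifs are orientation-sensitive; rows ordered by unit length then
    alphabetically.  Feeds Ward clustering of species SSR profiles.
    """
    import pandas as pd

    species = list(loci_by_species)
    motifs = sorted(
        {l.motif for loci in loci_by_species.values() for l in loci},
        key=lambda m: (len(m), m),
    )
    data = {
        sp: [int(any(l.motif == m for l in loci_by_species[sp])) for m in motifs]
        for sp in species
    }
    return pd.DataFrame(data, index=motifs, columns=species)


def motif_ubiquity(matrix: "pandas.DataFrame") -> "pandas.Series":  # noqa: F821
    """Percentage of species carrying each motif."""
    return matrix.mean(axis=1) * 100.0


def category_summary(loci: Iterable[SSRLocus]) -> "pandas.DataFrame":  # noqa: F821
    """Counts and percentages per SSR category (Mono ... Deca)."""
    import pandas as pd

    loci = list(loci)
    rows = []
    for u in range(1, 11):
        n = sum(1 for l in loci if l.unit_len == u)
        rows.append({"category": CATEGORY_NAMES[u], "unit_len": u, "count": n,
                     "percent": 100.0 * n / len(loci) if loci else 0.0})
    return pd.DataFrame(rows)
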