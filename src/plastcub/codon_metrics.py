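"""Codon-usage statistics: codon counts, RSCU, positional GC, GC3s, ENC, PR2.

All statistics operate on a :class:`CodonCountTable` built from one or more
coding sequences.  Stop codons (table 11) and codons containing ambiguous
bases are excluded from every count.

The effective number of codons (ENC, Wright's Nc) summarizes codon bias on
a scale from 20 (one codon per amino acid) to 61 (uniform synonymous
usage).  Nc is computed from class-averaged family homozygosities::

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where Fk is the mean homozygosity of the synonymous families with k codons
(9 two-fold, 1 three-fold, 5 four-fold and 3 six-fold families; Met and Trp
contribute the constant 2).  The expected ENC under compositional pressure
alone is ``2 + s + 29/(s^2 + (1-s)^2)`` with ``s`` the GC content at
synonymous third positions (GC3s).

PR2 (parity rule 2) coordinates are A3/(A3+T3) and G3/(G3+C3) over the
third positions of the eight four-fold degenerate codon blocks; under pure,
strand-symmetric mutation pressure both equal 0.5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .genetic_code import (
    DEGENERACY,
    FOURFOLD_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .plastome_io import CodingSequence

#: number of synonymous families per degeneracy class in table 11
_FAMILIES_PER_CLASS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCountTable:
    """Observed codon counts; stops and ambiguous codons never counted."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> list[int]:
        return [self.counts.get(c, 0) for c in SYNONYMOUS_FAMILIES[aa]]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(dict(merged))


def count_codons(
    cds: CodingSequence | str | Iterable[CodingSequence | str],
) -> CodonCountTable:
    """Frame-0 codon counts of one or several coding sequences.

    Accepts a :class:`CodingSequence`, a raw nucleotide string, or an
    iterable of either; counts are pooled additively.
    """
    if isinstance(cds, (CodingSequence, str)):
        cds = [cds]
    counts: Counter[str] = Counter()
    for item in cds:
        nt = item.nt if isinstance(item, CodingSequence) else str(item).upper()
        for i in range(0, len(nt) - len(nt) % 3, 3):
            codon = nt[i : i + 3]
            if codon in STOP_CODONS:
                continue
            if codon not in DEGENERACY:  # ambiguous base
                continue
            counts[codon] += 1
    return CodonCountTable(dict(counts))


def rscu(table: CodonCountTable) -> dict[str, float | None]:
    """Relative synonymous codon usage for every sense codon.

    RSCU of codon c is its count divided by the mean count of its synonymous
    family; 1 means no bias.  Families with zero total are reported missing
    (None); the single-codon families Met and Trp are reported as 1.0 when
    present and missing otherwise.
    """
    out: dict[str, float | None] = {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        total = sum(table.counts.get(c, 0) for c in fam)
        for c in fam:
            if total == 0:
                out[c] = None
            else:
                out[c] = table.counts.get(c, 0) * len(fam) / total
    return out


def positional_gc(
    cds: CodingSequence | str | Iterable[CodingSequence | str],
) -> tuple[float | None, float | None, float | None, float | None]:
    """(GC1, GC2, GC3, GC12) over non-stop, unambiguous codons.

    GC12 is the mean of GC1 and GC2.  Missing (all None) when no codon
    survives filtering.
    """
    table = count_codons(cds)
    if table.n_codons == 0:
        return (None, None, None, None)
    gc = [0, 0, 0]
    for codon, n in table.counts.items():
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += n
    n = table.n_codons
    gc1, gc2, gc3 = (g / n for g in gc)
    return (gc1, gc2, gc3, (gc1 + gc2) / 2)


def gc3s(table: CodonCountTable) -> float | None:
    """GC at synonymous third positions: third-position G+C fraction over
    codons of degenerate families only (Met, Trp and stops excluded)."""
    total = syn_gc = 0
    for codon, n in table.counts.items():
        if DEGENERACY[codon] < 2:
            continue
        total += n
        if codon[2] in "GC":
            syn_gc += n
    if total == 0:
        return None
    return syn_gc / total


def _family_homozygosity(counts: list[int], corrected: bool) -> float | None:
    """Wright's per-family homozygosity F from codon counts.

    Uncorrected: sum of squared proportions.  Corrected (finite sample):
    (n * sum(p^2) - 1) / (n - 1), requiring n >= 2.  Returns None when the
    family is unusable (too few codons, or corrected F <= 0).
    """
    n = sum(counts)
    if n == 0 or (corrected and n < 2):
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    if not corrected:
        return sum_p2
    f = (n * sum_p2 - 1) / (n - 1)
    return f if f > 0 else None


def enc(table: CodonCountTable, corrected: bool = True) -> float | None:
    """Wright's effective number of codons, capped to [20, 61].

    Class means average the homozygosities of usable families within each
    degeneracy class.  An empty three-fold class is imputed as the mean of
    the two- and four-fold class means (Wright's recommendation); any other
    empty class causes the result to be rescaled from the available classes.
    Missing when the table is empty.
    """
    if table.n_codons == 0:
        return None
    class_means: dict[int, float | None] = {}
    for size, n_families in _FAMILIES_PER_CLASS.items():
        fs = [
            f
            for aa, fam in SYNONYMOUS_FAMILIES.items()
            if len(fam) == size
            and (f := _family_homozygosity(table.family_counts(aa), corrected))
            is not None
        ]
        class_means[size] = sum(fs) / len(fs) if fs else None

    if class_means[3] is None and class_means[2] is not None and class_means[4] is not None:
        class_means[3] = (class_means[2] + class_means[4]) / 2

    nc = 2.0
    max_nc = 2.0
    for size, n_families in _FAMILIES_PER_CLASS.items():
        fbar = class_means[size]
        if fbar is None:
            continue
        nc += n_families / fbar
        max_nc += n_families * size
    if max_nc == 2.0:  # no degenerate family usable at all
        return None
    if max_nc < 61.0:  # some class missing entirely: rescale to the Nc scale
        nc = nc * 61.0 / max_nc
    return min(61.0, max(20.0, nc))


def expected_enc(gc3s_value: float) -> float:
    """Expected ENC under compositional constraint alone:
    ``2 + s + 29 / (s^2 + (1 - s)^2)`` for s = GC3s."""
    s = float(gc3s_value)
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def pr2(table: CodonCountTable) -> tuple[float | None, float | None]:
    """PR2 coordinates (A3/(A3+T3), G3/(G3+C3)) at four-fold third positions.

    Computed over the eight fully degenerate codon blocks; a coordinate with
    zero denominator is missing.
    """
    base3: Counter[str] = Counter()
    for codon, n in table.counts.items():
        if codon in FOURFOLD_CODONS:
            base3[codon[2]] += n
    at = base3["A"] + base3["T"]
    gc = base3["G"] + base3["C"]
    pr2_at = base3["A"] / at if at else None
    pr2_gc = base3["G"] / gc if gc else None
    return (pr2_at, pr2_gc)


@dataclass
class UsageProfile:
    """Per-gene (or per-genome) codon-usage summary."""

    name: str
    n_codons: int
    rscu: dict[str, float | None]
    enc: float | None
    gc1: float | None
    gc2: float | None
    gc3: float | None
    gc12: float | None
    gc3s: float | None
    pr2_at: float | None
    pr2_gc: float | None


def usage_profile(
    cds: CodingSequence | Iterable[CodingSequence],
    name: str | None = None,
    corrected_enc: bool = True,
) -> UsageProfile:
    """Full usage profile of a gene or a pooled set of genes."""
    if isinstance(cds, CodingSequence):
        label = name or cds.gene
        items: list[CodingSequence] = [cds]
    else:
        items = list(cds)
        label = name or (items[0].species if items else "")
    table = count_codons(items)
    gc1, gc2, gc3, gc12 = positional_gc(items)
    at3, gcp = pr2(table)
    return UsageProfile(
        name=label,
        n_codons=table.n_codons,
        rscu=rscu(table),
        enc=enc(table, corrected=corrected_enc),
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=gc12,
        gc3s=gc3s(table),
        pr2_at=at3,
        pr2_gc=gcp,
    )


def profile_table(profiles: Iterable[UsageProfile]) -> "pandas.DataFrame":  # noqa: F821
    """Long-format per-gene profile table (one row per profile)."""
    import pandas as pd

    rows = [
        {
            "name": p.name,
            "n_codons": p.n_codons,
            "enc": p.enc,
            "gc1": p.gc1,
            "gc2": p.gc2,
            "gc3": p.gc3,
            "gc12": p.gc12,
            "gc3s": p.gc3s,
            "pr2_at": p.pr2_at,
            "pr2_gc": p.pr2_gc,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)


def rscu_matrix(tables: Mapping[str, CodonCountTable]) -> "pandas.DataFrame":  # noqa: F821
    """Species-by-codon RSCU matrix with RNA-alphabet column headers."""
    import pandas as pd

    rows = {}
    for species, table in tables.items():
        values = rscu(table)
        rows[species] = {c.replace("T", "U"): values[c] for c in SENSE_CODONS}
    return pd.DataFrame.from_dict(rows, orient="index")
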