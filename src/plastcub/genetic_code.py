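"""Genetic-code tables and small sequence helpers.

Everything here is derived from NCBI translation table 11 (bacterial /
plant plastid), which assigns the same amino acids as the standard code
for all sense codons; stops are TAA, TAG and TGA.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon (DNA alphabet) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (the "family")
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: codon -> family size (degeneracy), sense codons only
DEGENERACY: dict[str, int] = {
    c: len(fam) for fam in SYNONYMOUS_FAMILIES.values() for c in fam
}

#: the four-fold degenerate codon blocks: first-two-base prefixes whose four
#: completions are all sense codons for the same amino acid (8 blocks in
#: table 11: CT, GT, TC, CC, AC, GC, CG, GG).  Used by the PR2 statistics.
FOURFOLD_PREFIXES: tuple[str, ...] = tuple(
    sorted(
        p
        for p in {c[:2] for c in SENSE_CODONS}
        if all(p + b in CODON_TO_AA for b in NUCLEOTIDES)
        and len({CODON_TO_AA[p + b] for b in NUCLEOTIDES}) == 1
    )
)

FOURFOLD_CODONS: frozenset[str] = frozenset(
    p + b for p in FOURFOLD_PREFIXES for b in NUCLEOTIDES
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a frame-0 DNA string under table 11; stops become '*'.

    Codons containing characters outside {A,C,G,T} become 'X'.
    """
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3].upper()
        if codon in CODON_TO_AA:
            aas.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append("X")
    return "".join(aas)


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS
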