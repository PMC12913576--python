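"""Shared fixtures: tiny hand-built genomes and GenBank text."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from plastcub.plastome_io import GeneFeature, Plastome

# 60 bp; positions chosen so g1 = ATG AAA TTT TAA (1..12, 1-based),
# g2 = complement(join(20..28,35..43)), trnX and rrnY fill the tail
GENBANK_TEXT = textwrap.dedent(
    """\
    LOCUS       TESTPLAST                 60 bp    DNA     circular PLN 01-JAN-2024
    DEFINITION  synthetic test plastome fragment.
    ACCESSION   TESTPLAST
    VERSION     TESTPLAST.1
    SOURCE      Synthetica testa
      ORGANISM  Synthetica testa
    FEATURES             Location/Qualifiers
         source          1..60
                         /organism="Synthetica testa"
         CDS             1..12
                         /gene="g1"
         CDS             complement(join(20..28,35..43))
                         /gene="g2"
         tRNA            45..50
                         /gene="trnX"
         rRNA            52..57
                         /gene="rrnY"
    ORIGIN
            1 atgaaatttt aagggcccgg tacgtacgta cgcagggttt acgtacgtaa ccggttaacc
    //
    """
)


@pytest.fixture
def genbank_file(tmp_path):
    path = tmp_path / "test.gb"
    path.write_text(GENBANK_TEXT)
    return path


def make_plastome_with_genes(
    gene_nts: dict[str, str],
    length: int = 2000,
    spacing: int = 50,
    seed: int = 0,
    strand: str = "+",
) -> Plastome:
    """Hand-rolled single-exon plastome: genes laid head-to-tail on random
    background (fixed seed)."""
    from plastcub.genetic_code import revcomp

    rng = np.random.default_rng(seed)
    arr = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)]))
    feats = []
    pos = 60
    for name, nt in gene_nts.items():
        placed = revcomp(nt) if strand == "-" else nt
        arr[pos : pos + len(nt)] = list(placed)
        feats.append(GeneFeature(name, "CDS", strand, ((pos, pos + len(nt)),)))
        pos += len(nt) + spacing
    assert pos < length
    return Plastome(id="toy", sequence="".join(arr), features=feats, species="Toy toy")
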