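"""Reading, writing and quality control of annotated plastid genomes.

A :class:`Plastome` is a circular DNA sequence plus an ordered list of gene
features (CDS / tRNA / rRNA) with exon structure and strand.  GenBank flat
files are parsed with Biopython; internally every coordinate is 0-based,
half-open, and an exon spanning the circular origin is split in two.

:func:`extract_cds` applies the quality filters used for codon-usage work:
the spliced, strand-corrected CDS must be divisible by three and free of
internal stop codons (translation table 11).  Terminal stops are removed
before any codon statistic; codons containing ambiguous bases are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

from .genetic_code import STOP_CODONS, revcomp

log = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")

#: maximum tolerated fraction of ambiguous codons in a retained CDS
MAX_AMBIGUOUS_CODON_FRACTION = 0.05


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: exons are 0-based half-open intervals."""

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]
    category: str | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.name}: feature needs at least one exon")
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.name}: empty exon [{s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        """Smallest interval covering all exons (no circular wrap)."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Plastome:
    """A circular annotated plastid genome."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    species: str = ""
    genus: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        L = len(self.sequence)
        for f in self.features:
            for s, e in f.exons:
                if not (0 <= s < L and 0 < e <= L):
                    raise ValueError(
                        f"{self.id}/{f.name}: exon [{s},{e}) outside [0,{L})"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genes(self, kind: str | None = None) -> list[GeneFeature]:
        if kind is None:
            return list(self.features)
        return [f for f in self.features if f.kind == kind]


@dataclass(frozen=True)
class CodingSequence:
    """A QC-passed coding sequence (spliced, strand-resolved, stop-trimmed)."""

    gene: str
    nt: str
    species: str = ""

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.nt[i : i + 3] for i in range(0, len(self.nt), 3))


def read_genbank(path: str | Path) -> Plastome:
    """Parse a GenBank flat file into a :class:`Plastome`.

    Gene/CDS/tRNA/rRNA features are captured with strand and exon structure;
    ``join()`` and ``complement()`` locations are resolved by Biopython and
    converted to 0-based half-open tuples.  Unparseable features are skipped
    with a warning; a record without sequence is a format error.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: GenBank record has no usable sequence")

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in FEATURE_KINDS:
            continue
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("product", ["unnamed"])[0]
        )
        try:
            loc = feat.location
            if loc is None:
                raise ValueError("missing location")
            parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
            strand = "-" if (loc.strand or 1) < 0 else "+"
            exons = tuple(
                sorted((int(p.start), int(p.end)) for p in parts)
            )
            features.append(GeneFeature(name, feat.type, strand, exons))
        except Exception as exc:  # malformed location: skip, keep parsing
            log.warning("%s: skipping %s feature %r: %s", path, feat.type, name, exc)

    species = record.annotations.get("organism", "") or ""
    genus = species.split()[0] if species else ""
    return Plastome(
        id=record.id or record.name or Path(path).stem,
        sequence=seq,
        features=features,
        species=species,
        genus=genus,
    )


def spliced_sequence(p: Plastome, f: GeneFeature) -> str:
    """Spliced, strand-corrected nucleotide sequence of a feature.

    Exons are concatenated in genomic order, then reverse-complemented as a
    whole for minus-strand genes, which restores transcript order.
    """
    nt = "".join(p.sequence[s:e] for s, e in f.exons)
    return revcomp(nt) if f.strand == "-" else nt


def extract_cds(p: Plastome) -> list[CodingSequence]:
    """Quality-controlled coding sequences of a plastome.

    Filters (removal, never an exception):

    * length not divisible by three;
    * internal stop codon (table 11) among unambiguous codons;
    * more than 5% of codons containing ambiguous bases;
    * fewer than two codons after trimming the terminal stop.

    Terminal stop codons are removed; a CDS lacking one is kept with a
    logged note (plastid annotations frequently omit it).  Codons containing
    N survive extraction here and are dropped later by the codon counters.
    IR-duplicated gene copies are both returned; deduplication by
    (gene, sequence) is a downstream choice.
    """
    out: list[CodingSequence] = []
    for f in p.genes("CDS"):
        nt = spliced_sequence(p, f)
        if len(nt) % 3 != 0:
            log.info("%s/%s: length %d not divisible by 3, dropped", p.id, f.name, len(nt))
            continue
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if not codons:
            continue
        if codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        else:
            log.debug("%s/%s: no terminal stop codon", p.id, f.name)
        if len(codons) < 2:
            continue
        ambiguous = sum(1 for c in codons if any(b not in "ACGT" for b in c))
        if ambiguous > MAX_AMBIGUOUS_CODON_FRACTION * len(codons):
            log.info("%s/%s: %d ambiguous codons, dropped", p.id, f.name, ambiguous)
            continue
        if any(c in STOP_CODONS for c in codons):
            log.info("%s/%s: internal stop codon, dropped", p.id, f.name)
            continue
        out.append(CodingSequence(gene=f.name, nt="".join(codons), species=p.species))
    return out


def dedupe_cds(cdss: Iterable[CodingSequence]) -> list[CodingSequence]:
    """Drop exact IR duplicates: one record per (gene, nucleotide sequence)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for c in cdss:
        key = (c.gene, c.nt)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# functional gene categories

#: prefix -> category; longest matching prefix wins.  Editable at run time.
CATEGORY_PREFIXES: dict[str, str] = {
    "psa": "photosystem I",
    "psb": "photosystem II",
    "atp": "ATP synthase",
    "pet": "cytochrome b6f",
    "ndh": "NADH dehydrogenase",
    "rbcL": "Rubisco",
    "rpo": "RNA polymerase",
    "rps": "small ribosomal proteins",
    "rpl": "large ribosomal proteins",
    "ycf": "hypothetical reading frames",
    "matK": "other",
    "clpP": "other",
    "infA": "other",
    "ccsA": "other",
    "cemA": "other",
    "accD": "other",
}

CATEGORIES: tuple[str, ...] = tuple(
    dict.fromkeys(CATEGORY_PREFIXES.values())
) + ("unknown",)


def assign_category(gene: str) -> str:
    """Functional category of a plastid gene symbol (prefix lookup)."""
    base = gene.split("-")[0]
    best = ""
    for prefix in CATEGORY_PREFIXES:
        if base.startswith(prefix) and len(prefix) > len(best):
            best = prefix
    return CATEGORY_PREFIXES[best] if best else "unknown"


# ---------------------------------------------------------------------------
# FASTA / tables

def write_fasta(cdss: Sequence[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in cdss:
            header = f">{c.gene}" + (f" [{c.species}]" if c.species else "")
            fh.write(header + "\n")
            for i in range(0, len(c.nt), 70):
                fh.write(c.nt[i : i + 70] + "\n")


def read_fasta_cds(path: str | Path) -> list[CodingSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species = ""
        if "[" in rec.description and rec.description.endswith("]"):
            species = rec.description.rsplit("[", 1)[1][:-1]
        out.append(CodingSequence(gene=rec.id, nt=str(rec.seq).upper(), species=species))
    return out


def write_genome_fasta(p: Plastome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{p.id} {p.species}\n".rstrip() + "\n")
        for i in range(0, len(p.sequence), 70):
            fh.write(p.sequence[i : i + 70] + "\n")


def gene_table(p: Plastome) -> "pandas.DataFrame":  # noqa: F821
    """Flat per-feature table (gene, kind, strand, exons, category)."""
    import pandas as pd

    rows = [
        {
            "gene": f.name,
            "kind": f.kind,
            "strand": f.strand,
            "exons": ";".join(f"{s}-{e}" for s, e in f.exons),
            "category": assign_category(f.name) if f.kind == "CDS" else "",
        }
        for f in p.features
    ]
    return pd.DataFrame(rows, columns=["gene", "kind", "strand", "exons", "category"])


def write_genbank(p: Plastome, path: str | Path) -> None:
    """Write a minimal GenBank flat file (sequence + gene features)."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(p.sequence),
        id=p.id,
        name=p.id.replace(".", "_")[:16] or "plastome",
        description=f"{p.species} chloroplast genome".strip(),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": p.species,
        },
    )
    for f in p.features:
        strand = -1 if f.strand == "-" else 1
        locs = [FeatureLocation(s, e, strand) for s, e in f.exons]
        loc = CompoundLocation(locs) if len(locs) > 1 else locs[0]
        record.features.append(
            SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]})
        )
    SeqIO.write(record, str(path), "genbank")


def rotate_plastome(p: Plastome, k: int) -> Plastome:
    """Rotate the circular genome so old position k becomes position 0.

    Features are shifted accordingly; a feature exon that would span the new
    origin is split into two intervals.  Useful for origin-invariance checks
    and for canonicalizing detected structures.
    """
    L = p.length
    k %= L
    seq = p.sequence[k:] + p.sequence[:k]
    feats = []
    for f in p.features:
        exons: list[tuple[int, int]] = []
        for s, e in f.exons:
            ns, ne = (s - k) % L, (e - k) % L or L
            if ns < ne:
                exons.append((ns, ne))
            else:  # wraps the new origin: split, keeping transcript order
                exons.append((ns, L))
                exons.append((0, ne))
        feats.append(replace(f, exons=tuple(exons)))
    return Plastome(id=p.id, sequence=seq, features=feats, species=p.species, genus=p.genus)
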