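"""Nei-Gojobori (1986) pairwise Ka/Ks estimation with Jukes-Cantor correction.

Site counting: each codon position contributes a synonymous-site fraction
equal to (synonymous single-nucleotide changes) / (allowed single-nucleotide
changes) at that position, where changes creating a stop codon are excluded
from both numerator and denominator; the nonsynonymous fraction is the
complement, so every codon contributes exactly 3 sites.

Difference counting: codons differing at k positions are scored by
averaging synonymous/nonsynonymous step counts over the k! substitution
pathways, discarding pathways that pass through a stop codon (equal
weights over the surviving pathways, as in the original method).

Rates are Jukes-Cantor corrected, d = -3/4 ln(1 - 4p/3); p >= 3/4 is
reported as saturated (rate missing, pair retained with a flag).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

from .genetic_code import CODON_TO_AA, NUCLEOTIDES, STOP_CODONS, translate
from .plastome_io import CodingSequence

log = logging.getLogger(__name__)

#: Ka/Ks above this is treated as an outlier and excluded from summaries
OUTLIER_RATIO = 10.0

CATEGORY_STRONG = "strong_purifying"
CATEGORY_RELAXED = "relaxed_purifying"
CATEGORY_POSITIVE = "positive"
CATEGORY_UNDEFINED = "undefined"


@dataclass
class KaKsResult:
    gene: str
    pair: tuple[str, str]
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float | None
    pn: float | None
    ks: float | None
    ka: float | None
    ratio: float | None
    saturated: bool = False
    skipped_codons: int = 0

    @property
    def category(self) -> str:
        return categorize(self)


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; s + n == 3.

    Missing (raises ValueError) for stop codons or codons with ambiguity.
    """
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = allowed = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue  # stop-creating changes excluded entirely
            allowed += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if allowed:
            s += syn / allowed
    return (s, 3.0 - s)


@lru_cache(maxsize=None)
def ng86_codon_differences(a: str, b: str) -> tuple[float, float] | None:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    For codons differing at k positions the k! substitution orderings are
    enumerated; orderings passing through a stop codon are discarded and
    (Sd, Nd) is the unweighted mean over the survivors.  None when every
    pathway is blocked by a stop codon.
    """
    a, b = a.upper(), b.upper()
    if a not in CODON_TO_AA or b not in CODON_TO_AA:
        raise ValueError(f"not sense codons: {a!r}, {b!r}")
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return (0.0, 0.0)
    valid: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        cur = a
        steps: list[bool] = []  # True = synonymous step
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                break
            steps.append(CODON_TO_AA[cur] == CODON_TO_AA[nxt])
            cur = nxt
        else:
            valid.append((sum(steps), len(steps) - sum(steps)))
    if not valid:
        return None
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return (sd, nd)


def _jc_correct(p: float) -> float | None:
    """Jukes-Cantor distance; None when saturated (argument <= 0)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg) + 0.0  # + 0.0 normalizes -0.0


def ng86_pair(a: CodingSequence, b: CodingSequence, gene: str | None = None) -> KaKsResult:
    """NG86 Ka, Ks and Ka/Ks between two codon-aligned coding sequences.

    Sequences must have equal length; codon columns where either side has a
    gap ('-') or ambiguity, or is a stop codon, are excluded pairwise.
    Codon pairs whose substitution pathways are all blocked by stops are
    skipped and logged.  Symmetric in its arguments.
    """
    nt_a = a.nt.upper()
    nt_b = b.nt.upper()
    if len(nt_a) != len(nt_b):
        raise ValueError(f"length mismatch: {len(nt_a)} vs {len(nt_b)}")
    if len(nt_a) % 3:
        raise ValueError("alignment length not divisible by 3")

    S = N = Sd = Nd = 0.0
    n_codons = 0
    skipped = 0
    for i in range(0, len(nt_a), 3):
        ca, cb = nt_a[i : i + 3], nt_b[i : i + 3]
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue  # gap, ambiguity or stop: excluded pairwise
        diff = ng86_codon_differences(ca, cb)
        if diff is None:
            skipped += 1
            log.debug("codon pair %s/%s: all pathways blocked by stops", ca, cb)
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diff[0]
        Nd += diff[1]
        n_codons += 1

    pair = (a.species or a.gene, b.species or b.gene)
    gene_name = gene or a.gene
    if n_codons == 0:
        return KaKsResult(gene_name, pair, 0, 0, 0, 0, 0, None, None, None, None, None,
                          skipped_codons=skipped)

    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ks = _jc_correct(ps) if ps is not None else None
    ka = _jc_correct(pn) if pn is not None else None
    saturated = (ps is not None and ps >= 0.75) or (pn is not None and pn >= 0.75)
    ratio = ka / ks if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(
        gene=gene_name, pair=pair, n_codons=n_codons,
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ks=ks, ka=ka,
        ratio=ratio, saturated=saturated, skipped_codons=skipped,
    )


def categorize(result: "KaKsResult | float | None") -> str:
    """Selection category from the Ka/Ks ratio.

    strong purifying: ratio < 0.5; relaxed purifying: 0.5 <= ratio <= 1;
    positive: ratio > 1; undefined when the ratio is missing.
    """
    ratio = result.ratio if isinstance(result, KaKsResult) else result
    if ratio is None:
        return CATEGORY_UNDEFINED
    if ratio < 0.5:
        return CATEGORY_STRONG
    if ratio <= 1.0:
        return CATEGORY_RELAXED
    return CATEGORY_POSITIVE


# ---------------------------------------------------------------------------
# codon-aware alignment (orthologs are near-identical; a simple global
# aligner on amino acids, back-translated to codons, is sufficient)

def align_codons(a: CodingSequence, b: CodingSequence) -> tuple[CodingSequence, CodingSequence]:
    """Codon-aware global alignment of two coding sequences.

    Needleman-Wunsch on the translated proteins (match 1, mismatch -1,
    gap -2), back-translated so gaps are whole codons ('---').
    """
    pa, pb = translate(a.nt), translate(b.nt)
    n, m = len(pa), len(pb)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = -2 * np.arange(n + 1)
    score[0, :] = -2 * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (1 if pa[i - 1] == pb[j - 1] else -1)
            up = score[i - 1, j] - 2
            left = score[i, j - 1] - 2
            best = max(diag, up, left)
            score[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(a.nt[3 * (i - 1) : 3 * i])
            out_b.append(b.nt[3 * (j - 1) : 3 * j])
            i, j = i - 1, j - 1
        elif move == 1 and i > 0:
            out_a.append(a.nt[3 * (i - 1) : 3 * i])
            out_b.append("---")
            i -= 1
        else:
            out_a.append("---")
            out_b.append(b.nt[3 * (j - 1) : 3 * j])
            j -= 1
    nt_a = "".join(reversed(out_a))
    nt_b = "".join(reversed(out_b))
    return (
        CodingSequence(gene=a.gene, nt=nt_a, species=a.species),
        CodingSequence(gene=b.gene, nt=nt_b, species=b.species),
    )


def gene_pair_kaks(a: CodingSequence, b: CodingSequence) -> KaKsResult:
    """Align two orthologous CDSs codon-aware, then run NG86."""
    aligned_a, aligned_b = align_codons(a, b)
    return ng86_pair(aligned_a, aligned_b)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_by_category(
    results: Iterable[KaKsResult],
    categories: Mapping[str, str] | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Per-functional-category Ka/Ks summary.

    Results with ratio > 10 are excluded as outliers before any summary.
    Columns: category, n, mean_ratio, fraction strong/relaxed/positive,
    Pearson r between Ka and Ks, one-sample t of ratios against 1 with
    Bonferroni adjustment over categories.
    """
    import pandas as pd
    from scipy import stats as sps

    from .plastome_io import assign_category

    kept = [
        r for r in results
        if r.ratio is not None and r.ratio <= OUTLIER_RATIO
    ]
    rows = []
    by_cat: dict[str, list[KaKsResult]] = {}
    for r in kept:
        cat = categories[r.gene] if categories else assign_category(r.gene)
        by_cat.setdefault(cat, []).append(r)
    raw_ps = {}
    for cat, rs in sorted(by_cat.items()):
        ratios = np.array([r.ratio for r in rs], float)
        kas = np.array([r.ka for r in rs], float)
        kss = np.array([r.ks for r in rs], float)
        cats = [categorize(r) for r in rs]
        if len(rs) >= 3 and np.std(kas) > 0 and np.std(kss) > 0:
            r_ka_ks = float(sps.pearsonr(kas, kss)[0])
        else:
            r_ka_ks = np.nan
        if len(rs) >= 2 and ratios.var(ddof=1) > 0:
            t, p = sps.ttest_1samp(ratios, 1.0)
        else:
            t, p = np.nan, np.nan
        raw_ps[cat] = p
        rows.append(
            {
                "category": cat,
                "n": len(rs),
                "mean_ratio": float(ratios.mean()),
                "frac_strong": cats.count(CATEGORY_STRONG) / len(rs),
                "frac_relaxed": cats.count(CATEGORY_RELAXED) / len(rs),
                "frac_positive": cats.count(CATEGORY_POSITIVE) / len(rs),
                "pearson_ka_ks": r_ka_ks,
                "t_vs_1": float(t) if t == t else np.nan,
                "p_vs_1": float(p) if p == p else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        m = df["p_vs_1"].notna().sum()
        df["p_vs_1_bonferroni"] = df["p_vs_1"].map(
            lambda p: min(1.0, p * m) if p == p else np.nan
        )
    return df


def category_contrasts(
    results: Iterable[KaKsResult],
    categories: Mapping[str, str] | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Pairwise category comparisons of Ka/Ks (Wilcoxon rank-sum, Cohen's d).

    Outliers (ratio > 10) excluded first; Bonferroni over the pairs tested.
    """
    import pandas as pd

    from .group_stats import bonferroni, cohens_d, wilcoxon_rank_sum
    from .plastome_io import assign_category

    by_cat: dict[str, list[float]] = {}
    for r in results:
        if r.ratio is None or r.ratio > OUTLIER_RATIO:
            continue
        cat = categories[r.gene] if categories else assign_category(r.gene)
        by_cat.setdefault(cat, []).append(r.ratio)
    cats = sorted(c for c, v in by_cat.items() if len(v) >= 2)
    rows = []
    for c1, c2 in itertools.combinations(cats, 2):
        stat, p = wilcoxon_rank_sum(by_cat[c1], by_cat[c2])
        d = cohens_d(by_cat[c1], by_cat[c2])
        rows.append({"category_a": c1, "category_b": c2, "wilcoxon_u": stat,
                     "p_raw": p, "cohens_d": d})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bonferroni"] = bonferroni(df["p_raw"].tolist())
    return df


def results_table(results: Iterable[KaKsResult]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "species_a": r.pair[0],
                "species_b": r.pair[1],
                "n_codons": r.n_codons,
                "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                "ka": r.ka, "ks": r.ks, "ratio": r.ratio,
                "category": r.category,
                "saturated": r.saturated,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Axt-format paired sequences

def read_axt(path) -> list[tuple[str, CodingSequence, CodingSequence]]:
    """Read Axt-like blocks: a header line, then the two aligned sequences.

    Returns (block_name, seq_a, seq_b) triples.
    """
    blocks = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i + 2 < len(lines) or (i + 2 == len(lines) and len(lines) - i == 3):
        name = lines[i].split()[0]
        a, b = lines[i + 1].upper(), lines[i + 2].upper()
        blocks.append(
            (name,
             CodingSequence(gene=name, nt=a, species=f"{name}_a"),
             CodingSequence(gene=name, nt=b, species=f"{name}_b"))
        )
        i += 3
    return blocks
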