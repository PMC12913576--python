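"""End-to-end orchestration over a directory of genomes.

:func:`run_all` sequences the full comparative analysis: per-genome
structure, descriptors, usage profiles and SSRs; per-gene pairwise Ka/Ks
across genomes; and the cross-genome tables (RSCU matrix and clustering,
neutrality fits, ENC-GC3s deviations, PR2 coordinates, SSR
presence/absence, multi-group tests and the descriptor correlation
matrix).  Per-genome failures are isolated and recorded in a failure
ledger; outputs are plain TSV/JSON.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_metrics import count_codons, profile_table, rscu_matrix, usage_profile
from .genome_structure import (
    detect_quadripartite,
    genome_stats,
    junction_report,
    stats_table,
)
from .group_stats import dunn_posthoc, kruskal_wallis, pearson_matrix
from .kaks import gene_pair_kaks, results_table
from .plastome_io import Plastome, dedupe_cds, extract_cds, read_genbank
from .selection_inference import (
    cluster_profiles,
    enc_deviation,
    linkage_to_newick,
    mutation_contribution,
    neutrality_regression,
)
from .ssr_scan import DEFAULT_THRESHOLDS, category_summary, presence_absence_matrix, scan_plastome

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    group_map: dict[str, str] = field(default_factory=dict)  # species -> group
    ssr_thresholds: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    min_ir: int = 1000
    kaks_outlier: float = 10.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            input_dir=Path(raw["input_dir"]),
            output_dir=Path(raw["output_dir"]),
            group_map=dict(raw.get("group_map", {})),
            ssr_thresholds={int(k): int(v) for k, v in raw.get("ssr_thresholds", DEFAULT_THRESHOLDS).items()},
            min_ir=int(raw.get("min_ir", 1000)),
            kaks_outlier=float(raw.get("kaks_outlier", 10.0)),
            seed=int(raw.get("seed", 0)),
        )


def load_genomes(input_dir: str | Path) -> list[Plastome]:
    paths = sorted(Path(input_dir).glob("*.gb")) + sorted(Path(input_dir).glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(f"no GenBank genomes (*.gb, *.gbk) in {input_dir}")
    return [read_genbank(p) for p in paths]


def run_all(config: RunConfig) -> dict[str, object]:
    """Run the full analysis; returns the report bundle as a dict of tables.

    Every table is also written under ``config.output_dir``; a manifest
    records the package version, config hash and any per-genome failures.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: dict[str, str] = {}
    genomes: list[Plastome] = []
    for path in sorted(Path(config.input_dir).glob("*.gb")) + sorted(
        Path(config.input_dir).glob("*.gbk")
    ):
        try:
            genomes.append(read_genbank(path))
        except Exception as exc:
            failures[str(path)] = str(exc)
            log.error("failed to read %s: %s", path, exc)
    if not genomes:
        raise FileNotFoundError(f"no readable genome in {config.input_dir}")

    bundle: dict[str, object] = {}
    structures = {}
    all_stats = {}
    junctions = []
    gene_profiles = []
    genome_tables = {}
    ssrs_by_species = {}
    cds_by_species = {}

    for g in genomes:
        try:
            s = detect_quadripartite(g.sequence, min_ir=config.min_ir)
            structures[g.id] = s
            all_stats[g.id] = genome_stats(g, s)
            for j in junction_report(s, g):
                junctions.append({"genome": g.id, "junction": j.junction,
                                  "position": j.position, "gene": j.gene,
                                  "distance": j.distance, "spans": j.spans})
            cds = dedupe_cds(extract_cds(g))
            cds_by_species[g.species or g.id] = cds
            genome_tables[g.species or g.id] = count_codons(cds)
            for c in cds:
                gene_profiles.append((g.species or g.id, usage_profile(c)))
            ssrs_by_species[g.species or g.id] = scan_plastome(g, config.ssr_thresholds)
        except Exception as exc:
            failures[g.id] = str(exc)
            log.error("genome %s failed: %s", g.id, exc)

    bundle["stats"] = stats_table(all_stats)
    bundle["junctions"] = pd.DataFrame(junctions)
    bundle["rscu"] = rscu_matrix(genome_tables)

    prof_df = profile_table([p for _, p in gene_profiles])
    prof_df.insert(0, "species", [sp for sp, _ in gene_profiles])
    bundle["profiles"] = prof_df

    # neutrality fits per species
    fits = []
    for sp in sorted({sp for sp, _ in gene_profiles}):
        fit = neutrality_regression([p for s, p in gene_profiles if s == sp])
        if fit is not None:
            fits.append({"species": sp, "slope": fit.slope, "intercept": fit.intercept,
                         "r_squared": fit.r_squared, "n_genes": fit.n_points,
                         "mutation_pct": mutation_contribution(fit)})
    bundle["neutrality"] = pd.DataFrame(fits)

    dev, frac = enc_deviation([p for _, p in gene_profiles])
    bundle["enc_deviation"] = dev
    bundle["enc_fraction_below"] = frac

    # SSR tables
    ssr_rows = [
        {"species": sp, "motif": l.motif, "unit_len": l.unit_len, "copies": l.copies,
         "start": l.start, "end": l.end, "compartment": l.compartment}
        for sp, loci in ssrs_by_species.items() for l in loci
    ]
    bundle["ssr_loci"] = pd.DataFrame(ssr_rows)
    bundle["ssr_matrix"] = presence_absence_matrix(ssrs_by_species)
    bundle["ssr_summary"] = pd.concat(
        {sp: category_summary(loci) for sp, loci in ssrs_by_species.items()},
        names=["species"],
    ) if ssrs_by_species else pd.DataFrame()

    # pairwise Ka/Ks on shared genes
    kaks_results = []
    species = sorted(cds_by_species)
    for sa, sb in itertools.combinations(species, 2):
        genes_a = {c.gene: c for c in cds_by_species[sa]}
        genes_b = {c.gene: c for c in cds_by_species[sb]}
        for gene in sorted(set(genes_a) & set(genes_b)):
            try:
                kaks_results.append(gene_pair_kaks(genes_a[gene], genes_b[gene]))
            except Exception as exc:
                failures[f"kaks:{gene}:{sa}|{sb}"] = str(exc)
    bundle["kaks"] = results_table(kaks_results)

    # clustering on RSCU (species x codon)
    rscu_df = bundle["rscu"].dropna(axis=1, how="all")
    if len(rscu_df) >= 2:
        cl = cluster_profiles(rscu_df)
        bundle["rscu_dendrogram"] = linkage_to_newick(cl)

    # multi-group comparison of descriptors
    stats_df = bundle["stats"]
    group_rows = []
    if config.group_map:
        by_group: dict[str, list[str]] = {}
        id_to_species = {g.id: g.species or g.id for g in genomes}
        for gid in stats_df.index:
            grp = config.group_map.get(id_to_species[gid])
            if grp is None:
                log.warning("%s not in group_map; excluded from group tests", gid)
                continue
            by_group.setdefault(grp, []).append(gid)
        usable = {g: ids for g, ids in by_group.items() if len(ids) >= 2}
        numeric = stats_df.select_dtypes("number")
        if len(usable) >= 2:
            for col in numeric.columns:
                groups = [numeric.loc[ids, col].dropna().tolist() for ids in usable.values()]
                if any(len(v) < 2 for v in groups):
                    continue
                res = kruskal_wallis(groups)
                row = {"parameter": col, "H": res.statistic, "p": res.p_value}
                if res.p_value < 0.05:
                    names = list(usable)
                    row["dunn"] = json.dumps(
                        [{"pair": f"{names[i]}|{names[j]}", "z": z, "p_adj": padj}
                         for (i, j), z, _praw, padj in dunn_posthoc(groups)]
                    )
                group_rows.append(row)
    bundle["group_tests"] = pd.DataFrame(group_rows)

    numeric = stats_df.select_dtypes("number").dropna(axis=1, how="all")
    r_mat, p_mat = pearson_matrix(numeric)
    bundle["correlation_r"] = r_mat
    bundle["correlation_p"] = p_mat

    # write everything
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t")
        elif isinstance(obj, str):
            (out / f"{name}.nwk").write_text(obj + "\n")
    config_hash = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config_hash": config_hash,
        "seed": config.seed,
        "n_genomes": len(genomes),
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
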