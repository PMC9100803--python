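"""End-to-end workflow orchestration.

Stages: (optional) reference sub-panel selection -> functional-haplotype
mining on the reference panel -> focal-panel matching and report tables ->
diversity analyses -> run manifest. Stages communicate through files in the
output directory and never mutate their inputs; all randomness flows from
one seed recorded in the manifest, so identical configuration and seed give
identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    AccessionRecord,
    GeneRegion,
    GenotypeMatrix,
    _chrom_key,
    merge_matrices,
    phenotype_map,
    read_tables,
    read_vcf_panel,
    write_nexus_tree,
)
from .reference_selector import selection_table
from .functional_haplotypes import (
    AssociationConfig,
    catalog_frame,
    mine_genome,
)
from .focal_catalog import (
    attribute_origins,
    chromosome_map,
    classify_catalog,
    entries_frame,
    summary_frame,
    term_frequency,
)
from . import diversity_stats as dv

logger = logging.getLogger(__name__)

STOPLIST = ("protein", "expressed", "putative", "domain", "containing", "family")


@dataclass
class RunConfig:
    ref_vcfs: list[Path]
    focal_vcfs: list[Path]
    phenotypes: Path
    metadata: Path
    genes: Path
    outdir: Path
    seed: int = 0
    association: AssociationConfig = field(default_factory=AssociationConfig)
    ld_group: str = "indica"
    rarefaction_reps: int = 100
    core_list: tuple[str, ...] = ()
    run_selection: bool = True

    def validate(self) -> None:
        for path in [self.phenotypes, self.metadata, self.genes,
                     *self.ref_vcfs, *self.focal_vcfs]:
            if not Path(path).exists():
                raise FileNotFoundError(f"input does not exist: {path}")
        if not self.ref_vcfs:
            raise FileNotFoundError("no reference VCF files given")
        if not self.focal_vcfs:
            raise FileNotFoundError("no focal VCF files given")


def vcfs_in_dir(directory: str | Path) -> list[Path]:
    return sorted(Path(directory).glob("*.vcf"))


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "ref_vcfs": [Path(p).name for p in config.ref_vcfs],
            "focal_vcfs": [Path(p).name for p in config.focal_vcfs],
            "phenotypes": Path(config.phenotypes).name,
            "metadata": Path(config.metadata).name,
            "genes": Path(config.genes).name,
        },
        "parameters": {
            "percentile": config.association.q,
            "min_carriers": config.association.min_carriers,
            "impact_classes": sorted(config.association.impact_classes),
            "ld_group": config.ld_group,
            "rarefaction_reps": config.rarefaction_reps,
        },
        "stages": {},
    }

    records, genes = read_tables(config.phenotypes, config.metadata, config.genes)
    ref_records = [r for r in records if r.panel == "reference"]
    focal_records = [r for r in records if r.panel == "focal"]

    stage = "select-samples"
    try:
        if config.run_selection:
            table = selection_table(ref_records, config.core_list)
            table.to_csv(outdir / "selected_samples.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"rows": int(len(table))}

        stage = "mine"
        ref_matrix = read_vcf_panel(config.ref_vcfs)
        phenotypes = phenotype_map(ref_records)
        associations = mine_genome(ref_matrix, genes, phenotypes, config.association)
        catalog = catalog_frame(associations)
        catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "genes": len(genes),
            "accessions": ref_matrix.n_accessions,
            "sites": ref_matrix.n_sites,
            "flagged_haplotypes": int(len(catalog)),
        }

        stage = "match"
        focal_matrix = read_vcf_panel(config.focal_vcfs)
        result = classify_catalog(associations, focal_matrix, records)
        entries_frame(result.entries).to_csv(
            outdir / "catalog_entries.tsv", sep="\t", index=False)
        summary_frame(result.summary).to_csv(
            outdir / "table1_summary.tsv", sep="\t", index=False)
        result.per_accession.to_csv(
            outdir / "table2_accessions.tsv", sep="\t", index=False)
        attribute_origins(associations, ref_records).to_csv(
            outdir / "origins.tsv", sep="\t", index=False)
        goslim_map = {g.gene_id: list(g.goslim_terms) for g in genes}
        flagged_genes = sorted({a.haplotype.gene_id for a in associations})
        term_frequency(flagged_genes, goslim_map, STOPLIST).to_csv(
            outdir / "term_counts.tsv", sep="\t", index=False)
        chromosome_map(result.entries, genes).to_csv(
            outdir / "chrom_map.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "entries": len(result.entries),
            "summary_rows": len(result.summary),
            "accessions": focal_matrix.n_accessions,
        }

        stage = "diversity"
        counts = run_diversity(
            ref_matrix, focal_matrix, records, genes, outdir,
            seed=config.seed, reps=config.rarefaction_reps,
            ld_group=config.ld_group,
        )
        manifest["stages"][stage] = counts
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def run_diversity(
    ref_matrix: GenotypeMatrix,
    focal_matrix: GenotypeMatrix,
    records: Sequence[AccessionRecord],
    genes: Sequence[GeneRegion],
    outdir: Path,
    seed: int = 0,
    reps: int = 100,
    ld_group: str = "indica",
) -> dict:
    """Diversity stage: pi comparison, QC SNPs, LD, K2P/Ward, SFS, export."""
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    counts: dict = {}

    # per-gene rarefied pi: focal panel against the reference pool
    sample_size = min(focal_matrix.n_accessions, ref_matrix.n_accessions)
    if sample_size < focal_matrix.n_accessions:
        warnings.warn(
            "reference pool smaller than focal panel; rarefaction sample size "
            f"capped at {sample_size}"
        )
    pi_rows = []
    for gene in genes:
        focal_idx = focal_matrix.sites_in_gene(gene)
        ref_idx = ref_matrix.sites_in_gene(gene)
        result = dv.rarefied_pi_comparison(
            focal_matrix.states[focal_idx, :] if focal_idx else
            np.empty((0, focal_matrix.n_accessions), dtype=np.int8),
            ref_matrix.states[ref_idx, :] if ref_idx else
            np.empty((0, ref_matrix.n_accessions), dtype=np.int8),
            gene.length, gene_id=gene.gene_id, reps=reps, rng=rng,
            sample_size=sample_size,
        )
        lo, hi = result.band
        pi_rows.append({
            "gene_id": gene.gene_id, "focal_pi": round(result.focal_pi, 8),
            "rarefied_mean": round(float(np.mean(result.rarefied_pis)), 8),
            "rarefied_p2.5": round(lo, 8), "rarefied_p97.5": round(hi, 8),
            "verdict": result.verdict,
        })
    pd.DataFrame(pi_rows).to_csv(outdir / "pi_comparison.tsv", sep="\t", index=False)
    counts["pi_genes"] = len(pi_rows)

    # QC SNP per gene, evaluated on the focal library
    qc_rows, qc_indices = [], []
    coverage = focal_matrix.coverage()
    freq = focal_matrix.alt_frequency()
    for gene in genes:
        cand = focal_matrix.sites_in_gene(gene)
        pick = dv.select_qc_snp(gene, cand, focal_matrix)
        if pick is None:
            continue
        site = focal_matrix.sites[pick]
        p = freq[pick]
        qc_rows.append({
            "gene_id": gene.gene_id, "chrom": site.chrom, "pos": site.pos,
            "coverage": round(float(coverage[pick]), 6),
            "maf": round(float(min(p, 1 - p)), 6),
        })
        qc_indices.append(pick)
    pd.DataFrame(qc_rows, columns=["gene_id", "chrom", "pos", "coverage", "maf"]
                 ).to_csv(outdir / "qc_snps.tsv", sep="\t", index=False)
    counts["qc_snps"] = len(qc_rows)

    # LD among QC SNPs, restricted to one variety group of the focal panel
    group_ids = [r.accession_id for r in records
                 if r.panel == "focal" and r.variety_group == ld_group
                 and r.accession_id in set(focal_matrix.accessions)]
    ld = pd.DataFrame(columns=["chrom", "pos_a", "pos_b", "gene_a", "gene_b",
                               "r2", "n_obs", "high_ld"])
    if len(group_ids) >= 2 and qc_indices:
        sub = focal_matrix.subset_accessions(group_ids)
        ld = dv.ld_table(sub, qc_indices)
    ld.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    counts["ld_pairs"] = int(len(ld))

    # combined-panel K2P distances, Ward tree, clusters, SFS, export
    combined = merge_matrices(ref_matrix, focal_matrix)
    qc_keys = [(focal_matrix.sites[i].chrom, focal_matrix.sites[i].pos)
               for i in qc_indices]
    comb_idx = [combined.site_index(c, p) for c, p in qc_keys]
    comb_idx = [i for i in comb_idx if i is not None]
    qc_combined = combined.restrict_sites(comb_idx)
    if qc_combined.n_sites:
        sequences = dv.matrix_to_sequences(qc_combined)
        dist, undefined = dv.k2p_matrix(sequences)
        if undefined:
            # drop the fewest accessions needed to remove all undefined pairs
            from collections import Counter

            pairs = set(undefined)
            dropped = set()
            while pairs:
                worst = Counter(x for pair in pairs for x in pair).most_common(1)[0][0]
                dropped.add(worst)
                pairs = {p for p in pairs if worst not in p}
            warnings.warn(
                f"dropping {len(dropped)} accessions with undefined (saturated) "
                "K2P pairs"
            )
            keep = [l for l in dist.index if l not in dropped]
            dist = dist.loc[keep, keep]
        dist.round(8).to_csv(outdir / "k2p_matrix.tsv", sep="\t")
        if len(dist) >= 2:
            z, k = dv.ward_dendrogram(dist)
            write_nexus_tree(z, list(dist.index), outdir / "tree.nex")
            clusters = dv.cluster_assignments(z, list(dist.index), k)
            clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            counts["suggested_clusters"] = int(k)
        per_chrom, genome = dv.sfs(qc_combined)
        for chrom, hist in per_chrom.items():
            dv.sfs_frame(hist).to_csv(outdir / f"sfs_{chrom}.tsv", sep="\t", index=False)
        dv.sfs_frame(genome).to_csv(outdir / "sfs_genome.tsv", sep="\t", index=False)
        counts["sfs_sites"] = int(genome.sum())
        dv.export_genotype_matrix(qc_combined, outdir / "genotypes.nex", "binary_nexus")
    return counts
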