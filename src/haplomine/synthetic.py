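"""Seeded synthetic breeding-panel generator.

Emulates the pipeline's inputs at desk scale: a phenotyped reference panel
and a focal panel split into elite cultivars (EC), non-focal varieties (NFV)
and external accessions, with annotated per-site impacts and optional
*planted* haplotypes whose carriers receive a phenotype shift of a stated
effect size (in trait-SD units).

Default panel sizes mirror the study design this generator emulates: a
200-accession phenotyped reference panel and a 279-accession focal panel
(35 EC + 190 NFV + 54 external). Gene count and sites per gene are kept
small (20 genes x 6 sites) so every pipeline stage runs in seconds.

Genotypes are drawn independently per site at a common ALT frequency; there
is no linkage structure, recombination map or coalescent realism, so tests
on these panels exercise the bookkeeping and statistics, not population-
genetic realism. Planted haplotypes are made exclusive to their designated
carriers (a chance all-ALT pattern in any other accession is perturbed at
one site) and carriers are kept non-missing at the planted gene's functional
sites, so the truth table is exact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ALT,
    MISSING,
    REF,
    AccessionRecord,
    GeneRegion,
    GenotypeMatrix,
    VariantSite,
    write_vcf,
)

REGIONS = (
    "South Asia", "East Asia", "Southeast Asia", "Africa",
    "Indo-Pacific", "Europe and Middle East", "Americas", "Australasia",
)
VARIETY_GROUPS = ("indica", "japonica", "aus", "aromatic", "admix")
IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
BASES = "ACGT"

# small functional vocabulary for GOSlim-style term tables
GOSLIM_VOCAB = (
    "auxin response protein", "cytochrome P450 domain", "chalcone synthase",
    "phosphate dehydrogenase", "glutamate synthesis protein",
    "kinase domain protein", "transcription factor", "expressed protein",
    "transporter protein", "ubiquitin ligase",
)


@dataclass(frozen=True)
class PlantedHaplotype:
    """A haplotype planted into the panels with a phenotypic effect.

    gene_index: which gene receives the haplotype.
    effect_sd: phenotype shift of reference carriers, in trait-SD units.
    n_ref_carriers: reference accessions carrying it (and shifted).
    n_focal_nfv / n_focal_ec: focal accessions of each role it is copied to.
    """

    gene_index: int
    effect_sd: float
    n_ref_carriers: int
    n_focal_nfv: int = 4
    n_focal_ec: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_ref: int = 200
    n_focal_ec: int = 35
    n_focal_nfv: int = 190
    n_focal_external: int = 54
    n_genes: int = 20
    sites_per_gene: int = 6
    n_chromosomes: int = 2
    gene_length: int = 500
    alt_freq: float = 0.15
    planted: tuple[PlantedHaplotype, ...] = ()
    pheno_mean: float = 8.0   # grain-length-like trait, mm
    pheno_sd: float = 1.0
    missing_rate: float = 0.02
    impact_mix: tuple[float, float, float, float] = (0.1, 0.3, 0.3, 0.3)

    def __post_init__(self) -> None:
        for name in ("n_ref", "n_focal_ec", "n_focal_nfv", "n_genes", "sites_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.alt_freq < 1.0:
            raise ValueError("alt_freq must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        for p in self.planted:
            if p.n_ref_carriers > self.n_ref:
                raise ValueError("planted carrier count exceeds n_ref")
            if not 0 <= p.gene_index < self.n_genes:
                raise ValueError("planted gene_index out of range")


@dataclass
class SimulatedPanel:
    ref_matrix: GenotypeMatrix
    focal_matrix: GenotypeMatrix
    records: list[AccessionRecord]
    genes: list[GeneRegion]
    phenotypes: dict[str, float]
    truth: pd.DataFrame


def _make_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneRegion]:
    genes = []
    per_chrom_counter = {f"chr{c + 1}": 0 for c in range(config.n_chromosomes)}
    for g in range(config.n_genes):
        chrom = f"chr{g % config.n_chromosomes + 1}"
        slot = per_chrom_counter[chrom]
        per_chrom_counter[chrom] += 1
        start = 1 + slot * config.gene_length * 2
        n_terms = int(rng.integers(1, 4))
        terms = tuple(rng.choice(GOSLIM_VOCAB, size=n_terms, replace=False))
        genes.append(GeneRegion(
            gene_id=f"g{g + 1:03d}", chrom=chrom, start=start,
            end=start + config.gene_length - 1,
            known_trait_gene=bool(rng.random() < 0.1),
            goslim_terms=terms,
        ))
    return genes


def _make_sites(
    genes: Sequence[GeneRegion], config: SimulationConfig, rng: np.random.Generator,
    planted_gene_idx: set[int],
) -> tuple[list[VariantSite], dict[str, list[int]]]:
    probs = np.asarray(config.impact_mix, dtype=float)
    probs = probs / probs.sum()
    sites: list[VariantSite] = []
    func_sites: dict[str, list[int]] = {}
    for g_idx, gene in enumerate(genes):
        positions = np.sort(rng.choice(
            np.arange(gene.start, gene.end + 1), size=config.sites_per_gene,
            replace=False,
        ))
        impacts = list(rng.choice(IMPACTS, size=config.sites_per_gene, p=probs))
        if g_idx in planted_gene_idx:
            # a planted gene must carry a functional signal
            impacts[0] = "HIGH"
            if config.sites_per_gene > 1:
                impacts[1] = "MODERATE"
        for pos, impact in zip(positions, impacts):
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            idx = len(sites)
            sites.append(VariantSite(
                chrom=gene.chrom, pos=int(pos), ref_allele=str(ref),
                alt_alleles=(str(alt),), filter_status="PASS",
                impact=str(impact), gene_id=gene.gene_id,
            ))
            if impact in ("HIGH", "MODERATE"):
                func_sites.setdefault(gene.gene_id, []).append(idx)
    return sites, func_sites


def _draw_states(
    n_sites: int, n_acc: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    states = np.where(
        rng.random((n_sites, n_acc)) < config.alt_freq, ALT, REF
    ).astype(np.int8)
    if config.missing_rate > 0:
        states[rng.random((n_sites, n_acc)) < config.missing_rate] = MISSING
    return states


def _plant(
    states: np.ndarray, rows: Sequence[int], carrier_cols: Sequence[int]
) -> None:
    """Write the all-ALT pattern into carriers; break chance copies elsewhere."""
    rows = list(rows)
    carrier_cols = set(carrier_cols)
    for j in range(states.shape[1]):
        if j in carrier_cols:
            states[rows, j] = ALT
        else:
            col = states[rows, j]
            if np.all(col == ALT):
                states[rows[0], j] = REF


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate the reference and focal panels in memory."""
    rng = np.random.default_rng(config.seed)
    planted_gene_idx = {p.gene_index for p in config.planted}
    genes = _make_genes(config, rng)
    sites, func_sites = _make_sites(genes, config, rng, planted_gene_idx)
    n_sites = len(sites)

    ref_ids = [f"REF{i + 1:04d}" for i in range(config.n_ref)]
    ec_ids = [f"EC{i + 1:03d}" for i in range(config.n_focal_ec)]
    nfv_ids = [f"NFV{i + 1:03d}" for i in range(config.n_focal_nfv)]
    ext_ids = [f"EXT{i + 1:03d}" for i in range(config.n_focal_external)]
    focal_ids = ec_ids + nfv_ids + ext_ids

    ref_states = _draw_states(n_sites, len(ref_ids), config, rng)
    focal_states = _draw_states(n_sites, len(focal_ids), config, rng)

    phenotypes = {
        acc: float(v) for acc, v in zip(
            ref_ids, rng.normal(config.pheno_mean, config.pheno_sd, len(ref_ids))
        )
    }

    truth_rows = []
    for p in config.planted:
        gene = genes[p.gene_index]
        rows = func_sites.get(gene.gene_id, [])
        if not rows:
            raise ValueError(f"planted gene {gene.gene_id} has no functional sites")
        ref_cols = list(rng.choice(len(ref_ids), size=p.n_ref_carriers, replace=False))
        _plant(ref_states, rows, ref_cols)
        for col in ref_cols:
            phenotypes[ref_ids[col]] += p.effect_sd * config.pheno_sd

        nfv_cols, ec_cols = [], []
        if p.n_focal_nfv:
            picks = rng.choice(len(nfv_ids), size=p.n_focal_nfv, replace=False)
            nfv_cols = [len(ec_ids) + int(i) for i in picks]
        if p.n_focal_ec:
            picks = rng.choice(len(ec_ids), size=p.n_focal_ec, replace=False)
            ec_cols = [int(i) for i in picks]
        _plant(focal_states, rows, nfv_cols + ec_cols)

        truth_rows.append({
            "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "site_positions": ",".join(str(sites[i].pos) for i in rows),
            "state_string": "1" * len(rows),
            "effect_sd": p.effect_sd,
            "ref_carriers": ",".join(sorted(ref_ids[c] for c in ref_cols)),
            "focal_nfv_carriers": ",".join(sorted(focal_ids[c] for c in nfv_cols)),
            "focal_ec_carriers": ",".join(sorted(focal_ids[c] for c in ec_cols)),
        })

    records: list[AccessionRecord] = []
    for acc in ref_ids:
        records.append(AccessionRecord(
            accession_id=acc, panel="reference", role="none",
            variety_group=str(rng.choice(VARIETY_GROUPS)),
            region=str(rng.choice(REGIONS)),
            phenotype=phenotypes[acc],
        ))
    for acc in focal_ids:
        role = "EC" if acc in set(ec_ids) else "NFV" if acc in set(nfv_ids) else "external"
        group = "indica" if rng.random() < 0.92 else str(rng.choice(VARIETY_GROUPS))
        records.append(AccessionRecord(
            accession_id=acc, panel="focal", role=role,
            variety_group=group, region="Southeast Asia",
        ))

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "chrom", "site_positions", "state_string", "effect_sd",
        "ref_carriers", "focal_nfv_carriers", "focal_ec_carriers",
    ])
    return SimulatedPanel(
        ref_matrix=GenotypeMatrix(list(sites), ref_ids, ref_states),
        focal_matrix=GenotypeMatrix(list(sites), focal_ids, focal_states),
        records=records, genes=genes, phenotypes=phenotypes, truth=truth,
    )


def generate_panel(
    config: SimulationConfig, outdir: str | Path, per_accession: bool = False
) -> dict[str, Path]:
    """Write the simulated panels and tables to ``outdir``.

    Outputs are byte-identical for equal configs (all randomness flows from
    ``config.seed`` and all file formatting is fixed).

    With ``per_accession=True`` the reference panel is written as one VCF per
    accession containing only that accession's non-reference records,
    exercising the gVCF absent-record-equals-REF convention downstream.
    """
    panel = simulate_panel(config)
    outdir = Path(outdir)
    ref_dir = outdir / "ref_vcf"
    focal_dir = outdir / "focal_vcf"
    ref_dir.mkdir(parents=True, exist_ok=True)
    focal_dir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    if per_accession:
        for acc in panel.ref_matrix.accessions:
            single = panel.ref_matrix.subset_accessions([acc])
            keep = [i for i in range(single.n_sites) if single.states[i, 0] != REF]
            write_vcf(single.restrict_sites(keep), ref_dir / f"{acc}.vcf")
        paths["ref_vcf_dir"] = ref_dir
    else:
        paths["ref_vcf"] = write_vcf(panel.ref_matrix, ref_dir / "reference.vcf")
        paths["ref_vcf_dir"] = ref_dir
    paths["focal_vcf"] = write_vcf(panel.focal_matrix, focal_dir / "focal.vcf")
    paths["focal_vcf_dir"] = focal_dir

    pheno = pd.DataFrame([
        {"accession_id": r.accession_id, "value": f"{r.phenotype:.6f}",
         "region": r.region, "variety_group": r.variety_group}
        for r in panel.records if r.phenotype is not None
    ])
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)

    meta = pd.DataFrame([
        {"accession_id": r.accession_id, "panel": r.panel, "role": r.role,
         "variety_group": r.variety_group, "region": r.region}
        for r in panel.records
    ])
    paths["metadata"] = outdir / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    genes = pd.DataFrame([
        {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end,
         "known_trait_gene": int(g.known_trait_gene),
         "goslim_terms": ";".join(g.goslim_terms)}
        for g in panel.genes
    ])
    paths["genes"] = outdir / "genes.tsv"
    genes.to_csv(paths["genes"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    panel.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat mapping (e.g. parsed YAML)."""
    mapping = dict(mapping)
    planted = tuple(
        PlantedHaplotype(**p) for p in mapping.pop("planted", []) or []
    )
    if "impact_mix" in mapping:
        mapping["impact_mix"] = tuple(mapping["impact_mix"])
    return SimulationConfig(planted=planted, **mapping)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
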