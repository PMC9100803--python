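"""Functional-haplotype mining.

A *functional haplotype* for a gene is the ordered pattern of
reference/alternative alleles an accession carries across the gene's
moderate- or high-impact SNPs. A haplotype is flagged as associated with an
extreme phenotype when the mean phenotype of its carriers (computed over the
phenotyped reference panel) falls strictly above the q-th quantile (or
strictly below the (1-q)-th) of the accession-level phenotype distribution,
and the haplotype has at least ``min_carriers`` carriers.

The default q = 0.866 corresponds to 1.5 standard deviations from the mean
of a normal distribution (two-sided coverage 2*Phi(1.5) - 1 ~ 0.866); a mean
over >= 5 carriers rarely reaches a 0.975-style tail, which is why the
threshold is deliberately milder than a conventional significance level.
No multiple-testing correction is applied across genes: the output is a
screening catalogue, not a set of calibrated hypothesis tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ALT,
    MISSING,
    REF,
    GeneRegion,
    GenotypeMatrix,
    _chrom_key,
)

logger = logging.getLogger(__name__)

DIRECTIONS = ("high", "low", "none")


@dataclass(frozen=True)
class AssociationConfig:
    """Tunable parameters of the haplotype-association screen.

    q: upper percentile threshold on the reference phenotype distribution,
       in (0.5, 1). Default 0.866 (the 1.5-SD equivalent).
    min_carriers: minimum number of reference-panel carriers, default 5.
    impact_classes: annotation impacts treated as functional.
    sd_equivalent: the normal-SD reading of the default q (documentation).
    """

    q: float = 0.866
    min_carriers: int = 5
    impact_classes: frozenset = frozenset({"MODERATE", "HIGH"})
    sd_equivalent: float = 1.5

    def __post_init__(self) -> None:
        if not 0.5 < self.q < 1:
            raise ValueError(f"percentile q must be in (0.5, 1); got {self.q}")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


@dataclass(frozen=True)
class FunctionalHaplotype:
    gene_id: str
    chrom: str
    site_positions: tuple[int, ...]
    state_string: str
    carriers: frozenset

    def __post_init__(self) -> None:
        if len(self.state_string) != len(self.site_positions):
            raise ValueError("state string length != number of sites")
        if "1" not in self.state_string:
            raise ValueError("a functional haplotype needs >= 1 alternative allele")


@dataclass(frozen=True)
class HaplotypeAssociation:
    haplotype: FunctionalHaplotype
    carrier_count: int
    mean_phenotype: float
    t_hi: float
    t_lo: float
    direction: str


def filter_functional_sites(
    matrix: GenotypeMatrix,
    genes: Sequence[GeneRegion],
    config: AssociationConfig = AssociationConfig(),
) -> dict[str, list[int]]:
    """Site indices with a functional impact, grouped by gene.

    A site is kept when its impact class is in ``config.impact_classes``.
    It is assigned to the gene named by its annotation when that gene is in
    the gene list; otherwise to the first gene (in list order) whose
    [start, end] interval contains it. Sites falling in no gene are dropped.
    """
    by_id = {g.gene_id: g for g in genes}
    by_chrom: dict[str, list[GeneRegion]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    grouped: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    for i, site in enumerate(matrix.sites):
        if site.impact not in config.impact_classes:
            continue
        gene = None
        if site.gene_id and site.gene_id in by_id:
            cand = by_id[site.gene_id]
            if cand.contains(site.chrom, site.pos):
                gene = cand
        if gene is None:
            for cand in by_chrom.get(site.chrom, ()):
                if cand.start <= site.pos <= cand.end:
                    gene = cand
                    break
        if gene is not None:
            grouped[gene.gene_id].append(i)
    return {gid: sorted(idx, key=lambda i: matrix.sites[i].pos)
            for gid, idx in grouped.items() if idx}


def build_gene_haplotypes(
    gene: GeneRegion,
    site_indices: Sequence[int],
    matrix: GenotypeMatrix,
) -> list[FunctionalHaplotype]:
    """Pool accessions by their state string over the gene's functional sites.

    Accessions with a MISSING state at any of the sites contribute no
    haplotype for this gene; all-REF strings are not emitted (a functional
    haplotype carries at least one alternative allele).
    """
    if not site_indices:
        return []
    idx = sorted(site_indices, key=lambda i: matrix.sites[i].pos)
    positions = tuple(matrix.sites[i].pos for i in idx)
    sub = matrix.states[idx, :]
    pools: dict[str, list[str]] = {}
    for j, acc in enumerate(matrix.accessions):
        column = sub[:, j]
        if np.any(column == MISSING):
            continue
        if not np.any(column == ALT):
            continue
        key = "".join("1" if v == ALT else "0" for v in column)
        pools.setdefault(key, []).append(acc)
    return [
        FunctionalHaplotype(
            gene_id=gene.gene_id, chrom=gene.chrom, site_positions=positions,
            state_string=state, carriers=frozenset(carriers),
        )
        for state, carriers in sorted(pools.items())
    ]


def phenotype_thresholds(
    phenotypes: Sequence[float], q: float
) -> tuple[float, float]:
    """(T_hi, T_lo): linear-interpolation order-statistic quantiles at q, 1-q."""
    values = np.asarray(list(phenotypes), dtype=float)
    if len(np.unique(values)) < 2:
        raise ValueError("degenerate phenotype distribution (< 2 distinct values)")
    return float(np.quantile(values, q)), float(np.quantile(values, 1.0 - q))


def associate_haplotypes(
    haplotypes: Iterable[FunctionalHaplotype],
    phenotypes: Mapping[str, float],
    config: AssociationConfig = AssociationConfig(),
    thresholds: Optional[tuple[float, float]] = None,
) -> list[HaplotypeAssociation]:
    """Score each haplotype's carrier-mean phenotype against the panel quantiles.

    ``thresholds`` may be precomputed once per run (they depend only on the
    reference phenotype distribution, not on the haplotype under test).
    """
    if thresholds is None:
        thresholds = phenotype_thresholds(list(phenotypes.values()), config.q)
    t_hi, t_lo = thresholds
    out = []
    for hap in haplotypes:
        values = [phenotypes[a] for a in hap.carriers]
        mean = float(np.mean(values))
        count = len(values)
        direction = "none"
        if count >= config.min_carriers:
            if mean > t_hi:
                direction = "high"
            elif mean < t_lo:
                direction = "low"
        out.append(HaplotypeAssociation(
            haplotype=hap, carrier_count=count, mean_phenotype=mean,
            t_hi=t_hi, t_lo=t_lo, direction=direction,
        ))
    return out


def mine_genome(
    matrix: GenotypeMatrix,
    genes: Sequence[GeneRegion],
    phenotypes: Mapping[str, float],
    config: AssociationConfig = AssociationConfig(),
) -> list[HaplotypeAssociation]:
    """Full reference-panel screen: flagged (direction != none) associations.

    Accessions without a phenotype are excluded before both the quantile
    computation and haplotype construction. Genes are processed
    independently, so the result is invariant to gene order.
    """
    phenotyped = [a for a in matrix.accessions if a in phenotypes]
    if len(phenotyped) < matrix.n_accessions:
        logger.info("excluding %d accessions without phenotypes",
                    matrix.n_accessions - len(phenotyped))
        matrix = matrix.subset_accessions(phenotyped)
    thresholds = phenotype_thresholds(
        [phenotypes[a] for a in phenotyped], config.q
    )
    grouped = filter_functional_sites(matrix, genes, config)
    gene_by_id = {g.gene_id: g for g in genes}
    flagged: list[HaplotypeAssociation] = []
    by_chrom_count: dict[str, int] = {}
    for gene_id, site_idx in grouped.items():
        gene = gene_by_id[gene_id]
        haps = build_gene_haplotypes(gene, site_idx, matrix)
        assoc = associate_haplotypes(haps, phenotypes, config, thresholds)
        hits = [a for a in assoc if a.direction != "none"]
        flagged.extend(hits)
        by_chrom_count[gene.chrom] = by_chrom_count.get(gene.chrom, 0) + len(hits)
    for chrom in sorted(by_chrom_count, key=_chrom_key):
        logger.info("chromosome %s: %d flagged haplotypes", chrom, by_chrom_count[chrom])
    flagged.sort(key=lambda a: (
        _chrom_key(a.haplotype.chrom), a.haplotype.site_positions,
        a.haplotype.gene_id, a.haplotype.state_string,
    ))
    return flagged


def catalog_frame(associations: Iterable[HaplotypeAssociation]) -> pd.DataFrame:
    """Flat catalogue table (one row per flagged haplotype)."""
    rows = [{
        "gene_id": a.haplotype.gene_id,
        "chrom": a.haplotype.chrom,
        "site_positions": ",".join(str(p) for p in a.haplotype.site_positions),
        "state_string": a.haplotype.state_string,
        "carrier_count": a.carrier_count,
        "mean_phenotype": round(a.mean_phenotype, 6),
        "direction": a.direction,
        "T_hi": round(a.t_hi, 6),
        "T_lo": round(a.t_lo, 6),
        "carriers": ",".join(sorted(a.haplotype.carriers)),
    } for a in associations]
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "site_positions", "state_string", "carrier_count",
        "mean_phenotype", "direction", "T_hi", "T_lo", "carriers",
    ])


def read_catalog(path) -> pd.DataFrame:
    """Read a catalogue TSV, preserving leading zeros in state strings."""
    return pd.read_csv(
        path, sep="\t",
        dtype={"state_string": str, "site_positions": str, "carriers": str,
               "gene_id": str, "chrom": str},
    )


def associations_from_frame(frame: pd.DataFrame) -> list[HaplotypeAssociation]:
    """Inverse of catalog_frame (used when stages communicate via TSV)."""
    out = []
    for _, row in frame.iterrows():
        hap = FunctionalHaplotype(
            gene_id=row["gene_id"], chrom=row["chrom"],
            site_positions=tuple(int(p) for p in str(row["site_positions"]).split(",")),
            state_string=str(row["state_string"]),
            carriers=frozenset(str(row["carriers"]).split(",")) if row.get("carriers") else frozenset(),
        )
        out.append(HaplotypeAssociation(
            haplotype=hap, carrier_count=int(row["carrier_count"]),
            mean_phenotype=float(row["mean_phenotype"]),
            t_hi=float(row["T_hi"]), t_lo=float(row["T_lo"]),
            direction=str(row["direction"]),
        ))
    return out
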