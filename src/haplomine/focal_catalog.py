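"""Focal-panel cataloguing of flagged haplotypes.

Given the haplotypes flagged in the reference panel, this module searches a
focal breeding panel for exact carriers, splits presence among elite
cultivars (EC), non-focal varieties (NFV, e.g. landraces) and external
accessions, attributes likely geographic/variety-group origins from the
reference carriers, and builds the summary report tables.

Counting conventions:

* chromosome summaries count *genes* (a gene with several flagged haplotypes
  in the same direction counts once), while the catalogue lists every
  haplotype;
* "not among ECs" means absent from every EC; "unique to NFVs" additionally
  requires absence from external-origin focal accessions.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .io_formats import (
    ALT,
    MISSING,
    REF,
    AccessionRecord,
    GeneRegion,
    GenotypeMatrix,
    _chrom_key,
)
from .functional_haplotypes import FunctionalHaplotype, HaplotypeAssociation


@dataclass(frozen=True)
class CatalogEntry:
    association: HaplotypeAssociation
    ec_carriers: frozenset
    nfv_carriers: frozenset
    external_carriers: frozenset

    @property
    def focal_carriers(self) -> frozenset:
        return self.ec_carriers | self.nfv_carriers | self.external_carriers


@dataclass(frozen=True)
class ChromosomeSummaryRow:
    chrom: str
    total: int
    n_nfv: int
    n_nfv_unique: int
    n_nfv_not_ec: int

    def __post_init__(self) -> None:
        if not (self.n_nfv_unique <= self.n_nfv_not_ec <= self.n_nfv <= self.total):
            raise ValueError(
                f"{self.chrom}: summary counts violate "
                "n_nfv_unique <= n_nfv_not_ec <= n_nfv <= total"
            )


class CatalogResult(NamedTuple):
    entries: list[CatalogEntry]
    summary: list[ChromosomeSummaryRow]
    per_accession: pd.DataFrame


def match_focal(
    haplotype: FunctionalHaplotype, focal: GenotypeMatrix
) -> set[str]:
    """Focal accessions whose states at the haplotype's positions match exactly.

    A position absent from the focal matrix is REF for every focal accession
    (gVCF semantics); an accession MISSING at any position is a non-carrier.
    """
    rows = []
    for pos in haplotype.site_positions:
        rows.append(focal.site_index(haplotype.chrom, pos))
    carriers = set()
    for j, acc in enumerate(focal.accessions):
        match = True
        for row, want in zip(rows, haplotype.state_string):
            state = REF if row is None else int(focal.states[row, j])
            if state == MISSING or state != (ALT if want == "1" else REF):
                match = False
                break
        if match:
            carriers.add(acc)
    return carriers


def _role_map(records: Iterable[AccessionRecord]) -> dict[str, str]:
    roles = {}
    for rec in records:
        if rec.panel != "focal":
            continue
        role = rec.role
        if role not in ("EC", "NFV", "external"):
            warnings.warn(
                f"focal accession {rec.accession_id} has no role; treated as external"
            )
            role = "external"
        roles[rec.accession_id] = role
    return roles


def build_entries(
    associations: Iterable[HaplotypeAssociation],
    focal: GenotypeMatrix,
    records: Iterable[AccessionRecord],
) -> list[CatalogEntry]:
    roles = _role_map(records)
    entries = []
    for assoc in associations:
        carriers = match_focal(assoc.haplotype, focal)
        by_role: dict[str, set] = {"EC": set(), "NFV": set(), "external": set()}
        for acc in carriers:
            by_role[roles.get(acc, "external")].add(acc)
        entries.append(CatalogEntry(
            association=assoc,
            ec_carriers=frozenset(by_role["EC"]),
            nfv_carriers=frozenset(by_role["NFV"]),
            external_carriers=frozenset(by_role["external"]),
        ))
    return entries


def _gene_presence(
    entries: Iterable[CatalogEntry], direction: str
) -> dict[str, dict]:
    """Per-gene focal presence, pooling haplotypes of one direction."""
    genes: dict[str, dict] = {}
    for e in entries:
        if e.association.direction != direction:
            continue
        hap = e.association.haplotype
        g = genes.setdefault(hap.gene_id, {
            "chrom": hap.chrom, "ec": set(), "nfv": set(), "external": set(),
        })
        g["ec"] |= e.ec_carriers
        g["nfv"] |= e.nfv_carriers
        g["external"] |= e.external_carriers
    return genes


def chromosome_summary(
    entries: Iterable[CatalogEntry], direction: str = "high"
) -> list[ChromosomeSummaryRow]:
    """Gene-level per-chromosome presence counts for one direction."""
    genes = _gene_presence(entries, direction)
    per_chrom: dict[str, Counter] = {}
    for info in genes.values():
        any_focal = bool(info["ec"] or info["nfv"] or info["external"])
        if not any_focal:
            continue
        c = per_chrom.setdefault(info["chrom"], Counter())
        c["total"] += 1
        if info["nfv"]:
            c["n_nfv"] += 1
            if not info["ec"]:
                c["n_nfv_not_ec"] += 1
                if not info["external"]:
                    c["n_nfv_unique"] += 1
    return [
        ChromosomeSummaryRow(
            chrom=chrom, total=c["total"], n_nfv=c["n_nfv"],
            n_nfv_unique=c["n_nfv_unique"], n_nfv_not_ec=c["n_nfv_not_ec"],
        )
        for chrom, c in sorted(per_chrom.items(), key=lambda kv: _chrom_key(kv[0]))
    ]


def aggregate_table(rows: Sequence[ChromosomeSummaryRow]) -> ChromosomeSummaryRow:
    """Element-wise totals row over per-chromosome summary rows."""
    if not rows:
        raise ValueError("cannot aggregate an empty summary")
    return ChromosomeSummaryRow(
        chrom="Total",
        total=sum(r.total for r in rows),
        n_nfv=sum(r.n_nfv for r in rows),
        n_nfv_unique=sum(r.n_nfv_unique for r in rows),
        n_nfv_not_ec=sum(r.n_nfv_not_ec for r in rows),
    )


def summary_frame(rows: Sequence[ChromosomeSummaryRow], totals: bool = True) -> pd.DataFrame:
    rows = list(rows)
    if totals and rows:
        rows = rows + [aggregate_table(rows)]
    return pd.DataFrame(
        [{"chrom": r.chrom, "total": r.total, "n_nfv": r.n_nfv,
          "n_nfv_unique": r.n_nfv_unique, "n_nfv_not_ec": r.n_nfv_not_ec}
         for r in rows],
        columns=["chrom", "total", "n_nfv", "n_nfv_unique", "n_nfv_not_ec"],
    )


def per_accession_counts(
    entries: Iterable[CatalogEntry],
    records: Iterable[AccessionRecord],
    direction: str = "high",
) -> pd.DataFrame:
    """Flagged genes carried by each focal accession that no EC carries.

    Sorted by count descending, then accession id; accessions carrying none
    are omitted.
    """
    genes = _gene_presence(entries, direction)
    counts: Counter = Counter()
    for info in genes.values():
        if info["ec"]:
            continue
        for acc in info["nfv"] | info["external"]:
            counts[acc] += 1
    roles = _role_map(records)
    rows = [{"accession_id": acc, "role": roles.get(acc, "external"), "n_genes": n}
            for acc, n in counts.items()]
    frame = pd.DataFrame(rows, columns=["accession_id", "role", "n_genes"])
    return frame.sort_values(
        ["n_genes", "accession_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def classify_catalog(
    associations: Iterable[HaplotypeAssociation],
    focal: GenotypeMatrix,
    records: Iterable[AccessionRecord],
    direction: str = "high",
) -> CatalogResult:
    """Match flagged haplotypes to the focal panel and build summary tables."""
    records = list(records)
    entries = build_entries(associations, focal, records)
    return CatalogResult(
        entries=entries,
        summary=chromosome_summary(entries, direction),
        per_accession=per_accession_counts(entries, records, direction),
    )


def entries_frame(entries: Iterable[CatalogEntry]) -> pd.DataFrame:
    rows = [{
        "gene_id": e.association.haplotype.gene_id,
        "chrom": e.association.haplotype.chrom,
        "state_string": e.association.haplotype.state_string,
        "direction": e.association.direction,
        "carrier_count_ref": e.association.carrier_count,
        "mean_phenotype": round(e.association.mean_phenotype, 6),
        "n_ec": len(e.ec_carriers),
        "n_nfv": len(e.nfv_carriers),
        "n_external": len(e.external_carriers),
        "ec_carriers": ",".join(sorted(e.ec_carriers)),
        "nfv_carriers": ",".join(sorted(e.nfv_carriers)),
        "external_carriers": ",".join(sorted(e.external_carriers)),
    } for e in entries]
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "state_string", "direction", "carrier_count_ref",
        "mean_phenotype", "n_ec", "n_nfv", "n_external",
        "ec_carriers", "nfv_carriers", "external_carriers",
    ])


def attribute_origins(
    associations: Iterable[HaplotypeAssociation],
    reference_records: Iterable[AccessionRecord],
) -> pd.DataFrame:
    """Origin tallies over (variety_group, region) cells of the reference panel.

    record_count sums reference carriers of the flagged haplotypes falling in
    each cell; accession_count is the cell's size in the reference panel;
    rate = record_count / accession_count controls for sampling bias and is
    reported to one decimal.
    """
    ref = [r for r in reference_records if r.panel == "reference"]
    cell_of = {r.accession_id: (r.variety_group or "unknown", r.region or "unknown")
               for r in ref}
    cell_sizes: Counter = Counter(cell_of.values())
    record_counts: Counter = Counter()
    for assoc in associations:
        for acc in assoc.haplotype.carriers:
            if acc in cell_of:
                record_counts[cell_of[acc]] += 1
    rows = []
    for cell in sorted(cell_sizes):
        group, region = cell
        n_acc = cell_sizes[cell]
        n_rec = record_counts.get(cell, 0)
        rows.append({
            "variety_group": group, "region": region,
            "record_count": n_rec, "accession_count": n_acc,
            "rate": round(n_rec / n_acc, 1) if n_acc else 0.0,
        })
    return pd.DataFrame(rows, columns=[
        "variety_group", "region", "record_count", "accession_count", "rate",
    ])


_TOKEN = re.compile(r"[a-z0-9][a-z0-9'-]*")


def term_frequency(
    gene_ids: Iterable[str],
    goslim_map: Mapping[str, Sequence[str]],
    stoplist: Iterable[str] = (),
) -> pd.DataFrame:
    """Case-insensitive token counts over the genes' functional terms.

    Each GOSlim term is tokenised into lowercase words; tokens in the
    stoplist are removed; counts are sorted descending then alphabetically.
    """
    stop = {s.lower() for s in stoplist}
    counts: Counter = Counter()
    for gid in gene_ids:
        for term in goslim_map.get(gid, ()):
            for token in _TOKEN.findall(term.lower()):
                if token not in stop:
                    counts[token] += 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["term", "count"])


def chromosome_map(
    entries: Iterable[CatalogEntry], genes: Sequence[GeneRegion]
) -> pd.DataFrame:
    """Plot-ready per-gene map: midpoint position, direction, focal presence."""
    gene_by_id = {g.gene_id: g for g in genes}
    best: dict[tuple[str, str], dict] = {}
    for e in entries:
        hap = e.association.haplotype
        key = (hap.gene_id, e.association.direction)
        d = best.setdefault(key, {"ec": set(), "nfv": set()})
        d["ec"] |= e.ec_carriers
        d["nfv"] |= e.nfv_carriers | e.external_carriers
    rows = []
    for (gene_id, direction), d in sorted(best.items()):
        gene = gene_by_id.get(gene_id)
        if gene is None:
            continue
        if d["ec"] and d["nfv"]:
            found = "both"
        elif d["ec"]:
            found = "EC"
        elif d["nfv"]:
            found = "NFV"
        else:
            found = "reference_only"
        rows.append({
            "gene_id": gene_id, "chrom": gene.chrom,
            "midpoint": (gene.start + gene.end) // 2,
            "direction": direction, "found_in": found,
        })
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "midpoint", "direction", "found_in"])
    if len(frame):
        frame = frame.sort_values(
            ["chrom", "midpoint", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
    return frame
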