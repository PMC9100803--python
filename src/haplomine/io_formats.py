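"""Input/output layer: VCF panels, annotation impact parsing, tabular metadata,
NEXUS tree output.

All coordinates are 1-based inclusive (VCF / MSU gene-list convention).
Genotypes are collapsed to a three-state code per accession and site:

* ``REF`` (0) — homozygous reference, or the site is absent from that
  accession's file (gVCF semantics: an unlisted position is implicitly
  homozygous reference),
* ``ALT`` (1) — any genotype carrying at least one alternative allele
  (rice panels are predominantly inbred, so the heterozygote collapse
  loses little information),
* ``MISSING`` (2) — an explicit ``./.`` call.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

REF = 0
ALT = 1
MISSING = 2

#: snpEff impact classes ordered by severity (most severe first).
IMPACT_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}
UNANNOTATED = "unannotated"

PANELS = ("reference", "focal")
ROLES = ("EC", "NFV", "external", "none")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessionRecord:
    """Panel membership and phenotype for one accession."""

    accession_id: str
    panel: str = "reference"
    role: str = "none"
    variety_group: str = ""
    region: str = ""
    phenotype: Optional[float] = None

    def __post_init__(self) -> None:
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r} for {self.accession_id}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.accession_id}")
        if self.role == "none" and self.panel != "reference":
            raise ValueError(
                f"role 'none' is only permitted on the reference panel "
                f"({self.accession_id})"
            )


@dataclass(frozen=True)
class GeneRegion:
    """An annotated gene region, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    known_trait_gene: bool = False
    goslim_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: positions are 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    filter_status: str = "."
    impact: str = UNANNOTATED
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} is not 1-based")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)


def _chrom_key(chrom: str) -> tuple:
    """Natural sort key so chr2 sorts before chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class GenotypeMatrix:
    """Three-state genotype matrix, sites x accessions."""

    sites: list[VariantSite]
    accessions: list[str]
    states: np.ndarray  # int8, shape (n_sites, n_accessions)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sites), len(self.accessions)):
            raise ValueError("states shape does not match sites x accessions")
        self._site_index = {(s.chrom, s.pos): i for i, s in enumerate(self.sites)}
        self._acc_index = {a: j for j, a in enumerate(self.accessions)}
        if len(self._acc_index) != len(self.accessions):
            raise ValueError("duplicated accession id in matrix")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def site_index(self, chrom: str, pos: int) -> Optional[int]:
        return self._site_index.get((chrom, pos))

    def coverage(self) -> np.ndarray:
        """Per-site fraction of accessions with a non-missing state."""
        if self.n_accessions == 0:
            return np.zeros(self.n_sites)
        return 1.0 - (self.states == MISSING).mean(axis=1)

    def alt_frequency(self) -> np.ndarray:
        """Per-site ALT frequency among non-missing accessions (NaN if none)."""
        obs = (self.states != MISSING).sum(axis=1).astype(float)
        alt = (self.states == ALT).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs > 0, alt / obs, np.nan)

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._acc_index[a] for a in ids]
        return GenotypeMatrix(list(self.sites), list(ids), self.states[:, cols])

    def restrict_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], list(self.accessions), self.states[idx, :]
        )

    def sites_in_gene(self, gene: GeneRegion) -> list[int]:
        return [
            i for i, s in enumerate(self.sites)
            if gene.contains(s.chrom, s.pos)
        ]


# ---------------------------------------------------------------------------
# ANN impact parsing
# ---------------------------------------------------------------------------

def parse_ann_impact(info_field: Optional[str]) -> str:
    """Maximum-severity snpEff impact from a raw INFO string or ANN value.

    Accepts either a full semicolon-joined INFO string ("DP=30;ANN=...") or a
    bare ANN value. The impact sits in the third pipe-delimited subfield of
    each comma-separated ANN entry. Entries with fewer than three subfields
    are skipped with a warning. Returns "unannotated" when no ANN key exists.
    """
    if not info_field:
        return UNANNOTATED
    ann_value = None
    if "|" in info_field and "ANN=" not in info_field and ";" not in info_field:
        ann_value = info_field
    else:
        for kv in info_field.split(";"):
            if kv.startswith("ANN="):
                ann_value = kv[len("ANN="):]
                break
    if ann_value is None:
        return UNANNOTATED
    best = None
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < 3 or not fields[2]:
            warnings.warn(f"malformed ANN entry skipped: {entry!r}")
            continue
        impact = fields[2].strip()
        if impact not in IMPACT_SEVERITY:
            warnings.warn(f"unknown impact class skipped: {impact!r}")
            continue
        if best is None or IMPACT_SEVERITY[impact] > IMPACT_SEVERITY[best]:
            best = impact
    return best if best is not None else UNANNOTATED


def parse_ann_gene(info_field: Optional[str]) -> Optional[str]:
    """Gene id (subfield 5) of the maximum-severity ANN entry, if any."""
    if not info_field:
        return None
    ann_value = None
    for kv in info_field.split(";"):
        if kv.startswith("ANN="):
            ann_value = kv[len("ANN="):]
    if ann_value is None and "|" in info_field and ";" not in info_field:
        ann_value = info_field
    if ann_value is None:
        return None
    best_gene, best_sev = None, -1
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < 5 or fields[2] not in IMPACT_SEVERITY:
            continue
        sev = IMPACT_SEVERITY[fields[2]]
        if sev > best_sev and fields[4]:
            best_gene, best_sev = fields[4], sev
    return best_gene


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf_panel(
    paths: Sequence[str | Path],
    accession_ids: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """Read one or more (possibly per-accession) VCF files into a matrix.

    The site set is the union across files. For an accession whose file has
    no record at a site in the union, the state is REF (gVCF semantics);
    explicit ``./.`` genotypes are MISSING; any genotype with at least one
    alternative allele collapses to ALT.
    """
    per_file: list[tuple[list[str], dict]] = []
    seen_samples: set[str] = set()
    site_meta: dict[tuple[str, int], dict] = {}

    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"VCF file not found: {path}")
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
            raise OSError(f"unreadable VCF file {path}: {exc}") from exc
        samples = list(vcf.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        dup = seen_samples.intersection(samples)
        if dup:
            raise ValueError(f"duplicated accession id(s) across files: {sorted(dup)}")
        seen_samples.update(samples)

        calls: dict[tuple[str, int], np.ndarray] = {}
        for variant in vcf:
            key = (variant.CHROM, variant.POS)
            info_raw = _raw_info(variant)
            impact = parse_ann_impact(info_raw)
            gene_id = parse_ann_gene(info_raw)
            filt = variant.FILTER if variant.FILTER is not None else "PASS"
            alts = tuple(variant.ALT)
            meta = site_meta.get(key)
            if meta is None:
                site_meta[key] = {
                    "ref": variant.REF,
                    "alts": set(alts),
                    "impact": impact,
                    "gene_id": gene_id,
                    "filter": filt,
                }
            else:
                if meta["ref"] != variant.REF:
                    warnings.warn(
                        f"REF mismatch at {key[0]}:{key[1]} "
                        f"({meta['ref']} vs {variant.REF}); keeping first"
                    )
                meta["alts"].update(alts)
                if IMPACT_SEVERITY.get(impact, -1) > IMPACT_SEVERITY.get(meta["impact"], -1):
                    meta["impact"] = impact
                    if gene_id:
                        meta["gene_id"] = gene_id
                if meta["gene_id"] is None and gene_id:
                    meta["gene_id"] = gene_id
                if meta["filter"] in ("PASS", ".") and filt not in ("PASS", "."):
                    meta["filter"] = filt
            # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            gt = variant.gt_types
            states = np.full(len(samples), REF, dtype=np.int8)
            states[gt == 1] = ALT
            states[gt == 3] = ALT
            states[gt == 2] = MISSING
            calls[key] = states
        per_file.append((samples, calls))

    all_samples = [s for samples, _ in per_file for s in samples]
    if accession_ids is not None:
        missing_ids = set(accession_ids) - set(all_samples)
        if missing_ids:
            raise ValueError(f"accessions absent from VCF files: {sorted(missing_ids)}")

    keys = sorted(site_meta, key=lambda k: (_chrom_key(k[0]), k[1]))
    sites = [
        VariantSite(
            chrom=k[0],
            pos=k[1],
            ref_allele=site_meta[k]["ref"],
            alt_alleles=tuple(sorted(site_meta[k]["alts"])),
            filter_status=site_meta[k]["filter"],
            impact=site_meta[k]["impact"],
            gene_id=site_meta[k]["gene_id"],
        )
        for k in keys
    ]
    states = np.full((len(keys), len(all_samples)), REF, dtype=np.int8)
    col = 0
    for samples, calls in per_file:
        ncol = len(samples)
        for i, k in enumerate(keys):
            if k in calls:
                states[i, col:col + ncol] = calls[k]
        col += ncol
    matrix = GenotypeMatrix(sites, all_samples, states)
    if accession_ids is not None:
        matrix = matrix.subset_accessions(list(accession_ids))
    return matrix


def _raw_info(variant) -> str:
    """Reconstruct a semicolon-joined INFO string from a cyvcf2 variant."""
    parts = []
    for key, value in variant.INFO:
        if value is True:
            parts.append(str(key))
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as a plain-text multi-sample VCF 4.2 file.

    States round-trip at the REF/ALT/MISSING level: REF -> 0/0, ALT -> 1/1,
    MISSING -> ./. . An ANN INFO entry is emitted for annotated sites.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for chrom in sorted({s.chrom for s in matrix.sites}, key=_chrom_key):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID'\">"
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.accessions)
    )
    gt_code = {REF: "0/0", ALT: "1/1", MISSING: "./."}
    order = sorted(range(matrix.n_sites),
                   key=lambda i: (_chrom_key(matrix.sites[i].chrom), matrix.sites[i].pos))
    for i in order:
        s = matrix.sites[i]
        if s.impact != UNANNOTATED:
            gene = s.gene_id or ""
            info = f"ANN={s.alt_alleles[0]}|variant|{s.impact}|{gene}|{gene}|"
        else:
            info = "."
        row = [
            s.chrom, str(s.pos), ".", s.ref_allele, ",".join(s.alt_alleles),
            ".", s.filter_status, info, "GT",
        ] + [gt_code[int(v)] for v in matrix.states[i]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def merge_matrices(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Union-merge two matrices over disjoint accession sets.

    Sites absent from one panel are REF for that panel's accessions
    (gVCF semantics, as in read_vcf_panel).
    """
    overlap = set(a.accessions) & set(b.accessions)
    if overlap:
        raise ValueError(f"accessions present in both matrices: {sorted(overlap)}")
    keys = sorted(
        {(s.chrom, s.pos) for s in a.sites} | {(s.chrom, s.pos) for s in b.sites},
        key=lambda k: (_chrom_key(k[0]), k[1]),
    )
    by_key_a = {(s.chrom, s.pos): i for i, s in enumerate(a.sites)}
    by_key_b = {(s.chrom, s.pos): i for i, s in enumerate(b.sites)}
    sites, states = [], np.full(
        (len(keys), a.n_accessions + b.n_accessions), REF, dtype=np.int8
    )
    for row, k in enumerate(keys):
        ia, ib = by_key_a.get(k), by_key_b.get(k)
        template = a.sites[ia] if ia is not None else b.sites[ib]
        if ia is not None and ib is not None:
            sb = b.sites[ib]
            alts = tuple(sorted(set(template.alt_alleles) | set(sb.alt_alleles)))
            impact = max(template.impact, sb.impact,
                         key=lambda x: IMPACT_SEVERITY.get(x, -1))
            template = replace(template, alt_alleles=alts, impact=impact,
                               gene_id=template.gene_id or sb.gene_id)
        sites.append(template)
        if ia is not None:
            states[row, :a.n_accessions] = a.states[ia]
        if ib is not None:
            states[row, a.n_accessions:] = b.states[ib]
    return GenotypeMatrix(sites, list(a.accessions) + list(b.accessions), states)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def read_tables(
    phenotype_path: str | Path,
    metadata_path: str | Path,
    gene_path: str | Path,
) -> tuple[list[AccessionRecord], list[GeneRegion]]:
    """Read the phenotype, panel-metadata and gene-region TSVs."""
    records = read_accession_tables(phenotype_path, metadata_path)
    genes = read_gene_table(gene_path)
    return records, genes


def read_accession_tables(
    phenotype_path: str | Path, metadata_path: str | Path
) -> list[AccessionRecord]:
    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    _require(pheno, ["accession_id", "value"], phenotype_path)
    _require(meta, ["accession_id", "panel", "role"], metadata_path)

    phenotypes: dict[str, float] = {}
    pheno_extra: dict[str, dict] = {}
    for i, row in pheno.iterrows():
        try:
            value = float(row["value"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{phenotype_path}: non-numeric phenotype at row {i + 2}: "
                f"{row['value']!r}"
            )
        phenotypes[row["accession_id"]] = value
        pheno_extra[row["accession_id"]] = {
            "region": row.get("region", "") or "",
            "variety_group": row.get("variety_group", "") or "",
        }

    records: list[AccessionRecord] = []
    seen: set[str] = set()
    for _, row in meta.iterrows():
        acc = row["accession_id"]
        if acc in seen:
            raise ValueError(f"duplicated accession id in metadata: {acc}")
        seen.add(acc)
        role = (row.get("role") or "none").strip()
        role = role if role in ROLES else role.upper() if role.upper() in ROLES else "none"
        records.append(AccessionRecord(
            accession_id=acc,
            panel=(row.get("panel") or "reference").strip().lower(),
            role=role,
            variety_group=_cell(row, "variety_group"),
            region=_cell(row, "region"),
            phenotype=phenotypes.get(acc),
        ))
    for acc, value in phenotypes.items():
        if acc not in seen:
            warnings.warn(f"accession {acc} in phenotype table but not metadata")
            extra = pheno_extra[acc]
            records.append(AccessionRecord(
                accession_id=acc, panel="reference", role="none",
                variety_group=extra["variety_group"], region=extra["region"],
                phenotype=value,
            ))
    return records


def _cell(row, key) -> str:
    value = row.get(key)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value)


def _require(frame: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_gene_table(gene_path: str | Path) -> list[GeneRegion]:
    genes = pd.read_csv(gene_path, sep="\t", dtype=str)
    _require(genes, ["gene_id", "chrom", "start", "end"], gene_path)
    out: list[GeneRegion] = []
    seen: set[str] = set()
    for _, row in genes.iterrows():
        if row["gene_id"] in seen:
            raise ValueError(f"duplicated gene_id {row['gene_id']} in {gene_path}")
        seen.add(row["gene_id"])
        terms = _cell(row, "goslim_terms")
        known = _cell(row, "known_trait_gene").strip().lower() in ("1", "true", "yes")
        out.append(GeneRegion(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            known_trait_gene=known,
            goslim_terms=tuple(t.strip() for t in terms.split(";") if t.strip()),
        ))
    return out


def phenotype_map(records: Iterable[AccessionRecord]) -> dict[str, float]:
    """accession_id -> phenotype for records that have one."""
    return {r.accession_id: r.phenotype for r in records if r.phenotype is not None}


# ---------------------------------------------------------------------------
# NEXUS tree output
# ---------------------------------------------------------------------------

def newick_from_linkage(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string from a scipy linkage matrix.

    Leaf branch lengths equal the height of their first merge; internal
    branch lengths are differences of merge heights.
    """
    from scipy.cluster.hierarchy import to_tree

    linkage = np.asarray(linkage, dtype=float)
    n = len(labels)
    if n == 0:
        raise ValueError("empty tree: no labels")
    if len(set(labels)) != n:
        raise ValueError("duplicate labels in tree")
    if n == 1:
        return f"{_nexus_safe(labels[0])}:0.0;"
    root = to_tree(linkage)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_nexus_safe(labels[node.id])}:{length:.10g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = fmt(root.left, root.dist)
    right = fmt(root.right, root.dist)
    return f"({left},{right});"


def _nexus_safe(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_tree(
    linkage: np.ndarray, labels: Sequence[str], path: str | Path,
    tree_name: str = "ward",
) -> Path:
    """Write a hierarchical-clustering tree as a NEXUS TREES block."""
    newick = newick_from_linkage(linkage, labels)
    path = Path(path)
    taxlabels = " ".join(_nexus_safe(l) for l in labels)
    path.write_text(
        "#NEXUS\n"
        "BEGIN TAXA;\n"
        f"    DIMENSIONS NTAX={len(labels)};\n"
        f"    TAXLABELS {taxlabels};\n"
        "END;\n"
        "BEGIN TREES;\n"
        f"    TREE {tree_name} = {newick}\n"
        "END;\n"
    )
    return path
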