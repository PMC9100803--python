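"""Auxiliary diversity analyses.

Nucleotide diversity (pi) with rarefied panel comparison, QC SNP selection,
linkage-disequilibrium r-squared, Kimura-2-parameter distances with Ward
dendrograms, site-frequency spectra, and genotype-matrix export.

All statistics operate on the haploid ALT-presence collapse used by the
haplotype miner, so the diversity numbers are internally consistent with the
haplotype definitions. pi is normalised per site over the gene's full length
L (Nei-Li style), not per segregating site.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import (
    ALT,
    MISSING,
    REF,
    GeneRegion,
    GenotypeMatrix,
    VariantSite,
    _chrom_key,
)

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
VALID_BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """The K2P logarithm argument is non-positive (distance undefined)."""


@dataclass(frozen=True)
class DiversityResult:
    gene_id: str
    focal_pi: float
    rarefied_pis: tuple[float, ...]
    verdict: str  # reduced | elevated | indistinct

    @property
    def band(self) -> tuple[float, float]:
        arr = np.asarray(self.rarefied_pis)
        return float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5))


@dataclass(frozen=True)
class DistanceResult:
    p: float  # transition proportion
    q: float  # transversion proportion
    d: float  # K2P distance


@dataclass(frozen=True)
class LDPair:
    site_a: int
    site_b: int
    r2: float
    n_obs: int


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(states: np.ndarray, length: int) -> float:
    """Per-site pairwise diversity over a gene region of ``length`` bases.

    ``states`` is a (sites x accessions) three-state array; sites MISSING in
    either member of a pair are excluded for that pair; the mean pairwise
    Hamming difference is divided by the region length.
    """
    states = np.asarray(states)
    n = states.shape[1]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 accessions")
    if length < 1:
        raise ValueError("region length must be >= 1")
    if states.shape[0] == 0:
        return 0.0
    obs = (states != MISSING).astype(np.float64)
    alt_obs = (states == ALT) * obs
    ref_obs = obs - alt_obs
    # pairwise-complete Hamming differences via two matrix products
    diff = alt_obs.T @ ref_obs + ref_obs.T @ alt_obs
    total = diff[np.triu_indices(n, k=1)].sum()
    n_pairs = n * (n - 1) / 2
    return float(total / n_pairs / length)


def pi_from_frequencies(states: np.ndarray, length: int) -> float:
    """Frequency-form pi on complete data: sum over sites of 2p(1-p) n/(n-1), / L.

    Algebraically identical to the pairwise-Hamming definition when no state
    is missing; kept as an independent formulation for cross-checking.
    """
    states = np.asarray(states)
    n = states.shape[1]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 accessions")
    if np.any(states == MISSING):
        raise ValueError("frequency-form pi requires complete data")
    p = (states == ALT).mean(axis=1)
    return float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1) / length)


def rarefied_pi_comparison(
    focal_states: np.ndarray,
    pool_states: np.ndarray,
    length: int,
    gene_id: str = "",
    reps: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    sample_size: Optional[int] = None,
) -> DiversityResult:
    """Compare focal-panel pi against rarefied subsamples of a larger pool.

    ``reps`` seeded subsamples of ``sample_size`` (default: the focal panel
    size) accessions are drawn without replacement from the pool; the verdict
    is *reduced* if focal pi falls strictly below the empirical 2.5th
    percentile of the rarefied values, *elevated* above the 97.5th,
    *indistinct* otherwise.
    """
    focal_states = np.asarray(focal_states)
    pool_states = np.asarray(pool_states)
    n_focal = focal_states.shape[1]
    n_pool = pool_states.shape[1]
    if sample_size is None:
        sample_size = n_focal
    if n_pool < sample_size:
        raise ValueError(
            f"pool ({n_pool}) smaller than rarefaction sample size ({sample_size})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    focal_pi = nucleotide_diversity(focal_states, length)
    pis = []
    for _ in range(reps):
        cols = rng.choice(n_pool, size=sample_size, replace=False)
        pis.append(nucleotide_diversity(pool_states[:, cols], length))
    arr = np.asarray(pis)
    lo, hi = np.percentile(arr, 2.5), np.percentile(arr, 97.5)
    if focal_pi < lo:
        verdict = "reduced"
    elif focal_pi > hi:
        verdict = "elevated"
    else:
        verdict = "indistinct"
    return DiversityResult(
        gene_id=gene_id, focal_pi=focal_pi, rarefied_pis=tuple(pis), verdict=verdict,
    )


# ---------------------------------------------------------------------------
# QC SNP selection
# ---------------------------------------------------------------------------

def select_qc_snp(
    gene: GeneRegion,
    candidate_indices: Sequence[int],
    matrix: GenotypeMatrix,
) -> Optional[int]:
    """One representative SNP per gene, by QC rules then highest coverage.

    Rejects sites with coverage <= 0.80, minor-allele frequency < 0.05, more
    than two alleles, or a FILTER other than PASS/"." . Among survivors the
    highest-coverage site wins, ties broken by lowest position.
    """
    coverage = matrix.coverage()
    freq = matrix.alt_frequency()
    best: Optional[tuple[float, int, int]] = None
    for i in candidate_indices:
        site = matrix.sites[i]
        if not gene.contains(site.chrom, site.pos):
            continue
        if site.filter_status not in ("PASS", "."):
            continue
        if site.n_alleles > 2:
            continue
        if coverage[i] <= 0.80:
            continue
        p = freq[i]
        if np.isnan(p) or min(p, 1.0 - p) < 0.05:
            continue
        key = (-coverage[i], site.pos, i)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(
    a: np.ndarray, b: np.ndarray, site_a: int = 0, site_b: int = 0
) -> Optional[LDPair]:
    """Squared Pearson correlation of 0/1 dosages on pairwise-complete data.

    Returns None (logged) when either vector is constant over the complete
    pairs; raises when fewer than two complete observations remain.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    both = (a != MISSING) & (b != MISSING)
    n_obs = int(both.sum())
    if n_obs < 2:
        raise ValueError("fewer than 2 pairwise-complete observations")
    x = (a[both] == ALT).astype(float)
    y = (b[both] == ALT).astype(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("LD pair (%s, %s) skipped: monomorphic on complete subset",
                    site_a, site_b)
        return None
    r = np.corrcoef(x, y)[0, 1]
    return LDPair(site_a=site_a, site_b=site_b, r2=float(r * r), n_obs=n_obs)


def ld_table(
    matrix: GenotypeMatrix,
    site_indices: Sequence[int],
    high_ld: float = 0.8,
) -> pd.DataFrame:
    """All within-chromosome pairwise r2 among the given sites."""
    rows = []
    idx = sorted(site_indices, key=lambda i: (_chrom_key(matrix.sites[i].chrom),
                                              matrix.sites[i].pos))
    for i, j in combinations(idx, 2):
        si, sj = matrix.sites[i], matrix.sites[j]
        if si.chrom != sj.chrom:
            continue
        try:
            pair = ld_r2(matrix.states[i], matrix.states[j], si.pos, sj.pos)
        except ValueError:
            continue
        if pair is None:
            continue
        rows.append({
            "chrom": si.chrom, "pos_a": si.pos, "pos_b": sj.pos,
            "gene_a": si.gene_id or "", "gene_b": sj.gene_id or "",
            "r2": round(pair.r2, 6), "n_obs": pair.n_obs,
            "high_ld": pair.r2 > high_ld,
        })
    return pd.DataFrame(rows, columns=[
        "chrom", "pos_a", "pos_b", "gene_a", "gene_b", "r2", "n_obs", "high_ld",
    ])


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

def k2p_from_proportions(p: float, q: float) -> float:
    """Kimura-2-parameter distance d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined at P={p}, Q={q} (saturated)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(seq_a: str, seq_b: str) -> DistanceResult:
    """Pairwise K2P distance between two equal-length base strings.

    Positions where either base is outside ACGT are skipped; transitions are
    purine<->purine or pyrimidine<->pyrimidine differences, transversions the
    rest.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    compared = transitions = transversions = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in VALID_BASES or y not in VALID_BASES:
            continue
        compared += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    p = transitions / compared
    q = transversions / compared
    return DistanceResult(p=p, q=q, d=k2p_from_proportions(p, q))


def matrix_to_sequences(matrix: GenotypeMatrix) -> dict[str, str]:
    """Expand REF/ALT states to base strings (MISSING -> N)."""
    chars = np.empty((matrix.n_sites, matrix.n_accessions), dtype="U1")
    for i, site in enumerate(matrix.sites):
        alt = site.alt_alleles[0] if site.alt_alleles else "N"
        row = matrix.states[i]
        chars[i][row == REF] = site.ref_allele
        chars[i][row == ALT] = alt
        chars[i][row == MISSING] = "N"
    return {acc: "".join(chars[:, j]) for j, acc in enumerate(matrix.accessions)}


def k2p_matrix(sequences: dict[str, str]) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Symmetric K2P distance matrix; undefined pairs returned separately.

    Vectorised over all accession pairs: transition/transversion counts are
    one-hot matrix products, giving results identical to per-pair
    :func:`k2p_distance` (asserted in the test suite).
    """
    labels = list(sequences)
    n = len(labels)
    if n == 0:
        raise ValueError("no sequences")
    length = len(next(iter(sequences.values())))
    codes = np.full((n, length), 4, dtype=np.uint8)
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i, label in enumerate(labels):
        seq = sequences[label].upper()
        if len(seq) != length:
            raise ValueError("sequences must have equal length")
        codes[i] = [lookup.get(ch, 4) for ch in seq]
    onehot = [(codes == c).astype(np.float64) for c in range(4)]
    a, c, g, t = onehot
    valid = (codes < 4).astype(np.float64)
    compared = valid @ valid.T
    transitions = a @ g.T + g @ a.T + c @ t.T + t @ c.T
    purines, pyrimidines = a + g, c + t
    transversions = purines @ pyrimidines.T + pyrimidines @ purines.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = transitions / compared
        q = transversions / compared
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        dist = np.where(
            (compared > 0) & (w1 > 0) & (w2 > 0),
            -0.5 * np.log(np.where((w1 > 0) & (w2 > 0), w1 * np.sqrt(np.abs(w2)), 1.0)),
            np.nan,
        )
    np.fill_diagonal(dist, 0.0)
    undefined = [
        (labels[i], labels[j])
        for i, j in zip(*np.nonzero(np.triu(np.isnan(dist), k=1)))
    ]
    return pd.DataFrame(dist, index=labels, columns=labels), undefined


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_dendrogram(distance: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, int]:
    """Ward's minimum-variance agglomeration of a precomputed distance matrix.

    Returns the scipy linkage matrix and a suggested cluster count: the cut
    below the largest gap between successive merge heights. A dendrogram
    whose merges are all at (numerically) zero height suggests one cluster.
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    bad = np.argwhere(~np.isfinite(d))
    if len(bad):
        pairs = [(int(i), int(j)) for i, j in bad if i < j]
        raise ValueError(f"undefined distance entries at index pairs {pairs}")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    z = linkage(squareform(d, checks=False), method="ward")
    heights = z[:, 2]
    tiny = 1e-12
    suggested = 1
    if heights[-1] > tiny and len(heights) > 1:
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))
        if gaps[i] > tiny:
            suggested = n - (i + 1)
    elif heights[-1] > tiny:
        suggested = 2
    return z, suggested


def cluster_assignments(z: np.ndarray, labels: Sequence[str], k: int) -> pd.DataFrame:
    assign = fcluster(z, t=k, criterion="maxclust")
    return pd.DataFrame({"accession_id": list(labels), "cluster": assign})


# ---------------------------------------------------------------------------
# site-frequency spectrum
# ---------------------------------------------------------------------------

def sfs(matrix: GenotypeMatrix) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Histograms of ALT carrier counts, per chromosome and genome-wide.

    Bin k (1..n accessions) holds the number of sites with exactly k ALT
    carriers among non-missing accessions; sites with zero ALT carriers fall
    in no bin. The genome-wide histogram is the sum over chromosomes.
    """
    if matrix.n_sites == 0:
        raise ValueError("SFS needs at least one site")
    n = matrix.n_accessions
    alt_counts = (matrix.states == ALT).sum(axis=1)
    per_chrom: dict[str, np.ndarray] = {}
    for i, site in enumerate(matrix.sites):
        hist = per_chrom.setdefault(site.chrom, np.zeros(n + 1, dtype=int))
        k = int(alt_counts[i])
        if k >= 1:
            hist[k] += 1
    genome = np.zeros(n + 1, dtype=int)
    for hist in per_chrom.values():
        genome += hist
    ordered = {c: per_chrom[c] for c in sorted(per_chrom, key=_chrom_key)}
    return ordered, genome


def sfs_frame(hist: np.ndarray) -> pd.DataFrame:
    ks = np.arange(1, len(hist))
    return pd.DataFrame({"alt_carriers": ks, "n_sites": hist[1:]})


# ---------------------------------------------------------------------------
# genotype-matrix export
# ---------------------------------------------------------------------------

def export_genotype_matrix(
    matrix: GenotypeMatrix, path: str | Path, fmt: str = "binary_nexus"
) -> Path:
    """Write a 0/1 character matrix (NEXUS DATA block or TSV).

    Only biallelic sites are exportable; a multi-allelic site raises with the
    offending position. MISSING states become '?' (NEXUS) / '.' (TSV).
    """
    for site in matrix.sites:
        if site.n_alleles > 2:
            raise ValueError(
                f"multi-allelic site {site.chrom}:{site.pos} cannot be exported"
            )
    path = Path(path)
    if fmt == "binary_nexus":
        code = {REF: "0", ALT: "1", MISSING: "?"}
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.n_accessions} NCHAR={matrix.n_sites};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "    MATRIX",
        ]
        for j, acc in enumerate(matrix.accessions):
            row = "".join(code[int(v)] for v in matrix.states[:, j])
            lines.append(f"    {acc}  {row}")
        lines += ["    ;", "END;"]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "plain_tsv":
        code = {REF: "0", ALT: "1", MISSING: "."}
        header = ["chrom", "pos", "ref", "alt"] + list(matrix.accessions)
        lines = ["\t".join(header)]
        for i, site in enumerate(matrix.sites):
            alt = site.alt_alleles[0] if site.alt_alleles else "."
            row = [site.chrom, str(site.pos), site.ref_allele, alt]
            row += [code[int(v)] for v in matrix.states[i]]
            lines.append("\t".join(row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read back a plain_tsv export (round-trip helper)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    accessions = list(frame.columns[4:])
    sites = []
    states = np.zeros((len(frame), len(accessions)), dtype=np.int8)
    code = {"0": REF, "1": ALT, ".": MISSING}
    for i, row in frame.iterrows():
        sites.append(VariantSite(
            chrom=row["chrom"], pos=int(row["pos"]),
            ref_allele=row["ref"],
            alt_alleles=(row["alt"],) if row["alt"] != "." else (),
        ))
        states[i] = [code[row[a]] for a in accessions]
    return GenotypeMatrix(sites, accessions, states)
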