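# Methods

## Haplotype model and association rule

An accession's functional haplotype for a gene is the ordered 0/1 string of
reference/alternative alleles over the gene's functional SNPs — those whose
snpEff-style annotation impact is MODERATE or HIGH (severity order
HIGH > MODERATE > LOW > MODIFIER; the maximum severity across a site's ANN
entries is used). A haplotype must contain at least one alternative allele;
all-reference accessions carry no haplotype for that gene. Each accession
carries at most one haplotype per gene, and an accession with a missing call
at any of a gene's functional sites contributes no haplotype for that gene
(imputing reference for an explicitly failed call would fabricate
haplotypes; truly absent records are already reference under gVCF
semantics).

Genotypes are collapsed to haploid presence states: any genotype containing
an alternative allele is ALT, `./.` is MISSING, everything else (including a
record absent from a per-accession gVCF-style file) is REF. Rice and most
inbreeding crops are nearly homozygous, so the heterozygote collapse loses
little information; it also makes haplotype identity well defined without
phasing. Multi-allelic sites are retained at read time (the QC rules need
the allele count) but collapse to the same ALT state in haplotypes.

A haplotype is associated with an extreme phenotype when its carrier count
is at least `min_carriers` (default 5) and its carrier-mean phenotype falls
strictly above the `q` quantile — or strictly below the `1−q` quantile — of
the accession-level phenotype distribution of the reference panel. Both
directions are always recorded. Quantiles are linear-interpolation order
statistics (`numpy.quantile` default), computed once per run over all
phenotyped reference accessions; accessions without a phenotype are excluded
from both the quantile and the carrier means. The default `q = 0.866`
corresponds to 1.5 standard deviations from the mean of a normal
distribution (two-sided coverage 2Φ(1.5)−1 ≈ 0.866). A conventional 0.975
threshold is deliberately not the default: the tested statistic is a mean
over ≥ 5 carriers, whose distribution is much tighter than the accession
distribution, so a 0.975 cut would flag almost nothing. No multiple-testing
correction is applied across the (potentially tens of thousands of) genes;
the output is a screening catalogue and downstream users should treat
individual flags accordingly.

Raising `q` or `min_carriers` can only shrink the flagged set
(monotonicity), which the test suite asserts.

## Focal cataloguing

A focal accession carries a flagged haplotype only on an exact match of the
full allele pattern at the haplotype's positions; a position absent from the
focal call set is reference (gVCF rule) and a missing call at any position
disqualifies the accession for that haplotype. Chromosome summaries count
*genes* (a gene with several flagged haplotypes in one direction counts
once): genes present in any focal accession, present in ≥ 1 NFV, present in
NFVs but absent from every EC, and unique to NFVs (additionally absent from
external-origin focal accessions). By construction
`n_nfv_unique ≤ n_nfv_not_ec ≤ n_nfv ≤ total`, enforced at row construction.
Per-accession counts list, for each focal accession, the flagged genes it
carries that no EC carries. Origin tallies count reference carriers per
(variety group, geographic region) cell, divided by the cell's panel size to
control sampling bias; rates are reported to one decimal, per-accession
means to two.

## Reference sub-panel selection

Within every (region × variety group) cell of the phenotyped pool, the
accessions with maximal and minimal phenotype are selected and unioned with
an always-kept core list. Ties go to the lexicographically smallest
accession id, making selection independent of row order. Accessions with a
missing region or group fall into an ("unknown", "unknown") cell rather than
being dropped. Region merging (e.g. treating Europe and the Middle East as
one region) is left to the metadata preparer.

## Diversity statistics

**Nucleotide diversity.** π = (mean pairwise Hamming difference between
haploid-collapsed accession sequences, with sites missing in either member
of a pair excluded for that pair) divided by the gene length L. The
per-length (not per-segregating-site) normalisation keeps π comparable
across genes and consistent with the gene-region framing of the haplotypes.
On complete data this equals the frequency form Σ 2p(1−p)·n/(n−1)/L — an
algebraic identity the tests assert numerically to 1e−12. Implementation is
two matrix products (pairwise-complete Hamming counts), so rarefaction is
cheap.

**Rarefaction.** Because π is sample-size sensitive, a focal panel's π is
compared against `reps` (default 100) subsamples of the focal panel's size
drawn without replacement from a larger reference pool. The verdict is
*reduced*/*elevated* when focal π falls strictly outside the empirical
2.5–97.5 percentile band of the rarefied values, else *indistinct*. The
band is empirical because the rarefied distribution is discrete and skewed;
no normal approximation is used. The library function requires
pool ≥ sample size; the pipeline caps the sample size at
min(|focal|, |pool|) with a warning when the mining reference panel is
smaller than the focal panel, and records the size used.

**QC SNP selection.** One SNP per gene: reject sites with coverage ≤ 0.80,
minor-allele frequency < 0.05, more than two alleles, or any FILTER other
than PASS/`.`; among survivors keep the highest-coverage site, ties broken
by lowest position. Coverage is evaluated on the focal library (the
reference library is assumed high quality).

**Linkage disequilibrium.** r² is the squared Pearson correlation of 0/1
dosages on pairwise-complete observations — the standard SNP-matrix
formulation, equal to D²/(p₁q₁p₂q₂) on haploid data (asserted in tests).
Pairs monomorphic on the complete subset are skipped with a log entry. LD
is computed within a single variety group (default *indica*) to avoid
mixing the distinct LD structure of diverged groups, and only within
chromosomes. Pairs with r² > 0.8 are flagged in the output table.

**K2P distances and Ward tree.** Sequences are rebuilt from the matrix
(REF/ALT expanded to actual bases, MISSING → N); positions with a non-ACGT
base in either sequence are skipped. With transition proportion P and
transversion proportion Q, d = −½ ln((1−2P−Q)·√(1−2Q)), undefined
(saturated) when either logarithm argument is non-positive; saturated pairs
are reported and the affected accessions dropped from clustering with a
warning. The full distance matrix is computed with one-hot matrix products;
the per-pair route is kept and the two are asserted equal. The dendrogram
uses Ward's minimum-variance criterion (scipy linkage on the precomputed
distances; an independent O(n³) Lance–Williams implementation serves as the
test oracle). The tree is often loosely called a neighbour-joining tree in
this application area; what is built here is exactly Ward agglomeration.
The suggested cluster count cuts below the **largest absolute gap** between
successive merge heights. A relative (ratio) gap was considered and
rejected: panels with duplicate sequences produce many zero-height merges,
making the first positive height an infinite relative gap and suggesting
nearly as many clusters as accessions. An all-zero dendrogram suggests one
cluster.

**Site-frequency spectrum.** Bin k holds the number of sites with exactly k
ALT carriers among non-missing accessions (k ≥ 1), per chromosome and
genome-wide (the sum). The binary NEXUS/TSV genotype export covers
biallelic sites only and errors on multi-allelic input, naming the site.

## Synthetic panels

The generator emulates the pipeline's inputs at desk scale. Defaults mirror
the study design the tool targets: a 200-accession phenotyped reference
panel; a 279-accession focal panel of 35 ECs, 190 NFVs and 54
external-origin accessions; trait values Normal(8.0, 1.0) (a grain-length-
like trait in mm); per-site ALT frequency 0.15; missing-call rate 0.02;
impact mix 10% HIGH / 30% MODERATE / 30% LOW / 30% MODIFIER; 20 genes × 6
sites on 2 chromosomes (full-genome gene counts are not desk-tractable and
add nothing to the logic under test). Planted haplotypes are the all-ALT
pattern over a gene's functional sites; reference carriers receive a
phenotype shift of `effect_sd` trait SDs, and the pattern is copied into a
configurable number of focal NFV (and optionally EC) accessions. So that
the truth table is exact, a chance all-ALT pattern in any non-designated
accession is perturbed at one site, and designated carriers are kept
non-missing at the planted sites. Everything is drawn from a single
`numpy.random.default_rng(seed)`, and file formatting is fixed, so equal
configs give byte-identical outputs.

What the generator does *not* emulate: linkage structure between sites
(sites are independent draws), recombination maps, population structure in
the genotypes (variety groups and regions are labels, not genetic clusters),
indels, and real annotation pipelines (impacts are sampled labels). Tests
passing on these panels therefore validate the bookkeeping, thresholds and
statistics — not robustness to the correlation structure of real panels.

## Pipeline and determinism

`run_all` executes selection → mining → focal matching → diversity →
manifest; stages communicate only via files in the output directory and no
stage mutates its inputs. The manifest records input file names, parameter
values, the seed, the package version and per-stage row counts. All
randomness (rarefaction subsampling) flows from the one seed, so identical
configuration and seed reproduce every output byte for byte. Any stage
failure aborts the run naming the stage. Exit codes: 0 success, 2 input
validation, 1 otherwise.

## Known limitations

- The association screen has no kinship/structure correction and no
  multiple-testing control; it is a catalogue builder, not a GWAS.
- Exact-match focal search means a single discordant or missing call hides a
  carrier; there is no fuzzy matching.
- The haploid collapse discards heterozygote information; panels of
  outcrossing species would need a different genotype model.
- π, LD and K2P all operate on the collapsed states/called bases; they are
  internally consistent but not substitutes for sequence-level estimators on
  heterozygous data.
- The cluster-count suggestion is a height-gap heuristic, not a model-based
  estimate.
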