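# haplomine

Functional-haplotype mining and cataloguing for phenotyped crop breeding
panels.

National breeding programs typically hold a small core of elite cultivars
(ECs) and a much larger collection of landraces and other non-focal varieties
(NFVs). `haplomine` addresses a practical question for such programs: *which
gene-level haplotypes, known from a large phenotyped reference panel to
associate with extreme values of a trait (say, grain length), are present in
the local panel — and are they already in the elite core, or sitting
overlooked in the landraces?* No local phenotyping experiment is required:
the association is computed once on the reference panel and the local panel
is only searched for carriers.

## Method

For every annotated gene region, the *functional haplotype* of an accession
is its pattern of reference/alternative alleles across the gene's
moderate- or high-impact SNPs (snpEff-style ANN annotations), with at least
one alternative allele. Genotypes are collapsed to haploid presence calls
(any ALT allele ⇒ ALT), appropriate for predominantly inbred panels, and
per-accession variant files follow gVCF semantics (an absent record is
homozygous reference; an explicit `./.` is missing).

For a haplotype *h* with carrier set *C(h)* in the reference panel, let
μ_h = mean trait value over *C(h)*, and let T_hi, T_lo be the q and 1−q
linear-interpolation quantiles of the accession-level trait distribution.
The haplotype is flagged

- **high** if |C(h)| ≥ m and μ_h > T_hi,
- **low**  if |C(h)| ≥ m and μ_h < T_lo,

with defaults q = 0.866 (the two-sided normal coverage at 1.5 SD,
2Φ(1.5)−1 ≈ 0.866) and m = 5 carriers. Flagged haplotypes are then matched
exactly (same allele pattern at the same positions) against the focal panel
and tabulated by chromosome: genes found in any focal accession, in ≥ 1 NFV,
in NFVs but no EC, and uniquely in NFVs. The deliberately mild threshold and
the absence of multiple-testing control make this a screening catalogue, not
a set of calibrated hypothesis tests.

Supporting analyses: per-gene nucleotide diversity π (mean pairwise per-site
difference over the gene length) with rarefied pool comparison; per-gene QC
SNP selection (coverage > 80%, MAF ≥ 5%, biallelic, PASS); LD r² among QC
SNPs within one variety group; Kimura-2-parameter distances with Ward
clustering and NEXUS tree output; site-frequency spectra; and a binary
NEXUS/TSV genotype export. A seeded synthetic-panel generator with planted
effect haplotypes makes every stage testable end to end.

## Worked example

```sh
python examples/mine_and_catalog.py
```

simulates a 60-accession reference panel and a 32-accession focal panel with
one planted haplotype (+3 SD effect, 8 reference carriers, copied into 3
NFVs) and prints:

```
flagged haplotypes (carrier-mean phenotype beyond the 0.866 quantile,
>= 5 reference carriers):
gene_id state_string  carrier_count  mean_phenotype direction     T_hi
   g002          111              8        11.48359      high 10.53415

per-chromosome gene counts in the focal panel
(total / in NFVs / unique to NFVs / absent from all ECs):
chrom  total  n_nfv  n_nfv_unique  n_nfv_not_ec
 chr2      1      1             1             1
Total      1      1             1             1
```

The planted gene (`g002`, all-ALT pattern `111` over its three functional
sites) is the only flag: its 8 carriers average 11.48 mm against an upper
threshold of 10.53 mm, and in the focal panel it is carried only by NFVs —
exactly the "useful variation sitting outside the elite core" the catalogue
is meant to surface. `examples/diversity_overview.py` and
`examples/relatedness_tree.py` demonstrate the diversity analyses.

The same workflow runs from the shell:

```sh
haplomine simulate --config sim.yaml --outdir panel/
haplomine all --ref-vcf-dir panel/ref_vcf --focal-vcf-dir panel/focal_vcf \
    --phenotypes panel/phenotypes.tsv --metadata panel/metadata.tsv \
    --genes panel/genes.tsv --seed 7 --outdir results/
```

writing `catalog.tsv`, `table1_summary.tsv`, `table2_accessions.tsv`,
`origins.tsv`, `term_counts.tsv`, the diversity tables, `tree.nex` and a
`manifest.json` recording inputs, parameters, seed and per-stage counts.
Identical inputs and seed give byte-identical outputs.

## Layout

- `src/haplomine/io_formats.py` — VCF panels (cyvcf2), ANN impact parsing,
  metadata/gene tables, NEXUS output
- `src/haplomine/reference_selector.py` — per-region × variety-group
  phenotypic-extreme selection of the reference sub-panel
- `src/haplomine/functional_haplotypes.py` — the miner
- `src/haplomine/focal_catalog.py` — focal matching, EC/NFV classification,
  origin tallies, term counts, report tables
- `src/haplomine/diversity_stats.py` — π, rarefaction, QC SNPs, LD, K2P,
  Ward, SFS, exports
- `src/haplomine/synthetic.py` — seeded panel generator with planted effects
- `src/haplomine/pipeline.py`, `src/haplomine/cli.py` — orchestration and
  the `haplomine` command

See `docs/methods.md` for the statistical conventions, parameter defaults
and known limitations.
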