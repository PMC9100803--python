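import numpy as np
import pytest

from haplomine.io_formats import (
    ALT,
    MISSING,
    REF,
    GeneRegion,
    GenotypeMatrix,
    VariantSite,
)
from haplomine.synthetic import PlantedHaplotype, SimulationConfig, simulate_panel


def make_site(pos, chrom="chr1", impact="MODERATE", ref="A", alt="G",
              filt="PASS", gene_id=None, alts=None):
    return VariantSite(
        chrom=chrom, pos=pos, ref_allele=ref,
        alt_alleles=alts if alts is not None else (alt,),
        filter_status=filt, impact=impact, gene_id=gene_id,
    )


def make_matrix(states, positions=None, accessions=None, chrom="chr1", **site_kw):
    states = np.asarray(states, dtype=np.int8)
    n_sites, n_acc = states.shape
    if positions is None:
        positions = [100 + 10 * i for i in range(n_sites)]
    if accessions is None:
        accessions = [f"a{j + 1}" for j in range(n_acc)]
    sites = [make_site(p, chrom=chrom, **site_kw) for p in positions]
    return GenotypeMatrix(sites, list(accessions), states)


@pytest.fixture(scope="session")
def planted_panel():
    """One planted high-effect gene (+3 SD, 8 reference carriers, 4 NFV copies)."""
    config = SimulationConfig(
        seed=11,
        planted=(PlantedHaplotype(gene_index=2, effect_sd=3.0, n_ref_carriers=8,
                                  n_focal_nfv=4),),
    )
    return simulate_panel(config)


@pytest.fixture(scope="session")
def small_panel_files(tmp_path_factory):
    """A small simulated panel written to disk (shared by CLI/pipeline tests)."""
    from haplomine.synthetic import generate_panel

    outdir = tmp_path_factory.mktemp("panel")
    config = SimulationConfig(
        seed=7, n_ref=60, n_focal_ec=8, n_focal_nfv=20, n_focal_external=4,
        n_genes=8, sites_per_gene=4,
        planted=(PlantedHaplotype(gene_index=1, effect_sd=3.0, n_ref_carriers=8,
                                  n_focal_nfv=3),),
    )
    paths = generate_panel(config, outdir)
    paths["config"] = config
    return paths
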