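import numpy as np
import pandas as pd
import pytest

from locus2gene.syndata import (
    PlantedArchitecture,
    derive_annotation,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas,
    uniform_layout,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-individual cohort with one shared locus and one mediation chain.

    chrom 1: cis gene with a planted eQTL that is also the GWAS causal variant
    chrom 2: mediator gene whose cis variant drives three trans targets
    """
    layout = (
        uniform_layout(30, chrom="1", start=1_000_000, spacing=20_000, maf=0.3)
        + uniform_layout(30, chrom="2", start=1_000_000, spacing=20_000, maf=0.4)
    )
    blocks = [(0, 15, 25), (15, 30, 25), (30, 45, 25), (45, 60, 25)]
    geno = simulate_genotypes(500, layout, blocks, seed=11)
    v_cis = geno.variants.iloc[7]["variant_id"]      # chrom 1, block 1
    v_med = geno.variants.iloc[37]["variant_id"]     # chrom 2, block 3
    arch = PlantedArchitecture(
        cis_effects={"geneA": (v_cis, 0.9), "mediator": (v_med, 0.9)},
        mediation_chains=[
            ("mediator", f"targ{i}", 0.8) for i in range(3)
        ],
        gwas_causal=[(v_cis, 0.9), (v_med, 0.9)],
        shared_flags={"locus1": "shared", "locus2": "shared"},
        de_target_set=["targ0", "targ1", "targ2"],
        background_genes=[f"bg{i}" for i in range(5)],
    )
    expr = simulate_expression(geno, arch, noise_sd=0.8, seed=12)
    annotation = derive_annotation(arch, geno)
    gwas = simulate_gwas(geno, arch.gwas_causal, prevalence_threshold=0.5, seed=13)
    return {
        "geno": geno,
        "arch": arch,
        "expr": expr,
        "annotation": annotation,
        "gwas": gwas,
        "v_cis": v_cis,
        "v_med": v_med,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
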