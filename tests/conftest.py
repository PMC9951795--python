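import numpy as np
import pytest

from metagrs import (ArchitectureConfig, run_gwas, simulate_effect_matrix,
                     simulate_genotypes, simulate_phenotypes)
from metagrs.grs import ld_block_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """One reusable single-trait cohort: genotypes, effects, phenotypes,
    disease GWAS summary statistics, and the LD block matrix."""
    cfg = ArchitectureConfig(n_traits=1, h2=np.array([0.4]), rg=np.eye(1),
                             causal_fraction=0.5, prevalence=0.08, seed=11)
    geno = simulate_genotypes(1500, 120, 12, (0.1, 0.5),
                              within_block_r=np.tile([0.0, 0.4, 0.8], 4),
                              seed=11)
    effects = simulate_effect_matrix(geno.variants, cfg)
    phen = simulate_phenotypes(geno, effects, cfg, seed=11)
    sumstats = run_gwas(geno, phen.traits[:, 0])
    sumstats.trait = "t0"
    return {
        "config": cfg,
        "genotypes": geno,
        "effects": effects,
        "phenotypes": phen,
        "sumstats": sumstats,
        "ld": ld_block_matrix(geno),
    }
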