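import numpy as np
import pytest

import metgp as mg


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return mg.SimulationConfig(
        n_parents=12,
        n_hybrids=30,
        n_markers=120,
        n_environments=4,
        variance_components={"A": 1.0, "D": 0.5, "residual": 1.0},
        seed=7,
    )


@pytest.fixture
def small_genotypes(small_config):
    return mg.maf_filter(mg.simulate_genotypes(small_config))


@pytest.fixture
def small_dataset(small_config, small_genotypes):
    """Genotypes, kernels, scaled W and phenotypes for a small trial."""
    geno = small_genotypes
    weather = mg.simulate_weather(small_config)
    W = mg.scale_and_qc(mg.summarize_interval_percentiles(weather))
    K_A = mg.gb_kernel(mg.additive_design(geno), labels=geno.hybrid_ids)
    K_D = mg.gb_kernel(mg.dominance_design(geno), labels=geno.hybrid_ids)
    K_W = mg.env_kernel(W, "GB")
    pheno, truth = mg.simulate_phenotypes(geno, small_config, K_A, K_D, K_W)
    return {
        "config": small_config,
        "genotypes": geno,
        "W": W,
        "K_A": K_A,
        "K_D": K_D,
        "K_W": K_W,
        "phenotypes": pheno,
        "truth": truth,
    }


@pytest.fixture
def quick_mcmc():
    return mg.McmcConfig(iterations=600, burn_in=200, thin=2, seed=11)
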