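import numpy as np
import pytest

import polyblup as pb


@pytest.fixture(scope="session")
def tetra_pop():
    """Medium tetraploid population for relationship-matrix checks."""
    return pb.sim_population(200, 800, ploidy=4, seed=42)


@pytest.fixture(scope="session")
def dom_fit():
    """Small end-to-end directional-dominance Stage-2 fit (shared)."""
    ms = pb.sim_population(100, 400, ploidy=4, seed=101)
    truth = pb.sim_genetic_values(ms, sigma2_A=1.0, sigma2_D=0.3,
                                  mu_beta=0.01, sigma2_gE=0.5, seed=102)
    _, s1 = pb.sim_phenotypes(ms, truth, n_envs=3, seed=103)
    fit = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-dominance"), geno=ms)
    return ms, truth, s1, fit


@pytest.fixture(scope="session")
def dom_state(dom_fit):
    _, _, _, fit = dom_fit
    return pb.blup_prep(fit)
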