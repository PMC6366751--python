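import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from prefqtl import (
    QtlSpec,
    SimulationConfig,
    compute_genoprob,
    simulate_backcross,
    simulate_preference_phenotypes,
)


@pytest.fixture(scope="session")
def small_cross():
    """A 3-chromosome backcross with one strong planted QTL (chr2 @ 20 cM).

    Small enough that every scan in the unit tests runs in well under a
    second, large enough (n = 120) that the QTL is unambiguous.
    """
    cfg = SimulationConfig(
        n_individuals=120,
        chromosomes=(("chr1", 40.0), ("chr2", 40.0), ("chr3", 40.0)),
        marker_spacing=10.0,
        qtl_specs=[QtlSpec("chr2", 20.0, 40.0)],
        seed=7,
    )
    lmap, obs, truth = simulate_backcross(cfg)
    pheno = simulate_preference_phenotypes(
        truth, lmap, cfg.qtl_specs, cfg.parental_means, cfg.overdispersion_sd, seed=8
    )
    probs = compute_genoprob(lmap, obs, error_rate=0.001, grid_step=10.0)
    return {
        "config": cfg,
        "lmap": lmap,
        "obs": obs,
        "truth": truth,
        "pheno": pheno,
        "probs": probs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
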