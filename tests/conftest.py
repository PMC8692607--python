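import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_pipeline():
    """One small simulated study run through selection and design, shared
    across tests that only read from it."""
    import cladecap as cc
    from cladecap.design import target_references

    cfg = cc.SimConfig(seed=7, n_loci=12)
    sim = cc.make_locus_set(cfg)
    params = cc.SelectionParams(focal_species=cfg.focal_species)
    result = cc.select_loci(
        sim.transcript_sets, sim.references, sim.reference_exons, params
    )
    panel = cc.build_panel(result.kept, [], cc.DesignParams())
    targets = target_references(result.kept)
    return {
        "config": cfg,
        "sim": sim,
        "params": params,
        "result": result,
        "panel": panel,
        "targets": targets,
    }
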