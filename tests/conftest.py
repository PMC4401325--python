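import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small noiseless simulation + pipeline run shared across tests."""
    from radmarkers.io import PipelineConfig
    from radmarkers.pipeline import run_pipeline
    from radmarkers.simulate import (SimulationConfig, emit_variant_calls,
                                     generate_parents, known_db_fixture)

    sim_cfg = SimulationConfig(
        seed=11, n_ssr_shared_equal=6, n_ssr_shared_divergent=5,
        n_ssr_a_only=4, n_ssr_b_only=4, n_snp=10, n_indel=8, n_background=3,
    )
    contigs_a, contigs_b, truth = generate_parents(sim_cfg)
    recs_ab, recs_ba = emit_variant_calls(truth, sim_cfg)
    db = known_db_fixture(truth, 0.5, sim_cfg.seed)
    result = run_pipeline(PipelineConfig(), contigs_a, contigs_b,
                          recs_ab, recs_ba, db)
    return {
        "sim_cfg": sim_cfg, "contigs_a": contigs_a, "contigs_b": contigs_b,
        "truth": truth, "recs_ab": recs_ab, "recs_ba": recs_ba,
        "db": db, "result": result,
    }
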