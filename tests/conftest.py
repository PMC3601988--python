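import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_power_report():
    """Pooling power/FDR experiment at the published study conditions.

    18 chromosomes, theta = rho = 0.001/bp, 75-bp paired reads at 14x
    mean pool depth with a Q30 error model, posterior-threshold calling
    within the 3-30x depth band; 10 replicates of 500 kb.  MAF bins are
    centred on multiples of 0.1 so that the 0.3 bin is [0.25, 0.35).
    """
    from poolscan.simulate import SimConfig, power_fdr_experiment

    config = SimConfig(seed=7, replicates=10, length=500_000)
    return power_fdr_experiment(
        config, maf_edges=(0.0, 0.05, 0.15, 0.25, 0.35, 0.45, 0.51)
    )
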