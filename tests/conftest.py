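import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=30, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

DEMO_SEED = 11
DEMO_READS = 40_000


@pytest.fixture(scope="session")
def demo(tmp_path_factory):
    """One shared demo: synthetic bundle + full pipeline run."""
    from pollenmir.pipeline import make_demo, run_pipeline

    root = tmp_path_factory.mktemp("demo")
    config_path, bundle = make_demo(root, seed=DEMO_SEED,
                                    total_reads=DEMO_READS)
    report = run_pipeline(config_path)
    return {"config": config_path, "bundle": bundle, "report": report,
            "root": root}


@pytest.fixture(scope="session")
def small_bundle():
    """In-memory synthetic genome (no libraries) for unit tests."""
    from pollenmir.synthetic import SyntheticGenomeSpec, build_genome

    return build_genome(SyntheticGenomeSpec(seed=7))
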