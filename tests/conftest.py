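import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (25 CRT + 21 IMRT), shared across tests."""
    from pbmtox.simulate import CohortGenerator

    return CohortGenerator().generate_cohort(7)


@pytest.fixture(scope="session")
def default_bundle(default_cohort):
    """Full analysis bundle for the shared cohort."""
    import warnings

    from pbmtox.pipeline import RunConfig, run_comparison
    from pbmtox.simulate import covariates_frame

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_comparison(
            {r.patient_id: r.dvhs for r in default_cohort.records},
            {r.patient_id: r.bloods for r in default_cohort.records},
            covariates_frame(default_cohort),
            RunConfig(seed=7),
        )
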