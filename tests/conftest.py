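import pytest
from hypothesis import HealthCheck, settings

from dusticu import linkage, strata, synthdata

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> synthdata.SynthConfig:
    """A small, fully observed synthetic world used across test modules."""
    return synthdata.SynthConfig(
        n_zips=8,
        years=(2005, 2006),
        storm_rate=2.0,
        monitor_missing_rate={},
        seed=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> synthdata.SyntheticBundle:
    return synthdata.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_days(small_bundle):
    """Expanded stratum-day table for the small world (exposures + counts)."""
    b = small_bundle
    dust = linkage.assign_storms_to_zips(b.storms, b.zone_footprints, b.zip_footprints, 20.0)
    expo = linkage.aggregate_monitors_to_zip(b.monitors, b.zip_footprints, 20.0)
    strata_list = strata.build_strata(dust, max_lag=5)
    days = strata.expand_stratum_days(strata_list, expo, b.icu, dust, max_lag=5)
    return {"dust": dust, "exposures": expo, "strata": strata_list, "days": days}
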