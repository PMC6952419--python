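import pytest
from hypothesis import HealthCheck, settings

from denovotrio import SyntheticCohortSpec, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_spec(seed: int = 11, **overrides) -> SyntheticCohortSpec:
    """A desk-scale cohort: same structure as the default, far fewer variants."""
    kwargs = dict(
        chromosomes=[("chr1", 2_000_000), ("chr2", 2_000_000)],
        n_dams=2,
        group_sizes={"control": 2, "ABE": 2, "BE4": 2},
        snv_rates={"control": 12.0, "ABE": 12.0, "BE4": 30.0},
        indel_rates={"control": 5.0, "ABE": 5.0, "BE4": 5.0},
        n_inherited=20,
        n_offtarget_sites=40,
        n_be4_complex_carriers=1,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticCohortSpec(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One generated small cohort shared by read-only tests."""
    outdir = tmp_path_factory.mktemp("small_cohort")
    return generate_cohort(small_spec(), outdir)
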