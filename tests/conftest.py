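import pytest
from hypothesis import HealthCheck, settings

import omicm as om

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec1px() -> om.AcquisitionSpec:
    """Single-pixel acquisition at full temporal resolution."""
    return om.AcquisitionSpec(width=1, height=1)


@pytest.fixture(scope="session")
def irf260(spec1px) -> om.IRF:
    return om.gaussian_irf(260.0, spec1px)


@pytest.fixture(scope="session")
def small_spec() -> om.AcquisitionSpec:
    """Small field geometry used for image-level tests."""
    return om.AcquisitionSpec(width=48, height=48, n_bins=128)


def two_group_design(
    n_per_group: int = 500, separation: float = 0.0, seed: int = 0
) -> om.CohortDesign:
    """Two-arm cohort; ``separation`` shifts the second arm's means."""
    healthy_nadh = om.default_group(om.NADH)
    healthy_fad = om.default_group(om.FAD)
    diseased_nadh = healthy_nadh.shifted(tau1=separation * 0.1, tau2=separation * 0.5,
                                         alpha1=-separation * 0.05)
    diseased_fad = healthy_fad.shifted(tau1=separation * 0.1, tau2=separation * 0.5,
                                       alpha1=-separation * 0.05)
    return om.CohortDesign(
        groups=(
            om.GroupDesign("healthy", {om.NADH: healthy_nadh, om.FAD: healthy_fad},
                           n_fields=1, n_cells_per_field=n_per_group),
            om.GroupDesign("diseased", {om.NADH: diseased_nadh, om.FAD: diseased_fad},
                           n_fields=1, n_cells_per_field=n_per_group),
        ),
        seed=seed,
    )
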