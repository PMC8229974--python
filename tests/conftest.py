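import pytest

from amplimeth.simulate import synthetic_amplicon

try:
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def dr4_amplicon():
    """Synthetic DR4 promoter amplicon: 136 bp, 6 CpG sites."""
    return synthetic_amplicon("DR4")


@pytest.fixture(scope="session")
def dr5_amplicon():
    """Synthetic DR5 promoter amplicon: 212 bp, 13 CpG sites."""
    return synthetic_amplicon("DR5")
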