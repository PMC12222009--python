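import pytest
from hypothesis import HealthCheck, settings

from caninakit.simulate import GenomeSpec, generate_chip_tracks, generate_pentaploid

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle_small():
    """Desk-scale pentaploid bundle for mapping/coverage tests."""
    spec = GenomeSpec(seed=101, chromosome_length=200_000,
                      centromere_length=28_000, n_sco_loci=6)
    return generate_pentaploid(spec)


@pytest.fixture(scope="session")
def bundle_default():
    """Full default-scale bundle (1 Mb chromosomes, 35 centromeres)."""
    return generate_pentaploid(GenomeSpec(seed=202))


@pytest.fixture(scope="session")
def chip_default(bundle_default):
    cenh3, h3, meth = generate_chip_tracks(bundle_default, seed=202)
    return cenh3, h3, meth
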