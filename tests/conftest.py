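import numpy as np
import pytest
from hypothesis import settings

from waxtransect import AlkaneProfile, SiteEnvironment

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


def make_profile(conc, sample_id="S1", species="Sp", site_id="T1",
                 dry_mass_g=0.1, replicate_group=None):
    """Terse AlkaneProfile builder for tests."""
    return AlkaneProfile(
        sample_id=sample_id, species=species, site_id=site_id,
        dry_mass_g=dry_mass_g, conc=conc, replicate_group=replicate_group,
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def random_profiles():
    """Profiles with positive random concentrations over C23-C33."""
    rng = np.random.default_rng(42)

    def make(n, allow_zero=False):
        out = []
        for i in range(n):
            conc = {c: float(v) for c, v in zip(range(23, 34), rng.gamma(2.0, 10.0, 11))}
            if allow_zero:
                for c in rng.choice(range(23, 34), size=rng.integers(0, 4), replace=False):
                    conc[int(c)] = 0.0
            out.append(make_profile(conc, sample_id=f"R{i}"))
        return out

    return make


@pytest.fixture
def small_sites():
    return [
        SiteEnvironment("T1", 700.0, 21.0, 99.5, 2400.0),
        SiteEnvironment("T2", 1500.0, 17.0, 98.8, 2100.0),
        SiteEnvironment("T3", 2300.0, 13.0, 97.9, 1900.0),
        SiteEnvironment("T4", 3100.0, 9.0, 96.5, 1650.0),
    ]
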