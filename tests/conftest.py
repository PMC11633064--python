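import pytest

from mandfrac.phantom import PhantomSpec, generate_phantom
from mandfrac.training import Scan


@pytest.fixture(scope="session")
def fractured_phantom():
    """One noise-free phantom with a single nondisplaced fracture."""
    spec = PhantomSpec(seed=11, n_fractures=1, displaced_fraction=0.0,
                       noise_sd=0.0)
    vol, mand, frac, records = generate_phantom(spec)
    return spec, vol, mand, frac, records


@pytest.fixture(scope="session")
def displaced_phantom():
    spec = PhantomSpec(seed=23, n_fractures=1, displaced_fraction=1.0,
                       noise_sd=0.0)
    vol, mand, frac, records = generate_phantom(spec)
    return spec, vol, mand, frac, records


@pytest.fixture(scope="session")
def small_scans():
    """A handful of noisy phantoms wrapped as training scans."""
    scans = []
    for i in range(4):
        spec = PhantomSpec(seed=400 + i, n_fractures=1 if i % 2 else 0)
        vol, mand, frac, _ = generate_phantom(spec)
        scans.append(Scan(f"scan{i}", vol.data, mand.data, frac.data))
    return scans


from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
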