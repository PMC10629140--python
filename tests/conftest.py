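import numpy as np
import pytest

import sctradiomics as s


@pytest.fixture(scope="session")
def phantom_case():
    """One default 64^3 head phantom (real image + masks), fixed seed."""
    return s.generate_phantom(s.PhantomSpec(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """3-subject cohort with the two stock degradation styles."""
    return s.generate_cohort(3, master_seed=5)


@pytest.fixture(scope="session")
def identity_cohort():
    """3-subject cohort whose synthetic images equal the real ones."""
    return s.generate_cohort(3, degradations=s.identity_degradations(), master_seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_discrete_volume(rng, max_side=5, max_ng=4, p_mask=0.8):
    """A random small integer volume + mask for matrix oracle sweeps."""
    shape = tuple(int(rng.integers(1, max_side + 1)) for _ in range(3))
    ng = int(rng.integers(1, max_ng + 1))
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask.flat[int(rng.integers(mask.size))] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, ng + 1, int(mask.sum()))
    ng_eff = int(levels[mask].max())
    return levels, mask, ng_eff
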