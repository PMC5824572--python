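import numpy as np
import pytest

from hic3d import ContactMap, Structure3D, build_restraints, make_chain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """4x4 symmetric contact map with one zero-IF pair (0,3)."""
    m = np.array(
        [
            [0.0, 4.0, 1.0, 0.0],
            [4.0, 0.0, 2.0, 1.0],
            [1.0, 2.0, 0.0, 5.0],
            [0.0, 1.0, 5.0, 0.0],
        ]
    )
    return ContactMap(m)


@pytest.fixture
def chain20():
    return make_chain(20, smoothness=0.6, seed=42)


def random_restraints(rng, n_beads, jitter=0.2):
    """Restraints from a random coordinate cloud with multiplicative jitter.

    Targets are genuine distances of a (hidden) configuration perturbed by
    lognormal noise, so the optimum is near but not at zero residual.
    """
    coords = rng.normal(size=(n_beads, 3))
    cmap_d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    iu, ju = np.triu_indices(n_beads, 1)
    d = cmap_d[iu, ju] * np.exp(rng.normal(0, jitter, size=len(iu)))
    from hic3d import RestraintSet

    return RestraintSet(i=iu, j=ju, d=d, alpha=1.0, n_beads=n_beads)


@pytest.fixture
def restraint_factory(rng):
    return lambda n_beads, jitter=0.2: random_restraints(rng, n_beads, jitter)
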