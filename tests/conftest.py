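import numpy as np
import pytest

import nichemargins as nm


@pytest.fixture(scope="session")
def small_world():
    """A 60x60 synthetic world with 4 countries and two scenarios."""
    cfg = nm.WorldConfig(n_rows=60, n_cols=60, n_countries=4, seed=3)
    return nm.generate_world(cfg)


@pytest.fixture(scope="session")
def latent(small_world):
    return nm.latent_environment(small_world)


@pytest.fixture(scope="session")
def species_set(small_world, latent):
    _, scores = latent
    truths = nm.random_species_truths(3, 3, scores.scores)
    species, cal = nm.generate_species_set(small_world, truths)
    return species, cal


@pytest.fixture(scope="session")
def gaussian_niche():
    """Niche model of a standard bivariate normal score cloud (n=5000)."""
    rng = np.random.default_rng(42)
    pts = rng.standard_normal((5000, 2))
    return nm.estimate_niche(pts, species_id="gauss", grid_size=200), pts
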