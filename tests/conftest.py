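import numpy as np
import pandas as pd
import pytest

import nichescan as ns


@pytest.fixture(scope="session")
def small_dataset():
    """Half-scale four-species study used by several suites."""
    return ns.generate_dataset(ns.default_scenario(seed=1, scale=0.5))


@pytest.fixture(scope="session")
def tiny_matrix():
    """One-species marker matrix: 10 sites, 60 loci, quick to scan."""
    land = ns.LandscapeSpec(n_sites=20, n_variables=4, seed=7)
    sites = ns.generate_sites(land)
    niche = ns.NicheSpec("sp", "env01", niche_width=2.0, baseline_occupancy=0.6)
    presence = ns.generate_presence(sites, [niche], seed=7)
    model = ns.GenotypeModel(n_loci=60, n_selected=0, neutral_fst=0.02,
                             n_individuals_per_site=12)
    matrix, truth = ns.generate_aflp(sites, presence, niche, model, seed=7)
    return matrix, truth, sites


def random_distance_matrix(rng, n, ids=None):
    """Helper: random symmetric non-negative distance matrix."""
    v = np.abs(rng.normal(size=(n, n)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return ns.DistanceMatrix(ids or [f"s{i}" for i in range(n)], v)
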