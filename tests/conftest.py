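import numpy as np
import pytest

from fmzdecomp import (
    ElementMap,
    FitOptions,
    build_valid_mask,
    compute_occupancy,
    define_clusters,
    intersubject_stats,
    make_design,
    make_geometry,
    make_ground_truth,
    pool_occupancy,
    simulate_study,
)


@pytest.fixture(scope="session")
def geometry():
    return make_geometry((16, 16, 16), n_regions_per_hemisphere=4, seed=1)


@pytest.fixture(scope="session")
def truth(geometry):
    return make_ground_truth(geometry, n_components=3, seed=7)


@pytest.fixture(scope="session")
def design():
    return make_design(8, 4, seed=3)


@pytest.fixture(scope="session")
def noiseless_study(geometry, truth, design):
    """Noise-free maps pushed through the full preprocessing chain."""
    baselines, posts = simulate_study(truth, design, noise_sd_occ=0.0, baseline_cv=0.0, seed=5)
    min_map, mean_map = intersubject_stats(baselines)
    valid = build_valid_mask(min_map, 0.1, geometry.mask)
    occ_maps = [
        compute_occupancy(
            ElementMap(geometry, b.data, valid.mask.copy()),
            ElementMap(geometry, p.data, valid.mask.copy()),
        )
        for b, p in zip(baselines, posts)
    ]
    clusters = define_clusters(geometry, (4, 4, 4), valid.mask)
    dataset = pool_occupancy(occ_maps, clusters, design)
    return {
        "baselines": baselines,
        "posts": posts,
        "mean_map": mean_map,
        "clusters": clusters,
        "dataset": dataset,
    }


@pytest.fixture(scope="session")
def m3c_fit(noiseless_study):
    from fmzdecomp import M3C, fit_model

    return fit_model(M3C, noiseless_study["dataset"], FitOptions(seed=0))


@pytest.fixture(scope="session")
def cluster_truth_fractions(truth, noiseless_study):
    clusters = noiseless_study["clusters"]
    mask = clusters.labels >= 0
    labels = clusters.labels[mask]
    m = clusters.n_clusters
    out = np.empty((m, truth.n_components))
    for k in range(truth.n_components):
        sums = np.bincount(labels, weights=truth.fractions[k][mask], minlength=m)
        out[:, k] = sums / clusters.sizes
    return out
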