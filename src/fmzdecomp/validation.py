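"""Simulation-based validation experiments.

End-to-end checks of the estimator on synthetic data with known ground
truth: noiseless and noisy parameter recovery, equivalence of the exact
per-cluster simplex solver with a dense grid search, round-trip
exactness of the simplex reparameterization, and recovery of the
generating model configuration by the selection rule.  These experiments
back both the test suite and ``scripts/acceptance.py``.

Problem sizes are scaled to desk-top runs: a 24-voxel cube (216
clusters of 64 voxels) for parameter recovery and an 8-voxel cube
(8 clusters) for the replicated model-selection experiment; the study
design is always 8 + 4 subjects with exposures log-spaced over
0.1-120 exposure units, spanning 0.1-10x every true K_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ElementMap
from .modelselect import evaluate_configs
from .occmodel import M2A, M3C, FitOptions, ModelConfig, fit_model, f_to_v, solve_fractions, v_to_f
from .preprocess import (
    OccupancyDataset,
    build_valid_mask,
    compute_occupancy,
    define_clusters,
    intersubject_stats,
    pool_occupancy,
)
from .synth import (
    GroundTruth,
    StudyDesign,
    make_design,
    make_geometry,
    make_ground_truth,
    simulate_study,
)

#: Four components, drug A occupying three of them (over-parameterized
#: alternative used in the selection-recovery experiment).
M4 = ModelConfig("M4", 4, {"A": (1, 2, 3), "B": (1,)})


@dataclass
class SimulatedStudy:
    truth: GroundTruth
    design: StudyDesign
    dataset: OccupancyDataset
    cluster_truth_fractions: np.ndarray  # (M, N) cluster-mean true f


def simulate_pooled_study(
    seed: int,
    noise_sd_occ: float,
    shape: tuple[int, int, int] = (24, 24, 24),
    n_a: int = 8,
    n_b: int = 4,
    block: tuple[int, int, int] = (4, 4, 4),
    n_regions: int = 4,
) -> SimulatedStudy:
    """Run the generative model plus preprocessing chain end to end."""
    geometry = make_geometry(shape, n_regions_per_hemisphere=n_regions, seed=seed)
    truth = make_ground_truth(geometry, n_components=3, seed=seed + 1)
    design = make_design(n_a, n_b, seed=seed + 2)
    baselines, posts = simulate_study(truth, design, noise_sd_occ, seed=seed + 3)
    min_map, _ = intersubject_stats(baselines)
    valid = build_valid_mask(min_map, 0.1, geometry.mask)
    occ_maps = [
        compute_occupancy(
            ElementMap(geometry, b.data, valid.mask.copy()),
            ElementMap(geometry, p.data, valid.mask.copy()),
        )
        for b, p in zip(baselines, posts)
    ]
    clusters = define_clusters(geometry, block, valid.mask)
    dataset = pool_occupancy(occ_maps, clusters, design)

    mask = clusters.labels >= 0
    labels = clusters.labels[mask]
    m = clusters.n_clusters
    truth_f = np.empty((m, truth.n_components))
    for k in range(truth.n_components):
        sums = np.bincount(labels, weights=truth.fractions[k][mask], minlength=m)
        truth_f[:, k] = sums / clusters.sizes
    return SimulatedStudy(truth, design, dataset, truth_f)


def parameter_recovery(seed: int, noise_sd_occ: float, **kwargs) -> dict:
    """Fit the generating configuration and compare to ground truth."""
    study = simulate_pooled_study(seed, noise_sd_occ, **kwargs)
    fit = fit_model(M3C, study.dataset, FitOptions(seed=seed))
    ki_err = []
    for drug, kis in study.truth.ki.items():
        for comp, true_ki in kis.items():
            ki_err.append(abs(fit.ki[drug][comp] - true_ki) / true_ki)
    f_err = np.abs(fit.fractions - study.cluster_truth_fractions)
    return {
        "ki_max_rel_error_pct": 100.0 * max(ki_err),
        "f_max_abs_error": float(f_err.max()),
        "f_median_abs_error": float(np.median(f_err)),
        "n_clusters": study.dataset.n_clusters,
        "ki_fitted": fit.ki,
        "converged": fit.converged,
    }


def grid_search_fractions(a: np.ndarray, y: np.ndarray, step: float = 0.01) -> tuple[np.ndarray, float]:
    """Dense grid-search oracle for the per-cluster simplex problem."""
    n_comp = a.shape[1]
    ticks = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    grids = np.meshgrid(*([ticks] * (n_comp - 1)), indexing="ij")
    head = np.stack([g.ravel() for g in grids], axis=1)
    keep = head.sum(1) <= 1.0 + 1e-12
    head = head[keep]
    pts = np.hstack([head, 1.0 - head.sum(1, keepdims=True)])
    ssr = ((pts @ a.T - y) ** 2).sum(1)
    best = int(ssr.argmin())
    return pts[best], float(ssr[best])


def inner_solver_vs_grid(seed: int, n_instances: int = 20, step: float = 0.01) -> dict:
    """Compare the exact face-enumeration solver with the grid oracle on
    random small instances (random exposures, K_i and noisy targets).

    Equivalence is judged on the objective: the exact solution must never
    be worse than the grid optimum, and after snapping the exact solution
    to the oracle's grid its SSR may exceed the grid optimum by at most
    the quadratic snapping bound lambda_max(A'A) * ||snap||^2.  The
    argmin distance is also reported, but near-flat valleys can place two
    almost equally good solutions more than one tick apart, so it is a
    diagnostic rather than the equivalence criterion.
    """
    rng = np.random.default_rng(seed)
    max_f_dev = 0.0
    max_ssr_excess = 0.0
    max_snap_margin = -np.inf  # snapped_excess - bound; equivalence holds iff <= 0
    for _ in range(n_instances):
        n_occ = int(rng.integers(6, 14))
        drugs = np.where(rng.random(n_occ) < 2 / 3, "A", "B")
        # ensure both drugs present
        drugs[0], drugs[1] = "A", "B"
        cp = np.exp(rng.uniform(np.log(0.1), np.log(120.0), n_occ))
        ki = {
            "A": {1: float(np.exp(rng.uniform(-1, 2))), 2: float(np.exp(rng.uniform(1, 4)))},
            "B": {1: float(np.exp(rng.uniform(-1, 2)))},
        }
        from .occmodel import occupancy_matrix

        a = occupancy_matrix(M3C, drugs, cp, ki)
        f_true = rng.dirichlet(np.ones(3))
        y = (a @ f_true + rng.normal(0, 0.05, n_occ))[None, :]
        f_exact, ssr_exact = solve_fractions(a, y)
        f_grid, ssr_grid = grid_search_fractions(a, y[0], step)
        max_ssr_excess = max(max_ssr_excess, float(ssr_exact[0] - ssr_grid))
        max_f_dev = max(max_f_dev, float(np.abs(f_exact[0] - f_grid).max()))
        # snap the exact solution onto the oracle's lattice (head
        # coordinates on ticks, last coordinate closing the simplex)
        head = np.round(f_exact[0][:-1] / step) * step
        head = np.clip(head, 0.0, 1.0)
        if head.sum() > 1.0:
            head *= 1.0 / head.sum()
            head = np.floor(head / step) * step
        f_snap = np.append(head, 1.0 - head.sum())
        snapped_excess = float(((f_snap @ a.T - y[0]) ** 2).sum() - ssr_grid)
        lam_max = float(np.linalg.norm(a, 2) ** 2)
        bound = lam_max * float(((f_snap - f_exact[0]) ** 2).sum())
        max_snap_margin = max(max_snap_margin, snapped_excess - bound)
    return {"max_f_deviation": max_f_dev, "max_ssr_excess": max_ssr_excess,
            "max_snap_margin": float(max_snap_margin), "n_instances": n_instances}


def simplex_roundtrip(seed: int, n_points: int = 1000) -> dict:
    """Round-trip error of the cumulative-ratio reparameterization."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    off_simplex = 0.0
    total = 0
    for n in (2, 3, 4):
        f = rng.dirichlet(np.ones(n), size=n_points)
        for row in f:
            back = v_to_f(f_to_v(row))
            worst = max(worst, float(np.abs(back - row).max()))
            off_simplex = max(off_simplex, abs(float(back.sum()) - 1.0), float(-back.min()))
            total += 1
        # arbitrary v must always map onto the simplex
        for row in rng.uniform(0, 1, size=(n_points // 10, n - 1)):
            g = v_to_f(row)
            off_simplex = max(off_simplex, abs(float(g.sum()) - 1.0), float(-g.min()))
    return {"max_roundtrip_error": worst, "max_simplex_violation": off_simplex, "n_points": total}


def selection_recovery(
    seed: int,
    n_replicates: int = 20,
    noise_sd_occ: float = 0.05,
    shape: tuple[int, int, int] = (8, 8, 8),
) -> dict:
    """Replicated model-selection experiment on data generated under the
    three-component configuration; reports how often it is selected
    against the two- and four-component alternatives."""
    hits = 0
    selected = []
    for r in range(n_replicates):
        study = simulate_pooled_study(seed * 100 + r, noise_sd_occ, shape=shape, n_regions=3)
        report = evaluate_configs(
            [M2A, M3C, M4], study.dataset, study.truth.geometry,
            options=FitOptions(seed=seed),
        )
        selected.append(report.selected)
        hits += report.selected == M3C.name
    return {
        "recovery_pct": 100.0 * hits / n_replicates,
        "selected": selected,
        "n_replicates": n_replicates,
    }
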