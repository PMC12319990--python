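"""Occupancy model family, simplex reparameterization, and the fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmzdecomp import (
    M2A,
    M3C,
    FitOptions,
    ModelConfig,
    enumerate_configs,
    f_to_v,
    fit_model,
    init_parameters,
    occupancy_matrix,
    predict_component_occupancy,
    predict_total_occupancy,
    solve_fractions,
    v_to_f,
)
from fmzdecomp.validation import grid_search_fractions


class TestConfigs:
    def test_m3c_structure(self):
        assert M3C.n_components == 3
        assert M3C.displaceable["A"] == (1, 2)
        assert M3C.displaceable["B"] == (1,)

    def test_m2a_lumped(self):
        assert M2A.displaceable == {"A": (1,), "B": (1,)}

    def test_drug_b_cannot_exceed_drug_a(self):
        with pytest.raises(ValueError, match="drug A"):
            ModelConfig("bad", 3, {"A": (1,), "B": (1, 2)})

    def test_last_component_non_displaceable(self):
        with pytest.raises(ValueError):
            ModelConfig("bad", 2, {"A": (1, 2), "B": (1,)})

    def test_enumeration_is_admissible_and_includes_named_shapes(self):
        cfgs = enumerate_configs()
        assert len(cfgs) == 6
        shapes = {(c.n_components, c.displaceable["A"], c.displaceable["B"]) for c in cfgs}
        assert (2, (1,), (1,)) in shapes  # M2a
        assert (3, (1, 2), (1,)) in shapes  # M3c


class TestPredictions:
    @pytest.mark.parametrize(
        "cp,ki,expected", [(1.0, 1.0, 0.5), (0.0, 2.0, 0.0), (3.0, 1.0, 0.75)]
    )
    def test_single_site_occupancy(self, cp, ki, expected):
        assert predict_component_occupancy(cp, ki) == pytest.approx(expected)

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            predict_component_occupancy(1.0, 0.0)

    def test_mixture_prediction(self):
        ki = {"A": {1: 1.0}, "B": {1: 1.0}}
        assert predict_total_occupancy([0.6, 0.4], M2A, "A", 1.0, ki) == pytest.approx(0.3)

    def test_non_displaceable_mass_contributes_nothing(self):
        ki = {"A": {1: 1.0, 2: 5.0}, "B": {1: 1.0}}
        assert predict_total_occupancy([0.0, 0.0, 1.0], M3C, "A", 1e9, ki) == pytest.approx(0.0)

    def test_saturation_limit_is_displaceable_mass(self):
        ki = {"A": {1: 1.0, 2: 5.0}, "B": {1: 1.0}}
        total = predict_total_occupancy([0.3, 0.2, 0.5], M3C, "A", 1e12, ki)
        assert total == pytest.approx(0.5, abs=1e-9)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="simplex"):
            predict_total_occupancy([0.7, 0.7], M2A, "A", 1.0, {"A": {1: 1.0}})

    def test_monotone_in_exposure(self):
        ki = {"A": {1: 0.5, 2: 7.0}, "B": {1: 1.0}}
        cps = np.geomspace(1e-3, 1e3, 50)
        vals = [predict_total_occupancy([0.3, 0.3, 0.4], M3C, "A", c, ki) for c in cps]
        assert np.all(np.diff(vals) >= 0)


class TestSimplexTransform:
    def test_uniform_fractions(self):
        np.testing.assert_allclose(f_to_v([1 / 3, 1 / 3, 1 / 3]), [0.5, 2 / 3])
        np.testing.assert_allclose(v_to_f([0.5, 2 / 3]), [1 / 3, 1 / 3, 1 / 3])

    def test_vertex(self):
        np.testing.assert_allclose(f_to_v([1.0, 0.0, 0.0]), [1.0, 1.0])
        np.testing.assert_allclose(v_to_f([1.0, 1.0]), [1.0, 0.0, 0.0])

    def test_degenerate_leading_zeros_convention(self):
        # all leading fractions zero: v defined as 0 there
        v = f_to_v([0.0, 0.0, 1.0])
        assert v[0] == 0.0
        np.testing.assert_allclose(v_to_f(v), [0.0, 0.0, 1.0])

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            f_to_v([-0.1, 1.1])

    def test_v_out_of_box_rejected(self):
        with pytest.raises(ValueError):
            v_to_f([1.2, 0.5])

    @given(st.integers(2, 4), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_on_interior_points(self, n, seed):
        f = np.random.default_rng(seed).dirichlet(np.ones(n))
        np.testing.assert_allclose(v_to_f(f_to_v(f)), f, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_any_box_point_maps_to_simplex(self, v):
        f = v_to_f(v)
        assert f.min() >= -1e-12
        assert abs(f.sum() - 1.0) < 1e-12


class TestInnerSolver:
    def test_matches_grid_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_occ = 10
            drugs = np.array(["A"] * 7 + ["B"] * 3)
            cp = np.exp(rng.uniform(np.log(0.1), np.log(100), n_occ))
            ki = {"A": {1: 1.0, 2: 15.0}, "B": {1: 2.0}}
            a = occupancy_matrix(M3C, drugs, cp, ki)
            y = (a @ rng.dirichlet(np.ones(3)) + rng.normal(0, 0.05, n_occ))[None]
            f_exact, ssr_exact = solve_fractions(a, y)
            f_grid, ssr_grid = grid_search_fractions(a, y[0], 0.01)
            assert ssr_exact[0] <= ssr_grid + 1e-12
            assert np.abs(f_exact[0] - f_grid).max() <= 0.015

    def test_exact_on_noiseless_targets(self):
        rng = np.random.default_rng(3)
        drugs = np.array(["A"] * 6 + ["B"] * 3)
        cp = np.geomspace(0.1, 100, 9)
        a = occupancy_matrix(M3C, drugs, cp, {"A": {1: 1.0, 2: 12.0}, "B": {1: 1.5}})
        f_true = rng.dirichlet(np.ones(3), size=50)
        f_hat, ssr = solve_fractions(a, f_true @ a.T)
        assert np.abs(f_hat - f_true).max() < 1e-8
        assert ssr.max() < 1e-18

    def test_output_rows_on_simplex(self):
        rng = np.random.default_rng(4)
        drugs = np.array(["A", "A", "B", "B"])
        a = occupancy_matrix(M2A, drugs, np.array([0.5, 5.0, 1.0, 10.0]), {"A": {1: 1.0}, "B": {1: 1.0}})
        f, _ = solve_fractions(a, rng.normal(0.2, 0.3, (30, 4)))
        assert f.min() >= 0
        np.testing.assert_allclose(f.sum(1), 1.0, atol=1e-12)


class TestFit:
    def test_two_point_algebraic_solution(self, geometry):
        """Drug A observations (C_p=1, occ=0.25), (C_p=4, occ=0.40) under a
        one-displaceable-component model solve to K_i = 1, f = (0.5, 0.5)."""
        from fmzdecomp import StudyDesign, define_clusters, pool_occupancy
        from fmzdecomp.grids import ElementMap
        import pandas as pd

        cfg = ModelConfig("A2", 2, {"A": (1,)})
        design = StudyDesign(
            pd.DataFrame(
                {"subject": ["s1", "s2"], "drug": ["A", "A"],
                 "dose_mg": [1.0, 4.0], "exposure": [1.0, 4.0]}
            )
        )
        cs = define_clusters(geometry, (16, 16, 16))
        maps = [
            ElementMap(geometry, np.full(geometry.shape, occ)) for occ in (0.25, 0.40)
        ]
        ds = pool_occupancy(maps, cs, design)
        fit = fit_model(cfg, ds)
        assert fit.ki["A"][1] == pytest.approx(1.0, rel=1e-6)
        assert fit.fractions[0, 0] == pytest.approx(0.5, abs=1e-8)
        assert fit.ssr < 1e-16

    def test_noiseless_recovery_of_generating_model(
        self, m3c_fit, truth, cluster_truth_fractions
    ):
        for drug, kis in truth.ki.items():
            for comp, true_ki in kis.items():
                assert m3c_fit.ki[drug][comp] == pytest.approx(true_ki, rel=0.01)
        assert np.abs(m3c_fit.fractions - cluster_truth_fractions).max() < 0.01

    def test_within_drug_ki_ordered_ascending(self, m3c_fit):
        assert m3c_fit.ki["A"][1] <= m3c_fit.ki["A"][2]

    def test_null_signal(self, geometry, design):
        from fmzdecomp import define_clusters, pool_occupancy
        from fmzdecomp.grids import ElementMap

        cs = define_clusters(geometry, (8, 8, 8))
        maps = [ElementMap(geometry, np.zeros(geometry.shape))] * design.n_occasions
        ds = pool_occupancy(maps, cs, design)
        fit = fit_model(M2A, ds)
        assert fit.ssr < 1e-12
        # no displaceable signal: either the fraction or the occupancy vanishes
        occ_at_max = max(
            fit.fractions[i, 0] * ds.design.exposures.max()
            / (ds.design.exposures.max() + fit.ki["A"][1])
            for i in range(ds.n_clusters)
        )
        assert occ_at_max < 1e-4

    def test_degenerate_single_exposure_rejected(self, geometry):
        import pandas as pd

        from fmzdecomp import StudyDesign, define_clusters, pool_occupancy
        from fmzdecomp.grids import ElementMap

        design = StudyDesign(
            pd.DataFrame(
                {"subject": ["s1", "s2", "s3"], "drug": ["A", "A", "B"],
                 "dose_mg": [1, 1, 1], "exposure": [2.0, 2.0, 1.0]}
            )
        )
        cs = define_clusters(geometry, (16, 16, 16))
        maps = [ElementMap(geometry, np.full(geometry.shape, 0.1))] * 3
        ds = pool_occupancy(maps, cs, design)
        with pytest.raises(ValueError, match="degenerate|distinct"):
            fit_model(ModelConfig("A2", 2, {"A": (1,), "B": (1,)}), ds)

    def test_objective_never_below_final_ssr(self, m3c_fit):
        assert m3c_fit.ssr <= min(m3c_fit.ssr_history) + 1e-12

    def test_initial_parameters_staggered_and_uniform(self, noiseless_study):
        theta0, v0 = init_parameters(M3C, noiseless_study["dataset"])
        ki0 = np.cumsum(theta0[:2])
        assert ki0[0] < ki0[1]  # drug A: component 1 gets the higher affinity
        np.testing.assert_allclose(v0[0], f_to_v([1 / 3, 1 / 3, 1 / 3]))

    def test_permuted_start_reaches_same_canonical_solution(self, noiseless_study, m3c_fit):
        theta_perm = m3c_fit.theta.copy()
        theta_perm[0] += 2.0  # start drug A high affinity in the wrong order
        theta_perm[1] = 0.5
        refit = fit_model(M3C, noiseless_study["dataset"], FitOptions(theta0=theta_perm))
        for drug in refit.ki:
            for comp in refit.ki[drug]:
                assert refit.ki[drug][comp] == pytest.approx(m3c_fit.ki[drug][comp], rel=1e-3)

    def test_confidence_intervals_bracket_noiseless_estimates(self, m3c_fit):
        for drug, kis in m3c_fit.ki.items():
            for comp, ki in kis.items():
                lo, hi = m3c_fit.ki_ci[drug][comp]
                assert lo <= ki <= hi
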