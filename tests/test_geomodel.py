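"""Geometric model algebra: the length model, scenarios and intercalation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notomorph import geomodel as gm

positive = st.floats(min_value=1e-2, max_value=1e4, allow_nan=False)


def _params(stages, l, v, a):
    t = pd.DataFrame({"l_ap": l, "volume": v, "area": a}, index=stages)
    t["area_bb"] = t["area"] * 1.2
    t.index.name = "stage"
    return gm.MeanCellParams(t)


def _eq1_consistent_params(v0, a0, v1, a1):
    """Two-stage parameters whose mean lengths satisfy the prism relation
    exactly (so scenario identities hold to machine precision)."""
    return _params([6, 10], [v0 / a0, v1 / a1], [v0, v1], [a0, a1])


class TestLengthModel:
    @pytest.mark.parametrize("v,a,l", [(1000, 200, 5), (250, 50, 5)])
    def test_prism_length(self, v, a, l):
        assert gm.ap_length_eq1(v, a) == l

    def test_prism_length_exact_for_fixture_cuboid(self, fixture_features):
        feats, _ = fixture_features
        r = feats[feats["cell_id"] == 1].iloc[0]
        assert gm.ap_length_eq1(
            r["volume_um3"], r["area_transverse_um2"]
        ) == pytest.approx(r["l_ap_um"])

    def test_non_positive_inputs_fail(self):
        with pytest.raises(ValueError):
            gm.ap_length_eq1(-1.0, 2.0)
        with pytest.raises(ValueError):
            gm.ap_length_eq1(1.0, 0.0)


class TestScenarioAlgebra:
    @given(v0=positive, a0=positive, v1=positive, a1=positive)
    @settings(max_examples=200, deadline=None)
    def test_scenario_identities(self, v0, a0, v1, a1):
        """shape-only l = V0/A(s); anisotropic l = l0*V/V0; their product
        relations hold to machine precision on eq1-consistent parameters."""
        p = _eq1_consistent_params(v0, a0, v1, a1)
        l0 = v0 / a0
        aniso = gm.scenario_ap_anisotropy(p, 10)
        iso = gm.scenario_isotropic_growth(p, 10)
        growth = gm.scenario_anisotropic_growth(p, 10)
        assert aniso == pytest.approx(v0 / a1, rel=1e-12)
        assert growth == pytest.approx(l0 * v1 / v0, rel=1e-12)
        assert iso == pytest.approx(l0 * (v1 / v0) ** (1 / 3), rel=1e-12)
        assert growth / iso == pytest.approx((v1 / v0) ** (2 / 3), rel=1e-12)

    def test_doubling_area_halves_constant_volume_length(self):
        p = _eq1_consistent_params(100.0, 10.0, 100.0, 20.0)
        assert gm.scenario_ap_anisotropy(p, 10) == pytest.approx(
            gm.scenario_ap_anisotropy(p, 6) / 2
        )

    def test_eightfold_volume_doubles_isotropic_length(self):
        p = _eq1_consistent_params(100.0, 10.0, 800.0, 10.0)
        assert gm.scenario_isotropic_growth(p, 10) == pytest.approx(20.0)
        assert gm.scenario_anisotropic_growth(p, 10) == pytest.approx(80.0)

    def test_start_stage_recovers_baseline(self):
        p = _eq1_consistent_params(100.0, 10.0, 300.0, 25.0)
        for fn in (gm.scenario_ap_anisotropy, gm.scenario_isotropic_growth,
                   gm.scenario_anisotropic_growth):
            assert fn(p, 6) == pytest.approx(10.0, rel=1e-12)

    @given(v0=positive, a0=positive, v1=positive, a1=positive)
    @settings(max_examples=100, deadline=None)
    def test_monotone_responses(self, v0, a0, v1, a1):
        p = _eq1_consistent_params(v0, a0, v1, a1)
        if a1 > a0:
            assert gm.scenario_ap_anisotropy(p, 10) < gm.scenario_ap_anisotropy(p, 6)
        if v1 > v0:
            assert gm.scenario_isotropic_growth(p, 10) > p.at(6, "l_ap")
            assert gm.scenario_anisotropic_growth(p, 10) > p.at(6, "l_ap")


class TestIntercalation:
    def test_stack_of_coins_is_beta_one(self):
        assert gm.intercalation_index(50.0, 10, 5.0) == 1.0

    def test_partial_intercalation(self):
        assert gm.intercalation_index(40.0, 10, 5.0) == pytest.approx(0.8)

    def test_beta_above_one_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert gm.intercalation_index(55.0, 10, 5.0) == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            gm.intercalation_index(5.0, 1, 5.0)
        with pytest.raises(ValueError):
            gm.neighborhood_length_eq2(0.5, 1, 5.0)

    @pytest.mark.parametrize("beta,expected", [(1.0, 50.0), (0.5, 25.0)])
    def test_group_length(self, beta, expected):
        assert gm.neighborhood_length_eq2(beta, 10, 5.0) == expected

    @given(l_n=positive, lbar=positive, n=st.integers(2, 40))
    @settings(max_examples=100, deadline=None)
    def test_index_and_length_round_trip(self, l_n, lbar, n):
        beta = gm.intercalation_index(min(l_n, n * lbar), n, lbar)
        back = gm.neighborhood_length_eq2(beta, n, lbar)
        assert back == pytest.approx(min(l_n, n * lbar), rel=1e-12)


class TestMeanCellParams:
    def test_means_and_sems(self):
        t = pd.DataFrame({
            "stage": [6, 6, 6], "l_ap_um": [5, 5, 5],
            "volume_um3": [90.0, 100.0, 110.0],
            "area_transverse_um2": [20, 20, 20],
            "area_bb_transverse_um2": [25, 25, 25],
        })
        p = gm.mean_cell_params(t)
        assert p.at(6, "volume") == pytest.approx(100.0)
        assert float(p.table.loc[6, "volume_sem"]) == pytest.approx(5.7735, abs=1e-3)

    def test_single_cell_stage_fails(self):
        t = pd.DataFrame({"stage": [6], "l_ap_um": [5.0],
                          "volume_um3": [100.0],
                          "area_transverse_um2": [20.0],
                          "area_bb_transverse_um2": [25.0]})
        with pytest.raises(ValueError, match=">= 3 cells"):
            gm.mean_cell_params(t)

    def test_missing_stage_listed(self):
        t = pd.DataFrame({"stage": [6] * 3, "l_ap_um": [5.0] * 3,
                          "volume_um3": [100.0] * 3,
                          "area_transverse_um2": [20.0] * 3,
                          "area_bb_transverse_um2": [25.0] * 3})
        with pytest.raises(ValueError, match="8"):
            gm.mean_cell_params(t, stages=[6, 8])

    def test_generator_means_match_programmed_values(self, trunk_data):
        data, feats = trunk_data
        gt = data.ground_truth
        p = gm.mean_cell_params(
            feats, l_col="l_ap_um", v_col="volume_um3",
            a_col="area_transverse_um2",
        )
        truth = gt.groupby("stage")[["l_ap_um", "volume_um3", "area_um2"]].mean()
        for s in p.stages:
            assert p.at(s, "l_ap") == pytest.approx(truth.loc[s, "l_ap_um"], rel=0.02)
            assert p.at(s, "volume") == pytest.approx(
                truth.loc[s, "volume_um3"], rel=0.02
            )


class TestScenarioNeighborhood:
    def _series(self, betas, n=10):
        t = pd.DataFrame({"beta": betas})
        t.index = pd.Index([6, 10], name="stage")
        t["l_n_um"] = np.nan
        return gm.IntercalationSeries(n=n, table=t)

    def test_intercalation_only_doubles_with_beta(self):
        p = _eq1_consistent_params(50.0, 10.0, 50.0, 10.0)
        series = self._series([0.5, 1.0])
        out = gm.scenario_neighborhood(p, series, "intercalation_only")
        lengths = out["neighborhood_length_um"].to_numpy()
        assert lengths[0] == pytest.approx(25.0)
        assert lengths[1] == pytest.approx(50.0)
        assert out["pct_change"].iloc[-1] == pytest.approx(100.0)

    def test_full_scenario_reproduces_measured_lengths(self, trunk_data):
        """Closure: feeding the measured betas and lengths back through the
        group-length relation reproduces the measured extents exactly."""
        data, _ = trunk_data
        gt = data.ground_truth.rename(
            columns={"area_um2": "area_transverse_um2"}
        )
        params = gm.mean_cell_params(gt)
        nl = gm.neighbourhood_lengths(
            gt, x_left_col="x_left_um", x_right_col="x_right_um"
        )
        series = gm.IntercalationSeries(n=10, table=nl)
        out = gm.scenario_neighborhood(params, series, "full")
        predicted = out.set_index("stage")["neighborhood_length_um"]
        measured = series.n * nl["beta"] * nl["l_ap_mean_um"]
        assert np.allclose(predicted, measured, rtol=1e-12)

    def test_shape_no_growth_underestimates_full(self, trunk_data):
        """Without growth, the staged spreading + intercalation programme
        cannot reproduce the measured neighbourhood elongation."""
        data, _ = trunk_data
        gt = data.ground_truth.rename(columns={"area_um2": "area_transverse_um2"})
        params = gm.mean_cell_params(gt)
        nl = gm.neighbourhood_lengths(
            gt, x_left_col="x_left_um", x_right_col="x_right_um"
        )
        series = gm.IntercalationSeries(n=10, table=nl)
        full = gm.scenario_neighborhood(params, series, "full")
        no_growth = gm.scenario_neighborhood(params, series, "shape_no_growth")
        assert (
            no_growth["pct_change"].iloc[-1] < full["pct_change"].iloc[-1]
        )

    def test_unknown_scenario_fails(self):
        p = _eq1_consistent_params(50.0, 10.0, 50.0, 10.0)
        with pytest.raises(ValueError, match="unknown scenario"):
            gm.scenario_neighborhood(p, self._series([0.5, 1.0]), "teleport")


class TestElongationComparison:
    def test_identical_series_zero_gap(self):
        s = pd.Series([10.0, 20.0, 30.0], index=[6, 8, 10])
        out = gm.elongation_comparison(s, s.copy())
        assert np.allclose(out["gap"], 0.0)

    def test_constant_series_flat_at_one(self):
        s = pd.Series([10.0, 10.0], index=[6, 8])
        out = gm.elongation_comparison(s, s.copy())
        assert np.allclose(out["tissue_rel"], 1.0)

    def test_posterior_addition_opens_positive_gap(self):
        """A generator run that adds posterior cells at later stages makes
        tissue-scale elongation outrun the 10-cell neighbourhoods."""
        from notomorph import synthetic as syn

        cfg = syn.trunk_config(
            cells_per_stage={6: 40, 8: 44, 10: 52, 12: 60, 14: 70},
            seed=13,
        )
        gt = syn.generate_notochord(cfg).ground_truth
        tissue = gt.groupby("stage").apply(
            lambda g: g["x_right_um"].max() - g["x_left_um"].min(),
            include_groups=False,
        )
        nl = gm.neighbourhood_lengths(
            gt, x_left_col="x_left_um", x_right_col="x_right_um"
        )
        out = gm.elongation_comparison(nl["l_n_um"], tissue)
        assert (out["gap"].iloc[1:] > 0).all()

    def test_mismatched_stages_fail(self):
        a = pd.Series([1.0, 2.0], index=[6, 8])
        b = pd.Series([1.0, 2.0], index=[6, 10])
        with pytest.raises(ValueError, match="share stages"):
            gm.elongation_comparison(a, b)
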