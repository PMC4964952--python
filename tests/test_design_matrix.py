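import numpy as np
import pytest
from scipy.integrate import quad

from cengrm import Dataset, ModelSpec, build_design
from cengrm.design_matrix import (
    darcy_flux,
    encode_sum_to_zero,
    fourier_seasonal,
    implied_level_coefficient,
    legendre_spatial,
    national_comprehensive,
    national_final,
)

from conftest import make_survey


class TestSumToZero:
    def test_contrast_definition_three_levels(self):
        C, kept, implied = encode_sum_to_zero(["a", "b", "c"],
                                              ["a", "b", "c", "a"])
        assert kept == ["a", "b"] and implied == "c"
        assert C[0].tolist() == [1.0, 0.0]      # "a"
        assert C[2].tolist() == [-1.0, -1.0]    # implied level
        assert C.shape == (4, 2)

    def test_fifteen_levels_give_fourteen_columns(self):
        levels = [f"g{i:02d}" for i in range(15)]
        C, kept, _ = encode_sum_to_zero(levels, levels * 2)
        assert C.shape[1] == 14

    def test_implied_coefficient_recovery(self):
        assert implied_level_coefficient([0.2, -0.5]) == pytest.approx(0.3)

    def test_single_level_inestimable(self):
        with pytest.raises(ValueError):
            encode_sum_to_zero(["a", "b"], ["a", "a"])


class TestLegendre:
    def test_midpoint_and_corner_values(self):
        bbox = (88.0, 92.0, 20.0, 26.0)
        X, names = legendre_spatial([90.0], [23.0], bbox, degree=2)
        row = dict(zip(names, X[0]))
        assert row["lon_P1"] == pytest.approx(0.0)
        assert row["lon_P2"] == pytest.approx(-0.5)
        assert row["lat_P2"] == pytest.approx(-0.5)
        X, names = legendre_spatial([92.0], [26.0], bbox, degree=2)
        row = dict(zip(names, X[0]))
        assert row["lon_P1"] == pytest.approx(1.0)
        assert row["lon_P2"] == pytest.approx(1.0)

    def test_basis_column_count(self):
        bbox = (0.0, 1.0, 0.0, 1.0)
        X1, _ = legendre_spatial([0.3], [0.7], bbox, degree=1)
        X2, _ = legendre_spatial([0.3], [0.7], bbox, degree=2)
        assert X1.shape[1] == 2
        assert X2.shape[1] == 7

    def test_orthogonality_by_quadrature(self):
        val, _ = quad(lambda x: x * 0.5 * (3 * x**2 - 1), -1, 1)
        assert abs(val) < 1e-12

    def test_outside_bbox_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            legendre_spatial([5.0], [0.5], (0, 1, 0, 1), degree=1)


class TestFourierSeasonal:
    @pytest.mark.parametrize(
        "date,expect_cos,expect_sin",
        [
            ("1998-12-31", 1.0, 0.0),     # day 365, full period
            ("1998-07-02", -1.0, 0.0),    # day 183 ~ half period
            ("1998-04-02", 0.0, 1.0),     # day 92 ~ quarter period
        ],
    )
    def test_period_landmarks(self, date, expect_cos, expect_sin):
        c, s = fourier_seasonal([date])
        assert c[0] == pytest.approx(expect_cos, abs=0.03)
        assert s[0] == pytest.approx(expect_sin, abs=0.03)

    def test_leap_day_maps_to_day_sixty(self):
        c_leap, s_leap = fourier_seasonal(["1996-02-29"])
        c_mar, s_mar = fourier_seasonal(["1997-03-01"])  # also day 60
        assert c_leap[0] == pytest.approx(c_mar[0])
        assert s_leap[0] == pytest.approx(s_mar[0])


class TestDarcyFlux:
    def test_formula_and_sign(self):
        assert darcy_flux(10.0, 0.001) == pytest.approx(-0.01)
        assert darcy_flux(5.0, 0.0) == 0.0
        assert np.sign(darcy_flux(3.0, -0.2)) == 1.0

    def test_negative_conductivity_rejected(self):
        with pytest.raises(ValueError):
            darcy_flux(-1.0, 0.1)


class TestBuildDesign:
    def test_single_continuous_gives_two_columns(self, small_dataset):
        dm = build_design(ModelSpec(continuous_terms=("tssc",)), small_dataset)
        assert dm.p == 2
        assert dm.columns == ["intercept", "tssc"]

    def test_geology_and_three_interactions_column_count(self):
        # 15-level geology main effect (14 columns) plus three interactions
        # (3 x 14 = 42): 56 columns, the degrees of freedom of the block
        survey, cov = make_survey(n=60, seed=11, geology=tuple(
            ["afo", "afy", "acl", "as", "asl", "ava", "br", "bs", "de",
             "dsd", "dsl", "dt", "mcp", "rb", "rm"]))
        ds = Dataset(survey, cov)
        spec = ModelSpec(
            continuous_terms=("depth", "tssc", "pgi_recharge"),
            categorical_terms=("geology",),
            interactions=(("geology", "depth"), ("geology", "tssc"),
                          ("geology", "pgi_recharge")),
        )
        dm = build_design(spec, ds)
        geo_cols = dm.term_blocks["geology"]
        inter_cols = [j for t, idx in dm.term_blocks.items() if ":" in t
                      for j in idx]
        assert len(geo_cols) == 14
        assert len(geo_cols) + len(inter_cols) == 56

    def test_interaction_is_contrast_times_covariate(self, small_dataset):
        spec = ModelSpec(continuous_terms=("tssc",),
                         categorical_terms=("geology",),
                         interactions=(("geology", "tssc"),))
        dm = build_design(spec, small_dataset)
        C = dm.X[:, dm.term_blocks["geology"]]
        v = small_dataset.joined()["tssc"].to_numpy(float)
        np.testing.assert_allclose(
            dm.X[:, dm.term_blocks["geology:tssc"]], C * v[:, None])

    def test_block_deletion_equals_reduced_spec(self, small_dataset):
        full = ModelSpec(continuous_terms=("tssc", "k_h"),
                         categorical_terms=("geology",))
        dm_full = build_design(full, small_dataset)
        dm_red = dm_full.drop_columns(dm_full.term_blocks["k_h"])
        dm_direct = build_design(full.drop_term("k_h"), small_dataset)
        assert dm_red.columns == dm_direct.columns
        np.testing.assert_allclose(dm_red.X, dm_direct.X)

    def test_categorical_contributions_sum_to_zero(self, small_dataset):
        spec = ModelSpec(categorical_terms=("geology",))
        dm = build_design(spec, small_dataset)
        C = dm.X[:, dm.term_blocks["geology"]]
        beta = np.array([0.4, -0.7])
        contrib = {g: None for g in ("dsd", "dsl", "dt")}
        geo = small_dataset.joined()["geology"]
        for g in contrib:
            contrib[g] = float((C[geo == g][0] * beta).sum())
        assert sum(contrib.values()) == pytest.approx(0.0)

    def test_deterministic(self, small_dataset):
        spec = ModelSpec(continuous_terms=("tssc",),
                         categorical_terms=("geology",),
                         spatial_poly_degree=2)
        a = build_design(spec, small_dataset)
        b = build_design(spec, small_dataset)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.bbox == b.bbox

    def test_missing_value_names_sites(self, small_dataset):
        small_dataset.covariates.loc[3, "tssc"] = np.nan
        with pytest.raises(ValueError, match="W003"):
            build_design(ModelSpec(continuous_terms=("tssc",)), small_dataset)

    def test_collinear_design_rejected(self, small_dataset):
        small_dataset.covariates["k_h"] = 2.0 * small_dataset.covariates["tssc"]
        with pytest.raises(ValueError, match="collinear|rank"):
            build_design(ModelSpec(continuous_terms=("tssc", "k_h")),
                         small_dataset)


def test_preset_shapes():
    comp, final = national_comprehensive(), national_final()
    assert len(comp.continuous_terms) == 12
    assert len(comp.interactions) == 3
    assert comp.seasonal and comp.spatial_poly_degree == 2
    assert len(final.continuous_terms) == 7
    assert not final.seasonal


def test_spec_yaml_round_trip(tmp_path):
    spec = national_final()
    p = tmp_path / "spec.yaml"
    spec.to_yaml(p)
    assert ModelSpec.from_yaml(p) == spec
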