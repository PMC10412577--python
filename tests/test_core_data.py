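import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccosol.core_data import (
    InvalidDensityError,
    InvalidGeometryError,
    MeasurementGeometry,
    SchemaError,
    SolubilityDataset,
    SolubilityRecord,
    UncertaintyBudget,
    concentration_to_mole_fraction,
    concentration_to_solubility,
    load_dataset,
    load_solute,
    propagate_uncertainty,
    save_dataset,
    save_solute,
    solubility_to_concentration,
)


class TestSampleConversions:
    def test_solubility_is_vial_concentration_scaled_by_volume_ratio(self, geometry):
        # Vs/Vl = 25/3
        assert concentration_to_solubility(0.012, geometry) == pytest.approx(0.1)
        assert concentration_to_solubility(0.0, geometry) == 0.0
        # inverse of the (308 K, 120 bar) solubility entry
        assert concentration_to_solubility(1.92e-3, geometry) == pytest.approx(0.016)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            MeasurementGeometry(Vs=1e-4, Vl=6e-4)

    @given(st.floats(min_value=1e-6, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_solubility_conversion_round_trip(self, cs):
        geom = MeasurementGeometry()
        assert solubility_to_concentration(
            concentration_to_solubility(cs, geom), geom
        ) == pytest.approx(cs, rel=1e-12)

    def test_mole_fraction_from_vial_concentration(self, geometry, nhm_props):
        # hand arithmetic: n_s = 1.644e-8 mol, n_CO2 = 1.048e-2 mol
        y2 = concentration_to_mole_fraction(1.92e-3, 769.0, nhm_props, geometry)
        assert y2 == pytest.approx(1.568e-6, rel=1e-3)
        assert concentration_to_mole_fraction(0.0, 769.0, nhm_props, geometry) == 0.0

    def test_mole_fraction_equal_moles_gives_half(self, geometry, nhm_props):
        rho = 769.0
        n_co2 = geometry.Vl * rho / geometry.M_co2
        cs = n_co2 * nhm_props.Mw / geometry.Vs
        assert concentration_to_mole_fraction(cs, rho, nhm_props, geometry) == pytest.approx(0.5)

    def test_mole_fraction_rejects_nonpositive_density(self, geometry, nhm_props):
        with pytest.raises(InvalidDensityError):
            concentration_to_mole_fraction(0.01, 0.0, nhm_props, geometry)

    @given(
        cs=st.floats(min_value=1e-6, max_value=1.0),
        bump=st.floats(min_value=1e-3, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_mole_fraction_monotone_in_concentration_and_density(self, cs, bump, nhm_props):
        geom = MeasurementGeometry()
        base = concentration_to_mole_fraction(cs, 700.0, nhm_props, geom)
        assert concentration_to_mole_fraction(cs + bump, 700.0, nhm_props, geom) > base
        assert concentration_to_mole_fraction(cs, 700.0 + bump, nhm_props, geom) < base


class TestUncertainty:
    def test_single_component(self):
        budget = UncertaintyBudget(components=((1.0, 0.02, 1.0),), coverage_k=2.0)
        u_rel, U = propagate_uncertainty(budget, 1.0)
        assert u_rel == pytest.approx(0.02)
        assert U == pytest.approx(0.04)

    def test_zero_uncertainties(self):
        budget = UncertaintyBudget(components=((1.0, 0.0, 2.0), (3.0, 0.0, 5.0)))
        assert propagate_uncertainty(budget, 1.0) == (0.0, 0.0)

    def test_three_four_five_identity(self):
        budget = UncertaintyBudget(components=((1.0, 0.03, 1.0), (1.0, 0.04, 1.0)))
        u_rel, _ = propagate_uncertainty(budget, 1.0)
        assert u_rel == pytest.approx(0.05)

    def test_zero_nominal_reports_component(self):
        budget = UncertaintyBudget(components=((1.0, 0.1, 1.0), (1.0, 0.1, 0.0)))
        with pytest.raises(ZeroDivisionError, match="1"):
            propagate_uncertainty(budget, 1.0)

    @given(
        comps=st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=5),
                st.floats(min_value=0.0, max_value=0.5),
                st.floats(min_value=0.1, max_value=10),
            ),
            min_size=2,
            max_size=6,
        ),
        scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_homogeneity(self, comps, scale):
        budget = UncertaintyBudget(components=tuple(comps))
        permuted = UncertaintyBudget(components=tuple(reversed(comps)))
        u1, _ = propagate_uncertainty(budget, 1.0)
        u2, _ = propagate_uncertainty(permuted, 1.0)
        assert u1 == pytest.approx(u2, rel=1e-12)
        scaled = UncertaintyBudget(components=tuple((p, scale * u, x) for p, u, x in comps))
        u3, _ = propagate_uncertainty(scaled, 1.0)
        assert u3 == pytest.approx(scale * u1, rel=1e-9)


class TestFixture:
    def test_shape_and_extremes(self, nhm_data):
        assert len(nhm_data) == 24
        assert nhm_data.temperatures == (308.0, 318.0, 328.0, 338.0)
        best = max(nhm_data.records, key=lambda r: r.S)
        assert (best.T, best.P, best.S) == (338, 270, 0.094)
        worst = min(nhm_data.records, key=lambda r: r.y2)
        assert (worst.T, worst.P) == (338, 120)
        assert worst.y2 == pytest.approx(0.032e-5)

    def test_isotherms_increase_with_pressure(self, nhm_data):
        for T in nhm_data.temperatures:
            iso = nhm_data.isotherm(T)
            y2 = iso.column("y2")
            s = iso.column("S")
            assert np.all(np.diff(y2) > 0)
            assert np.all(np.diff(s) > 0)

    def test_uncertainty_columns_ordered(self, nhm_data):
        for r in nhm_data.records:
            assert r.U >= r.sd_mean >= 0


class TestTableIO:
    def test_round_trip(self, tmp_path, nhm_data):
        path = tmp_path / "table.csv"
        save_dataset(nhm_data, path)
        back = load_dataset(path)
        assert len(back) == 24
        for a, b in zip(nhm_data.records, back.records):
            assert (a.T, a.P, a.rho, a.y2, a.S, a.sd_mean, a.U) == (
                b.T, b.P, b.rho, b.y2, b.S, b.sd_mean, b.U,
            )

    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            load_dataset(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_bar\n308,120\n")
        with pytest.raises(SchemaError, match="rho_kg_m3"):
            load_dataset(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "T_K,P_bar,rho_kg_m3,y2,S_g_L,sd_mean,U_expanded\n"
            "308,120,769,1e-6,0.016,,\n308,150,oops,1.2e-6,0.02,,\n"
        )
        with pytest.raises(SchemaError, match="row 2.*rho_kg_m3"):
            load_dataset(path)

    def test_duplicate_condition_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "T_K,P_bar,rho_kg_m3,y2,S_g_L,sd_mean,U_expanded\n"
            "308,120,769,1e-6,0.016,,\n308,120,769,1.2e-6,0.02,,\n"
        )
        with pytest.raises(SchemaError, match="duplicate"):
            load_dataset(path)

    def test_solute_yaml_round_trip(self, tmp_path, nhm_props):
        path = tmp_path / "solute.yaml"
        save_solute(nhm_props, path)
        back = load_solute(path)
        assert back == nhm_props


class TestRecordValidation:
    def test_mole_fraction_bounds(self):
        with pytest.raises(ValueError):
            SolubilityRecord(T=308, P=120, rho=769, y2=1.5, S=0.01)

    def test_dataset_sorted_and_unique(self):
        r1 = SolubilityRecord(T=318, P=120, rho=661, y2=1e-6, S=0.01)
        r2 = SolubilityRecord(T=308, P=150, rho=817, y2=1e-6, S=0.01)
        ds = SolubilityDataset((r1, r2))
        assert [r.T for r in ds.records] == [308, 318]
        with pytest.raises(ValueError, match="duplicate"):
            SolubilityDataset((r1, r1))
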