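"""Fraction schemes, analyte unit conversion, and study I/O."""

import math

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustrisk import (
    AnalyteDescriptor,
    FractionScheme,
    ValidationError,
    convert_oxide_to_element,
    load_study,
    oxide_to_element_factor,
    write_study,
)
from dustrisk.analytes import element_descriptor, oxide_descriptor, to_mg_per_kg
from dustrisk.study import substitute_lod


class TestFractionScheme:
    def test_default_labels_and_bounds(self):
        s = FractionScheme((800, 500, 250, 125, 45))
        assert s.labels == ("<45", "45-125", "125-250", "250-500", "500-800")
        assert s.oversize_label == ">800"
        assert s.bounds[0] == (0.0, 45.0)
        assert s.bounds[-1] == (500.0, 800.0)
        assert s.discard_above == 800.0

    @pytest.mark.parametrize("pts", [(), (45, 125), (800, 800), (-5, -10), (0, -1)])
    def test_invalid_cut_points_rejected(self, pts):
        with pytest.raises(ValidationError):
            FractionScheme(pts)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="900-1000"):
            FractionScheme().validate_label("900-1000")


class TestOxideConversion:
    # expected values frozen from a hand computation with IUPAC 2021
    # atomic masses (Fe 55.845, Ca 40.078, Al 26.982, O 15.999)
    @pytest.mark.parametrize("oxide,wt,expected", [
        ("Fe2O3", 5.0, 34971.538071352086),
        ("CaO", 1.0, 7146.958646147261),
        ("Al2O3", 14.12, 74731.67975990819),
        ("Fe2O3", 0.0, 0.0),
    ])
    def test_oxide_wt_percent_to_element_mg_per_kg(self, oxide, wt, expected):
        got = convert_oxide_to_element(wt, oxide_descriptor(oxide))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_factor_in_unit_interval(self):
        for ox in ("SiO2", "Al2O3", "Fe2O3", "MnO", "MgO", "CaO", "Na2O", "K2O",
                   "TiO2", "P2O5"):
            assert 0 < oxide_to_element_factor(ox) < 1

    def test_element_form_is_contract_violation(self):
        with pytest.raises(ValidationError, match="element-form"):
            convert_oxide_to_element(1.0, element_descriptor("Zn"))

    def test_normalisation_idempotent_for_element_basis(self):
        d = element_descriptor("Cu")
        assert to_mg_per_kg(123.456, d) == 123.456

    def test_oxide_descriptor_requires_factor(self):
        with pytest.raises(ValidationError):
            AnalyteDescriptor(name="XO", form="oxide", unit="wt_percent",
                              oxide_to_element=None)


class TestLodSubstitution:
    @pytest.mark.parametrize("rule,expected", [
        ("zero", 0.0), ("half", 2.5), ("full", 5.0)])
    def test_rules(self, rule, expected):
        assert substitute_lod(float("nan"), 5.0, rule) == expected

    def test_unknown_rule(self):
        with pytest.raises(ValidationError):
            substitute_lod(1.0, 5.0, "threequarters")


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory, bundle):
    d = tmp_path_factory.mktemp("study")
    write_study(bundle, d)
    return d


class TestStudyIO:
    def test_roundtrip_is_exact(self, study_dir, bundle):
        """Writing then re-loading reproduces every concentration bit-exactly."""
        re = load_study(study_dir / "concentrations.csv", study_dir / "sites.csv",
                        study_dir / "config.yaml")
        assert len(re.concentrations.pairs) == 30
        orig = bundle.concentrations.values.sort_index()
        back = re.concentrations.values.sort_index()[orig.columns]
        pd.testing.assert_frame_equal(orig, back, check_exact=True)
        pd.testing.assert_series_equal(
            bundle.background.values.sort_index(),
            re.background.values.sort_index(), check_exact=True, check_names=False)

    def test_below_lod_substitution_and_flag(self, study_dir, tmp_path):
        conc = pd.read_csv(study_dir / "concentrations.csv")
        # censor one As cell: value column carries the LOD
        mask = (conc.analyte == "As") & (conc.site_id == "S1") & (conc.fraction_label == "<45")
        conc.loc[mask, "below_lod"] = True
        conc.loc[mask, "value"] = 4.0
        p = tmp_path / "conc.csv"
        conc.to_csv(p, index=False)
        re = load_study(p, study_dir / "sites.csv", study_dir / "config.yaml")
        assert re.concentrations.below_lod.loc[("S1", "<45"), "As"]
        assert re.concentrations.values.loc[("S1", "<45"), "As"] == 2.0  # LOD/2
        assert re.concentrations.lod["As"] == 4.0

    @pytest.mark.parametrize("mutation,match", [
        (lambda c, s: c.assign(fraction_label=c.fraction_label.replace("<45", "900-1000")),
         "900-1000"),
        (lambda c, s: c.assign(value=[-1.0] + list(c.value[1:])), "negative"),
        (lambda c, s: c.assign(site_id=c.site_id.replace("S1", "S99")), "S99"),
        (lambda c, s: c.drop(columns=["analyte"]), "missing columns"),
    ])
    def test_malformed_concentration_tables_rejected(self, study_dir, tmp_path,
                                                     mutation, match):
        conc = pd.read_csv(study_dir / "concentrations.csv")
        sites = pd.read_csv(study_dir / "sites.csv")
        p = tmp_path / "bad.csv"
        mutation(conc, sites).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=match):
            load_study(p, study_dir / "sites.csv", study_dir / "config.yaml")

    def test_mixed_units_for_one_analyte_rejected(self, study_dir, tmp_path):
        conc = pd.read_csv(study_dir / "concentrations.csv")
        first_al = conc.index[conc.analyte == "Al2O3"][0]
        conc.loc[first_al, "unit"] = "wt_percent"  # rest stay mg_per_kg
        p = tmp_path / "bad_unit.csv"
        conc.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="reported in"):
            load_study(p, study_dir / "sites.csv", study_dir / "config.yaml")

    @pytest.mark.parametrize("mutation,match", [
        (lambda s: s.drop(columns=["<45"]), "mass column"),
        (lambda s: s.assign(area_swept_m2=0.0), "area_swept_m2"),
        (lambda s: s.assign(land_use="harbour"), "land use"),
        (lambda s: s.assign(total_mass_g=s.total_mass_g / 10.0), "exceeding total"),
        (lambda s: s.assign(**{"<45": -1.0}), ">= 0"),
    ])
    def test_malformed_site_tables_rejected(self, study_dir, tmp_path, mutation, match):
        sites = pd.read_csv(study_dir / "sites.csv")
        p = tmp_path / "sites.csv"
        mutation(sites).to_csv(p, index=False)
        with pytest.raises(ValidationError, match=match):
            load_study(study_dir / "concentrations.csv", p, study_dir / "config.yaml")
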