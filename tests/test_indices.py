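"""Enrichment factor, geo-accumulation index and their classifications."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustrisk import (
    CONSERVATIVE_OXIDES,
    ValidationError,
    classify_enrichment,
    classify_igeo,
    compute_pollution,
    enrichment_factor,
    geoaccumulation_index,
    reference_sum,
)
from dustrisk.indices import index_summary
from dustrisk.study import BackgroundReference

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestReferenceSum:
    def test_unit_components_sum(self):
        c = {a: 1.0 for a in CONSERVATIVE_OXIDES}
        assert reference_sum(c, CONSERVATIVE_OXIDES) == 6.0

    def test_brute_force_addition(self):
        # independent oracle: plain running total over realistic values
        vals = {"Al2O3": 74731.7, "MgO": 10854.7, "Na2O": 15579.1,
                "K2O": 25734.4, "TiO2": 3296.5, "P2O5": 654.6}
        expected = 0.0
        for v in vals.values():
            expected += v
        assert reference_sum(vals, CONSERVATIVE_OXIDES) == pytest.approx(expected)

    def test_missing_component_named(self):
        c = {a: 1.0 for a in CONSERVATIVE_OXIDES if a != "TiO2"}
        with pytest.raises(ValidationError, match="TiO2"):
            reference_sum(c, CONSERVATIVE_OXIDES)

    @given(k=positive)
    def test_homogeneity(self, k):
        c = {a: float(i + 1) for i, a in enumerate(CONSERVATIVE_OXIDES)}
        scaled = {a: k * v for a, v in c.items()}
        assert reference_sum(scaled, CONSERVATIVE_OXIDES) == pytest.approx(
            k * reference_sum(c, CONSERVATIVE_OXIDES), rel=1e-9)


class TestEnrichmentFactor:
    def test_background_identity(self):
        assert enrichment_factor(10, 100, 10, 100) == 1.0

    def test_worked_double_ratio(self):
        assert enrichment_factor(100, 10, 20, 40) == pytest.approx(20.0)

    def test_zero_background_undefined(self):
        with pytest.raises(ValidationError, match="xi_background"):
            enrichment_factor(1, 1, 0, 1)

    @given(xi_s=positive, eref_s=positive, xi_b=positive, eref_b=positive,
           k_sample=positive, k_background=positive)
    def test_invariance_under_common_layer_rescale(self, xi_s, eref_s, xi_b, eref_b,
                                                   k_sample, k_background):
        base = enrichment_factor(xi_s, eref_s, xi_b, eref_b)
        scaled = enrichment_factor(k_sample * xi_s, k_sample * eref_s,
                                   k_background * xi_b, k_background * eref_b)
        assert scaled == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("ef,label", [
        (1.0, "deficiency to minimal enrichment"),
        (1.999, "deficiency to minimal enrichment"),
        (2.0, "moderate enrichment"),
        (5.0, "significant enrichment"),
        (20.0, "very high enrichment"),
        (40.0, "extremely high enrichment"),
        (1e6, "extremely high enrichment"),
    ])
    def test_classification_left_closed(self, ef, label):
        assert classify_enrichment(ef) == label


class TestIgeo:
    def test_one_and_a_half_background_is_zero(self):
        assert geoaccumulation_index(1.5 * 7.0, 7.0) == 0.0

    def test_triple_background_is_one(self):
        assert geoaccumulation_index(3.0 * 7.0, 7.0) == pytest.approx(1.0)

    def test_equal_to_background(self):
        assert geoaccumulation_index(7.0, 7.0) == pytest.approx(-0.5849625007211563)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            geoaccumulation_index(0.0, 1.0)

    @given(c1=positive, c2=positive, b=positive)
    def test_strictly_increasing_in_concentration(self, c1, c2, b):
        lo, hi = min(c1, c2), max(c1, c2)
        if lo < hi:
            assert geoaccumulation_index(lo, b) < geoaccumulation_index(hi, b)

    @given(c=positive, b1=positive, b2=positive)
    def test_strictly_decreasing_in_background(self, c, b1, b2):
        lo, hi = min(b1, b2), max(b1, b2)
        if lo < hi:
            assert geoaccumulation_index(c, lo) > geoaccumulation_index(c, hi)

    @pytest.mark.parametrize("igeo,label", [
        (-0.1, "no contamination"),
        (0.0, "no contamination"),
        (0.5, "uncontaminated to moderate contamination"),
        (1.5, "moderate contamination"),
        (2.5, "moderate to heavy contamination"),
        (3.5, "heavy contamination"),
        (4.0, "heavy contamination"),
        (4.5, "heavy to extreme contamination"),
        (5.2, "extremely contaminated"),
    ])
    def test_mueller_classes(self, igeo, label):
        assert classify_igeo(igeo) == label

    def test_boundary_four_convention_flag(self):
        assert classify_igeo(4.0, four_in_heavy=False) == "heavy to extreme contamination"

    @given(st.floats(-20, 20, allow_nan=False))
    def test_classification_total_and_partitioning(self, x):
        """Every finite value maps to exactly one class under both
        boundary conventions."""
        for flag in (True, False):
            assert classify_igeo(x, four_in_heavy=flag)
        assert classify_enrichment(abs(x) + 1e-6)


class TestVectorisedPipeline:
    def test_matches_scalar_loop_oracle(self, bundle):
        """The table-driven EF/Igeo path agrees with an element-by-element
        scalar recomputation to within an ulp."""
        result = compute_pollution(bundle.concentrations, bundle.background,
                                   bundle.conservative_analytes)
        sub = result.table.sample(n=60, random_state=0)
        for row in sub.itertuples(index=False):
            sample = bundle.concentrations.values.loc[(row.site_id, row.fraction_label)]
            eref_s = sum(float(sample[a]) for a in bundle.conservative_analytes)
            eref_b = sum(float(bundle.background.values[a])
                         for a in bundle.conservative_analytes)
            c = float(sample[row.analyte])
            b = float(bundle.background.values[row.analyte])
            assert row.ef == pytest.approx((c / eref_s) / (b / eref_b), rel=1e-14)
            assert row.igeo == pytest.approx(np.log2(c / (1.5 * b)), rel=1e-14)

    def test_missing_background_analyte_named(self, bundle):
        background = BackgroundReference(
            values=bundle.background.values.drop("TiO2"), source_label="broken")
        with pytest.raises(ValidationError, match="TiO2"):
            compute_pollution(bundle.concentrations, background,
                              bundle.conservative_analytes)

    def test_fine_coarse_ratio_single_site_identity(self, noiseless_bundle):
        res = compute_pollution(noiseless_bundle.concentrations,
                                noiseless_bundle.background,
                                noiseless_bundle.conservative_analytes)
        summ = index_summary(res, noiseless_bundle.scheme)
        # noiseless generator: Sn target EF endpoints give ratio 9.0/1.5
        assert summ.loc["Sn", "ef_fine_coarse_ratio"] == pytest.approx(6.0, rel=1e-9)
        assert summ.loc["Sn", "ef_<45"] == pytest.approx(9.0, rel=1e-9)
        assert summ.loc["Sn", "ef_500-800"] == pytest.approx(1.5, rel=1e-9)
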