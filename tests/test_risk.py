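"""Three-route doses, hazard quotient/index and carcinogenic risk."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dustrisk import (
    DEFAULT_EXPOSURE,
    ValidationError,
    add_dermal,
    add_ingestion,
    add_inhalation,
    carcinogenic_risk,
    classify_cri,
    compute_risk,
    contribution_shares,
    hazard_index,
    hazard_quotient,
    lifetime_average_daily_dose,
)
from dustrisk.params import RECEPTORS, ROUTES
from dustrisk.risk import average_daily_dose, contact_rate

F = DEFAULT_EXPOSURE
conc = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestDoses:
    # frozen hand computations from the default exposure factors
    @pytest.mark.parametrize("fn,receptor,expected", [
        (add_ingestion, "child", 9.863013698630137e-4),
        (add_inhalation, "child", 2.7667203867848508e-8),
        (add_dermal, "child", 1.5780821917808219e-6),
        (add_dermal, "adult", 3.2178082191780817e-6),
    ])
    def test_dose_per_1000_mg_per_kg(self, fn, receptor, expected):
        assert fn(1000.0, F, receptor) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration_zero_dose(self):
        for route in ROUTES:
            for receptor in RECEPTORS:
                assert average_daily_dose(0.0, F, receptor, route) == 0.0

    def test_child_adult_ingestion_ratio(self):
        r = add_ingestion(1000, F, "child") / add_ingestion(1000, F, "adult")
        assert r == pytest.approx((200 / 15) / (100 / 70), rel=1e-12)  # 9.333…

    def test_inhalation_far_below_ingestion(self):
        ratio = add_inhalation(1000, F, "child") / add_ingestion(1000, F, "child")
        assert ratio < 1e-4

    def test_unknown_receptor_rejected(self):
        with pytest.raises(ValidationError, match="receptor"):
            add_ingestion(1.0, F, "teenager")

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            add_ingestion(-1.0, F, "child")

    @given(c=conc, k=st.floats(0.0, 100.0))
    def test_degree_one_homogeneity(self, c, k):
        for route in ROUTES:
            assert average_daily_dose(k * c, F, "child", route) == pytest.approx(
                k * average_daily_dose(c, F, "child", route), rel=1e-9, abs=1e-300)

    @given(c=st.floats(1e-3, 1e6))
    def test_child_dose_exceeds_adult_for_every_route_total(self, c):
        child = sum(average_daily_dose(c, F, "child", r) for r in ROUTES)
        adult = sum(average_daily_dose(c, F, "adult", r) for r in ROUTES)
        assert child > adult


class TestHazard:
    def test_hq_division(self):
        assert hazard_quotient(9.863013698630137e-4, 0.003) == pytest.approx(0.3288, abs=1e-4)

    def test_hq_boundary_identity(self):
        assert hazard_quotient(0.003, 0.003) == 1.0

    def test_absent_rfd_skipped_not_zero(self):
        assert hazard_quotient(1.0, None) is None
        assert hazard_index([0.2, None, 0.05]) == pytest.approx(0.25)

    def test_hi_is_sum_of_terms(self):
        assert hazard_index([0.2, 0.05, 0.01]) == pytest.approx(0.26)
        assert hazard_index([0.7]) == 0.7

    def test_all_routes_absent_is_error(self):
        with pytest.raises(ValidationError):
            hazard_index([None, None, None])


class TestLadd:
    def test_worked_inhalation_example(self):
        # 288 mg kg⁻¹: C·EF/AT_carc · Σ CR·ED/BW with PEF inside CR_inh
        got = lifetime_average_daily_dose(288.0, F, "inhalation")
        expected = 288 * 27 / (70 * 365) * (7.63 * 6 / 15 + 12.8 * 24 / 70) / 1.36e9
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.665e-9, rel=1e-3)

    def test_pef_applied_once_only_for_inhalation(self):
        ing = contact_rate(F, F.child, "ingestion")
        assert ing == pytest.approx(200 * 1e-6, rel=1e-12)
        derm = contact_rate(F, F.child, "dermal")
        assert derm == pytest.approx(1600 * 0.2 * 0.001 * 1e-6, rel=1e-12)
        inh = contact_rate(F, F.child, "inhalation")
        assert inh == pytest.approx(7.63 / 1.36e9, rel=1e-12)

    def test_as_printed_variant_differs(self):
        default = lifetime_average_daily_dose(288.0, F, "inhalation")
        printed = lifetime_average_daily_dose(288.0, F, "inhalation", as_printed=True)
        assert printed != pytest.approx(default, rel=0.01)

    @given(c=conc, k=st.floats(0.0, 50.0))
    def test_ladd_linear_in_concentration(self, c, k):
        for route in ROUTES:
            assert lifetime_average_daily_dose(k * c, F, route) == pytest.approx(
                k * lifetime_average_daily_dose(c, F, route), rel=1e-9, abs=1e-300)


class TestCri:
    def test_product_and_class(self):
        cri, label, strict = carcinogenic_risk(1.665e-9, 42.0)
        assert cri == pytest.approx(6.99e-8, rel=1e-3)
        assert label == "negligible" and not strict

    def test_tolerable_band_with_strict_flag(self):
        cri, label, strict = carcinogenic_risk(5e-5 / 42.0, 42.0)
        assert label == "tolerable" and strict  # above the 1e-5 regulatory line

    def test_zero_dose(self):
        cri, label, strict = carcinogenic_risk(0.0, 42.0)
        assert cri == 0.0 and label == "negligible" and not strict

    def test_absent_sf_skipped(self):
        assert carcinogenic_risk(1.0, None) is None

    @pytest.mark.parametrize("cri,label", [
        (9.9e-7, "negligible"), (1e-6, "tolerable"), (1e-4, "tolerable"),
        (1.1e-4, "harmful")])
    def test_band_closed_at_both_ends(self, cri, label):
        assert classify_cri(cri) == label


class TestShares:
    def test_simple_components(self):
        s = contribution_shares(pd.Series({"a": 1.0, "b": 1.0, "c": 2.0}))
        assert list(s) == [25.0, 25.0, 50.0]

    def test_all_zero_undefined(self):
        with pytest.raises(ValidationError):
            contribution_shares(pd.Series({"a": 0.0}))

    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=8))
    def test_sum_to_100_and_permutation_equivariance(self, vals):
        s = pd.Series(vals, index=[f"c{i}" for i in range(len(vals))])
        shares = contribution_shares(s)
        assert shares.sum() == pytest.approx(100.0, abs=1e-6)
        perm = s.iloc[::-1]
        assert np.allclose(contribution_shares(perm), shares.iloc[::-1], rtol=1e-12)


class TestWholeStudyRisk:
    def test_scalar_loop_oracle_three_analyte_toy(self, noiseless_bundle):
        """Vectorised study-level risk equals a hand loop over a 3-analyte
        restriction of the study."""
        analytes = ["Cr", "Cu", "Zn"]
        res = compute_risk(noiseless_bundle, analytes=analytes)
        tox = noiseless_bundle.toxicity
        f = noiseless_bundle.exposure
        sub = res.hazard.sample(n=20, random_state=1)
        for row in sub.itertuples(index=False):
            c = float(noiseless_bundle.concentrations.values.loc[
                (row.site_id, row.fraction_label), row.analyte])
            hi = 0.0
            for route in ROUTES:
                rfd = tox.rfd_for(row.analyte, route)
                if rfd is not None:
                    hi += average_daily_dose(c, f, row.receptor, route) / rfd
            assert row.hi == pytest.approx(hi, rel=1e-14)

    def test_hi_equals_sum_of_route_hqs(self, bundle):
        res = compute_risk(bundle)
        doses = res.doses
        key = ["site_id", "fraction_label", "receptor", "analyte"]
        summed = doses.groupby(key)["hq"].sum(min_count=1).dropna()
        merged = res.hazard.set_index(key)["hi"]
        joined = pd.concat([summed, merged], axis=1).dropna()
        assert np.allclose(joined.iloc[:, 0], joined.iloc[:, 1], rtol=1e-12)

    def test_child_total_dose_exceeds_adult_everywhere(self, bundle):
        res = compute_risk(bundle)
        wide = res.hazard.pivot_table(index=["site_id", "fraction_label", "analyte"],
                                      columns="receptor", values="sum_add")
        assert (wide["child"] > wide["adult"]).all()

    def test_inhalation_only_carcinogens_have_single_route(self, bundle):
        res = compute_risk(bundle)
        routes = res.carcinogenic.groupby("analyte")["route"].unique()
        assert set(routes["Cr"]) == {"inhalation"}
        assert set(routes["As"]) == {"ingestion", "inhalation", "dermal"}
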