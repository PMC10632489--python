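import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petdose import (
    F18,
    DoseLimits,
    DoseTable,
    ResidenceTable,
    SValueTable,
    WeightingScheme,
    absorbed_doses,
    compliance_check,
    effective_dose,
    get_weighting_scheme,
    s_from_components,
    synthetic_s_table,
)
from petdose.dose import ICRP60_WEIGHTS, ICRP103_WEIGHTS


def _s_table(entries):
    """entries: {(target, source): S}"""
    targets = sorted({t for t, _ in entries})
    sources = sorted({s for _, s in entries})
    mat = pd.DataFrame(0.0, index=targets, columns=sources)
    for (t, s), v in entries.items():
        mat.at[t, s] = v
    return SValueTable(mat)


def _residence(taus, injected=100.0):
    return ResidenceTable(taus_h=taus, isotope=F18, injected_mbq=injected)


class TestSFromComponents:
    @pytest.mark.parametrize(
        "phi, delta, mass, expected",
        [
            ([0.5], [2.0], 100.0, 0.01),
            ([0.0, 0.0], [1.0, 5.0], 10.0, 0.0),
            ([0.3, 0.2], [1.0, 2.0], 1.0, 0.7),
        ],
        ids=["single-emission", "no-absorption", "additive"],
    )
    def test_direct_substitution(self, phi, delta, mass, expected):
        assert s_from_components(phi, delta, mass) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mass", [0.0, -5.0])
    def test_nonpositive_mass_rejected(self, mass):
        with pytest.raises(ValueError, match="mass"):
            s_from_components([0.5], [1.0], mass)

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            s_from_components([1.2], [1.0], 10.0)

    def test_provenance_rebuild_must_match_stored_s(self):
        mat = pd.DataFrame([[0.02]], index=["liver"], columns=["liver"])
        prov = pd.DataFrame(
            {"target": ["liver"], "source": ["liver"], "phi": [[0.5]], "delta": [[2.0]],
             "mass_g": [100.0]}
        )
        with pytest.raises(ValueError, match="inconsistent"):
            SValueTable(mat, provenance=prov)
        SValueTable(mat / 2, provenance=prov)  # 0.01 == 0.5*2/100


class TestAbsorbedDoses:
    def test_single_source_linearity(self):
        s = _s_table({("liver", "liver"): 3e-3, ("liver", "remainder"): 0.0})
        res = _residence({"liver": 2.0})
        # remainder is 0.6394 h here but its S is zero
        doses = absorbed_doses(res, s)
        assert doses["liver"] == pytest.approx(6.0, rel=1e-12)  # 2 h * 3 uGy/(MBq h)

    def test_superposition_over_sources(self):
        from petdose import Isotope

        s = _s_table(
            {("t", "a"): 3e-3, ("t", "b"): 4e-3, ("t", "remainder"): 0.0}
        )
        # long-lived nuclide so tau = 1 + 2 h fits the closure budget
        res = ResidenceTable(
            taus_h={"a": 1.0, "b": 2.0}, isotope=Isotope("X", 600.0), injected_mbq=100.0
        )
        doses = absorbed_doses(res, s)
        assert doses["t"] == pytest.approx(11.0, rel=1e-12)

    def test_zero_residence_gives_zero_dose(self, s_table_for):
        organs = [o for o in s_table_for.sources if o != "remainder"]
        res = ResidenceTable(
            taus_h={o: 0.0 for o in organs}, isotope=F18, injected_mbq=100.0
        )
        doses = absorbed_doses(res, s_table_for)
        # only the remainder source (full budget) contributes
        rem = res.remainder_h
        for target in s_table_for.targets:
            assert doses[target] == pytest.approx(
                rem * s_table_for.value(target, "remainder") * 1000.0, rel=1e-12
            )

    def test_missing_source_column_names_the_pair(self):
        s = _s_table({("t", "a"): 1e-3})
        with pytest.raises(KeyError, match="remainder"):
            absorbed_doses(_residence({"a": 1.0}), s)

    @given(alpha=st.floats(0.01, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_engine_is_linear_in_residence_times(self, alpha):
        base_taus = {"liver": 0.5, "lungs": 0.1, "brain": 0.02}
        s = synthetic_s_table(list(base_taus), seed=3)
        d1 = absorbed_doses(_residence(base_taus), s)
        d2 = absorbed_doses(_residence({k: alpha * v for k, v in base_taus.items()}), s)
        # split off the remainder contribution, which closure makes affine
        rem1 = _residence(base_taus).remainder_h
        rem2 = _residence({k: alpha * v for k, v in base_taus.items()}).remainder_h
        for t in s.targets:
            organ_part1 = d1[t] / 1000.0 - rem1 * s.value(t, "remainder")
            organ_part2 = d2[t] / 1000.0 - rem2 * s.value(t, "remainder")
            assert organ_part2 == pytest.approx(alpha * organ_part1, rel=1e-9)


class TestWeightingSchemes:
    def test_builtin_schemes_sum_to_one(self):
        for name in ("icrp103", "icrp60"):
            assert sum(get_weighting_scheme(name).w_t.values()) == pytest.approx(1.0, abs=1e-9)

    def test_default_bladder_weight_is_0_04(self):
        scheme = get_weighting_scheme()
        assert scheme.name == "icrp103"
        assert scheme.weight("urinary_bladder") == 0.04
        assert scheme.weight("Urinary bladder wall") == 0.04  # alias resolution

    def test_icrp60_differs_on_gonads_and_bladder(self):
        assert ICRP60_WEIGHTS["gonads"] == 0.20
        assert ICRP60_WEIGHTS["urinary_bladder"] == 0.05
        assert ICRP103_WEIGHTS["gonads"] == 0.08

    def test_unnormalized_weights_rejected_at_load(self):
        with pytest.raises(ValueError, match="sum"):
            WeightingScheme("bad", {"liver": 0.5, "lung": 0.4})

    def test_unknown_scheme_name(self):
        with pytest.raises(ValueError, match="unknown weighting scheme"):
            get_weighting_scheme("icrp999")


class TestEffectiveDose:
    def test_bladder_only_dose_weights_at_0_04(self):
        doses = DoseTable({"urinary_bladder": 100.0})
        with pytest.warns(UserWarning, match="no dose entry"):
            e = effective_dose(doses, get_weighting_scheme("icrp103"))
        assert e == pytest.approx(4.0, rel=1e-12)

    def test_uniform_dose_normalization(self):
        scheme = get_weighting_scheme("icrp103")
        doses = DoseTable({tissue: 7.5 for tissue in scheme.w_t})
        assert effective_dose(doses, scheme) == pytest.approx(7.5, rel=1e-12)

    def test_all_zero_doses(self):
        scheme = get_weighting_scheme("icrp60")
        doses = DoseTable({tissue: 0.0 for tissue in scheme.w_t})
        assert effective_dose(doses, scheme) == 0.0

    def test_permutation_of_tissue_labels_is_invariant(self):
        scheme = get_weighting_scheme("icrp103")
        tissues = list(scheme.w_t)
        rng = np.random.default_rng(11)
        values = rng.uniform(1, 50, len(tissues))
        doses = DoseTable(dict(zip(tissues, values)))
        perm = rng.permutation(len(tissues))
        permuted_scheme = WeightingScheme(
            "perm", {tissues[i]: scheme.w_t[tissues[i]] for i in perm}, scheme.w_r
        )
        assert effective_dose(doses, permuted_scheme) == pytest.approx(
            effective_dose(doses, scheme), rel=1e-12
        )

    def test_w_r_scales_linearly(self):
        doses = DoseTable({"liver": 10.0})
        s1 = WeightingScheme("a", {"liver": 1.0}, w_r=1.0)
        s2 = WeightingScheme("b", {"liver": 1.0}, w_r=2.0)
        assert effective_dose(doses, s2) == 2 * effective_dose(doses, s1)


class TestCompliance:
    def test_clinical_scale_administration_passes(self):
        # 22.47 uSv/MBq at 262.5 MBq injected -> 5.898 mSv
        report = compliance_check(22.47, 262.5)
        assert report.total_msv == pytest.approx(5.898, abs=1e-3)
        assert report.pass_all

    def test_boundary_exactly_at_limit_passes(self):
        report = compliance_check(300.0, 100.0)  # exactly 30 mSv
        assert report.total_msv == 30.0
        assert report.pass_per_administration

    def test_exceeding_administration_limit_fails(self):
        report = compliance_check(200.0, 200.0)  # 40 mSv
        assert report.total_msv == pytest.approx(40.0)
        assert not report.pass_per_administration
        assert report.pass_per_year

    def test_default_limits_encode_30_and_50_msv(self):
        limits = DoseLimits()
        assert limits.per_administration_msv == 30.0
        assert limits.per_year_msv == 50.0

    def test_inverted_limits_rejected(self):
        with pytest.raises(ValueError):
            DoseLimits(per_administration_msv=60.0, per_year_msv=50.0)


class TestSyntheticSTable:
    def test_self_dose_dominance(self):
        s = synthetic_s_table(["liver", "lungs", "brain"], seed=5)
        m = s.matrix.to_numpy()
        for i in range(m.shape[0]):
            off = np.delete(m[i], i)
            assert m[i, i] >= 10 * off.max()

    def test_seeded_determinism(self):
        a = synthetic_s_table(["liver", "lungs"], seed=9).matrix
        b = synthetic_s_table(["liver", "lungs"], seed=9).matrix
        pd.testing.assert_frame_equal(a, b)

    def test_negative_s_rejected(self):
        mat = pd.DataFrame([[-1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError, match="non-negative"):
            SValueTable(mat)
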