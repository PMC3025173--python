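"""Penetrance tables, dialect algebra and identifiability bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famlik.params import (COLLAPSED_CELLS, DialectParameters,
                           FACTOR_NAMES, ORDERED_CELLS, PenetranceOverflowError,
                           RiskParameters, UnmappableDialectError,
                           build_penetrance_table, identifiable_set,
                           solve_child_maternal, to_default_dialect, to_dialect)

from conftest import random_risk_parameters

# the worked five-parameter example: both baseline conventions reproduce
# the same 7-cell penetrance table
EXAMPLE_TABLE = {
    ("11", "11"): 0.05, ("11", "12"): 0.10,
    ("12", "11"): 0.15, ("12", "12"): 0.30, ("12", "22"): 0.60,
    ("22", "12"): 0.40, ("22", "22"): 0.80,
}


class TestPenetranceTable:
    def test_identity_parameters_give_flat_table(self):
        t = build_penetrance_table(RiskParameters(baseline_alpha=0.1), 0.3)
        assert all(v == pytest.approx(0.1) for v in t.entries.values())
        assert all(v == pytest.approx(0.1) for v in t.collapsed_view.values())

    def test_child_plus_maternal_worked_example(self):
        p = RiskParameters(r1=2, r2=4, s1=3, s2=4, baseline_alpha=0.05)
        t = build_penetrance_table(p, 0.7)
        for cell, expected in EXAMPLE_TABLE.items():
            assert t.collapsed_view[cell] == pytest.approx(expected)

    def test_double_heterozygote_mixture(self):
        # maternal imprinting 2 with even weights: 0.1 * (0.5*2 + 0.5*1)
        p = RiskParameters(im=2, baseline_alpha=0.1)
        t = build_penetrance_table(p, 0.5)
        assert t.collapsed_view[("12", "12")] == pytest.approx(0.15)

    def test_cell_counts_and_mendelian_exclusions(self):
        t = build_penetrance_table(RiskParameters(baseline_alpha=0.1), 0.5)
        assert len(t.entries) == len(ORDERED_CELLS) == 8
        assert len(t.collapsed_view) == len(COLLAPSED_CELLS) == 7
        assert ("11", "22") not in t.collapsed_view
        assert ("22", "11") not in t.collapsed_view

    def test_overflow_names_offending_cell(self):
        p = RiskParameters(r2=4, s2=4, baseline_alpha=0.1)
        with pytest.raises(PenetranceOverflowError, match="g_m=22, g_c=22"):
            build_penetrance_table(p, 0.5)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            RiskParameters(r1=-1)
        with pytest.raises(ValueError):
            RiskParameters(baseline_alpha=1.5)


class TestBaselineConventions:
    """Both the (11,11)- and (22,22)-baseline solutions are exact."""

    def test_baseline_11_solution(self):
        assert solve_child_maternal(EXAMPLE_TABLE, "11") == pytest.approx(
            (0.05, 2, 4, 3, 4))

    def test_baseline_22_solution(self):
        assert solve_child_maternal(EXAMPLE_TABLE, "22") == pytest.approx(
            (0.8, 0.5, 0.25, 0.75, 0.25))

    def test_both_parameterizations_induce_identical_tables(self):
        a1, r1, r2, s1, s2 = solve_child_maternal(EXAMPLE_TABLE, "11")
        t1 = build_penetrance_table(
            RiskParameters(r1=r1, r2=r2, s1=s1, s2=s2, baseline_alpha=a1), 0.5)
        # 22-baseline: reading the table with roles of the alleles swapped
        a2, r1b, r2b, s1b, s2b = solve_child_maternal(EXAMPLE_TABLE, "22")
        assert a2 * r2b * s2b == pytest.approx(t1.collapsed_view[("11", "11")])
        assert a2 * r1b * s1b == pytest.approx(t1.collapsed_view[("12", "12")])
        assert a2 == pytest.approx(t1.collapsed_view[("22", "22")])


class TestDialects:
    def test_identity_maps(self):
        mfg = DialectParameters("mfg_1b", {"rho1": 1, "rho2": 1, "eta1": 1,
                                           "eta2": 1, "mu0": 1, "mu2": 1})
        rp, _ = to_default_dialect(mfg)
        assert rp.factors() == {n: 1.0 for n in FACTOR_NAMES}
        pl = DialectParameters("parimi_li", {k: 0.0 for k in
                                             ("a0", "d0", "am", "dm", "i_m", "i_c")})
        rp, _ = to_default_dialect(pl)
        assert rp.factors() == pytest.approx({n: 1.0 for n in FACTOR_NAMES})

    def test_mfg_incompatibility_parameter_maps_to_interactions(self):
        dp = DialectParameters("mfg_1b", {"rho1": 1, "rho2": 1, "eta1": 1,
                                          "eta2": 1, "mu0": 4, "mu2": 1})
        rp, _ = to_default_dialect(dp)
        assert rp.g11 == pytest.approx(0.25)
        assert rp.r1 == pytest.approx(4.0)
        # verified by cell-by-cell table equality on the round trip
        back = to_dialect(rp, "mfg_1b")
        assert back.values["mu0"] == pytest.approx(4.0)

    def test_later_weinberg_r2_is_original_r2_times_imprinting(self):
        rp = RiskParameters(r1=1.5, r2=2.25, im=1.8)
        dp = to_dialect(rp, "weinberg_later_im")
        assert dp.values["r2"] == pytest.approx(2.25 * 1.8)
        back, _ = to_default_dialect(dp)
        assert back.r2 == pytest.approx(2.25)

    def test_saturated_is_the_collapsed_table(self):
        rp = RiskParameters(r1=1.5, r2=2.0, s1=1.2, baseline_alpha=0.1)
        dp = to_dialect(rp, "saturated_delta")
        t = build_penetrance_table(rp, 0.5)
        for (gm, gc), pen in t.collapsed_view.items():
            assert dp.values[f"d{gm.count('2')}{gc.count('2')}"] == \
                pytest.approx(pen)

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            DialectParameters("mfg_1b", {"rho1": 1, "rho2": 1, "eta1": 1,
                                         "eta2": 1, "mu0": 1, "mu2": 1,
                                         "bogus": 2})
        with pytest.raises(ValueError, match="missing"):
            DialectParameters("matching", {"rho1": 1})

    def test_unmappable_table_raises(self):
        rp = RiskParameters(g12=2.0)  # weinberg dialects have no interactions
        with pytest.raises(UnmappableDialectError):
            to_dialect(rp, "weinberg_original_im")


@st.composite
def imprinting_models(draw):
    names = ("r1", "r2", "s1", "s2", "im")
    vals = {n: math.exp(draw(st.floats(-1.0, 1.0))) for n in names}
    return RiskParameters(**vals)


class TestDialectProperties:
    @settings(max_examples=50, deadline=None)
    @given(imprinting_models())
    def test_imprinting_dialects_are_table_identical(self, rp):
        """Original/later, maternal/paternal imprinting dialects all span the
        same single-imprinting table family."""
        for dialect in ("weinberg_original_im", "weinberg_later_im"):
            dp = to_dialect(rp, dialect)
            back, _ = to_default_dialect(dp)
            for gm, gc in ORDERED_CELLS:
                assert back.risk_product(gm, gc) == pytest.approx(
                    rp.risk_product(gm, gc), rel=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_mfg_1b_and_two_interaction_default_span_same_family(self, seed):
        rng = np.random.default_rng(seed)
        rp = random_risk_parameters(rng, names=("r1", "r2", "s1", "s2",
                                                "g11", "g22"))
        dp = to_dialect(rp, "mfg_1b")
        back, _ = to_default_dialect(dp)
        for gm, gc in ORDERED_CELLS:
            assert back.risk_product(gm, gc) == pytest.approx(
                rp.risk_product(gm, gc), rel=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_saturated_represents_any_compatible_table(self, seed):
        rng = np.random.default_rng(seed)
        deltas = {f"d{i}{j}": float(rng.uniform(0.01, 0.99))
                  for i, j in ((0, 0), (0, 1), (1, 0), (1, 1), (1, 2),
                               (2, 1), (2, 2))}
        rp, _ = to_default_dialect(DialectParameters("saturated_delta", deltas))
        t = build_penetrance_table(
            RiskParameters(baseline_alpha=deltas["d00"],
                           **{k: v for k, v in rp.factors().items()}), 0.5)
        for (gm, gc), pen in t.collapsed_view.items():
            assert pen == pytest.approx(deltas[f"d{gm.count('2')}{gc.count('2')}"],
                                        rel=1e-10)


class TestIdentifiableSet:
    def test_trio_canonical_seven(self):
        s = identifiable_set({"case_parent_trio"}, "mating_symmetry")
        assert set(s.names()) == {"r1", "r2", "s1", "s2", "im", "g11", "g22"}
        comp = {p.name: p.composite for p in s.params}
        assert comp["r2"] == "R2*gamma12"
        assert comp["im"] == "Im/Ip"

    def test_duo_at_most_six(self):
        s = identifiable_set({"case_mother_duo"}, "hwe_rm_free_af",
                             requested=("r1", "r2", "s1", "s2", "im"))
        assert s.max_free == 6
        assert s.warning is not None

    def test_overfull_duo_request_warns(self):
        s = identifiable_set(
            {"case_mother_duo"}, "hwe_rm_free_af",
            requested=("r1", "r2", "s1", "s2", "im", "g11", "g22"))
        assert "at most 6" in s.warning

    def test_empty_structures_rejected(self):
        with pytest.raises(ValueError):
            identifiable_set(set(), "hwe_rm_free_af")
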