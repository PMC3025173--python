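"""Maximum-likelihood fitting, LRTs, method presets and the logistic comparator."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from famlik.fit import (IdentifiabilityError, ModelSpec, fit_method, fit_model,
                        likelihood_ratio_test, logistic_duo_comparator,
                        model_sequence)
from famlik.simulate import scenario_table, simulate_structure
from famlik.tables import (NuisanceModel, StructureCounts,
                           structure_cell_table)
from famlik.params import RiskParameters

SCEN = scenario_table()


def expected_counts(kind, params, a2, n=10 ** 7):
    nu = NuisanceModel(regime="hwe_rm_free_af", a2=a2)
    probs = structure_cell_table(kind, params, nu).probs
    return StructureCounts(kind, np.round(probs * n).astype(np.int64))


class TestFitModel:
    def test_recovers_generating_values_from_expected_counts(self):
        p = SCEN["C"].params
        ds = [expected_counts("case_mother_duo", p, 0.3),
              expected_counts("parents_of_control", p, 0.3)]
        spec = ModelSpec(free_risk=("r1", "r2", "s1", "s2"),
                         regime="hwe_rm_free_af")
        fr = fit_model(ds, spec)
        assert fr.converged and fr.identifiable
        assert fr.estimate("r1") == pytest.approx(1.5, rel=1e-4)
        assert fr.estimate("r2") == pytest.approx(2.25, rel=1e-4)
        assert fr.estimate("s1") == pytest.approx(1.5, rel=1e-4)
        assert fr.estimate("s2") == pytest.approx(2.25, rel=1e-4)
        assert fr.nuisance.a2 == pytest.approx(0.3, abs=1e-4)

    def test_trio_recovery_under_mating_symmetry(self):
        p = SCEN["F"].params
        ds = [expected_counts("case_parent_trio", p, 0.3)]
        spec = ModelSpec(free_risk=("r1", "r2", "s1", "s2", "im"),
                         regime="mating_symmetry")
        fr = fit_model(ds, spec)
        assert fr.estimate("im") == pytest.approx(1.8, rel=1e-3)

    def test_duo_with_five_free_risk_and_free_af_is_flagged(self):
        # allele frequency is unidentifiable from duos alone with the full
        # five-parameter imprinting model
        rng = np.random.default_rng(1)
        duo = simulate_structure("case_mother_duo", SCEN["F"], 500, rng)
        spec = ModelSpec(free_risk=("r1", "r2", "s1", "s2", "im"),
                         regime="hwe_rm_free_af")
        fr = fit_model([duo], spec)
        assert not fr.identifiable

    def test_all_zero_counts_rejected(self):
        ds = StructureCounts("case_mother_duo", np.zeros(7, dtype=int))
        with pytest.raises(ValueError):
            fit_model([ds], ModelSpec(free_risk=("r1",)))

    def test_max_loglik_never_below_nested_null(self):
        rng = np.random.default_rng(4)
        duo = simulate_structure("case_mother_duo", SCEN["null"], 300, rng)
        poc = simulate_structure("parents_of_control", SCEN["null"], 300, rng)
        fr = fit_model([duo, poc],
                       ModelSpec(free_risk=("r1", "r2", "s1", "s2")))
        assert fr.max_loglik >= fr.null_loglik - 1e-8

    def test_adding_a_parameter_never_decreases_max_loglik(self):
        rng = np.random.default_rng(9)
        duo = simulate_structure("case_mother_duo", SCEN["C"], 400, rng)
        poc = simulate_structure("parents_of_control", SCEN["C"], 400, rng)
        lls = []
        for free in (("r1",), ("r1", "r2"), ("r1", "r2", "s1"),
                     ("r1", "r2", "s1", "s2")):
            lls.append(fit_model([duo, poc], ModelSpec(free_risk=free)).max_loglik)
        assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))


class TestLikelihoodRatioTest:
    def test_identical_specs_give_zero(self):
        rng = np.random.default_rng(2)
        duo = simulate_structure("case_mother_duo", SCEN["A"], 300, rng)
        poc = simulate_structure("parents_of_control", SCEN["A"], 300, rng)
        spec = ModelSpec(free_risk=("r1", "r2"))
        f = fit_model([duo, poc], spec)
        stat, df, p = likelihood_ratio_test(f, f)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_chi_square_reference(self):
        assert chi2.sf(3.84, 1) == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        duo = simulate_structure("case_mother_duo", SCEN["A"], 300, rng)
        poc = simulate_structure("parents_of_control", SCEN["A"], 300, rng)
        f1 = fit_model([duo, poc], ModelSpec(free_risk=("r1", "r2")))
        f2 = fit_model([duo, poc], ModelSpec(free_risk=("s1", "s2")))
        with pytest.raises(ValueError):
            likelihood_ratio_test(f1, f2)

    def test_lrt_invariant_to_im_or_ip_designation(self):
        rng = np.random.default_rng(6)
        trio = simulate_structure("case_parent_trio", SCEN["D"], 400, rng)
        f_im = fit_model([trio], ModelSpec(
            free_risk=("r1", "r2", "s1", "s2", "im"), regime="hwe_rm_free_af"))
        f_ip = fit_model([trio], ModelSpec(
            free_risk=("r1", "r2", "s1", "s2", "ip"), regime="hwe_rm_free_af"))
        assert f_im.max_loglik == pytest.approx(f_ip.max_loglik, abs=1e-6)
        assert f_im.null_loglik == pytest.approx(f_ip.null_loglik, abs=1e-6)


class TestMethodPresets:
    def test_method5_agrees_with_method4_under_hwe(self):
        rng = np.random.default_rng(12)
        duo = simulate_structure("case_mother_duo", SCEN["C"], 500, rng)
        poc = simulate_structure("parents_of_control", SCEN["C"], 500, rng)
        f4 = fit_method("4", [duo], [poc])
        f5 = fit_method("5", [duo], [poc])
        for name in ("r1", "r2", "s1", "s2"):
            assert f5.estimate(name) == pytest.approx(f4.estimate(name),
                                                      rel=0.15)

    def test_method1_wrong_fixed_af_inflates_type_i_error(self):
        # fixing the allele frequency at 0.4 when the truth is 0.3 biases
        # estimation and breaks the nominal level of the joint LRT
        reps, rej = 120, 0
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            duo = simulate_structure("case_mother_duo", SCEN["null"], 500, rng)
            fr = fit_method("1", [duo], free_risk=("r1", "r2", "s1", "s2"),
                            fixed_a2=0.4, seed=r)
            stat = 2 * (fr.max_loglik - fr.null_loglik)
            rej += chi2.sf(max(stat, 0), 4) < 0.05
        assert rej / reps > 0.15  # far above the nominal 0.05

    def test_missing_control_sample_raises(self):
        rng = np.random.default_rng(3)
        duo = simulate_structure("case_mother_duo", SCEN["A"], 100, rng)
        with pytest.raises(ValueError, match="parents_of_control"):
            fit_method("4", [duo], [])

    @pytest.mark.parametrize("scenario,method,case_kind,free", [
        ("A", "4", "case_mother_duo", ("r1", "r2")),
        ("B", "4", "case_mother_duo", ("s1", "s2")),
        ("C", "4", "case_mother_duo", ("r1", "r2", "s1", "s2")),
        ("D", "4", "case_mother_duo", ("r1", "r2", "im")),
        ("E", "4", "case_mother_duo", ("r1", "r2", "ip")),
        ("F", "4", "case_mother_duo", ("r1", "r2", "s1", "s2", "im")),
        ("G", "4", "case_mother_duo", ("r1", "r2", "s1", "s2", "ip")),
        ("H", "2a", "case_parent_trio", ("r1", "r2", "s1", "s2", "g11", "g22")),
        ("I", "2a", "case_parent_trio", ("r1", "r2", "s1", "s2", "im", "g11")),
        ("J", "2a", "case_parent_trio", ("r1", "r2", "s1", "s2", "ip", "g11")),
    ])
    def test_unbiased_estimation_across_scenarios(self, scenario, method,
                                                  case_kind, free):
        """Mean log-estimates over replicates sit within 3 Monte-Carlo SEs of
        the generating log relative risks, scenario by scenario."""
        scen = SCEN[scenario]
        reps = 200
        est = {p: [] for p in free}
        for r in range(reps):
            rng = np.random.default_rng(1000 * ord(scenario) + r)
            case = simulate_structure(case_kind, scen, 500, rng)
            ctrl = ([simulate_structure("parents_of_control", scen, 500, rng)]
                    if method == "4" else [])
            fr = fit_method(method, [case], ctrl, free_risk=free, seed=r)
            for p in free:
                est[p].append(fr.estimates[p].log_value)
        for p in free:
            arr = np.array(est[p])
            target = math.log(getattr(scen.params, p))
            mc_se = arr.std(ddof=1) / math.sqrt(reps)
            assert abs(arr.mean() - target) < 3 * mc_se + 1e-3, \
                f"{scenario}/{p}: mean {arr.mean():.4f} vs {target:.4f}"


@pytest.fixture(scope="module")
def trio_data():
    rng = np.random.default_rng(77)
    return simulate_structure("case_parent_trio", SCEN["F"], 500, rng)


class TestDialectInvariance:
    """The four imprinting dialects, MFG-1B vs the default two-interaction
    model, and the two saturated 7-parameter models each give identical
    maximized log-likelihoods."""

    def test_imprinting_dialects(self, trio_data):
        lls = []
        for dialect, free in [
                ("weinberg_original_im", ("r1", "r2", "s1", "s2", "im")),
                ("weinberg_original_ip", ("r1", "r2", "s1", "s2", "ip")),
                ("weinberg_later_im", ("r1", "r2", "s1", "s2", "im")),
                ("weinberg_later_ip", ("r1", "r2", "s1", "s2", "ip"))]:
            spec = ModelSpec(free_risk=free, regime="hwe_rm_free_af",
                             dialect=dialect)
            lls.append(fit_model([trio_data], spec, compute_se=False).max_loglik)
        assert max(lls) - min(lls) < 1e-6

    def test_mfg_1b_vs_default_interactions(self, trio_data):
        f_def = fit_model([trio_data], ModelSpec(
            free_risk=("r1", "r2", "s1", "s2", "g11", "g22"),
            regime="hwe_rm_free_af"), compute_se=False)
        f_mfg = fit_model([trio_data], ModelSpec(
            free_risk=("rho1", "rho2", "eta1", "eta2", "mu0", "mu2"),
            regime="hwe_rm_free_af", dialect="mfg_1b"), compute_se=False)
        assert abs(f_def.max_loglik - f_mfg.max_loglik) < 1e-6

    def test_saturated_seven_parameter_models(self, trio_data):
        f_def = fit_model([trio_data], ModelSpec(
            free_risk=("r1", "r2", "s1", "s2", "im", "g11", "g22"),
            regime="hwe_rm_free_af"), compute_se=False)
        f_mfg = fit_model([trio_data], ModelSpec(
            free_risk=("rho1", "rho2", "eta1", "eta2", "mu0", "mu2", "ip"),
            regime="hwe_rm_free_af", dialect="mfg_1b"), compute_se=False)
        assert abs(f_def.max_loglik - f_mfg.max_loglik) < 1e-6


class TestLogisticComparator:
    def make_duos(self, scenario, n, seed):
        rng = np.random.default_rng(seed)
        case = simulate_structure("case_mother_duo", SCEN[scenario], n, rng)
        ctrl = simulate_structure("control_mother_duo", SCEN[scenario], n, rng)
        return case, ctrl

    def test_null_data_coefficients_near_zero(self):
        case, ctrl = self.make_duos("null", 20000, 42)
        fr = logistic_duo_comparator(case, ctrl)
        for est in fr.estimates.values():
            assert abs(est.log_value) < 4 * est.log_se

    def test_child_effect_odds_ratios(self):
        case, ctrl = self.make_duos("A", 20000, 43)
        fr = logistic_duo_comparator(case, ctrl, free_risk=("r1", "r2"))
        assert fr.estimate("r1") == pytest.approx(1.5, rel=0.1)
        assert fr.estimate("r2") == pytest.approx(2.25, rel=0.1)

    def test_agrees_with_reference_glm(self):
        import statsmodels.api as sm
        from famlik.tables import cell_labels
        from famlik.fit import _duo_design_row
        case, ctrl = self.make_duos("C", 2000, 44)
        fr = logistic_duo_comparator(case, ctrl,
                                     free_risk=("r1", "r2", "s1", "s2"))
        labels = cell_labels("case_mother_duo")
        rows, y, w = [], [], []
        for yy, ds in ((1, case), (0, ctrl)):
            for lab, n in zip(labels, ds.counts):
                rows.append([1.0] + [_duo_design_row(lab, p, 0.7)
                                     for p in ("r1", "r2", "s1", "s2")])
                y.append(yy)
                w.append(n)
        res = sm.GLM(np.array(y), np.array(rows), freq_weights=np.array(w),
                     family=sm.families.Binomial()).fit()
        for i, p in enumerate(("r1", "r2", "s1", "s2")):
            assert fr.estimates[p].log_value == pytest.approx(
                res.params[i + 1], abs=1e-6)

    def test_saturated_loglik_difference_matches_multinomial(self):
        """With a saturated duo design, the logistic full-minus-null
        log-likelihood difference equals the multinomial two-sample
        (case table vs pooled) difference exactly."""
        case, ctrl = self.make_duos("H", 1500, 45)
        fr = logistic_duo_comparator(
            case, ctrl, free_risk=("r1", "r2", "s1", "s2", "g11", "g22"))

        def mult_ll(counts):
            n = counts.sum()
            nz = counts[counts > 0]
            return float(nz @ np.log(nz / n))

        full = mult_ll(case.counts) + mult_ll(ctrl.counts)
        pooled_counts = case.counts + ctrl.counts
        pooled_p = pooled_counts / pooled_counts.sum()
        null = (float(case.counts @ np.log(pooled_p))
                + float(ctrl.counts @ np.log(pooled_p)))
        assert (fr.max_loglik - fr.null_loglik) == pytest.approx(
            full - null, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        case, ctrl = self.make_duos("A", 500, 46)
        with pytest.raises(IdentifiabilityError):
            # im + ip + r1 + r2 over 7 cells with the fractional coding is
            # collinear (im + ip = number of risk alleles = r1 + 2 r2)
            logistic_duo_comparator(
                case, ctrl, free_risk=("r1", "r2", "im", "ip"))


class TestModelSequence:
    def test_tie_breaks_to_first_spec(self):
        rng = np.random.default_rng(8)
        duo = simulate_structure("case_mother_duo", SCEN["A"], 300, rng)
        poc = simulate_structure("parents_of_control", SCEN["A"], 300, rng)
        spec = ModelSpec(free_risk=("r1", "r2"))
        rows, best = model_sequence([duo, poc], [spec, spec])
        assert best == 0
        assert rows[0][2] == pytest.approx(rows[1][2], abs=1e-6)

    def test_true_parameterization_wins_by_aic(self):
        wins = 0
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(3000 + r)
            duo = simulate_structure("case_mother_duo", SCEN["B"], 500, rng)
            poc = simulate_structure("parents_of_control", SCEN["B"], 500, rng)
            specs = [ModelSpec(free_risk=("r1", "r2"), name="child"),
                     ModelSpec(free_risk=("s1", "s2"), name="maternal")]
            _rows, best = model_sequence([duo, poc], specs, seed=r)
            wins += best == 1
        assert wins > reps / 2

    def test_null_data_prefers_null_model(self):
        aic_null, aic_full = [], []
        for r in range(30):
            rng = np.random.default_rng(4000 + r)
            duo = simulate_structure("case_mother_duo", SCEN["null"], 500, rng)
            poc = simulate_structure("parents_of_control", SCEN["null"], 500,
                                     rng)
            specs = [ModelSpec(free_risk=(), name="null"),
                     ModelSpec(free_risk=("r1", "r2", "s1", "s2"),
                               name="full")]
            rows, _best = model_sequence([duo, poc], specs, seed=r)
            aic_null.append(rows[0][2])
            aic_full.append(rows[1][2])
        assert np.mean(aic_null) < np.mean(aic_full)
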