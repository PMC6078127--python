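import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import kmersub as ks
from kmersub.doseresponse import ec50_from_slope


def series(doses, fa, treatment="agent"):
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    return ks.DoseResponseSeries(
        treatment=treatment,
        doses_uM=doses,
        fa_mean=fa,
        fa_sd=np.zeros_like(fa),
        n_replicates=np.full(fa.shape, 6),
    )


def median_effect_series(m, Dm, doses, treatment="agent"):
    doses = np.asarray(doses, dtype=float)
    ratio = (doses / Dm) ** m
    return series(doses, ratio / (1 + ratio), treatment)


class TestFractionDead:
    @pytest.mark.parametrize(
        "control,treated,expected",
        [(1000, 840, 0.16), (375, 375, 0.0), (800, 872, -0.09)],
    )
    def test_direct_substitution(self, control, treated, expected):
        assert ks.fraction_dead(control, treated) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            ks.fraction_dead(0, 10)

    @settings(derandomize=True, max_examples=100)
    @given(
        control=st.floats(1, 1e6),
        treated=st.floats(0, 1e6),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, control, treated, c):
        assert ks.fraction_dead(control * c, treated * c) == pytest.approx(
            ks.fraction_dead(control, treated), abs=1e-9
        )


class TestSummarizePlate:
    def _plate(self, treated_signal, control_signal=1000.0, scramble_signal=None):
        records = [
            ks.PlateRecord(f"c{i}", "vehicle", 0.0, control_signal) for i in range(3)
        ]
        if scramble_signal is not None:
            records += [
                ks.PlateRecord(f"s{i}", "scramble", 1.0, scramble_signal)
                for i in range(3)
            ]
        records += [
            ks.PlateRecord(f"w{d}_{i}", "oligo", d, treated_signal)
            for d in (0.1, 0.3, 1.0)
            for i in range(3)
        ]
        return records

    def test_treated_equal_control_gives_zero_fa(self):
        (s,) = ks.summarize_plate(self._plate(1000.0))
        assert np.allclose(s.fa_mean, 0.0)

    def test_scramble_adjustment_is_subtractive(self):
        # raw treatment FA 0.30, scramble FA 0.05 -> adjusted 0.25
        (s,) = ks.summarize_plate(
            self._plate(700.0, scramble_signal=950.0), adjust_to_scramble=True
        )
        assert np.allclose(s.fa_mean, 0.25)

    def test_no_untreated_controls_is_an_error(self):
        records = [ks.PlateRecord("w1", "oligo", 0.1, 500.0)]
        with pytest.raises(ValueError, match="control"):
            ks.summarize_plate(records)

    def test_single_replicate_carries_warning(self):
        records = [ks.PlateRecord("c", "vehicle", 0.0, 1000.0),
                   ks.PlateRecord("w", "oligo", 0.1, 900.0)]
        (s,) = ks.summarize_plate(records)
        assert s.warnings

    def test_simulated_plate_recovers_generative_fa(self):
        records = ks.simulate_viability(
            m=1.5, Dm_uM=0.5, doses_uM=[0.03, 0.1, 0.3, 1, 3],
            replicates=24, noise_sd=0.05, seed=11,
        )
        (s,) = ks.summarize_plate(records)
        d = s.doses_uM
        truth = (d / 0.5) ** 1.5 / (1 + (d / 0.5) ** 1.5)
        # Monte-Carlo error ~ noise/sqrt(24)
        assert np.all(np.abs(s.fa_mean - truth) < 4 * 0.05 / np.sqrt(24) + 0.01)


class TestLinearSensitivity:
    def test_exact_line_recovered(self):
        doses_nM = np.array([30, 100, 300, 1000])
        s = series(doses_nM / 1000.0, 0.001 * doses_nM)
        fit = ks.linear_sensitivity(s)
        assert fit.slope == pytest.approx(0.1)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.ec50_uM == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "slope,expected_ec50",
        [(0.408, 0.12), (0.464, 0.11)],  # tabulated CHLA-10 sensitivities
    )
    def test_ec50_from_printed_slope(self, slope, expected_ec50):
        assert round(ec50_from_slope(slope), 2) == expected_ec50

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        doses = np.array([0.01, 0.03, 0.1, 0.3, 1.0, 3.0])
        fa = np.clip(0.05 + 0.2 * doses + rng.normal(0, 0.02, doses.size), None, 1.0)
        fit = ks.linear_sensitivity(series(doses, fa))
        x, y = doses * 1000, fa * 100
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_negative_slope_flagged_non_cytotoxic(self):
        s = series([0.1, 0.3, 1.0], [0.3, 0.2, 0.1])
        with pytest.warns(UserWarning, match="non-cytotoxic"):
            fit = ks.linear_sensitivity(s)
        assert not fit.cytotoxic
        assert fit.ec50_uM > 0  # reported from |slope|

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ks.linear_sensitivity(series([0.1, 0.3], [0.1, 0.2]))


class TestMedianEffect:
    def test_noise_free_identifiability(self):
        s = median_effect_series(1.0, 0.5, [0.03, 0.1, 0.3, 1, 3])
        fit = ks.median_effect_fit(s)
        assert fit.m == pytest.approx(1.0, rel=1e-12)
        assert fit.Dm_uM == pytest.approx(0.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_model_predicts_half_effect_at_Dm(self):
        fit = ks.median_effect_fit(median_effect_series(2.3, 0.7, [0.1, 0.3, 1, 3]))
        assert ks.dose_for_effect(fit, 0.5) == pytest.approx(fit.Dm_uM)

    def test_points_outside_unit_interval_excluded(self):
        s = series([0.01, 0.1, 0.3, 1.0], [0.0, 0.2, 0.5, 1.0])
        fit = ks.median_effect_fit(s)
        assert fit.n_points == 2 and fit.n_excluded == 2

    def test_fewer_than_two_usable_points_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ks.median_effect_fit(series([0.1, 1.0], [0.0, 1.0]))

    def test_stochastic_recovery_within_five_percent(self):
        # replicate-level lognormal-ish noise, median over 200 seeds
        m_true, Dm_true = 1.2, 0.4
        ms, dms = [], []
        for seed in range(200):
            records = ks.simulate_viability(
                m_true, Dm_true, [0.03, 0.1, 0.3, 1, 3],
                replicates=6, noise_sd=0.1, seed=seed,
            )
            (s,) = ks.summarize_plate(records)
            fit = ks.median_effect_fit(s)
            ms.append(fit.m)
            dms.append(fit.Dm_uM)
        assert abs(np.median(ms) - m_true) / m_true < 0.05
        assert abs(np.median(dms) - Dm_true) / Dm_true < 0.05


class TestDoseForEffect:
    def test_median_effect_dose_for_any_m(self):
        for m in (0.5, 1.0, 3.7):
            fit = ks.MedianEffectFit("a", m, 0.8, 1.0, 5)
            assert ks.dose_for_effect(fit, 0.5) == pytest.approx(0.8)

    def test_textbook_ninety_percent_effect(self):
        fit = ks.MedianEffectFit("a", 1.0, 1.0, 1.0, 5)
        assert ks.dose_for_effect(fit, 0.9) == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_inverts_forward_model(self, seed):
        rng = np.random.default_rng(seed)
        m, Dm, fa = rng.uniform(0.5, 3), rng.uniform(0.1, 2), rng.uniform(0.05, 0.95)
        fit = ks.MedianEffectFit("a", m, Dm, 1.0, 5)

        def forward(d):
            r = (d / Dm) ** m
            return r / (1 + r) - fa

        oracle = brentq(forward, 1e-9, 1e9)
        assert ks.dose_for_effect(fit, fa) == pytest.approx(oracle, rel=1e-9)

    def test_strictly_increasing_in_fa(self):
        fit = ks.MedianEffectFit("a", 1.7, 0.6, 1.0, 5)
        fas = np.linspace(0.05, 0.95, 19)
        doses = [ks.dose_for_effect(fit, f) for f in fas]
        assert np.all(np.diff(doses) > 0)

    def test_fa_outside_open_interval_rejected(self):
        fit = ks.MedianEffectFit("a", 1.0, 1.0, 1.0, 5)
        for fa in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ks.dose_for_effect(fit, fa)


class TestCombinationIndex:
    def _fit(self, m, Dm, name="a"):
        return ks.MedianEffectFit(name, m, Dm, 1.0, 5)

    def test_sham_self_combination_is_additive_at_any_fa(self):
        fit = self._fit(1.4, 0.6)
        for fa in (0.1, 0.5, 0.9):
            res = ks.combination_index([fit, fit], [0.5, 0.5], fit, fa=fa)
            assert res.ci == pytest.approx(1.0, abs=1e-12)
            assert res.label == "additive"

    def test_identical_components_any_split(self):
        fit = self._fit(2.0, 1.1)
        res = ks.combination_index([fit, fit], [0.25, 0.75], fit, fa=0.5)
        assert res.ci == pytest.approx(1.0)

    def test_halved_combo_dose_gives_ci_half(self):
        a, b = self._fit(1.0, 1.0, "a"), self._fit(1.0, 1.0, "b")
        combo = self._fit(1.0, 0.5, "mix")  # reaches each effect at half dose
        res = ks.combination_index([a, b], [0.5, 0.5], combo, fa=0.5)
        assert res.ci == pytest.approx(0.5)
        assert res.label == "synergy"

    def test_twelve_component_equal_fractions(self):
        fits = [self._fit(1.0, 1.0, f"c{i}") for i in range(12)]
        combo = self._fit(1.0, 1.0, "cocktail")
        res = ks.combination_index(fits, [1 / 12] * 12, combo, fa=0.5)
        assert res.ci == pytest.approx(1.0)

    def test_fractions_must_sum_to_one(self):
        fit = self._fit(1.0, 1.0)
        with pytest.raises(ValueError, match="fractions"):
            ks.combination_index([fit, fit], [0.5, 0.6], fit)


class TestClassification:
    @pytest.mark.parametrize(
        "ci,label",
        [(0.15, "synergy"), (210.0, "antagonism"), (1.10, "additive"),
         (0.9, "additive"), (0.89, "synergy"), (1.11, "antagonism")],
    )
    def test_bands(self, ci, label):
        assert ks.classify_interaction(ci) == label

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(ValueError):
            ks.classify_interaction(0.0)


class TestInteractionMatrix:
    def _result(self, a, b, ci):
        return ks.InteractionResult(
            (a, b), (0.5, 0.5), 0.5, ci, ks.classify_interaction(ci)
        )

    def test_agreement_gives_consensus_label(self):
        results = {
            "TC-32": [self._result("x", "y", 0.3)],
            "CHLA-10": [self._result("x", "y", 0.5)],
        }
        from kmersub.doseresponse import interaction_matrix

        matrices, consensus = interaction_matrix(results)
        assert matrices["TC-32"].loc["x", "y"] == "synergy"
        assert consensus.loc["x", "y"] == "synergy"

    def test_disagreement_is_discordant(self):
        from kmersub.doseresponse import interaction_matrix

        results = {
            "TC-32": [self._result("x", "y", 0.3)],
            "CHLA-10": [self._result("x", "y", 5.0)],
        }
        _, consensus = interaction_matrix(results)
        assert consensus.loc["x", "y"] == "discordant"

    def test_duplicate_pair_rejected(self):
        from kmersub.doseresponse import interaction_matrix

        with pytest.raises(ValueError, match="duplicate"):
            interaction_matrix(
                {"A": [self._result("x", "y", 0.3), self._result("y", "x", 2.0)]}
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_consensus_equals_brute_force_agreement(self, seed):
        from kmersub.doseresponse import interaction_matrix

        rng = np.random.default_rng(seed)
        agents = ["a", "b", "c", "d"]
        pairs = [(x, y) for i, x in enumerate(agents) for y in agents[i + 1 :]]
        cis = {}
        results = {}
        for line in ("L1", "L2"):
            rs = []
            for x, y in pairs:
                ci = float(rng.uniform(0.1, 3.0))
                cis[(line, x, y)] = ci
                rs.append(self._result(x, y, ci))
            results[line] = rs
        _, consensus = interaction_matrix(results)
        for x, y in pairs:
            labels = {
                ks.classify_interaction(cis[(line, x, y)]) for line in ("L1", "L2")
            }
            expect = labels.pop() if len(labels) == 1 else "discordant"
            assert consensus.loc[x, y] == expect
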