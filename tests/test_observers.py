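"""Tests of the synthetic-observer generator and binocular combination."""

import numpy as np
import pytest
from scipy.optimize import brentq

from qcsf.engine import Stimulus
from qcsf.model import CSFParameters, PsychometricSpec, aulcsf, csf_sensitivity
from qcsf.observers import (
    EyeDistribution,
    Regime,
    default_group_specs,
    derive_binocular_csf,
    generate_cohort,
    sample_observer,
    simulate_response,
)
from qcsf.summation import expected_binocular_probability


class TestDefaultSpecs:
    def test_group_sizes_and_fusers(self):
        specs = {s.name: s for s in default_group_specs()}
        assert [specs[g].n_subjects for g in ("AMB", "SWA", "NSC")] == [11, 20, 24]
        assert specs["AMB"].n_fusers == 5
        assert specs["SWA"].n_fusers == 7
        assert specs["NSC"].n_fusers == 24

    def test_amb_peak_frequency_means(self):
        amb = next(s for s in default_group_specs() if s.name == "AMB")
        assert 10 ** amb.nde.mean_log_frequency == pytest.approx(1.94)
        assert 10 ** amb.de.mean_log_frequency == pytest.approx(3.89)
        assert amb.de.mean_log_gain == pytest.approx(1.89)
        assert amb.nde.mean_log_gain == pytest.approx(1.77)

    def test_nsc_regime_is_supra_14(self):
        nsc = next(s for s in default_group_specs() if s.name == "NSC")
        assert nsc.regime_fusing.kind == "supra"
        assert nsc.regime_fusing.factor == pytest.approx(1.4)

    def test_group_aulcsf_targets_at_large_n(self):
        """Sampled group AULCSF means hit the calibration targets within 2%."""
        rng = np.random.default_rng(77)
        specs = {s.name: s for s in default_group_specs()}
        for dist, target in (
            (specs["AMB"].nde, 0.99),
            (specs["NSC"].nde, 1.65),
        ):
            vals = [aulcsf(dist.sample(rng), n_points=256) for _ in range(5000)]
            assert np.mean(vals) == pytest.approx(target, rel=0.02)


class TestSampleObserver:
    def test_zero_sd_returns_means_exactly(self):
        dist = EyeDistribution(1.5, 0.0, 0.5, 0.0, -0.5, 0.0, -0.3, 0.0)
        spec = default_group_specs()[2]
        gspec = type(spec)(
            name="X", n_subjects=1, fusion_fraction=1.0,
            nde=dist, de=dist,
            regime_fusing=Regime("supra", 1.0),
            regime_nonfusing=Regime("supra", 1.0),
        )
        obs = sample_observer(gspec, np.random.default_rng(0))
        assert obs.csf_nde.peak_gain == pytest.approx(10**1.5)
        assert obs.csf_nde.peak_frequency == pytest.approx(10**0.5)
        assert obs.csf_nde.bandwidth == pytest.approx(10**-0.5)
        assert obs.csf_nde.truncation == pytest.approx(10**-0.3)

    def test_fixed_seed_reproducible(self):
        spec = default_group_specs()[0]
        o1 = sample_observer(spec, np.random.default_rng(42), "A", True)
        o2 = sample_observer(spec, np.random.default_rng(42), "A", True)
        assert o1.csf_nde == o2.csf_nde
        assert o1.csf_de == o2.csf_de
        np.testing.assert_array_equal(
            o1.csf_bin.sensitivities, o2.csf_bin.sensitivities
        )

    def test_peak_frequency_law_of_large_numbers(self):
        amb_nde = next(s for s in default_group_specs() if s.name == "AMB").nde
        rng = np.random.default_rng(5)
        draws = amb_nde.mean_log_frequency + amb_nde.sd_log_frequency * \
            rng.standard_normal(10_000)
        se = amb_nde.sd_log_frequency / np.sqrt(10_000)
        assert abs(draws.mean() - np.log10(1.94)) < 3 * se


class TestBinocularCombination:
    def test_supra_unity_equals_monocular(self):
        p = CSFParameters(80.0, 3.0, 0.4, 0.6)
        prof = derive_binocular_csf(p, p, Regime("supra", 1.0))
        np.testing.assert_allclose(
            prof.sensitivities, csf_sensitivity(prof.frequencies, p), rtol=1e-12
        )

    def test_probability_with_blind_eye_tracks_better_eye(self):
        good = CSFParameters(80.0, 3.0, 0.4, 0.6)
        blind = CSFParameters(1e-6, 3.0, 0.4, 0.1)
        prof = derive_binocular_csf(good, blind, Regime("probability"))
        np.testing.assert_allclose(
            prof.sensitivities,
            csf_sensitivity(prof.frequencies, good),
            rtol=1e-6,
        )

    def test_probability_gain_matches_root_search_oracle(self, spec):
        """Identical eyes: the probability-summation gain at each frequency
        equals an independent brentq threshold search (gain ~ 1.1-1.2)."""
        p = CSFParameters(100.0, 4.0, 0.33, 0.5)
        prof = derive_binocular_csf(p, p, Regime("probability"), spec, n_points=16)
        for f, s_bin in zip(prof.frequencies, prof.sensitivities):
            tau = -np.log10(csf_sensitivity(f, p))

            def combined_minus_crit(c):
                from qcsf.model import psychometric_p

                pm = psychometric_p(c, tau, spec)
                return (
                    expected_binocular_probability(pm, pm, spec.guess_rate)
                    - spec.criterion_p
                )

            c_star = brentq(combined_minus_crit, tau - 3, tau + 1, xtol=1e-12)
            assert -np.log10(s_bin) == pytest.approx(c_star, abs=1e-9)
            gain = 10.0 ** (tau - c_star)
            assert 1.05 < gain < 1.25

    def test_probability_at_least_best_eye_sub_strictly_below(self):
        a = CSFParameters(60.0, 2.0, 0.35, 0.4)
        b = CSFParameters(90.0, 4.0, 0.3, 0.7)
        best = np.maximum
        prob = derive_binocular_csf(a, b, Regime("probability"))
        s_best = best(
            csf_sensitivity(prob.frequencies, a), csf_sensitivity(prob.frequencies, b)
        )
        assert np.all(prob.sensitivities >= s_best * (1 - 1e-9))
        sub = derive_binocular_csf(a, b, Regime("sub", 0.85))
        assert np.all(sub.sensitivities < s_best)

    def test_regeneration_is_exact(self):
        a = CSFParameters(60.0, 2.0, 0.35, 0.4)
        b = CSFParameters(90.0, 4.0, 0.3, 0.7)
        p1 = derive_binocular_csf(a, b, Regime("probability"))
        p2 = derive_binocular_csf(a, b, Regime("probability"))
        np.testing.assert_array_equal(p1.sensitivities, p2.sensitivities)


class TestSimulateResponse:
    def test_empirical_rates(self, spec):
        obs = sample_observer(
            default_group_specs()[2], np.random.default_rng(9), "X", True
        )
        f = 3.0
        s = csf_sensitivity(f, obs.csf_de)
        rng = np.random.default_rng(123)
        n = 10_000
        # far below threshold: guessing floor
        low = Stimulus(f, min(1.0, 10 ** (-np.log10(s) - 1.0)))
        rate_low = np.mean(
            [simulate_response(obs, "DE", low, rng) for _ in range(n)]
        )
        assert abs(rate_low - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)
        # at threshold: the 0.53 criterion
        at = Stimulus(f, 1.0 / s)
        rate_at = np.mean(
            [simulate_response(obs, "DE", at, rng) for _ in range(n)]
        )
        assert abs(rate_at - 0.53) < 3 * np.sqrt(0.53 * 0.47 / n)

    def test_fixed_seed_stream_reproducible(self):
        obs = sample_observer(
            default_group_specs()[0], np.random.default_rng(2), "X", False
        )
        stim = Stimulus(2.0, 0.05)
        r1 = [simulate_response(obs, "NDE", stim, np.random.default_rng(7))
              for _ in range(1)]
        rng_a, rng_b = np.random.default_rng(7), np.random.default_rng(7)
        seq_a = [simulate_response(obs, "BIN", stim, rng_a) for _ in range(50)]
        seq_b = [simulate_response(obs, "BIN", stim, rng_b) for _ in range(50)]
        assert seq_a == seq_b


class TestCohort:
    def test_default_structure(self):
        cohort = generate_cohort(seed=1)
        assert len(cohort.observers) == 55
        amb = cohort.group("AMB")
        swa = cohort.group("SWA")
        nsc = cohort.group("NSC")
        assert (len(amb), len(swa), len(nsc)) == (11, 20, 24)
        assert sum(o.fuses for o in amb) == 5
        assert sum(o.fuses for o in swa) == 7
        assert all(o.fuses for o in nsc)
        # regimes follow fusion status
        assert all(o.regime.kind == "probability" for o in amb)
        assert all(
            o.regime.kind == ("probability" if o.fuses else "sub") for o in swa
        )
        assert all(o.regime.kind == "supra" for o in nsc)

    def test_same_seed_identical_different_seed_differs(self):
        c1 = generate_cohort(seed=3)
        c2 = generate_cohort(seed=3)
        c3 = generate_cohort(seed=4)
        assert [o.csf_nde for o in c1.observers] == [o.csf_nde for o in c2.observers]
        assert [o.csf_nde for o in c1.observers] != [o.csf_nde for o in c3.observers]
        # same structure regardless of seed
        assert [o.group for o in c1.observers] == [o.group for o in c3.observers]
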