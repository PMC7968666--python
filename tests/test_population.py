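"""Covariate model, observation likelihood and marginal OFV."""
import math

import numpy as np
import pytest

import mozzipk as m
from mozzipk.population import DegenerateErrorModel, LaplaceObjective


class TestIndividualParams:
    def test_reference_mosquito_gets_population_values(self, reference):
        sp = m.individual_params(reference, 3.4, False, m.RandomEffects())
        assert sp.dose_ng == pytest.approx(0.28)
        assert sp.kel_ng_per_h == pytest.approx(0.0055)
        assert sp.tlag_h == pytest.approx(18.5)

    def test_ritonavir_adds_lag(self, reference):
        sp = m.individual_params(reference, 3.4, True, m.RandomEffects())
        assert sp.tlag_h == pytest.approx(29.9)

    def test_weight_doubling_at_unit_exponent(self, reference):
        sp = m.individual_params(reference, 6.8, False, m.RandomEffects())
        assert sp.dose_ng == pytest.approx(0.56)
        assert sp.kel_ng_per_h == pytest.approx(0.0055 * 2 ** 0.75)

    def test_random_effects_enter_lognormally(self, reference):
        sp = m.individual_params(
            reference, 3.4, False,
            m.RandomEffects(eta_dose=1.0, eta_kel=-1.0, kappa_batch=2.0))
        assert sp.dose_ng == pytest.approx(0.28 * math.exp(0.075 + 0.22))
        assert sp.kel_ng_per_h == pytest.approx(0.0055 * math.exp(-0.25))

    def test_variance_parameterization_flag(self, reference):
        cfg = m.ModelConfig(variance_parameterization=True)
        sp = m.individual_params(reference, 3.4, False,
                                 m.RandomEffects(eta_dose=1.0), config=cfg)
        assert sp.dose_ng == pytest.approx(0.28 * math.exp(math.sqrt(0.075)))


class TestObservationLoglik:
    def test_mode_value_additive_only(self):
        got = m.observation_loglik(0.1, 0.1, 0.0, 0.018)
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi * 0.018 ** 2))

    def test_zero_prediction_keeps_additive_floor(self):
        got = m.observation_loglik(0.01, 0.0, 0.5, 0.018)
        assert got == pytest.approx(
            -0.5 * math.log(2 * math.pi * 0.018 ** 2)
            - 0.01 ** 2 / (2 * 0.018 ** 2))

    def test_quadratic_in_residual(self):
        v = 0.018 ** 2
        base = m.observation_loglik(0.1, 0.1, 0.0, 0.018)
        one = m.observation_loglik(0.1 + 0.01, 0.1, 0.0, 0.018)
        two = m.observation_loglik(0.1 + 0.02, 0.1, 0.0, 0.018)
        assert base - one == pytest.approx(0.01 ** 2 / (2 * v))
        assert base - two == pytest.approx(0.02 ** 2 / (2 * v))

    def test_degenerate_variance_raises(self):
        with pytest.raises(DegenerateErrorModel):
            m.observation_loglik(0.0, 0.0, 0.0, 0.0)


class TestMarginalOFV:
    def test_no_random_effects_reduces_to_sum_of_logliks(self, small_design):
        truth = m.PopulationParams(omega_dose=0, omega_kel=0,
                                   omega_iov_dose=0)
        cfg = m.SimulationConfig(design=small_design, truth=truth, seed=3)
        records = m.simulate_pk_study(cfg)
        kept = [r for r in records if not r.blq]
        ll = 0.0
        for r in kept:
            sp = m.individual_params(truth, r.weight_mg, r.is_ritonavir,
                                     m.RandomEffects())
            ll += m.observation_loglik(r.amount_ng, m.amount_at(sp, r.time_h),
                                       truth.sigma_prop, truth.sigma_add_ng)
        got = m.marginal_neg2ll(truth, records, m.ModelConfig(blq_mode="drop"))
        assert got == pytest.approx(-2 * ll)

    def test_invariant_under_record_reordering(self, small_study, reference):
        _, records = small_study
        fwd = m.marginal_neg2ll(reference, records)
        rev = m.marginal_neg2ll(reference, records[::-1])
        assert fwd == pytest.approx(rev, abs=1e-4)

    def test_additive_over_independent_batches(self, small_design, reference):
        cfg = m.SimulationConfig(design=small_design, truth=reference, seed=9)
        records = m.simulate_pk_study(cfg)
        ofv1 = m.marginal_neg2ll(reference, records)
        clones = []
        for r in records:
            clones.append(m.MosquitoRecord(
                mosquito_id=r.mosquito_id + "x", batch_id=r.batch_id + "x",
                arm=r.arm, time_h=r.time_h, weight_mg=r.weight_mg,
                amount_ng=r.amount_ng, blq=r.blq))
        ofv2 = m.marginal_neg2ll(reference, records + clones)
        assert ofv2 == pytest.approx(2 * ofv1, abs=1e-3)

    def test_inflating_misspecified_additive_error_improves_fit(
            self, small_study, reference):
        _, records = small_study
        too_small = m.marginal_neg2ll(
            reference.replace(sigma_add_ng=1e-4), records)
        right_scale = m.marginal_neg2ll(reference, records)
        assert right_scale <= too_small

    def test_multi_matches_single_evaluations(self, small_study, reference):
        _, records = small_study
        pops = [reference, reference.replace(theta_dose_ng=0.3),
                reference.replace(omega_kel=0.4)]
        obj = LaplaceObjective(m.records_to_frame(records))
        multi = obj.neg2ll_multi(pops)
        singles = [m.marginal_neg2ll(p, records) for p in pops]
        np.testing.assert_allclose(multi, singles, atol=1e-6)

    def test_deterministic_after_arbitrary_history(self, small_study,
                                                   reference):
        _, records = small_study
        obj = LaplaceObjective(m.records_to_frame(records))
        first = obj.neg2ll(reference)
        rng = np.random.default_rng(0)
        for _ in range(5):
            obj.neg2ll(reference.replace(
                theta_dose_ng=float(rng.uniform(0.1, 0.5)),
                omega_kel=float(rng.uniform(0.05, 0.5))))
        assert obj.neg2ll(reference) == pytest.approx(first, abs=1e-5)
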