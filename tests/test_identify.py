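"""Identification tests: objective semantics, precondition errors,
invariance properties and quick recovery checks (the full-scale recovery
and noisy-refit experiments live in the acceptance suite)."""

import dataclasses

import numpy as np
import pytest

from cardiowean import (
    ControlCoefficients,
    FreeParameterSet,
    MeasurementVector,
    NoiseWeights,
    WeaningDataset,
    WeaningRecord,
    identify_single_flow,
    identify_weaning,
    objective_psi,
    objective_psi_weaning,
)


class TestObjectiveSingleFlow:
    def test_zero_at_perfect_fit(self, pig1, pig1_free, pig1_observables):
        psi = objective_psi(pig1_free, pig1_observables, Q_d=0.0, HR=pig1.HR)
        assert psi == pytest.approx(0.0, abs=1e-4)

    def test_unit_residual_and_quadratic_weighting(self, pig1, pig1_free,
                                                   pig1_observables, sigmas):
        y1 = dataclasses.replace(pig1_observables,
                                 P_a_mean=pig1_observables.P_a_mean + sigmas.sigma_Pa)
        psi1 = objective_psi(pig1_free, y1, sigmas, Q_d=0.0, HR=pig1.HR)
        assert psi1 == pytest.approx(1.0, abs=0.01)
        y2 = dataclasses.replace(pig1_observables,
                                 P_a_mean=pig1_observables.P_a_mean + 2 * sigmas.sigma_Pa)
        psi2 = objective_psi(pig1_free, y2, sigmas, Q_d=0.0, HR=pig1.HR)
        assert psi2 == pytest.approx(4.0, abs=0.02)

    def test_sigma_scaling_only_rescales_psi(self, pig1, pig1_free,
                                             pig1_observables, sigmas):
        y = dataclasses.replace(pig1_observables,
                                SV=pig1_observables.SV + sigmas.sigma_SV)
        psi = objective_psi(pig1_free, y, sigmas, Q_d=0.0, HR=pig1.HR)
        doubled = NoiseWeights(*(2 * v for v in sigmas.as_array()[[3, 1, 0, 2, 4]]))
        # construct explicitly to keep field order unambiguous
        doubled = NoiseWeights(sigma_maxVh=2 * sigmas.sigma_maxVh,
                               sigma_PPa=2 * sigmas.sigma_PPa,
                               sigma_Pa=2 * sigmas.sigma_Pa,
                               sigma_Pv=2 * sigmas.sigma_Pv,
                               sigma_SV=2 * sigmas.sigma_SV)
        psi_d = objective_psi(pig1_free, y, doubled, Q_d=0.0, HR=pig1.HR)
        assert psi_d == pytest.approx(psi / 4.0, rel=0.02)

    def test_missing_observable_named(self, pig1, pig1_free, pig1_observables):
        y = dataclasses.replace(pig1_observables, SV=float("nan"))
        with pytest.raises(ValueError, match="SV"):
            objective_psi(pig1_free, y, Q_d=0.0, HR=pig1.HR)
        with pytest.raises(ValueError, match="SV"):
            identify_single_flow(y, Q_d=0.0, HR=pig1.HR)


class TestSingleFlowRecovery:
    def test_recovery_from_nearby_start(self, pig1, pig1_free, pig1_observables):
        # perturbed start; noise-free target generated by the same model
        x0 = FreeParameterSet.from_array(
            pig1_free.as_array() * np.array([1.1, 0.9, 1.1, 0.9, 1.1]))
        fit = identify_single_flow(pig1_observables, Q_d=0.0, HR=pig1.HR,
                                   x0=x0, n_starts=1)
        assert fit.converged
        assert fit.psi <= 1e-2
        assert np.all(np.abs(fit.estimate.as_array() / pig1_free.as_array() - 1.0) < 0.01)

    def test_multi_start_seeds_agree_on_noise_free_data(self, pig1, pig1_free,
                                                        pig1_observables):
        # optimizer invariance: different random multi-start seeds land on
        # the same optimum of a noise-free problem
        psis = []
        for seed in (1, 2, 3, 4, 5):
            fit = identify_single_flow(pig1_observables, Q_d=0.0, HR=pig1.HR,
                                       x0=pig1_free, n_starts=2, spread=0.3,
                                       seed=seed)
            psis.append(fit.psi)
        assert max(psis) - min(psis) < 1e-3


class TestNoiseDegradation:
    def test_recovery_error_grows_with_noise_scale(self, pig1, pig1_free,
                                                   pig1_observables, sigmas):
        # averaged over seeds, the parameter-recovery RMSE is monotone in
        # the injected measurement-noise scale (0x, 1x, 2x study sigmas)
        rmse = []
        for scale in (0.0, 1.0, 2.0):
            errs = []
            for seed in (0, 1, 2):
                rng = np.random.default_rng(100 + seed)
                noise = scale * sigmas.as_array() / np.sqrt(10) * rng.standard_normal(5)
                y = MeasurementVector.from_array(pig1_observables.as_array() + noise)
                fit = identify_single_flow(y, Q_d=0.0, HR=pig1.HR,
                                           x0=pig1_free, n_starts=1)
                errs.append(np.mean((fit.estimate.as_array()
                                     / pig1_free.as_array() - 1.0) ** 2))
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] < rmse[1] < rmse[2]


def _flat_coeffs(free: FreeParameterSet, **slopes) -> ControlCoefficients:
    base = dict(E_Sl_h=0.0, A_Sl_h=0.0, E_Sl_a=0.0, R_Sl_s=0.0, SBV_Sl=0.0)
    base.update(slopes)
    return ControlCoefficients(E_0_h=free.E_h, A_0_h=free.A_h, E_0_a=free.E_a,
                               R_0_s=free.R_s, SBV_0=free.SBV, **base)


class TestObjectiveWeaning:
    @pytest.fixture(scope="class")
    def records(self, pig1, pig1_observables):
        return [WeaningRecord(Q_d=0.0, HR=pig1.HR, y=pig1_observables),
                WeaningRecord(Q_d=20.0, HR=pig1.HR, y=pig1_observables)]

    def test_single_record_reduces_to_single_flow(self, pig1, pig1_free,
                                                  pig1_observables, records):
        data = WeaningDataset(records=records[:1])
        c = _flat_coeffs(pig1_free)
        psi_w = objective_psi_weaning(c, data)
        psi_s = objective_psi(pig1_free, pig1_observables, Q_d=0.0, HR=pig1.HR)
        assert psi_w == pytest.approx(psi_s, abs=1e-6)

    def test_additive_over_records(self, pig1_free, pig1, pig1_observables):
        r = WeaningRecord(Q_d=0.0, HR=pig1.HR, y=pig1_observables)
        r2 = WeaningRecord(Q_d=1e-9, HR=pig1.HR, y=pig1_observables)
        c = _flat_coeffs(pig1_free)
        one = objective_psi_weaning(c, WeaningDataset(records=[r]))
        two = objective_psi_weaning(c, WeaningDataset(records=[r, r2]))
        assert two == pytest.approx(2 * one, abs=1e-4)

    def test_too_few_flows_rejected(self, records):
        with pytest.raises(ValueError, match="2 distinct flows"):
            identify_weaning(WeaningDataset(records=records[:1]))

    def test_two_flows_warns(self, records, pig1_free):
        data = WeaningDataset(records=records)
        with pytest.warns(UserWarning, match="n >= 3"):
            try:
                identify_weaning(data, max_nfev=1)
            except Exception:
                pass


class TestDatasetValidation:
    def test_duplicate_flows_rejected(self, pig1, pig1_observables):
        r = WeaningRecord(Q_d=5.0, HR=pig1.HR, y=pig1_observables)
        with pytest.raises(ValueError, match="distinct"):
            WeaningDataset(records=[r, r])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            WeaningDataset(records=[])

    def test_measurement_vector_invariants(self):
        with pytest.raises(ValueError):
            MeasurementVector(P_a_mean=60, PP_a=-1.0, P_v_mean=5, maxV_h=100, SV=30)
        with pytest.raises(ValueError):
            MeasurementVector(P_a_mean=60, PP_a=30, P_v_mean=5, maxV_h=20, SV=30)

    def test_control_coefficients_validation(self):
        with pytest.raises(ValueError, match="intercept"):
            ControlCoefficients(E_0_h=-1.0, A_0_h=0.03, E_0_a=1.5, R_0_s=1.2,
                                SBV_0=1000.0, E_Sl_h=0, A_Sl_h=0, E_Sl_a=0,
                                R_Sl_s=0, SBV_Sl=0)

    def test_at_flow_names_offending_parameter(self):
        c = ControlCoefficients(E_0_h=1.0, A_0_h=0.03, E_0_a=1.5, R_0_s=0.3,
                                SBV_0=1000.0, E_Sl_h=0, A_Sl_h=0, E_Sl_a=0,
                                R_Sl_s=-0.02, SBV_Sl=0)
        with pytest.raises(ValueError, match="R_s"):
            c.at_flow(30.0)
        assert c.at_flow(0.0).R_s == pytest.approx(0.3)
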