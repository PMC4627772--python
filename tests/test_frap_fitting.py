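import numpy as np
import pytest

from nucyto_loc.frap.fitting import (
    RecoveryFit,
    compare_mobility,
    fit_one_phase,
    immobile_fraction,
)
from nucyto_loc.frap.normalize import NormalizedRecovery, normalize_record
from nucyto_loc.synthgen.frapsim import FRAPSimSpec, simulate_frap_record


def make_recovery(i0=0.2, a=0.6, k=5.0, dt=1e-3, duration=3.0, noise=0.0,
                  seed=0):
    t = np.arange(0.0, duration, dt)
    y = i0 + a * (1 - np.exp(-k * t))
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, len(t))
    return NormalizedRecovery(t=t, y=y, i_frap_pre=1.0, i_ref_pre=1.0,
                              y_pre=np.ones(10))


class TestFitOnePhase:
    def test_exact_model_recovery(self):
        fit = fit_one_phase(make_recovery())
        assert fit.k == pytest.approx(5.0, abs=1e-6)
        assert fit.i0 == pytest.approx(0.2, abs=1e-6)
        assert fit.a == pytest.approx(0.6, abs=1e-6)
        assert fit.converged and fit.reliable

    def test_half_life_identity(self):
        fit = fit_one_phase(make_recovery())
        assert fit.t_half_s == pytest.approx(np.log(2) / 5.0, abs=1e-6)
        assert fit.t_half_s * fit.k == pytest.approx(np.log(2))

    def test_immobile_fraction_identity(self):
        fit = fit_one_phase(make_recovery(i0=0.1, a=0.7))
        assert fit.immobile_fraction_pct == pytest.approx(
            100 * (1 - fit.i0 - fit.a))
        assert fit.immobile_fraction_pct == pytest.approx(20.0, abs=1e-4)

    def test_too_few_samples_rejected(self):
        rec = make_recovery(dt=0.5)  # 6 samples
        with pytest.raises(ValueError, match="10"):
            fit_one_phase(rec)

    def test_time_axis_must_start_at_zero(self):
        rec = make_recovery()
        rec.t = rec.t + 0.5
        with pytest.raises(ValueError, match="start at 0"):
            fit_one_phase(rec)

    def test_noisy_fit_still_close(self):
        fit = fit_one_phase(make_recovery(noise=0.01, seed=1))
        assert fit.k == pytest.approx(5.0, rel=0.05)
        assert fit.converged

    def test_over_recovery_flagged(self):
        fit = fit_one_phase(make_recovery(i0=0.5, a=0.9))
        assert "over-recovery" in fit.flags
        assert not fit.reliable


class TestImmobileFraction:
    @pytest.mark.parametrize("plateau,expected", [(0.8, 20.0), (1.0, 0.0)])
    def test_values(self, plateau, expected):
        fit = RecoveryFit(i0=0.2, a=plateau - 0.2, k=5.0, residual_sd=0.0,
                          converged=True, n_points=100)
        assert immobile_fraction(fit) == pytest.approx(expected)

    def test_unconverged_rejected(self):
        fit = RecoveryFit(i0=0.2, a=0.5, k=5.0, residual_sd=0.0,
                          converged=False, n_points=100)
        with pytest.raises(ValueError, match="unconverged"):
            immobile_fraction(fit)

    def test_negative_retained_on_over_recovery(self):
        fit = RecoveryFit(i0=0.6, a=0.6, k=5.0, residual_sd=0.0,
                          converged=True, n_points=100)
        assert immobile_fraction(fit) == pytest.approx(-20.0)


class TestEndToEndRecovery:
    def test_simulated_record_round_trip(self):
        spec = FRAPSimSpec(mobile_fraction=0.75, k_true=6.0, bleach_depth=0.9)
        record, truth = simulate_frap_record(spec)
        fit = fit_one_phase(normalize_record(record))
        assert fit.k == pytest.approx(6.0, rel=1e-4)
        assert fit.immobile_fraction_pct == pytest.approx(
            truth.true_immobile_fraction_pct, abs=1e-3)

    def test_parameter_recovery_with_noise(self):
        errors_if, errors_k = [], []
        for seed in range(10):
            spec = FRAPSimSpec(mobile_fraction=0.8, k_true=5.0,
                               noise_sd=0.01, seed=seed, line_rate_hz=500)
            record, truth = simulate_frap_record(spec)
            fit = fit_one_phase(normalize_record(record))
            errors_if.append(abs(fit.immobile_fraction_pct
                                 - truth.true_immobile_fraction_pct))
            errors_k.append(abs(fit.k - 5.0) / 5.0)
        assert np.median(errors_if) <= 2.0
        assert np.median(errors_k) <= 0.10


class TestCompareMobility:
    @staticmethod
    def _fits(mobile, n=6, k=5.0, noise=0.01, seed0=0, rate=500.0):
        fits = []
        for s in range(n):
            spec = FRAPSimSpec(mobile_fraction=mobile, k_true=k,
                               noise_sd=noise, seed=seed0 + s,
                               line_rate_hz=rate)
            record, _ = simulate_frap_record(spec)
            fits.append(fit_one_phase(normalize_record(record)))
        return fits

    def test_identical_groups_ns(self):
        fits = self._fits(0.8)
        res = compare_mobility(fits, list(fits))
        assert res["immobile_fraction_pct"].stars == "ns"
        assert res["t_half_s"].p_value > 0.9

    def test_distinct_mobile_fractions_highly_significant(self):
        free = self._fits(1.0, seed0=100)
        bound = self._fits(0.82, seed0=200)
        res = compare_mobility(free, bound)
        assert res["immobile_fraction_pct"].p_value <= 1e-4
        assert res["immobile_fraction_pct"].stars == "****"

    def test_swapping_groups_flips_t_same_p(self):
        a = self._fits(1.0, seed0=100)
        b = self._fits(0.82, seed0=200)
        r1 = compare_mobility(a, b)["immobile_fraction_pct"]
        r2 = compare_mobility(b, a)["immobile_fraction_pct"]
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_group_rejected(self):
        fits = self._fits(0.8, n=2)
        with pytest.raises(ValueError, match="2 fits"):
            compare_mobility(fits[:1], fits)
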