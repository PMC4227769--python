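"""Synthetic observables: trace shapes, dead time, determinism, round trips."""

import numpy as np
import pytest

from flipkin.mechanism import (
    MechanismSpec,
    RateConstantSet,
    ValidationError,
    table1_rates,
)
from flipkin.phasefit import fit_exponential_phases, fit_single_turnover
from flipkin.synth import (
    FluorescenceModel,
    MixingExperiment,
    Trace,
    default_time_grid,
    read_trace,
    synthesize_association_trace,
    synthesize_competition_series,
    synthesize_double_mixing_trace,
    synthesize_single_turnover,
    synthesize_titration,
    tight_binding_fraction,
    write_trace,
)


def zero_rates():
    return RateConstantSet(k_on=0, k_off_ns=0, k_search=0, k_escape=0,
                          k_flip=0, k_unflip=0, k_chem=0)


class TestAssociationTraces:
    def test_no_flux_gives_flat_unit_signal(self, tec):
        exp = MixingExperiment("single-mix", 1e-7, 5e-8, noise_sd=0.0)
        tr = synthesize_association_trace(MechanismSpec(zero_rates()), tec,
                                          exp)
        assert np.allclose(tr.signal, 1.0, atol=1e-12)

    def test_wt_tec_rises_then_falls(self, wt_tec_trace):
        # fitted amplitude pattern: negative (rise) then positive (quench)
        fit = fit_exponential_phases(wt_tec_trace.times,
                                     wt_tec_trace.signal, 2)
        assert fit.amplitudes[0] < 0 < fit.amplitudes[1]
        peak = np.argmax(wt_tec_trace.signal)
        assert 0 < peak < len(wt_tec_trace) - 1

    def test_y162a_tec_shows_single_decreasing_phase(self, y162a, tec):
        # binding and searching complete within the dead time
        exp = MixingExperiment("single-mix", 400e-9, 100e-9, noise_sd=0.0,
                               times=default_time_grid(0.2, 400))
        tr = synthesize_association_trace(MechanismSpec(y162a), tec, exp)
        # decreasing throughout (tiny late drift from slow product
        # formation is below 1e-6 per point); no rise survives dead time
        assert tr.signal[0] == np.max(tr.signal)
        assert np.all(np.diff(tr.signal) < 1e-6)
        fit = fit_exponential_phases(tr.times, tr.signal, 1)
        k_obs = y162a.k_flip + y162a.k_unflip
        assert fit.rates[0] == pytest.approx(k_obs, rel=0.02)

    def test_dead_time_truncates_without_regridding(self, wt, tec):
        times = np.geomspace(2e-4, 1.0, 100)
        exp = MixingExperiment("single-mix", 3e-7, 5e-8, times=times,
                               dead_time=5e-3, noise_sd=0.0)
        tr = synthesize_association_trace(MechanismSpec(wt), tec, exp)
        np.testing.assert_array_equal(tr.times, times[times >= 5e-3])

    def test_fixed_seed_is_bit_identical(self, wt, tec):
        exp = MixingExperiment("single-mix", 3e-7, 5e-8, noise_sd=0.01,
                               seed=99)
        a = synthesize_association_trace(MechanismSpec(wt), tec, exp)
        b = synthesize_association_trace(MechanismSpec(wt), tec, exp)
        np.testing.assert_array_equal(a.signal, b.signal)

    def test_empty_post_dead_time_grid_errors(self, wt, tec):
        exp = MixingExperiment("single-mix", 3e-7, 5e-8,
                               times=np.array([1e-4, 5e-4, 1e-3]),
                               dead_time=1.5e-3)
        with pytest.raises(ValidationError):
            synthesize_association_trace(MechanismSpec(wt), tec, exp)


class TestDoubleMixing:
    def test_y162a_recovery_rate(self, y162a):
        exp = MixingExperiment("double-mix", 600e-9, 100e-9, age_time=1.0,
                               noise_sd=0.0,
                               times=np.geomspace(2e-4, 1.5, 400))
        tr = synthesize_double_mixing_trace(
            MechanismSpec(table1_rates("Y162A", "AEA")),
            FluorescenceModel.aea_default("Y162A"), exp)
        fit = fit_exponential_phases(tr.times, tr.signal, 1)
        assert fit.rates[0] == pytest.approx(10.0, rel=0.01)

    def test_wt_recovery_matches_chased_eigenvalue(self, wt, aea_wt):
        # oracle: smallest nonzero eigenvalue of the chased system is
        # k_unflip + k_chem (exit from SRC by either path)
        exp = MixingExperiment("double-mix", 300e-9, 100e-9, age_time=1.0,
                               noise_sd=0.0,
                               times=np.geomspace(1e-2, 4000, 400))
        tr = synthesize_double_mixing_trace(MechanismSpec(wt), aea_wt, exp)
        fit = fit_exponential_phases(tr.times, tr.signal, 1)
        assert fit.rates[0] == pytest.approx(wt.k_unflip + wt.k_chem,
                                             rel=1e-3)

    def test_no_unflip_means_flat_after_chase(self, aea_wt):
        rts = zero_rates().replace(k_on=1e9, k_search=100.0, k_flip=50.0)
        exp = MixingExperiment("double-mix", 3e-7, 1e-7, age_time=2.0,
                               noise_sd=0.0,
                               times=np.geomspace(1e-3, 10, 100))
        tr = synthesize_double_mixing_trace(MechanismSpec(rts), aea_wt, exp)
        assert np.ptp(tr.signal) < 1e-9

    def test_requires_positive_age_time(self, wt, aea_wt):
        exp = MixingExperiment("double-mix", 3e-7, 1e-7, age_time=0.0)
        with pytest.raises(ValidationError):
            synthesize_double_mixing_trace(MechanismSpec(wt), aea_wt, exp)


class TestTitration:
    def test_stoichiometric_limit_is_piecewise_linear(self):
        D_tot, q = 0.4e-6, 5.0
        E = np.linspace(0, 1.2e-6, 61)
        _, sig = synthesize_titration(1e-15, 1.0, D_tot, E, q)
        below = E <= 0.9 * D_tot
        # linear descent to the equivalence point, plateau at 1/q after
        slope = np.diff(sig[below]) / np.diff(E[below])
        assert np.allclose(slope, slope[0], rtol=1e-3)
        assert np.allclose(sig[E > 1.1 * D_tot], 1 / q, atol=1e-3)

    def test_zero_enzyme_gives_unit_signal(self):
        _, sig = synthesize_titration(5e-9, 1.0, 0.4e-6, [0.0], 5.0)
        assert sig[0] == pytest.approx(1.0)

    def test_quadratic_root_against_brute_force(self):
        # Kd = D_tot, E = D_tot, n = 1: fraction bound from the binding
        # quadratic, checked against numpy's polynomial root finder
        D = 1e-6
        roots = np.roots([1.0, -(D + D + D), D * D])
        brute = min(roots) / D
        assert brute == pytest.approx(0.38197, rel=1e-4)
        assert tight_binding_fraction(D, D, 1.0, D) == \
            pytest.approx(brute, rel=1e-9)

    def test_negative_kd_rejected(self):
        with pytest.raises(ValidationError):
            synthesize_titration(-1e-9, 1.0, 0.4e-6, [1e-7], 5.0)


class TestGelAssays:
    def test_single_turnover_starts_at_zero(self):
        t, frac = synthesize_single_turnover(1e-3, [0.0, 60.0, 600.0])
        assert frac[0] == 0.0

    def test_half_life(self):
        # k = 0.05 min^-1 -> half-reaction at ln2/k = 13.86 min
        k_per_s = 0.05 / 60.0
        _, frac = synthesize_single_turnover(k_per_s, [13.86 * 60.0])
        assert frac[0] == pytest.approx(0.5, abs=1e-3)

    def test_noiseless_round_trip_is_exact(self):
        t, frac = synthesize_single_turnover(8.0e-4,
                                             np.linspace(0, 5400, 30))
        fit = fit_single_turnover(t, frac)
        assert fit["k_obs"] == pytest.approx(8.0e-4, rel=1e-6)

    @pytest.mark.parametrize("N,expected", [
        (20e-6, 0.5), (0.0, 1.0), (np.inf, 0.0),
    ])
    def test_competition_definition_points(self, N, expected):
        _, norm = synthesize_competition_series(1.0, 20e-6, [N])
        assert norm[0] == pytest.approx(expected)

    def test_no_inhibition_series_is_flat(self):
        _, norm = synthesize_competition_series(
            1.0, np.inf, [0, 1e-6, 1e-5, np.inf])
        np.testing.assert_allclose(norm, 1.0)


class TestTraceIO:
    def test_csv_sidecar_roundtrip(self, wt, tec, tmp_path):
        exp = MixingExperiment("single-mix", 3e-7, 5e-8, noise_sd=0.003,
                               seed=4, experiment_id="assoc-1")
        tr = synthesize_association_trace(MechanismSpec(wt), tec, exp)
        path = tmp_path / "assoc-1.csv"
        write_trace(tr, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.times, tr.times, rtol=1e-12)
        np.testing.assert_allclose(back.signal, tr.signal, rtol=1e-12)
        assert back.experiment.seed == 4
        assert back.experiment.experiment_id == "assoc-1"
        assert path.read_text().splitlines()[0] == "time_s,signal"
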