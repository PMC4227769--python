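"""Mechanism scheme: conservation, relaxation rates, partition probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flipkin.mechanism import (
    MechanismSpec,
    RateConstantSet,
    SpeciesState,
    UndefinedValueError,
    ValidationError,
    commitment_to_catalysis,
    equilibrium_flip_constant,
    observed_flip_rate,
    occupancy_multiplier,
    simulate_stochastic,
    simulate_timecourse,
    table1_rates,
    unflip_from_commitment,
)
from flipkin.phasefit import fit_exponential_phases

rates_st = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


def make_rates(k_on=0.0, k_off=0.0, k_search=0.0, k_escape=0.0, k_flip=0.0,
               k_unflip=0.0, k_chem=0.0):
    return RateConstantSet(k_on=k_on, k_off_ns=k_off, k_search=k_search,
                          k_escape=k_escape, k_flip=k_flip,
                          k_unflip=k_unflip, k_chem=k_chem)


class TestSimulateTimecourse:
    def test_zero_rates_give_constant_trajectory(self):
        spec = MechanismSpec(make_rates())
        init = SpeciesState(E=2e-7, D=5e-8, IRC=1e-8)
        traj = simulate_timecourse(spec, init, np.linspace(0, 10, 50))
        assert np.allclose(traj.concentrations,
                           traj.concentrations[0], rtol=0, atol=1e-18)

    def test_flip_step_reaches_detailed_balance(self):
        # with no chemistry the SRC/IRC ratio relaxes to k_flip/k_unflip
        rts = make_rates(k_flip=3.0, k_unflip=1.5)
        spec = MechanismSpec(rts)
        init = SpeciesState(IRC=5e-8)
        traj = simulate_timecourse(spec, init, np.linspace(0, 50, 20))
        ratio = traj["SRC"][-1] / traj["IRC"][-1]
        assert ratio == pytest.approx(equilibrium_flip_constant(3.0, 1.5),
                                      rel=1e-6)

    def test_src_rise_rate_matches_eigenvalue_oracle(self):
        # independent oracle: diagonalize the 2x2 generator of IRC <-> SRC
        k_flip, k_unflip = 3.6, 1.6e-3
        A = np.array([[-k_flip, k_unflip], [k_flip, -k_unflip]])
        eig = np.sort(np.abs(np.linalg.eigvals(A)))
        assert eig[1] == pytest.approx(3.6016, rel=1e-12)

        rts = make_rates(k_flip=k_flip, k_unflip=k_unflip)
        traj = simulate_timecourse(MechanismSpec(rts),
                                   SpeciesState(IRC=5e-8, E=3e-7),
                                   np.linspace(1e-4, 3.0, 400))
        fit = fit_exponential_phases(traj.times, traj["SRC"] / 5e-8, 1)
        assert fit.rates[0] == pytest.approx(eig[1], rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k_on=st.floats(0, 1e9), k_search=rates_st, k_escape=rates_st,
           k_flip=rates_st, k_unflip=rates_st, k_chem=rates_st)
    def test_mass_conservation(self, k_on, k_search, k_escape, k_flip,
                               k_unflip, k_chem):
        rts = make_rates(k_on, 1.0, k_search, k_escape, k_flip, k_unflip,
                         k_chem)
        init = SpeciesState(E=3e-7, D=5e-8, ENS=1e-8, IRC=2e-9, SRC=1e-9)
        traj = simulate_timecourse(MechanismSpec(rts), init,
                                   np.geomspace(1e-4, 20.0, 60))
        dna = sum(traj[s] for s in ("D", "ENS", "IRC", "SRC", "P"))
        enz = sum(traj[s] for s in ("E", "ENS", "IRC", "SRC", "EQ"))
        assert np.max(np.abs(dna / init.total_dna - 1)) < 1e-8
        assert np.max(np.abs(enz / init.total_enzyme - 1)) < 1e-8

    def test_input_validation(self):
        spec = MechanismSpec(make_rates())
        with pytest.raises(ValidationError):
            simulate_timecourse(spec, SpeciesState(D=5e-8), [1.0, 0.5])
        with pytest.raises(ValidationError):
            SpeciesState(D=-1e-9)
        with pytest.raises(ValidationError):
            make_rates(k_flip=float("nan"))


class TestOccupancy:
    def test_additive_doubles_search_flux(self):
        rts = table1_rates("WT")
        spec = MechanismSpec(rts, occupancy_model="additive")
        m1 = occupancy_multiplier(spec, 2e-7, 1e-7)
        m2 = occupancy_multiplier(spec, 4e-7, 1e-7)
        assert m2 == pytest.approx(2 * m1)
        # the instantaneous NS -> IRC flux scales with the multiplier
        assert m2 * rts.k_search == pytest.approx(2 * m1 * rts.k_search)

    def test_single_model_and_capacity_cap(self):
        rts = table1_rates("WT")
        single = MechanismSpec(rts, occupancy_model="single")
        additive = MechanismSpec(rts, occupancy_model="additive")
        assert occupancy_multiplier(single, 1e-6, 1e-8) == 1.0
        assert occupancy_multiplier(additive, 1e-5, 1e-8) == 10.0
        assert occupancy_multiplier(additive, 1e-8, 1e-6) == 1.0


class TestStochastic:
    def test_no_unflip_gives_all_product(self):
        rts = make_rates(k_chem=0.01)
        tally = simulate_stochastic(MechanismSpec(rts, chase=True), 500, 1,
                                    horizon=1e5)
        assert tally.fraction_product == 1.0

    def test_zero_rates_stay_bound(self):
        tally = simulate_stochastic(MechanismSpec(make_rates(), chase=False),
                                    100, 1, horizon=10.0)
        assert tally.still_bound == 100

    def test_partition_matches_analytic_within_3se(self, wt):
        n = 100_000
        tally = simulate_stochastic(MechanismSpec(wt, chase=True), n, 11,
                                    horizon=1e5)
        p = commitment_to_catalysis(wt.k_chem, wt.k_unflip)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(tally.fraction_product - p) < 3 * se

    def test_y162a_partition_is_zero_at_gel_precision(self, y162a):
        tally = simulate_stochastic(MechanismSpec(y162a, chase=True),
                                    50_000, 5, horizon=1e4)
        assert commitment_to_catalysis(y162a.k_chem, y162a.k_unflip) == \
            pytest.approx(3.8e-5, rel=1e-3)
        assert tally.fraction_product < 5e-4

    def test_seed_reproducibility(self, wt):
        a = simulate_stochastic(MechanismSpec(wt, chase=True), 2000, 3, 1e4)
        b = simulate_stochastic(MechanismSpec(wt, chase=True), 2000, 3, 1e4)
        assert a == b


class TestDerivedConstants:
    @pytest.mark.parametrize("k_flip,k_unflip,expected", [
        (3.6, 1.6e-3, 2250.0),
        (170.0, 10.0, 17.0),
        (7.7, 7.7, 1.0),
    ])
    def test_equilibrium_flip_constant(self, k_flip, k_unflip, expected):
        assert equilibrium_flip_constant(k_flip, k_unflip) == \
            pytest.approx(expected)

    def test_equilibrium_undefined_at_zero_unflip(self):
        with pytest.raises(UndefinedValueError):
            equilibrium_flip_constant(1.0, 0.0)

    @pytest.mark.parametrize("k_chem,k_unflip,expected", [
        (8.0e-4, 1.6e-3, 1 / 3),
        (0.5, 0.0, 1.0),
        (3.8e-4, 10.0, 3.8e-4 / (3.8e-4 + 10.0)),
    ])
    def test_commitment(self, k_chem, k_unflip, expected):
        assert commitment_to_catalysis(k_chem, k_unflip) == \
            pytest.approx(expected)

    def test_commitment_monotonicity(self):
        base = commitment_to_catalysis(1e-3, 1e-2)
        assert commitment_to_catalysis(2e-3, 1e-2) > base
        assert commitment_to_catalysis(1e-3, 2e-2) < base
        with pytest.raises(UndefinedValueError):
            commitment_to_catalysis(0.0, 0.0)

    @pytest.mark.parametrize("k_chem,C,expected", [
        (8.0e-4, 0.30, 1.8667e-3),
        (4.3e-4, 0.08, 4.945e-3),
        (0.77, 0.5, 0.77),
    ])
    def test_unflip_from_commitment(self, k_chem, C, expected):
        assert unflip_from_commitment(k_chem, C) == \
            pytest.approx(expected, rel=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k_chem=st.floats(1e-6, 1e3), k_unflip=st.floats(1e-6, 1e3))
    def test_commitment_roundtrip(self, k_chem, k_unflip):
        C = commitment_to_catalysis(k_chem, k_unflip)
        assert unflip_from_commitment(k_chem, C) == \
            pytest.approx(k_unflip, rel=1e-12)

    def test_unflip_infinite_at_zero_commitment(self):
        with pytest.raises(UndefinedValueError):
            unflip_from_commitment(1e-3, 0.0)

    @pytest.mark.parametrize("k_flip,k_unflip,expected", [
        (3.6, 1.6e-3, 3.6016),
        (170.0, 10.0, 180.0),
        (0.0, 0.0, 0.0),
    ])
    def test_observed_flip_rate(self, k_flip, k_unflip, expected):
        assert observed_flip_rate(k_flip, k_unflip) == \
            pytest.approx(expected)

    def test_observed_rate_is_slowest_relaxation_of_flip_step(self):
        # eigenvalue check on the isolated two-state flipping step
        k_flip, k_unflip = 7.9, 4.6e-3
        A = np.array([[-k_flip, k_unflip], [k_flip, -k_unflip]])
        nonzero = np.max(np.abs(np.linalg.eigvals(A)))
        assert nonzero == pytest.approx(observed_flip_rate(k_flip, k_unflip))


class TestSerialization:
    def test_rate_set_json_roundtrip(self, wt):
        assert RateConstantSet.from_json(wt.to_json()) == wt

    def test_trajectory_csv_header(self, wt, tmp_path):
        traj = simulate_timecourse(MechanismSpec(wt),
                                   SpeciesState.premix(3e-7, 5e-8),
                                   np.linspace(0, 1, 10))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_s,E,D,ENS,IRC,SRC,P,EQ"
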