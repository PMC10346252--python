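"""Direct simulation: input signals, implicit stepping, convergence, I/O."""

import numpy as np
import pytest
from scipy.linalg import expm, lu_factor

from capnoflow.grid import CompartmentSpec, build_grid
from capnoflow.simulate import (
    InvalidChronogramError,
    InvalidInputError,
    Trajectory,
    make_chronogram,
    make_step_input,
    simulate_direct,
    step_implicit,
)


class TestInputs:
    def test_step_levels_match_published_capnia_concentrations(self):
        sig = make_step_input(40, 50, t_init=100, t_total=200, dt=1.0)
        assert sig.values[0] == pytest.approx(1.099, abs=1e-3)
        assert sig.values[-1] == pytest.approx(1.3738, abs=1e-3)
        assert sig.values[99] != sig.values[100]

    def test_degenerate_step_is_constant(self):
        sig = make_step_input(40, 40, t_init=50, t_total=100)
        assert np.ptp(sig.values) == 0.0

    def test_hypocapnia_step_level(self):
        sig = make_step_input(30, 40, t_init=50, t_total=100)
        assert sig.values[0] == pytest.approx(0.824, abs=1e-3)

    def test_negative_pressure_rejected(self):
        with pytest.raises(InvalidInputError):
            make_step_input(-1, 50, 10, 20)

    def test_chronogram_piecewise_levels(self):
        phases = [(0.0, 100.0, 1.0), (100.0, 50.0, 2.0), (150.0, 50.0, 0.5)]
        sig = make_chronogram(phases, dt=1.0)
        assert len(sig) == 200
        assert sig.values[99] == 1.0 and sig.values[100] == 2.0
        assert sig.values[-1] == 0.5

    def test_chronogram_rejects_gaps_and_overlaps(self):
        with pytest.raises(InvalidChronogramError):
            make_chronogram([(0, 100, 1.0), (120, 50, 2.0)])
        with pytest.raises(InvalidChronogramError):
            make_chronogram([(0, 100, 1.0), (80, 50, 2.0)])


def _toy_grid():
    specs = (CompartmentSpec("a", 1.0, 0.02, 1e-3, 1.0, 3),
             CompartmentSpec("b", 0.4, 0.05, 0.0, 2.0, 3))
    return build_grid(specs)


class TestStepping:
    def test_null_dynamics(self, device_grid):
        sig = make_step_input(0, 0, 10, 50, dt=1.0)
        # zero input: make a zero-pressure "step"
        traj = simulate_direct(device_grid, sig)
        assert np.all(traj.states == 0.0)
        assert np.all(traj.observations == 0.0)

    def test_constant_input_converges_to_steady_state(self):
        g = _toy_grid()
        sig = make_step_input(40, 40, 1, 4000, dt=1.0)
        traj = simulate_direct(g, sig)
        ss = g.steady_state(sig.values[0])
        assert traj.states[-1] == pytest.approx(ss, rel=1e-6, abs=1e-12)

    def test_single_step_solves_implicit_system(self, device_grid):
        dt = 1.0
        A = np.eye(13) - dt * device_grid.F
        lu = lu_factor(A)
        c0 = np.linspace(0, 1, 13)
        q = np.array([1.1, 0.0])
        c1 = step_implicit(c0, q, lu, device_grid.G, dt)
        assert A @ c1 == pytest.approx(c0 + dt * device_grid.G @ q, abs=1e-12)

    def test_against_matrix_exponential_oracle(self, device_grid):
        """Implicit Euler converges at first order to the exact-propagator
        trajectory of the 13-state system."""
        g = device_grid
        c_in = 1.0986666
        q = np.array([c_in, 0.0])
        T = 512.0
        # exact trajectory via the matrix exponential with constant input
        Fq = np.linalg.solve(g.F, g.G @ q)
        c_exact = (expm(g.F * T) @ Fq) - Fq
        errs = []
        for dt in (8.0, 4.0, 2.0):
            sig = make_step_input(40, 40, dt, T + dt / 2, dt=dt)
            traj = simulate_direct(g, sig)
            errs.append(np.abs(traj.states[-1] - c_exact).max())
        # halving dt roughly halves the global error
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.35)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.35)

    def test_state_norm_bounded_for_large_steps(self, device_grid):
        """Contractivity: even δt = 100 s keeps the trajectory bounded."""
        sig = make_step_input(40, 50, 500, 50000, dt=100.0)
        traj = simulate_direct(device_grid, sig)
        bound = sig.values.max() * max(s.H for s in device_grid.specs) * 10
        assert np.abs(traj.states).max() < bound

    def test_mismatched_dt_rejected(self, device_grid):
        sig = make_step_input(40, 50, 10, 100, dt=1.0)
        with pytest.raises(InvalidInputError):
            simulate_direct(device_grid, sig, dt=2.0)


class TestObservationAndNoise:
    def test_observation_is_measurement_cell_state_plus_noise(self, device_grid):
        sig = make_step_input(40, 50, 100, 400, dt=1.0)
        clean = simulate_direct(device_grid, sig)
        assert clean.observations == pytest.approx(
            clean.states[:, device_grid.h_index])
        noisy = simulate_direct(device_grid, sig, noise_variance=1e-6, seed=7)
        resid = noisy.observations - clean.observations
        assert np.std(resid) == pytest.approx(1e-3, rel=0.2)
        # states themselves carry no noise
        assert noisy.states == pytest.approx(clean.states)

    def test_noise_is_seed_reproducible(self, device_grid):
        sig = make_step_input(40, 50, 100, 300, dt=1.0)
        a = simulate_direct(device_grid, sig, noise_variance=1e-6, seed=3)
        b = simulate_direct(device_grid, sig, noise_variance=1e-6, seed=3)
        assert np.array_equal(a.observations, b.observations)

    def test_steady_profile_shows_dilution(self, device_grid):
        """At steady state the gas-side level sits far below the blood level
        (flushing by the collection air flow) and decreases with height."""
        c_in = 1.0986666
        ss = device_grid.steady_state(c_in)
        meas = ss[device_grid.slices["meas"]]
        coll = ss[device_grid.slices["coll"]]
        assert meas.max() < c_in
        gas = np.concatenate([meas, coll])
        assert np.all(np.diff(gas) <= 1e-12)

    def test_trajectory_csv_round_trip(self, device_grid, tmp_path):
        sig = make_step_input(40, 50, 50, 150, dt=1.0)
        traj = simulate_direct(device_grid, sig, noise_variance=1e-8, seed=5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = Trajectory.from_csv(path)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.states, traj.states)
        assert np.array_equal(back.observations, traj.observations)
        assert back.noise_seed == 5 and back.noise_variance == 1e-8
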