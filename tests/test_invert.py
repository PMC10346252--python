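"""Augmented state-space model and Kalman filter behaviour."""

import numpy as np
import pytest

from capnoflow.grid import CompartmentSpec, build_grid
from capnoflow.invert import (
    KalmanConfig,
    augment_with_ar1,
    kalman_predict,
    kalman_update,
    run_inversion,
    _DiscreteKalman,
)
from capnoflow.simulate import make_step_input, simulate_direct


def _toy_grid(n_interior=3):
    return build_grid(
        (CompartmentSpec("a", 1.0, 0.02, 1e-3, 1.0, n_interior),),
        include_outer_point=False,
    )


class TestAugmentation:
    def test_shapes_and_coupling(self, device_grid):
        model = augment_with_ar1(device_grid, phi=0.0)
        assert model.n_states == 14
        # the Dirichlet steering coefficient moves to the state coupling
        assert model.F_aug[1, 0] == pytest.approx(device_grid.G[0, 0])
        assert model.F_aug[1:, 1:] == pytest.approx(device_grid.F)
        assert model.h_index == device_grid.h_index + 1

    def test_random_walk_limit(self, device_grid):
        """phi = 0 leaves the input state with no deterministic drift."""
        model = augment_with_ar1(device_grid, phi=0.0)
        assert model.F_aug[0, 0] == 0.0
        A = np.eye(14) - 1.0 * model.F_aug
        assert A[0, 0] == 1.0

    @pytest.mark.parametrize("dt", [0.5, 1.0, 2.0])
    def test_implicit_self_transition(self, device_grid, dt):
        """Element 0 self-transition is 1/(1 − φδt) under the implicit scheme."""
        phi = -0.0036
        model = augment_with_ar1(device_grid, phi)
        A = np.eye(14) - dt * model.F_aug
        e0 = np.zeros(14)
        e0[0] = 1.0
        transition = np.linalg.solve(A, e0)[0]
        assert transition == pytest.approx(1.0 / (1.0 + 0.0036 * dt))

    def test_positive_phi_warns(self, device_grid):
        with pytest.warns(UserWarning):
            augment_with_ar1(device_grid, phi=0.01)

    def test_augmented_propagation_equals_direct_model(self, device_grid):
        """Pinning element 0 to the known input reproduces direct trajectories."""
        dt = 1.0
        sig = make_step_input(40, 50, 20, 120, dt=dt)
        direct = simulate_direct(device_grid, sig)
        model = augment_with_ar1(device_grid, 0.0)
        # eliminate element 0: with the input pinned to its known value the
        # remaining rows are exactly the direct model's implicit recursion
        c_aug = np.zeros(14)
        states = []
        A_grid = np.eye(13) - dt * device_grid.F
        for k in range(len(sig)):
            rhs = c_aug[1:] + dt * model.F_aug[1:, 0] * sig.values[k]
            c_aug = np.concatenate([[sig.values[k]], np.linalg.solve(A_grid, rhs)])
            states.append(c_aug[1:].copy())
        assert np.asarray(states) == pytest.approx(direct.states, abs=1e-10)


class TestKalmanRecursion:
    def test_noise_free_prediction_matches_direct_step(self, device_grid):
        model = augment_with_ar1(device_grid, 0.0)
        cfg = KalmanConfig(q_variance=0.0, r_variance=1e-6)
        c0 = np.arange(14.0)
        c_pred, P_pred = kalman_predict((c0, np.zeros((14, 14))), model, cfg)
        A = np.eye(14) - cfg.dt * model.F_aug
        assert A @ c_pred == pytest.approx(c0)
        assert P_pred == pytest.approx(np.zeros((14, 14)), abs=1e-300)

    def test_pure_process_noise(self, device_grid):
        model = augment_with_ar1(device_grid, 0.0)
        cfg = KalmanConfig(q_variance=1e-8, r_variance=1e-6,
                           process_noise="full")
        _, P_pred = kalman_predict((np.zeros(14), np.zeros((14, 14))), model, cfg)
        assert P_pred == pytest.approx(1e-8 * np.eye(14))

    def test_uninformative_measurement_keeps_prediction(self, device_grid):
        model = augment_with_ar1(device_grid, 0.0)
        cfg = KalmanConfig(r_variance=1e12)
        pred = (np.linspace(0, 1, 14), np.eye(14) * 1e-6)
        upd = kalman_update(pred, 5.0, model, cfg)
        assert np.abs(upd.gain).max() < 1e-12
        assert upd.estimate == pytest.approx(pred[0], abs=1e-10)

    def test_perfect_measurement_pins_observed_component(self):
        g = _toy_grid()
        model = augment_with_ar1(g, 0.0)
        cfg = KalmanConfig(r_variance=1e-15)
        pred = (np.zeros(model.n_states), np.eye(model.n_states))
        upd = kalman_update(pred, 2.5, model, cfg)
        assert upd.estimate[model.h_index] == pytest.approx(2.5, rel=1e-6)

    def test_nonfinite_measurement_is_skipped(self, device_grid):
        model = augment_with_ar1(device_grid, 0.0)
        cfg = KalmanConfig()
        pred = (np.ones(14), np.eye(14))
        with pytest.warns(UserWarning):
            upd = kalman_update(pred, float("nan"), model, cfg)
        assert upd.estimate == pytest.approx(pred[0])
        assert np.all(upd.gain == 0.0)

    def test_covariance_stays_symmetric_psd_long_run(self):
        """Joseph form keeps P symmetric PSD over 1e5 predict/update cycles."""
        g = _toy_grid(2)
        model = augment_with_ar1(g, -0.001)
        cfg = KalmanConfig(q_variance=1e-8, r_variance=1e-6)
        d = _DiscreteKalman(model, cfg)
        n = model.n_states
        c, P = np.zeros(n), np.eye(n)
        rng = np.random.default_rng(0)
        y = rng.normal(0.1, 1e-3, size=100_000)
        for k in range(len(y)):
            c, P = kalman_predict((c, P), model, cfg, _disc=d)
            upd = kalman_update((c, P), y[k], model, cfg, _disc=d)
            c, P = upd.estimate, upd.covariance
        assert np.abs(P - P.T).max() < 1e-12
        assert np.linalg.eigvalsh(P).min() >= -1e-15


class TestInversionPipeline:
    def test_empty_observations_give_empty_output(self, device_grid):
        model = augment_with_ar1(device_grid, 0.0)
        res = run_inversion(np.array([]), model, KalmanConfig())
        assert len(res) == 0

    def test_constant_steady_observation_recovers_constant_input(self, device_grid):
        c_in = 1.0986666
        ss = device_grid.steady_state(c_in)
        y = np.full(4000, ss[device_grid.h_index])
        model = augment_with_ar1(device_grid, 0.0)
        res = run_inversion(y, model, KalmanConfig())
        assert res.blood_estimate[-1] == pytest.approx(c_in, rel=1e-3)

    def test_pressure_output_uses_ostwald_solubility(self, device_grid, params):
        c_in = params.to_concentration(40.0)
        ss = device_grid.steady_state(c_in)
        y = np.full(3000, ss[device_grid.h_index])
        model = augment_with_ar1(device_grid, 0.0)
        res = run_inversion(y, model, KalmanConfig(), params=params)
        assert res.blood_pressure[-1] == pytest.approx(40.0, rel=1e-3)

    def test_matched_noiseless_step_converges_with_vanishing_innovations(
            self, step_study):
        """On matched-model noiseless data the blood estimate reaches the true
        step levels and innovations decay towards zero."""
        est = step_study.estimates[0.0]
        t = step_study.window_times
        # settled tails at both levels
        assert est[t < 12000][-10:].mean() == pytest.approx(1.0987, abs=2e-3)
        assert est[-10:].mean() == pytest.approx(1.3733, abs=2e-3)

    def test_inversion_csv_output(self, device_grid, tmp_path):
        model = augment_with_ar1(device_grid, 0.0)
        y = np.linspace(0, 0.1, 50)
        res = run_inversion(y, model, KalmanConfig())
        path = tmp_path / "inv.csv"
        res.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (50, 5)
        assert data[:, 1] == pytest.approx(res.blood_estimate)
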