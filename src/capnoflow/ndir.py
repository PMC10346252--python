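"""Dual-wavelength NDIR measurement model and calibration.

The device reads two thermopile voltages behind optical filters at
λ1 = 4.26 µm (a CO2 absorption peak) and λ2 = 3.91 µm (a water-neutral
reference).  Under Beer–Lambert attenuation the log-ratio of the voltages is
linear in the CO2 molar concentration; non-linear effects (broadband source
spectrum, multiple reflection paths, thermopile response) are captured by a
linear-quadratic model in a non-integer power of the concentration,

    −ln[U_λ1/U_λ2] ≈ ℓ + m·C^u + n·C^{2u},

whose non-negative parameters (m, n, u) — and optionally the intercept ℓ —
are fitted by nonlinear least squares against samples of known composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationModel",
    "CalibrationSample",
    "InvalidMeasurementError",
    "CalibrationFitError",
    "concentration_from_logratio",
    "forward_logratio",
    "synthesize_voltages",
    "fit_calibration",
    "samples_to_csv",
    "samples_from_csv",
]

WAVELENGTH_MEAS_UM = 4.26
WAVELENGTH_REF_UM = 3.91


class InvalidMeasurementError(ValueError):
    """Non-physical voltage or concentration fed to the NDIR model."""


class CalibrationFitError(RuntimeError):
    """The calibration fit failed (degenerate design or non-convergence)."""


@dataclass(frozen=True)
class CalibrationModel:
    """Linear-quadratic NDIR calibration with non-integer exponent.

    ``u_cal`` is the concentration exponent (named to avoid collision with
    the convection speed u of the transport model).
    """

    intercept: float        # ℓ = ln[U0,λ2 / U0,λ1], dimensionless
    m: float                # per (mol·m-3)^u_cal
    n: float                # per (mol·m-3)^(2 u_cal)
    u_cal: float            # dimensionless, > 0

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0 or self.u_cal <= 0:
            raise InvalidMeasurementError("m, n must be ≥ 0 and u_cal > 0")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CalibrationSample:
    """One supervised calibration point: known concentration and measured log-ratio."""

    concentration: float    # mol·m-3, ≥ 0
    log_ratio: float        # ln(U_λ1 / U_λ2), dimensionless

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidMeasurementError("calibration concentration must be ≥ 0")


def concentration_from_logratio(
    U_l1: float, U_l2: float, U0_l1: float, U0_l2: float, k_co2_l1: float
) -> float:
    """Beer–Lambert inversion of the dual-wavelength voltage ratio.

    C = −ln[(U_λ1/U_λ2)/(U0_λ1/U0_λ2)] / k_CO2(λ1), with the blank voltages
    U0 read in the absence of CO2.
    """
    if min(U_l1, U_l2, U0_l1, U0_l2) <= 0:
        raise InvalidMeasurementError("thermopile voltages must be positive")
    if k_co2_l1 <= 0:
        raise InvalidMeasurementError("attenuation coefficient must be positive")
    return -np.log((U_l1 / U_l2) / (U0_l1 / U0_l2)) / k_co2_l1


def forward_logratio(C, model: CalibrationModel):
    """Predicted −ln[U_λ1/U_λ2] for concentration(s) C ≥ 0."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise InvalidMeasurementError("concentration must be non-negative")
    powered = np.power(C, model.u_cal)  # C >= 0 and u_cal > 0: 0^u = 0
    out = model.intercept + model.m * powered + model.n * powered**2
    return out if out.ndim else float(out)


def synthesize_voltages(
    C, model: CalibrationModel, U0_l1: float = 1.0, U0_l2: float = 1.0
):
    """Synthetic thermopile voltage pair consistent with the calibration model.

    Returns (U_λ1, U_λ2) with U_λ2 held at its blank value; useful to
    generate calibration fixtures and to exercise the Beer–Lambert front end.
    """
    log_ratio = -np.asarray(forward_logratio(C, model))
    return U0_l1 * np.exp(log_ratio + np.log(U0_l2 / U0_l1)), np.full_like(
        log_ratio, U0_l2
    )


def _residuals(theta: np.ndarray, C: np.ndarray, y: np.ndarray, ell: float | None):
    if ell is None:
        ell_, m, n, u = theta
    else:
        ell_, (m, n, u) = ell, theta
    powered = np.power(C, u)
    return ell_ + m * powered + n * powered**2 - y


def fit_calibration(
    samples: Sequence[CalibrationSample],
    fit_intercept: bool = True,
    intercept: float = 0.0,
    gtol: float = 1e-10,
) -> tuple[CalibrationModel, float]:
    """Least-squares fit of the linear-quadratic model to calibration samples.

    Minimizes Ψ = Σ_i [ln(U_λ1(i)/U_λ2(i)) + ℓ + m·C_i^u + n·C_i^{2u}]², i.e.
    the squared residuals of ``forward_logratio`` against −log_ratio.  When
    ``fit_intercept`` is false, ℓ is fixed to ``intercept`` (its blank-
    measurement value ln[U0,λ2/U0,λ1]).  Non-negativity of (m, n, u) is
    enforced by bounded optimization; the start point is the linear limit
    (u = 1, n = 0, (ℓ, m) from an ordinary linear fit).

    Returns the fitted model and Ψ at the optimum.
    """
    C = np.array([s.concentration for s in samples], dtype=float)
    y = -np.array([s.log_ratio for s in samples], dtype=float)  # target ℓ+mC^u+nC^2u
    n_free = 4 if fit_intercept else 3
    if len(C) < n_free:
        raise CalibrationFitError(
            f"need at least {n_free} samples, got {len(C)}"
        )
    if len(np.unique(C)) < 2:
        raise CalibrationFitError("degenerate design: all concentrations equal")

    # linear-limit initialization
    X = np.column_stack([np.ones_like(C), C])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    ell0, m0 = float(coef[0]), max(float(coef[1]), 1e-12)
    if fit_intercept:
        theta0 = np.array([ell0, m0, 1e-12, 1.0])
        lower = [-np.inf, 0.0, 0.0, 1e-6]
        upper = [np.inf, np.inf, np.inf, np.inf]
        ell_fixed = None
    else:
        theta0 = np.array([m0, 1e-12, 1.0])
        lower = [0.0, 0.0, 1e-6]
        upper = [np.inf, np.inf, np.inf]
        ell_fixed = intercept

    res = least_squares(
        _residuals, theta0, args=(C, y, ell_fixed),
        bounds=(lower, upper), method="trf", gtol=gtol, xtol=1e-14, ftol=1e-14,
    )
    if not res.success:
        raise CalibrationFitError(
            f"calibration fit did not converge: {res.message} "
            f"(nfev={res.nfev}, cost trace final={res.cost:.3e})"
        )
    if ell_fixed is None:
        ell, m, n, u = res.x
    else:
        ell, (m, n, u) = ell_fixed, res.x
    psi = float(2.0 * res.cost)  # least_squares cost is 0.5·Σr²
    return CalibrationModel(intercept=float(ell), m=float(m), n=float(n),
                            u_cal=float(u)), psi


# -- CSV round trip ---------------------------------------------------------

def samples_to_csv(samples: Sequence[CalibrationSample], path: Union[str, Path]) -> None:
    body = np.array([[s.concentration, s.log_ratio] for s in samples])
    np.savetxt(path, body, delimiter=",", header="concentration,log_ratio",
               comments="", fmt="%.17g")


def samples_from_csv(path: Union[str, Path]) -> list[CalibrationSample]:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return [CalibrationSample(float(c), float(r)) for c, r in data]
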