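"""1D spatial discretization of the four-compartment CO2 transport column.

The column is ordered bottom-up along z: blood, skin (stratum corneum),
measurement cell, collection cell.  Each compartment contributes
``n_interior`` equidistant points at spacing ``δz = Δz/(n_interior + 1)``;
an extra outer point carries the zero-diffusive-flux closure at the top of
the collection cell.  With 3 interior points per compartment plus the outer
point the state has N = 13 entries.

The finite-difference operator F uses the central convection–diffusion
stencil inside each compartment,

    dc[i]/dt = (D/δz² + u/2δz)·c[i−1] − 2D/δz²·c[i] + (D/δz² − u/2δz)·c[i+1],

with three kinds of boundary handling:

* a Dirichlet condition at the bottom of the blood compartment, moved to the
  steering matrix G (column 0 drives the blood inlet concentration);
* a Neumann (zero diffusive flux) condition at the top of the column;
* Henry-law interface conditions between compartments.  Only diffusive flux
  crosses an interface: the two-sided continuity system (flux continuity +
  partial-pressure continuity) is solved for the interface concentrations and
  the closure is substituted for the across-interface neighbour.  The
  convective stream never crosses an interface — in blood it leaves laterally
  just below the skin, and in the collection cell fresh air enters just above
  the measurement cell carrying the exogenous inlet concentration (G column 1)
  and exits at the top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .params import ModelParams

__all__ = [
    "CompartmentSpec",
    "GridModel",
    "InvalidGeometryError",
    "PecletWarning",
    "interface_concentrations",
    "build_grid",
    "grid_from_params",
]

COMPARTMENT_ORDER = ("blood", "skin", "meas", "coll")


class InvalidGeometryError(ValueError):
    """The compartment geometry is inconsistent."""


class PecletWarning(UserWarning):
    """Cell Péclet number ≥ 1: the central advection scheme may oscillate."""


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry and transport properties of one compartment."""

    name: str
    height: float        # Δz, cm
    D: float             # diffusivity, cm2·s-1
    u: float             # mean axial convection speed, cm·s-1
    H: float             # dimensionless Henry coefficient
    n_interior: int = 3  # number of interior grid points

    def __post_init__(self) -> None:
        if self.height <= 0 or self.D <= 0:
            raise InvalidGeometryError(f"{self.name}: height and D must be positive")
        if self.n_interior < 1:
            raise InvalidGeometryError(f"{self.name}: need at least one interior point")
        if self.H <= 0:
            raise InvalidGeometryError(f"{self.name}: Henry coefficient must be positive")

    @property
    def dz(self) -> float:
        """Grid spacing δz = Δz/(n_interior + 1), cm."""
        return self.height / (self.n_interior + 1)

    @property
    def peclet(self) -> float:
        """Cell Péclet number u·δz/(2D)."""
        return abs(self.u) * self.dz / (2.0 * self.D)


def interface_concentrations(
    c_below: float,
    c_above: float,
    media_below: tuple[float, float, float],
    media_above: tuple[float, float, float],
) -> tuple[float, float]:
    """Interface concentration pair (c⁻, c⁺) for a diffusive-only interface.

    ``media_*`` are (D, δz, H) triples.  Solving diffusive-flux continuity
    together with Henry partial-pressure continuity c⁻/H⁻ = c⁺/H⁺ gives

        c⁻ = (D⁻/δz⁻·c_below + D⁺/δz⁺·c_above) / (D⁻/δz⁻ + (H⁺/H⁻)·D⁺/δz⁺)
        c⁺ = (H⁺/H⁻)·c⁻

    which reduces to the arithmetic average for identical media.
    """
    D_b, dz_b, H_b = media_below
    D_a, dz_a, H_a = media_above
    if min(D_b, dz_b, H_b, D_a, dz_a, H_a) <= 0:
        raise InvalidGeometryError("interface media properties must be positive")
    w_b, w_a, r = _interface_weights(media_below, media_above)
    c_minus = w_b * c_below + w_a * c_above
    return c_minus, r * c_minus


def _interface_weights(
    media_below: tuple[float, float, float],
    media_above: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Weights (w_below, w_above) of c⁻ in the state entries, and ratio H⁺/H⁻."""
    D_b, dz_b, H_b = media_below
    D_a, dz_a, H_a = media_above
    g_b = D_b / dz_b
    g_a = D_a / dz_a
    r = H_a / H_b
    denom = g_b + r * g_a
    return g_b / denom, g_a / denom, r


@dataclass(frozen=True)
class GridModel:
    """Discretized four-compartment transport model.

    F is the N×N spatial operator (s⁻¹); G the N×2 steering matrix whose
    columns drive the blood Dirichlet boundary and the collection-cell air
    inlet; h the observation selector picking the last measurement-cell point
    below the collection interface.
    """

    specs: tuple[CompartmentSpec, ...]
    z_positions: np.ndarray                       # cm, strictly increasing
    F: np.ndarray                                 # (N, N), s-1
    G: np.ndarray                                 # (N, 2), s-1
    h_index: int
    slices: dict[str, slice] = field(repr=False)  # state indices per compartment
    interface_index_pairs: tuple[tuple[int, int], ...] = ()
    include_outer_point: bool = True

    @property
    def n_states(self) -> int:
        return self.F.shape[0]

    @property
    def h(self) -> np.ndarray:
        """Canonical observation vector."""
        h = np.zeros(self.n_states)
        h[self.h_index] = 1.0
        return h

    def steady_state(self, c_boundary: float, c_inlet: float = 0.0) -> np.ndarray:
        """Solve F·c + G·q = 0 for the constant-input steady profile."""
        q = np.array([c_boundary, c_inlet])
        return np.linalg.solve(self.F, -self.G @ q)

    def export_csv(self, path: Union[str, Path]) -> None:
        """Dump z, F and G as plain CSV for inspection / cross-language checks."""
        path = Path(path)
        n = self.n_states
        header = "z_cm," + ",".join(f"F_{j}" for j in range(n)) + ",G_blood,G_inlet"
        body = np.column_stack([self.z_positions, self.F, self.G])
        np.savetxt(path, body, delimiter=",", header=header, comments="")


def build_grid(
    specs: Sequence[CompartmentSpec],
    include_outer_point: bool = True,
    warn_peclet: bool = True,
    lower_bc: str = "dirichlet",
    upper_bc: str = "neumann",
) -> GridModel:
    """Build the grid and assemble the operator for ordered compartments.

    ``specs`` are ordered bottom (blood side) to top (collection side).  With
    four compartments of 3 interior points each and the outer point included,
    the state dimension is 13.

    The device uses a Dirichlet condition at the blood inlet (driven through
    G column 0) and a zero-diffusive-flux Neumann condition at the top.
    Toy configurations may instead seal the bottom (``lower_bc="neumann"``)
    or prescribe the top concentration (``upper_bc="dirichlet"``, driven
    through G column 1, which the device reserves for the collection-cell
    air inlet).
    """
    specs = tuple(specs)
    if not specs:
        raise InvalidGeometryError("need at least one compartment")
    if lower_bc not in ("dirichlet", "neumann") or upper_bc not in ("dirichlet", "neumann"):
        raise InvalidGeometryError("boundary kinds must be 'dirichlet' or 'neumann'")
    if upper_bc == "dirichlet" and include_outer_point:
        raise InvalidGeometryError(
            "the outer point carries the Neumann closure; drop it for a "
            "Dirichlet top"
        )

    if warn_peclet:
        for s in specs:
            if s.peclet >= 1.0:
                warnings.warn(
                    f"compartment {s.name!r}: cell Péclet number {s.peclet:.3g} ≥ 1",
                    PecletWarning,
                    stacklevel=2,
                )

    # positions and index bookkeeping
    z_list: list[float] = []
    slices: dict[str, slice] = {}
    z0 = 0.0
    for s in specs:
        start = len(z_list)
        z_list.extend(z0 + s.dz * (i + 1) for i in range(s.n_interior))
        slices[s.name] = slice(start, len(z_list))
        z0 += s.height
    if include_outer_point:
        z_list.append(z0)  # top boundary point of the last compartment
    z = np.asarray(z_list)
    n = len(z_list)

    F = np.zeros((n, n))
    G = np.zeros((n, 2))

    # map: global index -> owning compartment
    owner: list[int] = []
    for ci, s in enumerate(specs):
        owner.extend([ci] * s.n_interior)
    if include_outer_point:
        owner.append(len(specs) - 1)

    interface_pairs: list[tuple[int, int]] = []

    for j in range(n):
        ci = owner[j]
        s = specs[ci]
        d = s.D / s.dz**2
        a = s.u / (2.0 * s.dz)

        is_outer = include_outer_point and j == n - 1
        is_top_neumann = j == n - 1 and upper_bc == "neumann"
        is_top_dirichlet = j == n - 1 and upper_bc == "dirichlet"
        below_is_interface = (
            not is_outer and j > 0 and owner[j - 1] != ci
        )
        above_is_interface = (
            not is_top_neumann and j < n - 1 and owner[j + 1] != ci
        )
        is_bottom = j == 0

        if is_top_neumann:
            # zero-diffusive-flux closure: dc/dt = 2D/δz²·(c_below − c)
            F[j, j] += -2.0 * d
            if j > 0:
                F[j, j - 1] += 2.0 * d
            elif lower_bc == "dirichlet":
                # single point: "below" is the Dirichlet boundary itself
                G[j, 0] += 2.0 * d
            else:
                F[j, j] += 2.0 * d  # sealed both ends: isolated cell
            continue

        F[j, j] += -2.0 * d

        # ---- lower neighbour -------------------------------------------
        if is_bottom and lower_bc == "neumann":
            # sealed bottom: mirror closure, dc/dt = 2D/δz²·(c_above − c)
            if above_is_interface or is_top_dirichlet:
                raise InvalidGeometryError("sealed bottom needs ≥ 2 interior points")
            F[j, j + 1] += 2.0 * d
            continue
        if is_bottom:
            # exogenous blood-inlet concentration, Dirichlet via steering
            G[j, 0] += d + a
        elif below_is_interface:
            s_below = specs[ci - 1]
            w_b, w_a, r = _interface_weights(
                (s_below.D, s_below.dz, s_below.H), (s.D, s.dz, s.H)
            )
            # c⁺ = r·(w_b·c[j−1] + w_a·c[j]); coupling is diffusive only
            F[j, j - 1] += d * r * w_b
            F[j, j] += d * r * w_a
            if s.u != 0.0:
                # convective stream enters above the interface with the
                # exogenous inlet concentration (fresh air in the collection
                # cell); the within-column advective part stays on c[j+1]
                G[j, 1] += a
            interface_pairs.append((j - 1, j))
        else:
            F[j, j - 1] += d + a

        # ---- upper neighbour -------------------------------------------
        if above_is_interface:
            s_above = specs[ci + 1]
            w_b, w_a, _ = _interface_weights(
                (s.D, s.dz, s.H), (s_above.D, s_above.dz, s_above.H)
            )
            # c⁻ = w_b·c[j] + w_a·c[j+1]; diffusive-only coupling
            F[j, j] += d * w_b
            F[j, j + 1] += d * w_a
            if s.u != 0.0:
                # lateral through-flow: the convective stream leaves the
                # column just below the interface carrying the local
                # concentration
                F[j, j] += -a
        elif is_top_dirichlet:
            G[j, 1] += d - a
        else:
            F[j, j + 1] += d - a

    return GridModel(
        specs=specs,
        z_positions=z,
        F=F,
        G=G,
        h_index=_observation_index(specs, slices),
        slices=slices,
        interface_index_pairs=tuple(interface_pairs),
        include_outer_point=include_outer_point,
    )


def _observation_index(specs: tuple[CompartmentSpec, ...], slices: dict[str, slice]) -> int:
    """NDIR optical measurement position: last measurement-cell point."""
    if "meas" in slices:
        return slices["meas"].stop - 1
    # degenerate grids (toys): observe the last point of the last compartment
    return slices[specs[-1].name].stop - 1


def grid_from_params(
    params: ModelParams | None = None,
    n_interior: int = 3,
    include_outer_point: bool = True,
) -> GridModel:
    """Build the device grid (N = 13 by default) from a parameter set."""
    p = params if params is not None else ModelParams()
    specs = (
        CompartmentSpec("blood", p.blood.dz, p.blood.D, p.blood.u_z,
                        p.blood.H_blood, n_interior),
        CompartmentSpec("skin", p.skin.dz, p.skin.D, 0.0, p.skin.H_skin, n_interior),
        CompartmentSpec("meas", p.air.dz_meas, p.air.D, 0.0, p.air.H_air, n_interior),
        CompartmentSpec("coll", p.air.dz_coll, p.air.D, p.air.u_z_coll,
                        p.air.H_air, n_interior),
    )
    return build_grid(specs, include_outer_point=include_outer_point)
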