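"""Physical and physiological parameters of the transcutaneous CO2 transport model.

The model works in a single internal unit system: lengths in cm, time in s,
concentration in mol·m⁻³, pressure in mmHg, diffusivity in cm²·s⁻¹.
Quantities published in other units (the stratum-corneum mass-transfer
coefficient in m·s⁻¹, the Bunsen solubility in mL(STPD)·mL⁻¹·mmHg⁻¹) are
converted at ingestion.

The default values describe a capnometry wristband operated at 42 °C: a
blood-irrigated tissue layer, the stratum corneum as the rate-limiting
diffusive barrier, an NDIR measurement cell in contact with the skin, and an
open collection cell flushed by a continuous air flow.  Every derived
constant (Henry coefficient of blood, skin solubility, mass-transfer and
Krogh constants, skin diffusivity) is recomputed here from the primary
literature values rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

__all__ = [
    "GAS_CONSTANT_R",
    "AIR_PRESSURE_MMHG",
    "PhysicalConstants",
    "BloodParams",
    "SkinParams",
    "AirParams",
    "ModelParams",
    "InvalidParameterError",
    "henry_from_ostwald",
    "linear_two_point",
    "bunsen_solubility",
    "mass_transfer_coefficient",
    "krogh_constant",
    "skin_diffusion",
    "mean_velocity",
    "pressure_to_concentration",
    "concentration_to_pressure",
    "blood_solubility_42C",
    "default_params",
]

#: Ideal gas constant in m³·mmHg·K⁻¹·mol⁻¹.
GAS_CONSTANT_R = 0.0623637
#: Total air pressure at 42 °C under the device, mmHg.
AIR_PRESSURE_MMHG = 831.21


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


@dataclass(frozen=True)
class PhysicalConstants:
    gas_constant_R: float = GAS_CONSTANT_R  # m3·mmHg·K-1·mol-1
    air_pressure_Pair: float = AIR_PRESSURE_MMHG  # mmHg at 42 °C

    def __post_init__(self) -> None:
        if self.gas_constant_R <= 0 or self.air_pressure_Pair <= 0:
            raise InvalidParameterError("physical constants must be strictly positive")


# ---------------------------------------------------------------------------
# elementary derivations
# ---------------------------------------------------------------------------

def henry_from_ostwald(beta: float, T: float, R: float = GAS_CONSTANT_R) -> float:
    """Dimensionless Henry coefficient H = beta * R * T.

    ``beta`` is the Ostwald solubility in mol·m⁻³·mmHg⁻¹ and ``T`` the
    absolute temperature in K.
    """
    if T <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {T}")
    if beta < 0:
        raise InvalidParameterError(f"solubility must be non-negative, got {beta}")
    return beta * R * T


def linear_two_point(t1: float, v1: float, t2: float, v2: float, t_query: float) -> float:
    """Value at ``t_query`` of the exact line through (t1, v1) and (t2, v2).

    Serves both the solubility extrapolation to 42 °C and the skin-conductance
    interpolation between the published 37 °C and 43 °C values.
    """
    if t1 == t2:
        raise InvalidParameterError("degenerate interpolation: t1 == t2")
    return v1 + (v2 - v1) * (t_query - t1) / (t2 - t1)


def bunsen_solubility(H_skin: float, Pair: float = AIR_PRESSURE_MMHG) -> float:
    """Bunsen CO2 solubility of the stratum corneum, mL(STPD)·mL⁻¹·mmHg⁻¹.

    alpha = H_skin / Pair.
    """
    if Pair <= 0:
        raise InvalidParameterError(f"air pressure must be positive, got {Pair}")
    if H_skin < 0:
        raise InvalidParameterError("Henry coefficient must be non-negative")
    return H_skin / Pair


def mass_transfer_coefficient(G_per_area: float, Pair: float = AIR_PRESSURE_MMHG) -> float:
    """Stratum-corneum mass-transfer coefficient kp in m·s⁻¹.

    kp = G_per_area * Pair * 1e-2, where ``G_per_area`` is the skin volume-flow
    conductance per unit area (mL·s⁻¹·cm⁻²·mmHg⁻¹) and 1e-2 is the unit
    conversion from mL·cm⁻² to m.
    """
    if G_per_area < 0 or Pair <= 0:
        raise InvalidParameterError("inputs must be positive")
    return G_per_area * Pair * 1e-2


def krogh_constant(kp_sc: float, dz_skin: float, Pair: float = AIR_PRESSURE_MMHG) -> float:
    """Krogh diffusion constant Kr in cm²·s⁻¹·mmHg⁻¹.

    Kr = kp·Δz_skin / Pair with kp converted from m·s⁻¹ to cm·s⁻¹ and
    ``dz_skin`` the stratum-corneum thickness in cm.
    """
    if kp_sc < 0 or dz_skin <= 0 or Pair <= 0:
        raise InvalidParameterError("inputs must be positive")
    return (kp_sc * 100.0) * dz_skin / Pair


def skin_diffusion(Kr: float, alpha: float) -> float:
    """Skin diffusion coefficient D = Kr / alpha in cm²·s⁻¹."""
    if alpha <= 0:
        raise InvalidParameterError(f"Bunsen solubility must be positive, got {alpha}")
    return Kr / alpha


def mean_velocity(Q: float, A: float) -> float:
    """Mean axial velocity u = Q / A (cm·s⁻¹) of a flow Q through section A."""
    if A <= 0:
        raise InvalidParameterError(f"cross-section must be positive, got {A}")
    return Q / A


def pressure_to_concentration(P: float, beta: float) -> float:
    """Concentration C = beta * P (mol·m⁻³) from partial pressure P (mmHg)."""
    if beta <= 0:
        raise InvalidParameterError(f"solubility must be positive, got {beta}")
    return beta * P


def concentration_to_pressure(C: float, beta: float) -> float:
    """Partial pressure P = C / beta (mmHg) from concentration C (mol·m⁻³)."""
    if beta <= 0:
        raise InvalidParameterError(f"solubility must be positive, got {beta}")
    return C / beta


# Published Ostwald solubilities of CO2 in blood used for the extrapolation.
_BETA_37C = 3.08e-2  # mol·m-3·mmHg-1 at 37 °C
_BETA_40C = 2.88e-2  # mol·m-3·mmHg-1 at 40 °C


def blood_solubility_42C(rounded: bool = False) -> float:
    """Ostwald solubility of CO2 in blood extrapolated to 42 °C.

    The unrounded value (~2.7467e-2 mol·m⁻³·mmHg⁻¹) is used internally for all
    pressure/concentration conversions; the two-significant-digit 2.75e-2 is a
    display value only.
    """
    beta = linear_two_point(37.0, _BETA_37C, 40.0, _BETA_40C, 42.0)
    return round(beta, 4) if rounded else beta


# ---------------------------------------------------------------------------
# compartment parameter records (defaults = published device values at 42 °C)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodParams:
    """Blood-irrigated tissue compartment.

    The published mean axial velocity (1.83e-4 cm·s⁻¹) is kept as the
    simulation value even though Q/A gives 1.8e-4; ``mean_velocity`` lets the
    caller check the small discrepancy.
    """

    dz: float = 0.3               # compartment height, cm
    dx: float = 5.0               # device length, cm
    dy: float = 2.0               # device width, cm
    D: float = 2.2e-5             # CO2 diffusivity at 42 °C, cm2·s-1
    u_z: float = 1.83e-4          # mean blood velocity along z, cm·s-1
    T_blood: float = 315.15       # K
    Q_blood: float = 1.8e-3       # blood flow, cm3·s-1
    beta_ostwald: float = field(default_factory=blood_solubility_42C)  # mol·m-3·mmHg-1

    def __post_init__(self) -> None:
        for name in ("dz", "dx", "dy", "D", "T_blood"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"blood parameter {name} must be positive")

    @property
    def A_blood(self) -> float:
        """Transverse section, cm²."""
        return self.dx * self.dy

    @property
    def H_blood(self) -> float:
        """Dimensionless Henry coefficient, beta·R·T."""
        return henry_from_ostwald(self.beta_ostwald, self.T_blood)


@dataclass(frozen=True)
class SkinParams:
    """Stratum corneum: the rate-limiting, purely diffusive barrier."""

    dz: float = 1.6e-3            # thickness (16 µm), cm
    H_skin: float = 1.6           # dimensionless Henry coefficient
    G_cond_37: float = 77e-9      # skin conductance per area at 37 °C, mL·s-1·cm-2·mmHg-1
    G_cond_43: float = 130e-9     # same at 43 °C
    Pair: float = AIR_PRESSURE_MMHG

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.H_skin <= 0 or self.Pair <= 0:
            raise InvalidParameterError("skin parameters must be positive")

    @property
    def G_cond_per_area(self) -> float:
        """Skin conductance per area at 42 °C by linear interpolation."""
        return linear_two_point(37.0, self.G_cond_37, 43.0, self.G_cond_43, 42.0)

    @property
    def alpha_bunsen(self) -> float:
        return bunsen_solubility(self.H_skin, self.Pair)

    @property
    def kp_sc(self) -> float:
        """Mass transfer coefficient, m·s⁻¹."""
        return mass_transfer_coefficient(self.G_cond_per_area, self.Pair)

    @property
    def Kr(self) -> float:
        """Krogh diffusion constant, cm²·s⁻¹·mmHg⁻¹."""
        return krogh_constant(self.kp_sc, self.dz, self.Pair)

    @property
    def D_derived(self) -> float:
        """Diffusivity Kr/alpha recomputed from the conductance chain, cm²·s⁻¹."""
        return skin_diffusion(self.Kr, self.alpha_bunsen)

    # The published table rounds the derived chain to 1e-7; keep that as the
    # simulation value so the operator matches the published parameter set.
    @property
    def D(self) -> float:
        return 1.0e-7


@dataclass(frozen=True)
class AirParams:
    """Gaseous media of the device column: measurement cell and collection cell."""

    dz_meas: float = 0.25         # measurement-cell height, cm
    dz_coll: float = 0.25         # collection-cell height, cm
    dx: float = 5.0               # cm
    dy: float = 2.0               # cm
    D: float = 0.18               # CO2 diffusivity in air at 42 °C, cm2·s-1
    H_air: float = 1.0            # dimensionless
    Q_air: float = 16.7e-3        # air flow, cm3·s-1 (1 mL·min-1)
    C_ambient: float = 0.0        # inlet CO2 concentration, mol·m-3 (filter assumed)

    #: Published ambient CO2 concentration if no inlet filter is fitted.
    C_AMBIENT_UNFILTERED = 0.01613  # mol·m-3

    def __post_init__(self) -> None:
        for name in ("dz_meas", "dz_coll", "D", "H_air", "Q_air"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"air parameter {name} must be positive")
        if self.C_ambient < 0:
            raise InvalidParameterError("ambient concentration must be non-negative")

    @property
    def u_z_coll(self) -> float:
        """Mean axial air velocity in the collection cell, cm·s⁻¹."""
        return mean_velocity(self.Q_air, self.dx * self.dy)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the four-compartment model."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    blood: BloodParams = field(default_factory=BloodParams)
    skin: SkinParams = field(default_factory=SkinParams)
    air: AirParams = field(default_factory=AirParams)

    @property
    def beta_blood(self) -> float:
        return self.blood.beta_ostwald

    def to_concentration(self, P_mmHg: float) -> float:
        return pressure_to_concentration(P_mmHg, self.beta_blood)

    def to_pressure(self, C: float) -> float:
        return concentration_to_pressure(C, self.beta_blood)

    # -- plain-text config (key = value) ------------------------------------

    _CONFIG_KEYS = {
        "blood": ("dz", "dx", "dy", "D", "u_z", "T_blood", "Q_blood", "beta_ostwald"),
        "skin": ("dz", "H_skin", "G_cond_37", "G_cond_43", "Pair"),
        "air": ("dz_meas", "dz_coll", "dx", "dy", "D", "H_air", "Q_air", "C_ambient"),
    }

    def to_config(self, path: Union[str, Path]) -> None:
        """Serialize to ``section.key = value`` lines (units as in the tables)."""
        lines = ["# capnoflow model parameters (cm, s, mol/m3, mmHg)"]
        for section in ("blood", "skin", "air"):
            obj = getattr(self, section)
            for key in self._CONFIG_KEYS[section]:
                lines.append(f"{section}.{key} = {getattr(obj, key)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: Union[str, Path]) -> "ModelParams":
        values: dict[str, dict[str, float]] = {"blood": {}, "skin": {}, "air": {}}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            section, _, name = key.strip().partition(".")
            if section not in values:
                raise InvalidParameterError(f"unknown config section {section!r}")
            values[section][name] = float(val)
        return cls(
            blood=BloodParams(**values["blood"]),
            skin=SkinParams(**values["skin"]),
            air=AirParams(**values["air"]),
        )

    def with_overrides(self, **sections) -> "ModelParams":
        """Return a copy with per-section field overrides.

        ``params.with_overrides(air={"Q_air": 2e-3}, skin={"dz": 2e-3})``
        """
        out = self
        for section, fields_ in sections.items():
            out = replace(out, **{section: replace(getattr(out, section), **fields_)})
        return out


def default_params() -> ModelParams:
    """The published device parameter set at 42 °C."""
    return ModelParams()
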