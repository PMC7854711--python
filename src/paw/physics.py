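"""Closed-form photoacoustic transduction and linear acoustics.

Piezophotonic films convert a nanosecond laser pulse into a pressure
pulse by the thermoelastic effect.  The conversion efficiency is set by
the Grüneisen parameter Γ = cs²β/Cp of the expanding matrix, and the peak
pressure depends on whether the optical penetration depth 1/µa is small
(thin absorber) or large (thick absorber) compared with the acoustic
transit length cs·τL during the laser pulse:

    thin absorber:   p_max = Γ E_L / (cs τ_L)
    thick absorber:  p_max = Γ E_L µ_a

Interfaces between media of different acoustic impedance Z transmit only
a fraction T = 4 Z1 Z2 / (Z1 + Z2)² of the incident acoustic intensity.
The Mechanical Index MI = p_rarefaction[MPa] / sqrt(f_centre[MHz]) is the
standard cavitation-risk proxy; MI > 0.7 marks the regime where
cavitation damage to cells becomes a concern.

API units follow the reporting conventions of the field: pressures in
MPa, fluences in mJ/cm², film thicknesses in µm, times in ns, absorption
coefficients in cm⁻¹. All arithmetic is done in SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import InvalidParameterError

#: Mechanical-index threshold above which cavitation damage is a concern.
MI_CAVITATION_THRESHOLD = 0.7

# unit conversions to SI
_MJ_PER_CM2_TO_J_PER_M2 = 10.0     # 1 mJ/cm² = 10 J/m²
_UM_TO_CM = 1e-4
_PER_CM_TO_PER_M = 100.0
_NS_TO_S = 1e-9
_PA_TO_MPA = 1e-6


def napierian_mu_a(absorbance: float, thickness_um: float) -> float:
    """Napierian absorption coefficient µa = 2.3·A/l in cm⁻¹.

    Parameters
    ----------
    absorbance
        Decadic absorbance A (dimensionless).
    thickness_um
        Film thickness l in micrometres.
    """
    if not thickness_um > 0:
        raise InvalidParameterError("thickness must be positive")
    if absorbance < 0:
        raise InvalidParameterError("absorbance must be non-negative")
    return 2.3 * absorbance / (thickness_um * _UM_TO_CM)


def gruneisen(sound_speed_ms: float, thermal_expansion_perK: float,
              heat_capacity_JkgK: float) -> float:
    """Grüneisen parameter Γ = cs²·β/Cp (dimensionless)."""
    if not heat_capacity_JkgK > 0:
        raise InvalidParameterError("heat capacity must be positive")
    return sound_speed_ms**2 * thermal_expansion_perK / heat_capacity_JkgK


def classify_absorber(mu_a_percm: float, sound_speed_ms: float,
                      tau_L_ns: float) -> str:
    """Classify an absorbing film as ``"thin"`` or ``"thick"``.

    A film is optically *thin* (for photoacoustic purposes) when the
    penetration depth 1/µa is smaller than the distance sound travels
    during the laser pulse, cs·τL; the boundary case is assigned to
    ``"thick"``.
    """
    for name, v in (("mu_a", mu_a_percm), ("sound speed", sound_speed_ms),
                    ("pulse duration", tau_L_ns)):
        if not v > 0:
            raise InvalidParameterError(f"{name} must be positive")
    penetration_m = 1.0 / (mu_a_percm * _PER_CM_TO_PER_M)
    transit_m = sound_speed_ms * tau_L_ns * _NS_TO_S
    return "thin" if penetration_m < transit_m else "thick"


def peak_pressure_thin(Gamma: float, fluence_mJcm2: float,
                       sound_speed_ms: float, tau_L_ns: float) -> float:
    """Peak pressure of a thin absorber, Γ·E_L/(cs·τ_L), in MPa."""
    if not (sound_speed_ms > 0 and tau_L_ns > 0):
        raise InvalidParameterError("sound speed and pulse duration must be positive")
    if Gamma < 0 or fluence_mJcm2 < 0:
        raise InvalidParameterError("Gamma and fluence must be non-negative")
    E_L = fluence_mJcm2 * _MJ_PER_CM2_TO_J_PER_M2
    return Gamma * E_L / (sound_speed_ms * tau_L_ns * _NS_TO_S) * _PA_TO_MPA


def peak_pressure_thick(Gamma: float, fluence_mJcm2: float,
                        mu_a_percm: float) -> float:
    """Peak pressure of a thick absorber, Γ·E_L·µa, in MPa."""
    if Gamma < 0 or fluence_mJcm2 < 0 or mu_a_percm < 0:
        raise InvalidParameterError("inputs must be non-negative")
    E_L = fluence_mJcm2 * _MJ_PER_CM2_TO_J_PER_M2
    return Gamma * E_L * mu_a_percm * _PER_CM_TO_PER_M * _PA_TO_MPA


def transmission_coefficient(Z1: float, Z2: float) -> float:
    """Acoustic intensity transmission T = 4·Z1·Z2/(Z1+Z2)² across an interface.

    Symmetric in its arguments, T ∈ (0, 1], with T = 1 only for matched
    impedances. Impedances in N·s·m⁻³ (any consistent unit works).
    """
    if not (Z1 > 0 and Z2 > 0):
        raise InvalidParameterError("impedances must be positive")
    return 4.0 * Z1 * Z2 / (Z1 + Z2) ** 2


def mechanical_index(p_rarefaction_MPa: float, f_centre_MHz: float) -> float:
    """Mechanical Index MI = p_rarefaction[MPa] / sqrt(f_centre[MHz]).

    ``p_rarefaction_MPa`` is the magnitude of the peak rarefaction
    pressure. Compare the result against :data:`MI_CAVITATION_THRESHOLD`
    (0.7) — see :func:`cavitation_risk`.
    """
    if not f_centre_MHz > 0:
        raise InvalidParameterError("centre frequency must be positive")
    if p_rarefaction_MPa < 0:
        raise InvalidParameterError("rarefaction pressure magnitude must be non-negative")
    return p_rarefaction_MPa / f_centre_MHz**0.5


def cavitation_risk(mi: float) -> bool:
    """True when the Mechanical Index exceeds the 0.7 cavitation threshold."""
    return mi > MI_CAVITATION_THRESHOLD


@dataclass
class MaterialAcoustics:
    """Acoustic and thermoelastic parameters of a medium.

    ``gruneisen_Gamma`` may be omitted, in which case it is derived as
    cs²β/Cp from the other fields.
    """

    name: str
    impedance_Z: float          # N·s·m⁻³
    sound_speed_cs: float       # m/s
    density_rho0: float         # kg/m³
    thermal_expansion_beta: float  # K⁻¹
    heat_capacity_Cp: float     # J·kg⁻¹·K⁻¹
    gruneisen_Gamma: Optional[float] = None

    def __post_init__(self) -> None:
        for fname in ("impedance_Z", "sound_speed_cs", "heat_capacity_Cp"):
            if not getattr(self, fname) > 0:
                raise InvalidParameterError(f"{fname} must be positive")
        if self.gruneisen_Gamma is None:
            self.gruneisen_Gamma = gruneisen(
                self.sound_speed_cs, self.thermal_expansion_beta,
                self.heat_capacity_Cp)


@dataclass
class FilmSpec:
    """Optical parameters of a piezophotonic film.

    ``mu_a_percm`` (Napierian, cm⁻¹) is derived from the decadic
    absorbance and thickness when not given explicitly.
    """

    label: str
    thickness_l_um: float
    absorbance_A: float
    mu_a_percm: Optional[float] = None
    p_max_MPa: Optional[float] = None  # measured peak pressure, if known

    def __post_init__(self) -> None:
        if not self.thickness_l_um > 0:
            raise InvalidParameterError("thickness must be positive")
        if self.absorbance_A < 0:
            raise InvalidParameterError("absorbance must be non-negative")
        if self.mu_a_percm is None:
            self.mu_a_percm = napierian_mu_a(self.absorbance_A, self.thickness_l_um)
        elif self.mu_a_percm < 0:
            raise InvalidParameterError("mu_a must be non-negative")


@dataclass
class LaserPulse:
    """Excitation laser pulse parameters."""

    fluence_EL_mJcm2: float
    duration_tauL_ns: float
    wavelength_nm: float = 532.0
    rep_rate_Hz: float = 10.0

    def __post_init__(self) -> None:
        if self.fluence_EL_mJcm2 < 0:
            raise InvalidParameterError("fluence must be non-negative")
        if not self.duration_tauL_ns > 0:
            raise InvalidParameterError("pulse duration must be positive")


#: Acoustic impedances (N·s·m⁻³) of the media relevant to film/water
#: interfaces: water, the PDMS matrix, polystyrene film hosts, and glass
#: substrates.
IMPEDANCES_NSM3: dict[str, float] = {
    "water": 1.494e6,
    "PDMS": 1.048e6,
    "polystyrene": 2.5e6,
    "glass": 14e6,
}

#: Measured properties of the piezophotonic films characterised at
#: 50 mJ/cm² and 532 nm: thickness (µm), decadic absorbance, and the
#: hydrophone peak pressure (MPa).  Absorbances above the
#: spectrophotometer ceiling are recorded at the A = 10 bound, so the
#: derived µa values are lower bounds.
FILM_TABLE: dict[str, FilmSpec] = {
    "CNT30": FilmSpec("CNT30", 30.0, 10.0, p_max_MPa=0.0),
    "CNT80-PDMS": FilmSpec("CNT80-PDMS", 80.0, 10.0, p_max_MPa=6.9),
    "CNT30-PDMS": FilmSpec("CNT30-PDMS", 30.0, 10.0, p_max_MPa=7.0),
    "CNT30-PDMS-plastic": FilmSpec("CNT30-PDMS-plastic", 30.0, 10.0, p_max_MPa=5.0),
    "CNT30-PDMS-glass": FilmSpec("CNT30-PDMS-glass", 30.0, 10.0, p_max_MPa=1.7),
    "MnTPP": FilmSpec("MnTPP", 70.0, 1.23, p_max_MPa=0.32),
}
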