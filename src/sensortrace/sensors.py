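"""Forward and inverse models of genetically encoded fluorescent sensors.

Three sensor families are covered:

* intensity sensors with Hill-type analyte binding (RCaMP1e for Ca²⁺),
* ratiometric FRET sensors with a quadratic Hill response (ATeam1.03 for ATP),
* dual-excitation redox sensors equilibrating with the DTT couple (roGFP1),
  from which compartment redox potentials follow via the Nernst equation.

All potentials are carried in volts internally; reporting layers render mV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SensorSpec",
    "PhysConstants",
    "RCAMP1E",
    "ATEAM103",
    "ROGFP1",
    "CONSTANTS",
    "CONSTANTS_DOOLEY",
    "E0_DTT_HANSON",
    "E0_DTT_DOOLEY",
    "hill_fraction_bound",
    "ratio_from_atp",
    "atp_from_ratio",
    "fraction_reduced",
    "dtt_ratio_from_fraction",
    "nernst_sensor_midpoint",
    "redox_potential",
    "ph_adjusted_e0",
    "SaturationError",
    "CalibrationError",
]

#: clamp applied to fractions before logarithms
FRACTION_EPS = 1e-6

E0_DTT_HANSON = -0.323  # V, consensus midpoint of the DTT couple at pH 7
E0_DTT_DOOLEY = -0.330  # V, alternative literature value


class SaturationError(ValueError):
    """Raised when a ratio is at or beyond the sensor's saturated limit."""


class CalibrationError(ValueError):
    """Raised when sensor calibration endpoints are degenerate or unstable."""


@dataclass(frozen=True)
class SensorSpec:
    """Binding and spectral constants of one genetically encoded sensor.

    Parameters
    ----------
    kd : float, optional
        Dissociation constant in the sensor's native concentration unit
        (μM for calcium sensors, mM for ATP sensors). Not meaningful for
        redox sensors, which are characterised by ``keq`` instead.
    hill_coefficient : float
        Cooperativity of analyte binding (dimensionless, > 0).
    dynamic_range : float, optional
        Rmax/Rmin of the FRET ratio; FRET sensors only, must exceed 1.
    keq : float, optional
        Equilibration constant of the sensor's thiol pair against the
        DTT redox couple; redox sensors only.
    pka : float, optional
        Informational only; never enters a computation.
    """

    name: str
    kd: Optional[float] = None
    hill_coefficient: float = 1.0
    dynamic_range: Optional[float] = None
    keq: Optional[float] = None
    pka: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kd is not None and not self.kd > 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if not self.hill_coefficient > 0:
            raise ValueError(
                f"hill_coefficient must be > 0, got {self.hill_coefficient}"
            )
        if self.dynamic_range is not None and not self.dynamic_range > 1:
            raise ValueError(
                f"dynamic_range must be > 1, got {self.dynamic_range}"
            )
        if self.keq is not None and not self.keq > 0:
            raise ValueError(f"keq must be > 0, got {self.keq}")


@dataclass(frozen=True)
class PhysConstants:
    """Physical constants for the Nernst conversion.

    ``ph_slope`` is the empirical 60.1 mV-per-pH-unit correction applied to
    the reference midpoint when a compartment is not at pH 7. ``e0_dtt`` is
    the formal midpoint potential of the DTT couple; two literature presets
    exist (−0.323 V and −0.330 V) and both are selectable.
    """

    gas_constant: float = 8.315  # J K^-1 mol^-1
    faraday: float = 9.649e4  # C mol^-1
    temperature: float = 303.15  # K (30 °C)
    electrons: int = 2
    ph_slope: float = 0.0601  # V per pH unit
    e0_dtt: float = E0_DTT_HANSON  # V

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if self.electrons < 1:
            raise ValueError("electrons must be >= 1")

    @property
    def rt_nf(self) -> float:
        """RT/nF in volts."""
        return (self.gas_constant * self.temperature) / (
            self.electrons * self.faraday
        )

    def with_e0_dtt(self, e0: float) -> "PhysConstants":
        return replace(self, e0_dtt=e0)


# Sensor presets (in vitro literature constants)
RCAMP1E = SensorSpec("RCaMP1e", kd=1.6, hill_coefficient=3.4, pka=5.9)  # kd μM
ATEAM103 = SensorSpec("ATeam1.03", kd=3.3, hill_coefficient=2.0, dynamic_range=2.3)  # kd mM
ROGFP1 = SensorSpec("roGFP1", keq=0.070)

CONSTANTS = PhysConstants()
CONSTANTS_DOOLEY = PhysConstants(e0_dtt=E0_DTT_DOOLEY)


def hill_fraction_bound(conc, spec: SensorSpec = RCAMP1E):
    """Fraction of sensor molecules with analyte bound at concentration ``conc``.

    Evaluates the Hill isotherm conc^n / (kd^n + conc^n). ``conc`` must be in
    the same unit as ``spec.kd``. Accepts scalars or arrays.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    if spec.kd is None:
        raise ValueError(f"sensor {spec.name!r} has no binding kd")
    n = spec.hill_coefficient
    x = (conc / spec.kd) ** n
    out = x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def ratio_from_atp(atp, spec: SensorSpec = ATEAM103, rmin: float = 1.0):
    """Forward FRET-ratio model: R = Rmin + (Rmax − Rmin)·[ATP]^h / (Kd^h + [ATP]^h).

    The Hill exponent is taken from ``spec`` (2 for ATeam1.03, a published
    simplification of 2.1). ``atp`` is in mM; output shares units with ``rmin``.
    """
    atp = np.asarray(atp, dtype=float)
    if np.any(atp < 0):
        raise ValueError("ATP concentration must be non-negative")
    if not rmin > 0:
        raise ValueError("rmin must be > 0")
    if spec.dynamic_range is None:
        raise ValueError(f"sensor {spec.name!r} has no dynamic_range")
    rmax = rmin * spec.dynamic_range
    frac = hill_fraction_bound(atp, spec)
    out = rmin + (rmax - rmin) * np.asarray(frac)
    return float(out) if out.ndim == 0 else out


def atp_from_ratio(r, spec: SensorSpec = ATEAM103, *, clip_subunity: bool = True):
    """Invert the FRET-ratio model: [ATP] = Kd·((r − 1)/(DR − r))^(1/h).

    ``r`` is the relative ratio R/Rmin. The expression is the exact algebraic
    inverse of :func:`ratio_from_atp` (re-derived from the forward model; for
    h = 2 it is the familiar square-root form). Values of r slightly below 1
    arise from baseline noise and are clipped to 0 mM with a logged warning;
    r at or beyond the dynamic range is a saturation error.
    """
    r = np.asarray(r, dtype=float)
    if spec.dynamic_range is None:
        raise ValueError(f"sensor {spec.name!r} has no dynamic_range")
    dr = spec.dynamic_range
    if np.any(r >= dr):
        raise SaturationError(
            f"relative ratio at/beyond dynamic range ({dr}): sensor saturated"
        )
    sub = r < 1.0
    if np.any(sub):
        if not clip_subunity:
            raise ValueError("relative ratio below 1 (sub-baseline)")
        logger.warning(
            "clipping %d sub-baseline ratio value(s) (r < 1) to 0 mM",
            int(np.count_nonzero(sub)),
        )
        r = np.where(sub, 1.0, r)
    h = spec.hill_coefficient
    out = spec.kd * ((r - 1.0) / (dr - r)) ** (1.0 / h)
    return float(out) if out.ndim == 0 else out


def fraction_reduced(f, f_red: float, f_ox: float):
    """Fraction of reduced sensor molecules from calibration endpoints.

    R = (F − F_ox)/(F_red − F_ox) where F_red and F_ox are the fully reduced
    (DTT) and fully oxidized (H₂O₂) plateau ratios. Noise can push the raw
    value outside [0, 1]; such values are clipped to the nearest bound with
    a logged warning.
    """
    if f_red == f_ox:
        raise CalibrationError("degenerate calibration: f_red == f_ox")
    f = np.asarray(f, dtype=float)
    with np.errstate(over="ignore"):
        raw = (f - f_ox) / (f_red - f_ox)
    n_out = int(np.count_nonzero((raw < 0) | (raw > 1)))
    if n_out:
        logger.warning(
            "clipping %d fraction-reduced value(s) outside [0, 1]", n_out
        )
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def dtt_ratio_from_fraction(r_frac: float, keq: float, eps: float = FRACTION_EPS) -> float:
    """[DTT_red]/[DTT_ox] implied by a sensor fraction-reduced value.

    Keq·R/(1 − R); R is clamped to [eps, 1 − eps] before the division and
    every clamp is logged, since the ratio (and hence the potential) is
    undefined at fully reduced or fully oxidized sensor.
    """
    if not keq > 0:
        raise ValueError("keq must be > 0")
    if not 0.0 <= r_frac <= 1.0:
        raise ValueError("fraction reduced must lie in [0, 1]")
    if r_frac < eps or r_frac > 1.0 - eps:
        logger.warning(
            "fraction reduced %.3g clamped to [%g, %g] before log", r_frac, eps, 1 - eps
        )
        r_frac = min(max(r_frac, eps), 1.0 - eps)
    return keq * r_frac / (1.0 - r_frac)


def nernst_sensor_midpoint(constants: PhysConstants = CONSTANTS, keq: float = 0.070) -> float:
    """Formal midpoint potential of the sensor couple, in volts.

    E0'(sensor) = E0'(DTT) − (RT/nF)·ln(Keq). With roGFP1's Keq = 0.070 and
    the DTT midpoint −0.323 V this evaluates to −0.288 V at 30 °C.
    """
    if not keq > 0:
        raise ValueError("keq must be > 0")
    return constants.e0_dtt - constants.rt_nf * math.log(keq)


def redox_potential(
    r_frac: float,
    constants: PhysConstants = CONSTANTS,
    keq: float = 0.070,
    eps: float = FRACTION_EPS,
) -> float:
    """Compartment redox potential (V) from the sensor's fraction reduced.

    E' = E0'(DTT) − (RT/nF)·ln(Keq·R/(1 − R)). Strictly decreasing in R:
    a more reduced compartment sits at a more negative potential.
    """
    ratio = dtt_ratio_from_fraction(r_frac, keq, eps=eps)
    return constants.e0_dtt - constants.rt_nf * math.log(ratio)


def ph_adjusted_e0(e0: float, ph: float, constants: PhysConstants = CONSTANTS) -> float:
    """Shift a pH-7 reference midpoint to another compartmental pH.

    E0'(pH) = E0' − 0.0601 V·(pH − 7); used for the mitochondrial matrix
    (pH 7.98). Values outside a loose physiological range only warn.
    """
    if not 5.0 <= ph <= 10.0:
        logger.warning("pH %.2f outside the expected physiological range [5, 10]", ph)
    return e0 - constants.ph_slope * (ph - 7.0)
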