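"""Chemical-shift-perturbation scoring and binding-isotherm fitting.

For an ¹⁵N-labeled protein titrated with an unlabeled ligand, per-residue
HSQC peak movements report on binding. The combined CSP score weights the
¹⁵N dimension by 1/5 to put it on the ¹H scale. Titration curves of shift
change versus ligand concentration are fitted with a single-site binding
model to extract the dissociation constant Kd; for weak (mM-range) binding
with the labeled protein in the low-μM range, the ligand-excess hyperbola
Δδ(L) = Δδmax·L/(Kd + L) is an excellent approximation of the exact
quadratic two-species solution, which remains available via ``protein_conc``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueShift",
    "TitrationSeries",
    "BindingFit",
    "combined_csp",
    "fit_binding_isotherm",
    "average_kd",
]

#: ¹⁵N shift scaling onto the ¹H scale
N15_SCALE = 5.0


@dataclass(frozen=True)
class ResidueShift:
    """Chemical-shift changes of one residue between two titration points."""

    residue: int
    delta_h: float  # ppm, 1H dimension
    delta_n: float  # ppm, 15N dimension

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError("residue index must be >= 1")
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_n)):
            raise ValueError("shifts must be finite")


@dataclass
class TitrationSeries:
    """Shift change of one residue across ligand concentrations."""

    residue: int
    ligand_conc: np.ndarray  # mM, strictly increasing (first may be 0)
    shifts: np.ndarray  # ppm

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.ligand_conc.shape != self.shifts.shape:
            raise ValueError("ligand_conc and shifts must have equal length")
        if np.any(np.diff(self.ligand_conc) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")
        if self.ligand_conc[0] < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class BindingFit:
    """Single-site binding fit of one (or one pooled) titration series."""

    kd: float  # mM
    delta_max: float  # ppm
    standard_error_kd: float  # mM, asymptotic
    residues_used: List[int] = field(default_factory=list)
    reliable: bool = True
    message: str = ""


def combined_csp(shift: ResidueShift) -> float:
    """Combined ¹H/¹⁵N perturbation: sqrt(ΔδH² + (ΔδN/5)²), in ppm.

    Invariant under sign flips of either shift; zero only when both are zero.
    """
    return math.hypot(shift.delta_h, shift.delta_n / N15_SCALE)


def _hyperbola(L, delta_max, kd):
    return delta_max * L / (kd + L)


def _quadratic(L, delta_max, kd, protein_conc):
    # exact bound fraction for labeled protein at concentration P
    P = protein_conc
    b = P + L + kd
    bound = (b - np.sqrt(b * b - 4.0 * P * L)) / (2.0 * P)
    return delta_max * bound


def fit_binding_isotherm(
    series: TitrationSeries,
    protein_conc: Optional[float] = None,
    kd_ceiling_factor: float = 10.0,
) -> BindingFit:
    """Nonlinear least-squares fit of a single-site binding isotherm.

    By default fits the ligand-excess hyperbola Δδ(L) = Δδmax·L/(Kd + L);
    pass ``protein_conc`` (mM) to use the exact quadratic two-species
    solution instead. Unweighted least squares. A fit whose Kd exceeds
    ``kd_ceiling_factor`` times the highest titrated concentration, or that
    fails to converge, is flagged unreliable. The fit is scale-equivariant:
    multiplying all shifts by c multiplies Δδmax by c and leaves Kd unchanged.
    """
    L = series.ligand_conc
    y = series.shifts
    if L.size < 4:
        logger.warning(
            "residue %d: only %d titration points (< 4); fit may be unstable",
            series.residue, L.size,
        )
    scale = float(np.max(np.abs(y))) or 1.0
    half = scale / 2.0
    above = L[np.abs(y) >= half] if np.any(np.abs(y) >= half) else L[-1:]
    p0 = (y[-1] if y[-1] != 0 else scale, max(float(above[0]), 1e-3))

    if protein_conc is not None:
        model = lambda Lx, dmax, kd: _quadratic(Lx, dmax, kd, protein_conc)
    else:
        model = _hyperbola

    try:
        popt, pcov = optimize.curve_fit(
            model, L, y, p0=p0,
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return BindingFit(
            kd=np.nan, delta_max=np.nan, standard_error_kd=np.nan,
            residues_used=[series.residue], reliable=False,
            message=f"fit failed: {exc}",
        )
    dmax, kd = float(popt[0]), float(popt[1])
    se_kd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan

    fit = BindingFit(
        kd=kd, delta_max=dmax, standard_error_kd=se_kd,
        residues_used=[series.residue],
    )
    lmax = float(L[-1])
    if kd > kd_ceiling_factor * lmax:
        fit.reliable = False
        fit.message = (
            f"Kd {kd:.3g} mM exceeds {kd_ceiling_factor}x the highest titrated "
            f"concentration ({lmax:.3g} mM): not identified by these data"
        )
        logger.warning("residue %d: %s", series.residue, fit.message)
    elif kd > lmax:
        logger.warning(
            "residue %d: Kd %.3g mM above the titration range (max %.3g mM); "
            "estimate is an extrapolation", series.residue, kd, lmax,
        )
    return fit


def average_kd(fits: Sequence[BindingFit]) -> Tuple[float, float]:
    """Arithmetic mean and sample SD of Kd over converged per-residue fits."""
    usable = [f for f in fits if f.reliable and math.isfinite(f.kd)]
    if len(usable) < 2:
        raise ValueError("need at least 2 converged fits to average")
    kds = np.array([f.kd for f in usable])
    return float(np.mean(kds)), float(np.std(kds, ddof=1))
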