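"""Optical model for dual-wavelength continuous-wave NIRS.

Couples optical-density changes at the two measurement wavelengths (730 and
850 nm by default) to hemoglobin concentration changes through the modified
Beer-Lambert law:

    dOD(lambda) = [eps(lambda, HbO) * dHbO + eps(lambda, HbR) * dHbR]
                  * DPF(lambda) * L

with concentrations in mM, extinction coefficients in cm^-1 mM^-1, the
source-detector separation L in cm and the dimensionless differential
pathlength factor DPF.  The shipped extinction table is a conventional
two-wavelength default (HbR dominating at 730 nm, HbO at 850 nm); absolute
scale does not matter downstream because correlation-based analyses are
invariant to per-channel linear scaling, and every value is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class OpticalModel:
    """Wavelengths, extinction coefficients, DPF and probe geometry.

    ``extinction[w, c]`` is the extinction coefficient of chromophore ``c``
    (0 = HbO, 1 = HbR) at wavelength index ``w``, in cm^-1 mM^-1.
    """

    wavelengths: tuple[float, float] = (730.0, 850.0)
    extinction: np.ndarray = field(
        default_factory=lambda: np.array([[0.390, 1.102], [1.058, 0.691]])
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    separation: float = 3.0  # cm

    def __post_init__(self) -> None:
        ext = np.asarray(self.extinction, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix (wavelength x chromophore)")
        object.__setattr__(self, "extinction", ext)
        if self.separation <= 0:
            raise ValueError("source-detector separation must be > 0")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF must be > 0")
        if np.linalg.cond(self.coupling_matrix()) > 1e12:
            raise ValueError("extinction matrix is singular (or numerically so)")

    def pathlengths(self) -> np.ndarray:
        """Effective optical pathlength DPF * L per wavelength (cm)."""
        return np.asarray(self.dpf, dtype=float) * self.separation

    def coupling_matrix(self) -> np.ndarray:
        """2x2 matrix A with dOD = A @ (dHbO, dHbR) in mM."""
        return self.extinction * self.pathlengths()[:, None]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.coupling_matrix()))


def default_optics() -> OpticalModel:
    return OpticalModel()
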