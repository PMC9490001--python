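"""Physical constants and spectrometer/field parameters.

All NMR interaction constants are derived from CODATA values with the
conventional model-free geometry: an effective N-H bond length of 1.02 Å and a
15N chemical-shift anisotropy of -160 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# CODATA / IUPAC values
MU0 = 4.0e-7 * np.pi  # vacuum permeability, T^2 m^3 / J
HBAR = 1.054571817e-34  # reduced Planck constant, J s
GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_N = -2.7126e7  # 15N gyromagnetic ratio, rad s^-1 T^-1
GAMMA_C = 6.728284e7  # 13C gyromagnetic ratio, rad s^-1 T^-1

KB_KJ_MOL = 0.0083145  # Boltzmann constant, kJ mol^-1 K^-1
R_GAS_KCAL = 1.98720425864083e-3  # gas constant, kcal mol^-1 K^-1

# Conventional bond lengths (Å)
R_NH = 1.02
R_CN = 1.329  # peptide C'(i-1)-N(i)

CSA_N = -160.0  # 15N chemical shift anisotropy, ppm


def dipolar_coupling_constant(pair: str) -> float:
    """Static dipolar interaction constant D_max (Hz) for a coupling type.

    ``D_calc = D_max * v^T S v`` for unit internuclear vector ``v`` and Saupe
    order matrix ``S``.  D_max = -(mu0/4pi) * gamma_i * gamma_j * hbar /
    (2 pi^2 r^3), i.e. the coupling observed for a bond perfectly aligned with
    the unique axis of a fully ordered medium (S_zz = 1) under this Saupe
    normalisation.
    """
    if pair == "N-H":
        g1, g2, r = GAMMA_N, GAMMA_H, R_NH
    elif pair == "C-N":
        g1, g2, r = GAMMA_C, GAMMA_N, R_CN
    else:
        raise ValueError(f"unknown coupling type {pair!r}; expected 'N-H' or 'C-N'")
    r_m = r * 1e-10
    return -(MU0 / (4 * np.pi)) * g1 * g2 * HBAR / (2 * np.pi**2 * r_m**3)


@dataclass(frozen=True)
class FieldParams:
    """Static-field and interaction parameters for one relaxation dataset.

    Parameters
    ----------
    frequency_mhz : proton Larmor frequency of the spectrometer (MHz).
    r_nh : effective N-H bond length (Å).
    csa : 15N chemical-shift anisotropy Δσ (ppm).
    """

    frequency_mhz: float = 700.0
    r_nh: float = R_NH
    csa: float = CSA_N
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N

    def __post_init__(self) -> None:
        if not self.frequency_mhz > 0:
            raise ValueError("proton frequency must be positive")
        for name in ("r_nh", "csa", "gamma_h", "gamma_n"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def omega_h(self) -> float:
        """1H angular frequency (rad/s)."""
        return 2 * np.pi * self.frequency_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """15N angular frequency magnitude (rad/s)."""
        return self.omega_h * abs(self.gamma_n) / self.gamma_h

    @property
    def d_factor(self) -> float:
        """Dipolar interaction strength d = (mu0/4pi) hbar gamma_H gamma_N / r^3 (rad/s)."""
        r_m = self.r_nh * 1e-10
        return (MU0 / (4 * np.pi)) * HBAR * self.gamma_h * abs(self.gamma_n) / r_m**3

    @property
    def c_factor(self) -> float:
        """CSA interaction strength c = omega_N * Δσ / sqrt(3) (rad/s)."""
        return self.omega_n * abs(self.csa) * 1e-6 / np.sqrt(3.0)
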