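"""Dielectric models for hydrated tissue in the terahertz band.

Liquid water dominates the THz response of soft tissue.  Its permittivity
in the 0.1-3 THz band is well described by a double-Debye relaxation model

    eps(f) = eps_inf + d_eps_1 / (1 - i 2 pi f tau_1)
                     + d_eps_2 / (1 - i 2 pi f tau_2)

and a water/tissue composite is homogenised with the symmetric Bruggeman
effective-medium rule.

Time convention
---------------
All frequency-domain physics in this package uses the e^(-i omega t)
convention: lossy media have Im(eps) >= 0 and Im(n) >= 0.  The discrete
Fourier transform in :mod:`numpy` synthesises signals with the opposite
kernel, so reflectances are conjugated exactly once, inside
:func:`thzcornea.simulate.synthesize_trace`, when they are imposed on
sampled pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DielectricParams",
    "WATER_DOUBLE_DEBYE",
    "debye_permittivity",
    "bruggeman_mix",
    "refractive_index",
]


@dataclass(frozen=True)
class DielectricParams:
    """Double-Debye relaxation parameters.

    Attributes
    ----------
    eps_inf:
        High-frequency (instantaneous) relative permittivity, >= 1.
    delta_eps_1, delta_eps_2:
        Relaxation strengths of the slow and fast processes, >= 0.
    tau_1, tau_2:
        Relaxation times in picoseconds, > 0.
    """

    eps_inf: float
    delta_eps_1: float
    delta_eps_2: float
    tau_1: float
    tau_2: float

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.delta_eps_1 < 0.0 or self.delta_eps_2 < 0.0:
            raise ValueError("relaxation strengths must be >= 0")
        if self.tau_1 <= 0.0 or self.tau_2 <= 0.0:
            raise ValueError("relaxation times must be > 0")


#: Double-Debye parameters for liquid water near room temperature
#: (slow cooperative relaxation ~8.24 ps, fast relaxation ~0.18 ps).
#: Static permittivity eps_inf + d1 + d2 = 78.36.
WATER_DOUBLE_DEBYE = DielectricParams(
    eps_inf=3.48,
    delta_eps_1=73.43,
    delta_eps_2=1.45,
    tau_1=8.24,
    tau_2=0.18,
)


def debye_permittivity(freq_thz, params: DielectricParams = WATER_DOUBLE_DEBYE):
    """Complex relative permittivity of a double-Debye medium.

    Parameters
    ----------
    freq_thz:
        Frequency (scalar or array) in THz, >= 0.
    params:
        Relaxation parameters; defaults to liquid water.

    Returns
    -------
    complex or np.ndarray
        eps(f) with Im(eps) >= 0 (e^(-i omega t) convention).
    """
    f = np.asarray(freq_thz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    omega = 2.0 * np.pi * f
    eps = (
        params.eps_inf
        + params.delta_eps_1 / (1.0 - 1j * omega * params.tau_1)
        + params.delta_eps_2 / (1.0 - 1j * omega * params.tau_2)
    )
    if np.isscalar(freq_thz):
        return complex(eps)
    return eps


def bruggeman_mix(eps_water, eps_background, water_fraction):
    """Bruggeman effective permittivity of a two-phase composite.

    Solves the symmetric mixing equation

        f (e_w - e) / (e_w + 2 e) + (1 - f) (e_b - e) / (e_b + 2 e) = 0

    which is quadratic in ``e``; the physical root (positive real part,
    non-negative imaginary part under the e^(-i omega t) convention) is
    returned.  Inputs broadcast against each other.

    Parameters
    ----------
    eps_water, eps_background:
        Complex permittivities of the two phases.
    water_fraction:
        Volume fraction of the water phase, in [0, 1].

    Raises
    ------
    ValueError
        If the fraction lies outside [0, 1] or no physical root exists.
    """
    f = np.asarray(water_fraction, dtype=float)
    if np.any(f < 0.0) or np.any(f > 1.0):
        raise ValueError("water_fraction must lie in [0, 1]")
    ew = np.asarray(eps_water, dtype=complex)
    eb = np.asarray(eps_background, dtype=complex)
    f, ew, eb = np.broadcast_arrays(f, ew, eb)

    # 2 e^2 - b e - e_w e_b = 0 with b = f (2 e_w - e_b) + (1-f) (2 e_b - e_w)
    b = f * (2.0 * ew - eb) + (1.0 - f) * (2.0 * eb - ew)
    disc = np.sqrt(b * b + 8.0 * ew * eb)
    r1 = (b + disc) / 4.0
    r2 = (b - disc) / 4.0

    tol = 1e-12
    ok1 = (r1.real > 0.0) & (r1.imag >= -tol)
    out = np.where(ok1, r1, r2)
    ok = (out.real > 0.0) & (out.imag >= -tol)
    if not np.all(ok):
        raise ValueError("no physical Bruggeman root for the given inputs")

    # endpoints are returned exactly (no floating cancellation)
    out = np.where(f == 0.0, eb, out)
    out = np.where(f == 1.0, ew, out)
    if out.ndim == 0:
        return complex(out)
    return out


def refractive_index(eps):
    """Complex refractive index n = sqrt(eps), principal branch.

    For Im(eps) >= 0 the principal square root has Im(n) >= 0, i.e. the
    medium absorbs under the package's e^(-i omega t) convention.
    """
    return np.sqrt(np.asarray(eps, dtype=complex))
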