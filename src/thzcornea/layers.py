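"""Plane-wave reflectance of stratified media at normal incidence.

The cornea is modelled as a stack of homogeneous layers (a discretised
hydration gradient) on a semi-infinite substrate.  The complex reflection
coefficient is computed with the characteristic (transfer) matrix method.

Field convention: e^(i(kz - omega t)) with k = 2 pi f n / c and
Im(n) >= 0, so lossy layers attenuate the forward wave.  With no finite
layers the result reduces to the Fresnel coefficient
r = (n0 - ns) / (n0 + ns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = ["C_UM_PER_PS", "LayerStack", "stratified_reflectance"]

#: Vacuum speed of light in micrometres per picosecond.
C_UM_PER_PS = 299.792458


@dataclass
class LayerStack:
    """Ordered stack of finite layers on a terminal half-space.

    ``layers`` lists ``(refractive_index, thickness_um)`` pairs from the
    incidence side inwards; each index may be a scalar or an array over
    the frequency grid the stack will be evaluated on.  The terminal
    half-space has an index but no thickness.
    """

    layers: Sequence[Tuple[np.ndarray | complex, float]] = field(default_factory=list)
    n_substrate: np.ndarray | complex = 1.0
    n_incident: complex = 1.0

    def __post_init__(self) -> None:
        for _, d in self.layers:
            if not d > 0.0:
                raise ValueError(f"finite layer thickness must be > 0, got {d}")


def stratified_reflectance(stack: LayerStack, freq_thz):
    """Complex reflection coefficient of a layer stack at normal incidence.

    Parameters
    ----------
    stack:
        Layer stack; per-layer indices broadcast against ``freq_thz``.
    freq_thz:
        Frequency (scalar or 1-D array) in THz, >= 0.

    Returns
    -------
    complex or np.ndarray
        r(f).  For passive (lossy) stacks |r| <= 1.
    """
    scalar = np.isscalar(freq_thz)
    f = np.atleast_1d(np.asarray(freq_thz, dtype=float))
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")

    m11 = np.ones(f.shape, dtype=complex)
    m12 = np.zeros(f.shape, dtype=complex)
    m21 = np.zeros(f.shape, dtype=complex)
    m22 = np.ones(f.shape, dtype=complex)

    for n, d in stack.layers:
        if not d > 0.0:
            raise ValueError(f"finite layer thickness must be > 0, got {d}")
        n = np.broadcast_to(np.asarray(n, dtype=complex), f.shape)
        delta = 2.0 * np.pi * f * n * d / C_UM_PER_PS
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, 1j * s / n
        a21, a22 = 1j * n * s, c
        m11, m12, m21, m22 = (
            a11 * m11 + a12 * m21,
            a11 * m12 + a12 * m22,
            a21 * m11 + a22 * m21,
            a21 * m12 + a22 * m22,
        )

    ns = np.broadcast_to(np.asarray(stack.n_substrate, dtype=complex), f.shape)
    n0 = complex(stack.n_incident)
    p = ns * m11 - m21
    q = ns * m12 - m22
    r = (p + n0 * q) / (n0 * q - p)
    if scalar:
        return complex(r[0])
    return r
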