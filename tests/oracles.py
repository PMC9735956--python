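"""Independent reference computations used to cross-check the package.

These are deliberately written with different algorithms from the
implementation (multiple-reflection series instead of transfer matrices,
explicit normal equations instead of polyfit) so agreement is evidence,
not tautology.
"""

import numpy as np

C_UM_PER_PS = 299.792458


def fresnel(ni, nj):
    return (ni - nj) / (ni + nj)


def airy_single_layer(n0, n1, ns, d_um, freq_thz, tol=1e-16, max_terms=10000):
    """Reflection of one finite layer by summing the bounce series."""
    delta = 2.0 * np.pi * freq_thz * n1 * d_um / C_UM_PER_PS
    phase = np.exp(2j * delta)
    r01, r12 = fresnel(n0, n1), fresnel(n1, ns)
    t01 = 2.0 * n0 / (n0 + n1)
    t10 = 2.0 * n1 / (n0 + n1)
    r10 = -r01
    total = r01
    term = t01 * t10 * r12 * phase
    for _ in range(max_terms):
        total = total + term
        term = term * r10 * r12 * phase
        if np.max(np.abs(term)) < tol:
            break
    return total


def airy_two_layer(n0, n1, n2, ns, d1_um, d2_um, freq_thz):
    """Two finite layers by nesting the closed Airy formula."""
    delta2 = 2.0 * np.pi * freq_thz * n2 * d2_um / C_UM_PER_PS
    p2 = np.exp(2j * delta2)
    r_lower = (fresnel(n1, n2) + fresnel(n2, ns) * p2) / (
        1.0 + fresnel(n1, n2) * fresnel(n2, ns) * p2
    )
    delta1 = 2.0 * np.pi * freq_thz * n1 * d1_um / C_UM_PER_PS
    p1 = np.exp(2j * delta1)
    return (fresnel(n0, n1) + r_lower * p1) / (1.0 + fresnel(n0, n1) * r_lower * p1)


def bruggeman_residual(eps_water, eps_background, fraction, eps_eff):
    """Value of the symmetric mixing equation at a candidate root."""
    return fraction * (eps_water - eps_eff) / (eps_water + 2.0 * eps_eff) + (
        1.0 - fraction
    ) * (eps_background - eps_eff) / (eps_background + 2.0 * eps_eff)


def ols_slope_intercept(x, y):
    """Least squares by the explicit normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return slope, ybar - slope * xbar
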