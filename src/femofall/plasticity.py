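"""J2 (von Mises) elastic-perfectly-plastic stress update with radial return.

Bone yields asymmetrically in tension and compression; each integration
point selects its yield stress by the sign of the trial mean stress
(compressive yield when the trial pressure is negative, tensile otherwise).
No hardening: beyond yield the stress is returned radially onto the fixed
yield surface.  All operations are vectorized over an arbitrary leading
batch shape (typically ``(n_elements, n_gauss)``).

Voigt ordering: [xx, yy, zz, xy, yz, zx]; strains use engineering shears,
stresses tensor components.
"""

from __future__ import annotations

import numpy as np

__all__ = ["elastic_matrix", "stress_update", "von_mises", "elastic_energy_density"]

_IVEC = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def elastic_matrix(E, nu):
    """Isotropic elasticity matrix in Voigt form, batched over E."""
    E = np.asarray(E, dtype=float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            C[..., i, j] = lam
        C[..., i, i] += 2 * mu
    for i in range(3, 6):
        C[..., i, i] = mu
    return C


def von_mises(sigma):
    """Von Mises equivalent stress of Voigt stresses (batched)."""
    s = deviator(sigma)
    return np.sqrt(
        1.5 * (s[..., 0] ** 2 + s[..., 1] ** 2 + s[..., 2] ** 2)
        + 3.0 * (s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2)
    )


def deviator(sigma):
    p = (sigma[..., 0] + sigma[..., 1] + sigma[..., 2]) / 3.0
    return sigma - p[..., None] * _IVEC


def stress_update(eps, eps_p, E, nu, sigma_yc, sigma_yt, switch_band: float = 0.05):
    """Radial-return update at every integration point.

    Parameters
    ----------
    eps, eps_p : (..., 6) total and plastic strain (engineering shears).
    E, sigma_yc, sigma_yt : (...) per-point modulus and yield stresses.
    nu : scalar Poisson ratio.
    switch_band : relative half-width of the smooth blend between the
        compressive and tensile yield stress around zero trial pressure
        (a hard switch would make the response discontinuous in strain and
        defeat Newton convergence); 0 recovers the sharp sign selection.

    Returns
    -------
    sigma : (..., 6) updated stress.
    eps_p_new : (..., 6) updated plastic strain.
    D : (..., 6, 6) consistent tangent moduli.
    dgamma : (...) plastic multiplier increment (0 where elastic).
    """
    E = np.asarray(E, dtype=float)
    mu = E / (2 * (1 + nu))
    K = E / (3 * (1 - 2 * nu))
    lam = K - 2 * mu / 3

    eps_e = eps - eps_p
    tr = eps_e[..., 0] + eps_e[..., 1] + eps_e[..., 2]
    sigma_tr = np.empty_like(eps_e)
    sigma_tr[..., :3] = 2 * mu[..., None] * eps_e[..., :3] + (lam * tr)[..., None]
    sigma_tr[..., 3:] = mu[..., None] * eps_e[..., 3:]

    p_tr = (sigma_tr[..., 0] + sigma_tr[..., 1] + sigma_tr[..., 2]) / 3.0
    s_tr = sigma_tr - p_tr[..., None] * _IVEC
    q_tr = np.sqrt(
        1.5 * (s_tr[..., 0] ** 2 + s_tr[..., 1] ** 2 + s_tr[..., 2] ** 2)
        + 3.0 * (s_tr[..., 3] ** 2 + s_tr[..., 4] ** 2 + s_tr[..., 5] ** 2)
    )
    if switch_band > 0:
        delta = switch_band * 0.5 * (sigma_yc + sigma_yt)
        w = np.clip((delta - p_tr) / (2.0 * delta), 0.0, 1.0)
        sigma_y = sigma_yt + w * (sigma_yc - sigma_yt)
    else:
        sigma_y = np.where(p_tr < 0, sigma_yc, sigma_yt)
    yielded = q_tr > sigma_y

    dgamma = np.where(yielded, (q_tr - sigma_y) / np.maximum(3 * mu, 1e-300), 0.0)
    q_safe = np.where(q_tr > 0, q_tr, 1.0)
    scale = np.where(yielded, sigma_y / q_safe, 1.0)
    s_new = s_tr * scale[..., None]
    sigma = s_new + p_tr[..., None] * _IVEC

    # flow direction (3/2) s/q; engineering-shear plastic strain increments
    flow = np.empty_like(s_new)
    flow[..., :3] = 1.5 * s_new[..., :3] / np.maximum(sigma_y, 1e-300)[..., None]
    flow[..., 3:] = 3.0 * s_new[..., 3:] / np.maximum(sigma_y, 1e-300)[..., None]
    eps_p_new = eps_p + dgamma[..., None] * flow

    D = elastic_matrix(E, nu)
    if np.any(yielded):
        beta = np.where(yielded, scale, 1.0)
        # deviatoric projector in engineering-Voigt form
        P = np.zeros(E.shape + (6, 6))
        for i in range(3):
            for j in range(3):
                P[..., i, j] = -1.0 / 3.0
            P[..., i, i] += 1.0
        for i in range(3, 6):
            P[..., i, i] = 0.5
        # unit deviatoric direction (tensor norm); rows contract engineering
        # strains correctly because the shear entries carry the tensor value
        norm = q_tr * np.sqrt(2.0 / 3.0)
        nrm = np.where(norm > 0, norm, 1.0)
        nvec = s_tr / nrm[..., None]
        Dp = np.zeros_like(D)
        for i in range(3):
            for j in range(3):
                Dp[..., i, j] = K
        Dp += 2 * (mu * beta)[..., None, None] * P
        Dp -= 2 * (mu * beta)[..., None, None] * np.einsum(
            "...i,...j->...ij", nvec, nvec
        )
        D = np.where(yielded[..., None, None], Dp, D)
    return sigma, eps_p_new, D, dgamma


def elastic_energy_density(sigma, eps, eps_p):
    """0.5 * sigma : (eps - eps_p), Voigt contraction with engineering shears."""
    eps_e = eps - eps_p
    return 0.5 * (
        np.sum(sigma[..., :3] * eps_e[..., :3], axis=-1)
        + np.sum(sigma[..., 3:] * eps_e[..., 3:], axis=-1)
    )
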