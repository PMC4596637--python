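"""Membrane enhancement: Hessian eigenvalue indicator and anisotropic diffusion.

A fluorescent cell membrane is locally a bright plane in 3D, so the smallest
eigenvalue of the intensity Hessian is strongly negative on membranes and
near zero inside cells — it is the landscape the watershed stage floods.
Before (or instead of) computing it on raw data, the membrane channel can be
denoised by divergence-form anisotropic diffusion whose tensor suppresses
smoothing across the membrane (along the eigenvector of the most negative
Hessian eigenvalue) while smoothing freely within the membrane plane.

All spatial scales are physical (µm); derivatives honour anisotropic voxel
spacing.  The explicit diffusion scheme uses staggered face fluxes with
zero-flux boundaries, so the total intensity is conserved to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Volume

__all__ = ["EnhanceParams", "anisotropic_diffusion", "membrane_indicator",
           "hessian_components"]


@dataclass(frozen=True)
class EnhanceParams:
    """Free parameters of the enhancement stage.

    sigma_hessian : Gaussian derivative scale in µm (≈ 1.2 × membrane
                    width, calibrated on synthetic fixtures; larger scales
                    wash out the thin interiors of edge cells).
    n_iter        : number of explicit diffusion steps.
    tau           : time step; ``None`` selects 0.9 × the explicit-scheme
                    stability bound for the grid.
    alpha         : floor in (0, 1) for the diffusion eigenvalue across the
                    membrane (0 would stop smoothing entirely).
    contrast_lambda : contrast scale of the eigenvalue response; ``None``
                    selects a robust scale (1.4826 × MAD) of the smallest
                    Hessian eigenvalue of the input.
    """

    sigma_hessian: float = 1.2
    n_iter: int = 10
    tau: float | None = None
    alpha: float = 0.05
    contrast_lambda: float | None = None

    def __post_init__(self):
        if self.sigma_hessian <= 0:
            raise ValueError("sigma_hessian must be positive")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.contrast_lambda is not None and self.contrast_lambda <= 0:
            raise ValueError("contrast_lambda must be positive")


def stability_bound(spacing) -> float:
    """Largest stable explicit time step for a unit-diffusivity tensor."""
    return 1.0 / (2.0 * sum(1.0 / s**2 for s in spacing))


def hessian_components(v: Volume, sigma_hessian: float):
    """Six unique components of the Gaussian-smoothed Hessian in µm⁻² units.

    Returns a dict keyed by axis pairs (0=z, 1=y, 2=x); derivatives are
    taken at scale ``sigma_hessian`` (µm) and scaled by the physical voxel
    spacing, so anisotropic stacks give geometrically correct curvature.
    """
    if sigma_hessian < max(v.spacing):
        raise ValueError(
            f"sigma_hessian ({sigma_hessian} µm) must be at least the coarsest "
            f"voxel spacing ({max(v.spacing)} µm)"
        )
    if min(v.shape) < 4:
        raise ValueError("volume smaller than the derivative stencil")
    sig_vox = v.sigma_voxels(sigma_hessian)
    # subtract the mean first: truncated derivative kernels have a small
    # nonzero DC response, so a constant offset would leak into the Hessian
    data = v.data - v.data.mean()
    H = {}
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = ndi.gaussian_filter(data, sigma=sig_vox, order=order,
                                    mode="nearest")
            H[(a, b)] = d / (v.spacing[a] * v.spacing[b])
    return H


def _hessian_matrix_field(H, shape):
    M = np.empty(shape + (3, 3))
    for a in range(3):
        for b in range(3):
            M[..., a, b] = H[(min(a, b), max(a, b))]
    return M


def membrane_indicator(v: Volume, sigma_hessian: float = 1.2) -> Volume:
    """Smallest eigenvalue of the local Hessian at scale ``sigma_hessian``.

    Strongly negative on bright plane-like structures (membranes), near zero
    in cell interiors; linear in the input intensity.
    """
    H = hessian_components(v, sigma_hessian)
    M = _hessian_matrix_field(H, v.shape)
    smallest = np.linalg.eigvalsh(M)[..., 0]
    return v.with_data(smallest)


def _diffusion_tensor(v: Volume, p: EnhanceParams):
    """Voxelwise plane-enhancing diffusion tensor.

    Eigenvalue along the membrane normal (eigenvector of the most negative
    Hessian eigenvalue μ₁): alpha + (1 − alpha)·exp(−(μ₁/λ)²); the two
    in-plane eigenvalues are 1.  D = I + (λ_normal − 1)·v₁v₁ᵀ.
    """
    H = hessian_components(v, p.sigma_hessian)
    M = _hessian_matrix_field(H, v.shape)
    vals, vecs = np.linalg.eigh(M)
    mu1 = vals[..., 0]
    v1 = vecs[..., :, 0]
    lam = p.contrast_lambda
    if lam is None:
        mad = np.median(np.abs(mu1 - np.median(mu1)))
        lam = 1.4826 * mad
        if lam <= 0:
            lam = 1.0  # flat image: tensor becomes isotropic anyway
    lam_normal = p.alpha + (1.0 - p.alpha) * np.exp(-((mu1 / lam) ** 2))
    D = {}
    for a in range(3):
        for b in range(a, 3):
            D[(a, b)] = (1.0 if a == b else 0.0) + (lam_normal - 1.0) * v1[..., a] * v1[..., b]
    return D


def _gradient(u, spacing):
    return [np.gradient(u, spacing[a], axis=a) for a in range(3)]


def _diffusion_step(u, D, spacing, tau):
    """One explicit conservative step of div(D grad u), zero-flux boundaries.

    Normal derivatives are exact two-point differences on faces; tangential
    derivatives and tensor components are averaged onto faces.  Face fluxes
    telescope, so the voxel sum is conserved to machine precision.
    """
    grad = _gradient(u, spacing)
    div = np.zeros_like(u)
    for a in range(3):
        h = spacing[a]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(None, -1)
        sl_hi[a] = slice(1, None)
        sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)
        # flux through interior faces along axis a
        flux = 0.5 * (D[(a, a)][sl_lo] + D[(a, a)][sl_hi]) * (u[sl_hi] - u[sl_lo]) / h
        for b in range(3):
            if b == a:
                continue
            key = (min(a, b), max(a, b))
            gb_face = 0.5 * (grad[b][sl_lo] + grad[b][sl_hi])
            flux = flux + 0.5 * (D[key][sl_lo] + D[key][sl_hi]) * gb_face
        dv = np.swapaxes(div, 0, a)
        f = np.swapaxes(flux, 0, a)
        dv[:-1] += f / h
        dv[1:] -= f / h
    return u + tau * div


def anisotropic_diffusion(v: Volume, p: EnhanceParams | None = None) -> Volume:
    """Plane-preserving anisotropic diffusion of a membrane channel.

    The diffusion tensor is built once from the eigen-decomposition of the
    Gaussian-smoothed Hessian of the input and held fixed over ``n_iter``
    explicit steps — a linear scheme that is fast, exactly conservative
    under the zero-flux boundaries, and adequate for the modest iteration
    counts used here.
    """
    p = p or EnhanceParams()
    tau = p.tau
    bound = stability_bound(v.spacing)
    if tau is None:
        tau = 0.9 * bound
    elif tau > bound:
        raise ValueError(
            f"tau={tau} exceeds the explicit stability bound {bound:.4g} "
            f"for spacing {v.spacing}"
        )
    elif tau <= 0:
        raise ValueError("tau must be positive")
    if p.n_iter == 0:
        return v
    D = _diffusion_tensor(v, p)
    u = v.data.copy()
    for _ in range(p.n_iter):
        u = _diffusion_step(u, D, v.spacing, tau)
    return v.with_data(u)
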