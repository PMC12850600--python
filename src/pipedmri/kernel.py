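"""Axially symmetric fiber-response kernels and spherical convolution.

The default kernel is the three-compartment white-matter model:
an intra-axonal stick (axial diffusivity Da), an axially symmetric
extra-axonal tensor (De_par, De_perp), and isotropic free water with
diffusivity fixed at 3 um^2/ms:

    K(b, z | xi) = f exp(-b Da z^2) + fw exp(-b Dw)
                   + (1 - f - fw) exp(-b (De_par - De_perp) z^2 - b De_perp)

with z = cos(angle between fiber and encoding direction). Rotational
invariants are Legendre projections K_l(b) = int_0^1 dz K(b, z) P_l(z);
the measured signal is a spherical convolution of the kernel with the
fODF, which in the SH basis is the product S_lm = K_l p_lm.

Kernels accept and ignore additional scalar protocol parameters (TE, t,
...) so extended protocols are structurally supported; alternative
axially symmetric kernels can be registered under a name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from . import spherical
from .spherical import SHCoefficients, even_degrees, gauss_legendre_01

__all__ = [
    "SMKernelParams",
    "StandardModelKernel",
    "sm_kernel",
    "kernel_invariants",
    "kernel_invariants_table",
    "convolve_signal",
    "convolve_signal_quadrature",
    "get_kernel",
    "register_kernel",
    "KERNEL_REGISTRY",
    "FREE_WATER_DIFFUSIVITY",
]

#: free-water diffusivity, um^2/ms (frozen for the default kernel)
FREE_WATER_DIFFUSIVITY = 3.0

#: quadrature order for Legendre projections (validated to ~1e-12 vs erf forms)
QUADRATURE_ORDER = 64


@dataclass(frozen=True)
class SMKernelParams:
    """Scalar tissue parameters of the three-compartment kernel.

    f: intra-axonal fraction; Da: intra-axonal axial diffusivity;
    De_par / De_perp: extra-axonal axial / radial diffusivities (um^2/ms);
    fw: free-water fraction; Dw: free-water diffusivity (metadata, frozen
    at 3 um^2/ms by default). Extra-axonal fraction is 1 - f - fw.
    """

    f: float
    Da: float
    De_par: float
    De_perp: float
    fw: float
    Dw: float = FREE_WATER_DIFFUSIVITY

    def validate(self) -> "SMKernelParams":
        if not (0.0 <= self.f and 0.0 <= self.fw and self.f + self.fw <= 1.0 + 1e-12):
            raise ValueError("fractions must satisfy 0 <= f, fw and f + fw <= 1")
        for name in ("Da", "De_par", "De_perp", "Dw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self

    @property
    def fe(self) -> float:
        return 1.0 - self.f - self.fw

    def as_array(self) -> np.ndarray:
        return np.array([self.f, self.Da, self.De_par, self.De_perp, self.fw])

    FIELDS = ("f", "Da", "De_par", "De_perp", "fw")

    @classmethod
    def from_array(cls, a: np.ndarray, Dw: float = FREE_WATER_DIFFUSIVITY) -> "SMKernelParams":
        return cls(*[float(x) for x in np.asarray(a)[:5]], Dw=Dw)


def sm_kernel(b, zeta, xi: SMKernelParams, **scalars) -> np.ndarray:
    """Kernel value K(b, zeta | xi); broadcasts over b and zeta.

    Extra scalar protocol parameters are accepted and ignored.
    """
    xi.validate()
    b = np.asarray(b, dtype=float)
    z2 = np.square(np.asarray(zeta, dtype=float))
    intra = xi.f * np.exp(-b * xi.Da * z2)
    water = xi.fw * np.exp(-b * xi.Dw)
    extra = xi.fe * np.exp(-b * (xi.De_par - xi.De_perp) * z2 - b * xi.De_perp)
    return intra + water + extra


def _sm_table(b: np.ndarray, zeta: np.ndarray, table: np.ndarray, Dw: float) -> np.ndarray:
    """Vectorized kernel over (b, zeta, sample) axes.

    ``table`` is (S, 5) with columns (f, Da, De_par, De_perp, fw); returns
    an array of shape (len(b), len(zeta), S).
    """
    f, Da, Dp, Dr, fw = (table[:, i] for i in range(5))
    fe = 1.0 - f - fw
    b = b[:, None, None]
    z2 = np.square(zeta)[None, :, None]
    out = f * np.exp(-b * Da * z2)
    out += fw * np.exp(-b * Dw)
    out += fe * np.exp(-b * (Dp - Dr) * z2 - b * Dr)
    return out


def kernel_invariants(b, xi: SMKernelParams, lmax: int = 2, **scalars) -> np.ndarray:
    """Legendre projections K_l(b | xi) for even l <= lmax.

    Returns shape (n_even_degrees, *shape(b)). Fixed Gauss-Legendre
    quadrature on [0, 1]; K_0(0) = 1 and K_l(0) = 0 for l > 0.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    z, w = gauss_legendre_01(QUADRATURE_ORDER)
    vals = sm_kernel(b[..., None], z, xi)          # (*b, Q)
    out = []
    for l in even_degrees(lmax):
        pl = np.polynomial.legendre.Legendre.basis(l)(z)
        out.append(vals @ (w * pl))
    return np.stack(out, axis=0)


def kernel_invariants_table(
    b: np.ndarray, table: np.ndarray, lmax: int = 2, Dw: float = FREE_WATER_DIFFUSIVITY
) -> np.ndarray:
    """K_l(b_i | xi_j) for a whole parameter table, shape (n_l, N_b, S).

    ``table`` is (S, 5) ordered (f, Da, De_par, De_perp, fw). Memory is
    kept bounded by chunking over samples.
    """
    b = np.asarray(b, dtype=float)
    table = np.asarray(table, dtype=float)
    z, w = gauss_legendre_01(QUADRATURE_ORDER)
    ells = even_degrees(lmax)
    proj = np.stack(
        [w * np.polynomial.legendre.Legendre.basis(l)(z) for l in ells], axis=0
    )  # (n_l, Q)
    out = np.empty((len(ells), b.size, table.shape[0]))
    chunk = max(1, int(2e7 // (b.size * z.size)))
    for s in range(0, table.shape[0], chunk):
        vals = _sm_table(b, z, table[s : s + chunk], Dw)   # (N_b, Q, c)
        out[:, :, s : s + chunk] = np.einsum("lq,bqs->lbs", proj, vals)
    return out


def stick_k0(b: float, Da: float) -> float:
    """Closed form K_0 for a pure stick: sqrt(pi/(4 b Da)) erf(sqrt(b Da))."""
    if b * Da == 0:
        return 1.0
    a = b * Da
    return float(math.sqrt(math.pi / (4.0 * a)) * erf(math.sqrt(a)))


# ---------------------------------------------------------------------------
# spherical convolution


def convolve_signal(
    xi: SMKernelParams,
    fodf: SHCoefficients,
    b: np.ndarray,
    g: np.ndarray,
    lmax: int | None = None,
    **scalars,
) -> np.ndarray:
    """Signal S_k = sum_lm K_l(b_k) p_lm Y_lm(g_k) for each measurement."""
    if lmax is None:
        lmax = fodf.lmax
    if lmax > fodf.lmax:
        raise ValueError("requested lmax exceeds the fODF band limit")
    b = np.asarray(b, dtype=float)
    K = kernel_invariants(b, xi, lmax=lmax)            # (n_l, K)
    basis = spherical.sh_real_block(lmax, g)           # (K, n_coeffs)
    S = np.zeros(b.shape)
    col = 0
    for il, l in enumerate(even_degrees(lmax)):
        nb = 2 * l + 1
        block = fodf.values[spherical.sh_index(l, -l) : spherical.sh_index(l, -l) + nb]
        S += K[il] * (basis[..., col : col + nb] @ block)
        col += nb
    return S


def sphere_product_grid(n_theta: int = 24, n_phi: int = 48) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quadrature on the sphere for the uniform measure.

    Gauss-Legendre in cos(theta) times a uniform phi grid; exact for
    band-limited integrands up to degree ~min(2*n_theta - 1, n_phi - 1).
    Returns (points (N, 3), weights summing to 1).
    """
    x, w = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(1.0 - x**2)
    pts = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.outer(x, np.ones(n_phi)).ravel(),
        ],
        axis=1,
    )
    wts = np.outer(w / 2.0, np.full(n_phi, 1.0 / n_phi)).ravel()
    return pts, wts


def convolve_signal_quadrature(
    xi: SMKernelParams,
    fodf: SHCoefficients,
    b: np.ndarray,
    g: np.ndarray,
    lmax: int | None = None,
    n_theta: int = 24,
) -> np.ndarray:
    """Brute-force quadrature of the spherical convolution.

    Integrates the l-truncated kernel against the fODF over the uniform
    probability measure on a deterministic product grid (exact for the
    band-limited integrand); an independent oracle for
    :func:`convolve_signal`.
    """
    if lmax is None:
        lmax = fodf.lmax
    n, wts = sphere_product_grid(n_theta=n_theta, n_phi=2 * n_theta)
    pvals = fodf.evaluate(n)                           # (N,)
    b = np.asarray(b, dtype=float)
    K = kernel_invariants(b, xi, lmax=lmax)            # (n_l, K)
    zeta = np.asarray(g, dtype=float) @ n.T            # (K, N)
    ker = np.zeros_like(zeta)
    for il, l in enumerate(even_degrees(lmax)):
        pl = np.polynomial.legendre.Legendre.basis(l)(zeta)
        ker += (2 * l + 1) * K[il][:, None] * pl
    return ker @ (wts * pvals)


# ---------------------------------------------------------------------------
# kernel registry (pluggable axially symmetric kernels)


class StandardModelKernel:
    """Registry wrapper for the default three-compartment kernel."""

    name = "standard_model"
    param_type = SMKernelParams

    @staticmethod
    def evaluate(b, zeta, xi: SMKernelParams, **scalars) -> np.ndarray:
        return sm_kernel(b, zeta, xi, **scalars)

    @staticmethod
    def invariants(b, xi: SMKernelParams, lmax: int = 2, **scalars) -> np.ndarray:
        return kernel_invariants(b, xi, lmax=lmax, **scalars)

    @staticmethod
    def invariants_table(b, table, lmax: int = 2, Dw: float = FREE_WATER_DIFFUSIVITY):
        return kernel_invariants_table(b, table, lmax=lmax, Dw=Dw)


KERNEL_REGISTRY: dict[str, type] = {StandardModelKernel.name: StandardModelKernel}


def register_kernel(kernel_cls) -> None:
    KERNEL_REGISTRY[kernel_cls.name] = kernel_cls


def get_kernel(name: str):
    try:
        return KERNEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown kernel {name!r}; registered: {sorted(KERNEL_REGISTRY)}"
        ) from None
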