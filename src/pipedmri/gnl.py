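"""Gradient-coil tensor fields and voxelwise effective diffusion encodings.

The coil tensor L_ij(r) relates actual to nominal gradients. For linear
tensor encoding with nominal (b0, g0) the effective b-value is
b = b0 g0^T N g0 with N = L^T L, and the effective direction is
L g0 / |L g0|. N decomposes into an isotropic part N0 = tr(N)/3 and five
degree-2 coefficients N_2m on symmetric trace-free basis tensors chosen so
that g^T M_2m g = Y_2m(g) in the real Racah basis; the scalar invariant
N2 = sqrt(sum_m N_2m^2 / 5) equals the standard deviation of b/b0 over
uniformly distributed nominal directions.

Units: b in ms/um^2, positions in mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.linalg import null_space

from . import spherical

__all__ = [
    "VoxelGrid",
    "CoilHarmonicModel",
    "GradientCoilTensorField",
    "NonlinearityDecomposition",
    "NominalProtocol",
    "VoxelProtocol",
    "DegenerateEncodingError",
    "expand_coil_field",
    "effective_btensor",
    "effective_lte",
    "nonlinearity_decomposition",
    "directional_stats",
    "deform_protocol",
    "motion_adjusted_btensor",
    "stf_basis",
    "solid_harmonic",
]

#: canonical direction carried by b = 0 volumes (excluded from deformation)
B0_DIRECTION = np.array([0.0, 0.0, 1.0])


class DegenerateEncodingError(RuntimeError):
    """L annihilates the encoding direction; measurement must be flagged."""


# ---------------------------------------------------------------------------
# solid harmonics as exact Cartesian polynomials


def _monomials(l: int) -> list[tuple[int, int, int]]:
    return [(i, j, l - i - j) for i in range(l + 1) for j in range(l + 1 - i)]


class _Poly:
    """Sparse trivariate polynomial: sum_t coeffs[t] * x^i y^j z^k."""

    def __init__(self, exps: np.ndarray, coeffs: np.ndarray):
        keep = np.abs(coeffs) > 1e-14
        self.exps = np.asarray(exps, dtype=int)[keep]
        self.coeffs = np.asarray(coeffs, dtype=float)[keep]

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.zeros(pts.shape[:-1])
        for (i, j, k), c in zip(self.exps, self.coeffs):
            out += c * pts[..., 0] ** i * pts[..., 1] ** j * pts[..., 2] ** k
        return out

    def deriv(self, axis: int) -> "_Poly":
        exps = self.exps.copy()
        coeffs = self.coeffs * exps[:, axis]
        exps[:, axis] = np.maximum(exps[:, axis] - 1, 0)
        return _Poly(exps, coeffs)


@lru_cache(maxsize=None)
def solid_harmonic(l: int, m: int) -> _Poly:
    """Real Racah solid harmonic S_lm(u) = |u|^l R_lm(u/|u|) as a polynomial.

    Built once per (l, m): the harmonic subspace of homogeneous degree-l
    polynomials is the nullspace of the Laplacian; the member matching
    R_lm on the sphere is found by least squares (exact, the fit is within
    the span). Degree-1 harmonics are exactly x, y, z for m = 1, -1, 0.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    mons = _monomials(l)
    if l < 2:
        basis = np.eye(len(mons))
    else:
        target = _monomials(l - 2)
        idx = {e: k for k, e in enumerate(target)}
        lap = np.zeros((len(target), len(mons)))
        for k, e in enumerate(mons):
            for ax in range(3):
                if e[ax] >= 2:
                    e2 = list(e)
                    e2[ax] -= 2
                    lap[idx[tuple(e2)], k] += e[ax] * (e[ax] - 1)
        basis = null_space(lap)
        assert basis.shape[1] == 2 * l + 1
    rng = np.random.default_rng(12345 + 10 * l + m)
    dirs = rng.normal(size=(8 * (2 * l + 1), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    design = np.stack(
        [_Poly(np.array(mons), basis[:, c])(dirs) for c in range(basis.shape[1])],
        axis=1,
    )
    rhs = spherical.sh_real(l, m, dirs)
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    resid = design @ sol - rhs
    assert np.max(np.abs(resid)) < 1e-10, "solid harmonic fit failed"
    return _Poly(np.array(mons), basis @ sol)


# ---------------------------------------------------------------------------
# grids and fields


@dataclass
class VoxelGrid:
    """Voxel lattice geometry: shape plus affine mapping index -> mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def centered(cls, shape: tuple[int, int, int], voxel_size_mm: float) -> "VoxelGrid":
        """Isotropic grid with the scanner isocenter at the grid center."""
        shape = tuple(int(s) for s in shape)
        aff = np.diag([voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
        return cls(shape, aff)

    def coords_mm(self) -> np.ndarray:
        """Scanner-frame coordinates of voxel centers, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        p = np.asarray(points_mm, dtype=float)
        return p @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class CoilHarmonicModel:
    """Solid-harmonic expansion of the field of each gradient coil.

    ``terms[axis]`` lists (degree, order, coefficient) triplets per coil
    axis (0 = x, 1 = y, 2 = z). Coefficients are dimensionless, normalized
    so the ideal coil is the pure linear term with unit coefficient;
    positions are scaled by ``reference_radius_mm`` before evaluation.
    """

    terms: dict[int, list[tuple[int, int, float]]]
    reference_radius_mm: float = 250.0

    # linear solid harmonics are x, y, z for (l, m) = (1,1), (1,-1), (1,0)
    _LINEAR_M = {0: 1, 1: -1, 2: 0}

    @classmethod
    def ideal(cls, reference_radius_mm: float = 250.0) -> "CoilHarmonicModel":
        return cls(
            {ax: [(1, cls._LINEAR_M[ax], 1.0)] for ax in range(3)},
            reference_radius_mm,
        )

    @property
    def max_degree(self) -> int:
        return max(l for ts in self.terms.values() for l, _, _ in ts)

    def validate(self) -> None:
        for ax in range(3):
            ts = self.terms.get(ax, [])
            if not any(l >= 1 for l, _, _ in ts):
                raise ValueError(
                    f"coil axis {ax}: model has no degree >= 1 term (constant "
                    "fields produce no gradient)"
                )

    def to_dict(self) -> dict:
        axes = "xyz"
        return {
            "reference_radius_mm": self.reference_radius_mm,
            "coils": {
                axes[ax]: [
                    {"degree": int(l), "order": int(m), "coefficient": float(c)}
                    for l, m, c in self.terms.get(ax, [])
                ]
                for ax in range(3)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoilHarmonicModel":
        axes = {"x": 0, "y": 1, "z": 2}
        terms = {
            axes[k]: [(t["degree"], t["order"], t["coefficient"]) for t in v]
            for k, v in d["coils"].items()
        }
        return cls(terms, float(d["reference_radius_mm"]))


@dataclass
class GradientCoilTensorField:
    """Per-voxel 3x3 coil tensor L on a voxel grid (scanner coordinates)."""

    grid: VoxelGrid
    L: np.ndarray  # (*shape, 3, 3)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (*self.grid.shape, 3, 3):
            raise ValueError("L array shape does not match grid")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("non-finite entries in L field")

    @classmethod
    def identity(cls, grid: VoxelGrid) -> "GradientCoilTensorField":
        L = np.broadcast_to(np.eye(3), (*grid.shape, 3, 3)).copy()
        return cls(grid, L)

    def flat(self) -> np.ndarray:
        """All voxel tensors as (n_voxels, 3, 3)."""
        return self.L.reshape(-1, 3, 3)

    def sample_mm(self, points_mm: np.ndarray, strict: bool = False) -> np.ndarray:
        """Trilinear sample of L at scanner-frame points (..., 3).

        Outside the grid, nearest-neighbor clamp with a warning by default;
        ``strict=True`` raises instead.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = self.grid.mm_to_index(pts)
        lo, hi = -0.5, np.asarray(self.grid.shape) - 0.5
        outside = np.any((idx < lo) | (idx > hi - 0.0), axis=-1) | np.any(
            idx > np.asarray(self.grid.shape) - 1, axis=-1
        ) | np.any(idx < 0, axis=-1)
        if np.any(outside):
            if strict:
                raise ValueError("sample point outside the calibrated L-field grid")
            warnings.warn(
                "L-field sampled outside its grid; clamping to the boundary",
                stacklevel=2,
            )
        out = np.empty((len(idx), 3, 3))
        coords = idx.T  # (3, n)
        for i in range(3):
            for j in range(3):
                out[:, i, j] = ndimage.map_coordinates(
                    self.L[..., i, j], coords, order=1, mode="nearest"
                )
        return out.reshape(*np.shape(points_mm)[:-1], 3, 3)


def expand_coil_field(model: CoilHarmonicModel, grid: VoxelGrid) -> GradientCoilTensorField:
    """Evaluate L_ij(r) analytically from the coil harmonic expansion.

    L_ij = d B_z^(j) / d x_i in coil-normalized units; derivatives are the
    exact polynomial gradients of the solid harmonics, not finite
    differences.
    """
    model.validate()
    u = grid.coords_mm() / model.reference_radius_mm
    L = np.zeros((*grid.shape, 3, 3))
    for ax in range(3):
        for l, m, c in model.terms.get(ax, []):
            poly = solid_harmonic(l, m)
            for i in range(3):
                L[..., i, ax] += c * poly.deriv(i)(u)
    return GradientCoilTensorField(grid, L)


# ---------------------------------------------------------------------------
# effective encodings


def _check_btensor(B: np.ndarray) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.shape[-2:] != (3, 3):
        raise ValueError("B-tensor must be 3x3")
    if not np.allclose(B, np.swapaxes(B, -1, -2), atol=1e-10):
        raise ValueError("B-tensor must be symmetric")
    return B


def effective_btensor(L: np.ndarray, B0: np.ndarray) -> np.ndarray:
    """Effective B-tensor L B0 L^T (rank-preserving for invertible L)."""
    B0 = _check_btensor(B0)
    L = np.asarray(L, dtype=float)
    return L @ B0 @ np.swapaxes(L, -1, -2)


def effective_lte(
    L: np.ndarray, b0: float | np.ndarray, g0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Effective LTE encoding: b = b0 g0^T (L^T L) g0, g = L g0 / |L g0|.

    Broadcasts over leading axes of ``L`` and ``g0``. Raises
    DegenerateEncodingError if L annihilates a direction with b0 > 0.
    """
    L = np.asarray(L, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    Lg = np.einsum("...ij,...j->...i", L, g0)
    nrm = np.linalg.norm(Lg, axis=-1)
    bad = (nrm < 1e-12) & (b0 > 0)
    if np.any(bad):
        raise DegenerateEncodingError("L annihilates an encoding direction")
    b = b0 * np.einsum("...i,...i->...", Lg, Lg)
    g = Lg / np.where(nrm > 0, nrm, 1.0)[..., None]
    return b, g


@lru_cache(maxsize=1)
def stf_basis() -> np.ndarray:
    """Symmetric trace-free tensors M_2m with g^T M_2m g = Y_2m(g), m=-2..2.

    Real Racah basis; all five have Frobenius norm sqrt(3/2) and are
    mutually orthogonal.
    """
    h = math.sqrt(3.0) / 2.0
    M = np.zeros((5, 3, 3))
    M[0] = h * np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])  # m = -2: sqrt(3) xy
    M[1] = h * np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]])  # m = -1: sqrt(3) yz
    M[2] = np.diag([-0.5, -0.5, 1.0])                       # m = 0: P_2
    M[3] = h * np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]])  # m = +1: sqrt(3) xz
    M[4] = h * np.diag([1.0, -1.0, 0.0])                    # m = +2
    return M


@dataclass
class NonlinearityDecomposition:
    """Irreducible decomposition of N = L^T L."""

    N: np.ndarray        # symmetric 3x3
    N0: float            # tr(N)/3
    N2m: np.ndarray      # five l=2 coefficients, m = -2..2
    N2: float            # sqrt(sum N2m^2 / 5) >= 0

    def reconstruct(self) -> np.ndarray:
        """N0 I + sum_m N_2m M_2m; equals N to machine precision."""
        return self.N0 * np.eye(3) + np.einsum("m,mij->ij", self.N2m, stf_basis())


def nonlinearity_decomposition(L: np.ndarray) -> NonlinearityDecomposition:
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite L")
    N = L.T @ L
    N0 = float(np.trace(N) / 3.0)
    aniso = N - N0 * np.eye(3)
    # basis tensors are orthogonal with squared Frobenius norm 3/2
    N2m = (2.0 / 3.0) * np.einsum("mij,ij->m", stf_basis(), aniso)
    N2 = float(np.sqrt(np.sum(N2m**2) / 5.0))
    return NonlinearityDecomposition(N, N0, N2m, N2)


def directional_stats(dec: NonlinearityDecomposition) -> tuple[float, float]:
    """(mean, std) of N(g) = g^T N g over uniformly distributed directions.

    mean = N0 exactly; std = N2 (the anisotropic part alone contributes,
    by Racah orthogonality of the Y_2m).
    """
    return dec.N0, dec.N2


def batched_decomposition(L_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (N0, N2m, N2) for an (V, 3, 3) stack of L tensors."""
    N = np.einsum("vki,vkj->vij", L_flat, L_flat)
    N0 = np.trace(N, axis1=1, axis2=2) / 3.0
    aniso = N - N0[:, None, None] * np.eye(3)
    N2m = (2.0 / 3.0) * np.einsum("mij,vij->vm", stf_basis(), aniso)
    N2 = np.sqrt(np.sum(N2m**2, axis=1) / 5.0)
    return N0, N2m, N2


# ---------------------------------------------------------------------------
# protocols


@dataclass
class NominalProtocol:
    """Ordered list of nominal encodings (b0, g0) plus optional scalars.

    ``scalars`` holds optional per-volume protocol parameters (TE, TI,
    diffusion time, ...) in ms, keyed by name.
    """

    b: np.ndarray        # (K,), ms/um^2
    g: np.ndarray        # (K, 3), unit where b > 0
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.b.ndim != 1 or self.g.shape != (self.b.size, 3):
            raise ValueError("protocol shapes inconsistent")
        if np.any(self.b < 0):
            raise ValueError("negative b-value")
        nrm = np.linalg.norm(self.g, axis=1)
        dw = self.b > 0
        if np.any(np.abs(nrm[dw] - 1.0) > 1e-6):
            raise ValueError("non-unit direction for a diffusion-weighted volume")
        self.g = self.g.copy()
        self.g[~dw] = B0_DIRECTION

    def __len__(self) -> int:
        return self.b.size


@dataclass
class VoxelProtocol:
    """Per-voxel effective encodings aligned with the acquisition order."""

    b: np.ndarray        # (..., K)
    g: np.ndarray        # (..., K, 3)
    degenerate: np.ndarray | None = None  # (..., K) bool flags
    scalars: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.g.shape != (*self.b.shape, 3):
            raise ValueError("protocol shapes inconsistent")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.b.shape, dtype=bool)

    @property
    def n_measurements(self) -> int:
        return self.b.shape[-1]


def deform_protocol(
    field: GradientCoilTensorField, nominal: NominalProtocol
) -> VoxelProtocol:
    """Apply the coil field to every encoding of every voxel.

    b = 0 volumes pass through unchanged with the canonical direction.
    Degenerate encodings (L g0 = 0 with b0 > 0) are flagged, not dropped.
    """
    if len(nominal) == 0:
        raise ValueError("empty nominal protocol")
    Lf = field.flat()                                   # (V, 3, 3)
    g0, b0 = nominal.g, nominal.b
    dw = b0 > 0
    Lg = np.einsum("vij,kj->vki", Lf, g0)               # (V, K, 3)
    nrm = np.linalg.norm(Lg, axis=-1)
    degen = (nrm < 1e-12) & dw[None, :]
    quad = np.einsum("vki,vki->vk", Lg, Lg)             # g0^T N g0
    b = np.where(dw[None, :], b0[None, :] * quad, 0.0)
    g = Lg / np.where(nrm > 0, nrm, 1.0)[..., None]
    g[:, ~dw, :] = B0_DIRECTION
    shape = field.grid.shape
    return VoxelProtocol(
        b.reshape(*shape, -1),
        g.reshape(*shape, -1, 3),
        degen.reshape(*shape, -1),
        scalars={k: v.copy() for k, v in nominal.scalars.items()},
    )


def motion_adjusted_btensor(
    field: GradientCoilTensorField,
    B0: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    r_mm: np.ndarray,
    strict: bool = False,
) -> np.ndarray:
    """Effective B-tensor with rigid motion: R B(r0) R^T with r0 = R^-1 (r - t).

    ``R``, ``t`` map the acquired frame to the final frame; L is evaluated
    at the original position and the result rotated into the final frame.
    Out-of-grid r0 is clamped with a warning (``strict=True`` raises).
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation")
    r0 = (np.asarray(r_mm, dtype=float) - np.asarray(t, dtype=float)) @ R
    # (R^-1 v = R^T v = v @ R for a row vector)
    L0 = field.sample_mm(r0, strict=strict)
    B = effective_btensor(L0, B0)
    return R @ B @ R.T
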