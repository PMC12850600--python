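"""Spherical harmonics in Racah normalization, rotations and invariants.

Racah convention: with the uniform probability measure dn on the sphere
(integrating to 1), the harmonics satisfy

    int dn  Y*_lm(n) Y_l'm'(n) = delta_ll' delta_mm' / (2l + 1),

so Y_00 == 1 and Y_l0(n) = P_l(cos theta). Internally, coefficients are
stored in a real symmetric-harmonics basis (even degrees only, antipodal
symmetry); complex accessors are provided. Coefficient ordering is degree
ascending, and within a degree order m = -l..l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "SHCoefficients",
    "eval_sh",
    "sh_real",
    "sh_complex",
    "sh_real_block",
    "even_degrees",
    "n_coeffs",
    "sh_index",
    "legendre_project",
    "gauss_legendre_01",
    "wigner_rotate",
    "wigner_d",
    "rotation_matrix_zyz",
    "sample_so3_uniform",
    "rotational_invariant",
    "delta_fodf",
]


# ---------------------------------------------------------------------------
# indexing helpers


def even_degrees(lmax: int) -> list[int]:
    """Even degrees 0, 2, ..., lmax."""
    return list(range(0, lmax + 1, 2))


def n_coeffs(lmax: int) -> int:
    """Number of real coefficients for even degrees up to ``lmax``."""
    return sum(2 * l + 1 for l in even_degrees(lmax))


def sh_index(l: int, m: int) -> int:
    """Flat index of (l, m) in the even-degree coefficient vector."""
    if l % 2 or abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m})")
    return sum(2 * k + 1 for k in range(0, l, 2)) + (m + l)


# ---------------------------------------------------------------------------
# harmonics evaluation


def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(directions, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("directions must have a trailing axis of length 3")
    norm = np.linalg.norm(d, axis=-1)
    if np.any(norm == 0):
        raise ValueError("zero direction vector")
    d = d / norm[..., None]
    theta = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
    phi = np.arctan2(d[..., 1], d[..., 0])
    return theta, phi


def sh_complex(l: int, m: int, directions: np.ndarray) -> np.ndarray:
    """Complex Racah-normalized Y_lm evaluated at unit 3-vectors."""
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    theta, phi = _to_angles(directions)
    scale = math.sqrt(4.0 * math.pi / (2 * l + 1))
    return scale * sph_harm_y(l, m, theta, phi)


def sh_real(l: int, m: int, directions: np.ndarray) -> np.ndarray:
    """Real Racah-normalized harmonic R_lm evaluated at unit 3-vectors.

    R_l0 = Y_l0; for m > 0, R_lm = sqrt(2) (-1)^m Re Y_lm and
    R_l,-m = sqrt(2) (-1)^m Im Y_lm. Same Racah orthogonality as the
    complex basis, with plain (unconjugated) products.
    """
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds l = {l}")
    if m == 0:
        return sh_complex(l, 0, directions).real
    y = sh_complex(l, abs(m), directions)
    sign = (-1) ** abs(m)
    if m > 0:
        return math.sqrt(2.0) * sign * y.real
    return math.sqrt(2.0) * sign * y.imag


def eval_sh(l: int, m: int, direction: np.ndarray) -> float | np.ndarray:
    """Real-basis harmonic at one or more directions (Racah convention)."""
    return sh_real(l, m, direction)


def sh_real_block(lmax: int, directions: np.ndarray) -> np.ndarray:
    """All even-degree real harmonics up to lmax, shape (..., n_coeffs)."""
    cols = [
        sh_real(l, m, directions)
        for l in even_degrees(lmax)
        for m in range(-l, l + 1)
    ]
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# real <-> complex coefficient conversion (per degree block)


def _real_block_to_complex(a: np.ndarray, l: int) -> np.ndarray:
    """Real coefficients a_{l,-l..l} -> complex c_{l,-l..l} (same function)."""
    a = np.asarray(a, dtype=float)
    c = np.zeros(2 * l + 1, dtype=complex)
    c[l] = a[l]
    for m in range(1, l + 1):
        am, amn = a[l + m], a[l - m]
        c[l + m] = ((-1) ** m) * (am - 1j * amn) / math.sqrt(2.0)
        c[l - m] = (am + 1j * amn) / math.sqrt(2.0)
    return c


def _complex_block_to_real(c: np.ndarray, l: int) -> np.ndarray:
    a = np.zeros(2 * l + 1)
    a[l] = c[l].real
    for m in range(1, l + 1):
        a[l + m] = math.sqrt(2.0) * ((-1) ** m) * c[l + m].real
        a[l - m] = -math.sqrt(2.0) * ((-1) ** m) * c[l + m].imag
    return a


# ---------------------------------------------------------------------------
# coefficient container


@dataclass
class SHCoefficients:
    """Even-degree SH coefficients in the real Racah basis.

    Attributes
    ----------
    lmax : maximum even degree.
    values : flat real array, ordering (l asc, m = -l..l).
    """

    lmax: int
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = n_coeffs(self.lmax)
        if self.values is None:
            self.values = np.zeros(n)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n,):
            raise ValueError(
                f"expected {n} coefficients for lmax={self.lmax}, "
                f"got shape {self.values.shape}"
            )

    normalization = "racah"

    def __getitem__(self, lm: tuple[int, int]) -> float:
        return float(self.values[sh_index(*lm)])

    def __setitem__(self, lm: tuple[int, int], value: float) -> None:
        self.values[sh_index(*lm)] = value

    def block(self, l: int) -> np.ndarray:
        """Real coefficients of degree l, order m = -l..l."""
        i = sh_index(l, -l)
        return self.values[i : i + 2 * l + 1]

    def complex_block(self, l: int) -> np.ndarray:
        return _real_block_to_complex(self.block(l), l)

    @classmethod
    def from_complex_blocks(cls, lmax: int, blocks: dict[int, np.ndarray]) -> "SHCoefficients":
        out = cls(lmax)
        for l, c in blocks.items():
            i = sh_index(l, -l)
            out.values[i : i + 2 * l + 1] = _complex_block_to_real(np.asarray(c), l)
        return out

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        """Expansion value at unit directions, shape (...,)."""
        basis = sh_real_block(self.lmax, directions)
        return basis @ self.values

    def copy(self) -> "SHCoefficients":
        return SHCoefficients(self.lmax, self.values.copy())


def rotational_invariant(coeffs: SHCoefficients, l: int) -> float:
    """Per-degree invariant p_l = sqrt(sum_m p_lm^2 / (2l+1)) >= 0."""
    if l > coeffs.lmax:
        raise ValueError(f"l={l} exceeds lmax={coeffs.lmax}")
    b = coeffs.block(l)
    return float(np.sqrt(np.sum(b**2) / (2 * l + 1)))


def delta_fodf(direction: np.ndarray, lmax: int) -> SHCoefficients:
    """Band-limited delta fODF peaked at ``direction`` (p_00 = 1)."""
    out = SHCoefficients(lmax)
    for l in even_degrees(lmax):
        for m in range(-l, l + 1):
            out[l, m] = (2 * l + 1) * float(sh_real(l, m, direction))
    return out


# ---------------------------------------------------------------------------
# Legendre projection on [0, 1]

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gauss_legendre_01(order: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on [0, 1] (cached)."""
    if order not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(order)
        _GL_CACHE[order] = (0.5 * (x + 1.0), 0.5 * w)
    return _GL_CACHE[order]


def legendre_project(f, l: int, order: int = 64) -> float | np.ndarray:
    """Integral over [0, 1] of f(zeta) P_l(zeta) by fixed Gauss-Legendre.

    ``f`` is a callable evaluated at the quadrature nodes, or an array of
    values already sampled at ``gauss_legendre_01(order)`` nodes (values may
    carry leading batch axes; the node axis must be last).
    """
    z, w = gauss_legendre_01(order)
    vals = np.asarray(f(z) if callable(f) else f, dtype=float)
    if vals.shape[-1] != z.size:
        raise ValueError("sample count does not match quadrature order")
    pl = np.polynomial.legendre.Legendre.basis(l)(z)
    out = vals @ (w * pl)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# rotations

_FACT = [math.factorial(k) for k in range(40)]


def wigner_d(l: int, beta: float) -> np.ndarray:
    """Small Wigner d-matrix d^l_{m'm}(beta), indexed [m'+l, m+l]."""
    d = np.zeros((2 * l + 1, 2 * l + 1))
    cb, sb = math.cos(beta / 2.0), math.sin(beta / 2.0)
    for mp in range(-l, l + 1):
        for m in range(-l, l + 1):
            pref = math.sqrt(
                _FACT[l + mp] * _FACT[l - mp] * _FACT[l + m] * _FACT[l - m]
            )
            s_min = max(0, m - mp)
            s_max = min(l + m, l - mp)
            tot = 0.0
            for s in range(s_min, s_max + 1):
                num = (-1.0) ** (mp - m + s)
                den = (
                    _FACT[l + m - s]
                    * _FACT[s]
                    * _FACT[mp - m + s]
                    * _FACT[l - mp - s]
                )
                tot += (
                    num
                    / den
                    * cb ** (2 * l + m - mp - 2 * s)
                    * sb ** (mp - m + 2 * s)
                )
            d[mp + l, m + l] = pref * tot
    return d


def _wigner_D(l: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    m = np.arange(-l, l + 1)
    d = wigner_d(l, beta)
    return np.exp(-1j * m[:, None] * alpha) * d * np.exp(-1j * m[None, :] * gamma)


def rotation_matrix_zyz(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """3x3 rotation R = Rz(alpha) Ry(beta) Rz(gamma)."""

    def rz(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(alpha) @ ry(beta) @ rz(gamma)


def wigner_rotate(coeffs: SHCoefficients, euler: tuple[float, float, float]) -> SHCoefficients:
    """Rotate an expansion: output f' satisfies f'(n) = f(R^-1 n).

    ``euler`` are ZYZ angles (alpha, beta, gamma) of the active rotation
    R = Rz(alpha) Ry(beta) Rz(gamma). Block-diagonal per degree; all
    rotational invariants are preserved.
    """
    alpha, beta, gamma = euler
    blocks: dict[int, np.ndarray] = {}
    for l in even_degrees(coeffs.lmax):
        c = coeffs.complex_block(l)
        blocks[l] = _wigner_D(l, alpha, beta, gamma) @ c
    return SHCoefficients.from_complex_blocks(coeffs.lmax, blocks)


def sample_so3_uniform(count: int, seed: int | np.random.Generator) -> np.ndarray:
    """ZYZ Euler angles drawn from the Haar measure on SO(3).

    alpha, gamma ~ U(0, 2pi); cos(beta) ~ U(-1, 1). Returns (count, 3).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = rng.uniform(0.0, 2.0 * math.pi, count)
    beta = np.arccos(rng.uniform(-1.0, 1.0, count))
    gamma = rng.uniform(0.0, 2.0 * math.pi, count)
    return np.stack([alpha, beta, gamma], axis=1)
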