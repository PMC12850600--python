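"""Kernel library, per-degree SVD factorization, Chebyshev interpolation.

The kernel invariants K_l(b | xi) are tabulated on Chebyshev nodes in b
(first kind, mapped to [0, bmax]) for a library of randomly sampled tissue
parameters, then factorized per degree by a truncated SVD

    K_l(b | xi) ~ sum_n s_n u_n(b) v_n(xi),

with u_n known on the nodes and extended to arbitrary b in [0, bmax] by
barycentric Chebyshev interpolation. The singular values decay roughly
exponentially, so a handful of components suffices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import kernel as kernel_mod
from .kernel import SMKernelParams, get_kernel
from .spherical import even_degrees

__all__ = [
    "LIBRARY_PRIORS",
    "KernelLibrary",
    "FactorizedBasis",
    "chebyshev_nodes",
    "build_library",
    "svd_factorize",
    "interp_u",
    "project_v",
    "sample_params",
]

#: library sampling ranges for the default kernel (f, Da, De_par, De_perp, fw)
LIBRARY_PRIORS: dict[str, tuple[float, float]] = {
    "f": (0.05, 0.95),
    "Da": (1.0, 3.0),
    "De_par": (1.0, 3.0),
    "De_perp": (0.1, 1.2),
    "fw": (0.0, 1.0),
}

DEFAULT_N_XI = 50_000
DEFAULT_N_B = 1000
DEFAULT_BMAX = 10.0
TEST_N_XI = 5000
TEST_N_B = 128


def chebyshev_nodes(n: int, bmax: float) -> np.ndarray:
    """Roots of the degree-n Chebyshev polynomial mapped to [0, bmax], ascending."""
    k = np.arange(n)
    x = np.cos((2 * k + 1) * np.pi / (2 * n))     # descending in (-1, 1)
    return (x[::-1] + 1.0) * 0.5 * bmax


def _barycentric_weights(n: int) -> np.ndarray:
    """Barycentric weights for first-kind Chebyshev nodes in ascending order."""
    k = np.arange(n)
    theta = (2 * k + 1) * np.pi / (2 * n)
    w = (-1.0) ** k * np.sin(theta)               # for descending nodes
    return w[::-1]


def sample_params(
    priors: dict[str, tuple[float, float]], count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform table (count, 5) over prior boxes with f + fw <= 1 by rejection."""
    lo = np.array([priors[k][0] for k in SMKernelParams.FIELDS])
    hi = np.array([priors[k][1] for k in SMKernelParams.FIELDS])
    if lo[0] + lo[4] > 1.0:
        raise ValueError("priors cannot satisfy f + fw <= 1")
    out = np.empty((0, 5))
    while out.shape[0] < count:
        draw = rng.uniform(lo, hi, size=(2 * count, 5))
        draw = draw[draw[:, 0] + draw[:, 4] <= 1.0]
        out = np.vstack([out, draw])
    return out[:count]


@dataclass
class KernelLibrary:
    """Tabulated K_l(b_i | xi_j) on Chebyshev nodes for a parameter table."""

    kernel_name: str
    b_nodes: np.ndarray                 # (N_b,), ascending
    bmax: float
    xi_table: np.ndarray                # (N_xi, 5)
    K: dict[int, np.ndarray]            # per even l: (N_b, N_xi)
    priors: dict[str, tuple[float, float]]
    seed: int

    @property
    def ells(self) -> list[int]:
        return sorted(self.K)


def build_library(
    kernel_name: str = "standard_model",
    priors: dict[str, tuple[float, float]] | None = None,
    n_xi: int = DEFAULT_N_XI,
    n_b: int = DEFAULT_N_B,
    bmax: float = DEFAULT_BMAX,
    lmax: int = 2,
    seed: int = 0,
) -> KernelLibrary:
    """Sample the prior box and tabulate kernel invariants on Chebyshev nodes."""
    priors = dict(LIBRARY_PRIORS if priors is None else priors)
    rng = np.random.default_rng(seed)
    table = sample_params(priors, n_xi, rng)
    b_nodes = chebyshev_nodes(n_b, bmax)
    kern = get_kernel(kernel_name)
    Kall = kern.invariants_table(b_nodes, table, lmax=lmax)   # (n_l, N_b, N_xi)
    if not np.all(np.isfinite(Kall)):
        raise ValueError("non-finite kernel library entries")
    K = {l: Kall[i] for i, l in enumerate(even_degrees(lmax))}
    return KernelLibrary(kernel_name, b_nodes, float(bmax), table, K, priors, seed)


@dataclass
class FactorizedBasis:
    """Truncated per-degree SVD triplets of a kernel library.

    Per degree l: singular values s (descending), left vectors u sampled at
    the Chebyshev nodes (N_b, N_l; orthonormal columns), right vectors v at
    the library samples (N_xi, N_l; orthonormal columns). Signs are fixed
    so the largest-magnitude element of each u_n is positive.
    """

    kernel_name: str
    b_nodes: np.ndarray
    bmax: float
    s: dict[int, np.ndarray]
    u: dict[int, np.ndarray]
    v: dict[int, np.ndarray]
    priors: dict[str, tuple[float, float]]
    seed: int
    recon_error: dict[int, float] = field(default_factory=dict)

    @property
    def ells(self) -> list[int]:
        return sorted(self.s)

    def n_components(self, l: int) -> int:
        return self.s[l].size

    @property
    def n_features(self) -> int:
        return sum(self.n_components(l) for l in self.ells)

    @property
    def n_columns(self) -> int:
        return sum(self.n_components(l) * (2 * l + 1) for l in self.ells)

    def provenance_id(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.kernel_name.encode())
        h.update(np.asarray(self.b_nodes).tobytes())
        for l in self.ells:
            h.update(self.s[l].tobytes())
            h.update(self.u[l].tobytes())
        return h.hexdigest()[:16]

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "format": "pipedmri-basis-v1",
            "kernel_name": self.kernel_name,
            "bmax": self.bmax,
            "priors": {k: list(v) for k, v in self.priors.items()},
            "seed": self.seed,
            "ells": self.ells,
            "recon_error": {str(k): v for k, v in self.recon_error.items()},
        }
        arrays = {"b_nodes": self.b_nodes, "meta": np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)}
        for l in self.ells:
            arrays[f"s_{l}"] = self.s[l]
            arrays[f"u_{l}"] = self.u[l]
            arrays[f"v_{l}"] = self.v[l]
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "FactorizedBasis":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            if meta.get("format") != "pipedmri-basis-v1":
                raise ValueError("unrecognized basis file format")
            ells = meta["ells"]
            return cls(
                kernel_name=meta["kernel_name"],
                b_nodes=z["b_nodes"],
                bmax=float(meta["bmax"]),
                s={l: z[f"s_{l}"] for l in ells},
                u={l: z[f"u_{l}"] for l in ells},
                v={l: z[f"v_{l}"] for l in ells},
                priors={k: tuple(v) for k, v in meta["priors"].items()},
                seed=int(meta["seed"]),
                recon_error={int(k): float(v) for k, v in meta["recon_error"].items()},
            )


def svd_factorize(
    library: KernelLibrary,
    n_components: int | dict[int, int] | None = None,
    energy_tol: float = 1e-6,
    max_components: int = 8,
) -> FactorizedBasis:
    """Truncated SVD of each per-degree library matrix.

    Truncation is by explicit per-degree counts or by relative energy
    tolerance (residual sum of s_n^2 below ``energy_tol`` of the total),
    hard-capped at ``max_components``.
    """
    s_d, u_d, v_d, err_d = {}, {}, {}, {}
    for l, M in library.K.items():
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        if isinstance(n_components, dict):
            nl = n_components[l]
        elif n_components is not None:
            nl = int(n_components)
        else:
            energy = np.cumsum(s**2) / np.sum(s**2)
            nl = min(int(np.searchsorted(energy, 1.0 - energy_tol) + 1), max_components)
        if nl > min(M.shape):
            raise ValueError(
                f"requested {nl} components for l={l}, library supports "
                f"at most {min(M.shape)}"
            )
        U, s, Vt = U[:, :nl], s[:nl], Vt[:nl]
        # sign convention: largest-|.| element of each u_n positive
        flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(nl)])
        U = U * flip
        Vt = Vt * flip[:, None]
        s_d[l], u_d[l], v_d[l] = s, U, Vt.T
        recon = (U * s) @ Vt
        err_d[l] = float(np.max(np.abs(recon - M)))
    return FactorizedBasis(
        kernel_name=library.kernel_name,
        b_nodes=library.b_nodes,
        bmax=library.bmax,
        s=s_d,
        u=u_d,
        v=v_d,
        priors=library.priors,
        seed=library.seed,
        recon_error=err_d,
    )


def _barycentric_matrix(b_nodes: np.ndarray, b: np.ndarray, bmax: float) -> np.ndarray:
    """Interpolation matrix A with A @ f(nodes) = f(b) (barycentric, exact at nodes)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < -1e-12) or np.any(b > bmax * (1 + 1e-12)):
        raise ValueError(f"b outside the interpolation range [0, {bmax}]")
    w = _barycentric_weights(b_nodes.size)
    diff = b[:, None] - b_nodes[None, :]
    exact_rows, exact_cols = np.nonzero(np.abs(diff) < 1e-12 * max(bmax, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        A = w[None, :] / diff
        A /= A.sum(axis=1, keepdims=True)
    if exact_rows.size:
        A[exact_rows] = 0.0
        A[exact_rows, exact_cols] = 1.0
    return A


def interp_u(
    basis: FactorizedBasis, l: int, b: np.ndarray, n: int | None = None
) -> np.ndarray:
    """Barycentric Chebyshev interpolation of u_n^(l) at b in [0, bmax].

    Returns (len(b), N_l) for all components, or (len(b),) for a single
    component index ``n`` (0-based). No extrapolation beyond [0, bmax].
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    A = _barycentric_matrix(basis.b_nodes, b, basis.bmax)
    U = basis.u[l] if n is None else basis.u[l][:, [n]]
    out = A @ U
    return out[:, 0] if n is not None else out


def project_v(
    basis: FactorizedBasis, xi: SMKernelParams | np.ndarray
) -> dict[int, np.ndarray]:
    """Right-basis coordinates v_n^(l)(xi) for arbitrary tissue parameters.

    Computes K_l at the Chebyshev nodes for each xi and projects onto the
    stored left vectors: v_n = u_n^T K / s_n. For in-library samples this
    reproduces the stored rows of v. ``xi`` may be a single parameter set
    or a table (S, 5); returns per degree an array (S, N_l) (or (N_l,)).
    """
    single = isinstance(xi, SMKernelParams)
    if single:
        xi.validate()
        table = xi.as_array()[None, :]
    else:
        table = np.atleast_2d(np.asarray(xi, dtype=float))
    kern = get_kernel(basis.kernel_name)
    lmax = max(basis.ells)
    Kall = kern.invariants_table(basis.b_nodes, table, lmax=lmax)
    out: dict[int, np.ndarray] = {}
    for i, l in enumerate(even_degrees(lmax)):
        if l not in basis.s:
            continue
        proj = (basis.u[l].T @ Kall[i])                    # (N_l, S)
        floor = 1e-14 * basis.s[l][0]
        small = basis.s[l] < floor
        if np.any(small):
            warnings.warn(
                f"dropping {int(small.sum())} numerically null components (l={l})",
                stacklevel=2,
            )
        v = np.where(small[:, None], 0.0, proj / np.where(small, 1.0, basis.s[l])[:, None])
        out[l] = v.T[0] if single else v.T
    return out


def reconstruct_K(
    basis: FactorizedBasis, l: int, b: np.ndarray, v_l: np.ndarray
) -> np.ndarray:
    """K_l(b | xi) rebuilt from the factorization: sum_n s_n u_n(b) v_n."""
    U = interp_u(basis, l, b)                              # (B, N_l)
    v_l = np.asarray(v_l, dtype=float)
    return (U * basis.s[l]) @ (v_l.T if v_l.ndim > 1 else v_l)
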