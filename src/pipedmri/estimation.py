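"""Voxelwise linear estimation of factorized tissue coefficients.

Each measurement of a voxel is modeled as

    S_k = sum_{n,l,m} alpha_nlm(b_k, g_k) gamma_nlm,
    alpha_nlm(b, g) = u_n^(l)(b) Y_lm(g),

so the per-voxel fit is a Moore-Penrose pseudoinverse applied to the
measurement vector. Voxels whose effective protocols agree after rounding
share a cached pseudoinverse. Rotational invariants gamma_nl and virtual
shell resampling are derived from the fitted coefficients.

Column ordering of the design matrix: degree l ascending, then component
n ascending, then order m = -l..l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import spherical
from .factorization import FactorizedBasis, interp_u
from .gnl import VoxelProtocol

__all__ = [
    "DesignMatrix",
    "GammaField",
    "ConditioningError",
    "design_matrix",
    "fit_gamma",
    "fit_volume",
    "gamma_invariants",
    "invariant_feature_names",
    "resample_signal",
]

PINV_RCOND = 1e-8
B_ROUND = 1e-4       # ms/um^2, protocol deduplication tolerance
G_ROUND = 1e-5
INVARIANT_FLOOR = 1e-9


class ConditioningError(RuntimeError):
    """Design matrix cannot resolve one or more (l, n) blocks."""


@dataclass
class DesignMatrix:
    """Protocol-specific design matrix alpha and its cached pseudoinverse."""

    alpha: np.ndarray                         # (K, C)
    columns: list[tuple[int, int, int]]       # (n, l, m) per column
    ells: list[int]
    n_per_l: dict[int, int]
    deficient_blocks: list[tuple[int, int]] = field(default_factory=list)
    _pinv: np.ndarray | None = None
    _cond: float | None = None

    @property
    def pinv(self) -> np.ndarray:
        if self._pinv is None:
            U, s, Vt = np.linalg.svd(self.alpha, full_matrices=False)
            keep = s > PINV_RCOND * s[0]
            self._pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
            self._cond = float(s[0] / s[keep][-1])
        return self._pinv

    @property
    def cond(self) -> float:
        _ = self.pinv
        return self._cond  # type: ignore[return-value]

    def block_slice(self, l: int, n: int) -> slice:
        start = 0
        for ll in self.ells:
            for nn in range(self.n_per_l[ll]):
                width = 2 * ll + 1
                if ll == l and nn == n:
                    return slice(start, start + width)
                start += width
        raise KeyError((l, n))


def design_matrix(basis: FactorizedBasis, b: np.ndarray, g: np.ndarray) -> DesignMatrix:
    """Build alpha_nlm(b_k, g_k) for one voxel's effective protocol.

    For l = 0 the columns are simply u_n(b_k) (Y_00 == 1). b = 0 rows are
    excluded from the direction-dependent (l > 0) columns: their direction
    is a placeholder. Rank-deficient (l, n) blocks (e.g. an l = 2 block
    with too few directions) are recorded in ``deficient_blocks``.
    """
    b = np.asarray(b, dtype=float).ravel()
    g = np.asarray(g, dtype=float).reshape(-1, 3)
    ells = basis.ells
    dw = b > 0
    cols: list[np.ndarray] = []
    index: list[tuple[int, int, int]] = []
    sh = {l: np.stack([spherical.sh_real(l, m, g) for m in range(-l, l + 1)], axis=1)
          for l in ells}
    for l in ells:
        U = interp_u(basis, l, b)                  # (K, N_l)
        for n in range(basis.n_components(l)):
            for im, m in enumerate(range(-l, l + 1)):
                col = U[:, n] * sh[l][:, im]
                if l > 0:
                    col = np.where(dw, col, 0.0)
                cols.append(col)
                index.append((n, l, m))
    alpha = np.stack(cols, axis=1)
    dm = DesignMatrix(
        alpha=alpha,
        columns=index,
        ells=list(ells),
        n_per_l={l: basis.n_components(l) for l in ells},
    )
    # conditioning check: rank of each whole-degree block across components
    # (shelled protocols with few distinct b cannot resolve all n jointly)
    for l in ells:
        nl = basis.n_components(l)
        lo = dm.block_slice(l, 0).start
        hi = dm.block_slice(l, nl - 1).stop
        blk = alpha[:, lo:hi]
        s = np.linalg.svd(blk, compute_uv=False)
        rank = int(np.sum(s > PINV_RCOND * max(s[0], 1e-30)))
        n_resolvable = rank // (2 * l + 1)
        for n in range(n_resolvable, nl):
            dm.deficient_blocks.append((l, n))
    return dm


def fit_gamma(design: DesignMatrix, signal: np.ndarray, check: bool = True) -> np.ndarray:
    """Least-squares gamma_nlm for one voxel: pinv(alpha) @ S."""
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != design.alpha.shape[0]:
        raise ValueError("signal length does not match design rows")
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite signal")
    if check and design.deficient_blocks:
        raise ConditioningError(
            f"design matrix deficient in (l, n) blocks {design.deficient_blocks}"
        )
    return signal @ design.pinv.T


@dataclass
class GammaField:
    """Fitted gamma coefficients over a voxel grid plus QC metadata."""

    gamma: np.ndarray                        # (*grid, C)
    columns: list[tuple[int, int, int]]
    ells: list[int]
    n_per_l: dict[int, int]
    mask: np.ndarray                         # (*grid,) bool
    basis_id: str
    cond: np.ndarray | None = None           # (*grid,)
    qc: dict = field(default_factory=dict)

    def invariants(self, floor: float = INVARIANT_FLOOR) -> np.ndarray:
        """Per-voxel gamma_nl features, shape (*grid, n_features); NaN = missing."""
        flat = self.gamma.reshape(-1, self.gamma.shape[-1])
        out = np.stack(
            [gamma_invariants(gv, self.ells, self.n_per_l, floor=floor) for gv in flat]
        )
        return out.reshape(*self.gamma.shape[:-1], -1)


def _protocol_key(b: np.ndarray, g: np.ndarray) -> bytes:
    bq = np.round(np.asarray(b) / B_ROUND).astype(np.int64)
    gq = np.round(np.asarray(g) / G_ROUND).astype(np.int64)
    return bq.tobytes() + gq.tobytes()


def fit_volume(
    basis: FactorizedBasis,
    data: np.ndarray,
    protocols: VoxelProtocol,
    mask: np.ndarray | None = None,
) -> GammaField:
    """Per-voxel gamma fit over a 4-D volume with pseudoinverse caching.

    Voxels whose effective protocols agree after rounding (b to 1e-4,
    directions to 1e-5) share one cached pseudoinverse. Per-voxel failures
    are collected in the QC report, not raised.
    """
    data = np.asarray(data, dtype=float)
    grid_shape = data.shape[:-1]
    K = data.shape[-1]
    if protocols.b.shape != (*grid_shape, K):
        raise ValueError("protocol shape does not match data")
    if mask is None:
        mask = np.ones(grid_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()

    flat_data = data.reshape(-1, K)
    flat_b = protocols.b.reshape(-1, K)
    flat_g = protocols.g.reshape(-1, K, 3)
    flat_mask = mask.reshape(-1)

    cache: dict[bytes, DesignMatrix] = {}
    C = basis.n_columns
    gamma = np.full((flat_data.shape[0], C), np.nan)
    cond = np.full(flat_data.shape[0], np.nan)
    errors: dict[int, str] = {}
    columns: list[tuple[int, int, int]] | None = None
    for vox in range(flat_data.shape[0]):
        if not flat_mask[vox]:
            continue
        S = flat_data[vox]
        if not np.all(np.isfinite(S)) or not np.any(S):
            flat_mask[vox] = False
            errors[vox] = "non-finite or all-zero signal"
            continue
        key = _protocol_key(flat_b[vox], flat_g[vox])
        dm = cache.get(key)
        if dm is None:
            try:
                dm = design_matrix(basis, flat_b[vox], flat_g[vox])
            except ValueError as exc:
                flat_mask[vox] = False
                errors[vox] = str(exc)
                continue
            cache[key] = dm
        try:
            gamma[vox] = fit_gamma(dm, S)
            cond[vox] = dm.cond
        except (ConditioningError, ValueError) as exc:
            flat_mask[vox] = False
            errors[vox] = str(exc)
    any_dm = next(iter(cache.values()), None)
    if any_dm is not None:
        columns = any_dm.columns
        ells, n_per_l = any_dm.ells, any_dm.n_per_l
    else:
        ells = basis.ells
        n_per_l = {l: basis.n_components(l) for l in ells}
        columns = [
            (n, l, m) for l in ells for n in range(n_per_l[l]) for m in range(-l, l + 1)
        ]
    return GammaField(
        gamma=gamma.reshape(*grid_shape, C),
        columns=columns,
        ells=ells,
        n_per_l=n_per_l,
        mask=flat_mask.reshape(grid_shape),
        basis_id=basis.provenance_id(),
        cond=cond.reshape(grid_shape),
        qc={"n_unique_protocols": len(cache), "errors": errors},
    )


def _split_blocks(
    gamma: np.ndarray, ells: list[int], n_per_l: dict[int, int]
) -> dict[int, np.ndarray]:
    """gamma vector (..., C) -> per degree arrays (..., N_l, 2l+1)."""
    out = {}
    start = 0
    for l in ells:
        width = n_per_l[l] * (2 * l + 1)
        blk = gamma[..., start : start + width]
        out[l] = blk.reshape(*gamma.shape[:-1], n_per_l[l], 2 * l + 1)
        start += width
    return out


def gamma_invariants(
    gamma: np.ndarray,
    ells: list[int],
    n_per_l: dict[int, int],
    floor: float = INVARIANT_FLOOR,
) -> np.ndarray:
    """Rotational invariants gamma_nl from one voxel's gamma_nlm.

    gamma_1l is the m-norm sqrt(sum_m gamma_1lm^2 / (2l+1)); higher-n
    invariants are gamma_1l times the average over m of the ratios
    gamma_nlm / gamma_1lm, weighted by gamma_1lm^2 (equal to the plain
    average for exact coefficients, but without small denominators it is
    stable against noise and truncation error). Ratios are
    rotation-invariant and keep relative signs. When gamma_1l falls below
    ``floor`` the degree's invariants are NaN (missing), since the ratio
    is undefined.

    Supports leading batch axes on ``gamma``. Feature ordering: l
    ascending, then n ascending.
    """
    gamma = np.asarray(gamma, dtype=float)
    blocks = _split_blocks(gamma, ells, n_per_l)
    feats = []
    for l in ells:
        blk = blocks[l]                                   # (..., N_l, 2l+1)
        g1 = blk[..., 0, :]
        denom = np.sum(g1**2, axis=-1)
        g1l = np.sqrt(denom / (2 * l + 1))
        ok = g1l > floor
        feats.append(np.where(ok, g1l, np.nan))
        for n in range(1, n_per_l[l]):
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.sum(blk[..., n, :] * g1, axis=-1) / denom
            feats.append(np.where(ok, g1l * ratio, np.nan))
    return np.stack(feats, axis=-1)


def invariant_feature_names(ells: list[int], n_per_l: dict[int, int]) -> list[str]:
    return [f"gamma_{n + 1}{l}" for l in ells for n in range(n_per_l[l])]


def resample_signal(
    gamma: np.ndarray,
    ells: list[int],
    n_per_l: dict[int, int],
    basis: FactorizedBasis,
    b_targets: np.ndarray,
    directions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Virtual-shell resampling of fitted voxels.

    Evaluates S(b, g) = alpha(b, g) gamma on each target b over a uniform
    direction set and projects onto SH per shell. Returns

    - signals, shape (..., n_b, n_dirs)
    - invariants S_l(b), shape (..., n_b, n_ells) (m-norm per degree).

    ``gamma`` may carry leading batch axes.
    """
    gamma = np.asarray(gamma, dtype=float)
    b_targets = np.atleast_1d(np.asarray(b_targets, dtype=float))
    directions = np.asarray(directions, dtype=float)
    blocks = _split_blocks(gamma, ells, n_per_l)
    sh = {
        l: np.stack([spherical.sh_real(l, m, directions) for m in range(-l, l + 1)], axis=0)
        for l in ells
    }   # (2l+1, D)
    nb, nd = b_targets.size, directions.shape[0]
    signals = np.zeros((*gamma.shape[:-1], nb, nd))
    invs = np.zeros((*gamma.shape[:-1], nb, len(ells)))
    for il, l in enumerate(ells):
        U = interp_u(basis, l, b_targets)                  # (nb, N_l)
        # S_lm(b) = sum_n u_n(b) gamma_nlm
        S_lm = np.einsum("bn,...nm->...bm", U, blocks[l])  # (..., nb, 2l+1)
        signals += np.einsum("...bm,md->...bd", S_lm, sh[l])
        invs[..., il] = np.sqrt(np.sum(S_lm**2, axis=-1) / (2 * l + 1))
    return signals, invs
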