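"""Training-set generation in factorized coefficient space and regression.

Training samples live directly in gamma space: gamma_nlm = s_n v_n(xi) p_lm,
with tissue parameters drawn from independent uniform priors and fODFs
built as mixtures of two axially symmetric lobes with geometrically
decaying invariants p_l = C lambda^l, each lobe rotated uniformly over
SO(3). Because the features are protocol-free, the regressor is trained
once and serves voxels with arbitrarily different protocols.

The regressor is an ordinary-least-squares polynomial of total degree W
(default 3) on standardized features, fitted per target.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import spherical
from .estimation import design_matrix, gamma_invariants, invariant_feature_names
from .factorization import FactorizedBasis, project_v, sample_params
from .kernel import SMKernelParams
from .spherical import SHCoefficients, even_degrees, sh_index

__all__ = [
    "TRAINING_PRIORS",
    "FODFSample",
    "TrainingSet",
    "TrainedRegressor",
    "sample_kernel_priors",
    "sample_fodf",
    "sample_fodf_batch",
    "make_training_set",
    "fit_polynomial",
    "predict",
]

#: independent uniform priors for training (f, Da, De_par, De_perp, fw)
TRAINING_PRIORS: dict[str, tuple[float, float]] = {
    "f": (0.05, 0.95),
    "Da": (0.5, 3.0),
    "De_par": (0.5, 3.0),
    "De_perp": (0.1, 1.5),
    "fw": (0.0, 1.0),
}

P2_RANGE = (0.02, 0.9)
LAMBDA_RANGE = (0.5, 0.9)
FODF_LMAX = 6


def sample_kernel_priors(
    count: int,
    seed: int | np.random.Generator,
    priors: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Uniform prior table (count, 5) with f + fw <= 1 enforced by rejection."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_params(TRAINING_PRIORS if priors is None else priors, count, rng)


# ---------------------------------------------------------------------------
# fODF sampling


@dataclass
class FODFSample:
    """Two-lobe fODF with its generating parameters."""

    coeffs: SHCoefficients
    p2: tuple[float, float]
    lam: tuple[float, float]
    weight: float
    euler: tuple[tuple[float, float, float], tuple[float, float, float]]


def _wigner_d_m0_batch(l: int, beta: np.ndarray) -> np.ndarray:
    """d^l_{m',0}(beta) for all m', vectorized over beta: shape (B, 2l+1)."""
    fact = [math.factorial(k) for k in range(2 * l + 1)]
    cb, sb = np.cos(beta / 2.0), np.sin(beta / 2.0)
    out = np.zeros((beta.size, 2 * l + 1))
    for mp in range(-l, l + 1):
        pref = math.sqrt(fact[l + mp] * fact[l - mp]) * fact[l]
        s_min = max(0, -mp)
        s_max = min(l, l - mp)
        tot = np.zeros(beta.size)
        for s in range(s_min, s_max + 1):
            den = fact[l - s] * fact[s] * fact[mp + s] * fact[l - mp - s]
            tot += ((-1.0) ** (mp + s) / den) * cb ** (2 * l - mp - 2 * s) * sb ** (mp + 2 * s)
        out[:, mp + l] = pref * tot
    return out


def _rotated_axial_blocks(
    p_l: np.ndarray, euler: np.ndarray, lmax: int
) -> np.ndarray:
    """Real p_lm of z-aligned axial lobes rotated by ZYZ Euler angles.

    ``p_l`` is (B, n_even_l) of per-degree invariants (degree 0 included,
    = 1); ``euler`` is (B, 3). Returns (B, n_coeffs(lmax)) real
    coefficients. For an axial lobe only the m = 0 column of the Wigner
    matrix enters, and the third Euler angle drops out.
    """
    B = euler.shape[0]
    alpha, beta = euler[:, 0], euler[:, 1]
    out = np.zeros((B, spherical.n_coeffs(lmax)))
    for il, l in enumerate(even_degrees(lmax)):
        c_l0 = math.sqrt(2 * l + 1) * p_l[:, il]          # complex m=0 coefficient
        d = _wigner_d_m0_batch(l, beta)                   # (B, 2l+1)
        i0 = sh_index(l, -l)
        for m in range(-l, l + 1):
            # c'_m = exp(-i m alpha) d_{m,0} c_l0
            re = np.cos(m * alpha) * d[:, m + l] * c_l0
            im = -np.sin(m * alpha) * d[:, m + l] * c_l0
            if m == 0:
                out[:, i0 + l] = re
            elif m > 0:
                out[:, i0 + l + m] = math.sqrt(2.0) * (-1) ** m * re
            else:
                am = -m
                re_p = np.cos(am * alpha) * d[:, am + l] * c_l0
                im_p = -np.sin(am * alpha) * d[:, am + l] * c_l0
                out[:, i0 + l + m] = -math.sqrt(2.0) * (-1) ** am * im_p
    return out


def sample_fodf_batch(
    count: int, seed: int | np.random.Generator, lmax: int = FODF_LMAX
) -> tuple[np.ndarray, pd.DataFrame]:
    """Vectorized two-lobe fODF sampler.

    Per lobe: p_2 ~ U(0.02, 0.9), lambda ~ U(0.5, 0.9), with
    p_l = C lambda^l and C = p_2 / lambda^2 so the drawn p_2 is the lobe's
    degree-2 invariant; each lobe is rotated by an SO(3)-uniform rotation
    and the two are mixed with weight w ~ U(0, 1). p_00 = 1 always.

    Returns (coefficients (count, n_coeffs), parameter table).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ells = even_degrees(lmax)
    blocks = []
    params = {}
    eulers = []
    for lobe in (1, 2):
        p2 = rng.uniform(*P2_RANGE, count)
        lam = rng.uniform(*LAMBDA_RANGE, count)
        C = p2 / lam**2
        p_l = np.stack(
            [np.ones(count) if l == 0 else C * lam**l for l in ells], axis=1
        )
        euler = spherical.sample_so3_uniform(count, rng)
        blocks.append(_rotated_axial_blocks(p_l, euler, lmax))
        params[f"p2_{lobe}"] = p2
        params[f"lambda_{lobe}"] = lam
        eulers.append(euler)
    w = rng.uniform(0.0, 1.0, count)
    coeffs = w[:, None] * blocks[0] + (1.0 - w)[:, None] * blocks[1]
    coeffs[:, 0] = 1.0  # p_00, exact
    params["weight"] = w
    table = pd.DataFrame(params)
    for i, name in enumerate(("alpha", "beta", "gamma")):
        table[f"{name}_1"] = eulers[0][:, i]
        table[f"{name}_2"] = eulers[1][:, i]
    return coeffs, table


def sample_fodf(seed: int | np.random.Generator, lmax: int = FODF_LMAX) -> FODFSample:
    """Draw a single two-lobe fODF (see :func:`sample_fodf_batch`)."""
    coeffs, tab = sample_fodf_batch(1, seed, lmax=lmax)
    row = tab.iloc[0]
    return FODFSample(
        coeffs=SHCoefficients(lmax, coeffs[0]),
        p2=(row.p2_1, row.p2_2),
        lam=(row.lambda_1, row.lambda_2),
        weight=row.weight,
        euler=(
            (row.alpha_1, row.beta_1, row.gamma_1),
            (row.alpha_2, row.beta_2, row.gamma_2),
        ),
    )


# ---------------------------------------------------------------------------
# training sets


@dataclass
class TrainingSet:
    """Feature and target tables plus generation provenance."""

    features: np.ndarray                  # (S, F)
    feature_names: list[str]
    targets: pd.DataFrame                 # xi columns + p_l columns
    feature_kind: str                     # "gamma_nlm" | "gamma_nl"
    basis_id: str
    noise_config: dict | None
    seed: int
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)


def _gamma_from_parts(
    basis: FactorizedBasis, v: dict[int, np.ndarray], p: np.ndarray
) -> np.ndarray:
    """gamma_nlm = s_n v_n(xi) p_lm, column order (l asc, n asc, m asc)."""
    cols = []
    for l in basis.ells:
        i0 = sh_index(l, -l)
        p_block = p[:, i0 : i0 + 2 * l + 1]               # (S, 2l+1)
        sv = basis.s[l] * v[l]                            # (S, N_l)
        for n in range(basis.n_components(l)):
            cols.append(sv[:, [n]] * p_block)
    return np.concatenate(cols, axis=1)


def make_training_set(
    basis: FactorizedBasis,
    n_samples: int,
    noise_config: dict | None = None,
    seed: int = 0,
    feature_kind: str = "gamma_nl",
    priors: dict[str, tuple[float, float]] | None = None,
) -> TrainingSet:
    """Generate protocol-free training data in gamma space.

    ``noise_config``: None for noiseless features, or
    ``{"snr": value, "b": ..., "g": ...}`` to add Gaussian measurement
    noise at the given b=0-referenced SNR propagated through the
    pseudoinverse of the reference protocol's design matrix.
    """
    if feature_kind not in ("gamma_nlm", "gamma_nl"):
        raise ValueError("feature_kind must be 'gamma_nlm' or 'gamma_nl'")
    rng = np.random.default_rng(seed)
    priors = dict(TRAINING_PRIORS if priors is None else priors)
    xi = sample_params(priors, n_samples, rng)
    lmax = max(basis.ells)
    p, _fodf_params = sample_fodf_batch(n_samples, rng, lmax=max(lmax, 2))
    p = p[:, : spherical.n_coeffs(lmax)]
    v = project_v(basis, xi)
    gamma = _gamma_from_parts(basis, v, p)

    if noise_config is not None:
        snr = float(noise_config["snr"])
        dm = design_matrix(basis, noise_config["b"], noise_config["g"])
        eps = rng.normal(scale=1.0 / snr, size=(n_samples, dm.alpha.shape[0]))
        gamma = gamma + eps @ dm.pinv.T

    ells = basis.ells
    n_per_l = {l: basis.n_components(l) for l in ells}
    if feature_kind == "gamma_nl":
        features = gamma_invariants(gamma, ells, n_per_l)
        feature_names = invariant_feature_names(ells, n_per_l)
    else:
        features = gamma
        feature_names = [
            f"gamma_{n + 1}{l}{m:+d}"
            for l in ells
            for n in range(n_per_l[l])
            for m in range(-l, l + 1)
        ]

    targets = pd.DataFrame(xi, columns=list(SMKernelParams.FIELDS))
    for l in ells:
        if l == 0:
            continue
        i0 = sh_index(l, -l)
        pb = p[:, i0 : i0 + 2 * l + 1]
        targets[f"p{l}"] = np.sqrt(np.sum(pb**2, axis=1) / (2 * l + 1))
    return TrainingSet(
        features=features,
        feature_names=feature_names,
        targets=targets,
        feature_kind=feature_kind,
        basis_id=basis.provenance_id(),
        noise_config=None if noise_config is None else {"snr": float(noise_config["snr"])},
        seed=seed,
        priors=priors,
    )


# ---------------------------------------------------------------------------
# polynomial regression


def _monomial_powers(n_features: int, degree: int) -> np.ndarray:
    """Exponent matrix (n_monomials, n_features), total degree <= degree."""
    powers = []
    for d in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_features), d):
            row = np.zeros(n_features, dtype=int)
            for i in combo:
                row[i] += 1
            powers.append(row)
    return np.array(powers)


def _monomial_design(x: np.ndarray, powers: np.ndarray) -> np.ndarray:
    out = np.ones((x.shape[0], powers.shape[0]))
    for j, row in enumerate(powers):
        for i, e in enumerate(row):
            if e:
                out[:, j] *= x[:, i] ** e
    return out


@dataclass
class TrainedRegressor:
    """Per-target polynomial coefficients on standardized gamma features."""

    degree: int
    feature_names: list[str]
    feature_kind: str
    target_names: list[str]
    powers: np.ndarray                    # (n_monomials, F)
    coeffs: np.ndarray                    # (n_monomials, T)
    feature_mean: np.ndarray
    feature_std: np.ndarray
    clamp: dict[str, tuple[float, float]]
    basis_id: str
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "format": "pipedmri-regressor-v1",
            "degree": self.degree,
            "feature_names": self.feature_names,
            "feature_kind": self.feature_kind,
            "target_names": self.target_names,
            "powers": self.powers.tolist(),
            "coeffs": self.coeffs.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "clamp": {k: list(v) for k, v in self.clamp.items()},
            "basis_id": self.basis_id,
            "provenance": self.provenance,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainedRegressor":
        d = json.loads(text)
        if d.get("format") != "pipedmri-regressor-v1":
            raise ValueError("unrecognized regressor file format")
        return cls(
            degree=d["degree"],
            feature_names=d["feature_names"],
            feature_kind=d["feature_kind"],
            target_names=d["target_names"],
            powers=np.array(d["powers"], dtype=int),
            coeffs=np.array(d["coeffs"]),
            feature_mean=np.array(d["feature_mean"]),
            feature_std=np.array(d["feature_std"]),
            clamp={k: tuple(v) for k, v in d["clamp"].items()},
            basis_id=d["basis_id"],
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "TrainedRegressor":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_polynomial(train: TrainingSet, degree: int = 3) -> TrainedRegressor:
    """OLS polynomial regression of total degree <= ``degree`` per target.

    Features are standardized before monomial expansion; rows with missing
    features are dropped. Solved by SVD-backed least squares.
    """
    x = np.asarray(train.features, dtype=float)
    y = train.targets.to_numpy(dtype=float)
    ok = np.all(np.isfinite(x), axis=1) & np.all(np.isfinite(y), axis=1)
    if not np.all(ok):
        warnings.warn(f"dropping {int((~ok).sum())} samples with missing features")
        x, y = x[ok], y[ok]
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    xs = (x - mean) / std
    powers = _monomial_powers(x.shape[1], degree)
    if x.shape[0] < 2 * powers.shape[0]:
        warnings.warn("few samples relative to the number of monomials")
    design = _monomial_design(xs, powers)
    coeffs, *_ = np.linalg.lstsq(design, y, rcond=None)
    clamp = {k: tuple(v) for k, v in train.priors.items()}
    for name in train.targets.columns:
        if name.startswith("p") and name[1:].isdigit():
            clamp[name] = (0.0, 1.0)
    return TrainedRegressor(
        degree=degree,
        feature_names=list(train.feature_names),
        feature_kind=train.feature_kind,
        target_names=list(train.targets.columns),
        powers=powers,
        coeffs=coeffs,
        feature_mean=mean,
        feature_std=std,
        clamp=clamp,
        basis_id=train.basis_id,
        provenance={"seed": train.seed, "noise": train.noise_config,
                    "n_samples": int(x.shape[0])},
    )


def predict(
    regressor: TrainedRegressor,
    features: np.ndarray,
    basis_id: str | None = None,
    clamp: bool = True,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Apply the regressor to per-voxel gamma features.

    Returns (predictions DataFrame, QC dict with ``missing`` and
    ``clamped`` boolean arrays). Rows with missing (NaN) features are not
    predicted. A basis/regressor provenance mismatch is a hard error.
    """
    if basis_id is not None and basis_id != regressor.basis_id:
        raise ValueError(
            "gamma features come from a different factorized basis than the "
            "regressor was trained on"
        )
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != len(regressor.feature_names):
        raise ValueError("feature count mismatch")
    missing = ~np.all(np.isfinite(x), axis=1)
    out = np.full((x.shape[0], len(regressor.target_names)), np.nan)
    clamped = np.zeros(x.shape[0], dtype=bool)
    if np.any(~missing):
        xs = (x[~missing] - regressor.feature_mean) / regressor.feature_std
        design = _monomial_design(xs, regressor.powers)
        pred = design @ regressor.coeffs
        if clamp:
            for j, name in enumerate(regressor.target_names):
                if name in regressor.clamp:
                    lo, hi = regressor.clamp[name]
                    hit = (pred[:, j] < lo) | (pred[:, j] > hi)
                    pred[:, j] = np.clip(pred[:, j], lo, hi)
                    tmp = np.zeros(x.shape[0], dtype=bool)
                    tmp[~missing] = hit
                    clamped |= tmp
        out[~missing] = pred
    df = pd.DataFrame(out, columns=regressor.target_names)
    return df, {"missing": missing, "clamped": clamped}
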