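"""Diffusion-geometry embedding of single-cell feature space ("cell cycle map").

The embedding follows the potential-of-heat-diffusion construction: an
alpha-decay kernel with adaptive k-nearest-neighbor bandwidths, row
normalization into a Markov diffusion operator, diffusion over t steps, a
potential transform of the t-step transition probabilities (log potential at
gamma = 1, a power-law potential otherwise), and a stress-minimizing 2-d
projection of the potential distances (classical MDS initialization followed
by SMACOF iterations). Everything is computed densely and exactly — the
intended problem sizes (up to a few tens of thousands of cells in the
original study, a few thousand in the synthetic tests) do not require
landmarking or approximate neighbor search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import FeatureTable, PipelineConfig

logger = logging.getLogger("arrestmap")

#: floor inside the log-potential transform (machine-epsilon scaled)
LOG_EPS = float(np.finfo(float).eps)


@dataclass
class EmbeddingParams:
    """knn/t/gamma parameter set (e.g. knn=150, t=20, gamma=1 for the
    reference proliferative map)."""

    knn: int = 150
    t: int = 20
    gamma: float = 1.0
    decay_alpha: float = 40.0
    dims: int = 2
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.knn < 2:
            raise ValueError("knn must be >= 2")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [-1, 1]")
        if self.dims != 2:
            raise ValueError("output dims must be 2")


@dataclass
class DiffusionOperator:
    """Row-stochastic diffusion operator P with its symmetric kernel K."""

    P: np.ndarray
    K: np.ndarray

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution of P (degree-proportional, P is
        reversible with respect to it)."""
        d = self.K.sum(axis=1)
        return d / d.sum()


@dataclass
class Embedding:
    coordinates: np.ndarray
    params: EmbeddingParams
    stress: float
    feature_list: tuple[str, ...] = field(default_factory=tuple)


def build_kernel(X: np.ndarray, knn: int, decay_alpha: float = 40.0) -> np.ndarray:
    """Symmetrized alpha-decay kernel with adaptive knn bandwidths.

    K_ij = 1/2 [exp(-(d_ij/sigma_i)^alpha) + exp(-(d_ij/sigma_j)^alpha)] with
    sigma_i the Euclidean distance from cell i to its knn-th neighbor.
    Duplicate points that would give sigma_i = 0 fall back to the smallest
    positive neighbor distance (logged).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X must not contain missing values")
    n = len(X)
    if n <= knn:
        raise ValueError(f"need more cells ({n}) than knn ({knn})")
    D = cdist(X, X)
    Dsorted = np.sort(D, axis=1)
    sigma = Dsorted[:, knn]  # column 0 is the self-distance
    zero = sigma == 0
    if zero.any():
        logger.warning("%d cells have sigma=0 (duplicates); using smallest "
                       "positive neighbor distance", int(zero.sum()))
        for i in np.flatnonzero(zero):
            pos = Dsorted[i][Dsorted[i] > 0]
            if len(pos) == 0:
                raise ValueError(f"cell {i} is identical to every other cell")
            sigma[i] = pos[0]
    with np.errstate(divide="ignore"):
        A = np.exp(-((D / sigma[:, None]) ** decay_alpha))
    K = 0.5 * (A + A.T)
    np.fill_diagonal(K, 1.0)
    return K


def diffusion_operator(K: np.ndarray) -> DiffusionOperator:
    """Row-normalize a symmetric non-negative kernel into a Markov operator."""
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-12):
        raise ValueError("kernel must be symmetric")
    if (K < 0).any():
        raise ValueError("kernel must be non-negative")
    rowsum = K.sum(axis=1)
    dead = np.flatnonzero(rowsum == 0)
    if len(dead):
        raise ValueError(f"isolated cells with zero kernel row sum: {dead.tolist()}")
    P = K / rowsum[:, None]
    return DiffusionOperator(P=P, K=K)


def potential_distances(
    operator: DiffusionOperator,
    t: int,
    gamma: float = 1.0,
    eps: float = LOG_EPS,
) -> np.ndarray:
    """Euclidean distances between potential representations of P^t rows.

    gamma = 1 uses the log potential U = -log(P^t + eps); other gamma use the
    power-law potential U = 2/(1-gamma) * (P^t)^((1-gamma)/2). The result is
    symmetric with a zero diagonal and satisfies the triangle inequality
    (it is a Euclidean embedding distance by construction).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if eps <= 0:
        raise ValueError("eps must be positive")
    Pt = np.linalg.matrix_power(operator.P, t)
    if gamma == 1.0:
        U = -np.log(Pt + eps)
    else:
        U = 2.0 / (1.0 - gamma) * Pt ** ((1.0 - gamma) / 2.0)
    Dist = cdist(U, U)
    Dist = 0.5 * (Dist + Dist.T)
    np.fill_diagonal(Dist, 0.0)
    return Dist


def _classical_mds(Dist: np.ndarray, dims: int) -> np.ndarray:
    n = len(Dist)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dist ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    # deterministic sign convention
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    return coords


def embed(
    distances: np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> Embedding:
    """Stress-minimizing 2-d layout of a distance matrix.

    Classical MDS provides the initial configuration; Guttman-transform
    (SMACOF) iterations then monotonically decrease the raw stress. The
    procedure is deterministic for a given input; ``seed`` is recorded for
    provenance.
    """
    Dist = np.asarray(distances, dtype=float)
    if not np.isfinite(Dist).all():
        raise ValueError("distance matrix contains non-finite entries")
    n = len(Dist)
    X = _classical_mds(Dist, dims)

    def stress_of(coords: np.ndarray) -> tuple[float, np.ndarray]:
        E = cdist(coords, coords)
        s = float(np.sum((Dist - E) ** 2) / 2.0)
        return s, E

    stress, E = stress_of(X)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(E > 0, Dist / E, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = (B @ X) / n
        new_stress, E_new = stress_of(X_new)
        if new_stress > stress:  # SMACOF guarantees non-increase; stop if flat
            break
        X, E = X_new, E_new
        if stress - new_stress < tol * max(stress, 1.0):
            stress = new_stress
            break
        stress = new_stress
    norm = np.sum(Dist ** 2) / 2.0
    final_stress = np.sqrt(stress / norm) if norm > 0 else 0.0
    params = EmbeddingParams(knn=2, seed=seed)  # placeholder; map_cells overwrites
    return Embedding(coordinates=X, params=params, stress=float(final_stress))


def map_cells(
    table: FeatureTable,
    params: EmbeddingParams,
    feature_list: tuple[str, ...] | None = None,
) -> Embedding:
    """Full pipeline: kernel -> operator -> potential distances -> embedding."""
    feats = tuple(feature_list) if feature_list else tuple(table.feature_names)
    X = table.data[list(feats)].to_numpy(dtype=float)
    K = build_kernel(X, params.knn, params.decay_alpha)
    op = diffusion_operator(K)
    Dist = potential_distances(op, params.t, params.gamma)
    emb = embed(Dist, dims=params.dims, seed=params.seed)
    emb.params = params
    emb.feature_list = feats
    logger.info(
        "embedded %d cells (knn=%d, t=%d, gamma=%g): stress %.4g",
        len(X), params.knn, params.t, params.gamma, emb.stress,
    )
    return emb


def operator_for_config(table: FeatureTable, config: PipelineConfig) -> DiffusionOperator:
    """Convenience: diffusion operator from a pipeline config's feature list."""
    feats = config.embedding_features or tuple(table.feature_names)
    X = table.data[list(feats)].to_numpy(dtype=float)
    K = build_kernel(X, config.knn, config.decay_alpha)
    return diffusion_operator(K)
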