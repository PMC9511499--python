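"""Diffusion pseudotime, arrest branches, trajectory profiles and scores.

Diffusion pseudotime (DPT) orders cells by their accumulated random-walk
transition distance from a root cell. With P the diffusion operator and Pi
the projection onto its stationary distribution, the accumulated transition
matrix is M = (I - (P - Pi))^-1 - I, which equals the series
sum_{s>=1} (P^s - Pi); dpt(x, y) is the Euclidean distance between rows of M.
The pseudotime of a cell is its dpt distance from the root, rescaled to
[0, 1] by the maximum.

Branch assignment is anchor-supervised: each arrest branch is designated by
an endpoint (anchor) cell and every cell joins the branch whose anchor is
nearest in dpt distance — branching structure is resolved by where random
walks end up, not by unsupervised branch detection.

Feature dynamics along a branch are profiled by binning pseudotime into
equal-width bins, keeping bins with at least 15 cells, and ordering features
by hierarchical clustering of their binned profiles (average linkage,
correlation distance) with a deterministic earlier-centroid-first leaf
rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components

from .io import FeatureTable
from .manifold import DiffusionOperator

logger = logging.getLogger("arrestmap")


@dataclass
class PseudotimeResult:
    root_id: str
    pseudotime: np.ndarray  # in [0, 1], 0 at the root
    branch: np.ndarray | None = None

    def __post_init__(self) -> None:
        pt = np.asarray(self.pseudotime, dtype=float)
        if pt.min() < -1e-12 or pt.max() > 1 + 1e-12:
            raise ValueError("pseudotime must lie in [0, 1]")


@dataclass
class TrajectoryProfile:
    """bins x features mean-intensity matrix for one branch."""

    matrix: pd.DataFrame          # index: retained bin index, columns: features
    counts: np.ndarray            # per-bin cell counts, length n_bins
    bin_edges: np.ndarray
    n_bins: int
    min_cells: int = 15
    feature_order: list[str] | None = None

    @property
    def retained_bins(self) -> np.ndarray:
        return self.matrix.index.to_numpy()

    @property
    def excluded_bins(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_bins), self.retained_bins)


#: Senescence marker signature: features elevated (+1) or depressed (-1) in
#: the senescent state, applied to control-z-normalized values.
DEFAULT_SENESCENCE_SIGNATURE = (
    ("gsk3b_nucleus_median", +1),
    ("phospho_t157_p27_nucleus_median", +1),
    ("p27_nucleus_median", +1),
    ("cdk4_nucleus_median", +1),
    ("cyclin_d1_nucleus_median", +1),
    ("cyclin_e_nucleus_median", +1),
    ("morphology_cell_area", +1),
    ("dna_cytoplasm_cell_ratio", -1),
)


# ---------------------------------------------------------------------------
# Diffusion pseudotime
# ---------------------------------------------------------------------------

def accumulated_transitions(operator: DiffusionOperator) -> np.ndarray:
    """M = (I - (P - Pi))^-1 - I on the non-stationary subspace.

    Raises on a disconnected neighbor graph (DPT distances are undefined
    across components), listing component sizes.
    """
    K = operator.K
    n_comp, labels = connected_components(K > 1e-12, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"neighbor graph is disconnected: component sizes {sizes}")
    P = operator.P
    n = len(P)
    pi = operator.stationary
    Pi = np.tile(pi, (n, 1))
    M = np.linalg.inv(np.eye(n) - (P - Pi)) - np.eye(n)
    return M


def dpt_distances(M: np.ndarray) -> np.ndarray:
    """Full cell x cell DPT distance matrix (Euclidean between rows of M)."""
    from scipy.spatial.distance import cdist

    D = cdist(M, M)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def dpt_from(M: np.ndarray, index: int) -> np.ndarray:
    """DPT distances from one cell to all cells."""
    diff = M - M[index]
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def diffusion_pseudotime(
    operator: DiffusionOperator,
    root: int,
    root_id: str | None = None,
) -> PseudotimeResult:
    """Pseudotime = dpt distance from the root, rescaled to [0, 1]."""
    M = accumulated_transitions(operator)
    d = dpt_from(M, root)
    top = d.max()
    pt = d / top if top > 0 else d
    return PseudotimeResult(root_id=root_id or str(root), pseudotime=pt)


def select_root(
    dna: np.ndarray,
    rb_ratio: np.ndarray,
    candidate_mask: np.ndarray,
) -> int:
    """Default root: the early-G1 anchor among candidate (G1 cycling) cells.

    Ranks candidates by low DNA content and high phospho/total RB (z-scored
    within the candidate set) and returns the global index of the best one.
    """
    idx = np.flatnonzero(candidate_mask)
    if len(idx) == 0:
        raise ValueError("no candidate root cells")
    d = np.asarray(dna, dtype=float)[idx]
    r = np.asarray(rb_ratio, dtype=float)[idx]
    z = lambda x: (x - x.mean()) / (x.std() or 1.0)  # noqa: E731
    score = z(d) - z(r)
    return int(idx[np.argmin(score)])


# ---------------------------------------------------------------------------
# Branch assignment
# ---------------------------------------------------------------------------

def assign_branches(
    dpt: np.ndarray,
    endpoints: dict[str, int],
) -> np.ndarray:
    """Assign every cell to the branch of its dpt-nearest anchor.

    ``endpoints`` maps branch label -> anchor cell index; ties go to the
    branch listed first. Coincident anchors (dpt distance 0 apart) are an
    error because they make the partition ill-defined.
    """
    if len(endpoints) < 2:
        raise ValueError("need at least 2 branch anchors")
    labels = list(endpoints)
    anchors = np.array([endpoints[b] for b in labels])
    for a in range(len(anchors)):
        for b in range(a + 1, len(anchors)):
            if dpt[anchors[a], anchors[b]] == 0 and anchors[a] != anchors[b]:
                raise ValueError(
                    f"anchors {labels[a]!r} and {labels[b]!r} are coincident"
                )
    dist_to_anchor = dpt[:, anchors]  # cells x branches
    best = np.argmin(dist_to_anchor, axis=1)  # argmin takes the first on ties
    out = np.array([labels[k] for k in best], dtype=object)
    for k, label in enumerate(labels):
        out[anchors[k]] = label
    return out


# ---------------------------------------------------------------------------
# Binned trajectory profiles
# ---------------------------------------------------------------------------

def bin_trajectory(
    pseudotime: np.ndarray,
    branch_mask: np.ndarray,
    table: FeatureTable,
    n_bins: int = 50,
    min_cells: int = 15,
    features: tuple[str, ...] | None = None,
) -> TrajectoryProfile:
    """Equal-width pseudotime bins over [0, 1] restricted to one branch.

    Bins with fewer than ``min_cells`` cells are excluded from the profile
    matrix (but remain visible in ``counts``).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    branch_mask = np.asarray(branch_mask, dtype=bool)
    if not branch_mask.any():
        raise ValueError("branch contains no cells")
    feats = list(features) if features else table.feature_names
    pt = np.asarray(pseudotime, dtype=float)[branch_mask]
    values = table.data.loc[branch_mask, feats].to_numpy(dtype=float)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pt, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    retained = np.flatnonzero(counts >= min_cells)
    rows = []
    for b in retained:
        rows.append(np.nanmean(values[which == b], axis=0))
    matrix = pd.DataFrame(rows, index=retained, columns=feats)
    if len(retained) < n_bins:
        logger.info("excluded %d/%d bins with < %d cells",
                    n_bins - len(retained), n_bins, min_cells)
    return TrajectoryProfile(
        matrix=matrix, counts=counts, bin_edges=edges,
        n_bins=n_bins, min_cells=min_cells,
    )


def order_features(profile: TrajectoryProfile) -> list[str]:
    """Dendrogram leaf order of features by the shape of their dynamics.

    Average-linkage agglomerative clustering on correlation distance (1 - r)
    between binned profiles. Leaf rotation is deterministic: at every merge
    the subtree whose mean profile has the earlier-pseudotime centroid comes
    first. Zero-variance profiles cannot enter the correlation metric and are
    placed last (logged).
    """
    mat = profile.matrix
    if mat.shape[1] < 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 features and >= 2 retained bins")
    X = mat.to_numpy(dtype=float).T  # features x bins
    var = X.var(axis=1)
    flat = var == 0
    active = np.flatnonzero(~flat)
    names = list(mat.columns)
    if flat.any():
        logger.warning("zero-variance feature profiles placed last: %s",
                       [names[i] for i in np.flatnonzero(flat)])
    if len(active) < 2:
        return [names[i] for i in active] + [names[i] for i in np.flatnonzero(flat)]

    Xa = X[active]
    Z = linkage(Xa, method="average", metric="correlation")
    centers = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2.0
    centers = centers[profile.retained_bins]

    def centroid_time(profile_vec: np.ndarray) -> float:
        w = profile_vec - profile_vec.min() + 1e-12
        return float(np.sum(centers * w) / np.sum(w))

    n = len(Xa)
    mean_profile: dict[int, np.ndarray] = {i: Xa[i] for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _dist, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        children[node] = (a, b)
        size[node] = size[a] + size[b]
        mean_profile[node] = (
            size[a] * mean_profile[a] + size[b] * mean_profile[b]
        ) / size[node]

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        ta, tb = centroid_time(mean_profile[a]), centroid_time(mean_profile[b])
        first, second = (a, b) if ta <= tb else (b, a)
        return leaves(first) + leaves(second)

    order = leaves(n + len(Z) - 1)
    ordered = [names[active[i]] for i in order]
    ordered += [names[i] for i in np.flatnonzero(flat)]
    profile.feature_order = ordered
    return ordered


# ---------------------------------------------------------------------------
# Senescence scoring and fate fractions
# ---------------------------------------------------------------------------

def senescence_score(
    table: FeatureTable,
    signature: tuple[tuple[str, int], ...] = DEFAULT_SENESCENCE_SIGNATURE,
) -> np.ndarray:
    """Mean of direction x control-z-value over the signature features.

    Assumes the table is matched-control z-normalized; a cell sitting at the
    control mean of every signature feature scores 0, and the score is linear
    in the z-values. Higher = more senescent.
    """
    if not signature:
        raise ValueError("signature must be non-empty")
    if any(d not in (+1, -1) for _, d in signature):
        raise ValueError("signature directions must be +1 or -1")
    missing = [f for f, _ in signature if f not in table.data.columns]
    if missing:
        raise ValueError(f"signature features missing from table: {missing}")
    acc = np.zeros(table.n_cells)
    for feat, direction in signature:
        acc = acc + direction * table.data[feat].to_numpy(dtype=float)
    return acc / len(signature)


def fate_fractions(labels) -> dict[str, int]:
    """Percentages per label, rounded to integers summing to exactly 100.

    Rounding is half-away-from-zero per label; any residual is assigned to
    the most frequent label. Example: counts {40 G2-arrested, 32 completing
    mitosis} -> {56%, 44%}.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    series = pd.Series(labels).value_counts()
    raw = 100.0 * series / series.sum()
    rounded = {k: int(np.floor(v + 0.5)) for k, v in raw.items()}
    residual = 100 - sum(rounded.values())
    if residual:
        rounded[series.idxmax()] += residual
    return rounded
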