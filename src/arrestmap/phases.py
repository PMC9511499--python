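"""Cell-cycle phase annotation, arrest calling and ploidy labeling.

Arrested (G0) cells are identified by thresholding the peak-normalized
phospho/total-RB ratio at 0.7: hyperphosphorylated RB (ratio near the upper
mode at 1) marks actively cycling cells, hypophosphorylated RB (near 0) marks
arrest. The boundary value itself is assigned to *cycling* because the
hyperphosphorylated peak sits at 1 after normalization, so the threshold lies
in the upper mode's basin.

Proliferative phases are called with a four-component Gaussian mixture over
nine features: the median nuclear intensities of PCNA, CDH1, SKP2, cyclin A,
E2F1, cyclin B1 and phospho-p27, plus nuclear area and DNA content. The
mixture is fitted on cycling cells only (G0 is handled by the RB threshold);
components are mapped to G1/S/G2/M by marker logic rather than manual
inspection: lowest-DNA component -> G1; among the rest, highest cyclin B1
with smallest nuclear area -> M; highest cyclin A among the others -> G2; the
remaining (intermediate-DNA, PCNA-high) component -> S.

Ploidy is banded on the peak-normalized DNA scale: 2C below 3, 4C in [3, 6),
8C at or above 6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import DEFAULT_PHASE_FEATURES, FeatureTable

logger = logging.getLogger("arrestmap")

PHASES = ("G1", "S", "G2", "M")


@dataclass
class ArrestParams:
    rb_ratio_feature: str = "phospho_total_rb_nucleus_ratio"
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("arrest threshold must lie in (0, 1)")


@dataclass
class PloidyParams:
    """Band boundaries on the peak-normalized (C-units/2) DNA scale."""

    boundary_2c_4c: float = 3.0
    boundary_4c_8c: float = 6.0

    def __post_init__(self) -> None:
        if not self.boundary_2c_4c < self.boundary_4c_8c:
            raise ValueError("ploidy boundaries must be strictly increasing")


@dataclass
class PhaseModel:
    mixture: GaussianMixture
    features: tuple[str, ...]
    component_phase: dict[int, str]
    #: per-feature standardization applied before the fit (the mixture
    #: likelihood is affine-equivariant but the k-means++ initialization is
    #: not; standardized features let restarts find the small M component)
    feature_mean: np.ndarray = None
    feature_scale: np.ndarray = None
    seed: int | None = None

    def __post_init__(self) -> None:
        phases = sorted(self.component_phase.values())
        if phases != sorted(PHASES):
            raise ValueError("component->phase map must be a bijection onto G1/S/G2/M")


def classify_cycling(rb_ratio, params: ArrestParams = ArrestParams()):
    """'cycling' iff rb_ratio >= threshold (boundary inclusive), else 'arrested'.

    Missing (NaN) ratios yield 'unclassifiable'; callers exclude and log them.
    Vectorized: accepts a scalar or an array.
    """
    arr = np.asarray(rb_ratio, dtype=float)
    if arr.shape == ():
        if not np.isfinite(arr):
            return "unclassifiable"
        return "cycling" if float(arr) >= params.threshold else "arrested"
    out = np.where(arr >= params.threshold, "cycling", "arrested").astype(object)
    out[~np.isfinite(arr)] = "unclassifiable"
    n_bad = int((out == "unclassifiable").sum())
    if n_bad:
        logger.info("%d cells unclassifiable (missing RB ratio)", n_bad)
    return out


def fit_phase_model(
    table: FeatureTable,
    features: tuple[str, ...] = DEFAULT_PHASE_FEATURES,
    seed: int | None = 0,
    n_restarts: int = 10,
) -> PhaseModel:
    """Fit the 4-component full-covariance mixture on cycling cells.

    k-means++-style initialization with ``n_restarts`` restarts, best
    log-likelihood kept; a fixed seed makes the restarts reproducible.
    """
    X = _phase_matrix(table, features)
    ok = np.isfinite(X).all(axis=1)
    X = X[ok]
    if len(X) < 4 * 50:
        logger.warning("only %d cells for the phase fit (< 200)", len(X))
    mu = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    gmm = GaussianMixture(
        n_components=4,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        random_state=seed,
        max_iter=500,
    )
    gmm.fit((X - mu) / scale)
    if not gmm.converged_:
        raise RuntimeError(
            "phase mixture failed to converge: "
            f"lower bound {gmm.lower_bound_:.3g} after {gmm.n_iter_} iterations"
        )
    raw_means = gmm.means_ * scale + mu
    mapping = _map_components(raw_means, features)
    return PhaseModel(gmm, tuple(features), mapping, mu, scale, seed)


def _phase_matrix(table: FeatureTable, features) -> np.ndarray:
    missing = [f for f in features if f not in table.data.columns]
    if missing:
        raise ValueError(f"phase features missing from table: {missing}")
    return table.data[list(features)].to_numpy(dtype=float)


def _map_components(means: np.ndarray, features) -> dict[int, str]:
    """Marker-logic assignment of mixture components to phases.

    ``means`` are the component means on the original feature scale.
    """
    feats = list(features)
    dna = means[:, feats.index("dna_nucleus_integrated")]
    cycb = means[:, feats.index("cyclin_b1_nucleus_median")]
    cyca = means[:, feats.index("cyclin_a_nucleus_median")]
    area = means[:, feats.index("morphology_nucleus_area")]

    mapping: dict[int, str] = {}
    g1 = int(np.argmin(dna))
    mapping[g1] = "G1"
    rest = [k for k in range(4) if k != g1]
    # M: high cyclin B1 and small (condensed) nuclear area
    score = _rank(cycb[rest]) - _rank(area[rest])
    m = rest[int(np.argmax(score))]
    mapping[m] = "M"
    rest = [k for k in rest if k != m]
    g2 = rest[int(np.argmax(cyca[rest]))]
    mapping[g2] = "G2"
    s = [k for k in rest if k != g2][0]
    mapping[s] = "S"
    return mapping


def _rank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(np.argsort(x))
    return order.astype(float)


def assign_phase(
    model: PhaseModel,
    table: FeatureTable,
    cycling_labels: np.ndarray,
) -> np.ndarray:
    """Per-cell phase in {G0, G1, S, G2, M}.

    Arrested cells are G0 regardless of the mixture posterior; cycling cells
    get the argmax-posterior phase. Cells with missing phase features or an
    unclassifiable arrest label come back 'unclassified' and are logged.
    """
    X = _phase_matrix(table, model.features)
    labels = np.asarray(cycling_labels, dtype=object)
    out = np.full(len(X), "unclassified", dtype=object)
    out[labels == "arrested"] = "G0"
    cyc = labels == "cycling"
    ok = cyc & np.isfinite(X).all(axis=1)
    if ok.any():
        comp = model.mixture.predict((X[ok] - model.feature_mean) / model.feature_scale)
        out[ok] = [model.component_phase[int(c)] for c in comp]
    n_un = int((out == "unclassified").sum())
    if n_un:
        logger.info("%d cells left unclassified (missing features/labels)", n_un)
    return out


def label_ploidy(dna_content_normalized, params: PloidyParams = PloidyParams()):
    """Band normalized DNA content into 2C / 4C / 8C."""
    arr = np.asarray(dna_content_normalized, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("DNA content must be non-negative")
    out = np.where(
        arr < params.boundary_2c_4c, "2C",
        np.where(arr < params.boundary_4c_8c, "4C", "8C"),
    ).astype(object)
    if out.shape == ():
        return out.item()
    return out
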