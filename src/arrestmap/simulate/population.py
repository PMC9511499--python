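"""Population simulator: cells on the proliferative-plus-arrest manifold."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..io import FeatureTable
from .dynamics import MarkerDynamicsSpec, default_dynamics, phase_of_theta

#: Latent state vocabulary: the proliferative cycle plus seven arrest states.
ARREST_STATES = (
    "cycling",
    "spontaneous_G0",
    "hypomitogenic_G0",
    "repstress_G0_2C",
    "repstress_G0_4C",
    "mitotic_skip",
    "senescent",
    "endoreduplicated_8C",
)

#: Default state mixture. Among replication-stress cells exiting the cycle the
#: 4C:2C split follows the observed 56%/44% fate bifurcation; ~5% of cells
#: occupy the polyploid 8C state after sustained stress.
DEFAULT_MIX = {
    "cycling": 0.40,
    "spontaneous_G0": 0.05,
    "hypomitogenic_G0": 0.15,
    "repstress_G0_2C": 0.08,
    "repstress_G0_4C": 0.10,
    "mitotic_skip": 0.07,
    "senescent": 0.10,
    "endoreduplicated_8C": 0.05,
}

#: Condition label attached to each latent state (spontaneous arrest occurs in
#: unperturbed cultures and therefore carries the control label).
STATE_CONDITION = {
    "cycling": "control",
    "spontaneous_G0": "control",
    "hypomitogenic_G0": "serum_starved_d7",
    "repstress_G0_2C": "etoposide_d3",
    "repstress_G0_4C": "etoposide_d3",
    "mitotic_skip": "etoposide_d3",
    "senescent": "etoposide_d3",
    "endoreduplicated_8C": "etoposide_d3",
}

STATE_PLOIDY = {
    "spontaneous_G0": "2C",
    "hypomitogenic_G0": "2C",
    "repstress_G0_2C": "2C",
    "repstress_G0_4C": "4C",
    "mitotic_skip": "4C",
    "senescent": "4C",
    "endoreduplicated_8C": "8C",
}


class ConfigError(ValueError):
    pass


@dataclass
class PopulationSimConfig:
    n_cells: int = 5000
    mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    raw_2c: float = 100.0
    raw_4c: float = 200.0
    noise_cv: float = 0.15
    #: relative tolerance on the DNA doubling invariant raw_4c = 2 * raw_2c
    ploidy_tol: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.mix) - set(ARREST_STATES)
        if unknown:
            raise ConfigError(f"unknown states in mix: {sorted(unknown)}")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"mix proportions must sum to 1 (got {total})")
        if any(p < 0 for p in self.mix.values()):
            raise ConfigError("mix proportions must be non-negative")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.raw_2c <= 0 or self.raw_4c <= 0:
            raise ConfigError("raw intensities must be positive")
        if abs(self.raw_4c / (2 * self.raw_2c) - 1.0) > self.ploidy_tol:
            raise ConfigError(
                "raw_4c must be ~2x raw_2c (DNA content doubles across S phase)"
            )


def simulate_population(
    config: PopulationSimConfig,
    dynamics: MarkerDynamicsSpec | None = None,
) -> FeatureTable:
    """Draw a synthetic cell population with exported ground truth.

    Each cell is assigned a latent state from ``config.mix``. Cycling cells
    get a uniform cycle position theta in [0, 1); arrested cells get a uniform
    arrest depth s in [0, 1]. Feature means follow the dynamics spec and are
    perturbed by multiplicative, mean-preserving log-normal noise with
    coefficient of variation ``noise_cv`` (times the per-feature scale). At
    ``noise_cv = 0`` every feature equals its mean function exactly.

    Ground-truth columns: ``phase`` (G1/S/G2/M from theta, G0 for arrested
    cells), ``arrest_state``, ``latent_pseudotime`` (theta for cyclers, depth
    s for arrested cells), and ``ploidy``.
    """
    config.validate()
    if dynamics is None:
        dynamics = default_dynamics(config.raw_2c, config.raw_4c)
    dynamics.validate()

    rng = np.random.default_rng(config.seed)
    states_vocab = [s for s in ARREST_STATES if config.mix.get(s, 0.0) > 0]
    probs = np.array([config.mix[s] for s in states_vocab])
    states = rng.choice(np.array(states_vocab, dtype=object), size=config.n_cells, p=probs)
    latent = rng.uniform(0.0, 1.0, size=config.n_cells)

    n = config.n_cells
    features = dynamics.feature_names
    means = np.empty((n, len(features)))
    cyc = states == "cycling"
    for j, feat in enumerate(features):
        col = np.empty(n)
        if cyc.any():
            col[cyc] = dynamics.cycling_mean(feat, latent[cyc])
        for branch in set(states[~cyc]):
            m = states == branch
            col[m] = dynamics.branch_mean(branch, feat, latent[m])
        means[:, j] = col

    if config.noise_cv > 0:
        values = np.empty_like(means)
        for j, feat in enumerate(features):
            cv = config.noise_cv * dynamics.noise_scale.get(feat, 1.0)
            if cv == 0:
                values[:, j] = means[:, j]
                continue
            sigma = np.sqrt(np.log1p(cv * cv))
            # mean-preserving multiplicative noise
            values[:, j] = means[:, j] * rng.lognormal(-sigma * sigma / 2, sigma, n)
    else:
        values = means

    phase = np.full(n, "G0", dtype=object)
    phase[cyc] = phase_of_theta(latent[cyc])

    ploidy = np.empty(n, dtype=object)
    for state, pl in STATE_PLOIDY.items():
        ploidy[states == state] = pl
    dna_mean = means[:, features.index("dna_nucleus_integrated")]
    ploidy[cyc] = np.where(dna_mean[cyc] < 1.5 * config.raw_2c, "2C", "4C")

    data = pd.DataFrame(values, columns=features)
    data.insert(0, "cell_id", [f"c{i:05d}" for i in range(n)])
    data.insert(1, "condition", [STATE_CONDITION[s] for s in states])
    data.insert(2, "replicate", "r1")
    data["phase"] = phase
    data["arrest_state"] = states
    data["latent_pseudotime"] = latent
    data["ploidy"] = ploidy
    return FeatureTable(data)


def simulate_y_population(
    n_per_arm: int = 300,
    dim: int = 12,
    noise_sd: float = 0.02,
    arm_length: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, int]]:
    """Three straight arms radiating from a common root in ``dim`` dimensions.

    A geometric fixture for branch-assignment tests: points are placed at
    uniform radii along three orthogonal unit directions plus isotropic
    Gaussian noise. Returns ``(X, arm_labels, radii, tip_anchor_index)``
    where the anchors are the outermost point of each arm.
    """
    if dim < 3:
        raise ValueError("dim must be >= 3 to hold three orthogonal arms")
    rng = np.random.default_rng(seed)
    arms = ["arm_a", "arm_b", "arm_c"]
    X, labels, radii = [], [], []
    for k, arm in enumerate(arms):
        direction = np.zeros(dim)
        direction[k] = 1.0
        r = rng.uniform(0.0, arm_length, size=n_per_arm)
        pts = np.outer(r, direction) + rng.normal(0, noise_sd, size=(n_per_arm, dim))
        X.append(pts)
        labels.extend([arm] * n_per_arm)
        radii.append(r)
    X = np.vstack(X)
    labels = np.array(labels, dtype=object)
    radii = np.concatenate(radii)
    anchors = {}
    for arm in arms:
        idx = np.flatnonzero(labels == arm)
        anchors[arm] = int(idx[np.argmax(radii[idx])])
    return X, labels, radii, anchors
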