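#!/usr/bin/env python
"""Pseudotime trajectories: depth recovery, branches, binned dynamics.

Runs diffusion pseudotime from the early-G1 root, assigns arrest branches by
deep ground-truth anchors, profiles feature dynamics along the hypomitogenic
arrest trajectory in 50 pseudotime bins (bins with fewer than 15 cells
excluded) and orders features by hierarchical clustering of their dynamics.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from arrestmap.pipeline import annotate_population, pseudotime_from_early_g1
from arrestmap.simulate import PopulationSimConfig, simulate_population
from arrestmap.trajectory import accumulated_transitions, bin_trajectory, dpt_from, order_features

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 7
BRANCHES = (
    "spontaneous_G0", "hypomitogenic_G0", "repstress_G0_2C", "repstress_G0_4C",
    "mitotic_skip", "senescent", "endoreduplicated_8C",
)


def main() -> None:
    table = simulate_population(PopulationSimConfig(n_cells=5000, seed=SEED))
    annotated = annotate_population(table, seed=0)
    pt, root, op = pseudotime_from_early_g1(annotated, knn=30)
    truth = table.data
    print(f"Root cell: {truth.loc[root, 'cell_id']} "
          f"(phase {truth.loc[root, 'phase']}, pseudotime 0)")

    rows = []
    for branch in BRANCHES:
        mask = (truth["arrest_state"] == branch).to_numpy()
        rho = spearmanr(pt[mask], truth.loc[mask, "latent_pseudotime"]).statistic
        rows.append({"branch": branch, "n_cells": int(mask.sum()),
                     "spearman_vs_depth": round(float(rho), 4)})
    branch_df = pd.DataFrame(rows)
    print("\nPseudotime vs generator arrest depth (Spearman, per branch):")
    print(branch_df.to_string(index=False))

    # branch assignment using the deepest ground-truth cell of each arm as anchor
    M = accumulated_transitions(op)
    depth = truth["latent_pseudotime"].to_numpy()
    anchors = {}
    for branch in BRANCHES:
        idx = np.flatnonzero((truth["arrest_state"] == branch).to_numpy())
        anchors[branch] = int(idx[np.argmax(depth[idx])])
    anchor_dist = np.column_stack([dpt_from(M, a) for a in anchors.values()])
    called = np.array(list(anchors))[np.argmin(anchor_dist, axis=1)]
    arrested = (truth["arrest_state"] != "cycling").to_numpy()
    truth_arr = truth.loc[arrested, "arrest_state"].to_numpy()
    acc = (called[arrested] == truth_arr).mean()
    # spontaneous and replication-stress 2C arrest share one molecular ramp,
    # and senescence is the continuation of mitotic skipping: group them to
    # measure how well the *distinct* trajectories are resolved
    groups = {
        "spontaneous_G0": "2C_arm", "repstress_G0_2C": "2C_arm",
        "mitotic_skip": "skip_senescence", "senescent": "skip_senescence",
        "hypomitogenic_G0": "hypomitogenic", "repstress_G0_4C": "4C_arm",
        "endoreduplicated_8C": "8C",
    }
    g = np.vectorize(groups.get)
    acc_grouped = (g(called[arrested]) == g(truth_arr)).mean()
    deep = arrested & (depth > 0.5)
    acc_deep = (
        g(called[deep]) == truth.loc[deep, "arrest_state"].map(groups).to_numpy()
    ).mean()
    print(f"\nAnchor-based branch assignment over arrested cells: "
          f"{acc:.3f} by state, {acc_grouped:.3f} by trajectory "
          f"(overlapping arms grouped), {acc_deep:.3f} for cells past "
          f"mid-depth — ambiguity is concentrated near the branch point, "
          f"as expected for anchor-nearest assignment.")

    # feature dynamics along the hypomitogenic trajectory
    mask = (truth["arrest_state"] == "hypomitogenic_G0").to_numpy()
    prof = bin_trajectory(pt, mask, annotated.table, n_bins=50, min_cells=15)
    order = order_features(prof)
    ordered = prof.matrix[order]
    RESULTS.mkdir(exist_ok=True)
    ordered.to_csv(RESULTS / "hypomitogenic_trajectory_profile.csv")
    branch_df.to_csv(RESULTS / "pseudotime_branch_recovery.csv", index=False)
    print(f"\nHypomitogenic profile: {len(prof.retained_bins)} bins retained, "
          f"{len(prof.excluded_bins)} excluded (<15 cells).")
    print(f"Feature order (first 5): {order[:5]}")
    print(f"Wrote {RESULTS / 'hypomitogenic_trajectory_profile.csv'} and "
          f"pseudotime_branch_recovery.csv")


if __name__ == "__main__":
    main()
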