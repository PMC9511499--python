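# arrestmap

Tools for mapping the molecular architecture of **cell-cycle arrest** from
hyperplexed single-cell immunofluorescence feature tables, with a synthetic
data generator that stands in for the imaging experiment.

## The problem

Iterative immunofluorescence imaging measures dozens of cell-cycle effectors
(cyclins, CDK inhibitors, RB phosphorylation, DNA content, morphology) in
thousands of individual cells. Asynchronous populations exposed to stress —
serum starvation, replication stress, oxidative stress — contain cells
distributed along a *proliferative* trajectory (G1 → S → G2 → M) and along
*arrest* trajectories that leave it: spontaneous and stress-induced
quiescence with 2C or 4C DNA content, mitotic skipping into a G1-like 4C
state, senescence, and endoreduplication into 8C polyploidy. `arrestmap`
reconstructs this architecture:

- **integration** — matched-control normalization
  (x → (x − μ_ctrl)/σ_ctrl, preserving treatment fold-changes) and bimodal
  *peak normalization* pinning the 2C/4C DNA modes to (2, 4) and the
  hypo-/hyper-phosphorylated RB-ratio modes to (0, 1);
- **phases** — arrest calling by thresholding phospho/total RB at 0.7
  (cycling iff ratio ≥ 0.7), a 4-component Gaussian-mixture phase model over
  nine features (median nuclear PCNA, CDH1, SKP2, cyclin A, E2F1, cyclin B1,
  phospho-p27, nuclear area, DNA content) with marker-logic component →
  G1/S/G2/M mapping, and 2C/4C/8C ploidy banding;
- **manifold** — the diffusion-geometry embedding behind the "cell-cycle
  map": α-decay kernel K_ij = ½[exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)]
  with adaptive knn bandwidths, row-stochastic diffusion operator P = D⁻¹K,
  potential transform U = −log(Pᵗ + ε) (γ = 1) and a classical-MDS + SMACOF
  stress-minimizing 2-d layout — implemented in full, not wrapped;
- **trajectory** — diffusion pseudotime
  M = (I − (P − Π))⁻¹ − I, dpt(x, y) = ‖M_x − M_y‖, with an early-G1 root;
  anchor-supervised branch assignment; pseudotime-binned feature-dynamics
  profiles (equal-width bins, bins with < 15 cells excluded) ordered by
  hierarchical clustering; a senescence signature score (mean directed
  control-z over GSK3β, phospho-T157-p27, p27, CDK4, cyclin D1, cyclin E,
  cell area, −DNA:cytoplasm); and exact-integer fate fractions;
- **timelapse** — CDK2 biosensor quantification (median intensity in a
  15-pixel ring outside the nucleus with a 2-pixel gap, background
  corrected, over median nuclear intensity) and rule-based classification of
  live-cell traces into proliferative, G2-arrest, post-mitotic-arrest,
  mitotic-skip/senescent and endoreduplication fates;
- **simulate** — generators for feature-table populations on the
  proliferative-plus-arrest manifold, biosensor trace archetypes, and disk
  phantoms, all with exported ground truth.

## Worked example

The numbered drivers under `analysis/` run the pipeline end-to-end on the
synthetic population and write their tables under `results/`. For example,
the live-cell validation step:

```bash
python analysis/06_timelapse_fates.py
```

prints

```
Classified 500 traces; accuracy vs generator fate: 1.0000
...
Arrested-trace fate split (this simulation): {'G2_exit': 55, 'completed_mitosis': 45}
Worked example from tracked-cell counts 40/32: {'G2_exit': 56, 'completed_mitosis': 44}

Phantom CDK2 ring ratio (cyto 400 / nuc 200, bg 100): 3.000
```

i.e. all 500 simulated biosensor traces are classified correctly at the
default noise level; among traces that arrest under replication stress, 55%
exit in G2 versus 45% completing mitosis in this simulation, and the
tracked-cell counts 40 (G2-arrested) vs 32 (mothers completing mitosis)
reproduce the 56%/44% split exactly. The disk phantom confirms the ring
quantification: (400 − 100)/(200 − 100) = 3.0.

The trajectory step (`analysis/04_trajectories.py`) reports how well
diffusion pseudotime recovers the generator's arrest depth within every
branch (Spearman ρ 0.92–0.97 at the default 15% measurement noise), and the
annotation step (`analysis/02_normalize_and_annotate.py`) prints the phase
confusion matrix (accuracy 0.998 at n = 5,000).

## Layout

```
src/arrestmap/      the library (io, simulate, integration, phases,
                    manifold, trajectory, timelapse, pipeline)
analysis/           numbered narrative drivers, thin wrappers over the library
tests/              pytest suite (unit, property and acceptance tests)
scripts/            acceptance recomputation
docs/methods.md     model assumptions, parameter choices, limitations
```
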