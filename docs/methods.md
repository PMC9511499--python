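# Methods

This note documents the models and procedures implemented in `arrestmap`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Normalization (integration)

Independently acquired hyperplexed datasets are integrated in two steps.

**Matched-control z-normalization.** For every feature, the mean μ and
sample (n−1) standard deviation σ are fitted on the control condition only,
and *every* cell — control or treated — is mapped to (x − μ)/σ. Scaling
treated cells by control statistics preserves treatment-induced
fold-changes; z-normalizing each condition separately would erase them.
Features with σ = 0 (constant in control) are reported and excluded rather
than divided by zero. Missing values propagate as NaN and never enter the
fitted statistics.

**Bimodal peak normalization.** Features with two intrinsic population
modes are pinned to a common scale by the affine map that sends the two
density modes to fixed targets: DNA content to (2, 4) — so the scale reads
in genome copies per 2 — and phospho-RB / phospho-total-RB ratios to (0, 1),
the hypo- and hyperphosphorylated states. Mode finding uses a Gaussian
kernel density with Silverman bandwidth on a 1024-point grid; local maxima
are ranked by prominence and the most prominent pair separated by at least
15% of the robust (1st–99th percentile) data range is kept. The robust range
matters: a rare polyploid (8C) tail stretches the full range enough to
disqualify the genuine 4C mode. A sample whose minor mode is below 5% of the
major mode's height is declared unimodal — an explicit error, never a
guessed pair of peaks. Which features are treated as bimodal is a
configuration input; DNA content and the RB ratios are the defaults.

## Arrest, phase and ploidy calling (phases)

**Arrest.** A cell is *cycling* iff its peak-normalized phospho/total-RB
ratio is ≥ 0.7, else *arrested* (G0). The boundary value belongs to cycling
because the hyperphosphorylated mode sits at 1 after normalization, so 0.7
lies in the upper mode's basin. The threshold is configurable.

**Phase.** Proliferative phases are called with a 4-component
full-covariance Gaussian mixture over nine features: median nuclear PCNA,
CDH1, SKP2, cyclin A, E2F1, cyclin B1 and phospho-p27, plus nuclear area and
DNA content. The mixture is fitted on cycling cells only (arrest is handled
by the RB threshold, and G0 cells would otherwise absorb a component).
Features are standardized before the fit: the mixture likelihood is
affine-equivariant, but the k-means++ initialization is not, and on raw
intensity scales the restarts reliably fail to seed the small (~3%) mitotic
component. Ten restarts are run and the best log-likelihood kept; a fixed
seed makes the restarts reproducible. Components are mapped to phases by
marker logic rather than manual inspection: lowest-DNA component → G1;
among the rest the component ranking highest in cyclin B1 and lowest in
nuclear area (condensed mitotic nuclei) → M; the highest-cyclin-A remainder
→ G2; the last (intermediate DNA, PCNA-high) → S. Arrested cells are G0
regardless of posterior; cycling cells get the argmax-posterior phase.

**Ploidy.** On the peak-normalized DNA scale: 2C below 3, 4C in [3, 6), 8C
at or above 6. The boundaries are package conventions (midpoints between the
2/4 and 4/8 anchors).

## Diffusion embedding (manifold)

The "cell-cycle map" is a diffusion-geometry embedding computed exactly and
densely; no approximate neighbor search or landmarking is used (intended
problem sizes are ≤ a few tens of thousands of cells).

1. **Kernel**: K_ij = ½[exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)], Euclidean
   d on the selected (normalized) features, σ_i the distance to the knn-th
   neighbor, decay α = 40 by default. Duplicate points (σ = 0) fall back to
   the smallest positive neighbor distance, logged.
2. **Diffusion operator**: P = D⁻¹K. Isolated cells (zero row sum) are an
   error naming the cell.
3. **Potential distances**: with γ = 1, U = −log(Pᵗ + ε), ε machine epsilon
   (≈ 2.2e-16); with γ ≠ 1 the power-law potential
   U = 2/(1−γ)·(Pᵗ)^((1−γ)/2). Distances are Euclidean between rows of U,
   symmetrized, zero diagonal.
4. **Layout**: classical MDS (eigendecomposition of the double-centered
   squared-distance matrix, deterministic sign convention) initializes
   SMACOF iterations (Guttman transform), which monotonically decrease raw
   stress; iteration stops at relative improvement < 1e-7 or 300 rounds.
   The procedure is fully deterministic; the seed is recorded for
   provenance only.

Reference parameter set for a headline map: knn = 150, t = 20, γ = 1.
Smaller populations need proportionally smaller knn and benefit from larger
t (diffusion must mix along the manifold before the log-potential saturates).

## Pseudotime, branches, profiles, scores (trajectory)

**Diffusion pseudotime.** With Π the rank-one projection onto the
stationary distribution of P (degree-proportional, since P is reversible),
the accumulated transition matrix is M = (I − (P − Π))⁻¹ − I, which equals
Σ_{s≥1}(Pᵗ − Π); dpt(x, y) = ‖M_x − M_y‖₂. Pseudotime is the dpt distance
from the root, rescaled to [0, 1] by the maximum. A disconnected neighbor
graph is an error listing component sizes. The default root is the early-G1
anchor: among cycling G1 cells, the one ranking lowest in DNA content and
highest in RB ratio (z-scored within the candidate set); the root is
configurable by cell id.

**Branches.** Branch assignment is anchor-supervised: the caller designates
one endpoint cell per arrest trajectory and every cell joins the branch of
its dpt-nearest anchor (ties to the first-listed branch). This makes the
behavior testable and mirrors how arrest trajectories are curated in
practice; unsupervised branch-point detection is out of scope. Ambiguity
concentrates near the branch point, where membership is genuinely
underdetermined.

**Profiles.** Feature dynamics along a branch are profiled over equal-width
pseudotime bins on [0, 1]; bins with fewer than 15 cells are excluded from
the profile matrix (they remain visible in the per-bin counts). Default 50
bins. Features are displayed in dendrogram leaf order from average-linkage
clustering on correlation distance (1 − r) between binned profiles, with a
deterministic rotation: at every merge the subtree whose mean profile has
the earlier-pseudotime centroid (profile-weighted mean of bin centers) comes
first. Zero-variance profiles cannot enter the correlation metric and are
placed last.

**Senescence score.** The mean over the signature of direction × control-z
value; the default signature is GSK3β, phospho-T157-p27, p27, CDK4,
cyclin D1, cyclin E and cell area up, DNA:cytoplasm ratio down. The mean-z
form is a deliberately simple linear stand-in for a trained multivariate
signature: a cell at control means scores 0 and the score is linear in the
z-values.

**Fate fractions.** Percentages are rounded half-away-from-zero per label
and any residual is assigned to the most frequent label, so they always sum
to exactly 100 (counts 40 vs 32 → 56% / 44%).

## Time-lapse quantification and fate rules (timelapse)

**CDK2 activity** = (median ring − background)/(median nuclear −
background), the ring being pixels at Chebyshev distance in (gap,
gap + width] from the nuclear mask, with width 15 px and gap 2 px by
default. Chebyshev distance via iterated 3×3 dilation gives unambiguous
pixel membership; pixel centers sit at integer coordinates and masks are
inclusive pixel sets. A background-corrected nuclear median below a small
positive guard (1e-6) flags the ratio unreliable and withholds it (NaN).

**Events.** S phase = maximal runs of PCNA-foci count ≥ threshold (default
3), bridging single-frame dropouts. Mitosis = a frame-to-frame DNA-proxy
drop of ≥ 40%.

**Fates.** Channels are median-filtered over 5 frames; an *arrest episode*
is CDK2 < 0.5 sustained ≥ 6 h. Rules, in order: (1) *endoreduplication* —
an arrest episode followed by CDK2 recovery above 1.0 and a later S-phase
interval with no mitosis between arrest onset and that second S phase;
(2) *G2 arrest (4C)* — CDK2 falls from above 1.0 into a terminal low run
with no subsequent mitosis and a p21 onset within ±2 frames of the
collapse; when cyclin channels are present and collapsed without any
mitosis the label is refined to *mitotic skip/senescent* (the skip rule is
a strict superset of the G2-arrest rule, so it is implemented as a
refinement rather than a later rule that could never fire);
(3) *post-mitotic arrest (2C)* — a mitosis followed by a terminal CDK2-low
run with p21 rising after the division; (4) otherwise *proliferative*. The
±2-frame simultaneity criterion is what separates G2 exits (p21 rises with
the CDK2 collapse) from daughter-cell arrest (p21 rises ~1 h after
division). The CDK2 levels 0.5/1.0 follow the convention for this sensor
family; the 6-h minimum duration and the p21 onset level (0.5) are package
conventions, all configurable. Traces shorter than the minimum arrest
duration are unclassifiable (an explicit error).

## The synthetic-data generator

The generator is the study stand-in: all recovery tests run against its
exported ground truth.

**Population.** Each cell draws a latent state from a configurable mixture
over {cycling, spontaneous G0, hypomitogenic G0, replication-stress G0 2C,
replication-stress G0 4C, mitotic skip, senescent, endoreduplicated 8C}.
Cycling cells get a uniform cycle position θ ∈ [0, 1) with phase boundaries
G1 [0, 0.45), S [0.45, 0.75), G2 [0.75, 0.97), M [0.97, 1) (approximate
human somatic phase durations); arrested cells get a uniform arrest depth
s ∈ [0, 1]. Marker means are piecewise-linear in θ, with step
discontinuities at phase boundaries (PCNA loading at S entry, APC/C-driven
cyclin A degradation and nuclear-envelope changes at mitosis) so that
phases form separable clusters by construction, plus smooth ramps within
phases. Arrest branches leave the cycle at a fixed exit position (early G1
for the 2C arms, G2 for the 4C arms) and interpolate linearly from the exit
value to branch targets as s grows. The encoded biology: DNA doubles across
S (raw 2C/4C intensities, default 100/200, constrained to a 2× ratio);
RB is abruptly dephosphorylated at exit (0.9 → 0.6) and declines with
depth; p21 rises along spontaneous and replication-stress arrest but stays
near baseline under hypomitogenic arrest, where almost every protein
declines while p27 rises; mitotic skipping collapses cyclins A/B without
division, raises CDH1 and lowers SKP2; senescence *continues* the skip
trajectory into elevated GSK3β/phospho-T157-p27/p27/CDK4/cyclin D1/
cyclin E, the largest cell areas and the lowest DNA:cytoplasm ratios at 4C;
the 8C state sits at doubled DNA without the p27/CDK4 elevation.
Spontaneous arrest follows the same molecular ramp as the replication-
stress 2C arm (it is driven by inherited endogenous replication stress), so
those two arms are distinguishable only by condition label, deliberately.
Noise is multiplicative, mean-preserving log-normal with coefficient of
variation `noise_cv` (default 0.15); ratio features get half the CV since
shared size/illumination factors cancel. At zero noise every feature equals
its mean function exactly. Default mixture: 40% cycling, with the 4C:2C
replication-stress split at 56:44 and ~5% 8C.

**Traces.** 10-min frames, 62-h default duration, 22-h cell cycle with
S phase from 9.9 to 16.5 h. Four archetypes (proliferative, G2 arrest,
post-mitotic arrest, endoreduplication with a 15–30 h dwell before
re-entry); the DNA proxy halves in one frame at mitosis (an unambiguous
detection target), p21 rises over 1 h at arrest onset (simultaneous with
the CDK2 collapse for G2 exits, 1 h after division for daughters). Event
ground truth (mitoses, S intervals) is derived frame-aligned from the
noiseless channel arrays, so "noiseless detection equals truth exactly" is
well-defined on the acquisition grid. Channel noise is additive Gaussian
(foci counts rounded and clipped).

**Phantoms.** Concentric-disk cells (nucleus, cytoplasmic annulus,
background) with exact masks, for ring-quantification fixtures.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: cell segmentation and tracking errors, staining
batch effects beyond a global control shift, spatial structure and
cell–cell interactions, asynchronous population age structure (θ and s are
uniform by construction), realistic marker fold-changes (dynamic ranges are
free parameters chosen to be well separated at the default noise), and the
feature-selection step that precedes embedding on real data (the feature
list is a configuration input).

## Problem sizes and defaults

Synthetic validation runs use n = 5,000 cells at noise_cv = 0.15 for
population recovery (kernel knn = 30 at that size), 500 traces for fate
classification, and n ≤ 50 instances for the brute-force oracle
equivalences (kernel, operator, potential distances, DPT; tolerance 1e-6).
These sizes resolve every structure the generator encodes while keeping the
full suite fast.

## Known limitations

- Branch assignment requires anchors; there is no unsupervised branch-point
  detection, and near-root cells are genuinely ambiguous.
- The senescence score is an unweighted linear signature, not a trained
  classifier.
- The GMM phase caller assumes the nine phase features are present and
  roughly log-normal within phases; heavily skewed or truncated features
  would need transformation upstream.
- Dense O(n²)–O(n³) linear algebra bounds practical problem sizes to a few
  tens of thousands of cells.
- Peak normalization requires genuinely bimodal samples; unimodal inputs
  fail loudly by design.
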