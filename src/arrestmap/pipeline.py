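"""High-level composition of the pipeline stages.

Thin orchestration over the module operations: normalize a feature table,
call arrest/phases/ploidy, and run diffusion pseudotime from the early-G1
root. Used by the analysis drivers and kept deliberately free of any logic of
its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integration import (
    NormalizationParams,
    PeakPair,
    apply_matched_normalization,
    detect_bimodal_peaks,
    fit_control_stats,
    peak_normalize,
)
from .io import FeatureTable
from .manifold import DiffusionOperator, build_kernel, diffusion_operator
from .phases import PhaseModel, assign_phase, classify_cycling, fit_phase_model, label_ploidy
from .trajectory import accumulated_transitions, dpt_from, select_root

#: the two canonically bimodal features and their peak-normalization targets
BIMODAL_TARGETS = {
    "dna_nucleus_integrated": (2.0, 4.0),
    "phospho_total_rb_nucleus_ratio": (0.0, 1.0),
}


@dataclass
class AnnotatedPopulation:
    """Everything the per-cell annotation stage produces."""

    table: FeatureTable            # z-normalized, with peak-normalized DNA/RB
    norm_params: NormalizationParams
    dna_normalized: np.ndarray     # C-units/2 scale
    rb_normalized: np.ndarray      # 0/1 hypo/hyper scale
    cycling: np.ndarray
    phase: np.ndarray
    ploidy: np.ndarray
    phase_model: PhaseModel


def annotate_population(
    table: FeatureTable,
    control_condition: str = "control",
    seed: int = 0,
) -> AnnotatedPopulation:
    """Normalize, then call arrest (RB threshold), phases (GMM) and ploidy."""
    norm_params = fit_control_stats(table, control_condition)
    znormed = apply_matched_normalization(table, norm_params)

    normalized = {}
    for feat, (lo_t, hi_t) in BIMODAL_TARGETS.items():
        raw = table.data[feat].to_numpy(dtype=float)
        lo, hi = detect_bimodal_peaks(raw)
        normalized[feat] = peak_normalize(raw, lo, hi, lo_t, hi_t)
        norm_params.peaks[feat] = PeakPair(lo, hi, lo_t, hi_t)
    dna_n = normalized["dna_nucleus_integrated"]
    rb_n = normalized["phospho_total_rb_nucleus_ratio"]

    cycling = classify_cycling(rb_n)
    phase_input = table.with_columns(dna_nucleus_integrated=dna_n)
    model = fit_phase_model(phase_input.subset(cycling == "cycling"), seed=seed)
    phase = assign_phase(model, phase_input, cycling)
    ploidy = label_ploidy(dna_n)
    return AnnotatedPopulation(
        table=znormed, norm_params=norm_params, dna_normalized=dna_n,
        rb_normalized=rb_n, cycling=cycling, phase=phase, ploidy=ploidy,
        phase_model=model,
    )


def pseudotime_from_early_g1(
    annotated: AnnotatedPopulation,
    knn: int = 30,
) -> tuple[np.ndarray, int, DiffusionOperator]:
    """DPT from the early-G1 anchor root on the z-normalized features.

    Returns (pseudotime in [0, 1], root index, diffusion operator).
    """
    X = annotated.table.features.to_numpy(dtype=float)
    op = diffusion_operator(build_kernel(X, knn=knn))
    root = select_root(
        annotated.dna_normalized,
        annotated.rb_normalized,
        (annotated.phase == "G1") & (annotated.cycling == "cycling"),
    )
    M = accumulated_transitions(op)
    d = dpt_from(M, root)
    top = d.max()
    return (d / top if top > 0 else d), root, op
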