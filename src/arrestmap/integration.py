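"""Matched-control normalization and bimodal peak normalization.

Independently acquired hyperplexed datasets are integrated in two steps.
First, every feature of every cell is z-normalized with the mean and (sample)
standard deviation of the *matched control* condition — treatment conditions
are scaled by control statistics so that treatment-induced fold-changes are
preserved rather than flattened out. Second, intrinsically bimodal features
are pinned to a common scale by an affine map that sends their two density
modes to fixed targets: DNA content to (2, 4) — the 2C and 4C peaks — and
phospho-RB / phospho-total-RB ratios to (0, 1), the hypo- and
hyperphosphorylated peaks.

Missing values propagate as NaN and never enter the fitted statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .io import FeatureTable

logger = logging.getLogger("arrestmap")


class UnimodalError(ValueError):
    """Peak detection found fewer than two sufficiently prominent modes."""


@dataclass
class PeakPair:
    lo_peak: float
    hi_peak: float
    lo_target: float
    hi_target: float

    def __post_init__(self) -> None:
        if self.hi_peak <= self.lo_peak:
            raise ValueError("hi_peak must exceed lo_peak")
        if not np.isfinite([self.lo_target, self.hi_target]).all() or (
            self.hi_target <= self.lo_target
        ):
            raise ValueError("targets must be finite with hi_target > lo_target")


@dataclass
class NormalizationParams:
    """Per-feature control statistics plus bimodal peak anchors."""

    control_condition: str
    mean: dict[str, float]
    std: dict[str, float]
    #: features excluded from z-normalization because their control sd was 0
    excluded: list[str] = field(default_factory=list)
    peaks: dict[str, PeakPair] = field(default_factory=dict)


def fit_control_stats(table: FeatureTable, control_condition: str) -> NormalizationParams:
    """Per-feature mean and sample sd over the control cells only.

    Features whose control sd is zero are reported and excluded from
    normalization rather than producing divisions by zero.
    """
    ctrl = table.data[table.data["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"no cells with control condition {control_condition!r}")
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    excluded: list[str] = []
    for feat in table.feature_names:
        vals = pd.to_numeric(ctrl[feat], errors="coerce").dropna()
        if len(vals) < 2:
            excluded.append(feat)
            continue
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0.0:
            excluded.append(feat)
            continue
        mean[feat], std[feat] = mu, sd
    if excluded:
        logger.warning(
            "%d features excluded from normalization (constant or <2 control "
            "values): %s", len(excluded), excluded[:10],
        )
    return NormalizationParams(control_condition, mean, std, excluded)


def apply_matched_normalization(
    table: FeatureTable, params: NormalizationParams
) -> FeatureTable:
    """z-score every cell with the control statistics, all conditions alike.

    The control subset of the output has mean 0 and sd 1 per feature; treated
    cells keep their fold-changes relative to control (the map is affine and
    rank-preserving within each feature).
    """
    missing = [
        f for f in table.feature_names
        if f not in params.mean and f not in params.excluded
    ]
    if missing:
        raise ValueError(f"features missing from normalization params: {missing}")
    out = table.data.copy()
    for feat, mu in params.mean.items():
        if feat in out.columns:
            out[feat] = (pd.to_numeric(out[feat], errors="coerce") - mu) / params.std[feat]
    return FeatureTable(out)


def detect_bimodal_peaks(
    values: np.ndarray,
    min_separation_frac: float = 0.15,
    min_height_ratio: float = 0.05,
    grid_size: int = 1024,
) -> tuple[float, float]:
    """Locate the two dominant density modes of a bimodal sample.

    A Gaussian kernel density with Silverman bandwidth is evaluated on a fine
    grid; local maxima are ranked by prominence and the most prominent pair
    separated by at least ``min_separation_frac`` of the robust (1st-99th
    percentile) data range is kept — the robust range keeps rare heavy tails
    (e.g. polyploid cells in a DNA-content sample) from inflating the
    separation requirement. If the minor mode's height falls below
    ``min_height_ratio`` of the major mode's, the sample is declared
    unimodal — never a silent guess.

    Returns ``(lo_peak, hi_peak)`` with lo < hi.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 100:
        raise ValueError("need at least 100 finite values for peak detection")
    lo, hi = values.min(), values.max()
    span = hi - lo
    robust_span = float(np.diff(np.percentile(values, [1, 99]))[0]) or span
    if span == 0:
        raise UnimodalError("all values identical")
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(lo - 0.05 * span, hi + 0.05 * span, grid_size)
    dens = kde(grid)
    idx, props = find_peaks(dens, prominence=0.0)
    if len(idx) < 2:
        raise UnimodalError("density has a single mode")
    order = np.argsort(props["prominences"])[::-1]
    major = idx[order[0]]
    minor = None
    for k in order[1:]:
        if abs(grid[idx[k]] - grid[major]) >= min_separation_frac * robust_span:
            minor = idx[k]
            break
    if minor is None:
        raise UnimodalError(
            "no second mode separated by "
            f">= {min_separation_frac:.0%} of the robust data range"
        )
    height_ratio = dens[minor] / dens[major]
    if height_ratio < min_height_ratio:
        raise UnimodalError(
            f"minor mode height ratio {height_ratio:.3f} below "
            f"{min_height_ratio}; treating sample as unimodal"
        )
    logger.info("bimodal peaks at %.4g / %.4g (minor/major height ratio %.2f)",
                grid[major], grid[minor], height_ratio)
    a, b = sorted((float(grid[major]), float(grid[minor])))
    return a, b


def peak_normalize(
    values: np.ndarray,
    lo_peak: float,
    hi_peak: float,
    lo_target: float,
    hi_target: float,
) -> np.ndarray:
    """Affine map sending the two raw modes to their targets.

    v' = lo_target + (v - lo_peak) * (hi_target - lo_target) / (hi_peak - lo_peak);
    strictly increasing and exact at both anchors.
    """
    pair = PeakPair(lo_peak, hi_peak, lo_target, hi_target)
    values = np.asarray(values, dtype=float)
    scale = (pair.hi_target - pair.lo_target) / (pair.hi_peak - pair.lo_peak)
    return pair.lo_target + (values - pair.lo_peak) * scale


def peak_normalize_table(
    table: FeatureTable,
    params: NormalizationParams,
    bimodal_targets: dict[str, tuple[float, float]],
) -> tuple[FeatureTable, NormalizationParams]:
    """Detect peaks and peak-normalize the listed bimodal features in place.

    ``bimodal_targets`` maps feature name -> (lo_target, hi_target), e.g.
    ``{"dna_nucleus_integrated": (2, 4), "phospho_total_rb_nucleus_ratio": (0, 1)}``.
    Detected anchors are recorded on ``params`` for provenance.
    """
    out = table.data.copy()
    for feat, (lo_t, hi_t) in bimodal_targets.items():
        if feat not in out.columns:
            raise ValueError(f"bimodal feature {feat!r} not in table")
        vals = pd.to_numeric(out[feat], errors="coerce").to_numpy()
        lo_p, hi_p = detect_bimodal_peaks(vals[np.isfinite(vals)])
        out[feat] = peak_normalize(vals, lo_p, hi_p, lo_t, hi_t)
        params.peaks[feat] = PeakPair(lo_p, hi_p, lo_t, hi_t)
    return FeatureTable(out), params
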