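"""Time-lapse biosensor quantification and trace fate classification.

CDK2 activity is read out as the ratio of background-corrected cytoplasmic to
nuclear intensity of a translocation sensor, with the cytoplasmic signal
quantified in a 15-pixel ring outside the segmented nucleus separated from it
by a 2-pixel gap. Live-cell fates are called from four channels — CDK2
activity, p21, PCNA-foci count (S-phase reporter) and a DNA proxy — using the
taxonomy observed under replication stress: cells either arrest in G2 without
dividing (with a simultaneous p21 rise), divide and arrest as daughters (p21
rising after division), re-enter S phase from a long G2 arrest without an
intervening mitosis (endoreduplication), or keep proliferating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, median_filter

logger = logging.getLogger("arrestmap")


class TraceTooShortError(ValueError):
    """Trace shorter than the minimum arrest duration: unclassifiable."""


@dataclass
class RingParams:
    """Cytoplasmic sampling ring outside the nucleus (pixels)."""

    width: int = 15
    gap: int = 2

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("ring width must be > 0")
        if self.gap < 0:
            raise ValueError("ring gap must be >= 0")


@dataclass
class Trace:
    """Uniformly sampled biosensor time series for one tracked cell.

    ``time_min`` is the acquisition grid in minutes; channels are aligned
    arrays. ``mitoses`` and ``s_phase`` carry the generator's ground-truth
    event annotations (times/intervals in minutes) when available.
    """

    time_min: np.ndarray
    cdk2_activity: np.ndarray
    p21: np.ndarray
    pcna_foci_count: np.ndarray
    dna_proxy: np.ndarray
    cyclin_d1: np.ndarray | None = None
    cyclin_a: np.ndarray | None = None
    mitoses: list[float] = field(default_factory=list)
    s_phase: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        steps = np.diff(self.time_min)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("time grid must be uniformly spaced")
        if np.any(self.cdk2_activity < 0):
            raise ValueError("cdk2_activity must be >= 0")
        if np.any(self.dna_proxy <= 0):
            raise ValueError("dna_proxy must be > 0")

    @property
    def frame_interval_min(self) -> float:
        return float(self.time_min[1] - self.time_min[0])

    @property
    def duration_min(self) -> float:
        return float(self.time_min[-1] - self.time_min[0])


@dataclass
class FateLabel:
    """Discrete trace fate plus the evidence used to call it (times in h)."""

    label: str
    arrest_onset_h: float | None = None
    p21_onset_h: float | None = None
    dwell_h: float | None = None


@dataclass
class FateThresholds:
    """Operational criteria for calling arrest in live traces.

    The CDK2 low/high levels (0.5 / 1.0) follow the literature convention for
    this sensor family; the 6-h minimum duration and the p21 onset level are
    package conventions, configurable.
    """

    cdk2_low: float = 0.5
    cdk2_high: float = 1.0
    arrest_min_duration_h: float = 6.0
    p21_onset_level: float = 0.5
    p21_sync_frames: int = 2
    smooth_frames: int = 5


# ---------------------------------------------------------------------------
# Ring quantification
# ---------------------------------------------------------------------------

def ring_mask(nuclear_mask: np.ndarray, params: RingParams) -> np.ndarray:
    """Pixels at Chebyshev distance in (gap, gap+width] from the nucleus."""
    struct = np.ones((3, 3), dtype=bool)
    outer = binary_dilation(nuclear_mask, struct, iterations=params.gap + params.width)
    inner = (
        binary_dilation(nuclear_mask, struct, iterations=params.gap)
        if params.gap > 0
        else nuclear_mask.astype(bool)
    )
    return outer & ~inner


def measure_cdk2_activity(
    image: np.ndarray,
    nuclear_mask: np.ndarray,
    params: RingParams = RingParams(),
    background: float = 0.0,
    denominator_guard: float = 1e-6,
) -> float:
    """CDK2 activity: (median ring - background) / (median nucleus - background).

    Returns NaN (value withheld, warning logged) when the background-corrected
    nuclear median falls below the positive denominator guard. Adding the same
    constant to the image and to ``background`` leaves the ratio unchanged.
    """
    nuclear_mask = nuclear_mask.astype(bool)
    if not nuclear_mask.any():
        raise ValueError("nuclear mask is empty")
    struct = np.ones((3, 3), dtype=bool)
    outer = binary_dilation(nuclear_mask, struct, iterations=params.gap + params.width)
    border = np.zeros_like(outer)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (outer & border).any():
        raise ValueError("cytoplasmic ring clips the image border")
    ring = outer & ~(
        binary_dilation(nuclear_mask, struct, iterations=params.gap)
        if params.gap > 0
        else nuclear_mask
    )
    if not ring.any():
        raise ValueError("cytoplasmic ring is empty")
    nuc = float(np.median(image[nuclear_mask])) - background
    cyto = float(np.median(image[ring])) - background
    if nuc <= denominator_guard:
        logger.warning("nuclear signal at/below background; CDK2 ratio withheld")
        return float("nan")
    return cyto / nuc


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_s_phase(trace: Trace, foci_threshold: int = 3) -> list[tuple[float, float]]:
    """Maximal runs of PCNA-foci count >= threshold, bridging 1-frame dropouts.

    Returns disjoint, sorted ``(start_time, end_time)`` intervals in minutes.
    """
    above = np.asarray(trace.pcna_foci_count) >= foci_threshold
    # bridge single-frame dropouts
    for i in range(1, len(above) - 1):
        if not above[i] and above[i - 1] and above[i + 1]:
            above[i] = True
    intervals = []
    i = 0
    t = trace.time_min
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def detect_mitosis(trace: Trace, drop_fraction: float = 0.4) -> list[float]:
    """Times (minutes) where the DNA proxy falls by >= 40% frame-to-frame."""
    dna = np.asarray(trace.dna_proxy, dtype=float)
    rel = np.diff(dna) / dna[:-1]
    idx = np.flatnonzero(rel <= -drop_fraction)
    return [float(trace.time_min[i + 1]) for i in idx]


# ---------------------------------------------------------------------------
# Fate classification
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, frames: int) -> np.ndarray:
    if frames <= 1:
        return np.asarray(x, dtype=float)
    return median_filter(np.asarray(x, dtype=float), size=frames, mode="nearest")


def _low_runs(low: np.ndarray) -> list[tuple[int, int]]:
    """Maximal index runs where ``low`` holds, as inclusive (start, end)."""
    runs = []
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def classify_fate(trace: Trace, thresholds: FateThresholds = FateThresholds()) -> FateLabel:
    """Assign one of the live-cell fate archetypes to a trace.

    Decision rules, in order:

    1. *endoreduplication* — an arrest episode (CDK2 below ``cdk2_low`` for at
       least ``arrest_min_duration_h``) followed by CDK2 recovery above
       ``cdk2_high`` and a later S-phase interval, with no mitosis between
       arrest onset and that second S phase.
    2. *G2_arrest_4C* — CDK2 falls from above ``cdk2_high`` into a sustained
       low state reaching the end of the trace, with no subsequent mitosis and
       a p21 rise within ±2 frames of the collapse (the simultaneity that
       marks a G2 exit). When cyclin channels are present and collapsed
       without a mitosis the same trace is refined to *mitotic_skip_senescent*.
    3. *postmitotic_arrest_2C* — a mitosis followed by sustained low CDK2 to
       the end of the trace with p21 rising after the division.
    4. otherwise *proliferative*.
    """
    dt_min = trace.frame_interval_min
    if trace.duration_min < thresholds.arrest_min_duration_h * 60:
        raise TraceTooShortError(
            "trace shorter than the minimum arrest duration; unclassifiable"
        )
    cdk2 = _smooth(trace.cdk2_activity, thresholds.smooth_frames)
    p21 = _smooth(trace.p21, thresholds.smooth_frames)
    t = np.asarray(trace.time_min, dtype=float)
    n = len(t)
    min_frames = int(round(thresholds.arrest_min_duration_h * 60 / dt_min))

    mitoses = detect_mitosis(trace)
    s_intervals = detect_s_phase(trace)
    episodes = [
        (i, j) for i, j in _low_runs(cdk2 < thresholds.cdk2_low) if j - i + 1 >= min_frames
    ]
    p21_above = np.flatnonzero(p21 >= thresholds.p21_onset_level)
    p21_onset_idx = int(p21_above[0]) if len(p21_above) else None

    # rule 1: endoreduplication
    for i0, i1 in episodes:
        after = cdk2[i1 + 1 :]
        if len(after) == 0 or np.max(after) <= thresholds.cdk2_high:
            continue
        recover_idx = i1 + 1 + int(np.argmax(after > thresholds.cdk2_high))
        second_s = [s for s in s_intervals if s[0] >= t[recover_idx]]
        if not second_s:
            continue
        s_start = second_s[0][0]
        if any(t[i0] <= m <= s_start for m in mitoses):
            continue
        return FateLabel(
            "endoreduplication",
            arrest_onset_h=t[i0] / 60,
            p21_onset_h=None if p21_onset_idx is None else t[p21_onset_idx] / 60,
            dwell_h=(t[i1] - t[i0]) / 60,
        )

    # rules 2/4: G2 arrest (terminal low run, preceded by high CDK2, p21 in sync)
    terminal = [e for e in episodes if e[1] >= n - 2]
    if terminal:
        i0, _ = terminal[-1]
        was_high = np.any(cdk2[:i0] > thresholds.cdk2_high)
        no_mitosis_after = not any(m >= t[i0] for m in mitoses)
        in_sync = (
            p21_onset_idx is not None
            and abs(p21_onset_idx - i0) <= thresholds.p21_sync_frames
        )
        if was_high and no_mitosis_after and in_sync:
            label = "G2_arrest_4C"
            if _cyclins_collapsed(trace) and not mitoses:
                label = "mitotic_skip_senescent"
            return FateLabel(
                label,
                arrest_onset_h=t[i0] / 60,
                p21_onset_h=t[p21_onset_idx] / 60,
            )

    # rule 3: post-mitotic arrest
    if mitoses and terminal:
        i0, _ = terminal[-1]
        last_mitosis = mitoses[-1]
        p21_after_division = (
            p21_onset_idx is not None and t[p21_onset_idx] > last_mitosis
        )
        if t[i0] >= last_mitosis - 2 * dt_min and p21_after_division:
            return FateLabel(
                "postmitotic_arrest_2C",
                arrest_onset_h=t[i0] / 60,
                p21_onset_h=t[p21_onset_idx] / 60,
            )

    return FateLabel("proliferative")


def _cyclins_collapsed(trace: Trace, fold: float = 0.3) -> bool:
    """True when a cyclin A channel is present and ends far below its peak."""
    if trace.cyclin_a is None:
        return False
    arr = np.asarray(trace.cyclin_a, dtype=float)
    tail = float(np.median(arr[-6:]))
    peak = float(np.max(arr))
    return peak > 0 and tail < fold * peak
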