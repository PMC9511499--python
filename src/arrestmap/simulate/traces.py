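"""Time-lapse trace simulator for the live-cell fate archetypes.

Each trace starts at a cell birth (just after a mitosis) and follows one of
four archetypes on a 10-minute acquisition grid:

* *proliferative* — CDK2 activity climbs from ~0.5 at birth to >1 before each
  division; the DNA proxy doubles across S phase (marked by PCNA foci) and
  halves in a single frame at mitosis.
* *G2_arrest_4C* — the cell completes S phase but arrests in G2: CDK2
  collapses to a low plateau simultaneously with a sharp p21 rise; no mitosis.
* *postmitotic_arrest_2C* — the mother divides normally, and the daughter
  stays CDK2-low with p21 rising shortly (~1 h) after division.
* *endoreduplication* — a G2 arrest, a dwell drawn from the configured
  15-30 h range, then CDK2 re-rises and a second S phase begins with no
  intervening mitosis, taking the DNA proxy from 4 to 8.

Channel noise is additive Gaussian (foci counts are rounded and clipped); at
zero noise every channel equals its archetype profile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..timelapse import FateLabel, Trace
from .population import ConfigError

FATES = ("proliferative", "G2_arrest_4C", "postmitotic_arrest_2C", "endoreduplication")

#: Default fate mixture: among stressed cells that arrest, 56% exit in G2 and
#: 44% complete mitosis before arresting; endoreduplication is rare (~5%).
DEFAULT_FATE_MIX = {
    "proliferative": 0.25,
    "G2_arrest_4C": 0.40,
    "postmitotic_arrest_2C": 0.30,
    "endoreduplication": 0.05,
}

DEFAULT_NOISE_SD = {
    "cdk2_activity": 0.05,
    "p21": 0.05,
    "dna_proxy": 0.08,
    "pcna_foci_count": 0.5,
}

# archetype timing on a 22-h cell cycle (hours after birth)
CYCLE_H = 22.0
S_START_H = 9.9
S_END_H = 16.5
ARREST_ONSET_H = 18.0  # G2
S_FOCI = 8
CDK2_BIRTH = 0.5
CDK2_MITOSIS = 1.2
CDK2_ARRESTED = 0.2
CDK2_REENTRY = 1.3
P21_BASE = 0.1
P21_HIGH = 1.0
P21_RISE_H = 1.0
REENTRY_RAMP_H = 4.0
S2_DURATION_H = 6.6


@dataclass
class TraceSimConfig:
    n_traces: int = 500
    frame_interval_min: float = 10.0
    duration_h: float = 62.0
    fate_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FATE_MIX))
    dwell_range_h: tuple[float, float] = (15.0, 30.0)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def validate(self) -> None:
        unknown = set(self.fate_mix) - set(FATES)
        if unknown:
            raise ConfigError(f"unknown fates in mix: {sorted(unknown)}")
        total = sum(self.fate_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"fate mix must sum to 1 (got {total})")
        if self.frame_interval_min <= 0:
            raise ConfigError("frame interval must be > 0")
        if self.dwell_range_h[0] > self.dwell_range_h[1]:
            raise ConfigError("dwell range must be (lo, hi) with lo <= hi")
        if self.duration_h < self.dwell_range_h[1] + CYCLE_H:
            raise ConfigError(
                "duration must cover the maximum dwell plus one cell cycle "
                f"({self.dwell_range_h[1] + CYCLE_H:.0f} h)"
            )


def _cycle_profiles(t_h: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CDK2, DNA and foci profiles for an unperturbed cycling cell."""
    phase_t = np.mod(t_h, CYCLE_H)
    cdk2 = CDK2_BIRTH + (CDK2_MITOSIS - CDK2_BIRTH) * phase_t / CYCLE_H
    in_s = (phase_t >= S_START_H) & (phase_t < S_END_H)
    dna = np.where(
        phase_t < S_START_H,
        2.0,
        np.where(in_s, 2.0 + 2.0 * (phase_t - S_START_H) / (S_END_H - S_START_H), 4.0),
    )
    foci = np.where(in_s, S_FOCI, 0)
    return cdk2, dna, foci


def _p21_rise(t_h: np.ndarray, onset_h: float) -> np.ndarray:
    ramp = np.clip((t_h - onset_h) / P21_RISE_H, 0.0, 1.0)
    return P21_BASE + (P21_HIGH - P21_BASE) * ramp


def _make_trace(fate: str, t_h: np.ndarray, dwell_h: float) -> tuple[dict, list, list]:
    """Noiseless channel dict plus ground-truth mitosis/S-interval frame indices."""
    cdk2, dna, foci = _cycle_profiles(t_h)
    p21 = np.full_like(t_h, P21_BASE)

    if fate == "proliferative":
        pass  # unperturbed cycling profiles as built
    elif fate in ("G2_arrest_4C", "endoreduplication"):
        onset = ARREST_ONSET_H
        arrested = t_h >= onset
        # collapse over two frames, then a low plateau
        dt = t_h[1] - t_h[0]
        ramp = np.clip((t_h - onset) / (2 * dt), 0.0, 1.0)
        cdk2 = np.where(
            arrested, cdk2[np.searchsorted(t_h, onset)] * (1 - ramp) + CDK2_ARRESTED * ramp, cdk2
        )
        dna = np.where(arrested, 4.0, dna)
        foci = np.where(arrested, 0, foci)
        p21 = _p21_rise(t_h, onset)
        if fate == "endoreduplication":
            reentry = onset + dwell_h
            rising = t_h >= reentry
            ramp2 = np.clip((t_h - reentry) / REENTRY_RAMP_H, 0.0, 1.0)
            cdk2 = np.where(rising, CDK2_ARRESTED + (CDK2_REENTRY - CDK2_ARRESTED) * ramp2, cdk2)
            s2_start = reentry + REENTRY_RAMP_H
            s2_end = s2_start + S2_DURATION_H
            in_s2 = (t_h >= s2_start) & (t_h < s2_end)
            foci = np.where(in_s2, S_FOCI, foci)
            dna = np.where(
                t_h >= s2_start,
                np.where(in_s2, 4.0 + 4.0 * (t_h - s2_start) / S2_DURATION_H, 8.0),
                dna,
            )
            p21 = np.where(rising, np.maximum(P21_BASE, P21_HIGH - 0.85 * ramp2), p21)
    elif fate == "postmitotic_arrest_2C":
        after = t_h >= CYCLE_H
        cdk2 = np.where(after, CDK2_ARRESTED + 0.1, cdk2)
        dna = np.where(after, 2.0, dna)
        foci = np.where(after, 0, foci)
        p21 = _p21_rise(t_h, CYCLE_H + 1.0)
    else:  # pragma: no cover
        raise ConfigError(f"unknown fate {fate!r}")

    # frame-aligned ground truth derived from the noiseless channels
    mitoses = [int(i + 1) for i in np.flatnonzero(dna[1:] <= 0.55 * dna[:-1])]
    s_phase = []
    in_s = foci > 0
    i = 0
    while i < len(in_s):
        if in_s[i]:
            j = i
            while j + 1 < len(in_s) and in_s[j + 1]:
                j += 1
            s_phase.append((int(i), int(j)))
            i = j + 1
        else:
            i += 1

    channels = {
        "cdk2_activity": cdk2,
        "p21": p21,
        "pcna_foci_count": foci.astype(float),
        "dna_proxy": dna,
    }
    return channels, mitoses, s_phase


def simulate_traces(config: TraceSimConfig) -> list[tuple[Trace, FateLabel]]:
    """Simulate biosensor traces; returns (trace, ground-truth fate) pairs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_h * 60 / config.frame_interval_min)) + 1
    time_min = np.arange(n_frames) * config.frame_interval_min
    t_h = time_min / 60.0

    fates_vocab = [f for f in FATES if config.fate_mix.get(f, 0.0) > 0]
    probs = np.array([config.fate_mix[f] for f in fates_vocab])
    fates = rng.choice(np.array(fates_vocab, dtype=object), size=config.n_traces, p=probs)

    out: list[tuple[Trace, FateLabel]] = []
    for i, fate in enumerate(fates):
        dwell = float(rng.uniform(*config.dwell_range_h))
        channels, mitoses, s_phase = _make_trace(fate, t_h, dwell)
        noisy = {}
        for name, arr in channels.items():
            sd = config.noise_sd.get(name, 0.0)
            vals = arr + rng.normal(0, sd, size=arr.shape) if sd > 0 else arr.copy()
            if name == "pcna_foci_count":
                vals = np.clip(np.round(vals), 0, None)
            elif name == "dna_proxy":
                vals = np.clip(vals, 0.1, None)
            else:
                vals = np.clip(vals, 0.0, None)
            noisy[name] = vals
        trace = Trace(
            time_min=time_min.copy(),
            mitoses=[float(time_min[i]) for i in mitoses],
            s_phase=[(float(time_min[a]), float(time_min[b])) for a, b in s_phase],
            **noisy,
        )
        onset = {
            "G2_arrest_4C": ARREST_ONSET_H,
            "endoreduplication": ARREST_ONSET_H,
            "postmitotic_arrest_2C": CYCLE_H,
        }.get(str(fate))
        label = FateLabel(
            str(fate),
            arrest_onset_h=onset,
            dwell_h=dwell if fate == "endoreduplication" else None,
        )
        out.append((trace, label))
    return out
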