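"""Marker mean dynamics over the proliferative cycle and arrest branches.

The latent state of a simulated cell is either a cycle position theta in
[0, 1) (proliferating) or an (arrest branch, arrest depth s in [0, 1]) pair.
Each marker has a piecewise-linear mean as a function of theta; each arrest
branch leaves the cycle at a fixed exit position and linearly interpolates
selected markers from their value at exit toward a branch-specific target as
the cell progresses deeper into arrest.

The shapes encode the canonical biology the generator must emulate:

* DNA content doubles across S phase (raw 2C -> 4C intensity).
* Cyclin D1 rises in late G2 and stays elevated through mitosis and into the
  next G1; cyclin A peaks in G2, cyclin B1 in M; PCNA is high in S.
* Arrest is accompanied by an abrupt loss of RB phosphorylation (the
  phospho/total-RB ratio falls from ~0.9 to a hypophosphorylated band).
* p21 is induced in spontaneous and replication-stress arrest but not under
  hypomitogenic (serum-starvation) arrest, where nearly every protein
  declines while p27 steadily increases.
* Mitotic skipping converts a 4C G2 cell into a G1-like state: cyclins A/B
  collapse to baseline without division, CDH1 rises, SKP2 falls.
* The senescent state carries the marker signature of deep arrest: elevated
  GSK3beta, phospho-T157-p27 and total p27, CDK4, cyclin D1 and cyclin E,
  the largest cell areas and the lowest DNA:cytoplasm ratio, at 4C.
* Endoreduplicated cells re-replicate to 8C but lack the p27/CDK4 elevation.

Absolute dynamic ranges (fold-changes) are free parameters of the generator,
chosen to be well separated relative to the default measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Cycle-position boundaries of the proliferative phases (fractions of the
#: cycle, approximating human somatic phase durations).
PHASE_BOUNDS = {"G1": (0.0, 0.45), "S": (0.45, 0.75), "G2": (0.75, 0.97), "M": (0.97, 1.0)}


def phase_of_theta(theta: np.ndarray) -> np.ndarray:
    """Map cycle positions to G1/S/G2/M labels."""
    theta = np.asarray(theta)
    out = np.full(theta.shape, "G1", dtype=object)
    out[theta >= PHASE_BOUNDS["S"][0]] = "S"
    out[theta >= PHASE_BOUNDS["G2"][0]] = "G2"
    out[theta >= PHASE_BOUNDS["M"][0]] = "M"
    return out


Breakpoints = list[tuple[float, float]]


@dataclass
class BranchSpec:
    """One arrest branch: where it leaves the cycle and where it goes.

    ``targets`` gives end values (at depth s=1) for markers that change along
    the branch; untargeted markers stay at their value at the exit position.
    ``overrides`` pins both the start and end value of a marker, for abrupt
    transitions at cycle exit (e.g. RB dephosphorylation) or ploidy that is
    fixed along the branch.
    """

    exit_theta: float
    targets: dict[str, float] = field(default_factory=dict)
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class MarkerDynamicsSpec:
    """Piecewise-linear cycling means plus per-branch arrest ramps."""

    cycling: dict[str, Breakpoints]
    branches: dict[str, BranchSpec]
    #: per-marker multiplier on the global noise CV (ratio features are less
    #: noisy because shared size/illumination factors cancel)
    noise_scale: dict[str, float] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.cycling)

    def cycling_mean(self, feature: str, theta: np.ndarray) -> np.ndarray:
        pts = self.cycling[feature]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        return np.interp(np.asarray(theta, dtype=float), xs, ys)

    def branch_endpoints(self, branch: str, feature: str) -> tuple[float, float]:
        spec = self.branches[branch]
        if feature in spec.overrides:
            return spec.overrides[feature]
        start = float(self.cycling_mean(feature, np.array([spec.exit_theta]))[0])
        end = spec.targets.get(feature, start)
        return start, end

    def branch_mean(self, branch: str, feature: str, s: np.ndarray) -> np.ndarray:
        start, end = self.branch_endpoints(branch, feature)
        s = np.asarray(s, dtype=float)
        return start + s * (end - start)

    def validate(self) -> None:
        for feat, pts in self.cycling.items():
            if any(v <= 0 for _, v in pts):
                raise ValueError(f"mean function of {feat!r} must stay positive")
        g1_baseline = {
            f: self.cycling_mean(f, np.array([0.2]))[0]
            for f in ("cyclin_a_nucleus_median", "cyclin_b1_nucleus_median")
        }
        for br in ("mitotic_skip", "senescent"):
            if br in self.branches:
                for f, base in g1_baseline.items():
                    _, end = self.branch_endpoints(br, f)
                    if end > 1.5 * base:
                        raise ValueError(
                            f"{f} must drop to baseline in branch {br!r}"
                        )
        if "hypomitogenic_G0" in self.branches:
            start, end = self.branch_endpoints(
                "hypomitogenic_G0", "p27_nucleus_median"
            )
            if end < start:
                raise ValueError("p27 must be non-decreasing along hypomitogenic arrest")


def default_dynamics(raw_2c: float = 100.0, raw_4c: float = 200.0) -> MarkerDynamicsSpec:
    """Default marker dynamics on the arbitrary-intensity-unit scale.

    ``raw_2c``/``raw_4c`` anchor the two DNA-content modes; everything else is
    in nominal a.u. around ~100.
    """
    lo, hi = raw_2c, raw_4c
    # duplicated breakpoint positions encode exact steps at phase boundaries
    # (PCNA loading at S entry, APC/C-driven degradation at anaphase, nuclear
    # envelope breakdown at mitosis): phases are separable by construction,
    # not only by the smooth ramps between them
    cycling: dict[str, Breakpoints] = {
        "dna_nucleus_integrated": [(0.0, lo), (0.45, lo), (0.75, hi), (1.0, hi)],
        "pcna_nucleus_median": [
            (0.0, 80), (0.45, 80), (0.45, 300), (0.75, 300), (0.75, 100), (1.0, 80),
        ],
        "cdh1_nucleus_median": [
            (0.0, 300), (0.45, 300), (0.45, 200), (0.75, 100), (1.0, 80),
        ],
        "skp2_nucleus_median": [
            (0.0, 80), (0.45, 150), (0.45, 180), (0.75, 250), (1.0, 220),
        ],
        "cyclin_a_nucleus_median": [
            (0.0, 60), (0.45, 80), (0.45, 140), (0.75, 280), (0.90, 350),
            (0.97, 330), (0.97, 120), (1.0, 100),
        ],
        "e2f1_nucleus_median": [
            (0.0, 120), (0.40, 300), (0.45, 300), (0.45, 240), (0.75, 120), (1.0, 90),
        ],
        "cyclin_b1_nucleus_median": [
            (0.0, 60), (0.45, 70), (0.75, 180), (0.97, 330), (0.97, 420), (1.0, 420),
        ],
        "phospho_p27_nucleus_median": [(0.0, 150), (0.45, 120), (0.75, 100), (1.0, 100)],
        "morphology_nucleus_area": [
            (0.0, 100), (0.45, 135), (0.75, 165), (0.97, 190), (0.97, 60), (1.0, 60),
        ],
        "cyclin_d1_nucleus_median": [
            (0.0, 220), (0.10, 120), (0.45, 100), (0.75, 110), (0.85, 140),
            (0.97, 250), (1.0, 250),
        ],
        "phospho_total_rb_nucleus_ratio": [(0.0, 0.9), (1.0, 0.9)],
        "p21_nucleus_median": [(0.0, 60), (1.0, 60)],
        "p27_nucleus_median": [(0.0, 150), (1.0, 150)],
        "cdk4_nucleus_median": [(0.0, 140), (1.0, 140)],
        "gsk3b_nucleus_median": [(0.0, 120), (1.0, 120)],
        "cyclin_e_nucleus_median": [
            (0.0, 150), (0.35, 260), (0.55, 150), (1.0, 120),
        ],
        "phospho_t157_p27_nucleus_median": [(0.0, 110), (1.0, 110)],
        "morphology_cell_area": [(0.0, 250), (0.97, 420), (1.0, 260)],
        "dna_cytoplasm_cell_ratio": [
            (0.0, 0.80), (0.45, 0.75), (0.75, 1.00), (1.0, 0.95),
        ],
    }

    # RB is abruptly dephosphorylated at cycle exit (0.9 -> 0.6) and keeps
    # declining with arrest depth, so arrest corridors remain feature-space
    # continua rather than disconnected islands
    rb_drop = ("phospho_total_rb_nucleus_ratio", (0.6, 0.05))
    rb_deep = ("phospho_total_rb_nucleus_ratio", (0.05, 0.02))
    branches = {
        # spontaneous arrest in unperturbed cultures is driven by endogenous
        # replication stress inherited from the mother cycle, so it follows
        # the same p21-driven molecular ramp as the 2C replication-stress arm
        "spontaneous_G0": BranchSpec(
            exit_theta=0.02,
            targets={
                "p21_nucleus_median": 350,
                "e2f1_nucleus_median": 70,
                "pcna_nucleus_median": 60,
                "cyclin_d1_nucleus_median": 80,
                "skp2_nucleus_median": 40,
            },
            overrides=dict([rb_drop]),
        ),
        "hypomitogenic_G0": BranchSpec(
            exit_theta=0.02,
            # global decline of nearly every protein; p27 is the exception
            targets={
                "pcna_nucleus_median": 40,
                "cdh1_nucleus_median": 110,
                "skp2_nucleus_median": 35,
                "cyclin_a_nucleus_median": 30,
                "e2f1_nucleus_median": 45,
                "cyclin_b1_nucleus_median": 30,
                "phospho_p27_nucleus_median": 60,
                "cyclin_d1_nucleus_median": 70,
                "cdk4_nucleus_median": 55,
                "gsk3b_nucleus_median": 55,
                "cyclin_e_nucleus_median": 55,
                "phospho_t157_p27_nucleus_median": 45,
                "p27_nucleus_median": 350,
                "p21_nucleus_median": 75,
            },
            overrides=dict([rb_drop]),
        ),
        "repstress_G0_2C": BranchSpec(
            exit_theta=0.02,
            targets={
                "p21_nucleus_median": 350,
                "e2f1_nucleus_median": 70,
                "pcna_nucleus_median": 60,
                "cyclin_d1_nucleus_median": 80,
                "skp2_nucleus_median": 40,
            },
            overrides=dict([rb_drop]),
        ),
        "repstress_G0_4C": BranchSpec(
            exit_theta=0.90,
            targets={
                "p21_nucleus_median": 350,
                "cyclin_a_nucleus_median": 180,
                "cyclin_b1_nucleus_median": 150,
                "e2f1_nucleus_median": 70,
            },
            overrides=dict([rb_drop]),
        ),
        "mitotic_skip": BranchSpec(
            exit_theta=0.90,
            # G1-like 4C state: G2/M cyclins degraded without division,
            # CDH1 (APC/C) up, SKP2 down
            targets={
                "cyclin_a_nucleus_median": 60,
                "cyclin_b1_nucleus_median": 60,
                "cdh1_nucleus_median": 320,
                "skp2_nucleus_median": 60,
                "p21_nucleus_median": 300,
                "e2f1_nucleus_median": 80,
                "cyclin_d1_nucleus_median": 230,
            },
            overrides=dict([rb_drop]),
        ),
        # senescence is entered *through* mitotic skipping: the branch starts
        # where the skip trajectory ends (G1-like 4C, cyclins collapsed) and
        # progresses into the deep senescent signature
        "senescent": BranchSpec(
            exit_theta=0.90,
            targets={},
            overrides=dict(
                [
                    rb_deep,
                    ("cyclin_a_nucleus_median", (60, 60)),
                    ("cyclin_b1_nucleus_median", (60, 60)),
                    ("cdh1_nucleus_median", (320, 320)),
                    ("skp2_nucleus_median", (60, 60)),
                    ("p21_nucleus_median", (300, 260)),
                    ("pcna_nucleus_median", (100, 70)),
                    ("e2f1_nucleus_median", (80, 80)),
                    ("cyclin_d1_nucleus_median", (230, 400)),
                    ("gsk3b_nucleus_median", (120, 350)),
                    ("phospho_t157_p27_nucleus_median", (110, 330)),
                    ("p27_nucleus_median", (150, 360)),
                    ("cdk4_nucleus_median", (140, 300)),
                    ("cyclin_e_nucleus_median", (120, 320)),
                    ("morphology_cell_area", (410, 900)),
                    ("dna_cytoplasm_cell_ratio", (0.97, 0.15)),
                ]
            ),
        ),
        "endoreduplicated_8C": BranchSpec(
            exit_theta=0.90,
            targets={
                "cyclin_d1_nucleus_median": 350,
                "cyclin_e_nucleus_median": 300,
                "morphology_cell_area": 700,
                "p21_nucleus_median": 250,
                "cyclin_a_nucleus_median": 120,
                "cyclin_b1_nucleus_median": 80,
                # polyploid cells lack the p27/CDK4 elevation of senescence
                "p27_nucleus_median": 80,
                "cdk4_nucleus_median": 80,
            },
            overrides=dict(
                [rb_deep, ("dna_nucleus_integrated", (2 * hi, 2 * hi))]
            ),
        ),
    }
    spec = MarkerDynamicsSpec(
        cycling=cycling,
        branches=branches,
        noise_scale={
            "phospho_total_rb_nucleus_ratio": 0.5,
            "dna_cytoplasm_cell_ratio": 0.5,
        },
    )
    spec.validate()
    return spec
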