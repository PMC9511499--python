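"""Feature-table and configuration I/O.

Single-cell hyperplexed imaging experiments produce one row per cell with
named intensity/morphology features (``marker_compartment_statistic``) plus
condition and replicate metadata. This module defines the in-memory container
(:class:`FeatureTable`, a thin validated wrapper around a pandas DataFrame),
round-trip CSV serialization, the pipeline configuration with its documented
defaults, and a plain-text run manifest for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("arrestmap")

#: Metadata columns every table carries.
METADATA_COLUMNS = ("cell_id", "condition", "replicate")

#: Optional ground-truth columns (synthetic-data plumbing; absent on real data).
GROUND_TRUTH_COLUMNS = ("phase", "arrest_state", "latent_pseudotime", "ploidy")

#: Recognized subcellular compartments encoded in feature names.
COMPARTMENTS = ("nucleus", "cytosol", "perinuclear", "membrane", "cell")


class SchemaError(ValueError):
    """A mandatory column is missing or a config key is unknown."""


class IntegrityError(ValueError):
    """Table content violates an invariant (e.g. duplicated cell_id)."""


@dataclass
class FeatureTable:
    """Cells x features with condition/replicate metadata.

    ``data`` holds one row per cell. Columns in :data:`METADATA_COLUMNS` are
    mandatory; columns in :data:`GROUND_TRUTH_COLUMNS` are optional; every
    other column is treated as a numeric feature. Missing feature values are
    NaN and are never silently dropped — downstream operations declare their
    own missing-value policy.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for col in METADATA_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"mandatory column missing: {col!r}")
        dup = self.data["cell_id"].duplicated()
        if dup.any():
            dupes = self.data.loc[dup, "cell_id"].unique()[:5].tolist()
            raise IntegrityError(f"duplicated cell_id values: {dupes}")
        for col in self.feature_names:
            if not pd.api.types.is_numeric_dtype(self.data[col]):
                # tolerate all-missing object columns read from CSV
                try:
                    self.data[col] = pd.to_numeric(self.data[col])
                except (ValueError, TypeError) as exc:
                    raise IntegrityError(
                        f"feature column {col!r} is not numeric"
                    ) from exc

    # -- accessors ----------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        skip = set(METADATA_COLUMNS) | set(GROUND_TRUTH_COLUMNS)
        return [c for c in self.data.columns if c not in skip]

    @property
    def features(self) -> pd.DataFrame:
        """Feature sub-frame indexed by cell_id."""
        return self.data.set_index("cell_id")[self.feature_names]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].reset_index(drop=True))

    def with_columns(self, **cols) -> "FeatureTable":
        out = self.data.copy()
        for name, values in cols.items():
            out[name] = np.asarray(values)
        return FeatureTable(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        if list(self.data.columns) != list(other.data.columns):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.data.reset_index(drop=True),
                other.data.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a CSV feature table, validating schema and cell_id uniqueness.

    Unknown feature columns are carried through untouched; empty fields become
    NaN (explicit missing markers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    categorical = set(METADATA_COLUMNS) | {"phase", "arrest_state", "ploidy"}
    data = pd.read_csv(path, float_precision="round_trip")
    for col in data.columns:
        if col in categorical:
            data[col] = data[col].where(data[col].isna(), data[col].astype(str))
    table = FeatureTable(data)
    n_missing = int(table.features.isna().sum().sum())
    if n_missing:
        logger.info("read %s: %d missing feature values flagged", path, n_missing)
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a table to CSV with full-precision numeric round-trip.

    Floats are serialized with ``repr`` precision (17 significant digits) so
    that write→read is the identity and two writes of the same table are
    byte-identical.
    """
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

#: The nine features the phase mixture model is trained on: median nuclear
#: intensities of seven cell-cycle effectors plus nuclear area and DNA content.
DEFAULT_PHASE_FEATURES = (
    "pcna_nucleus_median",
    "cdh1_nucleus_median",
    "skp2_nucleus_median",
    "cyclin_a_nucleus_median",
    "e2f1_nucleus_median",
    "cyclin_b1_nucleus_median",
    "phospho_p27_nucleus_median",
    "morphology_nucleus_area",
    "dna_nucleus_integrated",
)


@dataclass
class PipelineConfig:
    """Fully resolved pipeline parameters.

    Defaults encode the published analysis choices: an RB-ratio arrest
    threshold of 0.7 on the peak-normalized phospho/total-RB scale, pseudotime
    bins with fewer than 15 cells excluded from trajectory profiles, and the
    diffusion-embedding parameter set used for the main cell-cycle map
    (knn=150, t=20, gamma=1).
    """

    seed: int | None = None
    rb_threshold: float = 0.7
    rb_ratio_feature: str = "phospho_total_rb_nucleus_ratio"
    dna_feature: str = "dna_nucleus_integrated"
    phase_features: tuple[str, ...] = DEFAULT_PHASE_FEATURES
    embedding_features: tuple[str, ...] = ()  # empty = all features
    knn: int = 150
    t: int = 20
    gamma: float = 1.0
    decay_alpha: float = 40.0
    n_bins: int = 50
    min_cells_per_bin: int = 15
    control_condition: str = "control"

    #: stages that draw random numbers and therefore require a seed
    _STOCHASTIC_STAGES = ("phase_model", "embedding")

    def resolve(self) -> "PipelineConfig":
        """Validate and return self (idempotent)."""
        if self.knn < 2:
            raise ValueError("knn must be >= 2")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if not 0 < self.rb_threshold < 1:
            raise ValueError("rb_threshold must lie in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phase_features"] = list(self.phase_features)
        d["embedding_features"] = list(self.embedding_features)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys.

    A seed is mandatory because the phase mixture fit and the embedding are
    stochastic stages; configs without one fail fast rather than silently
    producing irreproducible runs.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    for key in ("phase_features", "embedding_features"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw).resolve()
    if cfg.seed is None:
        raise SchemaError(
            "config must set 'seed': stochastic stages "
            f"{PipelineConfig._STOCHASTIC_STAGES} are enabled"
        )
    return cfg


def write_run_manifest(config: PipelineConfig, path: str | Path, **extra) -> Path:
    """Echo the fully resolved config (plus free-form extras) to a JSON log."""
    path = Path(path)
    payload = {"config": config.to_dict(), **extra}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    logger.info("run manifest written to %s", path)
    return path
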