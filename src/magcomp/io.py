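"""Canonical file formats, run configuration, and report helpers.

One trial-table schema is shared by the simulator, the readers, and the
fitting pipeline, so externally deposited data only need a thin
converter to this layout to flow through unchanged:

    participant_id, experiment_kind, block, phase, trial_index,
    test_magnitude, response {same|different}, seconds_since_phase_start

All tables are plain comma-separated text; configs are YAML with a
versioned ``schema`` key.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import InvalidArgumentError, SchemaError
from .protocol import EXPERIMENT_KINDS

__all__ = [
    "TRIAL_COLUMNS",
    "FIT_COLUMNS",
    "RunConfig",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "write_heart_trace",
    "fits_to_frame",
    "steps_per_second",
    "config_hash",
]

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

TRIAL_COLUMNS = [
    "participant_id",
    "experiment_kind",
    "block",
    "phase",
    "trial_index",
    "test_magnitude",
    "response",
    "seconds_since_phase_start",
]

FIT_COLUMNS = [
    "participant_id",
    "experiment_kind",
    "phase",
    "amplitude",
    "mu",
    "sigma",
    "pse",
    "weber_fraction",
    "bias_percent",
    "r_squared",
    "converged",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to regenerate a simulated dataset bit-identically."""

    experiment_kind: str = "duration_while"
    n_participants: int = 15
    n_blocks: int = 2
    run_gain: float = 600.0 / 513.0
    between_subject_sd: float = 0.05
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    bonferroni_k: int = 3
    root_seed: int = 0
    output_directory: str = "."

    def __post_init__(self):
        if self.experiment_kind not in EXPERIMENT_KINDS:
            raise InvalidArgumentError(
                f"unknown experiment_kind {self.experiment_kind!r}"
            )

    def to_dict(self) -> dict:
        return {
            "schema": CONFIG_SCHEMA_VERSION,
            "experiment_kind": self.experiment_kind,
            "n_participants": self.n_participants,
            "n_blocks": self.n_blocks,
            "run_gain": self.run_gain,
            "between_subject_sd": self.between_subject_sd,
            "n_bootstrap": self.n_bootstrap,
            "alpha": self.alpha,
            "bonferroni_k": self.bonferroni_k,
            "root_seed": self.root_seed,
            "output_directory": self.output_directory,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError("config must be a mapping")
        version = raw.pop("schema", None)
        if version != CONFIG_SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported config schema {version!r}; expected "
                f"{CONFIG_SCHEMA_VERSION}"
            )
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}",
                              sorted(unknown))
        return cls(**raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def validate_trial_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming every offending column."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}", missing)
    bad = set(df["response"].unique()) - {"same", "different"}
    if bad:
        raise SchemaError(
            f"response column contains non-binary values: {sorted(bad)}",
            ["response"],
        )
    if (df["test_magnitude"] <= 0).any():
        raise SchemaError("test_magnitude must be positive", ["test_magnitude"])


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(df)
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trial_table(df)
    return df


def write_heart_trace(
    traces: dict[str, pd.DataFrame], path: str | Path
) -> None:
    """Write per-participant heart-rate traces as one long table."""
    frames = []
    for pid, tr in traces.items():
        frame = tr.copy()
        frame.insert(0, "participant_id", pid)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fits_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble fit-summary rows into the canonical fits table.

    Each row dict carries participant_id, experiment_kind, phase, a
    :class:`~magcomp.psychometric.PsychometricFit` under ``fit`` and the
    reference magnitude under ``reference``.
    """
    out = []
    for row in rows:
        fit = row["fit"]
        out.append(
            {
                "participant_id": row["participant_id"],
                "experiment_kind": row["experiment_kind"],
                "phase": row["phase"],
                "amplitude": fit.amplitude,
                "mu": fit.mu,
                "sigma": fit.sigma,
                "pse": fit.pse if fit.converged else float("nan"),
                "weber_fraction": fit.weber_fraction if fit.converged else float("nan"),
                "bias_percent": (
                    fit.bias_percent(row["reference"]) if fit.converged else float("nan")
                ),
                "r_squared": fit.r_squared,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(out, columns=FIT_COLUMNS)


def steps_per_second(total_steps: float, duration_s: float) -> float:
    """Mean cadence over a running bout, Hz (e.g. 1185.5 steps / 480 s = 2.47)."""
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    if total_steps < 0:
        raise InvalidArgumentError("total_steps must be >= 0")
    return total_steps / duration_s
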