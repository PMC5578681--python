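"""Tab-separated readers and writers, flat-file configuration, run manifests.

All tables are plain TSV with a header row; ``time_bin`` and ``unit_id`` are
0-based integers. Datasets at the scales this model targets (≤ 1e6 records)
stay small enough that inspectable text beats a binary container.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import ModelConfig
from .simulate import ObservationTable

__all__ = [
    "FormatError",
    "read_observations",
    "write_observations",
    "read_covariates",
    "write_covariates",
    "read_latents",
    "write_latents",
    "read_config",
    "write_config",
    "RunManifest",
]

_OBS_COLUMNS = ["observation_id", "time_bin", "unit_id", "count"]


class FormatError(ValueError):
    """Malformed input table; the message carries the offending line number."""


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse as TSV ({err})") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: line 1: missing required column(s) {', '.join(missing)}"
        )
    return df


def _first_bad_line(mask: np.ndarray) -> int:
    # +2: one for the header, one for 0- to 1-based line numbering
    return int(np.argmax(mask)) + 2


def read_observations(
    path: str | Path,
    n_time_bins: int | None = None,
    n_units: int | None = None,
) -> ObservationTable:
    """Read a long-format spike-count table.

    Duplicate (time_bin, unit_id) rows are legal — they are repeated
    presentations and simply raise ``M_tu``. The time and unit universes are
    inferred from the data unless given explicitly.
    """
    df = _read_tsv(path, _OBS_COLUMNS)
    for col in ("time_bin", "unit_id", "count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna().to_numpy() | (vals.to_numpy() % 1 != 0)
        if bad.any():
            raise FormatError(
                f"{path}: line {_first_bad_line(bad)}: non-integer value in '{col}'"
            )
        df[col] = vals.astype(int)
    neg = (df["count"] < 0).to_numpy()
    if neg.any():
        raise FormatError(
            f"{path}: line {_first_bad_line(neg)}: negative count"
        )
    for col in ("time_bin", "unit_id"):
        neg = (df[col] < 0).to_numpy()
        if neg.any():
            raise FormatError(
                f"{path}: line {_first_bad_line(neg)}: negative {col}"
            )
    return ObservationTable.from_frame(df, n_time_bins=n_time_bins, n_units=n_units)


def write_observations(table: ObservationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def _matrix_columns(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def write_covariates(x: np.ndarray, path: str | Path) -> None:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    df = pd.DataFrame(x, columns=_matrix_columns("x", x.shape[1]))
    df.insert(0, "time_bin", np.arange(x.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> np.ndarray:
    df = _read_tsv(path, ["time_bin"])
    cols = [c for c in df.columns if c.startswith("x")]
    x = df.sort_values("time_bin")[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        bad = ~np.all(np.isfinite(x), axis=1)
        raise FormatError(f"{path}: line {_first_bad_line(bad)}: non-finite covariate")
    if np.any(x < 0):
        bad = np.any(x < 0, axis=1)
        raise FormatError(
            f"{path}: line {_first_bad_line(bad)}: negative covariate "
            "(rescale columns to [0, 1])"
        )
    return x


def write_latents(z: np.ndarray, path: str | Path) -> None:
    z = np.atleast_2d(np.asarray(z))
    df = pd.DataFrame(z, columns=_matrix_columns("z", z.shape[1]))
    df.insert(0, "time_bin", np.arange(z.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_latents(path: str | Path) -> np.ndarray:
    df = _read_tsv(path, ["time_bin"])
    cols = [c for c in df.columns if c.startswith("z")]
    return df.sort_values("time_bin")[cols].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# configuration


def read_config(path: str | Path) -> ModelConfig:
    """Flat key-value config; keys mirror :class:`ModelConfig` fields, pairs
    given as two-element lists. Unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    return ModelConfig(**kwargs)


def write_config(config: ModelConfig, path: str | Path) -> None:
    snap = config_snapshot(config)
    with open(path, "w") as fh:
        yaml.safe_dump(snap, fh, sort_keys=False)


def config_snapshot(config: ModelConfig) -> dict:
    out = {}
    for f in dataclasses.fields(ModelConfig):
        v = getattr(config, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


# --------------------------------------------------------------------------
# manifests


@dataclass
class RunManifest:
    """Everything needed to re-run a command: inputs, config, seed, version,
    and per-stage wall times."""

    command: str
    inputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    wall_times: dict = field(default_factory=dict)
    _stage_started: dict = field(default_factory=dict, repr=False)

    def start(self, stage: str) -> None:
        self._stage_started[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.wall_times[stage] = round(
            time.perf_counter() - self._stage_started.pop(stage), 4
        )

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "inputs": self.inputs,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "wall_times_s": self.wall_times,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
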