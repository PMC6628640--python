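"""Readers, writers, configs and run manifests.

Clone-frequency matrices travel as delimited text (TSV by default, CSV
accepted): first column clone labels, header row sample labels, body
fractions in [0, 1] (or percentages with ``percent=True``).  Model parameter
sets are flat YAML/JSON mappings with exactly one of the two parameter
triples.  Every CLI run writes a JSON manifest capturing the command, a
digest of its settings, the RNG seed and any warnings, so deterministic
commands are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import CohortMatrix
from .params import SeedingModel

__all__ = [
    "read_frequency_matrix",
    "write_frequency_matrix",
    "read_model_config",
    "write_results",
    "RunManifest",
]

logger = logging.getLogger(__name__)

RENORM_TOL = 1e-2  # columns off by more than this are rejected, not fixed
FLOAT_FORMAT = "%.6g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_frequency_matrix(path, percent: bool = False,
                          tol: float = RENORM_TOL) -> CohortMatrix:
    """Read a clones x samples frequency table from delimited text.

    Columns summing to 1 within ``tol`` are renormalized (with a logged
    warning when off by more than 1e-6); worse columns are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: not a rectangular delimited table: {exc}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty frequency table")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = [
            (str(df.index[i]), str(df.columns[j]))
            for i, j in zip(*np.where(body.isna().to_numpy()))
        ][:5]
        raise ValueError(f"{path}: non-numeric cells at (clone, sample) {bad}")
    values = body.to_numpy(dtype=float)
    if percent:
        values = values / 100.0
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative frequency for clone {df.index[i]!r} in "
            f"sample {df.columns[j]!r}"
        )
    sums = values.sum(axis=0)
    off = np.abs(sums - 1.0)
    if np.any(off > tol):
        j = int(np.argmax(off))
        raise ValueError(
            f"{path}: sample column {df.columns[j]!r} sums to {sums[j]:.4g}; "
            f"columns must sum to 1 within {tol}"
        )
    return CohortMatrix(
        values,
        clone_labels=list(df.index.astype(str)),
        sample_labels=list(df.columns.astype(str)),
        tol=1e-6,
    )


def write_frequency_matrix(cohort: CohortMatrix, path) -> Path:
    path = Path(path)
    cohort.to_dataframe().to_csv(path, sep=_sep_for(path),
                                 float_format=FLOAT_FORMAT)
    return path


def read_model_config(path) -> SeedingModel:
    """Read a SeedingModel from a YAML or JSON key-value config."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            config = json.load(fh)
        else:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return SeedingModel.from_config(config)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    seed: int | None
    settings: dict
    warnings: list = field(default_factory=list)
    versions: str = field(default_factory=lambda: f"conseed {__version__}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.settings, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "settings": self.settings,
            "warnings": list(self.warnings),
            "versions": self.versions,
        }

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path


def write_results(tables: dict, outdir, manifest: RunManifest) -> list[Path]:
    """Write named DataFrames as TSV (stable column order, 6 significant
    figures) plus the JSON manifest alongside."""
    outdir = Path(outdir)
    if outdir.exists() and not outdir.is_dir():
        raise ValueError(f"{outdir} exists and is not a directory")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format=FLOAT_FORMAT)
        written.append(p)
    written.append(manifest.write(outdir / "manifest.json"))
    return written
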