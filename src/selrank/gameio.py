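"""File formats and reproducibility plumbing.

Games travel as CSV (square numeric matrix, optional strategy-name
header) or JSON ({"strategies": [...], "payoffs": [[...]]}); d-player
tables as CSV with columns k, a_k, b_k.  Every CLI output is paired with
a RunManifest JSON sufficient to re-run it bit-identically.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .games import MatrixGame, MultiplayerPayoffTable

__all__ = ["parse_game_file", "write_curve_tsv", "read_curve_tsv", "RunManifest"]


def parse_game_file(path, format: str | None = None):
    """Load a MatrixGame or MultiplayerPayoffTable from disk.

    ``format`` is "matrix-csv", "matrix-json" or "table-csv"; when None
    it is inferred from the extension and, for CSV, from the presence of
    the k/a_k/b_k header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.suffix.lower() == ".json":
            format = "matrix-json"
        else:
            head = path.open().readline()
            cols = {c.strip() for c in head.split(",")}
            format = "table-csv" if {"k", "a_k", "b_k"} <= cols else "matrix-csv"
    if format == "matrix-json":
        return MatrixGame.from_json(path)
    if format == "matrix-csv":
        return MatrixGame.from_csv(path)
    if format == "table-csv":
        return MultiplayerPayoffTable.from_csv(path)
    raise ValueError(f"unknown game format {format!r}")


def write_curve_tsv(curve, path, names=None) -> None:
    """Abundance curve as TSV: beta, x_1..x_n."""
    n = curve.n
    if names is None:
        names = [f"x_{i + 1}" for i in range(n)]
    df = pd.DataFrame(curve.x, columns=list(names))
    df.insert(0, "beta", curve.grid.values)
    df.to_csv(path, sep="\t", index=False)


def read_curve_tsv(path):
    from .rank_sweep import AbundanceCurve, BetaGrid

    df = pd.read_csv(path, sep="\t")
    grid = BetaGrid(df["beta"].to_numpy())
    return AbundanceCurve(grid=grid, x=df.drop(columns="beta").to_numpy())


def fixation_matrix_json(fm, path=None) -> str:
    """Dump a fixation matrix (debugging aid)."""
    obj = {
        "beta": fm.beta,
        "rho": np.where(np.isnan(fm.rho), None, fm.rho).tolist(),
        "log_rho": np.where(np.isnan(fm.log_rho), None, fm.log_rho).tolist(),
    }
    text = json.dumps(obj, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class RunManifest:
    """Everything needed to reproduce one CLI invocation bit-identically."""

    command: str
    config: dict
    seed: int | None = None
    outputs: list = field(default_factory=list)
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    @staticmethod
    def for_output(out_path) -> Path:
        out_path = Path(out_path)
        return out_path.with_name(out_path.name + ".manifest.json")
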