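"""Shared plumbing: validated table I/O, YAML configs, seeded RNG, run manifests.

All tabular interchange is plain comma-separated UTF-8 text with a mandatory
header row. Schemas declare the required columns, their dtypes and simple
row-level invariants; violations are reported with 1-based data row numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("waspqg")


class TableFormatError(ValueError):
    """Raised when an input table violates its schema."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "label", "count", "real"


@dataclass(frozen=True)
class TableSchema:
    """Declarative schema for a comma-separated table."""

    name: str
    columns: tuple[ColumnSpec, ...]
    # each checker: (row as Series) -> error message or None
    row_checks: tuple[tuple[str, Callable[[pd.Series], bool]], ...] = ()

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def _coerce_column(df: pd.DataFrame, col: ColumnSpec, table: str) -> None:
    s = df[col.name]
    if col.kind == "label":
        df[col.name] = s.astype(str)
        return
    numeric = pd.to_numeric(s, errors="coerce")
    bad = numeric.isna() & s.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise TableFormatError(
            f"{table}: column '{col.name}' is not numeric at data row {row}"
        )
    if col.kind == "count":
        frac = numeric.dropna() % 1
        if (frac != 0).any() or (numeric.dropna() < 0).any():
            row = int(numeric.index[(numeric % 1 != 0) | (numeric < 0)][0]) + 1
            raise TableFormatError(
                f"{table}: column '{col.name}' must hold non-negative integers "
                f"(data row {row})"
            )
        df[col.name] = numeric.astype("int64")
    else:
        df[col.name] = numeric.astype(float)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a comma-separated table against *schema*.

    Raises
    ------
    TableFormatError
        On a missing file, missing header/columns, type violations, or
        row-invariant violations; messages carry 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"{schema.name}: file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{schema.name}: empty file: {path}") from None
    missing = set(schema.column_names()) - set(df.columns)
    if missing:
        raise TableFormatError(
            f"{schema.name}: missing column(s) {sorted(missing)} in {path} "
            f"(is the header row present?)"
        )
    if df.empty:
        raise TableFormatError(f"{schema.name}: no data rows in {path}")
    df = df.reset_index(drop=True)
    for col in schema.columns:
        _coerce_column(df, col, schema.name)
    for message, check in schema.row_checks:
        ok = df.apply(check, axis=1)
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0]) + 1

            raise TableFormatError(f"{schema.name}: {message} (data row {row})")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# Concrete schemas used across the pipeline

TRIALS_SCHEMA = TableSchema(
    name="trials",
    columns=(
        ColumnSpec("female_id", "label"),
        ColumnSpec("day_id", "label"),
        ColumnSpec("line_id", "label"),
        ColumnSpec("generation", "count"),
        ColumnSpec("n_larvae", "count"),
        ColumnSpec("flies_emerged", "count"),
        ColumnSpec("flies_encapsulated", "count"),
        ColumnSpec("wasp_offspring", "count"),
    ),
    row_checks=(
        (
            "flies_encapsulated exceeds flies_emerged",
            lambda r: r["flies_encapsulated"] <= r["flies_emerged"],
        ),
        (
            "flies_emerged exceeds n_larvae",
            lambda r: r["flies_emerged"] <= r["n_larvae"],
        ),
        (
            "wasp_offspring exceeds dead larvae (n_larvae - flies_emerged)",
            lambda r: r["wasp_offspring"] <= r["n_larvae"] - r["flies_emerged"],
        ),
    ),
)

CONTROLS_SCHEMA = TableSchema(
    name="controls",
    columns=(
        ColumnSpec("day_id", "label"),
        ColumnSpec("vial_id", "label"),
        ColumnSpec("n_larvae", "count"),
        ColumnSpec("flies_emerged", "count"),
    ),
    row_checks=(
        (
            "flies_emerged exceeds n_larvae",
            lambda r: r["flies_emerged"] <= r["n_larvae"],
        ),
    ),
)

PEDIGREE_SCHEMA = TableSchema(
    name="pedigree",
    columns=(
        ColumnSpec("id", "label"),
        ColumnSpec("sex", "label"),
        ColumnSpec("dam", "label"),
        ColumnSpec("sire", "label"),
    ),
)

MEANS_SCHEMA = TableSchema(
    name="generation_means",
    columns=(
        ColumnSpec("line_id", "label"),
        ColumnSpec("generation", "count"),
        ColumnSpec("mean_all", "real"),
        ColumnSpec("mean_selected", "real"),
        ColumnSpec("mean_offspring", "real"),
    ),
)


# ---------------------------------------------------------------------------
# Config + RNG + manifest services


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (empty file -> {})."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, Mapping):
        raise TableFormatError(f"config {path} must be a YAML mapping")
    return dict(cfg)


def rng_from_seed(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic generator; spawn keys isolate independent streams."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI run.

    An output produced with a manifest can be regenerated from the recorded
    command, config hash and seed alone.
    """

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _digest(p)

    def write(self, path: str | Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        cfg_text = json.dumps(self.config, sort_keys=True, default=str)
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "package_version": _package_version(),
            "inputs": self.inputs,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
        return path


def _package_version() -> str:
    from waspqg import __version__

    return __version__


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
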