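"""Readers and writers for the package's plain-text formats.

Beta matrices are TSV/CSV with a ``probe_id`` first column and sample ids in
the header; sample sheets are CSV keyed by ``sample_id``; manifests are TSV
keyed by ``probe_id``.  The delimiter is auto-detected from the file
extension (``.tsv`` -> tab, ``.csv`` -> comma) and can be overridden.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .core import BetaMatrix, ParseError, ProbeManifest, SampleSheet

logger = logging.getLogger("comethnet")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path, delimiter: str | None, index_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.empty or df.shape[1] < 2:
        raise ParseError(f"{path}: empty or single-column table")
    first = df.columns[0]
    if first != index_col:
        raise ParseError(f"{path}: first column must be {index_col!r}, got {first!r}")
    return df.set_index(first)


def read_beta_matrix(
    path,
    delimiter: str | None = None,
    on_out_of_range: str = "reject",
) -> BetaMatrix:
    """Read a probes x samples beta matrix.

    ``on_out_of_range`` is ``"reject"`` (default: any value outside [0, 1]
    is a parse error) or ``"clamp"`` (values clipped into [0, 1]).
    """
    df = _read_table(path, delimiter, "probe_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric beta value ({exc})") from exc
    if on_out_of_range == "clamp":
        df = df.clip(0.0, 1.0)
    elif on_out_of_range != "reject":
        raise ParseError(f"unknown out-of-range policy {on_out_of_range!r}")
    try:
        return BetaMatrix(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_beta_matrix(beta: BetaMatrix, path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    beta.values.to_csv(path, sep=sep, index_label="probe_id", float_format="%.10g")


def read_sample_sheet(path, delimiter: str | None = None) -> SampleSheet:
    """Read a sample sheet; unknown columns are preserved as traits."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    df["sample_id"] = df["sample_id"].astype(str)
    try:
        return SampleSheet(df.set_index("sample_id"))
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str | None = None) -> None:
    path = Path(path)
    sheet.data.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="sample_id")


def read_manifest(path, delimiter: str | None = None) -> ProbeManifest:
    df = _read_table(path, delimiter, "probe_id")
    try:
        return ProbeManifest(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_manifest(manifest: ProbeManifest, path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    manifest.data.to_csv(path, sep=sep, index_label="probe_id")


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    """Route package logging to stderr at the given level."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
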