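"""Readers, writers, and run manifests.

Every format is plain text. Doses always travel with an explicit unit
column (``M``, ``mM``, ``uM``, ``nM``) and are converted to mol/l on read.
Gene models come from GFF3 (gene/tRNA/pseudogene/transposable-element
features, 1-based inclusive coordinates, strand required) or an
equivalent TSV. A run manifest records the configuration, seed, package
version and input checksums so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UNIT_FACTORS",
    "ParseError",
    "dose_to_molar",
    "read_growth_counts",
    "write_growth_counts",
    "read_compound_table",
    "read_dose_table",
    "read_plate_reader",
    "read_screen_counts",
    "write_screen_counts",
    "read_gene_models",
    "read_two_column_tsv",
    "write_table",
    "write_manifest",
]

UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


class ParseError(ValueError):
    """A malformed input file, naming the file and offending location."""


def dose_to_molar(value: float, unit: str) -> float:
    try:
        return float(value) * UNIT_FACTORS[unit]
    except KeyError:
        raise ParseError(f"unknown dose unit {unit!r}; expected one of {sorted(UNIT_FACTORS)}")


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")


def read_growth_counts(path) -> pd.DataFrame:
    """Long-format growth counts: ``well_id, time_h, count`` (TSV).

    Extra annotation columns (compound, dose...) pass through untouched.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"well_id", "time_h", "count"}, path)
    for col in ("time_h", "count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: line {line}: non-numeric {col!r}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_growth_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_compound_table(path) -> pd.DataFrame:
    """Compound metadata CSV: name, mw_g_per_mol, solvent, teratogen_truth
    and optional rat reference doses."""
    df = pd.read_csv(path)
    _require_columns(df, {"name", "mw_g_per_mol"}, path)
    if (pd.to_numeric(df["mw_g_per_mol"], errors="coerce") <= 0).any():
        raise ParseError(f"{path}: mw_g_per_mol must be numeric and > 0")
    return df


def read_dose_table(path) -> pd.DataFrame:
    """Dose dataset CSV ``endpoint, compound, dose, unit[, source]``.

    Returns the table with an added ``dose_molar`` column in mol/l.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"endpoint", "compound", "dose", "unit"}, path)
    df["dose_molar"] = [dose_to_molar(v, u) for v, u in zip(df["dose"], df["unit"])]
    return df


def read_plate_reader(csv_path, layout_path) -> pd.DataFrame:
    """Wide plate-reader export plus a YAML plate layout.

    The CSV has a ``time_h`` column and one column per well; the YAML maps
    well -> {compound, dose, unit, reporter, replicate[, channel]}. Returns
    a long table ``compound, dose_molar, reporter, replicate_id, time_h,
    fluorescence``.
    """
    wide = pd.read_csv(csv_path)
    _require_columns(wide, {"time_h"}, csv_path)
    with open(layout_path) as fh:
        layout = yaml.safe_load(fh)
    if not isinstance(layout, Mapping):
        raise ParseError(f"{layout_path}: expected a mapping of well -> metadata")
    rows = []
    for well, meta in layout.items():
        if well not in wide.columns:
            raise ParseError(f"{csv_path}: layout well {well!r} absent from export")
        for key in ("compound", "dose", "unit", "reporter", "replicate"):
            if key not in meta:
                raise ParseError(f"{layout_path}: well {well!r} missing {key!r}")
        rows.append(
            pd.DataFrame(
                {
                    "compound": meta["compound"],
                    "dose_molar": dose_to_molar(meta["dose"], meta["unit"]),
                    "reporter": meta["reporter"],
                    "replicate_id": str(meta["replicate"]),
                    "time_h": wide["time_h"],
                    "fluorescence": wide[well],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def read_screen_counts(path) -> pd.DataFrame:
    """Long screen count TSV ``insertion_id, screen, replicate, round,
    count`` (optional ``tag``/``unique`` columns)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, {"insertion_id", "screen", "replicate", "round", "count"}, path)
    return df


def write_screen_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


_GFF_EXCLUDED_TYPES = {
    "tRNA": "tRNA",
    "tRNA_gene": "tRNA",
    "pseudogene": "pseudogene",
    "transposable_element": "transposable_element",
    "transposable_element_gene": "transposable_element",
}
_GENE_TYPES = set(_GFF_EXCLUDED_TYPES) | {"gene", "protein_coding_gene"}


def read_gene_models(path) -> pd.DataFrame:
    """Gene models from GFF3 or an equivalent TSV.

    GFF3: ``gene``-like, tRNA, pseudogene and transposable-element features
    are kept; coordinates are 1-based inclusive; a record without a strand
    is rejected. TSV alternative: columns ``gene_id, chromosome, start,
    end, strand, gene_type``.

    Returns a DataFrame with exactly those six columns.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, {"gene_id", "chromosome", "start", "end", "strand", "gene_type"}, path)
        if not df["strand"].isin(["+", "-"]).all():
            raise ParseError(f"{path}: every record needs strand + or -")
        return df

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _GENE_TYPES:
                continue
            if strand not in ("+", "-"):
                raise ParseError(f"{path}: line {lineno}: missing strand; record rejected")
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed coordinate")
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}: line {lineno}: malformed coordinate")
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: feature lacks an ID attribute")
            rows.append(
                {
                    "gene_id": gene_id,
                    "chromosome": seqid,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "gene_type": _GFF_EXCLUDED_TYPES.get(ftype, "gene"),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand", "gene_type"]
    )


def read_two_column_tsv(path, columns: tuple[str, str]) -> pd.DataFrame:
    """Headerless or headered two-column TSV (blacklists, term->gene maps)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly 2 columns")
    if tuple(df.iloc[0]) == columns:  # headered variant
        df = df.iloc[1:].reset_index(drop=True)
    df.columns = list(columns)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV (the package's output dialect)."""
    df.to_csv(path, sep="\t", index=index)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: Mapping, inputs: Mapping[str, str] | None = None) -> Path:
    """Write run.manifest.json capturing config, versions and input checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: config[k] for k in sorted(config)},
        "versions": {
            "dictytox": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {
            name: _checksum(path) for name, path in sorted((inputs or {}).items())
        },
    }
    path = out_dir / "run.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
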