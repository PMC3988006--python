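"""Readers and writers for the tab-delimited table dialect shared by all stages.

Canonical dialect: UTF-8, Unix newlines, tab-separated, header row required,
missing values encoded as empty fields.  Gene identifiers are opaque,
case-sensitive strings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .metrics import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

SEP = "\t"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=SEP, index=False, na_rep="", lineterminator="\n")


def read_table(path, numeric_columns: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=SEP, dtype={"gene_id": str})
    if numeric_columns:
        for col in numeric_columns:
            if col not in df.columns:
                continue
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                line = int(bad.index[0]) + 2 if len(bad) else "?"
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r} near line {line}"
                ) from exc
    return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    cols = ["gene_id"] + [c for c in FEATURE_COLUMNS if c in table.columns]
    write_table(table[cols], path)


def read_feature_table(path) -> pd.DataFrame:
    """FeatureTable from disk: typed columns, empty fields become missing."""
    df = read_table(path, numeric_columns=FEATURE_COLUMNS)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: feature table must contain a 'gene_id' column")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id values: {sorted(set(dup))[:5]}")
    return df


def read_gene_list(path) -> list[str]:
    """One identifier per line; '#' comments and blank lines ignored;
    duplicates collapsed (keeping first occurrence) with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    genes: list[str] = []
    seen = set()
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            logger.warning("duplicate gene %r in %s; keeping first occurrence", line, path)
            continue
        seen.add(line)
        genes.append(line)
    if not genes:
        raise ValueError(f"{path}: gene list is empty")
    return genes


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_edge_list(path) -> pd.DataFrame:
    df = read_table(path)
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"{path}: edge list needs 'gene_a' and 'gene_b' columns")
    return df.astype({"gene_a": str, "gene_b": str})


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir,
    subcommand: str,
    seed: int | None,
    config: dict | None = None,
    inputs: Sequence[str] = (),
    outputs: Sequence[str] = (),
    status: str = "complete",
) -> Path:
    """One manifest per output directory, recording enough to reproduce the run."""
    from . import __version__

    outdir = Path(outdir)
    config_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "tool": "clockrank",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "status": status,
        "config": config or {},
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "input_digests": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
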