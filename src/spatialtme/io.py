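"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV (genes x AOIs, first column ``gene``, boolean column
``is_negative_probe``); annotations, cohorts and cell tables as CSV; gene-set
collections as standard GMT.  A run manifest is flat ``key=value`` text.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd


def write_counts_tsv(path, counts: pd.DataFrame, is_negative_probe: pd.Series) -> None:
    """Write a genes x AOIs count matrix with its negative-probe flags."""
    out = counts.copy()
    out.insert(0, "is_negative_probe", is_negative_probe.reindex(counts.index).astype(bool))
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a counts TSV; returns (counts, is_negative_probe)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "is_negative_probe" in df.columns:
        flags = df.pop("is_negative_probe").astype(bool)
    else:
        flags = pd.Series(False, index=df.index)
    return df, flags


def write_annotations_csv(path, annot: pd.DataFrame) -> None:
    annot.to_csv(path, index=False)


def read_annotations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cells_csv(path, cells: pd.DataFrame) -> None:
    cols = ["cell_id", "x_um", "y_um", "phenotype", "compartment"]
    extra = [c for c in cells.columns if c not in cols]
    cells[[c for c in cols if c in cells.columns] + extra].to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(path, sets: Mapping[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_manifest(path, params: Mapping[str, object]) -> None:
    """Record run parameters as ``key=value`` lines (one per parameter)."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]}\n")


def read_manifest(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
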