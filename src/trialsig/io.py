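"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as tab-delimited gene x sample tables, gene sets as GMT
(name, description, members...), clinical tables as CSV with a fixed schema,
and results as TSV/JSON.  All outputs are UTF-8 with LF line endings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CLINICAL_COLUMNS = ["sample", "arm", "response", "pfs_months", "event", "platinum_status"]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_genes(cls, name: str, genes, description: str = "") -> "GeneSet":
        return cls(name=name, description=description, members=frozenset(genes))

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated name, description, genes."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            sets.append(GeneSet.from_genes(parts[0], parts[2:], description=parts[1]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.sorted_members()]) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV; requires the fixed schema columns."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} is missing columns: {missing}")
    if df["sample"].duplicated().any():
        raise ValueError(f"duplicate sample identifiers in clinical table {path}")
    if (df["pfs_months"] < 0).any():
        bad = df.loc[df["pfs_months"] < 0, "sample"].tolist()
        raise ValueError(f"negative pfs_months for samples {bad}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
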