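"""File formats: GMT gene sets, expression TSV, edge-list networks, survival CSV.

All tabular formats are UTF-8 TSV/CSV with explicit headers (GMT
excepted, which follows the standard tab layout: name, description,
members). Gene identifiers are treated as opaque strings. Every
writer/reader pair is an identity on its domain.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_survival",
    "write_survival",
]


def read_gmt(path) -> dict[str, list]:
    """Read a GMT file into an ordered {name: member list} mapping."""
    path = Path(path)
    sets: dict[str, list] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[2:]:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and >= 1 member")
            name, members = parts[0], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"{path}:{lineno}: empty member list")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list], path, description: str = "") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, members in sets.items():
            if not members:
                raise ValueError(f"set {name!r} is empty")
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def signature_to_gmt(up, down, stem: str) -> dict[str, list]:
    """Two-line GMT layout for an up/down signature."""
    return {f"{stem}_UP": sorted(up), f"{stem}_DN": sorted(down)}


def read_expression(path) -> pd.DataFrame:
    """Gene-by-sample TSV: first column gene ids, header row sample ids."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    bad = df.isna()
    if bad.any().any():
        r = df.index[bad.any(axis=1)][0]
        c = df.columns[bad.any(axis=0)][0]
        raise ValueError(f"{path}: missing/non-numeric cell near ({r}, {c})")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cells: {exc}") from exc


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_network(path) -> pd.DataFrame:
    """Edge-list TSV with columns (parent, child[, support, cohorts])."""
    df = pd.read_csv(path, sep="\t", dtype={"parent": str, "child": str})
    if "parent" not in df.columns or "child" not in df.columns:
        raise ValueError(f"{path}: need parent and child columns")
    if (df["parent"] == df["child"]).any():
        raise ValueError(f"{path}: self-loop rows are not allowed")
    if "support" not in df.columns:
        warnings.warn(f"{path}: no support column; defaulting to 1.0")
        df["support"] = 1.0
    if "cohorts" not in df.columns:
        df["cohorts"] = ""
    return df[["parent", "child", "support", "cohorts"]]


def write_network(edges: pd.DataFrame, path) -> None:
    """Write (parent, child, support[, cohorts]) sorted lexicographically."""
    df = edges.copy()
    if "cohorts" not in df.columns:
        df["cohorts"] = ""
    df = df.sort_values(["parent", "child"])
    df.to_csv(path, sep="\t", index=False,
              columns=["parent", "child", "support", "cohorts"])


def read_survival(path) -> pd.DataFrame:
    """Survival CSV with columns (sample, time, event[, group, anchor_expr])."""
    df = pd.read_csv(path).set_index("sample")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="sample")
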