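"""Readers and writers for on-disk artifacts.

Everything tabular is tab-delimited UTF-8 with a header; gene sets use the
Broad GMT dialect (one set per line: name, description, then members).  TFS
codes are serialized as fixed-format strings ("6.0220", trailing digits
meaningful) and are never parsed as floating point.  Gene identifiers are
opaque case-sensitive tokens matched exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .normalize import HYB_COLUMNS, ORIENTATIONS

_FLAG_COLUMNS = [c for c in HYB_COLUMNS if c.startswith("flag_")]
_INTENSITY_COLUMNS = ["channel_A_intensity", "channel_B_intensity"]

RESULT_FILES = (
    "comparison_results.tsv",
    "tfs_assignments.tsv",
    "class_summary.tsv",
    "enrichment.tsv",
)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GO term, motif target set, or miRNA target set)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def write_hybridization(hyb: pd.DataFrame, path) -> None:
    df = hyb[HYB_COLUMNS].copy()
    for c in _FLAG_COLUMNS:
        df[c] = df[c].astype(bool).astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_hybridization(path) -> pd.DataFrame:
    """Read one hybridization table, validating schema and types strictly."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    missing = [c for c in HYB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[HYB_COLUMNS]
    df["gene_id"] = df["gene_id"].fillna("")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head(3).tolist()
        raise ValueError(f"{path}: duplicate probe_id values, e.g. {dups}")
    for c in _INTENSITY_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise")
        if df[c].isna().any() or (df[c] < 0).any():
            raise ValueError(f"{path}: column {c} has missing or negative values")
    bad = ~df["dye_orientation"].isin(ORIENTATIONS)
    if bad.any():
        raise ValueError(
            f"{path}: invalid dye_orientation values {set(df.loc[bad, 'dye_orientation'])}"
        )
    for c in _FLAG_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(bool)
    return df


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[["probe_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> pd.DataFrame:
    """Probe -> gene annotation; probes without a gene are kept, marked "".

    probe_id must be unique; gene assignments may be missing (unannotated
    probes pass through differential-expression analysis but are excluded
    from gene-level tables).
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    for c in ("probe_id", "gene_id"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe_id values")
    df["gene_id"] = df["gene_id"].fillna("")
    return df[["probe_id", "gene_id"]]


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one set per line, name TAB description TAB members...

    Duplicate members within a line are deduplicated; empty lines skipped;
    a line with fewer than three fields, or a repeated set name, is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            members = [f for f in fields[2:] if f]
            if len(fields) < 3 or not members:
                raise ValueError(f"{path}:{lineno}: gene-set line with no members")
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            sets.append(GeneSet(name, fields[1], frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def write_manifest(files: Mapping[int, list], path) -> None:
    """Manifest mapping comparisons 1-4 to their hybridization files."""
    doc = {
        "comparisons": {
            int(k): [str(f) for f in v] for k, v in sorted(files.items())
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifest(path) -> dict[int, list[Path]]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "comparisons" not in doc:
        raise ValueError(f"{path}: manifest must contain a 'comparisons' mapping")
    comps = doc["comparisons"]
    out: dict[int, list[Path]] = {}
    base = Path(path).parent
    for k, v in comps.items():
        k = int(k)
        if k not in (1, 2, 3, 4):
            raise ValueError(f"{path}: comparison key must be 1-4, got {k}")
        out[k] = [Path(f) if os.path.isabs(f) else base / f for f in v]
    missing = sorted(set((1, 2, 3, 4)) - set(out))
    if missing:
        raise ValueError(f"{path}: manifest missing comparisons {missing}")
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir, overwrite: bool = False
) -> list[Path]:
    """Write pipeline result tables as ``<name>.tsv`` under ``out_dir``.

    Refuses to clobber existing files unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_tfs_assignments(path) -> pd.DataFrame:
    """Read a tfs_assignments table, keeping TFS codes as exact strings."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "probe_id": str, "tfs": str, "tfs_class": str},
    )


def read_comparison_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})


def read_gene_list(path) -> list[str]:
    """One gene identifier per line; blanks skipped."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]
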