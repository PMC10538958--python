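"""Readers and writers for every on-disk format, plus config and run logging.

All tables are UTF-8 TSV with "." decimals; a missing value is written as
an empty cell and parsed back from an empty cell or "NA".  Writers emit
byte-stable output: fixed row/column order and fixed numeric formatting
(6 significant digits for scores and abundances, scientific notation for
p-values).  See FORMATS.md at the repository root for the column contracts.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .containers import AbundanceMatrix, AnnotationCollection, EdgeList, canonical_edge

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def fmt_value(x: float) -> str:
    """Abundances and scores: 6 significant digits; missing -> empty cell."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return format(float(x), ".6g")


def fmt_pvalue(x: float) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return format(float(x), ".6e")


# ---------------------------------------------------------------------------
# Matrices


def read_design(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample design TSV (columns: sample, group[, plex]).

    Returns (sample -> group, sample -> plex); the plex mapping is empty
    when no plex column is present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: design file needs 'sample' and 'group' columns")
    groups = dict(zip(df["sample"], df["group"]))
    plex = dict(zip(df["sample"], df["plex"])) if "plex" in df.columns else {}
    return groups, plex


def write_design(matrix: AbundanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["sample", "group"] + (["plex"] if matrix.sample_plex else [])
        fh.write("\t".join(cols) + "\n")
        for s in matrix.sample_ids:
            row = [s, matrix.sample_groups[s]]
            if matrix.sample_plex:
                row.append(str(matrix.sample_plex.get(s, "")))
            fh.write("\t".join(row) + "\n")


def read_matrix(
    path: str | Path,
    design_path: str | Path | None = None,
    value_scale: str = "raw_intensity",
    sample_groups: Optional[dict[str, str]] = None,
    sample_plex: Optional[dict[str, str]] = None,
) -> AbundanceMatrix:
    """Read a feature x sample TSV matrix.

    The first column is the feature id; remaining columns are samples.
    Empty cells and "NA" are parsed as missing.  Group metadata comes from
    a sidecar design TSV (``design_path``) or explicit mappings.  Duplicate
    feature ids and ragged rows raise with the offending line numbers.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: missing header row")
        cols = header.split("\t")
        samples = cols[1:]
        seen: dict[str, int] = {}
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {len(cols)})"
                )
            fid = parts[0]
            if fid in seen:
                raise ValueError(
                    f"{path}: duplicate feature id {fid!r} on lines {seen[fid]} and {lineno}"
                )
            seen[fid] = lineno
            ids.append(fid)
            rows.append(
                [np.nan if c in MISSING_TOKENS else float(c) for c in parts[1:]]
            )
    values = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    if design_path is not None:
        sample_groups, sample_plex = read_design(design_path)
    if sample_groups is None:
        raise ValueError("sample group metadata required (design_path or sample_groups)")
    groups = {s: sample_groups[s] for s in samples}
    plex = {s: sample_plex[s] for s in samples if sample_plex and s in sample_plex} or None
    return AbundanceMatrix(values=values, sample_groups=groups,
                           value_scale=value_scale, sample_plex=plex)


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy(dtype=float)
        for fid, row in zip(matrix.feature_ids, arr):
            fh.write(fid + "\t" + "\t".join(fmt_value(v) for v in row) + "\n")


_PVALUE_COLUMNS = ("p", "q", "grubbs_p")


def _is_pvalue_column(name: str) -> bool:
    return name in _PVALUE_COLUMNS or name.startswith(("p_", "q_", "padj_"))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Byte-stable TSV writer for result tables.

    Score/abundance columns use 6 significant digits, p/q columns use
    scientific notation, missing cells are empty.
    """
    out = df.copy()
    if index:
        out = out.reset_index()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            f = fmt_pvalue if _is_pvalue_column(str(col)) else fmt_value
            out[col] = out[col].map(f)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT annotation collections


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: term, description, then tab-separated members.

    Duplicate members within a term are collapsed; a duplicate term id or a
    line with fewer than 3 fields raises with the line number.
    """
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            term, desc = parts[0], parts[1]
            if term in terms:
                raise ValueError(f"{path}: duplicate term id {term!r} at line {lineno}")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValueError(f"{path}: term {term!r} at line {lineno} has no members")
            terms[term] = (desc, members)
    return AnnotationCollection(terms=terms)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.terms):
            desc, members = collection.terms[term]
            fh.write("\t".join([term, desc] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# SIF edge lists


def write_sif(network: EdgeList, path: str | Path) -> None:
    """Write a SIF file (source, relation, target) plus a companion
    node-attribute TSV at ``<path>.attrs.tsv``.

    Edges are canonicalized (lexicographic node order) and sorted, so the
    output is byte-stable.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            rel = network.edges[(a, b)].get("relation", "pp")
            fh.write(f"{a}\t{rel}\t{b}\n")
    attr_keys: list[str] = []
    for attrs in network.node_attributes.values():
        for k in attrs:
            if k not in attr_keys:
                attr_keys.append(k)
    with open(str(path) + ".attrs.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(["node"] + attr_keys) + "\n")
        for node in sorted(network.node_attributes):
            attrs = network.node_attributes[node]
            fh.write("\t".join([node] + [str(attrs.get(k, "")) for k in attr_keys]) + "\n")


def read_sif(path: str | Path) -> EdgeList:
    el = EdgeList()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                a, rel, b = parts[0], "pp", parts[1]
            elif len(parts) >= 3:
                a, rel, b = parts[0], parts[1], parts[2]
            else:
                raise ValueError(f"{path}: line {lineno} is not a SIF edge")
            if a == b:
                continue  # drop self-loops on read
            el.add_edge(a, b, relation=rel)
    return el


# ---------------------------------------------------------------------------
# Phosphosite tables


PHOSPHO_META_COLS = ["id", "protein", "position", "residue", "window", "localization_prob"]


def write_phospho_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a phosphosite table: metadata columns then per-sample log2
    intensities (empty cell = missing)."""
    sample_cols = [c for c in sites.columns if c not in PHOSPHO_META_COLS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PHOSPHO_META_COLS + sample_cols) + "\n")
        for _, row in sites.iterrows():
            meta = [
                str(row["id"]), str(row["protein"]), str(int(row["position"])),
                str(row["residue"]), str(row["window"]),
                format(float(row["localization_prob"]), ".4f"),
            ]
            vals = [fmt_value(row[c]) for c in sample_cols]
            fh.write("\t".join(meta + vals) + "\n")


def read_phospho_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "protein": str,
                                            "residue": str, "window": str},
                     na_values=["NA"], keep_default_na=True)
    missing = [c for c in PHOSPHO_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phosphosite table lacks columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Kinase motif mini-format


def read_motifs(path: str | Path):
    """Read the kinase motif TSV: kinase name, then ``offset:residues`` pairs.

    Offset 0 defines the allowed center residues.  Example line::

        PKA\t-3:R\t-2:R\t0:ST
    """
    from .kinase import KinaseMotif

    motifs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} has no offset constraints")
            name = parts[0]
            constraints: dict[int, frozenset] = {}
            for tok in parts[1:]:
                off_s, _, residues = tok.partition(":")
                if not residues:
                    raise ValueError(f"{path}: line {lineno}: bad constraint {tok!r}")
                constraints[int(off_s)] = frozenset(residues.upper())
            if 0 not in constraints:
                raise ValueError(f"{path}: line {lineno}: motif {name!r} lacks offset 0")
            motifs.append(KinaseMotif(name=name, constraints=constraints))
    return motifs


def write_motifs(motifs, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in motifs:
            toks = [f"{off}:{''.join(sorted(res))}" for off, res in sorted(m.constraints.items())]
            fh.write("\t".join([m.name] + toks) + "\n")


# ---------------------------------------------------------------------------
# Config and run logging


def load_config(path: str | Path) -> dict:
    """Load the structured config file (YAML sections of flat key-value)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class RunLogger:
    """Plain-text timestamped event log plus a deterministic run manifest.

    The log file carries wall-clock timestamps and therefore lives under
    ``<out_dir>/logs``; the manifest (config hash, seeds, paths, filter
    counts) is fully deterministic and is written next to the outputs.
    """

    def __init__(self, out_dir: str | Path, name: str = "run"):
        self.out_dir = Path(out_dir)
        (self.out_dir / "logs").mkdir(parents=True, exist_ok=True)
        self.log_path = self.out_dir / "logs" / f"{name}.log"
        self.manifest: dict = {"events": []}
        self._fh = open(self.log_path, "a", encoding="utf-8")

    def log(self, message: str, **record) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._fh.write(f"{stamp}\t{message}\n")
        self._fh.flush()
        if record:
            self.manifest["events"].append({"message": message, **record})

    def set(self, **fields) -> None:
        self.manifest.update(fields)

    def write_manifest(self, name: str = "run_manifest.json") -> Path:
        path = self.out_dir / name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return path

    def close(self) -> None:
        self._fh.close()
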