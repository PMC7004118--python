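"""Typed readers and writers for every external format the pipeline touches.

Canonical tabular dialect is TSV (tab separated, UTF-8, one header row).
Matrix and table writers emit a provenance header of ``# key: value``
lines recording the run seed and thresholds; readers skip ``#`` lines.
Gene identifiers are treated as opaque strings throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSignature,
    Module,
    ModuleHierarchy,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger("coexnet")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


def _provenance_lines(provenance: Mapping | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, stage_tag: str = "raw") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids).

    Rows containing any missing value are dropped and logged; duplicate
    gene or sample ids are rejected.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene id column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    body = df.drop(columns=[gene_col])
    for col in body.columns:
        coerced = pd.to_numeric(body[col], errors="coerce")
        bad = coerced.isna() & body[col].notna()
        if bad.any():
            row = genes[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ParseError(f"{path}: malformed numeric cell at gene {row!r}, sample {col!r}")
        body[col] = coerced
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{path}: duplicate gene ids present")
    keep = body.notna().all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d gene rows with missing values", path, n_dropped)
    genes = [g for g, k in zip(genes, keep) if k]
    return ExpressionMatrix(genes, [str(c) for c in body.columns],
                            body.to_numpy(dtype=float)[keep], stage_tag)


def write_expression_matrix(x: ExpressionMatrix, path, provenance: Mapping | None = None) -> None:
    meta = {"stage_tag": x.stage_tag, **(provenance or {})}
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta))
        x.to_frame().to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# survival tables


def read_survival_table(path, time_col: str = "time", event_col: str = "event",
                        sample_col: str = "sample_id",
                        strata_cols: Iterable[str] = ()) -> SurvivalTable:
    """Read a clinical TSV; rows with nonpositive time or non-binary event
    are dropped with the count logged."""
    df = _read_tsv(path)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    time = pd.to_numeric(df[time_col], errors="coerce")
    event = pd.to_numeric(df[event_col], errors="coerce")
    ok = time.notna() & (time > 0) & event.isin([0, 1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with invalid time/event", path, n_dropped)
    df = df.loc[ok]
    strata_cols = [c for c in strata_cols if c in df.columns]
    strata = df[strata_cols].reset_index(drop=True) if strata_cols else None
    return SurvivalTable(df[sample_col].astype(str).tolist(),
                         time.loc[ok].to_numpy(), event.loc[ok].to_numpy(int), strata)


def write_survival_table(s: SurvivalTable, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        s.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT gene-set collections


def read_gmt(path) -> list[GeneSignature]:
    """Read a standard GMT file: name TAB description TAB gene TAB gene ...

    Lines with fewer than three fields, or with an empty gene list after
    stripping, are skipped with a logged warning.
    """
    out: list[GeneSignature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line with <3 fields skipped", path, ln)
                continue
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("%s:%d: empty gene list for %r skipped", path, ln, name)
                continue
            out.append(GeneSignature(name, genes, "unsigned", desc))
    return out


def write_gmt(signatures: Iterable[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            genes = "\t".join(sorted(sig.genes))
            fh.write(f"{sig.name}\t{sig.source or sig.direction}\t{genes}\n")


# ---------------------------------------------------------------------------
# networks


def write_edge_list(graph: nx.Graph, path, provenance: Mapping | None = None) -> None:
    rows = sorted(
        (min(a, b), max(a, b), float(d.get("weight", 1.0)))
        for a, b, d in graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.17g}\n")


def read_edge_list(path) -> nx.Graph:
    df = _read_tsv(path)
    for col in ("gene_a", "gene_b", "weight"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    g = nx.Graph()
    for a, b, w in df[["gene_a", "gene_b", "weight"]].itertuples(index=False):
        g.add_edge(str(a), str(b), weight=float(w))
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


# ---------------------------------------------------------------------------
# module tables


def write_module_table(h: ModuleHierarchy, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("module_id\tparent_id\talpha\tsize\tgenes\thubs\n")
        for m in h.modules:
            genes = ";".join(sorted(m.genes))
            hubs = ";".join(sorted(m.hubs))
            parent = m.parent_id if m.parent_id is not None else "root"
            fh.write(f"{m.module_id}\t{parent}\t{m.alpha:g}\t{m.size}\t{genes}\t{hubs}\n")


def read_module_table(path) -> ModuleHierarchy:
    df = _read_tsv(path)
    modules = []
    for row in df.itertuples(index=False):
        genes = frozenset(str(row.genes).split(";")) if str(row.genes) else frozenset()
        hubs = (frozenset(str(row.hubs).split(";"))
                if isinstance(row.hubs, str) and row.hubs else frozenset())
        parent = None if row.parent_id == "root" else str(row.parent_id)
        modules.append(Module(str(row.module_id), parent, float(row.alpha), genes, hubs))
    return ModuleHierarchy(modules)


# ---------------------------------------------------------------------------
# generic result tables


def write_table(df: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def setup_logging(path: str | Path | None = None, level: int = logging.INFO) -> None:
    """Configure the package logger with timestamps, optionally to a file."""
    handler: logging.Handler
    handler = logging.FileHandler(path) if path else logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
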