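"""Readers and writers for the pipeline's on-disk formats.

* Expression matrices as TSV in the M3D convention (genes as rows, first
  column the gene identifier, header row of experiment identifiers) or
  transposed (samples as rows).
* Gold standards as DREAM5-style edge lists (``TF<TAB>target<TAB>1``) or
  RegulonDB ``network_tf_gene.txt``-style tab-separated files with ``#``
  comment lines and a configurable column map.
* Undirected / directed edge lists with per-edge attributes.
* Gaussian Bayesian network models as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GoldStandard
from .gbn import DAGStructure, GBNModel

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gold_standard",
    "write_gold_standard",
    "read_tf_list",
    "write_tf_list",
    "write_edge_list",
    "read_edge_list",
    "write_gbn_model",
    "read_gbn_model",
    "write_theta",
]

logger = logging.getLogger(__name__)


def read_expression_tsv(
    path, orientation: str = "genes_as_rows", standardized: bool = False
) -> ExpressionMatrix:
    """Read a rectangular TSV with header row and ID column into an
    ExpressionMatrix oriented samples x genes."""
    if orientation not in ("genes_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path}: {dups}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        for lineno, (_idx, row) in enumerate(frame.iterrows(), start=2):
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {cell!r} at line {lineno} of {path}"
                    ) from None
        raise
    if orientation == "genes_as_rows":
        return ExpressionMatrix(
            values=values.T,
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            standardized=standardized,
        )
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in frame.columns],
        sample_ids=[str(s) for s in frame.index],
        standardized=standardized,
    )


def write_expression_tsv(X: ExpressionMatrix, path, orientation: str = "genes_as_rows") -> None:
    frame = X.to_frame()
    if orientation == "genes_as_rows":
        frame = frame.T
        frame.index.name = "gene"
    elif orientation == "samples_as_rows":
        frame.index.name = "sample"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    frame.to_csv(path, sep="\t", float_format="%.10g")


def _regulondb_gene_name(protein_name: str) -> str:
    """RegulonDB TF protein names ('HyfR') map to gene names ('hyfR') by
    lower-casing the first character."""
    return protein_name[:1].lower() + protein_name[1:] if protein_name else protein_name


def read_gold_standard(
    path,
    dialect: str = "dream5",
    tf_ids=None,
    gene_ids=None,
    column_map: dict | None = None,
) -> GoldStandard:
    """Parse a directed TF->target edge list.

    dream5: 2-3 tab-separated columns (third, when present, must be 1 for a
    present edge; rows with 0 are skipped).  regulondb: tab-separated with
    ``#`` comment lines; ``column_map`` gives 0-based indices for
    ``{"tf": i, "target": j}`` (default ``{"tf": 0, "target": 1}``), and TF
    protein names are normalized to gene names.  Duplicates are collapsed,
    self-loops dropped with a logged count.  The TF set defaults to the union
    of edge sources unless ``tf_ids`` is supplied.
    """
    path = Path(path)
    cmap = {"tf": 0, "target": 1}
    if column_map:
        cmap.update(column_map)
    edges: set[tuple[str, str]] = set()
    self_loops = 0
    unmatched: set[str] = set()
    known = set(gene_ids) if gene_ids is not None else None
    known_lower = {g.lower(): g for g in known} if known is not None else None
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "regulondb" and line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "dream5":
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
                src, tgt = parts[0].strip(), parts[1].strip()
                if len(parts) >= 3 and parts[2].strip() not in ("", "1"):
                    continue
            elif dialect == "regulondb":
                needed = max(cmap["tf"], cmap["target"])
                if len(parts) <= needed:
                    raise ValueError(f"{path}:{lineno}: expected > {needed} columns")
                raw_name = parts[cmap["tf"]].strip()
                src = _regulondb_gene_name(raw_name)
                tgt = parts[cmap["target"]].strip()
                if known_lower is not None:
                    matched = known_lower.get(src.lower())
                    if matched is None:
                        unmatched.add(raw_name)
                        continue
                    src = matched
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if not src or not tgt:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            if src == tgt:
                self_loops += 1
                continue
            edges.add((src, tgt))
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    if unmatched:
        logger.warning("unmatched TF name(s) in %s: %s", path, sorted(unmatched))
    if not edges:
        raise ValueError(f"no edges parsed from {path}")
    sources = {a for a, _b in edges}
    tfs = set(tf_ids) if tf_ids is not None else sources
    genes = sorted(tfs | {g for e in edges for g in e})
    if gene_ids is not None:
        genes = sorted(set(genes) | set(gene_ids))
    return GoldStandard(tf_ids=tfs, edges=edges, gene_ids=genes)


def write_gold_standard(gold: GoldStandard, path) -> None:
    """DREAM5-style TSV: source<TAB>target<TAB>1."""
    with Path(path).open("w") as handle:
        for a, b in sorted(gold.edges):
            handle.write(f"{a}\t{b}\t1\n")


def read_tf_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_tf_list(tf_ids, path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in sorted(tf_ids)))


def write_edge_list(edges, path, attributes: dict | None = None, gold: GoldStandard | None = None, directed: bool = False) -> None:
    """TSV edge list with header.

    Undirected edges are written once with lexicographically ordered
    endpoints; ``attributes`` maps an edge (as passed) to a dict of extra
    columns; when ``gold`` is supplied a ``tp`` flag column is added.
    """
    attributes = attributes or {}
    rows = []
    attr_cols: list[str] = []
    for edge in edges:
        a, b = edge
        key = (a, b) if directed or a <= b else (b, a)
        row = {"a": key[0], "b": key[1]}
        for col, val in attributes.get(edge, {}).items():
            row[col] = val
            if col not in attr_cols:
                attr_cols.append(col)
        if gold is not None:
            row["tp"] = int((a, b) in gold.edges or (b, a) in gold.edges)
        rows.append(row)
    cols = (["child", "parent"] if directed else ["gene_a", "gene_b"]) + attr_cols
    if gold is not None:
        cols.append("tp")
    frame = pd.DataFrame(rows).rename(columns={"a": cols[0], "b": cols[1]})
    frame = frame.reindex(columns=cols)
    frame = frame.drop_duplicates(subset=cols[:2]).sort_values(cols[:2])
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gbn_model(model: GBNModel, path) -> None:
    payload = {
        "nodes": model.structure.nodes,
        "parents": {n: sorted(model.structure.parent_sets[n]) for n in model.structure.nodes},
        "beta": model.beta,
        "nu": model.nu,
        "mu": model.mu,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_gbn_model(path) -> GBNModel:
    payload = json.loads(Path(path).read_text())
    structure = DAGStructure(
        nodes=payload["nodes"],
        parent_sets={n: frozenset(p) for n, p in payload["parents"].items()},
    )
    return GBNModel(
        structure=structure,
        beta={n: dict(v) for n, v in payload["beta"].items()},
        nu=dict(payload["nu"]),
        mu=dict(payload["mu"]),
    )


def write_theta(theta: np.ndarray, gene_ids, path) -> None:
    pd.DataFrame(np.asarray(theta), index=list(gene_ids), columns=list(gene_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
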