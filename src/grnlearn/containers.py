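"""Core data containers shared across the pipeline.

An :class:`ExpressionMatrix` holds continuous expression values oriented as
samples x genes (the transpose of the M3D on-disk convention, which stores
genes as rows).  A :class:`GoldStandard` holds a curated directed TF->target
edge set used for true-positive scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GoldStandard"]


@dataclass
class ExpressionMatrix:
    """Samples x genes matrix of continuous expression values.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_genes)``.
    gene_ids
        Gene identifiers, one per column.
    sample_ids
        Sample (experiment) identifiers, one per row.
    standardized
        True when every gene column has sample mean 0 and sample standard
        deviation 1 (``n - 1`` denominator).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        self.gene_ids = list(self.gene_ids)
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.values.shape[0]} rows"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]

    def subset(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return replace(self, values=self.values[:, idx], gene_ids=list(gene_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(c) for c in frame.columns],
            sample_ids=[str(i) for i in frame.index],
            standardized=standardized,
        )


@dataclass
class GoldStandard:
    """Directed TF->target reference network.

    ``tf_ids`` lists every TF-encoding gene (decoy TFs included even when
    disconnected); ``edges`` are unique ordered (source, target) pairs, all
    sourced at TFs and free of self-loops; ``gene_ids`` is the ordered list of
    every gene in the study, decoys included.
    """

    tf_ids: set[str]
    edges: set[tuple[str, str]]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.tf_ids = set(self.tf_ids)
        self.edges = {(str(a), str(b)) for a, b in self.edges}
        self.gene_ids = list(self.gene_ids)
        genes = set(self.gene_ids)
        if len(genes) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in gold standard")
        if not self.tf_ids <= genes:
            raise ValueError("tf_ids must be a subset of gene_ids")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a}->{b} in gold standard")
            if a not in self.tf_ids:
                raise ValueError(f"edge source {a} is not a TF")
            if b not in genes:
                raise ValueError(f"edge target {b} not in gene_ids")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, tf: str) -> set[str]:
        return {b for a, b in self.edges if a == tf}
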