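import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from grnlearn import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


def make_expression(values, standardized=False, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(values=values, gene_ids=gene_ids, standardized=standardized)


def standardized_with_correlation(r, n, rng, gene_ids=("g1", "g2")):
    """Two columns with sample mean 0, sd 1 (n-1 denominator) and sample
    correlation exactly r, built from an orthonormalized random basis."""
    raw = rng.normal(size=(n, 2))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    u, v = q[:, 0], q[:, 1]
    u = u - u.mean()
    v = v - v.mean()
    # re-orthogonalize after centering, then scale to unit sample sd
    v = v - (v @ u) / (u @ u) * u
    u = u / u.std(ddof=1)
    v = v / v.std(ddof=1)
    x = u
    y = r * u + np.sqrt(1.0 - r * r) * v
    y = y / y.std(ddof=1)
    vals = np.column_stack([x, y])
    return make_expression(vals, standardized=True, gene_ids=list(gene_ids))
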