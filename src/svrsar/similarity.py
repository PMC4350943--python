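"""Tanimoto similarity over binary fingerprints.

On binary vectors the Tanimoto coefficient

    Tc(u, v) = |u ∩ v| / (|u| + |v| − |u ∩ v|)

coincides with the Tanimoto kernel K(u, v) = <u,v> / (<u,u> + <v,v> − <u,v>),
so one computation serves both the SAR scoring similarity and the SVR kernel.
Matrices are stored dense: data sets here are at most a few thousand
compounds, so O(n²) memory is acceptable.
"""

from __future__ import annotations

import numpy as np

from .data_io import DataSet
from .errors import ValidationError


def tanimoto(u: frozenset[int] | set[int], v: frozenset[int] | set[int]) -> float:
    """Tanimoto coefficient of two on-bit index sets.

    Symmetric, in [0, 1], equal to 1 iff u == v. Raises if both sets are
    empty (unreachable for fingerprints validated at load).
    """
    inter = len(u & v)
    union = len(u) + len(v) - inter
    if union == 0:
        raise ValidationError("tanimoto undefined for two empty fingerprints")
    return inter / union


def pairwise_matrix(dataset: DataSet) -> np.ndarray:
    """All pairwise Tc values for a compound set, in record order.

    The result is exactly symmetric with an exactly unit diagonal; these are
    enforced after the vectorized computation so downstream consumers (SVR
    kernel, MDS dissimilarities, SAR scoring) can rely on them bitwise.
    """
    X = dataset.fingerprint_matrix().astype(np.float64)
    inter = X @ X.T
    counts = X.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    M = inter / union
    M = (M + M.T) / 2.0  # BLAS gemm is not exactly symmetric
    np.fill_diagonal(M, 1.0)
    return np.clip(M, 0.0, 1.0)


def kernel_blocks(
    matrix: np.ndarray, row_indices, col_indices
) -> np.ndarray:
    """Sub-matrix of a precomputed kernel (e.g. test/train block).

    ``rows == cols`` yields the symmetric train/train block used to fit;
    distinct index sets yield the rectangular prediction block.
    """
    rows = np.asarray(row_indices, dtype=int)
    cols = np.asarray(col_indices, dtype=int)
    n = matrix.shape[0]
    for idx in (rows, cols):
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValidationError(f"kernel block index out of range [0, {n})")
    return matrix[np.ix_(rows, cols)]


def write_matrix_tsv(matrix: np.ndarray, path, ids: list[str] | None = None) -> None:
    """Debug dump of a similarity matrix as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        if ids is not None:
            fh.write("\t".join(ids) + "\n")
        for row in matrix:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
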