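"""Two-block partial least squares for morphometric covariation.

Given two blocks of shape variables measured on the same individuals
(e.g. body shape and pharyngeal jaw shape), the singular value
decomposition of their cross-covariance matrix yields pairs of axes that
maximise covariation between the blocks.  The first pair of PLS scores is
the "covariation" phenotype submitted to the QTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PLSResult:
    """Singular values, unit-norm loadings and scores of a two-block PLS."""

    singular_values: np.ndarray  # (k,), descending
    loadings_block1: np.ndarray  # (p1, k), unit-norm columns
    loadings_block2: np.ndarray  # (p2, k)
    scores_block1: np.ndarray  # (n, k): centered block 1 projected on loadings
    scores_block2: np.ndarray


def two_block_pls(X1: np.ndarray, X2: np.ndarray, k: int = 1) -> PLSResult:
    """SVD of the cross-covariance between two column-centered blocks.

    The covariance uses divisor n - 1.  Sign convention: in each loading
    pair, the first nonzero element of the block-1 loading is positive.
    Constant columns are allowed (they contribute zero covariance).
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n = X1.shape[0]
    if X2.shape[0] != n:
        raise ValueError("blocks must have the same number of rows")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    if k > min(X1.shape[1], X2.shape[1]):
        raise ValueError("k exceeds the smaller block dimension")
    X1c = X1 - X1.mean(axis=0)
    X2c = X2 - X2.mean(axis=0)
    C = X1c.T @ X2c / (n - 1)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    U, s, V = U[:, :k], s[:k], Vt[:k].T
    for j in range(k):
        nz = np.flatnonzero(np.abs(U[:, j]) > 1e-12)
        if nz.size and U[nz[0], j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return PLSResult(
        singular_values=s,
        loadings_block1=U,
        loadings_block2=V,
        scores_block1=X1c @ U,
        scores_block2=X2c @ V,
    )


def pls_phenotype(result: PLSResult, both_blocks: bool = True) -> np.ndarray:
    """The covariation phenotype for QTL mapping: the first-dimension
    scores of both blocks as an n x 2 matrix (or block 1 only, n x 1)."""
    s1 = result.scores_block1[:, :1]
    if not both_blocks:
        return s1
    return np.hstack([s1, result.scores_block2[:, :1]])
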