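"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from radqtl.cross import MISSING, CrossData, LinkageMap
from radqtl.hmm import F2_INIT, f2_step_matrix, kosambi_r


# ---------------------------------------------------------------------------
# Oracles (deliberately independent of the implementation under test)
# ---------------------------------------------------------------------------

def enumerate_genoprob(positions, observations, error_rate):
    """Posterior genotype probabilities by exhaustive hidden-path summation.

    ``positions``: ordered cM positions (one chromosome); ``observations``:
    same-length vector over {0, 1, 2, -1}.  Sums the joint probability of
    every one of the 3^K hidden paths directly.
    """
    K = len(positions)
    trans = [f2_step_matrix(kosambi_r(positions[k + 1] - positions[k])) for k in range(K - 1)]

    def emit(state, obs):
        if obs == MISSING:
            return 1.0
        return 1.0 - error_rate if state == obs else error_rate / 2.0

    post = np.zeros((K, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=K):
        p = F2_INIT[path[0]] * emit(path[0], observations[0])
        for k in range(1, K):
            p *= trans[k - 1][path[k - 1], path[k]] * emit(path[k], observations[k])
        total += p
        for k in range(K):
            post[k, path[k]] += p
    return post / total


def pairwise_diff_pi(H):
    """Window diversity by brute force: mean pairwise difference count over
    all haplotype pairs (no missing data)."""
    n = H.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(H[i] != H[j]))
    return total / (n * (n - 1) / 2)


def brute_force_window_stats(H):
    """S, pi, theta_w and Tajima's D from first principles for a complete
    0/1 haplotype matrix."""
    n = H.shape[0]
    counts = H.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    pi = pairwise_diff_pi(H[:, seg]) if S else 0.0
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    theta_w = S / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    D = (pi - theta_w) / denom if S > 0 and denom > 0 else np.nan
    return S, pi, theta_w, D


def univariate_hk_oracle(y, probs):
    """Classical 2-df F test of y on [1, x, z] via explicit least squares."""
    from scipy import stats

    x = probs[:, 2] - probs[:, 0]
    z = probs[:, 1]
    n = len(y)
    X = np.column_stack([np.ones(n), x, z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = sst - sse
    F = (ssr / 2.0) / (sse / (n - 3))
    return float(stats.f.sf(F, 2, n - 3))


def bayes_interval_oracle(positions, lods, prob=0.95):
    """Credible interval by explicit mass accumulation over positions
    ordered by descending weight."""
    w = 10.0 ** (np.asarray(lods, float) - np.max(lods))
    w = w / w.sum()
    order = sorted(range(len(w)), key=lambda i: (-w[i], i))
    acc, chosen = 0.0, []
    for i in order:
        chosen.append(i)
        acc += w[i]
        if acc >= prob - 1e-12:
            break
    pos = np.asarray(positions, float)[chosen]
    return float(pos.min()), float(pos.max())


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def toy_map(positions_by_lg):
    """LinkageMap from {lg: [pos, ...]}."""
    rows = []
    for lg, positions in positions_by_lg.items():
        for j, p in enumerate(positions):
            rows.append((f"{lg}_m{j + 1}", lg, float(p)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "lg", "pos_cM"]))


def make_cross(geno, positions_by_lg, parents=None, phenotypes=None):
    """CrossData from a genotype matrix and {lg: positions}."""
    lmap = toy_map(positions_by_lg)
    geno = np.asarray(geno, dtype=np.int8)
    if parents is None:
        parents = np.vstack(
            [np.zeros(lmap.n_markers, np.int8), np.full(lmap.n_markers, 2, np.int8)]
        )
    return CrossData(geno, np.asarray(parents, np.int8), lmap, phenotypes=phenotypes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
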