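"""Multivariate Haley-Knott genome scan with permutation thresholds.

At every grid position the phenotype matrix Y (n x p, column-centered) is
regressed on the expected genotype codings derived from the posterior
genotype probabilities: the additive coding ``x = P(BB) - P(AA)`` and the
dominance coding ``z = P(AB)``.  The joint 2-df test of the genotype
columns uses Pillai's trace (Wilks' lambda available) with the standard F
approximation; the parametric p-value is reported as a LOD-score
equivalent, ``-log10(p)``.  Genome-wide and chromosome-level significance
thresholds come from permuting phenotype rows (whole vectors, preserving
the trait covariance) and taking the upper quantile of the permuted
maximum LOD distribution.  Credible intervals for each significant peak
are computed by normalising ``10^LOD`` into a posterior mass over the
linkage group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from radqtl.hmm import GenoProbGrid

P_FLOOR = 1e-300  # p-values are floored here before -log10


@dataclass
class ScanResult:
    """Genome-scan output: per-position statistics, thresholds and peaks."""

    table: pd.DataFrame  # columns: lg, pos_cM, stat, p, lod_equiv, ve_pct, flagged
    statistic: str
    genome_threshold: float | None = None
    lg_thresholds: dict = field(default_factory=dict)
    n_perm: int = 0
    alpha: float = 0.05
    peaks: pd.DataFrame | None = None

    @property
    def max_lod(self) -> float:
        return float(self.table["lod_equiv"].max())

    def lg_table(self, lg) -> pd.DataFrame:
        return self.table[self.table["lg"] == lg]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _genotype_codings(probs: np.ndarray, dominance: bool) -> np.ndarray:
    """Haley-Knott codings per position: x = P(BB) - P(AA), z = P(AB).

    ``probs`` is (n_ind, K, 3); returns (K, n_ind, q) with q = 2 or 1.
    """
    x = (probs[:, :, 2] - probs[:, :, 0]).T
    if not dominance:
        return x[:, :, None]
    z = probs[:, :, 1].T
    return np.stack([x, z], axis=2)

_RANK_TOL = 1e-8


def _orthonormal_bases(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center and orthonormalise the genotype codings per position.

    ``G`` is (K, n, q).  Returns (Q, q_eff): Q is (K, n, q) with
    orthonormal columns (rank-deficient columns zeroed), q_eff the
    effective rank per position.  Centering absorbs the intercept.
    """
    K, n, q = G.shape
    Gc = G - G.mean(axis=1, keepdims=True)
    Q = np.zeros_like(Gc)
    q_eff = np.zeros(K, dtype=int)
    scale = np.sqrt(n)
    u = Gc[:, :, 0]
    norm = np.linalg.norm(u, axis=1)
    ok0 = norm > _RANK_TOL * scale
    Q[ok0, :, 0] = u[ok0] / norm[ok0, None]
    q_eff += ok0
    if q == 2:
        v = Gc[:, :, 1]
        proj = np.einsum("kn,kn->k", Q[:, :, 0], v)
        v = v - proj[:, None] * Q[:, :, 0]
        norm = np.linalg.norm(v, axis=1)
        ok1 = norm > _RANK_TOL * scale
        Q[ok1, :, 1] = v[ok1] / norm[ok1, None]
        q_eff += ok1
    return Q, q_eff


# ---------------------------------------------------------------------------
# Multivariate test statistics
# ---------------------------------------------------------------------------

def _pillai_F(V: np.ndarray, q: np.ndarray, p: int, n: int):
    """F approximation for Pillai's trace V with q hypothesis df, p traits."""
    s = np.minimum(q, p).astype(float)
    m = (np.abs(p - q) - 1) / 2.0
    n_e = n - q - 1  # residual df after intercept + q genotype columns
    nf = (n_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nf + s + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (V / (s - V)) * (df2 / df1)
    return F, df1, df2


def _wilks_F(lam: np.ndarray, q: np.ndarray, p: int, n: int):
    """Rao's F approximation for Wilks' lambda."""
    q = q.astype(float)
    n_e = n - q - 1
    t = np.where(
        p**2 + q**2 - 5 > 0, np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)), 1.0
    )
    df1 = p * q
    df2 = (n_e - (p - q + 1) / 2.0) * t - (p * q - 2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_t = lam ** (1.0 / t)
        F = (1 - lam_t) / lam_t * df2 / df1
    return F, df1, df2


class _ScanCore:
    """Precomputed per-grid quantities for fast (permuted) re-scans.

    Exploits the invariance of the total SSCP under row permutation of Y:
    only the 2 x p cross-products between the orthonormalised genotype
    basis and Y change per permutation.
    """

    def __init__(self, grid: GenoProbGrid, Y: np.ndarray, dominance: bool = True,
                 statistic: str = "pillai"):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.ndim != 2 or Y.shape[0] != grid.n_individuals:
            raise ValueError("phenotype rows must match the individuals in the grid")
        complete = ~np.isnan(Y).any(axis=1)
        self.n_dropped = int((~complete).sum())
        self.Y = Y[complete]
        self.n, self.p = self.Y.shape
        q = 2 if dominance else 1
        if self.n <= self.p + q + 1:
            raise ValueError("too few complete-phenotype individuals for the fit")
        self.statistic = statistic
        self.dominance = dominance
        probs = grid.probs[complete]
        G = _genotype_codings(probs, dominance)
        self.Q, self.q_eff = _orthonormal_bases(G)
        self.Yc = self.Y - self.Y.mean(axis=0)
        self.T = self.Yc.T @ self.Yc
        self.trace_T = float(np.trace(self.T))
        # guard against degenerate traits (zero-variance columns)
        self.Tinv = np.linalg.pinv(self.T)
        self.positions = grid.positions
        self.lg_codes, self.lg_labels = pd.factorize(grid.positions["lg"], sort=False)

    def stats_for(self, Y_like: np.ndarray):
        """Per-position (stat, p, lod, ve) for a phenotype matrix with the
        same total SSCP as the original (e.g. a row permutation of it)."""
        A = np.einsum("kni,np->kip", self.Q, Y_like)  # (K, q, p)
        return self._finish(A)

    def stats_for_batch(self, Y_batch: np.ndarray):
        """LOD curves for B phenotype matrices at once; Y_batch is (B, n, p).

        Returns lod array of shape (K, B)."""
        B = Y_batch.shape[0]
        K, n, q = self.Q.shape
        M = np.swapaxes(self.Q, 1, 2).reshape(K * q, n)
        flat = M @ Y_batch.transpose(1, 0, 2).reshape(n, B * self.p)
        A = flat.reshape(K, q, B, self.p).transpose(0, 2, 1, 3)  # (K, B, q, p)
        if self.statistic == "pillai":
            V = np.einsum("kbip,pq,kbiq->kb", A, self.Tinv, A)
            F, df1, df2 = _pillai_F(V, self.q_eff[:, None], self.p, self.n)
        else:
            lam = self._wilks_lambda(A)
            F, df1, df2 = _wilks_F(lam, self.q_eff[:, None], self.p, self.n)
        return self._lod(F, df1, df2, self.q_eff[:, None])

    def _wilks_lambda(self, A: np.ndarray) -> np.ndarray:
        # lambda = det(T - H) / det(T), H = A'A per position (q x q trick):
        # det(I - A T^{-1} A') in the q-dimensional hypothesis space.
        core = np.einsum("...ip,pq,...jq->...ij", A, self.Tinv, A)
        eye = np.eye(core.shape[-1])
        return np.linalg.det(eye - core)

    def _finish(self, A: np.ndarray):
        H_trace = np.einsum("kip,kip->k", A, A)
        if self.statistic == "pillai":
            V = np.einsum("kip,pq,kiq->k", A, self.Tinv, A)
            stat = V
            F, df1, df2 = _pillai_F(V, self.q_eff, self.p, self.n)
        else:
            lam = self._wilks_lambda(A)
            stat = lam
            F, df1, df2 = _wilks_F(lam, self.q_eff, self.p, self.n)
        lod, p = self._lod(F, df1, df2, self.q_eff, return_p=True)
        ve = 100.0 * H_trace / self.trace_T if self.trace_T > 0 else np.zeros_like(H_trace)
        return stat, p, lod, ve

    @staticmethod
    def _lod(F, df1, df2, q_eff, return_p: bool = False):
        F = np.asarray(F, dtype=float)
        pval = np.ones_like(F)
        ok = (q_eff > 0) & np.isfinite(F)
        pval[ok] = stats.f.sf(F[ok], np.broadcast_to(df1, F.shape)[ok],
                              np.broadcast_to(df2, F.shape)[ok])
        # perfect fits drive F to +inf; their p underflows to 0
        pval[(q_eff > 0) & np.isinf(F)] = 0.0
        lod = -np.log10(np.maximum(pval, P_FLOOR))
        return (lod, pval) if return_p else lod


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def hk_fit(
    Y: np.ndarray,
    probs: np.ndarray,
    dominance: bool = True,
    statistic: str = "pillai",
) -> tuple[float, float, float, float]:
    """Haley-Knott fit at a single position.

    Parameters
    ----------
    Y : (n, p) phenotype matrix (rows with any NaN are dropped).
    probs : (n, 3) genotype probability triples at the position.
    dominance : include the dominance coding (2-df test) or additive only.
    statistic : "pillai" or "wilks".

    Returns ``(stat, p_value, lod_equiv, ve_pct)``.  A rank-deficient
    design (constant codings) yields ``stat = 0, p = 1``.
    """
    probs = np.asarray(probs, dtype=float)
    grid = GenoProbGrid(
        positions=pd.DataFrame({"lg": ["_"], "pos_cM": [0.0],
                                "is_marker": [True], "marker": ["_"]}),
        probs=probs[:, None, :],
        error_rate=0.0,
        step_cM=0.0,
    )
    core = _ScanCore(grid, Y, dominance=dominance, statistic=statistic)
    stat, p, lod, ve = core.stats_for(core.Yc)
    return float(stat[0]), float(p[0]), float(lod[0]), float(ve[0])


def scan(
    grid: GenoProbGrid,
    Y: np.ndarray,
    dominance: bool = True,
    statistic: str = "pillai",
) -> ScanResult:
    """Genome scan: one Haley-Knott fit per grid position."""
    core = _ScanCore(grid, Y, dominance=dominance, statistic=statistic)
    stat, p, lod, ve = core.stats_for(core.Yc)
    table = grid.positions[["lg", "pos_cM"]].copy()
    table["stat"] = stat
    table["p"] = p
    table["lod_equiv"] = lod
    table["ve_pct"] = ve
    table["flagged"] = core.q_eff < (2 if dominance else 1)
    return ScanResult(table=table, statistic=statistic)


def permutation_thresholds(
    grid: GenoProbGrid,
    Y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    dominance: bool = True,
    statistic: str = "pillai",
    batch_size: int = 50,
) -> tuple[float, dict]:
    """Permutation thresholds for genome-wide and chromosome-level LOD.

    Phenotype rows are shuffled as whole vectors (the multivariate null
    keeps trait covariance intact); for each permutation the scan is
    recomputed and the genome-wide and per-linkage-group maxima recorded.
    The threshold is the ceil((1 - alpha) * n_perm)-th order statistic of
    each maximum distribution.

    Returns ``(genome_threshold, {lg: threshold})``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    core = _ScanCore(grid, Y, dominance=dominance, statistic=statistic)
    rng = np.random.default_rng(seed)
    n = core.n
    n_lg = len(core.lg_labels)
    genome_max = np.empty(n_perm)
    lg_max = np.empty((n_perm, n_lg))
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        Yb = core.Yc[perms]  # (b, n, p)
        lod = core.stats_for_batch(Yb)  # (K, b)
        genome_max[done : done + b] = lod.max(axis=0)
        for g in range(n_lg):
            sel = core.lg_codes == g
            lg_max[done : done + b, g] = lod[sel].max(axis=0)
        done += b
    k = max(int(np.ceil((1.0 - alpha) * n_perm)), 1)
    genome_thr = float(np.sort(genome_max)[k - 1])
    lg_thr = {
        lab: float(np.sort(lg_max[:, g])[k - 1]) for g, lab in enumerate(core.lg_labels)
    }
    return genome_thr, lg_thr


def bayes_interval(
    positions: np.ndarray, lods: np.ndarray, prob: float = 0.95
) -> tuple[float, float, bool]:
    """Bayesian credible interval for a QTL peak on one linkage group.

    Position weights are proportional to 10^LOD, normalised over the
    group; positions sorted by descending weight are accumulated until the
    cumulative mass reaches ``prob``; the interval is the [min, max]
    position of the accumulated set, so it always contains the peak.

    Returns ``(lo_cM, hi_cM, flagged)`` where ``flagged`` marks an
    uninformative (flat zero) curve for which the whole group is returned.
    """
    positions = np.asarray(positions, dtype=float)
    lods = np.asarray(lods, dtype=float)
    if positions.size == 0:
        raise ValueError("empty linkage group")
    if np.all(lods == 0):
        return float(positions.min()), float(positions.max()), True
    w = 10.0 ** (lods - lods.max())
    w = w / w.sum()
    order = np.argsort(-w, kind="stable")
    csum = np.cumsum(w[order])
    n_keep = int(np.searchsorted(csum, prob - 1e-12) + 1)
    chosen = positions[order[:n_keep]]
    return float(chosen.min()), float(chosen.max()), False


def summarize_peaks(
    result: ScanResult,
    genome_threshold: float,
    lg_thresholds: dict,
    prob: float = 0.95,
) -> pd.DataFrame:
    """Peak table: per linkage group exceeding its chromosome-level
    threshold, the (leftmost) peak position, LOD, VE and credible interval,
    plus whether the peak clears the genome-wide threshold."""
    rows = []
    for lg in dict.fromkeys(result.table["lg"]):
        sub = result.table[result.table["lg"] == lg]
        lod = sub["lod_equiv"].to_numpy()
        thr = lg_thresholds.get(lg, np.inf)
        if lod.max() < thr:
            continue
        i = int(np.argmax(lod))  # leftmost maximum
        lo, hi, flagged = bayes_interval(sub["pos_cM"].to_numpy(), lod, prob=prob)
        rows.append(
            {
                "lg": lg,
                "pos_cM": float(sub["pos_cM"].iloc[i]),
                "lod_equiv": float(lod[i]),
                "ve_pct": float(sub["ve_pct"].iloc[i]),
                "ci_lo_cM": lo,
                "ci_hi_cM": hi,
                "ci_prob": prob,
                "genome_wide": bool(lod[i] >= genome_threshold),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lg", "pos_cM", "lod_equiv", "ve_pct", "ci_lo_cM", "ci_hi_cM",
                 "ci_prob", "genome_wide", "flagged"],
    )


def run_scan(
    grid: GenoProbGrid,
    Y: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    dominance: bool = True,
    statistic: str = "pillai",
    ci_prob: float = 0.95,
) -> ScanResult:
    """Scan + permutation thresholds + peak summaries in one call."""
    result = scan(grid, Y, dominance=dominance, statistic=statistic)
    genome_thr, lg_thr = permutation_thresholds(
        grid, Y, n_perm=n_perm, alpha=alpha, seed=seed,
        dominance=dominance, statistic=statistic,
    )
    result.genome_threshold = genome_thr
    result.lg_thresholds = lg_thr
    result.n_perm = n_perm
    result.alpha = alpha
    result.peaks = summarize_peaks(result, genome_thr, lg_thr, prob=ci_prob)
    return result
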