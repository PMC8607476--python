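"""Multipoint genotype probabilities for an F2 intercross.

The hidden chain per linkage group has states (AA, AB, BB) with the F2
stationary distribution (1/4, 1/2, 1/4).  Transition probabilities between
adjacent loci follow the two-gamete model: each of the two gametes
recombines independently with probability ``r``, where ``r`` is obtained
from the cM distance via the Kosambi map function.  Observed genotypes are
emitted with a symmetric error rate ``epsilon`` (probability ``1 - epsilon``
for the true state, ``epsilon / 2`` for each other state); missing
observations are uninformative.  Posterior state probabilities at every
grid position come from forward-backward smoothing, with pseudomarkers
inserted as missing-emission positions on a regular cM grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from radqtl.cross import MISSING, CrossData

F2_INIT = np.array([0.25, 0.5, 0.25])


def kosambi_r(d_cM) -> np.ndarray | float:
    """Kosambi map function: cM distance -> recombination fraction.

    r = tanh(2 d) / 2 with d in Morgans; allows the partial positive
    crossover interference typical of most organisms.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(d_cM) else r


def f2_step_matrix(r: float) -> np.ndarray:
    """3x3 transition matrix over (AA, AB, BB) between adjacent F2 loci.

    Both gametes recombine independently with probability ``r``:
    AA -> [(1-r)^2, 2r(1-r), r^2], AB -> [r(1-r), (1-r)^2 + r^2, r(1-r)],
    BB mirrors AA.  Stationary distribution is (1/4, 1/2, 1/4).
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5], got {r}")
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


@dataclass
class GenoProbGrid:
    """Posterior genotype probabilities on a pseudomarker grid.

    ``positions`` has one row per grid point: ``lg``, ``pos_cM``,
    ``is_marker`` and ``marker`` (name or NaN).  ``probs`` is
    ``n_individuals x n_positions x 3`` with triples P(AA), P(AB), P(BB)
    summing to one.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    error_rate: float
    step_cM: float

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def lgs(self) -> list:
        return list(dict.fromkeys(self.positions["lg"]))

    def lg_slice(self, lg) -> np.ndarray:
        return np.flatnonzero((self.positions["lg"] == lg).to_numpy())


def _grid_positions(marker_pos: np.ndarray, step_cM: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge a regular grid (anchored at the first marker) with the markers.

    Returns (positions, marker_index) where marker_index[k] is the index
    into ``marker_pos`` if grid point k is a true marker, else -1.
    """
    lo, hi = marker_pos[0], marker_pos[-1]
    if step_cM > 0:
        n_steps = int(np.floor((hi - lo) / step_cM + 1e-9))
        grid = lo + step_cM * np.arange(n_steps + 1)
    else:
        grid = marker_pos.copy()
    pos = np.union1d(np.round(grid, 9), np.round(marker_pos, 9))
    marker_index = np.full(len(pos), -1, dtype=int)
    idx = np.searchsorted(pos, np.round(marker_pos, 9))
    marker_index[idx] = np.arange(len(marker_pos))
    return pos, marker_index


def _emission_probs(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """Emission weights (n_individuals x 3) for one marker's observations."""
    n = obs.shape[0]
    E = np.full((n, 3), error_rate / 2.0)
    seen = obs != MISSING
    E[seen, obs[seen]] = 1.0 - error_rate
    E[~seen] = 1.0
    return E


def calc_genoprob(
    cross: CrossData, step_cM: float = 0.5, error_rate: float = 1e-4
) -> GenoProbGrid:
    """Forward-backward smoothing of F2 genotype probabilities on a cM grid.

    Grid points are spaced ``step_cM`` apart starting at each linkage
    group's first marker; all true markers are grid points.  Emissions use
    a symmetric genotyping-error rate; pseudomarkers emit nothing.
    """
    n_ind = cross.n_individuals
    pos_frames = []
    prob_blocks = []
    for lg in cross.map.lgs:
        cols = cross.map.lg_indices(lg)
        marker_pos = cross.map.table["pos_cM"].to_numpy(float)[cols]
        marker_names = cross.map.markers[cols]
        pos, marker_index = _grid_positions(marker_pos, step_cM)
        K = len(pos)
        # per-position emissions; None marks an uninformative pseudomarker
        emissions = [
            _emission_probs(cross.genotypes[:, cols[marker_index[k]]], error_rate)
            if marker_index[k] >= 0
            else None
            for k in range(K)
        ]
        trans = [f2_step_matrix(float(kosambi_r(d))) for d in np.diff(pos)]

        alpha = np.empty((K, n_ind, 3))
        a = np.broadcast_to(F2_INIT, (n_ind, 3)).copy()
        if emissions[0] is not None:
            a = a * emissions[0]
        a = _normalize(a, lg, 0)
        alpha[0] = a
        for k in range(1, K):
            a = a @ trans[k - 1]
            if emissions[k] is not None:
                a = a * emissions[k]
            a = _normalize(a, lg, k)
            alpha[k] = a

        post = np.empty((n_ind, K, 3))
        b = np.ones((n_ind, 3))
        post[:, K - 1] = alpha[K - 1]
        for k in range(K - 2, -1, -1):
            nxt = b if emissions[k + 1] is None else b * emissions[k + 1]
            b = nxt @ trans[k].T
            b /= b.sum(axis=1, keepdims=True)
            p = alpha[k] * b
            post[:, k] = p / p.sum(axis=1, keepdims=True)

        pos_frames.append(
            pd.DataFrame(
                {
                    "lg": lg,
                    "pos_cM": pos,
                    "is_marker": marker_index >= 0,
                    "marker": [
                        marker_names[marker_index[k]] if marker_index[k] >= 0 else None
                        for k in range(K)
                    ],
                }
            )
        )
        prob_blocks.append(post)

    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProbGrid(positions=positions, probs=probs, error_rate=error_rate, step_cM=step_cM)


def _normalize(a: np.ndarray, lg, k: int) -> np.ndarray:
    c = a.sum(axis=1, keepdims=True)
    if np.any(c == 0):
        raise FloatingPointError(
            f"zero-probability observation path on LG {lg!r} at grid index {k}; "
            "use a positive error_rate when genotypes contradict the map"
        )
    return a / c
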