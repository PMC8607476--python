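"""Windowed population-genetic summary statistics.

Per nonoverlapping window (default 10 kb, tiled from position 0):
segregating sites S, nucleotide diversity theta-pi (the unbiased per-site
heterozygosity 2 j (m - j) / (m (m - 1)) summed over sites, with j derived
alleles among m observed), Watterson's theta S / a1, and Tajima's D

    D = (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))

with the standard sample-size constants a1, a2, b1, b2, c1, c2, e1, e2.
Statistics are computed from hard calls — haplotype matrices or diploid
genotypes expanded to allele counts — rather than genotype likelihoods;
missing data reduce the per-site observed allele count m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SiteMatrix:
    """Biallelic sites for one sequence: positions plus an allele matrix.

    ``alleles`` is n_samples x n_sites over {0, 1, -1} in haplotype mode
    or {0, 1, 2, -1} (derived-allele dosages) in diploid mode; -1 is
    missing.  Positions are 1-based and strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    ploidy: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != len(self.positions):
            raise ValueError("alleles must be n_samples x n_sites")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 (haplotypes) or 2 (genotype dosages)")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def site_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (j, m): derived-allele count and observed allele count."""
        obs = self.alleles != -1
        if self.ploidy == 1:
            j = np.where(obs, self.alleles, 0).sum(axis=0)
            m = obs.sum(axis=0)
        else:
            j = np.where(obs, self.alleles, 0).sum(axis=0)
            m = 2 * obs.sum(axis=0)
        return j.astype(np.int64), m.astype(np.int64)


@dataclass
class WindowStats:
    """Summary statistics of one window (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    n_sites: int  # segregating sites S
    pi: float
    theta_w: float
    tajima_d: float
    n_eff: int  # modal observed allele count used for the constants
    flag: str = ""


def site_pi(j: int, m: int) -> float:
    """Unbiased per-site diversity: 2 j (m - j) / (m (m - 1)).

    Equals the fraction of the m*(m-1)/2 allele pairs that differ.
    """
    if m < 2:
        raise ValueError("need at least two observed alleles")
    return 2.0 * j * (m - j) / (m * (m - 1.0))


def tajima_constants(n: int) -> dict:
    """Sample-size constants of Tajima's D for n sequences (n >= 2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _window_edges(chrom_length: int, window_size: int) -> np.ndarray:
    edges = np.arange(0, chrom_length, window_size, dtype=np.int64)
    return np.append(edges, chrom_length)


def window_stats(
    sites: SiteMatrix, window_size: int = 10_000, chrom_length: int | None = None
) -> list[WindowStats]:
    """Tile the sequence into nonoverlapping windows and summarise each.

    Windows are anchored at 0; the last partial window is kept (flagged
    ``partial``).  Sites with fewer than two observed alleles are skipped.
    Windows with S = 0 get D = NaN (flag ``no_segregating``); windows
    whose modal allele count is below 4 are flagged ``small_n`` because
    the D constants are unstable there.
    """
    if chrom_length is None:
        chrom_length = int(sites.positions[-1]) if sites.n_sites else window_size
    j, m = sites.site_counts()
    usable = m >= 2
    seg = usable & (j > 0) & (j < m)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site_pi = np.where(seg, 2.0 * j * (m - j) / np.maximum(m * (m - 1.0), 1), 0.0)
    site_window = (sites.positions - 1) // window_size  # 1-based pos -> window index

    out = []
    edges = _window_edges(chrom_length, window_size)
    for w in range(len(edges) - 1):
        start, end = int(edges[w]), int(edges[w + 1])
        in_win = (site_window == w) & usable
        S = int(np.count_nonzero(in_win & seg))
        pi = float(per_site_pi[in_win].sum())
        flags = []
        if end - start != window_size:
            flags.append("partial")
        if S > 0:
            m_seg = m[in_win & seg]
            n_eff = int(np.bincount(m_seg).argmax())  # modal observed count
            if n_eff < 4:
                flags.append("small_n")
                theta_w, D = np.nan, np.nan
            else:
                k = tajima_constants(n_eff)
                theta_w = S / k["a1"]
                denom = np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
                D = (pi - theta_w) / denom if denom > 0 else np.nan
        else:
            n_eff = 0
            theta_w = 0.0
            D = np.nan
            flags.append("no_segregating")
        out.append(
            WindowStats(
                chrom=sites.chrom, start=start, end=end, n_sites=S, pi=pi,
                theta_w=float(theta_w), tajima_d=float(D), n_eff=n_eff,
                flag=";".join(flags),
            )
        )
    return out


def windows_to_frame(stats: list[WindowStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.n_sites, s.pi, s.theta_w, s.tajima_d, s.n_eff, s.flag)
            for s in stats
        ],
        columns=["chrom", "start", "end", "n_sites", "pi", "theta_w", "tajima_d", "n_eff", "flag"],
    )


def read_vcf_sites(path) -> list[SiteMatrix]:
    """Read biallelic SNPs from a VCF into one SiteMatrix per contig.

    Haploid GT fields give a haplotype matrix; diploid GT fields give
    derived-allele dosages.  Multiallelic or non-SNP records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    by_chrom: dict[str, list] = {}
    ploidy = None
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        g = np.array(var.genotypes, dtype=object)
        calls = []
        for entry in var.genotypes:
            alleles = [a for a in entry[:-1] if a is not None]
            if ploidy is None:
                ploidy = len(alleles)
            if any(a < 0 for a in alleles):
                calls.append(-1)
            else:
                calls.append(sum(alleles))
        by_chrom.setdefault(var.CHROM, []).append((var.POS, calls))
    out = []
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: r[0])
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        mat = np.array([r[1] for r in rows], dtype=np.int8).T
        out.append(SiteMatrix(chrom=chrom, positions=pos, alleles=mat, ploidy=ploidy or 1))
    return out


def neutral_calibration(config) -> pd.DataFrame:
    """Simulate neutral windows and compare the summary statistics with
    their analytic expectations (E[S] = theta * a1, E[pi] = theta,
    E[D] approximately 0)."""
    from radqtl.simulate import simulate_neutral_windows

    if config.n_haplotypes < 4:
        raise ValueError("neutral calibration needs n >= 4 for stable D constants")
    wins = simulate_neutral_windows(config)
    k = tajima_constants(config.n_haplotypes)
    S_vals, pi_vals, D_vals = [], [], []
    for w in wins:
        if w.haplotypes.shape[1] == 0:
            S_vals.append(0)
            pi_vals.append(0.0)
            continue
        sm = SiteMatrix(
            chrom="win", positions=np.arange(1, w.haplotypes.shape[1] + 1),
            alleles=w.haplotypes, ploidy=1,
        )
        ws = window_stats(sm, window_size=w.window_length_bp,
                          chrom_length=w.window_length_bp)[0]
        S_vals.append(ws.n_sites)
        pi_vals.append(ws.pi)
        if np.isfinite(ws.tajima_d):
            D_vals.append(ws.tajima_d)
    rows = [
        ("S", np.mean(S_vals), np.std(S_vals, ddof=1), config.theta * k["a1"]),
        ("pi", np.mean(pi_vals), np.std(pi_vals, ddof=1), config.theta),
        ("tajima_d", np.mean(D_vals), np.std(D_vals, ddof=1), 0.0),
    ]
    return pd.DataFrame(rows, columns=["stat", "mean", "sd", "expected"])
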