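"""Contrasts of QTL regions against the genomic background.

Genes, transposable-element sites and diversity windows are partitioned
into inside/outside QTL regions (midpoint rule by default) and compared
with chi-square homogeneity tests (Pearson, no continuity correction),
rank-sum distribution comparisons of theta-pi and Tajima's D, TE
change-site counting within synteny blocks, and Euclidean distances
between genome-wide TE class compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from radqtl.cross import LinkageMap
from radqtl.windows import WindowStats, windows_to_frame


@dataclass
class IntervalSet:
    """Named genomic intervals (0-based half-open) with optional attributes.

    ``table`` needs columns ``chrom``, ``start``, ``end``; extra columns
    (gene id, TE class, selected/changed flags) ride along.  Exact
    duplicate intervals are dropped; overlaps within a set are allowed.
    """

    name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"interval table needs columns {sorted(required)}")
        t = self.table.drop_duplicates(subset=["chrom", "start", "end"]).reset_index(drop=True)
        if np.any(t["start"].to_numpy() < 0):
            raise ValueError("negative interval coordinates")
        if np.any(t["start"].to_numpy() >= t["end"].to_numpy()):
            raise ValueError("intervals must satisfy start < end")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_bed(cls, path, name: str | None = None, attr_names: list[str] | None = None):
        """Read a BED file; columns beyond chrom/start/end get ``attr_names``
        (default ``name``, ``attr1``, ``attr2``, ...)."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        n_extra = df.shape[1] - 3
        if attr_names is None:
            attr_names = (["name"] if n_extra >= 1 else []) + [
                f"attr{i}" for i in range(1, n_extra)
            ]
        df.columns = ["chrom", "start", "end"] + attr_names[:n_extra]
        return cls(name or str(path), df)

    def to_bed(self, path) -> None:
        self.table.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ContingencyTable2x2:
    """2x2 counts: rows = group, columns = inside/outside QTL."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TEProfile:
    """Genome-wide TE composition: per class, total bp and genome size."""

    genome_id: str
    class_bp: dict
    genome_size_bp: int

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        if any(v < 0 for v in self.class_bp.values()):
            raise ValueError("TE class bp must be non-negative")

    def fraction(self, te_class: str) -> float:
        return self.class_bp.get(te_class, 0) / self.genome_size_bp


# ---------------------------------------------------------------------------
# cM -> physical interpolation
# ---------------------------------------------------------------------------

def map_to_physical(
    ci_cM: tuple[float, float], lmap: LinkageMap, lg
) -> tuple[int, int]:
    """Convert a cM credible interval to a physical interval by linear
    interpolation between the flanking physically anchored markers.

    Endpoints beyond the terminal markers are clipped to the terminal
    marker positions, never extrapolated.
    """
    if "pos_bp" not in lmap.table.columns:
        raise ValueError("map carries no physical (pos_bp) coordinates")
    sub = lmap.table[(lmap.table["lg"] == lg) & lmap.table["pos_bp"].notna()]
    if len(sub) < 2:
        raise ValueError(f"LG {lg!r} has fewer than two physically anchored markers")
    cm = sub["pos_cM"].to_numpy(float)
    bp = sub["pos_bp"].to_numpy(float)
    lo, hi = ci_cM
    if lo > hi:
        raise ValueError("interval endpoints out of order")
    lo_bp = float(np.interp(np.clip(lo, cm[0], cm[-1]), cm, bp))
    hi_bp = float(np.interp(np.clip(hi, cm[0], cm[-1]), cm, bp))
    return int(round(lo_bp)), int(round(hi_bp))


# ---------------------------------------------------------------------------
# Interval assignment
# ---------------------------------------------------------------------------

def _merged_by_chrom(intervals: IntervalSet) -> dict:
    """Merge overlapping intervals per chromosome into sorted arrays."""
    out = {}
    for chrom, sub in intervals.table.groupby("chrom", sort=False):
        spans = sub[["start", "end"]].to_numpy(np.int64)
        spans = spans[np.argsort(spans[:, 0], kind="stable")]
        merged = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def assign_inside(
    items: IntervalSet, qtl: IntervalSet, rule: str = "midpoint"
) -> np.ndarray:
    """Boolean mask: which items fall inside the QTL regions.

    ``midpoint`` (default): an item is inside iff its midpoint lies in a
    QTL interval, so each item is counted exactly once.  ``any_overlap``:
    inside iff the item overlaps any QTL interval.  The partition is
    always exhaustive and disjoint.
    """
    if rule not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown rule {rule!r}")
    merged = _merged_by_chrom(qtl) if len(qtl) else {}
    inside = np.zeros(len(items), dtype=bool)
    for chrom, sub in items.table.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        if rule == "midpoint":
            mid = (s + e) // 2
            idx = np.searchsorted(starts, mid, side="right") - 1
            hit = (idx >= 0) & (mid < ends[np.clip(idx, 0, None)])
        else:
            idx = np.searchsorted(starts, e - 1, side="right") - 1
            # overlap iff some merged interval starting at or before the
            # item's last base ends after the item's first base
            hit = (idx >= 0) & (ends[np.clip(idx, 0, None)] > s)
        inside[sub.index.to_numpy()] = hit
    return inside


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def chisq_2x2(table: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns ``(chi2, df, p)`` with df = 1.  A zero row or column marginal
    raises ``degenerate_table``.
    """
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate_table: zero row or column marginal")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)


def compare_distributions(
    window_list: list[WindowStats], qtl: IntervalSet, rule: str = "midpoint"
) -> dict:
    """Compare theta-pi and Tajima's D between windows inside and outside
    the QTL regions.

    Windows are assigned by midpoint; windows with undefined D (no
    segregating sites) are excluded from the D comparison and counted.
    The distributional test is a two-sided rank-sum (Mann-Whitney) test,
    reported as exploratory.
    """
    df = windows_to_frame(window_list)
    wins = IntervalSet("windows", df)
    inside = assign_inside(wins, qtl, rule=rule)
    report: dict = {"rule": rule, "groups": {}, "tests": {}}
    groups = {"inside": wins.table[inside], "outside": wins.table[~inside]}
    for label, sub in groups.items():
        d_ok = sub["tajima_d"].notna()
        report["groups"][label] = {
            "n_windows": int(len(sub)),
            "n_d_excluded": int((~d_ok).sum()),
            "pi_mean": float(sub["pi"].mean()) if len(sub) else np.nan,
            "pi_median": float(sub["pi"].median()) if len(sub) else np.nan,
            "pi_sd": float(sub["pi"].std(ddof=1)) if len(sub) > 1 else np.nan,
            "d_mean": float(sub.loc[d_ok, "tajima_d"].mean()) if d_ok.any() else np.nan,
            "d_median": float(sub.loc[d_ok, "tajima_d"].median()) if d_ok.any() else np.nan,
            "d_sd": float(sub.loc[d_ok, "tajima_d"].std(ddof=1)) if d_ok.sum() > 1 else np.nan,
        }
    gi, go = groups["inside"], groups["outside"]
    if len(gi) >= 2 and len(go) >= 2:
        for col in ("pi", "tajima_d"):
            x = gi[col].dropna()
            y = go[col].dropna()
            if len(x) >= 2 and len(y) >= 2:
                u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                report["tests"][col] = {"u": float(u), "p": float(p)}
            else:
                report["tests"][col] = {"skipped": "too few defined values"}
    else:
        report["tests"]["skipped"] = "a group has fewer than 2 windows"
    return report


def te_change_contrast(
    te_sites: IntervalSet,
    qtl: IntervalSet,
    blocks: IntervalSet,
    rule: str = "midpoint",
    change_col: str = "changed",
    class_col: str = "te_class",
) -> dict:
    """Count TE change sites inside vs outside QTL regions.

    TE sites are first restricted to synteny blocks (cross-species
    comparisons are only meaningful where gene order is conserved), then
    cross-tabulated changed/unchanged x inside/outside and tested with an
    uncorrected chi-square.  A per-class breakdown table is included.
    """
    if change_col not in te_sites.table.columns:
        raise ValueError(f"TE sites need a {change_col!r} column")
    in_block = assign_inside(te_sites, blocks, rule=rule)
    kept = IntervalSet(te_sites.name, te_sites.table[in_block].reset_index(drop=True))
    inside = assign_inside(kept, qtl, rule=rule)
    changed = kept.table[change_col].to_numpy(bool)
    tab = ContingencyTable2x2(
        a=int((changed & inside).sum()),
        b=int((changed & ~inside).sum()),
        c=int((~changed & inside).sum()),
        d=int((~changed & ~inside).sum()),
    )
    chi2, dof, p = chisq_2x2(tab)
    by_class = None
    if class_col in kept.table.columns:
        by_class = (
            pd.DataFrame(
                {
                    "te_class": kept.table[class_col],
                    "inside": inside,
                    "changed": changed,
                }
            )
            .groupby(["te_class", "inside"])["changed"]
            .agg(n_sites="size", n_changed="sum")
            .reset_index()
        )
    return {
        "table": tab,
        "chi2": chi2,
        "df": dof,
        "p": p,
        "n_sites_in_blocks": int(len(kept)),
        "n_sites_dropped": int((~in_block).sum()),
        "by_class": by_class,
    }


# ---------------------------------------------------------------------------
# TE composition distances
# ---------------------------------------------------------------------------

def te_profiles_from_table(df: pd.DataFrame) -> list[TEProfile]:
    """Build TEProfiles from a long-format table with columns
    genome_id, te_class, total_bp, genome_size_bp."""
    out = []
    for gid, sub in df.groupby("genome_id", sort=False):
        sizes = sub["genome_size_bp"].unique()
        if len(sizes) != 1:
            raise ValueError(f"inconsistent genome size for {gid!r}")
        out.append(
            TEProfile(
                genome_id=str(gid),
                class_bp=dict(zip(sub["te_class"], sub["total_bp"])),
                genome_size_bp=int(sizes[0]),
            )
        )
    return out


def te_distance_matrix(profiles: list[TEProfile]) -> pd.DataFrame:
    """Euclidean distances between genome-wide TE compositions.

    Each genome becomes a vector of per-class fractions (total bp of the
    class divided by genome size) over the union of classes, absent
    classes contributing 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    classes = sorted({c for p in profiles for c in p.class_bp})
    M = np.array([[p.fraction(c) for c in classes] for p in profiles])
    D = squareform(pdist(M, metric="euclidean"))
    ids = [p.genome_id for p in profiles]
    return pd.DataFrame(D, index=ids, columns=ids)
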