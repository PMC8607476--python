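"""Cross data containers, file IO and marker/individual quality control.

Genotypes are encoded as ``int8``: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
The AA/BB labels refer to the two parental alleles at each marker, so an
F2 individual carrying two copies of the allele of parent 1 is AA.

The QC pipeline mirrors a standard ddRAD F2 workflow: keep markers whose
parental genotypes are informative (parents homozygous for different
alleles, or exactly one parent heterozygous), drop markers whose F2
segregation deviates from the Mendelian expectation (chi-square,
p < 0.001), then remove individuals with more than 10% missing genotypes
and finally loci typed in fewer than 80% of the remaining individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

AA, AB, BB, MISSING = 0, 1, 2, -1

_CODE_TO_STR = {AA: "AA", AB: "AB", BB: "BB", MISSING: "NA"}
_STR_TO_CODE = {"AA": AA, "AB": AB, "BA": AB, "BB": BB, "NA": MISSING, "-": MISSING, "": MISSING}


@dataclass
class LinkageMap:
    """Ordered marker map: one row per marker with linkage group and cM position.

    ``table`` has columns ``marker`` (unique names), ``lg`` (group label) and
    ``pos_cM`` (non-negative, strictly increasing within each group).  An
    optional ``pos_bp`` column anchors markers to physical coordinates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "lg", "pos_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dup = self.table["marker"][self.table["marker"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        for lg, sub in self.table.groupby("lg", sort=False):
            pos = sub["pos_cM"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on LG {lg!r}")
            if np.any(pos < 0):
                raise ValueError(f"negative cM position on LG {lg!r}")
        self.table = self.table.reset_index(drop=True)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def lgs(self) -> list:
        """Linkage-group labels in map order."""
        return list(dict.fromkeys(self.table["lg"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def lg_indices(self, lg) -> np.ndarray:
        """Column indices (map order) of the markers on one linkage group."""
        return np.flatnonzero((self.table["lg"] == lg).to_numpy())

    def subset(self, marker_names) -> "LinkageMap":
        keep = self.table["marker"].isin(set(marker_names))
        return LinkageMap(self.table.loc[keep].reset_index(drop=True))


@dataclass
class CrossData:
    """An F2 intercross: genotypes, parental genotypes, optional phenotypes.

    ``genotypes`` is ``n_individuals x n_markers`` int8 (columns in map
    order); ``parental_genotypes`` is ``2 x n_markers``; ``phenotypes`` is
    an ``n_individuals x p`` float matrix or None.
    """

    genotypes: np.ndarray
    parental_genotypes: np.ndarray
    map: LinkageMap
    phenotypes: np.ndarray | None = None
    individual_ids: list[str] = field(default_factory=list)
    qtl_genotypes: np.ndarray | None = None  # hidden truth at planted QTL (simulation only)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.parental_genotypes = np.asarray(self.parental_genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if m != self.map.n_markers:
            raise ValueError(
                f"genotype matrix has {m} markers but the map has {self.map.n_markers}"
            )
        if self.parental_genotypes.shape != (2, m):
            raise ValueError("parental_genotypes must be 2 x n_markers")
        if self.phenotypes is not None:
            self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
            if self.phenotypes.shape[0] != n:
                raise ValueError("phenotype rows must match individuals")
        if not self.individual_ids:
            self.individual_ids = [f"F2_{i + 1:04d}" for i in range(n)]
        elif len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset_markers(self, keep: np.ndarray) -> "CrossData":
        keep = np.asarray(keep)
        return CrossData(
            genotypes=self.genotypes[:, keep],
            parental_genotypes=self.parental_genotypes[:, keep],
            map=LinkageMap(self.map.table.iloc[keep].reset_index(drop=True)),
            phenotypes=self.phenotypes,
            individual_ids=list(self.individual_ids),
            qtl_genotypes=self.qtl_genotypes,
        )

    def subset_individuals(self, keep: np.ndarray) -> "CrossData":
        keep = np.asarray(keep)
        return CrossData(
            genotypes=self.genotypes[keep],
            parental_genotypes=self.parental_genotypes,
            map=self.map,
            phenotypes=None if self.phenotypes is None else self.phenotypes[keep],
            individual_ids=[self.individual_ids[i] for i in keep],
            qtl_genotypes=None if self.qtl_genotypes is None else self.qtl_genotypes[keep],
        )


@dataclass
class QCReport:
    """Accounting of a QC step: what was dropped and why, plus per-marker tests.

    Each dropped marker/individual carries exactly one primary reason.
    ``segregation`` holds the chi-square statistic and p-value per tested
    marker (retained and dropped alike).
    """

    dropped_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["individual", "reason", "value"])
    )
    dropped_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker", "reason", "value"])
    )
    segregation: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["marker", "pattern", "chi2", "p", "n_unexpected"]
        )
    )
    notes: list[str] = field(default_factory=list)

    def merged(self, other: "QCReport") -> "QCReport":
        def cat(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
            frames = [f for f in (a, b) if len(f)]
            if not frames:
                return a
            return pd.concat(frames, ignore_index=True)

        return QCReport(
            dropped_individuals=cat(self.dropped_individuals, other.dropped_individuals),
            dropped_markers=cat(self.dropped_markers, other.dropped_markers),
            segregation=cat(self.segregation, other.segregation),
            notes=self.notes + other.notes,
        )


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _decode_genotype(token: str) -> tuple[int, bool]:
    """Return (code, was_unknown). Unknown codes map to missing."""
    code = _STR_TO_CODE.get(str(token).strip().upper())
    if code is None:
        return MISSING, True
    return code, False


def write_cross(cross: CrossData, genotype_file, phenotype_file=None) -> None:
    """Write a cross-CSV (and optionally a phenotype TSV).

    Layout: row 1 marker names, row 2 linkage-group labels, row 3 cM
    positions, then one individual per row with the individual ID in the
    first column.  Parental rows use the reserved IDs ``P1`` and ``P2``.
    """
    tab = cross.map.table
    lines = [
        "id," + ",".join(map(str, tab["marker"])),
        "lg," + ",".join(map(str, tab["lg"])),
        "pos_cM," + ",".join(f"{p:g}" for p in tab["pos_cM"]),
    ]
    for pid, row in zip(("P1", "P2"), cross.parental_genotypes):
        lines.append(pid + "," + ",".join(_CODE_TO_STR[int(g)] for g in row))
    for iid, row in zip(cross.individual_ids, cross.genotypes):
        lines.append(str(iid) + "," + ",".join(_CODE_TO_STR[int(g)] for g in row))
    with open(genotype_file, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if phenotype_file is not None and cross.phenotypes is not None:
        write_phenotypes(cross.phenotypes, cross.individual_ids, phenotype_file)


def write_phenotypes(Y: np.ndarray, ids, phenotype_file) -> None:
    df = pd.DataFrame(Y, columns=[f"trait_{j + 1}" for j in range(Y.shape[1])])
    df.insert(0, "id", list(ids))
    df.to_csv(phenotype_file, sep="\t", index=False)


def read_cross(genotype_file, phenotype_file=None, map_file=None) -> tuple[CrossData, int]:
    """Read a cross-CSV (plus optional phenotype TSV and physical map TSV).

    Returns ``(cross, n_unknown_codes)`` where the second element counts
    genotype tokens that were not recognised and therefore set to missing.
    ``map_file``, if given, is a TSV with columns ``marker`` and ``pos_bp``
    anchoring markers to physical coordinates (merged into the map).
    """
    with open(genotype_file) as fh:
        raw = fh.read()
    rows = [line.split(",") for line in raw.strip().splitlines()]
    if len(rows) < 4:
        raise ValueError("cross-CSV needs marker/lg/pos rows plus at least one individual")
    markers = [t.strip() for t in rows[0][1:]]
    lgs = [t.strip() for t in rows[1][1:]]
    pos = [float(t) for t in rows[2][1:]]
    if not (len(markers) == len(lgs) == len(pos)):
        raise ValueError("marker, lg and position rows have different lengths")
    map_tab = pd.DataFrame({"marker": markers, "lg": lgs, "pos_cM": pos})
    if map_file is not None:
        phys = pd.read_csv(map_file, sep="\t")
        map_tab = map_tab.merge(phys[["marker", "pos_bp"]], on="marker", how="left")
    lmap = LinkageMap(map_tab)

    n_unknown = 0
    parents = np.full((2, len(markers)), MISSING, dtype=np.int8)
    ids, geno_rows = [], []
    for row in rows[3:]:
        rid = row[0].strip()
        if len(row) - 1 != len(markers):
            raise ValueError(f"row for {rid!r} has {len(row) - 1} genotypes, expected {len(markers)}")
        codes = np.empty(len(markers), dtype=np.int8)
        for j, tok in enumerate(row[1:]):
            codes[j], unknown = _decode_genotype(tok)
            n_unknown += unknown
        if rid in ("P1", "P2"):
            parents[0 if rid == "P1" else 1] = codes
        else:
            ids.append(rid)
            geno_rows.append(codes)
    if not geno_rows:
        raise ValueError("no F2 individuals in cross-CSV")
    G = np.vstack(geno_rows)

    Y = None
    if phenotype_file is not None:
        ph = pd.read_csv(phenotype_file, sep="\t")
        ph = ph.set_index(ph.columns[0])
        try:
            Y = ph.loc[ids].to_numpy(float)
        except KeyError as exc:
            raise ValueError(f"phenotype file is missing individuals: {exc}") from exc
    cross = CrossData(G, parents, lmap, phenotypes=Y, individual_ids=ids)
    return cross, n_unknown


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

#: parental-genotype patterns and their F2 expectations
_FULLY_INFORMATIVE = {(AA, BB), (BB, AA)}


def _marker_pattern(p1: int, p2: int) -> str:
    """Classify a marker by its parental genotypes."""
    if p1 == MISSING or p2 == MISSING:
        return "parent_missing"
    if (p1, p2) in _FULLY_INFORMATIVE:
        return "hom_hom"
    if (p1 == AB) != (p2 == AB):  # exactly one parent heterozygous
        return "het_hom"
    return "uninformative_parents"


def select_informative_markers(cross: CrossData) -> tuple[CrossData, QCReport]:
    """Keep markers whose parents are homozygous for different alleles or
    heterozygous in exactly one parent; drop everything else."""
    report = QCReport()
    patterns = [
        _marker_pattern(int(p1), int(p2)) for p1, p2 in cross.parental_genotypes.T
    ]
    keep, dropped = [], []
    for j, pat in enumerate(patterns):
        if pat in ("hom_hom", "het_hom"):
            keep.append(j)
        else:
            dropped.append((cross.map.markers[j], pat, np.nan))
    report.dropped_markers = pd.DataFrame(dropped, columns=["marker", "reason", "value"])
    return cross.subset_markers(np.array(keep, dtype=int)), report


def segregation_filter(
    cross: CrossData, p_threshold: float = 0.001
) -> tuple[CrossData, QCReport]:
    """Drop markers whose F2 genotype frequencies deviate from Mendelian
    expectation (chi-square p strictly below ``p_threshold``).

    Fully informative markers (both parents homozygous, different alleles)
    are tested against 1:2:1 over (AA, AB, BB), df = 2.  Markers with one
    heterozygous parent segregate 1:1 between the heterozygote and the
    homozygous-parent class (the F1 is het x hom at such markers); calls in
    the unexpected third class are excluded from the test but counted.
    """
    report = QCReport()
    keep, dropped, seg_rows = [], [], []
    for j in range(cross.n_markers):
        name = cross.map.markers[j]
        p1, p2 = (int(v) for v in cross.parental_genotypes[:, j])
        pattern = _marker_pattern(p1, p2)
        g = cross.genotypes[:, j]
        counts = np.array([(g == AA).sum(), (g == AB).sum(), (g == BB).sum()], dtype=float)
        if counts.sum() == 0:
            dropped.append((name, "all_missing", np.nan))
            continue
        if pattern == "hom_hom":
            n = counts.sum()
            expected = n * np.array([0.25, 0.5, 0.25])
            chi2 = float(((counts - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(chi2, df=2))
            n_unexpected = 0
        elif pattern == "het_hom":
            hom_class = p1 if p1 != AB else p2
            other_hom = BB if hom_class == AA else AA
            observed = np.array([counts[hom_class], counts[AB]])
            n_unexpected = int(counts[other_hom])
            n = observed.sum()
            if n == 0:
                dropped.append((name, "all_missing", np.nan))
                continue
            expected = n * np.array([0.5, 0.5])
            chi2 = float(((observed - expected) ** 2 / expected).sum())
            p = float(stats.chi2.sf(chi2, df=1))
        else:
            raise ValueError(
                f"marker {name!r} has not been parent-classified; "
                "run select_informative_markers first"
            )
        seg_rows.append((name, pattern, chi2, p, n_unexpected))
        if p < p_threshold:
            dropped.append((name, "segregation_distortion", p))
        else:
            keep.append(j)
    report.dropped_markers = pd.DataFrame(dropped, columns=["marker", "reason", "value"])
    report.segregation = pd.DataFrame(
        seg_rows, columns=["marker", "pattern", "chi2", "p", "n_unexpected"]
    )
    return cross.subset_markers(np.array(keep, dtype=int)), report


def missingness_filters(
    cross: CrossData,
    max_ind_missing: float = 0.10,
    min_locus_presence: float = 0.80,
) -> tuple[CrossData, QCReport]:
    """Remove individuals with missing fraction strictly above
    ``max_ind_missing``, then loci present in strictly fewer than
    ``min_locus_presence`` of the remaining individuals.

    The order (individuals first, then loci) changes the result and is
    therefore fixed and recorded in the report notes.
    """
    report = QCReport(notes=["filter order: individuals first, then loci"])
    miss_frac = (cross.genotypes == MISSING).mean(axis=1)
    keep_ind = np.flatnonzero(miss_frac <= max_ind_missing)
    dropped_ind = [
        (cross.individual_ids[i], "high_missingness", float(miss_frac[i]))
        for i in np.flatnonzero(miss_frac > max_ind_missing)
    ]
    out = cross.subset_individuals(keep_ind)
    if out.n_individuals == 0:
        raise ValueError("no_data_after_qc: every individual exceeded the missingness cap")

    presence = (out.genotypes != MISSING).mean(axis=0)
    keep_loc = np.flatnonzero(presence >= min_locus_presence)
    dropped_loc = [
        (out.map.markers[j], "low_presence", float(presence[j]))
        for j in np.flatnonzero(presence < min_locus_presence)
    ]
    out = out.subset_markers(keep_loc)
    if out.n_markers == 0:
        raise ValueError("no_data_after_qc: every locus fell below the presence threshold")

    report.dropped_individuals = pd.DataFrame(
        dropped_ind, columns=["individual", "reason", "value"]
    )
    report.dropped_markers = pd.DataFrame(dropped_loc, columns=["marker", "reason", "value"])
    return out, report


def run_qc(
    cross: CrossData,
    p_threshold: float = 0.001,
    max_ind_missing: float = 0.10,
    min_locus_presence: float = 0.80,
) -> tuple[CrossData, QCReport]:
    """Full QC pipeline: informative markers, segregation, missingness."""
    cross, rep1 = select_informative_markers(cross)
    cross, rep2 = segregation_filter(cross, p_threshold=p_threshold)
    cross, rep3 = missingness_filters(
        cross, max_ind_missing=max_ind_missing, min_locus_presence=min_locus_presence
    )
    return cross, rep1.merged(rep2).merged(rep3)
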