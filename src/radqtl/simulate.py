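"""Synthetic data with known ground truth for every stage of the pipeline.

Four generators:

* ``simulate_map`` / ``simulate_f2`` — a linkage map and an F2 intercross.
  Genotypes follow a Markov chain over the ordered loci of each linkage
  group with adjacent transition matrices derived from the Kosambi map
  function, i.e. the exact generative model assumed by the genotype
  probability HMM.  Symmetric genotyping error and missingness are applied
  afterwards.
* ``plant_qtl_phenotypes`` — multivariate phenotypes with planted QTL:
  Y_i = mu + sum_j (a_j x_ij + h_j z_ij) + e_i with additive coding
  x in {-1, 0, +1} for {AA, AB, BB}, dominance coding z in {0, 1, 0} and
  multivariate-normal residuals.  Effect sizes are calibrated so each QTL
  explains a requested percentage of the total phenotypic variance
  (trace of the genetic SSCP over trace of the total SSCP), using
  Var(x) = 1/2, Var(z) = 1/4, Cov(x, z) = 0 under 1:2:1 segregation.
* ``simulate_neutral_windows`` — neutral Kingman coalescent windows with
  infinite-sites mutation (E[S] = theta * a1, E[pi] = theta), for
  calibrating the window statistics.
* ``simulate_annotations`` — random interval fixtures (QTL regions, genes
  with selected flags, TE sites with change flags, synteny blocks) and TE
  class-composition tables with configurable planted enrichment, so the
  enrichment contrasts have a known truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radqtl.cross import AA, AB, BB, MISSING, CrossData, LinkageMap
from radqtl.hmm import F2_INIT, f2_step_matrix, kosambi_r

_ADD_CODE = np.array([-1.0, 0.0, 1.0])  # x for AA, AB, BB
_DOM_CODE = np.array([0.0, 1.0, 0.0])  # z for AA, AB, BB
VAR_X = 0.5  # Var(x) under 1:2:1
VAR_Z = 0.25  # Var(z) under 1:2:1


@dataclass
class QTLSpec:
    """One planted QTL: location, effect directions and target variance.

    ``additive`` and ``dominance`` are p-vectors giving the direction of
    the additive and dominance effects across phenotype dimensions; their
    overall scale is recalibrated to hit ``ve_pct`` (percent of total
    phenotypic variance explained, trace-ratio definition).
    """

    lg: object
    pos_cM: float
    additive: np.ndarray
    dominance: np.ndarray
    ve_pct: float

    def __post_init__(self) -> None:
        self.additive = np.atleast_1d(np.asarray(self.additive, dtype=float))
        self.dominance = np.atleast_1d(np.asarray(self.dominance, dtype=float))
        if self.additive.shape != self.dominance.shape:
            raise ValueError("additive and dominance effect vectors must match in length")
        if not 0 <= self.ve_pct < 100:
            raise ValueError("ve_pct must be in [0, 100)")


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic F2 cross.

    The defaults mirror a ddRAD cichlid intercross: 306 F2 individuals
    genotyped at 527 markers resolving 24 linkage groups, with shape-like
    multivariate phenotypes.
    """

    n_lg: int = 24
    lg_lengths: np.ndarray | float = 60.0  # cM per linkage group
    n_markers: int = 527
    n_f2: int = 306
    n_pheno_dims: int = 2
    missing_rate: float = 0.0
    genotyping_error: float = 0.0
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    residual_cov: np.ndarray | None = None  # default: identity
    seed: int = 0

    def __post_init__(self) -> None:
        self.lg_lengths = np.broadcast_to(
            np.asarray(self.lg_lengths, dtype=float), (self.n_lg,)
        ).copy()
        if np.any(self.lg_lengths <= 0):
            raise ValueError("linkage-group lengths must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.genotyping_error < 0.5:
            raise ValueError("genotyping_error must be in [0, 0.5)")
        if sum(q.ve_pct for q in self.qtl_spec) > 100:
            raise ValueError("total target VE exceeds 100%")
        if self.residual_cov is None:
            self.residual_cov = np.eye(self.n_pheno_dims)
        else:
            self.residual_cov = np.asarray(self.residual_cov, dtype=float)
            if self.residual_cov.shape != (self.n_pheno_dims, self.n_pheno_dims):
                raise ValueError("residual_cov must be p x p")
            if not np.allclose(self.residual_cov, self.residual_cov.T):
                raise ValueError("residual_cov must be symmetric")
            if np.any(np.linalg.eigvalsh(self.residual_cov) < -1e-10):
                raise ValueError("residual_cov must be positive semi-definite")


def simulate_map(config: SimConfig) -> LinkageMap:
    """Random linkage map: markers spread over linkage groups.

    Each group starts at 0 cM, ends at its map length, with interior
    markers uniform and strictly increasing.  Marker counts are balanced
    across groups (remainder goes to the first groups).
    """
    if config.n_markers < 2 * config.n_lg:
        raise ValueError("need at least two markers per linkage group")
    rng = np.random.default_rng(config.seed)
    base, extra = divmod(config.n_markers, config.n_lg)
    rows = []
    for g in range(config.n_lg):
        k = base + (1 if g < extra else 0)
        L = float(config.lg_lengths[g])
        while True:
            interior = np.sort(rng.uniform(0.0, L, size=k - 2)) if k > 2 else np.array([])
            pos = np.concatenate([[0.0], interior, [L]])
            if np.all(np.diff(pos) > 1e-9):
                break
        for j, p in enumerate(pos):
            rows.append((f"LG{g + 1:02d}_M{j + 1:03d}", f"LG{g + 1:02d}", float(p)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "lg", "pos_cM"]))


def _simulate_chain(rng, positions: np.ndarray, n_ind: int) -> np.ndarray:
    """F2 genotypes along one linkage group for n individuals."""
    K = len(positions)
    out = np.empty((n_ind, K), dtype=np.int8)
    out[:, 0] = rng.choice(3, size=n_ind, p=F2_INIT)
    for k in range(1, K):
        T = f2_step_matrix(float(kosambi_r(positions[k] - positions[k - 1])))
        cum = np.cumsum(T, axis=1)
        u = rng.random(n_ind)
        out[:, k] = (u[:, None] > cum[out[:, k - 1]]).sum(axis=1)
    return out


def simulate_f2(lmap: LinkageMap, config: SimConfig) -> CrossData:
    """Simulate an F2 cross on a map, plus true genotypes at planted QTL.

    The chain over each linkage group's ordered loci uses the same
    Kosambi-derived transition matrices as the HMM.  QTL loci from
    ``config.qtl_spec`` are inserted into the chain so their true
    (error-free) genotypes are recorded in ``cross.qtl_genotypes``;
    genotyping error and missingness apply to the observed markers only.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_f2
    geno = np.empty((n, lmap.n_markers), dtype=np.int8)
    qtl_by_lg: dict = {}
    for qi, q in enumerate(config.qtl_spec):
        qtl_by_lg.setdefault(q.lg, []).append((qi, float(q.pos_cM)))
    qtl_geno = np.empty((n, len(config.qtl_spec)), dtype=np.int8)

    for lg in lmap.lgs:
        cols = lmap.lg_indices(lg)
        marker_pos = lmap.table["pos_cM"].to_numpy(float)[cols]
        extras = qtl_by_lg.get(lg, [])
        for qi, qpos in extras:
            if not (marker_pos[0] <= qpos <= marker_pos[-1]):
                raise ValueError(f"QTL position {qpos} is off the map on LG {lg!r}")
        all_pos = np.concatenate([marker_pos, [p for _, p in extras]])
        order = np.argsort(all_pos, kind="stable")
        chain = _simulate_chain(rng, all_pos[order], n)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        geno[:, cols] = chain[:, inv[: len(marker_pos)]]
        for j, (qi, _) in enumerate(extras):
            qtl_geno[:, qi] = chain[:, inv[len(marker_pos) + j]]

    # symmetric genotyping error: replace by one of the other two states
    if config.genotyping_error > 0:
        err = rng.random(geno.shape) < config.genotyping_error
        shift = rng.integers(1, 3, size=geno.shape)
        geno[err] = ((geno[err] + shift[err]) % 3).astype(np.int8)
    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = MISSING

    parents = np.vstack(
        [np.full(lmap.n_markers, AA, np.int8), np.full(lmap.n_markers, BB, np.int8)]
    )
    return CrossData(
        genotypes=geno,
        parental_genotypes=parents,
        map=lmap,
        qtl_genotypes=qtl_geno if config.qtl_spec else None,
    )


def _calibrated_effects(config: SimConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rescale each QTL's effect vectors to hit its target VE.

    With Var(x) = 1/2, Var(z) = 1/4, Cov(x, z) = 0 and independent QTL,
    QTL j contributes genetic trace g_j = |a_j|^2 / 2 + |h_j|^2 / 4, and
    VE_j = g_j / (sum_k g_k + trace(residual_cov)).  Solving for the
    scaled traces: g_j' = t_j * r / (1 - sum_k t_k).
    """
    r = float(np.trace(config.residual_cov))
    if r <= 0:
        # noiseless limit: keep requested directions unscaled
        return [(q.additive, q.dominance) for q in config.qtl_spec]
    t = np.array([q.ve_pct / 100.0 for q in config.qtl_spec])
    total_t = t.sum()
    if total_t >= 1:
        raise ValueError("total target VE must be below 100% with nonzero residual")
    out = []
    for q, tj in zip(config.qtl_spec, t):
        g_raw = (q.additive @ q.additive) * VAR_X + (q.dominance @ q.dominance) * VAR_Z
        if tj == 0 or g_raw == 0:
            out.append((np.zeros_like(q.additive), np.zeros_like(q.dominance)))
            continue
        g_target = tj * r / (1.0 - total_t)
        c = np.sqrt(g_target / g_raw)
        out.append((c * q.additive, c * q.dominance))
    return out


def plant_qtl_phenotypes(cross: CrossData, config: SimConfig) -> CrossData:
    """Attach multivariate phenotypes with the planted QTL effects.

    Requires ``cross.qtl_genotypes`` (produced by ``simulate_f2`` when the
    config carries a ``qtl_spec``).  Residuals are multivariate normal
    with ``config.residual_cov``.
    """
    rng = np.random.default_rng(config.seed + 2)
    n, p = cross.n_individuals, config.n_pheno_dims
    Y = np.zeros((n, p))
    if config.qtl_spec:
        if cross.qtl_genotypes is None:
            raise ValueError("cross carries no QTL genotypes; simulate with the same config")
        for j, (a, h) in enumerate(_calibrated_effects(config)):
            if a.shape[0] != p:
                raise ValueError(
                    f"QTL {j} effect vector has length {a.shape[0]}, expected {p}"
                )
            g = cross.qtl_genotypes[:, j].astype(int)
            Y += np.outer(_ADD_CODE[g], a) + np.outer(_DOM_CODE[g], h)
    eigval, eigvec = np.linalg.eigh(config.residual_cov)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))
    Y += rng.standard_normal((n, p)) @ root.T
    return CrossData(
        genotypes=cross.genotypes,
        parental_genotypes=cross.parental_genotypes,
        map=cross.map,
        phenotypes=Y,
        individual_ids=list(cross.individual_ids),
        qtl_genotypes=cross.qtl_genotypes,
    )


def simulate_cross(config: SimConfig) -> CrossData:
    """Map + F2 genotypes + planted phenotypes in one call."""
    lmap = simulate_map(config)
    cross = simulate_f2(lmap, config)
    return plant_qtl_phenotypes(cross, config)


def realized_ve(cross: CrossData, qtl_index: int = 0) -> float:
    """Realized trace-ratio VE (%) of one planted QTL.

    Genetic values are the within-genotype-class phenotype means at the
    true QTL genotype; VE = 100 * trace(SSCP_genetic) / trace(SSCP_total).
    """
    if cross.phenotypes is None or cross.qtl_genotypes is None:
        raise ValueError("cross must carry phenotypes and QTL genotypes")
    Y = cross.phenotypes
    g = cross.qtl_genotypes[:, qtl_index].astype(int)
    Yc = Y - Y.mean(axis=0)
    total = float(np.einsum("ij,ij->", Yc, Yc))
    fitted = np.zeros_like(Yc)
    for cls in (0, 1, 2):
        sel = g == cls
        if sel.any():
            fitted[sel] = Yc[sel].mean(axis=0)
    model = float(np.einsum("ij,ij->", fitted, fitted))
    return 100.0 * model / total


# ---------------------------------------------------------------------------
# Neutral coalescent windows
# ---------------------------------------------------------------------------

@dataclass
class CoalescentConfig:
    """Neutral window simulation: Kingman coalescent + infinite sites.

    ``theta`` is the population mutation rate per window (theta = 4*N*mu*L
    in a diploid population, here simply the expected pairwise diversity
    per window); ``window_length_bp`` only positions the mutations.
    """

    n_haplotypes: int = 10
    theta: float = 5.0
    window_length_bp: int = 10_000
    n_windows: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need at least two haplotypes")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass
class NeutralWindow:
    """One simulated window: haplotypes (n x S over {0,1}) and positions."""

    haplotypes: np.ndarray
    positions: np.ndarray  # 1-based bp within the window
    window_length_bp: int


def _coalescent_tree(rng, n: int):
    """Sample a Kingman tree: returns (parent, branch_length) arrays for
    2n-1 nodes (leaves 0..n-1), times in coalescent units of 2N."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return parent, time


def simulate_neutral_windows(config: CoalescentConfig) -> list[NeutralWindow]:
    """Independent neutral windows under the standard coalescent.

    Mutations are Poisson with mean (theta / 2) * total tree length
    (time in units of 2N); each mutation lands on a branch with
    probability proportional to its length and is carried by all leaves
    below it, giving a 0/1 haplotype matrix per window with
    E[S] = theta * a1 and E[pi] = theta.  Site positions are uniform on
    the window.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_haplotypes
    windows = []
    for _ in range(config.n_windows):
        parent, time = _coalescent_tree(rng, n)
        n_nodes = len(parent)
        blen = np.zeros(n_nodes)
        has_parent = parent >= 0
        blen[has_parent] = time[parent[has_parent]] - time[has_parent]
        total = blen.sum()
        S = rng.poisson(0.5 * config.theta * total) if config.theta > 0 else 0
        # leaf sets below each node
        below = [np.zeros(n, dtype=bool) for _ in range(n_nodes)]
        for leaf in range(n):
            below[leaf][leaf] = True
        for node in range(n, n_nodes):  # children appear before parents
            kids = np.flatnonzero(parent == node)
            below[node] = below[kids[0]] | below[kids[1]]
        H = np.zeros((n, S), dtype=np.int8)
        if S > 0 and total > 0:
            branches = rng.choice(n_nodes, size=S, p=blen / total)
            for s, br in enumerate(branches):
                H[below[br], s] = 1
            pos = np.sort(rng.integers(1, config.window_length_bp + 1, size=S))
            order = np.arange(S)
        else:
            pos = np.array([], dtype=int)
            order = np.array([], dtype=int)
        windows.append(
            NeutralWindow(
                haplotypes=H[:, order], positions=pos,
                window_length_bp=config.window_length_bp,
            )
        )
    return windows


def write_windows_vcf(windows: list[NeutralWindow], path, chrom_prefix: str = "win") -> None:
    """Write simulated windows as one minimal VCF 4.2 with haploid GTs.

    Each window becomes its own contig (``win1``, ``win2``, ...), sites
    REF=A / ALT=T at their within-window positions.
    """
    n = windows[0].haplotypes.shape[0] if windows else 0
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for w, win in enumerate(windows):
        lines.append(f"##contig=<ID={chrom_prefix}{w + 1},length={win.window_length_bp}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [f"hap{i + 1}" for i in range(n)]
    lines.append("\t".join(header))
    for w, win in enumerate(windows):
        last = 0
        for s in range(win.haplotypes.shape[1]):
            pos = int(win.positions[s])
            if pos <= last:  # keep positions strictly increasing per contig
                pos = last + 1
            last = pos
            gts = "\t".join(str(int(g)) for g in win.haplotypes[:, s])
            lines.append(
                f"{chrom_prefix}{w + 1}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interval annotation fixtures
# ---------------------------------------------------------------------------

def simulate_annotations(
    genome_lengths: dict,
    n_genes: int = 500,
    n_te: int = 2000,
    n_qtl_intervals: int = 10,
    seed: int = 0,
    p_selected_inside: float = 0.1,
    p_selected_outside: float = 0.1,
    p_change_inside: float = 0.4,
    p_change_outside: float = 0.4,
    gene_length_bp: int = 5_000,
    te_length_bp: int = 300,
    qtl_length_bp: int = 500_000,
    n_synteny_blocks: int = 20,
    te_classes: tuple = ("DNA", "LINE", "SINE", "LTR", "Unknown"),
):
    """Random interval fixtures with a planted enrichment ground truth.

    Returns a dict with ``qtl``, ``genes``, ``te_sites`` and ``blocks``
    :class:`~radqtl.enrichment.IntervalSet` objects.  Gene selected flags
    are Bernoulli with separate inside/outside-QTL rates (assignment by
    midpoint), and likewise for TE change flags, so chi-square enrichment
    tests have a known null or planted effect.  Synteny blocks tile each
    chromosome contiguously.
    """
    from radqtl.enrichment import IntervalSet, assign_inside

    rng = np.random.default_rng(seed)
    chroms = list(genome_lengths)
    sizes = np.array([genome_lengths[c] for c in chroms], dtype=float)
    pchrom = sizes / sizes.sum()

    def _random_intervals(count, length):
        idx = rng.choice(len(chroms), size=count, p=pchrom)
        rows = []
        for i in idx:
            L = int(genome_lengths[chroms[i]])
            span = min(length, L)
            start = int(rng.integers(0, max(L - span, 0) + 1))
            rows.append((chroms[i], start, start + span))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        # exact duplicates would be collapsed downstream; drop them here so
        # attribute columns stay aligned with the interval rows
        return df.drop_duplicates().reset_index(drop=True)

    qtl = IntervalSet("qtl", _random_intervals(n_qtl_intervals, qtl_length_bp))
    genes_df = _random_intervals(n_genes, gene_length_bp)
    genes_df["gene_id"] = [f"gene{i + 1}" for i in range(len(genes_df))]
    inside = assign_inside(IntervalSet("genes", genes_df), qtl)
    p_sel = np.where(inside, p_selected_inside, p_selected_outside)
    genes_df["selected"] = (rng.random(len(genes_df)) < p_sel).astype(int)

    te_df = _random_intervals(n_te, te_length_bp)
    te_df["te_class"] = rng.choice(te_classes, size=len(te_df))
    te_inside = assign_inside(IntervalSet("te", te_df), qtl)
    p_chg = np.where(te_inside, p_change_inside, p_change_outside)
    te_df["changed"] = (rng.random(len(te_df)) < p_chg).astype(int)

    block_rows = []
    b = 0
    for c in chroms:
        L = int(genome_lengths[c])
        n_blk = max(1, int(round(n_synteny_blocks * genome_lengths[c] / sizes.sum())))
        edges = np.linspace(0, L, n_blk + 1, dtype=int)
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                b += 1
                block_rows.append((c, int(lo), int(hi), f"block{b}"))
    blocks = IntervalSet(
        "blocks", pd.DataFrame(block_rows, columns=["chrom", "start", "end", "name"])
    )
    return {
        "qtl": qtl,
        "genes": IntervalSet("genes", genes_df),
        "te_sites": IntervalSet("te_sites", te_df),
        "blocks": blocks,
    }


def simulate_te_profiles(
    n_genomes: int = 7,
    te_classes: tuple = ("DNA", "LINE", "SINE", "LTR", "Unknown"),
    genome_size_bp: int = 850_000_000,
    mean_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """TE class-composition table for a set of genomes (long format TSV:
    genome_id, te_class, total_bp, genome_size_bp)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genomes):
        for cls in te_classes:
            frac = rng.uniform(0.2, 1.8) * mean_fraction
            rows.append((f"genome{g + 1}", cls, int(frac * genome_size_bp), genome_size_bp))
    return pd.DataFrame(rows, columns=["genome_id", "te_class", "total_bp", "genome_size_bp"])
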