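# Methods

This note defines the statistical models implemented in `radqtl`, the
conventions behind every default, and the package's known limitations.

## 1. Genetic model and genotype probabilities

An F2 intercross between two inbred lines (P1 = AA, P2 = BB) is observed
at markers placed on linkage groups with centimorgan (cM) positions.
Genotypes are coded AA = 0, AB = 1, BB = 2, missing = −1.

Map distance `d` (cM) converts to recombination fraction with the
**Kosambi map function**

    r(d) = tanh(2d / 100) / 2,

which accounts for positive crossover interference at moderate distances.
Between adjacent positions the true genotype follows a Markov chain with
the F2 two-gamete transition matrix (stationary distribution ¼, ½, ¼):

    AA row: [(1−r)²,   2r(1−r),        r²      ]
    AB row: [r(1−r),   (1−r)² + r²,    r(1−r)  ]
    BB row: [r²,       2r(1−r),        (1−r)²  ]

Observed calls pass through a symmetric error channel: the true genotype
is reported with probability 1 − ε and each wrong genotype with ε/2;
missing calls are uninformative emissions. `calc_genoprob` runs a
normalized forward–backward pass per linkage group over the union of
marker positions and a regular pseudomarker grid (default step 0.5 cM,
anchored at the first marker), yielding posterior genotype probabilities
at every grid position. Pseudomarkers are handled as missing emissions,
so marker-only and grid results agree exactly.

`LinkageMap` requires strictly increasing positions within a linkage
group: co-located markers would imply r = 0 and a singular chain.
Co-located markers in real data must be deduplicated or jittered before
import.

## 2. Multivariate Haley–Knott scan

At each grid position the phenotype matrix Y (n × p) is regressed on the
expected genotype codings

    x = P(BB) − P(AA)   (additive),
    z = P(AB)           (dominance),

with an intercept (absorbed by column-centering). The joint 2-df test of
(x, z) on all p traits uses **Pillai's trace** V = trace(H T⁻¹), where H
is the hypothesis SSCP and T the total (centered) SSCP, with the standard
F approximation

    s = min(q, p),  m = (|p − q| − 1)/2,  n_f = (n_e − p − 1)/2,
    n_e = n − q − 1,
    F = [V / (s − V)] · [s(2 n_f + s + 1)] / [s(2m + s + 1)].

Wilks' lambda with Rao's F is available as an alternative. At p = 1 the
Pillai F reduces *exactly* to the classical 2-df regression F test (this
identity is enforced by an acceptance test to 1e-10). Significance is
reported as a **LOD equivalent**, −log10(p), with p floored at 1e-300;
rank-deficient designs (e.g. constant codings) report stat = 0, p = 1,
and a flag. Rows with any missing phenotype are dropped (complete-case).

**Variance explained** is the trace ratio 100 · trace(H)/trace(T) at the
fitted position — the multivariate analogue of R², chosen over
LOD-derived approximations because it is exact under the fitted model
and dimension-agnostic.

### Permutation thresholds

Genome-wide and per-chromosome significance thresholds come from
permuting phenotype **rows as whole vectors** (preserving the trait
covariance) and recording the maximum LOD per permutation, genome-wide
and within each linkage group. The threshold is the ⌈(1 − α)N⌉-th order
statistic of the N permuted maxima (default N = 1000, α = 0.05). Because
T is invariant under row permutation, only the q × p cross-products
between precomputed orthonormal genotype bases and Y are recomputed per
permutation, making thresholds cheap (one large matrix product per
batch).

### Credible intervals

For each linkage group whose maximum LOD clears its chromosome-level
threshold, a 95% Bayes credible interval is computed: position weights
∝ 10^LOD are normalised over the group, positions are accumulated in
descending-weight order until the mass reaches 0.95, and the interval is
the [min, max] of the accumulated set (it always contains the peak).
Flat zero curves return the whole group, flagged as uninformative.

## 3. Covariation phenotype (two-block PLS)

Given two centered trait blocks X₁ (n × p₁) and X₂ (n × p₂), the
cross-covariance C = X₁'X₂ / (n − 1) is decomposed by SVD; the first
left/right singular vectors give one score per individual per block
(sign fixed so the first nonzero block-1 loading is positive). The
two first-dimension scores form a bivariate "covariation" phenotype that
is scanned exactly like any other phenotype, asking which loci drive
coordinated variation between the blocks. Scores are affine-equivariant
in the inputs; the scan's LOD is invariant to affine transformations of
the phenotype, so block scaling does not affect mapping results.

## 4. Windowed diversity statistics

Biallelic SNPs (haploid 0/1 alleles or diploid 0/1/2 dosages; −1
missing) are summarised in nonoverlapping windows tiled from coordinate
0 (default 10 kb; a trailing partial window is kept and flagged). With
j derived alleles among m observed at a site,

    per-site π = 2 j (m − j) / (m (m − 1)),

summed over sites per window; Watterson's θ_W = S / a₁ with
a₁ = Σ_{i<n} 1/i evaluated at the window's modal allele count; and
Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).
Windows with fewer than 4 observed alleles or no segregating sites have
undefined D (NaN, flagged).

**Neutral calibration.** The package's coalescent simulator draws
Kingman genealogies — while k lineages remain, the waiting time to the
next coalescence is exponential with rate k(k−1)/2 in coalescent time
units of 2N generations — and Poisson mutations at rate θ/2 per unit
branch length, so E[S] = θ a₁ and
E[π] = θ per window. Tajima's D is a ratio of estimators: its mean under
neutrality is only approximately 0, with a small negative finite-sample
bias (≈ −0.07 at n = 10, θ = 5). Calibration checks therefore test S and
π against their exact expectations and D against a fixed ±0.15 band.

## 5. QTL-region vs background contrasts

- **cM → bp interpolation**: credible intervals are mapped to physical
  intervals by linear interpolation between physically anchored markers,
  clipped (never extrapolated) at terminal markers.
- **Assignment**: genes/TE sites/windows are partitioned inside/outside
  the merged QTL intervals by the **midpoint rule** (each item counted
  exactly once; `any_overlap` available). The partition is exhaustive
  and disjoint.
- **Enrichment**: 2 × 2 contingency tables (e.g. selected × inside) are
  tested with the uncorrected Pearson chi-square (df = 1). No continuity
  correction is applied anywhere in the package, for internal
  consistency with the segregation tests. Degenerate marginals raise an
  error rather than returning p = 1.
- **Diversity contrasts**: θπ and Tajima's D of windows inside vs
  outside QTL regions are compared with two-sided Mann–Whitney rank-sum
  tests (reported as exploratory; windows with undefined D are excluded
  and counted).
- **TE changes**: TE sites are first restricted to synteny blocks
  (cross-species presence/absence is only meaningful where gene order is
  conserved), then changed/unchanged × inside/outside is tested with the
  uncorrected chi-square, with a per-class breakdown.
- **TE composition distances**: each genome becomes a vector of
  per-class genomic fractions over the union of classes (absent class =
  0); distances are Euclidean.

## 6. Synthetic data

`radqtl.simulate` is a first-class module, not test scaffolding:

- **F2 crosses** are drawn from *the same generative model the HMM
  assumes* (Kosambi, F2 transition matrix, symmetric error channel,
  i.i.d. missingness), so correctness oracles and power studies probe
  the identical joint distribution. Defaults (306 individuals, 527
  markers, 24 × 60 cM linkage groups, 2 traits) are study-scale choices
  representative of a ddRAD cichlid intercross design.
- **Planted QTL** have exact population variance explained: with
  Var(x) = ½, Var(z) = ¼, Cov = 0 under 1:2:1, each QTL's effect vector
  is rescaled so its genetic trace g satisfies the trace-ratio VE
  target jointly with all other QTL and the residual covariance.
  The true QTL genotypes are carried alongside (`qtl_genotypes`) for
  realized-VE checks.
- **Neutral windows** from the Kingman coalescent (Section 4) with
  known E[S] and E[π], writable as VCF.
- **Annotation fixtures**: random gene/TE/QTL intervals with Bernoulli
  selected/changed flags at separate inside/outside rates, so enrichment
  tests have a known null or planted alternative; synteny blocks tile
  each chromosome; TE composition tables with known class fractions.

## 7. Parameter defaults and rationale

| Parameter | Default | Rationale |
|---|---|---|
| Grid step | 0.5 cM | fine enough that peak/CI discretisation ≪ CI width |
| Emission error ε | 1e-4 | tolerates rare miscalls without flattening posteriors |
| Permutations | 1000 | 0.05-quantile SE ≈ 0.007; standard practice |
| α | 0.05 | genome-wide type-I target |
| CI mass | 0.95 | conventional credible level |
| Segregation p | < 0.001 (strict) | conservative marker screen at panel scale |
| Individual missingness | > 10% removed (strict) | drops failed libraries, keeps typical samples |
| Locus presence | < 80% removed (strict) | removes weakly typed loci before mapping |
| Window size | 10 kb | resolves local diversity at RAD-like densities |
| QC order | individuals, then loci | locus presence evaluated on retained samples |

## 8. Limitations

- **Hard genotype calls only.** Low-coverage pipelines that propagate
  genotype *likelihoods* (rather than calls) into diversity statistics
  will differ from our call-based windows; the HMM's ε channel models
  miscalls but not depth-dependent uncertainty.
- The F2 HMM assumes fully informative, phase-known inbred parents;
  partially informative markers are either used as-is (het × hom) or
  excluded (het × het) by QC rather than modeled with a richer emission
  alphabet.
- Haley–Knott regression approximates interval-mapping maximum
  likelihood; it is slightly anticonservative under strong selective
  genotyping or heavy missingness.
- The Pillai F is an approximation for q > 1 and p > 2; permutation
  thresholds, not the parametric p-values, carry the genome-wide
  inference.
- The coalescent simulator is panmictic, constant-size, infinite-sites;
  it calibrates the statistics but does not model demography or linkage
  within windows (sites are exchangeable within a window).
- Rank-sum contrasts of adjacent windows ignore spatial autocorrelation
  along the genome and are reported as exploratory, consistent with the
  package's use of them.
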