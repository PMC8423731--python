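# Methods

## Design and model

The pipeline targets balanced multi-environment trials laid out as a
randomized complete block design within each environment: observation
`y_ijr` for genotype i, environment j, replicate block r(j),

    y_ijr = mu + e_j + b_r(j) + g_i + ge_ij + eps_ijr.

The combined ANOVA decomposes the total sum of squares into Env (df e−1),
Rep within Env (df e(r−1)), Gen (df g−1), Env×Gen (df (e−1)(g−1)) and
Residual (df e(r−1)(g−1)), computed by the closed-form balanced
decomposition. Genotype and interaction are tested against the residual
mean square. The error stratum for the environment test is not dictated by
the design alone; this package's convention is to test Env against
Rep(Env), the block stratum in which environments are actually replicated.
Unbalanced data are rejected by `combined_anova` (the expected-mean-squares
algebra below presumes balance); `cell_means` still works, so the stability
indices remain available, with heritability marked not computed.

Variance components come from expected mean squares with truncation at
zero (logged when it happens): σ²ε = MS_Res, σ²ge = (MS_GE − MS_Res)/r,
σ²g = (MS_Gen − MS_GE)/(e·r). Broad-sense heritability is reported on a
genotype-mean basis, H² = σ²g/(σ²g + σ²ge/e + σ²ε/(e·r)). REML would be the
tool for unbalanced data but adds nothing on a balanced design, and the
closed form keeps every downstream quantity checkable against a dense
mixed-model-equation solve. Genotype is treated as fixed for the ANOVA F
tests and as random for heritability and the BLUP indices — the standard
dual use in MET analysis.

## Stability indices

All indices operate on the genotype × environment cell-mean matrix `X`.

- **Finlay–Wilkinson** bi regresses `X_ij` on the environmental index
  `I_j = X̄·j − X̄··`. Since ΣI_j = 0, regressing raw values or deviations
  gives identical slopes; the implementation centers by the grand mean only
  so that the identity mean(bi) = 1 holds to machine precision. bi ≈ 0 is
  static (biological) stability; bi ≈ 1 tracks the panel average (dynamic
  stability in the regression sense).
- **Wricke ecovalence** Wi is a genotype's row sum of squares of the
  doubly-centered matrix Z; ΣWi equals the interaction SS of the cell
  means, which equals SS_GE/r from the ANOVA — a conservation identity the
  test suite checks on random instances.
- **AMMI**: Z = UΛVᵀ with K = min(g,e)−1 retained components. Scores use
  the symmetric √λ scaling, so component n's sum of squares is λ²n and the
  genotype scores enter ASV and MASI directly. ASV uses the first two
  components with the SSPC1/SSPC2 weighting; MASI aggregates the first N′
  components with weights θn (component share of interaction SS).
  N′ defaults to the components significant by Gollob's F test (component
  df g+e−1−2n, against the ANOVA residual MS, α = 0.05), with a floor of
  two. The MASI radical is implemented as √Σ(PCn·θn)² — the weighted
  product reading; the alternative reading √Σ(PCn² + θn²) is available via
  `masi(..., formula="printed_sum")` since the index's typography is
  ambiguous, and both variants are exercised in the tests.
- **YSI** adds the ASV rank to the descending-mean rank. Integer rank
  columns use ordinal ranking (ties broken by panel order), so every rank
  column is a permutation of 1..g and ΣYSI = g(g+1) exactly; competition
  ranking would break that identity and with it determinism of downstream
  rank sums.

## BLUP-based indices

On cell means with environments fixed, genotype and interaction random,
the balanced-design BLUPs have a closed shrinkage form that is exactly the
Henderson mixed-model-equation solution:

    g_i   = λ_g · d_i,                    λ_g  = σ²g / (σ²g + σ²ge/e + σ²ε/(e·r))
    ge_ij = λ_ge · (Z_ij + (1 − λ_g)·d_i), λ_ge = σ²ge / (σ²ge + σ²ε/r)

with d_i the raw genotype deviation. The second term in ge_ij is easy to
miss: the interaction effect is not constrained to zero genotype means, so
the part of d_i that the shrunken g_i does not absorb loads onto the
interaction BLUP. The test suite verifies equality with a dense MME solve
on 100 random instances at 1e-8.

HMRPGV is the harmonic mean over environments of GV_ij/μ_j with
GV = u_j + g_i + ge_ij; the true harmonic mean e/Σ(μ_j/GV_ij) is the
default (a literal reading without the count multiplier is available as
`formula="printed"`). The index is ratio-scale: any GV ≤ 0 raises an
error naming the offending cell, and the pipeline then skips the column
for that trait with a warning rather than failing — a trait whose genetic
values cross zero is simply not suited to a relative-performance index.
WAASB applies the same √λ-scaled SVD to the BLUP interaction matrix and
averages absolute genotype scores over all non-null components, weighted
by each component's share of the BLUP-interaction SS. WAASBY rescales mean
performance to [0,100] (max → 100) and WAASB to [100,0] (min → 100) and
blends them with weights θ_Y/θ_S, default 50/50 — the conventional
symmetric weighting, configurable because no single weighting is canonical.

**Classification.** The four mean × stability classes use median splits:
the mean axis on the trait mean, the stability axis on the mean of
per-index average ranks over a configurable column set (default ASV, MASI,
Wi, |bi−1|). Exact-median genotypes go to the high/stable side. A
clustering of the index matrix would also produce "approximately four
classes" but is not deterministic across library versions; the median
split matches the four quadrant definitions exactly and is reproducible.

## Diversity and LD

Frequencies are computed on non-missing calls with dosages always oriented
to the minor allele. GD = 2p(1−p), observed heterozygosity is the fraction
of dosage-1 calls, PIC = 1 − (p² + q²) − 2p²q². Density is SNPs per Mbp of
spanned positions. Aggregates are reported per chromosome, per genome
group (defaulting to the trailing letter of wheat-style chromosome names,
e.g. 1A → A), and genome-wide; group comparisons (cultivar / landrace /
total) rerun the same statistics on sample subsets over the identical
marker set.

LD is composite r² on unphased dosages: squared Pearson correlation on
pairwise-complete samples, within chromosomes only. Significance uses
n·r² ~ χ²(1) at α = 0.001. Pairs above `max_pairs` (default 2,000,000 per
chromosome) are subsampled with a seeded generator. Distance uses the cM
map when present for every marker, otherwise bp — genetic distances are
carried as optional input, never derived from physical positions. Decay
distance fits the Hill–Weir drift-recombination expectation of r² (with
the finite-sample correction, n = 2 × samples) by least squares over all
pairs and reports where the fitted curve crosses the threshold (default
r² = 0.1). Because that expectation cannot represent every decay profile
(block-structured LD in particular), the fit is accepted only if it tracks
the distance-binned empirical means within 0.1; otherwise the binned curve
itself is interpolated — the same fallback used on non-convergence. A
curve already below the threshold at the shortest observed distance
returns 0; a curve that never falls below it within the observed range
returns +inf (LD not yet decayed), logged either way.

## GWAS

Kinship is VanRaden method 1, K = WWᵀ/Σ2p_k(1−p_k) with W column-centered
at 2p_k, plus a 1e-6 diagonal ridge; missing dosages are mean-imputed per
marker inside kinship/PCA/GWAS design matrices only (diversity statistics
never impute). Structure covariates are the first k (default 3) principal
components of the centered dosage matrix, with a deterministic sign
convention (largest-|loading| marker positive).

The mixed model y = Xβ + u + ε, u ~ N(0, σ²aK), ε ~ N(0, σ²eI) is fitted by
rotating into the eigenbasis of K. The variance ratio δ = σ²a/σ²e is
profiled out of the restricted likelihood on the null (no-marker) model —
a grid search over log δ ∈ [−10, 10] refined by bounded scalar
minimization — and then reused for every marker (the P3D scheme), giving
each marker a generalized-least-squares Wald t test in the rotated space.
The GLM scan is the same machinery with unit weights. Monomorphic markers
get p = 1; a numerically perfect fit reports the smallest subnormal double
rather than zero. Each scan reports the genomic-control inflation factor
λ_gc (median Wald χ² over the 1-df median).

Significance is raw −log10(p) > 3, exactly the convention of
GAPIT/TASSEL-era wheat association studies; no multiple-testing correction
is applied by default. MTA confidence intervals are position ± the
chromosome's LD-decay distance; intervals that strictly overlap merge into
loci (markers exactly 2×decay apart remain separate loci). The pleiotropy
table lists markers significant for ≥ 2 responses over an identical marker
set, largest overlap first. Responses are the per-genotype stability-table
columns (mean and each index), scanned independently per trait.

## Synthetic data

The generator emulates a selfing-wheat diversity panel: 268 genotypes
split 180 landraces / 88 cultivars, six environments (four well-watered,
two rain-fed), two replicate blocks, four traits (GY g/plant, GN, SW g,
PH cm), 2000 biallelic SNPs on 21 chromosomes. Marker count is desk-scale
rather than GBS-scale; all per-marker statistics are means, so scale
affects precision, not expectation.

Genotypes: ancestral block frequencies ~ U(0.05, 0.95); two subpopulations
diverge by Balding–Nichols Beta draws with F = 0.10 (clear PCA separation
without caricature). LD comes from a shared-uniform copula within blocks
of 10 adjacent markers (mix weight 0.95, giving within-block dosage
r² ≈ 0.8 and zero between blocks); markers within a block share their
frequency, which is what makes the copula translate into high r². A
fraction 0.95 of individuals is fully inbred (haplotype doubled),
reproducing the ~0.02–0.03 observed heterozygosity of a selfing crop —
without this, the het < 10% filter would empty a panmictic panel. Blocks
carrying a planted QTL draw their frequency from U(0.2, 0.8), identical in
both subpopulations: causal variants stay polymorphic after the MAF filter
and are not confounded with structure.

Phenotypes follow the ANOVA decomposition with genotype effects
g_i = Σ βmain·dosage + N(0, var_g) and interaction
ge_ij = s_i·I_j + N(0, var_ge), where the sensitivity
s_i = Σ βsens·dosage + N(0, var_s) shifts the Finlay–Wilkinson slope
(E[bi] = 1 + s_i). Both g_i and s_i are centered, so SimTruth effects
average zero by construction. Trait variance components are set so the
plug-in H² spans the range typical of drought-contrasted wheat MET data
(GY ≈ 0.44 low, GN ≈ 0.71, SW ≈ 0.67, PH ≈ 0.90); default QTLs include a
dual-effect yield locus (βmain = 0.15, βsens = 0.25, the latter a major
stability QTL at ~55% of slope variance), one mean-only and one
sensitivity-only yield locus, and one mean locus per remaining trait.
Environment effects are drawn once per simulation and treated as fixed.
One global seed feeds named sub-streams (genotypes / effects / noise), so
stages are independently reproducible; the pipeline derives per-stage
sub-seeds by hashing `seed:stage`.

What the generator does **not** emulate: coalescent LD decay (LD is
step/block shaped), recombination maps (cM positions are uniform 0.25 cM
spacing), mutation, selection, non-Gaussian trait distributions, and the
hard positivity of real yields — with realistic environment variance a
Gaussian GY can produce negative genetic values, in which case HMRPGV is
skipped for that trait (real positive-valued data would not trigger this).
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted architecture under the stated
model, not robustness to field-data pathologies (spatial trends,
outliers, missing cells).

## Numerical and testing notes

- Seeds: every randomized step (simulation, LD pair subsampling) takes an
  explicit seed; nothing draws from global state. Derived seeds stay below
  2³¹.
- The GWAS calibration check uses a structured null panel with independent
  markers. With kinship estimated from the same few hundred LD blocks that
  are being tested, proximal contamination deflates λ_gc for any mixed
  model — the motivation for leave-one-chromosome-out schemes, which are
  out of scope here.
- Simulation sizes in the test suite (e.g. 50 end-to-end replicates at 200
  genotypes × 300 markers, 100 power replicates at 200 × 200) were chosen
  as the smallest panels at which the checked effects are comfortably
  identified; the full suite runs in well under a minute of compute per
  heavy test.
- Result TSVs print reals at 12 significant digits and round-trip exactly
  for string/integer columns.

## Known limitations

Balanced designs only for ANOVA/H²; single-trait stability (no multi-trait
index); no D′/haplotype LD; single-kinship single-random-effect MLM (no
multi-locus models, no genomic prediction); classification is a median
split, not the heatmap clustering sometimes used for the same four-class
narrative, so class counts on real data will differ from cluster-based
ones even when the quadrant semantics agree.
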