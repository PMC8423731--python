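"""Synthetic structured panels and multi-environment trial phenotypes.

The generator emulates a two-subpopulation crop panel (landraces vs
cultivars) genotyped at biallelic SNPs with local LD blocks, evaluated in a
randomized complete block design across several environments. Ground truth —
per-genotype main effects g_i, environmental sensitivities s_i (offsets to a
Finlay–Wilkinson slope of 1), environment effects and the planted QTLs — is
returned alongside the observations so every downstream statistic can be
checked against what was planted.

Phenotype model (per trait):

    y_ijr = mu + g_i + e_j + ge_ij + b_r(j) + eps_ijr
    g_i   = sum_q beta_main,q * dosage_iq  + N(0, var_g)      (then centered)
    ge_ij = s_i * I_j + N(0, var_ge)
    s_i   = sum_q beta_sens,q * dosage_iq + N(0, var_s)       (then centered)

with I_j the centered environment effect, so a QTL can move the mean, the
environmental sensitivity (the regression slope b_i = 1 + s_i in
expectation), or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PhenotypeRecords, ValidationError, validate_phenotypes

# wheat-like genome labels: 21 chromosomes in three homoeologous genomes
WHEAT_CHROMOSOMES = [f"{n}{g}" for g in "ABD" for n in range(1, 8)]


@dataclass
class TraitSpec:
    """One simulated trait: mean and variance components on the trait scale."""

    name: str
    mu: float
    var_g: float        # polygenic genotype-main variance (on top of QTLs)
    var_e_env: float    # environment main-effect variance
    var_ge: float       # free (non-regression) GEI variance
    var_resid: float    # plot residual variance
    var_s: float = 0.05     # variance of polygenic sensitivity offsets
    var_block: float = 0.02  # replicate-block-within-environment variance


@dataclass
class Qtl:
    marker_index: int
    trait: str
    beta_main: float = 0.0
    beta_sensitivity: float = 0.0


def _default_traits() -> list[TraitSpec]:
    # variance components chosen so plug-in H2 spans the low (GY) to high (PH)
    # heritability range typical of rain-fed/irrigated wheat MET data
    return [
        TraitSpec("GY", mu=1.8, var_g=0.05, var_e_env=0.30, var_ge=0.15, var_resid=0.45,
                  var_s=0.04, var_block=0.01),
        TraitSpec("GN", mu=38.7, var_g=45.0, var_e_env=80.0, var_ge=60.0, var_resid=100.0,
                  var_s=0.04, var_block=2.0),
        TraitSpec("SW", mu=2.0, var_g=0.06, var_e_env=0.15, var_ge=0.09, var_resid=0.18,
                  var_s=0.04, var_block=0.005),
        TraitSpec("PH", mu=100.0, var_g=120.0, var_e_env=150.0, var_ge=40.0, var_resid=80.0,
                  var_s=0.04, var_block=3.0),
    ]


def _default_qtls() -> list[Qtl]:
    # one pleiotropic (mean + sensitivity), one mean-only and one
    # sensitivity-only QTL for yield; one mean QTL for each other trait
    return [
        Qtl(marker_index=100, trait="GY", beta_main=0.15, beta_sensitivity=0.25),
        Qtl(marker_index=500, trait="GY", beta_main=0.15),
        Qtl(marker_index=900, trait="GY", beta_sensitivity=0.25),
        Qtl(marker_index=300, trait="GN", beta_main=4.0),
        Qtl(marker_index=700, trait="SW", beta_main=0.15),
        Qtl(marker_index=1100, trait="PH", beta_main=6.0),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel and trial.

    Defaults emulate a 268-genotype wheat panel (180 landraces, 88 cultivars)
    evaluated in six environments (four well-watered, two rain-fed) in an
    RCBD with two replications, genotyped at 2000 SNPs on 21 chromosomes.
    """

    n_genotypes: int = 268
    group_split: tuple[int, int] = (180, 88)  # (landrace, cultivar)
    n_environments: int = 6
    n_reps: int = 2
    n_markers: int = 2000
    n_chromosomes: int = 21
    ld_block_len: int = 10
    ld_block_mix: float = 0.95   # copula weight on the block-shared uniform
    inbreeding: float = 0.95     # fraction of fully inbred individuals (selfing crop)
    fst_like_divergence: float = 0.10
    marker_spacing_bp: int = 300_000
    marker_spacing_cm: float = 0.25
    traits: list[TraitSpec] = field(default_factory=_default_traits)
    qtls: list[Qtl] = field(default_factory=_default_qtls)
    seed: int = 42

    def __post_init__(self) -> None:
        if sum(self.group_split) != self.n_genotypes:
            raise ValidationError(
                f"group_split {self.group_split} must sum to n_genotypes={self.n_genotypes}"
            )
        if not 0.0 <= self.fst_like_divergence <= 0.5:
            raise ValidationError("fst_like_divergence must be in [0, 0.5]")
        trait_names = {t.name for t in self.traits}
        for t in self.traits:
            for v in (t.var_g, t.var_e_env, t.var_ge, t.var_resid, t.var_s, t.var_block):
                if v < 0:
                    raise ValidationError(f"negative variance in trait {t.name}")
        for q in self.qtls:
            if not 0 <= q.marker_index < self.n_markers:
                raise ValidationError(f"QTL marker index {q.marker_index} out of range")
            if q.trait not in trait_names:
                raise ValidationError(f"QTL trait {q.trait!r} not among simulated traits")

    def environment_names(self) -> list[str]:
        # four well-watered then rain-fed environments, wrapping if more needed
        names = []
        for j in range(self.n_environments):
            kind = "WW" if j < min(4, self.n_environments - 2) else "RF"
            names.append(f"{kind}{j + 1}")
        return names


@dataclass
class SimTruth:
    """Planted ground truth for one simulation."""

    genotype_effects: pd.DataFrame    # genotype x trait true g_i
    sensitivities: pd.DataFrame       # genotype x trait true s_i (slope - 1)
    environment_effects: pd.DataFrame  # environment x trait true e_j
    variance_components: pd.DataFrame  # trait x realized component variances
    qtls: list[Qtl]


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Named, independent sub-stream of the global seed."""
    stages = ("genotypes", "effects", "noise")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stages.index(stage),)))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a two-subpopulation SNP panel with block LD.

    Ancestral frequencies are Uniform(0.05, 0.95); each subpopulation's
    frequency is a Balding–Nichols-style Beta draw around the ancestral one
    with divergence parameter F. Haplotypes share one uniform per LD block:
    each marker uses the shared uniform with probability ``ld_block_mix``,
    otherwise a fresh one, producing high within-block and zero between-block
    correlation.
    """
    rng = _rng(cfg.seed, "genotypes")
    m, n = cfg.n_markers, cfg.n_genotypes
    F = cfg.fst_like_divergence

    # chromosome assignment first; LD blocks never straddle a chromosome
    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    chrom_idx = np.arange(m) // per_chrom
    idx_in_chrom = np.arange(m) % per_chrom
    block_id = chrom_idx * per_chrom + idx_in_chrom // cfg.ld_block_len
    block_id = np.unique(block_id, return_inverse=True)[1]
    n_blocks = block_id.max() + 1

    # one frequency per LD block (markers in a block share it, so shared-copula
    # draws translate into high within-block dosage correlation)
    p0_blk = rng.uniform(0.05, 0.95, size=n_blocks)
    # causal blocks segregate at intermediate frequency in both subpopulations:
    # a planted QTL must stay polymorphic and unconfounded with structure
    qtl_blocks = np.unique([block_id[q.marker_index] for q in cfg.qtls]).astype(int) \
        if cfg.qtls else np.array([], dtype=int)
    p0_blk[qtl_blocks] = rng.uniform(0.2, 0.8, size=len(qtl_blocks))
    p0 = p0_blk[block_id]
    if F > 0:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        blk = np.flatnonzero(np.diff(block_id, prepend=-1))  # first marker of each block
        p_sub = np.empty((2, m))
        for k in range(2):
            p_blk = rng.beta(a[blk], b[blk]).clip(1e-4, 1 - 1e-4)
            p_sub[k] = p_blk[block_id]
    else:
        p_sub = np.stack([p0, p0])
    if len(qtl_blocks):
        causal = np.isin(block_id, qtl_blocks)
        p_sub[:, causal] = p0[causal]

    group_of = np.repeat([0, 1], cfg.group_split)

    p = p_sub[group_of]                                           # (n, m)
    haps = []
    for hap in range(2):
        u_shared = rng.uniform(size=(n, n_blocks))[:, block_id]   # (n, m)
        u_free = rng.uniform(size=(n, m))
        use_shared = rng.uniform(size=(n, m)) < cfg.ld_block_mix
        u = np.where(use_shared, u_shared, u_free)
        haps.append((u < p).astype(np.int16))
    # selfing crop: a fully inbred line doubles its first haplotype
    inbred = rng.uniform(size=n) < cfg.inbreeding
    h2 = np.where(inbred[:, None], haps[0], haps[1])
    dosage = haps[0] + h2

    chrom_labels = (WHEAT_CHROMOSOMES * 3)[: cfg.n_chromosomes]
    chrom = np.array(chrom_labels)[chrom_idx]
    markers = pd.DataFrame({
        "marker": [f"S{c}_{i + 1}" for c, i in zip(chrom, idx_in_chrom)],
        "chrom": chrom,
        "pos_bp": (idx_in_chrom + 1) * cfg.marker_spacing_bp,
        "pos_cm": (idx_in_chrom + 1) * cfg.marker_spacing_cm,
        "ref": "A",
        "alt": "B",
    })
    samples = [f"G{i + 1:03d}" for i in range(n)]
    groups = np.where(group_of == 0, "landrace", "cultivar")
    from .io import _orient_minor

    dosage, markers = _orient_minor(dosage, markers)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage, groups=groups)


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig) -> tuple[PhenotypeRecords, SimTruth]:
    """Simulate the replicated multi-environment trial on an existing panel."""
    rng_eff = _rng(cfg.seed, "effects")
    rng_noise = _rng(cfg.seed, "noise")
    n = g.n_samples
    envs = cfg.environment_names()
    e_count, r_count = cfg.n_environments, cfg.n_reps

    dose = np.where(g.dosage == MISSING, np.nan, g.dosage).astype(float)
    dose = np.where(np.isnan(dose), np.nanmean(dose, axis=0), dose)
    dose_c = dose - dose.mean(axis=0)

    g_eff, s_eff, e_eff, vc_rows = {}, {}, {}, []
    rows_y = []
    for spec in cfg.traits:
        e_j = rng_eff.normal(0.0, np.sqrt(spec.var_e_env), size=e_count)
        I_j = e_j - e_j.mean()

        g_i = rng_eff.normal(0.0, np.sqrt(spec.var_g), size=n)
        s_i = rng_eff.normal(0.0, np.sqrt(spec.var_s), size=n)
        for q in cfg.qtls:
            if q.trait != spec.name:
                continue
            g_i = g_i + q.beta_main * dose_c[:, q.marker_index]
            s_i = s_i + q.beta_sensitivity * dose_c[:, q.marker_index]
        g_i = g_i - g_i.mean()
        s_i = s_i - s_i.mean()

        ge = s_i[:, None] * I_j[None, :] + rng_noise.normal(
            0.0, np.sqrt(spec.var_ge), size=(n, e_count))
        blocks = rng_noise.normal(0.0, np.sqrt(spec.var_block), size=(e_count, r_count))
        eps = rng_noise.normal(0.0, np.sqrt(spec.var_resid), size=(n, e_count, r_count))

        y = (spec.mu + g_i[:, None, None] + e_j[None, :, None] + ge[:, :, None]
             + blocks[None, :, :] + eps)

        gi_idx, ej_idx, r_idx = np.meshgrid(
            np.arange(n), np.arange(e_count), np.arange(r_count), indexing="ij")
        rows_y.append(pd.DataFrame({
            "genotype": np.array(g.samples)[gi_idx.ravel()],
            "environment": np.array(envs)[ej_idx.ravel()],
            "replicate": r_idx.ravel() + 1,
            "trait": spec.name,
            "value": y.ravel(),
        }))

        g_eff[spec.name] = g_i
        s_eff[spec.name] = s_i
        e_eff[spec.name] = e_j
        vc_rows.append({
            "trait": spec.name,
            "var_g_realized": float(g_i.var(ddof=1)),
            "var_s_realized": float(s_i.var(ddof=1)),
            "var_ge_free": spec.var_ge,
            "var_resid": spec.var_resid,
        })

    records = validate_phenotypes(pd.concat(rows_y, ignore_index=True), source="<simulated>")
    truth = SimTruth(
        genotype_effects=pd.DataFrame(g_eff, index=g.samples),
        sensitivities=pd.DataFrame(s_eff, index=g.samples),
        environment_effects=pd.DataFrame(e_eff, index=envs),
        variance_components=pd.DataFrame(vc_rows).set_index("trait"),
        qtls=[q for q in cfg.qtls],
    )
    return records, truth
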