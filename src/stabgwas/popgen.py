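"""Per-SNP diversity statistics and pairwise linkage disequilibrium.

Diversity per marker (frequencies on non-missing calls, minor-allele
oriented): MAF, gene diversity GD = 2p(1-p), observed heterozygosity (the
fraction of dosage-1 calls) and PIC = 1 - (p^2 + q^2) - 2 p^2 q^2.

LD is composite r^2 on unphased dosages: the squared Pearson correlation of
dosage vectors on pairwise-complete samples, with significance from the
chi-square statistic n * r^2 (1 df). Decay distance is where the fitted
Hill-Weir expectation of r^2 against distance crosses a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger("stabgwas")


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def pic_from_freq(p: np.ndarray) -> np.ndarray:
    """Polymorphism information content of a biallelic site at frequency p."""
    q = 1.0 - p
    return 1.0 - (p ** 2 + q ** 2) - 2.0 * p ** 2 * q ** 2


@dataclass
class SnpDiversity:
    per_marker: pd.DataFrame   # marker, chrom, maf, gd, het, pic
    per_chromosome: pd.DataFrame
    per_genome: pd.DataFrame | None
    genome_wide: pd.Series


def snp_diversity(g: GenotypeMatrix, genome_map: dict[str, str] | None = None) -> SnpDiversity:
    """MAF, gene diversity, heterozygosity and PIC per marker with aggregates.

    ``genome_map`` maps a chromosome to a genome group (e.g. "1A" -> "A");
    when omitted, the trailing letter of the chromosome label is used if all
    labels end in a letter.
    """
    if g.n_markers == 0:
        raise ValidationError("no markers")
    d = np.ma.masked_equal(g.dosage, MISSING)
    n_valid = (~d.mask).sum(axis=0) if np.ma.is_masked(d) else np.full(g.n_markers, g.n_samples)
    if (np.asarray(n_valid) < 2).any():
        raise ValidationError("marker with fewer than 2 non-missing calls")
    p = np.minimum(d.mean(axis=0).filled(0.0) / 2.0, 1 - d.mean(axis=0).filled(0.0) / 2.0)
    gd = 2.0 * p * (1.0 - p)
    het = (d == 1).mean(axis=0)
    het = het.filled(0.0) if np.ma.is_masked(het) else np.asarray(het)
    pic = pic_from_freq(p)
    if (p == 0).any():
        logger.info("%d monomorphic marker(s) present (maf = 0)", int((p == 0).sum()))

    pm = pd.DataFrame({
        "marker": g.markers["marker"],
        "chrom": g.markers["chrom"],
        "pos_bp": g.markers["pos_bp"],
        "maf": p, "gd": gd, "het": het, "pic": pic,
    })

    def agg(frame: pd.DataFrame) -> pd.Series:
        span = (frame["pos_bp"].max() - frame["pos_bp"].min()) / 1e6
        return pd.Series({
            "n_snps": len(frame),
            "density_per_mbp": len(frame) / span if span > 0 else np.nan,
            "maf": frame["maf"].mean(), "gd": frame["gd"].mean(),
            "het": frame["het"].mean(), "pic": frame["pic"].mean(),
        })

    per_chrom = pm.groupby("chrom", sort=True).apply(agg, include_groups=False)
    if genome_map is None:
        chroms = pm["chrom"].unique()
        if all(str(c)[-1].isalpha() for c in chroms):
            genome_map = {str(c): str(c)[-1] for c in chroms}
    per_genome = None
    if genome_map is not None:
        pm2 = pm.assign(genome=pm["chrom"].map(genome_map))
        per_genome = pm2.groupby("genome", sort=True).apply(agg, include_groups=False)
    genome_wide = agg(pm)
    genome_wide["density_per_mbp"] = per_chrom["density_per_mbp"].mean()
    return SnpDiversity(per_marker=pm, per_chromosome=per_chrom,
                        per_genome=per_genome, genome_wide=genome_wide)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDSummary:
    per_chromosome: pd.DataFrame  # tnsp, mean_r2, mean_distance, nssp, nssp_pct
    genome_wide: pd.Series
    pairs: pd.DataFrame           # chrom, m1, m2, distance, r2, p
    distance_unit: str
    alpha: float


def _pair_r2(dosage: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    """r^2 and complete-sample count for marker index pairs (columns of dosage)."""
    x = dosage[:, idx1].astype(float)
    y = dosage[:, idx2].astype(float)
    ok = (dosage[:, idx1] != MISSING) & (dosage[:, idx2] != MISSING)
    x[~ok] = np.nan
    y[~ok] = np.nan
    n = ok.sum(axis=0).astype(float)
    mx = np.nanmean(x, axis=0)
    my = np.nanmean(y, axis=0)
    cov = np.nansum((x - mx) * (y - my), axis=0)
    vx = np.nansum((x - mx) ** 2, axis=0)
    vy = np.nansum((y - my) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((vx > 0) & (vy > 0), cov ** 2 / (vx * vy), np.nan)
    return r2, n


def pairwise_ld(
    g: GenotypeMatrix,
    alpha: float = 0.001,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> LDSummary:
    """Within-chromosome pairwise r^2 with chi-square significance counts.

    Distance uses the cM map when present for every marker, otherwise bp.
    Chromosomes whose pair count exceeds ``max_pairs`` are subsampled with a
    seeded generator (logged). Zero-variance markers are skipped with a
    logged count.
    """
    use_cm = not g.markers["pos_cm"].isna().any()
    unit = "cM" if use_cm else "bp"
    pos = g.markers["pos_cm" if use_cm else "pos_bp"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    frames = []
    n_skipped = 0
    for chrom, sub in g.markers.groupby("chrom", sort=True):
        idx = np.asarray(sub.index)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        if len(idx) < 2:
            continue
        i1, i2 = np.triu_indices(len(idx), k=1)
        if len(i1) > max_pairs:
            pick = rng.choice(len(i1), size=max_pairs, replace=False)
            i1, i2 = i1[pick], i2[pick]
            logger.info("chromosome %s: subsampled %d of %d pairs", chrom, max_pairs, len(idx) * (len(idx) - 1) // 2)
        m1, m2 = idx[i1], idx[i2]
        r2, n = _pair_r2(g.dosage, m1, m2)
        ok = np.isfinite(r2)
        n_skipped += int((~ok).sum())
        pvals = stats.chi2.sf(n[ok] * r2[ok], df=1)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "m1": g.markers["marker"].to_numpy()[m1[ok]],
            "m2": g.markers["marker"].to_numpy()[m2[ok]],
            "distance": np.abs(pos[m2[ok]] - pos[m1[ok]]),
            "r2": r2[ok],
            "p": pvals,
        }))
    if n_skipped:
        logger.info("skipped %d pair(s) with a zero-variance marker", n_skipped)
    if not frames:
        raise ValidationError("no evaluable marker pairs")
    pairs = pd.concat(frames, ignore_index=True)

    def agg(frame: pd.DataFrame) -> pd.Series:
        nssp = int((frame["p"] < alpha).sum())
        return pd.Series({
            "tnsp": len(frame),
            "mean_r2": frame["r2"].mean(),
            "mean_distance": frame["distance"].mean(),
            "nssp": nssp,
            "nssp_pct": 100.0 * nssp / len(frame) if len(frame) else np.nan,
        })

    per_chrom = pairs.groupby("chrom", sort=True).apply(agg, include_groups=False)
    per_chrom = per_chrom.astype({"tnsp": int, "nssp": int})
    return LDSummary(per_chromosome=per_chrom, genome_wide=agg(pairs), pairs=pairs,
                     distance_unit=unit, alpha=alpha)


def hill_weir_expectation(distance: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Expected r^2 at a recombination-scaled distance C = rho * distance
    for a sample of n sequences (drift-recombination expectation with the
    finite-sample correction)."""
    c = rho * np.asarray(distance, dtype=float)
    t1 = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    t2 = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c ** 2)) / (n * (2.0 + c) * (11.0 + c))
    return t1 * t2


def ld_decay(pairs: pd.DataFrame, n_samples: int, r2_threshold: float = 0.1) -> float:
    """Distance at which the fitted expected-r^2 curve crosses the threshold.

    Fits the Hill-Weir expectation by least squares over (distance, r^2)
    pairs; returns 0.0 when the curve starts below the threshold, ``inf``
    when it never crosses within the observed distance range, and falls back
    to distance-binned means with linear interpolation if the fit fails.
    """
    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    keep = d > 0
    d, r2 = d[keep], r2[keep]
    if len(d) < 20:
        raise ValidationError("LD decay needs at least 20 pairs with positive distance")
    n_chrom = 2 * n_samples  # chromosomes sampled

    # distance-binned mean curve: the empirical decay profile, also the
    # lack-of-fit reference and the fallback estimator
    order = np.argsort(d)
    bins = np.array_split(order, max(5, min(50, len(d) // 20)))
    bd = np.array([d[b].mean() for b in bins])
    br = np.array([r2[b].mean() for b in bins])

    def curve(x, rho):
        return hill_weir_expectation(x, rho, n_chrom)

    fitted = None
    try:
        (rho_hat,), _ = optimize.curve_fit(
            curve, d, r2, p0=[1.0 / np.median(d)], bounds=(1e-12, np.inf), maxfev=5000)
        # drift-recombination expectation cannot represent e.g. step/block LD;
        # guard with a lack-of-fit check against the empirical binned curve
        if np.max(np.abs(curve(bd, rho_hat) - br)) <= 0.1:
            fitted = lambda x: hill_weir_expectation(x, rho_hat, n_chrom)
        else:
            logger.info("Hill-Weir curve misfits the empirical decay profile; "
                        "using binned means")
    except (RuntimeError, ValueError):
        logger.warning("Hill-Weir fit did not converge; using binned means")
    if fitted is None:
        fitted = lambda x: np.interp(x, bd, br)

    # evaluate over the observed distance range; "starts below" is judged at
    # the shortest observed pair distance
    grid = np.linspace(d.min(), d.max(), 2048)
    vals = np.asarray(fitted(grid))
    if vals[0] < r2_threshold:
        return 0.0
    below = np.flatnonzero(vals < r2_threshold)
    if len(below) == 0:
        logger.info("fitted LD curve never falls below %.3g in range; decay unresolved",
                    r2_threshold)
        return float("inf")
    k = below[0]
    x0, x1 = grid[k - 1], grid[k]
    y0, y1 = vals[k - 1], vals[k]
    return float(x0 + (y0 - r2_threshold) / (y0 - y1) * (x1 - x0))


def ld_decay_per_chromosome(ld: LDSummary, n_samples: int,
                            r2_threshold: float = 0.1) -> pd.Series:
    out = {}
    for chrom, sub in ld.pairs.groupby("chrom", sort=True):
        try:
            out[chrom] = ld_decay(sub, n_samples, r2_threshold)
        except ValidationError:
            out[chrom] = np.nan
    return pd.Series(out, name="decay_distance")


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def group_compare(g: GenotypeMatrix, alpha: float = 0.001, max_pairs: int = 2_000_000,
                  seed: int = 0, genome_map: dict[str, str] | None = None
                  ) -> dict[str, tuple[SnpDiversity, LDSummary | None]]:
    """Diversity and LD per group label plus the pooled panel ("Total").

    The marker set is identical across runs; groups with fewer than two
    samples are skipped with a warning, and a group with no evaluable marker
    pairs gets a None LD summary.
    """
    if g.groups is None:
        raise ValidationError("genotype matrix has no group labels")

    def one(sub: GenotypeMatrix, label: str):
        div = snp_diversity(sub, genome_map)
        try:
            ld = pairwise_ld(sub, alpha=alpha, max_pairs=max_pairs, seed=seed)
        except ValidationError as exc:
            logger.warning("LD skipped for group %r: %s", label, exc)
            ld = None
        return div, ld

    out: dict[str, tuple[SnpDiversity, LDSummary | None]] = {}
    for grp in sorted(set(g.groups)):
        idx = np.flatnonzero(g.groups == grp)
        if len(idx) < 2:
            logger.warning("group %r has %d sample(s); skipped", grp, len(idx))
            continue
        out[grp] = one(g.subset(sample_idx=idx), grp)
    out["Total"] = one(g, "Total")
    return out
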