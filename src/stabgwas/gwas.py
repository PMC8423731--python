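"""Kinship, structure PCA and single-marker association scans (GLM and MLM).

The mixed linear model is y = X b + u + e with u ~ N(0, sigma2_a K) and
e ~ N(0, sigma2_e I). The variance ratio delta = sigma2_a / sigma2_e is
estimated once on the null model (no marker) by maximizing the restricted
likelihood over the eigendecomposition of K, then every marker is tested by
a generalized-least-squares Wald test in the rotated space — the
"population parameters previously determined" scheme used by standard MLM
GWAS tools. Significance is declared on raw -log10(p) (default threshold 3)
and marker-trait-association confidence intervals come from per-chromosome
LD decay distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger("stabgwas")

#: smallest reportable p-value (underflow sentinel)
P_FLOOR = 5e-324

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)


def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Float dosage with per-marker mean imputation of missing calls."""
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def kinship_vanraden(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = W W' / sum 2 p (1-p).

    W is the dosage matrix centered at twice the allele frequency; a 1e-6
    ridge on the diagonal keeps K numerically positive definite.
    """
    d = _imputed_dosage(g)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValidationError("no polymorphic markers for kinship")
    w = d[:, poly] - 2.0 * p[poly]
    c = float((2.0 * p[poly] * (1.0 - p[poly])).sum())
    k = w @ w.T / c
    k[np.diag_indices_from(k)] += 1e-6
    return k


def structure_pca(g: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Leading principal-component scores of the centered dosage matrix.

    Sign convention: the largest-|loading| entry of each component's marker
    loading vector is positive, so scores are reproducible across runs.
    """
    if k <= 0:
        raise ValidationError("number of principal components must be positive")
    if k >= min(g.n_samples, g.n_markers):
        raise ValidationError(f"k={k} must be < min(samples, markers)")
    d = _imputed_dosage(g)
    d = d - d.mean(axis=0)
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var_share = (s[:k] ** 2) / (s ** 2).sum()
    logger.info("structure PCA: leading %d components explain %s of dosage variance",
                k, np.array2string(var_share, precision=3))
    return u[:, :k] * s[:k]


@dataclass
class GWASResult:
    response: str
    table: pd.DataFrame        # marker, chrom, pos_bp, beta, se, p, neglog10p, significant
    lambda_gc: float
    model: str
    threshold: float = 3.0
    variance_components: dict = field(default_factory=dict)

    def significant_markers(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _assemble_result(g, response_name, beta, se, pvals, model, threshold, vc=None):
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    neglog = -np.log10(pvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(np.isfinite(se) & (se > 0), (beta / se) ** 2, 0.0)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    table = pd.DataFrame({
        "marker": g.markers["marker"],
        "chrom": g.markers["chrom"],
        "pos_bp": g.markers["pos_bp"],
        "beta": beta,
        "se": se,
        "p": pvals,
        "neglog10p": neglog,
        "significant": neglog > threshold,
    })
    return GWASResult(response=response_name, table=table, lambda_gc=lam,
                      model=model, threshold=threshold,
                      variance_components=vc or {})


def _check_alignment(y: pd.Series | np.ndarray, g: GenotypeMatrix) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [s for s in g.samples if s not in y.index]
        if missing:
            raise ValidationError(f"response missing for sample(s): {missing[:5]}")
        y = y.loc[list(g.samples)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (g.n_samples,):
        raise ValidationError("response length does not match the number of samples")
    if not np.isfinite(y).all():
        raise ValidationError("response contains non-finite values")
    if np.ptp(y) == 0:
        raise ValidationError("response is constant")
    return y


def _weighted_scan(y, d, covariates, w, response, g, model, threshold, vc=None):
    """Per-marker GLS Wald tests with weights w (w = 1 for ordinary GLM).

    Residualizes response and markers on the covariates in the weighted inner
    product and tests each marker's slope with n - p - 1 degrees of freedom.
    """
    n = len(y)
    x0 = covariates
    p0 = x0.shape[1]
    sw = np.sqrt(w)
    x0w = x0 * sw[:, None]
    yw = y * sw
    dw = d * sw[:, None]
    q, _ = np.linalg.qr(x0w)
    ry = yw - q @ (q.T @ yw)
    rd = dw - q @ (q.T @ dw)

    dof = n - p0 - 1
    if dof <= 0:
        raise ValidationError("not enough samples for the covariate model")
    sxx = (rd ** 2).sum(axis=0)
    mono = sxx <= 1e-12 * n
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (rd * ry[:, None]).sum(axis=0) / sxx_safe
    rss = (ry ** 2).sum() - beta ** 2 * sxx_safe
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx_safe)
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta = np.where(mono, 0.0, beta)
    se = np.where(mono, np.inf, se)
    pvals = np.where(mono, 1.0, pvals)
    pvals = np.where(~mono & (pvals == 0.0), P_FLOOR, pvals)
    if mono.any():
        logger.info("%d monomorphic marker(s) assigned p = 1", int(mono.sum()))
    return _assemble_result(g, response, beta, se, pvals, model, threshold, vc)


def glm_scan(y, g: GenotypeMatrix, q: np.ndarray | None = None,
             threshold: float = 3.0, response_name: str = "trait") -> GWASResult:
    """Ordinary least-squares scan: y ~ intercept + structure PCs + dosage."""
    yv = _check_alignment(y, g)
    d = _imputed_dosage(g)
    cov = np.ones((len(yv), 1))
    if q is not None:
        cov = np.column_stack([cov, q])
    return _weighted_scan(yv, d, cov, np.ones(len(yv)), response_name, g, "GLM", threshold)


def _reml_delta(y_rot: np.ndarray, x_rot: np.ndarray, lam: np.ndarray) -> float:
    """Profile-REML estimate of delta = sigma2_a / sigma2_e on the null model."""
    n, p = x_rot.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        v = delta * lam + 1.0
        sw = 1.0 / np.sqrt(v)
        xw = x_rot * sw[:, None]
        yw = y_rot * sw
        xtx = xw.T @ xw
        try:
            beta = np.linalg.solve(xtx, xw.T @ yw)
        except np.linalg.LinAlgError:
            return np.inf
        r = yw - xw @ beta
        rss = float(r @ r)
        if rss <= 0:
            return np.inf
        sign, logdet_xtx = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.log(v).sum() + logdet_xtx
                     + (n - p))
        return -ll

    grid = np.linspace(-10.0, 10.0, 41)
    vals = [neg_reml(ld) for ld in grid]
    k = int(np.argmin(vals))
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))
    # treat the boundary as "no genetic variance"
    if res.x <= grid[0] + 1e-6 or (k == 0 and vals[0] <= min(vals)):
        if neg_reml(grid[0]) <= res.fun:
            delta = 0.0
    return delta


def mlm_scan(y, g: GenotypeMatrix, q: np.ndarray | None, k: np.ndarray,
             threshold: float = 3.0, response_name: str = "trait") -> GWASResult:
    """Mixed-model scan with kinship (PCA + K), P3D variance components."""
    yv = _check_alignment(y, g)
    kmat = np.asarray(k, dtype=float)
    if kmat.shape != (g.n_samples, g.n_samples):
        raise ValidationError("kinship shape does not match samples")
    if not np.allclose(kmat, kmat.T, atol=1e-10):
        raise ValidationError("kinship matrix is not symmetric")
    lam, u = np.linalg.eigh(kmat)
    if lam.min() < -1e-8:
        raise ValidationError(f"kinship not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)

    cov = np.ones((len(yv), 1))
    if q is not None:
        cov = np.column_stack([cov, q])
    y_rot = u.T @ yv
    x_rot = u.T @ cov
    d_rot = u.T @ _imputed_dosage(g)

    delta = _reml_delta(y_rot, x_rot, lam)
    w = 1.0 / (delta * lam + 1.0)
    # report component estimates on the null model at the chosen delta
    sw = np.sqrt(w)
    xw = x_rot * sw[:, None]
    yw = y_rot * sw
    beta0, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    sigma2_e = float(((yw - xw @ beta0) ** 2).sum() / (len(yv) - cov.shape[1]))
    vc = {"delta": delta, "sigma2_e": sigma2_e, "sigma2_a": delta * sigma2_e}
    logger.info("MLM %s: delta=%.4g sigma2_a=%.4g sigma2_e=%.4g",
                response_name, delta, vc["sigma2_a"], sigma2_e)
    return _weighted_scan(y_rot, d_rot, x_rot, w, response_name, g, "MLM", threshold, vc)


# ---------------------------------------------------------------------------
# MTA calling and pleiotropy
# ---------------------------------------------------------------------------

def call_mtas(res: GWASResult, ld_decay_by_chrom: dict[str, float] | pd.Series | None = None,
              threshold: float | None = None) -> pd.DataFrame:
    """Markers above the -log10(p) threshold, with LD-decay confidence intervals.

    Each MTA's interval is position +/- its chromosome's decay distance;
    overlapping intervals on a chromosome are merged into loci (the ``locus``
    column), so MTAs are reported individually and as merged loci.
    """
    thr = res.threshold if threshold is None else threshold
    hits = res.table[res.table["neglog10p"] > thr].copy()
    if hits.empty:
        return hits.assign(ci_lo=pd.Series(dtype=float), ci_hi=pd.Series(dtype=float),
                           locus=pd.Series(dtype=str))
    decay = pd.Series(ld_decay_by_chrom) if ld_decay_by_chrom is not None else None

    def span(row):
        d = float(decay.get(row["chrom"], 0.0)) if decay is not None else 0.0
        if not np.isfinite(d):
            d = 0.0
        return pd.Series({"ci_lo": row["pos_bp"] - d, "ci_hi": row["pos_bp"] + d})

    hits[["ci_lo", "ci_hi"]] = hits.apply(span, axis=1)
    hits = hits.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
    loci = []
    current_end, locus_n, prev_chrom = -np.inf, 0, None
    for _, row in hits.iterrows():
        if row["chrom"] != prev_chrom or row["ci_lo"] >= current_end:
            locus_n += 1
            current_end = row["ci_hi"]
            prev_chrom = row["chrom"]
        else:
            current_end = max(current_end, row["ci_hi"])
        loci.append(f"{row['chrom']}:L{locus_n}")
    hits["locus"] = loci
    return hits


def pleiotropy_overlap(results: dict[str, GWASResult],
                       mtas: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Markers significant for two or more responses, largest overlap first.

    When per-response MTA frames (from :func:`call_mtas`) are given, a
    locus-level overlap column is included alongside the marker-level one.
    """
    if len(results) < 2:
        raise ValidationError("pleiotropy overlap needs at least two responses")
    marker_sets = [tuple(r.table["marker"]) for r in results.values()]
    if len(set(marker_sets)) != 1:
        raise ValidationError("responses were scanned on different marker sets")
    rows = {}
    for resp, r in results.items():
        for m in r.significant_markers()["marker"]:
            rows.setdefault(m, set()).add(resp)
    rows = {m: resp for m, resp in rows.items() if len(resp) >= 2}
    if not rows:
        return pd.DataFrame(columns=["marker", "chrom", "pos_bp", "n_responses", "responses"])
    any_table = next(iter(results.values())).table.set_index("marker")
    out = pd.DataFrame({
        "marker": list(rows),
        "chrom": [any_table.loc[m, "chrom"] for m in rows],
        "pos_bp": [any_table.loc[m, "pos_bp"] for m in rows],
        "n_responses": [len(v) for v in rows.values()],
        "responses": [",".join(sorted(v)) for v in rows.values()],
    }).sort_values(["n_responses", "marker"], ascending=[False, True]).reset_index(drop=True)
    if mtas:
        locus_of = {}
        for resp, frame in mtas.items():
            for _, row in frame.iterrows():
                locus_of.setdefault(row["marker"], row.get("locus", ""))
        out["locus"] = out["marker"].map(locus_of).fillna("")
    return out


def manhattan_data(res: GWASResult) -> pd.DataFrame:
    """Plain Manhattan-plot export: marker, chromosome, position, -log10(p)."""
    return res.table[["marker", "chrom", "pos_bp", "neglog10p"]].copy()


def qq_data(res: GWASResult) -> pd.DataFrame:
    """QQ-plot export: expected vs observed -log10(p)."""
    obs = np.sort(res.table["neglog10p"].to_numpy())[::-1]
    n = len(obs)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": exp, "observed": obs})
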