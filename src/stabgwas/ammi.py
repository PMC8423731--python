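"""AMMI decomposition of the genotype x environment interaction and the
AMMI-derived stability indices ASV and MASI.

The interaction residual Z_ij = X_ij - Xbar_i. - Xbar_.j + Xbar_.. is
decomposed by SVD; scores use the symmetric sqrt(lambda) scaling so the sum
of squares of interaction principal component n equals lambda_n^2 and the
ASV formula can use raw scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .met import GEMeans


@dataclass
class AMMIFit:
    grand_mean: float
    genotype_effects: pd.Series       # deviations Xbar_i. - Xbar_..
    environment_effects: pd.Series
    genotype_scores: pd.DataFrame     # g x K, columns IPCA1..K, sqrt(lambda)-scaled
    environment_scores: pd.DataFrame  # e x K
    singular_values: np.ndarray       # length K, non-increasing
    ss_pc: np.ndarray                 # lambda_n^2 per component (cell-mean scale)
    theta: np.ndarray                 # share of interaction SS per component

    @property
    def K(self) -> int:
        return len(self.singular_values)

    def interaction_matrix(self) -> np.ndarray:
        """Reconstruct the doubly-centered residual from the scores."""
        return self.genotype_scores.to_numpy() @ self.environment_scores.to_numpy().T


def fit_ammi(m: GEMeans) -> AMMIFit:
    """Additive main effects plus SVD of the doubly-centered interaction."""
    x = m.matrix()
    if not np.isfinite(x).all():
        raise ValidationError("GE mean matrix contains non-finite cells")
    g, e = x.shape
    if g < 3 or e < 3:
        raise ValidationError(f"AMMI needs at least 3 genotypes and 3 environments, got {g}x{e}")
    grand = x.mean()
    g_eff = x.mean(axis=1) - grand
    e_eff = x.mean(axis=0) - grand
    z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(g, e) - 1  # double centering kills one dimension
    u, s, vt = u[:, :k], s[:k], vt[:k]
    root = np.sqrt(s)
    gscores = u * root
    escores = vt.T * root
    ss_pc = s ** 2
    total = ss_pc.sum()
    theta = ss_pc / total if total > 0 else np.zeros_like(ss_pc)

    cols = [f"IPCA{i + 1}" for i in range(k)]
    return AMMIFit(
        grand_mean=float(grand),
        genotype_effects=pd.Series(g_eff, index=m.values.index),
        environment_effects=pd.Series(e_eff, index=m.values.columns),
        genotype_scores=pd.DataFrame(gscores, index=m.values.index, columns=cols),
        environment_scores=pd.DataFrame(escores, index=m.values.columns, columns=cols),
        singular_values=s,
        ss_pc=ss_pc,
        theta=theta,
    )


def gollob_n_components(fit: AMMIFit, ms_resid: float, df_resid: int, r: int,
                        alpha: float = 0.05, minimum: int = 2) -> int:
    """Number of interaction components significant by Gollob's F test.

    Component n has df g + e - 1 - 2n; its mean square (on the plot scale,
    hence the multiplication by r) is tested against the ANOVA residual mean
    square. At least ``minimum`` components are always retained.
    """
    g = len(fit.genotype_effects)
    e = len(fit.environment_effects)
    n_sig = 0
    for n, sspc in enumerate(fit.ss_pc, start=1):
        df_n = g + e - 1 - 2 * n
        if df_n <= 0 or ms_resid <= 0 or df_resid <= 0:
            break
        f = (r * sspc / df_n) / ms_resid
        if stats.f.sf(f, df_n, df_resid) >= alpha:
            break
        n_sig = n
    return int(min(max(n_sig, minimum), fit.K))


def asv(fit: AMMIFit) -> pd.DataFrame:
    """AMMI stability value: ASV = sqrt(((SSPC1/SSPC2) * PC1)^2 + PC2^2).

    Lower is more stable. Returns the value and its ascending rank RASV
    (ties broken by genotype order so ranks are a permutation of 1..g).
    """
    if fit.K < 2:
        raise ValidationError("ASV requires at least two interaction components")
    if fit.ss_pc[1] <= 0:
        raise ValidationError(
            "second interaction component has zero sum of squares; ASV undefined "
            "(inspect the number of non-null components K)"
        )
    ratio = fit.ss_pc[0] / fit.ss_pc[1]
    pc1 = fit.genotype_scores["IPCA1"].to_numpy()
    pc2 = fit.genotype_scores["IPCA2"].to_numpy()
    val = np.sqrt((ratio * pc1) ** 2 + pc2 ** 2)
    rank = stats.rankdata(val, method="ordinal").astype(int)
    return pd.DataFrame({"ASV": val, "RASV": rank}, index=fit.genotype_scores.index)


def masi(fit: AMMIFit, n_components: int, formula: str = "weighted_product") -> pd.Series:
    """Modified AMMI stability index over the first ``n_components`` components.

    ``weighted_product`` (default) computes sqrt(sum_n (PC_gn * theta_n)^2),
    weighting each squared score by the squared share of interaction sum of
    squares; ``printed_sum`` computes sqrt(sum_n (PC_gn^2 + theta_n^2))
    instead. Lower is more stable.
    """
    if not 1 <= n_components <= fit.K:
        raise ValidationError(f"n_components must be in [1, {fit.K}], got {n_components}")
    pc = fit.genotype_scores.to_numpy()[:, :n_components]
    th = fit.theta[:n_components]
    if formula == "weighted_product":
        val = np.sqrt(((pc * th) ** 2).sum(axis=1))
    elif formula == "printed_sum":
        val = np.sqrt((pc ** 2 + th ** 2).sum(axis=1))
    else:
        raise ValidationError(f"unknown MASI formula {formula!r}")
    return pd.Series(val, index=fit.genotype_scores.index, name="MASI")
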