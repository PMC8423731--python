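"""Mixed-model BLUPs of genotype and GEI effects and the BLUP-based
stability indices RPGV/HMRPGV, WAASB and WAASBY.

Model on cell means: X_ij = u_j + g_i + ge_ij (+ mean error), environments
fixed, genotype and interaction effects random. On a balanced design the
BLUPs are shrunken raw effects:

    g_i   = lambda_g  * d_i,      lambda_g  = s2_g / (s2_g + s2_ge/e + s2_eps/(e r))
    ge_ij = lambda_ge * (Z_ij + (1 - lambda_g) * d_i),
                                  lambda_ge = s2_ge / (s2_ge + s2_eps/r)

with d_i = Xbar_i. - Xbar_.. the raw genotype deviation and Z the
doubly-centered residual. The second term in ge_ij arises because the
interaction effect is not constrained to zero genotype means: the part of
the genotype deviation the shrunken g_i does not absorb loads onto the
interaction BLUP. This closed form equals the Henderson mixed-model-equation
solution for the balanced design exactly (checked against a dense solve in
the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .met import GEMeans, VarianceComponents

logger = logging.getLogger("stabgwas")


@dataclass
class BlupFit:
    mu_j: pd.Series            # per-environment fixed means
    g_blup: pd.Series          # per-genotype BLUPs
    ge_blup: pd.DataFrame      # g x e interaction BLUPs
    vc: VarianceComponents
    lambda_g: float
    lambda_ge: float

    def genetic_values(self) -> pd.DataFrame:
        """GV_ij = u_j + g_i + ge_ij."""
        return self.ge_blup.add(self.mu_j, axis=1).add(self.g_blup, axis=0)


def fit_blup(m: GEMeans, vc: VarianceComponents) -> BlupFit:
    """Balanced-design BLUPs of genotype and interaction effects."""
    if vc.sigma2_g == 0 and vc.sigma2_ge == 0 and vc.sigma2_eps == 0:
        raise ValidationError("all variance components are zero; BLUP undefined")
    x = m.matrix()
    e, r = vc.e, vc.r
    grand = x.mean()
    gdev = x.mean(axis=1) - grand
    z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand

    denom_g = vc.sigma2_g + vc.sigma2_ge / e + vc.sigma2_eps / (e * r)
    lam_g = vc.sigma2_g / denom_g if denom_g > 0 else 0.0
    denom_ge = vc.sigma2_ge + vc.sigma2_eps / r
    lam_ge = vc.sigma2_ge / denom_ge if denom_ge > 0 else 0.0

    ge = lam_ge * (z + (1.0 - lam_g) * gdev[:, None])
    return BlupFit(
        mu_j=pd.Series(x.mean(axis=0), index=m.values.columns),
        g_blup=pd.Series(lam_g * gdev, index=m.values.index),
        ge_blup=pd.DataFrame(ge, index=m.values.index, columns=m.values.columns),
        vc=vc,
        lambda_g=lam_g,
        lambda_ge=lam_ge,
    )


def hmrpgv(fit: BlupFit, formula: str = "harmonic") -> pd.DataFrame:
    """Relative performance of genetic values: arithmetic (RPGV) and harmonic
    (HMRPGV) means of GV_ij / mu_j across environments.

    ``formula='harmonic'`` (default) is the true harmonic mean
    e / sum_j (mu_j / GV_ij); ``formula='printed'`` drops the count
    multiplier, 1 / sum_j (mu_j / GV_ij).
    """
    gv = fit.genetic_values()
    mu = fit.mu_j
    if (mu <= 0).any():
        bad = mu.index[mu <= 0][0]
        raise ValidationError(f"environment mean mu_j <= 0 at {bad!r}; "
                              "ratio-scale index undefined for this trait")
    rel = gv.div(mu, axis=1)
    if (rel <= 0).to_numpy().any():
        i, j = np.argwhere((rel <= 0).to_numpy())[0]
        raise ValidationError(
            f"genetic value <= 0 for genotype {rel.index[i]!r} in environment "
            f"{rel.columns[j]!r}; trait not suitable for a ratio-scale index"
        )
    e = rel.shape[1]
    inv_sum = (1.0 / rel).sum(axis=1)
    if formula == "harmonic":
        hm = e / inv_sum
    elif formula == "printed":
        hm = 1.0 / inv_sum
    else:
        raise ValidationError(f"unknown HMRPGV formula {formula!r}")
    return pd.DataFrame({"RPGV": rel.mean(axis=1), "HMRPGV": hm})


def waasb(fit: BlupFit) -> pd.Series:
    """Weighted average of absolute IPCA scores from the SVD of the BLUP
    interaction matrix: WAASB_g = sum_n |score_gn| * EP_n / sum_n EP_n over
    all non-null components, EP_n the share of BLUP-interaction sum of
    squares. Lower is more stable.
    """
    z = fit.ge_blup.to_numpy()
    g, e = z.shape
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    ss = s ** 2
    total = ss.sum()
    if total <= 0:
        logger.info("BLUP interaction matrix is zero; WAASB is identically zero")
        return pd.Series(np.zeros(g), index=fit.ge_blup.index, name="WAASB")
    keep = ss > total * 1e-12
    scores = (u * np.sqrt(s))[:, keep]
    ep = ss[keep] / total
    val = (np.abs(scores) * ep).sum(axis=1) / ep.sum()
    return pd.Series(val, index=fit.ge_blup.index, name="WAASB")


def waasby(mean_y: np.ndarray, waasb_vals: np.ndarray,
           theta_y: float = 50.0, theta_s: float = 50.0) -> np.ndarray:
    """Blend rescaled mean performance and rescaled WAASB into [0, 100].

    Yield is rescaled so the maximum maps to 100; WAASB so the minimum maps
    to 100; WAASBY = (rG * theta_y + rW * theta_s) / (theta_y + theta_s).
    """
    if theta_y < 0 or theta_s < 0 or theta_y + theta_s <= 0:
        raise ValidationError("weights must be non-negative with a positive sum")
    y = np.asarray(mean_y, dtype=float)
    w = np.asarray(waasb_vals, dtype=float)
    if len(y) < 2:
        raise ValidationError("WAASBY needs at least two genotypes")
    if np.ptp(y) == 0 or np.ptp(w) == 0:
        raise ValidationError("degenerate (constant) mean or WAASB vector")
    rg = (100.0 - 0.0) / (y.max() - y.min()) * (y - y.max()) + 100.0
    rw = (0.0 - 100.0) / (w.max() - w.min()) * (w - w.max()) + 0.0
    return (rg * theta_y + rw * theta_s) / (theta_y + theta_s)
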