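"""Regression- and ecovalence-based stability, rank-sum YSI and the
four-class mean x stability genotype classification.

Finlay-Wilkinson slope:   b_i = sum_j X_ij * I_j / sum_j I_j^2,
                          I_j = Xbar_.j - Xbar_..
Wricke ecovalence:        W_i = sum_j (X_ij - Xbar_i. - Xbar_.j + Xbar_..)^2
Yield stability index:    YSI = RASV + RY (rank of ASV + rank of mean,
                          rank 1 = most stable / highest mean).

Genotypes are classified into four groups by a median split on the trait
mean and on a composite stability rank: (I) high mean and stable, (II) high
mean and unstable, (III) low mean and stable, (IV) low mean and unstable.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import ammi as ammi_mod
from . import blup as blup_mod
from .io import ValidationError
from .met import GEMeans, VarianceComponents


def ordinal_rank(values: np.ndarray, ascending: bool = True) -> np.ndarray:
    """Integer ranks 1..g; ties broken by position so the result is a permutation."""
    v = np.asarray(values, dtype=float)
    return stats.rankdata(v if ascending else -v, method="ordinal").astype(int)


def finlay_wilkinson(m: GEMeans) -> pd.Series:
    """Per-genotype regression slope of cell means on the environmental index."""
    x = m.matrix()
    ij = x.mean(axis=0) - x.mean()
    ss_i = (ij ** 2).sum()
    if ss_i <= 0:
        raise ValidationError(
            "all environmental indices are zero; environments are indistinguishable"
        )
    # grand-mean centering changes nothing algebraically (sum I_j = 0) but
    # keeps the mean(bi) = 1 identity exact in floating point
    bi = ((x - x.mean()) * ij).sum(axis=1) / ss_i
    return pd.Series(bi, index=m.values.index, name="bi")


def wricke_ecovalence(m: GEMeans) -> pd.Series:
    """Per-genotype contribution to the interaction sum of squares."""
    x = m.matrix()
    z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    return pd.Series((z ** 2).sum(axis=1), index=m.values.index, name="Wi")


def ysi(asv_rank: np.ndarray, mean_rank: np.ndarray) -> np.ndarray:
    """Rank-sum of the ASV rank and the (descending) mean rank; lower is better."""
    asv_rank = np.asarray(asv_rank)
    mean_rank = np.asarray(mean_rank)
    if asv_rank.shape != mean_rank.shape:
        raise ValidationError("rank vectors must have equal length")
    return asv_rank + mean_rank


def classify_mean_stability(table: pd.DataFrame, stability_cols: list[str] | None = None,
                            mean_col: str = "mean") -> pd.Series:
    """Four-quadrant classification by median splits.

    The stability axis is the mean of per-index ascending ranks over
    ``stability_cols`` (default ASV, MASI, Wi and the rank of |bi - 1|);
    genotypes exactly at a median go to the high/stable side.
    """
    if stability_cols is None:
        stability_cols = [c for c in ("ASV", "MASI", "Wi", "bi_dev") if c in table.columns]
    if not stability_cols:
        raise ValidationError("no stability columns to classify on")
    for c in stability_cols:
        if c not in table.columns:
            raise ValidationError(f"stability column {c!r} not in table")
    ranks = np.column_stack([
        stats.rankdata(table[c].to_numpy(), method="average") for c in stability_cols
    ])
    composite = ranks.mean(axis=1)
    high = table[mean_col].to_numpy() >= np.median(table[mean_col].to_numpy())
    stable = composite <= np.median(composite)
    labels = np.where(high & stable, "I",
                      np.where(high & ~stable, "II",
                               np.where(~high & stable, "III", "IV")))
    return pd.Series(labels, index=table.index, name="class")


def stability_table(
    m: GEMeans,
    vc: VarianceComponents | None = None,
    anova=None,
    masi_formula: str = "weighted_product",
    n_components: int | None = None,
    theta_y: float = 50.0,
    theta_s: float = 50.0,
    stability_cols: list[str] | None = None,
    hmrpgv_formula: str = "harmonic",
) -> pd.DataFrame:
    """Assemble the full per-genotype stability record for one trait.

    Combines means, Finlay-Wilkinson slope, Wricke ecovalence, the AMMI
    indices (ASV, MASI), the rank-sum YSI and — when variance components are
    supplied — the BLUP-based HMRPGV, WAASB and WAASBY, then attaches ranks
    and the four-quadrant class label.
    """
    fit = ammi_mod.fit_ammi(m)
    mean = m.values.mean(axis=1)
    bi = finlay_wilkinson(m)
    wi = wricke_ecovalence(m)
    asv_df = ammi_mod.asv(fit)

    if n_components is None:
        if anova is not None:
            n_components = ammi_mod.gollob_n_components(
                fit, ms_resid=float(anova["Residual"]["MS"]),
                df_resid=int(anova["Residual"]["df"]), r=m.r)
        else:
            n_components = min(2, fit.K)
    masi_s = ammi_mod.masi(fit, n_components=n_components, formula=masi_formula)

    out = pd.DataFrame({
        "mean": mean,
        "bi": bi,
        "bi_dev": (bi - 1.0).abs(),
        "Wi": wi,
        "ASV": asv_df["ASV"],
        "MASI": masi_s,
    })
    out["RY"] = ordinal_rank(out["mean"].to_numpy(), ascending=False)
    out["RASV"] = asv_df["RASV"]
    out["YSI"] = ysi(out["RASV"].to_numpy(), out["RY"].to_numpy())

    if vc is not None:
        bfit = blup_mod.fit_blup(m, vc)
        try:
            out["HMRPGV"] = blup_mod.hmrpgv(bfit, formula=hmrpgv_formula)["HMRPGV"]
        except ValidationError as exc:
            # ratio-scale index undefined when a genetic value is non-positive
            logging.getLogger("stabgwas").warning("HMRPGV skipped for %s: %s", m.trait, exc)
        out["WAASB"] = blup_mod.waasb(bfit)
        try:
            out["WAASBY"] = blup_mod.waasby(out["mean"].to_numpy(), out["WAASB"].to_numpy(),
                                            theta_y=theta_y, theta_s=theta_s)
        except ValidationError as exc:
            logging.getLogger("stabgwas").warning("WAASBY skipped for %s: %s", m.trait, exc)

    for col, asc in (("bi_dev", True), ("Wi", True), ("MASI", True), ("YSI", True),
                     ("HMRPGV", False), ("WAASB", True), ("WAASBY", False)):
        if col in out.columns:
            out[f"rank_{col}"] = ordinal_rank(out[col].to_numpy(), ascending=asc)

    out["class"] = classify_mean_stability(out, stability_cols=stability_cols)
    return out
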