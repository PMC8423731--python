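"""Cell means, combined ANOVA and heritability for balanced RCBD MET data.

The design is replicates nested in environments (RCBD within each
environment), genotypes crossed with environments. On balanced data the sums
of squares decompose exactly; variance components come from the expected mean
squares and broad-sense heritability on a genotype-mean basis is

    H2 = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_eps / (e * r)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeRecords, ValidationError

logger = logging.getLogger("stabgwas")


@dataclass
class GEMeans:
    """Genotype x environment cell-mean matrix for one trait."""

    values: pd.DataFrame  # index genotypes, columns environments
    r: int                # replicates per cell (common, or minimum if unequal)
    trait: str

    @property
    def g(self) -> int:
        return self.values.shape[0]

    @property
    def e(self) -> int:
        return self.values.shape[1]

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class AnovaTable:
    table: pd.DataFrame  # index: source; columns df, SS, MS, F, p
    trait: str

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    e: int
    r: int
    H2: float
    trait: str = ""


def cell_means(p: PhenotypeRecords, trait: str) -> GEMeans:
    """Average over replicates into the genotype x environment matrix."""
    sub = p.data[p.data["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"no observations for trait {trait!r}")
    piv = sub.pivot_table(index="genotype", columns="environment", values="value",
                          aggfunc="mean")
    if piv.isna().any().any():
        missing = [(g, e) for g, e in zip(*np.where(piv.isna().to_numpy()))]
        pairs = [(piv.index[i], piv.columns[j]) for i, j in missing[:5]]
        raise ValidationError(f"empty genotype x environment cell(s): {pairs}")
    counts = sub.groupby(["genotype", "environment"], observed=True).size()
    if counts.nunique() == 1:
        r = int(counts.iloc[0])
    else:
        r = int(counts.min())
        logger.warning("unequal replicate counts for %s; recording r = min = %d", trait, r)
    return GEMeans(values=piv.sort_index(), r=r, trait=trait)


def combined_anova(p: PhenotypeRecords, trait: str) -> AnovaTable:
    """Balanced combined ANOVA with sources Env, Rep(Env), Gen, Env x Gen, Residual.

    Gen and Env x Gen are tested against the residual mean square; Env is
    tested against Rep(Env), the replicate-block stratum within environments.
    """
    sub = p.data[p.data["trait"] == trait]
    if sub.empty:
        raise ValidationError(f"no observations for trait {trait!r}")
    counts = sub.groupby(["genotype", "environment"], observed=True).size()
    if counts.nunique() != 1:
        raise ValidationError(
            f"combined ANOVA requires balanced data; trait {trait!r} has unequal "
            "replicate counts (use cell-mean analysis instead)"
        )
    r = int(counts.iloc[0])
    g = sub["genotype"].nunique()
    e = sub["environment"].nunique()
    if len(sub) != g * e * r:
        raise ValidationError(f"incomplete design for trait {trait!r}")

    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    env_means = sub.groupby("environment", observed=True)["value"].mean()
    gen_means = sub.groupby("genotype", observed=True)["value"].mean()
    cell = sub.groupby(["genotype", "environment"], observed=True)["value"].mean()
    rep_env = sub.groupby(["environment", "replicate"], observed=True)["value"].mean()

    ss_env = float(g * r * ((env_means - grand) ** 2).sum())
    ss_rep = float(g * ((rep_env - env_means.reindex(
        rep_env.index.get_level_values(0)).to_numpy()) ** 2).sum())
    ss_gen = float(e * r * ((gen_means - grand) ** 2).sum())
    inter = (cell
             - gen_means.reindex(cell.index.get_level_values(0)).to_numpy()
             - env_means.reindex(cell.index.get_level_values(1)).to_numpy()
             + grand)
    ss_ge = float(r * (inter ** 2).sum())
    ss_resid = ss_total - ss_env - ss_rep - ss_gen - ss_ge

    df = {
        "Env": e - 1,
        "Rep(Env)": e * (r - 1),
        "Gen": g - 1,
        "Env x Gen": (e - 1) * (g - 1),
        "Residual": e * (r - 1) * (g - 1),
    }
    ss = {"Env": ss_env, "Rep(Env)": ss_rep, "Gen": ss_gen,
          "Env x Gen": ss_ge, "Residual": max(ss_resid, 0.0)}
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in df}

    def ftest(num: str, den: str):
        if df[den] == 0 or not np.isfinite(ms[den]) or ms[den] <= 0:
            return np.nan, np.nan
        f = ms[num] / ms[den]
        return f, float(stats.f.sf(f, df[num], df[den]))

    rows = []
    for src in df:
        if src == "Env":
            f, pval = ftest("Env", "Rep(Env)")
        elif src in ("Gen", "Env x Gen"):
            f, pval = ftest(src, "Residual")
        else:
            f, pval = np.nan, np.nan
        rows.append({"source": src, "df": df[src], "SS": ss[src], "MS": ms[src],
                     "F": f, "p": pval})
    table = pd.DataFrame(rows).set_index("source")
    return AnovaTable(table=table, trait=trait)


def variance_components(a: AnovaTable, e: int, r: int) -> VarianceComponents:
    """EMS variance components and broad-sense heritability from a balanced ANOVA."""
    if e * r == 0:
        raise ValidationError("e and r must be positive")
    ms_resid = float(a["Residual"]["MS"])
    ms_ge = float(a["Env x Gen"]["MS"])
    ms_gen = float(a["Gen"]["MS"])

    sigma2_eps = ms_resid
    sigma2_ge = (ms_ge - ms_resid) / r
    sigma2_g = (ms_gen - ms_ge) / (e * r)
    for name, val in (("sigma2_ge", sigma2_ge), ("sigma2_g", sigma2_g)):
        if val < 0:
            logger.warning("%s estimate %.4g truncated to 0 for %s", name, val, a.trait)
    sigma2_ge = max(sigma2_ge, 0.0)
    sigma2_g = max(sigma2_g, 0.0)

    denom = sigma2_g + sigma2_ge / e + sigma2_eps / (e * r)
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_ge=sigma2_ge,
                              sigma2_eps=sigma2_eps, e=e, r=r, H2=h2, trait=a.trait)
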