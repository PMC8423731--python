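"""End-to-end orchestration: read -> filter -> ANOVA/H2 -> stability ->
classification -> diversity/LD -> GWAS -> MTAs/pleiotropy, with a single
seed, provenance headers on every artifact and a hash manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import gwas, io, met, popgen, stability
from .io import ResultTable, ValidationError

logger = logging.getLogger("stabgwas")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    phenotypes: str = ""
    genotypes: str = ""
    metadata: str | None = None
    genotype_format: str | None = None
    output_dir: str = "stabgwas_out"
    traits: list[str] | None = None          # default: all traits present
    maf_min: float = 0.05
    het_max: float = 0.10
    missing_max: float = 0.10
    masi_formula: str = "weighted_product"
    hmrpgv_formula: str = "harmonic"
    theta_y: float = 50.0
    theta_s: float = 50.0
    stability_cols: list[str] | None = None
    ld_alpha: float = 0.001
    ld_max_pairs: int = 2_000_000
    r2_threshold: float = 0.1
    gwas_model: str = "mlm"                  # "glm" or "mlm"
    n_pcs: int = 3
    gwas_threshold: float = 3.0
    gwas_responses: list[str] = field(
        default_factory=lambda: ["mean", "bi", "Wi", "ASV", "MASI", "YSI",
                                 "HMRPGV", "WAASB", "WAASBY"])
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.phenotypes, self.genotypes):
            if not p or not os.path.exists(p):
                raise ValidationError(f"input path does not exist: {p!r}")
        if self.metadata and not os.path.exists(self.metadata):
            raise ValidationError(f"metadata path does not exist: {self.metadata!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg.validate_paths()
    os.makedirs(cfg.output_dir, exist_ok=True)
    prov = {"version": __version__, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    manifest: dict = {"config": asdict(cfg), "outputs": {}, "stages": {}}

    def emit(name: str, df: pd.DataFrame, extra: dict | None = None) -> None:
        path = os.path.join(cfg.output_dir, name)
        io.write_result(ResultTable(df=df, provenance={**prov, **(extra or {})}), path)
        manifest["outputs"][name] = _sha256(path)

    def stage(name: str):
        def deco(fn):
            try:
                out = fn()
                manifest["stages"][name] = "ok"
                return out
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                _write_manifest(cfg, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    @stage("read")
    def _read():
        phen = io.read_phenotypes(cfg.phenotypes)
        geno = io.read_genotypes(cfg.genotypes, fmt=cfg.genotype_format,
                                 metadata=cfg.metadata)
        return phen, geno

    phen, geno = _read

    @stage("filter")
    def _filter():
        return io.apply_marker_filters(geno, cfg.maf_min, cfg.het_max, cfg.missing_max)

    geno_f = _filter
    traits = cfg.traits or phen.traits

    @stage("anova")
    def _anova():
        rows_a, rows_v, vcs, anovas = [], [], {}, {}
        for trait in traits:
            if phen.balanced:
                a = met.combined_anova(phen, trait)
                vc = met.variance_components(
                    a, e=len(phen.environments), r=int(a["Rep(Env)"]["df"] /
                                                       len(phen.environments)) + 1)
                anovas[trait] = a
                vcs[trait] = vc
                t = a.table.reset_index().assign(trait=trait)
                rows_a.append(t)
                rows_v.append({"trait": trait, "sigma2_g": vc.sigma2_g,
                               "sigma2_ge": vc.sigma2_ge, "sigma2_eps": vc.sigma2_eps,
                               "e": vc.e, "r": vc.r, "H2": vc.H2})
            else:
                logger.warning("unbalanced data: ANOVA/H2 skipped for %s "
                               "(cell-mean analysis only)", trait)
        if rows_a:
            emit("anova.tsv", pd.concat(rows_a, ignore_index=True))
            emit("heritability.tsv", pd.DataFrame(rows_v))
        return vcs, anovas

    vcs, anovas = _anova

    @stage("stability")
    def _stability():
        tables = {}
        for trait in traits:
            m = met.cell_means(phen, trait)
            tab = stability.stability_table(
                m, vc=vcs.get(trait), anova=anovas.get(trait),
                masi_formula=cfg.masi_formula, theta_y=cfg.theta_y,
                theta_s=cfg.theta_s, stability_cols=cfg.stability_cols,
                hmrpgv_formula=cfg.hmrpgv_formula)
            tables[trait] = tab
            emit(f"stability_{trait}.tsv", tab.reset_index(names="genotype"))
        return tables

    stab_tables = _stability

    @stage("diversity_ld")
    def _divld():
        seed_ld = stage_seed(cfg.seed, "ld")
        div = popgen.snp_diversity(geno_f)
        emit("diversity_per_chromosome.tsv", div.per_chromosome.reset_index())
        ld = popgen.pairwise_ld(geno_f, alpha=cfg.ld_alpha,
                                max_pairs=cfg.ld_max_pairs, seed=seed_ld)
        emit("ld_per_chromosome.tsv", ld.per_chromosome.reset_index(),
             extra={"distance_unit": ld.distance_unit, "alpha": cfg.ld_alpha})
        decay = popgen.ld_decay_per_chromosome(ld, n_samples=geno_f.n_samples,
                                               r2_threshold=cfg.r2_threshold)
        emit("ld_decay.tsv", decay.reset_index().rename(columns={"index": "chrom"}))
        if geno_f.groups is not None:
            grp = popgen.group_compare(geno_f, alpha=cfg.ld_alpha,
                                       max_pairs=cfg.ld_max_pairs, seed=seed_ld)
            rows = []
            for name, (d, l) in grp.items():
                row = {"group": name, **d.genome_wide.to_dict()}
                if l is not None:
                    row.update({f"ld_{k}": v for k, v in l.genome_wide.to_dict().items()})
                rows.append(row)
            emit("group_summary.tsv", pd.DataFrame(rows))
        return ld, decay

    ld, decay = _divld

    @stage("gwas")
    def _gwas():
        kin = gwas.kinship_vanraden(geno_f)
        pcs = gwas.structure_pca(geno_f, k=cfg.n_pcs)
        results, mta_frames, mta_rows = {}, {}, []
        for trait in traits:
            tab = stab_tables[trait]
            for col in cfg.gwas_responses:
                if col not in tab.columns:
                    continue
                resp = f"{trait}.{col}"
                y = tab[col].astype(float)
                if cfg.gwas_model == "mlm":
                    res = gwas.mlm_scan(y, geno_f, pcs, kin,
                                        threshold=cfg.gwas_threshold,
                                        response_name=resp)
                else:
                    res = gwas.glm_scan(y, geno_f, pcs,
                                        threshold=cfg.gwas_threshold,
                                        response_name=resp)
                results[resp] = res
                emit(f"gwas_{resp}.tsv", res.table,
                     extra={"model": res.model, "lambda_gc": f"{res.lambda_gc:.4f}"})
                mta = gwas.call_mtas(res, ld_decay_by_chrom=decay)
                mta_frames[resp] = mta
                if not mta.empty:
                    mta_rows.append(mta.assign(response=resp))
        if mta_rows:
            emit("mtas.tsv", pd.concat(mta_rows, ignore_index=True))
        overlap = gwas.pleiotropy_overlap(results, mtas=mta_frames) if len(results) > 1 \
            else pd.DataFrame()
        emit("pleiotropy_overlap.tsv", overlap)
        manhattan = pd.concat(
            [gwas.manhattan_data(r).assign(response=n) for n, r in results.items()],
            ignore_index=True)
        emit("manhattan.tsv", manhattan)
        return results

    _gwas
    _write_manifest(cfg, manifest)
    return manifest


def _write_manifest(cfg: PipelineConfig, manifest: dict) -> None:
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
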