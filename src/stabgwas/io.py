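"""Readers, writers and validation for phenotypes, genotypes and result tables.

Phenotypes arrive as a long CSV (genotype, environment, replicate, trait,
value). Genotypes arrive as a standard VCF or as a HapMap-dialect tab text
(rs#, alleles, chrom, pos, then one column of calls per sample); dosages are
always re-oriented to count the minor allele. Result tables leave as TSV with
``#``-prefixed provenance lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("stabgwas")

#: sentinel for a missing dosage call
MISSING = -1

PHENO_COLUMNS = ("genotype", "environment", "replicate", "trait", "value")

#: IUPAC ambiguity codes for heterozygous single-letter HapMap calls
_IUPAC_HET = {
    "R": ("A", "G"), "Y": ("C", "T"), "S": ("C", "G"),
    "W": ("A", "T"), "K": ("G", "T"), "M": ("A", "C"),
}


class FormatError(ValueError):
    """Input does not conform to the expected file format."""


class ValidationError(ValueError):
    """Input parses but violates a content invariant."""


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeRecords:
    """Long-format replicated multi-environment phenotype observations."""

    data: pd.DataFrame
    balanced: bool
    cell_counts: pd.DataFrame  # genotype x environment replicate counts per trait

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())


def read_phenotypes(path: str, column_map: dict[str, str] | None = None) -> PhenotypeRecords:
    """Read and validate a long-format phenotype CSV.

    Parameters
    ----------
    path:
        CSV with columns genotype, environment, replicate, trait, value
        (case-insensitive; remappable through *column_map*, which maps the
        canonical name to the name used in the file).
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    colmap = {k: (column_map or {}).get(k, k).lower() for k in PHENO_COLUMNS}
    for canon, actual in colmap.items():
        if actual not in df.columns:
            raise FormatError(f"phenotype file {path!r} is missing column {actual!r} ({canon})")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(PHENO_COLUMNS)]
    return validate_phenotypes(df, source=path)


def validate_phenotypes(df: pd.DataFrame, source: str = "<memory>") -> PhenotypeRecords:
    """Validate a phenotype frame already holding the canonical columns."""
    df = df.copy()
    try:
        df["replicate"] = df["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{source}: non-integer replicate: {exc}") from exc
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{source}: non-numeric or non-finite value at data row {row + 1}: "
            f"{df['value'].iloc[row]!r}"
        )
    df["value"] = values.astype(float)
    if (df["replicate"] < 1).any():
        raise ValidationError(f"{source}: replicate numbers must be >= 1")

    key_cols = ["genotype", "environment", "replicate", "trait"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        first = df.loc[dup, key_cols].iloc[0]
        raise ValidationError(
            f"{source}: duplicate observation key "
            f"({first['genotype']}, {first['environment']}, rep {first['replicate']}, "
            f"{first['trait']})"
        )

    counts = (
        df.groupby(["trait", "genotype", "environment"], observed=True)
        .size()
        .rename("n_reps")
        .reset_index()
    )
    balanced = counts["n_reps"].nunique() == 1
    if not balanced:
        off = counts[counts["n_reps"] != counts["n_reps"].mode().iloc[0]]
        logger.warning(
            "unbalanced phenotype data: %d cells deviate from the modal replicate "
            "count (first: trait=%s genotype=%s environment=%s n=%d)",
            len(off), *off.iloc[0][["trait", "genotype", "environment", "n_reps"]],
        )
    return PhenotypeRecords(data=df, balanced=balanced, cell_counts=counts)


def write_phenotypes(p: PhenotypeRecords, path: str) -> None:
    p.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with marker map.

    ``dosage`` holds values in {0, 1, 2} or :data:`MISSING`; orientation is
    always the minor allele (recomputed on load), so the per-marker frequency
    of the counted allele never exceeds 0.5 on non-missing calls.
    """

    samples: list[str]
    markers: pd.DataFrame  # marker, chrom, pos_bp, pos_cm (NaN allowed), ref, alt
    dosage: np.ndarray     # (n_samples, n_markers) int16
    groups: np.ndarray | None = None  # per-sample group labels

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValidationError("dosage values must be in {0, 1, 2, missing}")
        if self.markers["marker"].duplicated().any():
            raise ValidationError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker on non-missing calls."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        freq = d.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        g = self
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = GenotypeMatrix(
                samples=[g.samples[i] for i in sample_idx],
                markers=g.markers,
                dosage=g.dosage[sample_idx],
                groups=None if g.groups is None else g.groups[sample_idx],
            )
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            g = GenotypeMatrix(
                samples=g.samples,
                markers=g.markers.iloc[marker_idx].reset_index(drop=True),
                dosage=g.dosage[:, marker_idx],
                groups=g.groups,
            )
        return g


def _orient_minor(dosage: np.ndarray, markers: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosages so every marker counts its minor allele."""
    d = np.ma.masked_equal(dosage, MISSING)
    freq = d.mean(axis=0).filled(0.0) / 2.0
    flip = freq > 0.5
    if flip.any():
        out = dosage.copy()
        cols = out[:, flip]
        swapped = np.where(cols == MISSING, MISSING, 2 - cols)
        out[:, flip] = swapped
        markers = markers.copy()
        markers.loc[flip, ["ref", "alt"]] = markers.loc[flip, ["alt", "ref"]].to_numpy()
        dosage = out
    return dosage, markers


def _attach_groups(g: GenotypeMatrix, metadata_path: str | None) -> GenotypeMatrix:
    if metadata_path is None:
        return g
    meta = pd.read_csv(metadata_path, dtype=str)
    meta.columns = [c.strip().lower() for c in meta.columns]
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise FormatError(f"metadata file {metadata_path!r} is missing column {col!r}")
    lookup = dict(zip(meta["sample_id"], meta["group"]))
    missing = [s for s in lookup if s not in set(g.samples)]
    if missing:
        raise ValidationError(
            f"metadata sample(s) absent from genotype file: {missing[:5]}"
        )
    g.groups = np.array([lookup.get(s, "unassigned") for s in g.samples])
    return g


def read_genotypes(path: str, fmt: str | None = None, metadata: str | None = None) -> GenotypeMatrix:
    """Read a VCF or HapMap-dialect genotype file into minor-allele dosages.

    Multi-allelic sites are dropped (with a logged count). Group labels come
    from an optional sidecar CSV (columns sample_id, group).
    """
    if fmt is None:
        fmt = "hapmap" if path.endswith((".hmp.txt", ".hmp", ".hapmap.txt")) else (
            "vcf" if path.endswith((".vcf", ".vcf.gz")) else None)
    if fmt == "vcf":
        g = _read_vcf(path)
    elif fmt == "hapmap":
        g = _read_hapmap(path)
    else:
        raise FormatError(f"unknown genotype format {fmt!r} for {path!r}")
    return _attach_groups(g, metadata)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotype.array()[:, :2]
        dose = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", str(var.CHROM), int(var.POS),
                     np.nan, var.REF, var.ALT[0]))
        dosages.append(dose.astype(np.int16))
    vcf.close()
    if n_multi:
        logger.info("dropped %d multi-allelic site(s) from %s", n_multi, path)
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "pos_cm", "ref", "alt"])
    dosage = np.column_stack(dosages) if dosages else np.empty((len(samples), 0), np.int16)
    dosage, markers = _orient_minor(dosage, markers)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def _read_hapmap(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["rs#", "alleles", "chrom", "pos"]
    if list(df.columns[:4]) != fixed:
        raise FormatError(
            f"{path!r}: HapMap-dialect header must start with {fixed}, got "
            f"{list(df.columns[:4])}"
        )
    has_cm = df.columns[4] == "pos_cm"
    sample_start = 5 if has_cm else 4
    samples = list(df.columns[sample_start:])
    rows, dosages = [], []
    n_multi = 0
    for _, rec in df.iterrows():
        alleles = rec["alleles"].split("/")
        if len(alleles) != 2:
            n_multi += 1
            continue
        a, b = alleles
        het_codes = {a + b, b + a}
        het_iupac = {c for c, pair in _IUPAC_HET.items() if set(pair) == {a, b}}
        dose = np.empty(len(samples), np.int16)
        for k, s in enumerate(samples):
            call = rec[s]
            if call in ("NN", "N", "--", ""):
                dose[k] = MISSING
            elif call == b + b or call == b:
                dose[k] = 2
            elif call == a + a or call == a:
                dose[k] = 0
            elif call in het_codes or call in het_iupac:
                dose[k] = 1
            else:
                raise FormatError(
                    f"{path!r}: unrecognized call {call!r} for sample {s} at "
                    f"marker {rec['rs#']}"
                )
        cm = float(rec["pos_cm"]) if has_cm and rec["pos_cm"] not in ("", "NA") else np.nan
        rows.append((rec["rs#"], rec["chrom"], int(rec["pos"]), cm, a, b))
        dosages.append(dose)
    if n_multi:
        logger.info("dropped %d non-biallelic site(s) from %s", n_multi, path)
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "pos_cm", "ref", "alt"])
    dosage = np.column_stack(dosages) if dosages else np.empty((len(samples), 0), np.int16)
    dosage, markers = _orient_minor(dosage, markers)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def write_genotypes(g: GenotypeMatrix, path: str, fmt: str = "vcf") -> None:
    """Write dosages back out as a sites-only-FORMAT VCF or HapMap-dialect text."""
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "hapmap":
        _write_hapmap(g, path)
    else:
        raise FormatError(f"unknown genotype format {fmt!r}")


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(g.markers["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stabgwas\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, rec in g.markers.iterrows():
            calls = "\t".join(gt_map[int(d)] for d in g.dosage[:, j])
            fh.write(f"{rec['chrom']}\t{rec['pos_bp']}\t{rec['marker']}\t"
                     f"{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t{calls}\n")


def _write_hapmap(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rs#\talleles\tchrom\tpos\tpos_cm\t" + "\t".join(g.samples) + "\n")
        for j, rec in g.markers.iterrows():
            a, b = rec["ref"], rec["alt"]
            call_map = {0: a + a, 1: a + b, 2: b + b, MISSING: "NN"}
            calls = "\t".join(call_map[int(d)] for d in g.dosage[:, j])
            cm = "" if pd.isna(rec["pos_cm"]) else repr(float(rec["pos_cm"]))
            fh.write(f"{rec['marker']}\t{a}/{b}\t{rec['chrom']}\t{rec['pos_bp']}\t{cm}\t{calls}\n")


def write_metadata(g: GenotypeMatrix, path: str) -> None:
    if g.groups is None:
        raise ValidationError("genotype matrix has no group labels to write")
    pd.DataFrame({"sample_id": g.samples, "group": g.groups}).to_csv(path, index=False)


def apply_marker_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    het_max: float = 0.10,
    missing_max: float = 0.10,
) -> GenotypeMatrix:
    """Keep markers with MAF > maf_min, het fraction < het_max and missing <= missing_max."""
    for name, t in (("maf_min", maf_min), ("het_max", het_max), ("missing_max", missing_max)):
        if not 0.0 <= t <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {t}")
    miss = (g.dosage == MISSING).mean(axis=0)
    d = np.ma.masked_equal(g.dosage, MISSING)
    het = (d == 1).mean(axis=0).filled(0.0)
    maf = g.maf()
    keep = (maf > maf_min) & (het < het_max) & (miss <= missing_max)
    logger.info(
        "marker filters: %d/%d retained (removed %d low-MAF, %d high-het, %d high-missing)",
        int(keep.sum()), g.n_markers, int((maf <= maf_min).sum()),
        int((het >= het_max).sum()), int((miss > missing_max).sum()),
    )
    if not keep.any():
        raise ValidationError(
            "all markers removed by filters; review the maf_min/het_max/missing_max "
            "thresholds"
        )
    return g.subset(marker_idx=np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

@dataclass
class ResultTable:
    """A typed result frame plus provenance (tool version, config hash, seed)."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            raise ValidationError("result table has duplicate column names")


def _format_cell(x) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.12g}"
    return str(x)


def write_result(table: ResultTable, path: str) -> None:
    """Write TSV with '#'-prefixed provenance; reals at 12 significant digits."""
    prov = dict(table.provenance)
    prov.setdefault("tool", "stabgwas")
    prov["n_rows"] = len(table.df)
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(map(str, table.df.columns)) + "\n")
        for _, row in table.df.iterrows():
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def read_result(path: str) -> ResultTable:
    prov = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition(":")
            prov[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return ResultTable(df=df, provenance=prov)
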