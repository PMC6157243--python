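"""Domain containers and file I/O.

The pipeline touches four on-disk formats: dosage-coded genotypes (VCF),
a CpG-by-sample methylation beta-value matrix (TSV, with a side-car TSV of
CpG coordinates and probe-SNP exclusion lists), a phenotype/covariate table
(CSV), and a SNP effect-size table used to build the weighted lipid score
(TSV).  Analysis configuration round-trips through YAML.

Conventions
-----------
* Coordinates are 1-based, as in VCF.  The cis window around a CpG is the
  closed interval ``[pos - window_bp, pos + window_bp]``.
* Dosages count copies of the VCF ALT allele and lie in ``[0, 2]``
  (fractional values allowed for imputed genotypes); missing values are
  ``NaN``.
* Methylation is stored as beta values in ``[0, 1]``; missing is ``NaN``.
* Only biallelic variants are supported: the weighted-score formula assumes
  a biallelic risk-allele count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "ParseError",
    "GenotypeMatrix",
    "MethylationMatrix",
    "PhenotypeTable",
    "EffectSizeTable",
    "AnalysisConfig",
    "read_genotypes",
    "write_genotypes_vcf",
    "read_methylation",
    "write_methylation",
    "read_phenotypes",
    "write_phenotypes",
    "read_effect_sizes",
    "write_effect_sizes",
    "complete_cases",
]

PHENO_COLUMNS = ("sample_id", "tg", "hdl", "age", "sex", "center", "smoking", "family_id")


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class ParseError(ValueError):
    """A file could not be parsed into its container."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sample-by-SNP effect-allele (ALT) dosage matrix.

    ``snp_meta`` is indexed by SNP id with columns ``chrom``, ``pos``,
    ``effect_allele`` (ALT) and ``other_allele`` (REF).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.snp_ids, "SNP ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0, 2] for sample {self.sample_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.dosages[i, j]}"
            )
        if list(self.snp_meta.index) != self.snp_ids:
            self.snp_meta = self.snp_meta.loc[self.snp_ids]
        if (self.snp_meta["pos"] < 1).any():
            raise ValidationError("SNP positions must be >= 1 (1-based coordinates)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def subset(self, samples: Sequence[str] | None = None,
               snps: Sequence[str] | None = None) -> "GenotypeMatrix":
        samples = self.sample_ids if samples is None else list(samples)
        snps = self.snp_ids if snps is None else list(snps)
        ri = [self.sample_ids.index(s) for s in samples]
        ci = [self.snp_ids.index(s) for s in snps]
        return GenotypeMatrix(samples, snps, self.dosages[np.ix_(ri, ci)],
                              self.snp_meta.loc[snps])


@dataclass
class MethylationMatrix:
    """Sample-by-CpG beta-value matrix.

    ``cpg_meta`` is indexed by CpG id with columns ``chrom``, ``pos``,
    ``gene`` (may be empty) and ``probe_snp_ids`` (a set of SNP ids lying
    on the array probe, excluded from cis-instrument candidates).
    """

    sample_ids: list[str]
    cpg_ids: list[str]
    betas: np.ndarray
    cpg_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(s) for s in self.cpg_ids]
        self.betas = np.asarray(self.betas, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.cpg_ids, "CpG ids")
        if self.betas.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValidationError(
                f"beta matrix shape {self.betas.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.betas < 0) | (self.betas > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value outside [0, 1] for CpG {self.cpg_ids[j]!r}, "
                f"sample {self.sample_ids[i]!r}: {self.betas[i, j]}"
            )
        if list(self.cpg_meta.index) != self.cpg_ids:
            self.cpg_meta = self.cpg_meta.loc[self.cpg_ids]
        self.cpg_meta = self.cpg_meta.copy()
        self.cpg_meta["probe_snp_ids"] = [
            set(v) if not isinstance(v, set) else v
            for v in self.cpg_meta["probe_snp_ids"]
        ]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def beta_of(self, cpg_id: str) -> np.ndarray:
        return self.betas[:, self.cpg_ids.index(cpg_id)]

    def subset(self, samples: Sequence[str] | None = None,
               cpgs: Sequence[str] | None = None) -> "MethylationMatrix":
        samples = self.sample_ids if samples is None else list(samples)
        cpgs = self.cpg_ids if cpgs is None else list(cpgs)
        ri = [self.sample_ids.index(s) for s in samples]
        ci = [self.cpg_ids.index(c) for c in cpgs]
        return MethylationMatrix(samples, cpgs, self.betas[np.ix_(ri, ci)],
                                 self.cpg_meta.loc[cpgs])


@dataclass
class PhenotypeTable:
    """Per-sample lipids (mg/dL), covariates and family id.

    Wraps a DataFrame with columns ``sample_id, tg, hdl, age, sex, center,
    smoking, family_id``.  Lipids are strictly positive when present;
    missing values stay ``NaN`` (never imputed).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns {missing}")
        df = self.df.loc[:, list(PHENO_COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["family_id"] = df["family_id"].astype(str)
        _check_unique(df["sample_id"], "sample ids")
        if (df["family_id"].str.len() == 0).any() or df["family_id"].isin(["nan", "None"]).any():
            bad = df.loc[(df["family_id"].str.len() == 0)
                         | df["family_id"].isin(["nan", "None"]), "sample_id"].tolist()
            raise ValidationError(f"empty family_id for samples {bad[:5]}")
        for lipid in ("tg", "hdl"):
            vals = pd.to_numeric(df[lipid], errors="coerce")
            nonpos = df.loc[vals.notna() & (vals <= 0), "sample_id"].tolist()
            if nonpos:
                raise ValidationError(
                    f"non-positive {lipid} for sample(s) {nonpos[:5]}; lipids must be > 0"
                )
            df[lipid] = vals
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        df = df.set_index("sample_id", drop=False)
        df.index.name = None
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def subset(self, samples: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.df.loc[list(samples)].reset_index(drop=True))


@dataclass
class EffectSizeTable:
    """Published per-allele effect sizes used as lipid-score weights."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"snp_id", "effect_allele", "effect_size"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValidationError(f"effect-size table missing columns {sorted(missing)}")
        df = self.df.loc[:, ["snp_id", "effect_allele", "effect_size"]].copy()
        df["snp_id"] = df["snp_id"].astype(str)
        _check_unique(df["snp_id"], "SNP ids")
        df["effect_size"] = pd.to_numeric(df["effect_size"], errors="coerce")
        if not np.isfinite(df["effect_size"]).all():
            bad = df.loc[~np.isfinite(df["effect_size"]), "snp_id"].tolist()
            raise ValidationError(f"non-finite effect size for {bad[:5]}")
        self.df = df.reset_index(drop=True)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the defaults the method prescribes.

    ``window_bp``            half-width of the cis window around a CpG (bp)
    ``ld_r2_threshold``      minimum r^2 for an LD proxy to substitute a SNP
    ``enet_alpha``           elastic-net mixing parameter (1 = lasso)
    ``enet_cv_folds``        cross-validation folds for the penalty search
    ``enet_seed``            seed for the CV fold assignment
    ``bonferroni_alpha``     family-wise error rate for the screen
    ``bonferroni_n_tests``   Bonferroni divisor; ``None`` means "number of
                             CpGs actually tested for the trait"
    ``log_transform_lipids`` analyze lipids on the natural-log scale
    """

    window_bp: int = 50_000
    ld_r2_threshold: float = 0.8
    enet_alpha: float = 0.5
    enet_cv_folds: int = 10
    enet_seed: int = 123
    bonferroni_alpha: float = 0.05
    bonferroni_n_tests: int | None = None
    log_transform_lipids: bool = True

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be > 0")
        if not 0 < self.enet_alpha <= 1:
            raise ValidationError("enet_alpha must lie in (0, 1]")
        for name in ("ld_r2_threshold", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.bonferroni_n_tests is not None and self.bonferroni_n_tests < 1:
            raise ValidationError("bonferroni_n_tests must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# genotypes (VCF)
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into an ALT-dosage matrix.

    Dosage is the DS FORMAT value when present, otherwise the ALT-allele
    count from GT; uncalled genotypes become ``NaN``.  Multi-allelic records
    are rejected.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare exceptions on bad files
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    meta_rows = []
    try:
        for rec_no, var in enumerate(vcf, start=1):
            if len(var.ALT) != 1:
                raise ParseError(
                    f"multi-allelic record {var.CHROM}:{var.POS} (record {rec_no}) "
                    "is not supported; split or drop multi-allelic sites first"
                )
            snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
            try:
                ds = var.format("DS")
            except KeyError:   # DS not declared in the header
                ds = None
            if ds is not None:
                dos = np.asarray(ds, dtype=float).reshape(len(samples))
                dos = np.where(dos < -0.5, np.nan, dos)  # htslib missing sentinel
            else:
                gt = var.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
                dos = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
            cols.append(dos)
            ids.append(str(snp_id))
            meta_rows.append((str(var.CHROM), int(var.POS), str(var.ALT[0]), str(var.REF)))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(
            f"malformed VCF {path!r} at record {len(ids) + 1}: {exc}"
        ) from exc
    if not ids:
        raise ParseError(f"VCF {path!r} contains no variant records")
    meta = pd.DataFrame(meta_rows, index=ids,
                        columns=["chrom", "pos", "effect_allele", "other_allele"])
    return GenotypeMatrix(samples, ids, np.column_stack(cols), meta)


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF. Integral dosages are written as GT, else as DS."""
    integral = np.all(np.isnan(g.dosages) | (np.mod(g.dosages, 1) == 0))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=methylmr\n')
        for chrom in pd.unique(g.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        if integral:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, snp in enumerate(g.snp_ids):
            row = g.snp_meta.loc[snp]
            if integral:
                cells = []
                for d in g.dosages[:, j]:
                    if np.isnan(d):
                        cells.append("./.")
                    else:
                        k = int(d)
                        cells.append(["0/0", "0/1", "1/1"][k])
                fmt = "GT"
            else:
                cells = ["." if np.isnan(d) else f"{d:.6g}" for d in g.dosages[:, j]]
                fmt = "DS"
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['other_allele']}"
                     f"\t{row['effect_allele']}\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# methylation (TSV + side-car metadata)
# ---------------------------------------------------------------------------

def read_methylation(path: str | Path, meta_path: str | Path) -> MethylationMatrix:
    """Read a CpG-by-sample beta-value TSV and its metadata side-car.

    The matrix file has CpGs as rows (first column ``cpg_id``) and samples
    as columns.  The side-car TSV has columns ``cpg_id, chrom, pos, gene,
    probe_snp_ids`` with probe SNPs comma-separated.
    """
    try:
        mat = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse methylation matrix {path!r}: {exc}") from exc
    betas = mat.to_numpy(dtype=float).T  # -> sample x CpG
    cpg_ids = [str(c) for c in mat.index]
    sample_ids = [str(s) for s in mat.columns]
    with np.errstate(invalid="ignore"):
        bad = (betas < 0) | (betas > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value outside [0, 1] for CpG {cpg_ids[j]!r}, sample "
            f"{sample_ids[i]!r}: {betas[i, j]}"
        )
    try:
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cpg_id": str, "gene": str},
                           keep_default_na=False, na_values=[""])
    except Exception as exc:
        raise ParseError(f"cannot parse methylation metadata {meta_path!r}: {exc}") from exc
    meta = meta.set_index("cpg_id")
    probe = []
    for v in meta["probe_snp_ids"]:
        if isinstance(v, str) and v:
            probe.append(set(v.split(",")))
        else:
            probe.append(set())
    meta["probe_snp_ids"] = probe
    meta["gene"] = meta["gene"].fillna("")
    return MethylationMatrix(sample_ids, cpg_ids, betas, meta)


def write_methylation(m: MethylationMatrix, path: str | Path,
                      meta_path: str | Path) -> None:
    mat = pd.DataFrame(m.betas.T, index=pd.Index(m.cpg_ids, name="cpg_id"),
                       columns=m.sample_ids)
    mat.to_csv(path, sep="\t", float_format="%.10g")
    meta = m.cpg_meta.copy()
    meta["probe_snp_ids"] = [",".join(sorted(v)) for v in meta["probe_snp_ids"]]
    meta.index.name = "cpg_id"
    meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# phenotypes (CSV) and effect sizes (TSV)
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> PhenotypeTable:
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "family_id": str,
                                      "sex": str, "center": str, "smoking": str})
    except Exception as exc:
        raise ParseError(f"cannot parse phenotype CSV {path!r}: {exc}") from exc
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.df.to_csv(path, index=False, float_format="%.10g")


def read_effect_sizes(path: str | Path) -> EffectSizeTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "effect_allele": str})
    except Exception as exc:
        raise ParseError(f"cannot parse effect-size TSV {path!r}: {exc}") from exc
    return EffectSizeTable(df)


def write_effect_sizes(w: EffectSizeTable, path: str | Path) -> None:
    w.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# complete-case alignment
# ---------------------------------------------------------------------------

def complete_cases(
    g: GenotypeMatrix,
    m: MethylationMatrix,
    p: PhenotypeTable,
    required_columns: Iterable[str] = ("tg", "age", "sex", "center", "smoking", "family_id"),
    check_genotypes: bool = True,
    check_methylation: bool = True,
) -> tuple[GenotypeMatrix, MethylationMatrix, PhenotypeTable]:
    """Intersect samples and keep only rows complete in every required field.

    A sample is retained when it appears in all three inputs, has no missing
    value in any ``required_columns`` phenotype field, and (unless the
    corresponding check is disabled) has no missing dosage or beta value.
    The survivors are returned in canonical (sorted sample-id) order,
    identically across the three structures, so the result does not depend
    on input row order.  Stages that handle genotype missingness per SNP
    (e.g. LD-proxy substitution) disable ``check_genotypes``.
    """
    required_columns = list(required_columns)
    unknown = [c for c in required_columns if c not in PHENO_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown required phenotype columns {unknown}")
    common = set(g.sample_ids) & set(m.sample_ids) & set(p.sample_ids)
    keep = []
    for s in sorted(common):
        row = p.df.loc[s, required_columns]
        if row.isna().any():
            continue
        if check_genotypes and np.isnan(g.dosages[g.sample_ids.index(s)]).any():
            continue
        if check_methylation and np.isnan(m.betas[m.sample_ids.index(s)]).any():
            continue
        keep.append(s)
    if not keep:
        raise ValidationError(
            "no samples remain after complete-case filtering "
            f"(sample intersection had {len(common)} candidates)"
        )
    return g.subset(samples=keep), m.subset(samples=keep), p.subset(keep)
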