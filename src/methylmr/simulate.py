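"""Family-structured study simulator with known causal architecture.

The generator emulates the structure the analysis assumes: nuclear families
(founder pair plus children) sharing a family random intercept, founder
genotypes in Hardy-Weinberg proportions with fair Mendelian transmission to
children, a set of lipid-score SNPs with per-allele effects on log
triglycerides, cis-meQTL SNPs within the +/- 50 kb window driving a focal
CpG, log-normal lipids, and configurable causal coupling in either
direction plus optional directional pleiotropy.

Structural equations (evaluated in causal order for acyclic scenarios):

  log(TG) = nu + sum_k b_k g_k + delta * beta(M) + covariates + u_fam + e
  M       = mu + sum_j a_j g_j + gamma * log(TG)
            + pleiotropy_shift * sum_k g_k + covariates + u_fam + e
  beta(M) = 1 / (1 + 2^(-M))          (base-2 inverse logit, so beta
                                       values stay strictly inside (0, 1))

HDL-C is generated analogously to TG but without causal coupling.  Exactly
one of gamma (lipid -> methylation, M-value per unit log-TG) and delta
(methylation -> lipid, log-TG per unit beta value) may be nonzero unless
the scenario is explicitly flagged cyclic, in which case the pair of
equations is solved per sample by fixed-point iteration (tolerance 1e-10).

Distinct SNPs are simulated without linkage disequilibrium beyond what
family transmission induces; a duplicate-SNP injector creates perfect
proxies for LD-proxy tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (EffectSizeTable, GenotypeMatrix, MethylationMatrix,
                      PhenotypeTable, ValidationError, write_effect_sizes,
                      write_genotypes_vcf, write_methylation, write_phenotypes)

__all__ = ["SimulationScenario", "SimulatedStudy", "simulate_pedigree",
           "simulate_genotypes", "simulate_study", "write_fixture",
           "m_to_beta", "beta_to_m", "null_scenario",
           "lipid_to_meth_scenario", "meth_to_lipid_scenario",
           "pleiotropy_scenario"]


def m_to_beta(m) -> np.ndarray:
    """Base-2 inverse logit: M-value 0 maps to beta 0.5."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, float)))


def beta_to_m(b) -> np.ndarray:
    b = np.asarray(b, float)
    return np.log2(b / (1.0 - b))


@dataclass
class SimulationScenario:
    """Study conditions for one simulated dataset.

    Defaults describe a moderately sized family cohort with active genetic
    instruments in both directions and no causal coupling; scenario
    factories below set the couplings the different analyses exercise.
    """

    n_families: int = 150
    n_children: int | tuple[int, int] = (1, 3)   # fixed k, or uniform [lo, hi]
    chrom: str = "1"
    # lipid instrument SNPs (far from the CpG window)
    n_lipid_snps: int = 20
    lipid_effect_range: tuple[float, float] = (0.05, 0.25)  # per allele on log-TG
    lipid_snp_start: int = 10_000_000
    lipid_snp_spacing: int = 1_000_000
    # focal CpG and its cis window
    cpg_id: str = "cg_sim01"
    cpg_position: int = 1_000_000
    cpg_gene: str = "GENE1"
    n_cis_snps: int = 30
    cis_span: int = 45_000          # cis SNPs uniform within +/- this of the CpG
    meqtl_r2: float = 0.2           # residual-variance share of the causal meQTL
    n_probe_snps: int = 0
    n_null_cpgs: int = 0
    # causal architecture
    gamma: float = 0.0              # log-TG -> M-value
    delta: float = 0.0              # beta value -> log-TG
    pleiotropy_shift: float = 0.0   # direct lipid-SNP -> M-value, per allele
    cyclic: bool = False
    # trait means and variance components
    maf_range: tuple[float, float] = (0.05, 0.5)
    mu_m: float = -0.5
    nu_tg: float = 4.79             # log(120 mg/dL)
    nu_hdl: float = 3.91            # log(50 mg/dL)
    var_family_tg: float = 0.2
    var_resid_tg: float = 0.4
    var_family_m: float = 0.2
    var_resid_m: float = 0.6
    cov_effects_tg: dict = field(default_factory=lambda: {
        "age": 0.004, "sex_M": 0.10, "center_B": 0.05, "center_C": -0.05,
        "smoking_current": 0.10})
    cov_effects_m: dict = field(default_factory=lambda: {
        "age": 0.005, "sex_M": -0.05, "center_B": 0.02, "center_C": -0.02,
        "smoking_current": -0.10})
    cov_effects_hdl: dict = field(default_factory=lambda: {
        "age": 0.002, "sex_M": -0.15, "center_B": 0.02, "center_C": -0.02,
        "smoking_current": -0.05})
    # data-pathology injectors
    duplicate_snps: tuple[str, ...] = ()     # ids to clone as perfect proxies
    missing_dosage: dict = field(default_factory=dict)   # snp_id -> missing rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma != 0 and self.delta != 0 and not self.cyclic:
            raise ValidationError(
                "both gamma and delta nonzero requires the explicit cyclic flag"
            )
        for v in (self.var_family_tg, self.var_resid_tg, self.var_family_m,
                  self.var_resid_m):
            if v < 0:
                raise ValidationError("variance components must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    phenotypes: PhenotypeTable
    truth: dict

    @property
    def effect_sizes(self) -> EffectSizeTable:
        """Lipid-score weights: the true per-allele effects, ALT-coded."""
        rows = [{"snp_id": s, "effect_allele":
                 self.genotypes.snp_meta.loc[s, "effect_allele"],
                 "effect_size": es}
                for s, es in self.truth["lipid_effects"].items()]
        return EffectSizeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# pedigree and genotypes
# ---------------------------------------------------------------------------

def simulate_pedigree(n_families: int, family_size_dist=2,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Nuclear families: a founder pair plus k >= 1 children each.

    ``family_size_dist`` is the number of children: a fixed int, a
    ``(lo, hi)`` tuple for a uniform draw (inclusive), or a callable
    ``f(rng) -> int``.
    """
    if n_families < 2:
        raise ValidationError("need at least 2 families")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if callable(family_size_dist):
        draw = family_size_dist
    elif isinstance(family_size_dist, tuple):
        lo, hi = family_size_dist
        draw = lambda r: int(r.integers(lo, hi + 1))
    else:
        k = int(family_size_dist)
        draw = lambda r: k
    rows = []
    for f in range(1, n_families + 1):
        fam = f"fam{f:04d}"
        father, mother = f"{fam}_p1", f"{fam}_p2"
        rows.append({"sample_id": father, "family_id": fam, "father_id": "",
                     "mother_id": "", "role": "founder"})
        rows.append({"sample_id": mother, "family_id": fam, "father_id": "",
                     "mother_id": "", "role": "founder"})
        k = draw(rng)
        if k < 1:
            raise ValidationError("family size distribution produced < 1 child")
        for c in range(1, k + 1):
            rows.append({"sample_id": f"{fam}_c{c}", "family_id": fam,
                         "father_id": father, "mother_id": mother,
                         "role": "child"})
    return pd.DataFrame(rows)


def simulate_genotypes(pedigree: pd.DataFrame, n_snps: int,
                       positions=None, maf_range=(0.05, 0.5),
                       seed: int | np.random.Generator = 0,
                       mafs=None, snp_ids=None, chrom: str = "1") -> GenotypeMatrix:
    """Founders drawn binomial(2, MAF) per SNP (Hardy-Weinberg); children
    inherit one fair-coin allele from each parent."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = pedigree["sample_id"].tolist()
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    if mafs is None:
        mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    mafs = np.asarray(mafs, float)
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10_000
    positions = np.asarray(positions, int)
    if snp_ids is None:
        snp_ids = [f"rs{j + 1:05d}" for j in range(n_snps)]

    h1 = np.zeros((n, n_snps), dtype=np.int8)
    h2 = np.zeros((n, n_snps), dtype=np.int8)
    founders = pedigree.index[pedigree["role"] == "founder"]
    fi = [idx[s] for s in pedigree.loc[founders, "sample_id"]]
    h1[fi] = rng.random((len(fi), n_snps)) < mafs
    h2[fi] = rng.random((len(fi), n_snps)) < mafs
    children = pedigree.index[pedigree["role"] == "child"]
    for c in children:
        row = pedigree.loc[c]
        ci, pa, ma = idx[row["sample_id"]], idx[row["father_id"]], idx[row["mother_id"]]
        pick_p = rng.integers(0, 2, size=n_snps)
        pick_m = rng.integers(0, 2, size=n_snps)
        h1[ci] = np.where(pick_p == 0, h1[pa], h2[pa])
        h2[ci] = np.where(pick_m == 0, h1[ma], h2[ma])
    dosages = (h1 + h2).astype(float)
    meta = pd.DataFrame({"chrom": chrom, "pos": positions,
                         "effect_allele": "A", "other_allele": "G"},
                        index=snp_ids)
    return GenotypeMatrix(samples, list(snp_ids), dosages, meta)


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

def _cov_term(effects: dict, age, sex_m, center, smoking) -> np.ndarray:
    out = effects.get("age", 0.0) * age
    out = out + effects.get("sex_M", 0.0) * sex_m
    out = out + effects.get("center_B", 0.0) * (center == "B")
    out = out + effects.get("center_C", 0.0) * (center == "C")
    out = out + effects.get("smoking_current", 0.0) * smoking
    return out


def simulate_study(scenario: SimulationScenario) -> SimulatedStudy:
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    ped = simulate_pedigree(sc.n_families, sc.n_children, rng)
    n = len(ped)
    fam_codes, fams = pd.factorize(ped["family_id"])

    # --- SNP map: lipid instruments then cis SNPs around the CpG ----------
    lipid_ids = [f"rs_lip{j + 1:03d}" for j in range(sc.n_lipid_snps)]
    lipid_pos = sc.lipid_snp_start + np.arange(sc.n_lipid_snps) * sc.lipid_snp_spacing
    cis_ids = [f"rs_cis{j + 1:03d}" for j in range(sc.n_cis_snps)]
    cis_pos = np.sort(rng.integers(sc.cpg_position - sc.cis_span,
                                   sc.cpg_position + sc.cis_span + 1,
                                   size=sc.n_cis_snps))
    probe_ids = [f"rs_probe{j + 1:02d}" for j in range(sc.n_probe_snps)]
    probe_pos = sc.cpg_position + 1 + np.arange(sc.n_probe_snps)
    snp_ids = lipid_ids + cis_ids + probe_ids
    positions = np.concatenate([lipid_pos, cis_pos, probe_pos]).astype(int)
    mafs = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=len(snp_ids))

    g = simulate_genotypes(ped, len(snp_ids), positions=positions, seed=rng,
                           mafs=mafs, snp_ids=snp_ids, chrom=sc.chrom)

    # --- genetic effects ---------------------------------------------------
    b = rng.uniform(*sc.lipid_effect_range, size=sc.n_lipid_snps)
    lipid_effects = dict(zip(lipid_ids, map(float, b)))
    maf_meqtl = mafs[sc.n_lipid_snps] if sc.n_cis_snps else None
    if sc.n_cis_snps and sc.meqtl_r2 > 0:
        # effect sized so the meQTL explains meqtl_r2 of the non-covariate
        # methylation variance: a^2 var(g) = r2/(1-r2) * (var_fam + var_resid)
        var_g = 2.0 * maf_meqtl * (1.0 - maf_meqtl)
        a = float(np.sqrt(sc.meqtl_r2 / (1.0 - sc.meqtl_r2)
                          * (sc.var_family_m + sc.var_resid_m) / var_g))
        meqtl_effects = {cis_ids[0]: a}
    else:
        meqtl_effects = {}

    # --- covariates --------------------------------------------------------
    age = np.clip(rng.normal(50.0, 12.0, size=n), 18.0, 90.0)
    sex = rng.choice(["F", "M"], size=n)
    center = rng.choice(["A", "B", "C"], size=n)
    smoking = rng.choice(["never", "current"], size=n, p=[0.75, 0.25])
    sex_m = (sex == "M").astype(float)
    smk = (smoking == "current").astype(float)
    age_c = age - age.mean()

    # --- random components -------------------------------------------------
    F = len(fams)
    u_tg = rng.normal(0.0, np.sqrt(sc.var_family_tg), size=F)[fam_codes]
    u_m = rng.normal(0.0, np.sqrt(sc.var_family_m), size=F)[fam_codes]
    u_hdl = rng.normal(0.0, np.sqrt(sc.var_family_tg), size=F)[fam_codes]
    e_tg = rng.normal(0.0, np.sqrt(sc.var_resid_tg), size=n)
    e_m = rng.normal(0.0, np.sqrt(sc.var_resid_m), size=n)
    e_hdl = rng.normal(0.0, np.sqrt(sc.var_resid_tg), size=n)

    G_lip = g.dosages[:, :sc.n_lipid_snps]
    genetic_tg = G_lip @ b
    genetic_m = np.zeros(n)
    for snp, a_j in meqtl_effects.items():
        genetic_m = genetic_m + a_j * g.dosage_of(snp)
    pleio = sc.pleiotropy_shift * G_lip.sum(axis=1)

    base_tg = sc.nu_tg + genetic_tg \
        + _cov_term(sc.cov_effects_tg, age_c, sex_m, center, smk) + u_tg + e_tg
    base_m = sc.mu_m + genetic_m + pleio \
        + _cov_term(sc.cov_effects_m, age_c, sex_m, center, smk) + u_m + e_m

    if sc.gamma != 0 and sc.delta != 0:
        log_tg = base_tg.copy()     # Gauss-Seidel fixed point, cyclic scenario
        for _ in range(200):
            m_val = base_m + sc.gamma * log_tg
            new = base_tg + sc.delta * m_to_beta(m_val)
            if np.max(np.abs(new - log_tg)) < 1e-10:
                log_tg = new
                break
            log_tg = new
        m_val = base_m + sc.gamma * log_tg
    elif sc.gamma != 0:
        log_tg = base_tg
        m_val = base_m + sc.gamma * log_tg
    else:
        m_val = base_m
        log_tg = base_tg + sc.delta * m_to_beta(m_val)

    log_hdl = sc.nu_hdl + _cov_term(sc.cov_effects_hdl, age_c, sex_m, center, smk) \
        + u_hdl + e_hdl

    # --- assemble containers ----------------------------------------------
    cpg_ids = [sc.cpg_id] + [f"cg_null{j + 1:02d}" for j in range(sc.n_null_cpgs)]
    betas = [m_to_beta(m_val)]
    meta_rows = [{"cpg_id": sc.cpg_id, "chrom": sc.chrom, "pos": sc.cpg_position,
                  "gene": sc.cpg_gene, "probe_snp_ids": set(probe_ids)}]
    for j in range(sc.n_null_cpgs):
        u = rng.normal(0.0, np.sqrt(sc.var_family_m), size=F)[fam_codes]
        e = rng.normal(0.0, np.sqrt(sc.var_resid_m), size=n)
        betas.append(m_to_beta(sc.mu_m + u + e))
        meta_rows.append({"cpg_id": cpg_ids[j + 1], "chrom": sc.chrom,
                          "pos": sc.cpg_position + 20_000_000 * (j + 1),
                          "gene": "", "probe_snp_ids": set()})
    meta = pd.DataFrame(meta_rows).set_index("cpg_id")
    m = MethylationMatrix(ped["sample_id"].tolist(), cpg_ids,
                          np.column_stack(betas), meta)

    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": ped["sample_id"], "tg": np.exp(log_tg),
        "hdl": np.exp(log_hdl), "age": age, "sex": sex, "center": center,
        "smoking": smoking, "family_id": ped["family_id"]}))

    # --- pathology injectors ----------------------------------------------
    for snp in sc.duplicate_snps:
        dup_id = f"{snp}_dup"
        j = g.snp_ids.index(snp)
        g = GenotypeMatrix(
            g.sample_ids, g.snp_ids + [dup_id],
            np.column_stack([g.dosages, g.dosages[:, j]]),
            pd.concat([g.snp_meta, pd.DataFrame(
                [{"chrom": g.snp_meta.iloc[j]["chrom"],
                  "pos": int(g.snp_meta.iloc[j]["pos"]) + 1,
                  "effect_allele": "A", "other_allele": "G"}],
                index=[dup_id])]))
    for snp, rate in sc.missing_dosage.items():
        j = g.snp_ids.index(snp)
        hole = rng.random(n) < rate
        g.dosages[hole, j] = np.nan

    truth = {
        "seed": sc.seed, "n_samples": n, "n_families": F,
        "gamma": sc.gamma, "delta": sc.delta,
        "pleiotropy_shift": sc.pleiotropy_shift,
        "lipid_snp_ids": lipid_ids, "lipid_effects": lipid_effects,
        "meqtl_effects": {k: float(v) for k, v in meqtl_effects.items()},
        "cis_snp_ids": cis_ids, "probe_snp_ids": probe_ids,
        "cpg_id": sc.cpg_id, "mu_m": sc.mu_m, "nu_tg": sc.nu_tg,
        "var_family_tg": sc.var_family_tg, "var_resid_tg": sc.var_resid_tg,
        "var_family_m": sc.var_family_m, "var_resid_m": sc.var_resid_m,
        "maf": {s: float(f) for s, f in zip(snp_ids, mafs)},
    }
    return SimulatedStudy(g, m, pheno, truth)


def write_fixture(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study in the pipeline's input formats plus a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "meth": out / "methylation.tsv",
        "meth_meta": out / "methylation_meta.tsv",
        "pheno": out / "phenotypes.csv",
        "effects": out / "effect_sizes.tsv",
        "truth": out / "truth.json",
    }
    write_genotypes_vcf(study.genotypes, paths["vcf"])
    write_methylation(study.methylation, paths["meth"], paths["meth_meta"])
    write_phenotypes(study.phenotypes, paths["pheno"])
    write_effect_sizes(study.effect_sizes, paths["effects"])
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# scenario factories — the study conditions the analyses exercise
# ---------------------------------------------------------------------------

def null_scenario(seed: int, n_families: int = 150, n_children=2,
                  n_cis_snps: int = 30, **kw) -> SimulationScenario:
    """Active instruments in both directions, no causal coupling."""
    return SimulationScenario(n_families=n_families, n_children=n_children,
                              n_cis_snps=n_cis_snps, gamma=0.0, delta=0.0,
                              seed=seed, **kw)


def lipid_to_meth_scenario(seed: int, gamma: float = -0.12,
                           n_families: int = 500, n_children=2,
                           **kw) -> SimulationScenario:
    """Forward causal effect of log-TG on the focal CpG's M-value."""
    return SimulationScenario(n_families=n_families, n_children=n_children,
                              gamma=gamma, delta=0.0, seed=seed, **kw)


def meth_to_lipid_scenario(seed: int, delta: float = -2.36,
                           n_families: int = 500, n_children=2,
                           **kw) -> SimulationScenario:
    """Reverse causal effect of the focal CpG's beta value on log-TG."""
    return SimulationScenario(n_families=n_families, n_children=n_children,
                              gamma=0.0, delta=delta, seed=seed, **kw)


def pleiotropy_scenario(seed: int, shift: float = 0.1, gamma: float = -0.12,
                        n_families: int = 500, n_children=2,
                        **kw) -> SimulationScenario:
    """Forward effect plus a constant direct per-allele effect of every
    lipid-score SNP on the CpG — the violation MR-Egger detects."""
    return SimulationScenario(n_families=n_families, n_children=n_children,
                              gamma=gamma, delta=0.0, pleiotropy_shift=shift,
                              seed=seed, **kw)
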