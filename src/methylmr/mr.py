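"""Two-stage least squares, instrument-independence check, MR-Egger, and
the bidirectional driver.

Causal estimation is one-sample TSLS with family random intercepts in both
stages:

  stage 1:  exposure ~ score + covariates + (1 | family)
  stage 2:  outcome  ~ predicted_exposure + covariates + (1 | family)

where ``predicted_exposure`` is the stage-1 fixed-effect prediction (family
BLUPs excluded, so family variance correlated with the outcome cannot leak
into the instrumented exposure).  The stage-2 coefficient of the predicted
exposure is the causal estimate; its standard error is the naive
mixed-model one (no generated-regressor correction — see docs).

The independence check refits the outcome on the score *and* the
prediction: a score effect surviving adjustment for predicted exposure
signals a pathway around the exposure.  Because the fixed-effect prediction
is an exact linear combination of score and covariates, this model
conditions on the BLUP-inclusive prediction, which is what an R ``predict``
on the stage-1 mixed model returns.

MR-Egger regresses per-SNP outcome effects on exposure effects (weights
1/se_out^2, intercept free, exposure effects aligned non-negative); a
nonzero intercept indicates directional pleiotropy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (AnalysisConfig, EffectSizeTable, GenotypeMatrix,
                      MethylationMatrix, PhenotypeTable, ValidationError,
                      complete_cases)
from .instruments import (InstrumentStrength, ScoreVector, build_prs_m,
                          build_weighted_score, cis_candidates,
                          elastic_net_select, find_proxy)
from .lmm import LMMError, build_covariate_design, fit_lmm, lmm_residualize
from .screen import log_transform_lipid, screen_cpgs

__all__ = ["CausalEstimate", "EggerResult", "WeakInstrumentError",
           "CollinearityError", "tsls", "independence_test",
           "per_snp_effects", "mr_egger", "run_bidirectional",
           "report_to_json"]

_COND_MAX = 1e10
_F_MIN = 1e-6


class WeakInstrumentError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


@dataclass
class CausalEstimate:
    direction: str            # "lipid->methylation" or "methylation->lipid"
    exposure_id: str
    outcome_id: str
    stage1: InstrumentStrength
    predicted_exposure: np.ndarray
    causal_beta: float
    causal_se: float
    causal_p: float
    independence_p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "stage1_beta": float(self.stage1.beta),
            "stage1_se": float(self.stage1.se),
            "stage1_p": float(self.stage1.pvalue),
            "stage1_F": float(self.stage1.f_stat),
            "causal_beta": float(self.causal_beta),
            "causal_se": float(self.causal_se),
            "causal_p": float(self.causal_p),
            "independence_p": float(self.independence_p),
            "n": int(self.n),
        }


@dataclass
class EggerResult:
    intercept: float
    intercept_se: float
    intercept_p: float
    slope: float
    slope_se: float
    slope_p: float
    n_snps: int

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n_snps" else float(v))
                for k, v in self.__dict__.items()}


def _condition_number(design: pd.DataFrame) -> float:
    X = design.to_numpy(float)
    X = np.column_stack([np.ones(len(X)), X])
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    return float(np.linalg.cond(X / norms))


def _with_covariates(lead: dict[str, np.ndarray], covariates) -> pd.DataFrame:
    design = pd.DataFrame(lead)
    if covariates is not None:
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    return design


def independence_test(outcome, score: ScoreVector, predicted_exposure,
                      covariates, family_ids,
                      lambda_fixed: float | None = None) -> float:
    """p-value of the score term in
    ``outcome ~ score + covariates + predicted_exposure``."""
    design = _with_covariates(
        {"score": score.standardized,
         "predicted_exposure": np.asarray(predicted_exposure, float)},
        covariates)
    cond = _condition_number(design)
    if cond > _COND_MAX:
        raise CollinearityError(
            f"score and predicted exposure are numerically collinear "
            f"(condition number {cond:.3g} > {_COND_MAX:.0e}); inspect the "
            "stage-1 prediction — it must carry variation beyond the fixed design"
        )
    fit = fit_lmm(np.asarray(outcome, float), design, family_ids,
                  lambda_fixed=lambda_fixed)
    return fit.pvalue["score"]


def tsls(exposure, outcome, score: ScoreVector, covariates, family_ids,
         direction: str = "", exposure_id: str = "", outcome_id: str = "",
         lambda_fixed: float | None = None,
         run_independence: bool = True) -> CausalEstimate:
    """Two-stage least squares with family random intercepts.

    ``lambda_fixed`` pins the family variance ratio in every stage (0 gives
    plain least-squares stages, under which the single-instrument
    no-covariate estimate equals the Wald ratio exactly).
    """
    exposure = np.asarray(exposure, float).ravel()
    outcome = np.asarray(outcome, float).ravel()
    fam = np.asarray(family_ids)

    s1_design = _with_covariates({"score": score.standardized}, covariates)
    s1 = fit_lmm(exposure, s1_design, fam, lambda_fixed=lambda_fixed)
    f_stat = s1.wald_f("score")
    if f_stat < _F_MIN:
        raise WeakInstrumentError(
            f"instrument carries no signal for {exposure_id or 'exposure'} "
            f"(F = {f_stat:.3g} < {_F_MIN})"
        )
    predicted = s1.fitted_fixed

    s2_design = _with_covariates({"predicted_exposure": predicted}, covariates)
    cond = _condition_number(s2_design)
    if cond > _COND_MAX:
        raise CollinearityError(
            f"stage-2 design ill-conditioned (condition number {cond:.3g}); "
            "the instrument contributes too little variation to the prediction"
        )
    s2 = fit_lmm(outcome, s2_design, fam, lambda_fixed=lambda_fixed)

    indep_p = float("nan")
    if run_independence:
        try:
            indep_p = independence_test(
                outcome, score, predicted + s1.fitted_blup, covariates, fam,
                lambda_fixed=lambda_fixed)
        except (CollinearityError, LMMError) as exc:
            warnings.warn(f"independence test unavailable: {exc}", stacklevel=2)

    strength = InstrumentStrength(s1.coef["score"], s1.se["score"],
                                  s1.pvalue["score"], f_stat, s1.n)
    return CausalEstimate(
        direction=direction, exposure_id=exposure_id, outcome_id=outcome_id,
        stage1=strength, predicted_exposure=predicted,
        causal_beta=s2.coef["predicted_exposure"],
        causal_se=s2.se["predicted_exposure"],
        causal_p=s2.pvalue["predicted_exposure"],
        independence_p=indep_p, n=s2.n)


def per_snp_effects(g: GenotypeMatrix, snp_ids, exposure, outcome,
                    covariates, family_ids) -> pd.DataFrame:
    """Per-SNP exposure and outcome effects (two mixed-model fits each),
    effect alleles aligned so every exposure effect is non-negative.

    Monomorphic SNPs are excluded with a warning; fewer than 3 usable SNPs
    is an error because the Egger slope would be unidentified.
    """
    exposure = np.asarray(exposure, float).ravel()
    outcome = np.asarray(outcome, float).ravel()
    rows = []
    for snp in snp_ids:
        d = g.dosage_of(snp)
        mask = ~np.isnan(d)
        if np.ptp(d[mask]) == 0:
            warnings.warn(f"monomorphic SNP {snp} excluded from per-SNP effects",
                          stacklevel=2)
            continue
        cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
        fam = np.asarray(family_ids)[mask]
        fe = fit_lmm(exposure[mask], _with_covariates({"snp": d[mask]}, cov), fam)
        fo = fit_lmm(outcome[mask], _with_covariates({"snp": d[mask]}, cov), fam)
        be, bo = fe.coef["snp"], fo.coef["snp"]
        sign = -1.0 if be < 0 else 1.0     # align both effects jointly
        rows.append({"snp_id": snp, "beta_exp": sign * be, "se_exp": fe.se["snp"],
                     "beta_out": sign * bo, "se_out": fo.se["snp"]})
    if len(rows) < 3:
        raise ValidationError(
            f"only {len(rows)} polymorphic SNPs available; MR-Egger needs >= 3"
        )
    return pd.DataFrame(rows)


def mr_egger(effects: pd.DataFrame) -> EggerResult:
    """Weighted regression of outcome effects on exposure effects.

    Weights are 1/se_out^2; the free intercept estimates the average direct
    (pleiotropic) effect per variant.  Standard errors carry a
    multiplicative residual dispersion floored at 1; p-values use the
    normal approximation.
    """
    need = {"beta_exp", "se_out", "beta_out"}
    if not need <= set(effects.columns):
        raise ValidationError(f"effects table needs columns {sorted(need)}")
    k = len(effects)
    if k < 3:
        raise ValidationError(f"MR-Egger needs >= 3 SNPs; got {k}")
    bx = effects["beta_exp"].to_numpy(float)
    by = effects["beta_out"].to_numpy(float)
    se = effects["se_out"].to_numpy(float)
    if (se <= 0).any():
        raise ValidationError("outcome standard errors must be positive")
    if np.ptp(bx) == 0:
        raise ValidationError("all exposure effects equal; Egger slope unidentifiable")
    w = 1.0 / se**2
    X = np.column_stack([np.ones(k), bx])
    A = (X * w[:, None]).T @ X
    b = (X * w[:, None]).T @ by
    coef = np.linalg.solve(A, b)
    resid = by - X @ coef
    dispersion = max(float(resid @ (w * resid)) / (k - 2), 1.0)
    cov = dispersion * np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov))
    z = coef / ses
    p = 2.0 * stats.norm.sf(np.abs(z))
    return EggerResult(
        intercept=float(coef[0]), intercept_se=float(ses[0]), intercept_p=float(p[0]),
        slope=float(coef[1]), slope_se=float(ses[1]), slope_p=float(p[1]), n_snps=k)


# ---------------------------------------------------------------------------
# bidirectional driver
# ---------------------------------------------------------------------------

def _resolve_score_snps(g: GenotypeMatrix, effect_sizes: EffectSizeTable,
                        r2_threshold: float) -> tuple[EffectSizeTable, list[dict]]:
    """Substitute LD proxies for score SNPs that cannot be used directly.

    A table SNP with complete in-sample dosages is used as is.  One that is
    genotyped but has missing dosages is replaced by the strongest complete
    same-chromosome proxy at r^2 > threshold, the weight carried over and
    the proxy's coding aligned to the LD sign.  A SNP absent from the
    genotypes is dropped (no in-sample LD reference exists to find a proxy).
    """
    complete = [s for j, s in enumerate(g.snp_ids)
                if not np.isnan(g.dosages[:, j]).any()]
    complete_set = set(complete)
    rows, log = [], []
    for _, row in effect_sizes.df.iterrows():
        snp = row["snp_id"]
        if snp in complete_set:
            rows.append(dict(row))
            log.append({"snp_id": snp, "action": "used"})
            continue
        if snp not in g.snp_ids:
            log.append({"snp_id": snp, "action": "dropped",
                        "note": "not genotyped; no LD reference for proxy search"})
            continue
        chrom = g.snp_meta.loc[snp, "chrom"]
        cands = [c for c in complete
                 if c != snp and g.snp_meta.loc[c, "chrom"] == chrom]
        proxy = find_proxy(g, snp, cands, r2_threshold)
        if proxy is None:
            log.append({"snp_id": snp, "action": "dropped",
                        "note": f"no proxy with r^2 > {r2_threshold}"})
            continue
        a, b = g.dosage_of(snp), g.dosage_of(proxy)
        mask = ~(np.isnan(a) | np.isnan(b))
        corr = np.corrcoef(a[mask], b[mask])[0, 1]
        pmeta = g.snp_meta.loc[proxy]
        allele = pmeta["effect_allele"] if corr >= 0 else pmeta["other_allele"]
        rows.append({"snp_id": proxy, "effect_allele": allele,
                     "effect_size": row["effect_size"]})
        log.append({"snp_id": snp, "action": "proxied", "proxy": proxy,
                    "r2": float(corr * corr)})
    if not rows:
        raise ValidationError("no usable lipid-score SNPs after proxy resolution")
    resolved = pd.DataFrame(rows).drop_duplicates(subset="snp_id")
    return EffectSizeTable(resolved), log


def run_bidirectional(
    g: GenotypeMatrix,
    m: MethylationMatrix,
    p: PhenotypeTable,
    effect_sizes: EffectSizeTable,
    cpg_ids: list[str] | None = None,
    config: AnalysisConfig | None = None,
    traits: tuple[str, ...] = ("tg", "hdl"),
) -> dict:
    """Run the full bidirectional analysis and return a structured report.

    Per trait: (1) Bonferroni-gated association screen; then per surviving
    CpG (2) forward MR (lipid -> methylation) via the weighted lipid score
    with LD-proxy substitution, instrument strength, TSLS and the
    independence check, plus MR-Egger over the score SNPs; and (3) reverse
    MR (methylation -> lipid) via cis-candidate selection, covariate
    residualization, the elastic net, the methylation score, TSLS, the
    independence check and MR-Egger over the selected SNPs when at least 3
    are available.  Any stage failure is recorded for that CpG without
    aborting the others; "no instrument available" is an explicit outcome.
    """
    config = config or AnalysisConfig()
    report: dict = {"config": {k: v for k, v in config.__dict__.items()},
                    "traits": {}}

    for trait in traits:
        gs, ms, ps = complete_cases(
            g, m, p, required_columns=(trait, "age", "sex", "center",
                                       "smoking", "family_id"),
            check_genotypes=False, check_methylation=False)
        covars = build_covariate_design(ps.df)
        fam = ps.df["family_id"].to_numpy()
        lipid = log_transform_lipid(ps.df[trait].to_numpy(), ps.sample_ids) \
            if config.log_transform_lipids else ps.df[trait].to_numpy(float)

        screen = screen_cpgs(ms, ps, trait, cpg_ids=cpg_ids, config=config)
        trait_report = {"screen": [r.__dict__ for r in screen], "cpgs": {}}

        survivors = [r.cpg_id for r in screen if r.significant]
        if survivors:
            try:
                resolved, proxy_log = _resolve_score_snps(
                    gs, effect_sizes, config.ld_r2_threshold)
                prs_l = build_weighted_score(gs.subset(snps=resolved.snp_ids),
                                             resolved)
            except ValidationError as exc:
                prs_l, resolved, proxy_log = None, None, [{"error": str(exc)}]
            trait_report["prs_l_snps"] = proxy_log

        for cpg in survivors:
            entry: dict = {}
            beta_col = ms.beta_of(cpg)
            mask = ~np.isnan(beta_col)
            meth = beta_col[mask]
            lip = lipid[mask]
            cov = covars.loc[mask].reset_index(drop=True)
            fam_m = fam[mask]

            # ---- forward: lipid -> methylation -------------------------
            try:
                if prs_l is None:
                    raise ValidationError("no instrument available: lipid score "
                                          "could not be built")
                score = ScoreVector([s for s, keep in zip(ps.sample_ids, mask) if keep],
                                    prs_l.raw[mask],
                                    (prs_l.raw[mask] - prs_l.raw[mask].mean())
                                    / np.std(prs_l.raw[mask], ddof=1),
                                    prs_l.constituent_snps)
                est = tsls(lip, meth, score, cov, fam_m,
                           direction="lipid->methylation",
                           exposure_id=trait, outcome_id=cpg)
                entry["forward"] = est.to_dict()
                try:
                    eff = per_snp_effects(gs.subset(samples=score.sample_ids),
                                          [s for s, _ in score.constituent_snps],
                                          lip, meth, cov, fam_m)
                    entry["forward_egger"] = mr_egger(eff).to_dict()
                except ValidationError as exc:
                    entry["forward_egger"] = {"skipped": str(exc)}
            except (ValidationError, WeakInstrumentError, CollinearityError,
                    LMMError) as exc:
                entry["forward"] = {"error": str(exc)}

            # ---- reverse: methylation -> lipid -------------------------
            try:
                meta_row = ms.cpg_meta.loc[cpg]
                cands = cis_candidates(gs, meta_row, config.window_bp)
                gsub = gs.subset(samples=[s for s, keep in zip(ps.sample_ids, mask)
                                          if keep])
                complete_snps = [s for s in cands
                                 if not np.isnan(gsub.dosage_of(s)).any()]
                if not complete_snps:
                    raise ValidationError(
                        f"no instrument available: no complete cis SNP within "
                        f"+/-{config.window_bp} bp of {cpg}")
                resid = lmm_residualize(meth, cov, fam_m)
                inst = elastic_net_select(
                    resid, gsub.subset(snps=complete_snps),
                    alpha=config.enet_alpha, cv_folds=config.enet_cv_folds,
                    seed=config.enet_seed, target_id=cpg,
                    window=(str(meta_row["chrom"]),
                            int(meta_row["pos"]) - config.window_bp,
                            int(meta_row["pos"]) + config.window_bp))
                entry["reverse_instrument"] = inst.to_dict()
                prs_m = build_prs_m(gsub, inst)
                est = tsls(meth, lip, prs_m, cov, fam_m,
                           direction="methylation->lipid",
                           exposure_id=cpg, outcome_id=trait)
                entry["reverse"] = est.to_dict()
                if len(inst.selected) >= 3:
                    try:
                        eff = per_snp_effects(gsub, inst.snp_ids, meth, lip,
                                              cov, fam_m)
                        entry["reverse_egger"] = mr_egger(eff).to_dict()
                    except ValidationError as exc:
                        entry["reverse_egger"] = {"skipped": str(exc)}
                else:
                    entry["reverse_egger"] = {
                        "skipped": f"only {len(inst.selected)} instrument SNPs; "
                                   "MR-Egger needs >= 3"}
            except (ValidationError, WeakInstrumentError, CollinearityError,
                    LMMError) as exc:
                entry["reverse"] = {"error": str(exc)}

            trait_report["cpgs"][cpg] = entry
        report["traits"][trait] = trait_report
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization (sorted keys, fixed float repr)."""
    return json.dumps(_jsonify(report), sort_keys=True, indent=2)


def report_tables(report: dict) -> pd.DataFrame:
    """Flatten the MR sections into one row per CpG x direction."""
    rows = []
    for trait, tr in report.get("traits", {}).items():
        for cpg, entry in tr.get("cpgs", {}).items():
            for direction in ("forward", "reverse"):
                d = entry.get(direction)
                if d is None:
                    continue
                row = {"trait": trait, "cpg_id": cpg, "direction": direction}
                row.update({k: v for k, v in d.items()
                            if not isinstance(v, (list, dict))})
                rows.append(row)
    return pd.DataFrame(rows)
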