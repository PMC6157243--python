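"""Stage 1: covariate-adjusted association screen of CpGs against lipids.

Each candidate CpG is tested against the (natural-log transformed) lipid
trait with the family random-intercept model

    log(lipid) ~ methylation + age + sex + center + smoking + (1 | family)

and flagged significant under a Bonferroni-corrected threshold.  Only CpGs
passing this gate enter the Mendelian-randomization stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import AnalysisConfig, MethylationMatrix, PhenotypeTable, ValidationError
from .lmm import LMMError, build_covariate_design, fit_lmm

__all__ = ["AssociationResult", "log_transform_lipid", "bonferroni_threshold",
           "screen_cpgs"]

TRAITS = ("tg", "hdl")


@dataclass
class AssociationResult:
    cpg_id: str
    trait: str
    beta: float
    se: float
    pvalue: float
    n: int
    significant: bool
    error: str | None = None


def log_transform_lipid(values, sample_ids=None) -> np.ndarray:
    """Natural log of a strictly positive lipid vector."""
    v = np.asarray(values, float)
    ok = np.isnan(v) | (v > 0)
    if not ok.all():
        idx = int(np.argmin(ok))
        label = sample_ids[idx] if sample_ids is not None else f"index {idx}"
        raise ValidationError(
            f"non-positive lipid value {v[idx]} for sample {label}; "
            "log transform requires values > 0"
        )
    return np.log(v)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1); got {alpha}")
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1; got {n_tests}")
    return alpha / n_tests


def screen_cpgs(
    m: MethylationMatrix,
    p: PhenotypeTable,
    trait: str,
    cpg_ids: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> list[AssociationResult]:
    """Test each CpG against a lipid trait with the mixed model.

    A CpG whose fit fails (e.g. a constant methylation column) yields a
    result row carrying the error message; the remaining CpGs are still
    tested.  ``significant`` is ``pvalue <= alpha / n_tests`` where the
    Bonferroni divisor defaults to the number of CpGs tested here.
    """
    if trait not in TRAITS:
        raise ValidationError(f"trait must be one of {TRAITS}; got {trait!r}")
    config = config or AnalysisConfig()
    cpg_ids = list(cpg_ids) if cpg_ids is not None else list(m.cpg_ids)
    unknown = [c for c in cpg_ids if c not in m.cpg_ids]
    if unknown:
        raise ValidationError(f"CpGs not in methylation matrix: {unknown[:5]}")
    common = [s for s in m.sample_ids if s in set(p.sample_ids)]
    if not common:
        raise ValidationError("no overlapping samples between methylation and phenotypes")
    msub = m.subset(samples=common)
    pdf = p.df.loc[common]

    lipid = pdf[trait].to_numpy(float)
    covars = build_covariate_design(pdf)
    base_ok = (~np.isnan(lipid)) & (~np.isnan(covars.to_numpy()).any(axis=1)) \
        & pdf["family_id"].notna().to_numpy()

    n_tests = config.bonferroni_n_tests or len(cpg_ids)
    threshold = bonferroni_threshold(config.bonferroni_alpha, n_tests)

    results: list[AssociationResult] = []
    for cpg in cpg_ids:
        beta_col = msub.beta_of(cpg)
        mask = base_ok & ~np.isnan(beta_col)
        try:
            if mask.sum() < 3:
                raise LMMError("fewer than 3 complete cases")
            meth = beta_col[mask]
            if np.ptp(meth) == 0:
                raise LMMError("constant methylation column")
            y = lipid[mask]
            if config.log_transform_lipids:
                y = log_transform_lipid(y, np.asarray(common, dtype=object)[mask])
            design = covars.loc[mask].copy()
            design.insert(0, "methylation", meth)
            fit = fit_lmm(y, design, pdf.loc[mask, "family_id"].to_numpy())
            pv = fit.pvalue["methylation"]
            results.append(AssociationResult(
                cpg_id=cpg, trait=trait, beta=fit.coef["methylation"],
                se=fit.se["methylation"], pvalue=pv, n=fit.n,
                significant=bool(pv <= threshold)))
        except (LMMError, ValidationError) as exc:
            results.append(AssociationResult(
                cpg_id=cpg, trait=trait, beta=float("nan"), se=float("nan"),
                pvalue=float("nan"), n=int(mask.sum()), significant=False,
                error=str(exc)))
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabulate AssociationResult rows for TSV reporting."""
    return pd.DataFrame([r.__dict__ for r in results])
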