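"""Genetic instruments: weighted allele scores and elastic-net cis-meQTL
selection.

Two kinds of instrument are built:

* the lipid score — a weighted sum of risk-allele dosages with published
  per-allele effect sizes as weights,

      score_i = sum_j dosage_ij * ES_j / mean(ES),

  standardized to mean 0 and (n-1) standard deviation 1.  Before the
  formula is applied every SNP is aligned to its risk allele: a weight
  attached to the REF allele flips the dosage (2 - d), and a negative
  weight flips the SNP to the other allele so all weights are positive and
  the mean-weight denominator is stable.

* the methylation score — per CpG, candidate SNPs are taken from the
  +/- 50 kb cis window (minus SNPs lying on the array probe), methylation
  is residualized on covariates and family, and an elastic net
  (mixing 0.5, seeded 10-fold cross-validation, penalty at the CV-MSE
  minimum) selects the cis-meQTLs; the nonzero coefficients become score
  weights via the same construction.

The elastic-net path follows the glmnet conventions: 100 penalty values
log-spaced down from the smallest penalty that zeroes every coefficient,
ratio 1e-4 (1e-2 when p >= n), predictors standardized with the 1/n
standard deviation, and ties in CV error resolved toward the largest
(sparsest) penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .io_core import EffectSizeTable, GenotypeMatrix, ValidationError
from .lmm import fit_lmm

__all__ = ["ScoreVector", "InstrumentSet", "build_weighted_score", "ld_r2",
           "find_proxy", "cis_candidates", "elastic_net_select", "build_prs_m",
           "instrument_strength", "InstrumentStrength"]


@dataclass
class ScoreVector:
    """Per-sample weighted allele score, raw and standardized."""

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray
    constituent_snps: list[tuple[str, float]]


@dataclass
class InstrumentSet:
    """Elastic-net selection record for one target CpG."""

    target_id: str
    window: tuple[str, int, int] | None
    candidate_snp_ids: list[str]
    selected: list[tuple[str, float]]
    lambda_used: float
    cv_seed: int
    alpha_used: float
    status: str = "ok"   # ok | no_candidates | empty_selection

    @property
    def snp_ids(self) -> list[str]:
        return [s for s, _ in self.selected]

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "window": list(self.window) if self.window else None,
            "candidate_snp_ids": list(self.candidate_snp_ids),
            "selected": [[s, float(c)] for s, c in self.selected],
            "lambda_used": float(self.lambda_used),
            "cv_seed": int(self.cv_seed),
            "alpha_used": float(self.alpha_used),
            "status": self.status,
        }


def _standardize(raw: np.ndarray) -> np.ndarray:
    sd = np.std(raw, ddof=1)
    if sd == 0:
        raise ValidationError("score has zero variance; cannot standardize")
    return (raw - raw.mean()) / sd


def build_weighted_score(g: GenotypeMatrix, w: EffectSizeTable) -> ScoreVector:
    """Weighted risk-allele score over the SNPs of an effect-size table.

    Requires every table SNP to be present in the genotypes.  Alignment:
    dosages count ALT copies, so a weight whose effect allele is the REF
    allele flips the dosage; a negative weight flips the SNP to its other
    allele (d -> 2 - d, weight -> |weight|).
    """
    missing = [s for s in w.snp_ids if s not in g.snp_ids]
    if missing:
        raise ValidationError(f"score SNPs absent from genotypes: {missing}")
    if w.df.empty:
        raise ValidationError("effect-size table is empty")
    cols = []
    weights = []
    used: list[tuple[str, float]] = []
    for _, row in w.df.iterrows():
        snp, ea, es = row["snp_id"], row["effect_allele"], float(row["effect_size"])
        meta = g.snp_meta.loc[snp]
        d = g.dosage_of(snp).astype(float)
        if ea == meta["effect_allele"]:
            pass
        elif ea == meta["other_allele"]:
            d = 2.0 - d
        else:
            raise ValidationError(
                f"effect allele {ea!r} of {snp} matches neither ALT "
                f"({meta['effect_allele']!r}) nor REF ({meta['other_allele']!r})"
            )
        if es < 0:          # flip to the other allele so the weight is positive
            d = 2.0 - d
            es = -es
        if es == 0:
            raise ValidationError(f"zero effect size for {snp}; cannot weight")
        cols.append(d)
        weights.append(es)
        used.append((str(snp), es))
    weights = np.asarray(weights)
    mean_es = weights.mean()
    if mean_es <= 0:
        raise ValidationError("mean effect size is not positive")
    raw = np.column_stack(cols) @ weights / mean_es
    if np.isnan(raw).any():
        bad = [g.sample_ids[i] for i in np.flatnonzero(np.isnan(raw))[:5]]
        raise ValidationError(f"missing dosages for samples {bad}; score undefined")
    return ScoreVector(list(g.sample_ids), raw, _standardize(raw), used)


def ld_r2(g: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    a, b = g.dosage_of(snp_a), g.dosage_of(snp_b)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValidationError(f"fewer than 2 complete pairs for {snp_a}/{snp_b}")
    for snp, v in ((snp_a, a), (snp_b, b)):
        if np.ptp(v) == 0:
            raise ValidationError(f"monomorphic SNP {snp}; LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def find_proxy(g: GenotypeMatrix, target_snp: str, candidate_snps,
               r2_threshold: float = 0.8) -> str | None:
    """Best LD proxy: the candidate with maximal r^2 above the threshold,
    or ``None`` when no candidate qualifies."""
    best_id, best_r2 = None, r2_threshold
    for cand in candidate_snps:
        if cand == target_snp:
            return cand
        try:
            r2 = ld_r2(g, target_snp, cand)
        except ValidationError:
            continue
        if r2 > best_r2:
            best_id, best_r2 = cand, r2
    return best_id


def cis_candidates(g: GenotypeMatrix, cpg_meta_row: pd.Series,
                   window_bp: int = 50_000) -> list[str]:
    """SNPs on the CpG's chromosome within the closed window
    ``[pos - window_bp, pos + window_bp]``, minus probe SNPs."""
    chrom = str(cpg_meta_row["chrom"])
    pos = int(cpg_meta_row["pos"])
    probe = cpg_meta_row.get("probe_snp_ids", set()) or set()
    meta = g.snp_meta
    keep = (meta["chrom"].astype(str) == chrom) \
        & (np.abs(meta["pos"].astype(int) - pos) <= window_bp) \
        & ~meta.index.isin(list(probe))
    return [s for s in g.snp_ids if keep.loc[s]]


def elastic_net_select(
    residual_methylation,
    g_window: GenotypeMatrix,
    alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 123,
    target_id: str = "",
    window: tuple[str, int, int] | None = None,
    n_lambda: int = 100,
) -> InstrumentSet:
    """Select cis-meQTLs by cross-validated elastic net.

    Fits covariate-residualized methylation on the standardized candidate
    dosages over a descending penalty path, picks the penalty minimizing the
    seeded ``cv_folds``-fold cross-validated MSE (largest penalty on ties),
    and reports SNPs with nonzero coefficients there — coefficients on the
    original dosage scale.  Deterministic given the seed and invariant to
    candidate column order.
    """
    y = np.asarray(residual_methylation, float).ravel()
    if g_window.n_snps == 0:
        warnings.warn(f"no candidate SNPs for {target_id or 'target'}", stacklevel=2)
        return InstrumentSet(target_id, window, [], [], float("nan"), seed, alpha,
                             status="no_candidates")
    if len(y) != g_window.n_samples:
        raise ValidationError("residual vector and genotype window disagree on samples")
    order = np.argsort(np.asarray(g_window.snp_ids, dtype=object))  # order invariance
    snp_ids = [g_window.snp_ids[j] for j in order]
    X = g_window.dosages[:, order]
    mask = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    y, X = y[mask], X[mask]
    n = len(y)
    if n < 2 * cv_folds:
        raise ValidationError(f"need at least {2 * cv_folds} complete samples; got {n}")

    sd = X.std(axis=0)      # 1/n standard deviation, glmnet convention
    poly = sd > 0
    snp_ids = [s for s, keep in zip(snp_ids, poly) if keep]
    X = X[:, poly]
    candidates = list(snp_ids)
    if X.shape[1] == 0 or np.ptp(y) == 0:
        return InstrumentSet(target_id, window, candidates, [], float("nan"),
                             seed, alpha, status="empty_selection")
    Xs = (X - X.mean(axis=0)) / sd[poly]
    yc = y - y.mean()

    lam_max = float(np.max(np.abs(Xs.T @ yc)) / (n * alpha))
    if lam_max <= 0 or not np.isfinite(lam_max):
        return InstrumentSet(target_id, window, candidates, [], float("nan"),
                             seed, alpha, status="empty_selection")
    eps = 1e-4 if n > X.shape[1] else 1e-2
    lambdas = np.geomspace(lam_max, lam_max * eps, n_lambda)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sse = np.zeros(n_lambda)
    for train, val in kf.split(Xs):
        en = ElasticNet(alpha=lambdas[0], l1_ratio=alpha, fit_intercept=True,
                        warm_start=True, max_iter=10_000, tol=1e-7)
        for k, lam in enumerate(lambdas):
            en.set_params(alpha=lam)
            en.fit(Xs[train], y[train])
            resid = y[val] - en.predict(Xs[val])
            sse[k] += float(resid @ resid)
    mse = sse / n
    k_min = int(np.argmin(mse))        # first index on the descending path
    lam_min = float(lambdas[k_min])

    full = ElasticNet(alpha=lambdas[0], l1_ratio=alpha, fit_intercept=True,
                      warm_start=True, max_iter=50_000, tol=1e-9)
    for lam in lambdas[:k_min + 1]:    # warm path to lambda.min for stability
        full.set_params(alpha=lam)
        full.fit(Xs, y)
    coef_orig = full.coef_ / sd[poly]
    selected = [(snp_ids[j], float(coef_orig[j]))
                for j in np.flatnonzero(full.coef_ != 0)]
    status = "ok" if selected else "empty_selection"
    return InstrumentSet(target_id, window, candidates, selected, lam_min,
                         seed, alpha, status=status)


def build_prs_m(g: GenotypeMatrix, instrument: InstrumentSet) -> ScoreVector:
    """Weighted methylation score from elastic-net coefficients.

    Negative coefficients are flipped to the other allele inside the score
    construction so all weights end up positive.
    """
    if not instrument.selected:
        raise ValidationError(
            f"no instrument available for {instrument.target_id or 'target'}: "
            "elastic net selected no cis-meQTL"
        )
    rows = []
    for snp, coef in instrument.selected:
        rows.append({"snp_id": snp,
                     "effect_allele": g.snp_meta.loc[snp, "effect_allele"],
                     "effect_size": coef})
    return build_weighted_score(g, EffectSizeTable(pd.DataFrame(rows)))


@dataclass
class InstrumentStrength:
    beta: float
    se: float
    pvalue: float
    f_stat: float
    n: int


def instrument_strength(score: ScoreVector, exposure, covariates,
                        family_ids, lambda_fixed: float | None = None) -> InstrumentStrength:
    """Mixed-model association of the standardized score with the exposure;
    the single-instrument F statistic is the squared Wald z."""
    design = pd.DataFrame({"score": score.standardized})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        design = pd.concat([design, cov], axis=1)
    fit = fit_lmm(np.asarray(exposure, float), design, family_ids,
                  lambda_fixed=lambda_fixed)
    return InstrumentStrength(fit.coef["score"], fit.se["score"],
                              fit.pvalue["score"], fit.wald_f("score"), fit.n)
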