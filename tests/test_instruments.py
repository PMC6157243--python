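"""Weighted allele scores, LD proxies, cis windows and elastic-net
instrument selection (R glmnet as the independent oracle)."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylmr as mm
from methylmr.instruments import (build_prs_m, build_weighted_score,
                                  cis_candidates, elastic_net_select,
                                  find_proxy, instrument_strength, ld_r2)
from methylmr.io_core import EffectSizeTable, GenotypeMatrix, ValidationError
from methylmr.lmm import build_covariate_design, lmm_residualize

from conftest import study_frames


def _geno(dosages, snp_ids=None, pos=None, chrom="1", ea="A", oa="G"):
    dosages = np.asarray(dosages, float)
    n, k = dosages.shape
    snp_ids = snp_ids or [f"rs{j}" for j in range(k)]
    pos = pos if pos is not None else [100 * (j + 1) for j in range(k)]
    meta = pd.DataFrame({"chrom": chrom, "pos": pos, "effect_allele": ea,
                         "other_allele": oa}, index=snp_ids)
    return GenotypeMatrix([f"s{i}" for i in range(n)], snp_ids, dosages, meta)


def _effects(snp_ids, es, allele="A"):
    return EffectSizeTable(pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": allele, "effect_size": es}))


class TestWeightedScore:
    def test_hand_computed_example(self):
        g = _geno([[1, 2], [0, 1]])
        sv = build_weighted_score(g, _effects(["rs0", "rs1"], [0.2, 0.4]))
        np.testing.assert_allclose(sv.raw, [1.0 / 0.3, 0.4 / 0.3], rtol=1e-12)
        np.testing.assert_allclose(sv.standardized, [np.sqrt(0.5), -np.sqrt(0.5)],
                                   rtol=1e-12)

    def test_equal_weights_collapse_to_allele_count(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.3, size=(30, 4)).astype(float)
        sv = build_weighted_score(_geno(d), _effects([f"rs{j}" for j in range(4)],
                                                     [0.7] * 4))
        np.testing.assert_allclose(sv.raw, d.sum(axis=1), rtol=1e-12)

    def test_weight_doubling_is_exactly_neutral(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=(25, 3)).astype(float)
        ids = [f"rs{j}" for j in range(3)]
        es = [0.1, 0.25, 0.4]
        a = build_weighted_score(_geno(d), _effects(ids, es))
        b = build_weighted_score(_geno(d), _effects(ids, [2 * v for v in es]))
        assert np.array_equal(a.raw, b.raw)

    def test_negative_weight_flips_allele(self):
        d = np.array([[0.0, 1], [1, 1], [2, 0]])
        neg = build_weighted_score(_geno(d), _effects(["rs0", "rs1"], [-0.3, 0.3]))
        flipped = d.copy()
        flipped[:, 0] = 2 - flipped[:, 0]
        ref = build_weighted_score(_geno(flipped), _effects(["rs0", "rs1"], [0.3, 0.3]))
        np.testing.assert_allclose(neg.raw, ref.raw, rtol=1e-12)

    def test_ref_allele_weight_flips_dosage(self):
        d = np.array([[0.0], [1], [2], [1]])
        sv = build_weighted_score(_geno(d), _effects(["rs0"], [0.5], allele="G"))
        np.testing.assert_allclose(sv.raw, (2 - d[:, 0]), rtol=1e-12)

    def test_missing_snp_listed(self):
        with pytest.raises(ValidationError, match="rs9"):
            build_weighted_score(_geno([[1.0], [0]]), _effects(["rs9"], [0.2]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_standardization_contract(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, rng.uniform(0.1, 0.5), size=(20, 3)).astype(float)
        if np.ptp(d @ np.array([0.1, 0.2, 0.3])) == 0:
            return
        sv = build_weighted_score(_geno(d), _effects([f"rs{j}" for j in range(3)],
                                                     [0.1, 0.2, 0.3]))
        assert abs(sv.standardized.mean()) < 1e-8
        assert abs(sv.standardized.std(ddof=1) - 1) < 1e-8


class TestLD:
    def test_identical_and_mirrored_vectors(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.3, 50).astype(float)
        g = _geno(np.column_stack([a, a, 2 - a]))
        assert ld_r2(g, "rs0", "rs1") == pytest.approx(1.0)
        assert ld_r2(g, "rs0", "rs2") == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.3, size=(10_000, 2)).astype(float)
        assert ld_r2(_geno(d), "rs0", "rs1") < 0.01

    def test_monomorphic_errors(self):
        g = _geno(np.column_stack([np.ones(10), np.arange(10) % 3]))
        with pytest.raises(ValidationError, match="monomorphic"):
            ld_r2(g, "rs0", "rs1")

    def test_find_proxy_prefers_strongest(self):
        rng = np.random.default_rng(4)
        t = rng.binomial(2, 0.5, 4000).astype(float)
        strong, weak, indep = t.copy(), t.copy(), rng.binomial(2, 0.5, 4000).astype(float)
        noise = rng.random(4000)
        weak[noise < 0.08] = rng.binomial(2, 0.5, (noise < 0.08).sum())
        g = _geno(np.column_stack([t, strong, weak, indep]),
                  snp_ids=["t", "strong", "weak", "indep"])
        assert find_proxy(g, "t", ["weak", "strong", "indep"], 0.8) == "strong"
        assert find_proxy(g, "t", ["indep"], 0.8) is None
        assert find_proxy(g, "t", ["weak", "t"], 0.8) == "t"


class TestCisWindow:
    def test_closed_boundary_and_probe_exclusion(self):
        g = _geno(np.zeros((4, 4)) + [[0, 1, 2, 1]] ,
                  snp_ids=["far", "edge", "inside", "probe"],
                  pos=[49_999, 50_000, 100_010, 100_005])
        cpg = pd.Series({"chrom": "1", "pos": 100_000,
                         "probe_snp_ids": {"probe"}})
        assert cis_candidates(g, cpg, 50_000) == ["edge", "inside"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(1, 300_000, 40)
        g = _geno(rng.binomial(2, 0.3, size=(5, 40)).astype(float), pos=pos)
        cpg = pd.Series({"chrom": "1", "pos": 150_000, "probe_snp_ids": set()})
        expected = [s for s, p in zip(g.snp_ids, pos) if abs(int(p) - 150_000) <= 50_000]
        assert cis_candidates(g, cpg, 50_000) == expected


def _residual_setup(seed, **kw):
    st_ = mm.simulate_study(mm.null_scenario(seed=seed, n_families=200,
                                             n_cis_snps=50, **kw))
    cov, fam, _ = study_frames(st_)
    resid = lmm_residualize(st_.methylation.beta_of("cg_sim01"), cov, fam)
    cands = cis_candidates(st_.genotypes, st_.methylation.cpg_meta.loc["cg_sim01"])
    return st_, resid, st_.genotypes.subset(snps=cands)


class TestElasticNet:
    def test_zero_residuals_select_nothing(self):
        st_, resid, gw = _residual_setup(60)
        inst = elastic_net_select(np.zeros_like(resid), gw, seed=123)
        assert inst.selected == [] and inst.status == "empty_selection"

    def test_causal_snp_recovered(self):
        for seed in (61, 62, 63):
            st_, resid, gw = _residual_setup(seed)
            inst = elastic_net_select(resid, gw, seed=123)
            assert "rs_cis001" in inst.snp_ids

    def test_duplicate_snp_grouping(self):
        st_, resid, gw = _residual_setup(64, duplicate_snps=("rs_cis001",))
        inst = elastic_net_select(resid, gw, seed=123)
        assert {"rs_cis001", "rs_cis001_dup"} & set(inst.snp_ids)

    def test_deterministic_and_column_order_invariant(self):
        st_, resid, gw = _residual_setup(65)
        a = elastic_net_select(resid, gw, seed=123)
        b = elastic_net_select(resid, gw, seed=123)
        assert a.selected == b.selected and a.lambda_used == b.lambda_used
        perm = list(np.random.default_rng(0).permutation(gw.snp_ids))
        c = elastic_net_select(resid, gw.subset(snps=perm), seed=123)
        assert dict(a.selected) == pytest.approx(dict(c.selected))

    def test_selected_never_exceeds_bound(self):
        st_, resid, gw = _residual_setup(66)
        inst = elastic_net_select(resid, gw, seed=123)
        assert len(inst.selected) <= min(len(resid) - 1, gw.n_snps)
        assert all(c != 0 for _, c in inst.selected)
        assert set(inst.snp_ids) <= set(inst.candidate_snp_ids)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R oracle not on PATH")
    def test_coefficients_match_glmnet_at_fixed_lambda(self, tmp_path):
        rng = np.random.default_rng(42)
        n, p = 200, 15
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        beta = np.zeros(p)
        beta[[2, 7]] = [0.4, -0.3]
        y = X @ beta + rng.normal(0, 1, n)
        lam = 0.05
        from sklearn.linear_model import ElasticNet
        sd = X.std(axis=0)
        en = ElasticNet(alpha=lam, l1_ratio=0.5, fit_intercept=True,
                        max_iter=200_000, tol=1e-12).fit((X - X.mean(0)) / sd, y)
        mine = en.coef_ / sd
        pd.DataFrame(X).to_csv(tmp_path / "x.csv", index=False)
        pd.DataFrame({"y": y}).to_csv(tmp_path / "y.csv", index=False)
        script = (
            'suppressMessages(library(glmnet));'
            f'x <- as.matrix(read.csv("{tmp_path}/x.csv"));'
            f'y <- read.csv("{tmp_path}/y.csv")$y;'
            f'fit <- glmnet(x, y, alpha=0.5, lambda={lam}, standardize=TRUE, thresh=1e-14);'
            'cat(as.numeric(coef(fit))[-1], sep="\\n")')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(mine, ref, atol=1e-3)


class TestPrsM:
    def test_single_snp_equals_standardized_dosage(self, small_study):
        g = small_study.genotypes
        inst = mm.InstrumentSet("cg", None, ["rs_cis001"], [("rs_cis001", 0.4)],
                                0.1, 123, 0.5)
        sv = build_prs_m(g, inst)
        d = g.dosage_of("rs_cis001")
        np.testing.assert_allclose(sv.standardized,
                                   (d - d.mean()) / d.std(ddof=1), rtol=1e-10)

    def test_three_snp_hand_formula(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.4, size=(40, 3)).astype(float)
        g = _geno(d)
        coefs = [0.5, 0.2, -0.1]
        inst = mm.InstrumentSet("cg", None, list(g.snp_ids),
                                list(zip(g.snp_ids, coefs)), 0.1, 123, 0.5)
        sv = build_prs_m(g, inst)
        aligned = np.column_stack([d[:, 0], d[:, 1], 2 - d[:, 2]])
        w = np.array([0.5, 0.2, 0.1])
        np.testing.assert_allclose(sv.raw, aligned @ w / w.mean(), rtol=1e-12)

    def test_empty_selection_is_error(self, small_study):
        inst = mm.InstrumentSet("cg", None, [], [], float("nan"), 123, 0.5,
                                status="empty_selection")
        with pytest.raises(ValidationError, match="no instrument available"):
            build_prs_m(small_study.genotypes, inst)


class TestInstrumentStrength:
    def test_recovers_simulated_effect(self, small_study):
        cov, fam, logtg = study_frames(small_study)
        prs = build_weighted_score(
            small_study.genotypes.subset(snps=small_study.truth["lipid_snp_ids"]),
            small_study.effect_sizes)
        res = instrument_strength(prs, logtg, cov, fam)
        # the generator adds sum_k b_k g_k = raw * mean(b) to log-TG, so the
        # per-standardized-unit effect is sd(raw) * mean(b)
        b = np.array(list(small_study.truth["lipid_effects"].values()))
        truth = np.std(prs.raw, ddof=1) * b.mean()
        assert abs(res.beta - truth) < 3 * res.se
        assert res.f_stat > 30
        assert res.pvalue < 1e-6

    def test_score_identical_to_exposure_gives_huge_f(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        fam = np.repeat(np.arange(50), 4)
        sv = mm.ScoreVector([str(i) for i in range(200)], x,
                            (x - x.mean()) / x.std(ddof=1), [("s", 1.0)])
        res = instrument_strength(sv, x, None, fam)
        assert res.f_stat > 1e6

    def test_permuted_score_is_null_calibrated(self):
        rng = np.random.default_rng(9)
        n, reps, hits = 240, 150, 0
        fam = np.repeat([f"f{i}" for i in range(60)], 4)
        x = rng.normal(size=n)
        for _ in range(reps):
            z = rng.permutation(x)
            sv = mm.ScoreVector([str(i) for i in range(n)], z,
                                (z - z.mean()) / z.std(ddof=1), [("s", 1.0)])
            y = rng.normal(size=n)
            hits += instrument_strength(sv, y, None, fam).pvalue < 0.05
        rate = hits / reps
        ci = 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - ci <= rate <= 0.05 + ci
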