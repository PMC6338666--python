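"""The four association models, their algebraic relationships, and POE calls."""

import numpy as np
import pytest

from pogwas import (
    EffectSpec,
    EigenRotation,
    PhenotypeFrame,
    SimulationConfig,
    Variant,
    classify_poe,
    compute_pedigree_relationship,
    fit_variance_components,
    gene_drop_genotypes,
    gls_fit,
    profile_log_likelihood,
    run_all_models,
    run_differential_gwas,
    run_parental_gwas,
    run_standard_gwas,
    significance_filter,
    simulate_pedigree,
    simulate_phenotype,
)
from pogwas.association import AssociationResult, top_hits
from pogwas.genotypes import PhasedGenotypeMatrix


def _variant(pos=100, vid="v"):
    return Variant("1", pos, vid, "A", "G")


def _result(p, pos=100, vid="v", model="standard"):
    return AssociationResult(
        variant=_variant(pos, vid), model=model, n_analyzed=100, maf=0.2,
        beta=0.1, se=0.05, p=p,
    )


class TestReparameterization:
    def test_differential_equals_joint_parental_fit(self, sim_dataset):
        """The coefficient on d with x_pm as covariate must equal b_M - b_P
        from the joint maternal+paternal fit, with matching SE, p and
        restricted likelihood, at the same lambda (to 1e-8)."""
        G, pheno, A = sim_dataset["G"], sim_dataset["pheno"], sim_dataset["A"]
        diff = run_differential_gwas(G, pheno, A)
        rot = EigenRotation.from_relatedness(A)
        by_id = {r.variant.id: r for r in diff}
        checked = 0
        for j, v in enumerate(G.variants[:15]):
            r = by_id.get(v.id)
            if r is None:
                continue
            xm, xp = G.maternal[j], G.paternal[j]
            Z_joint = np.column_stack([pheno.W, xm, xp])
            fit = gls_fit(pheno.y, Z_joint, rot, r.lam)
            c = pheno.W.shape[1]
            contrast = fit.coefficients[c] - fit.coefficients[c + 1]
            var = (
                fit.covariance[c, c]
                + fit.covariance[c + 1, c + 1]
                - 2 * fit.covariance[c, c + 1]
            )
            se = np.sqrt(var)
            from pogwas.lmm import wald_test

            assert contrast == pytest.approx(r.beta, abs=1e-8)
            assert se == pytest.approx(r.se, abs=1e-8)
            assert wald_test(contrast, se, fit.df) == pytest.approx(r.p, abs=1e-8)
            ll_joint = profile_log_likelihood(pheno.y, Z_joint, rot, r.lam)
            assert ll_joint == pytest.approx(r.log_likelihood, abs=1e-8)
            checked += 1
        assert checked >= 10

    def test_degenerate_d_equals_standard_beta(self):
        """When X_M = X_P everywhere (d == 0) the variant carries no
        parent-of-origin signal; its pooled coefficient must match the
        standard GWAS exactly (the differential scan skips it)."""
        rng = np.random.default_rng(0)
        n = 80
        hom = rng.integers(0, 2, n).astype(float)  # X_M = X_P
        G = PhasedGenotypeMatrix([_variant()], [f"s{i}" for i in range(n)],
                                 hom[None, :], hom[None, :])
        pheno = PhenotypeFrame(
            sample_ids=[f"s{i}" for i in range(n)],
            y=hom * 0.3 + rng.standard_normal(n),
            W=np.ones((n, 1)),
        )
        from pogwas.lmm import RelatednessMatrix

        A = RelatednessMatrix(np.eye(n), [f"s{i}" for i in range(n)])
        std = run_standard_gwas(G, pheno, A)
        assert len(std) == 1
        diff = run_differential_gwas(G, pheno, A)
        assert diff == []  # no informative transmissions


class TestScans:
    def test_n_analyzed_identical_across_models_without_missingness(self, sim_dataset):
        G, pheno, A = sim_dataset["G"], sim_dataset["pheno"], sim_dataset["A"]
        res = run_all_models(G, pheno, A)
        by_id = {m: {r.variant.id: r for r in rows} for m, rows in res.items()}
        common = set.intersection(*(set(d) for d in by_id.values()))
        assert common
        for vid in common:
            ns = {by_id[m][vid].n_analyzed for m in by_id}
            assert len(ns) == 1

    def test_monomorphic_variant_skipped(self, sim_dataset):
        pheno, A = sim_dataset["pheno"], sim_dataset["A"]
        n = len(pheno.y)
        zeros = np.zeros((1, n))
        G = PhasedGenotypeMatrix([_variant()], pheno.sample_ids, zeros, zeros)
        assert run_standard_gwas(G, pheno, A) == []

    def test_too_few_samples_skipped(self, sim_dataset):
        pheno, A = sim_dataset["pheno"], sim_dataset["A"]
        n = len(pheno.y)
        mat = np.full((1, n), np.nan)
        pat = np.full((1, n), np.nan)
        mat[0, :5] = [0, 1, 0, 1, 1]
        pat[0, :5] = [1, 0, 0, 1, 0]
        G = PhasedGenotypeMatrix([_variant()], pheno.sample_ids, mat, pat)
        assert run_standard_gwas(G, pheno, A) == []

    def test_maternal_effect_gives_larger_maternal_statistics(self):
        """With a planted maternal-only effect the maternal scan must show
        systematically larger |t| than the paternal scan across seeds."""
        cfg = SimulationConfig(
            n_founders=60, n_generations=3, n_variants=1, causal_maf=0.3,
            sigma_g2=0.3, sigma_e2=0.7, seed=0,
        )
        ped = simulate_pedigree(cfg)
        A = compute_pedigree_relationship(ped)
        t_m, t_p = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            G, _ = gene_drop_genotypes(ped, cfg, allele_freqs=np.array([0.3]), rng=rng)
            pheno, _ = simulate_phenotype(
                G, ped, [EffectSpec(0, 0.5, 0.0)], cfg, A=A, rng=rng
            )
            rm = run_parental_gwas(G, pheno, A, "maternal")
            rp = run_parental_gwas(G, pheno, A, "paternal")
            t_m.append(abs(rm[0].beta / rm[0].se))
            t_p.append(abs(rp[0].beta / rp[0].se))
        assert np.mean(t_m) > np.mean(t_p)

    def test_null_p_values_roughly_uniform(self, sim_dataset):
        """With a polygenic-only trait the per-variant p-values should not be
        systematically inflated (quick small-scale calibration check)."""
        from scipy import stats

        G, pheno, A = sim_dataset["G"], sim_dataset["pheno"], sim_dataset["A"]
        res = run_standard_gwas(G, pheno, A)
        ps = np.array([r.p for r in res])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_opposite_effects_hidden_in_standard_visible_in_differential(self):
        """beta_M = -beta_P: the pooled regressor carries no signal while the
        differential test recovers beta_M - beta_P."""
        cfg = SimulationConfig(
            n_founders=100, n_generations=3, n_variants=1, causal_maf=0.3,
            sigma_g2=0.5, sigma_e2=0.5, seed=3,
        )
        ped = simulate_pedigree(cfg)
        A = compute_pedigree_relationship(ped)
        rng = np.random.default_rng(42)
        G, _ = gene_drop_genotypes(ped, cfg, allele_freqs=np.array([0.3]), rng=rng)
        pheno, _ = simulate_phenotype(
            G, ped, [EffectSpec(0, 0.6, -0.6)], cfg, A=A, rng=rng
        )
        std = run_standard_gwas(G, pheno, A)[0]
        diff = run_differential_gwas(G, pheno, A)[0]
        assert diff.p < std.p
        assert abs(diff.beta - 1.2) < 3 * diff.se
        assert diff.mean_effect is not None


class TestAlternativeStrategies:
    def test_lrt_agrees_with_wald_on_strong_signal(self):
        """The optional likelihood-ratio differential test must rank the same
        causal variant first and broadly agree with the Wald version."""
        from pogwas import run_differential_lrt

        cfg = SimulationConfig(
            n_founders=100, n_generations=3, n_variants=5, causal_maf=0.3,
            sigma_g2=0.3, sigma_e2=0.7, seed=13,
        )
        ped = simulate_pedigree(cfg)
        A = compute_pedigree_relationship(ped)
        rng = np.random.default_rng(13)
        G, _ = gene_drop_genotypes(ped, cfg, rng=rng)
        pheno, _ = simulate_phenotype(
            G, ped, [EffectSpec(0, 0.7, -0.7)], cfg, A=A, rng=rng
        )
        wald = run_differential_gwas(G, pheno, A)
        lrt = run_differential_lrt(G, pheno, A)
        assert len(lrt) == len(wald)
        best_w = min(wald, key=lambda r: r.p)
        best_l = min(lrt, key=lambda r: r.p)
        assert best_w.variant.id == best_l.variant.id == G.variants[0].id
        # Wald and LRT are asymptotically equivalent on the log-p scale
        assert abs(np.log10(best_l.p) - np.log10(best_w.p)) < 1.0

    def test_once_lambda_strategy_approximates_per_variant(self, sim_dataset):
        """The faster once-per-phenotype lambda mode must produce p-values
        close to the per-variant optimisation on a null trait."""
        G, pheno, A = sim_dataset["G"], sim_dataset["pheno"], sim_dataset["A"]
        per = run_standard_gwas(G, pheno, A)
        once = run_standard_gwas(G, pheno, A, lambda_strategy="once")
        assert len(per) == len(once)
        lp = np.log10([r.p for r in per])
        lo = np.log10([r.p for r in once])
        assert np.abs(lp - lo).max() < 0.5


class TestClassification:
    @pytest.mark.parametrize(
        "p_pat, p_mat, p_std, expected",
        [
            # most significant paternal LDL association: paternal-only call
            (8.06e-10, 4.21e-1, 4.24e-5, "paternal_only"),
            # age-of-menarche maternal association: maternal-only call
            (5.01e-1, 3.11e-8, 6.75e-3, "maternal_only"),
            # significant in both parents and the standard GWAS: excluded
            (1e-9, 1e-9, 1e-12, "none"),
            (0.5, 0.5, 0.5, "none"),
        ],
    )
    def test_single_parent_rule(self, p_pat, p_mat, p_std, expected):
        call = classify_poe(
            _variant(), p_standard=p_std, p_maternal=p_mat, p_paternal=p_pat,
            p_differential=0.5,
        )
        assert call.classification == expected

    def test_differential_reported_separately_and_may_co_occur(self):
        call = classify_poe(
            _variant(), p_standard=0.9, p_maternal=1e-9, p_paternal=0.4,
            p_differential=1e-9,
        )
        assert call.classification == "maternal_only"
        assert call.differential is True
        only_diff = classify_poe(
            _variant(), p_standard=0.9, p_maternal=0.3, p_paternal=0.4,
            p_differential=1e-9,
        )
        assert only_diff.classification == "differential"

    def test_missing_p_value_rejected(self):
        with pytest.raises(ValueError, match="maternal"):
            classify_poe(_variant(), 0.5, np.nan, 0.5, 0.5)


class TestSignificanceFilter:
    def test_strict_boundary(self):
        rows = [_result(5e-8, vid="at"), _result(4.10e-9, vid="below"),
                _result(1e-7, vid="above")]
        kept = significance_filter(rows)
        assert [r.variant.id for r in kept] == ["below"]

    def test_empty_input(self):
        assert significance_filter([]) == []

    def test_stable_order(self):
        rows = [_result(1e-9, pos=1, vid="a"), _result(1e-10, pos=2_500_000, vid="b")]
        assert [r.variant.id for r in significance_filter(rows)] == ["a", "b"]


def test_top_hits_greedy_window():
    rows = [
        _result(1e-12, pos=1_000_000, vid="lead"),
        _result(1e-10, pos=1_500_000, vid="shadow"),  # within 1 Mb of lead
        _result(1e-9, pos=5_000_000, vid="second"),
    ]
    hits = top_hits(rows)
    assert [r.variant.id for r in hits] == ["lead", "second"]
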