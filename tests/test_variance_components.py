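"""EM-REML: heritability arithmetic, recovery of known truth, invariants."""

import numpy as np
import pandas as pd
import pytest

from sireval import (
    ModelSpec,
    SimDesign,
    TraitModel,
    heritability,
    reml_bivariate,
    reml_single_trait,
    simulate_pedigree,
    simulate_phenotypes,
)
from sireval.variance_components import RelationshipSpectrum

from conftest import single_trait_model


class TestHeritability:
    @pytest.mark.parametrize(
        "s2a, s2p, expected",
        [
            (3.42, 21.37, 0.16),   # birth weight
            (3.78, 14.19, 0.27),   # age at first conception
            (1.66, 6.99, 0.24),    # daily milk yield
            (2.46, 9.50, 0.26),    # peak milk yield
            (263.29, 1505.90, 0.17),  # lactation length
        ],
    )
    def test_published_component_ratios(self, s2a, s2p, expected):
        assert round(heritability(s2a, s2p), 2) == expected

    def test_zero_additive_variance(self):
        assert heritability(0.0, 5.0) == 0.0

    def test_domain_violations_rejected(self):
        with pytest.raises(ValueError):
            heritability(1.0, 0.0)
        with pytest.raises(ValueError):
            heritability(2.0, 1.0)


class TestSingleTraitReml:
    def test_null_heritability_recovered(self):
        ped = simulate_pedigree(SimDesign(n_sires=25, progeny_per_sire=80, seed=20))
        model = TraitModel(trait_names=["y"], G=[[1e-12]], E=[[4.0]])
        rec = simulate_phenotypes(ped, model, seed=21).records
        vc = reml_single_trait(rec, ModelSpec("y"), ped=ped)
        assert vc.h2 <= 0.05

    def test_matches_halfsib_anova_on_balanced_design(self):
        s, k = 40, 60
        ped = simulate_pedigree(SimDesign(n_sires=s, progeny_per_sire=k, seed=22))
        rec = simulate_phenotypes(ped, single_trait_model(h2=0.3), seed=23).records
        vc = reml_single_trait(rec, ModelSpec("y"), ped=ped)
        groups = rec.groupby("sire")["y"]
        means, grand = groups.mean(), rec["y"].mean()
        msb = k * ((means - grand) ** 2).sum() / (s - 1)
        msw = groups.apply(lambda x: ((x - x.mean()) ** 2).sum()).sum() / (s * (k - 1))
        s2a_anova = 4 * (msb - msw) / k
        # both estimate the same sire variance; agreement within MC error
        se_anova = 4 * msb * np.sqrt(2 / (s - 1)) / k
        assert abs(vc.sigma2_a - s2a_anova) < 3 * se_anova

    def test_phenotypic_variance_identity_and_convergence_report(self):
        ped = simulate_pedigree(SimDesign(n_sires=10, progeny_per_sire=20, seed=24))
        rec = simulate_phenotypes(ped, single_trait_model(), seed=25).records
        vc = reml_single_trait(rec, ModelSpec("y"), ped=ped)
        assert vc.sigma2_p == vc.sigma2_a + vc.sigma2_e
        assert 0 <= vc.h2 <= 1
        assert vc.n_iter >= 1 and np.isfinite(vc.final_change)

    def test_loglik_monotone_over_iterations(self):
        ped = simulate_pedigree(SimDesign(n_sires=15, progeny_per_sire=25, seed=26))
        rec = simulate_phenotypes(ped, single_trait_model(h2=0.4), seed=27).records
        vc = reml_single_trait(rec, ModelSpec("y"), ped=ped, max_iter=300)
        ll = np.array(vc.loglik_path)
        assert np.all(np.diff(ll) >= -1e-6 * (1 + np.abs(ll[:-1])))

    def test_boundary_flagged_not_raised(self):
        ped = simulate_pedigree(SimDesign(n_sires=5, progeny_per_sire=10, seed=28))
        model = TraitModel(trait_names=["y"], G=[[1e-12]], E=[[1.0]])
        rec = simulate_phenotypes(ped, model, seed=29).records
        vc = reml_single_trait(rec, ModelSpec("y"), ped=ped, max_iter=4000)
        assert vc.sigma2_a > 0  # floored, never zero or negative

    def test_recovers_h2_with_fixed_effects_in_model(self):
        ped = simulate_pedigree(SimDesign(n_sires=40, progeny_per_sire=60, seed=30))
        model = TraitModel(
            trait_names=["y"],
            G=[[1.0]],
            E=[[3.0]],
            overall_means=[20.0],
            fixed_effects={"parity": {"1": [0.0], "2": [1.5], "3": [-0.8]}},
        )
        rec = simulate_phenotypes(ped, model, seed=31).records
        vc = reml_single_trait(rec, ModelSpec("y", ["parity"]), ped=ped)
        assert vc.h2 == pytest.approx(0.25, abs=0.08)
        assert vc.h2_se < 0.08


class TestBivariateReml:
    def test_identical_duplicated_trait_gives_unit_genetic_correlation(self):
        ped = simulate_pedigree(SimDesign(n_sires=20, progeny_per_sire=30, seed=40))
        rec = simulate_phenotypes(ped, single_trait_model(h2=0.3), seed=41).records
        rec["y2"] = rec["y"]
        res = reml_bivariate(rec, (ModelSpec("y"), ModelSpec("y2")), ped=ped)
        assert res.correlation.r_g == pytest.approx(1.0, abs=1e-3)

    def test_independent_traits_give_near_zero_genetic_correlation(self):
        # bias check at n = 4,000 records: mean r_g over replicates ~ 0
        ped = simulate_pedigree(SimDesign(n_sires=200, progeny_per_sire=20, seed=42))
        model = TraitModel(
            trait_names=["t1", "t2"], G=np.diag([1.0, 1.0]), E=np.diag([3.0, 3.0])
        )
        rec0 = simulate_phenotypes(ped, model, seed=43).records
        sp = RelationshipSpectrum.from_pedigree(ped, rec0["animal"].tolist())
        rgs = []
        for rep in range(5):
            rec = simulate_phenotypes(ped, model, seed=43 + rep).records
            res = reml_bivariate(
                rec, (ModelSpec("t1"), ModelSpec("t2")), spectrum=sp, tol=1e-6
            )
            rgs.append(res.correlation.r_g)
        assert abs(np.mean(rgs)) <= 0.1

    def test_marginals_agree_with_single_trait_fit_on_uncorrelated_data(self):
        ped = simulate_pedigree(SimDesign(n_sires=25, progeny_per_sire=40, seed=44))
        model = TraitModel(
            trait_names=["t1", "t2"], G=np.diag([1.0, 2.0]), E=np.diag([3.0, 2.0])
        )
        rec = simulate_phenotypes(ped, model, seed=45).records
        sp = RelationshipSpectrum.from_pedigree(ped, rec["animal"].tolist())
        res = reml_bivariate(
            rec, (ModelSpec("t1"), ModelSpec("t2")), spectrum=sp
        )
        for k, trait in enumerate(["t1", "t2"]):
            single = reml_single_trait(rec, ModelSpec(trait), spectrum=sp)
            assert res.G0[k, k] == pytest.approx(single.sigma2_a, rel=0.05, abs=0.02)
            assert res.R0[k, k] == pytest.approx(single.sigma2_e, rel=0.05, abs=0.02)

    def test_loglik_monotone(self):
        ped = simulate_pedigree(SimDesign(n_sires=15, progeny_per_sire=20, seed=46))
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        model = TraitModel(trait_names=["t1", "t2"], G=G, E=np.eye(2) * 2)
        rec = simulate_phenotypes(ped, model, seed=47).records
        res = reml_bivariate(
            rec, (ModelSpec("t1"), ModelSpec("t2")), ped=ped, max_iter=400
        )
        ll = np.array(res.loglik_path)
        assert np.all(np.diff(ll) >= -1e-6 * (1 + np.abs(ll[:-1])))

    def test_correlation_sign_matches_genetic_covariance(self):
        ped = simulate_pedigree(SimDesign(n_sires=30, progeny_per_sire=40, seed=48))
        G = np.array([[1.0, -0.6], [-0.6, 1.0]])
        model = TraitModel(trait_names=["t1", "t2"], G=G, E=np.eye(2) * 2)
        rec = simulate_phenotypes(ped, model, seed=49).records
        res = reml_bivariate(rec, (ModelSpec("t1"), ModelSpec("t2")), ped=ped)
        c = res.correlation
        assert np.sign(c.r_g) == np.sign(c.sigma_a_ij) == -1
        assert abs(c.r_g) <= 1 and abs(c.r_p) <= 1
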