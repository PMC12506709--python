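"""Animal-model MME assembly, BLUP solutions, and accuracy bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from sireval import (
    ModelSpec,
    SimDesign,
    a_inverse,
    accuracy_from_pev,
    build_mme,
    relationship_matrix,
    simulate_pedigree,
    simulate_phenotypes,
    solve_blup,
)
from sireval.errors import LinkageError

from conftest import gls_oracle, random_pedigree, single_trait_model


def _sim(n_sires, k, seed, h2=0.3):
    ped = simulate_pedigree(SimDesign(n_sires=n_sires, progeny_per_sire=k, seed=seed))
    rec = simulate_phenotypes(ped, single_trait_model(h2=h2), seed=seed + 1).records
    return ped, rec


class TestBuildMme:
    def test_single_animal_intercept_coefficient(self):
        rec = pd.DataFrame({"animal": ["A"], "y": [3.0]})
        ped_df = pd.DataFrame({"animal": ["A"], "sire": ["0"], "dam": ["0"]})
        from sireval import PedigreeTable, validate_and_sort

        ped = validate_and_sort(PedigreeTable(ped_df))
        system = build_mme(
            rec, ModelSpec("y"), a_inverse(ped), 1.0, 1.0, ped.ids
        )
        # animal equation: z'z + lambda * a^ii = 1 + 1 = 2
        M = system.coeff.toarray()
        assert M[1, 1] == pytest.approx(2.0)
        assert M.shape == (2, 2)

    def test_system_dimension_is_fixed_levels_plus_animals(self):
        ped, rec = _sim(3, 4, seed=0)
        rec["parity"] = ["1", "2", "3"] * 4
        system = build_mme(
            rec, ModelSpec("y", ["parity"]), a_inverse(ped), 1.0, 2.0, ped.ids
        )
        # intercept + 2 non-reference parity levels + every pedigree animal
        assert system.coeff.shape[0] == 3 + len(ped)

    def test_sparse_assembly_matches_dense_construction(self):
        ped, rec = _sim(4, 5, seed=1)
        rec["parity"] = (["1", "2"] * 10)[: len(rec)]
        lam_a, lam_e = 1.3, 2.6
        system = build_mme(
            rec, ModelSpec("y", ["parity"]), a_inverse(ped), lam_a, lam_e, ped.ids
        )
        from sireval.mixed_model import design_matrix

        X, _ = design_matrix(rec, ModelSpec("y", ["parity"]))
        q = len(ped)
        pos = {a: i for i, a in enumerate(ped.ids)}
        Z = np.zeros((len(rec), q))
        Z[np.arange(len(rec)), [pos[a] for a in rec["animal"]]] = 1.0
        Ainv = np.linalg.inv(relationship_matrix(ped).values)
        lam = lam_e / lam_a
        dense = np.block(
            [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Ainv]]
        )
        np.testing.assert_allclose(system.coeff.toarray(), dense, atol=1e-8)

    def test_record_for_unknown_animal_raises_linkage_error(self):
        ped, rec = _sim(2, 2, seed=2)
        rec.loc[0, "animal"] = "GHOST"
        with pytest.raises(LinkageError):
            build_mme(rec, ModelSpec("y"), a_inverse(ped), 1.0, 1.0, ped.ids)


class TestSolveBlup:
    def test_animal_without_records_gets_zero_ebv_and_zero_reliability(self):
        ped, rec = _sim(3, 3, seed=3)
        # add an unrelated founder with no records
        from sireval import PedigreeTable, validate_and_sort

        df = pd.concat(
            [ped.data, pd.DataFrame({"animal": ["LONER"], "sire": ["0"], "dam": ["0"]})],
            ignore_index=True,
        )
        ped2 = validate_and_sort(PedigreeTable(df))
        system = build_mme(rec, ModelSpec("y"), a_inverse(ped2), 1.0, 2.0, ped2.ids)
        _, ebv = solve_blup(system)
        row = ebv.table.loc["LONER"]
        assert row["ebv"] == pytest.approx(0.0, abs=1e-10)
        assert row["reliability"] == pytest.approx(0.0, abs=1e-10)
        assert row["accuracy"] == pytest.approx(0.0, abs=1e-10)

    def test_strong_shrinkage_limit_drives_ebvs_to_zero(self):
        ped, rec = _sim(3, 4, seed=4)
        system = build_mme(
            rec, ModelSpec("y"), a_inverse(ped), 1e-8, 1.0, ped.ids
        )
        _, ebv = solve_blup(system)
        assert np.abs(ebv.table["ebv"]).max() < 1e-4

    def test_blup_matches_gls_oracle_on_small_halfsib_design(self):
        ped, rec = _sim(3, 4, seed=5)
        s2a, s2e = 1.0, 3.0
        system = build_mme(rec, ModelSpec("y"), a_inverse(ped), s2a, s2e, ped.ids)
        _, ebv = solve_blup(system)
        A = relationship_matrix(ped).values
        beta, u = gls_oracle(rec, ModelSpec("y"), A, ped.ids, s2a, s2e)
        np.testing.assert_allclose(ebv.table["ebv"].to_numpy(), u, atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_blup_equals_gls_on_random_designs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        ped = random_pedigree(rng, n)
        recorded = [a for a in ped.ids if rng.random() < 0.7]
        if len(recorded) < 3:
            recorded = ped.ids[:3]
        rec = pd.DataFrame(
            {
                "animal": recorded,
                "y": rng.normal(10, 2, size=len(recorded)),
                "grp": rng.choice(["u", "v"], size=len(recorded)),
            }
        )
        spec = ModelSpec("y", ["grp"]) if rec["grp"].nunique() > 1 else ModelSpec("y")
        s2a, s2e = 1.5, 2.5
        system = build_mme(rec, spec, a_inverse(ped), s2a, s2e, ped.ids)
        fixed, ebv = solve_blup(system)
        A = relationship_matrix(ped).values
        beta, u = gls_oracle(rec, spec, A, ped.ids, s2a, s2e)
        np.testing.assert_allclose(fixed.to_numpy(), beta, atol=1e-7)
        np.testing.assert_allclose(ebv.table["ebv"].to_numpy(), u, atol=1e-7)

    def test_founder_ebvs_center_near_zero_on_balanced_design(self):
        ped, rec = _sim(30, 10, seed=6)
        system = build_mme(rec, ModelSpec("y"), a_inverse(ped), 1.0, 3.0, ped.ids)
        _, ebv = solve_blup(system)
        sires = [a for a in ped.ids if a.startswith("S")]
        mean_ebv = ebv.table.loc[sires, "ebv"].mean()
        sd_ebv = ebv.table.loc[sires, "ebv"].std()
        assert abs(mean_ebv) < 0.5 * sd_ebv


class TestAccuracy:
    def test_boundary_values(self):
        assert accuracy_from_pev(1.0, 1.0) == (0.0, 0.0)
        assert accuracy_from_pev(0.0, 1.0) == (1.0, 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_pev(-0.1, 1.0)
        with pytest.raises(ValueError):
            accuracy_from_pev(0.1, 0.0)

    def test_accuracy_equals_sqrt_reliability_and_bounded(self):
        ped, rec = _sim(5, 6, seed=7)
        system = build_mme(rec, ModelSpec("y"), a_inverse(ped), 1.2, 2.8, ped.ids)
        _, ebv = solve_blup(system)
        t = ebv.table.dropna(subset=["pev"])
        assert ((t["reliability"] >= 0) & (t["reliability"] <= 1)).all()
        np.testing.assert_allclose(
            t["accuracy"], np.sqrt(t["reliability"]), atol=1e-12
        )

    def test_accuracy_increases_with_progeny_count(self):
        # unbalanced families mirroring the shipped design extremes
        counts = [7, 41, 120, 300, 628]
        ped = simulate_pedigree(
            SimDesign(n_sires=len(counts), progeny_per_sire=counts, seed=8)
        )
        rec = simulate_phenotypes(ped, single_trait_model(h2=0.25), seed=9).records
        system = build_mme(rec, ModelSpec("y"), a_inverse(ped), 1.0, 3.0, ped.ids)
        _, ebv = solve_blup(system, pev_for=[f"S00{i+1}" for i in range(5)])
        acc = ebv.table.loc[[f"S00{i+1}" for i in range(5)], "accuracy"].to_numpy()
        assert np.all(np.diff(acc) > 0)
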