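import numpy as np
import pandas as pd
import pytest

from sireval import (
    ModelSpec,
    PedigreeTable,
    SimDesign,
    TraitModel,
    simulate_pedigree,
    simulate_phenotypes,
    validate_and_sort,
)
from sireval.variance_components import RelationshipSpectrum


@pytest.fixture
def toy_pedigree():
    """Six animals with a sire-daughter mating: offspring F = 0.25."""
    df = pd.DataFrame(
        {
            "animal": ["A", "B", "C", "D", "E", "X"],
            "sire": ["0", "0", "A", "A", "C", "A"],
            "dam": ["0", "0", "B", "B", "D", "D"],
        }
    )
    return validate_and_sort(PedigreeTable(df))


@pytest.fixture
def halfsib_pedigree():
    """3 sires x 5 daughters, unique dams."""
    return simulate_pedigree(SimDesign(n_sires=3, progeny_per_sire=5, seed=1))


def single_trait_model(h2=0.25, sigma2_p=4.0):
    s2a = h2 * sigma2_p
    return TraitModel(
        trait_names=["y"], G=[[s2a]], E=[[sigma2_p - s2a]], overall_means=[10.0]
    )


@pytest.fixture(scope="session")
def recovery_design():
    """Shared 50-sire x 80-daughter half-sib design with its relationship
    spectrum (eigendecomposition reused across replicates and tests)."""
    ped = simulate_pedigree(SimDesign(n_sires=50, progeny_per_sire=80, seed=2024))
    model = single_trait_model(h2=0.25, sigma2_p=4.0)
    records = simulate_phenotypes(ped, model, seed=0).records
    spectrum = RelationshipSpectrum.from_pedigree(ped, records["animal"].tolist())
    return {"ped": ped, "spectrum": spectrum, "model": model}


def random_pedigree(rng, n):
    """Random acyclic pedigree: each animal's parents are earlier animals
    or unknown."""
    rows = []
    for i in range(n):
        ids = [f"A{j}" for j in range(i)]
        sire = rng.choice(ids) if i > 1 and rng.random() < 0.6 else "0"
        dam = rng.choice(ids) if i > 1 and rng.random() < 0.6 else "0"
        rows.append((f"A{i}", sire, dam))
    return validate_and_sort(
        PedigreeTable(pd.DataFrame(rows, columns=["animal", "sire", "dam"]))
    )


def gls_oracle(records, spec, A, ids, s2a, s2e):
    """Generalized-least-squares solution from the explicit marginal
    covariance V = Z A Z' s2a + I s2e; the independent check on BLUP."""
    from sireval.mixed_model import design_matrix

    recs = records.dropna(subset=[spec.response])
    pos = {a: i for i, a in enumerate(ids)}
    rows = [pos[a] for a in recs["animal"].astype(str)]
    n, q = len(recs), len(ids)
    Z = np.zeros((n, q))
    Z[np.arange(n), rows] = 1.0
    X, _ = design_matrix(recs, spec)
    y = recs[spec.response].to_numpy(dtype=float)
    V = Z @ A @ Z.T * s2a + np.eye(n) * s2e
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2a * A @ Z.T @ Vi @ (y - X @ beta)
    return beta, u


def gene_drop(ped, n_reps, seed):
    """Monte-Carlo relationship estimate: drop founder alleles through the
    pedigree and count identity by descent."""
    rng = np.random.default_rng(seed)
    sire, dam = ped.parent_indices()
    n = len(ped)
    alleles = np.zeros((n, 2, n_reps), dtype=np.int32)
    next_id = 0
    for i in range(n):
        for slot, parent in enumerate((sire[i], dam[i])):
            if parent < 0:
                alleles[i, slot] = next_id
                next_id += 1
            else:
                pick = rng.integers(0, 2, size=n_reps)
                alleles[i, slot] = alleles[parent, pick, np.arange(n_reps)]
    est = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = np.zeros(n_reps)
            for a in range(2):
                for b in range(2):
                    ibd += alleles[i, a] == alleles[j, b]
            if i == j:
                # a_ii = 1 + F = 1 + P(the two alleles of i are IBD)
                vals = 1.0 + (alleles[i, 0] == alleles[i, 1])
            else:
                vals = ibd / 2.0
            est[i, j] = est[j, i] = vals.mean()
            se[i, j] = se[j, i] = vals.std(ddof=1) / np.sqrt(n_reps)
    return est, se
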