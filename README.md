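# sireval

Pedigree-based genetic evaluation of progeny-tested breeding bulls:
animal-model BLUP, EM-REML variance components, and a multi-trait economic
selection index — with a half-sib progeny-test simulator so the whole
pipeline is testable against known truth.

## The problem

Dairy breeding programs rank candidate sires by the performance of their
daughters.  Each bull leaves a paternal half-sib family of daughters on
many farms; the analyst must separate a bull's transmitted genetic merit
from herd, parity and genotype-grade effects, quantify how much of the
phenotypic variation is heritable, and combine several economically
relevant traits into a single score for selecting the top fraction of
bulls.  `sireval` implements that workflow for unbalanced field data such
as a crossbred Holstein-Friesian × Local progeny-testing scheme (51 sires
in three HF-grade groups, thousands of daughter records, family sizes from
7 to 628).

## The model

For each trait the animal model is

```
y = Xb + Zu + e,   u ~ N(0, A σ²_A),   e ~ N(0, I σ²_E)
```

where `A` is the numerator relationship matrix built from the pedigree
(diagonal `1 + F`).  Henderson's mixed-model equations

```
[ X'X      X'Z          ] [ b̂ ]   [ X'y ]
[ Z'X  Z'Z + λ A⁻¹      ] [ û ] = [ Z'y ],   λ = σ²_E / σ²_A
```

give BLUP breeding values `û` (EBV), with `A⁻¹` assembled sparsely by
Henderson's rules and inbreeding from Meuwissen–Luo ancestor tracing.
Prediction-error variances from the inverse coefficient matrix yield
reliability `r² = 1 − PEV/σ²_A`, accuracy `r`, and the predicted
transmitting ability `PTA = EBV/2`.

Variance components are estimated by EM-REML (monotone in the restricted
likelihood), giving heritability `h² = σ²_A/σ²_P` with `σ²_P = σ²_A + σ²_E`;
bivariate fits estimate genetic and phenotypic correlations
`r_g = σ_a12/√(σ²_a1 σ²_a2)`.  The selection index follows Hazel:
coefficients `b = P⁻¹ G a` from the phenotypic (P) and genetic (G)
variance-covariance matrices and economic values `a`; each bull's score is
`I = Σ b_t X_t` over standardized EBVs `X`, and the top `ceil(0.2 n)` bulls
are selected.

## Worked example

```python
import numpy as np
from sireval import *

design = SimDesign(n_sires=30, progeny_per_sire=40, seed=42)
ped = simulate_pedigree(design)
model = TraitModel(trait_names=["DMY"], G=[[1.66]], E=[[5.32]], overall_means=[7.9])
sim = simulate_phenotypes(ped, model, seed=43)

vc = reml_single_trait(sim.records, ModelSpec("DMY"), ped=ped)
print(f"h2 = {vc.h2:.3f} +/- {vc.h2_se:.3f}")

system = build_mme(sim.records, ModelSpec("DMY"), a_inverse(ped),
                   vc.sigma2_a, vc.sigma2_e, ped.ids)
fixed, ebvs = solve_blup(system)
sires = sorted(set(sim.records["sire"]))
print(ebvs.table.loc[sires].nlargest(3, "ebv")[
    ["ebv", "pta", "accuracy", "n_progeny_records"]].round(3))
```

Output:

```
h2 = 0.232 +/- 0.082
          ebv    pta  accuracy  n_progeny_records
animal
S021    1.875  0.937     0.829                 40
S006    1.801  0.900     0.829                 40
S018    1.455  0.727     0.829                 40
```

The simulation truth was `h² = 1.66/(1.66+5.32) = 0.238`; REML recovers
0.232 ± 0.082 from 1,200 daughter records, and the 30 sires' EBVs correlate
0.88 with their true (simulated) breeding values.  Each daily-milk-yield
EBV is in l/day; the PTA is the expected deviation a bull transmits to his
daughters, and accuracy 0.83 reflects 40 daughters per bull at this
heritability.

The full pipeline (outlier screen → descriptives → LS-means → REML → BLUP →
correlations → index → ranking) runs from a config:

```
sireval all -c examples/crossbred.yaml -o crossbred_out
```

which writes `filter_summary.csv`, `descriptives.csv`, `lsmeans.csv`,
`variance_components.csv`, `correlations.csv`, `solutions_<trait>.csv`,
`ranking.csv` and a `run_log.yaml`, all byte-reproducible for a fixed seed.

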