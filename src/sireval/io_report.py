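"""Readers, writers, configuration and the end-to-end evaluation pipeline.

``run_pipeline`` ties the stages together in the order a progeny-test
evaluation runs them:

    outlier filter -> descriptives / LS-means -> per-trait EM-REML
    -> animal-model BLUP (EBV, PTA, accuracy) -> pairwise genetic
    correlations -> economic selection index -> ranking report

All inputs and outputs are plain CSV (plus a YAML config and run log), and a
fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from sireval import presets
from sireval.errors import SchemaError
from sireval.fixed_effects_glm import describe, ls_means, two_sd_filter
from sireval.mixed_model import ModelSpec, build_mme, solve_blup
from sireval.pedigree import (
    PedigreeTable,
    a_inverse,
    read_pedigree_csv,
    relationship_matrix,
    validate_and_sort,
    write_pedigree_csv,
)
from sireval.selection_index import build_index
from sireval.synthetic_data import simulate_pedigree, simulate_phenotypes
from sireval.variance_components import (
    RelationshipSpectrum,
    reml_bivariate,
    reml_single_trait,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "read_phenotypes",
    "write_phenotypes",
    "run_pipeline",
]

DEFAULT_PAIRS = [("DMY", "PMY"), ("DO", "CI"), ("AFC", "DMY")]


def read_phenotypes(path, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a daughter-record CSV.

    Expects an ``animal`` column; ``NA`` (or empty) trait cells are accepted
    and excluded from the analyses of that trait only.  A malformed row
    raises a parse error naming the line; a requested trait absent from the
    header raises :class:`SchemaError`.
    """
    try:
        df = pd.read_csv(
            path, na_values=["NA"], index_col=False, on_bad_lines="error"
        )
    except pd.errors.ParserError as exc:
        raise SchemaError(f"malformed phenotype file {path}: {exc}") from exc
    if "animal" not in df.columns:
        raise SchemaError(f"{path} lacks required column 'animal'")
    df["animal"] = df["animal"].astype(str)
    if traits is not None:
        missing = [t for t in traits if t not in df.columns]
        if missing:
            raise SchemaError(f"trait column(s) not in {path}: {missing}")
    return df


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, na_rep="NA")


@dataclass
class PipelineConfig:
    """Configuration of a full evaluation run.

    With no ``pedigree_path``/``phenotype_path`` the shipped crossbred
    half-sib design is simulated (51 sires, 4,319 daughters by default;
    scalable through ``n_sires`` / ``total_daughters``).
    """

    seed: int = 1
    output_dir: str = "sireval_out"
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    traits: list[str] = field(default_factory=lambda: list(presets.TRAITS))
    n_sires: int = presets.N_SIRES
    total_daughters: int = presets.N_DAUGHTERS
    apply_filter: bool = True
    filter_group: str = "grade"
    fixed_factors: list[str] = field(
        default_factory=lambda: ["grade", "parity", "location"]
    )
    lsmeans_factor: str = "grade"
    reml_tol: float = 1e-8
    reml_max_iter: int = 5000
    correlation_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_PAIRS]
    )
    index_weights: dict[str, float] = field(
        default_factory=lambda: dict(presets.ECONOMIC_WEIGHTS)
    )
    selection_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.selection_fraction <= 1:
            raise ValueError(
                f"selection_fraction must be in (0, 1], got {self.selection_fraction}"
            )
        self.correlation_pairs = [tuple(p) for p in self.correlation_pairs]
        for pair in self.correlation_pairs:
            for t in pair:
                if t not in self.traits:
                    raise ValueError(f"correlation pair trait {t!r} not in traits")
        # weights for traits outside the configured list are simply unused
        self.index_weights = {
            t: w for t, w in self.index_weights.items() if t in self.traits
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["correlation_pairs"] = [list(p) for p in self.correlation_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineReport:
    """Handles to everything a pipeline run produced."""

    config: PipelineConfig
    paths: dict[str, Path]
    variance_components: pd.DataFrame
    correlations: pd.DataFrame
    sire_evaluations: pd.DataFrame
    ranking: pd.DataFrame
    log: dict


def _load_or_simulate(config: PipelineConfig, outdir: Path):
    if config.phenotype_path and config.pedigree_path:
        ped = validate_and_sort(read_pedigree_csv(config.pedigree_path))
        records = read_phenotypes(config.phenotype_path, config.traits)
        return ped, records
    design = presets.crossbred_design(
        seed=config.seed,
        n_sires=config.n_sires,
        total_daughters=config.total_daughters,
    )
    model = presets.crossbred_trait_model()
    model = type(model)(
        trait_names=config.traits,
        G=_subset(model.G, model.trait_names, config.traits),
        E=_subset(model.E, model.trait_names, config.traits),
        overall_means=[
            model.overall_means[list(model.trait_names).index(t)]
            for t in config.traits
        ],
        fixed_effects={
            f: {lv: _subvec(eff, model.trait_names, config.traits)
                for lv, eff in levels.items()}
            for f, levels in model.fixed_effects.items()
        },
    )
    ped = simulate_pedigree(design)
    sim = simulate_phenotypes(ped, model, seed=config.seed + 1)
    write_pedigree_csv(ped, outdir / "pedigree.csv")
    write_phenotypes(sim.records, outdir / "phenotypes.csv")
    return ped, sim.records


def _subset(m, names, wanted):
    idx = [list(names).index(t) for t in wanted]
    return np.asarray(m)[np.ix_(idx, idx)]


def _subvec(v, names, wanted):
    v = np.atleast_1d(v)
    return [float(v[list(names).index(t)]) for t in wanted]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full evaluation and write all report files.

    Writes, under ``config.output_dir``: ``filter_summary.csv``,
    ``descriptives.csv``, ``lsmeans.csv``, ``variance_components.csv``,
    ``correlations.csv``, ``ranking.csv`` (plus ``solutions_<trait>.csv``,
    the simulated ``pedigree.csv``/``phenotypes.csv`` when no input paths
    were given, and ``run_log.yaml``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    log: dict = {"seed": config.seed, "stages": {}}

    try:
        ped, records = _load_or_simulate(config, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load': {exc}") from exc
    traits = config.traits
    analysis = records.copy()

    # ---- stage: two-SD filter (per trait within group) -------------------
    filter_rows = []
    if config.apply_filter:
        groups = (
            records[config.filter_group]
            if config.filter_group in records.columns
            else None
        )
        for trait in traits:
            kept, removed = two_sd_filter(records[trait], groups)
            analysis.loc[removed.index, trait] = np.nan
            filter_rows.append(
                {
                    "trait": trait,
                    "n_input": int(records[trait].notna().sum()),
                    "n_removed": len(removed),
                    "pct_removed": 100.0 * len(removed)
                    / max(int(records[trait].notna().sum()), 1),
                }
            )
    filter_summary = pd.DataFrame(
        filter_rows,
        columns=["trait", "n_input", "n_removed", "pct_removed"],
    )
    paths["filter_summary"] = outdir / "filter_summary.csv"
    filter_summary.to_csv(paths["filter_summary"], index=False)
    log["stages"]["filter"] = {
        "applied": config.apply_filter,
        "removed": {r["trait"]: int(r["n_removed"]) for r in filter_rows},
    }

    # ---- stage: descriptives + LS-means ----------------------------------
    group_col = (
        config.filter_group if config.filter_group in analysis.columns else None
    )
    desc = pd.concat(
        [describe(analysis, t, group_by=group_col) for t in traits],
        ignore_index=True,
    )
    paths["descriptives"] = outdir / "descriptives.csv"
    desc.to_csv(paths["descriptives"], index=False)

    ls_rows = []
    factors = [f for f in config.fixed_factors if f in analysis.columns]
    for trait in traits:
        try:
            lt = ls_means(
                analysis, ModelSpec(trait, factors), config.lsmeans_factor
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'lsmeans' ({trait}): {exc}") from exc
        tab = lt.table.copy()
        tab.insert(0, "trait", trait)
        tab["omnibus_p"] = lt.omnibus_p
        ls_rows.append(tab)
    lsmeans_df = pd.concat(ls_rows, ignore_index=True)
    paths["lsmeans"] = outdir / "lsmeans.csv"
    lsmeans_df.to_csv(paths["lsmeans"], index=False)

    # ---- stage: REML per trait -------------------------------------------
    rel = relationship_matrix(ped)
    spectra: dict[str, RelationshipSpectrum] = {}
    vc_rows = []
    vcs = {}
    for trait in traits:
        recs_t = analysis.dropna(subset=[trait])
        spectra[trait] = RelationshipSpectrum.from_matrix(
            rel, recs_t["animal"].tolist()
        )
        vc = reml_single_trait(
            analysis,
            ModelSpec(trait, factors),
            tol=config.reml_tol,
            max_iter=config.reml_max_iter,
            spectrum=spectra[trait],
        )
        vcs[trait] = vc
        vc_rows.append(vc.as_row())
    vc_df = pd.DataFrame(vc_rows)
    paths["variance_components"] = outdir / "variance_components.csv"
    vc_df.to_csv(paths["variance_components"], index=False)
    log["stages"]["reml"] = {
        t: {"iterations": vcs[t].n_iter, "converged": bool(vcs[t].converged)}
        for t in traits
    }

    # ---- stage: BLUP / PTA / accuracy ------------------------------------
    ainv = a_inverse(ped)
    sires = sorted(
        set(records["sire"].astype(str)) & set(ped.ids)
    ) if "sire" in records.columns else []
    ebv_cols = {}
    eval_rows: dict[str, dict] = {s: {"bull": s} for s in sires}
    for trait in traits:
        vc = vcs[trait]
        system = build_mme(
            analysis.dropna(subset=[trait]),
            ModelSpec(trait, factors),
            ainv,
            vc.sigma2_a,
            vc.sigma2_e,
            ped.ids,
        )
        _, ebvset = solve_blup(system, pev_for=sires or None)
        tab = ebvset.table
        ebv_cols[trait] = tab["ebv"]
        sol_path = outdir / f"solutions_{trait}.csv"
        tab.loc[sires].to_csv(sol_path, na_rep="NA")
        paths[f"solutions_{trait}"] = sol_path
        for s in sires:
            eval_rows[s][f"pta_{trait}"] = tab.at[s, "pta"]
            eval_rows[s][f"acc_{trait}"] = tab.at[s, "accuracy"]
            eval_rows[s]["n_progeny"] = int(tab.at[s, "n_progeny_records"])

    # ---- stage: pairwise genetic correlations ----------------------------
    corr_rows = []
    for ti, tj in config.correlation_pairs:
        sub = analysis.dropna(subset=[ti, tj])
        spectrum = RelationshipSpectrum.from_matrix(rel, sub["animal"].tolist())
        try:
            res = reml_bivariate(
                analysis,
                (ModelSpec(ti, factors), ModelSpec(tj, factors)),
                tol=config.reml_tol,
                max_iter=config.reml_max_iter,
                spectrum=spectrum,
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'correlate' ({ti},{tj}): {exc}"
            ) from exc
        c = res.correlation
        corr_rows.append(
            {
                "trait_i": ti,
                "trait_j": tj,
                "r_g": c.r_g,
                "r_g_se": c.r_g_se,
                "r_p": c.r_p,
                "r_p_se": c.r_p_se,
                "sigma_a_ij": c.sigma_a_ij,
                "n_records": res.components[0].n_records,
                "converged": res.converged,
            }
        )
    corr_df = pd.DataFrame(
        corr_rows,
        columns=[
            "trait_i", "trait_j", "r_g", "r_g_se", "r_p", "r_p_se",
            "sigma_a_ij", "n_records", "converged",
        ],
    )
    paths["correlations"] = outdir / "correlations.csv"
    corr_df.to_csv(paths["correlations"], index=False)

    # ---- stage: selection index + ranking --------------------------------
    eval_df = pd.DataFrame(list(eval_rows.values())).set_index("bull")
    ranking = pd.DataFrame()
    if sires:
        ebv_matrix = pd.DataFrame(
            {t: ebv_cols[t].loc[sires] for t in traits}
        )
        weights = [config.index_weights.get(t, 0.0) for t in traits]
        result = build_index(
            ebv_matrix, weights=weights, fraction=config.selection_fraction
        )
        ranking = result.ranking.copy()
        grade_map = (
            records.drop_duplicates("sire").set_index("sire")["grade"]
            if "grade" in records.columns
            else pd.Series(dtype=str)
        )
        ranking.insert(0, "grade", [grade_map.get(b, "-") for b in ranking.index])
        ranking = ranking.join(eval_df, how="left")
        cols = ["grade", "n_progeny", "index_value", "rank", "selected"] + [
            c for t in traits for c in (f"pta_{t}", f"acc_{t}")
        ]
        ranking = ranking[[c for c in cols if c in ranking.columns]]
        log["stages"]["index"] = {
            "n_bulls": len(ranking),
            "n_selected": int(ranking["selected"].sum()),
            "fraction": config.selection_fraction,
        }
    paths["ranking"] = outdir / "ranking.csv"
    ranking.to_csv(paths["ranking"], index_label="bull", na_rep="NA")

    log["versions"] = {"sireval": _version()}
    paths["run_log"] = outdir / "run_log.yaml"
    with open(paths["run_log"], "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)

    if config.phenotype_path is None:
        paths["pedigree"] = outdir / "pedigree.csv"
        paths["phenotypes"] = outdir / "phenotypes.csv"

    return PipelineReport(
        config=config,
        paths=paths,
        variance_components=vc_df,
        correlations=corr_df,
        sire_evaluations=eval_df,
        ranking=ranking,
        log=log,
    )


def _version() -> str:
    from sireval import __version__

    return __version__
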