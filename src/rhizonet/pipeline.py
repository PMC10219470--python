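"""End-to-end orchestration: one config, one seed, one output manifest.

``run_all`` executes the whole analysis — input (or synthesis), rarefaction,
diversity + ordination, biomarker discovery, per-group co-occurrence
networks with keystone classification, and the soil-association stage —
writing every stage's tables under a run directory with a JSON manifest at
its root.  The master seed spawns one child seed per stage through a fixed
counter-based derivation, so adding a stage never perturbs the draws of
earlier stages and identical configs yield byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, differential, diversity, environment, network, synth
from .io_tables import (
    SOIL_VARIABLES,
    aggregate_to_rank,
    read_count_table,
    read_sample_frame,
    read_taxonomy,
    soil_matrix,
    write_network,
)

# fixed per-stage counters for seed derivation; append-only
STAGE_COUNTERS = {
    "synth": 0, "rarefy": 1, "anosim": 2, "lefse": 3,
    "network_a": 4, "network_b": 5, "environment": 6,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed (< 2^31) for one named stage."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_COUNTERS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the field-standard defaults:
    rarefaction depth 30,815; LEfSe alpha 0.05 / LDA 3.0; network |rho| >
    0.6, p < 0.05, prevalence > 0.5; Zi/Pi cutoffs 2.5 / 0.62; VIF 10."""
    seed: int
    outdir: str | Path = "rhizonet_run"
    counts_path: str | Path | None = None
    taxonomy_path: str | Path | None = None
    samples_path: str | Path | None = None
    synth_preset: str | None = None          # "paper44" generates inputs
    synth_overrides: dict = field(default_factory=dict)
    rarefaction_depth: int = diversity.DEFAULT_RAREFACTION_DEPTH
    alpha: float = 0.05
    lda_threshold: float = 3.0
    lefse_ranks: tuple[str, ...] = ("phylum", "family", "genus")
    n_boot: int = 30
    rho_min: float = 0.6
    p_max: float = 0.05
    prevalence: float = 0.5
    vif_threshold: float = 10.0
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if self.synth_preset is None and self.counts_path is None:
            raise ValueError("either input paths or a synth preset is required")
        for name in ("rarefaction_depth", "alpha", "lda_threshold", "rho_min",
                     "p_max", "prevalence", "vif_threshold", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class _StageRunner:
    """Runs one named stage, collecting warnings and renaming failures."""

    def __init__(self) -> None:
        self.warnings: list[str] = []

    def __call__(self, name: str, fn):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        self.warnings.extend(f"{name}: {w.message}" for w in wlist)
        return result


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Stage failures abort with the stage name in the raised error; the
    soil-association stage is skipped with a manifest warning when the
    metadata carries no soil columns.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _StageRunner()
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(dataclasses.asdict(config)),
        "seeds": {s: stage_seed(config.seed, s) for s in STAGE_COUNTERS},
        "stages": {},
        "warnings": [],
    }

    # ---- inputs ----------------------------------------------------------
    def load_inputs():
        if config.synth_preset is not None:
            if config.synth_preset != "paper44":
                raise ValueError(f"unknown synth preset {config.synth_preset!r}")
            cfg = synth.paper44_config(stage_seed(config.seed, "synth"),
                                       **config.synth_overrides)
            counts, tax, meta, truth = synth.generate(cfg)
            synth.write_outputs(outdir / "synth", counts, tax, meta, truth)
            return counts, tax, meta
        counts = read_count_table(config.counts_path)
        tax = read_taxonomy(config.taxonomy_path)
        meta = read_sample_frame(config.samples_path)
        return counts, tax, meta

    counts, tax, meta = run("input", load_inputs)
    manifest["stages"]["input"] = {"n_samples": len(counts), "n_otus": counts.shape[1]}

    # ---- rarefaction -----------------------------------------------------
    rare = run("rarefy", lambda: diversity.rarefy(
        counts, depth=config.rarefaction_depth, seed=stage_seed(config.seed, "rarefy")))
    meta_r = meta.loc[rare.index]
    manifest["stages"]["rarefy"] = {
        "depth": config.rarefaction_depth,
        "n_samples_kept": len(rare),
        "dropped_samples": sorted(set(counts.index) - set(rare.index)),
    }

    # ---- diversity -------------------------------------------------------
    def diversity_stage():
        ddir = outdir / "diversity"
        ddir.mkdir(exist_ok=True)
        alpha = diversity.alpha_diversity(rare)
        alpha.to_csv(ddir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
        dm = diversity.bray_curtis(rare)
        dm.to_csv(ddir / "bray_curtis.tsv", sep="\t", index_label="sample_id")
        ord_res = diversity.pcoa(dm)
        ord_res.coordinates.to_csv(ddir / "pcoa_coordinates.tsv", sep="\t",
                                   index_label="sample_id")
        ano = diversity.anosim(dm, meta_r["group"], n_permutations=config.n_permutations,
                               seed=stage_seed(config.seed, "anosim"))
        (ddir / "anosim.json").write_text(json.dumps({
            "R": ano.r, "p_value": ano.p_value,
            "n_permutations": ano.n_permutations}, indent=2, sort_keys=True))
        return alpha, ord_res, ano

    alpha_df, ordination, ano = run("diversity", diversity_stage)
    manifest["stages"]["diversity"] = {
        "mean_richness": float(alpha_df["richness"].mean()),
        "mean_shannon": float(alpha_df["shannon"].mean()),
        "pcoa_explained_pct": [round(100 * v, 4) for v in ordination.explained[:2]],
        "anosim_R": ano.r, "anosim_p": ano.p_value,
    }

    # ---- biomarkers ------------------------------------------------------
    def lefse_stage():
        res = differential.run_lefse(
            rare, tax, meta_r, ranks=config.lefse_ranks, alpha=config.alpha,
            lda_threshold=config.lda_threshold, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "lefse"))
        ldir = outdir / "lefse"
        ldir.mkdir(exist_ok=True)
        res.table.to_csv(ldir / "biomarkers.tsv", sep="\t", index=False)
        return res

    lefse_res = run("lefse", lefse_stage)
    manifest["stages"]["lefse"] = {
        rank: int(((lefse_res.table["rank"] == rank) & lefse_res.table["passes"]).sum())
        for rank in config.lefse_ranks
    }

    # ---- per-group networks ---------------------------------------------
    groups = sorted(meta_r["group"].unique())
    ndir = outdir / "network"
    ndir.mkdir(exist_ok=True)
    reports: dict = {}

    def network_stage(label: str, seed_name: str):
        sub = rare.loc[meta_r.index[meta_r["group"] == label]]
        filt = network.prevalence_filter(sub, config.prevalence)
        net = network.build_network(filt, tax, rho_min=config.rho_min,
                                    p_max=config.p_max, group=label)
        modules, q = network.detect_modules(net, seed=stage_seed(config.seed, seed_name))
        roles = network.zi_pi(net, modules)
        roles["genus"] = [str(tax.loc[o, "genus"]) if o in tax.index else "unclassified"
                          for o in roles.index]
        roles["abundance"] = filt.div(filt.sum(axis=1), axis=0).mean(axis=0)
        topo = network.topology_summary(net, modules, q)
        report = network.keystone_taxa(roles, tax, filt, group=label)
        write_network(net, ndir / f"network_{label}.graphml")
        roles.to_csv(ndir / f"node_roles_{label}.tsv", sep="\t", index_label="otu")
        (ndir / f"topology_{label}.json").write_text(
            json.dumps(_jsonable(topo.to_dict()), indent=2, sort_keys=True))
        return topo, report

    for label, seed_name in zip(groups, ("network_a", "network_b")):
        topo, report = run(f"network[{label}]",
                           lambda label=label, seed_name=seed_name: network_stage(label, seed_name))
        reports[label] = report
        manifest["stages"][f"network[{label}]"] = {
            **_jsonable(topo.to_dict()),
            "keystone_count": len(report.table),
            "keystone_read_share_pct": round(100 * report.share, 4),
        }

    def comparison_stage():
        cmp_table = network.compare_keystones(
            reports[groups[0]], reports[groups[1]], rare, meta_r, alpha=config.alpha)
        if len(cmp_table):
            cmp_table.to_csv(ndir / "keystone_comparison.tsv", sep="\t", index_label="otu")
        else:
            cmp_table.to_csv(ndir / "keystone_comparison.tsv", sep="\t", index=False)
        return cmp_table

    cmp_table = run("keystone_comparison", comparison_stage)
    manifest["stages"]["keystone_comparison"] = {
        "n_tested": len(cmp_table),
        "n_significant": int(cmp_table["significant"].sum()) if len(cmp_table) else 0,
    }

    # ---- soil associations ----------------------------------------------
    soil_cols = [c for c in SOIL_VARIABLES if c in meta_r.columns]
    if not soil_cols:
        manifest["warnings"].append("environment stage skipped: no soil columns in metadata")
    else:
        def environment_stage():
            edir = outdir / "environment"
            edir.mkdir(exist_ok=True)
            soil = soil_matrix(meta_r)
            retained, droplist = environment.vif_screen(soil, config.vif_threshold)
            community = network.prevalence_filter(rare, config.prevalence)
            cca_res = environment.cca(community, soil[retained])
            cca_res.excluded_variables = droplist
            cca_res.site_scores.to_csv(edir / "cca_site_scores.tsv", sep="\t",
                                       index_label="sample_id")
            cca_res.species_scores.to_csv(edir / "cca_species_scores.tsv", sep="\t",
                                          index_label="taxon")
            cca_res.biplot_scores.to_csv(edir / "cca_biplot_scores.tsv", sep="\t",
                                         index_label="variable")
            terms = environment.permutation_test_terms(
                community, soil[retained], n_permutations=config.n_permutations,
                seed=stage_seed(config.seed, "environment"))
            terms.to_csv(edir / "cca_term_tests.tsv", sep="\t", index_label="variable")
            phylum_rel = differential.normalize_tss(
                aggregate_to_rank(rare, tax, "phylum"), scale=1.0)
            heat = environment.phylum_soil_heatmap(phylum_rel, soil, alpha=config.alpha)
            heat.rho.to_csv(edir / "phylum_soil_rho.tsv", sep="\t", index_label="phylum")
            heat.p.to_csv(edir / "phylum_soil_p.tsv", sep="\t", index_label="phylum")
            keystone_otus = sorted(set().union(*(reports[g].table.index for g in groups)))
            keystone_otus = [o for o in keystone_otus if o in rare.columns]
            rel = rare.div(rare.sum(axis=1), axis=0)
            response = rel[keystone_otus].sum(axis=1) if keystone_otus \
                else pd.Series(0.0, index=rare.index)
            imp = None
            if response.std() > 0:
                imp = environment.lmg_importance(response, soil)
                imp.shares.to_csv(edir / "lmg_importance.tsv", sep="\t",
                                  index_label="variable")
            return retained, droplist, cca_res, terms, heat, imp

        retained, droplist, cca_res, terms, heat, imp = run("environment", environment_stage)
        manifest["stages"]["environment"] = {
            "retained_variables": retained,
            "excluded_variables": [[n, round(v, 3) if np.isfinite(v) else "inf"]
                                   for n, v in droplist],
            "cca_axis_pct": [round(100 * v, 4) for v in cca_res.axis_fractions[:2]],
            "term_tests": {v: {"F": round(float(terms.loc[v, "F"]), 4),
                               "p": float(terms.loc[v, "p"])} for v in terms.index},
            "n_significant_phylum_soil_pairs": int(heat.significant.to_numpy().sum()),
            "lmg_shares": _jsonable({k: round(float(v), 6) for k, v in imp.shares.items()})
            if imp is not None else None,
            "lmg_r_squared": round(float(imp.r_squared), 6) if imp is not None else None,
        }

    manifest["warnings"].extend(run.warnings)
    (outdir / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return manifest
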