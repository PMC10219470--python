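"""Synthetic paired-design microbiome generator with planted ground truth.

Emulates a two-condition paired field survey: ``n_sites`` sites, each
contributing one rhizosphere sample per condition (invaded ``AP`` vs native
``N``), so 44 samples under the default 22-site design.  Counts follow a
logistic-normal -> multinomial model:

    z[s, i] = base[i] + site[site(s), i] + group_effect[g(s), i]
              + sum_m loading[i, m] * factor[s, m] + eps[s, i]
    counts[s] ~ Multinomial(depth[s], softmax(z[s]))

The latent-factor term is what a Dirichlet-multinomial cannot express: it
plants blocks of positively co-varying OTUs (network modules) and a
designated hub per block that tracks the block factor with little private
noise, so that downstream co-occurrence analysis has a known answer.
Soil variables are drawn around fixed means with linear couplings to phylum
relative abundances, and total nitrogen is derived almost deterministically
from total carbon and total phosphorus so that collinearity screening has a
genuine victim.

Every planted structure is returned in a :class:`GroundTruth` record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import (
    RANKS,
    UNCLASSIFIED,
    write_count_table,
    write_sample_frame,
    write_taxonomy,
)

LN2 = float(np.log(2.0))

# phylum pool loosely shaped like a temperate soil fungal survey
PHYLUM_POOL: tuple[str, ...] = (
    "Ascomycota", "Basidiomycota", "Mortierellomycota",
    "Glomeromycota", "Chytridiomycota", "Mucoromycota",
)
PHYLUM_WEIGHTS: tuple[float, ...] = (0.45, 0.25, 0.10, 0.06, 0.06, 0.08)


@dataclass(frozen=True)
class PlantedBiomarker:
    """A taxon with a planted between-group abundance shift.

    ``log2_fc`` is the planted log2 fold change of the enriched group over
    the other; ``group`` names the enriched condition.
    """
    otu: str
    genus: str
    log2_fc: float
    group: str


@dataclass(frozen=True)
class PlantedModule:
    """A block of OTUs sharing one latent factor, with an optional hub.

    ``loading`` is the members' loading on the block factor.  The hub (if
    set) gets ``loading * hub_loading_scale`` and private noise
    ``hub_noise_sd`` instead of the global ``noise_sd``, making it a
    high-fidelity proxy of the factor and therefore a candidate network hub.
    """
    members: tuple[str, ...]
    loading: float
    hub: str | None = None


@dataclass(frozen=True)
class SoilVariable:
    """One soil covariate: baseline mean/sd plus optional structure.

    ``couplings`` maps phylum name -> coefficient: the variable gains
    ``coef * zscore(phylum relative abundance)`` on top of its noise.
    ``derived_from`` maps other soil variable -> slope; a derived variable
    is a linear combination of already-drawn variables plus ``noise_sd``
    noise (used to plant collinearity).
    """
    name: str
    mean: float
    sd: float
    couplings: Mapping[str, float] = field(default_factory=dict)
    derived_from: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float | None = None


@dataclass
class SynthConfig:
    """Full generative description of one synthetic survey.

    The seed is mandatory: the generator is a reproducible experiment, not
    a stream of convenience randomness.
    """
    seed: int
    n_sites: int = 22
    n_otus: int = 300
    group_labels: tuple[str, str] = ("AP", "N")
    # per-sample sequencing depth ~ LogNormal(meanlog, sdlog), mean ~40k reads;
    # the spread is narrow so the survey-style rarefaction depth of 30,815
    # sits below essentially every sample, as in a design rarefied at the
    # minimum observed depth
    depth_meanlog: float = 10.5936
    depth_sdlog: float = 0.08
    # latent log-abundance model
    base_mean: float = 0.0
    base_sd: float = 2.0
    noise_sd: float = 1.0
    site_sd: float = 0.5
    # planted taxa are drawn from the abundant tail so they are observable
    planted_base_mean: float = 1.3
    planted_base_sd: float = 0.25
    hub_loading_scale: float = 2.0
    hub_noise_sd: float = 0.25
    biomarkers: tuple[PlantedBiomarker, ...] = ()
    modules: tuple[PlantedModule, ...] = ()
    soil: tuple[SoilVariable, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SynthConfig.seed is mandatory")
        for b in self.biomarkers:
            if not np.isfinite(b.log2_fc):
                raise ValueError(f"non-finite fold change for {b.otu}")
            if b.group not in self.group_labels:
                raise ValueError(f"biomarker group {b.group!r} not in {self.group_labels}")
        seen: set[str] = set()
        for m in self.modules:
            if len(m.members) > self.n_otus:
                raise ValueError("module size exceeds n_otus")
            overlap = seen.intersection(m.members)
            if overlap:
                raise ValueError(f"module memberships overlap: {sorted(overlap)}")
            seen.update(m.members)


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset."""
    biomarkers: list[PlantedBiomarker]
    modules: dict[str, list[str]]
    hubs: list[str]
    soil_couplings: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "biomarkers": [dataclasses.asdict(b) for b in self.biomarkers],
            "modules": self.modules,
            "hubs": self.hubs,
            "soil_couplings": self.soil_couplings,
        }


def _otu_ids(n: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def default_soil_model() -> tuple[SoilVariable, ...]:
    """Soil covariates with couplings mirroring common field observations:
    total carbon tracks Ascomycota and opposes Basidiomycota/Glomeromycota;
    phosphorus pools oppose Basidiomycota; total nitrogen is almost a linear
    function of TC and TP (so it is the collinear variable a VIF screen at
    threshold 10 should discard)."""
    return (
        SoilVariable("pH", 7.8, 0.30),
        SoilVariable("TC", 18.0, 3.0, couplings={
            "Ascomycota": 2.0, "Basidiomycota": -1.5, "Glomeromycota": -0.8}),
        SoilVariable("TN", 1.6, 0.0, derived_from={"TC": 0.08, "TP": 0.30}, noise_sd=0.05),
        SoilVariable("TP", 0.70, 0.15, couplings={"Basidiomycota": -0.08}),
        SoilVariable("AN", 12.0, 3.0),
        SoilVariable("NN", 8.0, 2.5),
        SoilVariable("AP", 40.0, 12.0, couplings={"Basidiomycota": -6.0, "Chytridiomycota": 4.0}),
    )


def paper44_config(seed: int, **overrides) -> SynthConfig:
    """The default survey: 22 sites x 2 conditions, 300 OTUs, five planted
    genus-level biomarkers at 8-fold change (three enriched in the invaded
    condition, two in the native), three 31-OTU correlated blocks each with
    one hub, and the coupled soil model."""
    otus = _otu_ids(overrides.get("n_otus", 300))
    biomarker_genera = [
        ("Dioszegia", 3.0, "AP"), ("Tilletiopsis", 3.0, "AP"), ("Colacogloea", 3.0, "AP"),
        ("Alternaria", 3.0, "N"), ("Phaeosphaeria", 3.0, "N"),
    ]
    biomarkers = tuple(
        PlantedBiomarker(otu=otus[i], genus=g, log2_fc=fc, group=grp)
        for i, (g, fc, grp) in enumerate(biomarker_genera)
    )
    modules = []
    start = len(biomarkers)
    for _ in range(3):
        members = tuple(otus[start:start + 31])
        modules.append(PlantedModule(members=members, loading=1.1, hub=members[0]))
        start += 31
    cfg = dict(
        seed=seed,
        biomarkers=biomarkers,
        modules=tuple(modules),
        soil=default_soil_model(),
    )
    cfg.update(overrides)
    return SynthConfig(**cfg)


def null_config(config: SynthConfig) -> SynthConfig:
    """Zero every planted effect, keeping sizes and depths.

    Fold changes and factor loadings are set to zero, soil couplings are
    removed, and the shared site intercept is dropped so that samples are
    fully exchangeable across condition labels (the property type-I-error
    studies need).
    """
    return dataclasses.replace(
        config,
        biomarkers=tuple(dataclasses.replace(b, log2_fc=0.0) for b in config.biomarkers),
        modules=tuple(dataclasses.replace(m, loading=0.0) for m in config.modules),
        soil=tuple(dataclasses.replace(v, couplings={}) for v in config.soil),
        site_sd=0.0,
    )


def _make_taxonomy(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic fungal taxonomy: biomarker OTUs carry their planted genus;
    the rest draw a phylum from the pool and a family/genus from per-phylum
    pools, with a fraction left unclassified at genus or family level to
    exercise composite-label aggregation."""
    otus = _otu_ids(config.n_otus)
    planted_genus = {b.otu: b.genus for b in config.biomarkers}
    n_families, n_genera = 40, 90
    fam_phylum = rng.choice(len(PHYLUM_POOL), size=n_families, p=PHYLUM_WEIGHTS)
    genus_family = rng.integers(0, n_families, size=n_genera)
    rows = {}
    for otu in otus:
        g = int(rng.integers(0, n_genera))
        f = int(genus_family[g])
        phylum = PHYLUM_POOL[fam_phylum[f]]
        lineage = {
            "kingdom": "Fungi",
            "phylum": phylum,
            "class": f"{phylum[:-4]}cetes",
            "order": f"Order{f % 20:02d}",
            "family": f"Family{f:02d}",
            "genus": f"Genus{g:02d}",
        }
        u = rng.random()
        if otu in planted_genus:
            lineage["genus"] = planted_genus[otu]
        elif u < 0.10:          # unresolved below order
            lineage["family"] = UNCLASSIFIED
            lineage["genus"] = UNCLASSIFIED
        elif u < 0.30:          # unresolved at genus
            lineage["genus"] = UNCLASSIFIED
        rows[otu] = lineage
    tax = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    tax.index.name = "otu_id"
    return tax


def generate(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one dataset: (counts, taxonomy, sample frame, ground truth).

    Counts are samples x OTUs; row sums equal the drawn per-sample depths.
    Identical configs (same seed) produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = 2 * config.n_sites
    otus = _otu_ids(config.n_otus)
    otu_index = {o: i for i, o in enumerate(otus)}

    tax = _make_taxonomy(config, rng)

    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    sample_ids, groups, site_of = [], [], []
    for s in sites:
        for g in config.group_labels:
            sample_ids.append(f"{s}_{g}")
            groups.append(g)
            site_of.append(s)

    planted = {b.otu for b in config.biomarkers}
    for m in config.modules:
        planted.update(m.members)
    base = rng.normal(config.base_mean, config.base_sd, size=config.n_otus)
    for o in planted:
        base[otu_index[o]] = rng.normal(config.planted_base_mean, config.planted_base_sd)

    # group effect: +/- half the planted log-fold-change
    group_eff = np.zeros((2, config.n_otus))
    for b in config.biomarkers:
        delta = b.log2_fc * LN2
        enriched = config.group_labels.index(b.group)
        group_eff[enriched, otu_index[b.otu]] += delta / 2.0
        group_eff[1 - enriched, otu_index[b.otu]] -= delta / 2.0

    site_eff = rng.normal(0.0, config.site_sd, size=(config.n_sites, config.n_otus)) \
        if config.site_sd > 0 else np.zeros((config.n_sites, config.n_otus))

    # factor scores are standardized within each condition group so the
    # planted correlation strength is realized in every finite dataset
    # (per-group networks see exactly the configured block structure, not a
    # random rescaling of it by the luck of 22 draws)
    factors = rng.normal(size=(n_samples, len(config.modules)))
    if len(config.modules):
        grp = np.array([g for g in groups])
        for lab in config.group_labels:
            mask = grp == lab
            sub = factors[mask]
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
            factors[mask] = (sub - sub.mean(axis=0)) / sd
    loadings = np.zeros((config.n_otus, len(config.modules)))
    noise_sd = np.full(config.n_otus, config.noise_sd)
    for m_idx, mod in enumerate(config.modules):
        for o in mod.members:
            loadings[otu_index[o], m_idx] = mod.loading
        if mod.hub is not None:
            loadings[otu_index[mod.hub], m_idx] = mod.loading * config.hub_loading_scale
            noise_sd[otu_index[mod.hub]] = config.hub_noise_sd

    eps = rng.normal(size=(n_samples, config.n_otus)) * noise_sd

    z = base[None, :] + eps + factors @ loadings.T
    group_row = np.array([config.group_labels.index(g) for g in groups])
    site_row = np.array([sites.index(s) for s in site_of])
    z += group_eff[group_row, :] + site_eff[site_row, :]

    # softmax per sample -> composition; multinomial at the drawn depth
    z -= z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = np.maximum(np.round(rng.lognormal(config.depth_meanlog, config.depth_sdlog,
                                               size=n_samples)).astype(np.int64), 1)
    counts = np.vstack([rng.multinomial(int(depths[s]), comp[s]) for s in range(n_samples)])
    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=otus)

    meta = pd.DataFrame({"group": groups, "site": site_of},
                        index=pd.Index(sample_ids, name="sample_id"))

    # soil: baseline + phylum couplings; derived variables after their parents
    rel = counts / counts.sum(axis=1, keepdims=True)
    phylum_rel = pd.DataFrame(rel, columns=otus).T.groupby(tax["phylum"]).sum().T
    soil_cols: dict[str, np.ndarray] = {}
    for var in config.soil:              # baselines first: parents of derived vars
        if var.derived_from:
            continue
        vals = var.mean + rng.normal(0.0, var.sd, size=n_samples)
        for phylum, coef in var.couplings.items():
            if phylum in phylum_rel.columns:
                x = phylum_rel[phylum].to_numpy()
                sd = x.std()
                if sd > 0:
                    vals = vals + coef * (x - x.mean()) / sd
        soil_cols[var.name] = vals
    for var in config.soil:
        if not var.derived_from:
            continue
        vals = np.full(n_samples, var.mean)
        for parent, slope in var.derived_from.items():
            parent_var = next(v for v in config.soil if v.name == parent)
            vals = vals + slope * (soil_cols[parent] - parent_var.mean)
        vals = vals + rng.normal(0.0, var.noise_sd or 0.0, size=n_samples)
        soil_cols[var.name] = vals
    for var in config.soil:
        meta[var.name] = np.round(soil_cols[var.name], 4)

    truth = GroundTruth(
        biomarkers=list(config.biomarkers),
        modules={f"M{i + 1}": list(m.members) for i, m in enumerate(config.modules)},
        hubs=[m.hub for m in config.modules if m.hub is not None],
        soil_couplings={v.name: dict(v.couplings) for v in config.soil if v.couplings},
    )
    return counts_df, tax, meta, truth


def generate_null(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate from the effect-free version of ``config`` (see :func:`null_config`)."""
    return generate(null_config(config))


def write_outputs(outdir: str | Path, counts: pd.DataFrame, tax: pd.DataFrame,
                  meta: pd.DataFrame, truth: GroundTruth) -> dict[str, Path]:
    """Write the three TSVs plus the ground-truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "samples": outdir / "samples.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_count_table(counts, paths["counts"])
    write_taxonomy(tax, paths["taxonomy"])
    write_sample_frame(meta, paths["samples"])
    paths["ground_truth"].write_text(json.dumps(truth.to_dict(), indent=2))
    return paths
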