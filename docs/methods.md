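# Methods

## Scope and data model

The pipeline analyzes a paired two-condition microbiome survey: each site
contributes one sample per condition, stored as a samples × OTUs integer
count table, a rank-prefixed taxonomy (kingdom…genus; genus is treated as
the deepest rank since deeper levels rarely survive ITS classification),
and per-sample metadata with a condition label, a site identifier, and
seven soil variables (pH, TC, TN, TP, AN, NN, AP). TSV is the canonical
on-disk format; networks round-trip through GraphML or CSV edge lists.

Aggregation to higher ranks conserves the grand total. An OTU unclassified
at the target rank contributes to a composite column named after its
deepest classified ancestor (`f_unclassified_o__Tremellales` for an OTU
resolved to order but not family), so unclassified mass is kept distinct
per clade rather than pooled into one bucket.

## Synthetic survey generator

The generator is a logistic-normal → multinomial model. For sample *s* and
OTU *i*,

    z[s,i] = base[i] + site[site(s),i] + group[g(s),i]
             + Σ_m loading[i,m]·factor[s,m] + ε[s,i],

relative abundances are `softmax(z[s])`, and counts are a multinomial draw
at the sample's sequencing depth. A Dirichlet-multinomial cannot express
arbitrary positive/negative dependence between taxa; the latent factors
can, which is why this parameterization was chosen.

Defaults (the survey conditions; all overridable in `SynthConfig`):

| parameter | default | rationale |
|---|---|---|
| sites × conditions | 22 × 2 = 44 samples | the paired field design emulated |
| OTUs | 300 | desk-scale community with a realistic abundant tail |
| base log-abundance | N(0, 2) | log-normal rank-abundance curve, ~2 orders of magnitude spread |
| site intercept sd | 0.5 per OTU | pairing: shared deviation between a site's two samples |
| residual noise sd | 1.0 | per-sample, per-OTU log-scale variation |
| depth | LogNormal, mean ≈ 40,000, sdlog 0.08 | narrow spread so the conventional rarefaction depth of 30,815 sits below essentially every sample, as in a survey rarefied at its minimum observed depth |
| planted biomarkers | 5 genera at log2FC = 3 (three up in "AP", two in "N") | 8-fold shifts applied ± half to each condition |
| planted modules | 3 blocks × 31 OTUs, member loading 1.1 | within-block latent correlation ≈ 0.55, straddling the 0.6 edge threshold |
| hub per block | loading × 2, private noise 0.25 | a high-fidelity proxy of the block factor, hence the block's most connected node |
| planted base | N(1.3, 0.25) | planted taxa live in the abundant, well-quantified tail |
| soil model | couplings of TC/TP/AP to phyla; TN ≈ 0.08·TC + 0.30·TP + N(0, 0.05) | realistic chemistry signs; TN is the near-collinear variable a VIF-10 screen should discard |

Factor scores are standardized within each condition group. Without this,
the sampling variance of 22 factor draws rescales every within-block
correlation coherently, so whole datasets swing between "block saturated"
and "block invisible"; standardization makes the planted correlation
strength a property of every realized dataset, which is what planted
ground truth is for.

`generate_null` zeroes fold changes, loadings, couplings **and** the site
intercept, giving samples fully exchangeable across condition labels — the
premise of the type-I-error calibrations.

What the generator does **not** emulate: sequencing error and chimeras,
overdispersion beyond the logistic-normal layer, phylogenetic correlation
among taxa, spatial autocorrelation among sites, and any relationship
between taxonomy and correlation structure. Passing tests therefore show
the statistics are computed correctly and recover planted structure of the
stated strength — not that field data meet these assumptions.

## Stage-by-stage choices

**Rarefaction** subsamples without replacement to depth 30,815 (default)
with a single seeded draw, dropping and naming shallower samples. Each
rarefied count is then multivariate-hypergeometric, which the tests exploit
via the closed-form expected richness Σ_i [1 − C(N−n_i, d)/C(N, d)].

**Alpha/beta diversity.** Shannon uses the natural log (the dominant
convention in the R ecosystem these surveys use). Bray–Curtis is
Σ|x−y| / Σ(x+y). PCoA double-centers −d²/2 (Gower); negative eigenvalues —
possible for semi-metric dissimilarities — are reported but excluded from
the explained-variance denominator, and no Lingoes/Cailliez correction is
applied. ANOSIM is rank-based with average ranks on ties; the permutation
p counts ties as exceedances and adds one to numerator and denominator
(the standard conservative choice). Default 999 permutations, so the
smallest attainable p is 0.001. Alpha diversity and everything downstream
run on the rarefied table.

**LDA effect size.** Two classes, no subclass stratum (the subclass
Wilcoxon stage of the original procedure is degenerate with one stratum
and is omitted). After total-sum scaling to 1e6, taxa passing the
Kruskal–Wallis screen (α = 0.05) are scored over 30 bootstrap resamples
(2/3 of each class, with replacement): a pooled-covariance linear
discriminant with ridge 1e-6 (features can outnumber samples) is fitted,
its direction scaled to unit norm, and the per-feature effect is
0.5·(|w_j·Δ_j| + |Δ_j|) with Δ the class-mean difference; the score is
log10(1 + mean effect). The published procedure's effect formula is
under-documented, so this definition is fixed here as the package's own;
it is validated by planted-truth recovery and monotonicity, not numerical
identity with any historical implementation. Sample and feature order are
canonicalized internally so scores do not depend on table arrangement.

**Networks** are built per condition. Prevalence is strict (>50%:
23/44 passes, 22/44 does not). Edges need |ρ| > 0.6 (the absolute value —
such networks contain negative, competitive links) and two-sided p < 0.05
by the t-approximation; edge p-values are not multiplicity-corrected by
default (BH is available behind a flag). Modules come from seeded Louvain
modularity maximization on the unweighted graph; Q is recomputed
independently from Σ_m (e_m/E − (d_m/2E)²). Zi uses the population
standard deviation (a `use_sample_sd` flag switches), with Zi = 0 when a
module's within-degrees are constant; Pi = 0 for isolated nodes. Exact
threshold values fall to the lower role, so the four roles partition the
plane; connector additionally requires Zi ≤ 2.5 so kinless hubs remain
distinct. Topology counts non-isolated nodes, and the average path length
is over the largest connected component only — thresholded correlation
graphs are fragmented. The keystone set (non-peripherals) is compared
between conditions by two-sided Wilcoxon rank-sum on relative abundances
with Benjamini–Hochberg adjustment.

**Soil association.** VIF screening iteratively removes the predictor with
the largest 1/(1−R²) until all are ≤ 10, ties broken toward the later
column. CCA chi-square-standardizes the community table, regresses it
(row-weighted) on the standardized retained variables, and reads the
constrained axes from the SVD of the fitted matrix; axis percentages are
eigenvalue / total inertia, and total inertia equals the table's chi-square
statistic over the grand total (asserted in tests). Scores use
species-focused (type 2) scaling. The per-variable test is marginal — each
variable alone — with F = λ_v / ((total − λ_v)/(n − 2)) and free
permutation of community rows (the design gives no blocking restriction).
The importance analysis is LMG decomposition of the linear-model R² (exact
subset enumeration, ≤ 10 predictors) for the per-sample summed keystone
relative abundance; a random-forest importance is available as an optional
cross-check. The community matrix entering CCA is the prevalence-filtered
rarefied OTU table (configurable).

**Pipeline.** The master seed spawns per-stage child seeds through fixed
`SeedSequence` spawn keys (append-only counters), so adding a stage never
perturbs earlier stages and a fixed config yields byte-identical outputs.
Stage warnings (dropped samples, skipped pairs) are collected
machine-readably in the manifest; a metadata file without soil columns
skips the soil stage with a warning instead of failing the run.

## Problem sizes used in verification

Oracle tests run at enumeration scale (≤ 30-node graphs, 6-sample ANOSIM,
3-predictor LMG, 6×5 CCA fixtures). Calibration tests use 1,000 null
ANOSIM simulations (999 permutations each), 500 null CCA permutation tests
(199 permutations), 2,000 rarefaction draws, and 50 generator seeds for
biomarker recovery; the end-to-end determinism check runs the full
pipeline twice on a 150-OTU survey. These sizes make the whole suite run
in about a minute while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

- With 22 samples per condition and a hard |ρ| > 0.6 edge rule, a planted
  hub's within-module degree z-score is structurally capped near
  √(M−1) for detected module size M; per-hub keystone recovery plateaus
  around 70–80% however strong the planted loading, because hub–member
  correlation can never exceed the member–factor correlation. Keystone
  recovery is therefore verified on a well-powered design (40 sites) and,
  at survey scale, at the dataset level (at least one planted hub
  recovered).
- Only the five planted genera differ between conditions by default, so
  whole-community separation (ANOSIM R) in synthetic surveys is small —
  unlike field invasions, which shift many taxa at once.
- Compositional closure induces weak spurious correlation among abundant
  taxa; at n = 22 the ρ-threshold admits a background of such edges, which
  is realistic for this network methodology but means edge lists are not
  pure planted signal.
- The LDA effect size is this package's fixed definition (see above);
  absolute scores are comparable within analyses run by this package, not
  across tools.
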