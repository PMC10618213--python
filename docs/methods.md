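# Methods

## Endemism metrics

A phylogeny is rooted, with non-negative branch lengths and polytomies
permitted; the root carries no branch (any stem length on the root is
ignored in totals, since a root branch would span the full species set
and has no defined complement). For branch *b* with length *L_b*, the
branch's geographic range *R_b* is the number of analysed grid cells
holding at least one descendant tip — so a tip branch's range is that
species' range and an internal branch's range is the union of its
children's. Phylogenetic endemism is

PE(c) = Σ_{b ∋ c} L_b / R_b,

optionally divided by total tree length (`scaled=True`, the default in
the pipeline) so that PE is the proportion of the tree restricted to the
cell. Two exact identities are enforced by tests: summing unscaled PE
over cells returns the total length of branches with any gridded
descendant (each branch contributes L_b/R_b in exactly R_b cells), and
scaled PE sums to 1 when every branch has gridded descendants.

The comparison tree for RPE keeps topology and total length but gives
every branch the same length (total / branch count). Preserving total
length puts PE_original and PE_equal on one scale, making
RPE = PE_original/PE_equal a pure branch-length-shape ratio that equals
1 identically on an already-equal-branch-length tree. Zero-length
branches are legal and contribute nothing; cells whose comparison-tree
PE is zero have undefined RPE and are excluded from classification.

Cells with fewer than 5 species are removed before any metric is
computed (configurable); branch ranges are therefore post-filter counts.
Species present in the tree but not the grid (or vice versa) are
intersected away with a warning, and the filter is re-applied to the
tree because dropping cells can orphan species.

## Randomization null and CANAPE

The null shuffles the mapping of species to tips, leaving the grid
untouched: topology, the multiset of branch lengths, per-cell richness
and per-species range sizes are all preserved exactly. Implementation:
the branch × species descendant-tip incidence matrix is computed once,
and a tip shuffle is a column permutation, so each of the default 999
iterations costs one matrix product; a test pins this fast path to the
naive shuffle-and-recompute route. One-tailed rates use the add-one
convention p = (1 + #{null ≥ observed}) / (n_iter + 1); numerical ties
(relative tolerance 1e-9) count toward both tails, which is conservative
and makes a shuffle-invariant input (e.g. an equal-branch star tree)
exactly non-significant.

Classification at α = 0.05: a cell is an endemism candidate if
PE_original **or** PE_equal exceeds its 97.5% null quantile; candidates
are paleo if RPE is above its 97.5% quantile, neo if below the 2.5%
quantile, otherwise mixed. A `strict_mixed` variant additionally
requires both PE metrics significant for the mixed label. Neo, paleo and
mixed cells are the hotspots. Reported percentages round half away from
zero to one decimal, matching how such tables are conventionally
printed; the raw fractions are always retained.

## Driver models

The response is log10 of scaled PE; cells with PE = 0 cannot be
log-transformed and carry no endemism signal, so they are dropped (and
counted). Predictors (current MAT and AP, LGM and Miocene anomalies
defined as past − present, elevation range) are z-standardized with the
n−1 denominator so slopes are comparable; VIF = 1/(1−R²) flags
collinearity (perfect collinearity yields inf, not an exception).

The SAR error model y = Xβ + u, u = λWu + ε is fitted by maximum
likelihood with λ profiled out: at each candidate λ the GLS coefficients
and variance have closed forms, and log|I − λW| is computed exactly from
the (possibly complex) eigenvalues of W — exact and affordable up to a
few thousand cells, which is this package's intended scale. W is
row-standardized k-nearest-neighbour (planar distance, asymmetry
allowed, ties broken by stable k-d-tree order); k is scanned (default
1–8 in the pipeline) and chosen by AIC. β standard errors are asymptotic
normal from the information matrix conditional on λ̂; the λ standard
error comes from the numeric curvature of the profile likelihood.
AIC/BIC count coefficients + σ² (+ λ for the SAR) so OLS and SAR are
compared on one footing, and Nagelkerke pseudo-R² =
1 − exp((2/n)(ℓ₀ − ℓ)) uses the intercept-only non-spatial model as ℓ₀.
Two residual vectors are exposed: the structured u = y − Xβ̂ and the
whitened innovation (I − λ̂W)u; Moran's *I* diagnostics (analytic normal
approximation, optional permutation; distance-bin correlogram) are run
on the innovations, which should be white when the model holds.
Recovery experiments (n = 500 lattice, λ = 0.7) show |mean λ̂ bias|
< 0.01, 92–95% CI coverage, universal AIC preference over OLS, and
non-significant residual SAC in ≥ 90% of replicates.

## Permutation tests

The Fisher–Pitman statistic is the raw sum of one group (two-sample) or
the between-group sum of squares (k-sample; for k = 2 a monotone
transform of the two-sample statistic, and tested to give identical
exact p-values). Exact enumeration of all label partitions is used
automatically when their number is at most 50,000; otherwise a seeded
Monte-Carlo sample with the add-one correction. Defaults to 10,000
permutations (configurable — figure-quality runs often use 100,000).
Post-hoc pairwise comparisons adjust by single-step max-T against the
joint permutation distribution of the maximum standardized pairwise
statistic (the permutation analogue of Tukey's familywise control);
Holm is available as a deterministic fallback. The compact letter
display assigns letters from the maximal cliques of the
not-significantly-different graph, so two groups share a letter iff
their adjusted difference is non-significant.

Permutation tests assume exchangeability. Spatially clustered groups on
an autocorrelated surface violate it and genuinely inflate the variance
of group means; the test-suite calibration checks therefore use
scattered cell sets, while planted-block contrasts are validated by
direction and magnitude.

## Protection accounting

A protection scheme is a binary per-cell flag: either an any-overlap
existing-PA mask (upstream filtering rules are provenance metadata, not
behaviour) or the best-ranked ⌈k·n⌉ cells of a priority ordering
(top 17/30/50% correspond to the CBD-2020, 30×30 and Half-Earth
targets; nested by construction). Coverage is reported per hotspot
class — A-only, B-only, joint, non-hotspot — always with its
denominators; empty classes are undefined (NaN), never dropped.

## Synthetic scenarios

The generator's defaults define the demo study conditions: an 18×14
unit lattice (252 cells), 140 species (104 wide-ranging background + 36
planted endemics), birth–death base phylogeny (birth 1.0, death 0.3),
three 3×3 refugium blocks. Planted structure is explicit by grafting
onto the ultrametric base tree: paleo lineages are single tips attached
near the root (attachment ~5% of tree height, i.e. near-height isolated
pendant branches), neo lineages form a short-stemmed caterpillar
radiation (crown 3%, stem 8% of height) grafted onto a background
pendant edge, and the mixed block combines mid-depth grafts (~40%
height) with a radiation (60% of its species) — mid-depth attachment was
chosen because near-root grafts tip the block's RPE into the paleo tail
rather than leaving it non-extreme. Ranges grow by a rook-adjacency
spreading dye: background species draw lognormal target sizes
(median 14 cells, σ = 1) from clade-clustered seed cells (top-level
clades get centroids; seeds scatter with sd 5 cells), planted species
are confined to their block with 3–6-cell ranges — the lower bound
keeps within-block co-occurrence high enough for the mixed signature.
Environmental layers are unit-variance Gaussian random fields
(white noise smoothed with a Gaussian kernel, correlation
exp(−h²/4s²), s = 2 cells) mapped to natural scales; planted cells get
mean offsets in spatial-sd units (+1 for MAT/AP/elevation range,
anomalies pulled 0.8 sd toward zero, +0.75 for human modification and
future anomalies). Protection: the existing-PA mask protects the top
10% of an independent smooth surface; the priority score adds 2 sd on
planted cells before ranking, from which the nested top-k masks are cut.
All draws derive from one master seed via spawned seed sequences.

With these defaults the full pipeline recovers ≥ 1 correctly classified
cell of every planted type in ≥ 90% of seeds at 999 iterations (10/10
in the acceptance run). What the generator does *not* emulate: real
range-size/phylogeny correlation structure, anisotropy, climate-range
covariation, observation error and spatially varying sampling effort —
so passing tests demonstrate the machinery and its statistical
calibration, not field-data performance.

## Problem sizes and numerics

Default analysis sizes (252-cell scenario, 999 iterations, 100-replicate
recovery experiments, 1,000-replicate calibration at 2,000 permutations)
were chosen so the whole suite and the acceptance script each run in
well under a minute on one core while leaving every statistical check
properly powered; all are parameters, not limits. Tie detection in the
null uses relative tolerance 1e-9; the λ search is bounded inside the
admissible interval set by the extreme real eigenvalues of W with xatol
1e-8; distance ties in k-NN weights and rank ties in priority masks are
resolved by stable order and logged.
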