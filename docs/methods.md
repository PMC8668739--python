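# Methods

This note records the exact model, its parameters and defaults, the scope
of the synthetic-data generator, and the numerical choices made in the
implementation, so that results can be interpreted and the code audited
without reverse-engineering.

## Distribution models

**Model.** For each species, the relative occurrence rate over the
landscape is modeled as proportional to `exp(f(x))` with `f` a linear
combination of feature transforms of the environmental covariates — the
presence-background exponential (Gibbs) model. Fitting minimizes the
penalized negative log-likelihood

```
-mean_presence(Fβ) + log Σ_background exp(Fβ) − log n_bg + Σ_j λ_j |β_j|
```

on features standardized to mean 0, sd 1 over the combined
presence+background sample.

**Feature classes.** Linear (L), quadratic (Q) and hinge (H), combined as
LQH / LQ / QH / L / Q / H. Hinge knots sit at `m` equally spaced quantiles
`(i+1)/(m+1)` of each covariate (default `m = 10`; the end-to-end tests use
6 for speed), with forward hinges `max(0, (x−k)/(x_max−k))` and reverse
hinges `max(0, (k−x)/(k−x_min))`. Declared categorical covariates expand to
indicator columns regardless of the class combination.

**Penalty.** `λ_j = rm · base(class_j) / √n_presence` with base 1.0 for
L/Q/categorical and 0.5 for hinge features; the regularization multiplier
`rm` is the single smoothness dial, tuned over 0.5–5.0 in steps of 0.5.
Zero-variance features receive a coefficient of exactly 0.

**Optimization.** The objective is convex; the L1 term is handled exactly
by splitting each coefficient into nonnegative parts (β = u − v) and
running bound-constrained L-BFGS-B on the doubled problem (`ftol = 1e−9`,
`gtol = 1e−7`, 500 iterations). Because L-BFGS line searches can stall
within rounding error of the optimum, a non-"success" return is accepted
when the bound-projected gradient is below 1e−4 in infinity norm;
otherwise fitting raises and the pipeline degrades that species to its raw
presence points with a prominent warning. Fitted coefficients on
1-covariate problems match direct numerical maximization to better than 3
decimals (acceptance test 7).

**Output.** Suitability is the cloglog transform
`1 − exp(−exp(f − α + H))` with `α = logsumexp` of `f` over the background
and `H` the entropy of the normalized background distribution; a logistic
variant is available.

**Bias correction.** A sampling-effort surface is estimated by fitting the
default model (LQH, rm = 1) to all species' records pooled against a
uniform background; the per-species background (default 10,000 points;
2,000 in the end-to-end tests) is then drawn with replacement with
probability proportional to this surface, so that the species models
contrast presences against *surveyed* environment.

**Tuning and selection.** Candidates (6 class combos × 10 multipliers) are
scored by spatially structured cross-validation: species with ≥ 20 records
use four geographic blocks split at the presence median longitude and
latitude, masking the background to the training blocks; smaller samples
use a leave-one-out jackknife (training folds of n−1 ≥ 2 presences are
permitted there, while the study-level minimum to model a species at all
is 3). Folds yield the omission rate of test presences under the minimum
training-presence threshold (OR_MTP, strict `<`), the train−test AUC
difference (AUC_DIFF), and test AUC, averaged over folds; AUC uses the
Mann–Whitney rank form with ties counted one half. Selection keeps
candidates with AUC_TEST > 0.6 (falling back to the full set with a
warning if none qualify), then minimizes OR_MTP, breaks ties by minimal
AUC_DIFF, then maximal AUC_TEST; residual ties prefer the simpler feature
class (H, Q, L, QH, LQ, LQH) and the larger multiplier. The rule is a pure
function of the candidate set (order-invariant; acceptance test 8).

## From suitability to the presence-absence matrix

The order is fixed: aggregate fine-to-coarse by block **maximum** (NaN
ignored; ragged edges use available cells) → threshold → binarize → crop
to the study region. The threshold per species maximizes sensitivity +
specificity (maxSSS) over the distinct observed coarse scores, with
presence cells being the coarse cells containing that species' records and
background all finite coarse cells; scores ≥ threshold count as presence,
and score ties break toward the smallest threshold. Cropping keeps cells
whose *center* lies in the region polygon; range sizes are recomputed
after cropping, and species left without occupied cells are dropped with a
log message. Grids are north-up with half-open cell edges (a point on a
shared edge belongs to the south-east cell).

## Indices

With `B` the branch × species incidence matrix and `L` the branch lengths
(root edge excluded), cell PD is the length of branches on some present
tip's root path divided by total tree length, PE divides each branch by
the number of cells occupied by its descendants (so Σ_cells PE = PD of the
pool, and Σ_cells WE = n_species — both conservation identities are
acceptance tests), and RPD/RPE are ratios against the same topology with
all branch lengths set to 1 (any common constant cancels in the
length-scaled ratios, so unit lengths are equivalent to rescaling to equal
total length). Empty cells have PD = PE = 0 and undefined (NaN) ratios.

**Nulls.** The curveball trade algorithm randomizes the PAM while
preserving all row and column sums exactly: repeated trades between random
species pairs reshuffle the cells unique to either. Burn-in is 5 × fill
trades and replicates are 1 × fill trades apart (fill = total presences).
Matrices admitting no 2×2 checkerboard cannot move and are returned
unchanged with a warning. Percentile ranks use the midrank convention
`100·(#{null<obs} + ½#{null=obs})/n_iter` with an equality tolerance of
1e−12, flagged significant above 97.5 / below 2.5 (two-tailed 5%). On an
exchangeable random PAM the percentile ranks are uniform (acceptance
test 4).

## Turnover, bioregions, color maps

Simpson dissimilarity `β_sim = min(b,c) / (min(b,c) + a)` (a shared, b and
c unique species counts) deliberately ignores nestedness; PhyloSor
turnover substitutes shared and unique spanning-path branch lengths. On a
star phylogeny with equal branch lengths PD ∝ TD, PE ∝ WE and PhyloSor
equals Simpson (acceptance test 6). Bioregions come from average-linkage
(UPGMA) clustering cut to k clusters (default 4), labels canonicalized by
first appearance; color maps from classical scaling (PCoA) of the
dissimilarity matrix with the first three positive axes rescaled to
[0, 255], channels defaulting to midpoint 128 with a warning when fewer
than three positive axes exist.

## Synthetic worlds

The generator produces complete, internally consistent worlds:
environment (latitudinal gradient and ridge layers plus Gaussian-filtered
autocorrelated noise, each standardized), an ultrametric tree (constant-
rate birth–death, or hand-built ladder clades), Gaussian niches whose
optima evolve by Brownian motion on the tree (mixed with iid draws by a
`phylo_signal` weight), true occupancy at the coarse grid, and occurrence
records drawn without replacement proportional to suitability × sampling
bias with 3–42 points per species (log-uniform), jittered within cells.

Three presets define the study conditions:

- `southern_refuge` — an old endemic clade (long terminal branches,
  narrow niches at the far southern end of the gradient) plus young
  southern and northern subclades; a westward sampling-effort gradient.
  Planted truths: southward-increasing TD and PD, high refuge RPD, two
  faunas separable by turnover. Cells with no true occupants carry fauna
  label 0 (undefined) and are excluded from fauna-recovery scoring.
- `uniform` — occupancy exchangeable across cells (random ranges passed
  through a long curveball mix), for null-model calibration.
- `two_blocks` — disjoint northern and southern species pools, for
  turnover and bioregion sanity checks.

All sizes in the tests (40×20 fine grid, factor 4 aggregation, 19 species,
99 nulls, 2,000 background points, 6 hinge knots) are desk-scale choices
so the full pipeline runs in well under ten minutes on one CPU;
the defaults in the code (10,000 background, factor 100, 999 nulls, 10
knots) are sized for real-data use.

## Determinism

All randomness descends from a single integer seed through one
`numpy.random.SeedSequence`, split in a fixed order across stages (bias
background, species background, per-species evaluation, null ensemble).
Running the pipeline twice with the same inputs and seed produces
bit-identical outputs (acceptance test 10), and every output directory
contains a manifest with the seed, settings, and SHA-256 hashes of the
inputs.

## Limitations

- The SDM is a correlative presence-background model: it corrects for
  sampling bias only through the pooled-record effort surface and does not
  model detection, dispersal limitation, or biotic interactions.
- maxSSS thresholding with presence = record-containing coarse cells is
  sensitive to very small sample sizes; species with fewer than three
  usable records are represented by their raw points.
- Curveball nulls condition on both margins; they cannot detect structure
  expressed purely in richness or range sizes.
- Simpson/PhyloSor ignore nestedness by design; nested assemblages are at
  distance zero and will not separate into bioregions.
- PCoA color maps are only defined up to axis sign and scaling; colors are
  comparable within one map, not across maps.
- Rasters use the ESRI ASCII grid format (text); very large landscapes
  would need a binary raster backend, which is out of scope here.
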