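# Methods

## The data structure

A multigroup, multiblock metabolomics study is represented as a network of
data matrices. Each matrix X(g, b) holds the intensities of one
*observation set* g (a cohort–timepoint, e.g. `preHD`) on one *variable
block* b (an analytical setup, e.g. `RPLC+`). Matrices sharing an
observation set are linked row-wise and must carry identical, identically
ordered observation ids; matrices sharing a block are linked column-wise
with identical variable ids. Longitudinal designs are unfolded: a timepoint
is an observation set of its own, not a tensor axis, so subjects measured
twice contribute two profiles. The structure is validated on construction
(duplicate (g, b) pairs and id mismatches are errors; a disconnected
network is legal but warned about, since components of the network are then
fitted independently in effect).

## Scaling

Unit-variance scaling is applied per variable over the vertical
concatenation of *all* matrices in the variable's block, using the sample
(n−1) standard deviation. Pooling across observation sets is deliberate:
per-matrix centering would remove exactly the between-group mean
differences the leading component is supposed to capture. Zero-variance
variables are an error by default, or dropped from the whole block on
request. Scaling is idempotent to 1e−10. Missing values are not supported
in the core; upstream filtering/imputation must resolve them first.

## NetPCA

Component a minimizes Σ‖X(g,b) − t(g,a) p(b,a)ᵀ‖² subject to unit norm of
the concatenated loading vector, by alternating least squares:

    t(g) ← [Σ_b X(g,b) p(b)] / [Σ_b ‖p(b)‖²]
    p(b) ← [Σ_g X(g,b)ᵀ t(g)] / [Σ_g ‖t(g)‖²]

followed by global renormalization of the concatenated loading, with sums
restricted to the matrices actually present for that g or b. Convergence is
declared when the relative change of the residual objective falls below
`tol` (default 1e−9; an absolute floor of 1e−12 × total variance catches
exactly low-rank data), with `max_iter` 500 and a warning plus partial
model on non-convergence. The fitted rank-1 terms are deflated before the
next component. Loadings are initialized from the leading right singular
vector of each block's row-wise concatenation (deterministic); a seeded
random initialization is available for robustness checks. Each component is
sign-fixed so its largest-magnitude loading entry is positive.

Properties that follow and are enforced by tests: a single-matrix network
reproduces the truncated SVD (scores = σu, loadings = v) to 1e−8;
explained + residual sums of squares decompose the total exactly; block
influences sum to 100% per component. One property deserves care: with a
*complete* grid of matrices the ALS is equivalent to PCA of the fully
concatenated matrix, so successive score vectors are orthogonal **as
concatenations over all observation sets**, while the per-group sub-vectors
of a weakly structured group need not be orthogonal at all (we observe
cosines up to ~0.65 for a near-noise group). Orthogonality is therefore
asserted per score vector only in the single-matrix case and on the
concatenation for network fits.

Observation sets are not reweighted: each observation contributes equally,
so larger cohorts carry proportionally more influence. Supervised variants,
confidence ellipses and component-count cross-validation are out of scope.

### Variable-centric decomposition and markers

For variable v of block b, the percent of its total variance explained by
component a is [Σ_g ‖t(g,a)‖² p(b,a,v)²] / [Σ_g Σ_rows X(g,b)[·,v]²] × 100,
with the denominator taken on the scaled data. Markers of a component are
the variables at or above a threshold percent (default 20, inclusive),
sorted by descending percent with ties broken by variable id.

## QC preprocessing

Two standard LC-MS steps are provided upstream of network assembly.
**dQC/QC ratio filter**: per feature, the diluted-QC/QC intensity ratio is
computed over adjacent dQC–QC injection pairs (each dQC paired with the
nearest QC in injection order within its batch); the feature is kept iff
the ratio series' RSD ≤ 50% and the median ratio lies in [0.2, 0.8]
(inclusive). The RSD is read as applying to the ratio series, the point
estimate is the median (robust to single bad injections), and the expected
dilution window is taken as given rather than derived from a dilution
factor. **LOESS drift correction**: per feature and batch, a degree-1
LOESS (span 0.75 by default, configurable) of QC intensity on injection
order defines the drift curve; every injection is divided by the drift
value at its order (nearest fitted value outside the QC range — no
extrapolation) and multiplied by the batch QC median; batches are then
rescaled to a common global QC median. A configurable burn-in excludes
system-conditioning injections at the start of each batch from drift
fitting. Features with all-zero or non-positive QC signal cannot be
normalized and are passed through with a warning and an audit flag.

## Enrichment

Identifier mapping is exact matching after normalization (case-fold, trim,
strip a trailing compartment suffix) against node ids, names and external
ids, trying identifier types in a fixed priority order with first-hit-wins,
so mapping is deterministic. Over-representation uses the right-tailed
hypergeometric law (equivalently the one-sided Fisher exact test) with
population N = |universe|, successes K = |pathway ∩ universe|, draws
n = |selection|; Benjamini–Hochberg q-values are computed across tested
pathways. The universe is the whole compartment-collapsed network, not just
the mapped queries (the network-wide background convention); pathways with
K = 0 are skipped so untestable sets do not dilute the FDR denominator. At
3-decimal display, q ≤ 0.05 corresponds exactly to −log10 q ≥ 1.301.

## Compound graph operations

The compound graph joins metabolites that are substrate and product of the
same reaction, undirected (reversibility is irrelevant for path mining),
with parallel edges from distinct reactions merged and the carbon-transfer
flag OR-ed. Preparation for topology: **compartment collapse** merges nodes
differing only by a suffix (default pattern `_<1-2 alphanumerics>` at the
end, configurable), deleting the transport self-loops this creates and
unioning pathway memberships; **side-compound removal** deletes a
user-overridable list of ubiquitous auxiliaries (shipped default: water,
CO₂, phosphates, NAD(P)(H), FAD, nucleotide mono/di/triphosphates and
deoxy counterparts, CoA, common ions) plus any node flagged as a side
compound; **carbon filtering** deletes edges whose reactions move no carbon
atom (flags are inputs, expected from precomputed atom mappings — computing
atom maps is out of scope).

**Lightest paths** minimize the sum of squared node degrees along the path,
endpoints included, with degrees taken on the already-filtered graph;
distance(u, u) = 0. Including endpoints is the inclusive reading of
"nodes in the path"; self-distance 0 is required for a valid dissimilarity.
Implementation is a Dijkstra-style best-first search where entering node v
costs degree(v)², with the source's own cost added once; ties are broken by
fewer nodes, then lexicographically smallest node sequence, so results are
reproducible. A missing route returns an explicit disconnected result.
Subnetwork extraction takes the union of pairwise lightest paths between
seeds (disconnected pairs logged and skipped), restricted to the edges the
paths use, with seeds and intermediates flagged distinctly. The pairwise
distance matrix assigns disconnected pairs a sentinel of twice the largest
finite entry — under complete linkage this forces separate components to
merge last, approximating clustering them separately — or a configured
fallback when nothing is connected; all sentinel pairs are flagged, and a
warning is raised if a reported module spans one.

## Module clustering

Complete linkage (inter-cluster distance = max pairwise distance) is
implemented directly so the tie-break is deterministic: among pairs at the
minimal linkage, the pair whose smallest leaf id is lexicographically
smallest wins. Merge heights are non-decreasing; cutting at k undoes the
last k−1 merges, with cluster numbers assigned by smallest member id. The
number of modules k is a user parameter — the natural choice is visual
dendrogram inspection, which is not automatable — so a silhouette profile
over k = 2..10 is reported as explicit guidance. Single and average linkage
are available but not default (chaining). The module report lists members,
dominant pathways, within-module mean distance (0 for singletons) and the
dendrogram-ordered distance matrix for heatmaps.

## Synthetic generators

**Cohort.** The default design emulates the study structure exactly: five
cohorts (56 CTRL, 69 ICKD, 35 HD, 42 KG, 24 DV) with timepoint counts
(1, 1, 2, 3, 3) giving 10 observation sets and 393 profiles, and four
blocks of 88/38/27/65 variables (218 total), hence 40 matrices. Each matrix
is severity(g)·w_sev(b)ᵀ + dialysis(g)·w_dial(b)ᵀ + noise. The severity
levels order the groups clinically — CTRL = preDV = 0, postDV1/2 near 0,
ICKD 1.0, postHD 0.9, postKG2 0.8, postKG1 1.1, preKG 1.9, preHD 2.0 —
with per-subject jitter (sd 0.25) shared across a cohort's timepoints; the
dialysis axis loads on postHD only (level −1). The severity support covers
50% of each block's variables with amplitudes |N(1, 0.3²)| (a dominant
gradient with balanced block contributions), the dialysis support 15% with
amplitudes |N(1.5, 0.3²)|, and the noise is unit Gaussian per entry (the
simplest structure the bilinear model assumes; a heavier-tailed Student-t
option exists for robustness checks). Subjects are independent across
timepoints by default, with an optional subject random effect. What the
generator does *not* emulate: intensity-dependent heteroscedastic noise,
missingness, correlated metabolite families, batch structure within the
matrices, or realistic effect sizes — the planted effects are free
parameters, so recovered component-variance percentages characterize the
synthetic conditions, not any real cohort. Passing tests demonstrate that
the algorithms recover planted structure of this form, not that any
particular real dataset has such structure.

**Toy metabolic network.** Pathways are wired as cycles of carbon-transfer
edges (default 5 pathways × 6 metabolites); each pathway has a *connector*
metabolite with two extra intra-pathway chords, and bridges between
consecutive pathways run connector-to-connector. This makes connectors
local degree hubs, exactly the role ubiquitous inter-pathway compounds play
in real networks, so the squared-degree path weighting penalizes
inter-module crossings quadratically and the planted modules are compact
relative to the bridges — chain wiring with mid-chain bridges, by contrast,
produces boundary neighborhoods tighter than whole pathways and is not
reliably recoverable by complete linkage. Side compounds (default 2) attach
to 8 metabolites across pathways, making them global hubs; a fraction
(default 0.1) of extra random edges is flagged non-carbon. With the default
design the recovery pipeline returns the planted labels exactly.

**QC sequences.** Injection series with a QC and an adjacent dQC every 6
injections, multiplicative linear drift across each batch, per-batch scale
factors, and planted pathological features (median ratio ≈ 0.9, outside
the window; or wildly unstable ratios) for validating the filter.

## Pipeline

`run_pipeline` chains load → optional QC preprocessing → scaling → NetPCA →
influences → variable variance → markers → mapping → ORA → network
preparation → subnetwork → distances → clustering → module report, writing
every table plus a run log (version, seed, parameter echo — no timestamps,
so reruns are byte-identical). ORA runs on component-1 markers by default
(the dominant biological axis; treatment-specific axes can be enabled), and
subnetwork seeds default to mapped markers inside significant pathways,
widenable to all mapped markers. Any stage failure aborts with a
stage-tagged, machine-readable error. Figures: score plot by observation
set, ORA bars with the 1.301 threshold line, dendrogram-ordered heatmap.

## Problem sizes and determinism

Default analyses run the full 393 × 218 synthetic design; graph analyses
use the 32-node toy network; test oracles enumerate exhaustively at small
n (simple paths on ≤ 8 nodes, hypergeometric universes ≤ 12, agglomeration
≤ 7 leaves), where enumeration is exact. All randomness flows through
explicit integer seeds (numpy `default_rng` with fixed seed-sequence
children), so every table, model and figure is exactly reproducible.

## Known limitations

* The ALS objective is fixed as least-squares consensus; covariance-
  maximizing multiblock variants are not offered.
* Lightest-path tie-breaking compares node sequences, which is worst-case
  expensive on large dense graphs; the intended scale is curated metabolic
  networks after filtering.
* The sentinel policy for disconnected pairs injects a finite pseudo-
  distance; clusterings of highly fragmented graphs should be read together
  with the disconnected-pair flags.
* Identifier mapping is exact-match only (after normalization); no fuzzy
  or synonym-table matching.
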