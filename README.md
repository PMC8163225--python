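# metnetpca

Integrative analysis of multigroup, multiblock metabolomics data: **network
principal component analysis (NetPCA)** over a network of data matrices,
followed by **metabolic-network contextualization** of the selected markers
(pathway over-representation, lightest-path subnetworks on a
carbon-transfer-filtered compound graph, and complete-linkage clustering of
reaction-path distances into metabolic modules).

The package targets the common clinical-metabolomics situation where several
cohorts (possibly sampled at several timepoints) are profiled on several
analytical blocks — e.g. four LC-HRMS setups — so the data naturally unfold
into a *network of matrices*: one matrix per (observation set, variable
block) pair, linked row-wise when two matrices share their observations and
column-wise when they share their variables. It is written for
chemometricians and bioinformaticians who want a tested, scriptable version
of that workflow; because studies of this kind rarely deposit patient-level
data, a first-class synthetic generator emulates the study structure (five
renal-status cohorts, 10 observation sets, 4 blocks, 40 matrices, 393
profiles, 218 metabolites) with planted effects so every step is verifiable.

## The model

For matrices X<sub>(g,b)</sub> (observation set *g*, variable block *b*),
unit-variance scaled per variable over the pooled block concatenation,
component *a* solves

```
min  Σ_(g,b) ‖ X(g,b) − t(g,a) p(b,a)ᵀ ‖²    s.t.  ‖(p(1,a), …, p(B,a))‖ = 1
```

so all matrices of an observation set share one score vector t(g,a) and all
matrices of a block share one loading vector p(b,a) — the network links act
as constraints. The fit is alternating least squares with deflation between
components; on a single matrix it reduces exactly to ordinary PCA. The model
is then decomposed two ways:

* **block influence**: ‖t(g,a)‖²‖p(b,a)‖² as a percent of the component's
  explained variance — how much each matrix drives each component;
* **per-variable explained variance**: the percent of each metabolite's
  total variance captured per component; variables at ≥ 20% on a component
  are selected as its markers.

Markers are mapped onto a compound graph (metabolites joined when they are
substrate and product of the same reaction) and pathways are tested with the
right-tailed hypergeometric test, BH-corrected. For module discovery the
graph is prepared by compartment collapse, side-compound removal (H₂O, CO₂,
NAD, ATP/ADP/AMP, …) and deletion of edges that transfer no carbon atom;
paths minimize the **sum of squared node degrees** (avoiding residual hubs),
and the pairwise lightest-path distance matrix is clustered with complete
linkage.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each writes its tables under `results/`.

```sh
python analysis/01_simulate_study.py
python analysis/02_fit_netpca.py
```

prints

```
component variance: 16.2% / 2.8%
component-1 scores vs planted severity: r = 0.989
component-1 influence by group (top 3):
preHD    24.6
preKG    23.6
CTRL     21.9
component-2 influence by group (top 3):
postHD     77.3
markers at the 20% threshold: 88 on component 1, 10 on component 2
```

The leading component recovers the planted disease-severity gradient
(r = 0.989), dominated by the most severe pre-treatment groups; the second,
much smaller component is carried almost entirely by the post-hemodialysis
matrices — the planted dialysis-specific axis. Continuing,

```sh
python analysis/04_enrichment.py
python analysis/05_network_modules.py
```

maps 61% of the variables onto the network, finds the pathway holding the
planted markers as the only significant hit (q = 5.5e-06, against the
−log10(0.05) = 1.301 display threshold), and recovers the five planted
metabolic modules exactly (ARI = 1.00, with the silhouette profile peaking
at k = 5). `analysis/03_preprocess_qc.py` demonstrates the dQC/QC feature
filter and LOESS drift correction (QC RSD 21.2% → 1.5%), and
`analysis/06_full_pipeline_figures.py` runs the orchestrated pipeline and
renders the score plot, ORA chart and distance heatmap.

The same workflow is available as a CLI (`metnetpca generate | preprocess |
fit | enrich | network | cluster | run | figures`) driven by a YAML config.

## Layout

```
src/metnetpca/      library: data_network, netpca, preprocess, enrichment,
                    metnet, clustering, synthetic, pipeline, cli
analysis/           numbered study drivers (thin scripts over the library)
tests/              pytest suite with brute-force oracles and property tests
docs/methods.md     model, assumptions, parameter choices, limitations
scripts/acceptance.py
```
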