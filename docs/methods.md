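# Methods

## Scope

`connectogene` re-implements a connectome–transcriptome analysis chain for
studying how divergent thinking (DT) relates to the local and distributed
organization of resting-state functional networks, and how the resulting
cortical maps relate to regional gene expression. The package runs
end-to-end on synthetic cohorts with planted effects; every stage is exposed
as a library function and driven by the numbered scripts under `analysis/`.

## Association matrix

Per subject, node time series (BOLD-like, timepoints × nodes) are reduced to
a connectivity matrix by:

1. Pearson correlation between all node pairs (diagonal set to 0);
2. Fisher transform z = atanh(r), with r clipped to ±(1 − 1e−7) so perfect
   correlations stay finite;
3. removal of negative links (their interpretation in graph-theoretic
   integration analyses is contested);
4. Benjamini–Hochberg FDR pruning at q = 0.005 of the weakest links, with
   two-sided p-values from the t transform t = r·√((m−2)/(1−r²)) at m
   timepoints (a parametric null; a permutation alternative would be
   exchangeable but far slower, and the parametric form is standard for
   resting-state edge screening). BH runs on the upper triangle and the
   survivor set is mirrored;
5. min-max normalization over off-diagonal entries to [0, 1].

The diagonal is excluded from the min/max and forced to 0 throughout:
self-connectivity carries no information here.

## Stepwise, local and distributed chains

Stepwise functional connectivity (SFC) at step s accumulates walk weight
over walks of exactly s links:

    NSFC_1 = normalized association matrix
    SFC_s  = NSFC_{s−1} · NSFC_1   (diagonal zeroed)
    NSFC_s = SFC_s rescaled to [0, 1]

Two numerical choices deserve note, both forced by the support semantics of
the masks below:

- **Per-step rescaling divides by the maximum only.** The step equations
  define the diagonal as 0, so the matrix minimum of the nonnegative walk
  matrices is exactly 0 and (M − min)/(max − min) reduces to M/max. Taking
  the minimum over off-diagonal entries instead would subtract the weakest
  pair's weight at every step and re-zero it, destroying the distinction
  between "no walk" (a structural zero) and "weakest walk" — on a two-triangle
  barbell graph it empties the distributed seed entirely.
- **Each step product is symmetrized.** Zeroing the diagonal before the next
  product drops node-specific self-walk terms, which makes the raw product
  slightly asymmetric; the i→j and j→i walk weights are averaged. The nonzero
  pattern is identical either way, and the chain matrices remain valid
  undirected associations.

The **local chain** keeps direct links that also have a 2-step alternative
path (NSFC_2 ≠ 0): links inside modules. It propagates with its own first
step, NLC_s = NLC_{s−1} · NLC_1. The **distributed chain** seeds from node
pairs with *no* 1- or 2-step walk but a 4-step one — pairs bridging modules
— taking NDC_1 = NSFC_4 on that mask, and propagates with NSFC_1. The
asymmetry between the two recursions (LC propagates with NLC_1, DC with
NSFC_1) is deliberate and kept. Zero tests on the masks use a 1e−12
tolerance: post-normalization zeros are exact, but products accumulate
rounding.

**Weighted degree (WD)** per node sums its link weights over the normalized
step matrices of steps 2–7 (the per-step-normalized matrices are the only
ones defined at each step, so they are what is summed; step 1 is excluded as
the direct connectivity itself). Row sums of the symmetric matrices are used.

## WD–DT association

Per node, ordinary least squares regresses subject WD on [intercept, DT,
age, sex] (sex as a single 0/1 indicator); the statistic of interest is the
DT slope and its t value. WD maps are used raw (not standardized across
subjects).

Family-wise control re-implements cluster-extent Monte-Carlo correction on
an explicit node adjacency (no external binary, no anatomical smoothness
estimation): Gaussian noise maps are regressed through the identical
design, thresholded at the two-sided voxel p (default 0.05), and the
maximum supra-threshold cluster size (positive and negative masks
separately, max over both) is recorded per iteration. The minimum cluster
extent is the smallest k with estimated P(max ≥ k) ≤ α. Observed clusters
per t sign survive if they reach that extent. The API default is 10,000
iterations; the analysis drivers use that default, while tests and the
acceptance checks use 1,000-iteration nulls, which is ample for the small
synthetic graphs. Calibration was checked on a 12 × 20 rook-adjacency
lattice (240 nodes, 40 subjects): large enough that the discrete null of
the max cluster size has exceedance steps near α rather than far below it,
making the family-wise rate informative.

## Parcellation and transcriptome screen

Node statistic maps are summarized to regions by unweighted arithmetic
means (label 0 = unassigned, ignored; empty regions omitted). The default
regional frame has 68 cortical regions, matching the Desikan–Killiany
parcellation used to tabulate regional gene expression.

Each gene's regional expression profile is Pearson-correlated (Spearman
optional) with the regional connectivity map across the shared regions
(≥ 3 required). The empirical moments of all gene scores form the null;
genes beyond mean ± 2 SD form the candidate tails, with the lower tail
(high expression where connectivity is low) the default downstream list.
No spatial-autocorrelation-preserving null is used — the transcriptome
itself is the reference distribution, which inflates nominal significance
on spatially smooth maps; the planted-effect tests quantify recovery under
this screen as defined, not its false-positive behaviour on real atlases.

## Enrichment and interactome

Overrepresentation per term uses the one-sided Fisher exact
(hypergeometric upper tail) with Bonferroni correction across tested
terms; a term is reported when fold enrichment FE = (k/n)/(K/N) > 2 and
q < 0.05. The background defaults to the genes scored by the screen — the
screen defines the testable universe — not the union of the GMT.

Candidate genes are located in an undirected interaction network read from
an edge list (duplicate edges keep the maximum confidence; self-loops
dropped). Closeness centrality uses hop-count distances by default —
interaction confidences are not metric lengths — with an inverse-weight
option, and Wasserman–Faust component scaling for disconnected graphs.

## Semantic-distance creativity scoring

A response to a prompt is scored 1 − cosine(prompt, response) per
embedding space, giving 0 for identical, 1 for orthogonal and 2 for
opposed directions. Multi-word texts are represented by the element-wise
mean of their resolvable word vectors (additive composition; stop-word
handling is the caller's responsibility). Distances are averaged per
subject and space over all scored responses, and the latent DT score is
the first principal component of the column-standardized subject × space
matrix, sign-aligned to positive loadings; a one-factor
`FactorAnalysis` alternative sits behind `method="fa"`. PCA was chosen as
the default because with five strongly collinear indicators the first
component and a one-factor fit are nearly identical and PCA is
deterministic and assumption-light.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study, scaled down:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 60 | enough for a stable 4-predictor GLM; the study scale (175) is unnecessary for planted effects |
| n_nodes | 120 | 4 modules × 30; voxel-scale (~5,700) is out of reach and adds nothing to correctness |
| n_timepoints | 150 | a 5-minute scan at TR = 2 s |
| effect_size | −0.5 | standardized slope of the link-weight scaling, the negative direction the association stage must recover |
| n_genes / n_planted | 2000 / 50 | a screen large enough for stable empirical-null moments (the full atlas has ~20,700) |
| expr_noise_sd | 0.5 | planted gene scores ≈ −0.9, clearly separated from the ±0.12 background score spread |
| n_regions | 68 | the cortical parcellation size |
| age, sex | N(22.7, 6.4), 73% F | young, mostly-female cohort |

Subject time series are multivariate Gaussian with target correlation
I + 0.6·W_s, where W_s is the modular backbone with links incident to the
effect module scaled by max(1 + effect_size·z(DT), 0.05); the target is
repaired to positive definite by eigenvalue flooring and rescaled to unit
diagonal. The value 0.6 puts within-module correlations around 0.2–0.4 —
realistic for resting-state data and detectable at q = 0.005 with 150
timepoints.

Not emulated: hemodynamics, autocorrelated scanner noise, head motion,
spatial smoothness of maps (and hence spatially autocorrelated expression),
heavy-tailed expression distributions, and annotation/interaction databases
with realistic term overlap. Passing tests therefore demonstrate that the
*procedures* are correct and calibrated under clean Gaussian conditions,
not that effect sizes or gene counts from real cohorts would be reproduced.

## Problem sizes used by the test suite and acceptance script

Oracle equivalences run on 15–20-node graphs (20 seeds); calibration on
200 null datasets of 40 subjects × 240 lattice nodes with 1,000-iteration
cluster nulls; end-to-end recovery on 20 seeds at the default study
conditions (60 × 150 × 120, effect −0.5); the transcriptome screen on 10
seeds at 2,000 genes / 50 planted. These sizes give Monte-Carlo error well
inside the asserted bands while keeping a full run of suite plus
acceptance script under ten minutes on one CPU.

## Known limitations

- The empirical-null gene screen ignores spatial autocorrelation (above).
- The Monte-Carlo cluster null assumes exchangeable Gaussian noise across
  nodes; no smoothness kernel is estimated from residuals.
- Fold-enrichment values depend on the chosen background universe;
  numbers from annotation services with internal reference lists are not
  comparable without that list.
- Stepwise chains are defined for nonnegative, undirected association
  matrices only.
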