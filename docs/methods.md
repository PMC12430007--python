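# Methods

This note records the statistical models, the synthetic-data assumptions,
and the design decisions behind `macsig`, in the spirit of the model
documentation of mature scientific packages.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing model

Label-free intensities are log2-transformed and centered per feature over
all samples (pooling conditions), so downstream fold changes are
differences of centered log2 means.  Centering per feature was chosen over
per sample: with per-feature centering a fold change is invariant to
feature-specific ionization efficiency, which is the dominant nuisance in
label-free data; a config switch is not offered because the two choices
differ only by a per-sample constant that cancels in two-group contrasts.

Missingness in label-free data is left-censored: the probability of a
non-detection decreases with abundance.  Imputation is tiered per feature
and condition.  A feature measured in **more than 50%** of a condition's
replicates is treated as missing-near-random and imputed from
Normal(μ − 0.5σ, (0.3σ)²); a feature measured in **50% or fewer**
(including none) is treated as below the detection limit and imputed from
Normal(μ − 1.8σ, (0.3σ)²).  The boundary is strict: exactly half goes to
the strong-downshift tier.

μ and σ are **per-sample (column)** statistics over all present
log-intensities in the column being imputed.  The alternative — per-feature
statistics within the condition — is undefined precisely for the features
the strong tier exists for (fully missing conditions), which is why the
per-sample convention is the package default; `reference="feature"` is
available for features where it is defined.  Imputation draws are consumed
in row-major feature order then sample order, making the imputed matrix a
pure function of (table, seed) independent of storage layout.

## Moderated t and its prior

Two-group comparisons use the pooled-variance t-statistic on log2 values.
With moderation enabled, per-feature variances are shrunk toward a prior:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), where d = n_a + n_b − 2 and (s₀², d₀) are
estimated by moment matching on log variances under the scaled-F model
(log s² has excess variance trigamma(d₀/2) beyond the chi-square sampling
component; the trigamma equation is inverted by Newton iteration).  The
moderated statistic uses d + d₀ degrees of freedom; when the observed
variances are no more dispersed than sampling alone explains, d₀ → ∞ and
the test becomes a z-test against the common variance.  As d₀ → 0 the
moderated t reduces to the classical t (verified as a continuity test).
Under a Gaussian null the type-I error at p < 0.05 is calibrated (checked
at 2,000 features, 4v4).

## PTM adjustment

A phosphopeptide's fold change confounds phosphorylation-specific
regulation with its parent protein's abundance change.  The adjusted
statistic tests their difference:

    t = (log2FC_PTM − log2FC_protein) / SE
    SE = SP · sqrt(1/df_protein + 1/df_PTM)
    SP² = [SE²_protein (df_protein − 1) + SE²_PTM (df_PTM − 1)] / (df_protein + df_PTM − 2)

with df_protein + df_PTM − 2 degrees of freedom, two-sided, BH-corrected
over all adjusted tests; a site is *phospho-driven* when the adjusted test
is significant at 5%.  Three design points:

* **Degrees of freedom are per-level sample df** (n_a + n_b − 2 at each
  level), not moderation-inflated df.  The pooled-SD construction treats
  the two standard errors as dispersion estimates with their sampling df;
  substituting a moderation-augmented df collapses SE toward zero and
  destroys calibration.
* **The construction presumes a matched design**: phosphopeptide and
  protein measurements from the same samples share their biological
  protein-level variation, so the variance of the fold-change *difference*
  is dominated by the phospho-specific residual, which the pooled SE
  bounds from above.  With independent samples at the two levels the SE
  formula is anticonservative by roughly √df/√2 and should not be used.
* **Missing protein counterpart**: a site whose protein was not quantified
  passes through as phospho-driven with a `protein_missing` provenance
  flag — absence of protein evidence cannot demonstrate an
  abundance-driven change.

The *keep rule*: for every protein with at least one phospho-driven site,
all of that protein's raw-significant sites are retained for downstream
analysis; proteins without a driven site contribute none.

Multiplicity classes (singly/doubly/triply phosphorylated forms) are
separate features throughout; a site whose classes are *significant in
opposite directions* is removed entirely.  Discordance involving a
non-significant class does not trigger removal — requiring both directions
to be significant is the conservative reading of an ambiguous rule and is
flagged here as a deliberate choice.

**Known limitation — imputation × adjustment interaction.**  The phospho
and protein tables are imputed independently, so imputed entries break the
matched-sample pairing and bias the two layers' fold changes in different
directions.  At the synthetic default of ~15% missingness this raises the
false phospho-driven rate among features with imputed entries to roughly
10–18%, while complete features stay near the nominal level.  The
mechanism-separation test therefore runs on uncensored data; the kinase
recovery test runs through the full chain (censoring, imputation and all)
and still recovers the planted kinases because footprint enrichment
aggregates over ~30 substrates per kinase.

## Kinase footprints

Activity is inferred from the 2×2 table (upregulated × recognized) over
class-I sites (localization probability > 0.75), with a two-sided Fisher's
exact test using the point-probability convention (sum of table
probabilities ≤ the observed one) — stated because two-sided conventions
differ.  A kinase is called *upregulated* only when additionally its odds
ratio exceeds 1: the two-sided test alone also fires on depleted
footprints, which are not evidence of activity.  The curated-substrate test
is uncorrected by default (config switch for BH), matching the raw p < 0.05
convention; the predicted-family test is BH-corrected and additionally
requires ≥ 10 upregulated substrates.  Site-level family predictions are
filtered to posterior > 0.035 *and* posterior above the prior, then the top
3 families per site (ties at rank 3 all kept, for determinism without
arbitrary drops).

Signaling networks draw an edge kinase → target only when the target
protein carries an upregulated site the kinase recognizes.  Unmeasured
kinases enter only as bridges (adjacent to ≥ 1 upregulated and ≥ 1 other
measured kinase); in focused mode measured kinases adjacent to an
upregulated kinase stay in; in large mode non-upregulated measured kinases
must connect ≥ 2 upregulated kinases.

## Over-representation analysis

One hypergeometric engine (upper tail, P(X ≥ k)) serves all stages; an
EASE-style variant testing k − 1 is available for compatibility with
modified-Fisher annotation tools.  The background is always explicit.
Redundancy pruning walks results from most to least significant and retains
a set only if it is significant, within the size window, and contributes at
least 2 hit members not covered by previously retained sets; "covered"
counts hit members only (not full memberships), the reading that keeps
pruning independent of set sizes outside the data.

## Consensus and network integration

A gene is a bulk consensus hit when significant (adj. p < 0.05, fold ratio
> 4) in ≥ 3 of the per-dataset tables, after an eligibility prefilter
requiring above-median expression in ≥ 3 datasets; a union mode serves
comparisons with only two datasets.  DTU genes need evidence in at least
half the comparisons.  Direction consistency across datasets is recorded
but not required.

Interaction sources are filtered per role (combined score > 0.7; physical
interactions must carry a confidence value; confidence-scored > 0.7) and
merged as undirected simple edges with source provenance.  The integrative
network keeps edges whose both endpoints are significant in ≥ 1 omics
layer, drops connected components in which > 75% of nodes carry only DTU
evidence (applied per component, since a component is the unit a reader
would interpret as "a network"), and analyzes the largest remaining
component.

Current-flow betweenness is computed unnormalized (raw summed current
throughput, endpoints excluded); all downstream use is rank-based (e.g.
top-central nodes), which normalization cannot change.  On trees it equals
shortest-path betweenness, which the tests exploit as an oracle.

Module decomposition uses seeded multi-level (Louvain) modularity
optimization with the resolution scanned by bisection against a target mean
within-module degree (default 10).  The achieved degree is a step function
of resolution, so the target guides granularity coarsely: among partitions
within ±25% of the target degree the one with the highest resolution-1
modularity is returned (modularity is the actual objective; the degree
target alone systematically prefers over-split partitions), otherwise the
closest partition.  The achieved average degree and resolution are
reported on the partition object.

## Single cells

Cells arrive pre-labeled as macrophages; upstream isolation (embedding,
clustering, reference annotation) is out of scope.  QC removes cells with
< 500 or > 9000 expressed genes (boundaries kept) or > 10% mitochondrial
counts, then genes expressed in < 3 surviving cells.  Counts are
depth-normalized to 10,000 per cell and transformed with ln(1 + x) — the
natural-log convention that keeps zeros at zero.

The signature module score bins all genes into 24 equal-frequency bins by
average expression across cells (ties broken by gene id for determinism);
each signature gene is compared against 100 control genes drawn from its
bin (without replacement when the bin is large enough, with replacement
otherwise — small bins are not covered by the original recipe), and a
cell's score is the mean over signature genes of expression minus the
control mean.  Assignment: M1-like iff the M1 score is the strictly larger
one and positive, likewise M2-like; both scores ≤ 0 gives Na (unknown).
Zero counts as "not positive", the conservative reading of "negative"; an
exact positive tie is Na with a tie flag.  A single-marker mode assigns
M2-like when the marker (e.g. CD163) exceeds a configurable expression
cutoff, default any expression.

Single-cell differential expression uses per-gene Student t-tests on
normalized values, restricted to genes expressed in ≥ 10% of cells of
either group, Bonferroni-corrected; significance additionally requires an
average log2FC > 0.75 in the upregulated direction, computed as
log2(mean(expm1(x)) + 1) differences (config-switchable to
difference-of-means / ln 2).

## Synthetic data: what it emulates, what it does not

All generators are pure functions of their parameters and a seed.

* `gen_phosphoproteome` — baseline log2 intensities ~ Normal(25, 2) per
  protein (a realistic label-free dynamic range, so the imputation tiers
  matter), 2 conditions × 4 replicates by default.  Phosphopeptides
  inherit their protein's observed per-sample value (matched design,
  shared biological variation) plus a site offset and a phospho-specific
  residual at half the protein noise.  Kinase effects (default +2 log2 in
  the second condition, 20 kinases × 30 disjoint substrate sites, 3
  active) are planted at the phospho level only, on proteins *without* a
  protein-level effect; a disjoint 10% of proteins get the same shift at
  the protein level, so every planted site is attributable to exactly one
  mechanism.  Kinases are named after non-regulated proteins so
  kinase–kinase signaling edges can exist.  Censoring follows
  P(missing | x) = max_rate · expit(−(x − midpoint)·slope) with defaults
  (0.9, 22.5, 1.0) giving ~15% missingness, decreasing in intensity.
  Junk rows (contaminants, decoys, single-peptide proteins,
  non-phosphopeptides) exercise the cleaning rules and carry no truth.
* `gen_bulk_de_tables` — six datasets; truly regulated genes (5%) are
  significant in each dataset independently with probability 0.9
  (concordance), nulls at 1%; regulated genes get higher baseline
  expression so the above-median prefilter passes them.
* `gen_interaction_network` — a stochastic block model (4 × 40 nodes,
  p_in 0.3, p_out 0.01) spread over the three source roles, with a
  configurable fraction of confidences drawn below the merge thresholds.
* `gen_single_cells` — negative-binomial counts (dispersion 0.5),
  log-normal gene means and library sizes tuned so healthy cells express
  well over 500 of the 1,000 genes; 100-gene signatures per state shifted
  by 2^1.5 in the matching cells; 10 mitochondrial genes at a few percent
  of a typical library; ~5% of cells get 10× mitochondrial counts and ~2%
  a collapsed library to exercise the QC boundaries.

Not emulated: peptide-level identification, inter-feature biological
co-regulation beyond the planted structure, batch effects, isoform
structure behind the DTU calls, ambient RNA and doublets.  Passing recovery
tests therefore demonstrates correctness of the implemented rules and
statistics under the stated generative model, not performance on real
acquisitions.

## Problem sizes and numerics

Default synthetic sizes (200 proteins × 4 sites, 2,000 bulk genes × 6
datasets, 160-node graphs, 800–1,000 cells × 1,000 genes) were chosen so a
full pipeline run and the entire test suite complete interactively on a
laptop-class single core while leaving all planted effects comfortably
detectable.  Monte-Carlo checks use 10–20 seeds.  Numerical tie-breaks are
deterministic everywhere (sorted ids in binning, seeded Louvain, ordered
imputation draws); t = 0 with p = 1 is defined for zero fold change with
zero standard error, and ±∞ with p = 0 otherwise.
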