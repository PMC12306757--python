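# Methods

This note documents the models, parameter choices, and numerical
decisions behind `mtscape`, and what the synthetic benchmarks do and do
not demonstrate.

## The analysis model

The pipeline treats a presequence (MTS) as a short amino-acid sequence
whose targeting behaviour is governed by a handful of physicochemical
axes: net positive charge, hydroxylated-residue content, overall
hydrophobicity, and amphipathy (segregation of hydrophobic residues
onto one face of an idealized α-helix). The analysis asks whether
presequences fall into discrete groups along these axes and whether
group membership predicts the response of the parent protein to
mitochondrial perturbations.

Stages: curation → MTS–carrier fusion and per-residue embedding →
mean-pooling over the MTS span → 2-D projection → spectral grouping
with data-driven k → group-wise property statistics → permutation
scoring against perturbation fold-change tables.

## Curation rules

* Score filter: targeting score ≥ `min_score` (default **0.3**,
  inclusive; the threshold is a parameter, so a strict `>` reading is
  one flag away). Records lacking a score cannot pass and are dropped
  with a logged count.
* Length floor: length ≥ `min_length` (default **8**, i.e. "longer than
  7 residues").
* Deduplication per gene: keep the form identified most often; ties go
  to the longer form; remaining ties to the first in input order
  (deterministic and order-stable).
* Trivial entries (length ≤ 1 — a bare initiator Met — or empty) are
  removed; manual additions are appended with `source="manual"` and
  replace any same-id record.

Counts dropped at each rule are recorded in catalog metadata, so
|kept| + |dropped| always equals the input size.

## Fusion and embedding

Each MTS replaces the initiator methionine of a carrier protein
(default: mouse dihydrofolate reductase, DHFR), reproducing the classic
MTS-DHFR import-construct design: `fusion = MTS + carrier[1:]`, with
the MTS occupying span [0, len(MTS)). Embedders are pluggable: any
callable mapping a sequence to a finite L×d matrix with one row per
residue satisfies the contract (a pretrained protein language model can
be adapted behind it). Pooling takes the arithmetic mean of the MTS
rows only — carrier rows never contribute — including the MTS's own
initial Met.

### The surrogate embedder

The default embedder is deterministic and desk-scale, with six
per-residue features:

| column | meaning |
|---|---|
| `kd_hydrophobicity` | Kyte–Doolittle scale value |
| `formal_charge` | +1 (K/R), −1 (D/E), 0 otherwise (His neutral) |
| `hydroxyl` | indicator for S/T/Y |
| `window_mean_hydrophobicity` | centered running mean, window 9 |
| `window_hydrophobic_moment` | μH, window 9, δ = 100° = 100π/180 rad |
| `window_net_charge` | centered running mean of charge, window 9 |

Windows are centered and **edge-truncated** (they shrink at the
termini) rather than padded — padding would invent residues.

The hydrophobic moment is computed on hydrophobicity *deviations from
the window mean*: with local index i starting at 0 in each window and
h centered, μH = √[(Σ hᵢ sin iδ)² + (Σ hᵢ cos iδ)²] / N. Centering
makes μH a pure amphipathy measure: a uniformly hydrophobic stretch has
no hydrophobic *face* and scores exactly zero, whereas the uncentered
sum leaves a nonzero residual of the mean level whenever the window
does not span whole turns. Periodic placement at ~3.6-residue spacing
scores high either way.

'X' residues are rejected by default; an explicit policy
(`x_policy="mean"`) maps them to each scale's mean value.

## Projection and grouping

* UMAP with n_neighbors = 15, min_dist = 0.2, spread = 2.0,
  learning_rate = 0.5, n_epochs = 1000, fixed seed (default **1811**).
  Feature columns are z-scaled before projection (the surrogate's
  columns have heterogeneous units; scaling is a flag for embedders
  whose dimensions are homogeneous).
* Spectral clustering on the **2-D projection** with RBF affinity
  exp(−γ‖p−q‖²), γ = 1.1, and 20 k-means label-assignment restarts.
  γ = 1.1 is a length-scale choice that only makes sense on projected
  coordinates of O(1–10) extent, which is why clustering defaults to
  the projection; clustering in the full embedding space is available
  by calling `cluster()` on the vectors instead.
* Labels are canonicalized (decreasing cluster size, ties by ascending
  mean x) and lettered A, B, C, …, so "group A" is always the largest.
  The letter map can be overridden.
* Degenerate geometry (all points coincident) raises an error rather
  than returning arbitrary labels.

### Choosing the number of groups

For each k in [2, 12] the pipeline records the Calinski–Harabasz score
CH(k) = [B(k)/(k−1)] / [W(k)/(n−k)] and the within-cluster dispersion
W(k). The selection rule is an elbow criterion applied to the CH
curve: **k\* is the largest k whose CH exceeds the best CH at any
smaller k by at least 20 %** (`gain_threshold = 1.2`), falling back to
the plain argmax — with a low-confidence warning — when no split
clears the threshold.

Rationale: on compact 2-D projections, CH keeps creeping upward as
genuine groups are oversplit (tight UMAP filaments reward any further
subdivision), so the global argmax systematically overestimates k. The
CH *elbow* — the last materially profitable split — recovers the
generating group number on synthetic data where the argmax does not.
Comparing each k against the running maximum rather than its immediate
predecessor keeps the rule robust to one-off dips in the trace (a
single degenerate clustering run would otherwise manufacture a fake
"gain" at the next k). The threshold 1.2 means "a split must buy a 20 %
improvement in dispersion ratio to be believed"; it is a model-selection
constant of the package, exposed as a parameter. The full (k, CH, W)
trace is always returned for manual elbow inspection, and the
low-confidence flag also fires when max CH falls below a configurable
floor (CH scales with n, so the floor is meaningful only relative to a
given dataset size).

## Group statistics

* Kruskal–Wallis (tie-corrected, χ² approximation) per property across
  groups, α = 0.05. All-identical values return H = 0, p = 1.
* Where the omnibus test is significant, Dunn's post hoc z on pooled
  ranks with tie correction, either all-pairs or each cluster against
  the union of the others (default, matching the question "which group
  differs from the overall distribution"). Note the vs-rest mode's
  known artifact: one strongly shifted group is part of every other
  group's "rest", so unaffected groups can show weak opposite-signed
  hits; all-pairs mode avoids this.
* Benjamini–Hochberg adjustment is applied **within each property**
  across its comparisons, not across properties. BH is the step-up
  rule p̂(i) = min over j ≥ i of m·p(j)/j, capped at 1. (BH is *not*
  idempotent — re-adjusting adjusted values can inflate them — so
  adjusted p-values are terminal outputs, never re-fed.)
* Missing property values are dropped per property, never imputed.
  Tests are rank-based, so monotone transforms (e.g. log-abundance)
  change nothing.

## Perturbation scoring

For condition c and group g with quantified members Q(g):

* statistic T = mean |log2FC| over Q(g) (`sign_mode="both"`); the
  `positive_only` / `negative_only` modes restrict to fc > 0 (raw
  values) or fc < 0 (magnitudes), so all three are extremity scales.
* null: B subsets of size |Q(g)| drawn **without replacement from all
  clustered proteins quantified in the dataset** (equivalent to label
  permutation for a single group). Proteins quantified but not
  clustered are excluded from both the observed statistic and the null
  pool.
* p = (1 + #{T_null ≥ T_obs}) / (B + 1), one-sided, B = 99,999 by
  default. The +1 correction keeps p valid and strictly positive
  (floor 1/(B+1)). A two-sided variant (distance from the null mean)
  is available.
* z-scores standardize T across groups **within a condition** (sample
  sd); absent cells (no quantified members) stay absent and are
  excluded.
* Per-cell seeds are derived deterministically from the top-level seed
  via `SeedSequence`, so a full validation table is reproducible and
  individual cells are independent.

## Synthetic data

The generator builds sequences on an idealized helix: hydrophobic
residues (L/F/I/V/A) on a lattice with spacing `hydrophobic_period`
(3.6 ⇒ one helical face) and random phase; K/R, S/T, and optionally
D/E on exact rounded fractions of the remaining positions; filler from
A/G/Q/N; leading residue forced to Met; length ~ rounded
Normal(length_mean, length_sd) clipped at 8. Targeting scores are
Uniform(0.3, 1), times-identified 1 + Poisson(2). Residue-class counts
are allocated exactly and then placed by shuffling, so within-group
compositional variance comes from length and placement, not sampling
noise — groups are compositionally tight by construction.

The seven-group preset varies charge (0.15/0.3/0.45/0.6), hydroxyl
fraction (0.10–0.55), hydrophobic spacing (2.2/3.6/7.5), length
(16–40) and acid tolerance across archetypes chosen to be well
separated on the surrogate's feature axes. This coupling is
intentional: separability is controlled only through interpretable
physicochemical parameters, which is exactly the feature space the
surrogate measures. Passing recovery tests therefore shows that the
*pipeline machinery* (embedding, pooling, projection, model selection,
clustering) preserves and recovers physicochemical group structure; it
does **not** show that real yeast presequences form seven groups, that
a pretrained language model's 768-d geometry matches the surrogate's,
or that real fold-change tables behave like Gaussian noise with
group-constant shifts. Real-data properties the generator does not
emulate: sequence grammar beyond composition/periodicity, correlated
properties across columns, heavy-tailed abundances, structured
missingness, and batch effects.

Property tables are Normal(baseline + group shift, noise_sd) per
column with realistic baselines and a per-group categorical
functional-category draw; fold-change tables are Normal(group effect,
noise_sd) with optional dropout. All generators are pure functions of
(parameters, seed), with independent per-generator streams so the
catalog is stable when only effects change.

## Problem sizes and runtime choices

The test suite and acceptance script run the seven-group preset at
n = 30 per group (210 MTS), model-selection recovery over 10 seeds,
permutation exactness at B = 99,999 against full enumeration of
C(6,2) = 15 subsets, null calibration with 500 simulated datasets at
B = 999, and injected-effect detection at B = 9,999 — sizes chosen so
the whole suite completes in about a minute on one CPU while leaving
every statistical check well-powered. The defaults in the library
(B = 99,999, k ∈ [2, 12]) match the analysis scale the pipeline is
meant for (hundreds of presequences, a handful of conditions).

## Known limitations

* The surrogate embedder is a transparent physicochemical stand-in
  with d = 6; it does not reproduce the coordinates of any pretrained
  protein language model, and no attempt is made to reproduce
  real-data cluster coordinates. The embedder contract is the
  extension point for plugging such a model in.
* UMAP determinism is guaranteed only for a fixed seed on a fixed
  platform/library version (single-threaded layout).
* The CH-elbow gain threshold (1.2) is a heuristic constant; for data
  whose CH trace is flat or noisy, inspect the returned trace and the
  low-confidence flag rather than trusting k* blindly.
* Cluster-vs-rest Dunn comparisons carry the "contaminated rest"
  artifact described above.
* The permutation test conditions on the realized fold changes; it
  tests exchangeability of group labels, not measurement error in the
  fold changes themselves.
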