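# mtscape

Physicochemical classification of mitochondrial targeting sequences
(MTS, "presequences") and validation of the resulting groups against
perturbation proteomics.

Most matrix-targeted mitochondrial proteins carry an N-terminal
presequence: a positively charged amphipathic helix, rich in
hydroxylated residues and depleted of acidic ones, cleaved after
import. Presequences are far from uniform, and their differences have
functional consequences — some recruit specific cytosolic factors,
some respond more strongly to import stress. `mtscape` provides a
tested pipeline for asking, in silico, *how many kinds of presequence
there are and whether the kinds matter*:

1. **Curate** a presequence catalog: keep entries with a targeting
   score ≥ 0.3 and length > 7 residues, collapse duplicates to the form
   identified most often (ties: the longer form), drop bare-initiator
   entries, add manual records.
2. **Embed** each presequence as an engineered MTS–DHFR fusion (the MTS
   replaces the carrier's initiator Met, mimicking classic import
   constructs), run a per-residue embedder over the fusion, discard the
   carrier rows and mean-pool the MTS rows into one vector per
   presequence. The embedder is a pluggable contract; the default is a
   deterministic physicochemical surrogate (Kyte–Doolittle
   hydrophobicity, formal charge, hydroxylated-residue indicator, and
   windowed mean hydrophobicity, hydrophobic moment μH at δ = 100°, and
   net charge).
3. **Map the landscape**: UMAP to 2-D (n_neighbors = 15, min_dist = 0.2,
   spread = 2.0, learning_rate = 0.5, n_epochs = 1000), then spectral
   clustering on a radial-basis affinity exp(−γ‖p−q‖²) with γ = 1.1 and
   20 label-assignment restarts. The number of groups k is selected from
   the Calinski–Harabasz trace, CH(k) = [B(k)/(k−1)] / [W(k)/(n−k)], by
   an elbow rule (last k whose CH improves materially on all smaller k).
   Groups are lettered A, B, C, … by decreasing size.
4. **Group statistics**: Kruskal–Wallis across groups for each protein
   property (gravy, abundance, length, …), Dunn's post hoc test
   (cluster-vs-rest or all-pairs) with Benjamini–Hochberg adjustment,
   and functional-category composition per group.
5. **Perturbation response**: for each condition of a log2 fold-change
   table and each group, the mean absolute log2FC of the group's
   quantified members is compared against size-matched random protein
   groupings — a permutation test with 99,999 iterations and the
   +1-corrected one-sided Monte-Carlo p-value
   p = (1 + #{T_null ≥ T_obs}) / (B + 1) — and z-scored across groups
   within the condition for cross-dataset comparability.

A first-class synthetic-data module generates presequence catalogs,
property tables and fold-change tables with *known* group structure
(groups differ along interpretable axes: charge, hydroxyl content,
hydrophobicity, amphipathy), so every stage of the pipeline is testable
end-to-end with a ground truth and no downloads.

## Worked example

`examples/02_embed_and_cluster.py` generates the seven-group synthetic
preset (210 presequences), embeds, projects and clusters them, and
compares the recovered partition with the generating truth:

```
210 MTS embedded into 6 pooled feature dimensions
selected k* = 7 (Calinski-Harabasz elbow)
 k     ch       w
 2   82.0 43121.2
 3  125.4 27180.5
 ...
 6 2027.9  1185.6
 7 7140.5   283.5
 8 6797.9   254.1
 ...
group sizes: {'A': 31, 'B': 31, 'C': 30, 'D': 30, 'E': 30, 'F': 29, 'G': 29}
adjusted Rand index vs generating groups: 0.978
```

The CH trace jumps sharply at k = 7 and flattens after it — the elbow —
and the recovered groups agree with the generating ones almost
perfectly (ARI 0.978; 1.0 would be identity).

`examples/04_perturbation_response.py` injects a −2.0 log2FC effect
(noise sd 0.3) into group A and scores every group:

```
letter  n_used  stat      p     z  significant
     A      30 1.993 0.0001  2.26         True
     B      30 0.210 0.9992 -0.43        False
     ...
significant cells: [('A', 'both'), ('A', 'negative_only')]
```

Group A's mean |log2FC| (≈2) is more extreme than every one of the
9,999 random size-30 groupings (p at the Monte-Carlo floor), while the
unaffected groups sit at the noise level; only A is flagged, and only
in the sign modes consistent with a depletion effect.

The other examples cover catalog curation (`01`) and group-wise
property statistics (`03`). Each prints what it computes and what the
numbers mean.

## Command line

The same pipeline is available as a thin CLI:

```sh
mts simulate --preset seven-groups --seed 1811 --out sim/
mts curate --in sim/catalog.tsv --format tsv --out curated.tsv
mts embed --catalog curated.tsv --out emb
mts landscape --vectors emb_vectors.tsv --k auto --seed 1811 --out land
mts groupstats --clusters land_clusters.tsv --properties sim/properties.tsv --out stats
mts validate --clusters land_clusters.tsv --datasets sim/perturbation.tsv --out results.tsv
mts run-all --catalog sim/catalog.tsv --properties sim/properties.tsv \
    --datasets sim/perturbation.tsv --seed 1811 --out run/
```

`run-all` writes every stage's TSV plus a `manifest.json` (input
digests, parameters, seeds, version) sufficient to re-execute an
identical run.

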