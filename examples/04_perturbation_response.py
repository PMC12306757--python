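"""Score group responses to a perturbation with the permutation test.

Injects a -2.0 log2 fold-change effect (noise sd 0.3) into group A of
the seven-group synthetic preset, then asks, for every group and sign
mode, whether its mean absolute log2FC is more extreme than
size-matched random protein groupings (9,999 permutations).
"""

from mtscape import generate_catalog, generate_perturbation, run_validation, seven_groups_preset
from mtscape.landscape import ClusterModel

SEED = 1811

_, truth = generate_catalog(seven_groups_preset(), seed=SEED)
model = ClusterModel.from_assignments(truth)

datasets = generate_perturbation(truth, affected={"A": -2.0}, noise_sd=0.3, seed=SEED)
table = run_validation(datasets, model, n_iter=9_999, alpha=0.05, seed=SEED)

both = table[table["sign_mode"] == "both"]
print("condition cond01, sign mode 'both':")
print(
    both[["letter", "n_used", "stat", "p", "z", "significant"]]
    .round({"stat": 3, "z": 2})
    .to_string(index=False)
)
sig = table[table["significant"]]
print(f"\nsignificant cells: {[tuple(r) for r in sig[['letter','sign_mode']].values]}")

# Group A's mean |log2FC| (~2.0) is far beyond any random grouping of the
# same size (p at the Monte-Carlo floor), while unaffected groups sit near
# the noise level (~0.24) with large p; the z column standardizes the
# statistic across groups within the condition.
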