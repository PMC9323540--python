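"""Descriptor-matrix preparation: pruning, standardization, stratified folds.

Generates a small synthetic cation series, removes unusable descriptor
columns, standardizes the rest, and builds the deterministic every-tenth
cross-validation folds used throughout the package.
"""

from ilqspr import SyntheticSpec, assign_folds, make_planted_linear, prune_descriptors, standardize

spec = SyntheticSpec(seed=42, n=30, p=40, n_collinear_decoys=3, n_constant_decoys=2)
matrix, y, truth = make_planted_linear(spec)
print(f"raw matrix: {matrix.n} cations x {matrix.p} descriptors")

pruned, removed = prune_descriptors(matrix, collinearity_threshold=0.95)
reasons = {}
for r in removed:
    reasons[r.reason] = reasons.get(r.reason, 0) + 1
print(f"pruned to {pruned.p} descriptors; removed by reason: {reasons}")

std = standardize(pruned)
print(f"standardized: column means ~0 (max |mean| = {abs(std.values.mean(0)).max():.2e})")

folds = assign_folds(y, n_folds=10)
print(f"fold sizes: {folds.fold_sizes()}")
print("each fold spans the whole logK range (rank j goes to fold j mod 10),")
print("so every held-out fold is representative of the response distribution.")
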