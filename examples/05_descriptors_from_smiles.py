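"""From cation SMILES to a modeling-ready descriptor matrix (needs RDKit).

Builds a miniature property series of real ionic-liquid cation families
(imidazolium, pyridinium, ammonium, ...), computes the RDKit 2D descriptor
set and prepares the matrix exactly as a real modeling run would.
"""

from ilqspr import (
    CationRecord,
    PropertySeries,
    RDKitDescriptorEngine,
    compute_descriptors,
    prune_descriptors,
    standardize,
)

series = PropertySeries(
    solute="hexane",
    records=(
        CationRecord("[BMIm]+", "CCCCn1cc[n+](C)c1", 1.59),
        CationRecord("[HMIm]+", "CCCCCCn1cc[n+](C)c1", 1.97),
        CationRecord("[BMPy]+", "CCCC[n+]1ccccc1C", 1.50),
        CationRecord("[N1114]+", "CCCC[N+](C)(C)C", 1.49),
        CationRecord("[BMPyrr]+", "CCCC[N+]1(C)CCCC1", 1.61),
        CationRecord("[Et3S]+", "CC[S+](CC)CC", 1.20),
    ),
)
# logK values above are illustrative placeholders on the hexane scale

matrix = compute_descriptors(series, RDKitDescriptorEngine())
print(f"computed {matrix.p} 2D descriptors for {matrix.n} cations")

pruned, removed = prune_descriptors(matrix, collinearity_threshold=0.95)
print(f"after pruning: {pruned.p} descriptors "
      f"({len(removed)} removed: missing/constant/collinear)")

std = standardize(pruned)
print(f"standardized matrix ready for modeling: {std.n} x {std.p}")
print("with a measured logK series of ~60 cations this matrix is what the")
print("selection procedures (OMP/expulsion, greedy substitution) consume.")
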