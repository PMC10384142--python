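"""Call codominant alleles from fragment sizes and fingerprint accessions.

Fragment sizes come from gel scoring: a fragment matching the
reference-size product is allele A, the alternative-size product B, both
together H (heterozygote), and a single product >=30 bp larger than both
expected sizes is a novel allele (C, then D, in order of first detection).
Band presence/absence feeds Jaccard similarity and a UPGMA dendrogram, and
an exhaustive search finds the smallest marker subset that tells every
accession apart.
"""

import pandas as pd

from indelmark import (
    call_alleles,
    jaccard_matrix,
    min_discriminating_set,
    score_bands,
    upgma,
)

accessions = ["M01", "M02", "M03", "M04", "M05", "M06"]

# observed fragment sizes (bp) for three markers, per accession
observed = {
    "SM001": {"M01": [250], "M02": [250], "M03": [250],
              "M04": [280], "M05": [280], "M06": [280]},
    "SM002": {"M01": [180], "M02": [210], "M03": [180, 210],
              "M04": [210], "M05": [250], "M06": [180]},
    "SM003": {"M01": [320], "M02": [300], "M03": [300],
              "M04": [320], "M05": [300], "M06": []},
}
expected = {"SM001": (250, 280), "SM002": (180, 210), "SM003": (300, 320)}

matrix = pd.DataFrame(index=accessions, columns=list(observed), dtype=object)
for marker, obs in observed.items():
    calls = call_alleles(obs, *expected[marker], marker_id=marker)
    for acc, call in calls.items():
        matrix.loc[acc, marker] = call.call
print("allele matrix (A=ref, B=alt, H=both, C=novel, None=no product):")
print(matrix.to_string())

bands = score_bands(matrix)
sim = jaccard_matrix(bands)
print("\nJaccard similarities (shared bands / union of bands):")
print(sim.round(2).to_string())

tree = upgma(1 - sim)
print("\nUPGMA dendrogram (ultrametric, heights = join distance / 2):")
print(tree.newick())

result = min_discriminating_set(matrix)
print(f"minimum discriminating marker set: {result.markers} "
      f"({'optimal' if result.optimal else 'heuristic'}) — the fewest "
      "markers whose combined profiles are unique per accession")
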