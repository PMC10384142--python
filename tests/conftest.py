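import numpy as np
import pytest

from indelmark import RunConfig, SimSpec, generate_indel_vcf, generate_reference
from indelmark.variant_filtering import GenotypeCall, GenotypeState, VariantRecord


@pytest.fixture
def cfg():
    return RunConfig()


def make_record(states, contig="c1", position=1000, ref="ATTTTTTTTTTTTTTTT", alt="A",
                depth=50, gq=60):
    """Build a VariantRecord from short state codes: r/h/a/m."""
    lookup = {
        "r": GenotypeState.HOM_REF,
        "h": GenotypeState.HET,
        "a": GenotypeState.HOM_ALT,
        "m": GenotypeState.MISSING,
    }
    calls = tuple(
        GenotypeCall(state=lookup[s], depth=depth, gq=gq) for s in states
    )
    return VariantRecord(
        contig=contig, position=position, ref_allele=ref, alt_allele=alt, calls=calls
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """~300-locus simulation with genotype-quality noise near the filter
    thresholds, plus its reference and ground truth."""
    spec = SimSpec(
        seed=42,
        het_noise_rate=0.10,
        missing_rate=0.12,
        dp_distribution=(15.0, 6.0),
        gq_distribution=(40.0, 12.0),
    )
    reference = generate_reference(spec)
    records, truth = generate_indel_vcf(reference, spec)
    return spec, reference, records, truth


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-noise simulation: codes and counts are exactly the composition."""
    spec = SimSpec(
        seed=7,
        het_noise_rate=0.0,
        missing_rate=0.0,
        dp_distribution=(50.0, 5.0),
        gq_distribution=(80.0, 5.0),
        edge_fraction=0.05,
    )
    reference = generate_reference(spec)
    records, truth = generate_indel_vcf(reference, spec)
    return spec, reference, records, truth


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive re-implementations)

def oracle_two_stage_filter(records, min_depth=10, min_gq=30, max_missing=0.2):
    """Direct per-rule filter re-scan, independent of the library's code path."""
    relaxed, strict = [], []
    for rec in records:
        states = []
        for call in rec.calls:
            s = call.state.value
            if s != "missing" and (call.depth < min_depth or call.gq < min_gq):
                s = "missing"
            states.append(s)
        n = len(states)
        n_missing = states.count("missing")
        if n_missing / n > max_missing:
            continue
        informative = [s for s in states if s != "missing"]
        if all(s == "hom_ref" for s in informative) or all(
            s == "hom_alt" for s in informative
        ):
            continue
        relaxed.append((rec.contig, rec.position))
        if "het" not in states and "missing" not in states:
            strict.append((rec.contig, rec.position))
    return relaxed, strict


def oracle_upgma_heights(D, labels):
    """Naive O(n^3) UPGMA: recompute every cluster distance from the original
    leaf-pair matrix at each step. Returns {frozenset(leaves): height}."""
    D = np.asarray(D, dtype=float)
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    heights = {c: 0.0 for c in clusters}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [
                        D[index[a], index[b]]
                        for a in clusters[i]
                        for b in clusters[j]
                    ]
                )
                key = tuple(sorted([min(clusters[i]), min(clusters[j])]))
                if best is None or (d, key) < (best[0], best[3]):
                    best = (d, i, j, key)
        d, i, j, _ = best
        merged = clusters[i] | clusters[j]
        heights[merged] = d / 2.0
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def tree_cluster_heights(tree):
    """{frozenset(leaves under node): node height} for every internal node."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.name])
        leaves = frozenset()
        for child in node.children:
            leaves |= walk(child)
        out[leaves] = node.height
        return leaves

    walk(tree.root)
    return out
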