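"""Synthetic references, multi-sample InDel VCFs, and phenotype tables.

The generator emulates the data a six-accession resequencing study hands to
the marker pipeline: contig-level reference sequence, biallelic InDel loci
with a controlled number of hom-ref / het / hom-alt calls per locus (the
three-digit polymorphic-type composition), per-genotype depth and genotype
quality draws, heterozygote noise, missing calls, a realistic InDel length
spectrum, and a configurable fraction of loci placed too close to a contig
end to support primer design. Every locus is recorded in a ground-truth
table so downstream stages can be checked for exact recovery.

Phenotype tables are multivariate normal draws with requested trait means,
SDs and correlation structure, optionally split into clusters, with the
ordinal plant-color trait discretized to {1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import write_fasta, write_vcf
from .variant_filtering import GenotypeCall, GenotypeState, VariantRecord

#: Polymorphic-type composition observed across 30,845 fully homozygous loci
#: in a six-accession milk-thistle screen, rescaled to 300 loci (largest
#: remainder). Used as the default simulated locus mix.
DEFAULT_COMPOSITION: dict[str, int] = {
    "105": 46,
    "204": 32,
    "303": 33,
    "402": 59,
    "501": 130,
}

#: Default InDel length spectrum: heavily skewed toward short events, with a
#: usable tail past the 15 bp marker threshold and a few >100 bp events that
#: the size window must reject.
DEFAULT_LENGTH_SPECTRUM: tuple[tuple[int, float], ...] = (
    (1, 30), (2, 16), (3, 10), (4, 8), (5, 6), (8, 5), (12, 4),
    (16, 4), (20, 4), (25, 3), (30, 3), (40, 3), (50, 2), (60, 1),
    (80, 1), (110, 0.5), (150, 0.3),
)


def scale_composition(counts: Mapping[str, int], total: int) -> dict[str, int]:
    """Rescale a per-code locus composition to a new total (largest remainder)."""
    grand = sum(counts.values())
    raw = {code: n * total / grand for code, n in counts.items()}
    floors = {code: int(np.floor(v)) for code, v in raw.items()}
    shortfall = total - sum(floors.values())
    by_remainder = sorted(raw, key=lambda c: (raw[c] - floors[c], c), reverse=True)
    for code in by_remainder[:shortfall]:
        floors[code] += 1
    return floors


@dataclass(frozen=True)
class SimSpec:
    """Full specification of one simulated dataset (seed included)."""

    n_contigs: int = 8
    contig_lengths: tuple[int, ...] = (150_000,) * 8
    n_accessions: int = 6
    group_composition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    indel_length_distribution: tuple[tuple[int, float], ...] = DEFAULT_LENGTH_SPECTRUM
    het_noise_rate: float = 0.02
    missing_rate: float = 0.05
    dp_distribution: tuple[float, float] = (30.0, 8.0)
    gq_distribution: tuple[float, float] = (60.0, 15.0)
    edge_fraction: float = 0.05
    min_edge_distance: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.contig_lengths) != self.n_contigs:
            raise ValueError("contig_lengths must have n_contigs entries")
        if any(length <= 0 for length in self.contig_lengths):
            raise ValueError("contig lengths must be positive")
        for rate in (self.het_noise_rate, self.missing_rate, self.edge_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for code in self.group_composition:
            if len(code) != 3 or not code.isdigit():
                raise ValueError(f"bad polymorphic-type code {code!r}")
            if sum(int(d) for d in code) != self.n_accessions:
                raise ValueError(
                    f"code {code!r} digits must sum to n_accessions "
                    f"({self.n_accessions})"
                )
        if any(length <= 0 for length, _ in self.indel_length_distribution):
            raise ValueError("InDel lengths must be positive")

    @property
    def accession_ids(self) -> list[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_accessions)]


def generate_reference(spec: SimSpec) -> dict[str, str]:
    """Random uniform-composition contigs, deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    return {
        f"contig{i + 1:02d}": "".join(
            bases[rng.integers(0, 4, size=length)]
        )
        for i, length in enumerate(spec.contig_lengths)
    }


def _truncated_normal_int(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    draws = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.maximum(draws, 0)


_STATE_FOR_DIGIT = (GenotypeState.HOM_REF, GenotypeState.HET, GenotypeState.HOM_ALT)


def generate_indel_vcf(
    reference: Mapping[str, str], spec: SimSpec
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Simulate biallelic InDel loci with a controlled genotype composition.

    Returns the records (left-anchored REF/ALT, one call per accession) and a
    ground-truth table with the pre-noise code, true size difference,
    direction and contig-edge distance of every locus. Noise is applied in a
    fixed order — heterozygote flips first, then missing masking — so
    expected post-noise counts are computable in closed form.
    """
    rng = np.random.default_rng(spec.seed + 1)
    contig_names = list(reference)
    contig_seqs = [reference[name] for name in contig_names]

    lengths = np.array([l for l, _ in spec.indel_length_distribution])
    weights = np.array([w for _, w in spec.indel_length_distribution], dtype=float)
    weights /= weights.sum()
    max_len = int(lengths.max())

    codes = [
        code for code, n in sorted(spec.group_composition.items()) for _ in range(n)
    ]
    rng.shuffle(codes)
    total = len(codes)
    n_edge = int(round(spec.edge_fraction * total))
    if n_edge > 2 * len(contig_names):
        raise ValueError(
            f"{n_edge} contig-edge loci requested but only "
            f"{2 * len(contig_names)} contig ends available"
        )

    # interior slots: non-overlapping windows clear of both contig ends
    margin = spec.min_edge_distance + 310
    slot_width = 2 * 200 + max_len + 10
    slots: list[tuple[int, int]] = []  # (contig index, 1-based position)
    for ci, seq in enumerate(contig_seqs):
        usable = len(seq) - 2 * margin - max_len
        for j in range(max(0, usable // slot_width)):
            slots.append((ci, margin + 1 + j * slot_width))
    if len(slots) < total - n_edge:
        raise ValueError(
            f"composition needs {total - n_edge} interior loci but contigs "
            f"only fit {len(slots)}"
        )
    slot_order = rng.permutation(len(slots))

    records: list[VariantRecord] = []
    truth_rows: list[dict[str, object]] = []
    for k, code in enumerate(codes):
        is_edge = k < n_edge
        if is_edge:
            ci = k % len(contig_names)
            seq = contig_seqs[ci]
            offset = int(rng.integers(2, max(3, spec.min_edge_distance - max_len)))
            if k < len(contig_names):  # left end
                pos = offset
            else:  # right end
                pos = len(seq) - max_len - offset
        else:
            ci, pos = slots[slot_order[k - n_edge]]
            seq = contig_seqs[ci]
        indel_len = int(rng.choice(lengths, p=weights))
        insertion = bool(rng.integers(0, 2))
        pos0 = pos - 1
        anchor = seq[pos0]
        if insertion:
            ref_allele = anchor
            alt_allele = anchor + "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=indel_len)]
            )
        else:
            ref_allele = seq[pos0 : pos0 + indel_len + 1]
            alt_allele = anchor

        states = [
            _STATE_FOR_DIGIT[digit_idx]
            for digit_idx, digit in enumerate(code)
            for _ in range(int(digit))
        ]
        rng.shuffle(states)
        # het flips first, then missing masking (fixed noise order)
        states = [
            GenotypeState.HET
            if s is not GenotypeState.HET and rng.random() < spec.het_noise_rate
            else s
            for s in states
        ]
        states = [
            GenotypeState.MISSING if rng.random() < spec.missing_rate else s
            for s in states
        ]
        dps = _truncated_normal_int(rng, *spec.dp_distribution, spec.n_accessions)
        gqs = _truncated_normal_int(rng, *spec.gq_distribution, spec.n_accessions)
        calls = tuple(
            GenotypeCall(state=s, depth=int(dp), gq=int(gq))
            for s, dp, gq in zip(states, dps, gqs)
        )
        end = pos + len(ref_allele) - 1
        records.append(
            VariantRecord(
                contig=contig_names[ci],
                position=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                calls=calls,
            )
        )
        truth_rows.append(
            {
                "contig": contig_names[ci],
                "position": pos,
                "true_code": code,
                "size_difference": indel_len,
                "direction": "insertion" if insertion else "deletion",
                "edge_distance": min(pos - 1, len(seq) - end),
            }
        )

    order = sorted(range(total), key=lambda i: (records[i].contig, records[i].position))
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return records, truth


#: Default trait names: plant height (cm), seed weight (g), flower head
#: number, seed weight per flower head (g), spine length (mm), plant color
#: at harvest (ordinal 1-3).
DEFAULT_TRAITS = ("PH", "SW", "FHN", "SW/FHN", "SL", "PC")


def generate_phenotypes(
    n: int,
    trait_means: Sequence[float],
    trait_sds: Sequence[float],
    correlation: np.ndarray,
    n_clusters: int = 1,
    seed: int = 0,
    trait_names: Sequence[str] = DEFAULT_TRAITS,
    cluster_spread: float = 3.0,
) -> pd.DataFrame:
    """Multivariate-normal phenotype table with optional cluster structure.

    ``correlation`` must be symmetric positive semi-definite. With
    ``n_clusters > 1``, accessions are assigned to clusters (labels in
    ``df.attrs['clusters']``) and each cluster's trait means are offset by
    ``cluster_spread`` SDs along a random direction. Physical traits are
    clipped at zero; a trait named 'PC' is discretized to {1, 2, 3}.
    """
    means = np.asarray(trait_means, dtype=float)
    sds = np.asarray(trait_sds, dtype=float)
    corr = np.asarray(correlation, dtype=float)
    p = len(means)
    if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation must be a symmetric p x p matrix")
    if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    rng = np.random.default_rng(seed)
    cov = np.outer(sds, sds) * corr
    values = rng.multivariate_normal(means, cov, size=n, method="svd")
    labels = np.zeros(n, dtype=int)
    if n_clusters > 1:
        labels = rng.integers(0, n_clusters, size=n)
        directions = rng.normal(size=(n_clusters, p))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        values += cluster_spread * directions[labels] * sds
    table = pd.DataFrame(
        values,
        columns=list(trait_names),
        index=[f"A{i + 1:03d}" for i in range(n)],
    )
    for name in trait_names:
        if name == "PC":
            table[name] = np.clip(np.rint(table[name]), 1, 3).astype(int)
        else:
            table[name] = table[name].clip(lower=0.0)
    table.attrs["clusters"] = labels
    return table


def simulate_to_dir(spec: SimSpec, outdir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, VCF and ground-truth TSV for a SimSpec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(spec)
    records, truth = generate_indel_vcf(reference, spec)
    paths = {
        "fasta": outdir / "reference.fa",
        "vcf": outdir / "indels.vcf",
        "truth": outdir / "ground_truth.tsv",
    }
    write_fasta(reference, paths["fasta"])
    contig_lengths = {name: len(seq) for name, seq in reference.items()}
    write_vcf(records, spec.accession_ids, paths["vcf"], contig_lengths)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
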