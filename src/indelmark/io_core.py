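"""Standard-format I/O and printed-table arithmetic.

VCF reading goes through pysam and yields only length-discordant (InDel)
records as :class:`~indelmark.variant_filtering.VariantRecord`. Writing is a
plain-text VCF 4.2 emitter so that a fixed simulation specification produces
byte-identical output. Mapping-statistics tables are recomputed from raw read
counts, and ultrametric trees are serialized to Newick via scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from skbio import TreeNode

from .variant_filtering import GenotypeCall, GenotypeState, VariantRecord


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as report tables conventionally do."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# VCF

_REQUIRED_FORMATS = ("GT", "DP", "GQ")


def _genotype_state(indices: tuple[int | None, ...], alt_index: int) -> GenotypeState:
    if any(i is None for i in indices):
        return GenotypeState.MISSING
    allowed = {0, alt_index}
    if not set(indices) <= allowed:
        # involves some other ALT of a multi-allelic record
        return GenotypeState.MISSING
    if all(i == 0 for i in indices):
        return GenotypeState.HOM_REF
    if all(i == alt_index for i in indices):
        return GenotypeState.HOM_ALT
    return GenotypeState.HET


def read_vcf(path: str | Path, sample_order: Sequence[str]) -> list[VariantRecord]:
    """Read the InDel records of a multi-sample VCF.

    Multi-allelic records are split into one biallelic record per ALT;
    genotypes involving neither REF nor that ALT become missing. SNPs
    (equal-length REF/ALT) and symbolic alleles are skipped.

    Raises ``ValueError`` if GT, DP or GQ is absent from the header FORMAT
    declarations or if ``sample_order`` names a sample not in the file.
    """
    with pysam.VariantFile(str(path)) as vcf:
        for fmt in _REQUIRED_FORMATS:
            if fmt not in vcf.header.formats:
                raise ValueError(f"VCF {path} lacks required FORMAT field {fmt!r}")
        header_samples = list(vcf.header.samples)
        unknown = [s for s in sample_order if s not in header_samples]
        if unknown:
            raise ValueError(f"samples {unknown} not present in VCF {path}")
        records: list[VariantRecord] = []
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or alt.startswith("<") or alt == "*":
                    continue
                if len(alt) == len(rec.ref):
                    continue
                calls = []
                for sample in sample_order:
                    data = rec.samples[sample]
                    gt = data.get("GT", (None,))
                    dp = data.get("DP")
                    gq = data.get("GQ")
                    calls.append(
                        GenotypeCall(
                            state=_genotype_state(tuple(gt), alt_index),
                            depth=int(dp) if dp is not None else 0,
                            gq=int(gq) if gq is not None else 0,
                        )
                    )
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        calls=tuple(calls),
                    )
                )
    return records


_GT_STRING = {
    GenotypeState.HOM_REF: "0/0",
    GenotypeState.HET: "0/1",
    GenotypeState.HOM_ALT: "1/1",
    GenotypeState.MISSING: "./.",
}


def write_vcf(
    records: Iterable[VariantRecord],
    sample_order: Sequence[str],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write biallelic records as plain-text VCF 4.2 (deterministic output)."""
    lines = ["##fileformat=VCFv4.2", "##source=indelmark"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_order),
    ]
    for rec in records:
        fields = [
            rec.contig,
            str(rec.position),
            ".",
            rec.ref_allele,
            rec.alt_allele,
            ".",
            "PASS",
            ".",
            "GT:DP:GQ",
        ]
        fields += [
            f"{_GT_STRING[c.state]}:{c.depth}:{c.gq}" for c in rec.calls
        ]
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load contig sequences keyed by record id (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mapping summary

@dataclass(frozen=True)
class MappingCounts:
    """Raw read-mapping counts for one accession."""

    accession_id: str
    total_trimmed: int
    mapped: int
    unmapped: int
    properly_paired: int

    def __post_init__(self) -> None:
        if self.mapped + self.unmapped != self.total_trimmed:
            raise ValueError(
                f"{self.accession_id}: mapped + unmapped != total_trimmed"
            )
        if self.properly_paired > self.mapped:
            raise ValueError(f"{self.accession_id}: properly_paired > mapped")


def mapping_summary(counts: Sequence[MappingCounts]) -> pd.DataFrame:
    """Per-accession mapping percentages plus a Total row.

    Percentages are recomputed from the raw counts (the Total row from the
    summed counts, not from averaging rows) and rounded half-up to one
    decimal: mapped% and unmapped% of total trimmed reads, properly-paired%
    of total and of mapped reads.
    """
    rows = []
    for c in counts:
        if c.total_trimmed == 0:
            raise ValueError(f"{c.accession_id}: zero total_trimmed, percentages undefined")
        rows.append(c)
    totals = MappingCounts(
        accession_id="Total",
        total_trimmed=sum(c.total_trimmed for c in rows),
        mapped=sum(c.mapped for c in rows),
        unmapped=sum(c.unmapped for c in rows),
        properly_paired=sum(c.properly_paired for c in rows),
    )
    out = []
    for c in [*rows, totals]:
        mapped_pct = round_half_up(c.mapped / c.total_trimmed * 100, 1)
        out.append(
            {
                "accession": c.accession_id,
                "total_trimmed": c.total_trimmed,
                "mapped": c.mapped,
                "unmapped": c.unmapped,
                "properly_paired": c.properly_paired,
                "properly_paired_pct": round_half_up(
                    c.properly_paired / c.total_trimmed * 100, 1
                ),
                "mapped_pct": mapped_pct,
                "unmapped_pct": round_half_up(100 - mapped_pct, 1),
                "properly_paired_of_mapped_pct": round_half_up(
                    c.properly_paired / c.mapped * 100, 1
                ),
            }
        )
    return pd.DataFrame(out).set_index("accession")


# ---------------------------------------------------------------------------
# Newick

def _as_treenode(tree) -> TreeNode:
    if hasattr(tree, "to_treenode"):
        return tree.to_treenode()
    if isinstance(tree, TreeNode):
        return tree
    raise TypeError(f"cannot serialize {type(tree).__name__} as Newick")


def write_newick(tree, path: str | Path) -> None:
    """Serialize an ultrametric tree (or any scikit-bio TreeNode) to Newick.

    Raises on an empty tree or duplicate leaf labels.
    """
    node = _as_treenode(tree)
    labels = [tip.name for tip in node.tips()]
    if not labels:
        raise ValueError("refusing to write an empty tree")
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    node.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
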