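"""Two-stage genotype-aware filtering of multi-sample InDel loci.

The screening proceeds in two passes. The *relaxed* pass applies per-genotype
minima (depth, genotype quality) by masking failing calls to missing, then
drops loci whose missing fraction exceeds the allowed maximum and loci that
are monomorphic among the remaining non-missing calls. The *strict* pass then
keeps only loci where every accession carries an unambiguous homozygous call
— the prerequisite for coding a locus as a three-digit polymorphic type with
no heterozygote component and for designing codominant PCR markers from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .config import RunConfig

logger = logging.getLogger(__name__)


class GenotypeState(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class GenotypeCall:
    """One accession's diploid call at a locus, with its support metrics."""

    state: GenotypeState
    depth: int = 0
    gq: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.gq < 0:
            raise ValueError("depth and gq must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic locus with one genotype call per accession.

    Positions are 1-based as in VCF. For InDel records the reference and
    alternative alleles differ in length; both are stored left-anchored
    (shared leading base), the convention of standard variant callers.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    calls: tuple[GenotypeCall, ...]

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    def state_counts(self) -> dict[GenotypeState, int]:
        counts = {state: 0 for state in GenotypeState}
        for call in self.calls:
            counts[call.state] += 1
        return counts


@dataclass
class FilterReport:
    """Accounting for one filter stage: how many loci went in and came out."""

    stage: str
    records_in: int = 0
    records_out: int = 0
    genotypes_masked: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records_out > self.records_in:
            raise ValueError("records_out cannot exceed records_in")


def _mask_low_quality(record: VariantRecord, cfg: RunConfig) -> tuple[VariantRecord, int]:
    masked = 0
    new_calls = []
    for call in record.calls:
        if call.state is not GenotypeState.MISSING and (
            call.depth < cfg.min_depth or call.gq < cfg.min_gq
        ):
            new_calls.append(replace(call, state=GenotypeState.MISSING))
            masked += 1
        else:
            new_calls.append(call)
    if masked:
        record = replace(record, calls=tuple(new_calls))
    return record, masked


def relaxed_filter(
    records: Iterable[VariantRecord], cfg: RunConfig
) -> tuple[list[VariantRecord], FilterReport]:
    """Mask sub-threshold genotypes, then drop high-missingness and
    monomorphic loci.

    A genotype with depth below ``cfg.min_depth`` or genotype quality below
    ``cfg.min_gq`` is set to missing (the call is discarded, not the locus).
    A locus is removed if its missing fraction exceeds
    ``cfg.max_missing_fraction``, or if all remaining non-missing calls agree
    on a single homozygous class (no allele contrast left to genotype).
    Input order is preserved.
    """
    report = FilterReport(stage="relaxed")
    kept: list[VariantRecord] = []
    removed = {"missingness": 0, "monomorphic": 0}
    for record in records:
        report.records_in += 1
        record, masked = _mask_low_quality(record, cfg)
        report.genotypes_masked += masked
        counts = record.state_counts()
        n = len(record.calls)
        if n == 0 or counts[GenotypeState.MISSING] / n > cfg.max_missing_fraction:
            removed["missingness"] += 1
            continue
        informative = n - counts[GenotypeState.MISSING]
        if (
            counts[GenotypeState.HOM_REF] == informative
            or counts[GenotypeState.HOM_ALT] == informative
        ):
            removed["monomorphic"] += 1
            continue
        kept.append(record)
    report.records_out = len(kept)
    report.removed = removed
    logger.info(
        "relaxed filter: %d loci in, %d out (%d genotypes masked; %d dropped "
        "for missingness, %d monomorphic)",
        report.records_in,
        report.records_out,
        report.genotypes_masked,
        removed["missingness"],
        removed["monomorphic"],
    )
    return kept, report


def strict_filter(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep only loci where every accession is homozygous and called.

    Any heterozygous or missing call disqualifies the whole locus. Survivors
    of a preceding :func:`relaxed_filter` are guaranteed to retain at least
    one hom-ref and one hom-alt accession (monomorphic loci were already
    removed there).
    """
    report = FilterReport(stage="strict")
    kept: list[VariantRecord] = []
    removed = {"het_or_missing": 0}
    for record in records:
        report.records_in += 1
        counts = record.state_counts()
        if counts[GenotypeState.HET] or counts[GenotypeState.MISSING]:
            removed["het_or_missing"] += 1
            continue
        kept.append(record)
    report.records_out = len(kept)
    report.removed = removed
    logger.info(
        "strict filter: %d loci in, %d out (%d dropped for het/missing calls)",
        report.records_in,
        report.records_out,
        removed["het_or_missing"],
    )
    return kept, report


def filter_report_tsv(reports: Sequence[FilterReport]) -> str:
    lines = ["stage\trecords_in\trecords_out\tgenotypes_masked"]
    for rep in reports:
        lines.append(
            f"{rep.stage}\t{rep.records_in}\t{rep.records_out}\t{rep.genotypes_masked}"
        )
    return "\n".join(lines) + "\n"
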