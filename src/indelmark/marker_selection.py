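"""Polymorphic-type classification and PCR-marker candidate selection.

A locus observed across *n* accessions is summarized as a three-digit code
``hma``: the count of accessions homozygous for the reference allele, the
count of heterozygotes, and the count homozygous for the alternative allele.
With six accessions the fully homozygous codes are '105', '204', '303',
'402' and '501'; the balanced '303' type (three accessions per allele) is
the most discriminating configuration and is the default marker target.

Candidate markers are then restricted to a gel-resolvable size-difference
window (15-100 bp inclusive by default), required to sit more than 200 bp
from either contig end so that flanking sequence is available for primer
design, and labeled insertion or deletion relative to the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .variant_filtering import GenotypeState, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolymorphicType:
    """Three-digit genotype-class code for a locus, e.g. '303'.

    ``n_missing`` counts calls excluded from all three digits when the locus
    still carries missing data (classification before the strict filter).
    """

    code: str
    n_missing: int = 0

    def __str__(self) -> str:
        return self.code


def classify_polymorphic_type(record: VariantRecord) -> PolymorphicType:
    """Code a locus by its (hom-ref, het, hom-alt) accession counts.

    Missing calls contribute to no digit and are reported via ``n_missing``.
    Raises if any class count exceeds 9 (the code is digit-limited).
    """
    counts = record.state_counts()
    h = counts[GenotypeState.HOM_REF]
    m = counts[GenotypeState.HET]
    a = counts[GenotypeState.HOM_ALT]
    if max(h, m, a) > 9:
        raise ValueError(
            f"{record.contig}:{record.position}: class count exceeds 9, "
            "not representable as a three-digit code"
        )
    return PolymorphicType(code=f"{h}{m}{a}", n_missing=counts[GenotypeState.MISSING])


def size_difference(record: VariantRecord) -> int:
    """Absolute REF/ALT length difference in bp."""
    diff = abs(len(record.ref_allele) - len(record.alt_allele))
    if diff == 0:
        raise ValueError(
            f"{record.contig}:{record.position}: equal-length alleles, not an InDel"
        )
    return diff


def grouping_table(
    records: Iterable[VariantRecord],
    thresholds: Sequence[int] = (15, 20, 25),
) -> pd.DataFrame:
    """Count loci per polymorphic-type code, overall and at size thresholds.

    Columns: ``n`` (all loci of that code) and one ``>=T bp`` column per
    threshold, counting loci whose size difference is at least T. A Total
    row holds the column sums.
    """
    thresholds = sorted(thresholds)
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        code = classify_polymorphic_type(rec).code
        row = counts.setdefault(
            code, {"n": 0, **{f">={t} bp": 0 for t in thresholds}}
        )
        row["n"] += 1
        diff = size_difference(rec)
        for t in thresholds:
            if diff >= t:
                row[f">={t} bp"] += 1
    columns = ["n"] + [f">={t} bp" for t in thresholds]
    table = pd.DataFrame.from_dict(counts, orient="index", columns=columns)
    table = table.sort_index()
    table.loc["Total"] = table.sum()
    table.index.name = "code"
    return table.astype(int)


@dataclass(frozen=True)
class MarkerCandidate:
    """A selected InDel locus with everything needed to design a PCR assay."""

    marker_id: str
    source: VariantRecord
    size_difference: int
    direction: str  # 'insertion' | 'deletion' relative to the reference
    edge_distance: int
    left_flank: str
    right_flank: str
    expected_fragments: tuple[tuple[int, ...], ...] = ()
    """Per accession, the predicted fragment size(s): one size for a
    homozygote, both for a heterozygote, empty if the call is missing."""

    @property
    def expected_ref_size(self) -> int:
        return len(self.left_flank) + len(self.source.ref_allele) + len(self.right_flank)

    @property
    def expected_alt_size(self) -> int:
        return len(self.left_flank) + len(self.source.alt_allele) + len(self.right_flank)


@dataclass
class ExclusionReport:
    """Itemized record of why each rejected locus was dropped."""

    excluded: list[tuple[str, str]] = field(default_factory=list)  # (locus id, rule)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, rule in self.excluded:
            out[rule] = out.get(rule, 0) + 1
        return out


def edge_distance(record: VariantRecord, contig_length: int) -> int:
    """Reference bases between the variant and the nearer contig end.

    Computed on 1-based inclusive coordinates: ``pos - 1`` bases lie left of
    the leftmost affected base and ``contig_length - end`` lie right of the
    last affected reference base.
    """
    end = record.position + len(record.ref_allele) - 1
    if end > contig_length:
        raise ValueError(
            f"{record.contig}:{record.position}: variant overruns contig "
            f"of length {contig_length}"
        )
    return min(record.position - 1, contig_length - end)


def _expected_fragments(
    record: VariantRecord, ref_size: int, alt_size: int
) -> tuple[tuple[int, ...], ...]:
    out = []
    for call in record.calls:
        if call.state is GenotypeState.HOM_REF:
            out.append((ref_size,))
        elif call.state is GenotypeState.HOM_ALT:
            out.append((alt_size,))
        elif call.state is GenotypeState.HET:
            out.append((ref_size, alt_size))
        else:
            out.append(())
    return tuple(out)


def select_candidates(
    records: Iterable[VariantRecord],
    reference: Mapping[str, str],
    cfg: RunConfig,
    flank_len: int = 200,
) -> tuple[list[MarkerCandidate], ExclusionReport]:
    """Select marker candidates of the target polymorphic type.

    Keeps loci whose code equals ``cfg.target_code``, whose size difference
    lies in ``[cfg.min_size_diff, cfg.max_size_diff]`` and which sit strictly
    more than ``cfg.min_edge_distance`` bp from either contig end. Rejected
    loci are itemized with the first rule they failed. Candidates are
    returned in (contig, position) order with flanks of ``flank_len`` bp
    (clipped to the available contig sequence) and per-accession expected
    fragment sizes.
    """
    report = ExclusionReport()
    candidates: list[MarkerCandidate] = []
    for rec in sorted(records, key=lambda r: (r.contig, r.position)):
        locus = f"{rec.contig}:{rec.position}"
        if rec.contig not in reference:
            raise KeyError(f"contig {rec.contig!r} absent from reference")
        code = classify_polymorphic_type(rec).code
        if code != cfg.target_code:
            report.excluded.append((locus, f"code {code} != target {cfg.target_code}"))
            continue
        diff = size_difference(rec)
        if diff < cfg.min_size_diff:
            report.excluded.append((locus, f"size {diff} < {cfg.min_size_diff} bp"))
            continue
        if diff > cfg.max_size_diff:
            report.excluded.append((locus, f"size {diff} > {cfg.max_size_diff} bp"))
            continue
        contig_seq = reference[rec.contig]
        dist = edge_distance(rec, len(contig_seq))
        if dist <= cfg.min_edge_distance:
            report.excluded.append(
                (locus, f"edge distance {dist} <= {cfg.min_edge_distance} bp")
            )
            continue
        flank = min(flank_len, dist)
        pos0 = rec.position - 1  # 0-based leftmost affected base
        ref_end = pos0 + len(rec.ref_allele)
        left = contig_seq[pos0 - flank : pos0]
        right = contig_seq[ref_end : ref_end + flank]
        direction = (
            "insertion" if len(rec.alt_allele) > len(rec.ref_allele) else "deletion"
        )
        ref_size = flank * 2 + len(rec.ref_allele)
        alt_size = flank * 2 + len(rec.alt_allele)
        candidates.append(
            MarkerCandidate(
                marker_id=f"SM{len(candidates) + 1:03d}",
                source=rec,
                size_difference=diff,
                direction=direction,
                edge_distance=dist,
                left_flank=left,
                right_flank=right,
                expected_fragments=_expected_fragments(rec, ref_size, alt_size),
            )
        )
    logger.info(
        "candidate selection: %d kept, %d excluded (%s)",
        len(candidates),
        len(report.excluded),
        report.counts(),
    )
    return candidates, report


def extract_flanks(
    candidate: MarkerCandidate,
    reference: Mapping[str, str],
    flank_len: int,
) -> dict[str, object]:
    """Build a Primer3-ready region record around a candidate InDel.

    Returns left/right flanks of exactly ``flank_len`` bp, the combined
    template (left + REF allele + right), and the target interval within the
    template, plus the record serialized as Primer3 tag=value text.
    """
    rec = candidate.source
    contig_seq = reference[rec.contig]
    if candidate.edge_distance < flank_len:
        raise ValueError(
            f"{candidate.marker_id}: flank of {flank_len} bp overruns contig "
            f"(edge distance {candidate.edge_distance} bp)"
        )
    pos0 = rec.position - 1
    ref_end = pos0 + len(rec.ref_allele)
    left = contig_seq[pos0 - flank_len : pos0]
    right = contig_seq[ref_end : ref_end + flank_len]
    template = left + rec.ref_allele + right
    target_start = flank_len  # 0-based within template
    target_len = len(rec.ref_allele)
    primer3_text = (
        f"SEQUENCE_ID={candidate.marker_id}\n"
        f"SEQUENCE_TEMPLATE={template}\n"
        f"SEQUENCE_TARGET={target_start},{target_len}\n"
        "=\n"
    )
    return {
        "marker_id": candidate.marker_id,
        "left_flank": left,
        "right_flank": right,
        "template": template,
        "target": (target_start, target_len),
        "primer3": primer3_text,
    }


def candidates_tsv(candidates: Sequence[MarkerCandidate]) -> str:
    lines = [
        "marker_id\tcontig\tposition\tsize_difference\tdirection\tedge_distance"
        "\texpected_ref_size\texpected_alt_size"
    ]
    for c in candidates:
        lines.append(
            f"{c.marker_id}\t{c.source.contig}\t{c.source.position}\t"
            f"{c.size_difference}\t{c.direction}\t{c.edge_distance}\t"
            f"{c.expected_ref_size}\t{c.expected_alt_size}"
        )
    return "\n".join(lines) + "\n"
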