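"""Classify loci into polymorphic types and select '303' marker candidates.

Each locus is coded by three digits: accessions homozygous-reference /
heterozygous / homozygous-alternative. The balanced '303' type splits six
accessions 3:3 and is the most informative for fingerprinting. Candidates
must also have a 15-100 bp size difference (resolvable on agarose gel) and
sit >200 bp from a contig end (room for primers).
"""

from indelmark import (
    RunConfig,
    SimSpec,
    extract_flanks,
    grouping_table,
    relaxed_filter,
    select_candidates,
    strict_filter,
)
from indelmark.synthetic_data import generate_indel_vcf, generate_reference

spec = SimSpec(seed=42, het_noise_rate=0.0, missing_rate=0.0,
               dp_distribution=(50, 5), gq_distribution=(80, 5))
reference = generate_reference(spec)
records, _ = generate_indel_vcf(reference, spec)
cfg = RunConfig()
strict, _ = strict_filter(relaxed_filter(records, cfg)[0])

table = grouping_table(strict)
print("polymorphic-type grouping (loci per code, and at size thresholds):")
print(table.to_string())

candidates, report = select_candidates(strict, reference, cfg)
print(f"\n'303' candidates passing size and contig-edge rules: {len(candidates)}")
for rule, n in sorted(report.counts().items()):
    print(f"  excluded {n:3d}: {rule}")

if candidates:
    region = extract_flanks(candidates[0], reference, flank_len=200)
    print(f"\nfirst candidate {candidates[0].marker_id}: "
          f"{candidates[0].direction} of {candidates[0].size_difference} bp, "
          f"expected fragments {candidates[0].expected_ref_size}/"
          f"{candidates[0].expected_alt_size} bp with 200 bp primer flanks")
    print("Primer3 record starts:", region["primer3"].splitlines()[0])
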