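"""Recompute a read-mapping summary table from raw per-accession counts.

Percentages are always derived from the raw counts — the Total row from the
summed counts rather than averaged percentages — and rounded half-up to one
decimal, the convention of sequencing-report tables.
"""

from indelmark import mapping_summary
from indelmark.datasets import MAPPING_COUNTS

table = mapping_summary(list(MAPPING_COUNTS))
print(table[["mapped_pct", "unmapped_pct", "properly_paired_pct",
             "properly_paired_of_mapped_pct"]].to_string())
print(f"\n{table.loc['Total', 'total_trimmed']:,} trimmed reads overall; "
      f"{table.loc['Total', 'mapped_pct']}% mapped to the reference "
      "assembly, of which "
      f"{table.loc['Total', 'properly_paired_of_mapped_pct']}% were "
      "properly paired")
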