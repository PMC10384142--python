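"""Published summary tables from the six-accession milk-thistle screen.

These are the printed inputs of the study this package operationalizes:
read-mapping counts per accession, the six selected accessions' trait
values, the polymorphic-type grouping counts over the 30,845 strictly
filtered InDels, and the wet-lab validation outcome counts for the 231
tested markers. They let the report arithmetic (percentages, totals,
means +/- SD) be recomputed from raw counts, and they parameterize
realistic synthetic datasets.
"""

from __future__ import annotations

import pandas as pd

from .io_core import MappingCounts

#: Trimmed/mapped/properly-paired read counts per accession (raw counts;
#: every percentage is derived from these).
MAPPING_COUNTS: tuple[MappingCounts, ...] = (
    MappingCounts("M01", 108_554_670, 97_690_066, 10_864_604, 81_978_182),
    MappingCounts("M02", 136_302_598, 116_215_035, 20_087_563, 96_982_188),
    MappingCounts("M03", 146_110_578, 131_474_969, 14_635_609, 109_901_174),
    MappingCounts("M04", 146_000_972, 130_085_152, 15_915_820, 108_315_504),
    MappingCounts("M05", 121_009_526, 104_304_345, 16_705_181, 86_915_402),
    MappingCounts("M06", 122_017_832, 107_898_658, 14_119_174, 90_503_310),
)

ACCESSIONS = ("M01", "M02", "M03", "M04", "M05", "M06")

#: Six-accession trait values: plant height (cm), seed weight (g), flower
#: head number, seed weight per flower head (g), spine length (mm), plant
#: color at harvest (1=green, 2=brown, 3=green-brown).
SIX_ACCESSION_TRAITS = pd.DataFrame(
    {
        "PH": [121.5, 100.1, 136.2, 141.6, 131.9, 134.2],
        "SW": [116.1, 79.5, 118.8, 97.2, 142.0, 109.1],
        "FHN": [40.4, 38.7, 37.7, 25.4, 43.9, 45.0],
        "SW/FHN": [2.7, 2.1, 3.0, 3.8, 3.2, 2.4],
        "SL": [39.7, 46.4, 43.9, 28.7, 45.8, 22.9],
        "PC": [2.7, 2.7, 2.7, 2.3, 2.7, 2.7],
    },
    index=list(ACCESSIONS),
)

#: Population-level trait means and sample SDs over all 220 accessions.
POPULATION_TRAIT_MOMENTS = pd.DataFrame(
    {
        "mean": [109.8, 112.2, 37.5, 2.6, 20.7, 2.6],
        "sd": [27.0, 85.0, 21.7, 1.4, 6.0, 0.8],
    },
    index=["PH", "SW", "FHN", "SW/FHN", "SL", "PC"],
)

#: Locus counts per polymorphic-type code among the strictly filtered
#: InDels, with counts at increasing size-difference thresholds.
GROUPING_COUNTS = pd.DataFrame(
    {
        "n": [4750, 3334, 3410, 6114, 13_237],
        ">=15 bp": [259, 207, 234, 480, 1161],
        ">=20 bp": [165, 127, 161, 321, 777],
        ">=25 bp": [114, 92, 115, 221, 557],
    },
    index=["105", "204", "303", "402", "501"],
)

#: Size differences (bp) of the three selected '303' candidates that
#: exceeded the 100 bp gel-resolvability ceiling and were dropped.
OVERSIZED_CANDIDATE_DIFFS = (107, 176, 248)

#: Wet-lab validation outcome counts over the 231 tested markers.
VALIDATION_COUNTS = {"polymorphic": 177, "failed_amplification": 33, "monomorphic": 21}

#: Markers scoring a polymorphic band between the two Korean native
#: accessions (M05 vs M06) out of the 231 tested.
M05_M06_POLYMORPHIC = 171
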