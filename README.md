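# indelmark

InDel marker development and germplasm fingerprinting for small accession
panels, from a multi-sample VCF and a contig-level reference assembly.

Resequencing a handful of germplasm accessions against a draft assembly
yields millions of insertion/deletion variants; only a tiny, carefully
screened subset makes useful PCR markers. `indelmark` implements that
screen end to end for an *n*-accession panel (the motivating use case is a
six-accession milk-thistle, *Silybum marianum*, panel M01–M06):

1. **Two-stage genotype filtering** — per-genotype minima (depth ≥ 10,
   genotype quality ≥ 30) mask individual calls; loci with > 20 % missing
   calls or no allele contrast are dropped (relaxed pass); loci with any
   heterozygous or missing call are then removed (strict pass).
2. **Polymorphic-type classification** — each locus is coded by three
   digits *(h, m, a)*: accessions homozygous-reference, heterozygous, and
   homozygous-alternative. For six accessions the fully homozygous codes
   are '105', '204', '303', '402', '501'; the balanced **'303'** type
   (3 : 3 split) is the most discriminating and is the marker target.
3. **Candidate selection** — '303' loci with a REF/ALT size difference in
   [15, 100] bp (resolvable on agarose) and > 200 bp from either contig
   end (room for primers) become marker candidates, with flanking sequence
   and Primer3-ready region records.
4. **Codominant fingerprinting** — fragment sizes are scored as alleles
   (A = reference size, B = alternative, H = both, C/D = novel fragments
   ≥ 30 bp larger than both expected sizes, lettered in detection order),
   expanded to 1/0 band columns, compared by Jaccard similarity
   S = n₁₁/(n₁₁+n₁₀+n₀₁), clustered by UPGMA (1 − S), and reduced to the
   **minimum discriminating marker set** by exhaustive subset search.
5. **Phenotype statistics** — trait mean ± SD summaries, Welch
   subset-vs-population contrasts, Pearson correlations,
   correlation-matrix PCA with component–trait-correlation loadings, and
   Ward clustering of standardized traits.

A first-class synthetic-data module generates reference contigs,
multi-sample InDel VCFs with controlled genotype-class composition
(plus DP/GQ draws, heterozygote noise, missingness and contig-edge
placement) and phenotype tables with specified moments — every stage is
testable against known ground truth without external data.

## Worked example

```python
from indelmark import (RunConfig, SimSpec, generate_reference,
                       generate_indel_vcf, relaxed_filter, strict_filter,
                       grouping_table, select_candidates)

spec = SimSpec(seed=42, het_noise_rate=0.05, missing_rate=0.05)
reference = generate_reference(spec)
records, truth = generate_indel_vcf(reference, spec)
cfg = RunConfig()
relaxed, r1 = relaxed_filter(records, cfg)
strict, r2 = strict_filter(relaxed)
print(len(records), len(relaxed), len(strict))
```

prints `300 255 143`: of 300 simulated loci, 255 survive the relaxed pass
(57 genotypes were masked for low DP/GQ) and 143 are fully homozygous
across all six accessions. Grouping and selecting from a zero-noise run
(`examples/02_group_and_select_markers.py`):

```
         n  >=15 bp  >=20 bp  >=25 bp
105     46        9        8        6
204     32        4        3        1
303     33        7        6        5
402     59       14       12       11
501    130       27       22       18
Total  300       61       51       41

'303' candidates passing size and contig-edge rules: 7
```

33 of 300 loci are balanced '303'; 7 of those also clear the 15–100 bp
size window and the 200 bp contig-edge rule, and leave as marker
candidates with expected fragment sizes and Primer3 input records. The
`examples/` directory holds one short script per capability (simulation +
filtering, marker selection, fingerprinting, phenotype statistics, mapping
reports); each prints the numbers it computes and what they mean. A thin
CLI mirrors the same stages
(`indelmark simulate|filter|group|select|fingerprint|phenostats`).

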