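# scubshift

Synonymous codon usage bias (SCUB) shift analysis for paired CDS collections:
a recipient cultivar and a derived (somatic-hybrid) line.

Given two CDS FASTA files, optional pairwise alignments and an optional
chromosome-assignment table, the pipeline computes:

- **Overall SCUB** — per-amino-acid C/G-ending over A/T-ending ratios across
  the 59-codon synonymous set (stops, ATG and TGG excluded), and the total
  NNA/NNT/NNC/NNG third-position frequencies, with cross-sample chi-square
  tests on the raw counts.
- **Partitioned SCUB** — the same tables per mapped/unmapped,
  introgressed/non-introgressed chromosome sets, allelic groups 1–7 and
  sub-genomes A/B/D, plus cross-partition consistency (coefficient of
  variation and Cronbach's alpha).
- **Indel-region SCUB** — indels detected as gap runs in pairwise alignments;
  codons classified into 5′-flank, 3′-flank, two-sides and remote regions
  (15-codon windows, >45 nt terminal exclusion, <90 nt inter-indel segments
  dropped) with region-wise ending tables and tests.
- **Methylation signature** — CpG-deamination ratios: within-codon NXA/NXG,
  codon-boundary NT|X/NC|X, per-amino-acid A/G-ending codon pairs, and
  hybrid/recipient ratio-of-ratios with chi-square and t-tests.
- **Synthetic data** — a seeded generator producing ancestral/derived CDS
  pairs with configurable CpG-context and indel-proximal substitution
  enrichment, frame-preserving deletions, gap-exact alignments, a
  21-chromosome assignment table and a full replayable event log.

## CLI

```sh
# generate a synthetic bundle (FASTA pair, alignments, chromosome map, truth)
scubshift simulate --out sim/ --seed 1 --n-records 200 --length 200 \
    --sub-rate 0.01 --cpg-multiplier 10 --indel-rate 0.5

# run the full analysis
scubshift analyze --recipient sim/recipient.fasta --hybrid sim/hybrid.fasta \
    --aligned sim/aligned.fasta --chrom-map sim/chromosome_map.tsv --out analysis/

# print the summary of a finished run
scubshift report --analysis-dir analysis/
```

`analyze` also accepts a YAML config (`--config`, keys mirroring
`scubshift.pipeline.AnalysisConfig`); the introgressed chromosome set defaults
to `1B 1D 2A 2D 5B 6D` and is configurable (`--introgressed`). Omitting
`--aligned` skips the indel-region stage and leaves the others unchanged.

Outputs are TSV tables (`per_aa_scub.tsv`, `ending_frequencies.tsv`,
`ending_tests.tsv`, `methylation_ratios.tsv`, `aa_pair_ratios.tsv`,
`region_frequencies.tsv`, `region_tests.tsv`, `consistency_cv.tsv`,
`consistency_alpha.tsv`, …) that always carry the raw counts next to each
ratio/p-value, plus `summary.json` and a run `manifest.json`. Reruns with the
same seed are byte-identical.

## Library use

```python
from scubshift import (
    generate_ancestral_cds, mutate_genome, MutationParams,
    count_synonymous_codons, extract_codons, total_ending_frequencies,
)

ancestral = generate_ancestral_cds(100, 200, seed=7)
result = mutate_genome(ancestral, MutationParams(sub_rate=0.01, cpg_multiplier=10, seed=7))
counts = count_synonymous_codons(extract_codons(result.derived[0]))
print(total_ending_frequencies(counts))
```
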