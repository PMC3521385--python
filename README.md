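# mitocount

Estimate mitochondrial DNA (mtDNA) copy number from paired-end whole-genome
sequencing (WGS) reads.

A WGS library samples nuclear and mitochondrial molecules in proportion to
their base content, so the fraction of sequenced bases that came from the
mitochondrial genome determines the average number of mtDNA copies per
diploid nuclear genome equivalent:

```
mtBases / allBases = k·M / (ploidy·N + k·M)
k = mtBases · ploidy · N / ((allBases − mtBases) · M)
```

where `N` is the haploid nuclear base count, `M` the mitochondrial genome
length and `k` the copy number.

The assay runs in three stages:

1. **Typing** (`mitocount.mito_typing`) — reconstruct the sample's
   homoplasmic mitochondrial consensus by guided greedy overlap assembly:
   a reference mtDNA picks a beginning and an ending anchor read from the
   pool, extension proceeds by longest verified overlap, and each position
   is called by majority vote over all covering reads (so homoplasmic
   differences from the reference are retained).
2. **Separation** (`mitocount.read_classifier`) — classify every read pair
   with an error-tolerant seed-and-verify mapper against the circular
   consensus; a pair counts as mitochondrial only when both mates place on
   opposite strands with a circular pairing distance inside the insert
   window. Per-run base totals land in a CSV. A minimal allele pileup over
   the separated reads flags candidate heteroplasmic sites.
3. **Estimation** (`mitocount.copy_number`) — pool per-run counts, apply
   the copy-number formula, and compare sample groups with a one-way ANOVA
   over per-run ratios.

`mitocount.simulate` generates synthetic paired-end datasets with a planted
copy number, reference divergence, sequencing error, optional heteroplasmy
and optional NUMT (nuclear copy of a mitochondrial segment), plus per-pair
truth labels — everything here is tested against it without any downloads.

## CLI

```sh
# synthetic dataset with truth labels
mitocount simulate --nuclear-length 2000000 --mito-length 16569 --true-k 650 \
    --n-pairs 200000 --error-rate 0.01 --mito-divergence 20 --seed 1 --out-dir sim/

# stage 1: type the consensus
mitocount type --reference sim/mito_reference.fasta \
    --reads sim/reads_R1.fastq --reads sim/reads_R2.fastq --out-prefix typed

# stage 2: separate mitochondrial pairs per run
mitocount count --consensus typed.consensus.fasta \
    --run run1:sim/reads_R1.fastq,sim/reads_R2.fastq --out runs.csv

# stage 3: estimate the copy number
mitocount estimate --runs-csv runs.csv --nuclear-bases 2000000 \
    --consensus typed.consensus.fasta --sample demo --out summary.csv

# group comparison (one per-run CSV per group)
mitocount compare sampleA.runs.csv sampleB.runs.csv sampleC.runs.csv

# or everything at once from a JSON manifest
mitocount pipeline --manifest manifest.json --reference sim/mito_reference.fasta \
    --nuclear-bases 2000000 --out-dir out/
```

The manifest is JSON:
`{"sample_id": "s1", "runs": [{"run_id": "r1", "paths": ["R1.fastq", "R2.fastq"]}]}`.
FASTQ inputs may be gzipped; interleaved files take `--interleaved`.

The per-run CSV schema is frozen:
`run_id,total_reads,mito_reads,all_bases,mt_bases,mt_ratio`.

## Notes and known limitations

- Substitution-only model throughout (no indel-aware overlaps or gapped
  alignment); Illumina-style paired-end data is the target.
- Reads matching both the nuclear and mitochondrial genome (NUMTs) cannot
  be distinguished by a single-genome filter; any pair passing the
  mitochondrial gate is counted, a documented bias source. The simulator's
  `--numt-length` flag exercises it.
- `N` (haploid nuclear base count) is a required input: pass a constant
  via `--nuclear-bases`.
- Not suitable for organisms whose organellar genomes exchange segments
  with the nuclear genome (e.g. plants).
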