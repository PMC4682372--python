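# subsetq

Quality-based subset selection of high-depth sequencing reads for *de novo*
assembly. When a dataset is sequenced far deeper than an assembler needs,
`subsetq` picks the most trustworthy fraction of it using per-read quality
statistics:

* **minimal quality (MQV)** — the smallest Phred score in a read; reads are
  kept when their MQV is at or above a threshold;
* **product score** — the product over bases of the correctness probability
  `1 - 10^(-Q/10)`, either over the whole read (overlap-graph assemblers) or
  as the minimum over all `L - k + 1` length-`k` windows (de Bruijn graph
  assemblers); reported on a 0–100 scale;
* **PE-MQV** — the minimum of the two mates' MQVs, so a pair is kept or
  dropped as a unit;
* a seeded **random baseline** for comparison.

Thresholds are read off the cumulative score distribution for a target
subset fraction, or derived from a target coverage depth; when no reference
genome is available, genome size and depth are estimated from the k-mer
multiplicity spectrum. A seeded synthetic-FASTQ generator makes the whole
pipeline testable without external data.

## Command-line usage

All subcommands accept plain or gzip-compressed FASTQ (Phred+33 by default,
`--offset 64` for legacy encodings). Logs go to stderr; reports are JSON.

```sh
# 1. synthesize a paired dataset (or bring your own FASTQ)
subsetq synth --n 100000 --paired --read-length 150 --seed 7 --out pe.fastq

# 2. score distribution + cumulative percentages + dataset summary
subsetq stats pe.fastq --kind pe-mqv -o pe            # writes pe.hist.tsv, pe.cum.tsv, pe.summary.json

# 3. pick a threshold for a target subset fraction ...
subsetq threshold --hist pe.hist.tsv --target-fraction 0.5 --report th.json

#    ... or for a target coverage depth (genome size known or estimated)
subsetq estimate pe.fastq --k 25 --report est.json
subsetq threshold --hist pe.hist.tsv --target-depth 60 \
    --genome-size 1.1e9 --total-bases 125e9 --report th.json

# 4. emit the subset (FASTA by default, --out-format fastq to keep qualities)
subsetq filter-pe pe.fastq --threshold 21 --out subset.fa --report sel.json
```

Single-end filtering supports `--mode minq`, `--mode productq` (optionally
windowed with `--k`), and `--mode random --fraction F --seed S`:

```sh
subsetq filter-se reads.fastq --mode productq --threshold 0.10 --k 21 --out subset.fa
subsetq score reads.fastq --mode minq --out scores.tsv
```

Paired input may be interleaved (single file) or two synchronized files
(`-2 mate2.fastq`, with `--out2` for split output). `stats` processes data
in chunks (`--chunk-size`, `--workers`); results are bit-identical to the
serial computation regardless of chunking.

## Library layout

| module | contents |
| --- | --- |
| `subsetq.fastq_io` | FASTQ/FASTA streaming, gzip transparency, pair synchronization |
| `subsetq.scoring` | quality decoding, error probabilities, MQV / product / windowed scores, PE-MQV |
| `subsetq.stats` | histograms, cumulative views, dataset summaries, deterministic chunk-merge |
| `subsetq.selection` | threshold determination, SE/PE/random filters, selection reports |
| `subsetq.kmer_coverage` | k-mer multiplicity spectra, genome-size and depth estimation |
| `subsetq.simulate` | seeded quality models, synthetic reads/pairs, toy-genome read sampling |
| `subsetq.cli` | `subsetq` subcommands wiring the stages together |
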