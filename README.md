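# miniolc

A desk-scale hierarchical overlap–layout–consensus (OLC) assembler for
noisy long reads (PacBio/Nanopore-like), built for studying how an
assembler separates near-identical repeats by error-rate statistics
alone. It implements the full pipeline of a modern hierarchical
assembler at sizes that run on a laptop:

* **adaptive tf–idf weighted MinHash overlapping** — candidate read pairs
  from fixed-size sketches where a k-mer with weight
  `w_q = tf_q · idf_q` receives `w_q` hash draws per sketch slot,
  `idf_q = T(log(f_max/f_q − a))` rescaled onto `[1, idf_max]`; overlap
  extent and error estimated from bottom sketches via the Mash distance
  `d = −ln(2j/(1+j))/k`;
* **hierarchical read correction** — global/local evidence filters
  (each read donates to ≤ C partners, each accepts ≤ 2C), corrected-length
  estimation, and consensus over an alignment DAG that splits reads where
  edge weight < 4;
* **overlap-based trimming** — largest interval at depth ≥ C by overlaps
  of error ≤ E and length ≥ L, plus hairpin-adapter and chimeric-junction
  detection from orientation patterns and spanning counts;
* **overlap error adjustment** — two-pass majority voting that rewrites
  overlap error rates (never the reads) as if sequencing errors were
  resolved, separating them from true copy divergence;
* **best-overlap-graph assembly** — per-end best dovetail edges under an
  automatically estimated cutoff (`median + 6·MAD` of best-edge errors),
  per-window contig error profiles, contained-read placement, bubble
  handling, statistical repeat annotation/splitting, and GFA 1.0 output;
* **a synthetic-data module** — genomes with multi-copy repeats at
  controlled pairwise divergence, log-normal noisy reads, and exact truth
  layouts for every downstream check.

Audience: anyone studying assembly algorithms — the package favors
clarity and testability over large-genome performance.

## Worked example

Simulate a 60 kb genome with two 8 kb repeat copies at 4% divergence,
sequence it to 30× at 10% error, and assemble:

```
miniolc simdata genome --length 60000 --seed 1 \
    --repeat 2:8000:0.04:14000,37000 --out genome.fasta
miniolc simdata reads genome.fasta --coverage 30 --error-rate 0.10 \
    --seed 2 --out-prefix reads
miniolc all reads.fastq --genome-size 60000 --seed 1 --outdir asm/
```

The final command prints a report like:

```
miniolc assembly report
=======================
input reads:      573
contigs:          1
unassembled:      37
total bases:      59029
longest contig:   59029
N50:              59029
NG50:             59029
error model:      median 0.0033  MAD 0.0016  cutoff 0.0129
overlap records:  34934
```

Reading it: the two diverged repeat copies were assembled into a single
contig spanning the genome (no split at the repeat) because the
automatically estimated overlap error cutoff (1.3%, from the median and
MAD of best-edge error rates after correction and error adjustment)
excludes the ~4%-error cross-copy overlaps while keeping same-copy ones.
`asm/` contains the consensus contigs (`contigs.fasta`), the assembly
graph (`assembly.gfa`, GFA 1.0), the read layout (`layout.tsv`) and the
report. Reads whose best placement exceeds the local error tolerance are
listed as `unassembled` rather than forced into a contig.

Stages also run independently (`miniolc correct`, `miniolc trim`,
`miniolc assemble`), each recomputing overlaps for its inputs;
`miniolc --show-defaults` prints every tunable parameter as YAML, and
`--config file.yaml` overrides them.

As a library:

```python
from miniolc import (GenomeSpec, RepeatSpec, ReadSimSpec, PipelineConfig,
                     simulate_genome, simulate_reads, run_pipeline)

g = simulate_genome(GenomeSpec(length=60_000, seed=1,
                               repeats=[RepeatSpec(2, 8000, 0.04,
                                                   [14_000, 37_000])]))
reads, truth = simulate_reads(g.sequence, ReadSimSpec(coverage=30,
                                                      error_rate=0.10,
                                                      seed=2))
out = run_pipeline(reads, PipelineConfig(genome_size=60_000, seed=1))
for contig in out.contigs:
    print(contig.name, contig.cls, len(contig.consensus or ""))
```

## File formats

Inputs are FASTA/FASTQ (gzip allowed). Outputs are plain text: PAF-style
overlap records with an `er:f:` error-rate tag, a GFA 1.0 assembly graph,
TSV layouts/clear ranges/edit logs/coverage tracks, and FASTA contigs.
The k-mer spectrum has no standard format and is persisted as a small
binary file (magic `MOLCSPEC`, then k, f_max, f_min, cutoff count and
fraction, total k-mers, and the sorted hash/count arrays,
little-endian); `KmerSpectrum.save`/`KmerSpectrum.load` round-trip it.
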