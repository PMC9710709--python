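# sfstools

Detection of *sample-specific strings*: given a target read set and a
reference collection (reads or genomes), `sfstools` enumerates the
substring-free set of strings that occur in the targets but nowhere in
the references — on either strand by default — without mapping any read.
Each reported string is a shortest witness of sequence novel to the
target sample, which makes the output a compact, alignment-free signature
of the variation (SNVs, indels, SVs, inversions) separating two samples.

The package provides:

* `sfstools.fmd_index` — a bidirectional FM-index over a DNA collection
  and its reverse complements, with constant-time backward (prepend) and
  forward (append) bi-interval extension, plus a single-strand mode.
* `sfstools.search` — the exact specific-string enumeration (complete,
  worst-case quadratic per target) and a relaxed linear-time variant
  whose emissions are pairwise disjoint on the target and bounded in
  number by the edit distance to the reference; abundance (tau)
  filtering and strand-canonical aggregation.
* `sfstools.oracle` — brute-force reference solvers (test-only).
* `sfstools.simulate` — a diploid trio simulator (inherited variants,
  de novo insertions/deletions/inversions, HiFi-like long reads) with
  full coordinate tracking, so variant coverage is decided by liftover
  instead of alignment.
* `sfstools.evaluation` — precision/recall of specific strings against
  the simulated truth set, plus an end-to-end trio benchmark.
* `sfstools.cli` / `sfstools.io` — the `sfstools` command and
  FASTA/FASTQ (optionally gzipped) and TSV I/O.

## Command-line usage

```sh
# build an index over the reference sample (reads or genome)
sfstools index reference.fa -o reference.fmd          # add --single-strand to skip reverse complements

# enumerate target-specific strings
sfstools search target.fq --index reference.fmd --mode exact \
    --tau 5 --threads 4 -o specific.tsv \
    --emissions-out emissions.tsv --fasta-out specific.fa

# merge per-batch tables
sfstools aggregate part1.tsv part2.tsv --tau 5 -o merged.tsv

# simulate a trio and evaluate child-specific strings
sfstools simulate --genome-length 50000 --denovo 20 --coverage 30 \
    --seed 1 -o sim/
sfstools index sim/parents.fq -o parents.fmd
sfstools search sim/child.fq --index parents.fmd \
    -o child.tsv --emissions-out child_emissions.tsv
sfstools evaluate --emissions child_emissions.tsv --truth sim/truth.tsv \
    --reads sim/reads.tsv --tau 5 -o report.json
```

Output tables are deterministic (descending count, then lexicographic);
results are independent of `--threads`.

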