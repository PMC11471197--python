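# chimscreen

Screening pipeline for candidate chimeric RNAs called from bulk RNA-seq.
Starting from a caller-style candidate table (gene pair, breakpoints,
junction sequence, read support), the pipeline:

1. **filters** candidates seen in a normal-tissue background panel
   (ordered gene-pair or breakpoint keys);
2. **classifies** each candidate by parental-gene location
   (inter-chromosomal / intra-chromosomal / read-through) and by
   junction-site position (E/E, E/M, M/E, M/M — exon edge vs exon middle,
   strand-aware donor/acceptor edges) and drops the M/M class;
3. **quantifies** per-sample support by building fixed-length (default
   28 nt) junction probes and counting reads that contain them, using an
   agrep-style bit-parallel (bitap) matcher with configurable mismatch
   allowance, Hamming or edit distance, and both orientations;
4. **compares** case and control cohorts: presence/absence, group-exclusive
   chimera sets, cross-database frequency tables with a direction-consistency
   flag, marker sensitivity/specificity, and parental-gene chromosome
   enrichment (one-sided binomial, Benjamini-Hochberg corrected).

A synthetic-data module generates a complete toy universe — genome, exon
annotation, planted chimeric transcripts covering every category, error-bearing
case/control FASTQ files, caller table, background panel, and a truth ledger —
so the whole pipeline runs and is tested without any external data.

## Command line

```sh
# generate a synthetic dataset (deterministic for a given seed)
chimscreen simulate --seed 1 --out-dir data/

# panel filter + classification + MM filter + category summary
chimscreen screen --calls data/calls.tsv --annotation data/annotation.gtf \
    --panel data/panel.tsv --out-dir screen/

# junction-probe matching over a cohort
chimscreen match --calls data/calls.tsv --samples data/samples.tsv \
    --out-dir match/ --k 0 --distance-model hamming

# cohort comparison (repeat --match-table NAME PATH per database)
chimscreen compare --match-table db1 match/match_table.tsv \
    --marker CHIM001 --calls data/calls.tsv --annotation data/annotation.gtf \
    --out-dir compare/

# or everything in one go
chimscreen all --seed 1 --out-dir run/
```

Exit codes: 0 success, 1 runtime/validation failure, 2 usage/config error.
Every run writes a `run_metadata.json` (parameters, seed, input hashes) next
to its outputs; identical inputs and seed give byte-identical outputs,
regardless of `--threads`.

## Conventions

All internal coordinates are 0-based, intervals half-open. GTF (1-based
closed) and caller breakpoints (1-based) are converted at the I/O boundary.
`breakpoint5` is the last transcribed base of the 5' segment, `breakpoint3`
the first transcribed base of the 3' segment. Junction probes are centered:
L/2 bases on each side of the breakpoint.

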