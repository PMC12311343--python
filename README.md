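# isoprimer

Isoform-aware qPCR primer design. Given a genome FASTA, a GENCODE/Ensembl-style
GTF, a transcriptome FASTA and an isoform quantification table (TSV: transcript
ID column plus one TPM column per sample), `isoprimer` designs and prioritizes
primer pairs that target **all expressed splicing isoforms** of the requested
genes:

1. **Expressed-isoform choice** — per-gene quantile threshold on mean TPM
   (default: 75th percentile, i.e. the top 25% of isoforms count as expressed).
2. **Transcript models** — GTF exons are parsed into transcript models;
   transcripts with transcript support level (TSL) > 3 are excluded as design
   templates (missing TSL passes).
3. **Junction ranking** — each splice junction's 10-nt probe (5 nt each side)
   is searched in the gene's isoforms; junctions are ranked by prevalence.
4. **Design** — up to 5 primer pairs per junction, one primer overlapping the
   junction (≥7 nt on its 5' side, ≥4 nt on its 3' side), under hard
   constraints: length 20–25 nt, GC 30–60%, Tm 55–75 °C (nearest-neighbor
   model, parameters pinned in `thermo.py`), product 100–300 bp, homopolymer
   runs ≤ 4, self/pair complementarity and hairpin screens. Single-isoform
   genes get junction-free pairs.
5. **In-silico PCR** — mismatch-tolerant (default 20% of primer length,
   Hamming, both strands, either oligo on either strand) against the
   transcriptome; any product on another gene discards the pair.
6. **Prioritization** — pairs whose specific products differ by >25 nt are
   discarded; survivors are scored by expressed-abundance coverage plus a
   per-isoform bonus and a ~200-bp product preference; a single full-coverage
   pair is preferred, otherwise a greedy set cover returns multiple pairs.
7. **Genomic cross-check** — selected pairs are screened against the genome
   (product cap 3500 bp); predicted genomic amplicons go to
   `genomic_mismatch.txt`, which is empty when none are predicted.

Outputs: `primers.tsv` (validation candidates), `primers_order.tsv`
(ready-for-order), `primer_omnibus.tsv` (every designed pair with discard
reasons), per-gene text reports under `outputs/`, `genomic_mismatch.txt`, a
JSON run manifest, and optionally one xlsx workbook with the three tables as
sheets. Runs are fully deterministic.

## CLI

```sh
# generate a synthetic test locus (no downloads needed anywhere)
isoprimer fixtures make --seed 42 --outdir fx

# run the pipeline
cat > cfg.yaml <<EOF
genome: fx/genome.fa
gtf: fx/annotation.gtf
transcriptome: fx/transcriptome.fa
quant_table: fx/kalcounts.tsv
gene_list: fx/genes.txt
outdir: out
EOF
isoprimer run --config cfg.yaml [--genes G1,G2] [--threshold 75] [--mismatch-pct 20] [--outdir DIR]
```

All defaults (threshold percentile, mismatch %, design constraints, scoring
weights, amplicon cap, quantile scope gene/global) are config keys; design
constraints go under a `constraints:` mapping (e.g. `product_len: [120, 250]`).

The same functionality is available as a library:

```python
from isoprimer.cli import RunConfig, run_pipeline
results = run_pipeline(RunConfig(genome=..., gtf=..., ...))
```

## Layout

| module | role |
| --- | --- |
| `isoprimer.annotation` | GTF/FASTA → transcript models, TSL filter, junctions, probes, prevalence ranking |
| `isoprimer.expression` | quantification table parsing, quantile expressed-isoform calls |
| `isoprimer.thermo` | GC, nearest-neighbor Tm, runs, complementarity, hairpins |
| `isoprimer.design` | junction-overlapping pair enumeration and penalty ranking |
| `isoprimer.ispcr` | mismatch-tolerant in-silico PCR, genomic cross-check |
| `isoprimer.prioritize` | specificity/spread filters, scoring, greedy selection |
| `isoprimer.report` | TSV/xlsx tables, per-gene text reports |
| `isoprimer.fixtures` | seeded synthetic loci with controlled splicing structure |
| `isoprimer.cli` | config, orchestration, `isoprimer` command |
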