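# retrometh

Locus- and family-level DNA-methylation analysis of LINE-1 and *Alu*
retrotransposons from CpG-array beta matrices.

The package annotates array probes to repeat elements, classifies repeat
subfamilies by evolutionary age, detects total / family-level / locus-level
differential methylation between cohorts (Welch or pooled t-tests with
Benjamini-Hochberg FDR), tests gene-region feature enrichment of
significant positions, derives cohort-unique target loci via Venn logic
plus a secondary re-test, integrates methylation signatures with
multi-study expression results through an inverse-relationship filter, and
evaluates candidate loci as single-CpG ROC classifiers.  A seeded
synthetic-data generator produces complete fixture sets (repeat BED, probe
manifest, sample sheet, beta matrix with planted effects, expression
studies with planted direction-controlled effects) so the whole pipeline
is testable offline.

## Command-line usage

A one-command synthetic demo:

```sh
retrometh simulate --demo --seed 1 --out demo/
retrometh run-all --config demo/config.yaml
```

`run-all` executes annotate → total/family/locus differential methylation
per comparison → feature enrichment → Venn partition and variant target
loci → expression integration → ROC → covariate balance, writing every
intermediate table (TSV with provenance comment headers), a run log and a
summary into the configured output directory.  Reruns with the same config
and seed are byte-identical.

Individual stages are also exposed:

```sh
retrometh annotate  --repeats repeats.bed --manifest manifest.csv --out annotated.tsv
retrometh dmp       --beta beta.tsv --samples samples.csv --annotation annotated.tsv \
                    --case heterogeneous --control control --out dmp_out/
retrometh enrich    --dmps dmp_out/dmps.tsv --annotation annotated.tsv \
                    --element-class Alu --out enrichment.tsv
retrometh targets   --dmps-dir dmps/ --beta beta.tsv --samples samples.csv \
                    --variant variantB --heterogeneous heterogeneous --out targets.tsv
retrometh integrate --dmps dmps.tsv --annotation annotated.tsv --degs degs.tsv \
                    --min-delta 0.05 --min-studies 2 --out candidates.tsv
retrometh roc       --beta beta.tsv --samples samples.csv --probes cg000020 \
                    --case variantB --controls control,variantA --out roc.tsv
```

## File formats

- **Repeat annotation**: BED4/BED6, tab-separated, 0-based half-open.
- **Probe manifest**: CSV with `probe_id, chrom, pos, strand, gene_names,
  gene_features` (1-based positions; `;`-separated parallel gene lists).
- **Beta matrix**: TSV, probes x samples, values in [0, 1].
- **Sample sheet**: CSV with `sample_id, group` plus optional `sex, age`.
- **DEG tables**: TSV with `study_id, gene, log2FC, q`.

Probe CpG footprints are matched to repeats as 2-bp half-open intervals
`[pos-1, pos+1)`; when several repeats overlap, the maximal-overlap repeat
wins with deterministic coordinate-based tie-breaking.

## Layout

- `src/retrometh/io_annotation.py` — repeat/manifest parsing, taxonomy,
  interval annotation
- `src/retrometh/synthetic.py` — seeded fixture generator
- `src/retrometh/diffmeth.py` — beta/M transform, t-tests, BH, total /
  family / locus differential methylation
- `src/retrometh/enrichment.py` — Fisher exact feature enrichment
- `src/retrometh/cohorts.py` — Venn partition, target-locus selection,
  covariate balance
- `src/retrometh/integration.py` — DMP→gene mapping, DEG calling,
  inverse-relationship candidate filter
- `src/retrometh/roc.py` — Mann-Whitney AUC, ROC curves, DeLong/bootstrap CIs
- `src/retrometh/pipeline.py`, `src/retrometh/cli.py` — orchestration and CLI
- `src/retrometh/scenarios.py` — canned benchmark scenarios with planted truth
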