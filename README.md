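# venomalt

An integrative transcriptome–proteome analysis toolkit for venom-gland
systems, built around the idea that alternative transcription multiplies the
protein output of venom genes. It provides:

- **`annotation_model`** — GTF transcript models, gene loci, multi-transcript
  census, novel-intergenic locus classification, splice-junction support.
- **`splice_events`** — strand-aware classification of transcript pairs into
  the seven standard event classes (A5SS, A3SS, exon skipping, mutually
  exclusive exons, alternative first/last exons, intron retention) and
  per-locus / per-label frequency summaries.
- **`orf_proteins`** — ORF scanning (>90 nt, three sense frames), protein
  selection by the best-homology-hit frame (longest overall without a hit),
  first-Met trimming, 100%-identity deduplication.
- **`protein_inference`** — peptide/protein probability and ≥2-peptide
  filtering, Occam-parsimony grouping of indistinguishable proteins, removal
  of subsumed proteins and contaminants, minimum/maximum distinct-protein
  enumeration, per-gene contribution summaries.
- **`expression_analysis`** — TPM, a pluggable two-condition
  negative-binomial exact test with Benjamini–Hochberg control, the
  three-comparison venom-gland upregulation intersection, expression-rank
  and spatial-pattern classification.
- **`integration_report`** — category tabulation, two-proportion chi-square,
  printed-style percentage reporting, inventory × upregulation tables.
- **`synthetic_data`** — seeded fixture generation with exact ground truth:
  loci planted with chosen event classes and designed ORFs, peptide evidence
  realizing a chosen unique/grouped/subsumed structure, and
  negative-binomial count matrices with planted upregulated transcripts.

## CLI

```sh
venomalt simulate --seed 1 --out fixtures/           # synthetic data + ground truth
venomalt annotate --gtf fixtures/annotation.gtf --reference-gtf ref.gtf \
    --junctions junctions.tsv --out-prefix out/ann
venomalt events --gtf fixtures/annotation.gtf --out-prefix out/ev
venomalt predict-proteins --fasta fixtures/transcripts.fa --hits hits.tsv \
    --out-prefix out/prot
venomalt infer --evidence fixtures/evidence.tsv --proteins fixtures/proteins.fa \
    --contaminant keratin --contaminant trypsin --out-prefix out/inf
venomalt express --counts fixtures/counts.tsv --lengths fixtures/lengths.tsv \
    --tissues fixtures/tissues.tsv --out-prefix out/ex
venomalt report --k1 58 --n1 86 --k2 11922 --n2 58158
```

File formats are plain text: GTF for annotations, FASTA for sequences,
tab-separated tables for junctions (`chrom start end strand count`),
homology hits (`transcript_id subject e_value frame`), peptide evidence
(`peptide_sequence peptide_probability protein_ids protein_probability`,
protein ids semicolon-joined), and count/length/tissue matrices.

## Notes

The differential-expression engine is a simple exact negative-binomial test
(median-of-ratios normalization, method-of-moments common dispersion) with
BH control. It is intentionally pluggable (`engine=` parameter) and is not
numerically equivalent to empirical-Bayes tools; the surrounding logic (+5
pseudocount, three pairwise venom-gland comparisons at 5% FDR, intersection)
is fixed.
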