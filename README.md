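# mirseed

A tested, reusable pipeline for miRNA target discovery from expression
data: differential-expression categorization, exact seed-complementary
site scanning in 3'UTRs, hypergeometric over-representation of predicted
targets, multi-evidence candidate filtering with cross-species support,
ranked-list (GSEA-style) signature enrichment, and cross-model miRNA
overlap — exercisable end to end on synthetic data with planted truth.

## Modules

| module        | role |
|---------------|------|
| `mirseed.formats`     | readers/writers for FASTA, TSV expression matrices + sample sheets, GMT gene sets, flat target-prediction and ortholog tables; strict validation |
| `mirseed.synthio`     | synthetic UTR sets, expression matrices and per-model miRNA tables with planted, exactly recoverable ground truth |
| `mirseed.diffexpr`    | quantile normalization, moderated two-sample t, Benjamini–Hochberg FDR, up/down categorization, qPCR 2^-dCT |
| `mirseed.seedtargets` | seed extraction (nt 2–7 hexamer / 1–8 octamer), exact-match site scanning, per-source target sets, source intersection with Venn counts |
| `mirseed.enrichdown`  | hypergeometric upper-tail enrichment of predicted targets in the up/down categories against the expressed background |
| `mirseed.rankenrich`  | weighted running-sum enrichment score, gene-tag permutation NES / nominal p |
| `mirseed.candidates`  | candidate-table assembly, in-vivo ortholog support flags, cross-model overlap with sign consistency |

## CLI

Everything is reachable through the `mirseed` console script:

```sh
# validate inputs
mirseed io validate utrs.fa --kind fasta

# synthetic data with planted truth
mirseed simulate expression --n-features 500 --n-planted 50 --shift -1.5 --seed 1 --out sim/
mirseed simulate utrs --n-utrs 200 --mirnas mirnas.fa --fraction 0.1 --seed 1 --out sim/
mirseed simulate models --seed 1 --out sim/

# differential expression and categorization
mirseed de --matrix sim/matrix.tsv --samples sim/samples.tsv \
    --contrast treatment:control --out de.tsv
mirseed categorize --de de.tsv --aveexpr 7.0 --lfc 0.7 --fdr 0.05

# seed-site scanning and source intersection
mirseed targets scan --utrs utrs.fa --mirnas mirnas.fa --variant seed2_7 \
    --min-sites 1 --out sites.tsv
mirseed targets intersect --tables a.tsv --tables b.tsv --tables c.tsv \
    --mirna miR-199a-5p --min-sources 3

# enrichment of predicted targets in the down/up categories
mirseed enrich --de de.tsv --targets targets.tsv --aveexpr 7.0 --lfc 0.7 \
    --fdr 0.05 --out enrich.tsv

# ranked-list signature enrichment
mirseed gsea --ranked de.tsv --sets sig.gmt --nperm 1000 --seed 7 --out gsea.tsv

# candidate table with optional in-vivo ortholog support
mirseed candidates --de de.tsv --targets targets.tsv --mirna miR-199a-5p \
    --aveexpr 7.0 --lfc 1.5 --fdr 0.01 --min-sources 3 \
    --invivo mouse_de.tsv --orthologs orth.tsv --alpha 0.05 --out table.tsv

# cross-model miRNA overlap
mirseed overlap --models lung.tsv --models liver.tsv --models kidney.tsv --alpha 0.01
```

## Conventions

- Tabular formats are tab-separated UTF-8 with a header row; missing
  expression values are rejected, never imputed.
- FASTA input is normalized (U→T, uppercase) so RNA and DNA files scan
  identically; mature miRNAs are kept in the RNA alphabet.
- Site coordinates are 0-based half-open on the given strand (UTRs are
  supplied 5'→3'); overlapping occurrences are all counted.
- Category thresholds are strict on |logFC| and adjusted p, inclusive on
  AveExpr.
- All generators and permutation procedures are deterministic under their
  seed argument.
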