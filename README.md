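# npscreen

Screening brain expression data for neuropsychiatric-disorder genes.

Alzheimer's-disease patients frequently develop neuropsychiatric symptoms —
mood swings, hallucinations, depression — that overlap with the symptoms of
bipolar disorder (BIP), schizophrenia (SCZ) and major depressive disorder
(MDD). `npscreen` implements the analysis used to ask whether the genes
associated with those three disorders are differentially expressed in an AD
mouse model: a probe-level microarray of forebrain-specific presenilin
double-knockout (PSEN-dKO) versus wild-type mice, sampled in two brain
regions (cortex, hippocampus) at two ages (7 and 18 months).

The package is aimed at transcriptomics analysts who want this screen as
tested, scriptable code rather than a spreadsheet workflow: every stage is a
library function, every report a plain TSV, and a synthetic-data module
generates complete study bundles with planted ground truth so the machinery
can be verified end to end without any external download.

## The method

1. **Disorder gene pools.** GO annotations (GAF 2.2) are filtered to the
   target taxon (*Mus musculus*, 10090) and to the qualifiers `part_of`,
   `involved_in`, `enables`, `contributes_to`, `colocalizes_with`, dropping
   `NOT`-qualified records. Each of 13 distinct GO terms (14 slots; histone
   H3-K4 methylation is listed under both BIP and SCZ) is expanded through
   transitive `is_a` descendants, and each disorder's pool is the
   deduplicated union of its term gene sets. The pool report carries the
   overlap accounting Σ|term set| − |union| (the "redundant memberships").
2. **Differential expression.** Per (region, age) condition, each probe gets
   a two-sided Welch t-test on log2 intensities (Student's pooled-variance
   test available as an option) and a linear-scale fold change
   FC = mean(KO)/mean(WT). A probe is significant when *p* < 0.05 **and**
   max(FC, 1/FC) > 1.3, both strict; probes collapse to genes by the
   any-probe-significant rule with the minimum-*p* probe as representative.
   Bonferroni and Benjamini–Hochberg adjusted p-values are reported
   alongside.
3. **Disorder statistics.** Per term and condition: *n* DEGs and
   100·*n*/pool-size; per disorder: the deduplicated DEG count over the pool
   union, its percentage, and its share of all DEGs on the array. Disorders
   are ranked by DEG *number* (the headline criterion) and by *percentage* —
   the two can disagree.
4. **Cross-age classification.** Genes significant at both ages in a region
   are "common genes"; a common gene with FC > 1 at one age and FC < 1 at
   the other is *contra-regulated*, and a common gene found in exactly one
   region is *region-specific*.

## Worked example

Run the full screen on the bundled `paper_like` synthetic study (snapshot
pool sizes, named cross-age genes planted with their published fold changes,
two arrays per group like the original pooled design):

```bash
npscreen run-all --preset paper_like --seed 1 --out results/demo
```

```
run complete; manifest at results/demo/manifest.json
  cortex_7m: 14 pool DEGs of 50 total
  cortex_18m: 19 pool DEGs of 47 total
  hippocampus_7m: 13 pool DEGs of 50 total
  hippocampus_18m: 26 pool DEGs of 61 total
```

Each line is one (region, age) condition: the number of significant genes
inside the three disorder pools, out of the array-wide DEG total. The output
directory contains the pool report (per-term sizes and union accounting):

```
disorder  term        name                                      n_genes
BIP       GO:0051568  Histone H3-K4 methylation                 32
BIP       GO:0007129  (Chromosomal) synapsis                    23
BIP       GO:0090066  Regulation of anatomical structure size   54
BIP       GO:0070192  Chromosome organization involved in meiosis  362
BIP       TOTAL       union (23 redundant)                      448
```

plus per-condition DEG tables, the term/disorder statistics grid,
number-vs-percentage rankings, the Venn-style direction counts, and the
cross-age table. For example, `cross_age.tsv` from the run above includes

```
Paxbp1  cortex       MDD  True  True  1.454  0.754  common  contra         True
Arc     hippocampus  SCZ  True  True  1.816  0.567  common  contra         True
Arpc1b  hippocampus  BIP  True  True  1.636  2.070  common  consistent_up  True
```

— *Arc* and *Paxbp1* are common genes that flipped direction between 7 and
18 months (contra-regulated), and all three are region-specific (last
column). The `inputs/` subdirectory holds the generated fixture together
with its ground-truth tables (`truth_planted_degs.tsv`,
`truth_cross_age.tsv`), so every call can be checked against what was
planted.

User data runs through the same path with no code change — point the flags
(or a YAML config) at your own files in the documented TSV/GAF/OBO layout:

```bash
npscreen validate --expression expr.tsv --samples samples.tsv \
    --probe-map probes.tsv --gaf annotations.gaf --obo ontology.obo
npscreen run-all --expression expr.tsv --samples samples.tsv \
    --probe-map probes.tsv --gaf annotations.gaf --obo ontology.obo \
    --out results/myrun
```

Stage-wise subcommands (`simulate`, `pools`, `deg`, `stats`, `crossage`)
expose each step separately.

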