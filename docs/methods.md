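# Methods

## The screen

The analysis asks, for an expression study with a 2 genotypes × 2 regions ×
2 ages factorial design, how strongly each of three neuropsychiatric
disorders is represented among the genes that respond to genotype. It is a
*gene-pool screen*, not an enrichment test: disorder pools are fixed gene
sets built from GO terms, differential expression is called per condition,
and the disorders are compared by raw DEG counts and percentages. No
hypergeometric or permutation p-values are attached to the disorder
comparison — the ranking is descriptive, which is why the package reports
both ranking keys (number and percentage) and the cell-level counts needed
to audit them.

## Disorder pools

Pools are defined by a disorder → GO-term configuration (packaged preset:
4 BIP terms, 5 SCZ terms, 5 MDD terms; 14 slots, 13 distinct terms, the
histone H3-K4 methylation term shared between BIP and SCZ — both the slot
count and the distinct count are surfaced in the pool report rather than
silently choosing one). Annotation handling:

* **GAF 2.2** column mapping (symbol 3, qualifier 4, GO id 5, evidence 7,
  taxon 13); malformed lines are logged with line numbers and skipped, never
  fatal. A QuickGO TSV adapter maps header-named exports onto the same
  record type, so the core is dialect-agnostic.
* **Filters**: taxon equality, no leading `NOT`, at least one qualifier in
  the allowed set; records with no qualifier are dropped. Filtering is
  idempotent and order-preserving.
* **Expansion**: only `is_a` edges are traversed (transitively); `part_of`
  and other relationships in the OBO file are parsed but ignored, with a log
  notice. The graph must be acyclic; expansion of a term returns the term
  plus all descendants whose `is_a` closure contains it.
* **Gene identity** is the case-sensitive symbol string. No alias
  resolution is attempted; users bringing real annotation exports must
  pre-map synonyms to one symbol per gene.
* Annotations to terms outside the configured set survive parsing and are
  excluded only at pool-building time, so fixtures can carry decoys.

Pool-size accounting is exact set algebra: `redundant_memberships` =
Σ per-term set sizes − |union|, per disorder.

## Differential expression

* **Statistic**: two-sided Welch (unequal-variance) t-test on
  log2-transformed intensities. The upstream software behind this kind of
  spreadsheet screen does not document its test; Welch is the defensible
  default for tiny, possibly unequal groups, and a pooled-variance Student
  option (`test="student"`) is provided for sensitivity analysis. With zero
  variance in both groups the p-value is 1 for equal means and 0 otherwise.
* **Fold change**: ratio of linear-scale group means, KO/WT. Mean rather
  than median (the choice is undocumented upstream; means match the
  log-normal model).
* **Criterion**: significant iff p < α (default 0.05) **and**
  max(FC, 1/FC) > threshold (default 1.3), both strict. The symmetric form
  is deliberate: published cross-age tables of this design star sub-unity
  fold changes (e.g. 0.692), so "fold change of 1.3" must cover
  down-regulation.
* **Probe → gene collapse**: a gene is significant iff any of its probes
  is; the reported p and FC come from the minimum-p probe (ties: smallest
  probe id lexicographically). This any-probe rule is liberal and can only
  increase gene counts relative to stricter rules (all-probe agreement,
  median-probe); it is prominently documented because it changes counts.
* **Multiple testing**: Bonferroni and Benjamini–Hochberg adjusted p-values
  are computed across the GO-filtered pool probes of each condition and
  reported as columns next to the raw p. The primary criterion uses raw p —
  at these group sizes corrected thresholds leave essentially nothing, and
  the screen's purpose is comparative counting, not family-wise inference.

## Statistics and classification

Percentages are displayed half-up: two decimals for per-term and per-pool
percentages, one decimal plus an integer convenience column for the share of
all DEGs (69/2261 → 3.1% → "3"). Ranking is descending on the chosen key
with ties broken by the other key, then alphabetically. Cross-age classes:
common = significant at both ages (direction-agnostic, so a contra-regulated
gene is still common); contra = fold changes straddling 1; FC exactly 1 maps
to a separate `flat` class for totality (unreachable for significant genes).
Region specificity = common in exactly one of the two regions.

## The synthetic-data generator

Intensities follow a log-normal model: log2 intensity = baseline (default
8.0) + planted KO effect + Gaussian noise, exponentiated to the linear
scale. Defaults mirror the emulated study where it states them: two arrays
per group (its pooled design), 1–4 probes per gene (probe multiplicity
≈ 2.1 in the emulated data), and snapshot per-term pool sizes with exact
overlap counts, realized by a largest-first greedy construction that places
redundant memberships by reusing already-placed genes. Where the study
states nothing, defaults are chosen once as field-realistic values:
log2-scale noise SD 0.15 (typical replicate variability for normalized
arrays) and |log2 effect| = 1 for generic planted DEGs.

Presets:

* `null` — no effects; ≥ 10,000 probes and **8 arrays per group**. This
  group size is a calibration-design choice, separate from "emulate the
  study": Welch's test is markedly conservative at n = 2 per group
  (empirical type-I rate ≈ 0.022 at α = 0.05), so a two-array null cannot
  measure the caller's calibration. At n = 8 the empirical rate is ≈ 0.05
  and the 3-binomial-SE acceptance band is meaningful.
* `paper_like` — full disorder fixture; named cross-age genes planted with
  their published fold changes at the cells where they were significant;
  extra one-condition effects sized so SCZ leads the DEG count in all four
  conditions, counts rise sharply at 18 months and the hippocampus changes
  more than the cortex; 40 background DEGs per condition outside the pools.
  Default two arrays per group reproduces the study's *power regime* (few,
  noisy calls); recovery checks override to 10 arrays per group, where a
  pilot run gives ≥ 95% sensitivity for |log2 effect| = 1 (measured ≈ 99%),
  the documented recovery threshold.
* `contra_demo` — one gene at +0.7/−0.7 log2 across the two ages in the
  hippocampus, 10 arrays per group so the planted contra pattern is
  recovered with near-certainty.

What the generator does **not** emulate: probe-level affinity differences,
background correction and normalization artifacts, correlated noise between
probes of a gene, batch effects, or annotation errors. Passing recovery
tests therefore demonstrates that the pipeline's logic is correct under its
stated model, not that the biological conclusions of any real dataset are
reproducible from raw arrays.

All randomness flows from one user seed through per-stage derived seeds
(BLAKE2 hash of seed + stage label), so outputs are bit-reproducible and
adding a stage never perturbs another stage's draws.

## Numerical and design choices

* Strict inequalities at both criterion thresholds; a probe exactly at
  p = 0.05 or FC = 1.3 fails.
* Condition iteration order fixed to (cortex, hippocampus) × (7, 18);
  all report rows sorted; floats written with a fixed `%.10g` format —
  identical config + seed gives byte-identical TSVs.
* The published per-term pool sizes are treated as fixture parameters (a
  2017 annotation snapshot cannot be regenerated from live GO); analyses of
  real data recompute pools from the user's own GAF/OBO.
* Scaled-down problem sizes for the bundled scenarios (≈ 1,600–4,200 genes,
  ≈ 4,000–10,500 probes) keep every check fast while preserving the pool
  structure; they are stated here as the package's own fixture dimensions.
* Degenerate inputs: empty p-value lists adjust to empty; empty gene lists
  give empty probe maps; a two-term overlap specification beyond
  Σsizes − max(sizes) is rejected with the violated bound; genes absent
  from one age's records can never be classed common.

## Known limitations

* The DEG caller assumes normalized, strictly positive intensities; no
  normalization, background or batch correction is performed.
* With two arrays per group the Welch test is conservative and power is
  poor — this is faithful to the emulated design, and it is why headline
  counts from such designs should be read as descriptive.
* The disorder ranking has no attached uncertainty; treat "SCZ first by
  number" as a summary of counts, not a tested hypothesis.
* Gene symbols are matched exactly; alias drift between the probe map and
  the annotation file will silently shrink pools (the validator reports
  coverage of the matrix by the probe map, but cannot detect symbol drift).
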