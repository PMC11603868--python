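# Methods

## Problem and model

`laminadiv` analyzes the *divergence* between two parallel differential-
expression experiments — in the motivating application, laser-capture
microdissected layer-3 (L3) and layer-5 (L5) pyramidal neurons from the same
subjects, trisomy-21 versus control. The upstream DE fit (a mixed-model
pipeline producing per-gene log2 fold change and raw p-value per lamina) is
consumed, not reproduced. Downstream of that, every computation in the
published analysis style is implemented: gene classification, open
gene-set enrichment with directionality, five-cohort layer-specific
labeling, uDEG contribution binning, PPI hub ranking, and ontology ancestor
annotation.

### Gene classification

Each gene appearing in either table receives exactly one category at
significance level α (raw p, default 0.05):

| category | rule |
|---|---|
| convergent_up / convergent_down | p<α in both laminae, same LFC sign |
| divergent | p<α in both, opposite LFC signs |
| unique_a / unique_b | p<α in exactly one lamina |
| not_significant | neither |

The **uDEG set** of a lamina is its unique genes plus *all* divergent genes
(divergent genes belong to both laminae's uDEG sets), giving the identity
|uDEG_x| = |unique_x| + |divergent|. Significance tiers p<0.01 / p<0.05 are
carried per lamina. Genes present in only one table are treated as
non-significant in the absent lamina (absence after an upstream
expression filter is ambiguous); a `missing_policy="exclude"` switch drops
them instead. A gene with LFC exactly 0 and p<α in both laminae is labeled
`convergent_flat` and logged — sign() is undefined at 0; the case is
practically unreachable with real DE output. Raw p-values are used for
classification by design; adjusted columns, if present upstream, are
ignored here but can be carried through the tables.

### LFC binning

uDEGs are histogrammed by LFC in fixed-width bins (default 0.25 log2
units), half-open and closed on the boundary nearer zero:
[k·w, (k+1)·w) for LFC ≥ 0 and [−(k+1)·w, −k·w) for LFC < 0. This makes the
histogram deterministic and mirror-symmetric; an LFC of exactly +0.25 falls
in [0.25, 0.50), and LFC 0 counts as "up" ([0, w)).

### Enrichment

Over-representation of a query (cohort) within a background universe uses
the exact upper-tail hypergeometric probability P(X ≥ k) with
Benjamini–Hochberg adjustment across all tested sets. The universe is the
set of genes actually tested for DE in that lamina (the DEG table), not the
genome: this mirrors the effect of the upstream expression filter and is a
documented assumption, since commercial pathway tools rarely state their
background. Sets are intersected with the universe before testing; sets
with no universe member are skipped.

Directionality per set is the signed-proportion statistic
z = (n_up − n_down)/√(n_up + n_down) over overlapping genes with a known
direction of change; z is NA when no overlapping gene has a direction, and
|z| threshold 0 maps z>0→up, z<0→down, z=0→mixed. This is an open
approximation to proprietary activation scores; no numeric equivalence with
any commercial implementation is claimed.

**Discreteness caveat.** The exact hypergeometric tail is a discrete test:
the attainable rejection level just below a nominal α sits at or below α.
At the default synthetic conditions (universe 2 000, query ≈ 375, set sizes
30–80) the analytic expectation of P(p_raw < 0.05) under the null is
0.0357, and Monte-Carlo measurement reproduces it (≈ 0.036). A "5% of sets
significant under the null" calibration is therefore only an upper
approximation; the test is conservative, never anticonservative. We keep
the exact tail rather than a mid-p variant because exactness (never
exceeding the nominal level) is the property practitioners rely on.

### Five-cohort labeling

Enrichment is run for five cohorts: each lamina's uDEGs (`a_unique`,
`b_unique`), each lamina's full DEG list (`a_all`, `b_all`), and the
convergent genes. Per term and cohort a flag in
{significant_up, significant_down, significant_nodir, not_significant} is
recorded (pathway-level significance uses raw p by default — matching the
gene-level convention — with a BH-adjusted mode available; direction from
the activation z, with z = 0 or NA mapping to `nodir`).

The labeling rule, evaluated in order:

1. *Layer-specific eligibility* for lamina X: significant in X_unique and
   X_all, and the other lamina's full list is either not significant or
   (unless `strict`) significant in the strictly opposite direction.
2. If exactly one lamina is eligible → `x_layer_specific`.
3. If **both** are eligible — possible only when both full lists are
   significant with opposite directions — the signal cannot be attributed
   to one lamina and the term is `divergent_between_laminae`. This
   tie-break is what makes the labeling mirror-symmetric on swap-symmetric
   flag vectors; preferring either lamina would violate symmetry.
4. Both full lists significant: opposite directions →
   `divergent_between_laminae`; otherwise (same direction, or a `nodir`
   involved, treated as "not opposing") → `genotype_shared`.
5. Significant only in one lamina's uDEG cohort → `x_unique_only`.
6. Anything else → `unlabeled`.

The function is total and single-valued over all 4⁵ = 1024 flag vectors
(checked exhaustively) and mirror-symmetric under lamina swap. The
`strict` flag restricts layer-specific to the "other lamina silent" reading
only.

Ancestor reports list, for each focus term, every term reachable by
child→parent edges in the ontology DAG, each carrying its *own* label —
labels are never propagated along edges. Keyword categorization is
case-insensitive substring matching on term names with first-match-wins
priority in configuration order.

### uDEG contribution

For each (layer-specific) term, contribution = 100·|term ∩ uDEGs| / |term ∩
all DEGs|. Terms with no DEG member are skipped (they cannot be a
dysregulated process). Bins: one aggregate "<50", then half-open [50,60),
[60,70), [70,80), [80,90), and [90,100] closed at 100. Bin shares sum to
100% of the binned terms; per-bin and per-category means are computed over
member terms only, categories sorted by descending mean.

### PPI analysis

STRING-style exports are consumed as simple undirected graphs. The induced
subnetwork keeps edges with both endpoints in the gene set and confidence ≥
cutoff (default 0.4, the usual medium-confidence threshold); unscored edges
pass any cutoff. Degree counts distinct partners; hub selection sorts by
descending degree with lexicographic tie-breaking (the published "top 39"
convention names no tie rule, so a deterministic one is imposed), and
supports top-k, minimum-degree, or their intersection.

## Synthetic cohort

The generator draws a gene universe (default 2 000 genes) with true classes
sampled multinomially at fractions mirroring the motivating study's
proportions of tested genes: convergent 13% (split evenly up/down), unique-A
16%, unique-B 11%, divergent 1%, null 59%. Truly significant calls draw
p ~ U(0, α·f) with f = 0.5 — positional p-values, since only the position
relative to α matters downstream — and LFC magnitudes from a Gamma with
mean 0.7 and sd 0.35 log2 units (signs per class); null calls draw
p ~ U(0,1) and LFC ~ N(0, 0.15). Null and unique genes therefore cross α in
the "wrong" lamina at about rate α, so recovery tests bound category counts
by 3σ multinomial intervals around expectations that include this
misclassification, rather than asserting equality.

Gene sets: 200 uniform background sets of size 30–80 plus 5 planted sets of
size 50 drawing 60% of members from the true lamina-A uDEG pool. PPI: an
Erdős–Rényi background (300 nodes sampled from the uDEG pool, edge
probability 0.02, confidence U(0.15, 1)) with 5 planted hubs wired to ≥ 60
partners at confidence U(0.6, 1) so they survive the 0.4 cutoff. A gene
annotation assigns a focus chromosome (default "21") to 40 genes with an
elevated non-coding fraction, emulating the triplicated-chromosome biotype
tally. A random DAG over term ids (each term attaching to up to two earlier
terms) stands in for the ontology.

All draws are keyed to a mandatory integer seed through per-stage seed
sequences, so every artifact is bit-reproducible across platforms.

**What the generator does not emulate:** correlated expression between
genes, between-subject variance structure, p-value/LFC dependence, realistic
ontology topology or term-size distributions, and scale-free PPI degree
distributions. Passing recovery tests therefore demonstrates correctness of
the downstream computations under known truth, not performance of the
upstream DE model on real tissue.

## Numerical and design choices

- Gene identifiers are trimmed and upper-cased before any join (HGNC symbol
  convention); duplicates after normalization are an error, never silently
  collapsed, because classification is per-gene.
- p-values of exactly 0 are rejected at ingest (DE software emits small
  positives; protects log transforms).
- Delimiters and column names are explicit configuration — no sniffing.
- BH adjustment via the standard step-up; verified against a hand-applied
  oracle. Hypergeometric tails verified against exhaustive rational-
  arithmetic enumeration for all N ≤ 25.
- Analysis stages are seed-free; reruns on identical inputs produce
  byte-identical `summary.json`.
- Desk-scale problem sizes (2 000-gene universe, ≈ 200 sets, 300-node
  networks, ≤ 100 replicate seeds) were chosen so the full suite and the
  reproduction script each run in well under a minute while keeping all
  planted-recovery margins wide.

## Known limitations

- The published dataset-level counts (thousands of DEGs, STRING PPI totals,
  GO process counts, bin percentages) depend on the real GEO data and on
  proprietary or versioned resources (IPA, STRING, GO releases) and are not
  reproduced; only the arithmetic identities the published counts imply
  (uDEG appending, the 7/14 = 50% biotype tally, the 60/75 → 67.5 category
  mean) are fixed contracts. The source analyses also contain internally
  inconsistent counts between sections; this package reports its own
  internally consistent counts instead.
- The activation z is a deliberate approximation; terms dominated by genes
  of unknown direction are labeled `nodir`/NA rather than scored.
- Null calibration of the exact enrichment test is conservative (see the
  discreteness caveat above).
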