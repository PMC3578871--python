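# Methods

## The screening model

The package analyses a gene × organ abundance matrix in RPKM units
(reads per kilobase of exon per million mapped reads,
`RPKM = 1e9·C/(N·L)` for C reads on a gene of length L bp in a library
of N mapped reads). The motivating design is an eight-organ floral
atlas of a papilionoid legume — sepal, dorsal petal, lateral petal,
ventral petal, stamen, carpel, with leaf and root as vegetative
controls — but any organ vocabulary can be configured through
`OrganScheme`.

For a target category *t* (a single organ, the merged petal category, or
an ABC-domain combination A = {sepal, petal}, B = {petal, stamen},
C = {stamen, carpel}) and a gene with category expression Xᵢ, two
statistics are computed against the remaining categories O:

```
Z     = (Xᵢ − μ(O)) / SD(O)
Ratio = (Xᵢ + c) / (mean(O) + c)
```

A gene is **enriched** in *t* when Ratio > 2.0 and Z > 3.75, and
**downregulated** when Ratio < 0.5 and Z < −1.5; the inequalities are
strict, exactly as the cutoffs are stated. No multiple-testing
machinery is attached: the screen is a fixed-threshold rule, not a
hypothesis test, and its operating characteristics are established here
by planted-truth simulation instead.

Several details of this statistic are under-determined by its usual
verbal description, and the package fixes them as follows:

- **The "other" set.** The comparison universe is the six categories
  {sepal, petal, stamen, carpel, leaf, root} (petals merged into their
  mean by default; a flag keeps the three raw petal columns, giving
  eight). A domain's "others" are the categories sharing *no member
  organ* with it, so B = {petal, stamen} is compared against sepal,
  carpel, leaf and root. Leaf and root are always in the comparison
  set.
- **O is a mean.** "Expression in all of the other organs" is read as
  the arithmetic mean over the other categories, symmetric with μ in
  the Z-score.
- **SD is the sample (n−1) standard deviation** — conventional for the
  5–7 values involved; population SD is available via `ddof=0`.
- **SD = 0.** A gene expressed only in the target category has μ ≈ 0
  and SD = 0 among the others; the Z-score is reported as +∞ (−∞ when
  Xᵢ < μ, 0 at equality) so that such genes pass (or fail) the cutoff
  rather than becoming NaN. The sentinels compare normally against any
  finite threshold.
- **Pseudocount.** c = 0.01 RPKM is added to the numerator and
  denominator of the Ratio only, guaranteeing finiteness without
  touching the Z-score. Both statistics are invariant to rescaling the
  matrix (exactly so at c = 0; at c > 0 the pseudocount carries
  expression units and should be scaled with the data).
- **Category means.** The merged petal category is the mean of its
  three member columns, and a domain is the mean of its member
  *categories*, so the petal triplet counts once inside A and B.

## Organ similarity

Organ-pairwise similarity uses Spearman rank correlation on raw RPKM
(rank statistics are transform-invariant, so no normalisation is
needed). Adjacent-organ scatter correlations are Pearson r, by default
on log2(x+1) values, with a raw option — the appropriate scale for
expression scatter plots is a presentation choice, so both are exposed.
Domain-boundary profiles are per-gene
`log2((x_t + c)/(mean(non-adjacent floral categories) + c))`, where
non-adjacency is the complement of the adjacency list
(sepal–petal, petal–stamen, stamen–carpel) within the floral
categories: sepal is contrasted with {stamen, carpel}, petal with
{carpel}, stamen with {sepal}, carpel with {sepal, petal}.

Organ clustering is agglomerative with distance 1 − Pearson r between
category columns and average linkage. Because only a handful of
categories are clustered, the agglomeration is written out explicitly
rather than delegated to `scipy.cluster.hierarchy`: that makes the
tie-break deterministic (lexicographically smallest pair of cluster
label tuples) where scipy's is input-order dependent. The test suite
cross-checks the merge heights against scipy's `linkage` on tie-free
inputs. Dendrograms serialize to Newick with each child's branch
length equal to its parent's merge height minus its own.

qPCR agreement uses the 2^−ΔΔCt fold change
(ΔΔCt = ΔCt_sample − ΔCt_calibrator, ΔCt = Ct_target − Ct_reference)
and a per-gene cross-platform Pearson r across organs; a gene is
concordant when r > 0.707 (strict). A constant profile on either
platform has no defined correlation and is counted as a non-pass, never
silently as r = 0. Pass rates are rounded half-up to one decimal;
enrichment percentages to two decimals.

## Cross-species concordance

Homology comes from 12-column BLAST tabular files. Hits at
E-value < 1e-5 (strict) are reduced per query to the best hit (minimal
E-value, ties by maximal bitscore, then smallest subject id);
reciprocal-best mode keeps the mutual pairs and is guaranteed
one-to-one. Best-hit mode is the default for one-directional surveys;
reciprocal-best for one-to-one comparisons.

Each source-enriched gene is classified in the partner species with
precedence EE > DE > UE:

- **NH** — no homolog under the map;
- **EE** — the homolog is enriched in *any* screened partner category
  (a `counterpart_only` flag restricts this to the same category, for
  counterpart-organ conservation analyses);
- **DE** — homolog expression exceeds the detection threshold
  (default > 0, configurable — "detectable" has no standard definition)
  in at least one screened partner column;
- **UE** — otherwise.

The accounting table enforces the identities HH = DE + EE + UE and
NH + HH = enriched per category and in the Total column; they are
property-tested on random classifications and validated at
construction time.

## Motif scanning

Promoters are the 2,000 bp (configurable) immediately upstream of a
gene feature, taken from GFF3 `gene` rows by default (the feature type
is a flag; the feature start stands proxy for the start codon).
Minus-strand promoters are reverse-complemented so all promoters read
5′→3′ toward the gene; windows truncated at contig edges are flagged
`clipped`.

Patterns use the 15-letter IUPAC alphabet. A genome base outside
{A, C, G, T} never matches any pattern position, keeping counts over N
runs conservative. Overlapping occurrences are all counted (the task
is site counting, not tokenization). On both-strand scans a
reverse-strand hit is reported with the forward-coordinate start and
the forward-strand subsequence; a palindromic site therefore yields two
hits — distinct (start, strand) pairs — which is documented behaviour
and collapsible with `collapse_palindromes`. Pattern libraries are
ranked by genes-with-≥1-site, then total sites, then name.

## The synthetic-data generator

`simulate_expression` draws per-gene baselines log-normally (median
`baseline_mean`, default 5 RPKM; log-SD 1.0 — RPKM distributions are
right-skewed and the screen is scale-free, so only the dispersion shape
matters), multiplies the member-organ columns of planted enriched genes
by `effect_fold` (default 10), divides for planted downregulated genes,
and applies multiplicative log-normal noise with coefficient of
variation `noise_cv` (default 0.2). At zero noise a planted gene's
"other" categories are exactly equal, so Z hits the +∞ sentinel and
Ratio equals the fold: planted truth is recoverable by construction,
which is what makes sensitivity/specificity exactly measurable.

`simulate_homology` gives a fraction of genes (default 0.8) a unique
partner-species ortholog as mutual best hits at E = 1e-30, conserves
the enrichment of a planted-enriched gene's partner with probability
`conserved_enrichment_fraction` (default 0.5), zeroes a small fraction
of non-conserved partners (default 0.05, exercising UE), and always
interleaves decoy hits above the E-value cutoff so the filtering logic
is never vacuous. `simulate_promoters` plants non-overlapping concrete
pattern instances in uniform-ACGT background (background occurrences
are possible and deliberately not suppressed — scans recover *at least*
the planted count). `simulate_qpcr` produces
Ct = 30 − log2(expression + c) plus optional Gaussian cycle noise with
a constant reference gene, so noiseless Ct back-transforms to an exact
monotone image of expression.

What the generator does *not* emulate: gene-length and coverage biases,
count overdispersion at low expression, correlated organ noise,
many-to-many homology families, promoter base composition. Passing
planted-recovery tests therefore demonstrates the correctness of the
statistics and bookkeeping under the stated model, not screen
performance on real tissue libraries.

A note on cross-category planting: a gene planted as sepal-enriched is
*legitimately* enriched in domain A under the statistic (the A-mean is
lifted while A's comparison set stays flat, driving Z to +∞), so
planted-recovery operating characteristics are evaluated per category
class — organ-level plants against organ screens, domain plants against
domain screens. This is a property of the statistic, not an artifact
of the generator.

## Validation problem sizes

The test and acceptance runs use matrices of up to ~50 genes × 8 organs
for exact oracle equivalence (hundreds of random matrices against a
from-first-principles recomputation), 400-gene simulations for
planted recovery (100 enriched + 40 downregulated plants; 10 seeds at
20% noise), 200 planted orthologs per run for the conserved-fraction
estimate (EE/HH within three binomial standard deviations of the
planted fraction), and hundreds of random ≤200 bp sequence /
≤8 bp pattern cases for the motif-scan oracle. These sizes give exact
or tight-binomial checks while keeping the whole suite in seconds.

## Known limitations

- The screen's thresholds are taken as given; the package does not
  calibrate them, and offers no error-rate guarantees off the
  simulation model.
- Spearman/Pearson p-values are not computed; the operative criteria
  are the r thresholds themselves.
- Printed percentages are recomputed exactly from their count pairs;
  source tables whose printed percentages disagree with their own
  numerator/denominator pairs are not reproduced.
- GFF3 handling extracts only the feature rows needed for promoter
  anchoring; it is not a general-purpose GFF3 model.
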