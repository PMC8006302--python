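# Methods

## Data model and filters

The unit record is an annotated V(D)J rearrangement (subject, chain, V/J
call, CDR3 amino-acid sequence, isotype), held in AIRR/MiAIRR-style TSV
columns. `cdr3_aa` is the junction *without* the flanking conserved
residues; when an input table carries only `junction_aa`, the first and
last residues are stripped (configurable, applied uniformly). All
positions are 0-based half-open internally.

Quality filtering is applied in a fixed order because depth is defined on
the *retained* records: (a) junction nucleotide length not divisible by 3
(untranslatable; skipped with a warning when the column is absent), then
(b) isotypes other than IgM/IgD — records with unknown isotype are dropped
under the strict default and kept with `keep_unknown_isotype=True` for
tables that never recorded isotype — then (c) whole subjects with fewer
than `min_depth = 2000` retained rearrangement records. Depth counts
retained records, not raw reads. Filtering is idempotent.

## Clonal clusters

Sequences are pooled across subjects and partitioned within each
(V gene, J gene, CDR3 length) class — gene level, allele suffixes
stripped, first call of a multi-call — by agglomerative **complete
linkage** on the normalized Hamming distance, cut at the threshold `T`.
Complete linkage bounds the cluster diameter: no two members differ at
more than `T` of their positions; this invariant is asserted on the
output. Paired defaults follow the method design: `T = 0.15` with
`n_min = 7`, `T = 0.25`/10, `T = 0.6`/20. "Independent members" defaults
to distinct (subject, CDR3) pairs after per-subject deduplication of
identical sequences; counting distinct subjects instead is available via
`independent="subjects"`.

Implementation: greedy agglomeration — repeatedly merge the active pair
with the smallest complete-linkage distance until it exceeds `T`, which
for a monotone linkage equals cutting the dendrogram at `T`. Merge ties
break on the smallest index pair (clusters keyed by their smallest member
index), making the partition platform-independent. Because complete-
linkage clusters can never straddle two connected components of the
`distance <= T` graph, the quadratic merge loop runs only inside such
components; candidate edges are found by a pigeonhole screen (a pair with
at most `m = floor(T*L)` mismatches must agree exactly on one of `m + 1`
contiguous chunks), which keeps classes of mutually dissimilar sequences
linear-time. The same partition is verified against a naive all-pairs
agglomeration oracle in the tests.

The consensus is the per-position majority residue (count-weighted over
member sequences), which minimises the summed Hamming distance; ties
break alphabetically. Cluster feature values are each subject's fraction
of retained sequences assigned to the cluster. Subjects that did not
contribute members (holdout subjects scored against training-derived
clusters) are assigned per sequence to the nearest consensus of the
matching class when within `T`, else to no cluster. Group-biased cluster
selection keeps clusters with at least `purity = 0.7` of member sequences
(count-weighted) from one cohort, computed on training labels only.

## Other representations

Annotation features: per-subject V usage, J usage, V-J pair usage, CDR3
length histogram and isotype usage, each family normalised to sum to 1
per subject. Atchley k-mer features: CDR3s are decomposed into
overlapping k-mers (`k = 3` by default) and each residue encoded by the
five published Atchley factor scores (polarity, secondary-structure
propensity, size, codon diversity, charge; transcribed verbatim and
guarded by a checksum — note the published factors are centred but not
all unit-variance). The repertoire-level summary is the mean and standard
deviation of each encoded position over all of a subject's k-mers; this
aggregation is this package's choice, since the per-k-mer encoding is
otherwise consumed instance-wise by the MIL stage.

## Classification pipeline

Each iteration: stratified 80/20 subject split → (cluster representation)
clustering and purity selection on the training subjects only → z-score
fitted on training rows, applied with the same parameters to holdout rows
(zero-variance columns dropped and logged) → random-forest importance
ranking (100 trees; mean decrease in impurity averaged over up to 10
stratified folds inside the training set, capped by the minority class
count) keeping the top 1,000 → LR-RFE (10% of features eliminated per
round by smallest |coefficient|) down to 300, or to an RFECV-chosen size
(candidate sizes along the elimination path, mean CV F1, ties to the
smallest size) → ridge logistic regression (`C = 1/l2_strength`,
default strength 1.0) → holdout F1 and accuracy, with **case** as the
positive class. Iteration seeds derive from the master seed by a counter;
the whole pipeline is a pure function of (data, config, seed).

If no cluster survives purity selection (common under the permuted-label
control) the iteration degenerates to an intercept-only model predicting
the training-majority class. This keeps the control honest but inflates
its F1 (an all-case prediction on a balanced holdout has F1 ≈ 0.67 even
though accuracy is ≈ 0.5); chance level is therefore read from the
*accuracy* ("prediction rate"), and both metrics are reported.

The permutation control shuffles training labels per iteration; holdout
labels are never used in any fitting step (audited bitwise in the tests)
and stay intact for scoring. Feature aggregation over iterations reports
the selection frequency (features above 40% form the headline report) and
associates each feature with the cohort given by the sign of its summed
logistic weight (positive = case). Clusters are re-built per split by
default, matching features across iterations by their
`V|J|length|consensus` identity.

## Enrichment

CSEA walks the importance-ranked cluster list, adding
`|r_i| / sum_{j in S} |r_j|` on members of set `S` and subtracting
`1/(N - |S|)` otherwise; ES is the maximum absolute deviation of the walk,
whose endpoint is identically 0 (asserted per call). The null permutes
the attribute labels over clusters (set sizes preserved);
`p = (1 + #{null >= obs}) / (1 + n_perm)`, `NES = ES / mean(null ES)`,
and FDR is the GSEA-style ratio of null-to-observed NES tail proportions,
clipped to [0, 1]. The importance measure fed to CSEA is the selection
frequency; weight magnitudes can be supplied instead.

k-mer enrichment first balances the two sequence sets exactly per length
(`min(count_A, count_B)` drawn without replacement at every length), then
tests each k-mer's 2x2 table (count vs remaining k-mers per set) with the
**two-sided** Fisher exact test — computed vectorised from the
hypergeometric pmf with the conventional 1e-7 relative tie tolerance, and
verified against `scipy.stats.fisher_exact` and an exact rational oracle
in the tests — followed by Benjamini-Hochberg correction (significant at
q < 0.05). Fold changes are oriented case/control with a 0.5 pseudocount
on zero counts. The conjoint-triad representation maps residues to the
fixed seven classes {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
{D,E}, {C} before k-mer counting. Case/control sequence sets default to
the consensus sequences of the top 100 case- and control-associated
clusters (configurable).

## Multiple-instance motif model

Bags are cluster consensus sequences of the top-ranked clusters (half per
association, 300 by default); instances are their contiguous 3-mers,
encoded as 5 Atchley factors x 3 positions plus the 3-mer's relative
position `start/(n_kmers - 1)` (0 for a single-3-mer sequence). The bag
probability is the logistic transform of the *maximum* instance score
plus an intercept; duplicating instances can never change a bag's score.
Fitting is full-batch Adam on the bag-level penalised log-likelihood with
a subgradient through the hard max (first-argmax tie-break), zero
initialisation, instance standardisation from training statistics only,
L2 on the weights; non-convergence returns the best iterate with a
warning. Evaluation uses a stratified seeded 80/20 bag split; the weight
vector reshaped to factor x position is the motif report.

## Synthetic generator

The generator emulates the study conditions: 48 case and 44 control
subjects with a constant 2,000 sequences each (the post-filter depth
floor), heavy chain by default, ~50 IMGT-style V names with Zipf(1)
weights and 6 J names with Zipf(1.5) weights (top-gene usages around 20%
and 55%), CDR3 lengths rounded from a normal distribution (mean 15, sd 3)
truncated to [5, 30] by redrawing, and uniform background CDR3
composition over the 20 AAs — a neutral null that cannot leak signal.
Ten planted clusters (even indices case-biased, odd control-biased) are
grown from random seed CDR3s mutated at 0.03 per position; each cluster's
100 members go to a subject of the biased cohort with probability
`planted_purity = 0.9` and replace random background rows, keeping depth
constant. Cluster size, mutation rate and counts are configurable; the
defaults above were fixed once as a regime in which roughly 1-2 extra
sequences per cluster land in each biased-cohort subject — strong but not
degenerate signal. An optional motif specification embeds one
conjoint-triad-class 3-mer per planted seed, so triad-level enrichment
has ground truth; `plant_ct_depletion` then destroys such triads in
case-biased clusters with probability `1 - factor` each (overlapping
occurrences make the realised depletion slightly stronger than `factor`).
Ground truth (seeds, biases, member sequence ids) is emitted separately
and never enters the AIRR table.

What the generator does *not* model: nucleotide-level recombination,
somatic hypermutation lineages, sequencing error, per-subject depth
heterogeneity, isotype-cohort interactions, and realistic positional
amino-acid composition of CDR3s. Passing tests therefore demonstrate
that the pipeline recovers the kinds of signal it is designed for and
stays at chance when none is planted — not that real naive repertoires
contain such signal.

## Problem sizes and numerical choices

The repeated-holdout suites run 50 iterations at the full synthetic
cohort scale (92 subjects x 2,000 sequences); enrichment and MIL checks
use smaller cohorts sized so that each stage's statistics, not runtime,
dominate. Monte-Carlo p-values use the (1+count)/(1+n) estimator;
permutation nulls preserve set sizes; all tie-breaks (consensus residues,
merge order, argmax instances, RFECV sizes) are deterministic and
documented above. Degenerate inputs (empty repertoires, single-class
splits, all-constant features, sets spanning the whole ranked list) are
either legal no-ops, logged skips, or explicit errors per the module
docstrings.

## Known limitations

The full supplementary annotation-feature inventory of the motivating
study is not reproduced (representative families only, with an extension
point); D-gene features are omitted by default since D calls are often
ambiguous. Heavy/light combination is a column concatenation of per-chain
matrices over shared subjects. The RFECV step is off by default inside
the repeated pipeline for cost reasons and available as
`use_rfecv=True`. Reported accuracies on synthetic data should not be
read as estimates of performance on real repertoires.
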