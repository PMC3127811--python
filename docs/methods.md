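# Methods

## Scope and data model

`mitonet` analyzes a quantitative comparison of mitochondria from
mtDNA-depleted (ρ⁰) and parental (ρ⁺) cells. Its inputs are tables a
proteomics/transcriptomics core would hand over after identification and
quantification: a per-protein linear abundance ratio ρ⁰/ρ⁺, reference
catalogs of organelle proteins plus a cellular-component annotation, a
weighted physical/functional association table, flat term annotations,
and a replicated two-condition expression matrix with per-entry detection
p-values. Peptide-level processing, live database retrieval and bead-level
array summarization are upstream of this package.

## Regulation classification

A protein is *up* iff ratio ≥ `up_min` (default 1.5), *down* iff
ratio ≤ `down_max` (default 0.67), else *unchanged*; both boundaries are
inclusive. 0.67 is kept as the conventional printed two-decimal value for
a 1.5-fold decrease rather than the exact fraction 2/3, so a reported
ratio of exactly 0.67 is called down. Ratios are used on the linear scale
everywhere except the concordance analysis. Rows with missing ratios are
dropped with a logged count; non-positive or non-finite ratios are hard
errors naming the protein, since they indicate a broken upstream
quantification rather than a missing one.

## Reliability tiering

Independent localization evidence enters in two forms: the organelle
cellular-component annotation and a list of named reference sets. The
default combination rule is a conjunction (annotated **and** in ≥ 1
reference set); a disjunctive rule is exposed as `rule="or"` because
either reading of pooled evidence is defensible for catalogs of very
different provenance. Proteins failing the rule are rescued through
*single-hop* links to reference-tier proteins — physical channel first,
then functional — which keeps the tiers disjoint and mirrors the idea
that interaction partners co-localize. Links to rescued proteins do not
propagate; transitive rescue would let a single spurious edge chain
arbitrary contaminants into the reliable set.

## Network statistics

The functional network is a simple undirected graph induced on the
reliable set; duplicate link rows collapse to the maximum-confidence row.
Analysis runs on the largest connected component (ties broken toward the
component containing the lexicographically smallest id, for determinism).
Link categories use only endpoint classes; the reported
intra-percentage is taken over *regulatory* links (both endpoints up or
down), with the full edge count reported alongside, so both the
regulatory-only and the all-edges totals are always visible.

Per-protein link fractions use regulatory edges as the denominator, so a
node's intra and inter fractions sum to one; nodes with no regulatory
edge are excluded rather than counted as zeros. Shortest paths are
unweighted breadth-first distances over all edges of the major component
— confidence scores are probabilities of association, not lengths, and
using them as weights would need an unprincipled transform. The pair
universe defaults to all connected regulated pairs; an adjacent-pairs-only
mode is available behind a flag.

The Mann–Whitney U test is implemented in-package: U from mid-ranks, and
a p-value either by exact enumeration of all group labelings of the
pooled sample (pooled n ≤ 12; correct in the presence of ties) or by the
normal approximation with tie-corrected variance and a 0.5 continuity
correction. A pooled sample with one distinct value returns p = 1 with a
warning. Defaults are one-sided in the direction under test (same-class
paths shorter; intra fractions larger), two-sided by flag.

## Module detection

The similarity matrix holds edge confidences, zero where no edge, one on
the diagonal. Clustering is agglomerative average linkage (UPGMA):
repeatedly merge the pair of clusters with the largest unweighted mean
cross-pair similarity, stopping when that best mean falls below `tau`.
Because average linkage is monotone, this greedy stopping rule equals a
global dendrogram cut at height 1 − τ, which is how it is computed
(SciPy average linkage on the dissimilarity 1 − s); the greedy O(n³)
formulation serves as the reference oracle in the test suite.

The cut default is `tau = 0.1`. With absent pairs entered as similarity
0, the expected mean similarity between two sub-clusters of one true
module is roughly (edge density within the module) × (mean edge
confidence) — about 0.3 × 0.8 ≈ 0.24 under the generator defaults, and
lower for sparser real association networks — while the between-module
expectation is one to two orders of magnitude smaller. Any cut above the
within-module expectation fragments true modules regardless of data
quality, so the default sits between the two expectations; it is a
property of similarity-on-sparse-graphs clustering, not a tuned constant.
Clusters below `min_size = 3` go to an unassigned pool: a "module" of two
proteins is an edge, not a functional unit.

A cluster is promoted to a functional module when both its best term
enrichment and its regulation enrichment are below α = 0.01 (raw one-sided
hypergeometric upper-tail p; an optional Benjamini–Hochberg adjustment of
the per-cluster term p-values exists but is off by default, matching the
fixed-α selection convention). The background for both tests is the
clustered universe — the major-component proteins, restricted for term
enrichment to proteins carrying ≥ 1 term. Terms with fewer than two
annotated cluster members are not tested. Regulation-enrichment ties
break toward the direction with more members, logged. Annotations are
flat sets; ontology parent–child propagation is out of scope.

## Concordance analysis

Intensities are log₂-transformed before quantile normalization (each
column's values are replaced by across-column rank means; ties receive
the mean of their target quantiles). A gene is dropped when its detection
p exceeds 0.05 in *every* sample of at least one condition — per-sample
dropouts are tolerated, total dropout in a condition makes the ratio
meaningless. The mRNA log₂ ratio is the mean over all replicate pairs of
the normalized log₂ differences, which equals the difference of
per-condition means.

k-means (k = 5, ten restarts, seeded) runs on the 2-D
(protein log₂ ratio, mRNA log₂ ratio) points. Cluster labels come from
centroid geometry with a dead zone δ = log₂(1.2): both coordinates above
+δ → up_up, both below −δ → down_down, mixed signs → up_down / down_up,
and the centroid nearest the origin → unchanged. Centroid geometries
matching no label (e.g. when one planted group is too small to hold its
own centroid) raise an error naming the centroids rather than guessing.
Module expression summaries report mean ± sd (n − 1) of *linear* protein
and mRNA ratios over profiled members, matching box-plot-style reporting.

`pattern_agreement` compares two classifications of the same proteins
(e.g. two proteomic platforms) as the percentage of shared ids with equal
class, plus a two-sided exact binomial test of the agreement count
against the chance-agreement rate implied by the two marginal class
distributions. The binomial reference is a convention of this package —
no particular statistic is standard for this comparison — and its p-value
is reported descriptively, never asserted.

## Synthetic worlds

The generator plants, from one seeded RNG:

* **Modules** — 5 up and 8 down modules of 20 proteins by default, each
  with an opposing fraction of 0.05 (members whose protein moves against
  the module, emulating negative regulators). Protein effects are
  N(±1, 0.3) on the log₂ scale, so the 1.5-fold thresholds capture most
  planted members while leaving realistic overlap.
* **Background** — 400 non-module proteins scattered over the five
  concordance patterns (fractions 0.60 / 0.08 / 0.12 / 0.08 / 0.12 for
  unchanged / up_up / down_down / up_down / down_up): real studies find
  all five groups populated, with negative correlation slightly more
  common than positive, and a generator lacking the four corner
  populations leaves the k = 5 labeling geometrically ill-posed.
* **Links** — a stochastic block model: within-module pairs at
  p_in = 0.3 with confidence ~ Beta(8, 2), all other pairs at
  p_out = 0.01 with Beta(2, 8); pairs touching a contaminant at
  p = 0.0005, so contaminants stay sparsely connected. 30% of links are
  physical-channel.
* **Reference evidence** — genuine proteins carry the organelle
  annotation with sensitivity 0.9 and appear in each of 13 reference sets
  with sensitivity 0.5; contaminants (150 proteins, never flagged
  referenced in the truth table) enter only at a 2% false-positive rate.
* **Annotations** — a dominant module term on 80% of members plus
  uniform background terms.
* **Expression** — log₂ intensity = base N(7, 1) + condition effect +
  N(0, 0.3) per replicate (three per condition); module genes carry the
  compensatory +1 log₂ mRNA effect in ρ⁰ regardless of protein direction;
  detection p is small for expressed genes, and 5% of non-module genes
  are planted undetected.

What the generator does **not** emulate: correlated noise between
replicates, intensity-dependent variance, shared proteins between
modules, ontology structure, cross-contamination of reference catalogs,
or the long-tailed degree distributions of curated association networks.
Passing tests therefore demonstrate correctness of the pipeline's logic
and its behavior under the planted statistical structure, not performance
on any particular real database snapshot.

## Problem sizes and determinism

The default world holds 810 proteins (260 in modules, 400 background,
150 contaminants) — a deliberate desk-scale setting at which the whole
pipeline runs in about a second and the recovery suites (ten block-model
worlds of 200 proteins; 500 planted concordance points) in a few seconds.
Statistical outcomes that depend on the full-size curated networks — the
astronomically small U-test p-values, the exact module inventory — are
treated as directional properties, not numeric targets. Every stochastic
step (generator, k-means restarts) draws from explicit seeds; a
fixed-seed pipeline run serializes byte-identically.

## Known limitations

* The reliability rescue assumes link confidence is trustworthy enough
  that one edge suffices; no confidence threshold is applied at the
  rescue stage (only at network construction via `score_min`).
* Average-linkage clustering with a global cut cannot represent nested
  modules; a module split by a sparse seam may appear as two clusters
  sharing a dominant term (and then as two detected modules).
* Centroid-sign labeling of the k-means partition requires all five
  concordance populations to be large enough to own a centroid; very
  small or very skewed profile sets fail loudly by design.
* Enrichment uses raw p-values at a fixed α by convention; with many
  clusters and terms the family-wise error is uncontrolled unless the
  optional Benjamini–Hochberg flag is enabled.
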