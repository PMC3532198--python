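# Methods

This note documents the statistical procedures `dddkit` implements, the
choices made where a design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Digital differential display

EST libraries are digitally pooled: per-gene counts are summed over the
member libraries of each pool and the pool total is the sum of the
declared library depths (declared totals may exceed the sum of per-gene
counts, allowing unassigned reads).  For each gene with a nonzero count
in either pool:

* transcript frequency *f* = count / pool total;
* signed fold = max(*f_T*, *f_O*) / min(*f_T*, *f_O*), signed by the
  **test pool**: positive when the test pool has the larger frequency.
  One zero frequency makes the fold *exclusive* ("+" if only the test
  pool expresses the gene, "−" otherwise); equal frequencies give +1.
  A single sign convention with an explicit test-pool designation
  reproduces contrasts whose reports order their pools differently.
* two-sided Fisher exact p-value by the point-probability rule: with
  margins fixed, sum the hypergeometric probabilities of all tables
  whose probability is at most that of the observed table, with a
  relative tolerance of 1+1e−7 guarding float ties.  The enumeration
  runs over the gene margin (count_A + count_B), which is small for
  EST data, in log space via `scipy.stats.hypergeom.logpmf`; when
  every table qualifies the p-value is exactly 1.
* Benjamini–Hochberg q-values over all tested genes
  (`statsmodels.stats.multitest`).

Filtering keeps records with fold magnitude ≥ 2 by default; exclusive
records always survive.  No p-value threshold is applied by default —
the fold rule is the operative filter, and an optional `alpha` cuts on
q-values when requested.  Reported frequencies are rounded half-up to
4 decimals and fold magnitudes to 2 decimals; all arithmetic uses the
unrounded values.

## Subtractive filtering

Candidate narrowing is a fixed sequence — intersect the two contrasts,
apply exclusion lists, map identifiers to a canonical namespace — each
step appending `(step, n_before, n_removed, n_after)` to a provenance
log.  Exclusion and mapping do not commute unless the mapping is
injective on the exclusion list, which is why the order is fixed.
Identifiers without a mapping are dropped with a warning rather than
passed through, and canonical duplicates collapse keeping the first
occurrence; both choices make hit counts shrink on conversion, which is
the observable behaviour of real-world id conversion.  Identifier text
is opaque: nothing assumes a particular accession scheme.

## Wang semantic similarity

S-values propagate from the anchor term upward in topological order, so
each term in the anchor's ancestor closure is visited once; on a DAG
this equals the maximum over all upward paths of the product of edge
weights (verified against a path-enumeration oracle in the tests).
Edge weights default to the standard Wang constants, 0.8 for `is_a` and
0.6 for `part_of`, and are configurable.  Direct annotations anchor the
computation — ancestors enter only through S-value propagation — and
per-term S-value tables are cached when building a matrix so each term
propagates once.

Gene-level similarity is the best-match average.  Scores from BP, MF
and CC are combined by an unweighted mean over the namespaces in which
*both* genes are annotated; the namespaces used are returned alongside
the score for auditability.  A pair with no shared annotated namespace
is missing (NaN), not zero: zero-filling would assert dissimilarity
where there is simply no information.  Candidate rows that are missing
against every reference gene are dropped from the similarity matrix
with a warning.

## Clustering and multiscale bootstrap

Genes are clustered on 1 − Pearson correlation between their
similarity profiles.  Missing entries are handled pairwise-complete;
a pair sharing fewer than 3 columns, or a constant profile, is an error
in the observed clustering.  Inside bootstrap replicates a constant
profile (possible when a resample draws uninformative columns) is
instead treated as uncorrelated (distance 1), so replicates never
abort; replicate and observed clustering otherwise share the same code
path.  The distance matrix is explicitly symmetrised because
`numpy.corrcoef` is symmetric only to rounding.

Agglomeration is UPGMA by default (complete and single linkage are
available), with a deterministic tie-break: among equal minimum
distances the pair whose merged membership set is lexicographically
smallest merges first.  Determinism matters because bootstrap support
counts exact membership-set matches between replicate trees and the
observed tree.

For each scale factor r in 0.5, 0.6, …, 1.4 the reference columns are
resampled with replacement to size n_r = round(n·r) (minimum 3), B
times (default 1000).  A node's BP at a scale is the fraction of
replicate trees containing its exact membership set.  The AU fit
follows the probit formulation: ψ_r = Φ⁻¹(1 − BP_r) is regressed on
(√ρ_r, 1/√ρ_r) with weights B·φ(ψ_r)²/(BP_r(1−BP_r)), giving
(v, c), AU = 1 − Φ(v − c) and fitted BP = 1 − Φ(v + c).  Scales with
BP exactly 0 or 1 carry no probit information and are excluded from
the fit; when fewer than two informative scales remain the curve's
direction decides directly — AU = BP = 1 for a curve pinned high,
0 for one pinned low.  (Clamping such scales to [1/(2B), 1−1/(2B)] and
fitting instead produces a near-constant ψ curve whose fit splits
arbitrarily between v and c and lands AU near 0.6 even for nodes hit
in essentially every replicate; the exclusion rule, which pvclust also
uses, gives the behaviour one actually wants from a perfectly stable
cluster.)  `fit_au` still clamps boundary values defensively when
called directly.

Cluster selection is top-down: report a node and prune its subtree when
AU ≥ α (default 0.95).  Leaves are never reported, and neither is the
root: the full gene set is contained in every replicate tree by
construction, so its AU is 1 regardless of structure and reporting it
would always swallow every real cluster.  Panels are then the
intersections of the selected clusters (in dendrogram order) with the
biomarker list, numbered consecutively; panel numbering deliberately
follows dendrogram order rather than size.

## Synthetic data

The generator emulates the structure of pooled EST studies at desk
scale: baseline transcript proportions from a symmetric Dirichlet
(concentration 0.5, giving the right-skewed abundance profile typical
of transcriptomes), per-library depths uniform on 2×10⁴–5×10⁴, and
multinomial per-library counts — multinomial rather than independent
Poisson because an EST library has a fixed sequencing depth.
Differential genes are planted by multiplying (up) or dividing (down)
their query-condition proportion by a stated fold and renormalising.
The default design is 6 reference, 6 query and 20 other-tissue
libraries over 300 genes — far smaller than a public EST compendium
but structurally identical, chosen so every downstream stage runs in
seconds.

Toy ontologies grow one term at a time, each attaching to one (70%) or
two existing terms, `is_a` with probability 0.8 and `part_of`
otherwise; acyclicity holds by construction.  Functionally coherent
groups are planted by assigning each group a branch (a term plus its
descendants) in every namespace — branches chosen greedily smallest
first among disjoint candidates, since small branches maximise how many
disjoint groups fit — and group members draw Poisson-many terms from
their branch, leaking to a uniform namespace-wide term with a
configurable probability.  Background genes draw uniformly.  The
packaged two-group dataset (44 genes, 2 groups of 22, 4 terms per gene
per namespace, zero leakage) holds out 10 genes per group as reference
columns, so each candidate's profile is high against its own group's
columns and low against the other's; 20 columns keep small-scale
resamples from collapsing onto a single group's columns.

What the generator does **not** emulate: EST sequencing error, 3′
coverage bias, library normalisation artefacts, inter-library
biological variability beyond multinomial noise, and the scale and
annotation depth of the real GO.  Passing tests therefore demonstrate
the correctness and calibration of the machinery, not that a specific
published gene list would be recovered from live databases.

## Numerical and degenerate-input policy

* Fold changes from a gene absent in both pools are an error (such
  genes are filtered before scoring).
* Fisher inputs are validated (counts within totals); empty or full
  gene margins give p = 1.
* Correlation values are clipped to [−1, 1] before distances.
* Bootstrap runs are fully reproducible from (matrix, seed); the RNG is
  a single `numpy` Generator consumed in a fixed scale-major order.
* Terms in the same namespace but disconnected components share no
  ancestor and score 0; cross-namespace term pairs are an error.

## Known limitations

* AU estimation uses the probit WLS formulation; maximum-likelihood
  refinements and AU standard errors are not implemented.
* The OBO reader supports the subset needed for the Wang measure
  (`is_a`, `relationship: part_of`, obsolescence); `intersection_of`
  and cross-products are ignored.
* GAF evidence codes are not filtered by default; an inclusion list can
  be supplied.
* Fisher exact enumeration is exact but the log-space accumulation is
  accurate only to ~1e−13 absolute; the tests bound it at 1e−12.
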