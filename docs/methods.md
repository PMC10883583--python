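# Methods

This note documents the modeling choices behind `sefingerprint`: what each
stage assumes, which parameters matter and why their defaults are what they
are, what the synthetic data does and does not emulate, and where the
method's limits are.

## Region unification

Per-sample SE and CE calls for the same underlying element differ in their
boundaries, so cross-sample comparison starts from a unified candidate
list. Two regions of the same class are treated as the same element when
their intersection covers at least `min_overlap` (default 0.25) of the
**smaller** region's width; merging is the transitive closure of this
relation, computed with a sweep plus union-find. Transitive (single-
linkage) closure is the only order-independent choice that yields a
partition of the input calls, and it makes `merge_regions` idempotent and
permutation-invariant (both property-tested, and checked against a
brute-force O(n²) oracle).

Choices worth knowing about:

- *Denominator.* The fraction can be taken over the smaller width
  (default), the more permissive of the two per-region fractions
  (`either`, numerically identical to `smaller`), or reciprocally
  (`reciprocal`: both regions must reach the cutoff). The smaller-width
  rule maximizes merging symmetry; published observations suggest the
  final lists are quite insensitive to the cutoff in the 0–25% range, so
  the alternatives are config options rather than forks of the method.
- *Cutoff 0.* A literal "fraction ≥ 0" would merge disjoint regions;
  merging therefore additionally requires a strictly positive
  intersection. Abutting half-open intervals share no base and never
  merge.
- *Coordinates.* 0-based half-open (BED) everywhere internally. Strand is
  ignored for SEs/CEs (H3K27Ac is unstranded) and used only to orient
  promoter exclusion windows (TSS −3 kb / +1 kb, mirrored on the minus
  strand).
- *CE → SE assignment.* Each unified CE belongs to the unified SE it
  shares the most bases with; ties break to the SE with the smaller start
  so the assignment is deterministic. CEs overlapping no SE are flagged,
  not dropped silently.

## Activity matrix

Raw activity is total per-base H3K27Ac coverage within each unified
region. Replicates are **summed** per cell line (preserving count
semantics for the normalization below; a mean is one flag away).

Depth normalization is median-of-ratios (RLE): rows with all-positive
counts define a geometric-mean pseudo-reference, and each column's size
factor is the median of its ratios to that reference. Rows containing a
zero are excluded from the size-factor computation but are still
normalized. The size factor captures each cell line's effective sequencing
depth; note two properties that matter for interpretation:

- Scaling columns by depths d_j multiplies the size factors by d_j and the
  whole normalized matrix by the single constant geomean(d). Cross-column
  comparisons — which is all the downstream model uses — are therefore
  exactly depth-free, but the absolute scale of normalized values is only
  defined up to that constant.
- With strongly bimodal on/off rows (the situation here), the
  pseudo-reference sits below the typical column value, so normalized
  values carry a panel-wide offset relative to naive per-column scaling.
  This is inherent to RLE on enhancer matrices and harmless: every column
  shares the offset.

Zeros in the normalized matrix are replaced by half the column's minimum
positive value (per cell line), with the pre-imputation zero positions kept
in a mask; log2 is applied only after imputation, with no pseudocount.
Imputation exists purely to keep the log-scale model finite — the mask, not
the imputed value, carries the information that coverage was absent.

CEs contributing ≤ 3% of their SE's summed activity in **every** cell line
are removed before modeling (they are retained if they pass anywhere; the
filter is evaluated per cell line because contribution is a per-sample
notion). Per-kilobase activity (signal / width × 1000) is provided for
comparisons against orthogonal assays such as STARR-seq or PRO-seq
coverage.

## Mixture model for CE states

Log2 activities of one CE across the panel are modeled as a two-component
Gaussian mixture; the component with the larger mean is "active". Fitting
is plain EM run to an objective change ≤ 1e-8 (cap 1000 iterations,
non-convergence is a logged warning), and the per-iteration objective is
recorded — monotonicity is asserted on every fit in the test suite.

Panel-wide **global priors** come first: for each cell line, a
two-component mixture is fit to the genome-wide CE activities (excluding
pre-imputation zeros), and the component means/SDs are averaged across
cell lines. These consensus parameters serve two roles in the per-CE fits:

1. *Initialization* — component means and SDs start at the priors, weights
   at 0.5/0.5.
2. *Weak anchoring (default)* — the per-CE fit maximizes a penalized
   objective with conjugate priors on each component: `prior_kappa = 1`
   pseudo-observation on each mean and `prior_nu = 2` on each variance.
   This is deliberately weak — about one phantom data point against ~60
   real ones — but it prevents a well-documented failure of unconstrained
   1-D mixture ML: a component collapsing onto a tight few-point
   subcluster (e.g. a run of near-identical low values) with tiny
   variance, which swallows the real active/inactive split. On synthetic
   panels this pathology hit a few percent of CEs and produced per-CE
   state accuracies as low as 0.37; with the anchor the fits are clean.
   `prior_mode="init"` disables the penalty and reproduces pure ML EM.

Occurrences that were zero before imputation are excluded from the per-CE
likelihood and called inactive directly: zero coverage is inactivity by
definition, and the imputed half-minimum placeholders would otherwise form
an artificial spike below the inactive component — exactly the subcluster
the previous paragraph warns about.

A fit is **degenerate** when the variance floor (1e-3 log2² units) is
crossed, the fitted means are closer than half the pooled SD, or a
component claims less than one expected observation. Degenerate CEs are
the uniformly active / uniformly inactive ones — there is no split for a
two-component model to find — and their cell lines are assigned to
whichever global prior mean is nearer. State calls from proper fits use
the strict rule: active iff the posterior probability of the active
component is > 0.5 (exactly 0.5 is inactive). For symmetric fits (equal
SDs and weights) the implied activity cutoff is analytically the midpoint
of the component means; in general it lies strictly between them and
varies per CE, which is the point of fitting per-CE models at all.

## Specificity and the prevalence threshold

Active prevalence is the fraction of cell lines called active;
cell-specific active (inactive) CEs are those with active (inactive)
prevalence strictly below the threshold, carrying their minority cell
lines. CEs with prevalence exactly 0 have an empty minority set and are
not calls — they are the uniform classes.

The threshold is data-derived. For every cutoff in 0, 0.01, …, 0.5 the
CEs below it are selected, the cell lines are clustered on the selected
CEs' log2 activities (Ward linkage, Euclidean distance, tree cut at
k = number of cancer types; all configurable), and the partition is scored
against the true cancer types with the variation of information (natural
log; the base cancels after scaling). An empty selection scores the
single-cluster VI — maximal uninformativeness. Both axes are min-max
scaled to [0, 1], the VI curve is smoothed with a local quadratic
(Savitzky–Golay, window 11 grid points), and the selected threshold is the
knee: the cutoff where the smoothed slope climbs back through −1 after the
curve's dominant descent. Implementation detail that matters on noisy
curves: the slope ≤ −1 condition can also fire briefly on plateau noise
before the drop and on small dips near 0.5; the rule therefore anchors on
the steepest point of the curve and takes the last cutoff of its
contiguous steep run. If the slope never reaches −1 (e.g. a flat curve),
the fallback picks the cutoff closest to the ideal low-VI/low-cutoff
corner (minimizing scaled VI + scaled cutoff) with a warning. The same
selected threshold is applied to both the active and the inactive scans.

Cell-specific calls are promoted to cancer-specific when ≥ 2 cell lines of
one cancer type carry the state, or when a cancer has exactly one cell
line in the panel and that line carries it. An SE containing
cancer-specific CEs is a fingerprint SE; it is listed once per cancer it
is specific to (so one SE can appear under several cancers) and carries a
category — `active_only`, `inactive_only`, `both`, or `none` — derived
from all its specific CEs.

## Synthetic data

The generator emulates the structure the pipeline assumes, with defaults
chosen as a realistic desk-scale panel: 10 cancers × 3 cell lines × 2
replicates, 200 SEs with 5 CEs each (~1.4–14 kb CE widths, nested in
non-overlapping SEs across 5 chromosomes), 500 non-SE background enhancers
for normalization, log2 activity components N(3, 1) and N(9, 1) (the
active/inactive separation seen in well-behaved H3K27Ac panels; also the
regime in which a two-component model is the right tool), per-sample depth
factors uniform in [0.5, 2], replicate noise with SD 0.25 log2 units, 5%
excess zeros among inactive occurrences, and 5% boundary jitter per
sample. 15% of CEs are planted cancer-specific (half active, half
inactive) at ~0.15 prevalence: all cell lines of one cancer plus single
cells from distinct other cancers (round-half-up cell counts, so a design
aiming at prevalence p never undershoots it); 1% each are uniformly
active/inactive. Counts are rounded continuous signal by default (keeping
closed-form expectations for size-factor recovery); a Poisson mode is one
flag away. Everything is a pure function of the config, whose seed is
recorded in the output.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: peak-calling artifacts and batch structure;
copy-number and input-control biases; correlated CE activities within an
SE; heavy-tailed or skewed activity distributions; cancers with unequal
cell-line counts; zeros among active occurrences; SE calls missing from
individual samples. Zero injection is also restricted to CE rows so that
the background-enhancer set always provides all-positive reference rows
for RLE; a real panel could in principle lack such rows, which the
normalizer reports as an error rather than guessing.

## Numerical choices and degenerate inputs

- EM tolerance 1e-8 on the objective; variance floor 1e-3 (log2²);
  max_iter 1000. EM is deterministic given its initialization — no random
  restarts by default.
- Mean-anchoring `kappa = 1`, variance-anchoring `nu = 2` pseudo-
  observations (see above); both configurable, `prior_mode="init"`
  disables them.
- Ties: equal CE↔SE intersections break to the smaller SE start; the
  posterior rule at exactly 0.5 calls inactive; the specificity rule is
  strictly below threshold.
- A cell line whose global fit degenerates is excluded from the prior
  average with a warning; all cell lines degenerating is an error. A
  column that is entirely zero cannot be imputed and is an error. A matrix
  with no all-positive row has no size factors and is an error.
- Savitzky–Golay window is clipped to the grid length (kept odd) for
  short grids.
- In BED exports, coordinates and identifiers round-trip losslessly;
  member-level provenance of unified regions is not representable in BED
  and survives only in the database tables.

## Limitations

- The two-component assumption cannot represent CEs with graded or
  three-state activity; such CEs get forced binary splits.
- The threshold-selection clustering configuration (distance, linkage, cut
  rule) is not identified by the method itself; a different configuration
  shifts the VI curve and hence the knee. The selected threshold should be
  read as data-and-configuration dependent, not as a universal constant.
- Prevalence treats cell lines symmetrically; panels with very unequal
  cancer representation bias both the prevalence spectrum and the
  clustering, and the ≥ 2-cell-line rule becomes weak for cancers with
  exactly two lines.
- RLE assumes most reference rows are comparable across columns; panels
  where nearly all enhancers switch states violate this and shift the
  common scale (harmless) and, in extreme cases, the factors themselves
  (not harmless).
- Gene-mode queries use a configurable TSS window (default 50 kb) or
  gene-body overlap; this is a proximity heuristic, not an
  interaction-based target assignment.
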