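# Methods

## Model and assumptions

The pipeline assumes an ordered, genes × time-points real matrix with a
single observation per time point (log-ratios or any common scale).
Co-expression is modelled as an *error-bounded linear pattern*: genes
x and r agree over a window when every cell of x can be written as the
corresponding cell of r plus a constant (shifting), times a constant
(scaling, for strictly positive data), or through one affine map
(linear), up to a per-cell residual bound ε.  Coherence is judged
against one certifying reference gene per bicluster rather than
pairwise, which keeps the criterion exactly error-bounded and makes
enumeration tractable.

Reorganization — the object of interest — is inferred purely from
bicluster *start* events.  The boundary score
`R(g,t) = starts / max(1, continuations)` deliberately normalizes new
patterns by persisting ones: a gene that begins several new patterns
while carrying few old ones is changing its co-expression context.
Because membership is strict (`R > θ`, θ = 1 by default), a gene needs
at least two simultaneous pattern starts (or more starts than
continuations) to count as a boundary gene.  A corollary worth knowing:
in perfectly clean data where each reorganization creates exactly one
maximal bicluster, no gene is ever a boundary gene.  Detection relies
on multi-scale or fragmented pattern structure, which real noisy data
supplies in abundance (and which the synthetic generator plants
explicitly; see below).

Block assembly is gene-wise: each maximal run of consecutive boundary
time points opens a segment that lasts until the gene's next boundary
run (or the final column), and genes with identical segments form one
temporal block.  This construction satisfies the four membership
conditions literally — every member boundary at the start, none at
start−1 or at the end, all at end+1, with the first/last column as
escapes — and yields cell-disjoint blocks by construction.  Two
refinements:

* a *disorder period* is recorded when members re-appear on the
  boundary at columns immediately following the start (consecutive
  reorganization);
* a segment lying entirely inside its own boundary run — possible only
  at the global right edge — is a reorganization with no observed
  aftermath and is not emitted as a block.  This mirrors the fact that
  trailing columns shorter than the minimum bicluster length are never
  segmented.

The network stage assumes linear relations throughout (hence Pearson
and partial correlation rather than mutual information).  The link
strength conditions each candidate X–Y association on the *least
favourable* other target gene, so relations conducted entirely through
a third target gene are suppressed; the mean over source genes makes LS
a property of the block pair, bounded by 1 in magnitude.

## Parameters

| Parameter | Default | Meaning and guidance |
|---|---|---|
| ε (error bound) | data-dependent | Per-cell residual tolerance, in expression units. 0.0001 recovers exact planted patterns; on real log-ratio data values near 0.1 balance noise tolerance against pattern dilution, with a grid such as {0.05, …, 0.25} worth scanning. |
| min_genes × min_cols | 2 × 2 (enumeration floor) | Minimum bicluster size. Small sizes over-divide; longer windows merge sub-blocks. 3×2 suits short phases (3 columns); 10×5 is a reasonable scale for ~10³ genes × 18 columns. |
| pattern | shifting | `scaling` = shifting on log(D); `linear` subsumes both but is no longer reference-symmetric and costs an affine fit per window. |
| θ (boundary threshold) | 1 | Strict start/continuation odds required for boundary status. |
| p (expansion threshold) | 0.8 | Pearson correlation an outside gene needs with block members over the block window. Signed; linkage `any` / `all` / `mean` selects the quantifier over members (default `any`). |
| LS threshold | 0.9 | Strict, signed link-strength cut for network edges; an absolute-value variant is available as a flag. |
| ANOVA α | 0.05 | Raw-p cutoff for the prefilter; no multiple-testing correction at this stage (the filter is a recall-oriented screen, not an inference). |

## Synthetic generators: what they emulate, and what they do not

`generate_block_matrix` plants exact shifting patterns (template plus
per-gene offset, optional Gaussian noise) in a uniform background — the
planted-submatrix benchmark for enumeration.  The default design is a
10×15 matrix with five 5-gene × 4-column blocks; ten rows force gene
reuse, so the two row halves alternate and same-half windows never
overlap (placement is a seeded draw recorded in the ground truth).
Because any continuous background makes a spurious ε = 0.0001 match a
measure-zero event, exact recovery is the correct expectation there.

`generate_phase_series` emulates a synchronized two-cell-cycle course:
co-expression groups persist within phases, and at each phase change a
`turnover_fraction` of genes is reassigned to a different group (the
reorganization events; 6 phases × 3 points and turnover 0.5 by
default).  Groups come in pairs sharing a base random-walk template,
the second group of a pair displaced by a constant on the last column
of each phase.  That displacement is the deliberate two-scale device:
every phase start opens both a tight within-group pattern and a looser
cross-pair pattern spanning the phase minus its final column, giving
switching genes two simultaneous bicluster starts and hence R = 2 > θ
at every change point, including the last.  An earlier variant using a
within-phase linear ramp was rejected because a bounded periodic offset
admits arbitrarily long cross-pair windows anchored mid-phase, smearing
boundary counts across the whole axis.

What passing on these fixtures does *not* show: the generators have no
missing values, no amplitude trends, no phase-length variability, no
partially overlapping planted patterns, and their noise is i.i.d.
Gaussian well below ε.  Results on real courses depend on ε and size
settings in ways the clean fixtures cannot probe, and the boundary-peak
behaviour relies on reorganizations being synchronized across genes.

`chain_fixture` plants three temporally overlapping blocks whose genes
are near-copies across adjacent blocks over independent random walks,
so the planted cascade B1→B2→B3 is the unique strong-link structure.

## Numerical choices

* Windows are 0-based inclusive `[start, end]` everywhere; I/O prints
  17-significant-digit floats so matrix round-trips are bitwise exact.
* Discretization is prefix-closed per (reference, window start): a gene
  drops out permanently once any prefix violates ε.  For shifting
  patterns this is automatic (the residual is monotone in the window);
  for linear fits it is imposed, keeping rows encodable as left-anchored
  1-runs.
* Enumeration collects, per reference and start, one candidate per
  distinct per-gene maximal reach, then removes candidates whose gene
  set and window are jointly contained in another's; ties are reported
  once under the canonical (start, end, sorted genes) key.  An
  exhaustive triple-loop enumerator with the same contract ships as
  `bruteforce_biclusters` for verification.
* Partial correlation returns NaN when |C| with the conditioning gene
  reaches 1 (within 1e-12); the link strength skips such Z and falls
  back to the plain Pearson correlation when no conditioning gene
  remains (|G2| ≤ 2, or all Z degenerate).  Singleton targets reduce to
  mean plain correlation.  Evaluation periods shorter than 3 points
  yield no edge.
* Constant profiles: the ANOVA filter drops flat genes with a warning
  (F undefined); expansion treats constant outsiders as non-correlated;
  the partial correlation raises on constant inputs.
* Missing values are resolved at parse time (`drop_gene` default, or
  `fill_row_mean`); all downstream code assumes finite data.

## Open design points, resolved here

* The boundary-score denominator guards the first column: every window
  trivially "starts" at column 0, so R is defined as 0 there and
  first-column escapes in the membership conditions take over.
* The expansion quantifier over member correlations is not fixed by the
  block definition; `any` is the default because single-anchor joining
  reproduces the large expansions seen in practice, with `all` and
  `mean` as stricter options.
* Link strength is thresholded signed, not absolute, by default; strong
  negative relations can be admitted with `--absolute`.
* Blocks sharing a start column can be linked in both directions; a
  rendering flag (`--omit-same-start-edges`) suppresses these sideways
  edges to foreground asynchronous cascade structure.

## Limitations

* Enumeration is polynomial but the dominance filter is quadratic in
  the number of candidates; matrices beyond ~10⁴ genes × dozens of
  columns call for pre-filtering (the ANOVA stage exists for this).
* Blocks never span a boundary gap: a gene reorganizing twice within
  two columns produces single-column structure that is dropped at the
  right edge and never segmented at the left edge (column 0 cannot be
  a boundary).
* The TBN is a screen for candidate cascade relations, not a causal
  discovery procedure: first-order partial correlation on short windows
  has broad sampling variability, and the admissibility rule encodes
  temporal order, not mechanism.
* Enrichment consumes whatever GMT the user supplies; no ontology
  propagation or annotation retrieval is performed, and the default
  universe (all genes surviving the prefilter) should be replaced when
  a better-matched background is available.
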