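# Methods

This note records the statistical model behind each index, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical/design decisions a maintainer would want to know.

## Data model and filtering

The observational unit is one prey item with its forager (individual), nest
cell (one sealed foraging bout), taxonomy (family, genus), ecological guild,
and two linear sizes (total body length and carapace width, mm).  Filtering
mirrors a nest-excavation protocol: cells with fewer than
`min_items_per_cell = 5` intact prey are discarded (too few items to
characterise a bout); at most `max_cells_per_individual` cells (default 3)
are retained per individual, chosen uniformly at random; prey unidentifiable
to genus are excluded from genus-level tabulations only; size-damaged
specimens are excluded from size analyses only.  Family is modelled as always
recoverable unless the specimen is flagged unidentifiable.  All random
selection flows from one named, seeded generator owned by the pipeline, so
"randomly selected" steps are reproducible; the selection is written to a
JSON provenance sidecar.  After selection, individuals (pooled over their
kept cells) are the unit of analysis.

## Diet overlap (PS_i, IS)

`PS_i = 1 − 0.5 Σ_j |p_ij − q_j|` with `q` the **equal-weight** mean of the
individual proportion vectors (default), not the pooled-count proportions.
Equal weighting makes each forager count once regardless of how many items
it stored, and it is the convention under which a pure specialist on a
private resource in a population of N foragers scores exactly `PS_i = 1/N`
(≈0.03–0.04 at N = 30, matching how extreme specialists are reported in
field studies of this design); pooled-count weighting is available via
`q_weighting="pooled"`.  The null test redraws each individual's diet as an
`n_i`-trial multinomial over the observed `q` and **re-estimates `q` inside
every replicate**, so the null distribution is of the same estimator as the
observed statistic.  p-values use `(r+1)/(R+1)` one-tailed toward small IS,
with ties counted as extreme (conservative); the floor at `R = 999`
replicates is 0.001.

## Niche width (WIC/BIC/TNW)

All variances use the n-denominator (maximum-likelihood) form and
individuals contribute with weight `n_i/n`, which makes `TNW = WIC + BIC` an
exact identity (law of total variance) rather than an approximation — the
identity is asserted to 1e-9 relative tolerance in the tests.  Sizes are
analysed on the raw mm scale by default; `log_transform=True` applies a log
before decomposition (the ratio is already invariant to affine rescaling,
so the flag matters only for genuinely multiplicative size structure).  The
null permutes the pooled values across individuals preserving every `n_i`
(exact, distribution-free).  Degenerate inputs: a population with zero total
variance is an error ("niche width undefined"); two singleton individuals
are accepted and give ratio 0 with p = 1 (every permutation is equivalent).

## Network metrics (C_ws, NODF)

Edge weights are pairwise proportional similarities — the same overlap
family as PS_i, keeping one overlap definition package-wide.  The node
clustering coefficient is the geometric-mean weighted-triangle form
`c_i = Σ_{j<k} (w_ij w_jk w_ik)^{1/3} / [(N−1)(N−2)/2]`, i.e. triangles
normalised by **all** triplet pairs rather than by each node's realised
neighbour pairs.  This choice is what makes the sign semantics come out
right: a uniform generalist network has clustering = density = 1 and
`C_ws = 0`; two disjoint specialist pairs give clustering 0, density 1/3,
`C_ws = −1`; and any partition into tight disjoint groups keeps clustering
below density (hence `C_ws < 0`), because a module of size g contributes
`~(g/N)²` of the possible triangles while density falls only as `g/N`.
Normalising by realised neighbour pairs instead would score tight modules at
clustering 1 and flip the sign.  The exact formula behind published C_ws
values lives in the cited network literature rather than in any data we can
rerun, so this operationalization is validated against the qualitative
anchors only.  C_ws significance is two-sided (departures in both directions
are interpretable) over the same multinomial diet resampling as the PS_i
test.

NODF scores every ordered row pair with strictly decreasing fill by the
percentage of the sparser row's presences shared by the fuller row (ties and
empty rows score 0), likewise for columns, and averages over all
`N(N−1)/2 + K(K−1)/2` pairs.  The implementation is validated exhaustively
against an independent literal translation on all 512 3×3 binary matrices
and cross-checked against vegan's `nestednodf` (sorted, unweighted) through
Rscript.  The null model draws independent cells with probability
`(rowfill_i/K + colfill_j/N)/2` from the observed binary matrix; replicates
with empty rows/columns are retained (redrawing until valid would bias the
null).  Because those probabilities are re-estimated from each dataset, the
default test is *conditionally* calibrated: its p-value is approximate
(typically conservative under margin-homogeneous data) rather than exactly
uniform.  For calibration studies the generating probability matrix can be
passed explicitly (`probabilities=`), which restores exact exchangeability
between the observed matrix and its null replicates; the type-I suite uses
that design and lands within the binomial 99% CI of nominal 0.05.

## Classical tests

One-way ANOVA (`F = MS_between/MS_within`, df `(k−1, n−k)`) and the paired
t-test (sample-SD denominator `n−1`, two-sided) with tail probabilities from
scipy's F and t distributions.  The two-group ANOVA equals the squared
pooled-variance t-test, asserted in the tests.  The post-hoc pairwise
comparison offered alongside the ANOVA (`pairwise_welch_bonferroni`) is a
deliberately plain stand-in — Welch t-tests with Bonferroni correction — for
the unnamed letter-grouping procedures field papers attach to such figures.

## Synthetic populations

The generator emulates a dense single-colony sampling frame: 30 individuals,
1–3 cells each, 5–25 items per cell, and a resource pool of 6 spider genera
(3 families, 3 hunting guilds) with availability
`q0 = (0.73, 0.09, 0.08, 0.05, 0.03, 0.02)` — one strongly dominant
orb-weaver, echoing field populations where a single golden orb-weaver
species makes up ~73% of prey and orb weavers >90%.  Diet structures:
`dirichlet` (`p_i ~ Dirichlet(αKq0)`; default `α = 0.5`, chosen once to give
wide PS_i spreads with coexisting specialists and generalists — note the
resulting population IS sits above values reported from field data with
richer resource pools, because overlap is floored by having only 6
categories), `nested` (individual i uses the top `r_i` resources of `q0`,
giving strict subset chains by construction), and `modular` (disjoint
resource blocks per group).  Per cell, the base diet is mixed with a fresh
redraw in proportion `drift`.  Sizes are `μ_k + δ_i + ε` with per-resource
means (3.5–9 mm body length, 1.1–2.2 mm carapace width, inside reported
field ranges), between-individual SD `σ_b` and within SD `σ_w` (defaults
1.5/1.5 mm body length, 0.4/0.4 mm carapace width), truncated at a 0.1 mm
floor; truncations are counted and logged (≈0.5% of draws at defaults).

What the generator does **not** emulate: real taxonomic richness (6
resources vs dozens of genera in the field), prey sex and age structure,
seasonal availability shifts, kleptoparasitism, spatial foraging, or
measurement error on sizes.  Passing tests therefore demonstrate that the
estimators recover known structure under a faithful but simplified sampling
frame — not that any particular field dataset would reproduce published
values.

## Pipeline designs

The single-cell design selects one random qualifying cell per individual and
reports, per classification level, the PS_i range, IS and its p (the shape
of a published specialization table), C_ws with p, NODF with its null mean
and p, and WIC/TNW per size measure.  The temporal design restricts to
individuals holding the full cell complement (default 3), compares PS_i from
one random cell against PS_i from all cells pooled with a paired t-test, and
reports the mean difference (single − pooled): ≈0 or positive under
temporally consistent diets, negative when diets drift between bouts
(because a single drifted bout looks more specialized than the pooled
record).  Cells are treated as unordered — their construction order is not
recoverable from a nest — so no sequence inference is attempted.  The subset
design restricts to individuals whose entire usable diet is one named
resource and tests size specialization inside that group (WIC/TNW plus
ANOVA among individuals), separating size- from taxon-specialization.
Reports at different classification levels are presented side by side
without cross-level significance comparison, since the number of resources
differs by level.

## Problem sizes and tolerances

Monte Carlo defaults are 999 replicates (p floor 0.001).  The validation
suite uses exhaustive enumeration where feasible (all 3×3 binary matrices
for NODF; all joint multinomial outcomes for diet matrices with ≤6 items;
all permutations for ≤8 sizes) and requires Monte Carlo agreement within 3
standard errors at 9 999 replicates.  Type-I calibration uses 200 datasets
of 199 replicates at the 30-individual sampling frame; parameter-recovery
checks use 20 replicate populations per condition, with the
variance-component recovery averaged over 10 populations of 20 individuals
× 200 items (a single 20-individual estimate of the between-individual
component has ~0.08 SD, so single-run ±0.05 agreement would be noise-bound).
Numerical choices: variances clipped at 0 against cancellation; Monte Carlo
tie comparisons use a 1e-12 absolute slack; all child seeds are drawn from
the pipeline's single generator and kept below 2³¹.

## Known limitations

- The C_ws operationalization reproduces the documented sign anchors but
  published numeric C_ws values cannot validate it without the underlying
  field data.
- The default NODF null is margin-conditional and approximate (see above);
  treat marginal p-values near 0.05 with care.
- Equal-weight vs pooled `q` changes PS_i for unbalanced samples; the
  equal-weight default is an inference from how extreme specialists are
  scored in the motivating study design, not a universal convention.
- The temporal design's single-cell diet is a subsample of the pooled diet,
  so the two PS_i estimates are positively correlated; the paired t-test is
  valid for the difference but its power depends on items per bout.
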