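# Methods

## The single-sequence Kappa Index of Coincidence

The classical index of coincidence compares two texts position by
position; the single-sequence adaptation compares a DNA window with
itself at every possible lag. For a window `A` of length `L` and
`N = L − 1`:

* for each lag `u = 1…N`, the shifted copy is `A[u+1…N]` — note the
  window's **final character never participates**, a quirk of the original
  formulation that is reproduced exactly;
* the lag's contribution is the percentage of matching positions,
  `100 · matches / (N − u)`;
* KIC is the mean contribution over lags, rounded to 2 decimals.

The maximal lag `u = N` compares zero positions. As literally written the
algorithm divides by zero there; two repairs are implemented:

* `count_as_zero` (default): the empty lag contributes 0 and the mean
  divides by `N`. This is the minimal repair. Consequences: a homopolymer
  scores `100·(N−1)/N` (96.55 at window 30, 0.00 at window 2), never 100.
* `exclude_from_mean`: the empty lag is dropped (divide by `N − 1`),
  restoring 100 for perfect repeats; undefined at window length 2 (an
  error).

`N` (the ambiguity code) never matches any base, including another `N`,
and is excluded from every C+G count: ambiguity is absence of information,
not a fifth symbol. Rounding is IEEE-754 round-half-to-even on the double
value (`half_even`), matching the semantics of the usual
language-runtime `Round`; `half_away` is selectable. The two modes can
differ by at most one unit in the last decimal, and nothing downstream
depends on the choice.

The alphabet size `Q = 4` appears in the statistic's random baseline —
each lag matches at rate `1/Q` for i.i.d. uniform DNA, so a random 30-nt
window averages `25·28/29 ≈ 24.14` — but the per-lag percentages
themselves do not use it; `KicConfig.alphabet_size` is carried for
documentation and for the baseline property test.

### What window KIC actually measures

Because each lag is normalized to a percentage before averaging, window
KIC is dominated by *composition concentration* plus tandem periodicity,
not by arbitrary "orderliness". Tandem-periodic windows (`AAG`×10,
`AAAAAG`×5) score strictly above their composition baseline and shuffling
them lowers expected KIC; but a window of two abutting blocks
(`A¹⁵G¹⁵`) scores *below* its shuffle average, because long lags
anti-match and every lag carries equal weight. Homopolymer tracts elevate
promoter-level KIC through the windows that lie fully inside the tract
(which are pure-composition windows at the 96.55 ceiling), not through
window-internal order. The shuffle-contrast property test therefore uses
a tandem-repeat window, where the property genuinely holds.

## Sliding scan

Windows start at 0 and advance by `step` (defaults 30 / 1, giving
`floor((L−30)/1)+1 = 971` windows on a 1000-nt promoter); only full
windows are scored. The scan computes, per lag, the match-indicator vector
over the whole sequence once and takes sliding partial sums (O(L·W)
total), which is exactly equivalent to running the per-window definition
window by window; the equivalence is asserted against a deliberately naive
double-loop oracle in the tests. Window positions are 0-based; the
TSS-relative span (−700…+299 by default) is metadata only.

`CG_tot` is the whole-promoter (C+G)% over unambiguous bases. Per window,
`CG_abs` is the plain (C+G)% and `CG_rel = CG_abs · CG_tot / 100` — the
promoter-relative mode, which is the default for pattern building; the
absolute mode is available (`cg_relative=false`). An all-`N` window or
promoter is an error rather than a silent zero.

## Patterns, centroids, regions

A promoter pattern has one point per window, `x` = the chosen CG series,
`y` = KIC. The "center of weight" is the **unweighted arithmetic mean of
all window points**. A density-weighted or cluster-weighted centroid
would be alternatives; the unweighted mean is the minimal reading (each
window contributes exactly one point) and is what the tests and the
chromosome aggregation use. Y-axis clusters are segmented by histogramming
y into fixed bins (default width 1.0, anchored at 0) and merging adjacent
occupied bins; runs holding ≥ `min_points` (default 5) points are
reported. Both parameters are conventions, not derived quantities.

Region classification assigns pattern points (usually centroids) to six
qualitative repeat classes laid out on the plane — A: low-x/high-y (long
poly(dA:dT) tracts), B: mid-x/high-y, C: high-x/high-y (long poly(dC:dG)
tracts), D: high-x/mid-y, E: mid-x/mid-y (evenly interspersed bases,
A,T,C,G ≈ 25%), F: low-x/mid-y — with first-match-wins rectangles and an
"unclassified" catch-all. **The numeric boundaries are configuration**,
shipped as an editable JSON rule file. The defaults (x: low < 15,
mid 15–55, high ≥ 55; y: mid 15–45, high ≥ 60) were fixed from the
analytic expectations of the default promoter-relative scan: a uniform
promoter centers near x = 50·50/100 = 25 and y ≈ 24.1; a promoter
dominated by poly(dA) tracts near x ≈ 0–5 with y well above 60; a
poly(dG)-dominated one near x ≈ 80–90. In absolute-CG mode the x scale
doubles for typical promoters and the rule file should be edited
accordingly.

## Chromosome aggregation

Summaries report per-chromosome `n`, mean and **population** (divide-by-n)
SD of centroid KIC and CG — the scanned promoters are treated as the
analyzed population, so single-promoter chromosomes have SD 0 and users
comparing against sample SDs should expect a `√(n/(n−1))` factor.
Orderings are stable sorts by the chosen mean, ties broken by karyotype
token order 1…22, X, Y. The density map is a 2D histogram over the
centroid bounding box expanded 1% per side (0.5 absolute when degenerate);
optional Gaussian smoothing (sigma in bin units) is renormalized to
conserve total mass to 1e−6. Correlation against external count tables
(e.g. genetic-disease counts per chromosome, user-supplied) is Spearman
rank correlation with average ranks over the chromosome intersection,
requiring ≥ 3 shared chromosomes; it is the minimal quantitative stand-in
for eyeballed "direct association" claims. The arc table links
size-adjacent chromosomes at their KIC ranks with radius = half the rank
distance; the quantitative content is the ordering, rendering is left to
the caller. Axis conventions differ across published figure styles
(KIC-vs-CG or CG-vs-KIC); this package fixes x = CG, y = KIC everywhere
and labels outputs explicitly.

## Synthetic promoter generator

The generator emulates the promoter classes the scan discriminates, not
real promoter biology: an i.i.d. background (default 1000 nt, uniform
base composition) with planted tracts — a motif repeated `copies` times,
inserted `count` times at non-overlapping positions drawn uniformly from
the currently feasible starts, with bounded whole-placement restarts for
dense packings. Two mutation operators model the two evolutionary regimes:
`ssm_expand` duplicates a random substring in place (slipped-strand
mispairing; expansion only — contractions are out of scope), growing the
sequence by `events · motif_length`; `mutate_point` substitutes each
position independently at a given rate, uniformly among the three other
bases (`N` positions are left untouched). Everything is seeded; cohorts
derive one deterministic sub-stream per record from `(seed, index)`, so
outputs are byte-identical across runs.

What the generator does **not** emulate: real promoter element grammar
(TATA/GC boxes), CpG islands, isochore structure, positional biases
relative to the TSS, or indels other than tandem duplication. Passing
tests therefore demonstrate that the pipeline detects and ranks planted
repeat structure under controlled composition — not that any particular
biological chromosome ordering is correct.

The planted-gradient cohort (`planted_repeat_cohort`) assigns chromosome
k (karyotype order) k−1 poly(dA) tracts of 20 nt per promoter, 50
promoters per chromosome by default — mirroring the 24 × 50 = 1200 cohort
shape used in chromosome-specificity analyses — so planted density is the
only systematic between-chromosome difference and Spearman rank recovery
against it has an exact ground truth.

## Problem sizes and numerics

Default test/acceptance sizes: 1,000 oracle windows (lengths 2–60, 4% N),
10,000 random windows for the 24.14 limit (tolerance ±0.3, ≈ 6 SEs),
24 × 50 promoters for rank recovery, 30 seeds per directional mutation
test (one-sided t-tests at p < 0.01; composition neutrality asserted as
|mean Δcg_abs| < 1 percentage point, several SEs wide), 50 seeds per
region class. The whole suite runs in well under a minute on one core;
the sliding scan of 1200 × 1000-nt promoters takes ~1 s via the
cumulative-sum formulation.

## Known limitations

* Window KIC saturates at `100·(N−1)/N` under the default policy; scores
  are not comparable across different window sizes without rescaling.
* The region rule defaults assume the promoter-relative CG mode and
  roughly balanced backgrounds; skewed genomes need edited rules.
* Spearman correlation over 24 chromosomes has low power; the permutation
  calibration test documents the null behaviour but no multiple-testing
  machinery is provided.
* The generator plants tracts by overwriting background, so realized
  background composition shifts slightly toward the tract base; planted
  density remains the only *between-chromosome* difference.
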