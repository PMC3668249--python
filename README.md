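# kicscan

Characterization of gene-promoter sequences by a single-sequence **Kappa
Index of Coincidence (KIC)** and sliding-window **(C+G)%**, for regulatory
genomics work on simple-sequence repeats (SSRs) and short tandem repeats
(STRs) in promoter regions.

Promoters (typically the TSS-relative span −700…+299, i.e. 1000 nt) are
scanned with a short sliding window (default 30 nt, step 1). Each window
yields two values, which together form a 2D "promoter pattern"; pattern
centroids aggregate into per-chromosome summaries, orderings, density maps
and correlations against external per-chromosome count tables. A seeded
synthetic-promoter generator (planted tracts, slippage expansions, point
mutations) makes the whole pipeline testable without any sequence
download.

## The statistic

For a window `A` of length `L`, let `N = L − 1`. For each lag
`u = 1…N` compare the window with itself shifted by `u`, over its first
`N` characters only:

```
contribution(u) = 100 · #{ i : A[i] = A[i+u], i = 1…N−u } / (N − u)
KIC(A) = round( Σ_u contribution(u) / N , 2 )
```

The maximal lag has no pairs; by default it contributes 0 while staying in
the denominator (`count_as_zero`), so a homopolymer scores exactly
`100·(N−1)/N` — 96.55 for a 30-nt window — and an i.i.d. uniform DNA
window averages `25·(N−1)/N ≈ 24.14` (per-lag match rate `1/Q` with
`Q = 4`). The alternative `exclude_from_mean` policy divides by `N − 1`
and restores 100 for perfect repeats. An ambiguous `N` base never matches
anything.

(C+G)% comes as the absolute window percentage `CG_abs` and the
promoter-relative value `CG_rel = CG_tot/(#A+#C+#G+#T)_window · (#C+#G)_window`,
i.e. `CG_abs · CG_tot / 100`, where `CG_tot` is the whole-promoter (C+G)%.
Patterns plot `x = CG_rel` (default) against `y = KIC` per window.

## Worked example

`examples/pattern_and_regions.py` builds three synthetic 1000-nt
promoters, scans them and classifies their pattern centroids:

```
promoter     centroid x centroid y  region
polyA-built        0.91      78.18       A
polyG-built       81.66      78.69       C
uniform           23.15      24.07       E
```

A promoter built of long poly(dA) tracts centers in the low-CG/high-KIC
corner (region A: poly(dA:dT)-tract-like), a poly(dG)-built one in the
high-CG/high-KIC corner (region C), and a uniform-composition promoter at
the random baseline (region E: evenly interspersed nucleotides) — x is the
promoter-relative (C+G)% and y the mean window KIC, so "uniform" lands
near (25, 24).

Other examples: `scan_single_promoter.py` (window profile anatomy),
`chromosome_ordering.py` (per-chromosome aggregation and rank recovery on
a planted repeat-density gradient), `mutation_dynamics.py` (slippage
raises KIC, point mutation lowers it), `density_map.py` (centroid density
surface).

## Command line

The same workflow is scriptable from a shell:

```sh
kicscan synth --n-per-chromosome 50 --seed 1 --out-fasta cohort.fasta
kicscan scan cohort.fasta --out-profile profiles.tsv --out-centroid centroids.tsv
kicscan cohort centroids.tsv --out-summary summary.tsv --out-order-kic order.tsv
kicscan density centroids.tsv --out density.tsv
kicscan region-annotate centroids.tsv --out regions.tsv
```

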