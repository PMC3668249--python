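"""Chromosome-level aggregation on a planted repeat-density gradient.

Generates a 24-chromosome x 20-promoter synthetic cohort in which
chromosome k carries k-1 planted poly(dA) tracts per promoter (the only
systematic difference), scans everything, summarizes centroids per
chromosome, orders chromosomes by mean KIC and correlates the means
against the planted densities.
"""

from kicscan import (
    KicConfig,
    centroid,
    correlate_with_counts,
    make_pattern,
    order_chromosomes,
    planted_repeat_cohort,
    sliding_scan,
    summarize_by_chromosome,
)

config = KicConfig()
cohort, densities = planted_repeat_cohort(n_per_chromosome=20, seed=7)
centroids = [
    centroid(make_pattern(sliding_scan(rec, config), config)) for rec in cohort
]
summaries = summarize_by_chromosome(centroids)

order = order_chromosomes(summaries, key="kic")
rho, n = correlate_with_counts(summaries, densities, key="kic")

print("chromosomes by mean promoter KIC (densest planted repeats first):")
print("  " + " ".join(order))
print(f"Spearman(planted tract density, mean KIC) = {rho:.3f} over {n} chromosomes")
for s in summaries[:3]:
    print(
        f"  chr{s.chromosome}: n={s.n_promoters} mean KIC {s.mean_kic:.2f} "
        f"(sd {s.sd_kic:.2f}), mean CG {s.mean_cg:.2f}"
    )

# A perfect rho = 1.0 means the per-chromosome mean of pattern-centroid KIC
# recovers the planted repeat-density ranking exactly — the mechanism by
# which repeat-rich chromosomes separate from repeat-poor ones.
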