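"""Chromosome-level aggregation of pattern centroids.

Per-chromosome means and standard deviations of centroid KIC and (C+G)%,
chromosome orderings by either statistic, the 2D centroid density map
(low density -> blue, high -> red when rendered), arc tables linking
size-adjacent chromosomes in KIC order, and Spearman correlation of
chromosome-level means against external per-chromosome count tables
(e.g. genetic-disease counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from kicscan.pattern import PatternCentroid
from kicscan.sequence_io import CHROMOSOMES

__all__ = [
    "ChromosomeSummary",
    "DensityMap",
    "summarize_by_chromosome",
    "order_chromosomes",
    "density_map",
    "correlate_with_counts",
    "chromosome_arcs",
    "write_summary_tsv",
    "write_ordering_tsv",
]

# karyotype order used for tie-breaking and stable output: 1..22, X, Y, then others
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_RANK.get(chrom, len(_CHROM_RANK)), chrom)


@dataclass
class ChromosomeSummary:
    """Aggregate of one chromosome's promoter-pattern centroids.

    Standard deviations are population SDs (divide by n): the scanned
    promoters are treated as the analyzed population, so a chromosome with
    a single promoter has sd 0.
    """

    chromosome: str
    n_promoters: int
    mean_kic: float
    sd_kic: float
    mean_cg: float
    sd_cg: float


@dataclass
class DensityMap:
    """2D histogram of centroids; rows index y bins, columns x bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # int, shape (n_bins_y, n_bins_x)
    smoothing_sigma: float = 0.0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def smoothed(self) -> np.ndarray:
        """Gaussian-smoothed surface (sigma in bin units), renormalized so
        total mass equals the raw count total."""
        if self.smoothing_sigma <= 0:
            return self.counts.astype(float)
        surf = ndimage.gaussian_filter(
            self.counts.astype(float), sigma=self.smoothing_sigma, mode="constant"
        )
        s = surf.sum()
        if s > 0:
            surf *= self.counts.sum() / s
        return surf


def summarize_by_chromosome(
    centroids: Sequence[PatternCentroid],
) -> list[ChromosomeSummary]:
    """One summary per distinct chromosome, in karyotype order.

    Means/SDs are over that chromosome's centroid x (CG) and y (KIC)
    coordinates; SDs are population SDs (ddof=0).
    """
    if not centroids:
        raise ValueError("no centroids to summarize")
    df = pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in centroids],
            "x": [c.x for c in centroids],
            "y": [c.y for c in centroids],
        }
    )
    out: list[ChromosomeSummary] = []
    for chrom, grp in df.groupby("chromosome", sort=False):
        out.append(
            ChromosomeSummary(
                chromosome=str(chrom),
                n_promoters=len(grp),
                mean_kic=float(grp["y"].mean()),
                sd_kic=float(grp["y"].std(ddof=0)),
                mean_cg=float(grp["x"].mean()),
                sd_cg=float(grp["x"].std(ddof=0)),
            )
        )
    out.sort(key=lambda s: _chrom_sort_key(s.chromosome))
    return out


def order_chromosomes(
    summaries: Sequence[ChromosomeSummary],
    key: Literal["kic", "cg"] = "kic",
    direction: Literal["desc", "asc"] = "desc",
) -> list[str]:
    """Chromosomes sorted by mean KIC or mean CG.

    The sort is stable and deterministic; ties are broken by karyotype
    token order (1..22, X, Y).
    """
    if not summaries:
        raise ValueError("no summaries to order")
    attr = "mean_kic" if key == "kic" else "mean_cg"
    sign = -1.0 if direction == "desc" else 1.0
    ordered = sorted(
        summaries,
        key=lambda s: (sign * getattr(s, attr), _chrom_sort_key(s.chromosome)),
    )
    return [s.chromosome for s in ordered]


def density_map(
    centroids: Sequence[PatternCentroid],
    n_bins_x: int = 50,
    n_bins_y: int = 50,
    smoothing_sigma: float = 0.0,
) -> DensityMap:
    """2D histogram over the centroid cloud's bounding box.

    The box is expanded by 1% of its span on each side (a fixed 0.5 when
    the span is degenerate) so that boundary centroids bin cleanly.  The
    raw counts always sum to the number of centroids; smoothing is applied
    lazily via :meth:`DensityMap.smoothed` and conserves total mass.
    """
    if not centroids:
        raise ValueError("no centroids to bin")
    if n_bins_x < 1 or n_bins_y < 1:
        raise ValueError("bin counts must be >= 1")
    x = np.array([c.x for c in centroids], float)
    y = np.array([c.y for c in centroids], float)

    def _expand(lo: float, hi: float) -> tuple[float, float]:
        span = hi - lo
        pad = 0.01 * span if span > 0 else 0.5
        return lo - pad, hi + pad

    xr = _expand(float(x.min()), float(x.max()))
    yr = _expand(float(y.min()), float(y.max()))
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=[n_bins_x, n_bins_y], range=[xr, yr]
    )
    return DensityMap(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts.T.astype(np.int64),  # rows = y bins
        smoothing_sigma=smoothing_sigma,
    )


def correlate_with_counts(
    summaries: Sequence[ChromosomeSummary],
    counts: Mapping[str, int],
    key: Literal["kic", "cg"] = "kic",
) -> tuple[float, int]:
    """Spearman rank correlation between per-chromosome means and a count table.

    Computed over the intersection of chromosomes present in both inputs;
    ties receive average ranks (scipy's default).  Returns (rho, n).

    Raises
    ------
    ValueError
        if fewer than 3 chromosomes are shared.
    """
    attr = "mean_kic" if key == "kic" else "mean_cg"
    shared = [s for s in summaries if s.chromosome in counts]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} chromosomes shared between summaries and counts; "
            "need >= 3"
        )
    vals = [getattr(s, attr) for s in shared]
    cnts = [counts[s.chromosome] for s in shared]
    rho = stats.spearmanr(vals, cnts).statistic
    return float(rho), len(shared)


def chromosome_arcs(kic_order: Sequence[str]) -> pd.DataFrame:
    """Arc table joining size-adjacent chromosomes along the KIC ordering.

    Chromosomes sit on an axis at their rank in ``kic_order``; each pair
    adjacent in karyotype (size) order — (1,2), (2,3), ..., (X,Y) — is
    joined by a semicircle whose radius is half the rank distance.  The
    quantitative content of the resulting arc diagram is the ordering
    itself; rendering is left to the caller.
    """
    rank = {c: i for i, c in enumerate(kic_order)}
    rows = []
    present = [c for c in CHROMOSOMES if c in rank]
    for a, b in zip(present, present[1:]):
        ra, rb = rank[a], rank[b]
        rows.append(
            {
                "chrom_a": a,
                "chrom_b": b,
                "rank_a": ra,
                "rank_b": rb,
                "radius": abs(ra - rb) / 2.0,
            }
        )
    return pd.DataFrame(rows, columns=["chrom_a", "chrom_b", "rank_a", "rank_b", "radius"])


def write_summary_tsv(
    summaries: Sequence[ChromosomeSummary], path: str | Path
) -> None:
    """TSV: ``chromosome  n_promoters  mean_kic  sd_kic  mean_cg  sd_cg``."""
    with open(path, "w", newline="\n") as fh:
        fh.write("chromosome\tn_promoters\tmean_kic\tsd_kic\tmean_cg\tsd_cg\n")
        for s in summaries:
            fh.write(
                f"{s.chromosome}\t{s.n_promoters}\t{s.mean_kic:.6f}\t"
                f"{s.sd_kic:.6f}\t{s.mean_cg:.6f}\t{s.sd_cg:.6f}\n"
            )


def write_ordering_tsv(order: Sequence[str], path: str | Path, key: str) -> None:
    """TSV of an ordering: ``rank  chromosome  key``."""
    with open(path, "w", newline="\n") as fh:
        fh.write("rank\tchromosome\tkey\n")
        for i, chrom in enumerate(order, start=1):
            fh.write(f"{i}\t{chrom}\t{key}\n")
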