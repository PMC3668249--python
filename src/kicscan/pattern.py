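"""Image-based promoter patterns: the 2D point cloud of per-window
((C+G)%, KIC) pairs, its center of weight, y-axis cluster segmentation,
and rule-based classification of pattern regions.

A pattern plots one point per sliding window: x = the window's (C+G)%
(promoter-relative by default), y = the window's Kappa IC.  Repeat-rich
windows push points up (high KIC); G/C-rich windows push points right.
The pattern's unweighted centroid ("center of weight") summarizes the
promoter in a single point.

Region classification mirrors the qualitative layout of simple-sequence-
repeat classes on the pattern plane:

    A  low x, high y   — long poly(dA)/poly(dT) tracts
    B  mid x, high y   — non-ordered short homopolymer tracts of mixed base
    C  high x, high y  — long poly(dC)/poly(dG) tracts
    D  high x, mid y   — short poly(dC)/poly(dG) tracts
    E  mid x, mid y    — evenly interspersed nucleotides (A,T,C,G ~ 25%)
    F  low x, mid y    — short poly(dA)/poly(dT) tracts

The numeric boundaries are configuration, not published values; the
defaults below are derived from the analytic expectations of the scan in
its default promoter-relative CG mode (a uniform i.i.d. promoter centers
near x ~ 25, y ~ 24; homopolymer-tract windows near y ~ 96.6 with x near 0
or near the promoter (C+G)%), and ship as an editable JSON rule file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from kicscan.kic_core import KicConfig, WindowProfile, DEFAULT_CONFIG

__all__ = [
    "PromoterPattern",
    "PatternCentroid",
    "RegionRule",
    "RegionRuleSet",
    "make_pattern",
    "centroid",
    "segment_y_clusters",
    "classify_region",
    "default_region_rules",
]


@dataclass
class PromoterPattern:
    """The 2D point cloud of one promoter: points[i] = (x=(C+G)%, y=KIC)."""

    seq_id: str
    chromosome: str
    points: np.ndarray  # shape (n, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PatternCentroid:
    """Center of weight of a promoter pattern, with provenance."""

    seq_id: str
    chromosome: str
    x: float
    y: float
    n_points: int


@dataclass(frozen=True)
class RegionRule:
    """One half-open rectangle [x_lo, x_hi) x [y_lo, y_hi) with a label."""

    label: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.x_range[0] < self.x_range[1]):
            raise ValueError(f"rule {self.label!r}: x_range not lo < hi")
        if not (self.y_range[0] < self.y_range[1]):
            raise ValueError(f"rule {self.label!r}: y_range not lo < hi")

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_range[0] <= x < self.x_range[1]
            and self.y_range[0] <= y < self.y_range[1]
        )


@dataclass(frozen=True)
class RegionRuleSet:
    """Ordered rules; first match wins; unmatched points are "unclassified"."""

    rules: tuple[RegionRule, ...]

    def to_json(self, path: str | Path | None = None) -> str:
        data = [
            {"label": r.label, "x_range": list(r.x_range), "y_range": list(r.y_range)}
            for r in self.rules
        ]
        s = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "RegionRuleSet":
        text = (
            Path(source).read_text()
            if isinstance(source, Path)
            or (isinstance(source, str) and Path(source).is_file())
            else str(source)
        )
        data = json.loads(text)
        return cls(
            rules=tuple(
                RegionRule(
                    label=str(d["label"]),
                    x_range=(float(d["x_range"][0]), float(d["x_range"][1])),
                    y_range=(float(d["y_range"][0]), float(d["y_range"][1])),
                )
                for d in data
            )
        )


# x bands (promoter-relative CG): low < 15, mid 15-55, high >= 55.
# y bands (KIC percent): mid 15-45, high >= 60.
_X_LOW = (0.0, 15.0)
_X_MID = (15.0, 55.0)
_X_HIGH = (55.0, 101.0)
_Y_MID = (15.0, 45.0)
_Y_HIGH = (60.0, 101.0)


def default_region_rules() -> RegionRuleSet:
    """The default A-F rule set (boundaries are configurable, not canonical)."""
    return RegionRuleSet(
        rules=(
            RegionRule("A", _X_LOW, _Y_HIGH),
            RegionRule("B", _X_MID, _Y_HIGH),
            RegionRule("C", _X_HIGH, _Y_HIGH),
            RegionRule("D", _X_HIGH, _Y_MID),
            RegionRule("E", _X_MID, _Y_MID),
            RegionRule("F", _X_LOW, _Y_MID),
        )
    )


def make_pattern(
    profile: WindowProfile, config: KicConfig = DEFAULT_CONFIG
) -> PromoterPattern:
    """Build the pattern from a window profile: one (x, y) point per window.

    x is the promoter-relative CG series when ``config.cg_relative`` is
    True, else the absolute series; y is the window KIC.  Window order is
    preserved.
    """
    if len(profile) == 0:
        raise ValueError(f"profile {profile.seq_id!r} is empty")
    x = profile.cg_rel if config.cg_relative else profile.cg_abs
    points = np.column_stack([np.asarray(x, float), np.asarray(profile.kic, float)])
    return PromoterPattern(
        seq_id=profile.seq_id, chromosome=profile.chromosome, points=points
    )


def centroid(pattern: PromoterPattern) -> PatternCentroid:
    """Unweighted center of weight: the arithmetic mean of all pattern points."""
    if len(pattern) == 0:
        raise ValueError(f"pattern {pattern.seq_id!r} is empty")
    mx, my = pattern.points.mean(axis=0)
    return PatternCentroid(
        seq_id=pattern.seq_id,
        chromosome=pattern.chromosome,
        x=float(mx),
        y=float(my),
        n_points=len(pattern),
    )


def segment_y_clusters(
    pattern: PromoterPattern, bin_width: float = 1.0, min_points: int = 5
) -> list[tuple[float, float, int]]:
    """Segment the pattern's y-axis into clusters of windows.

    The y values are histogrammed into bins of ``bin_width`` anchored at 0;
    maximal runs of adjacent occupied bins holding at least ``min_points``
    points are reported as ``(y_lo, y_hi, n_points)``, sorted by y_lo.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    y = pattern.points[:, 1]
    idx = np.floor(y / bin_width).astype(np.int64)
    occupied = np.bincount(idx - idx.min())
    offset = int(idx.min())

    clusters: list[tuple[float, float, int]] = []
    run_start: int | None = None
    run_count = 0
    for i, n in enumerate(list(occupied) + [0]):  # sentinel flushes last run
        if n > 0:
            if run_start is None:
                run_start = i
            run_count += int(n)
        elif run_start is not None:
            if run_count >= min_points:
                clusters.append(
                    (
                        (run_start + offset) * bin_width,
                        (i + offset) * bin_width,
                        run_count,
                    )
                )
            run_start, run_count = None, 0
    return clusters


def classify_region(
    point: tuple[float, float] | PatternCentroid,
    rules: RegionRuleSet | None = None,
) -> str:
    """Label a pattern point (or centroid) by the first matching region rule.

    Returns "unclassified" when no rule contains the point.
    """
    if rules is None:
        rules = default_region_rules()
    if isinstance(point, PatternCentroid):
        x, y = point.x, point.y
    else:
        x, y = float(point[0]), float(point[1])
    for rule in rules.rules:
        if rule.contains(x, y):
            return rule.label
    return "unclassified"
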