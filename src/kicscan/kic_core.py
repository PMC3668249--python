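"""The two scalar measures — single-sequence Kappa Index of Coincidence and
promoter-normalized window (C+G)% — and the sliding-window scan.

Kappa Index of Coincidence (KIC) of a window A of length L, as computed by
the original promoter-analysis algorithm:

    N = L - 1
    for each lag u = 1..N:
        B = A[u+1 .. N]            (1-based; the window's LAST character
                                    never participates)
        contribution(u) = 100 * #{i : A[i] = B[i]} / len(B)
    KIC = Round( sum(contributions) / N , 2 )

The lag u = N has an empty B (len(B) = 0); as literally printed the
algorithm divides by zero there.  Two repairs are offered via
``KicConfig.empty_lag_policy``:

* ``count_as_zero`` (default): the empty lag contributes 0 and the mean
  still divides by N — the minimal repair of the printed algorithm.  A
  homopolymer then scores exactly ``100*(N-1)/N`` (96.55 for a 30-nt
  window), not 100.
* ``exclude_from_mean``: the empty lag is dropped and the mean divides by
  N-1, restoring 100 for perfect repeats.

An ambiguous base N never counts as a match (not even against another N)
and is excluded from all C+G counts.

(C+G)% comes in two flavours: the absolute window percentage CG_abs, and
the promoter-relative value CG_rel = CG_tot / n_window_bases * (#C + #G),
i.e. the window percentage rescaled by the whole-promoter (C+G)% — so a
window's CG_rel equals CG_abs * CG_tot / 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Literal

import numpy as np

from kicscan.sequence_io import PromoterRecord

__all__ = [
    "KicConfig",
    "WindowProfile",
    "kappa_ic",
    "cg_total",
    "cg_window",
    "sliding_scan",
]

# base encoding: A,C,G,T -> 0..3; N -> 4 (never matches, excluded from CG)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4
_AMBIG = 4
_CG_CODES = (1, 2)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255))
        raise ValueError(f"illegal character {seq[pos]!r} at position {pos}")
    return codes


@dataclass(frozen=True)
class KicConfig:
    """Scan configuration.

    Parameters
    ----------
    window_size : int
        Sliding-window length in nt (default 30).
    step : int
        Window step in nt (default 1).
    alphabet_size : int
        Q, the alphabet size (4 for DNA).  Documented for the statistic's
        random baseline (expected per-lag match rate 1/Q); the lag
        percentages themselves do not use it.
    empty_lag_policy : {"count_as_zero", "exclude_from_mean"}
        Treatment of the degenerate maximal lag (see module docstring).
    rounding : {"half_even", "half_away"}
        Rounding mode for the final KIC percentage.  ``half_even`` is
        IEEE-754 round-half-to-even on the double value, matching the
        original implementation's runtime; ``half_away`` rounds ties away
        from zero.
    decimals : int
        Decimal places for KIC rounding (default 2).
    cg_relative : bool
        If True (default), pattern x-coordinates use the promoter-relative
        CG_rel series; if False, the absolute window CG_abs.
    """

    window_size: int = 30
    step: int = 1
    alphabet_size: int = 4
    empty_lag_policy: Literal["count_as_zero", "exclude_from_mean"] = "count_as_zero"
    rounding: Literal["half_even", "half_away"] = "half_even"
    decimals: int = 2
    cg_relative: bool = True

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        if self.empty_lag_policy not in ("count_as_zero", "exclude_from_mean"):
            raise ValueError(f"unknown empty_lag_policy {self.empty_lag_policy!r}")
        if self.rounding not in ("half_even", "half_away"):
            raise ValueError(f"unknown rounding {self.rounding!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "KicConfig":
        """Load from a JSON string or file path; unknown keys are rejected."""
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file())
            else str(source)
        )
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = KicConfig()


@dataclass
class WindowProfile:
    """Aligned per-window vectors for one promoter.

    All percentage vectors share one length (the window count);
    ``cg_rel[i] == cg_abs[i] * cg_total / 100`` for every window.
    """

    seq_id: str
    chromosome: str
    window_starts: np.ndarray
    kic: np.ndarray
    cg_rel: np.ndarray
    cg_abs: np.ndarray
    cg_total: float
    config: KicConfig = field(default_factory=KicConfig)

    def __len__(self) -> int:
        return len(self.window_starts)


def _round(values: np.ndarray | float, config: KicConfig) -> np.ndarray | float:
    if config.rounding == "half_even":
        return np.round(values, config.decimals)
    scale = 10.0**config.decimals
    return np.floor(np.abs(values) * scale + 0.5) / scale * np.sign(values)


def kappa_ic(window: str, config: KicConfig = DEFAULT_CONFIG) -> float:
    """Kappa Index of Coincidence of a single window, in percent.

    The window is compared against itself at every lag u = 1..N where
    N = len(window) - 1; see the module docstring for the exact recipe.
    Result lies in [0, 100].

    Raises
    ------
    ValueError
        if the window is shorter than 2 (no lags exist), or under
        ``exclude_from_mean`` if it has length exactly 2 (the only lag is
        the empty one).
    """
    codes = _encode(window)
    L = len(codes)
    if L < 2:
        raise ValueError(f"window length {L} < 2: Kappa IC undefined")
    N = L - 1
    s = codes[:N]  # final character excluded, as in the printed algorithm
    total = 0.0
    for u in range(1, N):
        a = s[: N - u]
        m = (a == s[u:]) & (a != _AMBIG)
        total += 100.0 * int(m.sum()) / (N - u)
    if config.empty_lag_policy == "count_as_zero":
        denom = N
    else:
        denom = N - 1
        if denom == 0:
            raise ValueError(
                "length-2 window has only the empty lag; "
                "exclude_from_mean leaves nothing to average"
            )
    return float(_round(total / denom, config))


def cg_total(sequence: str) -> float:
    """(C+G)% of a whole sequence: 100*(#C+#G)/(#A+#C+#G+#T).

    N bases are excluded from numerator and denominator.  Raises
    ``ValueError`` if no unambiguous base is present.
    """
    codes = _encode(sequence)
    unamb = int((codes != _AMBIG).sum())
    if unamb == 0:
        raise ValueError("sequence has no unambiguous bases; (C+G)% undefined")
    cg = int(np.isin(codes, _CG_CODES).sum())
    return 100.0 * cg / unamb


def cg_window(
    window: str, cg_total_value: float, config: KicConfig = DEFAULT_CONFIG
) -> float:
    """Window (C+G)%, promoter-relative by default.

    With ``config.cg_relative`` True the result is
    ``cg_total_value / n_unambiguous * (#C + #G)`` — the window percentage
    rescaled by the whole-promoter (C+G)%.  With it False the scale factor
    is 100 (plain window percentage).
    """
    codes = _encode(window)
    unamb = int((codes != _AMBIG).sum())
    if unamb == 0:
        raise ValueError("window has no unambiguous bases; (C+G)% undefined")
    cg = int(np.isin(codes, _CG_CODES).sum())
    scale = cg_total_value if config.cg_relative else 100.0
    return scale / unamb * cg


def _window_count(L: int, window: int, step: int) -> int:
    return (L - window) // step + 1


def sliding_scan(
    record: PromoterRecord, config: KicConfig = DEFAULT_CONFIG
) -> WindowProfile:
    """Scan a promoter with the sliding window, computing KIC and (C+G)%.

    Windows start at 0 and advance by ``config.step``; only full windows
    are scored, so the window count is ``floor((L - W)/step) + 1``.
    ``cg_total`` is computed once from the whole sequence.

    The per-window KIC is computed by sliding partial sums of the per-lag
    match indicators (O(L*W) overall), which is exactly equivalent to
    running :func:`kappa_ic` on each window.
    """
    seq = record.sequence
    L = len(seq)
    W = config.window_size
    if L < W:
        raise ValueError(
            f"record {record.id!r}: length {L} shorter than window {W}"
        )
    codes = _encode(seq)
    nwin = _window_count(L, W, config.step)
    starts = np.arange(nwin, dtype=np.int64) * config.step

    N = W - 1
    if config.empty_lag_policy == "count_as_zero":
        denom = N
    else:
        denom = N - 1
        if denom == 0:
            raise ValueError(
                "window_size 2 under exclude_from_mean has no non-empty lag"
            )

    kic_sum = np.zeros(nwin)
    for u in range(1, N):
        # in-window matches at lag u use only the window's first N bases:
        # positions t..t+N-u-1 against t+u..t+N-1
        a = codes[: L - u]
        b = codes[u:]
        m = ((a == b) & (a != _AMBIG)).astype(np.float64)
        csum = np.concatenate(([0.0], np.cumsum(m)))
        counts = csum[starts + (N - u)] - csum[starts]
        kic_sum += 100.0 * counts / (N - u)
    kic = np.asarray(_round(kic_sum / denom, config), dtype=np.float64)

    cg_tot = cg_total(seq)
    is_cg = np.isin(codes, _CG_CODES).astype(np.float64)
    is_unamb = (codes != _AMBIG).astype(np.float64)
    cg_csum = np.concatenate(([0.0], np.cumsum(is_cg)))
    un_csum = np.concatenate(([0.0], np.cumsum(is_unamb)))
    cg_counts = cg_csum[starts + W] - cg_csum[starts]
    un_counts = un_csum[starts + W] - un_csum[starts]
    if (un_counts == 0).any():
        bad = int(starts[int(np.argmax(un_counts == 0))])
        raise ValueError(
            f"record {record.id!r}: window starting at {bad} is all-N; "
            "(C+G)% undefined"
        )
    cg_abs = 100.0 / un_counts * cg_counts
    cg_rel = cg_tot / un_counts * cg_counts

    return WindowProfile(
        seq_id=record.id,
        chromosome=record.chromosome,
        window_starts=starts,
        kic=kic,
        cg_rel=cg_rel,
        cg_abs=cg_abs,
        cg_total=cg_tot,
        config=config,
    )
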