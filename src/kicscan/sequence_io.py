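"""FASTA ingest, chromosome labelling and tabular output.

Promoter sequences arrive as multi-FASTA; the chromosome of each record is
taken from a sidecar two-column TSV (id -> chromosome token) when supplied,
otherwise parsed from the FASTA header, otherwise ``"unknown"``.  Sequences
are uppercased, U is mapped to T, and any character outside {A,C,G,T,N} is
rejected with the offending record and position named.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from kicscan.kic_core import WindowProfile
    from kicscan.pattern import PatternCentroid

__all__ = [
    "PromoterRecord",
    "Cohort",
    "normalize_chromosome",
    "read_fasta",
    "write_fasta",
    "write_profile_tsv",
    "write_centroid_tsv",
    "read_centroid_tsv",
    "read_counts_tsv",
]

#: Canonical human chromosome tokens, in karyotype order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_TOKEN_RE = re.compile(r"(?:chr)?([0-9]{1,2}|X|Y)", re.IGNORECASE)
_VALID_BASES = frozenset("ACGTN")
_DEFAULT_TSS_WINDOW = (-700, 299)


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad characters, duplicate ids...)."""


@dataclass
class PromoterRecord:
    """One promoter sequence with its identity and chromosome label.

    ``tss_window`` records the TSS-relative span the sequence is meant to
    cover, default (-700, +299); it is presentation metadata only — all
    window arithmetic is 0-based on the stored sequence.
    """

    id: str
    sequence: str
    chromosome: str = "unknown"
    tss_window: tuple[int, int] = _DEFAULT_TSS_WINDOW

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise SequenceError(
                f"record {self.id!r}: sequence length {len(self.sequence)} < 2"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            pos = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise SequenceError(
                f"record {self.id!r}: illegal character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Cohort:
    """An ordered collection of promoter records from one source."""

    records: list[PromoterRecord] = field(default_factory=list)
    source_label: str = ""

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_chromosome(self) -> dict[str, list[PromoterRecord]]:
        """Partition records by chromosome label (every record in exactly one group)."""
        groups: dict[str, list[PromoterRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.chromosome, []).append(rec)
        return groups


def normalize_chromosome(token: str) -> str:
    """Normalize a chromosome token to {"1".."22","X","Y"} or "unknown".

    Strips a leading "chr" (any case), uppercases X/Y and drops leading
    zeros from numeric tokens.
    """
    t = token.strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    t = t.upper()
    if t in ("X", "Y"):
        return t
    if t.isdigit():
        t = str(int(t))
        if t in CHROMOSOMES:
            return t
    return "unknown"


def _chromosome_from_header(description: str) -> str:
    # first whitespace token (after the id) fully matching chr?(1-22|X|Y)
    for tok in description.split():
        m = _CHROM_TOKEN_RE.fullmatch(tok)
        if m:
            chrom = normalize_chromosome(m.group(1))
            if chrom != "unknown":
                return chrom
    return "unknown"


def _normalize_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise SequenceError(
            f"record {rec_id!r}: illegal character {seq[pos]!r} at position {pos}"
        )
    return seq


def read_chrom_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id -> chromosome token."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise SequenceError(f"chromosome map {path} needs 2 columns")
    return {
        str(i): normalize_chromosome(str(c))
        for i, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_fasta(
    path: str | Path,
    chrom_map: str | Path | None = None,
    source_label: str | None = None,
) -> Cohort:
    """Load a promoter cohort from multi-FASTA.

    Chromosome labels come from ``chrom_map`` (sidecar TSV) when present,
    else from the FASTA header (first token matching ``chr?(1-22|X|Y)``),
    else ``"unknown"``.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    SequenceError
        on duplicate ids or characters outside {A,C,G,T,N} (after
        uppercasing and U->T).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    mapping = read_chrom_map(chrom_map) if chrom_map is not None else {}

    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise SequenceError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _normalize_sequence(str(entry.seq), entry.id)
        if entry.id in mapping:
            chrom = mapping[entry.id]
        else:
            chrom = _chromosome_from_header(entry.description)
        records.append(PromoterRecord(id=entry.id, sequence=seq, chromosome=chrom))
    return Cohort(records=records, source_label=source_label or path.name)


def write_fasta(cohort: Cohort | Iterable[PromoterRecord], path: str | Path) -> None:
    """Write records as FASTA with headers ``>id chr<chromosome>`` (60-col wrap)."""
    records = cohort.records if isinstance(cohort, Cohort) else list(cohort)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            label = f" chr{rec.chromosome}" if rec.chromosome != "unknown" else ""
            fh.write(f">{rec.id}{label}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_profile_tsv(profiles: Sequence["WindowProfile"], path: str | Path) -> None:
    """Write sliding-window profiles as TSV.

    Columns: ``seq_id  window_start  kic  cg_rel  cg_abs``; one row per
    window; window_start is the 0-based index of the window's first base;
    values formatted with 2 decimals (the KIC algorithm's own rounding
    precision).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    with open(path, "w", newline="\n") as fh:
        fh.write("seq_id\twindow_start\tkic\tcg_rel\tcg_abs\n")
        for p in profiles:
            for start, kic, rel, ab in zip(p.window_starts, p.kic, p.cg_rel, p.cg_abs):
                fh.write(f"{p.seq_id}\t{start}\t{kic:.2f}\t{rel:.2f}\t{ab:.2f}\n")


def write_centroid_tsv(
    centroids: Sequence["PatternCentroid"], path: str | Path
) -> None:
    """Write pattern centroids as TSV: ``seq_id chromosome x_cg y_kic n_windows``."""
    centroids = list(centroids)
    if not centroids:
        raise ValueError("no centroids to write")
    with open(path, "w", newline="\n") as fh:
        fh.write("seq_id\tchromosome\tx_cg\ty_kic\tn_windows\n")
        for c in centroids:
            fh.write(f"{c.seq_id}\t{c.chromosome}\t{c.x:.6f}\t{c.y:.6f}\t{c.n_points}\n")


def read_centroid_tsv(path: str | Path) -> list["PatternCentroid"]:
    """Read a centroid TSV written by :func:`write_centroid_tsv`."""
    from kicscan.pattern import PatternCentroid

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"seq_id", "chromosome", "x_cg", "y_kic", "n_windows"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceError(f"centroid TSV {path} missing columns {sorted(missing)}")
    return [
        PatternCentroid(
            seq_id=str(r.seq_id),
            chromosome=str(r.chromosome),
            x=float(r.x_cg),
            y=float(r.y_kic),
            n_points=int(r.n_windows),
        )
        for r in df.itertuples(index=False)
    ]


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    """Read a per-chromosome non-negative integer count table (2-column TSV).

    Used for e.g. genetic-disease counts per chromosome.  A header line is
    accepted if its second field is non-numeric.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise SequenceError(f"counts table {path} needs 2 columns")
    counts: dict[str, int] = {}
    for tok, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
        try:
            n = int(val)
        except ValueError:
            continue  # header row
        if n < 0:
            raise SequenceError(f"negative count for chromosome {tok!r}")
        counts[normalize_chromosome(str(tok))] = n
    return counts
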