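"""Seeded generator of promoter-like sequences with planted repeat structure.

Emulates the sequence classes the scan is designed to discriminate:

* an i.i.d. background of configurable length and base composition
  (default 1000 nt, uniform over A,C,G,T — the TSS-relative span
  -700..+299 used throughout);
* planted tracts — a motif repeated a given number of times (poly(dA:dT)
  or poly(dC:dG) homopolymer runs, short tandem repeats of any period) —
  overwriting non-overlapping uniform-random spans;
* slipped-strand-mispairing (SSM) expansion events: in-place tandem
  duplication of a random substring, the mutation mode that builds and
  extends repeats;
* i.i.d. point mutations, the mode that erodes them.

Everything is driven by integer seeds; equal (config, seed) gives
byte-identical sequences.  Cohort generation derives one sub-stream per
record from (seed, record index), so records are reproducible
individually and in bulk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from kicscan.sequence_io import CHROMOSOMES, Cohort, PromoterRecord

__all__ = [
    "TractSpec",
    "SynthConfig",
    "generate",
    "generate_with_manifest",
    "mutate_point",
    "ssm_expand",
    "generate_cohort",
    "planted_repeat_cohort",
    "write_manifest",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PLACEMENT_RESTARTS = 1000


@dataclass(frozen=True)
class TractSpec:
    """A planted repeat: ``motif`` repeated ``copies`` times, ``count`` inserts."""

    motif: str
    copies: int
    count: int = 1

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"tract motif must be non-empty over ACGT: {self.motif!r}")
        if self.copies < 1 or self.count < 1:
            raise ValueError("tract copies and count must be >= 1")

    @property
    def tract_length(self) -> int:
        return len(self.motif) * self.copies


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for one synthetic promoter.

    ``background_probs`` are the (A, C, G, T) emission probabilities of the
    i.i.d. background; planted tracts overwrite random non-overlapping
    spans; ``point_mutation_rate`` applies a final i.i.d. substitution pass.
    """

    length: int = 1000
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tracts: tuple[TractSpec, ...] = ()
    point_mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        p = np.asarray(self.background_probs, float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("background_probs must be 4 non-negative values summing to 1")
        total = sum(t.tract_length * t.count for t in self.tracts)
        if total > self.length:
            raise ValueError(
                f"planted tracts total {total} nt exceed sequence length {self.length}"
            )
        if not (0.0 <= self.point_mutation_rate <= 1.0):
            raise ValueError("point_mutation_rate must be in [0, 1]")


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def _place_tracts(
    config: SynthConfig, rng: np.random.Generator
) -> list[tuple[int, TractSpec]]:
    """Choose non-overlapping start positions for every tract insert.

    Each insert draws its start uniformly from the positions still feasible
    given earlier placements (computed from the free gaps).  Dense packings
    can still fragment the free space into gaps too short for a remaining
    insert; in that case the whole placement restarts (bounded retries)
    before giving up with ``RuntimeError``.
    """
    inserts: list[TractSpec] = []
    for spec in config.tracts:
        if spec.tract_length > config.length:
            raise ValueError(f"tract {spec.motif!r} x{spec.copies} longer than sequence")
        inserts.extend([spec] * spec.count)

    for _restart in range(_PLACEMENT_RESTARTS):
        gaps: list[tuple[int, int]] = [(0, config.length)]  # half-open free spans
        out: list[tuple[int, TractSpec]] = []
        for spec in inserts:
            tlen = spec.tract_length
            feasible = [max(0, (e - s) - tlen + 1) for s, e in gaps]
            total = sum(feasible)
            if total == 0:
                break  # fragmented: restart the placement
            pick = int(rng.integers(0, total))
            for (s, e), nfeas in zip(list(gaps), feasible):
                if pick < nfeas:
                    start = s + pick
                    gaps.remove((s, e))
                    if start > s:
                        gaps.append((s, start))
                    if start + tlen < e:
                        gaps.append((start + tlen, e))
                    gaps.sort()
                    out.append((start, spec))
                    break
                pick -= nfeas
        else:
            return out
    raise RuntimeError(
        f"could not place all tracts without overlap after "
        f"{_PLACEMENT_RESTARTS} placement attempts"
    )


def generate_with_manifest(
    config: SynthConfig,
    record_id: str = "synth",
    chromosome: str = "unknown",
) -> tuple[PromoterRecord, list[dict]]:
    """Generate one promoter plus a manifest of planted tract positions.

    The manifest lists, per insert, the motif, copy number, start and end
    (0-based half-open) — enough for tests to assert on planted structure.
    """
    rng = _rng(config.seed)
    seq = rng.choice(_BASES, size=config.length, p=np.asarray(config.background_probs))
    manifest: list[dict] = []
    for start, spec in _place_tracts(config, rng):
        tract = np.frombuffer(
            (spec.motif * spec.copies).encode("ascii"), dtype=np.uint8
        )
        seq[start : start + len(tract)] = tract
        manifest.append(
            {
                "motif": spec.motif,
                "copies": spec.copies,
                "start": start,
                "end": start + len(tract),
            }
        )
    record = PromoterRecord(
        id=record_id, sequence=seq.tobytes().decode("ascii"), chromosome=chromosome
    )
    if config.point_mutation_rate > 0:
        record = mutate_point(
            record, config.point_mutation_rate, seed=int(rng.integers(0, 2**31))
        )
    return record, manifest


def generate(
    config: SynthConfig, record_id: str = "synth", chromosome: str = "unknown"
) -> PromoterRecord:
    """Generate one synthetic promoter (see :func:`generate_with_manifest`)."""
    record, _ = generate_with_manifest(config, record_id, chromosome)
    return record


def mutate_point(record: PromoterRecord, rate: float, seed: int = 0) -> PromoterRecord:
    """I.i.d. point-mutation corruption.

    Each position is independently substituted with probability ``rate``,
    uniformly among the three other unambiguous bases; N positions are
    left untouched (there is no defined substitution set for them).
    Length is preserved.  ``rate=1`` changes every A/C/G/T position.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed)
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(seq)) < rate
    hit &= seq != ord("N")
    idx = np.flatnonzero(hit)
    if idx.size:
        # substitute uniformly among the 3 other bases: offset 1..3 in base order
        base_index = np.searchsorted(np.sort(_BASES), seq[idx])
        offsets = rng.integers(1, 4, size=idx.size)
        seq[idx] = np.sort(_BASES)[(base_index + offsets) % 4]
    return PromoterRecord(
        id=record.id,
        sequence=seq.tobytes().decode("ascii"),
        chromosome=record.chromosome,
        tss_window=record.tss_window,
    )


def ssm_expand(
    record: PromoterRecord, motif_length: int, events: int, seed: int = 0
) -> PromoterRecord:
    """Slipped-strand-mispairing expansion: in-place tandem duplications.

    Per event, a random substring of ``motif_length`` is duplicated
    immediately after itself, so the sequence grows by
    ``events * motif_length``.  Repeated events compound: duplications can
    land inside earlier duplications, building longer tandem arrays — the
    repeat-expansion regime.
    """
    if motif_length < 1:
        raise ValueError("motif_length must be >= 1")
    if events < 0:
        raise ValueError("events must be >= 0")
    if motif_length > len(record.sequence):
        raise ValueError(
            f"motif_length {motif_length} exceeds sequence length {len(record.sequence)}"
        )
    rng = _rng(seed)
    seq = record.sequence
    for _ in range(events):
        start = int(rng.integers(0, len(seq) - motif_length + 1))
        motif = seq[start : start + motif_length]
        seq = seq[: start + motif_length] + motif + seq[start + motif_length :]
    return PromoterRecord(
        id=record.id,
        sequence=seq,
        chromosome=record.chromosome,
        tss_window=record.tss_window,
    )


def generate_cohort(
    n_per_chromosome: int,
    chromosomes: Sequence[str] = CHROMOSOMES,
    config: SynthConfig | None = None,
    tracts_by_chromosome: Mapping[str, Sequence[TractSpec]] | None = None,
    seed: int = 0,
    source_label: str = "synthetic",
) -> tuple[Cohort, list[dict]]:
    """Generate a labelled cohort: ``n_per_chromosome`` promoters per chromosome.

    Each record gets its own deterministic sub-stream derived from
    ``(seed, record index)``; ``tracts_by_chromosome`` optionally overrides
    the base config's planted tracts per chromosome.  Returns the cohort
    and a combined manifest (one entry per record, with its planted
    tracts).
    """
    if n_per_chromosome < 1:
        raise ValueError("n_per_chromosome must be >= 1")
    base = config or SynthConfig()
    records: list[PromoterRecord] = []
    manifest: list[dict] = []
    index = 0
    for chrom in chromosomes:
        tracts = (
            tuple(tracts_by_chromosome.get(chrom, base.tracts))
            if tracts_by_chromosome is not None
            else base.tracts
        )
        for j in range(n_per_chromosome):
            sub_seed = int(
                _rng(seed, index).integers(0, 2**31)
            )  # stable per (seed, index)
            cfg = SynthConfig(
                length=base.length,
                background_probs=base.background_probs,
                tracts=tracts,
                point_mutation_rate=base.point_mutation_rate,
                seed=sub_seed,
            )
            rec_id = f"chr{chrom}_p{j:04d}"
            rec, m = generate_with_manifest(cfg, record_id=rec_id, chromosome=chrom)
            records.append(rec)
            manifest.append({"id": rec_id, "chromosome": chrom, "tracts": m})
            index += 1
    return Cohort(records=records, source_label=source_label), manifest


def planted_repeat_cohort(
    n_per_chromosome: int = 50,
    length: int = 1000,
    tract_motif: str = "A",
    tract_copies: int = 20,
    seed: int = 0,
) -> tuple[Cohort, dict[str, int]]:
    """Cohort whose chromosomes differ only in planted repeat density.

    Chromosome k (in karyotype order 1..22, X, Y) receives k-1 poly-tract
    inserts of ``tract_motif * tract_copies`` per promoter, so planted
    density rises monotonically from 0 (chromosome 1) to 23 (Y) while
    background composition, length and everything else stay identical.
    Returns the cohort and the planted density per chromosome — the ground
    truth for rank-recovery checks.
    """
    densities = {chrom: k for k, chrom in enumerate(CHROMOSOMES)}
    tracts_by_chrom = {
        chrom: (
            (TractSpec(motif=tract_motif, copies=tract_copies, count=k),)
            if k > 0
            else ()
        )
        for chrom, k in densities.items()
    }
    base = SynthConfig(length=length)
    cohort, _ = generate_cohort(
        n_per_chromosome=n_per_chromosome,
        chromosomes=CHROMOSOMES,
        config=base,
        tracts_by_chromosome=tracts_by_chrom,
        seed=seed,
        source_label="planted-repeat-gradient",
    )
    return cohort, densities


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    """Write a planted-tract manifest as JSON."""
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
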