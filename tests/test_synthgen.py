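"""Synthetic promoter generator: determinism, planted structure, mutation
operators and their directional effects on the KIC statistic."""

import json

import numpy as np
import pytest

from kicscan import (
    KicConfig,
    SynthConfig,
    TractSpec,
    cg_total,
    generate,
    generate_cohort,
    kappa_ic,
    mutate_point,
    planted_repeat_cohort,
    sliding_scan,
    ssm_expand,
)
from kicscan.sequence_io import CHROMOSOMES
from kicscan.synthgen import generate_with_manifest, write_manifest


def _mean_kic(record, cfg=KicConfig()):
    return float(np.mean(sliding_scan(record, cfg).kic))


class TestGenerate:
    def test_deterministic_from_seed(self):
        cfg = SynthConfig(length=100, seed=7)
        assert generate(cfg).sequence == generate(cfg).sequence
        assert generate(cfg).sequence != generate(SynthConfig(length=100, seed=8)).sequence

    def test_planted_polyA_run_present(self):
        cfg = SynthConfig(length=100, tracts=(TractSpec("A", 50),), seed=3)
        assert "A" * 50 in generate(cfg).sequence

    def test_cg_only_background(self):
        cfg = SynthConfig(length=200, background_probs=(0, 0.5, 0.5, 0), seed=1)
        rec = generate(cfg)
        assert set(rec.sequence) <= {"C", "G"}
        assert cg_total(rec.sequence) == 100.0

    def test_background_composition_converges(self):
        probs = (0.4, 0.1, 0.2, 0.3)
        rec = generate(SynthConfig(length=100_000, background_probs=probs, seed=5))
        freq = [rec.sequence.count(b) / len(rec.sequence) for b in "ACGT"]
        np.testing.assert_allclose(freq, probs, atol=0.005)

    def test_manifest_reports_true_tract_spans(self):
        cfg = SynthConfig(length=300, tracts=(TractSpec("AG", 10, count=2),), seed=11)
        rec, manifest = generate_with_manifest(cfg)
        assert len(manifest) == 2
        for entry in manifest:
            assert rec.sequence[entry["start"] : entry["end"]] == "AG" * 10

    def test_overfull_tracts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SynthConfig(length=100, tracts=(TractSpec("A", 60, count=2),))

    def test_dense_packing_places_all_tracts(self):
        # 100 of 100 nt occupied: only near-exact packings exist, found via restarts
        cfg = SynthConfig(
            length=100, tracts=(TractSpec("A", 45, count=2), TractSpec("G", 10)), seed=0
        )
        rec, manifest = generate_with_manifest(cfg)
        assert len(manifest) == 3
        spans = sorted((m["start"], m["end"]) for m in manifest)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping


class TestMutatePoint:
    def test_rate_zero_is_identity(self):
        rec = generate(SynthConfig(length=100, seed=2))
        assert mutate_point(rec, 0.0, seed=9).sequence == rec.sequence

    def test_rate_one_changes_every_base(self):
        rec = generate(SynthConfig(length=100, seed=2))
        mut = mutate_point(rec, 1.0, seed=9)
        assert all(a != b for a, b in zip(rec.sequence, mut.sequence))
        assert len(mut.sequence) == 100

    def test_erodes_repeat_kic(self):
        """Point mutation on a poly(A) 30-mer drags KIC below the 96.55
        homopolymer value, the repeat-disruption regime."""
        from kicscan import PromoterRecord

        base = PromoterRecord("polyA", "A" * 30)
        vals = [kappa_ic(mutate_point(base, 0.3, seed=s).sequence) for s in range(500)]
        assert np.mean(vals) < 96.55

    def test_preserves_n_positions(self):
        from kicscan import PromoterRecord

        rec = PromoterRecord("n", "ANNA" * 10)
        mut = mutate_point(rec, 1.0, seed=4)
        assert all(b == "N" for b, m in zip(rec.sequence, mut.sequence) if b == "N")


class TestSsmExpand:
    def test_zero_events_is_identity(self):
        rec = generate(SynthConfig(length=50, seed=1))
        assert ssm_expand(rec, 5, 0, seed=2).sequence == rec.sequence

    def test_duplication_in_place(self):
        from kicscan import PromoterRecord

        rec = PromoterRecord("t", "ACGT")
        out = {ssm_expand(rec, 2, 1, seed=s).sequence for s in range(50)}
        assert out <= {"ACACGT", "ACGCGT", "ACGTGT"}
        assert "ACGCGT" in out  # the 'CG' duplication

    def test_length_grows_by_events_times_motif(self):
        rec = generate(SynthConfig(length=200, seed=6))
        out = ssm_expand(rec, motif_length=7, events=12, seed=3)
        assert len(out.sequence) == 200 + 7 * 12

    def test_motif_longer_than_sequence_rejected(self):
        rec = generate(SynthConfig(length=20, seed=6))
        with pytest.raises(ValueError):
            ssm_expand(rec, motif_length=21, events=1, seed=0)

    def test_raises_mean_kic_of_random_background(self):
        """Slippage expansions plant tandem structure, raising mean window KIC."""
        deltas = []
        for s in range(30):
            rec = generate(SynthConfig(length=1000, seed=s))
            deltas.append(_mean_kic(ssm_expand(rec, 10, 200, seed=s + 1000)) - _mean_kic(rec))
        assert np.mean(deltas) > 0
        assert sum(d > 0 for d in deltas) >= 28


class TestCohortGeneration:
    def test_shape_and_labels(self):
        cohort, manifest = generate_cohort(n_per_chromosome=2, seed=0)
        assert len(cohort) == 48
        assert sorted(cohort.by_chromosome()) == sorted(CHROMOSOMES)
        assert len({r.id for r in cohort}) == 48
        assert len(manifest) == 48

    def test_bytes_identical_across_runs(self):
        a, _ = generate_cohort(n_per_chromosome=1, seed=42)
        b, _ = generate_cohort(n_per_chromosome=1, seed=42)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_planted_gradient_density_is_monotone(self):
        cohort, densities = planted_repeat_cohort(n_per_chromosome=2, seed=0)
        assert densities["1"] == 0 and densities["Y"] == 23
        # chromosome Y's records must actually carry 23 planted tracts' worth of A runs
        y_rec = cohort.by_chromosome()["Y"][0]
        assert y_rec.sequence.count("A" * 20) >= 20

    def test_manifest_json_round_trip(self, tmp_path):
        _, manifest = generate_cohort(n_per_chromosome=1, chromosomes=["1", "2"], seed=1)
        path = tmp_path / "manifest.json"
        write_manifest(manifest, path)
        assert json.loads(path.read_text()) == manifest
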