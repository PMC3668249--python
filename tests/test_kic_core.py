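"""Unit and property tests for the KIC statistic and the sliding scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kicscan import KicConfig, PromoterRecord, cg_total, cg_window, kappa_ic, sliding_scan

from .oracle import kic_naive

EXCLUDE = KicConfig(empty_lag_policy="exclude_from_mean")

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)
dna_with_n = st.text(alphabet="ACGTN", min_size=2, max_size=60)


class TestKappaIC:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ("ACGT", 0.00),  # no positional coincidence at any lag
            ("AAAA", 66.67),  # lags 1,2 give 100; empty lag 3 gives 0; 200/3
            ("AAAAA", 75.00),  # 300/4
            ("A" * 30, 96.55),  # closed form 100*(N-1)/N, N=29
        ],
    )
    def test_hand_enumerated_values(self, window, expected, config):
        assert kappa_ic(window, config) == pytest.approx(expected, abs=0.005)

    def test_excluding_the_empty_lag_restores_100_for_perfect_repeats(self):
        assert kappa_ic("AAAA", EXCLUDE) == 100.00
        assert kappa_ic("G" * 30, EXCLUDE) == 100.00

    @pytest.mark.parametrize("length", range(2, 101))
    def test_homopolymer_closed_form(self, length, config):
        n = length - 1
        assert kappa_ic("T" * length, config) == round(100.0 * (n - 1) / n, 2)

    def test_too_short_windows_rejected(self, config):
        with pytest.raises(ValueError):
            kappa_ic("A", config)
        # length 2 under exclude_from_mean has only the empty lag
        with pytest.raises(ValueError):
            kappa_ic("AA", EXCLUDE)

    def test_ambiguous_base_never_matches_even_itself(self, config):
        # NN..N would be a perfect homopolymer if N matched N
        assert kappa_ic("N" * 10, config) == 0.00
        assert kappa_ic("ANAN", config) == kappa_ic("ATAG", config)

    @given(window=dna_with_n)
    def test_matches_naive_oracle(self, window):
        assert kappa_ic(window) == pytest.approx(kic_naive(window), abs=0.01)
        if len(window) > 2:
            assert kappa_ic(window, EXCLUDE) == pytest.approx(
                kic_naive(window, "exclude_from_mean"), abs=0.01
            )

    @given(window=dna_with_n)
    def test_range_is_0_to_100(self, window):
        assert 0.0 <= kappa_ic(window) <= 100.0

    def test_zero_iff_no_lag_matches(self, config):
        assert kappa_ic("ACGTACG"[:4], config) == 0.0
        assert kappa_ic("AACG", config) > 0.0  # lag 1 has one match

    def test_rounding_modes_differ_only_at_ties(self):
        half_away = KicConfig(rounding="half_away")
        # 100*1/8 lag structure engineered to give .125-type ties is hard to
        # hit exactly; just check both modes stay within half an ulp of 0.01
        for w in ("ACGTACGTAC", "AAGCTTAAGC", "AGAGAGAG"):
            assert abs(kappa_ic(w) - kappa_ic(w, half_away)) <= 0.01


class TestCG:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGCC", 100.0), ("ATAT", 0.0), ("ACGN", 200.0 / 3), ("ACGT", 50.0)],
    )
    def test_cg_total(self, seq, expected):
        assert cg_total(seq) == pytest.approx(expected)

    def test_cg_total_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            cg_total("NNNN")

    @pytest.mark.parametrize(
        "window, tot, relative, expected",
        [
            ("GGGG", 40.0, True, 40.0),
            ("GGGG", 40.0, False, 100.0),
            ("ATCG", 50.0, True, 25.0),
        ],
    )
    def test_cg_window(self, window, tot, relative, expected):
        cfg = KicConfig(cg_relative=relative)
        assert cg_window(window, tot, cfg) == pytest.approx(expected)

    def test_cg_window_all_ambiguous_rejected(self, config):
        with pytest.raises(ValueError):
            cg_window("NNN", 50.0, config)


class TestSlidingScan:
    def test_window_count_arithmetic(self, config, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        profile = sliding_scan(PromoterRecord("p", seq), config)
        assert len(profile) == 971  # floor((1000-30)/1)+1

    def test_single_window_when_length_equals_window(self, config):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"  # exactly 30 nt
        profile = sliding_scan(PromoterRecord("p", seq), config)
        assert len(profile) == 1
        assert profile.kic[0] == kappa_ic(seq, config)

    def test_too_short_sequence_names_the_record(self, config):
        with pytest.raises(ValueError, match="shorty"):
            sliding_scan(PromoterRecord("shorty", "ACGT" * 7 + "A"), config)

    def test_step_reduces_window_count(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        cfg = KicConfig(step=10)
        profile = sliding_scan(PromoterRecord("p", seq), cfg)
        assert len(profile) == (300 - 30) // 10 + 1
        assert list(profile.window_starts[:3]) == [0, 10, 20]

    def test_scan_agrees_with_per_window_scalars(self, config, rng):
        """The cumulative-sum scan must equal running kappa_ic/cg_window per window."""
        seq = "".join(rng.choice(list("ACGTN"), 150, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        rec = PromoterRecord("r", seq)
        profile = sliding_scan(rec, config)
        tot = cg_total(seq)
        for j, start in enumerate(profile.window_starts):
            w = seq[start : start + 30]
            assert profile.kic[j] == pytest.approx(kappa_ic(w, config), abs=1e-9)
            assert profile.cg_rel[j] == pytest.approx(cg_window(w, tot, config), abs=1e-9)

    def test_cg_rel_equals_cg_abs_scaled_by_total(self, config, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), 200, p=[0.4, 0.2, 0.15, 0.25]))
            profile = sliding_scan(PromoterRecord("r", seq), config)
            np.testing.assert_allclose(
                profile.cg_rel, profile.cg_abs * profile.cg_total / 100.0, atol=1e-9
            )

    def test_random_sequence_mean_kic_near_analytic_limit(self, config, rng):
        """I.i.d. uniform windows average 25*(N-1)/N ~ 24.14 (per-lag match rate 1/Q)."""
        windows = rng.choice(list("ACGT"), size=(2000, 30))
        vals = [kappa_ic("".join(w), config) for w in windows]
        assert np.mean(vals) == pytest.approx(25.0 * 28 / 29, abs=0.5)

    def test_shuffling_a_tandem_repeat_window_preserves_cg_but_lowers_kic(self, rng):
        """Periodic tandem structure scores above its composition baseline, so
        a uniform shuffle strictly lowers expected KIC while cg_abs is fixed."""
        window = "AAG" * 10  # period-3 short tandem repeat
        base_kic = kappa_ic(window)
        base_cg = cg_total(window)
        shuffled_kic = []
        for _ in range(200):
            perm = "".join(rng.permutation(list(window)))
            assert cg_total(perm) == base_cg
            shuffled_kic.append(kappa_ic(perm))
        assert np.mean(shuffled_kic) < base_kic


class TestKicConfig:
    def test_json_round_trip(self, tmp_path):
        cfg = KicConfig(window_size=40, step=2, cg_relative=False)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert KicConfig.from_json(path) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            KicConfig.from_json('{"window_size": 30, "wndow": 1}')

    @pytest.mark.parametrize(
        "kwargs", [{"window_size": 1}, {"step": 0}, {"alphabet_size": 1},
                   {"empty_lag_policy": "crash"}, {"rounding": "stochastic"}]
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KicConfig(**kwargs)
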