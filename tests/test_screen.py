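"""Window enumeration, filtering, off-target k-mer screen, and ranking."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condsirna import (
    NucleicSequence,
    ScreenConfig,
    build_kmer_index,
    count_offtarget_hits,
    enumerate_windows,
    evaluate_window,
    rank_candidates,
    reverse_complement,
)
from condsirna.screen import (
    ScreenError,
    TriggerWindow,
    UNSCREENED,
    offtarget_hit_records,
    windows_to_frame,
)

from conftest import PRINTED_SENSOR


def rand_seq(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(alphabet) for _ in range(n))


class TestEnumerate:
    @pytest.mark.parametrize("L,count", [(40, 27), (31, 1), (33, 6), (100, 207)])
    def test_count_matches_closed_form(self, L, count):
        trigger = NucleicSequence("t", "A" * L)
        assert len(enumerate_windows(trigger)) == count == sum(
            max(0, L - w + 1) for w in (31, 32, 33)
        )

    @given(st.integers(min_value=31, max_value=120))
    @settings(max_examples=40, deadline=None)
    def test_count_property(self, L):
        trigger = NucleicSequence("t", "A" * L)
        assert len(enumerate_windows(trigger)) == sum(
            max(0, L - w + 1) for w in (31, 32, 33)
        )

    def test_windows_are_true_subsequences_in_order(self):
        rng = random.Random(3)
        trigger = NucleicSequence("t", rand_seq(rng, 50))
        wins = enumerate_windows(trigger)
        assert [(w.start, w.length) for w in wins] == sorted(
            (w.start, w.length) for w in wins
        )
        for w in wins:
            assert (
                w.sequence.residues
                == trigger.residues[w.start - 1 : w.start + w.length - 1]
            )

    def test_too_short_trigger_rejected(self):
        with pytest.raises(ScreenError):
            enumerate_windows(NucleicSequence("t", "A" * 30))


class TestEvaluate:
    def test_printed_window_metrics(self, printed_window):
        cfg = ScreenConfig()
        ev = evaluate_window(TriggerWindow("t", 1, 31, printed_window), cfg)
        assert ev.sensor.residues == PRINTED_SENSOR
        assert ev.motif_hits == ()
        assert ev.gc == 17 / 31
        assert ev.offtarget_hits == UNSCREENED
        assert ev.passes(cfg)

    def test_weak_window_fails_on_mmmm(self):
        cfg = ScreenConfig()
        ev = evaluate_window(
            TriggerWindow("t", 1, 31, NucleicSequence("t", "AU" * 15 + "A")), cfg
        )
        assert any(m == "MMMM" for m, _ in ev.motif_hits)
        assert not ev.passes(cfg)

    def test_g_run_window_fails(self):
        cfg = ScreenConfig()
        # a CCCC run on the window is a GGGG run on the synthesized sensor
        seq = NucleicSequence("t", "CCCC" + "GACU" * 7)  # 32 nt
        ev = evaluate_window(TriggerWindow("t", 1, 32, seq), cfg)
        assert any(m == "GGGG" for m, _ in ev.motif_hits)
        assert not ev.passes(cfg)


class TestKmerIndex:
    def test_single_record_kmer_count(self):
        rng = random.Random(5)
        rec = NucleicSequence("r", rand_seq(rng, 20))
        index = build_kmer_index([rec], k=15)
        assert sum(len(v) for v in index.occurrences.values()) == 6  # L - k + 1

    def test_identical_records_map_to_both_ids(self):
        rec = NucleicSequence("r1", "ACGUACGUACGUACGUACGU")
        rec2 = NucleicSequence("r2", rec.residues)
        index = build_kmer_index([rec, rec2], k=15)
        for occs in index.occurrences.values():
            assert {rid for rid, _ in occs} == {"r1", "r2"}

    def test_short_record_skipped_with_warning(self, caplog):
        rng = random.Random(6)
        ok = NucleicSequence("ok", rand_seq(rng, 30))
        short = NucleicSequence("short", "ACGU")
        with caplog.at_level("WARNING", logger="condsirna.screen"):
            index = build_kmer_index([ok, short], k=15)
        assert index.record_ids == ("ok",)
        assert "short" in caplog.text

    def test_empty_background_rejected(self):
        with pytest.raises(ScreenError):
            build_kmer_index([], k=15)


class TestOfftarget:
    def naive_hits(self, sensor, records, k, exclusions=frozenset()):
        """Oracle: direct substring scan, both strands, over every record."""
        queries = (sensor.residues, reverse_complement(sensor).residues)
        kmers = {
            q[i : i + k] for q in queries for i in range(len(q) - k + 1)
        }
        hits = 0
        for rec in records:
            if rec.id in exclusions or len(rec) < k:
                continue
            if any(km in rec.residues for km in kmers):
                hits += 1
        return hits

    def test_implanted_copy_is_found(self):
        rng = random.Random(9)
        sensor = NucleicSequence("s", rand_seq(rng, 31))
        decoy = rand_seq(rng, 100) + sensor.residues[5:20] + rand_seq(rng, 50)
        records = [NucleicSequence("bg", decoy)]
        index = build_kmer_index(records, k=15)
        assert count_offtarget_hits(sensor, index) >= 1
        assert "bg" in offtarget_hit_records(sensor, index)

    def test_unrelated_background_scores_zero(self):
        sensor = NucleicSequence("s", "GCAU" * 8)
        records = [NucleicSequence("bg", "AC" * 50)]
        index = build_kmer_index(records, k=15)
        assert count_offtarget_hits(sensor, index) == 0

    def test_intended_target_excluded_by_id(self, printed_window):
        sensor = reverse_complement(printed_window, id="sensor")
        target = NucleicSequence("nppa", "A" * 40 + printed_window.residues + "C" * 40)
        index = build_kmer_index([target], k=15)
        assert count_offtarget_hits(sensor, index) == 1
        assert count_offtarget_hits(sensor, index, {"nppa"}) == 0

    def test_counts_match_naive_scan(self):
        rng = random.Random(21)
        sensor = NucleicSequence("s", rand_seq(rng, 31))
        records = []
        for i in range(12):
            body = rand_seq(rng, rng.randint(40, 120))
            if i % 3 == 0:  # implant a shared 15-mer in a third of them
                pos = rng.randint(0, 10)
                body = body[:pos] + sensor.residues[3:18] + body[pos:]
            records.append(NucleicSequence(f"r{i}", body))
        index = build_kmer_index(records, k=15)
        assert count_offtarget_hits(sensor, index) == self.naive_hits(
            sensor, records, 15
        )

    def test_sensor_shorter_than_k_rejected(self):
        index = build_kmer_index([NucleicSequence("r", "ACGU" * 10)], k=15)
        with pytest.raises(ScreenError):
            count_offtarget_hits(NucleicSequence("s", "ACGUACGU"), index)


class TestRanking:
    def window(self, start, gc, fold, motifs=(), hits=0):
        n = 31
        n_gc = round(gc * n)
        seq = NucleicSequence("t", "G" * n_gc + "A" * (n - n_gc))
        return TriggerWindow(
            "t", start, n, seq,
            sensor=reverse_complement(seq),
            gc=gc, motif_hits=motifs, fold=fold, offtarget_hits=hits,
        )

    def test_gc_distance_then_fold_then_start(self):
        a = self.window(10, 0.48, fold=3)
        b = self.window(5, 0.52, fold=1)
        c = self.window(1, 0.50, fold=4)
        d = self.window(2, 0.50, fold=2)
        ranked = rank_candidates([a, b, c, d])
        # 0.50 windows first (fold 2 before 4); 0.48/0.52 tie broken by fold
        assert [(w.start, w.fold) for w in ranked] == [
            (2, 2), (1, 4), (5, 1), (10, 3),
        ]

    def test_hard_filters_exclude(self):
        bad_gc = self.window(1, 0.70, fold=0)
        motif = self.window(2, 0.50, fold=0, motifs=(("GGGG", 1),))
        offt = self.window(3, 0.50, fold=0, hits=2)
        ok = self.window(4, 0.50, fold=0)
        assert rank_candidates([bad_gc, motif, offt, ok]) == [ok]

    def test_single_survivor(self):
        w = self.window(1, 0.5, fold=0)
        assert rank_candidates([w]) == [w]

    def test_tightening_gc_bounds_is_monotone(self):
        rng = random.Random(13)
        windows = [
            self.window(i, round(rng.uniform(0.3, 0.7), 3), fold=0)
            for i in range(1, 40)
        ]
        wide = ScreenConfig(gc_bounds=(0.40, 0.60))
        narrow = ScreenConfig(gc_bounds=(0.45, 0.55))
        survivors_wide = {w.start for w in rank_candidates(windows, wide)}
        survivors_narrow = {w.start for w in rank_candidates(windows, narrow)}
        assert survivors_narrow <= survivors_wide

    def test_report_frame_is_deterministic(self, printed_window):
        cfg = ScreenConfig()
        trigger = NucleicSequence(
            "t", "GCAU" * 5 + printed_window.residues + "AUGC" * 5
        )
        frames = []
        for _ in range(2):
            evaluated = [
                evaluate_window(w, cfg) for w in enumerate_windows(trigger, cfg)
            ]
            frames.append(windows_to_frame(evaluated, cfg).to_csv(sep="\t"))
        assert frames[0] == frames[1]


class TestConfig:
    def test_invalid_gc_bounds_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(gc_bounds=(0.6, 0.5))

    def test_small_k_rejected(self):
        with pytest.raises(ScreenError):
            ScreenConfig(offtarget_k=4)
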