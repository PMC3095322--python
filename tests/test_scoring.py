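"""The positional penalty score and curation filter."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import oracle_window_min, random_duplex
from mirtarmap.scanner import DuplexAlignment, duplex_from_gapped
from mirtarmap.scoring import (PairClass, ScoringParams, classify_column,
                               column_penalty, curate, score_duplex)


def make_duplex(mirna_gapped: str, target_gapped: str) -> DuplexAlignment:
    return duplex_from_gapped("m", "t", mirna_gapped, target_gapped,
                              1, sum(c != "-" for c in target_gapped), "+")


def perfect(mirna_seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in mirna_seq)


MIR20 = "UGGAGUGUGAUAGUCCCUUG"          # 20 nt
MIR24 = "UGGAGUGUGAUAGUCCCUUGGCAU"      # 24 nt


class TestClassifyColumn:
    @pytest.mark.parametrize("mb,tb,expected", [
        ("A", "U", PairClass.MATCH),
        ("U", "A", PairClass.MATCH),
        ("G", "C", PairClass.MATCH),
        ("C", "G", PairClass.MATCH),
        ("G", "U", PairClass.WOBBLE),
        ("U", "G", PairClass.WOBBLE),
        ("A", "C", PairClass.MISMATCH),
        ("A", "A", PairClass.MISMATCH),
        ("C", "U", PairClass.MISMATCH),
        ("A", "-", PairClass.INDEL),
        ("-", "G", PairClass.INDEL),
        ("A", "T", PairClass.MATCH),   # DNA-alphabet target tolerated
    ])
    def test_classification_total(self, mb, tb, expected):
        assert classify_column(mb, tb) is expected

    def test_double_gap_is_error(self):
        with pytest.raises(ValueError):
            classify_column("-", "-")


class TestColumnPenalty:
    @pytest.mark.parametrize("cls,pos,expected", [
        (PairClass.MATCH, 1, 0.0),
        (PairClass.WOBBLE, 3, 0.5),    # wobble penalty is position-free
        (PairClass.WOBBLE, 15, 0.5),
        (PairClass.INDEL, 1, 2.0),
        (PairClass.INDEL, None, 2.0),
        (PairClass.MISMATCH, 1, 1.0),  # position 1 is outside the seed zone
        (PairClass.MISMATCH, 2, 1.5),
        (PairClass.MISMATCH, 4, 1.5),
        (PairClass.MISMATCH, 7, 1.5),
        (PairClass.MISMATCH, 8, 1.0),
        (PairClass.MISMATCH, 12, 1.0),
    ])
    def test_penalties(self, cls, pos, expected):
        assert column_penalty(cls, pos) == pytest.approx(expected)

    def test_mismatch_needs_position(self):
        with pytest.raises(ValueError):
            column_penalty(PairClass.MISMATCH, None)


class TestScoreDuplex:
    def test_perfect_20mer_scores_zero_one_window(self):
        aln = make_duplex(MIR20, perfect(MIR20))
        s = score_duplex(aln)
        assert s.score == 0.0
        assert len(s.per_window_scores) == 1

    def test_wobble_plus_distal_mismatch(self):
        # one G:U wobble (position 2) + one mismatch at position 12
        tgt = list(perfect(MIR20))
        assert MIR20[1] == "G"
        tgt[1] = "U"    # miRNA G at position 2 faces U → wobble, 0.5
        assert MIR20[11] == "A"
        tgt[11] = "A"   # A:A mismatch at position 12 → 1.0
        s = score_duplex(make_duplex(MIR20, "".join(tgt)))
        assert s.score == pytest.approx(1.5)  # 0.5 + 1.0

    def test_24mer_defect_at_22_escapes_early_windows(self):
        tgt = list(perfect(MIR24))
        assert MIR24[21] == "C"
        tgt[21] = "U"   # C:U mismatch at position 22
        s = score_duplex(make_duplex(MIR24, "".join(tgt)))
        assert len(s.per_window_scores) == 5  # 24 - 20 + 1
        assert s.score == 0.0                 # windows 1 and 2 exclude pos 22
        assert s.best_window_start in (1, 2)
        assert max(s.per_window_scores) == pytest.approx(1.0)

    def test_insertion_between_window_columns_charged(self):
        mg = MIR20[:10] + "-" + MIR20[10:]
        tg = perfect(MIR20)[:10] + "A" + perfect(MIR20)[10:]
        s = score_duplex(make_duplex(mg, tg))
        assert s.score == pytest.approx(2.0)

    def test_two_nt_gap_costs_four(self):
        mg = MIR20[:10] + "--" + MIR20[10:]
        tg = perfect(MIR20)[:10] + "AA" + perfect(MIR20)[10:]
        s = score_duplex(make_duplex(mg, tg))
        assert s.score == pytest.approx(4.0)

    def test_seed_mismatch_escapes_late_windows(self):
        # seed mismatch at position 3 of a 24-mer: 1.5 in windows starting
        # at 1-3, excluded from windows starting at 4-5 → minimum 0
        tgt = list(perfect(MIR24))
        assert MIR24[2] == "G"
        tgt[2] = "G"  # G:G mismatch at position 3
        s = score_duplex(make_duplex(MIR24, "".join(tgt)))
        assert s.per_window_scores == pytest.approx((1.5, 1.5, 1.5, 0.0, 0.0))
        assert s.score == 0.0
        assert s.best_window_start == 4

    def test_window_relative_seed_flag(self):
        # mismatch at absolute position 8 (outside the seed): absolutely
        # keyed it costs 1.0 in every window; window-relative it becomes a
        # seed mismatch (relative positions 7..4) in windows starting 2-5
        tgt = list(perfect(MIR24))
        assert MIR24[7] == "U"
        tgt[7] = "C"  # U:C mismatch at position 8
        s_abs = score_duplex(make_duplex(MIR24, "".join(tgt)))
        s_rel = score_duplex(make_duplex(MIR24, "".join(tgt)),
                             ScoringParams(seed_by_window_position=True))
        assert max(s_abs.per_window_scores) == pytest.approx(1.0)
        assert s_rel.per_window_scores == pytest.approx(
            (1.0, 1.5, 1.5, 1.5, 1.5))

    def test_short_coverage_is_error(self):
        aln = make_duplex(MIR20[:19] + "-", perfect(MIR20)[:19] + "A")
        with pytest.raises(ValueError, match="19 miRNA positions"):
            score_duplex(aln)

    def test_score_matches_oracle_on_random_duplexes(self):
        rng = np.random.default_rng(20260923)
        for _ in range(1000):
            columns, positions = random_duplex(rng)
            aln = DuplexAlignment(
                mirna_id="m", target_id="t", target_start=1,
                target_end=max(1, sum(tb != "-" for _, tb in columns)),
                strand="+", columns=columns, mirna_positions=positions)
            expected = oracle_window_min(columns, positions)
            got = score_duplex(aln)
            assert got.score == pytest.approx(expected), (columns, positions)
            assert got.score == pytest.approx(min(got.per_window_scores))

    def test_perfect_duplex_scores_zero_any_length(self):
        rng = np.random.default_rng(5)
        for m in range(20, 27):
            mir = "".join("ACGU"[i] for i in rng.integers(0, 4, m))
            assert score_duplex(make_duplex(mir, perfect(mir))).score == 0.0

    def test_degrading_a_column_never_decreases_score(self):
        # turning a Watson-Crick column into a mismatch, or inserting an
        # extra indel column, can only raise (or keep) the window minimum
        rng = np.random.default_rng(11)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(200):
            columns, positions = random_duplex(rng)
            base = score_duplex(DuplexAlignment(
                mirna_id="m", target_id="t", target_start=1,
                target_end=max(1, sum(tb != "-" for _, tb in columns)),
                strand="+", columns=columns,
                mirna_positions=positions)).score
            matches = [k for k, (mb, tb) in enumerate(columns)
                       if tb != "-" and mb != "-" and comp[mb] == tb]
            if matches:
                k = matches[rng.integers(len(matches))]
                worse = list(columns)
                worse[k] = (columns[k][0], columns[k][0])  # self-pair: mismatch
                degraded = score_duplex(DuplexAlignment(
                    mirna_id="m", target_id="t", target_start=1,
                    target_end=max(1, sum(tb != "-" for _, tb in worse)),
                    strand="+", columns=tuple(worse),
                    mirna_positions=positions)).score
                assert degraded >= base - 1e-9
            k = int(rng.integers(1, len(columns)))
            bulged = list(columns)
            bulged.insert(k, ("-", "A"))
            pos2 = list(positions)
            pos2.insert(k, None)
            degraded = score_duplex(DuplexAlignment(
                mirna_id="m", target_id="t", target_start=1,
                target_end=max(1, sum(tb != "-" for _, tb in bulged)),
                strand="+", columns=tuple(bulged),
                mirna_positions=tuple(pos2))).score
            assert degraded >= base - 1e-9


class TestCurate:
    def test_strict_threshold(self):
        from mirtarmap.scoring import SiteScore
        pairs = [(s, SiteScore(score=s, best_window_start=1,
                               per_window_scores=(s,)))
                 for s in (0.0, 0.5, 2.5, 3.0, 3.5)]
        kept = curate(pairs)
        assert [p[0] for p in kept] == [0.0, 0.5, 2.5]

    def test_boundary_just_below(self):
        from mirtarmap.scoring import SiteScore
        pairs = [(i, SiteScore(score=2.999, best_window_start=1,
                               per_window_scores=(2.999,)))
                 for i in range(3)]
        assert len(curate(pairs)) == 3

    def test_idempotent(self):
        from mirtarmap.scoring import SiteScore
        rng = np.random.default_rng(3)
        pairs = [(i, SiteScore(score=s, best_window_start=1,
                               per_window_scores=(s,)))
                 for i, s in enumerate(rng.uniform(0, 6, size=50).round(1))]
        once = curate(pairs)
        assert curate(once) == once

    def test_empty(self):
        assert curate([]) == []
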