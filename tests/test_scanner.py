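"""Antisense duplex scanner: planted-site recovery, strand handling, and
equivalence with the brute-force enumerator."""
from __future__ import annotations

import numpy as np
import pytest

from mirtarmap import scoring
from mirtarmap.scanner import (DuplexAlignment, ScanParams, render_alignment,
                               scan, scan_exhaustive)
from mirtarmap.seqio import MatureMiRNA, TargetSequence, revcomp_dna
from mirtarmap.simulate import _rand_dna, _rand_rna, build_site_sequence


def mk_mirna(rng, length=21):
    return MatureMiRNA(id="sly-miRx", sequence=_rand_rna(rng, length))


def embed(rng, mirna, profile, kind="UNIGENE", strand="+", flank=30):
    """A target carrying exactly one planted site; returns (target, start,
    end) with plus-strand coordinates."""
    site = build_site_sequence(mirna.sequence, profile, rng).replace("U", "T")
    if strand == "-":
        site = revcomp_dna(site)
    left = _rand_dna(rng, flank)
    right = _rand_dna(rng, flank)
    seq = left + site + right
    return (TargetSequence(id="t1", kind=kind, sequence=seq),
            flank + 1, flank + len(site))


class TestScanBasics:
    def test_perfect_complement_single_ungapped_hit(self):
        rng = np.random.default_rng(1)
        mir = mk_mirna(rng)
        target, start, end = embed(rng, mir, [])
        hits = scan(mir, target)
        assert len(hits) == 1
        (h,) = hits
        assert (h.target_start, h.target_end, h.strand) == (start, end, "+")
        assert len(h.columns) == len(mir)
        assert all("-" not in col for col in h.columns)
        assert scoring.score_duplex(h).score == 0.0

    def test_minus_strand_hit_reported_in_plus_frame(self):
        rng = np.random.default_rng(2)
        mir = mk_mirna(rng)
        target, start, end = embed(rng, mir, [], kind="BAC", strand="-")
        hits = scan(mir, target)
        assert [(h.target_start, h.target_end, h.strand) for h in hits] == \
            [(start, end, "-")]
        # oracle: scanning the reverse complement finds it on '+' at the
        # mirrored coordinates
        rc = TargetSequence(id="t1", kind="BAC",
                            sequence=revcomp_dna(target.sequence))
        L = len(target)
        rc_hits = [h for h in scan(mir, rc) if h.strand == "+"]
        assert [(L - h.target_end + 1, L - h.target_start + 1)
                for h in rc_hits] == [(start, end)]

    def test_unigene_minus_strand_not_scanned(self):
        rng = np.random.default_rng(3)
        mir = mk_mirna(rng)
        target, _, _ = embed(rng, mir, [], kind="UNIGENE", strand="-")
        assert scan(mir, target) == []

    def test_no_complementarity_empty(self):
        mir = MatureMiRNA(id="polyU", sequence="U" * 21)
        target = TargetSequence(id="polyT", kind="UNIGENE", sequence="T" * 80)
        assert scan(mir, target) == []

    def test_short_target_warns_and_returns_empty(self, caplog):
        mir = MatureMiRNA(id="m", sequence="ACGUACGUACGUACGUACGUA")
        short = TargetSequence(id="t", kind="UNIGENE", sequence="ACG" * 6)
        with caplog.at_level("WARNING"):
            assert scan(mir, short) == []
        assert "shorter than 20" in caplog.text

    def test_mirna_below_window_skipped(self, caplog):
        mir = MatureMiRNA(id="m19", sequence="ACGUACGUACGUACGUACG")  # 19 nt
        target = TargetSequence(id="t", kind="UNIGENE",
                                sequence=revcomp_dna("ACGTACGTACGTACGTACG") * 4)
        with caplog.at_level("WARNING"):
            assert scan(mir, target) == []
        assert "cannot be scored" in caplog.text


class TestPlantedProfiles:
    @pytest.mark.parametrize("profile,expected", [
        ([(3, "wobble")], 0.5),
        ([(12, "mismatch")], 1.0),
        ([(4, "mismatch")], 1.5),
        ([(10, "insertion")], 2.0),
        ([(10, "deletion")], 2.0),
        ([(5, "mismatch"), (15, "wobble")], 2.0),
    ])
    def test_planted_profile_recovered_at_expected_score(self, profile,
                                                         expected):
        rng = np.random.default_rng(sum(p for p, _ in profile))
        mir = mk_mirna(rng)
        if any(e == "wobble" and mir.sequence[p - 1] not in "GU"
               for p, e in profile):
            seq = list(mir.sequence)
            for p, e in profile:
                if e == "wobble" and seq[p - 1] not in "GU":
                    seq[p - 1] = "G"
            mir = MatureMiRNA(id=mir.id, sequence="".join(seq))
        target, start, end = embed(rng, mir, profile)
        hits = scan(mir, target)
        assert len(hits) == 1
        assert (hits[0].target_start, hits[0].target_end) == (start, end)
        assert scoring.score_duplex(hits[0]).score == pytest.approx(expected)

    def test_single_indel_site_identical_in_both_modes(self):
        rng = np.random.default_rng(42)
        mir = mk_mirna(rng)
        target, _, _ = embed(rng, mir, [(9, "insertion")])
        fast = scan(mir, target)
        slow = scan_exhaustive(mir, target)
        assert fast == slow
        assert len(fast) == 1
        assert sum(mb == "-" for mb, _ in fast[0].columns) == 1


class TestInvariants:
    def test_column_count_bounded_by_band(self):
        rng = np.random.default_rng(9)
        params = ScanParams()
        for _ in range(20):
            mir = mk_mirna(rng, int(rng.integers(20, 25)))
            target = TargetSequence(id="t", kind="BAC",
                                    sequence=_rand_dna(rng, 300))
            for h in scan(mir, target, params):
                assert len(h.columns) <= len(mir) + params.band_width

    def test_strand_symmetry_on_random_bacs(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            mir = mk_mirna(rng)
            target, _, _ = embed(rng, mir, [(11, "mismatch")], kind="BAC",
                                 strand="+" if rng.random() < 0.5 else "-")
            L = len(target)
            rc = TargetSequence(id="t1", kind="BAC",
                                sequence=revcomp_dna(target.sequence))
            fwd = {(h.target_start, h.target_end, h.strand)
                   for h in scan(mir, target)}
            flipped = {(L - h.target_end + 1, L - h.target_start + 1,
                        "-" if h.strand == "+" else "+")
                       for h in scan(mir, rc)}
            assert fwd == flipped

    def test_exhaustive_guard(self):
        mir = MatureMiRNA(id="m", sequence="ACGUACGUACGUACGUACGUA")
        big = TargetSequence(id="big", kind="UNIGENE",
                             sequence="ACGT" * 2600)
        with pytest.raises(ValueError, match="refuses"):
            scan_exhaustive(mir, big)

    def test_max_sites_cap(self):
        rng = np.random.default_rng(12)
        mir = mk_mirna(rng)
        site = build_site_sequence(mir.sequence, [], rng).replace("U", "T")
        seq = ("".join(_rand_dna(rng, 15) + site for _ in range(6))
               + _rand_dna(rng, 15))
        target = TargetSequence(id="t", kind="UNIGENE", sequence=seq)
        capped = scan(mir, target, ScanParams(max_sites_per_pair=3))
        assert len(capped) == 3
        full = scan(mir, target)
        assert len(full) == 6


class TestOracleEquivalence:
    """scan must equal scan_exhaustive element-wise; the wide 100-fixture
    sweep lives in the acceptance suite, this is a quick targeted version."""

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalence_small_fixtures(self, seed):
        rng = np.random.default_rng(1000 + seed)
        band = (1, 1, 2)[seed % 3]
        params = ScanParams(band_width=band)
        mir = mk_mirna(rng, int(rng.integers(20, 23)))
        kind = "BAC" if seed % 2 else "UNIGENE"
        if rng.random() < 0.7:
            profile = [(int(rng.integers(2, len(mir))), "mismatch")]
            if band and rng.random() < 0.5:
                profile.append((int(rng.integers(2, len(mir) - 1)),
                                "insertion"))
            strand = "-" if (kind == "BAC" and rng.random() < 0.5) else "+"
            target, _, _ = embed(rng, mir, profile, kind=kind, strand=strand,
                                 flank=25)
        else:
            target = TargetSequence(id="t1", kind=kind,
                                    sequence=_rand_dna(rng, 70))
        assert scan(mir, target, params) == scan_exhaustive(mir, target,
                                                            params)


def test_render_alignment_layout():
    rng = np.random.default_rng(77)
    mir = mk_mirna(rng)
    target, _, _ = embed(rng, mir, [(3, "wobble")])
    (h,) = scan(mir, target)
    lines = render_alignment(h).split("\n")
    assert len(lines) == 3
    assert lines[0].startswith("5'") and lines[0].endswith("3'")
    assert lines[2].startswith("3'") and lines[2].endswith("5'")
    assert ":" in lines[1] and "|" in lines[1]
    assert len(lines[0]) == len(lines[1]) == len(lines[2])
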