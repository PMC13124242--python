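"""Annotation tracks, majority-rule pixels, contig placement, rendering."""

from collections import Counter

import numpy as np
import pytest

from karyokit._encode import revcomp
from karyokit.db import AMBIGUOUS, GAP, NOVEL, ParameterError
from karyokit.karyogram import (
    UNPLACED,
    ContigPlacement,
    FeatureCallTrack,
    RenderOptions,
    annotate_sequence,
    assign_contig,
    bin_majority,

    orient_contig,
    place_assembly,
    render_karyogram,
)
from karyokit.simulate import SyntheticContig


def _fabricated_track(calls, k=31, name="t", F=8):
    calls = np.asarray(calls, dtype=np.int32)
    return FeatureCallTrack(
        name, calls.size + k - 1, k, calls,
        np.zeros(F, np.int64), np.zeros(F, np.int64),
    )


def _mode_oracle(window):
    """Independent majority oracle: counts, then the documented precedence
    telomere > centromere > arm (lowest id) > ambiguous > novel > gap."""
    prec = {AMBIGUOUS: 10**6, NOVEL: 10**6 + 1, GAP: 10**6 + 2}
    counts = Counter(int(v) for v in window)
    return min(counts, key=lambda v: (-counts[v], prec.get(v, v)))


class TestAnnotate:
    def test_arm_substring_is_pure_arm(self, toy_ref, toy_db):
        lay = toy_ref.layout["chr3"]
        seq = toy_ref.sequences["chr3"][lay.cen_end : lay.cen_end + 40_000]
        track = annotate_sequence(toy_db, seq, "frag")
        fid = next(f.feature_id for f in toy_db.features if f.name == "chr3_q")
        non_gap = track.calls[track.calls != GAP]
        assert (non_gap == fid).all()

    def test_revcomp_mirrors_calls_and_inverts_votes(self, toy_ref, toy_db):
        lay = toy_ref.layout["chr2"]
        seq = toy_ref.sequences["chr2"][lay.tel1_end : lay.tel1_end + 30_000]
        fwd = annotate_sequence(toy_db, seq, "f")
        rev = annotate_sequence(toy_db, revcomp(seq), "r")
        assert np.array_equal(rev.calls, fwd.calls[::-1])
        assert np.array_equal(rev.strand_match, fwd.strand_mismatch)
        assert np.array_equal(rev.strand_mismatch, fwd.strand_match)

    def test_random_sequence_is_mostly_novel(self, toy_db, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        track = annotate_sequence(toy_db, seq, "rand")
        assert (track.calls == NOVEL).mean() >= 0.99

    def test_short_sequence_yields_empty_track(self, toy_db):
        track = annotate_sequence(toy_db, "ACGT", "tiny")
        assert track.calls.size == 0


class TestBinMajority:
    def test_matches_brute_force_mode_on_random_tracks(self, rng):
        for _ in range(25):
            m = int(rng.integers(50, 3000))
            calls = rng.choice([0, 1, 2, 3, 4, AMBIGUOUS, NOVEL, GAP], m)
            track = _fabricated_track(calls)
            pixel_bp = int(rng.integers(31, 500))
            pt = bin_majority(track, pixel_bp)
            for p in range(pt.labels.size):
                window = calls[p * pixel_bp : (p + 1) * pixel_bp]
                if window.size:
                    assert pt.labels[p] == _mode_oracle(window)

    def test_60_40_centromere_majority(self):
        calls = np.array([1] * 60 + [2] * 40, dtype=np.int32)
        pt = bin_majority(_fabricated_track(calls), 100)
        assert pt.labels[0] == 1  # centromere wins the pixel

    def test_all_novel_is_all_white(self):
        pt = bin_majority(_fabricated_track([NOVEL] * 500), 100)
        assert (pt.labels == NOVEL).all()

    def test_pixel_smaller_than_k_rejected(self):
        with pytest.raises(ParameterError):
            bin_majority(_fabricated_track([0] * 10), 16)

    def test_default_pixel_span(self, toy_db, toy_ref):
        track = annotate_sequence(toy_db, toy_ref.sequences["chr1"], "chr1")
        pt = bin_majority(track)
        assert pt.pixel_bp == 250_000


class TestAssignOrientOrder:
    def test_single_arm_contig_fully_assigned(self, toy_ref, toy_db):
        lay = toy_ref.layout["chr2"]
        seq = toy_ref.sequences["chr2"][lay.tel1_end : lay.cen_start]
        track = annotate_sequence(toy_db, seq, "p2")
        assert assign_contig(track, toy_db) == ("chr2", 1.0)

    def test_pure_centromere_is_unplaced(self, toy_ref, toy_db):
        lay = toy_ref.layout["chr1"]
        seq = toy_ref.sequences["chr1"][lay.cen_start : lay.cen_end]
        track = annotate_sequence(toy_db, seq, "cen")
        chrom, frac = assign_contig(track, toy_db)
        assert chrom == UNPLACED and frac == 0.0

    def test_fusion_assignment_fraction(self, toy_db):
        fids = {f.name: f.feature_id for f in toy_db.features}
        calls = [fids["chr1_p"]] * 700 + [fids["chr3_p"]] * 300
        chrom, frac = assign_contig(_fabricated_track(calls), toy_db)
        assert chrom == "chr1"
        assert frac == pytest.approx(0.7)

    def test_orientation_forward_and_reverse(self, toy_ref, toy_db):
        seq = toy_ref.sequences["chr1"]
        fwd = annotate_sequence(toy_db, seq, "f")
        rev = annotate_sequence(toy_db, revcomp(seq), "r")
        assert orient_contig(fwd, toy_db) == "+"
        assert orient_contig(rev, toy_db) == "-"

    def test_order_concordance_breaks_vote_ties(self, toy_db):
        fids = {f.name: f.feature_id for f in toy_db.features}
        calls = [fids["chr1_q"]] * 200 + [1] * 100 + [fids["chr1_p"]] * 200
        track = _fabricated_track(calls)  # zero strand votes, q before p
        assert orient_contig(track, toy_db, "chr1") == "-"

    def test_order_p_before_cen_q_before_q(self, toy_ref, toy_db):
        lay = toy_ref.layout["chr1"]
        pieces = [
            SyntheticContig("p_only", "chr1", lay.tel1_end, lay.cen_start),
            SyntheticContig("cen_q", "chr1", lay.cen_start, lay.cen_end + 30_000),
            SyntheticContig("q_only", "chr1", lay.cen_end + 30_000, lay.tel2_start),
        ]
        tracks = [
            annotate_sequence(toy_db, c.sequence(toy_ref), c.name) for c in pieces
        ]
        placements = place_assembly(toy_db, tracks)
        assert [p.name for p in placements] == ["p_only", "cen_q", "q_only"]

    def test_chromosome_order_and_unplaced_last(self, toy_ref, toy_db, rng):
        tracks = [
            annotate_sequence(toy_db, seq, name)
            for name, seq in toy_ref.sequences.items()
        ]
        junk = "".join(rng.choice(list("ACGT"), 5000))
        tracks.append(annotate_sequence(toy_db, junk, "junk"))
        placements = place_assembly(toy_db, tracks)
        assert [p.chromosome for p in placements] == ["chr1", "chr2", "chr3", UNPLACED]

    def test_assignment_invariant_to_annotation_order(self, small_ref):
        from karyokit.db import build_feature_db
        from karyokit.db import FeatureAnnotation

        reordered = FeatureAnnotation(list(reversed(small_ref.annotation.intervals)))
        db2 = build_feature_db(small_ref.sequences, reordered, 31)
        for name, seq in small_ref.sequences.items():
            track = annotate_sequence(db2, seq, name)
            assert assign_contig(track, db2)[0] == name


class TestRender:
    def _track_of_length(self, length, call=NOVEL):
        calls = np.full(length - 30, call, dtype=np.int32)
        return FeatureCallTrack(
            f"len{length}", length, 31, calls, np.zeros(8, np.int64), np.zeros(8, np.int64)
        )

    def _placements(self, tracks):
        return [
            ContigPlacement(t.name, UNPLACED, "+", i, 0.0, t.length)
            for i, t in enumerate(tracks)
        ]

    def test_draw_filter_default_1mbp(self, toy_db):
        tracks = [self._track_of_length(800_000), self._track_of_length(2_000_000)]
        svg = render_karyogram(tracks, self._placements(tracks), toy_db)
        # one background rect + per drawn contig: >=1 fill rect + 1 border
        assert svg.count("<rect") == 3
        both = render_karyogram(
            tracks, self._placements(tracks), toy_db, RenderOptions(min_draw_bp=0)
        )
        assert both.count("<rect") == 5

    def test_rendering_is_deterministic(self, toy_ref, toy_db):
        tracks = [
            annotate_sequence(toy_db, seq, name)
            for name, seq in toy_ref.sequences.items()
        ]
        placements = place_assembly(toy_db, tracks)
        opts = RenderOptions(min_draw_bp=0, pixel_bp=10_000)
        a = render_karyogram(tracks, placements, toy_db, opts)
        b = render_karyogram(tracks, placements, toy_db, opts)
        assert a == b
        assert a.startswith("<?xml")

    def test_empty_canvas_has_legend(self, toy_db):
        svg = render_karyogram([], [], toy_db)
        assert "legend" in svg
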