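"""Computational karyograms from k-mer feature calls.

An assembly sequence is annotated position by position against a
:class:`~karyokit.db.FeatureDatabase` (one call per k-mer window), the call
track is binned into fixed-span pixels colored by majority rule, contigs
are assigned to chromosomes, oriented, and ordered, and the whole layout is
rendered as an SVG karyogram: one colored vertical rectangle per drawn
sequence, grouped by chromosome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import palette
from ._encode import kmer_codes, seq_to_codes
from .db import (
    AMBIGUOUS,
    GAP,
    NOVEL,
    STRAND_FWD,
    STRAND_MIXED,
    FeatureDatabase,
    ParameterError,
)

logger = logging.getLogger(__name__)

UNPLACED = "UNPLACED"

# expected positional rank of feature calls along an oriented chromosome:
# p arm -> centromere -> q arm (telomere calls are global and carry no
# left/right identity, so they are excluded from rank statistics)
_RANK_P, _RANK_CEN, _RANK_Q = 1.0, 2.0, 3.0


@dataclass
class FeatureCallTrack:
    """Per-window feature classification of one contig."""

    name: str
    length: int
    k: int
    calls: np.ndarray  # int32: feature_id | AMBIGUOUS | NOVEL | GAP
    strand_match: np.ndarray  # per-feature counts of orientation agreement
    strand_mismatch: np.ndarray

    def __post_init__(self):
        expect = max(0, self.length - self.k + 1)
        if self.calls.shape[0] != expect:
            raise ValueError(
                f"calls length {self.calls.shape[0]} != L-k+1 = {expect}"
            )


@dataclass
class PixelTrack:
    pixel_bp: int
    labels: np.ndarray  # int32 in call space (feature_id | AMBIGUOUS | NOVEL | GAP)
    last_pixel_bp: int


@dataclass
class ContigPlacement:
    name: str
    chromosome: str  # chromosome label or UNPLACED
    orientation: str  # "+" | "-"
    order_rank: int
    assignment_fraction: float
    length: int = 0
    haplotype: str = ""


def annotate_sequence(db: FeatureDatabase, seq: str, name: str = "seq") -> FeatureCallTrack:
    """Alignment-free annotation: one call per k-mer window of ``seq``.

    Windows containing non-ACGT characters are GAP; windows absent from the
    database are NOVEL. Strand votes are accumulated only for unambiguous
    feature calls whose stored strand is not MIXED.
    """
    k = db.k
    codes = seq_to_codes(seq)
    fwd, rev, valid = kmer_codes(codes, k)
    m = fwd.shape[0]
    F = db.n_features
    calls = np.full(m, GAP, dtype=np.int32)
    match = np.zeros(F, dtype=np.int64)
    mismatch = np.zeros(F, dtype=np.int64)
    if m:
        canon = np.minimum(fwd, rev)
        payload, strand = db.lookup_codes(canon)
        calls[valid] = payload[valid]
        votable = valid & (payload >= 0) & (strand != STRAND_MIXED)
        if votable.any():
            query_fwd = fwd <= rev
            agree = query_fwd[votable] == (strand[votable] == STRAND_FWD)
            fids = payload[votable]
            match += np.bincount(fids[agree], minlength=F)
            mismatch += np.bincount(fids[~agree], minlength=F)
    return FeatureCallTrack(name, len(seq), k, calls, match, mismatch)


def _mode_call(window: np.ndarray) -> int:
    """Modal call; ties resolve telomere > centromere > arm (lowest id) >
    ambiguous > novel > gap, which is ascending order of a remapped key."""
    vals, counts = np.unique(window, return_counts=True)
    # remap sentinels above all feature ids so smaller key = higher precedence
    key = np.where(vals >= 0, vals, 0x7FFFFFF0 - vals)  # AMB<NOVEL<GAP after map
    best = np.lexsort((key, -counts))[0]
    return int(vals[best])


def bin_majority(track: FeatureCallTrack, pixel_bp: int = 250_000) -> PixelTrack:
    """Majority-rule pixels: each pixel spans ``pixel_bp`` bases of sequence
    and takes the modal call of the k-mer windows starting inside it."""
    if pixel_bp < track.k:
        raise ParameterError(f"pixel_bp {pixel_bp} < k {track.k}")
    n_pix = max(1, math.ceil(track.length / pixel_bp))
    labels = np.full(n_pix, NOVEL, dtype=np.int32)
    for p in range(n_pix):
        window = track.calls[p * pixel_bp : (p + 1) * pixel_bp]
        if window.size:
            labels[p] = _mode_call(window)
    last = track.length - (n_pix - 1) * pixel_bp
    return PixelTrack(pixel_bp, labels, last)


def pixel_color(label: int, db: FeatureDatabase) -> str:
    if label >= 0:
        return palette.to_hex(db.feature(int(label)).color)
    if label == AMBIGUOUS:
        return palette.to_hex(palette.AMBIGUOUS_COLOR)
    return palette.to_hex(palette.NOVEL_COLOR)  # NOVEL and GAP render white


def _arm_info(db: FeatureDatabase) -> tuple[dict[int, str], dict[int, str]]:
    chrom_of, arm_of = {}, {}
    for f in db.arm_features():
        chrom_of[f.feature_id] = f.chromosome
        arm_of[f.feature_id] = f.arm
    return chrom_of, arm_of


def assign_contig(
    track: FeatureCallTrack, db: FeatureDatabase, min_fraction: float = 0.5
) -> tuple[str, float]:
    """Chromosome with the most p+q arm calls, or UNPLACED.

    Telomere, centromere, ambiguous, novel, and gap calls are uninformative
    for assignment (the first two are global features). The fraction is
    winner arm calls / all arm calls.
    """
    chrom_of, _ = _arm_info(db)
    counts: dict[str, int] = {c: 0 for c in db.chromosomes}
    fids, n = np.unique(track.calls[track.calls >= 2], return_counts=True)
    for fid, c in zip(fids, n):
        counts[chrom_of[int(fid)]] += int(c)
    informative = sum(counts.values())
    if informative == 0:
        return UNPLACED, 0.0
    best = max(db.chromosomes, key=lambda c: counts[c])
    frac = counts[best] / informative
    if frac < min_fraction:
        return UNPLACED, frac
    return best, frac


def _rank_series(track: FeatureCallTrack, db: FeatureDatabase, chromosome: str):
    """(positions, expected ranks) of p/cen/q calls for one chromosome."""
    chrom_of, arm_of = _arm_info(db)
    ranks = np.full(track.calls.shape, np.nan)
    cen = track.calls == 1
    ranks[cen] = _RANK_CEN
    for fid, chrom in chrom_of.items():
        if chrom != chromosome:
            continue
        sel = track.calls == fid
        ranks[sel] = _RANK_P if arm_of[fid] == "P" else _RANK_Q
    mask = ~np.isnan(ranks)
    return np.nonzero(mask)[0], ranks[mask]


def orient_contig(
    track: FeatureCallTrack, db: FeatureDatabase, chromosome: str | None = None
) -> str:
    """'+' if strand votes agree with the stored reference orientation;
    ties fall back to p->centromere->q positional concordance, then '+'."""
    matches = int(track.strand_match.sum())
    mismatches = int(track.strand_mismatch.sum())
    if matches > mismatches:
        return "+"
    if mismatches > matches:
        return "-"
    if chromosome is None:
        chromosome, _ = assign_contig(track, db)
    if chromosome != UNPLACED:
        pos, ranks = _rank_series(track, db, chromosome)
        if pos.size >= 2:
            slope = np.cov(pos.astype(float), ranks)[0, 1]
            if slope < 0:
                return "-"
    return "+"


def mean_expected_rank(
    track: FeatureCallTrack, db: FeatureDatabase, chromosome: str
) -> float:
    """Mean p/cen/q rank of a contig's calls; 2.0 (mid-chromosome) when the
    contig carries no rank-informative calls."""
    _, ranks = _rank_series(track, db, chromosome)
    if ranks.size == 0:
        return _RANK_CEN
    return float(ranks.mean())


def place_assembly(
    db: FeatureDatabase,
    tracks: list[FeatureCallTrack],
    min_fraction: float = 0.5,
    haplotype_of=None,
) -> list[ContigPlacement]:
    """Assign, orient, and order a set of annotated contigs."""
    placements = []
    chrom_index = {c: i for i, c in enumerate(db.chromosomes)}
    keyed = []
    for track in tracks:
        chrom, frac = assign_contig(track, db, min_fraction)
        orient = orient_contig(track, db, chrom if chrom != UNPLACED else None)
        hap = haplotype_of(track.name) if haplotype_of else ""
        pl = ContigPlacement(track.name, chrom, orient, 0, frac, track.length, hap)
        if chrom == UNPLACED:
            key = (1, 0, 0.0, -track.length, track.name)
        else:
            key = (
                0,
                chrom_index[chrom],
                mean_expected_rank(track, db, chrom),
                -track.length,
                track.name,
            )
        keyed.append((key, pl))
    keyed.sort(key=lambda t: t[0])
    out = []
    for rank, (_, pl) in enumerate(keyed):
        pl.order_rank = rank
        out.append(pl)
    return out


@dataclass
class RenderOptions:
    pixel_bp: int = 250_000
    min_draw_bp: int = 1_000_000
    column_width: int = 16
    column_gap: int = 10
    group_gap: int = 22
    row_px: float = 1.0  # drawn height per pixel row
    margin: int = 40
    label: bool = True


def render_karyogram(
    tracks: list[FeatureCallTrack],
    placements: list[ContigPlacement],
    db: FeatureDatabase,
    options: RenderOptions | None = None,
) -> str:
    """Render a deterministic SVG karyogram.

    Each drawn sequence is one vertical rectangle whose pixel rows follow
    its majority-rule pixel track; sequences shorter than
    ``options.min_draw_bp`` are classified and placed but not drawn.
    Reverse-oriented contigs are drawn flipped.
    """
    opt = options or RenderOptions()
    track_by_name = {t.name: t for t in tracks}
    order = sorted(placements, key=lambda p: p.order_rank)
    drawn = [p for p in order if p.length >= opt.min_draw_bp and p.name in track_by_name]
    if not drawn:
        logger.warning("no sequences pass the %d bp draw filter", opt.min_draw_bp)

    max_pix = 1
    pixel_tracks: dict[str, PixelTrack] = {}
    for p in drawn:
        pt = bin_majority(track_by_name[p.name], opt.pixel_bp)
        pixel_tracks[p.name] = pt
        max_pix = max(max_pix, pt.labels.shape[0])

    height = int(opt.margin * 2 + max_pix * opt.row_px + (30 if opt.label else 0))
    parts: list[str] = []
    x = opt.margin
    prev_group: tuple[str, str] | None = None
    for p in drawn:
        group = (p.chromosome, p.haplotype)
        if prev_group is not None:
            x += opt.group_gap if group != prev_group else opt.column_gap
        prev_group = group
        pt = pixel_tracks[p.name]
        labels = pt.labels if p.orientation == "+" else pt.labels[::-1]
        y = opt.margin
        # merge runs of identical color into single rects to keep the SVG small
        i = 0
        n = labels.shape[0]
        while i < n:
            j = i
            color = pixel_color(int(labels[i]), db)
            while j + 1 < n and pixel_color(int(labels[j + 1]), db) == color:
                j += 1
            h = (j - i + 1) * opt.row_px
            parts.append(
                f'<rect x="{x}" y="{y + i * opt.row_px:.1f}" '
                f'width="{opt.column_width}" height="{h:.1f}" '
                f'fill="{color}" stroke="none"/>'
            )
            i = j + 1
        parts.append(
            f'<rect x="{x}" y="{y}" width="{opt.column_width}" '
            f'height="{n * opt.row_px:.1f}" fill="none" stroke="#404040" '
            f'stroke-width="0.5"/>'
        )
        if opt.label:
            lab = p.chromosome if p.chromosome != UNPLACED else p.name
            if p.haplotype:
                lab = f"{lab}:{p.haplotype}"
            parts.append(
                f'<text x="{x + opt.column_width / 2:.1f}" '
                f'y="{y + n * opt.row_px + 14:.1f}" font-size="9" '
                f'font-family="sans-serif" text-anchor="middle">{lab}</text>'
            )
        x += opt.column_width
    if not drawn:
        parts.append(
            f'<text x="{opt.margin}" y="{opt.margin}" font-size="12" '
            f'font-family="sans-serif">no sequences pass the draw filter '
            f"(min {opt.min_draw_bp} bp); legend: blue=telomere, "
            f"orange=centromere, gray=ambiguous, white=novel</text>"
        )
    width = max(x + opt.margin, 2 * opt.margin + 200)
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">\n'
        f'<rect x="0" y="0" width="{width}" height="{height}" fill="#ffffff"/>\n'
    )
    return head + "\n".join(parts) + "\n</svg>\n"
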