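"""Deterministic synthetic genomes, assemblies, diploids, and read pairs.

The toy reference emulates the structure the karyogram and completeness
modules depend on: each chromosome is telomere array - unique p arm -
centromeric satellite array - unique q arm - telomere array. Telomere
arrays are (TTAGGG)n (reverse-complemented at the 5' terminus, as on a real
forward strand); the centromere is an alpha-satellite-like array of a
single monomer shared across chromosomes, with per-copy mutations so
arrays differ between chromosomes while still mapping to the one global
centromere feature. Arms are random sequence and therefore k-mer-disjoint
across chromosomes (verified at build time), except for optionally injected
shared segmental duplications.

Derived assemblies are built from an explicit event log (splits, telomere
drops, extractions, reverse complements, fusions), so each contig's true
completeness category is known by construction. Diploids add heterozygous
SNVs at a stated per-base rate on the arms, and the read simulator and
scorer stand in for a short-read aligner: per mate and per haplotype the
alignment score is match_score * matches - mismatch_penalty * mismatches at
the read's true locus (defaults 1 and 4).

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._encode import kmer_codes, revcomp, seq_to_codes
from .db import AnnotationInterval, FeatureAnnotation, KaryokitError
from .phasing import HapAlignment, PairAlignmentSummary
from .qc import Category

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(KaryokitError):
    pass


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    codes = seq_to_codes(seq).copy()
    hit = np.nonzero(rng.random(codes.shape[0]) < rate)[0]
    if hit.size:
        codes[hit] = (codes[hit] + rng.integers(1, 4, hit.size)) % 4
    return bytes(_BASES[codes]).decode()


@dataclass(frozen=True)
class ToyGenomeSpec:
    seed: int = 0
    n_chrom: int = 3
    arm_len: tuple[int, int] = (45_000, 55_000)
    telomere_unit: str = "TTAGGG"
    telomere_copies: int = 2_000
    centromere_monomer_len: int = 171
    centromere_copies: int = 400
    monomer_divergence: float = 0.02
    # (length_bp, source arm "chrN_p|q", target arm) segmental duplication
    shared_dup: tuple[int, str, str] | None = None
    acrocentric: tuple[str, ...] = ()
    acro_p_len: int = 6_000

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass(frozen=True)
class ChromLayout:
    tel1_end: int
    cen_start: int
    cen_end: int
    tel2_start: int
    length: int


@dataclass
class ToyReference:
    spec: ToyGenomeSpec
    sequences: dict[str, str]
    annotation: FeatureAnnotation
    layout: dict[str, ChromLayout]


def make_reference(spec: ToyGenomeSpec, k: int = 31, check_unique: bool = True) -> ToyReference:
    """Generate the toy reference and its feature annotation."""
    rng = np.random.default_rng(spec.seed)
    tel_len = len(spec.telomere_unit) * spec.telomere_copies
    monomer = _random_seq(rng, spec.centromere_monomer_len)
    cen_len = spec.centromere_monomer_len * spec.centromere_copies
    if min(spec.arm_len) < 2 * k:
        raise GenerationError(
            f"arms of {min(spec.arm_len)} bp are too short for k={k} uniqueness; "
            "use longer arms"
        )

    seqs: dict[str, str] = {}
    layout: dict[str, ChromLayout] = {}
    intervals: list[AnnotationInterval] = []
    arms: dict[str, str] = {}
    tel_left = revcomp(spec.telomere_unit * spec.telomere_copies)
    tel_right = spec.telomere_unit * spec.telomere_copies
    for name in spec.chrom_names:
        p_len = (
            spec.acro_p_len
            if name in spec.acrocentric
            else int(rng.integers(spec.arm_len[0], spec.arm_len[1] + 1))
        )
        q_len = int(rng.integers(spec.arm_len[0], spec.arm_len[1] + 1))
        p_arm = _random_seq(rng, p_len)
        q_arm = _random_seq(rng, q_len)
        cen = "".join(
            _mutate(rng, monomer, spec.monomer_divergence)
            for _ in range(spec.centromere_copies)
        )
        arms[f"{name}_p"] = p_arm
        arms[f"{name}_q"] = q_arm
        seq = tel_left + p_arm + cen + q_arm + tel_right
        L = len(seq)
        lay = ChromLayout(
            tel1_end=tel_len,
            cen_start=tel_len + p_len,
            cen_end=tel_len + p_len + cen_len,
            tel2_start=L - tel_len,
            length=L,
        )
        seqs[name] = seq
        layout[name] = lay
        intervals += [
            AnnotationInterval(name, 0, lay.tel1_end, "TELOMERE"),
            AnnotationInterval(name, lay.tel1_end, lay.cen_start, "ARM", name, "P"),
            AnnotationInterval(name, lay.cen_start, lay.cen_end, "CENTROMERE"),
            AnnotationInterval(name, lay.cen_end, lay.tel2_start, "ARM", name, "Q"),
            AnnotationInterval(name, lay.tel2_start, L, "TELOMERE"),
        ]

    if spec.shared_dup is not None:
        dup_len, src, dst = spec.shared_dup
        if src not in arms or dst not in arms:
            raise GenerationError(f"unknown arm in shared_dup: {src!r} or {dst!r}")
        if dup_len >= min(len(arms[src]), len(arms[dst])) - 2 * k:
            raise GenerationError("shared_dup longer than its arms allow")
        s_off = int(rng.integers(k, len(arms[src]) - dup_len - k))
        d_off = int(rng.integers(k, len(arms[dst]) - dup_len - k))
        segment = arms[src][s_off : s_off + dup_len]
        dst_chrom, dst_arm = dst.rsplit("_", 1)
        lay = layout[dst_chrom]
        base = lay.tel1_end if dst_arm == "p" else lay.cen_end
        seq = seqs[dst_chrom]
        seqs[dst_chrom] = seq[: base + d_off] + segment + seq[base + d_off + dup_len :]
        arms[dst] = arms[dst][:d_off] + segment + arms[dst][d_off + dup_len :]

    if check_unique and spec.shared_dup is None:
        _check_arm_disjoint(arms, k)
    return ToyReference(spec, seqs, FeatureAnnotation(intervals), layout)


def _check_arm_disjoint(arms: dict[str, str], k: int) -> None:
    codes, owner = [], []
    for i, (name, seq) in enumerate(sorted(arms.items())):
        fwd, rev_, valid = kmer_codes(seq_to_codes(seq), k)
        canon = np.minimum(fwd, rev_)[valid]
        codes.append(np.unique(canon))
        owner.append(np.full(codes[-1].shape, i, dtype=np.int32))
    allc = np.concatenate(codes)
    own = np.concatenate(owner)
    order = np.argsort(allc, kind="stable")
    allc, own = allc[order], own[order]
    dup = (allc[1:] == allc[:-1]) & (own[1:] != own[:-1])
    if dup.any():
        raise GenerationError(
            f"{int(dup.sum())} k-mers shared between arms at k={k}; "
            "use longer arms or a different seed"
        )


# ---------------------------------------------------------------------------
# derived assemblies with truth labels


@dataclass
class SyntheticContig:
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    fused_with: "SyntheticContig | None" = None
    truth: Category | None = None

    def length(self, ref: ToyReference) -> int:
        n = self.end - self.start
        if self.fused_with is not None:
            n += self.fused_with.length(ref)
        return n

    def sequence(self, ref: ToyReference) -> str:
        seq = ref.sequences[self.chrom][self.start : self.end]
        if self.strand == "-":
            seq = revcomp(seq)
        if self.fused_with is not None:
            seq = seq + self.fused_with.sequence(ref)
        return seq


# event vocabulary ----------------------------------------------------------


@dataclass(frozen=True)
class SplitAt:
    contig: str
    pos: int  # relative to the current contig


@dataclass(frozen=True)
class DropTelomere:
    contig: str
    end: str  # "L" | "R"


@dataclass(frozen=True)
class RevComp:
    contig: str


@dataclass(frozen=True)
class Extract:
    contig: str
    start: int
    end: int  # relative, half-open


@dataclass(frozen=True)
class Fuse:
    contig_a: str
    contig_b: str
    name: str = ""


AssemblyEvent = SplitAt | DropTelomere | RevComp | Extract | Fuse

_TRUTH_MARGIN = 500  # bp of a feature required before a terminus counts as flanked


def infer_truth(contig: SyntheticContig, ref: ToyReference) -> Category | None:
    """Completeness category implied by a contig's source coordinates.

    Fusions mix sources and have no defined category (None).
    """
    if contig.fused_with is not None:
        return None
    lay = ref.layout[contig.chrom]
    s, e, m = contig.start, contig.end, _TRUTH_MARGIN
    tel_l = s < lay.tel1_end - m
    tel_r = e > lay.tel2_start + m
    cen_l = lay.cen_start <= s < lay.cen_end - m
    cen_r = lay.cen_start + m < e <= lay.cen_end
    p_bp = max(0, min(e, lay.cen_start) - max(s, lay.tel1_end))
    q_bp = max(0, min(e, lay.tel2_start) - max(s, lay.cen_end))
    cen_bp = max(0, min(e, lay.cen_end) - max(s, lay.cen_start))
    cen_complete = cen_bp >= (lay.cen_end - lay.cen_start) - m

    if tel_l and tel_r:
        return Category.COMPLETE_CHROMOSOME
    if (tel_l != tel_r) and (
        (tel_l and cen_r) or (tel_r and cen_l) or (p_bp > m and q_bp > m and cen_complete)
    ):
        return Category.COMPLETE_ARM
    if s >= lay.cen_start and e <= lay.cen_end:
        return Category.CENTROMERE
    left = tel_l or cen_l
    right = tel_r or cen_r
    if left != right:
        return Category.PARTIAL_ARM
    if not left and not right:
        return Category.MARKER
    return None


def derive_assembly(
    ref: ToyReference, events: Iterable[AssemblyEvent]
) -> list[SyntheticContig]:
    """Apply an event log to the reference chromosomes and return contigs
    with their constructed truth categories."""
    contigs: dict[str, SyntheticContig] = {}
    for name, seq in ref.sequences.items():
        contigs[name] = SyntheticContig(name, name, 0, len(seq))

    def _simple(name: str) -> SyntheticContig:
        c = contigs[name]
        if c.fused_with is not None:
            raise KaryokitError(f"event not supported on fused contig {name}")
        return c

    def _abs(c: SyntheticContig, rel: int) -> int:
        n = c.end - c.start
        if not (0 <= rel <= n):
            raise KaryokitError(f"position {rel} outside contig {c.name} (len {n})")
        return c.start + rel if c.strand == "+" else c.end - rel

    for ev in events:
        if isinstance(ev, SplitAt):
            c = _simple(ev.contig)
            cut = _abs(c, ev.pos)
            lo = SyntheticContig(f"{c.name}.1", c.chrom, c.start, cut, c.strand)
            hi = SyntheticContig(f"{c.name}.2", c.chrom, cut, c.end, c.strand)
            if c.strand == "-":
                lo, hi = (
                    SyntheticContig(f"{c.name}.1", c.chrom, cut, c.end, "-"),
                    SyntheticContig(f"{c.name}.2", c.chrom, c.start, cut, "-"),
                )
            del contigs[c.name]
            contigs[lo.name] = lo
            contigs[hi.name] = hi
        elif isinstance(ev, DropTelomere):
            c = _simple(ev.contig)
            lay = ref.layout[c.chrom]
            left_in_source = (ev.end == "L") == (c.strand == "+")
            if left_in_source:
                c.start = max(c.start, lay.tel1_end)
            else:
                c.end = min(c.end, lay.tel2_start)
        elif isinstance(ev, RevComp):
            c = _simple(ev.contig)
            c.strand = "-" if c.strand == "+" else "+"
        elif isinstance(ev, Extract):
            c = _simple(ev.contig)
            a, b = _abs(c, ev.start), _abs(c, ev.end)
            c.start, c.end = min(a, b), max(a, b)
        elif isinstance(ev, Fuse):
            a = contigs.pop(ev.contig_a)
            b = contigs.pop(ev.contig_b)
            fused = SyntheticContig(
                ev.name or f"{a.name}+{b.name}", a.chrom, a.start, a.end, a.strand, b
            )
            contigs[fused.name] = fused
        else:  # pragma: no cover
            raise KaryokitError(f"unknown event {ev!r}")

    out = []
    for name in sorted(contigs):
        c = contigs[name]
        c.truth = infer_truth(c, ref)
        out.append(c)
    return out


def preset_suite(ref: ToyReference, seed: int = 0) -> list[SyntheticContig]:
    """The standard truth-labeled suite: per chromosome, one contig of each
    of the five completeness categories (plus a second partial arm), with
    randomized cut positions and random orientations."""
    rng = np.random.default_rng(seed)
    contigs: list[SyntheticContig] = []

    def add(name: str, chrom: str, s: int, e: int):
        strand = "+" if rng.random() < 0.5 else "-"
        c = SyntheticContig(name, chrom, s, e, strand)
        c.truth = infer_truth(c, ref)
        contigs.append(c)

    for chrom in ref.spec.chrom_names:
        lay = ref.layout[chrom]
        p_len = lay.cen_start - lay.tel1_end
        q_len = lay.tel2_start - lay.cen_end
        cen_len = lay.cen_end - lay.cen_start
        add(f"{chrom}_full", chrom, 0, lay.length)
        if rng.random() < 0.5:  # drop one telomere: tel-p-cen-q or p-cen-q-tel
            add(f"{chrom}_onearm", chrom, 0, lay.tel2_start)
        else:
            add(f"{chrom}_onearm", chrom, lay.tel1_end, lay.length)
        add(f"{chrom}_cen", chrom, lay.cen_start, lay.cen_end)
        # telomere + partial p
        u = int(p_len * rng.uniform(0.3, 0.8))
        add(f"{chrom}_telp", chrom, 0, lay.tel1_end + u)
        # interior q fragment: marker
        a = lay.cen_end + int(q_len * rng.uniform(0.1, 0.3))
        b = a + int(q_len * rng.uniform(0.3, 0.5))
        add(f"{chrom}_marker", chrom, a, b)
        # partial centromere + partial q
        s = lay.cen_start + int(cen_len * rng.uniform(0.1, 0.3))
        e = lay.cen_end + int(q_len * rng.uniform(0.4, 0.8))
        add(f"{chrom}_cenq", chrom, s, e)
    return contigs


# ---------------------------------------------------------------------------
# diploids and read pairs


@dataclass
class DiploidTruth:
    hap1: dict[str, str]
    hap2: dict[str, str]
    variants: pd.DataFrame  # columns chrom, pos, ref, alt (0-based, on hap1 coords)
    het_rate: float

    def het_positions(self, chrom: str) -> np.ndarray:
        sel = self.variants[self.variants["chrom"] == chrom]
        return sel["pos"].to_numpy(dtype=np.int64)


def make_diploid(ref: ToyReference, het_rate: float, seed: int = 0) -> DiploidTruth:
    """Diploid derivative: hap1 is the reference; hap2 carries heterozygous
    substitutions placed uniformly on the arms (outside telomere/centromere
    annotations) at ``het_rate`` per base. Substitutions only, so the two
    haplotypes stay position-aligned."""
    if not (0.0 <= het_rate <= 0.05):
        raise KaryokitError(f"het_rate must be in [0, 0.05], got {het_rate}")
    rng = np.random.default_rng(seed)
    hap2: dict[str, str] = {}
    rows = []
    for name, seq in ref.sequences.items():
        codes = seq_to_codes(seq).copy()
        eligible = np.zeros(codes.shape[0], dtype=bool)
        for iv in ref.annotation.intervals:
            if iv.seq_name == name and iv.klass == "ARM":
                eligible[iv.start : iv.end] = True
        pos = np.nonzero(eligible & (rng.random(codes.shape[0]) < het_rate))[0]
        for p in pos:
            old = int(codes[p])
            new = (old + int(rng.integers(1, 4))) % 4
            rows.append((name, int(p), "ACGT"[old], "ACGT"[new]))
            codes[p] = new
        hap2[name] = bytes(_BASES[codes]).decode()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return DiploidTruth(dict(ref.sequences), hap2, variants, het_rate)


@dataclass
class SimulatedPair:
    pair_id: str
    hap: int  # truth haplotype (1 or 2)
    chrom: str
    start: int  # fragment start on the haplotype (0-based)
    insert: int
    r1: str  # forward-strand read
    r2: str  # reverse-strand read, stored read-oriented (revcomp of fragment end)
    n_errors: int = 0


def simulate_pairs(
    diploid: DiploidTruth,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: int = 350,
    insert_sd: float = 35.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[SimulatedPair]:
    """Sample read pairs uniformly from a uniformly chosen haplotype."""
    chroms = sorted(diploid.hap1)
    lengths = np.array([len(diploid.hap1[c]) for c in chroms], dtype=np.float64)
    if read_len > insert_mean or insert_mean > lengths.min():
        raise KaryokitError(
            f"infeasible geometry: read_len {read_len} <= insert_mean "
            f"{insert_mean} <= min chromosome length {int(lengths.min())} required"
        )
    rng = np.random.default_rng(seed)
    weights = lengths / lengths.sum()
    pairs = []
    for i in range(n_pairs):
        hap = 1 if rng.random() < 0.5 else 2
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        seq = (diploid.hap1 if hap == 1 else diploid.hap2)[chrom]
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), read_len, len(seq)))
        start = int(rng.integers(0, len(seq) - insert + 1))
        frag = seq[start : start + insert]
        r1, r2 = frag[:read_len], revcomp(frag[-read_len:])
        n_err = 0
        if error_rate > 0:
            r1, e1 = _with_errors(rng, r1, error_rate)
            r2, e2 = _with_errors(rng, r2, error_rate)
            n_err = e1 + e2
        pairs.append(
            SimulatedPair(f"pair{i:06d}", hap, chrom, start, insert, r1, r2, n_err)
        )
    return pairs


def _with_errors(rng: np.random.Generator, read: str, rate: float) -> tuple[str, int]:
    codes = seq_to_codes(read).copy()
    hit = np.nonzero(rng.random(codes.shape[0]) < rate)[0]
    if hit.size:
        codes[hit] = (codes[hit] + rng.integers(1, 4, hit.size)) % 4
    return bytes(_BASES[codes]).decode(), int(hit.size)


def pair_het_overlap(diploid: DiploidTruth, pair: SimulatedPair, read_len: int) -> int:
    """Number of heterozygous sites under either mate of a pair."""
    pos = diploid.het_positions(pair.chrom)
    if pos.size == 0:
        return 0
    w1 = (pair.start, pair.start + read_len)
    w2 = (pair.start + pair.insert - read_len, pair.start + pair.insert)
    n = 0
    for lo, hi in (w1, w2):
        n += int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
    # subtract double-counted overlap of the two windows
    lo, hi = max(w1[0], w2[0]), min(w1[1], w2[1])
    if hi > lo:
        n -= int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
    return n


@dataclass
class ScoredPair:
    pair: SimulatedPair
    as_mate: dict[int, tuple[int, int]]  # hap -> (AS mate1, AS mate2)
    proper: dict[int, bool]


def _score_all(
    pairs: Sequence[SimulatedPair],
    diploid: DiploidTruth,
    match: int = 1,
    mismatch: int = 4,
    proper_floor_frac: float = 0.5,
) -> list[ScoredPair]:
    out = []
    for p in pairs:
        read_len = len(p.r1)
        floor = proper_floor_frac * match * read_len
        r1 = seq_to_codes(p.r1)
        r2f = seq_to_codes(revcomp(p.r2))  # mate 2 back in reference orientation
        as_mate: dict[int, tuple[int, int]] = {}
        proper: dict[int, bool] = {}
        for hap, seqs in ((1, diploid.hap1), (2, diploid.hap2)):
            ref = seqs[p.chrom]
            t1 = seq_to_codes(ref[p.start : p.start + read_len])
            s2 = p.start + p.insert - read_len
            t2 = seq_to_codes(ref[s2 : s2 + read_len])
            mm1 = int((r1 != t1).sum())
            mm2 = int((r2f != t2).sum())
            a1 = match * (read_len - mm1) - mismatch * mm1
            a2 = match * (read_len - mm2) - mismatch * mm2
            as_mate[hap] = (a1, a2)
            proper[hap] = a1 >= floor and a2 >= floor
        out.append(ScoredPair(p, as_mate, proper))
    return out


def score_pairs(
    pairs: Sequence[SimulatedPair],
    diploid: DiploidTruth,
    match: int = 1,
    mismatch: int = 4,
    proper_floor_frac: float = 0.5,
) -> list[PairAlignmentSummary]:
    """Alignment-score summaries for each pair against both haplotypes."""
    out = []
    for sp in _score_all(pairs, diploid, match, mismatch, proper_floor_frac):
        haps = {}
        for hap in (1, 2):
            a1, a2 = sp.as_mate[hap]
            haps[hap] = HapAlignment(
                proper_pair=sp.proper[hap],
                as_sum=a1 + a2,
                refs=(sp.pair.chrom, sp.pair.chrom),
                mapq=(60, 60),
            )
        out.append(PairAlignmentSummary(sp.pair.pair_id, haps[1], haps[2]))
    return out


def write_alignments_sam(
    pairs: Sequence[SimulatedPair],
    diploid: DiploidTruth,
    path_h1: str,
    path_h2: str,
    combined_path: str | None = None,
    match: int = 1,
    mismatch: int = 4,
    proper_floor_frac: float = 0.5,
    seed_note: str = "",
) -> None:
    """Emit minimally valid per-haplotype (and optionally combined) SAM so
    the phasing module's stream path can be exercised end to end.

    In the combined file each mate is placed on its higher-scoring
    haplotype (reference names prefixed ``hap1_``/``hap2_``) with MAPQ 60,
    or on hap1 with MAPQ 0 when the scores tie — emulating an aligner's
    ambiguous placement."""
    import pysam

    scored = _score_all(pairs, diploid, match, mismatch, proper_floor_frac)
    read_len = len(pairs[0].r1) if pairs else 0

    def _header(names_lengths, comment):
        return pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "queryname"},
                "SQ": [{"SN": n, "LN": ln} for n, ln in names_lengths],
                "CO": [comment] if comment else [],
            }
        )

    def _rec(header, name, ref, pos, mate, proper, as_score, seq, mapq=60):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.reference_name = ref
        a.reference_start = pos
        a.mapping_quality = mapq
        flag = 0x1 | (0x40 if mate == 1 else 0x80)
        if proper:
            flag |= 0x2
        flag |= 0x20 if mate == 1 else 0x10
        a.flag = flag
        a.query_sequence = seq
        a.cigarstring = f"{len(seq)}M"
        a.set_tag("AS", as_score)
        return a

    comment = f"karyokit synthetic alignments {seed_note}".strip()
    for hap, path in ((1, path_h1), (2, path_h2)):
        seqs = diploid.hap1 if hap == 1 else diploid.hap2
        header = _header(sorted((c, len(s)) for c, s in seqs.items()), comment)
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            for sp in scored:
                p = sp.pair
                a1, a2 = sp.as_mate[hap]
                s2 = p.start + p.insert - read_len
                fh.write(
                    _rec(header, p.pair_id, p.chrom, p.start, 1, sp.proper[hap], a1, p.r1)
                )
                fh.write(
                    _rec(
                        header, p.pair_id, p.chrom, s2, 2, sp.proper[hap], a2,
                        revcomp(p.r2),
                    )
                )
    if combined_path is None:
        return
    names_lengths = sorted(
        [(f"hap1_{c}", len(s)) for c, s in diploid.hap1.items()]
        + [(f"hap2_{c}", len(s)) for c, s in diploid.hap2.items()]
    )
    header = _header(names_lengths, comment)
    with pysam.AlignmentFile(combined_path, "w", header=header) as fh:
        for sp in scored:
            p = sp.pair
            s2 = p.start + p.insert - read_len
            for mate, pos, seq in ((1, p.start, p.r1), (2, s2, revcomp(p.r2))):
                scores = {h: sp.as_mate[h][mate - 1] for h in (1, 2)}
                if scores[1] == scores[2]:
                    hap, mapq = 1, 0
                else:
                    hap = 1 if scores[1] > scores[2] else 2
                    mapq = 60
                fh.write(
                    _rec(
                        header, p.pair_id, f"hap{hap}_{p.chrom}", pos, mate,
                        sp.proper[hap], scores[hap], seq, mapq,
                    )
                )
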