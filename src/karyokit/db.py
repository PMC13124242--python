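"""K-mer feature databases for alignment-free sequence annotation.

The database maps every canonical k-mer of an annotated reference genome to
a genomic feature: the (single, global) telomere feature, the (single,
global) centromere feature, or one of the chromosome-specific arm features
(e.g. ``chr1_p``). A k-mer whose sequence occurs in two or more distinct
features is stored as AMBIGUOUS. K-mers absent from the database are NOVEL
at query time and represent sequence not present in the reference.

Keys are canonicalized (lexicographic minimum of a k-mer and its reverse
complement) so that reverse-complemented query sequences are still
annotated; a per-key strand tag (FWD/REV/MIXED, the orientation of the
reference occurrence(s) relative to the canonical form) is retained so that
contig orientation can be voted on downstream.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import struct
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import palette
from ._encode import encode_kmer, kmer_codes, seq_to_codes

logger = logging.getLogger(__name__)

# call / payload sentinels shared by the whole package
AMBIGUOUS = -1
NOVEL = -2
GAP = -3

STRAND_FWD = 0
STRAND_REV = 1
STRAND_MIXED = 2

_MAGIC = b"KKDB"
_VERSION = 1

_KLASS_PRIORITY = {"TELOMERE": 3, "CENTROMERE": 2, "ARM": 1}


class KaryokitError(Exception):
    """Base error for this package."""


class AnnotationError(KaryokitError):
    pass


class ParameterError(KaryokitError):
    pass


class FormatError(KaryokitError):
    pass


class CallKind(Enum):
    FEATURE = "feature"
    AMBIGUOUS = "ambiguous"
    NOVEL = "novel"
    INVALID = "invalid"


@dataclass(frozen=True)
class Feature:
    feature_id: int
    name: str
    klass: str  # TELOMERE | CENTROMERE | ARM
    chromosome: str = ""
    arm: str = ""  # P | Q (ARM only)
    color: tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class AnnotationInterval:
    seq_name: str
    start: int
    end: int
    klass: str
    chromosome: str = ""
    arm: str = ""

    def feature_name(self) -> str:
        if self.klass == "TELOMERE":
            return "TEL"
        if self.klass == "CENTROMERE":
            return "CEN"
        return f"{self.chromosome}_{self.arm.lower()}"


@dataclass
class FeatureAnnotation:
    """BED-style feature intervals (0-based, half-open)."""

    intervals: list[AnnotationInterval] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path: str | Path) -> "FeatureAnnotation":
        intervals = []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise FormatError(f"BED line needs 4 columns: {line!r}")
                intervals.append(
                    _interval_from_bed(parts[0], int(parts[1]), int(parts[2]), parts[3])
                )
        return cls(intervals)

    def to_bed(self, path: str | Path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"#{header}\n")
            for iv in self.intervals:
                fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\t{iv.feature_name()}\n")

    def validate(self, seq_lengths: Mapping[str, int]) -> None:
        by_chrom_arms: dict[str, list[AnnotationInterval]] = {}
        for iv in self.intervals:
            if iv.seq_name not in seq_lengths:
                raise AnnotationError(f"interval on unknown sequence {iv.seq_name!r}")
            L = seq_lengths[iv.seq_name]
            if not (0 <= iv.start < iv.end <= L):
                raise AnnotationError(
                    f"interval out of bounds: {iv.seq_name}:{iv.start}-{iv.end} "
                    f"(sequence length {L})"
                )
            if iv.klass == "ARM":
                by_chrom_arms.setdefault(iv.chromosome, []).append(iv)
        for chrom, ivs in by_chrom_arms.items():
            ivs = sorted(ivs, key=lambda v: (v.seq_name, v.start))
            for a, b in zip(ivs, ivs[1:]):
                if a.seq_name == b.seq_name and b.start < a.end:
                    raise AnnotationError(
                        f"overlapping arm intervals on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


def _interval_from_bed(seq_name: str, start: int, end: int, label: str) -> AnnotationInterval:
    if label == "TEL":
        return AnnotationInterval(seq_name, start, end, "TELOMERE")
    if label == "CEN":
        return AnnotationInterval(seq_name, start, end, "CENTROMERE")
    if "_" in label:
        chrom, _, arm = label.rpartition("_")
        if arm.lower() in ("p", "q"):
            return AnnotationInterval(seq_name, start, end, "ARM", chrom, arm.upper())
    raise FormatError(f"unrecognized BED feature label {label!r}")


def _build_feature_table(annotation: FeatureAnnotation) -> tuple[list[Feature], list[str]]:
    """TEL=0, CEN=1, then arm features in order of first appearance."""
    chromosomes: list[str] = []
    arm_names: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for iv in annotation.intervals:
        if iv.klass != "ARM":
            continue
        if iv.chromosome not in chromosomes:
            chromosomes.append(iv.chromosome)
        key = (iv.chromosome, iv.arm)
        if key not in seen:
            seen.add(key)
            arm_names.append(key)
    n_chrom = len(chromosomes)
    features = [
        Feature(0, "TEL", "TELOMERE", color=palette.TELOMERE_COLOR),
        Feature(1, "CEN", "CENTROMERE", color=palette.CENTROMERE_COLOR),
    ]
    for fid, (chrom, arm) in enumerate(arm_names, start=2):
        color = palette.arm_color(chromosomes.index(chrom), n_chrom, arm)
        features.append(Feature(fid, f"{chrom}_{arm.lower()}", "ARM", chrom, arm, color))
    return features, chromosomes


@dataclass
class KmerCall:
    kind: CallKind
    feature_id: int | None = None
    strand_match: bool | None = None  # query orientation vs stored orientation


class FeatureDatabase:
    """Canonical k-mer -> feature payload map with a feature table."""

    def __init__(
        self,
        k: int,
        features: list[Feature],
        chromosomes: list[str],
        keys: np.ndarray,
        payloads: np.ndarray,
        strands: np.ndarray,
    ):
        self.k = k
        self.features = features
        self.chromosomes = chromosomes
        self.keys = keys  # sorted uint64
        self.payloads = payloads  # int32; feature_id or AMBIGUOUS
        self.strands = strands  # int8; FWD/REV/MIXED
        self._by_name = {f.name: f for f in features}

    # -- introspection -------------------------------------------------
    def __len__(self) -> int:
        return int(self.keys.shape[0])

    @property
    def n_features(self) -> int:
        return len(self.features)

    def feature(self, fid: int) -> Feature:
        return self.features[fid]

    def arm_features(self) -> list[Feature]:
        return [f for f in self.features if f.klass == "ARM"]

    def chromosome_of(self, fid: int) -> str:
        return self.features[fid].chromosome

    # -- queries -------------------------------------------------------
    def lookup_codes(self, canon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized membership: (payload, strand) per code; NOVEL if absent."""
        idx = np.searchsorted(self.keys, canon)
        idx_c = np.minimum(idx, max(len(self.keys) - 1, 0))
        if len(self.keys):
            found = self.keys[idx_c] == canon
        else:
            found = np.zeros(canon.shape, dtype=bool)
        payload = np.full(canon.shape, NOVEL, dtype=np.int32)
        strand = np.full(canon.shape, STRAND_MIXED, dtype=np.int8)
        payload[found] = self.payloads[idx_c[found]]
        strand[found] = self.strands[idx_c[found]]
        return payload, strand

    def lookup(self, kmer: str) -> KmerCall:
        if len(kmer) != self.k:
            raise ParameterError(f"k-mer length {len(kmer)} != database k {self.k}")
        code = encode_kmer(kmer)
        if code is None:
            return KmerCall(CallKind.INVALID)
        from ._encode import revcomp_code

        rc = revcomp_code(code, self.k)
        canon = min(code, rc)
        query_fwd = code <= rc
        payload, strand = self.lookup_codes(np.array([canon], dtype=np.uint64))
        p, s = int(payload[0]), int(strand[0])
        if p == NOVEL:
            return KmerCall(CallKind.NOVEL)
        match: bool | None = None
        if s != STRAND_MIXED:
            match = query_fwd == (s == STRAND_FWD)
        if p == AMBIGUOUS:
            return KmerCall(CallKind.AMBIGUOUS, strand_match=match)
        return KmerCall(CallKind.FEATURE, feature_id=p, strand_match=match)

    # -- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        header = {
            "k": self.k,
            "chromosomes": self.chromosomes,
            "features": [
                {
                    "feature_id": f.feature_id,
                    "name": f.name,
                    "klass": f.klass,
                    "chromosome": f.chromosome,
                    "arm": f.arm,
                    "color": list(f.color),
                }
                for f in self.features
            ],
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<H", _VERSION))
            fh.write(struct.pack("<Q", len(blob)))
            fh.write(blob)
            fh.write(struct.pack("<Q", len(self.keys)))
            fh.write(self.keys.astype("<u8").tobytes())
            fh.write(self.payloads.astype("<i4").tobytes())
            fh.write(self.strands.astype("i1").tobytes())

    @classmethod
    def load(cls, path: str | Path) -> "FeatureDatabase":
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != _MAGIC:
                raise FormatError(f"not a feature database (bad magic {magic!r})")
            (version,) = struct.unpack("<H", _read_exact(fh, 2))
            if version != _VERSION:
                raise FormatError(f"unsupported database version {version}")
            (blob_len,) = struct.unpack("<Q", _read_exact(fh, 8))
            header = json.loads(_read_exact(fh, blob_len))
            (n,) = struct.unpack("<Q", _read_exact(fh, 8))
            keys = np.frombuffer(_read_exact(fh, 8 * n), dtype="<u8").astype(np.uint64)
            payloads = np.frombuffer(_read_exact(fh, 4 * n), dtype="<i4").astype(np.int32)
            strands = np.frombuffer(_read_exact(fh, n), dtype="i1").astype(np.int8)
        features = [
            Feature(
                d["feature_id"], d["name"], d["klass"], d["chromosome"], d["arm"],
                tuple(d["color"]),
            )
            for d in header["features"]
        ]
        return cls(header["k"], features, header["chromosomes"], keys, payloads, strands)


def _read_exact(fh: io.BufferedReader, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IOError(f"truncated database file: wanted {n} bytes, got {len(data)}")
    return data


def build_feature_db(
    reference: Mapping[str, str] | Iterable[tuple[str, str]],
    annotation: FeatureAnnotation,
    k: int = 31,
) -> FeatureDatabase:
    """Build the canonical k-mer -> feature database from an annotated reference.

    Every ACGT-only k-mer whose window overlaps an annotated interval is
    stored once under its canonical code. A window overlapping intervals of
    several classes at one locus resolves by precedence
    TELOMERE > CENTROMERE > ARM (ties between two arm intervals resolve to
    the smaller feature id). A k-mer sequence occurring in two or more
    distinct resolved features is AMBIGUOUS.
    """
    if not (3 <= k <= 31) or k % 2 == 0:
        raise ParameterError(f"k must be odd and in [3, 31], got {k}")
    seqs = dict(reference.items() if isinstance(reference, Mapping) else reference)
    if not seqs:
        raise KaryokitError("empty reference: no sequences")
    annotation.validate({name: len(s) for name, s in seqs.items()})

    features, chromosomes = _build_feature_table(annotation)
    fid_of = {f.name: f.feature_id for f in features}

    all_canon: list[np.ndarray] = []
    all_fid: list[np.ndarray] = []
    all_fwd: list[np.ndarray] = []
    total_windows = 0
    covered_windows = 0
    for name, seq in seqs.items():
        ivs = [iv for iv in annotation.intervals if iv.seq_name == name]
        L = len(seq)
        m = L - k + 1
        if m <= 0:
            continue
        total_windows += m
        if not ivs:
            logger.warning("sequence %s has no annotation; its k-mers are excluded", name)
            continue
        # per-position packed key: priority(2b) then inverted feature id, so a
        # window max picks highest-priority, then lowest-feature-id interval
        key = np.zeros(L, dtype=np.uint32)
        for iv in ivs:
            fid = fid_of[iv.feature_name()]
            packed = np.uint32((_KLASS_PRIORITY[iv.klass] << 20) | (0xFFFFF - fid))
            np.maximum(key[iv.start : iv.end], packed, out=key[iv.start : iv.end])
        win_key = np.lib.stride_tricks.sliding_window_view(key, k).max(axis=1)
        fwd, rev, valid = kmer_codes(seq_to_codes(seq), k)
        keep = valid & (win_key != 0)
        covered_windows += int(keep.sum())
        wfid = (0xFFFFF - (win_key[keep] & 0xFFFFF)).astype(np.int32)
        canon = np.minimum(fwd[keep], rev[keep])
        all_canon.append(canon)
        all_fid.append(wfid)
        all_fwd.append(fwd[keep] <= rev[keep])

    if total_windows:
        uncovered = 1.0 - covered_windows / total_windows
        if uncovered > 0:
            logger.warning(
                "%.2f%% of reference k-mer windows are unannotated and excluded",
                100.0 * uncovered,
            )

    if not all_canon:
        keys = np.empty(0, dtype=np.uint64)
        payloads = np.empty(0, dtype=np.int32)
        strands = np.empty(0, dtype=np.int8)
        return FeatureDatabase(k, features, chromosomes, keys, payloads, strands)

    canon = np.concatenate(all_canon)
    fid = np.concatenate(all_fid)
    is_fwd = np.concatenate(all_fwd)

    order = np.argsort(canon, kind="stable")
    canon, fid, is_fwd = canon[order], fid[order], is_fwd[order]
    keys, starts = np.unique(canon, return_index=True)
    fid_min = np.minimum.reduceat(fid, starts)
    fid_max = np.maximum.reduceat(fid, starts)
    fwd_any = np.bitwise_or.reduceat(is_fwd, starts)
    rev_any = np.bitwise_or.reduceat(~is_fwd, starts)

    payloads = np.where(fid_min == fid_max, fid_min, AMBIGUOUS).astype(np.int32)
    strands = np.full(keys.shape, STRAND_MIXED, dtype=np.int8)
    strands[fwd_any & ~rev_any] = STRAND_FWD
    strands[~fwd_any & rev_any] = STRAND_REV
    return FeatureDatabase(k, features, chromosomes, keys, payloads, strands)
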