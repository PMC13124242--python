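"""Structural completeness classification and contiguity statistics.

Every contig or scaffold is placed in exactly one of five structural
categories based on its k-mer feature call track:

* ``COMPLETE_CHROMOSOME`` — telomeric sequence at both termini
  (telomere-to-telomere).
* ``COMPLETE_ARM`` — at least one complete arm: one terminus telomeric and
  the opposite flank centromeric, or a p-centromere-q span missing a single
  telomere.
* ``CENTROMERE`` — (almost) entirely centromeric sequence.
* ``PARTIAL_ARM`` — arm-specific sequence flanked on exactly one side by
  telomeric or centromeric sequence.
* ``MARKER`` — arm-specific sequence with neither flank telomeric nor
  centromeric.

Contiguity statistics are computed against an expected genome size G:
NG(x) is the maximum length L* such that sequences of length >= L* together
cover at least x% of G, LG(x) the number of sequences used, and
auN = sum(L_i^2) / sum(L_i), the area under the Nx curve, which does not
depend on G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .db import GAP, FeatureDatabase, KaryokitError, ParameterError
from .karyogram import UNPLACED, FeatureCallTrack, assign_contig


class Category(Enum):
    COMPLETE_CHROMOSOME = "complete_chromosome"
    COMPLETE_ARM = "complete_arm"
    PARTIAL_ARM = "partial_arm"
    CENTROMERE = "centromere"
    MARKER = "marker"


class ClassificationError(KaryokitError):
    pass


@dataclass
class ClassifyParams:
    """Thresholds of the completeness cascade (bp counts are in k-mer calls,
    which approximate bases for k << contig length)."""

    terminal_window_bp: int = 10_000  # cap on the terminal window
    terminal_window_frac: float = 0.05  # ... or 5% of contig length if smaller
    tel_frac: float = 0.5  # telomeric terminus: >=50% telomere calls
    cen_frac: float = 0.5  # centromeric flank: >=50% centromere calls
    cen_pure_frac: float = 0.9  # 'entirely centromeric' threshold
    cen_min_bp: int = 50_000  # centromere presence for p-cen-q spans
    min_assign_fraction: float = 0.5  # arm-specificity threshold


@dataclass
class Evidence:
    tel_start: bool
    tel_end: bool
    cen_start: bool
    cen_end: bool
    centromere_fraction: float
    centromere_bp: int
    dominant_chromosome: str
    assignment_fraction: float
    dominant_arm_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class CompletenessCall:
    name: str
    category: Category
    evidence: Evidence


def _flank_fraction(calls: np.ndarray, fid: int, window: int, end: str) -> float:
    win = calls[:window] if end == "start" else calls[-window:]
    informative = win[win != GAP]
    if informative.size == 0:
        return 0.0
    return float((informative == fid).sum() / informative.size)


def classify_contig(
    track: FeatureCallTrack,
    db: FeatureDatabase,
    params: ClassifyParams | None = None,
) -> CompletenessCall:
    """Classify one contig into the five-category completeness scheme.

    The cascade is evaluated in order and the first match wins:
    complete chromosome > complete arm > centromere > partial arm > marker.
    Scaffold gap (N-run) calls are neutral: they never count toward a
    feature and are excluded from fraction denominators.
    """
    p = params or ClassifyParams()
    calls = track.calls
    if calls.size == 0:
        raise ClassificationError(f"empty call track for {track.name}")

    w = max(1, min(p.terminal_window_bp, int(p.terminal_window_frac * calls.size)))
    tel_start = _flank_fraction(calls, 0, w, "start") >= p.tel_frac
    tel_end = _flank_fraction(calls, 0, w, "end") >= p.tel_frac
    cen_start = _flank_fraction(calls, 1, w, "start") >= p.cen_frac
    cen_end = _flank_fraction(calls, 1, w, "end") >= p.cen_frac

    non_gap = calls[calls != GAP]
    cen_bp = int((non_gap == 1).sum())
    cen_fraction = cen_bp / non_gap.size if non_gap.size else 0.0

    chrom, frac = assign_contig(track, db, p.min_assign_fraction)
    arm_specific = chrom != UNPLACED

    arm_fracs: dict[str, float] = {}
    if chrom != UNPLACED:
        arm_calls = calls[calls >= 2]
        for f in db.arm_features():
            if f.chromosome == chrom and arm_calls.size:
                arm_fracs[f.name] = float((arm_calls == f.feature_id).sum() / arm_calls.size)
    has_p = any(n.endswith("_p") and v > 0 for n, v in arm_fracs.items())
    has_q = any(n.endswith("_q") and v > 0 for n, v in arm_fracs.items())
    spans_pcq = has_p and has_q and cen_bp >= p.cen_min_bp

    evidence = Evidence(
        tel_start, tel_end, cen_start, cen_end, cen_fraction, cen_bp, chrom, frac, arm_fracs
    )

    if tel_start and tel_end:
        cat = Category.COMPLETE_CHROMOSOME
    elif (tel_start != tel_end) and (
        (tel_start and cen_end) or (tel_end and cen_start) or spans_pcq
    ):
        cat = Category.COMPLETE_ARM
    elif cen_fraction >= p.cen_pure_frac:
        cat = Category.CENTROMERE
    elif arm_specific and (
        (tel_start or cen_start) != (tel_end or cen_end)
    ):
        cat = Category.PARTIAL_ARM
    else:
        # arm-specific with no flanks, or residual contigs with no feature
        # evidence at all: marker
        cat = Category.MARKER
    return CompletenessCall(track.name, cat, evidence)


@dataclass
class ContiguityStats:
    """NGx/LGx curves, NG50/LG50, and auN for one set of sequence lengths."""

    lengths: np.ndarray  # sorted descending
    genome_size: int
    total_bp: int
    aun: float

    @classmethod
    def from_lengths(cls, lengths: Sequence[int], genome_size: int) -> "ContiguityStats":
        arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
        if arr.size == 0:
            raise ParameterError("lengths must be non-empty")
        if (arr <= 0).any():
            raise ParameterError("all lengths must be positive")
        if genome_size <= 0:
            raise ParameterError(f"genome size must be positive, got {genome_size}")
        return cls(arr, int(genome_size), int(arr.sum()), aun(arr))

    def ng(self, x: float) -> tuple[int, int, bool]:
        """(NG(x), LG(x), defined). NG(x) is the length of the sequence at
        which the descending cumulative sum first reaches x% of G; when the
        total is short of x% of G the value is undefined and reported as
        (0, 0, False)."""
        target = self.genome_size * x / 100.0
        if target <= 0:
            return int(self.lengths[0]), 1, True
        cum = np.cumsum(self.lengths)
        if cum[-1] < target:
            return 0, 0, False
        i = int(np.searchsorted(cum, target, side="left"))
        return int(self.lengths[i]), i + 1, True

    @property
    def ng50(self) -> int:
        return self.ng(50)[0]

    @property
    def lg50(self) -> int:
        return self.ng(50)[1]

    def curve(self, xs: Sequence[float] | None = None):
        """NGx/LGx table as a pandas DataFrame (columns x, ng, lg, defined)."""
        import pandas as pd

        if xs is None:
            xs = np.arange(0, 101, 1)
        rows = []
        for x in xs:
            ngx, lgx, ok = self.ng(float(x))
            rows.append((float(x), ngx, lgx, ok))
        return pd.DataFrame(rows, columns=["x", "ng", "lg", "defined"])


def aun(lengths: Sequence[int]) -> float:
    """Area under the Nx curve: sum(L^2) / sum(L). Independent of any
    expected genome size."""
    arr = np.asarray(lengths, dtype=np.float64)
    if arr.size == 0:
        raise ParameterError("lengths must be non-empty")
    return float((arr * arr).sum() / arr.sum())


def ngx_curve(lengths: Sequence[int], genome_size: int) -> ContiguityStats:
    return ContiguityStats.from_lengths(lengths, genome_size)
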