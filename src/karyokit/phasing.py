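"""Short-read pair phasing against a diploid assembly.

Two procedures:

* Alignment-score (AS) phasing: read pairs are aligned separately to each
  haplotype; the summed AS of mate 1 and mate 2 is compared between
  haplotypes and each pair falls into exactly one of five mutually
  exclusive groups — not properly mapped, sex chromosome, hap1, hap2, or
  homozygous (equal summed AS).
* Mapping-quality phasing: read pairs aligned to the combined diploid
  assembly are phased when both mates map to the same haplotype with
  MAPQ >= a threshold (default 10), otherwise unphased.

A diagnostic compares the concordant distribution (summed AS on the
assigned haplotype) with the discordant distribution (summed AS of the same
pairs on the other haplotype): two-parameter exponential fits and a
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .db import KaryokitError

logger = logging.getLogger(__name__)


class PhaseGroup(Enum):
    NOT_PROPERLY_MAPPED = "not_properly_mapped"
    SEX_CHROMOSOME = "sex_chromosome"
    HAP1 = "hap1"
    HAP2 = "hap2"
    HOMOZYGOUS = "homozygous"


class MapqPhase(Enum):
    HAP1 = "hap1"
    HAP2 = "hap2"
    UNPHASED = "unphased"


@dataclass
class HapAlignment:
    """One pair's alignment evidence against one haplotype."""

    proper_pair: bool = False
    as_sum: int | None = None  # defined only when both mates align with AS
    refs: tuple[str | None, str | None] = (None, None)
    mapq: tuple[int | None, int | None] = (None, None)


@dataclass
class PairAlignmentSummary:
    pair_id: str
    hap1: HapAlignment
    hap2: HapAlignment

    def hap(self, h: int) -> HapAlignment:
        return self.hap1 if h == 1 else self.hap2


def _collate_stream(records) -> dict[str, dict[int, object]]:
    """Read name -> {1: mate1 record, 2: mate2 record}, primary only."""
    pairs: dict[str, dict[int, object]] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            continue
        mate = 1 if rec.is_read1 else 2
        pairs.setdefault(rec.query_name, {})[mate] = rec
    return pairs


def _hap_from_mates(mates: dict[int, object]) -> HapAlignment:
    refs: list[str | None] = [None, None]
    mapqs: list[int | None] = [None, None]
    scores: list[int | None] = [None, None]
    proper_flags = []
    for mate in (1, 2):
        rec = mates.get(mate)
        if rec is None or rec.is_unmapped:
            proper_flags.append(False)
            continue
        if not rec.has_tag("AS"):
            logger.warning(
                "aligned record %s mate %d lacks AS tag; treated as unaligned",
                rec.query_name, mate,
            )
            proper_flags.append(False)
            continue
        refs[mate - 1] = rec.reference_name
        mapqs[mate - 1] = rec.mapping_quality
        scores[mate - 1] = int(rec.get_tag("AS"))
        proper_flags.append(bool(rec.is_proper_pair))
    proper = len(proper_flags) == 2 and all(proper_flags) and None not in scores
    as_sum = None
    if scores[0] is not None and scores[1] is not None:
        as_sum = scores[0] + scores[1]
    return HapAlignment(proper, as_sum, tuple(refs), tuple(mapqs))


def _open_sam(source):
    import pysam

    if isinstance(source, (str, Path)):
        return pysam.AlignmentFile(str(source), check_sq=False)
    return source


def summarize_pairs(alignments_h1, alignments_h2) -> list[PairAlignmentSummary]:
    """Collate two per-haplotype SAM/BAM streams into per-pair summaries.

    ``alignments_h1``/``alignments_h2`` may be paths or iterables of pysam
    records. Read names seen with only a single mate in every stream are
    excluded with a warning.
    """
    streams = []
    for src in (alignments_h1, alignments_h2):
        opened = isinstance(src, (str, Path))
        fh = _open_sam(src)
        streams.append(_collate_stream(fh))
        if opened:
            fh.close()
    h1, h2 = streams
    names = sorted(set(h1) | set(h2))
    out = []
    for name in names:
        m1, m2 = h1.get(name, {}), h2.get(name, {})
        if len(m1) < 2 and len(m2) < 2:
            logger.warning("read %s is unpaired in both streams; excluded", name)
            continue
        out.append(PairAlignmentSummary(name, _hap_from_mates(m1), _hap_from_mates(m2)))
    return out


def phase_pair_as(
    summary: PairAlignmentSummary, sex_refs: frozenset[str] | set[str] = frozenset()
) -> PhaseGroup:
    """Five-group AS-based assignment for one pair.

    Evaluation order: not properly mapped on either haplotype; any mate on
    a sex-chromosome reference; proper on exactly one haplotype (assigned
    to it); equal summed AS (homozygous); higher summed AS wins.
    """
    h1, h2 = summary.hap1, summary.hap2
    if not h1.proper_pair and not h2.proper_pair:
        return PhaseGroup.NOT_PROPERLY_MAPPED
    for hap in (h1, h2):
        if any(r in sex_refs for r in hap.refs if r is not None):
            return PhaseGroup.SEX_CHROMOSOME
    if h1.proper_pair != h2.proper_pair:
        return PhaseGroup.HAP1 if h1.proper_pair else PhaseGroup.HAP2
    if h1.as_sum == h2.as_sum:
        return PhaseGroup.HOMOZYGOUS
    return PhaseGroup.HAP1 if h1.as_sum > h2.as_sum else PhaseGroup.HAP2


def phase_pairs_as(
    summaries: Iterable[PairAlignmentSummary],
    sex_refs: frozenset[str] | set[str] = frozenset(),
) -> dict[str, PhaseGroup]:
    return {s.pair_id: phase_pair_as(s, sex_refs) for s in summaries}


def default_hap_of_ref(ref: str) -> int:
    """Haplotype attribution for combined-assembly reference names using the
    'hap1_'/'hap2_' prefix convention."""
    if ref.startswith("hap1_"):
        return 1
    if ref.startswith("hap2_"):
        return 2
    raise KaryokitError(f"cannot attribute reference {ref!r} to a haplotype")


def phase_pair_mapq(
    refs: Sequence[str | None],
    mapqs: Sequence[int | None],
    threshold: int = 10,
    hap_of_ref=default_hap_of_ref,
) -> MapqPhase:
    """MAPQ-based phasing of one pair aligned to the combined assembly:
    both mates on one haplotype with MAPQ >= threshold, else unphased."""
    if len(refs) != 2 or len(mapqs) != 2:
        raise KaryokitError("expected exactly two mates")
    if any(r is None or q is None for r, q in zip(refs, mapqs)):
        return MapqPhase.UNPHASED
    haps = {hap_of_ref(r) for r in refs}
    if len(haps) != 1:
        return MapqPhase.UNPHASED
    if min(mapqs) < threshold:
        return MapqPhase.UNPHASED
    return MapqPhase.HAP1 if haps.pop() == 1 else MapqPhase.HAP2


def phase_stream_mapq(
    combined, threshold: int = 10, hap_of_ref=default_hap_of_ref
) -> dict[str, MapqPhase]:
    """MAPQ phasing over a combined-assembly SAM/BAM stream."""
    opened = isinstance(combined, (str, Path))
    fh = _open_sam(combined)
    pairs = _collate_stream(fh)
    if opened:
        fh.close()
    out = {}
    for name, mates in sorted(pairs.items()):
        refs: list[str | None] = [None, None]
        mapqs: list[int | None] = [None, None]
        for mate in (1, 2):
            rec = mates.get(mate)
            if rec is not None and not rec.is_unmapped:
                refs[mate - 1] = rec.reference_name
                mapqs[mate - 1] = rec.mapping_quality
        out[name] = phase_pair_mapq(refs, mapqs, threshold, hap_of_ref)
    return out


# ---------------------------------------------------------------------------
# distribution diagnostics


def ks_2sample_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic: supremum gap between the two ECDFs."""
    a = np.sort(np.asarray(a, dtype=np.float64))
    b = np.sort(np.asarray(b, dtype=np.float64))
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def ks_2sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(D, asymptotic p) with effective n = n1*n2/(n1+n2) and the Kolmogorov
    survival function."""
    d = ks_2sample_d(a, b)
    ne = len(a) * len(b) / (len(a) + len(b))
    p = float(special.kolmogorov(np.sqrt(ne) * d))
    return d, min(max(p, 0.0), 1.0)


def fit_exponential(sample: np.ndarray) -> tuple[float, float]:
    """Two-parameter exponential maximum-likelihood fit:
    location = sample minimum, scale = mean - minimum."""
    arr = np.asarray(sample, dtype=np.float64)
    if arr.size == 0:
        raise KaryokitError("cannot fit an exponential to an empty sample")
    loc = float(arr.min())
    return loc, float(arr.mean() - loc)


@dataclass
class ASDistributionComparison:
    concordant: np.ndarray
    discordant: np.ndarray
    median_concordant: float
    median_discordant: float
    fit_concordant: tuple[float, float]  # (location, scale)
    fit_discordant: tuple[float, float]
    ks_d: float
    ks_p: float


def compare_as_distributions(
    assignments: Mapping[str, PhaseGroup],
    summaries: Iterable[PairAlignmentSummary],
) -> ASDistributionComparison:
    """Concordant vs discordant summed-AS distributions over phased pairs.

    Only pairs assigned hap1/hap2 with a summed AS on both haplotypes
    contribute; the concordant value is the pair's AS on its assigned
    haplotype and the discordant value its AS on the other, so the two
    samples are equal-sized by construction.
    """
    conc, disc = [], []
    for s in summaries:
        group = assignments.get(s.pair_id)
        if group not in (PhaseGroup.HAP1, PhaseGroup.HAP2):
            continue
        if s.hap1.as_sum is None or s.hap2.as_sum is None:
            continue
        if group is PhaseGroup.HAP1:
            conc.append(s.hap1.as_sum)
            disc.append(s.hap2.as_sum)
        else:
            conc.append(s.hap2.as_sum)
            disc.append(s.hap1.as_sum)
    if len(conc) < 2:
        raise KaryokitError(
            f"need >=2 phased pairs with AS on both haplotypes, got {len(conc)}"
        )
    conc_arr = np.asarray(conc, dtype=np.float64)
    disc_arr = np.asarray(disc, dtype=np.float64)
    d, p = ks_2sample(conc_arr, disc_arr)
    return ASDistributionComparison(
        conc_arr,
        disc_arr,
        float(np.median(conc_arr)),
        float(np.median(disc_arr)),
        fit_exponential(conc_arr),
        fit_exponential(disc_arr),
        d,
        p,
    )


@dataclass
class PhaseSummary:
    counts: dict[PhaseGroup, int]
    total: int
    phased_fraction: float


def phase_summary(assignments: Mapping[str, PhaseGroup]) -> PhaseSummary:
    """Per-group counts and the phased fraction (hap1+hap2)/total."""
    counts = {g: 0 for g in PhaseGroup}
    for g in assignments.values():
        counts[g] += 1
    total = len(assignments)
    phased = counts[PhaseGroup.HAP1] + counts[PhaseGroup.HAP2]
    return PhaseSummary(counts, total, phased / total if total else 0.0)
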