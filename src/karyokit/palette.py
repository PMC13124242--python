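"""Fixed color semantics for karyogram rendering.

Telomere is blue, centromere orange, ambiguous gray, novel/gap white.
Each chromosome gets a distinct hue; its p arm is drawn at 60% of the q
arm's saturation so the two arms of one chromosome read as light/dark
shades of the same color.
"""

from __future__ import annotations

import colorsys

RGB = tuple[int, int, int]

TELOMERE_COLOR: RGB = (0, 80, 255)
CENTROMERE_COLOR: RGB = (255, 140, 0)
AMBIGUOUS_COLOR: RGB = (150, 150, 150)
NOVEL_COLOR: RGB = (255, 255, 255)

_Q_SAT = 0.85
_P_SAT_SCALE = 0.6
_VAL = 0.82


def chromosome_hue(index: int, n_chrom: int) -> float:
    n = max(n_chrom, 1)
    # golden-angle-free even spacing; deterministic in (index, n)
    return (index % n) / n


def arm_color(index: int, n_chrom: int, arm: str) -> RGB:
    """Color of arm 'P' or 'Q' of the index-th chromosome (of n_chrom)."""
    hue = chromosome_hue(index, n_chrom)
    sat = _Q_SAT if arm.upper() == "Q" else _Q_SAT * _P_SAT_SCALE
    r, g, b = colorsys.hsv_to_rgb(hue, sat, _VAL)
    return (int(round(r * 255)), int(round(g * 255)), int(round(b * 255)))


def to_hex(rgb: RGB) -> str:
    return "#%02x%02x%02x" % rgb
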