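"""Color scales and the 768-row lookup table mapping values to RGB.

A :class:`ColorScale` is an ordered list of RGB anchor colors.  The default
tricolor runs green -> black -> red, the microarray convention for
down-regulated -> unchanged -> up-regulated expression.  :func:`build_lut`
discretizes the gradient into exactly 768 rows (a 256-level color mode times
three anchors) by piecewise-linear interpolation in RGB space: the 767
inter-row steps are divided as evenly as possible among the segments between
consecutive anchors, remainder steps going to the earlier segments.
A normalized value in [0, 1] selects its nearest LUT row (round half up).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np

from .errors import DomainError, ValidationError

#: Total number of discretization levels in a lookup table.
LUT_ROWS = 768

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class ColorScale:
    """Ordered RGB anchor colors; each channel an integer in 0..255."""

    anchors: tuple[RGB, ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValidationError("a color scale needs at least one anchor")
        for a in self.anchors:
            if len(a) != 3 or any(not (0 <= ch <= 255) for ch in a):
                raise ValidationError(f"invalid RGB anchor {a!r}: channels must be 0..255")
        object.__setattr__(self, "anchors", tuple(tuple(int(c) for c in a) for a in self.anchors))


#: Green -> black -> red, the classic expression-heatmap tricolor.
DEFAULT_TRICOLOR = ColorScale(((0, 255, 0), (0, 0, 0), (255, 0, 0)))


@dataclass
class ColorLUT:
    """A (768, 3) integer matrix; row 0 is the first anchor, row 767 the last."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        if self.rows.shape != (LUT_ROWS, 3):
            raise ValidationError(
                f"a color LUT must be {LUT_ROWS}x3, got {self.rows.shape}"
            )


def _round_half_up(x: float) -> int:
    return floor(x + 0.5)


def build_lut(scale: ColorScale) -> ColorLUT:
    """Discretize ``scale`` into the 768x3 lookup matrix.

    With ``s`` segments between consecutive anchors, the 767 steps are split
    as ``767 // s`` each plus one extra for the first ``767 % s`` segments.
    Channel values are rounded half up.  Anchor colors land exactly on their
    boundary rows.
    """
    if len(scale.anchors) < 2:
        raise ValidationError(
            f"building a LUT needs at least 2 anchors, got {len(scale.anchors)}"
        )
    n_seg = len(scale.anchors) - 1
    base, rem = divmod(LUT_ROWS - 1, n_seg)
    rows = np.empty((LUT_ROWS, 3), dtype=int)
    rows[0] = scale.anchors[0]
    pos = 0
    for s in range(n_seg):
        steps = base + (1 if s < rem else 0)
        a = scale.anchors[s]
        b = scale.anchors[s + 1]
        for t in range(1, steps + 1):
            frac = t / steps
            rows[pos + t] = [
                _round_half_up(a[ch] + (b[ch] - a[ch]) * frac) for ch in range(3)
            ]
        pos += steps
    return ColorLUT(rows)


def map_value(nv: float, lut: ColorLUT) -> RGB:
    """Return the LUT row nearest to ``nv`` in [0, 1] (round half up)."""
    if not (0.0 <= nv <= 1.0):
        raise DomainError(f"normalized value {nv!r} outside [0, 1]")
    idx = _round_half_up(nv * (LUT_ROWS - 1))
    return tuple(int(c) for c in lut.rows[idx])


def parse_hex_colors(text: str) -> ColorScale:
    """Parse a comma-separated list of ``#RRGGBB`` hex triplets."""
    anchors = []
    for tok in text.split(","):
        tok = tok.strip().lstrip("#")
        if len(tok) != 6:
            raise ValidationError(f"bad hex color {tok!r}: expected RRGGBB")
        try:
            anchors.append(tuple(int(tok[i : i + 2], 16) for i in (0, 2, 4)))
        except ValueError:
            raise ValidationError(f"bad hex color {tok!r}") from None
    return ColorScale(tuple(anchors))
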