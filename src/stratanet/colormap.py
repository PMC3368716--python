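"""Per-layer color encoding of time-course values.

Node values map linearly onto a two-endpoint gradient anchored at each
layer's own (min, max) over the whole time course — layers are never pooled,
since different layers may measure incomparable quantities.  A value of
exactly zero, or a missing value, is drawn grey ("absolute zero": no signal,
or no measurement).  Similarity-score bins (0..10) use a separate
white-to-red ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model_io import LayerStats

__all__ = [
    "RGB",
    "ColorScale",
    "YELLOW_BLUE",
    "COLORBLIND_SAFE",
    "value_to_color",
    "score_to_color",
    "rgb_to_hex",
]

RGB = tuple[int, int, int]

GREY: RGB = (128, 128, 128)
WHITE: RGB = (255, 255, 255)
RED: RGB = (255, 0, 0)

#: values within this distance of 0 count as "absolute zero" and draw grey
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ColorScale:
    """Two-endpoint gradient with a dedicated zero/missing color.

    ``low_color`` is the endpoint at the layer minimum and ``high_color`` at
    the maximum; ``reversed=True`` swaps them (published figure conventions
    differ on which end is yellow, so the orientation is configurable).
    ``colorblind_safe`` marks the preset built from a diverging blue-orange
    pair instead of yellow-blue.
    """

    low_color: RGB = (255, 255, 0)
    high_color: RGB = (0, 0, 255)
    zero_color: RGB = GREY
    reversed: bool = False
    colorblind_safe: bool = False

    def __post_init__(self) -> None:
        for c in (self.low_color, self.high_color, self.zero_color):
            if not all(0 <= x <= 255 for x in c):
                raise ValueError(f"RGB components out of [0, 255]: {c}")
        if self.low_color == self.high_color:
            raise ValueError("gradient endpoints must be distinct")

    @property
    def endpoints(self) -> tuple[RGB, RGB]:
        """(color at min, color at max) after applying orientation."""
        if self.reversed:
            return self.high_color, self.low_color
        return self.low_color, self.high_color


#: default: yellow at the layer minimum, blue at the maximum
YELLOW_BLUE = ColorScale()

#: Okabe-Ito blue/orange diverging pair, safe for common color blindness
COLORBLIND_SAFE = ColorScale(
    low_color=(0, 114, 178), high_color=(230, 159, 0), colorblind_safe=True
)


def _lerp(a: RGB, b: RGB, s: float) -> RGB:
    return tuple(round(a[i] + s * (b[i] - a[i])) for i in range(3))  # type: ignore[return-value]


def value_to_color(
    value: float | None,
    stats: LayerStats,
    scale: ColorScale = YELLOW_BLUE,
    tolerance: float = 1e-9,
) -> RGB:
    """Map one value to a color using its layer's (min, max) anchors.

    Linear interpolation between the scale endpoints over
    ``[stats.min_value, stats.max_value]``.  Exactly-zero or missing values
    return the zero color regardless of where zero falls in the range.  A
    constant layer (min == max) maps every value to the low endpoint.  Values
    outside the range by more than ``tolerance`` (relative to the span, or
    absolute for a degenerate span) indicate stale stats and raise.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return scale.zero_color
    if abs(value) <= ZERO_TOL:
        return scale.zero_color
    lo, hi = stats.min_value, stats.max_value
    span = hi - lo
    slack = tolerance * max(span, 1.0)
    if value < lo - slack or value > hi + slack:
        raise ValueError(
            f"value {value} outside layer range [{lo}, {hi}]; "
            "stats are stale — recompute layer_stats"
        )
    low_end, high_end = scale.endpoints
    if span == 0:
        return low_end
    s = min(1.0, max(0.0, (value - lo) / span))
    return _lerp(low_end, high_end, s)


def score_to_color(bin: int) -> RGB:
    """Color for a similarity-score bin: 0 → white, 10 → red, linear between."""
    if not isinstance(bin, (int,)) or isinstance(bin, bool):
        raise ValueError(f"bin must be an integer, got {bin!r}")
    if not 0 <= bin <= 10:
        raise ValueError(f"bin {bin} outside 0..10")
    return _lerp(WHITE, RED, bin / 10)


def rgb_to_hex(color: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)
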