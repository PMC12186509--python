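"""Currency rounding helpers.

All model arithmetic is carried out in floats at full precision; rounding
happens only at reporting boundaries.  Dollar amounts round half away from
zero to whole dollars ("half-up" in the accounting sense), which is what
printed budget tables use; Python's built-in banker's rounding would
disagree on exact .5 cases.
"""

from __future__ import annotations

import math


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to *ndigits* decimals, ties away from zero.

    >>> round_half_up(2.5)
    3.0
    >>> round_half_up(-2.5)
    -3.0
    """
    scale = 10.0**ndigits
    scaled = x * scale
    # nudge by one ulp so values that are conceptually exact halves but sit
    # a hair below due to float representation still round up
    return math.copysign(math.floor(abs(scaled) + 0.5 + 1e-9), scaled) / scale


def dollars(x: float) -> int:
    """Round a dollar amount to a whole-dollar int, half away from zero."""
    return int(round_half_up(x))


def percent(x: float) -> int:
    """Round a percentage to the nearest integer, half away from zero."""
    return int(round_half_up(x))
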