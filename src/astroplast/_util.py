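"""Small shared helpers: deterministic rounding and text formatting."""

from __future__ import annotations

import math

#: printf-style format used for every float written to delimited text.
#: 9 significant digits keeps outputs diffable and bit-stable across runs.
FLOAT_FMT = "%.9g"


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1).

    Used wherever a duration in seconds is converted to a sample count, so
    that the conversion is platform-independent (banker's rounding is not).
    """
    return int(math.floor(x + 0.5))


def fmt_float(x: float) -> str:
    return FLOAT_FMT % x


def check_finite(name: str, value: float, allow_inf: bool = False) -> None:
    if isinstance(value, bool) or value is None:
        raise ValueError(f"{name} must be a finite number, got {value!r}")
    if math.isnan(value):
        raise ValueError(f"{name} is NaN")
    if not allow_inf and math.isinf(value):
        raise ValueError(f"{name} is non-finite ({value})")
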