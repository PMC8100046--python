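"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x):
    """Round to nearest integer with halves going up (0.5 -> 1, 1.5 -> 2).

    This is the single rounding convention used everywhere a real value is
    quantized to an 8-bit intensity or a pixel index.  ``np.round`` rounds
    halves to even and would silently change boundary cases.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def round_half_up_int(x) -> int:
    return int(round_half_up(x))
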