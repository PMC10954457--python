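"""Closed-form layout geometry shared by renderers and tests.

Tests assert on these data-space quantities (and on the layout reports
built from them), never on rendered pixels.
"""

from __future__ import annotations

import numpy as np

from ..errors import AnalysisError

#: pairing-probability arcs are binned into discrete colour classes
PAIRPROB_BINS = ((0.8, 1.01, "prob>=0.8"), (0.6, 0.8, "0.6-0.8"),
                 (0.3, 0.6, "0.3-0.6"), (0.1, 0.3, "0.1-0.3"))


def arc_geometry(i: int, j: int) -> tuple[float, float]:
    """Semicircle for a pair (i, j): center (i+j)/2, radius (j-i)/2."""
    if i >= j:
        raise AnalysisError(f"arc needs i < j, got ({i}, {j})")
    return (i + j) / 2.0, (j - i) / 2.0


def circle_position(k: int, n: int, radius: float = 1.0) -> tuple[float, float]:
    """Nucleotide k (1-based) of an n-nt circle plot: angle 2*pi*k/n."""
    theta = 2.0 * np.pi * k / n
    return radius * np.cos(theta), radius * np.sin(theta)


def probability_bin(p: float) -> str | None:
    for lo, hi, label in PAIRPROB_BINS:
        if lo <= p < hi:
            return label
    return None


def color_class(value: float, breakpoints: tuple[float, float]) -> int:
    """Pure 3-way classification of a value by (low, high) breakpoints."""
    lo, hi = breakpoints
    if not np.isfinite(value):
        return -1
    if value < lo:
        return 0
    if value < hi:
        return 1
    return 2
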