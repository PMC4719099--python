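"""Highest-density intervals of posterior sample arrays.

The HDI is the *shortest* interval containing a given posterior mass; every
value inside has higher (empirical) density than any value outside, unlike
the equal-tailed quantile interval, which can be wider for skewed
posteriors.
"""

from __future__ import annotations

import math

import numpy as np


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval over the sorted draws containing ``mass`` of them.

    The interval spans ``ceil(mass * n)`` consecutive order statistics; ties
    in width are broken toward the smallest lower bound.  Requires at least
    100 draws — fewer cannot summarize a posterior tail meaningfully.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need at least 100 draws, got {n}")
    if np.isnan(x).any():
        raise ValueError("draws contain NaN")
    m = math.ceil(mass * n)
    if m >= n:
        raise ValueError(f"{n} draws cannot resolve a {mass:.4g} interval")
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum = smallest lower bound
    return float(x[i]), float(x[i + m - 1])
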