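"""Small shared statistics helpers."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


def ci95(values: Sequence[float]) -> tuple[float, float]:
    """Normal-approximation 95% CI for the mean: mean +/- 1.96 * SD/sqrt(n).

    A single value yields the degenerate interval (v, v).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ci95 requires at least one value")
    m = float(v.mean())
    if v.size == 1:
        return (m, m)
    se = float(v.std(ddof=1)) / math.sqrt(v.size)
    return (m - 1.96 * se, m + 1.96 * se)


def ci95_bootstrap(
    values: Sequence[float], n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for the mean (alternative to ``ci95``)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ci95_bootstrap requires at least one value")
    if v.size == 1:
        return (float(v[0]), float(v[0]))
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return (float(lo), float(hi))
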