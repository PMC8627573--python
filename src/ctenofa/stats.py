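"""Shared statistical utilities."""

from __future__ import annotations

import numpy as np

__all__ = ["holm_adjust"]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment controlling the familywise error rate.

    Sort p-values ascending, multiply the i-th smallest (1-based) by
    (m - i + 1), enforce a running maximum so adjusted values are monotone
    in the raw ordering, cap at 1, and restore the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out
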