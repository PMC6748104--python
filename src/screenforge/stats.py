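"""Shared count statistics: one-sided Fisher enrichment and BH step-up FDR.

Both screen arms reduce to a 2x2 enrichment question per feature plus a
multiple-testing correction, so the primitives live here rather than in
either pipeline.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

__all__ = ["fisher_enrichment", "fisher_enrichment_vec", "bh_adjust"]


def fisher_enrichment(a: int, A: int, b: int, B: int) -> float:
    """One-sided Fisher exact p for enrichment of a feature in the selected pool.

    The 2x2 table is [[a, A - a], [b, B - b]]: ``a`` of ``A`` selected-pool
    insertions fall in the feature, ``b`` of ``B`` control-pool insertions do.
    The alternative is enrichment in the selected pool (upper tail).

    Under the margins, a ~ Hypergeom(M=A+B, K=a+b, n=A), and the one-sided
    Fisher p equals P(X >= a).
    """
    a, A, b, B = int(a), int(A), int(b), int(B)
    if min(a, b) < 0 or a > A or b > B:
        raise ValueError(f"invalid 2x2 table: a={a}, A={A}, b={b}, B={B}")
    if A < 1 or B < 1:
        raise ValueError("both pool totals must be >= 1")
    # sf can underflow to exactly 0 for extreme tables; keep p in (0, 1]
    return float(max(hypergeom.sf(a - 1, A + B, a + b, A),
                     np.finfo(float).tiny))


def fisher_enrichment_vec(a, b, A: int, B: int) -> np.ndarray:
    """Vectorized `fisher_enrichment` over per-gene counts with shared totals."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(a > A) or np.any(b > B):
        raise ValueError("counts outside [0, total]")
    return np.maximum(hypergeom.sf(a - 1, A + B, a + b, A),
                      np.finfo(float).tiny)


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1 and mapped back to
    input order.  ``m`` defaults to the number of tests; a larger universe can
    be supplied when only a subset of an m-test family was actually computed.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    n = p.size
    if n == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = n
    if m < n:
        raise ValueError("universe m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
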