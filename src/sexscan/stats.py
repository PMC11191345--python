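"""Shared statistical primitives: BH step-up FDR and one-sided enrichment tails."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted p-values,
    mapped back to the input order. NaNs propagate.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = ranked
    q[ok] = out
    return q


def enrichment_pvalue(n_hit: int, n_drawn: int, n_marked: int, n_total: int) -> float:
    """One-sided (greater) Fisher p for a 2x2 enrichment table.

    P(X >= n_hit) with X ~ Hypergeom(N=n_total, K=n_marked, n=n_drawn):
    the chance of drawing at least ``n_hit`` marked genes in a window of
    ``n_drawn`` genes from a universe of ``n_total`` containing
    ``n_marked`` marked genes. Equals the one-sided Fisher exact test on
    [[hit, drawn-hit], [marked-hit, total-marked-drawn+hit]].
    """
    if n_drawn == 0 or n_marked == 0:
        return 1.0
    return float(_st.hypergeom.sf(n_hit - 1, n_total, n_marked, n_drawn))
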