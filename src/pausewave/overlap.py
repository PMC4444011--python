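"""Treatment-concordance statistics on reactive gene sets.

Given the reactive sets of two treatments over a declared gene universe, the
stage reports the 2x2 Venn partition, a Fisher exact enrichment p-value for
the overlap, the overlap fraction |A n B| / |A|, and the squared Pearson
correlation of the two treatments' corrected log2 fold changes over the
shared genes.  The Fisher test is computed from hypergeometric tail sums in
log space (log-factorials), so it stays exact for universes of tens of
thousands of genes where naive factorials overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "overlap_table",
    "fisher_exact",
    "hypergeom_tail_all",
    "pearson_r2",
    "concordance",
]


@dataclass
class OverlapResult:
    """Venn partition and concordance statistics over a gene universe."""

    both: int
    a_only: int
    b_only: int
    neither: int
    overlap_fraction: float
    fisher_p: float | None = None
    pearson_r2: float | None = None
    alternative: str = "greater"

    @property
    def universe_size(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.both, self.a_only, self.b_only, self.neither)

    def to_dict(self) -> dict:
        return {
            "both": self.both,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "neither": self.neither,
            "universe": self.universe_size,
            "overlap_fraction": self.overlap_fraction,
            "fisher_p": self.fisher_p,
            "pearson_r2": self.pearson_r2,
            "alternative": self.alternative,
        }


def overlap_table(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Exact 2x2 partition of the universe by membership in A and B.

    Both sets must be subsets of the universe; offenders are listed.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ValueError(
            f"{len(stray)} set member(s) outside the declared universe, "
            f"e.g. {sorted(stray)[:5]}"
        )
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(u) - both - a_only - b_only
    frac = both / len(a) if a else 0.0
    return OverlapResult(both=both, a_only=a_only, b_only=b_only,
                         neither=neither, overlap_fraction=frac)


def _log_pmf(k: np.ndarray, n_total: int, n_a: int, n_b: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N=n_total, K=n_a, n=n_b)."""

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return (
        log_choose(n_a, k)
        + log_choose(n_total - n_a, n_b - k)
        - log_choose(n_total, n_b)
    )


def fisher_exact(
    cells: Sequence[int] | np.ndarray, alternative: str = "greater"
) -> float:
    """Fisher exact test on a 2x2 table ``[[both, a_only], [b_only, neither]]``.

    The hypergeometric tail is summed in log space.  ``greater`` sums
    P(X >= both) at fixed margins (enrichment of the overlap); ``two-sided``
    sums all tables whose point probability does not exceed the observed
    one's (with the usual 1+1e-7 relative guard against ties lost to
    rounding).  A zero margin makes the table degenerate: p = 1 with a
    logged note.
    """
    table = np.asarray(cells, dtype=np.int64).reshape(2, 2)
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    both, a_only = table[0]
    b_only, neither = table[1]
    n_total = int(table.sum())
    n_a = int(both + a_only)
    n_b = int(both + b_only)
    margins = (n_a, n_total - n_a, n_b, n_total - n_b)
    if 0 in margins:
        logger.info("degenerate margins %s; Fisher p = 1", margins)
        return 1.0
    k_min = max(0, n_a + n_b - n_total)
    k_max = min(n_a, n_b)
    ks = np.arange(k_min, k_max + 1)
    logp = _log_pmf(ks, n_total, n_a, n_b)
    if alternative == "greater":
        tail = logp[ks >= both]
        p = float(np.exp(logsumexp(tail)))
    elif alternative == "two-sided":
        log_obs = logp[both - k_min]
        mask = logp <= log_obs + np.log1p(1e-7)
        p = float(np.exp(logsumexp(logp[mask])))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return min(p, 1.0)


def hypergeom_tail_all(n_total: int, n_a: int, n_b: int) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """One-sided (greater) p-values for every feasible overlap count.

    Returns ``(ks, p)`` where ``p[i] = P(X >= ks[i])`` over the full
    hypergeometric support at the given margins — the whole family of
    enrichment p-values for one universe/set-size configuration.
    """
    k_min = max(0, n_a + n_b - n_total)
    k_max = min(n_a, n_b)
    ks = np.arange(k_min, k_max + 1)
    pmf = np.exp(_log_pmf(ks, n_total, n_a, n_b))
    sf = np.cumsum(pmf[::-1])[::-1]
    return ks, np.minimum(sf, 1.0)


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    universe: Iterable[str],
    *,
    threshold: float = 1.0,
    use_corrected: bool = True,
    alternative: str = "greater",
    r2_min_raw_l2fc: float | None = 1.0,
) -> OverlapResult:
    """End-to-end concordance of two contrasts' reactive gene sets.

    ``table_a``/``table_b`` are expression tables (see
    :func:`pausewave.expression.build_expression_table`) for the two
    treatments against the same mock.  Reactive sets are called at
    ``threshold``, restricted to the universe, partitioned, Fisher-tested,
    and the corrected log2 fold changes of the shared genes are correlated.
    The correlation considers only shared genes with a raw |log2 FC| of at
    least ``r2_min_raw_l2fc`` in both contrasts (default: 2-fold), so genes
    admitted to the sets purely through the low-expression correction do not
    dilute the concordance estimate with counting noise; pass ``None`` to
    correlate every shared gene.
    """
    from .expression import call_reactive_genes

    u = set(universe)
    set_a = set(call_reactive_genes(table_a, threshold,
                                    use_corrected=use_corrected).index) & u
    set_b = set(call_reactive_genes(table_b, threshold,
                                    use_corrected=use_corrected).index) & u
    res = overlap_table(set_a, set_b, u)
    res.alternative = alternative
    res.fisher_p = fisher_exact(
        [[res.both, res.a_only], [res.b_only, res.neither]], alternative
    )
    shared = sorted(set_a & set_b)
    if r2_min_raw_l2fc is not None:
        shared = [
            g
            for g in shared
            if abs(table_a.loc[g, "l2fc"]) >= r2_min_raw_l2fc
            and abs(table_b.loc[g, "l2fc"]) >= r2_min_raw_l2fc
        ]
    if len(shared) >= 3:
        col = "corrected_l2fc" if use_corrected else "l2fc"
        try:
            res.pearson_r2 = pearson_r2(
                table_a.loc[shared, col], table_b.loc[shared, col]
            )
        except ValueError:
            res.pearson_r2 = None
    return res
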