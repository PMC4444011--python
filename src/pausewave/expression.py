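"""Expression quantification and reactive-gene calling.

The stage computes per-gene RPKM (reads per kilobase of exonic model per
million uniquely mapped reads), rescales library composition with TMM
(trimmed mean of M-values) factors, and scores each treatment-vs-mock
contrast with a *corrected* log2 fold change:

    corrected_l2fc = sign(l2fc) * (|l2fc| + gamma^-(exp - offset))

where ``exp`` is the base-10 log of the average expression of the two
samples in the contrast (RPKM, floored with a pseudo-value) and ``gamma > 1``
controls how fast the correction decays with expression.  The additive term
lets genuinely responding but weakly expressed genes clear a fold-change
threshold; it vanishes for well-expressed genes.  By default the correction
is applied symmetrically to the magnitude so that up- and down-regulation
are treated alike; ``literal=True`` reproduces the asymmetric form in which
a positive correction is added to the signed log fold change directly.

A gene is called *reactive* in a contrast when its absolute (corrected)
log2 fold change meets the threshold; the default threshold of 1 is the
2-fold criterion.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "compute_rpkm",
    "tmm_factors",
    "corrected_l2fc",
    "build_expression_table",
    "call_reactive_genes",
    "expressed_universe",
]

PSEUDO_RPKM = 0.1


def compute_rpkm(cm: CountMatrix, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Genes x samples RPKM: count / (exonic kb) / (library size in millions).

    Every counted gene must have a model with positive exonic length; the
    raw, unscaled library sizes are used (TMM rescaling is applied
    downstream where requested).
    """
    length = {g.gene_id: g.exonic_length for g in genes}
    missing = [gid for gid in cm.gene_ids if gid not in length]
    if missing:
        raise ValueError(
            f"{len(missing)} counted gene(s) lack a gene model, e.g. "
            f"{missing[:5]}"
        )
    if (cm.library_sizes == 0).any():
        raise ValueError("zero library size")
    kb = np.array([length[g] / 1000.0 for g in cm.gene_ids])
    if (kb <= 0).any():
        raise ValueError("gene model with non-positive exonic length")
    millions = cm.library_sizes / 1e6
    rpkm = cm.counts / kb[:, None] / millions[None, :]
    return pd.DataFrame(rpkm, index=cm.gene_ids, columns=cm.sample_ids)


def _quantile_per_sample(counts: np.ndarray, lib: np.ndarray, p: float = 0.75
                         ) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference.

    Genes zero in either sample are dropped; the extreme 30% of M-values
    (each tail) and 5% of A-values are trimmed; the factor is 2 to the
    precision-weighted mean of the surviving M-values, with weights from the
    binomial delta method.
    """
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError(
            "no genes expressed in both samples; cannot compute a TMM factor"
        )
    o = obs[keep].astype(float)
    r = ref[keep].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not sel.any():
        raise ValueError(
            "no genes survive TMM trimming; use smaller trim fractions"
        )
    f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(2.0**f)


def tmm_factors(
    cm: CountMatrix,
    reference_sample: str | None = None,
    *,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    When no reference is named, the sample whose upper-quartile abundance is
    closest to the mean upper quartile is chosen.  Dividing each library size
    by its factor gives the composition-corrected effective library size.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.library_sizes.astype(float)
    if reference_sample is None:
        f75 = _quantile_per_sample(cm.counts, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = cm.sample_ids.index(reference_sample)
    ref = cm.counts[:, ref_idx]
    if not (ref > 0).any():
        raise ValueError("reference sample has no nonzero counts")
    factors = np.array(
        [
            _tmm_pair(cm.counts[:, j], ref, lib[j], lib[ref_idx],
                      logratio_trim, sum_trim)
            for j in range(cm.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids, name="tmm_factor")


def corrected_l2fc(
    fc,
    exp_term,
    gamma: float = 5.0,
    offset: float = 0.0,
    *,
    literal: bool = False,
):
    """Low-expression-corrected log2 fold change.

    ``fc`` is the (pseudo-floored) fold change, ``exp_term`` the base-10 log
    of average expression.  The correction magnitude is
    ``gamma**-(exp_term - offset)``; by default it inflates ``|l2fc|`` with
    the sign restored (sign of an exactly null fold change is taken as
    positive), while ``literal=True`` adds it to the signed value.
    """
    fc = np.asarray(fc, dtype=float)
    exp_term = np.asarray(exp_term, dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold change must be > 0 (floor with pseudo-values)")
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    l2fc = np.log2(fc)
    correction = gamma ** -(exp_term - offset)
    if literal:
        out = l2fc + correction
    else:
        sign = np.where(l2fc < 0, -1.0, 1.0)
        out = sign * (np.abs(l2fc) + correction)
    return out if out.ndim else float(out)


def build_expression_table(
    cm: CountMatrix,
    genes: Sequence[GeneModel],
    treated: str,
    mock: str,
    *,
    gamma: float = 5.0,
    offset: float = 0.0,
    pseudo_rpkm: float = PSEUDO_RPKM,
    use_tmm: bool = True,
    literal_formula: bool = False,
) -> pd.DataFrame:
    """Per-gene expression table for one treatment-vs-mock contrast.

    Columns: ``rpkm_mock``, ``rpkm_treated`` (TMM-rescaled when requested),
    ``exp_term`` (log10 of the contrast-average RPKM, floored at the pseudo
    value), ``l2fc`` (on pseudo-floored RPKM) and ``corrected_l2fc``.  TMM
    factors and settings are carried in ``DataFrame.attrs``.
    """
    rpkm = compute_rpkm(cm, genes)
    factors = None
    if use_tmm and cm.n_samples >= 2:
        factors = tmm_factors(cm)
        rpkm = rpkm / factors  # effective library size = N * factor
    for name in (treated, mock):
        if name not in rpkm.columns:
            raise ValueError(f"sample {name!r} not in count matrix")
    rt = rpkm[treated].to_numpy()
    rm = rpkm[mock].to_numpy()
    fc = (rt + pseudo_rpkm) / (rm + pseudo_rpkm)
    exp_term = np.log10(np.maximum((rt + rm) / 2.0, pseudo_rpkm))
    l2fc = np.log2(fc)
    corr = corrected_l2fc(fc, exp_term, gamma, offset, literal=literal_formula)
    table = pd.DataFrame(
        {
            "rpkm_mock": rm,
            "rpkm_treated": rt,
            "exp_term": exp_term,
            "l2fc": l2fc,
            "corrected_l2fc": corr,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    table.attrs.update(
        contrast=(treated, mock),
        gamma=gamma,
        offset=offset,
        pseudo_rpkm=pseudo_rpkm,
        literal_formula=literal_formula,
        tmm_factors=None if factors is None else dict(factors),
    )
    return table


def call_reactive_genes(
    table: pd.DataFrame,
    threshold: float = 1.0,
    *,
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Genes whose |(corrected) log2 fold change| meets ``threshold``.

    Returns the reactive subset of the table with a ``direction`` column
    (up/down, by the sign of the raw log2 fold change; an exactly null
    change counts as up, matching the correction's sign policy).
    """
    if table.empty:
        return table.assign(direction=pd.Series(dtype=object))
    stat = table["corrected_l2fc"] if use_corrected else table["l2fc"]
    hits = table[np.abs(stat) >= threshold].copy()
    hits["direction"] = np.where(hits["l2fc"] < 0, "down", "up")
    return hits


def expressed_universe(
    cm: CountMatrix,
    genes: Sequence[GeneModel],
    floor: float = PSEUDO_RPKM,
) -> set[str]:
    """Default gene universe for overlap statistics: genes whose RPKM
    reaches the pseudo-floor in every sample."""
    rpkm = compute_rpkm(cm, genes)
    keep = (rpkm >= floor).all(axis=1)
    return set(rpkm.index[keep])
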