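"""Multiple-testing thresholds for the phenome scan.

Implements the rank-based 5% false-discovery-rate rule used to call
findings in the scan — ``P_t(rank) = alpha * rank / n`` where *rank* is the
largest rank position whose p-value falls below its own threshold — the
Bonferroni threshold ``alpha / n``, and quantile-quantile plot data with
both reference lines attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ThresholdResult", "bonferroni_threshold", "fdr_rank_threshold",
           "qq_data"]

logger = logging.getLogger(__name__)


@dataclass
class ThresholdResult:
    """Thresholds and the significant sets they induce."""

    n_tests: int
    alpha: float
    bonferroni_threshold: float
    fdr_threshold: float
    fdr_rank: int
    significant_fdr: list = field(default_factory=list)
    significant_bonferroni: list = field(default_factory=list)

    def __post_init__(self):
        assert 0 <= self.fdr_rank <= self.n_tests
        # the FDR threshold can never undercut Bonferroni when any test passes
        if self.fdr_rank > 0:
            assert self.fdr_threshold >= self.bonferroni_threshold - 1e-300

    def summary(self) -> str:
        return (
            f"n_tests={self.n_tests}  alpha={self.alpha}\n"
            f"Bonferroni threshold: {self.bonferroni_threshold:.3g} "
            f"({len(self.significant_bonferroni)} significant)\n"
            f"FDR threshold:        {self.fdr_threshold:.3g} "
            f"(rank {self.fdr_rank}, {len(self.significant_fdr)} significant)"
        )


def bonferroni_threshold(n: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return alpha / n


def fdr_rank_threshold(pvalues, alpha: float = 0.05,
                       field_ids=None, strict: bool = True) -> ThresholdResult:
    """Rank-based FDR threshold over a set of scan p-values.

    P-values are sorted ascending; the FDR rank is the largest position k
    with ``p_(k) < alpha * k / n`` (strict inequality by default), and the
    threshold is ``P_t = alpha * rank / n``.  Final set membership uses
    ``p <= P_t``.  This is the step-up construction, so every
    Bonferroni-significant test is also FDR-significant.

    Parameters
    ----------
    pvalues : array-like of p-values in [0, 1]
    alpha : target false discovery rate
    field_ids : optional labels aligned with ``pvalues``; defaults to indices
    strict : use ``<`` in the rank rule (default) rather than ``<=``
    """
    p = np.asarray(pvalues, float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if field_ids is None:
        field_ids = list(range(n))
    field_ids = list(field_ids)
    if len(field_ids) != n:
        raise ValueError("field_ids must align with pvalues")

    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, n + 1)
    crit = alpha * ranks / n
    passing = p_sorted < crit if strict else p_sorted <= crit
    fdr_rank = int(ranks[passing][-1]) if passing.any() else 0
    p_t = alpha * fdr_rank / n

    bonf = bonferroni_threshold(n, alpha)
    sig_fdr = [fid for fid, pv in zip(field_ids, p) if pv <= p_t]
    sig_bonf = [fid for fid, pv in zip(field_ids, p) if pv <= bonf]
    return ThresholdResult(n_tests=n, alpha=alpha, bonferroni_threshold=bonf,
                           fdr_threshold=p_t, fdr_rank=fdr_rank,
                           significant_fdr=sig_fdr,
                           significant_bonferroni=sig_bonf)


def qq_data(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    The i-th smallest p-value is paired with the uniform quantile
    ``(i - 0.5) / n``.  Zero p-values are floored at the smallest positive
    double and logged.  The returned frame carries the Bonferroni and FDR
    reference lines as attributes (``.attrs``).
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("%d zero p-values floored at %g", n_zero,
                       np.finfo(float).tiny)
        p = np.maximum(p, np.finfo(float).tiny)
    n = p.size
    p_sorted = np.sort(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    out = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(p_sorted),
    })
    thr = fdr_rank_threshold(p, alpha=alpha)
    out.attrs["bonferroni_line"] = -np.log10(thr.bonferroni_threshold)
    out.attrs["fdr_line"] = (-np.log10(thr.fdr_threshold)
                             if thr.fdr_threshold > 0 else np.nan)
    return out
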