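"""Two-sample Mendelian randomization on harmonized summary statistics.

Given per-SNP associations with the exposure (beta_x, se_x) from one GWAS
and with the outcome (beta_y, se_y) from another, estimates the causal
effect of the exposure by the inverse-variance-weighted (IVW) method,
MR-Egger regression (whose intercept indexes unbalanced horizontal
pleiotropy), the weighted median, and simple/weighted mode-based methods,
plus the single-instrument Wald ratio.

Reporting convention: the exposure is age at natural menopause in years and
estimates are reported per year *decrease* by default (``per_decrease``),
matching a score that counts ANM-decreasing alleles; the per-year-increase
scale is available by flag.  Flipping the exposure direction negates slopes
and leaves the Egger intercept (an average direct effect on the outcome)
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "SummaryStatsPair",
    "MREstimate",
    "TwoSampleMR",
    "TwoSampleMRResults",
    "harmonize",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_based",
]

logger = logging.getLogger(__name__)

Z95 = st.norm.ppf(0.975)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
#: palindromic SNPs with frequency in this band cannot be aligned by eaf
PALINDROMIC_EAF_BAND = (0.42, 0.58)


@dataclass
class SummaryStatsPair:
    """Harmonized per-SNP exposure/outcome association record.

    Both betas refer to the same effect allele; ``beta_x`` is in years of
    exposure per allele, ``beta_y`` in outcome units per allele.
    """

    snp: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    effect_allele: str = "A"
    other_allele: str = "G"
    eaf: float = np.nan

    def __post_init__(self):
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(f"{self.snp}: standard errors must be positive")


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    q_stat: float | None = None
    note: str = ""

    def __post_init__(self):
        if np.isfinite(self.ci_low) and np.isfinite(self.ci_high):
            assert self.ci_low <= self.estimate <= self.ci_high

    def summary(self) -> str:
        s = (f"{self.method}: {self.estimate:.4g} "
             f"(95% CI {self.ci_low:.4g}, {self.ci_high:.4g}; "
             f"SE {self.se:.3g}; p={self.pvalue:.3g}; n={self.n_snps})")
        if self.intercept is not None:
            s += (f"\n  intercept {self.intercept:.4g} "
                  f"(SE {self.intercept_se:.3g}; p={self.intercept_pvalue:.3g})")
        return s


def _as_arrays(pairs):
    pairs = list(pairs)
    bx = np.array([p.beta_x for p in pairs], float)
    sx = np.array([p.se_x for p in pairs], float)
    by = np.array([p.beta_y for p in pairs], float)
    sy = np.array([p.se_y for p in pairs], float)
    return bx, sx, by, sy


def _finalize(method, theta, se, n_snps, per_decrease, pvalue=None,
              **extra) -> MREstimate:
    """Assemble an MREstimate, flipping the slope sign for per-year-decrease."""
    if per_decrease:
        theta = -theta
    lo, hi = theta - Z95 * se, theta + Z95 * se
    if pvalue is None:
        pvalue = 2.0 * st.norm.sf(abs(theta) / se) if se > 0 else np.nan
    return MREstimate(method=method, estimate=float(theta), se=float(se),
                      ci_low=float(lo), ci_high=float(hi),
                      pvalue=float(pvalue), n_snps=n_snps, **extra)


# ---------------------------------------------------------------------------
# harmonization

def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC


def harmonize(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame):
    """Align outcome summary statistics to the exposure's effect alleles.

    SNPs are matched by id.  Swapped effect/other alleles flip the outcome
    beta and complement its frequency; strand flips (complement alleles) are
    resolved silently.  Strand-ambiguous (A/T, C/G) SNPs with frequency in
    (0.42, 0.58) in either source are excluded, as are unmatched SNPs and
    irreconcilable allele pairs.

    Returns
    -------
    pairs : list of SummaryStatsPair
    exclusions : list of (snp, reason) tuples
    """
    exc: list[tuple[str, str]] = []
    out_by_snp = {str(r.snp): r for r in outcome_stats.itertuples()}
    pairs = []
    for e in exposure_stats.itertuples():
        snp = str(e.snp)
        o = out_by_snp.get(snp)
        if o is None:
            exc.append((snp, "not_in_outcome"))
            continue
        ea_x, oa_x = str(e.effect_allele).upper(), str(e.other_allele).upper()
        ea_y, oa_y = str(o.effect_allele).upper(), str(o.other_allele).upper()
        eaf_x = float(getattr(e, "eaf", np.nan))
        eaf_y = float(getattr(o, "eaf", np.nan))

        if _is_palindromic(ea_x, oa_x) or _is_palindromic(ea_y, oa_y):
            lo, hi = PALINDROMIC_EAF_BAND
            in_band = ((np.isnan(eaf_x) or lo < eaf_x < hi)
                       or (np.isnan(eaf_y) or lo < eaf_y < hi))
            if in_band:
                exc.append((snp, "palindromic_ambiguous"))
                continue
            # alignable by frequency: concordant eafs mean same orientation
            flip = (eaf_x < 0.5) != (eaf_y < 0.5)
        else:
            comp = {a: COMPLEMENT.get(a, "?") for a in (ea_y, oa_y)}
            if (ea_y, oa_y) == (ea_x, oa_x):
                flip = False
            elif (ea_y, oa_y) == (oa_x, ea_x):
                flip = True
            elif (comp[ea_y], comp[oa_y]) == (ea_x, oa_x):
                flip = False
            elif (comp[ea_y], comp[oa_y]) == (oa_x, ea_x):
                flip = True
            else:
                exc.append((snp, "allele_mismatch"))
                continue

        beta_y = float(o.beta)
        if flip:
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y if not np.isnan(eaf_y) else eaf_y
        pairs.append(SummaryStatsPair(
            snp=snp, beta_x=float(e.beta), se_x=float(e.se),
            beta_y=beta_y, se_y=float(o.se),
            effect_allele=ea_x, other_allele=oa_x, eaf=eaf_x))
    for o in outcome_stats.itertuples():
        if str(o.snp) not in set(exposure_stats["snp"].astype(str)):
            exc.append((str(o.snp), "not_in_exposure"))
    return pairs, exc


# ---------------------------------------------------------------------------
# estimators

def wald_ratio(pair: SummaryStatsPair, per_decrease: bool = True) -> MREstimate:
    """Single-instrument causal estimate beta_y / beta_x.

    SE by the first-order delta method: ``se_y / |beta_x|``.
    """
    if pair.beta_x == 0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    theta = pair.beta_y / pair.beta_x
    se = pair.se_y / abs(pair.beta_x)
    return _finalize("wald_ratio", theta, se, 1, per_decrease)


def ivw(pairs, random_effects: bool = True,
        per_decrease: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate: regression through the origin.

    Slope of beta_y on beta_x with weights 1/se_y², forced through zero:
    ``theta = sum(w bx by) / sum(w bx²)``.  With ``random_effects`` the SE
    is inflated by the multiplicative residual-heterogeneity scale
    ``sqrt(max(1, Q/(k-1)))``; Cochran's Q is reported either way.
    """
    pairs = list(pairs)
    if len(pairs) == 1:
        return wald_ratio(pairs[0], per_decrease=per_decrease)
    if len(pairs) < 2:
        raise ValueError("IVW needs at least 2 instruments")
    bx, _, by, sy = _as_arrays(pairs)
    w = 1.0 / sy**2
    denom = np.sum(w * bx**2)
    theta = np.sum(w * bx * by) / denom
    se = np.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    if random_effects and len(pairs) > 1:
        se *= np.sqrt(max(1.0, q / (len(pairs) - 1)))
    return _finalize("ivw", theta, se, len(pairs), per_decrease, q_stat=q)


def egger(pairs, per_decrease: bool = True) -> MREstimate:
    """MR-Egger: weighted regression of beta_y on beta_x with free intercept.

    Pairs are first oriented so every beta_x >= 0 (a joint sign flip leaves
    the causal slope unchanged); weights are 1/se_y².  A nonzero intercept
    indicates unbalanced horizontal pleiotropy.  SEs use the residual scale
    floored at 1 and t-distribution inference with k-2 degrees of freedom.
    """
    pairs = list(pairs)
    k = len(pairs)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _as_arrays(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2

    # weighted least squares normal equations with design [1, bx]
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    coef = np.linalg.solve(XtW @ X, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(XtW @ X) * max(sigma2, 1.0)
    alpha, theta = coef
    se_alpha, se_theta = np.sqrt(np.diag(cov))
    p_theta = 2.0 * st.t.sf(abs(theta) / se_theta, df=k - 2)
    p_alpha = 2.0 * st.t.sf(abs(alpha) / se_alpha, df=k - 2)
    return _finalize("egger", theta, se_theta, k, per_decrease,
                     pvalue=p_theta, intercept=float(alpha),
                     intercept_se=float(se_alpha),
                     intercept_pvalue=float(p_alpha))


def _ratio_weights(pairs):
    """Per-SNP Wald ratios and inverse-variance weights (delta method).

    SNPs with beta_x = 0 are excluded and logged.
    """
    kept = [p for p in pairs if p.beta_x != 0]
    dropped = [p.snp for p in pairs if p.beta_x == 0]
    if dropped:
        logger.info("excluded %d SNP(s) with beta_x=0: %s",
                    len(dropped), dropped)
    ratios = np.array([p.beta_y / p.beta_x for p in kept])
    se_ratio = np.array([p.se_y / abs(p.beta_x) for p in kept])
    w = 1.0 / se_ratio**2
    return kept, ratios, w


def _weighted_median(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, ww = ratios[order], w[order]
    ww = ww / ww.sum()
    cum = np.cumsum(ww) - 0.5 * ww  # standardized cumulative weight
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = np.searchsorted(cum, 0.5, side="right") - 1
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j]))


def weighted_median(pairs, n_boot: int = 1000, seed: int = 0,
                    per_decrease: bool = True) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Consistent when instruments carrying at least half the weight are valid.
    Weights are inverse ratio variances; the estimate interpolates where the
    standardized cumulative weight crosses 0.5.  SE by seeded parametric
    bootstrap resampling beta_x, beta_y from their standard errors.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    kept, ratios, w = _ratio_weights(pairs)
    theta = _weighted_median(ratios, w)
    se = _bootstrap_se(kept, lambda r, ww: _weighted_median(r, ww),
                       n_boot, seed, weighted=True)
    return _finalize("weighted_median", theta, se, len(kept), per_decrease)


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = float(st.median_abs_deviation(ratios, scale="normal"))
    s = 0.9 * min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return factor * s * n ** (-1 / 5)


def _mode_estimate(ratios: np.ndarray, w: np.ndarray, factor: float) -> float:
    h = _mode_bandwidth(ratios, factor)
    if h == 0 or len(np.unique(ratios)) == 1:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (w[None, :] * st.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_based(pairs, weighted: bool = False, bandwidth_factor: float = 1.0,
               n_boot: int = 1000, seed: int = 0,
               per_decrease: bool = True) -> MREstimate:
    """Mode of the per-SNP Wald-ratio density (simple or weighted).

    A Gaussian kernel density over the ratios, with bandwidth
    ``bandwidth_factor`` times the modified-Silverman scale
    ``0.9 min(sd, mad) n^{-1/5}``, is maximized on a fixed grid.  The simple
    mode uses equal weights, the weighted mode inverse-variance weights.
    Consistent when the most common ratio comes from valid instruments
    (zero modal pleiotropy).  SE by seeded parametric bootstrap.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("mode-based estimation needs at least 3 instruments")
    kept, ratios, iv_w = _ratio_weights(pairs)
    w = iv_w / iv_w.sum() if weighted else np.full(len(kept), 1.0 / len(kept))
    theta = _mode_estimate(ratios, w, bandwidth_factor)
    se = _bootstrap_se(kept, lambda r, ww: _mode_estimate(r, ww, bandwidth_factor),
                       n_boot, seed, weighted=weighted)
    method = "weighted_mode" if weighted else "simple_mode"
    return _finalize(method, theta, se, len(kept), per_decrease)


def _bootstrap_se(pairs, stat, n_boot: int, seed: int, weighted: bool) -> float:
    """Parametric bootstrap: resample betas from their SEs, recompute stat."""
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _as_arrays(pairs)
    k = len(pairs)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.standard_normal(k) * sx
        byb = by + rng.standard_normal(k) * sy
        ok = bxb != 0
        r = byb[ok] / bxb[ok]
        if weighted:
            w = (np.abs(bxb[ok]) / sy[ok]) ** 2
        else:
            w = np.full(ok.sum(), 1.0 / max(int(ok.sum()), 1))
        est[b] = stat(r, w)
    return float(np.std(est, ddof=1))


# ---------------------------------------------------------------------------
# model object

METHODS = {
    "ivw": lambda pairs, n_boot, seed, pd_: ivw(pairs, per_decrease=pd_),
    "egger": lambda pairs, n_boot, seed, pd_: egger(pairs, per_decrease=pd_),
    "weighted_median": lambda pairs, n_boot, seed, pd_: weighted_median(
        pairs, n_boot=n_boot, seed=seed, per_decrease=pd_),
    "simple_mode": lambda pairs, n_boot, seed, pd_: mode_based(
        pairs, weighted=False, n_boot=n_boot, seed=seed, per_decrease=pd_),
    "weighted_mode": lambda pairs, n_boot, seed, pd_: mode_based(
        pairs, weighted=True, n_boot=n_boot, seed=seed, per_decrease=pd_),
}


@dataclass
class TwoSampleMRResults:
    """Estimates from a suite of two-sample MR methods."""

    estimates: list
    n_snps: int
    exclusions: list

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "method": e.method, "n_snps": e.n_snps, "estimate": e.estimate,
            "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "pvalue": e.pvalue, "intercept": e.intercept,
            "intercept_se": e.intercept_se, "intercept_p": e.intercept_pvalue,
            "q_stat": e.q_stat,
        } for e in self.estimates]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = [f"Two-sample MR on {self.n_snps} harmonized SNPs"
                + (f" ({len(self.exclusions)} excluded)" if self.exclusions else "")]
        return "\n".join(head + [e.summary() for e in self.estimates])


class TwoSampleMR:
    """Two-sample MR model over harmonized summary statistics.

    Construct from a list of :class:`SummaryStatsPair` or from raw exposure
    and outcome summary tables via :meth:`from_summary_tables` (which
    harmonizes alleles first).  ``fit`` runs the requested estimators.
    """

    def __init__(self, pairs, exclusions=None):
        self.pairs = list(pairs)
        self.exclusions = list(exclusions or [])
        if not self.pairs:
            raise ValueError("no instruments after harmonization")

    @classmethod
    def from_summary_tables(cls, exposure_stats: pd.DataFrame,
                            outcome_stats: pd.DataFrame) -> "TwoSampleMR":
        pairs, exc = harmonize(exposure_stats, outcome_stats)
        return cls(pairs, exclusions=exc)

    def fit(self, methods=("ivw", "egger", "weighted_median",
                           "simple_mode", "weighted_mode"),
            n_boot: int = 1000, seed: int = 0,
            per_decrease: bool = True) -> TwoSampleMRResults:
        unknown = [m for m in methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}; "
                             f"choose from {sorted(METHODS)}")
        ests = [METHODS[m](self.pairs, n_boot, seed, per_decrease)
                for m in methods]
        return TwoSampleMRResults(estimates=ests, n_snps=len(self.pairs),
                                  exclusions=self.exclusions)
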