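"""Automated phenome-wide scan of a genetic risk score.

Each phenome field is typed by rule (declared or auto-resolved), preprocessed
(continuous outcomes are inverse-normal rank transformed), and routed to the
regression matching its type — linear, logistic, proportional-odds, or
multinomial — with the score as the exposure of interest, adjusted for age
and ten genetic principal components.  Estimates are mean differences or
log-odds per unit increase of the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "FieldMeta",
    "ScanResult",
    "PhenomeScan",
    "PhenomeScanResults",
    "resolve_trait_type",
    "inverse_normal_rank_transform",
    "run_phenome_scan",
]

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("continuous", "binary", "ordered_categorical",
               "unordered_categorical", "auto")

#: auto-typing cut-offs on the number of distinct non-missing values
AUTO_BINARY_LEVELS = 2
AUTO_CONTINUOUS_MIN_LEVELS = 20

#: binary fields with fewer cases (or controls) are skipped: separation guard
MIN_CASES = 10


@dataclass
class FieldMeta:
    """Metadata for one phenome field."""

    field_id: str
    declared_type: str = "auto"
    ordered_levels: list | None = None
    category: str = ""

    def __post_init__(self):
        if self.declared_type not in TRAIT_TYPES:
            raise ValueError(f"unknown declared_type {self.declared_type!r}")
        if (self.ordered_levels is not None
                and self.declared_type != "ordered_categorical"):
            raise ValueError("ordered_levels only valid for ordered fields")


@dataclass
class ScanResult:
    """Result of one field's regression in the scan."""

    field_id: str
    resolved_type: str
    model: str
    estimate: float
    se: float
    pvalue: float
    n_complete: int
    n_cases: int | None = None
    converged: bool = True
    category: str = ""


class FieldSkipped(Exception):
    """Internal signal: field cannot be analysed; carries the reason."""


def resolve_trait_type(values: pd.Series, meta: FieldMeta) -> str:
    """Resolve a field's analysis type from its metadata and observed values.

    Declared (non-auto) types pass through after validation.  Auto fields
    follow the rule table: 2 distinct values -> binary; numeric with >= 20
    distinct values -> continuous; numeric with 3-19 distinct values ->
    ordered categorical (natural numeric order); non-numeric with >= 3
    levels -> unordered categorical.
    """
    v = values.dropna()
    if v.empty:
        raise FieldSkipped("all values missing")
    n_distinct = v.nunique()
    if n_distinct == 1:
        raise FieldSkipped("constant field")

    declared = meta.declared_type
    if declared == "binary":
        if n_distinct != AUTO_BINARY_LEVELS:
            raise ValueError(
                f"field {meta.field_id!r} declared binary but has "
                f"{n_distinct} observed levels")
        return "binary"
    if declared != "auto":
        return declared

    if n_distinct == AUTO_BINARY_LEVELS:
        return "binary"
    numeric = pd.api.types.is_numeric_dtype(v)
    if numeric and n_distinct >= AUTO_CONTINUOUS_MIN_LEVELS:
        return "continuous"
    if numeric:
        return "ordered_categorical"
    return "unordered_categorical"


def inverse_normal_rank_transform(values: pd.Series) -> pd.Series:
    """Map values to standard-normal quantiles of their (average) ranks.

    A non-missing value with rank r among m receives the normal quantile at
    ``(r - 0.5) / m``; ties share the average-rank quantile; missing entries
    stay missing.  The transform is monotone, so rank-based inference is
    unchanged while the marginal becomes Gaussian.
    """
    v = pd.Series(values).astype(float)
    mask = v.notna()
    m = int(mask.sum())
    if m < 2:
        raise ValueError("need at least 2 non-missing values")
    if v[mask].nunique() == 1:
        raise FieldSkipped("constant field: rank transform undefined")
    ranks = st.rankdata(v[mask], method="average")
    out = v.copy()
    out[mask] = st.norm.ppf((ranks - 0.5) / m)
    return out


@dataclass
class PhenomeScanResults:
    """Container for scan output: one ScanResult per analysable field."""

    results: list
    skipped: list  # (field_id, reason) pairs
    n_fields: int

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "field_id": r.field_id, "resolved_type": r.resolved_type,
            "model": r.model, "estimate": r.estimate, "se": r.se,
            "pvalue": r.pvalue, "n": r.n_complete, "n_cases": r.n_cases,
            "converged": r.converged, "category": r.category,
        } for r in self.results]
        return pd.DataFrame(rows, columns=[
            "field_id", "resolved_type", "model", "estimate", "se", "pvalue",
            "n", "n_cases", "converged", "category"])

    @property
    def pvalues(self) -> pd.Series:
        """P-values of converged fields, indexed by field id."""
        conv = [r for r in self.results if r.converged]
        return pd.Series([r.pvalue for r in conv],
                         index=[r.field_id for r in conv], name="pvalue")

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Phenome scan: {self.n_fields} fields, "
                 f"{len(self.results)} analysed, {len(self.skipped)} skipped"]
        if len(df):
            counts = df["resolved_type"].value_counts()
            lines += [f"  {t}: {c}" for t, c in counts.items()]
            lines.append(f"  non-converged: {int((~df['converged']).sum())}")
        return "\n".join(lines)


class PhenomeScan:
    """Scan model: phenome fields regressed on a score with adjustment.

    Parameters
    ----------
    phenome : DataFrame
        One column per field, row-aligned with ``score`` and ``covariates``.
    meta : sequence of FieldMeta (one per phenome column)
    score : ScoreVector or array-like
        The exposure of interest (GRS).
    covariates : DataFrame
        Must contain ``age`` and ``pc1`` … ``pc10``.  A ``sex`` column, if
        present, is ignored: scans run within one sex.
    """

    REQUIRED_COVARIATES = ("age",) + tuple(f"pc{i}" for i in range(1, 11))

    def __init__(self, phenome: pd.DataFrame, meta, score, covariates: pd.DataFrame):
        score_arr = np.asarray(
            score.to_numpy() if hasattr(score, "to_numpy") else score, float)
        if not (len(phenome) == len(score_arr) == len(covariates)):
            raise ValueError(
                f"row counts disagree: phenome={len(phenome)}, "
                f"score={len(score_arr)}, covariates={len(covariates)}")
        missing = [c for c in self.REQUIRED_COVARIATES
                   if c not in covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        meta = list(meta)
        meta_ids = [m.field_id for m in meta]
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate field ids in metadata")
        unknown = [m.field_id for m in meta if m.field_id not in phenome.columns]
        if unknown:
            raise ValueError(f"metadata for absent fields: {unknown}")
        self.phenome = phenome.reset_index(drop=True)
        self.meta = meta
        self.score = score_arr
        self.covariates = (covariates[list(self.REQUIRED_COVARIATES)]
                           .reset_index(drop=True).astype(float))

    def fit(self) -> PhenomeScanResults:
        results, skipped = [], []
        base = pd.DataFrame({"grs": self.score})
        base = pd.concat([base, self.covariates], axis=1)
        base_ok = base.notna().all(axis=1)
        for m in self.meta:
            try:
                results.append(self._fit_field(m, base, base_ok))
            except FieldSkipped as exc:
                logger.info("field %s skipped: %s", m.field_id, exc)
                skipped.append((m.field_id, str(exc)))
        return PhenomeScanResults(results=results, skipped=skipped,
                                  n_fields=len(self.meta))

    # -- single-field routing -------------------------------------------

    def _fit_field(self, meta: FieldMeta, base: pd.DataFrame,
                   base_ok: pd.Series) -> ScanResult:
        y_raw = self.phenome[meta.field_id]
        mask = base_ok & y_raw.notna()
        y = y_raw[mask]
        X = base[mask]
        n = int(mask.sum())
        if n == 0:
            raise FieldSkipped("no complete-case rows")
        rtype = resolve_trait_type(y, meta)

        if rtype == "continuous":
            fit = self._fit_linear(y, X)
        elif rtype == "binary":
            fit = self._fit_logistic(y, X)
        elif rtype == "ordered_categorical":
            fit = self._fit_ordered(y, X, meta)
        else:
            fit = self._fit_multinomial(y, X)
        est, se, p, model_name, n_cases, converged = fit
        return ScanResult(field_id=meta.field_id, resolved_type=rtype,
                          model=model_name, estimate=est, se=se, pvalue=p,
                          n_complete=n, n_cases=n_cases, converged=converged,
                          category=meta.category)

    def _fit_linear(self, y, X):
        y_t = inverse_normal_rank_transform(y.astype(float))
        res = sm.OLS(y_t.to_numpy(), sm.add_constant(X.to_numpy())).fit()
        # column 1 is the score (column 0 the constant)
        return (float(res.params[1]), float(res.bse[1]),
                float(res.pvalues[1]), "linear", None, True)

    def _fit_logistic(self, y, X):
        levels = sorted(y.unique())
        y01 = (y == levels[1]).astype(int)
        n_cases = int(y01.sum())
        if min(n_cases, len(y01) - n_cases) < MIN_CASES:
            raise FieldSkipped(f"binary field with <{MIN_CASES} cases/controls")
        Xc = sm.add_constant(X.to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y01.to_numpy(), Xc).fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            return (np.nan, np.nan, np.nan, "logistic", n_cases, False)
        return (float(res.params[1]), float(res.bse[1]),
                float(res.pvalues[1]), "logistic", n_cases, converged)

    def _fit_ordered(self, y, X, meta):
        if meta.ordered_levels is not None:
            cats = list(meta.ordered_levels)
        else:
            cats = sorted(y.unique())
        y_cat = pd.Categorical(y, categories=cats, ordered=True)
        if pd.isna(y_cat).any():
            # declared levels may have round-tripped through text; retry
            # with values and levels both coerced to strings
            coerced = pd.Categorical(
                y.map(lambda v: str(int(v)) if isinstance(v, float)
                      and float(v).is_integer() else str(v)),
                categories=[str(c) for c in cats], ordered=True)
            if pd.isna(coerced).any():
                raise FieldSkipped("values outside declared ordered levels")
            y_cat = coerced
        y_cat = pd.Series(y_cat).reset_index(drop=True)

        def _try(score_scale):
            Xs = X.reset_index(drop=True).copy()
            Xs["grs"] = Xs["grs"] / score_scale
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = OrderedModel(y_cat, Xs, distr="logit")
                res = mod.fit(method="bfgs", disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
            pvals = np.asarray(res.pvalues)
            return (float(params[0]) / score_scale,
                    float(bse[0]) / score_scale, float(pvals[0]))

        try:
            est, se, p = _try(1.0)
            return (est, se, p, "ordered_logistic", None, True)
        except Exception:
            # retry once with the score rescaled to unit variance
            try:
                scale = float(np.std(X["grs"])) or 1.0
                est, se, p = _try(scale)
                return (est, se, p, "ordered_logistic", None, True)
            except Exception:
                return (np.nan, np.nan, np.nan, "ordered_logistic", None, False)

    def _fit_multinomial(self, y, X):
        codes, _ = pd.factorize(y, sort=True)
        Xc = sm.add_constant(X.to_numpy())
        X0 = sm.add_constant(X.drop(columns="grs").to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.MNLogit(codes, Xc).fit(disp=0, maxiter=200)
                null = sm.MNLogit(codes, X0).fit(disp=0, maxiter=200)
            conv = (full.mle_retvals.get("converged", True)
                    and null.mle_retvals.get("converged", True))
            if not conv:
                raise RuntimeError("no convergence")
        except Exception:
            return (np.nan, np.nan, np.nan, "multinomial", None, False)
        k_contrasts = full.params.shape[1]  # non-reference categories
        lr = 2.0 * (full.llf - null.llf)
        p = float(st.chi2.sf(max(lr, 0.0), df=k_contrasts))
        # report the largest-magnitude category contrast of the score
        score_coefs = np.asarray(full.params)[1, :]
        score_ses = np.asarray(full.bse)[1, :]
        j = int(np.argmax(np.abs(score_coefs)))
        return (float(score_coefs[j]), float(score_ses[j]), p,
                "multinomial", None, True)


def run_phenome_scan(score, phenome: pd.DataFrame, meta,
                     covariates: pd.DataFrame) -> PhenomeScanResults:
    """Convenience wrapper: build a :class:`PhenomeScan` and fit it."""
    return PhenomeScan(phenome, meta, score, covariates).fit()


def write_meta_tsv(meta, path) -> None:
    """Write field metadata (ordered levels pipe-separated)."""
    rows = [{
        "field_id": m.field_id,
        "declared_type": m.declared_type,
        "ordered_levels": ("|".join(map(str, m.ordered_levels))
                           if m.ordered_levels else "."),
        "category": m.category or ".",
    } for m in meta]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        levels = None
        if row["ordered_levels"] not in (".", "", None) and pd.notna(row["ordered_levels"]):
            levels = row["ordered_levels"].split("|")
        cat = "" if row["category"] in (".", None) or pd.isna(row["category"]) else row["category"]
        out.append(FieldMeta(field_id=row["field_id"],
                             declared_type=row["declared_type"],
                             ordered_levels=levels, category=cat))
    return out
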