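"""One-sample Mendelian randomization by two-stage estimation.

Stage one regresses the exposure (age at natural menopause, years) on the
genetic risk score plus covariates (age and ten genetic principal
components) and keeps the fitted values — the genetically predicted
exposure.  Stage two regresses the outcome on that prediction plus the same
covariates: linear regression for continuous outcomes, logistic for binary
ones.  Estimates are reported per year *decrease* of the exposure by
default: a log-odds of +0.04 per year increase is reported as -0.04, i.e.
an odds ratio of exp(-0.04) ≈ 0.96 per year decrease.

Second-stage standard errors are the plain regression SEs and do not
propagate first-stage uncertainty; with instrument F-statistics in the
thousands this term is negligible, and the reported estimates carry a note
saying so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .instruments import (DegenerateInstrumentError, InstrumentStrength,
                          instrument_strength, ScoreVector)
from .twosample import MREstimate, Z95

__all__ = ["FirstStage", "OneSampleMR", "predict_exposure",
           "two_stage_estimate"]

COVARIATE_COLS = ("age",) + tuple(f"pc{i}" for i in range(1, 11))


@dataclass
class FirstStage:
    """Fitted first stage: genetically predicted exposure + diagnostics."""

    fitted: pd.Series
    strength: InstrumentStrength
    params: pd.Series


def _covariate_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATE_COLS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    return covariates[list(COVARIATE_COLS)].astype(float)


def predict_exposure(score, exposure: pd.Series,
                     covariates: pd.DataFrame) -> FirstStage:
    """First stage: exposure regressed on score + age + 10 PCs.

    Returns the fitted (genetically predicted) exposure values and
    instrument-strength diagnostics (marginal R² and F of the score).
    """
    s = np.asarray(score.to_numpy() if hasattr(score, "to_numpy") else score,
                   float)
    x = np.asarray(exposure, float)
    cov = _covariate_matrix(covariates)
    if not (len(s) == len(x) == len(cov)):
        raise ValueError("score, exposure and covariates must be row-aligned")
    mask = ~(np.isnan(s) | np.isnan(x)) & cov.notna().all(axis=1).to_numpy()
    if mask.sum() < 3:
        raise ValueError("need at least 3 complete rows")
    if np.var(s[mask]) == 0:
        raise DegenerateInstrumentError("score has zero variance")

    X = sm.add_constant(np.column_stack([s[mask], cov.to_numpy()[mask]]))
    res = sm.OLS(x[mask], X).fit()
    fitted = pd.Series(np.full(len(s), np.nan), name="predicted_exposure")
    fitted[mask] = res.fittedvalues
    strength = instrument_strength(
        ScoreVector(values=pd.Series(s[mask]), n_snps_used=0),
        pd.Series(x[mask]))
    names = ["const", "grs"] + list(COVARIATE_COLS)
    return FirstStage(fitted=fitted, strength=strength,
                      params=pd.Series(res.params, index=names))


def two_stage_estimate(predicted: pd.Series, outcome: pd.Series,
                       outcome_type: str, covariates: pd.DataFrame,
                       per_decrease: bool = True) -> MREstimate:
    """Second stage: outcome on genetically predicted exposure + covariates.

    ``outcome_type`` is ``"continuous"`` (linear regression, estimate is a
    mean difference) or ``"binary"`` (logistic, estimate is a log-odds).
    The reported sign is per year decrease of the exposure by default.
    """
    if outcome_type not in ("continuous", "binary"):
        raise ValueError(f"outcome_type must be continuous or binary, "
                         f"got {outcome_type!r}")
    pred = np.asarray(predicted, float)
    y = np.asarray(outcome, float)
    cov = _covariate_matrix(covariates)
    mask = ~(np.isnan(pred) | np.isnan(y)) & cov.notna().all(axis=1).to_numpy()
    X = sm.add_constant(np.column_stack([pred[mask], cov.to_numpy()[mask]]))
    converged = True
    if outcome_type == "continuous":
        res = sm.OLS(y[mask], X).fit()
    else:
        classes = np.unique(y[mask])
        if len(classes) != 2:
            raise ValueError("binary outcome needs both classes present")
        y01 = (y[mask] == classes[1]).astype(int)
        res = sm.Logit(y01, X).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
    beta, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
    if per_decrease:
        beta = -beta
    return MREstimate(
        method=f"two_stage_{'linear' if outcome_type == 'continuous' else 'logistic'}",
        estimate=beta, se=se, ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=p, n_snps=int(mask.sum()),
        note="second-stage SE; first-stage uncertainty not propagated"
             + ("" if converged else "; NOT CONVERGED"))


class OneSampleMR:
    """Two-stage one-sample MR model for one cohort.

    Parameters
    ----------
    score : ScoreVector or array-like
    exposure : Series of exposure values (years)
    covariates : DataFrame with ``age`` and ``pc1`` … ``pc10``
    """

    def __init__(self, score, exposure: pd.Series, covariates: pd.DataFrame):
        self.score = score
        self.exposure = exposure
        self.covariates = covariates
        self._first_stage: FirstStage | None = None

    @property
    def first_stage(self) -> FirstStage:
        if self._first_stage is None:
            self._first_stage = predict_exposure(self.score, self.exposure,
                                                 self.covariates)
        return self._first_stage

    def fit(self, outcome: pd.Series, outcome_type: str,
            per_decrease: bool = True) -> MREstimate:
        """Estimate the causal effect of the exposure on one outcome."""
        return two_stage_estimate(self.first_stage.fitted, outcome,
                                  outcome_type, self.covariates,
                                  per_decrease=per_decrease)

    def fit_many(self, phenome: pd.DataFrame, field_types: dict,
                 per_decrease: bool = True) -> pd.DataFrame:
        """Estimate effects for several outcome fields; returns a table."""
        rows = []
        for fid, ftype in field_types.items():
            est = self.fit(phenome[fid], ftype, per_decrease=per_decrease)
            rows.append({"field_id": fid, "outcome_type": ftype,
                         "method": est.method, "estimate": est.estimate,
                         "se": est.se, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "pvalue": est.pvalue,
                         "n": est.n_snps})
        return pd.DataFrame(rows)
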