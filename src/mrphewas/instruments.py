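"""Genetic instrument management and weighted risk-score construction.

The instruments are SNPs associated with the exposure (age at natural
menopause, ANM) in an external GWAS, each carrying a published per-allele
effect in years of ANM.  The genetic risk score (GRS) is the weighted sum
of *ANM-decreasing* allele dosages, so a higher score means genetically
earlier menopause.  Also provides distance + r² pruning, stratification
by DNA-damage-response (DDR) pathway annotation, and instrument-strength
diagnostics (first-stage R² and F-statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentSet",
    "ScoreVector",
    "InstrumentStrength",
    "MissingInstrumentError",
    "DegenerateInstrumentError",
    "compute_grs",
    "prune_instruments",
    "stratify_instruments",
    "instrument_strength",
]

#: Columns every instrument table must carry.
REQUIRED_COLUMNS = ("snp", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "eaf")
#: Optional columns recognised by this module.
OPTIONAL_COLUMNS = ("se", "pval", "annotation")

VALID_ANNOTATIONS = frozenset({"DDR", "non-DDR", "unknown"})


class MissingInstrumentError(KeyError):
    """Raised when instrument SNPs are absent from a genotype matrix."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            f"{len(self.missing_ids)} instrument(s) absent from genotype "
            f"matrix: {', '.join(map(str, self.missing_ids[:10]))}"
            + ("…" if len(self.missing_ids) > 10 else "")
        )


class DegenerateInstrumentError(ValueError):
    """Raised when the score has zero variance (no instrument signal)."""


@dataclass
class InstrumentSet:
    """A set of SNP instruments with published weights and annotations.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per SNP with columns ``snp, chrom, pos, effect_allele,
        other_allele, beta, eaf`` and optionally ``se, pval, annotation``.
        ``beta`` is the published per-effect-allele change of the exposure
        in years (signed as published); ``eaf`` the effect-allele frequency.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"instrument table missing columns: {missing}")
        if t["snp"].duplicated().any():
            dups = t.loc[t["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate instrument ids: {dups}")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")
        if (t["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        beta = t["beta"].to_numpy(float)
        if not np.all(np.isfinite(beta)) or np.any(beta == 0):
            raise ValueError("weights must be finite and nonzero")
        eaf = t["eaf"].to_numpy(float)
        if np.any((eaf <= 0) | (eaf >= 1)):
            raise ValueError("eaf must lie strictly in (0, 1)")
        if "annotation" in t.columns:
            bad = set(t["annotation"].dropna()) - VALID_ANNOTATIONS
            if bad:
                raise ValueError(f"unknown annotations: {sorted(bad)}")
        else:
            self.table = t = t.assign(annotation="unknown")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    def subset(self, snp_ids) -> "InstrumentSet":
        """Return the instruments with the given ids, preserving metadata."""
        keep = self.table[self.table["snp"].isin(set(snp_ids))]
        return InstrumentSet(keep.copy())

    @classmethod
    def from_tsv(cls, path) -> "InstrumentSet":
        return cls(pd.read_csv(path, sep="\t", na_values=["."]))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep=".")

    def oriented(self) -> pd.DataFrame:
        """Instrument table re-oriented so the counted allele decreases ANM.

        Published weights with ``beta > 0`` (effect allele *increases* ANM)
        are flipped: the other allele is counted with weight ``|beta|`` and
        complemented frequency.  Adds ``weight_abs`` (always positive, years
        of earlier ANM per counted allele), ``counted_allele`` and
        ``counted_eaf`` columns and a ``flip`` flag.
        """
        t = self.table.copy()
        flip = t["beta"].to_numpy(float) > 0
        t["flip"] = flip
        t["weight_abs"] = np.abs(t["beta"].to_numpy(float))
        t["counted_allele"] = np.where(flip, t["other_allele"], t["effect_allele"])
        t["counted_eaf"] = np.where(flip, 1.0 - t["eaf"], t["eaf"])
        return t


@dataclass
class ScoreVector:
    """Per-individual weighted allele score.

    ``values`` are in expected years of *earlier* menopause: higher score =
    more ANM-decreasing alleles.
    """

    values: pd.Series
    n_snps_used: int
    missing_note: str = "none"

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(float)


@dataclass
class InstrumentStrength:
    """First-stage diagnostics: variance explained and F-statistic."""

    r_squared: float
    f_statistic: float
    n: int
    f_statistic_k: float = field(default=np.nan)

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.f_statistic < 0:
            raise ValueError("f_statistic must be >= 0")


def _validate_dosages(d: np.ndarray) -> None:
    with np.errstate(invalid="ignore"):
        bad = (d < 0) | (d > 2)
    if np.any(bad & ~np.isnan(d)):
        raise ValueError("dosages must lie in [0, 2] (or be missing)")


def compute_grs(genotypes: pd.DataFrame, instruments: InstrumentSet,
                missing: str = "impute") -> ScoreVector:
    """Weighted sum of ANM-decreasing allele dosages.

    Each instrument is re-oriented so the counted allele decreases the
    exposure; the score is ``sum_j |w_j| * d*_ij`` over oriented dosages
    ``d*``.  Missing dosages are mean-imputed at ``2 * counted_eaf``
    (``missing="impute"``, the default) or the individual is dropped
    (``missing="complete_case"``, scores set to NaN for affected rows).

    Parameters
    ----------
    genotypes : DataFrame, individuals x SNPs
        Allele dosages in [0, 2]; NaN marks missing.  Columns are SNP ids
        and must cover the instrument set.
    instruments : InstrumentSet
    missing : {"impute", "complete_case"}

    Returns
    -------
    ScoreVector
        Scores in expected years of earlier menopause.
    """
    if missing not in ("impute", "complete_case"):
        raise ValueError(f"unknown missing-data policy: {missing!r}")
    oriented = instruments.oriented()
    absent = [s for s in oriented["snp"] if s not in genotypes.columns]
    if absent:
        raise MissingInstrumentError(absent)

    dos = genotypes[oriented["snp"].tolist()].to_numpy(float)
    _validate_dosages(dos)

    flip = oriented["flip"].to_numpy(bool)
    dos_oriented = np.where(flip[None, :], 2.0 - dos, dos)

    w = oriented["weight_abs"].to_numpy(float)
    n_missing = int(np.isnan(dos_oriented).sum())
    if n_missing == 0:
        note = "none"
    elif missing == "impute":
        fill = 2.0 * oriented["counted_eaf"].to_numpy(float)
        dos_oriented = np.where(np.isnan(dos_oriented), fill[None, :], dos_oriented)
        note = f"{n_missing} missing dosages imputed to 2*frequency"
    else:
        note = f"{n_missing} missing dosages; affected individuals scored NaN"

    scores = dos_oriented @ w
    return ScoreVector(values=pd.Series(scores, index=genotypes.index, name="grs"),
                       n_snps_used=len(oriented), missing_note=note)


def _pruning_order(table: pd.DataFrame) -> np.ndarray:
    """Ranking for greedy pruning: ascending published p-value when present,
    else descending |beta|/se, else lexicographic id; ties broken by id."""
    ids = table["snp"].astype(str)
    if "pval" in table.columns and table["pval"].notna().all():
        key = table["pval"].to_numpy(float)
    elif "se" in table.columns and table["se"].notna().all():
        key = -(np.abs(table["beta"].to_numpy(float))
                / table["se"].to_numpy(float))
    else:
        key = np.zeros(len(table))
    order = sorted(range(len(table)), key=lambda i: (key[i], ids.iloc[i]))
    return np.asarray(order)


def prune_instruments(instruments: InstrumentSet, genotypes: pd.DataFrame,
                      window: int = 10_000_000,
                      r2_max: float = 0.001) -> InstrumentSet:
    """Greedy distance + r² pruning of the instrument set.

    Candidates are visited in ascending published p-value order (tie-break:
    ascending SNP id) and kept unless they fall within ``window`` base pairs
    of an already-kept SNP on the same chromosome, or their squared dosage
    correlation with any kept SNP is ``>= r2_max``.

    Defaults mirror a 10,000 kb / r² < 0.001 independence rule.
    """
    t = instruments.table
    if t["pos"].isna().any():
        raise ValueError("all instruments need positions for pruning")
    absent = [s for s in t["snp"] if s not in genotypes.columns]
    if absent:
        raise MissingInstrumentError(absent)

    dos = genotypes[t["snp"].tolist()].to_numpy(float)
    _validate_dosages(dos)

    chrom = t["chrom"].astype(str).to_numpy()
    pos = t["pos"].to_numpy(float)
    kept: list[int] = []
    for i in _pruning_order(t):
        ok = True
        for k in kept:
            if chrom[i] == chrom[k] and abs(pos[i] - pos[k]) < window:
                ok = False
                break
            r2 = _dosage_r2(dos[:, i], dos[:, k])
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    keep_ids = t.iloc[sorted(kept)]["snp"]
    return InstrumentSet(t[t["snp"].isin(set(keep_ids))].copy())


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def stratify_instruments(instruments: InstrumentSet, which: str) -> InstrumentSet:
    """Subset the instruments by pathway annotation (``"DDR"`` / ``"non-DDR"``).

    DDR and non-DDR subsets partition the annotated instruments.
    """
    if which not in ("DDR", "non-DDR"):
        raise ValueError(f"which must be 'DDR' or 'non-DDR', got {which!r}")
    t = instruments.table
    sub = t[t["annotation"] == which]
    if sub.empty:
        warnings.warn(f"no instruments annotated {which!r}", stacklevel=2)
    return InstrumentSet(sub.copy())


def instrument_strength(score: ScoreVector, exposure: pd.Series,
                        n_regressors: int = 1) -> InstrumentStrength:
    """First-stage strength: R² and F from exposure-on-score regression.

    The univariable closed form ``F = R² (n - 2) / (1 - R²)`` is the
    primary statistic; ``f_statistic_k`` carries the k-regressor form
    ``F = (R²/k) / ((1 - R²)/(n - k - 1))`` for comparison with analyses
    that adjust for covariates in the first stage.
    """
    s = score.to_numpy()
    x = np.asarray(exposure, float)
    mask = ~(np.isnan(s) | np.isnan(x))
    s, x = s[mask], x[mask]
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 complete score/exposure pairs")
    if np.var(s) == 0:
        raise DegenerateInstrumentError("score has zero variance")
    r = np.corrcoef(s, x)[0, 1]
    r2 = float(r * r)
    if r2 >= 1.0:
        return InstrumentStrength(r_squared=1.0, f_statistic=np.inf, n=n,
                                  f_statistic_k=np.inf)
    f1 = r2 * (n - 2) / (1.0 - r2)
    k = n_regressors
    fk = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return InstrumentStrength(r_squared=r2, f_statistic=float(f1), n=n,
                              f_statistic_k=float(fk))
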