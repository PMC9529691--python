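"""Synthetic cohorts and GWAS summary statistics with known ground truth.

Emulates the statistical structure an MR-pheWAS assumes: unlinked
Hardy-Weinberg genotypes at configurable allele frequencies; an exposure
(age at natural menopause, mean 50, SD 5 years) driven by the weighted
allele score to a configurable variance explained; a mixed-type phenome
causally downstream of the exposure; a shared confounder; balanced or
directional horizontal pleiotropy (direct SNP-to-trait effects); male
cohorts that share the genotype-generating process but lack the exposure
pathway entirely (negative controls); and paired exposure/outcome summary
statistics for two-sample MR.

Every draw comes from named substreams of one global seed, so partial
reruns (e.g. the male cohort alone) reproduce the shared components —
instruments and pleiotropic effects — bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
import scipy.stats as st

from .instruments import InstrumentSet, compute_grs
from .scan import FieldMeta
from .twosample import SummaryStatsPair

__all__ = ["TraitSpec", "SimConfig", "CohortData", "TruthRecord",
           "simulate_cohort", "simulate_male_cohort",
           "simulate_summary_stats", "write_cohort", "write_sumstats",
           "sumstats_frames"]

TRAIT_TYPES = ("continuous", "binary", "ordered_categorical",
               "unordered_categorical")
PLEIOTROPY_MODES = ("none", "balanced", "directional")

#: non-palindromic allele pairs used for simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: per-category slope pattern for unordered (multinomial) traits
_MULTINOMIAL_PATTERN = np.array([0.0, 1.0, -1.0, 0.5, -0.5, 0.25, -0.25])


@dataclass
class TraitSpec:
    """Descriptor of one phenome field to simulate.

    ``effect`` is the true causal effect per year of exposure: a slope for
    continuous traits, a log-odds for binary, a latent-scale slope for
    ordered, and the scale of per-category multinomial slopes for unordered
    traits.
    """

    field_id: str
    trait_type: str = "continuous"
    effect: float = 0.0
    category: str = ""
    prevalence: float = 0.3      # binary only
    n_levels: int = 4            # ordered / unordered only
    noise_sd: float = 1.0        # continuous only
    age_effect: float = 0.0      # slope per year of age on the trait
    pleiotropic: bool = True     # receives direct SNP effects when mode != none

    def __post_init__(self):
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary" and not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.trait_type.endswith("categorical") and self.n_levels < 3:
            raise ValueError("categorical traits need >= 3 levels")


def default_trait_spec() -> list:
    """A small mixed-type phenome: null plus exposure-driven fields."""
    return [
        TraitSpec("cont_null", "continuous", 0.0, category="null"),
        TraitSpec("cont_effect", "continuous", 0.2, category="metabolic"),
        TraitSpec("bin_null", "binary", 0.0, category="null"),
        TraitSpec("bin_effect", "binary", 0.04, category="cancer"),
        TraitSpec("ord_effect", "ordered_categorical", 0.1, category="bone"),
        TraitSpec("unord_null", "unordered_categorical", 0.0, category="null"),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated population.

    Defaults mirror the emulated cohort: exposure mean 50 years (SD 5),
    267 instruments of which a 104/267 fraction sit in DNA-damage-response
    genes, and a score explaining 7.3% of exposure variance.
    """

    n_individuals: int = 5000
    n_snps: int = 267
    maf_range: tuple = (0.05, 0.5)
    exposure_mean: float = 50.0
    exposure_sd: float = 5.0
    target_r2: float = 0.073
    confounder_effect: tuple = (0.0, 0.0)   # per-SD slopes on exposure, outcomes
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    trait_spec: list = field(default_factory=default_trait_spec)
    seed: int = 0
    missing_rate: float = 0.0
    ld_block: tuple | None = None           # (block_size, dosage correlation)
    population_structure: bool = False
    ddr_fraction: float = 104 / 267

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo < 1 and 0 < hi < 1 and lo <= hi):
            raise ValueError("maf_range must lie in (0, 1)")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if not 0 <= self.target_r2 < 1:
            raise ValueError("target_r2 must lie in [0, 1)")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not self.trait_spec:
            raise ValueError("trait_spec must be nonempty")
        self.trait_spec = [t if isinstance(t, TraitSpec) else TraitSpec(**t)
                           for t in self.trait_spec]
        ids = [t.field_id for t in self.trait_spec]
        if len(set(ids)) != len(ids):
            raise ValueError("trait field ids must be unique")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("maf_range", "confounder_effect", "ld_block"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_spec"] = [asdict(t) for t in self.trait_spec]
        return d


@dataclass
class CohortData:
    """Individual-level data for one simulated population."""

    genotypes: pd.DataFrame
    covariates: pd.DataFrame
    exposure: pd.Series | None
    phenome: pd.DataFrame
    meta: list

    def __post_init__(self):
        n = len(self.genotypes)
        if not (len(self.covariates) == len(self.phenome) == n):
            raise ValueError("row counts disagree across components")
        if self.exposure is not None and len(self.exposure) != n:
            raise ValueError("exposure length disagrees with genotypes")
        d = self.genotypes.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any((d < 0) | (d > 2)):
                raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n(self) -> int:
        return len(self.genotypes)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated cohort.

    ``snp_effects``: true per-effect-allele exposure effects (years).
    ``trait_effects``: true causal effect per year of exposure, per field.
    ``pleiotropy``: direct SNP-to-trait effects on the counted
    (exposure-decreasing) allele scale, SNPs x fields.
    """

    snp_effects: pd.DataFrame
    trait_effects: pd.DataFrame
    pleiotropy: pd.DataFrame


# ---------------------------------------------------------------------------
# seeded substreams

_STREAMS = ("instruments", "genotypes_female", "genotypes_male",
            "covariates_female", "covariates_male", "exposure",
            "traits_female", "traits_male", "pleiotropy",
            "missing_female", "missing_male")


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# components

def _make_instruments(config: SimConfig, rng) -> InstrumentSet:
    m = config.n_snps
    lo, hi = config.maf_range
    eaf = rng.uniform(lo, hi, m)
    beta = rng.uniform(0.05, 0.35, m) * rng.choice([-1.0, 1.0], m)
    z = rng.uniform(6.0, 25.0, m)
    se = np.abs(beta) / z
    pval = 2.0 * st.norm.sf(z)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    chrom = [str(1 + i % 22) for i in range(m)]
    pos = [1_000_000 + 20_000_000 * (i // 22) for i in range(m)]
    n_ddr = int(round(config.ddr_fraction * m))
    ann = np.array(["DDR"] * n_ddr + ["non-DDR"] * (m - n_ddr))
    rng.shuffle(ann)
    return InstrumentSet(pd.DataFrame({
        "snp": [f"rs{i + 1:06d}" for i in range(m)],
        "chrom": chrom, "pos": pos,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "beta": beta, "se": se, "pval": pval, "eaf": eaf,
        "annotation": ann,
    }))


def _draw_genotypes(config: SimConfig, instruments: InstrumentSet, rng,
                    pcs: np.ndarray | None) -> pd.DataFrame:
    n, m = config.n_individuals, len(instruments)
    p = instruments.table["eaf"].to_numpy(float)
    if config.population_structure and pcs is not None:
        # frequency gradient along the first principal component
        p_ind = expit(logit(p)[None, :] + 0.3 * pcs[:, [0]])
    else:
        p_ind = np.broadcast_to(p, (n, m))

    if config.ld_block is None:
        dos = rng.binomial(2, p_ind).astype(float)
    else:
        block, rho = config.ld_block
        dos = np.zeros((n, m))
        thr = st.norm.ppf(p_ind)
        for allele in range(2):  # two independent allele draws per person
            z = np.empty((n, m))
            for start in range(0, m, block):
                stop = min(start + block, m)
                shared = rng.standard_normal((n, 1))
                indep = rng.standard_normal((n, stop - start))
                z[:, start:stop] = (np.sqrt(rho) * shared
                                    + np.sqrt(1 - rho) * indep)
            dos += (z < thr).astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dos[mask] = np.nan
    return pd.DataFrame(dos, columns=instruments.snp_ids)


def _draw_covariates(n: int, rng, sex: int) -> pd.DataFrame:
    cov = pd.DataFrame({"age": rng.uniform(40.0, 70.0, n),
                        "sex": float(sex)})
    for i in range(1, 11):
        cov[f"pc{i}"] = rng.standard_normal(n)
    return cov


def _draw_pleiotropy(config: SimConfig, rng) -> pd.DataFrame:
    """Direct SNP-to-trait effects, shared between the sexes."""
    m = config.n_snps
    fields = [t.field_id for t in config.trait_spec]
    alpha = np.zeros((m, len(fields)))
    if config.pleiotropy_mode != "none":
        mean = (config.pleiotropy_mean
                if config.pleiotropy_mode == "directional" else 0.0)
        for j, t in enumerate(config.trait_spec):
            if t.pleiotropic:
                alpha[:, j] = rng.normal(mean, config.pleiotropy_sd, m)
    snp_ids = [f"rs{i + 1:06d}" for i in range(m)]
    return pd.DataFrame(alpha, index=snp_ids, columns=fields)


def _draw_exposure(config: SimConfig, score: np.ndarray, confounder: np.ndarray,
                   rng) -> tuple[np.ndarray, float]:
    """Exposure = mean - b*(score - mean(score)) + confounder + noise.

    b is solved so the score explains ``target_r2`` of the marginal variance
    ``exposure_sd²``; the confounder contributes its squared slope; the noise
    picks up the remainder.  Returns (exposure, b).
    """
    c_x = config.confounder_effect[0]
    var_noise = config.exposure_sd**2 * (1.0 - config.target_r2) - c_x**2
    if var_noise < 0:
        raise ValueError("confounder_effect on exposure too large for the "
                         "requested exposure_sd and target_r2")
    sd_score = float(np.std(score))
    if config.target_r2 > 0 and sd_score == 0:
        raise ValueError("score has zero variance; cannot plant target_r2")
    b = (config.exposure_sd * np.sqrt(config.target_r2) / sd_score
         if config.target_r2 > 0 else 0.0)
    x = (config.exposure_mean
         - b * (score - score.mean())
         + c_x * confounder
         + rng.normal(0.0, np.sqrt(var_noise), len(score)))
    return x, b


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    """Intercept making mean(expit(c + lp)) equal the target prevalence."""
    def f(c):
        return expit(c + lp).mean() - prevalence
    lo, hi = -30.0, 30.0
    return brentq(f, lo, hi)


def _draw_traits(config: SimConfig, exposure_centered: np.ndarray,
                 confounder: np.ndarray, age: np.ndarray,
                 pleio_term: pd.DataFrame, rng):
    """Generate all phenome fields from their descriptors."""
    n = len(confounder)
    c_y = config.confounder_effect[1]
    cols, meta = {}, []
    for t in config.trait_spec:
        lp = (t.effect * exposure_centered
              + c_y * confounder
              + t.age_effect * (age - 55.0)
              + pleio_term[t.field_id].to_numpy())
        if t.trait_type == "continuous":
            y = lp + rng.normal(0.0, t.noise_sd, n)
            levels = None
        elif t.trait_type == "binary":
            c0 = _solve_intercept(lp, t.prevalence)
            y = (rng.random(n) < expit(c0 + lp)).astype(float)
            levels = None
        elif t.trait_type == "ordered_categorical":
            latent = lp + rng.logistic(0.0, 1.0, n)
            qs = np.quantile(latent, np.linspace(0, 1, t.n_levels + 1)[1:-1])
            y = np.digitize(latent, qs).astype(float)
            levels = list(range(t.n_levels))
        else:  # unordered: multinomial logit via Gumbel-max utilities
            # per-category slope pattern scales the whole linear predictor,
            # giving category-specific exposure, confounder and direct effects
            k = t.n_levels
            util = _MULTINOMIAL_PATTERN[:k][None, :] * lp[:, None]
            util = util + rng.gumbel(0.0, 1.0, (n, k))
            y = np.array([f"cat{c}" for c in util.argmax(axis=1)], dtype=object)
            levels = None
        cols[t.field_id] = y
        meta.append(FieldMeta(field_id=t.field_id, declared_type=t.trait_type,
                              ordered_levels=levels, category=t.category))
    return pd.DataFrame(cols), meta


def _pleio_dosage_term(genotypes: pd.DataFrame, instruments: InstrumentSet,
                       alpha: pd.DataFrame) -> pd.DataFrame:
    """Per-individual direct-effect term: oriented dosages @ alpha."""
    oriented = instruments.oriented()
    dos = genotypes[oriented["snp"].tolist()].to_numpy(float)
    flip = oriented["flip"].to_numpy(bool)
    dos = np.where(flip[None, :], 2.0 - dos, dos)
    fill = 2.0 * oriented["counted_eaf"].to_numpy(float)
    dos = np.where(np.isnan(dos), fill[None, :], dos)
    term = dos @ alpha.loc[oriented["snp"]].to_numpy()
    return pd.DataFrame(term, columns=alpha.columns)


# ---------------------------------------------------------------------------
# public generators

def simulate_cohort(config: SimConfig):
    """Simulate a female cohort with an exposure-mediated phenome.

    Returns ``(CohortData, InstrumentSet, TruthRecord)``.  Deterministic
    under ``config.seed``.
    """
    rngs = _streams(config.seed)
    instruments = _make_instruments(config, rngs["instruments"])
    cov = _draw_covariates(config.n_individuals, rngs["covariates_female"], sex=0)
    pcs = cov[[f"pc{i}" for i in range(1, 11)]].to_numpy()
    genotypes = _draw_genotypes(config, instruments, rngs["genotypes_female"], pcs)

    score = compute_grs(genotypes, instruments).to_numpy()
    rng_exp = rngs["exposure"]
    confounder = rng_exp.standard_normal(config.n_individuals)
    exposure, b = _draw_exposure(config, score, confounder, rng_exp)

    alpha = _draw_pleiotropy(config, rngs["pleiotropy"])
    pleio_term = _pleio_dosage_term(genotypes, instruments, alpha)
    phenome, meta = _draw_traits(config, exposure - config.exposure_mean,
                                 confounder, cov["age"].to_numpy(),
                                 pleio_term, rngs["traits_female"])

    truth = TruthRecord(
        snp_effects=pd.DataFrame({
            "snp": instruments.snp_ids,
            "beta_x_true": b * instruments.table["beta"].to_numpy(float),
        }),
        trait_effects=pd.DataFrame({
            "field_id": [t.field_id for t in config.trait_spec],
            "trait_type": [t.trait_type for t in config.trait_spec],
            "effect_per_year": [t.effect for t in config.trait_spec],
        }),
        pleiotropy=alpha,
    )
    cohort = CohortData(genotypes=genotypes, covariates=cov,
                        exposure=pd.Series(exposure, name="exposure"),
                        phenome=phenome, meta=meta)
    return cohort, instruments, truth


def simulate_male_cohort(config: SimConfig):
    """Simulate a male negative-control cohort: no exposure pathway.

    Genotypes follow the same generative process (same instruments, same
    pleiotropic effects as the female cohort under the same seed); phenome
    fields receive only confounder, covariate and direct SNP effects.
    Returns ``(CohortData, TruthRecord)``.
    """
    rngs = _streams(config.seed)
    instruments = _make_instruments(config, rngs["instruments"])
    cov = _draw_covariates(config.n_individuals, rngs["covariates_male"], sex=1)
    pcs = cov[[f"pc{i}" for i in range(1, 11)]].to_numpy()
    genotypes = _draw_genotypes(config, instruments, rngs["genotypes_male"], pcs)

    rng_t = rngs["traits_male"]
    confounder = rng_t.standard_normal(config.n_individuals)
    alpha = _draw_pleiotropy(config, rngs["pleiotropy"])
    pleio_term = _pleio_dosage_term(genotypes, instruments, alpha)
    no_exposure = np.zeros(config.n_individuals)
    phenome, meta = _draw_traits(config, no_exposure, confounder,
                                 cov["age"].to_numpy(), pleio_term, rng_t)

    truth = TruthRecord(
        snp_effects=pd.DataFrame({"snp": instruments.snp_ids,
                                  "beta_x_true": np.zeros(len(instruments))}),
        trait_effects=pd.DataFrame({
            "field_id": [t.field_id for t in config.trait_spec],
            "trait_type": [t.trait_type for t in config.trait_spec],
            "effect_per_year": [0.0] * len(config.trait_spec),
        }),
        pleiotropy=alpha,
    )
    cohort = CohortData(genotypes=genotypes, covariates=cov, exposure=None,
                        phenome=phenome, meta=meta)
    return cohort, truth


def simulate_summary_stats(instruments: InstrumentSet, true_effect: float,
                           pleiotropy_mode: str = "none",
                           n_exposure: int = 200_000,
                           n_outcome: int = 100_000, seed: int = 0,
                           pleiotropy_sd: float = 0.0,
                           pleiotropy_mean: float = 0.0,
                           exposure_sd: float = 5.0,
                           outcome_sd: float = 1.0):
    """Paired exposure/outcome GWAS summary statistics for two-sample MR.

    Per SNP j (published effect-allele orientation): the estimated exposure
    effect is the instrument weight plus sampling noise with SE consistent
    with ``n_exposure`` and the allele frequency; the outcome effect is
    ``true_effect * w_j`` plus a direct (pleiotropic) effect — zero, mean
    zero, or nonzero mean, by mode, applied on the exposure-increasing
    orientation so directional pleiotropy is directional — plus its own
    sampling noise.  ``true_effect`` is per year *increase* of the exposure.
    """
    if n_exposure < 2 or n_outcome < 2:
        raise ValueError("sample sizes must be >= 2")
    if len(instruments) == 0:
        raise ValueError("instrument set is empty")
    if pleiotropy_mode not in PLEIOTROPY_MODES:
        raise ValueError(f"unknown pleiotropy_mode {pleiotropy_mode!r}")
    rng = np.random.default_rng(seed)
    t = instruments.table
    w = t["beta"].to_numpy(float)
    p = t["eaf"].to_numpy(float)
    m = len(t)
    var_g = 2.0 * p * (1.0 - p)
    se_x = exposure_sd / np.sqrt(var_g * n_exposure)
    se_y = outcome_sd / np.sqrt(var_g * n_outcome)
    if pleiotropy_mode == "none":
        alpha = np.zeros(m)
    else:
        mean = pleiotropy_mean if pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, pleiotropy_sd, m)
    beta_x = w + rng.standard_normal(m) * se_x
    beta_y = (true_effect * w + np.sign(w) * alpha
              + rng.standard_normal(m) * se_y)
    return [SummaryStatsPair(snp=row.snp, beta_x=bx, se_x=sx,
                             beta_y=by, se_y=sy,
                             effect_allele=row.effect_allele,
                             other_allele=row.other_allele, eaf=row.eaf)
            for row, bx, sx, by, sy in zip(t.itertuples(), beta_x, se_x,
                                           beta_y, se_y)]


# ---------------------------------------------------------------------------
# tab-separated output

def sumstats_frames(pairs, n_exposure: int, n_outcome: int):
    """Split harmonized pairs into exposure and outcome summary tables."""
    def frame(beta, se, n):
        return pd.DataFrame({
            "snp": [p.snp for p in pairs],
            "effect_allele": [p.effect_allele for p in pairs],
            "other_allele": [p.other_allele for p in pairs],
            "eaf": [p.eaf for p in pairs],
            "beta": beta, "se": se,
            "pval": 2.0 * st.norm.sf(np.abs(np.array(beta) / np.array(se))),
            "n": n,
        })
    exp = frame([p.beta_x for p in pairs], [p.se_x for p in pairs], n_exposure)
    out = frame([p.beta_y for p in pairs], [p.se_y for p in pairs], n_outcome)
    return exp, out


def write_sumstats(pairs, outdir, n_exposure: int, n_outcome: int) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp, out = sumstats_frames(pairs, n_exposure, n_outcome)
    exp.to_csv(outdir / "sumstats_exposure.tsv", sep="\t", index=False,
               na_rep=".")
    out.to_csv(outdir / "sumstats_outcome.tsv", sep="\t", index=False,
               na_rep=".")


def write_cohort(cohort: CohortData, truth: TruthRecord, outdir,
                 instruments: InstrumentSet | None = None) -> None:
    """Write a cohort as the pipeline's tab-separated file set."""
    from pathlib import Path
    from .scan import write_meta_tsv
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False,
                            na_rep=".")
    cohort.covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False,
                             na_rep=".")
    if cohort.exposure is not None:
        cohort.exposure.to_frame().to_csv(outdir / "exposure.tsv", sep="\t",
                                          index=False, na_rep=".")
    cohort.phenome.to_csv(outdir / "phenome.tsv", sep="\t", index=False,
                          na_rep=".")
    write_meta_tsv(cohort.meta, outdir / "phenome_meta.tsv")
    truth_long = pd.concat([
        truth.snp_effects.rename(columns={"snp": "id", "beta_x_true": "value"})
        .assign(kind="snp_exposure_effect"),
        truth.trait_effects.rename(columns={"field_id": "id",
                                            "effect_per_year": "value"})
        [["id", "value"]].assign(kind="trait_causal_effect"),
    ])
    truth_long.to_csv(outdir / "truth.tsv", sep="\t", index=False, na_rep=".")
    if instruments is not None:
        instruments.to_tsv(outdir / "instruments.tsv")
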