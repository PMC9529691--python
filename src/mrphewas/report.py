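"""End-to-end orchestration and reporting.

``run_pipeline`` composes the whole analysis on a simulated population:
generate the cohort, build the genetic risk score (full, pruned, and
DDR / non-DDR stratified), scan the female phenome and the male
negative-control phenome, apply the multiple-testing thresholds, follow up
significant continuous/binary fields with one-sample MR, and run the
two-sample estimator suite on simulated summary statistics.  Every stage
writes tab-separated output and the run manifest records digests and counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .instruments import (compute_grs, instrument_strength, prune_instruments,
                          stratify_instruments)
from .onesample import OneSampleMR
from .scan import run_phenome_scan
from .simulate import (SimConfig, simulate_cohort, simulate_male_cohort,
                       simulate_summary_stats, write_cohort, write_sumstats)
from .thresholds import ThresholdResult, fdr_rank_threshold, qq_data
from .twosample import TwoSampleMR

__all__ = ["RunManifest", "run_pipeline", "category_summary", "compare_sexes"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Record of one pipeline run: config, digests, counts, stage status."""

    config: dict
    seed: int
    digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "seed": self.seed,
            "digests": self.digests, "counts": self.counts,
            "stages": self.stages, "timestamp": self.timestamp,
        }, indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: SimConfig, outdir, true_effect_2s: float = 0.04,
                 alpha: float = 0.05) -> RunManifest:
    """Run the full MR-pheWAS pipeline on one simulated population.

    Outputs are written under ``outdir``; the manifest records per-file
    sha-256 digests and stage counts.  Idempotent under a fixed seed: two
    runs with the same config produce identical digests.  Failures in a
    stage are recorded in the manifest and downstream stages are skipped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    state: dict = {}
    stage_fns = [
        ("simulate", _stage_simulate),
        ("grs", _stage_grs),
        ("scan", _stage_scan),
        ("thresholds", _stage_thresholds),
        ("mr_onesample", _stage_mr1),
        ("mr_twosample", _stage_mr2),
    ]
    failed = False
    for name, fn in stage_fns:
        if failed:
            manifest.stages[name] = "skipped: upstream failure"
            continue
        try:
            fn(config, outdir, state, manifest,
               true_effect_2s=true_effect_2s, alpha=alpha)
            manifest.stages[name] = "ok"
            logger.info("stage %s: ok", name)
        except Exception as exc:  # stage failure must not abort the run
            manifest.stages[name] = f"failed: {exc}"
            logger.error("stage %s failed: %s", name, exc)
            failed = True

    for f in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.json")):
        if f.name != "manifest.json":
            manifest.digests[f.name] = _digest(f)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _stage_simulate(config, outdir, state, manifest, **kw):
    cohort, instruments, truth = simulate_cohort(config)
    male_cohort, _ = simulate_male_cohort(config)
    write_cohort(cohort, truth, outdir, instruments=instruments)
    state.update(cohort=cohort, male_cohort=male_cohort,
                 instruments=instruments, truth=truth)
    manifest.counts["n_individuals"] = cohort.n
    manifest.counts["n_snps"] = len(instruments)


def _stage_grs(config, outdir, state, manifest, **kw):
    cohort, instruments = state["cohort"], state["instruments"]
    score = compute_grs(cohort.genotypes, instruments)
    pruned = prune_instruments(instruments, cohort.genotypes)
    scores = pd.DataFrame({"grs_full": score.values})
    for which, label in (("DDR", "grs_ddr"), ("non-DDR", "grs_nonddr")):
        sub = stratify_instruments(instruments, which)
        if len(sub):
            scores[label] = compute_grs(cohort.genotypes, sub).values
    scores["grs_pruned"] = compute_grs(cohort.genotypes, pruned).values
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False, na_rep=".")
    strength = instrument_strength(score, cohort.exposure)
    state.update(score=score, pruned=pruned, strength=strength,
                 male_score=compute_grs(state["male_cohort"].genotypes,
                                        instruments))
    manifest.counts["n_snps_pruned"] = len(pruned)
    manifest.counts["first_stage_r2"] = strength.r_squared
    manifest.counts["first_stage_f"] = strength.f_statistic


def _stage_scan(config, outdir, state, manifest, **kw):
    cohort, male = state["cohort"], state["male_cohort"]
    res_f = run_phenome_scan(state["score"], cohort.phenome, cohort.meta,
                             cohort.covariates)
    res_m = run_phenome_scan(state["male_score"], male.phenome, male.meta,
                             male.covariates)
    res_f.to_frame().to_csv(outdir / "scan_female.tsv", sep="\t", index=False,
                            na_rep=".")
    res_m.to_frame().to_csv(outdir / "scan_male.tsv", sep="\t", index=False,
                            na_rep=".")
    state.update(scan_female=res_f, scan_male=res_m)
    manifest.counts["fields_scanned"] = res_f.n_fields
    manifest.counts["fields_analysed"] = len(res_f)
    manifest.counts["fields_skipped"] = len(res_f.skipped)


def _stage_thresholds(config, outdir, state, manifest, alpha=0.05, **kw):
    out = {}
    for sex, res in (("female", state["scan_female"]),
                     ("male", state["scan_male"])):
        p = res.pvalues
        thr = fdr_rank_threshold(p.to_numpy(), alpha=alpha,
                                 field_ids=p.index.tolist())
        out[sex] = thr
        qq = qq_data(p.to_numpy(), alpha=alpha)
        qq.to_csv(outdir / f"qq_{sex}.tsv", sep="\t", index=False)
        manifest.counts[f"significant_fdr_{sex}"] = len(thr.significant_fdr)
        manifest.counts[f"significant_bonferroni_{sex}"] = (
            len(thr.significant_bonferroni))
    state["thresholds"] = out
    with open(outdir / "thresholds.json", "w") as fh:
        json.dump({sex: {
            "n_tests": t.n_tests, "alpha": t.alpha,
            "bonferroni_threshold": t.bonferroni_threshold,
            "fdr_threshold": t.fdr_threshold, "fdr_rank": t.fdr_rank,
            "significant_fdr": list(t.significant_fdr),
            "significant_bonferroni": list(t.significant_bonferroni),
        } for sex, t in out.items()}, fh, indent=2)


def _stage_mr1(config, outdir, state, manifest, **kw):
    cohort = state["cohort"]
    thr = state["thresholds"]["female"]
    types = {r.field_id: r.resolved_type for r in state["scan_female"]}
    follow = {fid: types[fid] for fid in thr.significant_fdr
              if types.get(fid) in ("continuous", "binary")}
    if not follow:
        manifest.counts["mr1_fields"] = 0
        return
    model = OneSampleMR(state["score"], cohort.exposure, cohort.covariates)
    table = model.fit_many(cohort.phenome, follow)
    table.to_csv(outdir / "mr1_results.tsv", sep="\t", index=False, na_rep=".")
    manifest.counts["mr1_fields"] = len(table)
    state["mr1"] = table


def _stage_mr2(config, outdir, state, manifest, true_effect_2s=0.04, **kw):
    pairs = simulate_summary_stats(
        state["instruments"], true_effect=true_effect_2s,
        pleiotropy_mode=config.pleiotropy_mode,
        pleiotropy_sd=config.pleiotropy_sd,
        pleiotropy_mean=config.pleiotropy_mean,
        seed=config.seed + 1)
    write_sumstats(pairs, outdir, n_exposure=200_000, n_outcome=100_000)
    res = TwoSampleMR(pairs).fit(seed=config.seed + 2)
    res.to_frame().to_csv(outdir / "mr2_results.tsv", sep="\t", index=False,
                          na_rep=".")
    manifest.counts["mr2_methods"] = len(res.estimates)
    state["mr2"] = res


# ---------------------------------------------------------------------------
# summaries

def category_summary(results, meta, thresholds: ThresholdResult) -> pd.DataFrame:
    """Findings per category at the FDR and Bonferroni thresholds."""
    cat = {m.field_id: (m.category or "unspecified") for m in meta}
    fdr = set(thresholds.significant_fdr)
    bonf = set(thresholds.significant_bonferroni)
    rows = {}
    for r in results:
        c = cat.get(r.field_id, "unspecified")
        row = rows.setdefault(c, {"category": c, "n_fields": 0,
                                  "n_fdr": 0, "n_bonferroni": 0})
        row["n_fields"] += 1
        row["n_fdr"] += r.field_id in fdr
        row["n_bonferroni"] += r.field_id in bonf
    out = pd.DataFrame(rows.values()).sort_values("category")
    return out.reset_index(drop=True)


def compare_sexes(results_female, results_male, thresholds_female,
                  thresholds_male, which: str = "fdr") -> pd.DataFrame:
    """Classify every field as female-only / male-only / both / neither.

    Both scans must cover the same field universe; ``which`` selects the
    threshold ("fdr" or "bonferroni").
    """
    ids_f = {r.field_id for r in results_female}
    ids_m = {r.field_id for r in results_male}
    if ids_f != ids_m:
        diff = sorted(ids_f.symmetric_difference(ids_m))
        raise ValueError(f"field universes differ: {diff}")
    attr = ("significant_fdr" if which == "fdr"
            else "significant_bonferroni")
    sig_f = set(getattr(thresholds_female, attr))
    sig_m = set(getattr(thresholds_male, attr))
    rows = []
    for fid in sorted(ids_f):
        f, m = fid in sig_f, fid in sig_m
        cls = ("both" if f and m else "female-only" if f
               else "male-only" if m else "neither")
        rows.append({"field_id": fid, "significant_female": f,
                     "significant_male": m, "classification": cls})
    return pd.DataFrame(rows)
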