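"""End-to-end orchestration of the synthetic study, with a run manifest.

A run mirrors the study design: a development cohort with paired genotypes
and tumor expression is simulated; ROR-P is scored from expression; the
ROR-P PRS is built (LD pruning, HWE fill, residualization, scan, repeated
cross-validated threshold selection, final weights); one or more independent
validation cohorts drawn from the same population are scored and the PRS is
tested against breast cancer-specific survival with ancestry adjustment; a
comparator ER-/ER+ likelihood-ratio PRS is built from simulated case-case
summary statistics and evaluated jointly; the study-level hazard ratios are
combined by REML random-effects meta-analysis.

Every stage draws its randomness from a substream of the single root seed,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .comparator import prune_and_weight_er_prs, score_lr_prs
from .prs import (
    cv_threshold_selection,
    fill_missing_genotypes,
    fit_final_weights,
    ld_prune,
    score_prs,
    standardize_prs,
)
from .scoring import score_expression
from .simulate import SimulationConfig, simulate_cohort, simulate_summary_stats
from .survival import cox_fit, gronnesby_borgan, km_tertiles, random_effects_meta

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of a full synthetic run."""

    seed: int = 0
    outdir: str = "rorp_prs_run"
    n_dev: int = 2500
    n_validation: tuple[int, ...] = (5000, 2500)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    normalization_reps: int = 1000
    cv_folds: int = 5
    cv_repeats: int = 10
    r2_threshold: float = 0.2
    max_missing: float = 0.05
    write_vcf: bool = False
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        if "n_validation" in raw:
            raw["n_validation"] = tuple(raw["n_validation"])
        return cls(simulation=sim, **raw)


def _seed(root: int, stage: int) -> int:
    """Derive a per-stage seed below 2**31 from the root seed."""
    return int(np.random.SeedSequence(entropy=root, spawn_key=(stage,)).generate_state(1)[0] % (2**31))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def add_stage(self, name: str, wall: float, counts: dict, exclusions: list | None = None) -> None:
        self.stages.append(
            {"stage": name, "seconds": round(wall, 3), "counts": counts,
             "exclusions": exclusions or []}
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "results": self.results,
                },
                fh,
                indent=2,
                default=str,
            )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate -> score-rorp -> build-prs -> validate -> meta."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    manifest = RunManifest(config=cfg_dict, version=__version__)
    t0 = _time.time()

    # ---- development cohort -------------------------------------------------
    dev_cfg = replace(config.simulation, n_samples=config.n_dev, seed=_seed(config.seed, 0))
    dev = simulate_cohort(dev_cfg)
    rio.write_genotypes_tsv(dev.genotypes, out / "dev_genotypes.tsv")
    rio.write_snp_info_tsv(dev.genotypes, out / "dev_snp_info.tsv")
    rio.write_expression_tsv(dev.expression, out / "dev_expression.tsv")
    dev.clinical.to_csv(out / "dev_clinical.tsv", sep="\t", index_label="sample")
    dev.truth.samples.to_csv(out / "dev_ground_truth.tsv", sep="\t", index_label="sample")
    dev.centroids.to_tsv(out / "centroids.tsv")
    rio.write_table(dev.ld, out / "dev_ld.tsv")
    if config.write_vcf:
        rio.write_vcf(dev.genotypes, out / "dev_genotypes.vcf")
    manifest.add_stage(
        "simulate_dev", _time.time() - t0,
        {"samples": len(dev.clinical), "snps": dev.genotypes.dosages.shape[1]},
    )

    # ---- ROR-P scoring ------------------------------------------------------
    t0 = _time.time()
    scored = score_expression(
        dev.expression,
        dev.truth.samples["er_status"],
        dev.centroids,
        probe_map=dev.probe_map,
        n_reps=config.normalization_reps,
        seed=_seed(config.seed, 1),
    )
    scored.to_csv(out / "dev_rorp.tsv", sep="\t", index_label="sample")
    n_called = int(scored["call"].notna().sum())
    manifest.add_stage(
        "score_rorp", _time.time() - t0,
        {"samples": len(scored), "called": n_called},
        exclusions=[{"reason": "degenerate_expression", "count": len(scored) - n_called}],
    )

    # ---- PRS construction ---------------------------------------------------
    t0 = _time.time()
    candidates = ld_prune(dev.genotypes.candidates(), dev.ld, config.r2_threshold)
    filled, fill_report = fill_missing_genotypes(
        dev.genotypes, config.max_missing, seed=_seed(config.seed, 2)
    )
    candidates = candidates[candidates["snp"].isin(filled.snps)]
    covars = dev.clinical[[f"PC{i}" for i in range(1, 11)] + ["study"]]
    cv = cv_threshold_selection(
        scored["rorp"], covars, filled, candidates,
        k=config.cv_folds, repeats=config.cv_repeats, seed=_seed(config.seed, 3),
    )
    weights = fit_final_weights(scored["rorp"], covars, filled, cv.selected_snps)
    rio.write_table(weights, out / "prs_weights.tsv")
    rio.write_table(cv.summary(), out / "cv_thresholds.tsv")
    n_excluded = int(fill_report["excluded"].sum())
    manifest.add_stage(
        "build_prs", _time.time() - t0,
        {
            "candidates_in": len(dev.genotypes.candidates()),
            "after_ld_prune": len(candidates),
            "selected_threshold": cv.selected_threshold,
            "selected_snps": cv.n_selected,
            "cv_r2": float(cv.mean_r2[np.argmax(cv.mean_r2)]),
        },
        exclusions=[{"reason": "missingness_gt_max", "count": n_excluded}],
    )
    manifest.results["cv_r2"] = float(np.max(cv.mean_r2))
    manifest.results["selected_threshold"] = cv.selected_threshold
    manifest.results["n_selected_snps"] = cv.n_selected

    # ---- comparator ER-/ER+ PRS --------------------------------------------
    t0 = _time.time()
    stats_tbl = simulate_summary_stats(
        dev.truth.population, dev_cfg, seed=_seed(config.seed, 4)
    )
    lr_weights = prune_and_weight_er_prs(stats_tbl, dev.ld, config.r2_threshold)
    rio.write_table(stats_tbl, out / "summary_stats.tsv")
    rio.write_table(lr_weights, out / "er_prs_weights.tsv")
    manifest.add_stage(
        "build_er_prs", _time.time() - t0,
        {"stats_in": len(stats_tbl), "weights_out": len(lr_weights)},
    )

    # ---- validation cohorts -------------------------------------------------
    study_results, joint_results, validation_rows = [], [], []
    for vi, n_val in enumerate(config.n_validation):
        t0 = _time.time()
        val_cfg = replace(
            config.simulation, n_samples=n_val, seed=_seed(config.seed, 10 + vi)
        )
        val = simulate_cohort(val_cfg, population=dev.truth.population, centroids=dev.centroids)
        vfilled, _ = fill_missing_genotypes(
            val.genotypes, config.max_missing, seed=_seed(config.seed, 20 + vi)
        )
        prs_raw, coverage = score_prs(vfilled, weights)
        prs = standardize_prs(prs_raw)
        lr_raw, lr_cov = score_lr_prs(vfilled, lr_weights)
        lr = standardize_prs(lr_raw, mode="log-zscore")
        records = val.clinical.copy()
        records["rorp_prs"] = prs
        records["er_prs"] = lr
        model = cox_fit(records, "rorp_prs", "ancestry")
        joint = cox_fit(records, ["rorp_prs", "er_prs"], "ancestry")
        km = km_tertiles(records, "rorp_prs")
        gb_stat, gb_df, gb_p = gronnesby_borgan(model)
        label = f"study_{vi + 1}"
        res = model.results[0]
        res.label = label
        study_results.append(res)
        joint_results.append(joint.results[0])
        validation_rows.append(
            {
                "study": label, "n": res.n, "events": res.events,
                "hr_per_sd": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p, "snp_coverage": coverage, "er_prs_coverage": lr_cov,
                "logrank_chi2": km.chi2, "logrank_p": km.p,
                "gb_stat": gb_stat, "gb_df": gb_df, "gb_p": gb_p,
                "joint_rorp_hr": joint.results[0].estimate,
                "er_prs_hr": joint.results[1].estimate,
            }
        )
        records.to_csv(out / f"validation_{vi + 1}_records.tsv", sep="\t", index_label="sample")
        manifest.add_stage(
            f"validate_{vi + 1}", _time.time() - t0,
            {"samples": n_val, "events": res.events, "snp_coverage": coverage},
        )
        if config.make_plots:
            from .plots import km_plot

            km_plot(km, out / f"validation_{vi + 1}_km.png")

    val_df = pd.DataFrame(validation_rows)
    rio.write_table(val_df, out / "validation_results.tsv")

    # ---- meta-analysis ------------------------------------------------------
    t0 = _time.time()
    meta = random_effects_meta(study_results)
    manifest.results.update(
        {
            "meta_hr": meta.summary,
            "meta_ci_low": meta.ci_low,
            "meta_ci_high": meta.ci_high,
            "meta_p": meta.p,
            "tau2": meta.tau2,
            "cochran_q": meta.q,
            "i2": meta.i2,
            "study_hrs": [r.estimate for r in study_results],
        }
    )
    rio.write_table(
        pd.DataFrame(
            [
                {
                    "label": "summary", "hr": meta.summary, "ci_low": meta.ci_low,
                    "ci_high": meta.ci_high, "p": meta.p, "tau2": meta.tau2,
                    "q": meta.q, "i2": meta.i2,
                }
            ]
        ),
        out / "meta_results.tsv",
    )
    manifest.add_stage("meta", _time.time() - t0, {"studies": len(study_results)})

    for f in sorted(out.glob("*.tsv")):
        manifest.outputs[f.name] = _checksum(f)
    manifest.to_json(out / "manifest.json")
    return manifest
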