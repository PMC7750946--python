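"""End-to-end orchestration: simulate -> QC -> phenotype derivation ->
GRS -> observational -> one-sample MR -> two-sample MR -> report.

Every stage consumes the previous stage's output; a manifest records the
seeds, stage order, package version and digests of all written tables, so
identical configurations reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .grs import harmonize, instrument_strength, rescale_score, weighted_score
from .io import (
    variant_records,
    write_cohort,
    write_dosages,
    write_pairs,
    write_summary_stats,
    write_true_params,
    write_variants,
    write_weights,
)
from .observational import inverse_normal, summarize_cohort
from .onesample import TwoStageIV
from .phenotype import derive_all, tabulate_flowchart
from .qc import filter_variants, select_unrelated
from .simulate import simulate_cohort
from .twosample import TwoSampleMR, gwas_scan, make_summary_stats

log = logging.getLogger("refluxmr")

__all__ = ["run_pipeline", "make_report"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run all enabled stages in dependency order; returns the result
    bundle and writes tables plus a manifest under ``out_dir``."""
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.sim.validate()
    results: dict = {"config": {"sim": config.sim.to_dict(),
                                "covariates": config.covariates}}
    written: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage_done(name: str, t_start: float) -> None:
        timings[name] = round(time.time() - t_start, 3)
        log.info("stage %-14s done in %.2fs", name, timings[name])

    if not config.stages.get("simulate", True):
        raise RuntimeError("pipeline requires the simulate stage")

    t = time.time()
    try:
        cohort = simulate_cohort(config.sim)
    except Exception as exc:  # halt with stage name and cause
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    write_cohort(cohort.table, out / "cohort.tsv")
    write_dosages(cohort.dosages, cohort.variants["variant_id"],
                  out / "dosages.tsv")
    write_variants(cohort.variants, out / "variants.tsv")
    write_pairs(cohort.pairs, out / "pairs.tsv")
    write_true_params(cohort.true_params, out / "true_params.json")
    for f in ("cohort.tsv", "dosages.tsv", "variants.tsv", "pairs.tsv",
              "true_params.json"):
        written[f] = _digest(out / f)
    stage_done("simulate", t)

    table = cohort.table
    dosages = cohort.dosages.astype(float)
    variants = cohort.variants

    # --- QC ---------------------------------------------------------------
    if config.stages.get("qc", True):
        t = time.time()
        try:
            retained = select_unrelated(
                table["iid"].tolist(),
                list(zip(cohort.pairs["id1"], cohort.pairs["id2"])),
                seed=config.sim.seed,
            )
            vtab = variants.copy()
            # simulated external-GWAS p-values: instruments were selected at
            # genome-wide significance in their discovery study
            vtab["p"] = 1e-10
            records = variant_records(vtab)
            kept_records = filter_variants(records)
            kept_ids = {r.variant_id for r in kept_records}
        except Exception as exc:
            raise RuntimeError(f"stage 'qc' failed: {exc}") from exc
        keep_rows = table["iid"].isin(retained).to_numpy()
        vmask = variants["variant_id"].isin(kept_ids).to_numpy()
        results["qc"] = {
            "n_total": int(len(table)),
            "n_unrelated": int(keep_rows.sum()),
            "n_variants_total": int(len(variants)),
            "n_variants_kept": int(vmask.sum()),
        }
        stage_done("qc", t)
    else:
        keep_rows = np.ones(len(table), bool)
        vmask = np.ones(len(variants), bool)

    sub = table[keep_rows].reset_index(drop=True)
    sub_dos = dosages[keep_rows][:, vmask]
    sub_variants = variants[vmask].reset_index(drop=True)
    gamma = np.asarray(cohort.true_params.gamma)[vmask]

    # --- phenotype derivation --------------------------------------------
    status = None
    if config.stages.get("derive", True):
        t = time.time()
        try:
            status = derive_all(sub)
            flow = tabulate_flowchart(status)
        except Exception as exc:
            raise RuntimeError(f"stage 'derive' failed: {exc}") from exc
        flow.to_csv(out / "flowchart.tsv", sep="\t", index=False)
        written["flowchart.tsv"] = _digest(out / "flowchart.tsv")
        results["flowchart"] = flow.to_dict("records")
        stage_done("derive", t)

    case = (status["primary_status"] == "case").to_numpy() if status is not None \
        else sub["latent_case"].to_numpy(bool)

    # --- GRS --------------------------------------------------------------
    wgrs = None
    if config.stages.get("grs", True):
        t = time.time()
        try:
            weights = pd.DataFrame(
                {
                    "variant_id": sub_variants["variant_id"],
                    "effect_allele": sub_variants["effect_allele"],
                    "other_allele": sub_variants["other_allele"],
                    "beta": gamma,
                    "se": np.full(len(gamma), 1e-3),
                    "p": np.full(len(gamma), 1e-10),
                    "trait": "exposure",
                }
            )
            write_weights(weights, out / "weights.tsv")
            written["weights.tsv"] = _digest(out / "weights.tsv")
            harm = harmonize(weights, sub_variants)
            ws = weighted_score(sub_dos, harm.instruments, harm.flip)
            wgrs = rescale_score(ws, harm.instruments)
            strength = instrument_strength(
                wgrs, sub["exposure"].to_numpy(),
                sub[config.covariates] if config.covariates else None,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'grs' failed: {exc}") from exc
        results["grs"] = {"n_variants": int(len(harm.instruments)),
                          "n_flipped": harm.n_flipped, **strength}
        pd.DataFrame({"iid": sub["iid"], "ws": ws, "wgrs": wgrs}).to_csv(
            out / "scores.tsv", sep="\t", index=False)
        written["scores.tsv"] = _digest(out / "scores.tsv")
        stage_done("grs", t)

    # --- observational ----------------------------------------------------
    if config.stages.get("observational", True):
        t = time.time()
        try:
            demo = summarize_cohort(
                sub, np.where(case, "case", "control"),
                traits=["age", "sex", "exposure"],
                covariate_cols=config.covariates,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'observational' failed: {exc}") from exc
        demo.to_csv(out / "observational.tsv", sep="\t", index=False)
        written["observational.tsv"] = _digest(out / "observational.tsv")
        results["observational"] = demo.to_dict("records")
        stage_done("observational", t)

    # --- one-sample MR ----------------------------------------------------
    if config.stages.get("mr_one_sample", True) and wgrs is not None:
        t = time.time()
        try:
            model = TwoStageIV(
                case.astype(float), sub["exposure"].to_numpy(), wgrs,
                sub[config.covariates] if config.covariates else None,
            )
            res1 = model.fit()
        except Exception as exc:
            raise RuntimeError(f"stage 'mr_one_sample' failed: {exc}") from exc
        results["mr_one_sample"] = {
            "estimate": res1.estimate,
            "se": res1.reported_se,
            "or": res1.odds_ratio,
            "or_ci95": list(res1.or_ci95),
            "p": res1.pvalue,
            "stage1_F": res1.stage1["F"],
            "n": res1.nobs,
        }
        stage_done("mr_one_sample", t)

    # --- two-sample MR ----------------------------------------------------
    if config.stages.get("mr_two_sample", True):
        t = time.time()
        try:
            # full (related-inclusive) cohort scans, as a two-sample design
            # run inside one cohort
            x_std = inverse_normal(table["exposure"].to_numpy())
            all_case = table["latent_case"].to_numpy(float) \
                if status is None else None
            if all_case is None:
                full_status = derive_all(table)
                all_case = (full_status["primary_status"] == "case").to_numpy(float)
            scan_x = gwas_scan(dosages[:, vmask], x_std,
                               trait_type="continuous",
                               variant_ids=sub_variants["variant_id"].tolist())
            scan_y = gwas_scan(dosages[:, vmask], all_case,
                               trait_type="binary",
                               variant_ids=sub_variants["variant_id"].tolist())
            sx = scan_x.rename(columns={"beta": "beta_x", "se": "se_x",
                                        "p": "p_x"})
            sy = scan_y.rename(columns={"beta": "beta_y", "se": "se_y",
                                        "p": "p_y"})
            stats = make_summary_stats(sx, sy)
            write_summary_stats(stats, out / "summary_stats.tsv")
            written["summary_stats.tsv"] = _digest(out / "summary_stats.tsv")
            mr2 = TwoSampleMR(stats, design="one-cohort")
            fits = mr2.fit_all(seed=config.sim.seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'mr_two_sample' failed: {exc}") from exc
        results["mr_two_sample"] = {
            name: {
                "estimate": r.estimate, "se": r.se, "or": r.odds_ratio,
                "or_ci95": list(r.or_ci95), "p": r.p,
                "q": r.q_statistic, "intercept": r.intercept,
                "intercept_p": r.intercept_p,
            }
            for name, r in fits.items()
        }
        stage_done("mr_two_sample", t)

    # --- report + manifest -------------------------------------------------
    if config.stages.get("report", True):
        report = make_report(results)
        (out / "report.md").write_text(report)
        written["report.md"] = _digest(out / "report.md")
        results["report_path"] = str(out / "report.md")

    manifest = {
        "package": "refluxmr",
        "version": __version__,
        "seed": config.sim.seed,
        "stages": [s for s, on in config.stages.items() if on],
        "timings_s": timings,
        "files": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    results["manifest"] = manifest
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return results


def _fmt_or(d: dict) -> str:
    lo, hi = d["or_ci95"]
    return f"{d['or']:.2f} ({lo:.2f}-{hi:.2f})"


def make_report(results: dict) -> str:
    """Deterministic human-readable markdown report of one pipeline run."""
    lines = ["# refluxmr pipeline report", ""]
    if "qc" in results:
        q = results["qc"]
        lines += [
            "## Quality control",
            f"- individuals: {q['n_total']} total, {q['n_unrelated']} unrelated retained",
            f"- variants: {q['n_variants_total']} total, {q['n_variants_kept']} pass filters",
            "",
        ]
    if "flowchart" in results:
        lines += ["## Phenotype definitions (nested counts)",
                  "", "| definition | cases | controls | excluded |",
                  "|---|---|---|---|"]
        for row in results["flowchart"]:
            lines.append(
                f"| {row['definition']} | {row['cases']} | "
                f"{row['controls']} | {row['excluded']} |")
        lines.append("")
    if "grs" in results:
        g = results["grs"]
        lines += [
            "## Genetic risk score",
            f"- {g['n_variants']} variants ({g['n_flipped']} orientation flips)",
            f"- incremental R² = {g['r2']:.4f}, F = {g['F']:.1f}",
            "",
        ]
    if "observational" in results:
        lines += ["## Observational associations",
                  "", "| trait | controls | cases | OR (95% CI) | p |",
                  "|---|---|---|---|---|"]
        for row in results["observational"]:
            p = row["p"]
            lines.append(
                f"| {row['trait']} | {row['controls']} | {row['cases']} | "
                f"{row['odds_ratio']} | {p:.2g} |")
        lines.append("")
    if "mr_one_sample" in results or "mr_two_sample" in results:
        lines += ["## Mendelian randomization (OR per SD exposure)",
                  "", "| method | OR (95% CI) | p |", "|---|---|---|"]
        if "mr_one_sample" in results:
            d = results["mr_one_sample"]
            lines.append(f"| one-sample two-stage IV | {_fmt_or(d)} | {d['p']:.2g} |")
        for name, d in results.get("mr_two_sample", {}).items():
            lines.append(f"| two-sample {name} | {_fmt_or(d)} | {d['p']:.2g} |")
        lines.append("")
    return "\n".join(lines)
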