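"""End-to-end orchestration: simulate -> K-scan -> refine -> K-rescan -> evaluate.

The protocol follows the published analysis order: first pick a plausible K
(number of ancestral haplotypes) on the unfiltered SNP set, then run the
iterative SNP refinement at that K, then re-assess K on the filtered set,
and finally impute and report concordance. A manifest records the config,
seeds and per-stage outputs so a run is reproducible from it alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np

from . import __version__
from .design import CostParams, choose_k, sweep
from .evaluate import concordance_report, observed_maf
from .hmm import HMMParams, run_em
from .io import RunConfig, write_sample_metadata, write_vcf
from .refine import RefinementPlan, refine_snp_set
from .simdata import CrossDesign, SimCohort, medaka_cross_design, simulate_cohort

logger = logging.getLogger("f2impute")

__all__ = ["k_scan", "full_run", "build_cohort"]


def build_cohort(config: RunConfig, seed: int) -> SimCohort:
    """Simulate the cohort a config describes (design, genome, sequencing)."""
    g = config["genome"]
    c = config["cohort"]
    if c["design"] == "medaka":
        base = medaka_cross_design()
    elif c["design"] == "single_cross":
        base = CrossDesign(crosses=(("72-2", "55-2", 481),))
    else:
        raise ValueError(f"unknown cohort design {c['design']!r}")
    scale = float(c["scale"])
    if scale != 1.0:
        base = CrossDesign(
            crosses=tuple((s, d, max(1, math.ceil(n * scale))) for s, d, n in base.crosses),
            n_f1_truth_per_cross=base.n_f1_truth_per_cross,
            n_f2_truth=base.n_f2_truth,
            f2_truth_cross=base.f2_truth_cross,
        )
    from .simdata import MEDAKA_LINES

    panel_lines = MEDAKA_LINES if set(base.lines) <= set(MEDAKA_LINES) else None
    _, cohort = simulate_cohort(
        design=base,
        panel_lines=panel_lines,
        n_chrom=g["n_chrom"],
        chrom_len=g["chrom_len"],
        n_sites=g["n_sites"],
        exp_rate=g["exp_rate"],
        residual_het=c["residual_het"],
        mean_depth=c["mean_depth"],
        base_error=c["base_error"],
        truth_depth=c["truth_depth"],
        seed=seed,
    )
    return cohort


def k_scan(
    cohort: SimCohort,
    grid: tuple[int, ...],
    params: HMMParams,
    site_idx: np.ndarray | None = None,
) -> dict:
    """Mean truth-sample r² for each candidate K; best K = argmax (ties: smaller K)."""
    sub = cohort if site_idx is None else cohort.take_sites(site_idx)
    truth = sub.truth_mask
    results = {}
    for K in grid:
        p = dataclasses.replace(params, K=K)
        res = run_em(sub.ref_counts, sub.alt_counts, sub.genome_map, p, base_error=sub.base_error)
        rep = concordance_report(res.dosage[truth], sub.truth_genotypes[truth])
        results[int(K)] = rep.mean_per_sample_r2
        logger.info("K-scan: K=%d mean r2=%.4f", K, rep.mean_per_sample_r2)
    best = max(sorted(results), key=lambda k: results[k])
    return {"grid": results, "best_k": int(best)}


def full_run(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the whole pipeline into a run directory; returns its path."""
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {"version": __version__, "config": config.values, "seed": seed, "stages": {}}
    stage = "simulate"
    try:
        cohort = build_cohort(config, seed)
        write_sample_metadata(out / "samples.tsv", cohort)
        write_vcf(
            str(out / "truth.vcf"),
            cohort.genome_map,
            cohort.sample_ids,
            gt=cohort.truth_genotypes,
        )
        write_vcf(
            str(out / "reads.vcf"),
            cohort.genome_map,
            cohort.sample_ids,
            ad=(cohort.ref_counts, cohort.alt_counts),
        )
        manifest["stages"]["simulate"] = {
            "n_samples": cohort.n_samples,
            "n_sites": cohort.genome_map.n_sites,
            "n_truth": int(cohort.truth_mask.sum()),
            "outputs": ["samples.tsv", "truth.vcf", "reads.vcf"],
        }

        imp = config["imputation"]
        k_default = imp["K"] if imp["K"] else choose_k(len(cohort.design.lines))
        base_params = HMMParams(
            K=int(k_default),
            n_gen=int(imp["n_gen"]),
            exp_rate=float(imp["exp_rate"]),
            n_iterations=int(imp["n_iterations"]),
            seed=seed,
            refill_enabled=bool(imp["refill"]),
        )

        stage = "k_scan_initial"
        scan1 = k_scan(cohort, tuple(config["k_scan"]["grid"]), base_params)
        manifest["stages"][stage] = scan1
        chosen_k = scan1["best_k"]

        stage = "refinement"
        params = dataclasses.replace(base_params, K=chosen_k)
        plan = RefinementPlan(
            thresholds=tuple(config["refinement"]["thresholds"]),
            truth_target_depth=float(config["refinement"]["truth_target_depth"]),
        )
        trace = refine_snp_set(cohort, params, plan, seed=seed)
        np.savetxt(
            out / "final_sites.tsv",
            np.column_stack(
                [
                    [cohort.genome_map.chromosomes[ci][0] for ci in cohort.genome_map.chrom_index[trace.final_sites]],
                    cohort.genome_map.pos[trace.final_sites].astype(str),
                ]
            ),
            fmt="%s",
            delimiter="\t",
            header="chrom\tpos",
            comments="",
        )
        with open(out / "refinement_trace.tsv", "w") as fh:
            fh.write("iteration\tthreshold\tn_before\tn_after\tmean_r2\n")
            for i in range(len(trace.thresholds)):
                fh.write(
                    f"{i + 1}\t{trace.thresholds[i]}\t{trace.n_before[i]}\t{trace.n_after[i]}\t{trace.mean_r2[i]:.6f}\n"
                )
        manifest["stages"][stage] = {
            "n_before": trace.n_before,
            "n_after": trace.n_after,
            "mean_r2": trace.mean_r2,
            "outputs": ["final_sites.tsv", "refinement_trace.tsv"],
        }

        stage = "k_scan_filtered"
        scan2 = k_scan(cohort, tuple(config["k_scan"]["grid"]), base_params, site_idx=trace.final_sites)
        manifest["stages"][stage] = scan2
        final_k = scan2["best_k"]

        stage = "final_imputation"
        final_cohort = cohort.take_sites(trace.final_sites)
        final_params = dataclasses.replace(base_params, K=final_k)
        res = run_em(
            final_cohort.ref_counts,
            final_cohort.alt_counts,
            final_cohort.genome_map,
            final_params,
            base_error=final_cohort.base_error,
        )
        gt_call = np.argmax(res.genotype_probs, axis=2)
        write_vcf(
            str(out / "imputed.vcf"),
            final_cohort.genome_map,
            final_cohort.sample_ids,
            gt=gt_call,
            ds=res.dosage,
            gp=res.genotype_probs,
            info_score=res.info,
        )
        truth = final_cohort.truth_mask
        maf = observed_maf(final_cohort.truth_genotypes[truth])
        rep = concordance_report(res.dosage[truth], final_cohort.truth_genotypes[truth], maf=maf)
        rep.maf_bins.to_csv(out / "concordance_maf_bins.tsv", sep="\t", index=False)
        with open(out / "concordance_per_sample.tsv", "w") as fh:
            fh.write("sample_id\tr2\n")
            for sid, r2 in zip(np.array(final_cohort.sample_ids)[truth], rep.per_sample_r2):
                fh.write(f"{sid}\t{r2:.6f}\n")
        manifest["stages"][stage] = {
            "K": final_k,
            "mean_per_sample_r2": rep.mean_per_sample_r2,
            "outputs": ["imputed.vcf", "concordance_maf_bins.tsv", "concordance_per_sample.tsv"],
        }

        if config["sweep"]["enabled"]:
            stage = "sweep"
            sw = sweep(
                final_cohort,
                tuple(config["sweep"]["depth_grid"]),
                tuple(config["sweep"]["n_grid"]),
                final_params,
                CostParams(**{k: float(v) for k, v in config["cost"].items()}),
                replicates=int(config["sweep"]["replicates"]),
                seed=seed,
            )
            sw.to_csv(out / "sweep.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {"rows": len(sw), "outputs": ["sweep.tsv"]}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out
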