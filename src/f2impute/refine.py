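"""Iterative SNP-set refinement.

Starting from the sites that are polymorphic among the high-coverage truth
samples, the refinement loop repeatedly (i) thins the truth samples' reads to
a low target depth, (ii) imputes the whole cohort jointly, (iii) scores every
SNP by its squared Pearson correlation against the truth genotypes across
the truth samples, and (iv) drops SNPs below a per-iteration threshold. The
default schedule runs five iterations with thresholds 0.5, 0.5, 0.75, 0.9,
0.9, mirroring the published protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .evaluate import per_sample_concordance
from .hmm import HMMParams, run_em
from .simdata import SimCohort

__all__ = [
    "RefinementPlan",
    "RefinementTrace",
    "initial_snp_set",
    "per_snp_r2",
    "refine_snp_set",
]

DEFAULT_THRESHOLDS = (0.5, 0.5, 0.75, 0.9, 0.9)


@dataclass(frozen=True)
class RefinementPlan:
    """Per-iteration minimum r² thresholds and the truth-thinning depth."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    truth_target_depth: float = 0.5

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if any(not 0 <= t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class RefinementTrace:
    """Book-keeping of one refinement run."""

    n_before: list[int] = field(default_factory=list)
    n_after: list[int] = field(default_factory=list)
    thresholds: list[float] = field(default_factory=list)
    mean_r2: list[float] = field(default_factory=list)
    final_sites: np.ndarray | None = None  # indices into the cohort's site axis


def initial_snp_set(truth_genotypes: np.ndarray) -> np.ndarray:
    """Sites polymorphic (minor allele count >= 1) among the truth samples.

    ``truth_genotypes`` is (n_truth, T) in {0, 1, 2}. Returns sorted site
    indices; raises if nothing is retained.
    """
    g = np.asarray(truth_genotypes)
    if g.ndim != 2 or g.shape[0] < 1:
        raise ValueError("need at least one truth sample")
    ac = g.sum(axis=0)
    mac = np.minimum(ac, 2 * g.shape[0] - ac)
    keep = np.flatnonzero(mac >= 1)
    if keep.size == 0:
        raise ValueError("no polymorphic site among the truth samples")
    return keep


def per_snp_r2(dosage_truth: np.ndarray, truth_genotypes: np.ndarray) -> np.ndarray:
    """Per-site r² of imputed dosage vs truth genotype across truth samples.

    NaN where either vector is constant across the truth samples.
    """
    d = np.asarray(dosage_truth, dtype=float)
    g = np.asarray(truth_genotypes, dtype=float)
    if d.shape != g.shape:
        raise ValueError("dosage and truth shapes differ")
    if d.shape[0] < 2:
        raise ValueError("need at least 2 truth samples")
    dm = d - d.mean(axis=0)
    gm = g - g.mean(axis=0)
    sd = np.sqrt((dm**2).sum(axis=0))
    sg = np.sqrt((gm**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dm * gm).sum(axis=0) / (sd * sg)
    r2 = r * r
    r2[(sd == 0) | (sg == 0)] = np.nan
    return r2


def _thin_truth_reads(cohort: SimCohort, target_depth: float, rng: np.random.Generator) -> SimCohort:
    """Binomially thin the truth samples' reads to ``target_depth``."""
    from .design import downsample_depth  # local import: avoids a module cycle

    return downsample_depth(cohort, target_depth, rng, only_truth=True)


def refine_snp_set(
    cohort: SimCohort,
    params: HMMParams,
    plan: RefinementPlan = RefinementPlan(),
    impute_fn: Callable | None = None,
    seed: int | np.random.Generator = 0,
) -> RefinementTrace:
    """Run the iterative refinement loop on a sequenced cohort.

    ``impute_fn(cohort_subset, params, iteration) -> (N, T_subset) dosage``
    may be injected (e.g. for testing); by default each iteration runs
    :func:`f2impute.hmm.run_em` jointly on the low-coverage samples and the
    thinned truth samples. Undefined per-SNP r² counts as below threshold.
    """
    truth_mask = cohort.truth_mask
    if truth_mask.sum() < 2:
        raise ValueError("refinement needs at least 2 flagged truth samples")
    rng = np.random.default_rng(seed)
    thinned = _thin_truth_reads(cohort, plan.truth_target_depth, rng)
    sites = initial_snp_set(cohort.truth_genotypes[truth_mask])

    if impute_fn is None:

        def impute_fn(sub: SimCohort, p: HMMParams, iteration: int) -> np.ndarray:
            return run_em(sub.ref_counts, sub.alt_counts, sub.genome_map, p, base_error=sub.base_error).dosage

    trace = RefinementTrace()
    for it, thr in enumerate(plan.thresholds):
        sub = thinned.take_sites(sites)
        it_params = dataclasses.replace(params, seed=params.seed + it)
        dosage = impute_fn(sub, it_params, it)
        r2 = per_snp_r2(dosage[truth_mask], sub.truth_genotypes[truth_mask])
        keep = ~np.isnan(r2) & (r2 >= thr)
        rep = per_sample_concordance(dosage[truth_mask], sub.truth_genotypes[truth_mask])
        trace.n_before.append(int(sites.size))
        trace.n_after.append(int(keep.sum()))
        trace.thresholds.append(float(thr))
        trace.mean_r2.append(rep.mean_per_sample_r2)
        if not keep.any():
            raise RuntimeError(f"refinement iteration {it + 1} dropped every site (threshold {thr})")
        sites = sites[keep]
    trace.final_sites = sites
    return trace
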