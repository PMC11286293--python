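"""Design-space machinery: downsampling, the K rule, the cost model, sweeps.

The experimental design question — how much coverage and how many samples an
F2 imputation study needs — is explored by thinning reads (depth), dropping
samples (cohort size), removing whole crosses (founder diversity), and
scoring each scenario by its concordance and its relative sequencing +
library cost.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import per_sample_concordance
from .hmm import HMMParams, run_em
from .simdata import CrossDesign, SimCohort

__all__ = [
    "CostParams",
    "DEFAULT_REMOVAL_ORDER",
    "downsample_depth",
    "downsample_samples",
    "downsample_crosses",
    "cross_step_table",
    "choose_k",
    "cost",
    "relative_cost",
    "sweep",
]

# published order in which founder lines are removed from the design
DEFAULT_REMOVAL_ORDER = ("22-1", "68-1", "79-2", "15-1", "62-2", "139-4")


@dataclass(frozen=True)
class CostParams:
    """Sequencing + library-prep cost constants.

    g: haploid genome size (bp); flowcell_output: mean usable bp per flow
    cell; cf: cost per flow cell; cp: cost per sample library. The defaults
    are the medaka figures with costs normalized to cp = 1, so cf equals the
    published cf/cp ratio.
    """

    g: float = 734_040_372.0
    flowcell_output: float = 273_542_732_637.0
    cf: float = 683.89
    cp: float = 1.0

    def __post_init__(self) -> None:
        if min(self.g, self.flowcell_output, self.cf, self.cp) <= 0:
            raise ValueError("all cost parameters must be positive")


def downsample_depth(
    cohort: SimCohort,
    d_target: float,
    seed: int | np.random.Generator = 0,
    truth_target: float | None = None,
    only_truth: bool = False,
) -> SimCohort:
    """Binomially thin each sample's reads to a target mean depth.

    Per sample the retention factor is ``min(1, d_target / d_original)`` with
    ``d_original`` the realized mean depth; samples already at or below the
    target are untouched. Truth samples are thinned to ``truth_target``
    (default: same as the cohort); ``only_truth`` leaves the low-coverage
    samples alone, which is how truth reads are equalized to the cohort before
    joint imputation.
    """
    if d_target <= 0:
        raise ValueError("d_target must be > 0")
    if cohort.ref_counts is None:
        raise ValueError("cohort has no reads to thin")
    rng = np.random.default_rng(seed)
    truth = cohort.truth_mask
    d_orig = cohort.realized_depths()
    targets = np.full(cohort.n_samples, float(d_target))
    targets[truth] = d_target if truth_target is None else truth_target
    factor = np.minimum(1.0, targets / np.maximum(d_orig, 1e-300))
    if only_truth:
        factor[~truth] = 1.0
    ref = cohort.ref_counts.copy()
    alt = cohort.alt_counts.copy()
    todo = np.flatnonzero(factor < 1.0)
    for i in todo:
        ref[i] = rng.binomial(ref[i], factor[i])
        alt[i] = rng.binomial(alt[i], factor[i])
    out = cohort.take_samples(np.arange(cohort.n_samples))
    out.ref_counts = ref
    out.alt_counts = alt
    out.haplotype_origins = cohort.haplotype_origins
    return out


def downsample_samples(
    cohort: SimCohort,
    n_target: int,
    seed: int | np.random.Generator = 0,
) -> SimCohort:
    """Random subset of ``n_target`` samples, always retaining truth samples."""
    truth = cohort.truth_mask
    n_truth = int(truth.sum())
    if n_target < n_truth:
        raise ValueError(f"n_target={n_target} smaller than the {n_truth} truth samples")
    if n_target > cohort.n_samples:
        raise ValueError("n_target larger than the cohort")
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(~truth)
    chosen = rng.choice(pool, size=n_target - n_truth, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(truth), chosen]))
    return cohort.take_samples(idx)


def downsample_crosses(
    cohort: SimCohort,
    design: CrossDesign,
    removal_order: tuple[str, ...] = DEFAULT_REMOVAL_ORDER,
) -> list[dict]:
    """Iteratively remove every cross involving each named line.

    Returns one record per step (the full cohort first): the remaining
    founder-line count, the remaining cross count (a reciprocal pair counts
    as one cross), and the reduced cohort. Truth samples belonging to removed
    crosses are dropped too.
    """
    known = set(design.lines)
    for line in removal_order:
        if line not in known:
            raise ValueError(f"unknown line {line!r} in removal order")
    cross_ids = np.array([s.cross_id for s in cohort.samples])
    removed_lines: set[str] = set()
    steps = []

    def snapshot() -> dict:
        active = [
            cid
            for cid, (sire, dam, _) in enumerate(design.crosses)
            if not ({sire, dam} & removed_lines)
        ]
        pairs = {frozenset((design.crosses[cid][0], design.crosses[cid][1])) for cid in active}
        lines = set()
        for p in pairs:
            lines |= set(p)
        keep = np.isin(cross_ids, active)
        return {
            "n_lines": len(lines),
            "n_crosses": len(pairs),
            "cohort": cohort.take_samples(np.flatnonzero(keep)),
            "removed": tuple(sorted(removed_lines)),
        }

    steps.append(snapshot())
    for line in removal_order:
        removed_lines.add(line)
        steps.append(snapshot())
    return steps


def cross_step_table(design: CrossDesign, removal_order: tuple[str, ...] = DEFAULT_REMOVAL_ORDER) -> list[tuple[int, int]]:
    """(lines, crosses) bookkeeping after each removal step, without a cohort."""
    removed: set[str] = set()
    out = []
    for line in removal_order:
        if line not in set(design.lines):
            raise ValueError(f"unknown line {line!r}")
        removed.add(line)
        pairs = {
            frozenset((s, d))
            for s, d, _ in design.crosses
            if not ({s, d} & removed)
        }
        lines = set()
        for p in pairs:
            lines |= set(p)
        out.append((len(lines), len(pairs)))
    return out


def choose_k(n_founder_lines: int) -> int:
    """Number of ancestral haplotypes: twice the number of founder lines."""
    if n_founder_lines < 1:
        raise ValueError("need at least one founder line")
    return 2 * n_founder_lines


def cost(n: float, d: float, params: CostParams = CostParams()) -> float:
    """Total cost of sequencing n samples at mean depth d.

    cost = (n * d * g / flowcell_output) * cf + n * cp
    """
    if n < 0 or d < 0:
        raise ValueError("n and d must be >= 0")
    return (n * d * params.g / params.flowcell_output) * params.cf + n * params.cp


def relative_cost(n: float, d: float, n_ref: float, d_ref: float, params: CostParams = CostParams()) -> float:
    """Cost of scenario (n, d) as a fraction of the reference scenario."""
    ref = cost(n_ref, d_ref, params)
    if ref <= 0:
        raise ValueError("reference cost must be positive")
    return cost(n, d, params) / ref


def sweep(
    cohort: SimCohort,
    depth_grid: tuple[float, ...],
    n_grid: tuple[int, ...],
    params: HMMParams,
    cost_params: CostParams = CostParams(),
    replicates: int = 3,
    seed: int = 0,
    n_ref: int | None = None,
    d_ref: float | None = None,
    eval_on: str = "truth",
) -> pd.DataFrame:
    """Accuracy-vs-cost grid over (cohort size, mean depth).

    For every (n, d, replicate): subset to n samples (truth retained), thin
    reads to depth d (truth included), impute with EM, score the mean
    per-sample r² on the truth samples, and compute the cost relative to the
    reference scenario (default: the input cohort's size and realized mean
    low-coverage depth).

    ``eval_on="all"`` scores every sample instead of only the flagged truth
    samples — available in simulation, where every genotype is known, and
    much less noisy when the truth set is small.
    """
    if not depth_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    if n_ref is None:
        n_ref = cohort.n_samples
    if d_ref is None:
        d_ref = float(cohort.realized_depths()[~cohort.truth_mask].mean())
    ss = np.random.SeedSequence(seed)
    rows = []
    for n in n_grid:
        for d in depth_grid:
            for rep in range(replicates):
                child = np.random.default_rng(ss.spawn(1)[0])
                try:
                    sub = downsample_samples(cohort, n, child)
                    sub = downsample_depth(sub, d, child)
                    res = run_em(
                        sub.ref_counts,
                        sub.alt_counts,
                        sub.genome_map,
                        dataclasses.replace(params, seed=params.seed + rep),
                        base_error=sub.base_error,
                    )
                    mask = sub.truth_mask if eval_on == "truth" else np.ones(sub.n_samples, dtype=bool)
                    rep_r2 = per_sample_concordance(
                        res.dosage[mask], sub.truth_genotypes[mask]
                    ).mean_per_sample_r2
                except Exception as exc:  # re-raise with grid context
                    raise RuntimeError(f"sweep failed at (n={n}, d={d}, replicate={rep})") from exc
                rows.append(
                    {
                        "n_samples": n,
                        "mean_depth": d,
                        "replicate": rep,
                        "mean_r2": rep_r2,
                        "relative_cost": relative_cost(n, d, n_ref, d_ref, cost_params),
                    }
                )
    return pd.DataFrame(rows)
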