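"""Synthetic multi-parent F2 cohorts.

Generates the data structures the imputation analysis assumes: a panel of
nearly-inbred founder lines with residual heterozygosity, F1 hybrids, F2
intercross offspring produced by explicit meioses on a uniform genetic map,
and per-sample per-site allelic read counts from low-pass sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomeMap",
    "FounderPanel",
    "CrossDesign",
    "Sample",
    "SimCohort",
    "make_genome_map",
    "simulate_founders",
    "meiosis",
    "simulate_cross",
    "simulate_reads",
    "simulate_cohort",
    "medaka_cross_design",
    "MEDAKA_LINES",
    "MEDAKA_CROSSES",
]

# §-free restatement of the published medaka design this package emulates:
# eight MIKK-panel founder lines crossed in 10 F2 crosses (one of them
# reciprocal, hence 11 entries), with the printed per-cross F2 sample counts.
MEDAKA_LINES = ("72-2", "55-2", "139-4", "15-1", "62-2", "68-1", "79-2", "22-1")
MEDAKA_CROSSES = (
    ("72-2", "79-2", 153),
    ("72-2", "15-1", 141),
    ("72-2", "139-4", 153),
    ("139-4", "72-2", 149),
    ("72-2", "55-2", 481),
    ("72-2", "62-2", 142),
    ("72-2", "68-1", 164),
    ("68-1", "79-2", 147),
    ("15-1", "62-2", 158),
    ("55-2", "139-4", 373),
    ("72-2", "22-1", 148),
)


@dataclass(frozen=True)
class GenomeMap:
    """Biallelic SNP positions on chromosomes plus a uniform genetic map.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    chrom_index
        Per-site chromosome index into ``chromosomes`` (int array, length T).
    pos
        Per-site 1-based bp position, strictly increasing within a chromosome.
    exp_rate
        Recombination rate in cM/Mb (uniform along the genome).
    """

    chromosomes: tuple[tuple[str, int], ...]
    chrom_index: np.ndarray
    pos: np.ndarray
    exp_rate: float

    def __post_init__(self) -> None:
        if self.exp_rate < 0:
            raise ValueError("exp_rate must be >= 0")
        for ci, (name, length) in enumerate(self.chromosomes):
            p = self.pos[self.chrom_index == ci]
            if p.size and (np.any(np.diff(p) <= 0) or p[0] < 1 or p[-1] > length):
                raise ValueError(f"positions on {name} not strictly increasing in [1, {length}]")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def chrom_sites(self, ci: int) -> np.ndarray:
        """Site indices belonging to chromosome ``ci``."""
        return np.flatnonzero(self.chrom_index == ci)

    def new_chrom_start(self) -> np.ndarray:
        """Boolean mask, True where a site opens a new chromosome."""
        start = np.zeros(self.n_sites, dtype=bool)
        if self.n_sites:
            start[0] = True
            start[1:] = np.diff(self.chrom_index) != 0
        return start

    def subset(self, site_idx: np.ndarray) -> "GenomeMap":
        """Map restricted to the given (sorted) site indices."""
        site_idx = np.asarray(site_idx, dtype=int)
        return GenomeMap(self.chromosomes, self.chrom_index[site_idx], self.pos[site_idx], self.exp_rate)


@dataclass(frozen=True)
class FounderPanel:
    """Founder line haplotypes over the map sites.

    ``haplotypes`` has shape (n_lines, 2, T) with alleles in {0, 1};
    ``residual_het`` is the nominal fraction of heterozygous (line, site) pairs.
    """

    line_ids: tuple[str, ...]
    haplotypes: np.ndarray
    residual_het: float

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line(self, line_id: str) -> np.ndarray:
        return self.haplotypes[self.line_ids.index(line_id)]

    def consensus(self, line_id: str) -> np.ndarray:
        """Per-site mean allele of a line's two haplotypes (its 'line haplotype')."""
        return self.line(line_id).mean(axis=0)


@dataclass(frozen=True)
class CrossDesign:
    """Ordered F2 crosses ``(sire_line, dam_line, n_f2_samples)`` plus truth plan.

    ``n_f1_truth_per_cross`` flags that many F1 per *distinct unordered line
    pair* as high-coverage truth samples; ``n_f2_truth`` extra F2 truth samples
    are taken from the cross at index ``f2_truth_cross`` (default: the first).
    """

    crosses: tuple[tuple[str, str, int], ...]
    n_f1_truth_per_cross: int = 1
    n_f2_truth: int = 2
    f2_truth_cross: int = 0

    def __post_init__(self) -> None:
        for sire, dam, n in self.crosses:
            if n < 0:
                raise ValueError(f"negative F2 count for {sire} x {dam}")

    @property
    def lines(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for sire, dam, _ in self.crosses:
            seen.setdefault(sire)
            seen.setdefault(dam)
        return tuple(seen)

    @property
    def line_pairs(self) -> tuple[frozenset, ...]:
        """Distinct unordered founder-line pairs (a reciprocal cross counts once)."""
        seen: dict[frozenset, None] = {}
        for sire, dam, _ in self.crosses:
            seen.setdefault(frozenset((sire, dam)))
        return tuple(seen)

    @property
    def n_crosses(self) -> int:
        return len(self.line_pairs)

    @property
    def n_f2(self) -> int:
        return sum(n for _, _, n in self.crosses)

    def validate_against(self, panel: FounderPanel) -> None:
        known = set(panel.line_ids)
        for sire, dam, _ in self.crosses:
            if sire not in known or dam not in known:
                raise ValueError(f"cross {sire} x {dam} references a line absent from the panel")


def medaka_cross_design() -> CrossDesign:
    """The published eight-line, ten-cross medaka design (2209 F2 samples).

    The two high-coverage F2 truth samples sit in the 72-2 x 55-2 cross, the
    cross that survives the full cross-downsampling ladder.
    """
    return CrossDesign(crosses=MEDAKA_CROSSES, f2_truth_cross=MEDAKA_CROSSES.index(("72-2", "55-2", 481)))


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cross_id: int  # index into CrossDesign.crosses; -1 for none
    generation: str  # "F1" or "F2"
    is_truth: bool
    depth: float  # target mean sequencing depth (x-coverage)


@dataclass
class SimCohort:
    """Samples, their true diploid genotypes, and (once sequenced) read counts.

    ``truth_genotypes``: (N, T) int8 in {0,1,2} (alternate-allele count).
    ``ref_counts`` / ``alt_counts``: (N, T) integer read counts, None until
    :func:`simulate_reads` has run.
    """

    genome_map: GenomeMap
    design: CrossDesign
    samples: list[Sample]
    truth_genotypes: np.ndarray
    ref_counts: np.ndarray | None = None
    alt_counts: np.ndarray | None = None
    base_error: float | None = None
    haplotype_origins: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def truth_mask(self) -> np.ndarray:
        return np.array([s.is_truth for s in self.samples], dtype=bool)

    def realized_depths(self) -> np.ndarray:
        """Per-sample mean reads per site, from the simulated read counts."""
        if self.ref_counts is None:
            raise ValueError("reads not simulated yet")
        return (self.ref_counts + self.alt_counts).mean(axis=1)

    def take_samples(self, idx: np.ndarray) -> "SimCohort":
        idx = np.asarray(idx, dtype=int)
        return SimCohort(
            genome_map=self.genome_map,
            design=self.design,
            samples=[self.samples[i] for i in idx],
            truth_genotypes=self.truth_genotypes[idx],
            ref_counts=None if self.ref_counts is None else self.ref_counts[idx],
            alt_counts=None if self.alt_counts is None else self.alt_counts[idx],
            base_error=self.base_error,
            haplotype_origins=None
            if self.haplotype_origins is None
            else self.haplotype_origins[idx],
        )

    def take_sites(self, site_idx: np.ndarray) -> "SimCohort":
        site_idx = np.asarray(site_idx, dtype=int)
        return SimCohort(
            genome_map=self.genome_map.subset(site_idx),
            design=self.design,
            samples=list(self.samples),
            truth_genotypes=self.truth_genotypes[:, site_idx],
            ref_counts=None if self.ref_counts is None else self.ref_counts[:, site_idx],
            alt_counts=None if self.alt_counts is None else self.alt_counts[:, site_idx],
            base_error=self.base_error,
            haplotype_origins=None
            if self.haplotype_origins is None
            else self.haplotype_origins[:, :, site_idx],
        )


def make_genome_map(
    n_chrom: int,
    chrom_len: int,
    n_sites: int,
    exp_rate: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> GenomeMap:
    """Draw ``n_sites`` SNP positions per chromosome, uniformly without replacement.

    ``exp_rate`` is the uniform recombination rate in cM/Mb.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites per chromosome")
    if n_sites > chrom_len:
        raise ValueError(f"cannot place {n_sites} distinct sites on a {chrom_len} bp chromosome")
    rng = np.random.default_rng(seed)
    chroms = tuple((f"chr{c + 1}", int(chrom_len)) for c in range(n_chrom))
    chrom_index = np.repeat(np.arange(n_chrom), n_sites)
    pos = np.concatenate(
        [np.sort(rng.choice(chrom_len, size=n_sites, replace=False)) + 1 for _ in range(n_chrom)]
    )
    return GenomeMap(chroms, chrom_index, pos.astype(np.int64), float(exp_rate))


def simulate_founders(
    genome_map: GenomeMap,
    n_lines: int,
    residual_het: float = 0.01,
    seed: int | np.random.Generator = 0,
    af_low: float = 0.05,
    af_high: float = 0.95,
    line_ids: tuple[str, ...] | None = None,
) -> FounderPanel:
    """Simulate nearly-inbred founder lines.

    At each site a population alternate-allele frequency is drawn from
    Uniform(``af_low``, ``af_high``); each line's consensus allele is a
    Bernoulli draw from it; a fraction ``residual_het`` of (line, site) pairs
    is then made heterozygous. Sites fixed across the whole panel are redrawn
    so every site is polymorphic among the 2*n_lines haplotypes.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 founder lines")
    if not 0 <= residual_het < 0.5:
        raise ValueError("residual_het must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    T = genome_map.n_sites
    af = rng.uniform(af_low, af_high, size=T)
    consensus = (rng.random((n_lines, T)) < af).astype(np.int8)
    # redraw consensus alleles at panel-monomorphic sites until all polymorphic
    fixed = np.flatnonzero(consensus.min(axis=0) == consensus.max(axis=0))
    while fixed.size:
        consensus[:, fixed] = (rng.random((n_lines, fixed.size)) < af[fixed]).astype(np.int8)
        sub = consensus[:, fixed]
        fixed = fixed[sub.min(axis=0) == sub.max(axis=0)]
    haps = np.repeat(consensus[:, None, :], 2, axis=1)
    if residual_het > 0:
        het = rng.random((n_lines, T)) < residual_het
        # a heterozygous pair is (0,1) in random phase
        phase = rng.integers(0, 2, size=(n_lines, T))
        haps[:, 0, :] = np.where(het, phase, haps[:, 0, :])
        haps[:, 1, :] = np.where(het, 1 - phase, haps[:, 1, :])
    if line_ids is None:
        line_ids = tuple(f"L{i + 1}" for i in range(n_lines))
    if len(line_ids) != n_lines:
        raise ValueError("line_ids length must equal n_lines")
    return FounderPanel(tuple(line_ids), haps.astype(np.int8), float(residual_het))


def meiosis(
    parent_hap_a: np.ndarray,
    parent_hap_b: np.ndarray,
    genome_map: GenomeMap,
    seed: int | np.random.Generator = 0,
    return_origin: bool = False,
):
    """One gamete: a crossover mosaic of the two parental haplotypes.

    Per chromosome the crossover count is Poisson(exp_rate * L_Mb / 100) and
    crossover positions are uniform; the starting haplotype is a fair coin.
    With ``return_origin`` also returns the 0/1 parental-origin vector.
    """
    rng = np.random.default_rng(seed)
    gm = genome_map
    origin = np.empty(gm.n_sites, dtype=np.int8)
    for ci, (_, length) in enumerate(gm.chromosomes):
        idx = gm.chrom_sites(ci)
        lam = gm.exp_rate * (length / 1e6) / 100.0
        n_xo = rng.poisson(lam)
        xo = np.sort(rng.uniform(0, length, size=n_xo))
        start = rng.integers(0, 2)
        # parity of crossovers left of each site decides the active haplotype
        n_left = np.searchsorted(xo, gm.pos[idx].astype(float))
        origin[idx] = (start + n_left) % 2
    gamete = np.where(origin == 0, parent_hap_a, parent_hap_b).astype(np.int8)
    if return_origin:
        return gamete, origin
    return gamete


def simulate_cross(
    panel: FounderPanel,
    design: CrossDesign,
    genome_map: GenomeMap,
    seed: int | np.random.Generator = 0,
    keep_origins: bool = False,
) -> SimCohort:
    """Breed the design: F0 -> F1 -> F2, recording true genotypes.

    Each F1 carries one gamete from the sire line and one from the dam line;
    each F2 carries gametes from two distinct F1 parents of its cross, so F2
    haplotypes sit two meioses away from the founder haplotypes. Truth flags
    follow the design's truth plan (default: one F1 per distinct cross plus
    two F2 of the first cross).
    """
    design.validate_against(panel)
    rng = np.random.default_rng(seed)
    gm = genome_map
    T = gm.n_sites
    samples: list[Sample] = []
    genos: list[np.ndarray] = []
    origins: list[np.ndarray] = [] if keep_origins else None  # founder-line index per hap per site

    line_index = {lid: i for i, lid in enumerate(panel.line_ids)}
    truth_pairs_done: set[frozenset] = set()

    for cid, (sire, dam, n_f2) in enumerate(design.crosses):
        sire_h = panel.line(sire)
        dam_h = panel.line(dam)
        pair = frozenset((sire, dam))

        # two F1 parents for the intercross, plus flagged F1 truth samples
        def f1() -> tuple[np.ndarray, np.ndarray]:
            g1 = meiosis(sire_h[0], sire_h[1], gm, rng)
            g2 = meiosis(dam_h[0], dam_h[1], gm, rng)
            return g1, g2

        f1_parents = [f1(), f1()]
        n_truth_f1 = design.n_f1_truth_per_cross if pair not in truth_pairs_done else 0
        truth_pairs_done.add(pair)
        for j in range(n_truth_f1):
            h1, h2 = f1_parents[j % len(f1_parents)]
            samples.append(Sample(f"{sire}x{dam}_F1_{j + 1}", cid, "F1", True, np.nan))
            genos.append((h1 + h2).astype(np.int8))
            if keep_origins:
                origins.append(
                    np.stack(
                        [
                            np.full(T, line_index[sire], dtype=np.int16),
                            np.full(T, line_index[dam], dtype=np.int16),
                        ]
                    )
                )

        for j in range(n_f2):
            pa, pb = f1_parents[0], f1_parents[1]
            if keep_origins:
                ga, oa = meiosis(pa[0], pa[1], gm, rng, return_origin=True)
                gb, ob = meiosis(pb[0], pb[1], gm, rng, return_origin=True)
                lab_a = np.where(oa == 0, line_index[sire], line_index[dam]).astype(np.int16)
                lab_b = np.where(ob == 0, line_index[sire], line_index[dam]).astype(np.int16)
                origins.append(np.stack([lab_a, lab_b]))
            else:
                ga = meiosis(pa[0], pa[1], gm, rng)
                gb = meiosis(pb[0], pb[1], gm, rng)
            is_truth = cid == design.f2_truth_cross and j < design.n_f2_truth
            samples.append(Sample(f"{sire}x{dam}_F2_{j + 1}", cid, "F2", is_truth, np.nan))
            genos.append((ga + gb).astype(np.int8))

    return SimCohort(
        genome_map=gm,
        design=design,
        samples=samples,
        truth_genotypes=np.stack(genos) if genos else np.empty((0, T), dtype=np.int8),
        haplotype_origins=np.stack(origins) if keep_origins and origins else None,
    )


def simulate_reads(
    cohort: SimCohort,
    mean_depth: float = 1.4,
    base_error: float = 0.01,
    seed: int | np.random.Generator = 0,
    depth_cv: float = 0.5,
    truth_depth: float = 40.0,
    fixed_depth: bool = False,
) -> SimCohort:
    """Fill per-(sample, site) allelic read counts by low-pass sequencing.

    Per sample a mean depth is drawn from Gamma(mean=``mean_depth``,
    CV=``depth_cv``) (or fixed when ``fixed_depth``); truth samples sequence at
    ``truth_depth``. Read totals per site are Poisson(depth); each read reports
    the alternate allele with probability ``p(1-e) + (1-p)e`` where
    ``p = genotype / 2`` and ``e`` is the per-read base error.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= base_error < 0.5:
        raise ValueError("base_error must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    N, T = cohort.truth_genotypes.shape
    depths = np.empty(N)
    truth = cohort.truth_mask
    if fixed_depth or depth_cv == 0 or mean_depth == 0:
        depths[:] = mean_depth
    else:
        shape = 1.0 / depth_cv**2
        depths[:] = rng.gamma(shape, mean_depth / shape, size=N)
    depths[truth] = truth_depth
    total = rng.poisson(np.broadcast_to(depths[:, None], (N, T)))
    p = cohort.truth_genotypes / 2.0
    p_alt = p * (1 - base_error) + (1 - p) * base_error
    alt = rng.binomial(total, p_alt)
    new_samples = [replace(s, depth=float(d)) for s, d in zip(cohort.samples, depths)]
    return SimCohort(
        genome_map=cohort.genome_map,
        design=cohort.design,
        samples=new_samples,
        truth_genotypes=cohort.truth_genotypes,
        ref_counts=(total - alt).astype(np.int32),
        alt_counts=alt.astype(np.int32),
        base_error=float(base_error),
        haplotype_origins=cohort.haplotype_origins,
    )


def simulate_cohort(
    design: CrossDesign | None = None,
    n_chrom: int = 1,
    chrom_len: int = 5_000_000,
    n_sites: int = 2000,
    exp_rate: float = 2.0,
    residual_het: float = 0.01,
    mean_depth: float = 1.4,
    base_error: float = 0.01,
    seed: int = 0,
    fixed_depth: bool = False,
    truth_depth: float = 40.0,
    keep_origins: bool = False,
    panel_lines: tuple[str, ...] | None = None,
) -> tuple[FounderPanel, SimCohort]:
    """Convenience wrapper: map + founders + cross + reads in one seeded call.

    ``panel_lines`` simulates a founder panel larger than the lines actually
    crossed; SNP sites are polymorphic across that panel, so a cross between
    two of its lines sees a realistic fraction of within-cross monomorphic
    sites (as when a study-wide SNP set is applied to a single cross).
    """
    ss = np.random.SeedSequence(seed)
    r_map, r_fnd, r_cross, r_reads = [np.random.default_rng(s) for s in ss.spawn(4)]
    if design is None:
        design = medaka_cross_design()
    gm = make_genome_map(n_chrom, chrom_len, n_sites, exp_rate, r_map)
    lines = panel_lines if panel_lines is not None else design.lines
    missing = set(design.lines) - set(lines)
    if missing:
        raise ValueError(f"panel_lines must cover the design's lines; missing {sorted(missing)}")
    panel = simulate_founders(gm, len(lines), residual_het, r_fnd, line_ids=lines)
    cohort = simulate_cross(panel, design, gm, r_cross, keep_origins=keep_origins)
    cohort = simulate_reads(
        cohort,
        mean_depth,
        base_error,
        r_reads,
        truth_depth=truth_depth,
        fixed_depth=fixed_depth,
    )
    return panel, cohort
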