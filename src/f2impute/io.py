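"""VCF / TSV I/O and run configuration.

Reading goes through cyvcf2; writing emits plain VCFv4.2 text with GT
(unphased), DS (dosage) and GP (genotype probabilities) FORMAT fields and an
INFO_SCORE INFO field. Only biallelic SNP records are loaded; everything else
is skipped with a logged count. Positions are 1-based as per the standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .simdata import GenomeMap, SimCohort

logger = logging.getLogger("f2impute")

__all__ = [
    "read_vcf",
    "write_vcf",
    "write_sample_metadata",
    "read_sample_metadata",
    "RunConfig",
    "load_config",
]


def read_vcf(path: str, exclude_contigs: tuple[str, ...] = ("MT",)) -> dict:
    """Load a VCF into site metadata plus genotype and/or read-count tables.

    Returns a dict with ``chrom``, ``pos``, ``ref``, ``alt`` site arrays,
    ``samples``, and whichever of ``gt`` (N, T genotypes in {0,1,2}; -1 for
    missing), ``ad_ref`` / ``ad_alt`` (N, T read counts), ``ds`` (N, T
    dosages) the file carries. Multiallelic and non-SNP records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    fmts_seen: set[str] = set()
    chroms, poss, refs, alts = [], [], [], []
    gt_rows, ad_ref_rows, ad_alt_rows, ds_rows = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if var.CHROM in exclude_contigs:
            n_skipped += 1
            continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        fmts = set(var.FORMAT)
        fmts_seen |= fmts
        if "GT" in fmts:
            g = np.asarray(var.genotypes)[:, :2]
            row = np.where((g < 0).any(axis=1), -1, g.clip(min=0).sum(axis=1))
            gt_rows.append(row.astype(np.int8))
        if "AD" in fmts:
            ad = var.format("AD")
            ad = np.where(ad < 0, 0, ad)
            ad_ref_rows.append(ad[:, 0].astype(np.int32))
            ad_alt_rows.append(ad[:, 1].astype(np.int32))
        if "DS" in fmts:
            ds_rows.append(var.format("DS")[:, 0].astype(float))
    if not chroms:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    if not fmts_seen & {"GT", "AD", "DS"}:
        raise ValueError(f"{path}: VCF carries neither GT nor AD")
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP/excluded records", path, n_skipped)
    out = {
        "chrom": np.array(chroms),
        "pos": np.array(poss, dtype=np.int64),
        "ref": np.array(refs),
        "alt": np.array(alts),
        "samples": samples,
    }
    if gt_rows:
        out["gt"] = np.stack(gt_rows, axis=1)
    if ad_ref_rows:
        out["ad_ref"] = np.stack(ad_ref_rows, axis=1)
        out["ad_alt"] = np.stack(ad_alt_rows, axis=1)
    if ds_rows:
        out["ds"] = np.stack(ds_rows, axis=1)
    return out


def write_vcf(
    path: str,
    genome_map: GenomeMap,
    sample_ids: list[str],
    gt: np.ndarray | None = None,
    ad: tuple[np.ndarray, np.ndarray] | None = None,
    ds: np.ndarray | None = None,
    gp: np.ndarray | None = None,
    info_score: np.ndarray | None = None,
) -> None:
    """Write a VCFv4.2 file over the map's sites.

    ``gt`` (N, T) in {0,1,2} (or -1 for missing), ``ad`` a (ref, alt) pair of
    (N, T) arrays, ``ds`` (N, T) dosages, ``gp`` (N, T, 3), ``info_score``
    (T,). REF/ALT are written as A/T placeholders (simulated sites carry no
    nucleotide identity).
    """
    if gt is None and ad is None and ds is None:
        raise ValueError("nothing to write: provide gt, ad or ds")
    fmt_keys = []
    if gt is not None:
        fmt_keys.append("GT")
    if ad is not None:
        fmt_keys.append("AD")
    if ds is not None:
        fmt_keys.append("DS")
    if gp is not None:
        fmt_keys.append("GP")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=f2impute\n")
        for name, length in genome_map.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        if info_score is not None:
            fh.write('##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation info score">\n')
        if gt is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if ad is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">\n')
        if ds is not None:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior alternate-allele dosage">\n')
        if gp is not None:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        fmt = ":".join(fmt_keys)
        for t in range(genome_map.n_sites):
            chrom = genome_map.chromosomes[genome_map.chrom_index[t]][0]
            info = "." if info_score is None else (
                "INFO_SCORE=." if np.isnan(info_score[t]) else f"INFO_SCORE={info_score[t]:.4f}"
            )
            cols = [chrom, str(int(genome_map.pos[t])), ".", "A", "T", ".", "PASS", info, fmt]
            for i in range(len(sample_ids)):
                parts = []
                if gt is not None:
                    parts.append(gt_str[int(gt[i, t])])
                if ad is not None:
                    parts.append(f"{int(ad[0][i, t])},{int(ad[1][i, t])}")
                if ds is not None:
                    parts.append(f"{ds[i, t]:.4f}")
                if gp is not None:
                    parts.append(",".join(f"{p:.4f}" for p in gp[i, t]))
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")


def write_sample_metadata(path: str, cohort: SimCohort) -> None:
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "cross": [s.cross_id for s in cohort.samples],
            "generation": [s.generation for s in cohort.samples],
            "is_truth": [s.is_truth for s in cohort.samples],
            "depth": [s.depth for s in cohort.samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def cohort_from_files(
    reads_vcf: str,
    truth_vcf: str,
    samples_tsv: str,
    exp_rate: float = 2.0,
) -> SimCohort:
    """Assemble a cohort from an AD VCF, a GT truth VCF and a metadata TSV.

    Truth genotypes are taken from the truth VCF for the samples flagged
    ``is_truth`` in the metadata; other rows are zero-filled (they are never
    read by refinement or evaluation).
    """
    from .simdata import CrossDesign, Sample

    reads = read_vcf(reads_vcf)
    if "ad_ref" not in reads:
        raise ValueError(f"{reads_vcf}: no AD field")
    truth = read_vcf(truth_vcf)
    if "gt" not in truth:
        raise ValueError(f"{truth_vcf}: no GT field")
    meta = read_sample_metadata(samples_tsv).set_index("sample_id")
    chrom_names = list(dict.fromkeys(reads["chrom"]))
    gm = GenomeMap(
        tuple((c, int(reads["pos"][reads["chrom"] == c].max())) for c in chrom_names),
        np.array([chrom_names.index(c) for c in reads["chrom"]]),
        reads["pos"],
        exp_rate,
    )
    samples = []
    N, T = len(reads["samples"]), gm.n_sites
    gt = np.zeros((N, T), dtype=np.int8)
    key = {(c, p): j for j, (c, p) in enumerate(zip(truth["chrom"], truth["pos"]))}
    shared = np.array([key.get((c, p), -1) for c, p in zip(reads["chrom"], reads["pos"])])
    if np.any(shared < 0):
        raise ValueError("truth VCF does not cover all sites of the reads VCF")
    for i, sid in enumerate(reads["samples"]):
        row = meta.loc[sid]
        samples.append(
            Sample(sid, int(row.get("cross", -1)), str(row.get("generation", "F2")), bool(row["is_truth"]), float(row.get("depth", np.nan)))
        )
        if bool(row["is_truth"]):
            if sid not in truth["samples"]:
                raise ValueError(f"truth sample {sid} missing from {truth_vcf}")
            gt[i] = truth["gt"][truth["samples"].index(sid)][shared]
    return SimCohort(
        genome_map=gm,
        design=CrossDesign(crosses=()),
        samples=samples,
        truth_genotypes=gt,
        ref_counts=reads["ad_ref"],
        alt_counts=reads["ad_alt"],
        base_error=0.01,
    )


# ---------------------------------------------------------------------------
# run configuration

_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "f2impute_run",
    "genome": {"n_chrom": 1, "chrom_len": 5_000_000, "n_sites": 2000, "exp_rate": 2.0},
    "cohort": {
        "design": "medaka",  # or "single_cross"
        "scale": 1.0,  # multiplies the per-cross F2 counts
        "residual_het": 0.01,
        "mean_depth": 1.4,
        "base_error": 0.01,
        "truth_depth": 40.0,
    },
    "imputation": {
        "K": None,  # None -> twice the founder-line count
        "n_gen": 2,
        "exp_rate": 2.0,
        "n_iterations": 100,
        "refill": False,
    },
    "refinement": {"thresholds": [0.5, 0.5, 0.75, 0.9, 0.9], "truth_target_depth": 0.5},
    "k_scan": {"grid": [2, 4, 8, 16, 24]},
    "cost": {
        "g": 734_040_372,
        "flowcell_output": 273_542_732_637,
        "cf": 683.89,
        "cp": 1.0,
    },
    "sweep": {
        "enabled": False,
        "depth_grid": [0.25, 0.5, 1.0],
        "n_grid": [100, 400],
        "replicates": 3,
    },
}


@dataclass
class RunConfig:
    """Validated nested configuration for the end-to-end pipeline."""

    values: dict = field(default_factory=lambda: _deep_copy(_DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.values[key]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=False)


def _deep_copy(d):
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _merge(default: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dv in default.items():
        if key in user:
            uv = user[key]
            if isinstance(dv, dict):
                if not isinstance(uv, dict):
                    raise ValueError(f"config section {path + key!r} must be a mapping")
                out[key] = _merge(dv, uv, path + key + ".")
            else:
                out[key] = uv
        else:
            out[key] = _deep_copy(dv) if isinstance(dv, dict) else dv
    unknown = set(user) - set(default)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Defaults, optionally overlaid with a YAML file; unknown keys rejected."""
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    merged = _merge(_DEFAULT_CONFIG, user)
    if overrides:
        merged = _merge(merged, overrides)
    return RunConfig(values=merged)
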