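"""Imputation concordance metrics.

Accuracy is summarized as the squared Pearson correlation (r²) between
imputed dosages and true genotypes: per truth sample across sites (then
averaged), and pooled across site-sample pairs within minor-allele-frequency
bins of width 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceReport",
    "pearson_r2",
    "per_sample_concordance",
    "maf_binned_concordance",
    "observed_maf",
]

BIN_WIDTH = 0.05


@dataclass
class ConcordanceReport:
    per_sample_r2: np.ndarray
    mean_per_sample_r2: float
    maf_bins: pd.DataFrame | None = None


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xm = x - x.mean()
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum())
    sy = np.sqrt((ym**2).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    r = (xm * ym).sum() / (sx * sy)
    return float(r * r)


def per_sample_concordance(dosage: np.ndarray, truth: np.ndarray) -> ConcordanceReport:
    """r² across all sites, per sample, plus the unweighted mean across samples."""
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if dosage.shape != truth.shape:
        raise ValueError("dosage and truth shapes differ")
    r2 = np.array([pearson_r2(dosage[i], truth[i]) for i in range(dosage.shape[0])])
    return ConcordanceReport(per_sample_r2=r2, mean_per_sample_r2=float(np.nanmean(r2)))


def observed_maf(truth: np.ndarray) -> np.ndarray:
    """Per-site minor-allele frequency from diploid genotypes in {0, 1, 2}."""
    truth = np.asarray(truth, dtype=float)
    af = truth.mean(axis=0) / 2.0
    return np.minimum(af, 1.0 - af)


def maf_binned_concordance(
    dosage: np.ndarray,
    truth: np.ndarray,
    maf: np.ndarray,
) -> pd.DataFrame:
    """Pooled r² per MAF bin of width 0.05.

    Sites fall in bins [0.05 i, 0.05 (i+1)); the last bin is closed at 0.5.
    Within a bin all (site, sample) dosage/truth pairs are pooled into a
    single correlation; the bin's plotted MAF is the mean observed MAF of its
    member sites. Empty bins carry count 0 and NaN r².
    """
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    maf = np.asarray(maf, dtype=float)
    if np.any(maf > 0.5) or np.any(maf < 0):
        raise ValueError("MAF must lie in [0, 0.5]")
    n_bins = int(round(0.5 / BIN_WIDTH))
    which = np.minimum((maf / BIN_WIDTH).astype(int), n_bins - 1)  # MAF 0.5 -> last bin
    rows = []
    for b in range(n_bins):
        sites = np.flatnonzero(which == b)
        if sites.size:
            pooled_r2 = pearson_r2(dosage[:, sites].ravel(), truth[:, sites].ravel())
            mean_maf = float(maf[sites].mean())
        else:
            pooled_r2, mean_maf = float("nan"), float("nan")
        rows.append(
            {
                "bin_low": b * BIN_WIDTH,
                "bin_high": (b + 1) * BIN_WIDTH,
                "mean_maf": mean_maf,
                "r2": pooled_r2,
                "n_snps": int(sites.size),
            }
        )
    return pd.DataFrame(rows)


def concordance_report(
    dosage: np.ndarray,
    truth: np.ndarray,
    maf: np.ndarray | None = None,
) -> ConcordanceReport:
    """Per-sample and (optionally) MAF-binned concordance in one call."""
    rep = per_sample_concordance(dosage, truth)
    if maf is not None:
        rep.maf_bins = maf_binned_concordance(dosage, truth, maf)
    return rep
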