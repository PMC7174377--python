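"""Post-variant-calling copy-number and enrichment statistics.

Operates downstream of alignment and variant calling: selects SNVs whose
variant allele frequency (VAF) is enriched in treated lines over the
baseline population, converts per-SNP allele counts into B-allele
frequencies (BAF) and log R ratios (LRR), segments the LRR signal,
classifies segments as heterozygous or loss-of-heterozygosity (LOH) with
an exact binomial test, solves sample ploidy (psi) on a grid by distance
of continuous allele-specific copy numbers to integers (purity rho fixed
at 1 for cell lines), and calls gains/losses from depth ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "PloidySolution",
    "vaf_enrichment",
    "compute_baf_lrr",
    "segment_signal",
    "test_segment_heterozygosity",
    "binomial_tail_probability",
    "solve_ploidy",
    "call_depth_ratio",
]

#: SNPs used for BAF/LRR must be common polymorphisms away from telomeric
#: artefact regions: global minor allele frequency in [0.1, 0.2] and
#: genomic position of at least 100 kb.
GMAF_RANGE = (0.1, 0.2)
MIN_POSITION = 100_000

BASES = ("A", "C", "G", "T")


@dataclass
class Segment:
    """A contiguous genomic segment with its copy-number evidence."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_snps: int
    mean_lrr: float
    het_flag: Optional[bool] = None
    het_major_af: Optional[float] = None  # median major AF of het SNPs
    het_p_value: Optional[float] = None
    depth_ratio: Optional[float] = None
    call: Optional[str] = None  # gain | loss | neutral

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one SNP")


@dataclass
class PloidySolution:
    """Grid-search ploidy fit with purity fixed at 1."""

    psi: float
    rho: float
    distance: float
    grid: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not 1.5 - 1e-9 <= self.psi <= 5.5 + 1e-9:
            raise ValueError("psi outside the searched range [1.5, 5.5]")
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


# ---------------------------------------------------------------------------
# SNV enrichment
# ---------------------------------------------------------------------------

def vaf_enrichment(
    snv_table: pd.DataFrame,
    treated_samples: Sequence[str],
    pot_sample: str = "POT",
    fold: float = 10.0,
    min_cov: int = 10,
) -> pd.DataFrame:
    """SNVs whose VAF is enriched ``fold``-fold in any treated line over POT.

    ``snv_table`` must carry ``vaf_<sample>`` and ``cov_<sample>`` columns
    for the POT sample and each treated sample.  SNVs must reach
    ``min_cov`` coverage in all samples; a POT VAF of 0 is floored at
    1 / (coverage + 1) so enrichment stays finite.

    Returns the enriched subset with an ``enriched_in`` column listing the
    treated samples reaching the fold change.
    """
    if f"vaf_{pot_sample}" not in snv_table.columns:
        raise ValueError(f"missing POT column vaf_{pot_sample}")
    samples = [pot_sample, *treated_samples]
    for s in samples:
        for prefix in ("vaf_", "cov_"):
            if f"{prefix}{s}" not in snv_table.columns:
                raise ValueError(f"missing column {prefix}{s}")

    cov_ok = np.logical_and.reduce(
        [snv_table[f"cov_{s}"].to_numpy() >= min_cov for s in samples]
    )
    pot_vaf = snv_table[f"vaf_{pot_sample}"].to_numpy(dtype=float)
    pot_cov = snv_table[f"cov_{pot_sample}"].to_numpy(dtype=float)
    pot_floor = np.where(pot_vaf > 0, pot_vaf, 1.0 / (pot_cov + 1.0))

    enriched_in = []
    any_enriched = np.zeros(len(snv_table), dtype=bool)
    per_sample = {}
    for s in treated_samples:
        hit = snv_table[f"vaf_{s}"].to_numpy(dtype=float) >= fold * pot_floor
        per_sample[s] = hit
        any_enriched |= hit
    keep = cov_ok & any_enriched
    out = snv_table.loc[keep].copy()
    out["enriched_in"] = [
        ",".join(s for s in treated_samples if per_sample[s][i])
        for i in np.flatnonzero(keep)
    ]
    return out


# ---------------------------------------------------------------------------
# BAF / LRR
# ---------------------------------------------------------------------------

def compute_baf_lrr(
    snp_table: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    gmaf_range: tuple[float, float] = GMAF_RANGE,
    min_position: int = MIN_POSITION,
) -> pd.DataFrame:
    """BAF and LRR from per-SNP base counts.

    Input columns: ``chrom``, ``pos``, ``A``, ``C``, ``G``, ``T`` and
    optionally ``gmaf``.  SNPs are filtered to ``gmaf`` within
    ``gmaf_range`` (when the column is present) and position of at least
    ``min_position``.

    The major allele frequency is the highest base count divided by total
    coverage; the BAF is that value or its complement with probability 1/2
    each (random A/B allele assignment, seeded).  LRR is log2(coverage)
    recentred by subtracting the global median.  Zero-coverage SNPs are
    dropped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = snp_table.copy()
    if "gmaf" in df.columns:
        df = df[(df["gmaf"] >= gmaf_range[0]) & (df["gmaf"] <= gmaf_range[1])]
    df = df[df["pos"] >= min_position]

    counts = df[list(BASES)].to_numpy(dtype=float)
    coverage = counts.sum(axis=1)
    if np.any(coverage == 0):
        warnings.warn(f"dropping {int((coverage == 0).sum())} zero-coverage SNPs")
        df = df[coverage > 0]
        counts = df[list(BASES)].to_numpy(dtype=float)
        coverage = counts.sum(axis=1)
    if len(df) == 0:
        raise ValueError("no SNPs left after filtering")

    major_af = counts.max(axis=1) / coverage
    flip = rng.random(len(df)) < 0.5
    baf = np.where(flip, 1.0 - major_af, major_af)
    log2cov = np.log2(coverage)
    lrr = log2cov - np.median(log2cov)

    out = df.copy()
    out["coverage"] = coverage
    out["major_af"] = major_af
    out["baf"] = baf
    out["lrr"] = lrr
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best binary split point of a signal and its t-like statistic.

    For every split 1 <= i < n, computes the two-sample t statistic between
    x[:i] and x[i:] under a pooled variance estimate; returns the argmax
    split and its |t|.
    """
    n = len(x)
    csum = np.cumsum(x)
    tot = csum[-1]
    i = np.arange(1, n)
    mean_l = csum[:-1] / i
    mean_r = (tot - csum[:-1]) / (n - i)
    css = np.cumsum(x**2)
    ss_l = css[:-1] - i * mean_l**2
    ss_r = (css[-1] - css[:-1]) - (n - i) * mean_r**2
    dof = np.maximum(n - 2, 1)
    pooled = np.sqrt(np.maximum(ss_l + ss_r, 0.0) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean_l - mean_r) / (pooled * np.sqrt(1.0 / i + 1.0 / (n - i)))
    # 0/0 (flat on both sides) is no evidence; x/0 with x > 0 is a clean step
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf)
    best = int(np.argmax(t))
    return best + 1, float(t[best])


def _segment_recursive(
    x: np.ndarray, start: int, threshold: float, min_size: int, breaks: list[int]
) -> None:
    if len(x) < 2 * min_size:
        return
    split, t = _best_split(x)
    if split < min_size or len(x) - split < min_size:
        # restrict to admissible splits
        n = len(x)
        cands = []
        for i in range(min_size, n - min_size + 1):
            cands.append(i)
        if not cands:
            return
        stats_at = []
        for i in cands:
            xl, xr = x[:i], x[i:]
            num = abs(xl.mean() - xr.mean())
            pooled = np.sqrt(
                max(((xl - xl.mean()) ** 2).sum() + ((xr - xr.mean()) ** 2).sum(), 0.0)
                / max(n - 2, 1)
            )
            den = pooled * np.sqrt(1 / len(xl) + 1 / len(xr))
            stats_at.append(num / den if den > 0 else (np.inf if num > 0 else 0.0))
        j = int(np.argmax(stats_at))
        split, t = cands[j], stats_at[j]
    if t <= threshold:
        return
    breaks.append(start + split)
    _segment_recursive(x[:split], start, threshold, min_size, breaks)
    _segment_recursive(x[split:], start + split, threshold, min_size, breaks)


def segment_signal(
    values: Sequence[float],
    positions: Sequence[int],
    chromosomes: Sequence[str],
    threshold: float = 5.0,
    min_size: int = 3,
) -> list[Segment]:
    """Segment a per-SNP signal into contiguous constant-mean pieces.

    Recursive binary splitting per chromosome on a t-like statistic; a
    split is accepted when |t| exceeds ``threshold``.  Positions must be
    sorted within each chromosome.  Externally produced segments can be
    supplied directly to the downstream calls instead.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    chromosomes = np.asarray(chromosomes, dtype=object)
    segments: list[Segment] = []
    for chrom in pd.unique(chromosomes):
        mask = chromosomes == chrom
        pos = positions[mask]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
        x = values[mask]
        breaks: list[int] = []
        _segment_recursive(x, 0, threshold, min_size, breaks)
        bounds = [0, *sorted(breaks), len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                Segment(
                    chromosome=str(chrom),
                    start=int(pos[a]),
                    end=int(pos[b - 1]),
                    n_snps=b - a,
                    mean_lrr=float(x[a:b].mean()),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# Heterozygosity / LOH test
# ---------------------------------------------------------------------------

def binomial_tail_probability(k: int, n: int, p: float) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def test_segment_heterozygosity(
    major_afs: Sequence[float],
    het_threshold: float = 0.9,
    null_prop: float = 0.05,
    alpha: float = 0.05,
) -> tuple[bool, Optional[float], float]:
    """Classify a segment as heterozygous or LOH by exact binomial test.

    ``major_afs`` are the per-SNP major allele frequencies of the segment.
    SNPs with major AF below ``het_threshold`` count as heterozygous; the
    one-sided exact binomial test asks whether more than ``null_prop`` of
    the segment is heterozygous.  Returns ``(het_flag, median_het_major_af,
    p_value)``; the median major AF over heterozygous SNPs is reported
    only for heterozygous segments.
    """
    afs = np.asarray(major_afs, dtype=float)
    if afs.size == 0:
        raise ValueError("segment has no SNPs")
    het = afs < het_threshold
    k = int(het.sum())
    p = binomial_tail_probability(k, afs.size, null_prop)
    het_flag = p < alpha
    med = float(np.median(afs[het])) if het_flag and k else None
    return het_flag, med, p


# ---------------------------------------------------------------------------
# Ploidy grid search
# ---------------------------------------------------------------------------

def solve_ploidy(
    segments: pd.DataFrame,
    psi_range: tuple[float, float] = (1.5, 5.5),
    psi_step: float = 0.01,
    weight_by_snps: bool = True,
    rho: float = 1.0,
) -> PloidySolution:
    """Grid-search sample ploidy from segment LRR and allelic imbalance.

    ``segments`` needs columns ``mean_lrr``, ``n_snps``, ``het_flag`` and
    ``het_major_af`` (major-allele fraction of heterozygous segments; LOH
    segments may carry NaN, treated as major fraction 1).  For each psi on
    the grid, continuous copy numbers are

        total = psi * 2**mean_lrr
        major = het_major_af * total      (1.0 * total for LOH segments)
        minor = total - major

    and the objective is the (SNP-count weighted) sum of squared distances
    of major and minor to their nearest integers.  Purity is fixed at
    ``rho = 1``; the psi with the smallest distance wins.
    """
    if len(segments) == 0:
        raise ValueError("no segments supplied")
    lrr = segments["mean_lrr"].to_numpy(dtype=float)
    n_snps = segments["n_snps"].to_numpy(dtype=float)
    major_frac = segments["het_major_af"].to_numpy(dtype=float).copy()
    if "het_flag" in segments.columns:
        loh = ~segments["het_flag"].to_numpy(dtype=bool)
        major_frac[loh] = 1.0
    major_frac = np.where(np.isnan(major_frac), 1.0, major_frac)
    w = n_snps if weight_by_snps else np.ones_like(n_snps)

    psis = np.arange(psi_range[0], psi_range[1] + psi_step / 2, psi_step)
    total = psis[:, None] * np.power(2.0, lrr)[None, :]
    major = major_frac[None, :] * total
    minor = total - major
    dist = (
        w[None, :] * ((major - np.round(major)) ** 2 + (minor - np.round(minor)) ** 2)
    ).sum(axis=1)
    best = int(np.argmin(dist))
    grid = pd.DataFrame({"psi": psis, "distance": dist})
    return PloidySolution(
        psi=float(psis[best]), rho=rho, distance=float(dist[best]), grid=grid
    )


# ---------------------------------------------------------------------------
# Depth-ratio calls
# ---------------------------------------------------------------------------

def call_depth_ratio(
    depth_ratios: Sequence[float],
    gain_threshold: float = 1.2,
    loss_threshold: float = 0.8,
) -> list[str]:
    """Gain/loss/neutral calls from treated-vs-baseline depth ratios.

    Gains are ratios strictly above ``gain_threshold``, losses strictly
    below ``loss_threshold``; the boundaries themselves are neutral.
    """
    ratios = np.asarray(depth_ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("depth ratios must be positive")
    return [
        "gain" if r > gain_threshold else "loss" if r < loss_threshold else "neutral"
        for r in ratios
    ]
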