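"""Per-barcode growth rates and resistance phenotypes from frequency tables.

The baseline frequency of a barcode is taken conservatively as the maximum
of its frequencies in the two DMSO control flasks, f0 = Max(fD7, fD8).
Its growth rate in a drug-treated replicate harvested after T weeks is

    r = (1/T) * ln(fR / f0)   [per week]

and a phenotype is assigned from the pattern of replicates in which r > 0:
positive in at least one gefitinib AND one trametinib replicate means
double-resistant; in two or more replicates of one drug arm only,
single-drug resistant; in exactly one replicate overall, putatively
de novo; otherwise sensitive.  Barcodes absent from both DMSO flasks have
no measurable rate and are labelled undetermined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .barcode_processing import BarcodeCensus

__all__ = [
    "PHENOTYPES",
    "DOUBLE_RESISTANT",
    "GEF_RESISTANT",
    "TRM_RESISTANT",
    "DE_NOVO",
    "SENSITIVE",
    "UNDETERMINED",
    "GrowthRecord",
    "baseline_frequency",
    "growth_rate",
    "assign_phenotypes",
    "build_growth_table",
    "phenotype_proportions",
    "floating_trajectories",
    "census_similarity",
    "fit_log_linear_growth",
    "functional_subclones",
]

DOUBLE_RESISTANT = "DOUBLE_RESISTANT"
GEF_RESISTANT = "GEF_RESISTANT"
TRM_RESISTANT = "TRM_RESISTANT"
DE_NOVO = "DE_NOVO"
SENSITIVE = "SENSITIVE"
UNDETERMINED = "UNDETERMINED"

PHENOTYPES = (
    DOUBLE_RESISTANT,
    GEF_RESISTANT,
    TRM_RESISTANT,
    DE_NOVO,
    SENSITIVE,
    UNDETERMINED,
)

#: Weeks between drug exposure and harvest for each drug arm.
DEFAULT_T_WEEKS = {"GEF": 4.0, "TRM": 9.0}


@dataclass
class GrowthRecord:
    """Baseline frequency, per-replicate rates and phenotype of one barcode."""

    barcode: str
    f0: Optional[float]
    fR: dict[str, float] = field(default_factory=dict)
    r: dict[str, float] = field(default_factory=dict)
    phenotype: str = UNDETERMINED
    observed_in_replicate: bool = False


def baseline_frequency(fD7: float, fD8: float) -> Optional[float]:
    """Conservative baseline f0 = Max(fD7, fD8); None when absent from both."""
    if not (0.0 <= fD7 <= 1.0 and 0.0 <= fD8 <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    f0 = max(fD7, fD8)
    return f0 if f0 > 0 else None


def growth_rate(fR: float, f0: float, t_weeks: float) -> float:
    """Per-week growth rate r = (1/T) ln(fR / f0).

    ``fR = 0`` (barcode extinct in the replicate) returns -inf, which the
    phenotype rules treat as a negative rate.
    """
    if f0 is None or f0 <= 0:
        raise ValueError("growth rate undefined for f0 <= 0")
    if t_weeks <= 0:
        raise ValueError("t_weeks must be positive")
    if fR < 0:
        raise ValueError("fR must be non-negative")
    if fR == 0:
        return -math.inf
    return math.log(fR / f0) / t_weeks


def _arm(replicate: str) -> str:
    for arm in ("GEF", "TRM", "DMSO"):
        if replicate.upper().startswith(arm):
            return arm
    raise ValueError(f"unknown replicate label: {replicate!r}")


def assign_phenotypes(
    rates: Mapping[str, Mapping[str, float]],
    undetermined: Iterable[str] = (),
) -> dict[str, str]:
    """Assign one phenotype per barcode from per-replicate growth rates.

    ``rates`` maps barcode -> {replicate label -> r}.  Rules, in order:

    1. r > 0 in >=1 GEF and >=1 TRM replicate  -> double-resistant
    2. r > 0 in >=2 GEF replicates, none TRM   -> gefitinib-resistant
    3. r > 0 in >=2 TRM replicates, none GEF   -> trametinib-resistant
    4. r > 0 in exactly one replicate overall  -> putatively de novo
    5. any measured rates otherwise            -> sensitive
    6. barcodes listed in ``undetermined`` (no DMSO baseline) -> undetermined
    """
    out: dict[str, str] = {}
    for barcode, reps in rates.items():
        pos_gef = sum(1 for lab, r in reps.items() if _arm(lab) == "GEF" and r > 0)
        pos_trm = sum(1 for lab, r in reps.items() if _arm(lab) == "TRM" and r > 0)
        if pos_gef >= 1 and pos_trm >= 1:
            out[barcode] = DOUBLE_RESISTANT
        elif pos_gef >= 2 and pos_trm == 0:
            out[barcode] = GEF_RESISTANT
        elif pos_trm >= 2 and pos_gef == 0:
            out[barcode] = TRM_RESISTANT
        elif pos_gef + pos_trm == 1:
            out[barcode] = DE_NOVO
        else:
            out[barcode] = SENSITIVE
    for barcode in undetermined:
        out[barcode] = UNDETERMINED
    return out


def build_growth_table(
    censuses: Sequence[BarcodeCensus],
    t_weeks: Mapping[str, float] = DEFAULT_T_WEEKS,
    dmso_ids: tuple[str, str] = ("DMSO7", "DMSO8"),
    min_f0: float = 0.0,
) -> pd.DataFrame:
    """Full growth-rate and phenotype table from attached final censuses.

    Uses the two DMSO censuses for the baseline and every final attached
    GEF/TRM census as a drug replicate.  Returns a tidy DataFrame indexed
    by barcode with columns ``f0``, ``r_<replicate>`` for each replicate,
    and ``phenotype``.  ``min_f0`` optionally suppresses rate estimates
    for barcodes below a baseline-frequency floor (off by default).
    """
    by_id = {c.sample_id: c for c in censuses}
    for sid in dmso_ids:
        if sid not in by_id:
            raise ValueError(f"missing DMSO census {sid!r}")
    d7, d8 = (by_id[s].frequencies for s in dmso_ids)
    reps = [
        c
        for c in censuses
        if c.condition in ("GEF", "TRM")
        and c.compartment == "attached"
        and c.timepoint is None
    ]
    if not reps:
        raise ValueError("no final attached drug-replicate censuses found")

    barcodes = set(d7) | set(d8)
    for c in reps:
        barcodes |= set(c.counts)

    rows = []
    rates: dict[str, dict[str, float]] = {}
    undetermined = []
    for bc in sorted(barcodes):
        f0 = baseline_frequency(d7.get(bc, 0.0), d8.get(bc, 0.0))
        if min_f0 > 0 and f0 is not None and f0 < min_f0:
            f0 = None
        row: dict = {"barcode": bc, "f0": f0}
        if f0 is None:
            undetermined.append(bc)
        else:
            rates[bc] = {}
            for c in reps:
                t = t_weeks[c.condition]
                r = growth_rate(c.frequency(bc), f0, t)
                rates[bc][c.sample_id] = r
                row[f"r_{c.sample_id}"] = r
        rows.append(row)

    phenos = assign_phenotypes(rates, undetermined=undetermined)
    df = pd.DataFrame(rows).set_index("barcode")
    df["phenotype"] = pd.Series(phenos)
    return df


def phenotype_proportions(
    table: pd.DataFrame,
    censuses: Sequence[BarcodeCensus] = (),
) -> pd.DataFrame:
    """Unique-barcode proportions and pooled frequencies per phenotype.

    Proportions are over unique barcodes in ``table``; pooled frequencies
    are the summed barcode frequencies of each phenotype class in each
    provided census.
    """
    counts = table["phenotype"].value_counts()
    out = pd.DataFrame(
        {
            "n_barcodes": [int(counts.get(p, 0)) for p in PHENOTYPES],
        },
        index=pd.Index(PHENOTYPES, name="phenotype"),
    )
    out["proportion"] = out["n_barcodes"] / max(len(table), 1)
    for census in censuses:
        freqs = census.frequencies
        pooled = []
        for p in PHENOTYPES:
            bcs = table.index[table["phenotype"] == p]
            pooled.append(sum(freqs.get(b, 0.0) for b in bcs))
        out[f"pooled_{census.sample_id}"] = pooled
    return out


def floating_trajectories(censuses: Sequence[BarcodeCensus]) -> pd.DataFrame:
    """Tidy per-barcode frequency time series from weekly floating censuses.

    Returns columns ``replicate``, ``week``, ``barcode``, ``frequency``.
    Missing weeks simply do not appear (no interpolation); replicates
    with no floating samples yield no rows.
    """
    rows = []
    floats = [c for c in censuses if c.compartment == "floating"]
    for c in sorted(floats, key=lambda c: (c.sample_id, c.timepoint or 0)):
        for bc, f in c.frequencies.items():
            rows.append((c.sample_id.split("-F")[0], c.timepoint, bc, f))
    return pd.DataFrame(rows, columns=["replicate", "week", "barcode", "frequency"])


def census_similarity(a: BarcodeCensus, b: BarcodeCensus, metric: str = "cosine") -> float:
    """Cosine similarity (or 1 - total variation) between two censuses."""
    barcodes = sorted(set(a.counts) | set(b.counts))
    fa = np.array([a.frequency(x) for x in barcodes])
    fb = np.array([b.frequency(x) for x in barcodes])
    if metric == "cosine":
        na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
        if na == 0 or nb == 0:
            return 0.0
        return float(fa @ fb / (na * nb))
    if metric == "tv":
        return float(1.0 - 0.5 * np.abs(fa - fb).sum())
    raise ValueError(f"unknown metric {metric!r}")


def fit_log_linear_growth(times: Sequence[float], values: Sequence[float]) -> float:
    """Growth rate per unit time by OLS on log-transformed measurements."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(values <= 0):
        raise ValueError("values must be positive for log transformation")
    from scipy import stats

    res = stats.linregress(times, np.log(values))
    return float(res.slope)


def functional_subclones(
    table: pd.DataFrame,
    distance_cutoff: float = 0.5,
) -> pd.Series:
    """Group barcodes with similar growth dynamics into functional subclones.

    Agglomerative (average-linkage) clustering on the vector of
    per-replicate growth rates, cut at ``distance_cutoff`` (euclidean).
    Barcodes with any unmeasurable rate (undetermined or -inf) are left
    ungrouped (label 0).
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    rcols = [c for c in table.columns if c.startswith("r_")]
    X = table[rcols].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    labels = np.zeros(len(table), dtype=int)
    if ok.sum() >= 2:
        Z = linkage(X[ok], method="average", metric="euclidean")
        labels[ok] = fcluster(Z, t=distance_cutoff, criterion="distance")
    elif ok.sum() == 1:
        labels[ok] = 1
    return pd.Series(labels, index=table.index, name="subclone")
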