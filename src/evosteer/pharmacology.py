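"""Drug-screen analytics and dose-response fitting.

Raw plate-reader fluorescence is converted into a percentage of
inhibition (PCI) against plate-internal controls,

    PCI = 100 * (c_pos - I) / (c_pos - c_neg),

where c_pos is the mean of drug-free wells seeded with cells and c_neg the
mean of empty wells.  Collateral-sensitivity hits are compounds whose mean
PCI change versus a control line reaches the top six (after excluding
changes below 5%) in more than one concentration or replicate.  Viability
curves are summarised by a two-parameter log-logistic model,

    y(x) = 100 / (1 + (x / ec50)^hill),

fitted by non-linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Well",
    "PlateReading",
    "DoseResponseFit",
    "plate_percent_inhibition",
    "rank_and_identify_hits",
    "fit_dose_response",
    "ic50_fold_change",
]

#: Number of control wells of each kind on a screening plate.
N_CONTROL_WELLS = 14


@dataclass
class Well:
    well_id: str
    role: str  # positive_control | empty | compound
    intensity: float
    compound_id: Optional[str] = None
    concentration: Optional[float] = None  # nM

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensities must be non-negative")
        if self.role not in ("positive_control", "empty", "compound"):
            raise ValueError(f"unknown well role {self.role!r}")


@dataclass
class PlateReading:
    """One screening plate: wells with roles and raw intensities."""

    plate_id: str
    wells: list[Well]
    line: Optional[str] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not any(w.role == "positive_control" for w in self.wells):
            raise ValueError("plate needs at least one positive-control well")
        if not any(w.role == "empty" for w in self.wells):
            raise ValueError("plate needs at least one empty (negative) well")

    def control_means(self) -> tuple[float, float]:
        c_pos = float(np.mean([w.intensity for w in self.wells if w.role == "positive_control"]))
        c_neg = float(np.mean([w.intensity for w in self.wells if w.role == "empty"]))
        return c_pos, c_neg


@dataclass
class DoseResponseFit:
    ec50: float  # nM
    hill: float
    residual_norm: float
    identifiable: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return 100.0 / (1.0 + (x / self.ec50) ** self.hill)


def plate_percent_inhibition(plate: PlateReading) -> pd.DataFrame:
    """Percentage of inhibition for every compound well of a plate.

    Returns a DataFrame with columns ``well_id``, ``compound_id``,
    ``concentration`` and ``pci``.  PCI is 0 at the positive-control mean
    and 100 at the empty-well mean.
    """
    c_pos, c_neg = plate.control_means()
    if c_pos == c_neg:
        raise ValueError(f"degenerate plate {plate.plate_id!r}: c_pos == c_neg")
    rows = [
        (w.well_id, w.compound_id, w.concentration,
         100.0 * (c_pos - w.intensity) / (c_pos - c_neg))
        for w in plate.wells
        if w.role == "compound"
    ]
    return pd.DataFrame(rows, columns=["well_id", "compound_id", "concentration", "pci"])


def rank_and_identify_hits(
    pci_changes: pd.DataFrame,
    min_change: float = 5.0,
    top_k: int = 6,
) -> pd.DataFrame:
    """Collateral-sensitivity hits from PCI changes versus a control line.

    ``pci_changes`` holds one row per compound x concentration x replicate
    with columns ``compound``, ``concentration``, ``replicate`` and
    ``pci_change`` (mean PCI change versus the control line, matched on
    concentration and replicate).  For each (concentration, replicate)
    list, compounds with change below ``min_change`` are excluded and the
    top ``top_k`` of the remainder kept; compounds tied at the last rank
    are all kept and flagged.  Hits are compounds appearing in more than
    one list.

    Returns a per-compound DataFrame with ``n_lists``, ``hit`` and
    ``tied_at_cutoff`` columns, hits first, sorted by descending list
    membership then best change.
    """
    required = {"compound", "concentration", "replicate", "pci_change"}
    if not required <= set(pci_changes.columns):
        raise ValueError(f"pci_changes needs columns {sorted(required)}")

    appearances: dict[str, int] = {}
    tied: set[str] = set()
    best: dict[str, float] = {}
    for _, grp in pci_changes.groupby(["concentration", "replicate"], sort=False):
        grp = grp[grp["pci_change"] >= min_change]
        if grp.empty:
            continue
        ranked = grp.sort_values(["pci_change", "compound"], ascending=[False, True])
        if len(ranked) > top_k:
            cutoff = ranked["pci_change"].iloc[top_k - 1]
            keep = ranked[ranked["pci_change"] >= cutoff]
            if len(keep) > top_k:
                tied |= set(keep.loc[keep["pci_change"] == cutoff, "compound"])
        else:
            keep = ranked
        for comp, change in zip(keep["compound"], keep["pci_change"]):
            appearances[comp] = appearances.get(comp, 0) + 1
            best[comp] = max(best.get(comp, -np.inf), change)

    out = pd.DataFrame(
        {
            "compound": list(appearances),
            "n_lists": [appearances[c] for c in appearances],
            "best_change": [best[c] for c in appearances],
            "tied_at_cutoff": [c in tied for c in appearances],
        }
    )
    out["hit"] = out["n_lists"] > 1
    return out.sort_values(
        ["hit", "n_lists", "best_change"], ascending=False
    ).reset_index(drop=True)


def _normalise_growth(
    responses: np.ndarray,
    controls: Optional[tuple[Sequence[float], Sequence[float]]],
) -> np.ndarray:
    if controls is None:
        return responses
    pos, neg = (float(np.mean(c)) for c in controls)
    if pos == neg:
        raise ValueError("degenerate controls: positive mean equals negative mean")
    return 100.0 * (responses - neg) / (pos - neg)


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    controls: Optional[tuple[Sequence[float], Sequence[float]]] = None,
) -> DoseResponseFit:
    """Fit the two-parameter log-logistic viability model.

    ``doses`` are drug concentrations (nM, > 0); ``responses`` are raw OD
    readings when ``controls`` (positive-control and empty-well readings)
    are given, otherwise already-normalised percent growth.  The model
    y(x) = 100 / (1 + (x/ec50)^hill) is fitted by non-linear least squares
    on log10(dose), with ec50 bounded within [min dose / 100,
    max dose * 100] and initialised from the dose bracketing 50% growth.

    Curves showing no inhibition are flagged non-identifiable (ec50
    pinned at the upper bound).
    """
    x = np.asarray(doses, dtype=float)
    y = _normalise_growth(np.asarray(responses, dtype=float), controls)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct dose levels")
    if np.any(x <= 0):
        raise ValueError("doses must be positive")

    lo, hi = x.min() / 100.0, x.max() * 100.0
    # initial ec50: dose whose mean response is nearest 50% growth
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ec50_0 = float(xs[np.argmin(np.abs(ys - 50.0))])
    ec50_0 = min(max(ec50_0, lo), hi)

    def resid(theta):
        log_ec50, hill = theta
        return 100.0 / (1.0 + (x / 10.0**log_ec50) ** hill) - y

    res = least_squares(
        resid,
        x0=[np.log10(ec50_0), 1.0],
        bounds=([np.log10(lo), 0.01], [np.log10(hi), 20.0]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not res.success:
        raise RuntimeError(
            f"dose-response fit did not converge: {res.message}; "
            f"best iterate ec50={10**res.x[0]:.4g} nM, hill={res.x[1]:.4g}"
        )
    ec50, hill = 10.0 ** res.x[0], res.x[1]
    identifiable = ec50 < hi * 0.999 and float(np.ptp(y)) > 1.0
    return DoseResponseFit(
        ec50=float(ec50),
        hill=float(hill),
        residual_norm=float(np.linalg.norm(res.fun)),
        identifiable=bool(identifiable),
        n_points=len(x),
    )


def ic50_fold_change(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> float:
    """Fold change of fitted EC50s, fit_b relative to fit_a."""
    for f in (fit_a, fit_b):
        if not isinstance(f, DoseResponseFit):
            raise TypeError("arguments must be DoseResponseFit instances")
    return fit_b.ec50 / fit_a.ec50
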