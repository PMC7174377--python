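"""Stochastic simulators of in vitro experimental evolution.

Two experiment designs are modelled:

1. *Re-plating*: a flask is seeded with ``n0`` cells, grown to ``nmax``,
   and re-plated back down to ``n0``; every division carries a probability
   ``mu`` of a resistance-conferring mutation.  The quantity of interest is
   the waiting time until the first resistant mutant arises.

2. *Outgrowth and split*: a population of uniquely barcoded founder cells
   is grown without re-plating (linear birth-death with rates ``b`` and
   ``d`` per cell per hour), then split at random into equal replicate
   flasks.  The quantity of interest is the probability that a surviving
   barcode is represented in exactly ``k`` of the replicates.

An exact inclusion-exclusion occupancy distribution is provided as an
analytic oracle for the split simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp, log
from typing import Optional

import numpy as np

__all__ = [
    "SimDesign",
    "OccupancyDistribution",
    "expected_mutants",
    "implied_resistance_loci",
    "simulate_replating_waiting_times",
    "gillespie_birth_death",
    "birth_death_final_sizes",
    "surviving_mean_size",
    "outgrowth_time_for_mean",
    "simulate_pot_split",
    "occupancy_distribution_exact",
    "occupancy_mixture",
]

#: Default birth/death rates per cell per hour for the HCC827 line at 20%
#: oxygen and 2 g/L glucose.
DEFAULT_BIRTH_RATE = 0.032
DEFAULT_DEATH_RATE = 0.002

#: Default per-division probability of a resistance-conferring mutation.
DEFAULT_MU = 2e-8

#: One growth cycle n0 -> nmax corresponds to 14 days of culture.
DEFAULT_CYCLE_DAYS = 14.0


@dataclass
class SimDesign:
    """Parameters of the stochastic evolution simulations.

    Attributes
    ----------
    mu : float
        Probability of a resistance mutation per cell division.
    n0, nmax : int
        Seeded population size and size at re-plating (n0 < nmax).
    replate_fraction : float
        Fraction of cells kept at each re-plating (n0 / nmax by default).
    b, d : float
        Birth and death rate per cell per hour (d < b).
    n_lineages : int
        Number of uniquely barcoded founder cells in the outgrowth.
    n_replicates : int
        Number of equal parts in the random split.
    n_sims : int
        Number of independent waiting-time simulations.
    n_outgrowths : int
        Independent POT outgrowths in the split simulation.
    cycle_days : float
        Calendar duration of one n0 -> nmax growth cycle.
    t_outgrowth : float or None
        Outgrowth duration in hours; ``None`` selects the duration at
        which surviving lineages average ``target_mean_size`` cells.
    target_mean_size : float
        Desired mean surviving clone size used when ``t_outgrowth`` is
        ``None``.
    n_splits : int
        Random splits per simulated outgrowth (results are averaged).
    max_cycles : int
        Safety cap for the waiting-time simulation when ``mu`` is tiny.
    seed : int
        Master seed; sub-streams are spawned deterministically.
    """

    mu: float = DEFAULT_MU
    n0: int = 2_000_000
    nmax: int = 40_000_000
    replate_fraction: float = field(default=None)  # type: ignore[assignment]
    b: float = DEFAULT_BIRTH_RATE
    d: float = DEFAULT_DEATH_RATE
    n_lineages: int = 10_000
    n_replicates: int = 8
    n_sims: int = 10_000
    n_outgrowths: int = 5
    cycle_days: float = DEFAULT_CYCLE_DAYS
    t_outgrowth: Optional[float] = None
    target_mean_size: float = 185.0
    n_splits: int = 4
    max_cycles: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0 < self.n0 < self.nmax:
            raise ValueError("require 0 < n0 < nmax")
        if self.b < 0 or self.d < 0:
            raise ValueError("birth and death rates must be non-negative")
        if self.d >= self.b:
            raise ValueError("require d < b for supercritical growth")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.replate_fraction is None:
            self.replate_fraction = self.n0 / self.nmax

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class OccupancyDistribution:
    """P(a surviving barcode occupies exactly k of R replicates), k = 0..R."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < -1e-12):
            raise ValueError("occupancy probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("occupancy probabilities must sum to 1")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def n_replicates(self) -> int:
        return len(self.probabilities) - 1

    def __getitem__(self, k: int) -> float:
        return float(self.probabilities[k])


# ---------------------------------------------------------------------------
# Expected number of resistant mutants
# ---------------------------------------------------------------------------

def expected_mutants(mu: float, n0: float, nmax: float, replatings: int) -> float:
    """Expected number of resistant mutants arising over repeated re-platings.

    Each growth phase n0 -> nmax involves (nmax - n0) cell divisions, each
    mutating with probability mu, so the expectation is
    ``mu * (nmax - n0) * replatings``.
    """
    if mu < 0 or n0 < 0 or nmax < 0 or replatings < 0:
        raise ValueError("all arguments must be non-negative")
    if nmax < n0:
        raise ValueError("nmax must be >= n0")
    return mu * (nmax - n0) * replatings


def implied_resistance_loci(mu: float, per_bp_rate: float = 1e-9) -> float:
    """Number of distinct resistance-conferring mutations implied by ``mu``.

    A composite resistance mutation probability mu per division, against a
    healthy per-base-pair mutation rate, implies mu / per_bp_rate distinct
    single-base changes that each confer resistance.
    """
    if mu < 0 or per_bp_rate <= 0:
        raise ValueError("rates must be positive")
    return mu / per_bp_rate


# ---------------------------------------------------------------------------
# Re-plating waiting times
# ---------------------------------------------------------------------------

def simulate_replating_waiting_times(design: SimDesign) -> "pd.DataFrame":
    """Simulate waiting times until the first resistance mutation.

    Each simulation grows n0 -> nmax (D = nmax - n0 divisions, each
    mutating with probability mu), re-plates back to n0, and repeats until
    the first mutation.  The division index of the first mutation is a
    geometric variate with success probability mu, which is exact in
    distribution; per-cycle bookkeeping of individual cells is not needed.

    Within the mutating cycle, calendar time is assigned by mapping the
    division index through deterministic exponential growth of the
    population (cells divide faster as the population grows), with one
    full cycle lasting ``design.cycle_days`` days.

    Returns a DataFrame with columns ``sim``, ``cycle`` (1-based),
    ``waiting_time_days`` and ``censored``.  Runs that exceed
    ``design.max_cycles`` without a mutation are flagged censored at the
    cap.
    """
    import pandas as pd

    rng = design.rng()
    divisions_per_cycle = design.nmax - design.n0
    n = design.n_sims

    if design.mu > 0:
        # geometric: number of divisions up to and including the first mutation
        g = rng.geometric(design.mu, size=n).astype(float)
    else:
        g = np.full(n, np.inf)

    cycles = np.ceil(g / divisions_per_cycle)
    censored = ~np.isfinite(cycles) | (cycles > design.max_cycles)
    cycles = np.where(censored, design.max_cycles, cycles)

    # division index within the mutating cycle, in (0, 1]
    within = np.where(
        censored, 1.0, (g - (cycles - 1) * divisions_per_cycle) / divisions_per_cycle
    )
    # population at division k grows as n0 * exp(r t): t/T = ln(1 + k*(M-1)) / ln M
    # with M = nmax/n0 the fold expansion per cycle.
    m = design.nmax / design.n0
    frac_time = np.log1p(within * (m - 1.0)) / log(m)
    waiting = ((cycles - 1) + frac_time) * design.cycle_days

    return pd.DataFrame(
        {
            "sim": np.arange(n),
            "cycle": cycles.astype(int),
            "waiting_time_days": waiting,
            "censored": censored,
        }
    )


# ---------------------------------------------------------------------------
# Linear birth-death (Gillespie)
# ---------------------------------------------------------------------------

def gillespie_birth_death(
    b: float,
    d: float,
    start_size: int = 1,
    t_end: Optional[float] = None,
    size_cap: Optional[int] = None,
    seed: int | np.random.Generator = 0,
    return_trajectory: bool = False,
):
    """Exact stochastic simulation of a linear birth-death process.

    Events occur at total rate (b + d) * n; each event is a birth with
    probability b / (b + d).  Stops at ``t_end`` hours, at ``size_cap``
    cells, or at extinction, whichever comes first.

    Returns the final population size, or ``(times, sizes)`` arrays when
    ``return_trajectory`` is set.
    """
    if b < 0 or d < 0:
        raise ValueError("rates must be non-negative")
    if start_size < 1:
        raise ValueError("start_size must be >= 1")
    if t_end is None and size_cap is None:
        raise ValueError("provide t_end or size_cap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t, n = 0.0, int(start_size)
    times, sizes = [0.0], [n]
    total_rate = b + d
    while n > 0:
        if size_cap is not None and n >= size_cap:
            break
        if total_rate == 0.0:
            break  # b = d = 0: static population
        wait = rng.exponential(1.0 / (total_rate * n))
        if t_end is not None and t + wait > t_end:
            break
        t += wait
        n += 1 if rng.random() < b / total_rate else -1
        if return_trajectory:
            times.append(t)
            sizes.append(n)
    if return_trajectory:
        return np.asarray(times), np.asarray(sizes)
    return n


def birth_death_final_sizes(
    b: float,
    d: float,
    t_end: float,
    n_lineages: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Final sizes of ``n_lineages`` independent birth-death lineages.

    Vectorized event-driven simulation: identical in law to running
    :func:`gillespie_birth_death` per lineage (exponential waiting times,
    rate-proportional event choice), but advancing all live lineages in
    lock-step for speed.
    """
    sizes = np.ones(n_lineages, dtype=np.int64)
    clock = np.zeros(n_lineages)
    active = np.arange(n_lineages)
    total_rate = b + d
    if total_rate == 0.0:
        return sizes
    p_birth = b / total_rate
    while active.size:
        n = sizes[active]
        wait = rng.exponential(1.0, size=active.size) / (total_rate * n)
        clock[active] += wait
        alive = clock[active] <= t_end
        idx = active[alive]
        births = rng.random(idx.size) < p_birth
        sizes[idx] += np.where(births, 1, -1)
        active = idx[sizes[idx] > 0]
    return sizes


def surviving_mean_size(b: float, d: float, t: float) -> float:
    """Mean size at time t of a birth-death lineage conditional on survival.

    For the linear process from one cell, E[n(t) | n(t) > 0]
    = (b e^{(b-d)t} - d) / (b - d).
    """
    return (b * exp((b - d) * t) - d) / (b - d)


def outgrowth_time_for_mean(target_mean: float, b: float, d: float) -> float:
    """Outgrowth duration (hours) giving the requested mean surviving size."""
    if target_mean <= 1:
        raise ValueError("target mean size must exceed 1")
    return log((target_mean * (b - d) + d) / b) / (b - d)


# ---------------------------------------------------------------------------
# Outgrowth + random equal split
# ---------------------------------------------------------------------------

def simulate_pot_split(design: SimDesign, return_sizes: bool = False):
    """Occupancy of barcodes across replicate flasks after outgrowth + split.

    Grows ``design.n_lineages`` uniquely barcoded founder cells by the
    birth-death process for ``design.t_outgrowth`` hours, discards extinct
    lineages, pools the surviving cells and splits the pool into
    ``design.n_replicates`` equal parts uniformly at random without
    replacement.  The empirical fraction of surviving barcodes present in
    exactly k replicates is averaged over ``design.n_outgrowths``
    outgrowths x ``design.n_splits`` splits each.

    Returns an :class:`OccupancyDistribution`; with ``return_sizes`` also
    returns the concatenated surviving clone sizes (for the analytic
    mixture oracle).
    """
    if design.n_lineages < 1:
        raise ValueError("need at least one lineage")
    t_end = design.t_outgrowth
    if t_end is None:
        t_end = outgrowth_time_for_mean(design.target_mean_size, design.b, design.d)

    rng = design.rng()
    R = design.n_replicates
    occ_counts = np.zeros(R + 1)
    n_surviving_total = 0
    all_sizes = []

    for _ in range(design.n_outgrowths):
        sizes = birth_death_final_sizes(design.b, design.d, t_end, design.n_lineages, rng)
        sizes = sizes[sizes > 0]
        if sizes.size == 0:
            continue
        all_sizes.append(sizes)
        labels = np.repeat(np.arange(sizes.size), sizes)
        n_cells = labels.size
        for _ in range(design.n_splits):
            perm = rng.permutation(n_cells)
            # equal-size split: replicate of the cell at permuted position i
            rep_of_pos = (np.arange(n_cells) * R) // n_cells
            rep = np.empty(n_cells, dtype=np.int64)
            rep[perm] = rep_of_pos
            # count distinct replicates per barcode
            pair = labels * R + rep
            present = np.unique(pair)
            k_per_barcode = np.bincount(present // R, minlength=sizes.size)
            occ_counts += np.bincount(k_per_barcode, minlength=R + 1)
            n_surviving_total += sizes.size

    if n_surviving_total == 0:
        raise RuntimeError("all lineages went extinct in every simulation")
    dist = OccupancyDistribution(occ_counts / occ_counts.sum())
    if return_sizes:
        return dist, np.concatenate(all_sizes)
    return dist


def occupancy_distribution_exact(n: int, R: int) -> OccupancyDistribution:
    """Exact occupancy distribution for n cells placed into R equal replicates.

    Inclusion-exclusion over equal-probability multinomial placement:
    P(exactly k occupied) = C(R, k) * sum_j (-1)^j C(k, j) ((k-j)/R)^n.
    """
    if n < 1 or R < 1:
        raise ValueError("n and R must be >= 1")
    p = np.zeros(R + 1)
    for k in range(1, R + 1):
        s = 0.0
        for j in range(k + 1):
            s += (-1) ** j * comb(k, j) * ((k - j) / R) ** n
        p[k] = comb(R, k) * s
    return OccupancyDistribution(np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum())


def occupancy_mixture(sizes: np.ndarray, R: int) -> OccupancyDistribution:
    """Analytic occupancy mixture over an empirical clone-size distribution.

    Averages the exact inclusion-exclusion occupancy over the observed
    sizes; serves as the oracle against which the empirical split
    simulation is validated.
    """
    sizes = np.asarray(sizes)
    uniq, counts = np.unique(sizes, return_counts=True)
    w = counts / counts.sum()
    # E[x^n] under the size distribution, per inclusion-exclusion term
    p = np.zeros(R + 1)
    for k in range(1, R + 1):
        s = 0.0
        for j in range(k + 1):
            x = (k - j) / R
            s += (-1) ** j * comb(k, j) * float(np.sum(w * np.power(x, uniq.astype(float))))
        p[k] = comb(R, k) * s
    return OccupancyDistribution(np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum())
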