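"""Synthetic datasets with the clonal structure the pipeline assumes.

Generates every input the analysis consumes: a baseline (POT) population
of uniquely barcoded lineages carrying pre-existing resistant subclones at
realistic frequencies, replicate flasks evolved under gefitinib,
trametinib or DMSO with weekly floating (dead-cell) samples, amplicon
reads over the weak/strong barcode alphabet with sequencing errors,
per-SNP allele-count profiles with known integer copy numbers, and
drug-screen plates with internal controls.

Every generated object is accompanied by its ground truth so parameter
recovery can be scored end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import clonal_inference as ci
from .barcode_processing import DEFAULT_WS_PATTERN, BarcodeCensus
from .evolution_simulators import outgrowth_time_for_mean
from .pharmacology import N_CONTROL_WELLS, PlateReading, Well

logger = logging.getLogger(__name__)

__all__ = [
    "CloneDefinition",
    "PopulationSpec",
    "ExperimentDesign",
    "ExperimentDataset",
    "generate_population_spec",
    "simulate_experiment",
    "emit_barcode_reads",
    "write_fastq",
    "generate_snp_dataset",
    "generate_screen_plates",
    "default_screen_effects",
]

#: Baseline (POT) frequencies of the pre-existing resistant subclones.
DEFAULT_CLONE_FREQUENCIES = {
    ci.GEF_RESISTANT: 0.024,
    ci.DOUBLE_RESISTANT: 0.0091,
    ci.TRM_RESISTANT: 0.0057,
}

#: Final attached frequencies each resistant subclone reaches per drug arm
#: (averages across replicates); growth rates are derived from these
#: anchors via r = ln(f_final / f_0) / T.
DEFAULT_FINAL_FREQUENCIES = {
    ci.GEF_RESISTANT: {"GEF": 0.328, "TRM": 0.002},
    ci.DOUBLE_RESISTANT: {"GEF": 0.224, "TRM": 0.861},
    ci.TRM_RESISTANT: {"GEF": 0.0005, "TRM": 0.042},
}

DEFAULT_T_WEEKS = {"GEF": 4.0, "TRM": 9.0}

DEFAULT_FLANK_FWD = "TGAGTCTGACAG"
DEFAULT_FLANK_REV = "CTAGCATAGAGT"


@dataclass
class CloneDefinition:
    """A subclone: its POT frequency and net growth rate per condition."""

    clone_id: str
    phenotype: str
    initial_frequency: float
    growth_rate_per_condition: dict[str, float]  # per week, keys GEF/TRM/DMSO

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_frequency <= 1.0:
            raise ValueError("clone frequencies must lie in [0, 1]")
        if self.phenotype not in ci.PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        r = self.growth_rate_per_condition
        checks = {
            ci.DOUBLE_RESISTANT: r.get("GEF", 0) > 0 and r.get("TRM", 0) > 0,
            ci.GEF_RESISTANT: r.get("GEF", 0) > 0 and r.get("TRM", 0) <= 0,
            ci.TRM_RESISTANT: r.get("TRM", 0) > 0 and r.get("GEF", 0) <= 0,
            ci.SENSITIVE: r.get("GEF", 0) <= 0 and r.get("TRM", 0) <= 0,
        }
        if self.phenotype in checks and not checks[self.phenotype]:
            raise ValueError(
                f"growth-rate signs inconsistent with phenotype {self.phenotype}"
            )


@dataclass
class PopulationSpec:
    """Clonal composition of the barcoded founder population."""

    clones: list[CloneDefinition]
    n_lineages: int = 2_500
    barcode_length: int = 30
    flank_fwd: str = DEFAULT_FLANK_FWD
    flank_rev: str = DEFAULT_FLANK_REV
    ws_pattern: str = DEFAULT_WS_PATTERN

    def __post_init__(self) -> None:
        total = sum(c.initial_frequency for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValueError(f"clone frequencies sum to {total:.4f} > 1")
        if self.n_lineages < len(self.clones):
            raise ValueError("need at least one lineage per clone")
        if len(self.ws_pattern) != self.barcode_length:
            raise ValueError("ws_pattern length must equal barcode_length")

    @property
    def resistant_frequency(self) -> float:
        return sum(
            c.initial_frequency for c in self.clones if c.phenotype != ci.SENSITIVE
        )


@dataclass
class ExperimentDesign:
    """Layout and sampling parameters of the synthetic experiment."""

    n_gef: int = 3
    n_trm: int = 3
    n_dmso: int = 2
    gef_weeks: int = 4
    trm_weeks: int = 9
    seed_cells: int = 12_000_000
    depth: int = 300_000  # reads per attached census
    depth_floating: int = 300_000
    pot_mean_size: float = 150.0  # mean surviving cells per barcode in the POT
    b: float = 0.032  # per-hour birth rate during POT outgrowth
    d: float = 0.002  # per-hour death rate during POT outgrowth
    turnover: float = 0.05  # weekly death fraction of standing (growing) clones

    def replicate_ids(self) -> dict[str, list[str]]:
        return {
            "DMSO": [f"DMSO{7 + i}" for i in range(self.n_dmso)],
            "GEF": [f"GEF{1 + i}" for i in range(self.n_gef)],
            "TRM": [f"TRM{self.n_gef + 1 + i}" for i in range(self.n_trm)],
        }


@dataclass
class ExperimentDataset:
    """All censuses of one synthetic experiment plus the generating truth."""

    censuses: list[BarcodeCensus]
    truth: pd.DataFrame  # indexed by barcode
    spec: PopulationSpec
    design: ExperimentDesign
    expected_floating: dict[tuple[str, int], dict[str, float]] = field(
        default_factory=dict
    )
    fastq_paths: dict[str, str] = field(default_factory=dict)

    def census(self, sample_id: str) -> BarcodeCensus:
        for c in self.censuses:
            if c.sample_id == sample_id:
                return c
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Population spec
# ---------------------------------------------------------------------------

def generate_population_spec(config: Optional[Mapping] = None) -> PopulationSpec:
    """Build a PopulationSpec; defaults are the printed POT clone frequencies.

    ``config`` may override ``clone_frequencies`` (phenotype -> POT
    frequency), ``final_frequencies``, ``t_weeks`` and any PopulationSpec
    field.  The sensitive background fills whatever frequency the
    resistant clones do not use; its growth rate per drug arm is solved so
    that frequencies still sum to one at harvest (replicator consistency).
    """
    config = dict(config or {})
    freqs = dict(config.pop("clone_frequencies", DEFAULT_CLONE_FREQUENCIES))
    finals = dict(config.pop("final_frequencies", DEFAULT_FINAL_FREQUENCIES))
    t_weeks = dict(config.pop("t_weeks", DEFAULT_T_WEEKS))

    total = sum(freqs.values())
    if total > 1.0:
        raise ValueError(f"clone frequencies sum to {total:.4f} > 1")

    clones = []
    for phenotype, f0 in freqs.items():
        if f0 == 0:
            continue
        fin = finals[phenotype]
        rates = {"DMSO": 0.0}
        for arm, t in t_weeks.items():
            rates[arm] = math.log(fin[arm] / f0) / t
        clones.append(
            CloneDefinition(
                clone_id=phenotype.lower(),
                phenotype=phenotype,
                initial_frequency=f0,
                growth_rate_per_condition=rates,
            )
        )

    f_bg = 1.0 - total
    if f_bg > 0:
        bg_rates = {"DMSO": 0.0}
        for arm, t in t_weeks.items():
            remainder = 1.0 - sum(finals[c.phenotype][arm] for c in clones)
            if remainder <= 0:
                raise ValueError(f"resistant final frequencies fill the {arm} arm")
            bg_rates[arm] = math.log(remainder / f_bg) / t
        clones.append(
            CloneDefinition(
                clone_id="background",
                phenotype=ci.SENSITIVE,
                initial_frequency=f_bg,
                growth_rate_per_condition=bg_rates,
            )
        )
    return PopulationSpec(clones=clones, **config)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _random_ws_barcodes(
    n: int, pattern: str, rng: np.random.Generator
) -> np.ndarray:
    """n distinct barcodes over the weak/strong alphabet."""
    w = np.array(list("AT"))
    s = np.array(list("GC"))
    out: set[str] = set()
    while len(out) < n:
        need = n - len(out)
        cols = []
        for sym in pattern:
            alphabet = w if sym == "W" else s
            cols.append(alphabet[rng.integers(0, 2, size=need)])
        block = np.stack(cols, axis=1)
        out.update("".join(row) for row in block)
    return np.array(sorted(out)[:n])


def _pot_sizes(
    n_lineages: int, b: float, d: float, mean_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Founder lineage sizes after POT outgrowth.

    Samples from the exact transient law of the linear birth-death
    process at the time where the mean surviving lineage has
    ``mean_size`` cells: extinction with probability alpha, otherwise a
    geometric size (identical in law to event-by-event simulation).
    """
    t = outgrowth_time_for_mean(mean_size, b, d)
    ert = math.exp((b - d) * t)
    alpha = d * (ert - 1.0) / (b * ert - d)
    beta = b * (ert - 1.0) / (b * ert - d)
    survive = rng.random(n_lineages) >= alpha
    sizes = np.zeros(n_lineages, dtype=np.int64)
    sizes[survive] = rng.geometric(1.0 - beta, size=int(survive.sum()))
    return sizes


def simulate_experiment(
    spec: PopulationSpec,
    design: Optional[ExperimentDesign] = None,
    seed: int = 0,
) -> ExperimentDataset:
    """Simulate the full barcoded evolution experiment.

    The POT is grown by per-lineage birth-death outgrowth; each replicate
    flask is seeded by a random draw of ``design.seed_cells`` cells from
    the POT; under each drug, every barcode's expected log-frequency
    trajectory follows its clone's growth rate, with multinomial
    sequencing sampling at census time; cells lost from declining clones,
    plus a weekly turnover of standing clones, are routed to weekly
    floating censuses; DMSO replicates drift only by sampling.
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(seed)

    # --- assign founders to clones -------------------------------------
    n = spec.n_lineages
    counts = [int(round(c.initial_frequency * n)) for c in spec.clones]
    short = n - sum(counts)
    # any rounding slack goes to the largest clone (the background)
    counts[int(np.argmax(counts))] += short
    clone_of = np.repeat(np.arange(len(spec.clones)), counts)
    rng.shuffle(clone_of)
    barcodes = _random_ws_barcodes(n, spec.ws_pattern, rng)

    # --- POT outgrowth --------------------------------------------------
    sizes = _pot_sizes(n, design.b, design.d, design.pot_mean_size, rng)
    total_cells = int(sizes.sum())
    pot_freq = sizes / total_cells

    censuses: list[BarcodeCensus] = []

    def census_from_freqs(freqs, sample_id, condition, depth, timepoint=None,
                          compartment="attached"):
        draw = rng.multinomial(depth, freqs / freqs.sum())
        nz = draw > 0
        counts_map = dict(zip(barcodes[nz], draw[nz].tolist()))
        return BarcodeCensus(
            sample_id=sample_id,
            counts=counts_map,
            condition=condition,
            timepoint=timepoint,
            compartment=compartment,
        )

    censuses.append(census_from_freqs(pot_freq, "POT", "POT", design.depth))

    rep_ids = design.replicate_ids()
    rates = {
        arm: np.array(
            [c.growth_rate_per_condition.get(arm, 0.0) for c in spec.clones]
        )[clone_of]
        for arm in ("GEF", "TRM", "DMSO")
    }
    weeks = {"GEF": design.gef_weeks, "TRM": design.trm_weeks}
    expected_floating: dict[tuple[str, int], dict[str, float]] = {}

    for arm, ids in rep_ids.items():
        for sample_id in ids:
            seed_draw = rng.multinomial(design.seed_cells, pot_freq)
            f_seed = seed_draw / design.seed_cells
            if arm == "DMSO":
                censuses.append(
                    census_from_freqs(f_seed, sample_id, "DMSO", design.depth)
                )
                continue
            r = rates[arm]
            t_final = weeks[arm]
            m_prev = f_seed
            for week in range(1, t_final + 1):
                m_now = f_seed * np.exp(r * week)
                deaths = np.maximum(m_prev - m_now, 0.0) + design.turnover * m_now
                if deaths.sum() > 0:
                    expected_floating[(sample_id, week)] = {}
                    ef = deaths / deaths.sum()
                    nz = ef > 0
                    expected_floating[(sample_id, week)] = dict(
                        zip(barcodes[nz], ef[nz].tolist())
                    )
                    censuses.append(
                        census_from_freqs(
                            deaths,
                            f"{sample_id}-F{week}",
                            arm,
                            design.depth_floating,
                            timepoint=week,
                            compartment="floating",
                        )
                    )
                m_prev = m_now
            censuses.append(census_from_freqs(m_prev, sample_id, arm, design.depth))

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "clone_id": [spec.clones[i].clone_id for i in clone_of],
            "phenotype": [spec.clones[i].phenotype for i in clone_of],
            "pot_cells": sizes,
            "pot_frequency": pot_freq,
            "r_GEF": rates["GEF"],
            "r_TRM": rates["TRM"],
        }
    ).set_index("barcode")

    return ExperimentDataset(
        censuses=censuses,
        truth=truth,
        spec=spec,
        design=design,
        expected_floating=expected_floating,
    )


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def emit_barcode_reads(
    census: BarcodeCensus,
    depth: int,
    error_rate: float = 0.001,
    seed: int | np.random.Generator = 0,
    fail_q_fraction: float = 0.0,
    flank_fwd: str = DEFAULT_FLANK_FWD,
    flank_rev: str = DEFAULT_FLANK_REV,
    q_pass: int = 37,
    q_fail: int = 20,
) -> list[tuple[str, str, str]]:
    """Amplicon reads (id, sequence, quality) for a barcode census.

    Read counts are multinomial on the census frequencies at the
    requested ``depth``; each read is flank_fwd + barcode + flank_rev with
    independent per-base substitution errors at ``error_rate``.  A
    ``fail_q_fraction`` of reads receives a single base at quality
    ``q_fail`` (exactly at the boundary of the strict Q > 20 filter); all
    other bases carry ``q_pass``.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    if depth == 0:
        logger.warning("zero depth requested for %s: emitting no reads", census.sample_id)
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    bcs = sorted(census.counts)
    freqs = np.array([census.counts[b] for b in bcs], dtype=float)
    freqs /= freqs.sum()
    n_per = rng.multinomial(depth, freqs)

    templates = [flank_fwd + b + flank_rev for b in bcs]
    tmpl_arr = np.frombuffer("".join(templates).encode(), dtype=np.uint8).reshape(
        len(bcs), -1
    )
    reads = np.repeat(tmpl_arr, n_per, axis=0).copy()
    n_reads, read_len = reads.shape

    if error_rate > 0:
        mask = rng.random(reads.shape) < error_rate
        n_err = int(mask.sum())
        if n_err:
            # substitute with a uniformly random *different* base
            offsets = rng.integers(1, 4, size=n_err)
            cur = reads[mask]
            cur_idx = np.searchsorted(_BASE_BYTES, cur)
            reads[mask] = _BASE_BYTES[(cur_idx + offsets) % 4]

    quals = np.full(reads.shape, q_pass + 33, dtype=np.uint8)
    n_fail = int(round(fail_q_fraction * n_reads))
    if n_fail:
        fail_rows = rng.choice(n_reads, size=n_fail, replace=False)
        fail_cols = rng.integers(0, read_len, size=n_fail)
        quals[fail_rows, fail_cols] = q_fail + 33

    order = rng.permutation(n_reads)
    out = []
    for i, row in enumerate(order):
        out.append(
            (
                f"{census.sample_id}:read{i}",
                reads[row].tobytes().decode(),
                quals[row].tobytes().decode(),
            )
        )
    return out


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    """Write (id, sequence, quality) records as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SNP allele-count profiles
# ---------------------------------------------------------------------------

def generate_snp_dataset(
    cn_segments: Sequence[tuple[int, int]],
    n_snps: int | Sequence[int] = 200,
    depth: float = 100.0,
    psi_true: float = 3.0,
    seed: int = 0,
    base_error: float = 0.002,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP allele counts for segments of known integer copy number.

    Each ``(major, minor)`` segment contributes SNPs on its own
    chromosome (``n_snps`` per segment, or one count per segment).
    Coverage is Poisson with mean proportional to
    (major + minor) / psi_true; the major-allele read count is binomial
    with expected fraction major / (major + minor) (LOH segments,
    minor = 0, look homozygous up to ``base_error``).

    Downstream LRR normalisation recentres by the global median SNP, so a
    faithful profile should give the modal copy state the majority of
    SNPs, as real genomes do; equal-size segments place the median at the
    edge of the modal state and bias the recovered ploidy.

    Returns ``(snp_table, segment_truth)``; the SNP table carries chrom,
    pos, A/C/G/T counts and gmaf, ready for :func:`compute_baf_lrr`.
    """
    if not 1.5 <= psi_true <= 5.5:
        raise ValueError("psi_true must lie in [1.5, 5.5]")
    if np.isscalar(n_snps):
        n_per_segment = [int(n_snps)] * len(cn_segments)
    else:
        n_per_segment = [int(x) for x in n_snps]
        if len(n_per_segment) != len(cn_segments):
            raise ValueError("n_snps must be scalar or one count per segment")
    rng = np.random.default_rng(seed)
    rows = []
    seg_rows = []
    for si, (major, minor) in enumerate(cn_segments):
        n_snps_seg = n_per_segment[si]
        if major < 0 or minor < 0 or int(major) != major or int(minor) != minor:
            raise ValueError("copy numbers must be non-negative integers")
        total = major + minor
        if total == 0:
            raise ValueError("segment with total copy number 0")
        chrom = str(si + 1)
        p_major = major / total
        p_major = p_major * (1 - base_error) + (1 - p_major) * base_error
        pos0 = 100_000
        step = 1_000
        cov = rng.poisson(depth * total / psi_true, size=n_snps_seg)
        maj_counts = rng.binomial(cov, p_major)
        min_counts = cov - maj_counts
        # random assignment of major/minor to base letters per SNP
        maj_base = rng.integers(0, 4, size=n_snps_seg)
        min_base = (maj_base + rng.integers(1, 4, size=n_snps_seg)) % 4
        gmaf = rng.uniform(0.1, 0.2, size=n_snps_seg)
        for j in range(n_snps_seg):
            base_counts = [0, 0, 0, 0]
            base_counts[maj_base[j]] += int(maj_counts[j])
            base_counts[min_base[j]] += int(min_counts[j])
            rows.append(
                (chrom, pos0 + j * step, *base_counts, gmaf[j])
            )
        seg_rows.append(
            (chrom, pos0, pos0 + (n_snps_seg - 1) * step, n_snps_seg, major, minor)
        )
    snp_table = pd.DataFrame(
        rows, columns=["chrom", "pos", "A", "C", "G", "T", "gmaf"]
    )
    segment_truth = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "n_snps", "major_cn", "minor_cn"]
    )
    return snp_table, segment_truth


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------

def default_screen_effects(
    n_compounds: int,
    concentrations: Sequence[float],
    lines: Sequence[str],
    control_line: str,
    n_hits: int = 12,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """True inhibition fractions per line: shared baseline + planted hits.

    Every compound has a baseline inhibition shared across lines; the
    first ``n_hits`` compounds gain a large extra inhibition in the
    non-control lines (collateral sensitivity), increasing with
    concentration.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.0, 0.25, size=(n_compounds, len(concentrations)))
    effects = {}
    boost = np.linspace(0.35, 0.6, len(concentrations))
    for line in lines:
        e = base.copy()
        if line != control_line:
            e[:n_hits] = np.clip(e[:n_hits] + boost[None, :], 0.0, 1.0)
        effects[line] = e
    return effects


def generate_screen_plates(
    n_compounds: int = 485,
    effects: Optional[Mapping[str, np.ndarray]] = None,
    noise_sd: float = 150.0,
    seed: int = 0,
    concentrations: Sequence[float] = (20.0, 200.0, 800.0),
    lines: Sequence[str] = ("DMSO7_F4", "TRM4_D6", "TRM4_E9"),
    control_line: str = "DMSO7_F4",
    n_replicates: int = 3,
    c_pos_mean: float = 10_000.0,
    c_neg_mean: float = 2_000.0,
    wells_per_plate: int = 384,
) -> list[PlateReading]:
    """Screening plates for each line x replicate x concentration.

    Compound-well intensity is c_neg + (1 - inhibition) * (c_pos - c_neg)
    plus Gaussian noise; every plate carries 14 drug-free positive-control
    wells and 14 empty negative-control wells.  Compounds overflow onto
    additional plates when they exceed the plate capacity.
    """
    if effects is None:
        effects = default_screen_effects(
            n_compounds, concentrations, lines, control_line, seed=seed
        )
    rng = np.random.default_rng(seed)
    capacity = wells_per_plate - 2 * N_CONTROL_WELLS
    plates: list[PlateReading] = []
    for line in lines:
        inh = np.asarray(effects[line], dtype=float)
        if inh.shape != (n_compounds, len(concentrations)):
            raise ValueError(
                f"effects[{line!r}] must have shape (n_compounds, n_concentrations)"
            )
        for rep in range(1, n_replicates + 1):
            for ci_, conc in enumerate(concentrations):
                for chunk_start in range(0, n_compounds, capacity):
                    chunk = range(chunk_start, min(chunk_start + capacity, n_compounds))
                    plate_id = (
                        f"{line}_rep{rep}_{conc:g}nM_p{chunk_start // capacity + 1}"
                    )
                    wells = []
                    for w in range(N_CONTROL_WELLS):
                        wells.append(
                            Well(
                                well_id=f"pos{w}",
                                role="positive_control",
                                intensity=max(
                                    0.0, c_pos_mean + rng.normal(0.0, noise_sd)
                                ),
                            )
                        )
                        wells.append(
                            Well(
                                well_id=f"neg{w}",
                                role="empty",
                                intensity=max(
                                    0.0, c_neg_mean + rng.normal(0.0, noise_sd)
                                ),
                            )
                        )
                    for c in chunk:
                        mean_i = c_neg_mean + (1.0 - inh[c, ci_]) * (
                            c_pos_mean - c_neg_mean
                        )
                        wells.append(
                            Well(
                                well_id=f"c{c}",
                                role="compound",
                                compound_id=f"compound{c:04d}",
                                concentration=float(conc),
                                intensity=max(0.0, mean_i + rng.normal(0.0, noise_sd)),
                            )
                        )
                    plates.append(
                        PlateReading(
                            plate_id=plate_id, wells=wells, line=line, replicate=rep
                        )
                    )
    return plates
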