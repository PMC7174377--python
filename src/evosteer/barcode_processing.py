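"""Amplicon read processing for semi-random lineage barcodes.

Reads carrying a 30-bp semi-random barcode between two fixed 12-bp primer
flanks are quality-filtered, the barcode segment extracted by regular
expression, and sequencing/PCR errors collapsed by merging each
non-conforming sequence into its nearest Hamming neighbour that matches
the library's weak/strong base pattern (W = A/T, S = G/C).
"""

from __future__ import annotations

import logging
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeCensus",
    "DEFAULT_WS_PATTERN",
    "read_and_filter_fastq",
    "matches_ws_pattern",
    "merge_barcodes",
    "census_to_frequencies",
    "write_census_tsv",
    "read_census_tsv",
]

#: ClonTracer-style barcodes alternate weak (A/T) and strong (G/C) bases.
DEFAULT_WS_PATTERN = "WS" * 15

_WS_BASES = {"W": "AT", "S": "GC"}


@dataclass
class BarcodeCensus:
    """Per-sample barcode counts with sample metadata.

    ``counts`` maps each barcode sequence to a non-negative read (or cell)
    count; ``frequencies`` are derived by normalisation.
    """

    sample_id: str
    counts: dict[str, int]
    condition: str = "POT"  # POT | DMSO | GEF | TRM
    timepoint: Optional[int] = None  # week index; None = final/baseline
    compartment: str = "attached"  # attached | floating
    flagged_singletons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("barcode counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {b: 0.0 for b in self.counts}
        return {b: c / tot for b, c in self.counts.items()}

    def frequency(self, barcode: str) -> float:
        tot = self.total
        return self.counts.get(barcode, 0) / tot if tot else 0.0

    def __len__(self) -> int:
        return len(self.counts)


def read_and_filter_fastq(
    path,
    min_q: int = 20,
    flank_fwd: str = "TGAGTCTGACAG",
    flank_rev: str = "CTAGCATAGAGT",
    barcode_length: int = 30,
) -> Counter:
    """Extract raw barcode counts from a FASTQ file.

    Keeps only reads whose base qualities are strictly greater than
    ``min_q`` at every position, then extracts the ``barcode_length``-base
    segment between exact matches of the two primer flanks.

    Returns a Counter mapping barcode sequence to read count.
    """
    if len(flank_fwd) != 12 or len(flank_rev) != 12:
        raise ValueError("primer flanks must be 12 bases each")
    pattern = re.compile(
        re.escape(flank_fwd.upper())
        + f"([ACGTN]{{{barcode_length}}})"
        + re.escape(flank_rev.upper())
    )
    counts: Counter = Counter()
    n_records = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        n_records += 1
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise ValueError(f"malformed FASTQ record at index {i}: no qualities")
        if min(quals) <= min_q:
            continue
        m = pattern.search(str(rec.seq).upper())
        if m:
            counts[m.group(1)] += 1
    if n_records and not counts:
        warnings.warn("no reads passed quality filtering and flank extraction")
    return counts


def matches_ws_pattern(seq: str, pattern: str = DEFAULT_WS_PATTERN) -> bool:
    """True iff ``seq`` matches the weak/strong base pattern exactly.

    Each W position must hold A or T, each S position G or C; lengths
    must agree.
    """
    if set(pattern) - set("WS"):
        raise ValueError("pattern may contain only W and S symbols")
    if len(seq) != len(pattern):
        return False
    return all(base in _WS_BASES[sym] for base, sym in zip(seq.upper(), pattern))


def _hamming_matrix(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between two byte-encoded sequence arrays."""
    return (queries[:, None, :] != refs[None, :, :]).sum(axis=2)


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def merge_barcodes(
    raw_counts: Mapping[str, int],
    max_hamming: int = 2,
    pattern: str = DEFAULT_WS_PATTERN,
    sample_id: str = "sample",
    **census_kwargs,
) -> BarcodeCensus:
    """Collapse sequencing/PCR errors onto pattern-conforming representatives.

    Barcodes conforming to the weak/strong pattern act as representatives.
    First, low-count conforming barcodes are absorbed by conforming
    neighbours of strictly higher count within ``max_hamming`` mismatches
    (errors can themselves produce pattern-valid sequences); conforming
    barcodes further apart, or of equal count, stay separate.  Then every
    non-conforming barcode, in descending count order, is merged into the
    nearest remaining representative within ``max_hamming``; ties on
    distance go to the representative with the higher count, then
    lexicographically smallest sequence.  Barcodes with no representative
    in range are retained as singletons and flagged.  Total counts are
    conserved.
    """
    lengths = {len(b) for b in raw_counts}
    if len(lengths) > 1:
        raise ValueError("all barcode sequences must have the same length")

    merged: dict[str, int] = {}
    nonconforming: list[str] = []
    for seq, cnt in raw_counts.items():
        if matches_ws_pattern(seq, pattern):
            merged[seq] = merged.get(seq, 0) + cnt
        else:
            nonconforming.append(seq)

    # phase 1: collapse conforming barcodes into strictly more abundant
    # conforming neighbours (ascending count, so satellites go first)
    if len(merged) > 1 and max_hamming > 0:
        conf = sorted(merged, key=lambda s: (merged[s], s))
        enc = _encode(conf)
        alive = {s: True for s in conf}
        index = {s: i for i, s in enumerate(conf)}
        for seq in conf:
            if not alive[seq]:
                continue
            cnt = merged[seq]
            cand = [s for s in conf if alive[s] and merged[s] > cnt]
            if not cand:
                continue
            rows = enc[[index[s] for s in cand]]
            dists = (rows != enc[index[seq]]).sum(axis=1)
            dmin = int(dists.min())
            if dmin <= max_hamming:
                ties = [cand[j] for j in np.flatnonzero(dists == dmin)]
                target = min(ties, key=lambda r: (-merged[r], r))
                merged[target] += merged.pop(seq)
                alive[seq] = False

    flagged: set[str] = set()
    reps = sorted(merged)
    if reps and nonconforming:
        rep_enc = _encode(reps)
        q_enc = _encode(nonconforming)
        dists = _hamming_matrix(q_enc, rep_enc)
        order = sorted(
            range(len(nonconforming)),
            key=lambda i: (-raw_counts[nonconforming[i]], nonconforming[i]),
        )
        for i in order:
            row = dists[i]
            dmin = row.min()
            if dmin <= max_hamming:
                candidates = [reps[j] for j in np.flatnonzero(row == dmin)]
                # tie-break: higher current count, then lexicographic
                target = min(candidates, key=lambda r: (-merged[r], r))
                merged[target] += raw_counts[nonconforming[i]]
            else:
                merged[nonconforming[i]] = raw_counts[nonconforming[i]]
                flagged.add(nonconforming[i])
    elif nonconforming:
        for seq in nonconforming:
            merged[seq] = raw_counts[seq]
            flagged.add(seq)

    assert sum(merged.values()) == sum(raw_counts.values()), "merge lost counts"
    return BarcodeCensus(
        sample_id=sample_id, counts=merged, flagged_singletons=flagged, **census_kwargs
    )


def census_to_frequencies(census: BarcodeCensus) -> dict[str, float]:
    """Normalised barcode frequencies; errors on an empty census."""
    if census.total == 0:
        raise ValueError(f"census {census.sample_id!r} has no counts")
    return census.frequencies


def write_census_tsv(census: BarcodeCensus, path) -> None:
    """Write a census as TSV (sample_id, barcode, count, frequency)."""
    freqs = census.frequencies
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\tcount\tfrequency\n")
        for bc in sorted(census.counts):
            fh.write(f"{census.sample_id}\t{bc}\t{census.counts[bc]}\t{freqs[bc]:.10g}\n")


def read_census_tsv(path, **kwargs) -> BarcodeCensus:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    if df.empty:
        raise ValueError(f"empty census table: {path}")
    sample_id = str(df["sample_id"].iloc[0])
    counts = dict(zip(df["barcode"], df["count"].astype(int)))
    return BarcodeCensus(sample_id=sample_id, counts=counts, **kwargs)
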