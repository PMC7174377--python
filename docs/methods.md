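# Methods

`evosteer` implements the quantitative machinery of a barcode-tracked
*evolutionary steering* experiment: a large barcoded cancer cell
population (the POT) carrying rare pre-existing resistant subclones is
split into replicate flasks, exposed to one of two targeted drugs
(an EGFR inhibitor, "GEF", or a MEK inhibitor, "TRM") or to DMSO, and the
clonal composition is read out by amplicon sequencing of 30-bp
weak/strong lineage barcodes. This note documents the models, the
parameter choices, and the limits of what the synthetic tests establish.

## Stochastic simulators

**Re-plating waiting times.** A flask seeded with N0 cells grows to Nmax
and is re-plated back to N0; each of the (Nmax − N0) divisions per cycle
carries a resistance-mutation probability μ. The division index of the
first mutation is geometric with success probability μ, which is exact in
distribution, so the simulator draws that index directly instead of
book-keeping individual cells (10⁴ simulations run in milliseconds).
Calendar time within the mutating cycle maps the division index through
deterministic exponential growth (one cycle = 14 days). Defaults:
μ = 2×10⁻⁸, N0 = 2×10⁶, Nmax = 4×10⁷. Two closed forms serve as oracles:
the expected mutant count μ(Nmax − N0)×replatings, and the
Poisson/geometric approximation for the cycle of first occurrence
(P(cycle 1) ≈ 1 − e^(−0.76) ≈ 0.53 at defaults). With μ = 0 the
simulation is censored at a configurable cycle cap.

**POT outgrowth and 8-way split.** Each founder lineage grows as a linear
birth–death process (b = 0.032, d = 0.002 per cell per hour, the measured
rates for this cell line at 20% O₂ / 2 g/L glucose). The event-driven
Gillespie simulation is vectorised across lineages (identical in law to a
per-lineage event loop) and cross-checked in the tests against the exact
transient law of the process: extinction probability
α(t) = d(e^{rt}−1)/(be^{rt}−d) and a geometric surviving-size
distribution with mean (be^{rt}−d)/(b−d), r = b−d. Surviving lineages
are pooled and the cells split into 8 equal replicates uniformly at
random without replacement; the occupancy distribution (fraction of
surviving barcodes present in exactly k replicates) is averaged over 5
outgrowths × 4 splits (desk-scale version of the original
10 × 20 protocol).

*Outgrowth duration.* No duration is fixed by the experimental
description, and the occupancy numbers depend on it. The default stops
when surviving lineages average **185 cells** (t ≈ 172 h), inside the
150–200 band implied by the experiment (10⁶ barcoded founders expanded
to ~1.2–1.5×10⁸ cells, plus the conditioning on survival); within that
band the analytic occupancy mixture spans 87.2–90.2% for 8/8, and 185
reproduces the reported 90/4/2 occupancy triple most closely
(89.5/3.9/2.0). The mean size is exposed as `target_mean_size`.

*Analytic oracle.* P(exactly k of R replicates occupied | clone size n)
is computed exactly by inclusion–exclusion over equal-probability
multinomial placement, and the empirical occupancy is required to match
the mixture of this distribution over the realised clone sizes within 3
Monte-Carlo standard errors. (Multinomial placement is an approximation
to the without-replacement split, accurate because every clone is tiny
relative to the pooled population.)

## Synthetic experiment generator

The generator produces every input the inference consumes, with known
truth. Its defaults are the study's conditions:

- Pre-existing resistant subclones at POT frequencies 2.4%
  (GEF-resistant), 0.91% (double-resistant) and 0.57% (TRM-resistant);
  the sensitive background fills the remaining 96.12%.
- Clone growth rates are **log-frequency rates per week**, anchored on
  the final attached frequencies the subclones reach: 32.8% (GEF arm,
  4 weeks) and 0.2% (TRM arm) for the GEF-resistant clone; 22.4% / 86.1%
  for the double-resistant clone; 0.05% / 4.2% for the TRM-resistant
  clone. The background rate per arm is solved so frequencies sum to one
  at harvest (replicator consistency); DMSO rates are zero.
- 2,500 uniquely barcoded founder lineages. This is a desk-scale
  stand-in for the ~10⁶ founders of the real experiment, chosen so that
  a POT census sequenced at the study's depth (3×10⁵ reads) detects a
  barcode richness comparable to the ~2,300 barcodes actually observed;
  at 10⁶ founders every barcode would sit below the depth floor.
- POT outgrowth sampled from the exact transient birth–death law
  (mean surviving size 150 cells); replicate flasks seeded by a
  12-million-cell multinomial draw; censuses are multinomial samples of
  3×10⁵ reads (the census *is* the sequencing sample).
- Weekly floating (dead-cell) samples per drug replicate (4 weeks GEF,
  9 weeks TRM): deaths accumulate within each week as the positive part
  of each barcode's abundance decline, plus a 5%-per-week turnover of
  standing clones, and are flushed at the weekly media change.
- Amplicon reads are flank(12) + barcode(30) + flank(12) with
  independent per-base substitution errors; read counts are multinomial
  at the requested depth; a configurable fraction of reads carries a
  single base at Q = 20, exactly at the boundary of the strict Q > 20
  filter. Barcodes use the alternating weak/strong alphabet (WS)×15
  (W ∈ {A,T}, S ∈ {G,C}; the phase is configurable).

What the generator does **not** model: persistor/plasticity dynamics,
PCR amplification bias and chimeras, indels in reads, overdispersed
(non-multinomial) sequencing noise, doubly barcoded cells, and barcode
sharing between cells. Passing recovery tests therefore demonstrate
correctness of the estimators under multinomial sampling noise and the
planted clonal structure, not robustness to every artefact of real
libraries.

## Barcode processing

Reads must have quality strictly greater than 20 at *every* position;
the 30-bp barcode is extracted by regular expression between exact
12-base primer flanks. Error merging assigns sequences to
representatives matching the weak/strong pattern using Hamming distance
(default threshold 2; 30-bp barcodes at ≤0.5% per-base error rarely
accrue more than 2 errors). Because a substitution preserves the W/S
pattern with probability 1/3, error reads can themselves look
pattern-valid; conforming barcodes are therefore first collapsed into
strictly more abundant conforming neighbours within the threshold
(equal counts never merge, which keeps the operation idempotent), then
non-conforming barcodes are merged into the nearest surviving
representative (ties: higher count, then lexicographic). Counts are
conserved exactly; unmergeable sequences are kept and flagged. The
exact merge procedure used on the original data is unpublished, so the
printed barcode tallies (2,295 POT barcodes etc.) are emulation targets,
not reproduction targets.

## Clonal inference

Baseline frequency f0 = Max(fD7, fD8) over the two DMSO controls — the
conservative choice, since a larger baseline can only lower the inferred
growth rate. Growth rate per replicate: r = (1/T) ln(fR / f0), with
T = 4 weeks (GEF) and 9 weeks (TRM); fR = 0 maps to r = −∞, treated as
a negative rate by the phenotype rules rather than as missing.
Phenotype rules, in order: positive r in ≥1 GEF *and* ≥1 TRM replicate →
double-resistant; ≥2 GEF and no TRM → GEF-resistant; ≥2 TRM and no GEF →
TRM-resistant; exactly one positive replicate → putatively de novo;
otherwise sensitive; barcodes absent from both DMSO controls →
undetermined. "Positive" means r > 0 strictly, with no frequency floor
by default (a `min_f0` filter exists but is off, since none is described
for the original analysis).

Recovery scoring in the end-to-end report conditions on barcodes whose
*true* baseline frequency reaches 10⁻⁴ (below that, a 3×10⁵-read census
carries too few reads for any estimator). The headline growth-rate RMSE
compares the per-arm estimate — the mean of the finite per-replicate
estimates — against the planted clone rate, because the planted truth is
one rate per (barcode, arm); the per-replicate RMSE is reported
alongside and is dominated by Poisson read-count tails in low-frequency
barcodes. Functional subclones (barcodes with similar growth dynamics)
are grouped by average-linkage agglomerative clustering on the vector of
per-replicate rates with a configurable euclidean cutoff; no specific
method is prescribed by the source analysis, so this is a package
choice. Confluence growth curves are summarised by the OLS slope of
log-transformed values.

## Genomic profiles

SNV selection: coverage ≥ 10 in all samples and treated VAF ≥ 10× the
POT VAF, with a zero POT VAF floored at 1/(coverage+1). BAF at common
SNPs (global minor allele frequency 0.1–0.2, position ≥ 100 kb): highest
base count over coverage, randomly complemented with probability ½
(seeded) to emulate A/B allele assignment; LRR = log2(coverage) minus
the global median. Segmentation is a simplified recursive binary
change-point routine on a pooled-variance t statistic (threshold 5,
minimum 3 SNPs per segment) — a stand-in for CBS adequate for
piecewise-constant synthetic signals; externally produced segments are
accepted unchanged as the supported path for exact reproduction.
Heterozygosity per segment: count SNPs with major allele frequency
< 0.9 and test, by exact one-sided binomial tail, whether more than 5%
of the segment is heterozygous (reject at p < 0.05 → heterozygous;
otherwise LOH). The median major AF over heterozygous SNPs represents
the segment's allelic imbalance.

Ploidy: purity fixed at ρ = 1 (cell lines); for ψ on a 0.01 grid over
[1.5, 5.5], total copy = ψ·2^LRR, major = (median het major AF)·total
(1.0·total for LOH segments), minor = total − major; the objective is
the SNP-count-weighted sum of squared distances of major and minor to
their nearest integers, and the smallest-distance ψ wins (unweighted
mode available). The 2^LRR scaling assumes depth-proportional coverage
(sequencing gamma = 1). One numerical caveat, verified in the tests:
the global-median LRR reference sits at the *median SNP*, so profiles in
which the modal copy state holds only a bare majority of SNPs (e.g.
three equal-size segments) place that reference at the edge of the
modal coverage distribution and bias ψ upward by a few percent; profiles
shaped like real genomes — modal state holding most SNPs, minor states
on both sides — recover ψ to ±0.05. Depth-ratio calls: gain above 1.2,
loss below 0.8, boundaries neutral.

## Pharmacology

PCI = 100(c_pos − I)/(c_pos − c_neg), with c_pos/c_neg the means of 14
drug-free and 14 empty wells per plate; degenerate plates (c_pos =
c_neg) are rejected. Hits: per (concentration, replicate) list, drop
compounds with mean PCI change below 5 points, rank descending, keep the
top six (ties at rank six all kept and flagged — the selection rule does
not say); a compound in more than one list is a hit. Dose–response:
percent growth normalised to six positive / six negative control wells,
then y(x) = 100/(1 + (x/ec50)^hill) fitted by bounded nonlinear least
squares on log10(ec50) (ec50 within [min dose/100, max dose×100],
hill within [0.01, 20], initialised from the dose nearest 50% growth).
Curves with no inhibition are flagged non-identifiable. Noiseless
curves are recovered to 10⁻⁶ relative accuracy; with 5-point response
noise the median relative EC50 error stays under 10%.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline spawns
per-stage seeds from one master seed via `numpy.random.SeedSequence`, so
full runs are bit-reproducible. Default problem sizes — 10,000 lineages
and 5×4 outgrowth/splits for the occupancy simulation, 10⁴ waiting-time
simulations, 2,500 founder lineages at 3×10⁵ reads per census for the
end-to-end run, 400 segments for the calibration check — are the
package's chosen balance of Monte-Carlo error against runtime; all
complete in seconds on one core. The FASTQ leg of the end-to-end run
processes one census at 2×10⁴ reads through emission → quality filter →
extraction → merging (parser-level behaviour does not depend on depth);
census-level multinomial sampling carries the sequencing noise for the
recovery statistics.

## Known limitations

- The replicate split and drug-arm dynamics are expectation-plus-
  multinomial, not agent-based; week-to-week genetic drift within a
  flask beyond census sampling is not modelled.
- The segmentation routine is not a bit-exact CBS reimplementation.
- The ploidy model fixes purity at 1 and gamma at 1; impure samples or
  array data would need both generalised.
- Printed data-derived quantities from the original experiment (exact
  barcode counts, IC50 fold-changes of specific compounds) depend on
  unpublished processing details and deposited raw data; they anchor the
  generator's defaults but are not reproduction targets.
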