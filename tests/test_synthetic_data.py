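"""Generator invariants: clonal structure, dynamics, reads, plates, SNPs."""

import math

import numpy as np
import pytest

from evosteer import clonal_inference as ci
from evosteer import synthetic_data as sd


class TestPopulationSpec:
    def test_default_resistant_clones_sum(self, default_spec):
        """Default POT carries 2.4% + 0.91% + 0.57% = 3.88% resistant cells,
        matching the reported ~3.9% combined resistant frequency."""
        assert default_spec.resistant_frequency == pytest.approx(0.0388)
        assert default_spec.resistant_frequency == pytest.approx(0.039, abs=0.0005)

    def test_zero_resistant_clones_all_background(self):
        spec = sd.generate_population_spec({"clone_frequencies": {}})
        assert len(spec.clones) == 1
        bg = spec.clones[0]
        assert bg.phenotype == ci.SENSITIVE
        assert bg.initial_frequency == pytest.approx(1.0)

    def test_overfull_frequencies_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_population_spec(
                {
                    "clone_frequencies": {
                        ci.GEF_RESISTANT: 0.6,
                        ci.TRM_RESISTANT: 0.6,
                    }
                }
            )

    def test_growth_rates_anchored_on_final_frequencies(self, default_spec):
        dbl = next(c for c in default_spec.clones if c.phenotype == ci.DOUBLE_RESISTANT)
        assert dbl.growth_rate_per_condition["TRM"] == pytest.approx(
            math.log(0.861 / 0.0091) / 9
        )
        assert dbl.growth_rate_per_condition["GEF"] == pytest.approx(
            math.log(0.224 / 0.0091) / 4
        )

    def test_phenotype_rate_sign_consistency_enforced(self):
        with pytest.raises(ValueError, match="signs"):
            sd.CloneDefinition(
                clone_id="x",
                phenotype=ci.DOUBLE_RESISTANT,
                initial_frequency=0.01,
                growth_rate_per_condition={"GEF": 0.5, "TRM": -0.5, "DMSO": 0.0},
            )


class TestSimulateExperiment:
    def test_census_frequencies_sum_to_one(self, default_dataset):
        for census in default_dataset.censuses:
            assert sum(census.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_fixed_seed(self, default_spec):
        a = sd.simulate_experiment(default_spec, sd.ExperimentDesign(), seed=42)
        b = sd.simulate_experiment(default_spec, sd.ExperimentDesign(), seed=42)
        assert [c.sample_id for c in a.censuses] == [c.sample_id for c in b.censuses]
        for ca, cb in zip(a.censuses, b.censuses):
            assert ca.counts == cb.counts
        assert a.truth.equals(b.truth)

    def test_expected_sample_layout(self, default_dataset):
        ids = {c.sample_id for c in default_dataset.censuses}
        assert {"POT", "DMSO7", "DMSO8", "GEF1", "GEF2", "GEF3", "TRM4", "TRM5",
                "TRM6"} <= ids
        # weekly floating samples: 4 per GEF replicate, 9 per TRM replicate
        for rep in ("GEF1", "GEF2", "GEF3"):
            assert {f"{rep}-F{w}" for w in range(1, 5)} <= ids
        for rep in ("TRM4", "TRM5", "TRM6"):
            assert {f"{rep}-F{w}" for w in range(1, 10)} <= ids

    def test_selection_direction_follows_clone_rates(self, default_dataset):
        """A clone growing under GEF but dying under TRM rises in the GEF
        censuses and falls in the TRM censuses relative to baseline."""
        truth = default_dataset.truth
        gefr = truth.index[truth["phenotype"] == ci.GEF_RESISTANT]
        pot = default_dataset.census("POT").frequencies
        f_pot = sum(pot.get(b, 0.0) for b in gefr)
        for rep in ("GEF1", "GEF2", "GEF3"):
            f = default_dataset.census(rep).frequencies
            assert sum(f.get(b, 0.0) for b in gefr) > 2 * f_pot
        for rep in ("TRM4", "TRM5", "TRM6"):
            f = default_dataset.census(rep).frequencies
            assert sum(f.get(b, 0.0) for b in gefr) < f_pot

    def test_final_floating_matches_final_attached(self, default_dataset):
        """Dominant barcodes of the last floating sample match the harvest."""
        for rep, week in (("GEF1", 4), ("TRM4", 9)):
            attached = default_dataset.census(rep)
            floating = default_dataset.census(f"{rep}-F{week}")
            sim = ci.census_similarity(attached, floating)
            assert sim > 0.5, f"{rep}: cosine {sim:.3f}"

    def test_resistant_floating_trajectory_rises_in_expectation(self, default_dataset):
        truth = default_dataset.truth
        resistant = truth.index[truth["phenotype"] == ci.DOUBLE_RESISTANT]
        pooled = []
        for week in range(1, 10):
            ef = default_dataset.expected_floating[("TRM4", week)]
            pooled.append(sum(ef.get(b, 0.0) for b in resistant))
        assert all(b > a for a, b in zip(pooled, pooled[1:]))

    def test_dmso_drifts_only_by_sampling(self, default_dataset):
        pot = default_dataset.census("POT")
        dmso = default_dataset.census("DMSO7")
        assert ci.census_similarity(pot, dmso) > 0.99


class TestEmitReads:
    def test_zero_error_single_barcode_identical_reads(self):
        census = sd.BarcodeCensus(sample_id="s", counts={"TG" * 15: 5})
        reads = sd.emit_barcode_reads(census, depth=100, error_rate=0.0, seed=0)
        assert len(reads) == 100
        seqs = {seq for _, seq, _ in reads}
        assert seqs == {sd.DEFAULT_FLANK_FWD + "TG" * 15 + sd.DEFAULT_FLANK_REV}

    def test_read_count_conservation(self, default_dataset):
        census = default_dataset.census("DMSO7")
        reads = sd.emit_barcode_reads(census, depth=5_000, error_rate=0.001, seed=1)
        assert len(reads) == 5_000

    def test_error_rate_matches_binomial_model(self):
        """Fraction of reads with a corrupted barcode ~ 1 - (1-e)^30."""
        bc = "TG" * 15
        census = sd.BarcodeCensus(sample_id="s", counts={bc: 1})
        e = 0.005
        reads = sd.emit_barcode_reads(census, depth=20_000, error_rate=e, seed=2)
        bad = sum(1 for _, seq, _ in reads if seq[12:42] != bc)
        expected = 1 - (1 - e) ** 30
        se = math.sqrt(expected * (1 - expected) / 20_000)
        assert abs(bad / 20_000 - expected) < 4 * se

    def test_fail_fraction_gets_boundary_quality(self):
        census = sd.BarcodeCensus(sample_id="s", counts={"TG" * 15: 1})
        reads = sd.emit_barcode_reads(
            census, depth=1_000, error_rate=0.0, seed=3, fail_q_fraction=0.1
        )
        n_fail = sum(1 for _, _, q in reads if min(ord(c) - 33 for c in q) == 20)
        assert n_fail == 100

    def test_zero_depth_warns_and_returns_empty(self, caplog):
        census = sd.BarcodeCensus(sample_id="s", counts={"TG" * 15: 1})
        with caplog.at_level("WARNING"):
            assert sd.emit_barcode_reads(census, depth=0) == []
        assert "zero depth" in caplog.text


class TestSnpDataset:
    def test_balanced_segment_mean_major_af_near_half(self):
        snp, _ = generated = sd.generate_snp_dataset(
            [(1, 1)], n_snps=400, depth=500, psi_true=2.0, seed=4
        )
        counts = snp[["A", "C", "G", "T"]].to_numpy()
        major = counts.max(axis=1) / counts.sum(axis=1)
        # major allele frequency of a balanced site is folded noise above 1/2
        assert 0.5 <= major.mean() < 0.53

    def test_loh_segment_looks_homozygous(self):
        snp, _ = sd.generate_snp_dataset([(2, 0)], n_snps=200, depth=200, seed=5)
        counts = snp[["A", "C", "G", "T"]].to_numpy()
        major = counts.max(axis=1) / counts.sum(axis=1)
        assert (major > 0.97).mean() > 0.95

    def test_zero_copy_segment_rejected(self):
        with pytest.raises(ValueError, match="copy"):
            sd.generate_snp_dataset([(0, 0)], n_snps=10)

    def test_coverage_scales_with_copy_number(self):
        snp, truth = sd.generate_snp_dataset(
            [(1, 1), (2, 2)], n_snps=500, depth=300, psi_true=2.0, seed=6
        )
        cov = snp[["A", "C", "G", "T"]].sum(axis=1)
        by_chrom = cov.groupby(snp["chrom"]).mean()
        assert by_chrom["2"] / by_chrom["1"] == pytest.approx(2.0, rel=0.05)


class TestScreenPlates:
    def test_compound_well_count(self):
        plates = sd.generate_screen_plates(
            n_compounds=485, noise_sd=0.0, lines=("L1",), control_line="L1",
            n_replicates=3, seed=7,
        )
        n_compound_wells = sum(
            1 for p in plates for w in p.wells if w.role == "compound"
        )
        assert n_compound_wells == 485 * 3 * 3

    def test_every_plate_has_control_wells(self):
        plates = sd.generate_screen_plates(n_compounds=50, seed=8)
        for p in plates:
            roles = [w.role for w in p.wells]
            assert roles.count("positive_control") == 14
            assert roles.count("empty") == 14

    def test_noiseless_intensities_hit_control_means(self):
        effects = {"L1": np.zeros((4, 3)), "L2": np.ones((4, 3))}
        plates = sd.generate_screen_plates(
            n_compounds=4, effects=effects, noise_sd=0.0,
            lines=("L1", "L2"), control_line="L1", n_replicates=1, seed=9,
        )
        for p in plates:
            c_pos, c_neg = p.control_means()
            wells = [w.intensity for w in p.wells if w.role == "compound"]
            target = c_pos if p.line == "L1" else c_neg
            assert wells == pytest.approx([target] * len(wells))
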