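"""Simulated catalogs, cohorts and read sets against their design targets."""

import numpy as np
import pytest

from hervk_typer.reference import build_unique_reference
from hervk_typer.simulate import (
    PROVIRUS,
    SimulationConfig,
    SimulationError,
    default_prevalences,
    reads_for_sample,
    sample_read_layout,
    simulate_catalog,
    simulate_cohort,
    simulate_reads,
)


def pairwise_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestSimulateCatalog:
    def test_divergence_matches_substitution_expectation(self):
        config = SimulationConfig(n_loci=6, provirus_length=4000, ltr_length=400,
                                  seed=11)
        catalog, _ = simulate_catalog(config)
        seqs = [l.primary_allele.sequence for l in catalog]
        d = config.divergence
        # both copies mutate independently from the ancestor: sites agree
        # when neither mutated, or both mutated to the same base
        expected = (1 - d) ** 2 + d**2 / 3
        idents = [
            pairwise_identity(seqs[i], seqs[j])
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        ]
        assert abs(np.mean(idents) - expected) < 0.01

    def test_loci_exceed_eighty_percent_identity(self):
        config = SimulationConfig(n_loci=4, provirus_length=3000, ltr_length=300,
                                  seed=12)
        catalog, _ = simulate_catalog(config)
        seqs = [l.primary_allele.sequence for l in catalog]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) > 0.8

    def test_zero_divergence_warns_and_forces_reporting_group(self):
        config = SimulationConfig(n_loci=2, divergence=0.0, provirus_length=2000,
                                  ltr_length=200, seed=13)
        with pytest.warns(UserWarning, match="indistinguishable"):
            catalog, _ = simulate_catalog(config)
        ref = build_unique_reference(catalog, k=50)
        ids = catalog.locus_ids
        assert ref.reporting_groups[ids[0]] == ref.reporting_groups[ids[1]]
        assert ref.T_per_locus[ids[1]] == 0
        assert ref.T_per_locus[ids[0]] > 0

    def test_ltr_duplicated_at_both_ends(self):
        config = SimulationConfig(n_loci=2, provirus_length=2500, ltr_length=300,
                                  seed=14)
        catalog, _ = simulate_catalog(config)
        for locus in catalog:
            seq = locus.primary_allele.sequence
            assert seq[:300] == seq[-300:]
            assert locus.primary_allele.ltr_intervals == [(0, 300), (2200, 2500)]

    def test_zero_ltr_length_disables_ltr_intervals(self):
        config = SimulationConfig(n_loci=2, ltr_length=0, provirus_length=2000,
                                  seed=15)
        catalog, _ = simulate_catalog(config)
        assert all(not l.primary_allele.ltr_intervals for l in catalog)

    def test_solo_sequence_is_the_single_ltr(self):
        config = SimulationConfig(n_loci=2, provirus_length=2500, ltr_length=300,
                                  seed=16)
        catalog, context = simulate_catalog(config)
        for locus in catalog:
            ltr = context[locus.locus_id]["ltr"]
            assert len(ltr) == 300
            from hervk_typer.simulate import codes_to_str

            assert codes_to_str(ltr) == locus.primary_allele.sequence[:300]


class TestSimulateCohort:
    def base_config(self, **kw):
        defaults = dict(n_loci=2, provirus_length=2000, ltr_length=200,
                        n_samples=50, seed=17)
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_certain_provirus_prevalence_is_homozygous_everywhere(self):
        config = self.base_config(
            n_populations=1, prevalences=[[[1.0, 0.0, 0.0]] * 2]
        )
        catalog, _ = simulate_catalog(config)
        truth = simulate_cohort(catalog, config)
        assert (truth.hap_states == PROVIRUS).all()
        assert (truth.observed_states() == "provirus").all().all()

    def test_certain_absence(self):
        config = self.base_config(
            n_populations=1, prevalences=[[[0.0, 0.0, 1.0]] * 2]
        )
        catalog, _ = simulate_catalog(config)
        truth = simulate_cohort(catalog, config)
        assert (truth.observed_states() == "absent").all().all()

    def test_haplotype_frequency_within_binomial_interval(self):
        config = self.base_config(
            n_samples=2000, n_populations=1,
            prevalences=[[[0.3, 0.1, 0.6]] * 2],
        )
        catalog, _ = simulate_catalog(config)
        truth = simulate_cohort(catalog, config)
        n_hap = 2000 * 2
        observed = (truth.hap_states[:, 0, :] == PROVIRUS).mean()
        sd = np.sqrt(0.3 * 0.7 / n_hap)
        assert abs(observed - 0.3) < 3 * sd

    def test_unmatched_prevalence_shape_rejected(self):
        with pytest.raises(SimulationError):
            self.base_config(n_populations=2, prevalences=[[[1, 0, 0]] * 2])

    def test_prevalence_rows_must_sum_to_one(self):
        with pytest.raises(SimulationError):
            self.base_config(
                n_populations=1, prevalences=[[[0.5, 0.2, 0.2]] * 2]
            )

    def test_generated_prevalences_are_population_structured(self):
        config = self.base_config(n_populations=3)
        prev = default_prevalences(config)
        assert prev.shape == (3, 2, 3)
        assert np.allclose(prev.sum(axis=2), 1.0)
        assert not np.allclose(prev[0, :, 0], prev[1, :, 0])


class TestReadLayout:
    def test_read_count_matches_depth(self):
        rng = np.random.default_rng(18)
        config = SimulationConfig(read_length=100, error_rate=0.0, seed=0)
        starts, _ = sample_read_layout(rng, 10_000, config, depth=15.0)
        expected = 15.0 * 10_000 / 100
        assert abs(len(starts) - expected) <= 3 * np.sqrt(expected)

    def test_starts_lie_in_range_and_are_sorted(self):
        rng = np.random.default_rng(19)
        config = SimulationConfig(read_length=100, seed=0)
        starts, _ = sample_read_layout(rng, 5_000, config, depth=8.0)
        assert starts.min() >= 0
        assert starts.max() <= 5_000 - 100
        assert (np.diff(starts) >= 0).all()

    def test_error_mask_rate(self):
        rng = np.random.default_rng(20)
        config = SimulationConfig(read_length=100, error_rate=0.01, seed=0)
        _, mask = sample_read_layout(rng, 50_000, config, depth=20.0)
        assert mask is not None
        assert mask.mean() == pytest.approx(0.01, rel=0.1)

    def test_read_longer_than_region_rejected(self):
        rng = np.random.default_rng(21)
        config = SimulationConfig(read_length=100, seed=0)
        with pytest.raises(SimulationError):
            sample_read_layout(rng, 50, config, depth=5.0)


class TestSimulatedReads:
    def small(self):
        config = SimulationConfig(
            n_loci=2, n_samples=4, provirus_length=1500, ltr_length=200,
            flank_length=150, depth=10.0, error_rate=0.0, seed=22,
        )
        catalog, context = simulate_catalog(config)
        truth = simulate_cohort(catalog, config)
        return config, catalog, context, truth

    def test_read_names_encode_source(self):
        config, catalog, context, truth = self.small()
        reads = reads_for_sample(truth, catalog, context, 0)
        assert reads
        for name, seq, chrom, pos in reads:
            assert name.startswith("S0000:")
            assert len(seq) == config.read_length
            assert chrom == "sim1"

    def test_deterministic_given_seed(self):
        config, catalog, context, truth = self.small()
        a = reads_for_sample(truth, catalog, context, 1)
        b = reads_for_sample(truth, catalog, context, 1)
        assert a == b

    def test_fastq_and_truth_files_written(self, tmp_path):
        config, catalog, context, truth = self.small()
        paths = simulate_reads(truth, catalog, context, tmp_path)
        for sample in truth.sample_ids:
            assert paths[sample].exists()
            text = paths[sample].read_text()
            assert text.startswith("@")
        assert paths["metadata"].exists()
        assert paths["truth"].exists()

    def test_bam_reads_sit_on_their_locus(self, tmp_path):
        import pysam

        config, catalog, context, truth = self.small()
        paths = simulate_reads(truth, catalog, context, tmp_path, write_bam=True)
        with pysam.AlignmentFile(str(paths["bam"])) as bam:
            names = [r.query_name for r in bam.fetch()]
        assert names
        fastq_reads = sum(
            len(reads_for_sample(truth, catalog, context, i))
            for i in range(config.n_samples)
        )
        assert len(names) == fastq_reads
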