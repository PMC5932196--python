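"""Allotetraploid simulator: determinism, truth tables, candidate calling,
the coverage-filter straw man, and the anchor-reach closed form."""

import dataclasses

import numpy as np
import pytest
import scipy.stats

from haplosweep import (
    ConfigError,
    SimConfig,
    anchor_reach,
    build_table,
    call_markers,
    enumerate_site_pairs,
    evaluate,
    make_genomes,
    naive_coverage_filter_snps,
    read_candidate_sites,
    simulate,
)


class TestConfig:
    def test_probabilities_validated(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, homeolog_divergence=1.5).validate()
        with pytest.raises(ConfigError):
            SimConfig(seed=1, error_rate=-0.1).validate()

    def test_coverage_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, coverage=0).validate()

    def test_snp_placement_requires_anchors(self, tmp_path):
        config = dataclasses.replace(
            SimConfig(seed=1), homeolog_divergence=0.0, n_snps=5
        )
        with pytest.raises(ConfigError):
            simulate(config, tmp_path)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        config = dataclasses.replace(
            SimConfig(seed=42), ancestor_length=3000, n_snps=5, coverage=8.0
        )
        r1 = simulate(config, tmp_path / "a")
        r2 = simulate(config, tmp_path / "b")
        assert r1.vcf_path.read_bytes() == r2.vcf_path.read_bytes()
        assert r1.truth.homeolog_sites == r2.truth.homeolog_sites
        assert r1.truth.accession_snps == r2.truth.accession_snps
        for acc in r1.bam_paths:
            assert (
                r1.bam_paths[acc].read_bytes() == r2.bam_paths[acc].read_bytes()
            )

    def test_different_seed_changes_the_truth(self, tmp_path):
        base = dataclasses.replace(
            SimConfig(seed=1), ancestor_length=3000, n_snps=5, coverage=8.0
        )
        r1 = simulate(base, tmp_path / "a")
        r2 = simulate(dataclasses.replace(base, seed=2), tmp_path / "b")
        assert r1.truth.homeolog_sites != r2.truth.homeolog_sites


class TestTruthAndCandidates:
    def test_no_variation_gives_empty_candidate_vcf(self, tmp_path):
        config = dataclasses.replace(
            SimConfig(seed=5),
            ancestor_length=3000,
            homeolog_divergence=0.0,
            n_snps=None,
            snp_rate=0.0,
            error_rate=0.0,
            coverage=8.0,
        )
        result = simulate(config, tmp_path)
        assert read_candidate_sites(result.vcf_path) == []

    def test_snps_disjoint_from_anchors_and_near_one(self):
        config = SimConfig(seed=9)
        rng = np.random.default_rng(config.seed)
        _, _, _, truth = make_genomes(config, rng)
        anchors = truth.anchor_positions
        assert len(truth.accession_snps) == config.n_snps
        for snp in truth.accession_snps:
            assert snp.pos not in anchors
            assert any(
                abs(snp.pos - a) <= config.snp_anchor_dist for a in anchors
            )
            assert snp.ref_base != snp.alt_base

    def test_truth_table_round_trips_through_tsv(self, tmp_path, sim_small):
        from haplosweep import TruthTable

        truth = TruthTable.read(sim_small.out_dir)
        assert truth.homeolog_sites == sim_small.truth.homeolog_sites
        assert truth.accession_snps == sim_small.truth.accession_snps

    def test_read_counts_near_expected_coverage(self, sim_small):
        import pysam

        config = sim_small.config
        expected = 2 * 2 * round(
            config.coverage * config.ancestor_length / (2 * config.read_length)
        )  # two subgenomes, two mates per fragment
        for bam in sim_small.bam_paths.values():
            with pysam.AlignmentFile(str(bam), "rb") as af:
                n = af.count()
            assert n == expected

    def test_homeolog_site_count_binomial_across_seeds(self):
        """Divergence draws are per-base Bernoulli, so anchor counts over
        seeds must match the Binomial(L, d) mean and spread."""
        L, d = 2000, 0.02
        counts = []
        for seed in range(60):
            config = dataclasses.replace(
                SimConfig(seed=seed),
                ancestor_length=L,
                homeolog_divergence=d,
                n_snps=None,
            )
            rng = np.random.default_rng(seed)
            _, _, _, truth = make_genomes(config, rng)
            counts.append(len(truth.homeolog_sites))
        mean, var = L * d, L * d * (1 - d)
        assert abs(np.mean(counts) - mean) < 3 * np.sqrt(var / len(counts))
        # two-sided chi-square bound on the sample variance
        ratio = np.var(counts, ddof=1) / var
        lo = scipy.stats.chi2.ppf(0.0005, 59) / 59
        hi = scipy.stats.chi2.ppf(0.9995, 59) / 59
        assert lo < ratio < hi


class TestNaiveCoverageFilter:
    def test_no_variation_yields_zero_calls(self, tmp_path):
        config = dataclasses.replace(
            SimConfig(seed=5),
            ancestor_length=3000,
            homeolog_divergence=0.0,
            n_snps=None,
            error_rate=0.0,
            coverage=8.0,
        )
        result = simulate(config, tmp_path)
        ref = result.reference_path.read_text().split("\n", 1)[1].replace("\n", "")
        calls = naive_coverage_filter_snps(
            result.bam_paths, ref, expected_coverage=2 * config.coverage
        )
        assert all(not c for c in calls.values())

    def test_coverage_filtering_leaves_homeolog_false_positives(self, sim_clean):
        """The straw man: homeolog sites whose sampled depth happens to fall
        inside the expected-coverage band are called as SNPs even though
        they are not polymorphic between accessions."""
        config = sim_clean.config
        ref = sim_clean.reference_path.read_text().split("\n", 1)[1].replace("\n", "")
        calls = naive_coverage_filter_snps(
            sim_clean.bam_paths, ref, expected_coverage=2 * config.coverage
        )
        result = evaluate(calls, sim_clean.truth)
        assert result.n_false_positive > 0
        assert result.fpr > 0


class TestEvaluate:
    def test_perfect_and_empty_callers(self, sim_clean):
        sites = read_candidate_sites(sim_clean.vcf_path)
        pairs = enumerate_site_pairs(sites, sim_clean.config.read_length)
        bams = {a: str(p) for a, p in sim_clean.bam_paths.items()}
        markers = call_markers(build_table(pairs, bams))
        perfect = evaluate(
            markers, sim_clean.truth, candidate_sites=sites,
            window=sim_clean.config.read_length,
        )
        assert perfect.n_discoverable > 0
        empty = evaluate(
            [], sim_clean.truth, candidate_sites=sites,
            window=sim_clean.config.read_length,
        )
        assert empty.tpr == 0.0
        assert empty.fpr == 0.0


class TestAnchorReach:
    @pytest.mark.parametrize(
        "n,read_length,expected",
        [(0, 150, 0), (10, 75, 1_500), (1, 150, 300)],
    )
    def test_closed_form(self, n, read_length, expected):
        assert anchor_reach(n, read_length) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            anchor_reach(-1, 150)
        with pytest.raises(ValueError):
            anchor_reach(10, 0)
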