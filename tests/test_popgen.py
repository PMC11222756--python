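"""Leray trimming, haplotype/SNP counting, cluster MCMC, signed-rank test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lerayhap import simulate
from lerayhap.popgen import (
    ClusterPosterior,
    ClusterRunParams,
    LerayWindow,
    SnpMatrix,
    compare_fragments,
    count_haplotypes,
    estimate_clusters,
    extract_snp_sites,
    locate_and_trim,
    wilcoxon_signed_rank,
)
from lerayhap.seqs import random_coding_sequence


@pytest.fixture(scope="module")
def gene():
    return random_coding_sequence(516, 5, np.random.default_rng(1))


class TestLocateAndTrim:
    def test_full_length_sequence_trims_to_313(self, gene):
        seqs = [("full", gene[60:60 + 650])]
        trimmed, reports = locate_and_trim(seqs, gene, 5)
        assert len(trimmed[0][1]) == 313
        assert reports[0].covered

    def test_in_frame_66_bp_deletion_gives_247(self, gene):
        w = LerayWindow()
        seq = gene[60:60 + 650]
        lo = w.nt_start + 30 - 60  # deletion inside the window, in frame
        deleted = seq[:lo] + seq[lo + 66:]
        trimmed, _ = locate_and_trim([("del66", deleted)], gene, 5)
        assert len(trimmed[0][1]) == 247
        assert (313 - 247) // 3 == 22  # amino acids lost

    def test_sequence_ending_before_window_excluded(self, gene):
        w = LerayWindow()
        short = gene[: w.nt_start - 30]
        ok = gene[60:60 + 650]
        trimmed, reports = locate_and_trim([("short", short), ("ok", ok)], gene, 5)
        assert [r.covered for r in reports] == [False, True]
        assert [sid for sid, _ in trimmed] == ["ok"]

    def test_nothing_covering_window_rejected(self, gene):
        with pytest.raises(ValueError):
            locate_and_trim([("short", gene[:100])], gene, 5)


class TestHaplotypes:
    def test_one_variable_site_two_haplotypes(self):
        seqs = [("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGAACGT")]
        summary = count_haplotypes(seqs)
        assert summary.n_haplotypes == 2
        assert summary.n_segregating_sites == 1
        assert summary.frequencies == {"hap1": 2, "hap2": 1}

    def test_identical_sequences_single_haplotype(self):
        summary = count_haplotypes([("a", "ACGT"), ("b", "acgt")])
        assert summary.n_haplotypes == 1 and summary.n_segregating_sites == 0

    def test_planned_haplotypes_recovered(self):
        rng = np.random.default_rng(4)
        cfg = simulate.SpeciesConfig("sp", random_coding_sequence(105, 2, rng), 2, 5, 8)
        haps = simulate.generate_haplotype_set(cfg, seed=5)
        draws = [(f"s{i}", haps[int(rng.integers(5))][1]) for i in range(50)]
        present = len({s for _, s in draws})
        assert count_haplotypes(draws).n_haplotypes == present == 5

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            count_haplotypes([])


class TestSnpSites:
    def test_invariant_matrix_empty(self):
        snps = extract_snp_sites([("a", "ACGT"), ("b", "ACGT")])
        assert snps.n_loci == 0 and snps.matrix.shape == (2, 0)

    def test_single_variable_site(self):
        snps = extract_snp_sites([("a", "ACGT"), ("b", "ACCT")])
        assert snps.positions == [2]
        assert snps.matrix.tolist() == [[1], [0]]  # C < G in sorted state order

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACGTN"), size=60, p=[0.24] * 4 + [0.04])) for _ in range(12)]
        seqs = [(f"s{i}", r) for i, r in enumerate(rows)]
        snps = extract_snp_sites(seqs)
        brute = [
            c for c in range(60)
            if len({r[c] for r in rows} & set("ACGT")) >= 2
        ]
        assert snps.positions == brute

    def test_ambiguous_cells_coded_missing(self):
        snps = extract_snp_sites([("a", "ANT"), ("b", "GCT"), ("c", "AGT")])
        assert snps.positions == [0, 1]
        assert snps.matrix[0].tolist() == [0, -1]


class TestClusterEstimator:
    def test_no_snps_point_mass_at_one(self):
        snps = extract_snp_sites([("a", "ACGT"), ("b", "ACGT")])
        post = estimate_clusters(snps)
        assert post.modal_k == 1 and post.modal_density == 1.0

    def test_posterior_sums_to_one(self):
        data = simulate.generate_popset(2, 8, 6, 400, seed=3)
        post = estimate_clusters(
            extract_snp_sites(data.sequences),
            ClusterRunParams(n_generations=20_000, burn_in=40, seed=0),
        )
        assert post.posterior.sum() == pytest.approx(1.0)
        assert post.modal_density == pytest.approx(post.posterior[post.modal_k - 1])

    def test_label_permutation_invariance(self):
        data = simulate.generate_popset(2, 10, 8, 400, seed=6)
        snps = extract_snp_sites(data.sequences)
        perm = np.random.default_rng(0).permutation(len(snps.ids))
        shuffled = SnpMatrix(
            [snps.ids[i] for i in perm], snps.positions, snps.matrix[perm], snps.n_states
        )
        params = ClusterRunParams(n_generations=30_000, burn_in=60, seed=11)
        p1 = estimate_clusters(snps, params)
        p2 = estimate_clusters(shuffled, params)
        assert p1.modal_k == p2.modal_k
        assert abs(p1.modal_density - p2.modal_density) < 0.15

    def test_single_sequence_rejected(self):
        snps = extract_snp_sites([("a", "ACGT")])
        with pytest.raises(ValueError):
            estimate_clusters(snps)

    def test_correlated_model_not_available(self):
        snps = extract_snp_sites([("a", "ACGT"), ("b", "ACCT")])
        with pytest.raises(NotImplementedError):
            estimate_clusters(snps, ClusterRunParams(frequency_model="correlated"))


class TestSignedRank:
    def test_all_zero_differences_p_one(self):
        w, p, n = wilcoxon_signed_rank([0, 0, 0])
        assert (w, p, n) == (0.0, 1.0, 0)

    def test_exact_enumeration_oracle_n8(self):
        rng = np.random.default_rng(2)
        d = rng.integers(-5, 6, size=8).astype(float)
        d[d == 0] = 1
        w_obs, p, _ = wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            w = sum(r for r, s in zip(ranks, signs) if s)
            if w >= w_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / 256)

    def test_agrees_with_scipy_exact(self):
        d = np.array([3, 1, 2, 4, -1, 2, 5, 1], dtype=float)
        w, p, _ = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="greater")
        assert w == ref.statistic and p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.integers(-6, 7, size=12).astype(float)
            d[d == 0] = 2
            _, p_exact, _ = wilcoxon_signed_rank(d, exact_max_n=12)
            _, p_norm, _ = wilcoxon_signed_rank(d, exact_max_n=0)
            assert abs(p_exact - p_norm) <= 0.01


class TestCompareFragments:
    def test_report_fields(self):
        pairs = [("d1", 3, 2), ("d2", 2, 2), ("d3", 4, 1), ("d4", 2, 1)]
        report = compare_fragments(pairs, n_sequences=[30, 40, 50, 60], lengths=[600, 650, 700, 750])
        assert report.n == 4 and report.n_nonzero == 3
        assert report.mean_original > report.mean_trimmed
        assert 0 <= report.p_value <= 1
        assert np.isfinite(report.corr_nseq_k[0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            compare_fragments([("d1", 2, 1)])


class TestTrimmingMonotonicity:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_trimmed_haplotypes_never_exceed_original(self, seed, gene):
        data = simulate.generate_popset(
            2, 8, 6, 650, seed=seed, fixed_placement="outside" if seed % 2 else "inside"
        )
        trimmed, _ = locate_and_trim(data.sequences, data.gene, data.code_id)
        h_orig = count_haplotypes(data.sequences).n_haplotypes
        h_trim = count_haplotypes(trimmed).n_haplotypes
        assert h_trim <= h_orig
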