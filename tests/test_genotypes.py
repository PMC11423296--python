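"""Genotype container, I/O round-trips, filtering, imputation, PC scores."""

import numpy as np
import pytest

import tsopt
from tsopt.genotypes import GenotypeMatrix, filter_genotypes, impute_missing, pc_scores


def make(dosage, missing=None, ids=None, loci=None):
    dosage = np.asarray(dosage)
    V, J = dosage.shape
    return GenotypeMatrix(
        dosage, missing,
        ids or [f"i{k}" for k in range(V)],
        loci or [f"l{k}" for k in range(J)],
    )


class TestContainer:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            make([[0, 3]])

    def test_alt_freq_ignores_missing(self):
        g = make([[0, 2], [2, 2]], missing=[[False, True], [False, False]])
        assert g.alt_freq[0] == pytest.approx(0.5)
        assert g.alt_freq[1] == pytest.approx(1.0)


class TestVcfIO:
    def test_round_trip_preserves_dosage_and_missing(self, tmp_path, small_complete_panel):
        cfg = tsopt.SimulationConfig(n_individuals=15, n_loci=40, seed=8,
                                     missing_locus_rate=0.1, missing_indiv_rate=0.05)
        g = tsopt.simulate_genotypes(cfg)
        path = tmp_path / "panel.vcf"
        tsopt.write_genotypes(g, path, format="vcf")
        back = tsopt.read_genotypes(path, format="vcf")
        assert back.individual_ids == g.individual_ids
        assert back.locus_ids == g.locus_ids
        assert np.array_equal(back.missing, g.missing)
        assert np.array_equal(back.dosage[~back.missing], g.dosage[~g.missing])

    def test_het_and_missing_codes(self, tmp_path):
        g = make([[1, 0], [2, 1]], missing=[[False, True], [False, False]])
        path = tmp_path / "t.vcf"
        tsopt.write_genotypes(g, path)
        back = tsopt.read_genotypes(path)
        assert back.dosage[0, 0] == 1  # 0/1 -> dosage 1
        assert back.missing[0, 1]  # ./. -> missing

    def test_matrix_round_trip(self, tmp_path):
        g = make([[0, 1, 2], [2, 1, 0]], missing=[[False, False, True],
                                                  [False, False, False]])
        path = tmp_path / "t.tsv"
        tsopt.write_genotypes(g, path, format="matrix")
        back = tsopt.read_genotypes(path, format="matrix")
        assert np.array_equal(back.missing, g.missing)
        assert np.array_equal(back.dosage[~back.missing], g.dosage[~g.missing])

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            tsopt.read_genotypes("/nonexistent.vcf")


class TestFiltering:
    def test_rare_allele_dropped_at_maf_floor(self):
        # locus 0 at p = 1/200 < 0.01; locus 1 common
        dosage = np.zeros((100, 2), dtype=int)
        dosage[0, 0] = 1
        dosage[:50, 1] = 2
        out = filter_genotypes(make(dosage), min_maf=0.01)
        assert out.locus_ids == ["l1"]

    def test_clean_balanced_matrix_unchanged(self):
        g = make([[0, 2], [2, 0], [1, 1], [1, 1]])
        out = filter_genotypes(g)
        assert out.dosage.shape == (4, 2)

    def test_toy_matrix_matches_brute_force(self):
        # 4 individuals x 3 loci; locus 1 is 50% missing (drop at 30%);
        # individual 3 is then 1/2 missing (drop at 45%)
        dosage = np.array([[0, 1, 2], [1, 0, 1], [2, 0, 1], [1, 2, 0]])
        missing = np.array([
            [False, True, False],
            [False, True, False],
            [False, False, False],
            [True, False, True],
        ])
        g = make(dosage, missing)
        # independent brute-force application of the rules, loci first
        maf = g.minor_allele_freq
        keep_loci = [j for j in range(3)
                     if maf[j] >= 0.01 and missing[:, j].mean() <= 0.30]
        keep_ind = [v for v in range(4)
                    if missing[v][keep_loci].mean() <= 0.45]
        out = filter_genotypes(g)
        assert out.locus_ids == [f"l{j}" for j in keep_loci]
        assert out.individual_ids == [f"i{v}" for v in keep_ind]

    def test_empty_result_is_explicit(self):
        g = make([[0, 0], [0, 0]])  # all monomorphic
        with pytest.raises(ValueError, match="no loci"):
            filter_genotypes(g)

    def test_filter_equivariant_under_relabeling(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(12, 20))
        missing = rng.random((12, 20)) < 0.2
        g = make(dosage, missing)
        perm = rng.permutation(12)
        gp = g.take_individuals(perm)
        a = filter_genotypes(g)
        b = filter_genotypes(gp)
        assert sorted(a.individual_ids) == sorted(b.individual_ids)
        assert a.locus_ids == b.locus_ids


class TestImputation:
    def test_mean_round_rounds_half_up(self):
        # observed {0,2,2,2}: p = 0.75, 2p = 1.5 -> 2
        g = make([[0], [2], [2], [2], [0]], missing=[[False]] * 4 + [[True]])
        out = impute_missing(g, "mean_round")
        assert out.dosage[4, 0] == 2

    def test_mode_takes_plurality(self):
        g = make([[1], [1], [2], [0]], missing=[[False], [False], [False], [True]])
        assert impute_missing(g, "mode").dosage[3, 0] == 1

    def test_complete_matrix_is_identity(self, small_complete_panel):
        out = impute_missing(small_complete_panel)
        assert np.array_equal(out.dosage, small_complete_panel.dosage)

    def test_all_missing_locus_errors(self):
        g = make([[0, 0], [1, 0]], missing=[[False, True], [False, True]])
        with pytest.raises(ValueError, match="filter"):
            impute_missing(g)


class TestPcScores:
    def test_duplicated_individuals_have_equal_scores(self, small_complete_panel):
        g = small_complete_panel
        dup = g.take_individuals(list(range(g.n_individuals)) + [0])
        s = pc_scores(dup, 4)
        np.testing.assert_allclose(s.scores[0], s.scores[-1], atol=1e-8)

    def test_scores_centered_and_variance_complete(self, small_complete_panel):
        s = pc_scores(small_complete_panel)
        np.testing.assert_allclose(s.scores.mean(axis=0), 0, atol=1e-8)
        x = small_complete_panel.dosage - small_complete_panel.dosage.mean(axis=0)
        total = np.sum(np.var(x, axis=0, ddof=1))
        full = pc_scores(small_complete_panel, small_complete_panel.n_individuals - 1)
        assert np.sum(full.explained_variance) == pytest.approx(total, rel=1e-8)

    def test_orthogonal_nonincreasing(self, small_complete_panel):
        s = pc_scores(small_complete_panel, 6)
        gram = s.scores.T @ s.scores
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-6)
        assert (np.diff(s.explained_variance) <= 1e-9).all()

    def test_groups_separated_on_structured_panel(self):
        from sklearn.metrics import silhouette_score

        cfg = tsopt.SimulationConfig(
            n_individuals=90, n_loci=1000, group_sizes=(30, 30, 30), fst=0.3,
            seed=13, missing_locus_rate=0.0, missing_indiv_rate=0.0,
        )
        g = tsopt.simulate_genotypes(cfg, complete=True)
        s = pc_scores(g, 2)
        labels = np.repeat([0, 1, 2], 30)
        assert silhouette_score(s.scores, labels) > 0

    def test_truncation_warns_beyond_rank(self, small_complete_panel):
        with pytest.warns(UserWarning, match="truncating"):
            s = pc_scores(small_complete_panel, small_complete_panel.n_individuals + 5)
        assert s.n_components <= small_complete_panel.n_individuals - 1
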