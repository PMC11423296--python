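"""Training-set criteria: closed forms, dense oracles, invariances."""

import itertools

import numpy as np
import pytest

import tsopt
from tsopt.criteria import (
    CriterionContext,
    cdmean,
    cdmin,
    d_optimality,
    ene_value,
    maximin,
    minimax,
    multiple_design,
    pev_criterion,
    r_score,
    _r_score_impl,
)


@pytest.fixture(scope="module")
def panel8():
    """8-individual structured panel with G, S, D for dense oracles."""
    cfg = tsopt.SimulationConfig(
        n_individuals=8, n_loci=40, group_sizes=(3, 3, 2), n_qtl=10, fst=0.3,
        seed=77, missing_locus_rate=0.0, missing_indiv_rate=0.0,
    )
    g = tsopt.simulate_genotypes(cfg, complete=True)
    return g, CriterionContext(
        G=tsopt.vanraden_g(g), S=tsopt.pc_scores(g, 4),
        D=tsopt.modified_rogers(g), n_markers=40, variance_ratio=1.0,
    )


class TestDOptimality:
    def test_orthonormal_scores_give_zero(self):
        S = np.eye(5)[:, :3]
        ctx = CriterionContext(S=S, n_markers=10)
        assert d_optimality([0, 1, 2], ctx).value == pytest.approx(0.0, abs=1e-6)

    def test_duplicate_worse_than_distinct(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(5, 3))
        S = np.vstack([S, S[1]])  # row 5 duplicates row 1
        ctx = CriterionContext(S=S, n_markers=10)
        with_dup = d_optimality([0, 1, 5], ctx).value
        distinct = d_optimality([0, 1, 2], ctx).value
        assert with_dup < distinct

    def test_permutation_invariance(self, panel8):
        _, ctx = panel8
        a = d_optimality([0, 3, 5], ctx).value
        b = d_optimality([5, 0, 3], ctx).value
        assert a == pytest.approx(b)


class TestCDCriteria:
    def test_matches_dense_incidence_matrix_oracle(self, panel8):
        """CDmean/CDmin from the packed implementation equal the literal
        (G Z' P Z G) ./ G evaluation with explicit Z, V and P matrices."""
        g, ctx = panel8
        G = ctx.G
        test = np.array([6, 7])
        for tr in itertools.combinations(range(6), 3):
            trn = np.array(tr)
            Z = np.zeros((3, 8))
            Z[np.arange(3), trn] = 1
            V = Z @ G @ Z.T + np.eye(3)
            Vi = np.linalg.inv(V)
            one = np.ones((3, 1))
            P = Vi - Vi @ one @ np.linalg.inv(one.T @ Vi @ one) @ one.T @ Vi
            CD = (G @ Z.T @ P @ Z @ G) / G
            d = np.diag(CD)
            assert cdmean(trn, ctx, test).value == pytest.approx(
                np.nanmean(d[test]), abs=1e-9
            )
            assert cdmin(trn, ctx, test).value == pytest.approx(
                np.nanmin(d[test]), abs=1e-9
            )
            assert np.nanmin(d) >= -1e-8 and np.nanmax(d) <= 1 + 1e-8

    def test_monotone_under_training_growth(self, panel8):
        _, ctx = panel8
        test = np.array([6, 7])
        for tr in itertools.combinations(range(6), 3):
            base = cdmean(np.array(tr), ctx, test).value
            for extra in set(range(6)) - set(tr):
                grown = cdmean(np.array(tr + (extra,)), ctx, test).value
                assert grown >= base - 1e-9

    def test_cdmin_bounded_by_cdmean(self, panel8):
        _, ctx = panel8
        for tr in itertools.combinations(range(6), 3):
            t = np.array(tr)
            assert cdmin(t, ctx).value <= cdmean(t, ctx).value + 1e-12

    def test_single_test_member_collapses_to_same_value(self, panel8):
        _, ctx = panel8
        t, test = np.array([0, 1, 2]), np.array([7])
        assert cdmin(t, ctx, test).value == pytest.approx(cdmean(t, ctx, test).value)

    def test_infinite_noise_kills_information(self, panel8):
        g, _ = panel8
        ctx = CriterionContext(G=tsopt.vanraden_g(g), n_markers=40,
                               variance_ratio=1e12)
        assert cdmean([0, 1, 2], ctx).value == pytest.approx(0.0, abs=1e-6)


class TestPev:
    def test_test_duplicated_in_training_gives_leverage_below_one(self, panel8):
        g, _ = panel8
        ctx = CriterionContext(S=tsopt.pc_scores(g, 4), n_markers=40,
                               lambda_pev=1e-8)
        v = pev_criterion(np.array([0, 1, 2, 6, 7]), ctx, np.array([6, 7])).value
        assert 0 < v <= 1 + 1e-6

    def test_monotone_under_training_growth(self, panel8):
        _, ctx = panel8
        test = np.array([6, 7])
        for tr in itertools.combinations(range(6), 3):
            base = pev_criterion(np.array(tr), ctx, test).value
            for extra in set(range(6)) - set(tr):
                grown = pev_criterion(np.array(tr + (extra,)), ctx, test).value
                assert grown <= base + 1e-9

    def test_stronger_ridge_lowers_value(self, panel8):
        g, _ = panel8
        t, test = np.array([0, 1, 2]), np.array([6, 7])
        small = CriterionContext(S=tsopt.pc_scores(g, 4), n_markers=40,
                                 lambda_pev=1e-3)
        large = CriterionContext(S=tsopt.pc_scores(g, 4), n_markers=40,
                                 lambda_pev=10.0)
        assert pev_criterion(t, large, test).value < pev_criterion(t, small, test).value

    def test_nonpositive_lambda_rejected(self, panel8):
        _, ctx = panel8
        bad = CriterionContext(S=ctx.S, n_markers=40, lambda_pev=0.0)
        bad.lambda_pev = 0.0
        with pytest.raises(ValueError, match="lambda"):
            pev_criterion([0, 1, 2], bad, [6, 7])


class TestRScore:
    def test_test_permutation_invariance(self, panel8):
        _, ctx = panel8
        t = np.array([0, 1, 2])
        a = r_score(t, ctx, np.array([5, 6, 7])).value
        b = r_score(t, ctx, np.array([7, 5, 6])).value
        assert a == pytest.approx(b)

    def test_duplicates_of_test_beat_disjoint_random_sets(self):
        """The criterion's purpose: a training set genetically identical
        to the test set must look better than an unrelated one."""
        wins = 0
        for rep in range(10):
            cfg = tsopt.SimulationConfig(
                n_individuals=30, n_loci=300, group_sizes=(10, 10, 10),
                n_qtl=50, fst=0.3, seed=300 + rep,
                missing_locus_rate=0.0, missing_indiv_rate=0.0,
            )
            g = tsopt.simulate_genotypes(cfg, complete=True)
            dup = g.take_individuals(list(range(30)) + list(range(8)))
            ctx = CriterionContext(S=tsopt.pc_scores(dup, 6), n_markers=300)
            test = np.arange(8)
            rng = np.random.default_rng(rep)
            r_dup = r_score(np.arange(30, 38), ctx, test).value
            r_rnd = r_score(np.sort(rng.choice(np.arange(8, 30), 8, False)),
                            ctx, test).value
            wins += r_dup > r_rnd
        assert wins >= 8

    def test_literal_denominator_flag_changes_scale_not_sign(self, panel8):
        _, ctx = panel8
        t, test = np.array([0, 1, 2]), np.array([5, 6, 7])
        a = r_score(t, ctx, test).value
        b = _r_score_impl(t, ctx, test, sqrt_denominator=False).value
        assert np.sign(a) == np.sign(b)
        assert a != b


class TestDistanceCriteria:
    def test_maximin_zero_with_duplicates(self):
        D = np.array([[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]])
        ctx = CriterionContext(D=D, n_markers=10)
        assert maximin([0, 1, 2], ctx).value == 0.0

    def test_maximin_nonincreasing_as_set_grows(self, panel8):
        _, ctx = panel8
        base = maximin([0, 3, 5], ctx).value
        for extra in (1, 2, 4, 6, 7):
            assert maximin([0, 3, 5, extra], ctx).value <= base + 1e-12

    def test_minimax_zero_when_training_duplicates_test(self):
        D = np.zeros((4, 4))
        D[0, 2] = D[2, 0] = D[1, 3] = D[3, 1] = 0.0
        D[0, 1] = D[1, 0] = D[2, 3] = D[3, 2] = 0.8
        D[0, 3] = D[3, 0] = D[1, 2] = D[2, 1] = 0.8
        ctx = CriterionContext(D=D, n_markers=10)
        # train {0,1} are zero-distance copies of test {2,3}... only 0-2, 1-3
        D2 = np.zeros((4, 4))
        D2[0, 3] = D2[3, 0] = D2[1, 2] = D2[2, 1] = 0.9
        ctx2 = CriterionContext(D=D2, n_markers=10)
        assert minimax([0, 1], ctx2, [2, 3]).value == pytest.approx(0.9)
        assert minimax([0, 1], CriterionContext(D=np.zeros((4, 4)), n_markers=10),
                       [2, 3]).value == 0.0

    def test_minimax_increases_with_far_member(self, panel8):
        _, ctx = panel8
        far = int(np.argmax(ctx.D[:, 6]))
        test = np.array([6])
        near = np.argsort(ctx.D[:, 6])[1:3]
        assert (minimax(np.append(near, far), ctx, test).value
                >= minimax(near, ctx, test).value)

    def test_multiple_design_value_and_feasibility(self, panel8):
        _, ctx = panel8
        t, test = np.array([0, 1, 2]), np.array([6, 7])
        res = multiple_design(t, ctx, test)
        within = ctx.D[np.ix_(t, t)][np.triu_indices(3, 1)].mean()
        between = ctx.D[np.ix_(t, test)].mean()
        assert res.value == pytest.approx(within - between)
        tight = multiple_design(t, ctx, test, distance_band=(0.0, 1e-6))
        assert not tight.feasible

    def test_ene_spacing_on_even_line(self):
        x = np.arange(5) * 0.2
        D = np.abs(x[:, None] - x[None, :])
        ctx = CriterionContext(D=D, n_markers=10)
        assert ene_value(np.arange(5), ctx).value == pytest.approx(0.2)

    def test_ene_zero_for_identical_pair(self):
        D = np.zeros((3, 3))
        ctx = CriterionContext(D=D, n_markers=10)
        assert ene_value([0, 1], ctx).value == 0.0


class TestRegistryAndInvariances:
    def test_unknown_name_rejected(self, panel8):
        _, ctx = panel8
        with pytest.raises(ValueError, match="unknown criterion"):
            tsopt.evaluate("aopt", [0, 1], ctx)

    @pytest.mark.parametrize("name", sorted(tsopt.CRITERIA))
    def test_relabeling_invariance(self, name, panel8):
        """Every criterion is invariant under joint relabeling of
        individuals (permuting the matrices and the index sets)."""
        g, _ = panel8
        ctx = CriterionContext(G=tsopt.vanraden_g(g), S=tsopt.pc_scores(g, 4),
                               D=tsopt.modified_rogers(g), n_markers=40,
                               variance_ratio=1.0)
        perm = np.random.default_rng(0).permutation(8)
        gp = g.take_individuals(perm)
        ctxp = CriterionContext(G=tsopt.vanraden_g(gp), S=tsopt.pc_scores(gp, 4),
                                D=tsopt.modified_rogers(gp), n_markers=40,
                                variance_ratio=1.0)
        inv = np.argsort(perm)
        train, test = np.array([0, 2, 5]), np.array([6, 7])
        a = tsopt.evaluate(name, train, ctx, test).value
        b = tsopt.evaluate(name, inv[train], ctxp, inv[test]).value
        assert a == pytest.approx(b, abs=1e-8)

    def test_signed_score_flips_minimize(self, panel8):
        _, ctx = panel8
        t, test = np.array([0, 1, 2]), np.array([6, 7])
        assert tsopt.signed_score("pev", t, ctx, test) == pytest.approx(
            -pev_criterion(t, ctx, test).value
        )
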