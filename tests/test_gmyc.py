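import itertools

import numpy as np
import pytest

from cyanodelim import gmyc, simulate
from cyanodelim.core_io import CyanodelimError, UltrametricTree
from cyanodelim.gmyc import (GMYCFit, IntervalTable, candidate_thresholds,
                             fit_multiple, fit_null, fit_single,
                             interval_decomposition, likelihood_ratio_test,
                             model_loglik, single_class_table)


def make_table(x, k, coal, events):
    return IntervalTable(np.asarray(x, float), np.asarray(k, float),
                         np.asarray(coal, float), np.asarray(events, int),
                         entities=[[0]])


class TestIntervalDecomposition:
    def test_hand_enumerated_six_tip_tree(self, six_tip_tree):
        """Waiting times and per-class lineage counts checked by hand.

        Threshold 3 on the fixture tree yields entities {A,B}, {C,D},
        {E,F}; intervals (root->tips) span heights
        10-5-3-2-1.5-1-0 with the counts enumerated below.
        """
        tab = interval_decomposition(six_tip_tree, 3.0)
        assert tab.n_entities == 3
        assert np.allclose(tab.x, [5, 2, 1, 0.5, 0.5, 1])
        assert np.allclose(tab.k, [2, 3, 0, 0, 0, 0])
        assert list(tab.n_events) == [1, 1, 0, 1, 1, 1]
        assert np.allclose(tab.coal.sum(axis=1), [0, 0, 0, 2, 4, 6])
        assert tab.x.sum() == pytest.approx(six_tip_tree.tree_height)

    def test_threshold_just_below_root_forces_two_entities(self):
        t = UltrametricTree.from_newick(
            "((A:1,B:1):3,(C:1.5,D:1.5):2.5);")
        tab = interval_decomposition(t, 3.9)
        assert tab.n_entities == 2
        assert all(len(e) == 2 for e in tab.entities)

    def test_threshold_below_all_nodes_gives_singletons(self, six_tip_tree):
        tab = interval_decomposition(six_tip_tree, 0.5)
        assert tab.n_entities == 6
        assert (tab.coal <= 0).all()  # no coalescent class remains

    def test_threshold_outside_depth_rejected(self, six_tip_tree):
        with pytest.raises(CyanodelimError, match="outside"):
            interval_decomposition(six_tip_tree, 11.0)


class TestModelLoglik:
    def test_single_interval_closed_form(self):
        tab = make_table([1.0], [1.0], [[0.0]], [1])
        assert model_loglik(tab, 2.0, 1.0, 0.0, 1.0) == \
            pytest.approx(np.log(2) - 2)

    def test_two_interval_hand_sum(self):
        # b = [0.5*2, 0.5*1] = [1, 0.5]; L = (ln1 - 1) + (ln0.5 - 1)
        tab = make_table([1.0, 2.0], [2.0, 1.0], [[0.0], [0.0]], [1, 1])
        expected = (np.log(1.0) - 1.0) + (np.log(0.5) - 1.0)
        assert model_loglik(tab, 0.5, 1.0, 0.0, 1.0) == pytest.approx(expected)

    def test_coalescent_term_hand_value(self):
        # three lineages in one entity: factor 6; b = 0.5 * 6 = 3
        tab = make_table([1.0], [0.0], [[6.0]], [1])
        assert model_loglik(tab, 0.0, 1.0, 0.5, 1.0) == \
            pytest.approx(np.log(3) - 3)

    def test_zero_hazard_event_interval_is_minus_inf(self):
        tab = make_table([1.0], [0.0], [[0.0]], [1])
        assert model_loglik(tab, 1.0, 1.0, 1.0, 1.0) == -np.inf

    @pytest.mark.parametrize("c", [0.1, 2.0, 37.5])
    def test_time_rescaling_jacobian(self, c, six_tip_tree):
        tab = interval_decomposition(six_tip_tree, 3.0)
        base = model_loglik(tab, 0.7, 1.2, 0.4, 0.8)
        scaled = IntervalTable(tab.x * c, tab.k, tab.coal, tab.n_events,
                               tab.entities)
        rescaled = model_loglik(scaled, 0.7 / c, 1.2, 0.4 / c, 0.8)
        n_events = tab.n_events.sum()
        assert rescaled == pytest.approx(base - n_events * np.log(c))


class TestFitting:
    def test_recovers_five_deep_species(self):
        tree, _, _ = simulate.simulate_species_tree_sample(
            5, 6, separation_ratio=20, seed=1)
        fit = fit_single(tree)
        assert fit.n_entities == 5
        assert 5 in fit.conf_set

    def test_nesting_of_likelihoods(self):
        tree, _, _ = simulate.simulate_species_tree_sample(
            4, 4, separation_ratio=20, seed=3)
        null = fit_null(tree)
        single = fit_single(tree)
        multi = fit_multiple(tree, max_thresholds=3)
        assert single.loglik >= null.loglik - 1e-6
        assert multi.loglik >= single.loglik - 1e-6

    def test_confidence_set_contains_estimate(self):
        tree, _, _ = simulate.simulate_species_tree_sample(
            3, 5, separation_ratio=10, seed=7)
        fit = fit_single(tree)
        assert fit.n_entities in fit.conf_set

    def test_exhaustive_scan_agreement_small_trees(self):
        """fit_single matches a brute-force threshold scan on <= 8 tips.

        The oracle re-implements the likelihood sum directly from the
        interval table, scans a dense parameter grid per candidate
        threshold, polishes the best grid point with an independent
        simplex search, and compares the selected entity count.
        """
        from scipy.optimize import minimize

        def neg_ll(theta, tab):
            ld, pd_, lc, pc = np.exp(theta[0]), theta[1], np.exp(theta[2]), \
                theta[3]
            if not (0 <= pd_ <= 3 and 0 <= pc <= 3):
                return 1e12
            A = np.where(tab.k > 0, tab.k ** pd_, 0.0)
            B = np.where(tab.coal > 0, tab.coal ** pc, 0.0).sum(axis=1)
            b = ld * A + lc * B
            if np.any((b <= 0) & (tab.n_events > 0)):
                return 1e12
            lg = np.where(b > 0, np.log(np.where(b > 0, b, 1)), 0.0)
            return -(tab.n_events * lg - b * tab.x).sum()

        lam = np.linspace(-10, 10, 41)
        ps = np.linspace(0, 3, 13)
        grid = np.array(list(itertools.product(lam, ps, lam, ps)))
        for seed in (0, 1, 2):
            tree, _, _ = simulate.simulate_species_tree_sample(
                2, 4, separation_ratio=20, seed=seed)
            fit = fit_single(tree)
            best = None
            for T in candidate_thresholds(tree):
                tab = interval_decomposition(tree, float(T))
                A = np.where(tab.k > 0, tab.k[None, :] ** grid[:, [1]], 0.0)
                C = np.where(tab.coal > 0, tab.coal, 0.0)
                B = np.stack([np.where(tab.coal > 0, C ** pc, 0.0).sum(axis=1)
                              for pc in ps])          # (len(ps), n_int)
                pc_idx = np.searchsorted(ps, grid[:, 3])
                b = (np.exp(grid[:, [0]]) * A
                     + np.exp(grid[:, [2]]) * B[pc_idx])
                ev = tab.n_events[None, :]
                with np.errstate(divide="ignore"):
                    lg = np.where(b > 0, np.log(np.where(b > 0, b, 1)), 0.0)
                    L = (ev * lg - b * tab.x[None, :]).sum(axis=1)
                L[np.any((b <= 0) & (ev > 0), axis=1)] = -np.inf
                top = -np.inf
                for gi in np.argsort(L)[-5:]:
                    res = minimize(neg_ll, grid[gi], args=(tab,),
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-10,
                                            "maxiter": 4000})
                    top = max(top, -res.fun)
                if best is None or top > best[0]:
                    best = (top, tab.n_entities)
            assert fit.n_entities == best[1]
            assert fit.loglik == pytest.approx(best[0], abs=1e-3)

    def test_two_regime_tree_multiple_threshold(self):
        """A clade with much deeper coalescents needs its own threshold."""
        nwk = ("(((a1:0.05,a2:0.05):0.05,(a3:0.05,a4:0.05):0.05):9.9,"
               "((b1:1,b2:1):1,(b3:1,b4:1):1):8);")
        tree = UltrametricTree.from_newick(nwk)
        single = fit_single(tree)
        multi = fit_multiple(tree, max_thresholds=3)
        assert multi.loglik >= single.loglik - 1e-6


class TestLRT:
    def _fit(self, L, model="single", thresholds=(1.0,)):
        return GMYCFit(model, list(thresholds), 1.0, 1.0, 1.0, 1.0, L,
                       {"A": 0, "B": 0, "C": 0}, 1 if model == "null" else 2)

    def test_printed_table_arithmetic_single(self):
        # LR = 2*(497.2483 - 487.751); the published table prints 18.99447
        res = likelihood_ratio_test(self._fit(487.751, "null", ()),
                                    self._fit(497.2483))
        assert res.statistic == pytest.approx(18.99447, abs=1e-3)
        assert res.df == 3
        assert res.stars in {"*", "**", "***"}

    def test_printed_table_arithmetic_multiple(self):
        res = likelihood_ratio_test(
            self._fit(487.751, "null", ()),
            self._fit(499.4952, "multiple", (1.0, 2.0)))
        assert res.statistic == pytest.approx(23.48842, abs=1e-3)
        assert res.df == 4

    def test_identical_likelihoods_give_unit_p(self):
        res = likelihood_ratio_test(self._fit(100.0, "null", ()),
                                    self._fit(100.0))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_model_below_null_clamped_with_flag(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = likelihood_ratio_test(self._fit(100.0, "null", ()),
                                        self._fit(99.0))
        assert res.statistic == 0.0 and res.clamped


class TestBoundaryPartitions:
    def test_near_root_threshold_one_entity_per_root_child(self, six_tip_tree):
        tab = interval_decomposition(six_tip_tree, 9.9)
        assert tab.n_entities == 2

    def test_null_table_single_class(self, six_tip_tree):
        tab = single_class_table(six_tip_tree)
        assert tab.n_entities == 1
        assert (tab.k == 0).all()
        assert tab.x.sum() == pytest.approx(six_tip_tree.tree_height)
        # lineage counts 2..6 appear as n(n-1) factors
        assert sorted(tab.coal[:, 0]) == [2, 6, 12, 20, 30]
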