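"""Mk likelihoods, model fitting, MCMC, taxon matching, simulation."""

import math

import numpy as np
import pandas as pd
import pytest

from karyofuse import mk
from karyofuse.simulate import TreeSimConfig, simulate_tree
from oracles import enumerate_loglik


class TestNewick:
    def test_three_tip_parse(self):
        phy = mk.read_newick("((A:1,B:1):1,C:2);")
        assert phy.n_tips == 3
        assert set(phy.tip_labels) == {"A", "B", "C"}
        root_children = phy.children[phy.root_id]
        assert len(root_children) == 2

    def test_round_trip_random_trees(self):
        for seed in range(30):
            phy = simulate_tree(TreeSimConfig(n_tips=12, death_rate=0.3, seed=seed))
            text = mk.write_newick(phy)
            back = mk.read_newick(text)
            assert sorted(back.tip_labels) == sorted(phy.tip_labels)
            assert np.allclose(sorted(back.edge_lengths()),
                               sorted(phy.edge_lengths()), atol=1e-9)

    def test_malformed_raises(self):
        with pytest.raises(Exception):
            mk.read_newick("((A:1,B:1")


class TestRateModel:
    def test_rows_sum_to_zero(self):
        model = mk.RateModel.four_state()
        Q = model.build_q(np.arange(1, model.n_params + 1) * 0.01)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-14)
        assert (Q[~np.eye(4, dtype=bool).reshape(4, 4)] >= 0).all()

    def test_share_reduces_free_parameters(self):
        model = mk.RateModel.four_state()
        reduced = model.share({"q_XYF.XY": "q_fiss", "q_ZWF.ZW": "q_fiss"})
        assert reduced.n_params == model.n_params - 1
        Q = reduced.build_q({n: 0.1 for n in reduced.param_names})
        states = list(reduced.states)
        assert Q[states.index("XYF"), states.index("XY")] == \
            Q[states.index("ZWF"), states.index("ZW")]

    def test_negative_rate_rejected(self):
        model = mk.RateModel.four_state()
        with pytest.raises(ValueError):
            model.build_q(np.full(model.n_params, -0.1))

    def test_six_state_space(self):
        model = mk.RateModel.six_state()
        assert model.states == mk.SIX_STATES
        assert model.n_params == 10


class TestLikelihood:
    def test_no_change_possible_with_zero_rates(self):
        phy = mk.read_newick("((A:1,B:1):1,C:2);")
        model = mk.RateModel.four_state()
        tips = pd.DataFrame(np.tile([1.0, 0, 0, 0], (3, 1)),
                            index=["A", "B", "C"], columns=model.states)
        ll = mk.mk_likelihood(phy, tips, model, np.zeros(model.n_params))
        assert ll == pytest.approx(math.log(1 / 4))

    @pytest.mark.parametrize("make_model", [mk.RateModel.four_state,
                                            mk.RateModel.six_state])
    def test_pruning_matches_enumeration(self, make_model, rng):
        """Exhaustive interior-state summation on trees up to 6 tips."""
        model = make_model()
        k = len(model.states)
        for n_tips in (3, 4, 5, 6):
            phy = simulate_tree(TreeSimConfig(n_tips=n_tips, seed=100 + n_tips))
            vals = rng.uniform(0.02, 1.5, model.n_params)
            tips = pd.DataFrame(np.eye(k)[rng.integers(0, k, n_tips)],
                                index=phy.tip_labels, columns=model.states)
            ll = mk.mk_likelihood(phy, tips, model, vals)
            ll_oracle = enumerate_loglik(phy, tips, model, vals)
            assert ll == pytest.approx(ll_oracle, abs=1e-10)

    def test_tip_order_invariance(self, small_tree, rng):
        model = mk.RateModel.four_state()
        vals = rng.uniform(0.05, 0.5, model.n_params)
        tips, _ = mk.simulate_characters(small_tree, model, vals, seed=5)
        ll1 = mk.mk_likelihood(small_tree, tips, model, vals)
        ll2 = mk.mk_likelihood(small_tree, tips.iloc[::-1], model, vals)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_ambiguous_tips_uniform_rows(self, small_tree):
        model = mk.RateModel.four_state()
        tips = pd.DataFrame(np.full((small_tree.n_tips, 4), 0.25),
                            index=small_tree.tip_labels, columns=model.states)
        ll = mk.mk_likelihood(small_tree, tips, model, np.full(model.n_params, 0.1))
        # fully ambiguous data: likelihood = (1/4)^ntips regardless of rates
        assert ll == pytest.approx(small_tree.n_tips * math.log(0.25), rel=1e-9)

    def test_transition_matrices_row_stochastic(self, rng):
        from karyofuse.mk import _transition_matrices
        model = mk.RateModel.six_state()
        Q = model.build_q(rng.uniform(0.01, 2.0, model.n_params))
        P = _transition_matrices(Q, np.array([0.0, 0.01, 0.5, 3.0, 50.0]))
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
        assert np.allclose(P[0], np.eye(6), atol=1e-12)  # zero branch length


class TestFit:
    def test_rate_recovery_on_simulated_data(self):
        """Median over replicate simulations recovers the generating fusion
        rates to within 50%."""
        model = mk.RateModel.four_state()
        truth = {"q_XY.XYF": 0.1, "q_XYF.XY": 0.02, "q_ZW.ZWF": 0.02,
                 "q_ZWF.ZW": 0.02, "q_XY.ZW": 0.05, "q_ZW.XY": 0.05}
        vals = [truth[n] for n in model.param_names]
        est = []
        for rep in range(5):
            phy = simulate_tree(TreeSimConfig(n_tips=500, seed=200 + rep))
            tips, _ = mk.simulate_characters(phy, model, vals,
                                             root_state="XY", seed=300 + rep)
            fit = mk.fit_ml(phy, tips, model, n_starts=2, seed=rep)
            est.append(fit.params["q_XY.XYF"])
        med = float(np.median(est))
        assert 0.5 * truth["q_XY.XYF"] <= med <= 1.5 * truth["q_XY.XYF"]

    def test_degenerate_all_same_state_hits_zero_boundary(self, medium_tree):
        model = mk.RateModel.four_state()
        tips = pd.DataFrame(np.tile([1.0, 0, 0, 0], (medium_tree.n_tips, 1)),
                            index=medium_tree.tip_labels, columns=model.states)
        fit = mk.fit_ml(medium_tree, tips, model, n_starts=1)
        assert fit.params["q_XY.XYF"] < 1e-6

    def test_constrained_model_never_beats_full(self, medium_tree):
        model = mk.RateModel.four_state()
        vals = [0.08, 0.02, 0.08, 0.02, 0.03, 0.03]
        tips, _ = mk.simulate_characters(medium_tree, model, vals, seed=9)
        fit_full = mk.fit_ml(medium_tree, tips, model, n_starts=2, seed=1)
        reduced = model.share({"q_XY.XYF": "q_fuse", "q_ZW.ZWF": "q_fuse"})
        fit_red = mk.fit_ml(medium_tree, tips, reduced, n_starts=2, seed=1)
        assert fit_red.loglik <= fit_full.loglik + 1e-6


class TestLRT:
    def test_identical_fits_give_null_result(self, medium_tree):
        model = mk.RateModel.four_state()
        vals = [0.05] * model.n_params
        tips, _ = mk.simulate_characters(medium_tree, model, vals, seed=2)
        full = mk.fit_ml(medium_tree, tips, model, n_starts=1)
        pseudo_reduced = mk.MLFit(
            model=model.share({"q_XY.ZW": "q_XY.ZW"}), params=full.params,
            loglik=full.loglik, converged=True, n_starts=1)
        pseudo_reduced.model = model.share({"q_ZW.XY": "q_XY.ZW"})
        test = mk.lrt(full, pseudo_reduced)
        assert test.statistic == pytest.approx(0.0, abs=1e-9)
        assert test.p_value == pytest.approx(1.0)
        assert test.df == 1

    def test_df_equals_sharing_rank_difference(self, medium_tree):
        model = mk.RateModel.four_state()
        reduced = model.share({"q_XYF.XY": "q_fiss", "q_ZWF.ZW": "q_fiss",
                               "q_XY.ZW": "q_turn", "q_ZW.XY": "q_turn"})
        tips, _ = mk.simulate_characters(medium_tree, model,
                                         [0.05] * model.n_params, seed=3)
        full = mk.fit_ml(medium_tree, tips, model, n_starts=1)
        red = mk.fit_ml(medium_tree, tips, reduced, n_starts=1)
        assert mk.lrt(full, red).df == 2


class TestMcmc:
    def test_prior_only_chain_recovers_exponential_prior(self):
        model = mk.RateModel.four_state()
        run = mk.run_mcmc(None, None, model, prior_mean=0.05,
                          n_steps=4000, burn_in=500, seed=13)
        post = run.posterior
        for name in model.param_names:
            assert post[name].mean() == pytest.approx(0.05, rel=0.15)
        assert (post[model.param_names[0]] >= 0).all()

    def test_seed_determinism(self, medium_tree):
        model = mk.RateModel.four_state()
        tips, _ = mk.simulate_characters(medium_tree, model,
                                         [0.05] * model.n_params, seed=4)
        r1 = mk.run_mcmc(medium_tree, tips, model, n_steps=50, burn_in=10, seed=7)
        r2 = mk.run_mcmc(medium_tree, tips, model, n_steps=50, burn_in=10, seed=7)
        pd.testing.assert_frame_equal(r1.samples, r2.samples)

    def test_post_burn_in_length(self):
        model = mk.RateModel.four_state()
        run = mk.run_mcmc(None, None, model, n_steps=500, burn_in=120, seed=1)
        assert len(run.posterior) == 500 - 120


class TestSimulateCharacters:
    def test_zero_rates_freeze_root_state(self, medium_tree):
        model = mk.RateModel.four_state()
        tips, nodes = mk.simulate_characters(medium_tree, model,
                                             np.zeros(model.n_params),
                                             root_state="ZW", seed=0)
        assert (tips["ZW"] == 1.0).all()
        assert set(nodes.values()) == {"ZW"}

    def test_determinism(self, medium_tree):
        model = mk.RateModel.four_state()
        vals = [0.1] * model.n_params
        t1, n1 = mk.simulate_characters(medium_tree, model, vals, seed=42)
        t2, n2 = mk.simulate_characters(medium_tree, model, vals, seed=42)
        pd.testing.assert_frame_equal(t1, t2)
        assert n1 == n2

    def test_long_branches_reach_stationarity(self):
        """Tip frequencies on long independent branches approach the chain's
        stationary distribution."""
        model = mk.RateModel.four_state()
        vals = {"q_XY.XYF": 0.2, "q_XYF.XY": 0.4, "q_ZW.ZWF": 0.1,
                "q_ZWF.ZW": 0.4, "q_XY.ZW": 0.3, "q_ZW.XY": 0.3}
        vec = [vals[n] for n in model.param_names]
        pi = model.stationary_distribution(vec)
        n = 80
        newick = "(" + ",".join(f"t{i}:200.0" for i in range(n)) + ");"
        phy = mk.read_newick(newick)
        freqs = np.zeros(4)
        for seed in range(12):
            tips, _ = mk.simulate_characters(phy, model, vec, seed=seed)
            freqs += tips.to_numpy().sum(axis=0)
        freqs /= freqs.sum()
        assert np.abs(freqs - pi).max() < 4 * np.sqrt(pi.max() / (12 * n)) + 0.01


class TestMatchTaxa:
    def _table(self, species):
        return pd.DataFrame({"species": species,
                             "heterogamety": ["XY"] * len(species),
                             "fusion": ["none"] * len(species)})

    def test_exact_match_and_prune(self):
        phy = mk.read_newick("((Genus_a:1,Genus_b:1):1,Other_c:2);")
        table = self._table(["Genus_a"])
        pruned, aligned, rep = mk.match_taxa(phy, table, seed=0)
        assert pruned.tip_labels == ["Genus_a"]
        assert rep.pruned == ["Genus_b", "Other_c"]

    def test_genus_substitution_respects_cap(self):
        phy = mk.read_newick(
            "(((Gen_p:1,Gen_q:1):1,(Gen_r:1,Gen_s:1):1):1,Out_x:3);")
        # Gen_a matches nothing in tree; Gen_p exact; cap=2 allows ONE substitution
        table = self._table(["Gen_p", "Gen_a", "Gen_b", "Gen_c", "Out_x"])
        pruned, aligned, rep = mk.match_taxa(phy, table, seed=1)
        assert len(rep.substitutions) == 1  # cap reached at 2 representatives
        genus_count = sum(1 for t in pruned.tip_labels if t.startswith("Gen"))
        assert genus_count == 2

    def test_never_substitutes_exact_match(self):
        phy = mk.read_newick("((Gen_p:1,Gen_q:1):1,Out_x:3);")
        table = self._table(["Gen_p", "Gen_q", "Gen_z", "Out_x"])
        _, _, rep = mk.match_taxa(phy, table, seed=3)
        assert rep.substitutions == []
        assert set(rep.exact) == {"Gen_p", "Gen_q", "Out_x"}

    def test_substitution_determinism(self):
        phy = mk.read_newick(
            "((Gen_p:1,(Gen_q:1,Gen_r:1):0.5):1,Out_x:3);")
        table = self._table(["Gen_a", "Gen_b", "Gen_c", "Out_x"])
        runs = [mk.match_taxa(phy, table, seed=5)[2].substitutions
                for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]
        assert len(runs[0]) == 2  # cap of two per genus

    def test_empty_intersection_raises(self):
        phy = mk.read_newick("((Aus_a:1,Bus_b:1):1,Cus_c:2);")
        table = self._table(["Dus_d", "Eus_e"])
        with pytest.raises(ValueError):
            mk.match_taxa(phy, table, seed=0)


class TestTipStateMatrix:
    def test_state_mapping_four_and_six(self):
        table = pd.DataFrame([
            {"species": "s1", "heterogamety": "XY", "fusion": "none"},
            {"species": "s2", "heterogamety": "XY", "fusion": "YA"},
            {"species": "s3", "heterogamety": "ZW", "fusion": "ZA"},
            {"species": "s4", "heterogamety": "ZW", "fusion": "unknown"},
        ])
        m4 = mk.tip_state_matrix(table, ["s1", "s2", "s3", "s4", "s5"],
                                 mk.FOUR_STATES)
        assert m4.loc["s1", "XY"] == 1.0
        assert m4.loc["s2", "XYF"] == 1.0
        assert m4.loc["s3", "ZWF"] == 1.0
        assert (m4.loc["s4"] == 0.25).all()  # ambiguous
        assert (m4.loc["s5"] == 0.25).all()  # absent from the table
        m6 = mk.tip_state_matrix(table, ["s2", "s3"], mk.SIX_STATES)
        assert m6.loc["s2", "X1X2Y"] == 1.0
        assert m6.loc["s3", "ZW1W2"] == 1.0
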