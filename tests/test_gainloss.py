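"""Two-state gain/loss model: likelihood, posteriors, stochastic mapping and
event calling."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from trnadyn.gainloss import (TwoStateModel, branch_event_probs_exact,
                              call_events, discrete_gamma_rates, fit_rates,
                              marginal_posteriors, pruning_loglik, reconstruct,
                              root_report, stochastic_map, total_rates,
                              transition_matrix)
from trnadyn.phylo import TreeIndex, read_newick
from trnadyn.repertoire import PresenceMatrix
from trnadyn.simulate import simulate_presence, simulate_tree


def enumeration_loglik(model, idx, tips):
    """Brute-force likelihood summing over all internal-state assignments."""
    states = {int(t): s for t, s in zip(idx.tips, tips)}
    internal = [i for i in range(idx.n_nodes) if not idx.is_tip(i)]
    P = {i: transition_matrix(model, idx.branch_length[i])
         for i in range(idx.n_nodes)}
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(states)
        st.update(dict(zip(internal, assign)))
        pr = model.prior[st[idx.root]]
        for i in range(idx.n_nodes):
            if idx.parent[i] >= 0:
                pr *= P[i][st[idx.parent[i]], st[i]]
        total += pr
    return np.log(total)


def enumeration_marginals(model, idx, tips):
    states = {int(t): s for t, s in zip(idx.tips, tips)}
    internal = [i for i in range(idx.n_nodes) if not idx.is_tip(i)]
    P = {i: transition_matrix(model, idx.branch_length[i])
         for i in range(idx.n_nodes)}
    marg = np.zeros(idx.n_nodes)
    z = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(states)
        st.update(dict(zip(internal, assign)))
        pr = model.prior[st[idx.root]]
        for i in range(idx.n_nodes):
            if idx.parent[i] >= 0:
                pr *= P[i][st[idx.parent[i]], st[i]]
        z += pr
        for i in range(idx.n_nodes):
            marg[i] += pr * st[i]
    return marg / z


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(TwoStateModel(1.0, 2.0), 0.0)
        assert np.allclose(P, np.eye(2))

    def test_stationary_limit(self):
        P = transition_matrix(TwoStateModel(1.0, 1.0), 1e6)
        assert np.allclose(P, 0.5)

    def test_matches_matrix_exponential(self):
        model = TwoStateModel(2.0, 1.0)
        Q = np.array([[-2.0, 2.0], [1.0, -1.0]])
        for t in (0.1, 0.3, 2.5):
            assert np.allclose(transition_matrix(model, t), expm(Q * t),
                               atol=1e-12)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(20):
            g, l = rng.uniform(0.05, 5, 2)
            s, t = rng.uniform(0, 2, 2)
            model = TwoStateModel(g, l)
            lhs = transition_matrix(model, s) @ transition_matrix(model, t)
            assert np.allclose(lhs, transition_matrix(model, s + t), atol=1e-12)
            assert np.allclose(transition_matrix(model, t).sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(TwoStateModel(1, 1), -0.1)


class TestPruning:
    def test_single_tip_zero_branch(self):
        idx = TreeIndex(read_newick("(A:0.0,B:0.0);"))
        model = TwoStateModel(1.0, 1.0, root_prior=[0.5, 0.5])
        ll = pruning_loglik(model, idx, {"A": 1, "B": 1})
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_enumeration_on_random_trees(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            idx = TreeIndex(simulate_tree(n, seed=int(rng.integers(2 ** 31))))
            model = TwoStateModel(*rng.uniform(0.1, 3, 2))
            tips = rng.integers(0, 2, n)
            assert pruning_loglik(model, idx, tips) == pytest.approx(
                enumeration_loglik(model, idx, tips), abs=1e-10)

    def test_certainty_limit(self):
        idx = TreeIndex(read_newick("(A:0.5,B:0.5);"))
        model = TwoStateModel(1e-9, 1e-9, root_prior=[0.0, 1.0])
        ll = pruning_loglik(model, idx, {"A": 1, "B": 1})
        assert ll == pytest.approx(0.0, abs=1e-6)

    def test_gamma_categories_average_to_one(self):
        rates = discrete_gamma_rates(0.7, 4)
        assert rates.mean() == pytest.approx(1.0)
        assert (np.diff(rates) > 0).all()


class TestMarginalPosteriors:
    def test_matches_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 6))
            idx = TreeIndex(simulate_tree(n, seed=int(rng.integers(2 ** 31))))
            model = TwoStateModel(*rng.uniform(0.1, 3, 2))
            tips = rng.integers(0, 2, n)
            post = marginal_posteriors(model, idx, tips)
            assert np.allclose(post, enumeration_marginals(model, idx, tips),
                               atol=1e-10)

    def test_tips_reproduce_observations(self, five_tip_index):
        tips = np.array([1, 0, 1, 1, 0])
        post = marginal_posteriors(TwoStateModel(0.5, 0.5), five_tip_index, tips)
        assert np.allclose(post[five_tip_index.tips], tips)

    def test_cherry_of_present_tips_pulls_root_up(self, cherry_index):
        post = marginal_posteriors(TwoStateModel(1.0, 1.0, root_prior=[0.5, 0.5]),
                                   cherry_index, [1, 1])
        assert post[cherry_index.root] > 0.5


class TestStochasticMap:
    def test_agrees_with_closed_form(self, rng):
        idx = TreeIndex(simulate_tree(25, seed=77))
        model = TwoStateModel(0.6, 1.1)
        tips = rng.integers(0, 2, 25)
        pg, pl = stochastic_map(model, idx, tips, n_maps=4000, seed=5)
        pg_e, pl_e = branch_event_probs_exact(model, idx, tips)
        se = 3 * np.sqrt(0.25 / 4000) + 1e-3
        assert np.max(np.abs(pg - pg_e)) < 4 * 0.0079 + 0.01
        assert np.max(np.abs(pl - pl_e)) < 4 * 0.0079 + 0.01

    def test_forced_gain_on_observed_transition(self, cherry_index):
        # both tips present, ancestor forced absent by a prior on state 0:
        # a gain is certain somewhere, and with present tips each terminal
        # branch's endpoint pair (0 -> 1) forces at least one gain
        model = TwoStateModel(0.2, 0.2, root_prior=[1.0, 0.0])
        pg, pl = stochastic_map(model, cherry_index, [1, 1], n_maps=500, seed=3)
        assert pg[cherry_index.tips].max() > 0.99

    def test_near_zero_rates_give_no_events(self, five_tip_index):
        model = TwoStateModel(1e-8, 1e-8, root_prior=[1.0, 0.0])
        pg, pl = stochastic_map(model, five_tip_index, [0, 0, 0, 0, 0],
                                n_maps=300, seed=1)
        assert pg.max() < 0.01 and pl.max() < 0.01

    def test_reproducible_for_fixed_seed(self, five_tip_index):
        model = TwoStateModel(0.8, 0.8)
        args = (model, five_tip_index, [1, 0, 1, 0, 1])
        pg1, pl1 = stochastic_map(*args, n_maps=400, seed=9)
        pg2, pl2 = stochastic_map(*args, n_maps=400, seed=9)
        assert (pg1 == pg2).all() and (pl1 == pl2).all()


class TestEventCalling:
    def _recon(self, p_gain, p_loss):
        from trnadyn.gainloss import Reconstruction
        return {"X": Reconstruction("X", TwoStateModel(1, 1),
                                    np.zeros(3), np.array(p_gain),
                                    np.array(p_loss), 0.0)}

    def test_threshold_inclusive(self):
        events = call_events(self._recon([0.79, 0.8, 0.95], [0, 0, 0]))
        assert sorted(events["node"]) == [1, 2]

    def test_both_types_called_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            events = call_events(self._recon([0.9, 0, 0], [0.85, 0, 0]))
        assert len(events) == 2
        assert "both gain and loss" in caplog.text

    def test_total_rates_and_root_report(self):
        recons = self._recon([0.5, 0.25, 0.0], [0.1, 0.0, 0.2])
        rates = total_rates(recons)
        assert rates.iloc[0]["gain_sum"] == pytest.approx(0.75)
        assert rates.iloc[0]["loss_sum"] == pytest.approx(0.3)
        assert root_report(recons).iloc[0]["root_presence"] == 0.0


class TestFitRates:
    def test_constant_column_skipped(self, medium_tree_index):
        idx = medium_tree_index
        n = len(idx.tip_labels)
        values = np.column_stack([np.ones(n, int), np.zeros(n, int)])
        matrix = PresenceMatrix(list(idx.tip_labels), ["AAA", "AAC"], values)
        models, skipped = fit_rates(idx, matrix)
        assert skipped == ["AAA", "AAC"] and not models

    def test_loss_only_data_pins_gain_at_lower_bound(self):
        idx = TreeIndex(simulate_tree(120, seed=31))
        tips, _, _ = simulate_presence(idx, 0.0 + 1e-9, 0.8, root_state=1,
                                       seed=32)
        col = np.array([tips[l] for l in idx.tip_labels])
        if col.min() == col.max():
            pytest.skip("degenerate simulation draw")
        matrix = PresenceMatrix(list(idx.tip_labels), ["AAA"], col.reshape(-1, 1))
        # uniform root prior isolates the transition rates from the
        # stationary-prior coupling at the root
        models, _ = fit_rates(idx, matrix, bounds=(1e-3, 50.0),
                              uniform_root_prior=True)
        assert models["AAA"].gain == pytest.approx(1e-3, rel=0.5)

    def test_recovers_simulated_rates_within_factor_two(self):
        idx = TreeIndex(simulate_tree(300, seed=61))
        tips, _, _ = simulate_presence(idx, 0.5, 2.0, seed=62)
        col = np.array([tips[l] for l in idx.tip_labels])
        matrix = PresenceMatrix(list(idx.tip_labels), ["AAA"], col.reshape(-1, 1))
        models, _ = fit_rates(idx, matrix)
        total = models["AAA"].gain + models["AAA"].loss
        assert 0.5 * 2.5 < total < 2.0 * 2.5

    def test_root_posteriors_track_data(self, medium_tree_index):
        idx = medium_tree_index
        n = len(idx.tip_labels)
        present = PresenceMatrix(list(idx.tip_labels), ["AAA"],
                                 np.ones((n, 1), int))
        model = TwoStateModel(0.01, 0.01)
        recons = reconstruct(idx, present, models={"AAA": model}, method="exact")
        assert recons["AAA"].root_posterior > 0.99
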