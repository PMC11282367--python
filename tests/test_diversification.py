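"""EBD and HiSSE likelihoods against closed forms and reductions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from paleorange.characters import DiscreteCharacterData, StateSpace
from paleorange.diversification import (BIOME_SPACE, EBDModel, HiSSEModel,
                                        biome_independent_model,
                                        coldest_biome_coding, derived_rates,
                                        ebd_loglik, ebd_prior_logdensity,
                                        hisse_loglik)
from paleorange.simulate import simulate_tree
from paleorange.trees import read_tree


def bd_closed_form(tree, lam, mu, rho):
    """Constant-rate birth-death oracle (closed-form p0/p1), conditioned
    on the root age and survival of both root lineages."""
    def p0p1(t):
        r = lam - mu
        if abs(r) < 1e-12:
            g = 1 + lam * rho * t
            return 1 - rho / g, rho / g ** 2
        ert = np.exp(r * t)
        g = lam * rho * ert + lam * (1 - rho) - mu
        return 1 - r * rho * ert / g, rho * r ** 2 * ert / g ** 2

    p0r, p1r = p0p1(tree.root_age)
    ll = 2 * np.log(p1r) - 2 * np.log(1 - p0r)
    for v in tree.postorder():
        if tree.children[v] and v != tree.root:
            ll += np.log(lam * p0p1(float(tree.ages[v]))[1])
    return ll


def yule_closed_form(tree, lam):
    """Pure-birth oracle: conditioned on root age; each non-root internal
    node contributes lam e^{-lam t}, each lineage pair survival e^{-lam t}
    terms collapse into the standard Yule density."""
    return bd_closed_form(tree, lam, 0.0, 1.0)


class TestEBD:
    @pytest.mark.parametrize("lam,mu,rho", [
        (0.3, 0.1, 1.0), (0.3, 0.1, 0.6), (0.25, 0.25, 0.8), (0.1, 0.3, 0.9)])
    def test_single_interval_equals_closed_form(self, five_tip_tree, lam, mu, rho):
        m = EBDModel(root_age=five_tip_tree.root_age, lam=[lam], mu=[mu], rho=rho)
        assert ebd_loglik(five_tip_tree, m) == pytest.approx(
            bd_closed_form(five_tip_tree, lam, mu, rho), abs=1e-8)

    def test_yule_limit(self, five_tip_tree):
        m = EBDModel(root_age=five_tip_tree.root_age, lam=[0.2], mu=[1e-300])
        assert ebd_loglik(five_tip_tree, m) == pytest.approx(
            yule_closed_form(five_tip_tree, 0.2), abs=1e-8)

    def test_merging_equal_rate_intervals_is_invariant(self, five_tip_tree):
        rng = np.random.default_rng(0)
        for _ in range(5):
            lam, mu = rng.uniform(0.05, 0.5, 2)
            m1 = EBDModel(root_age=five_tip_tree.root_age, lam=[lam], mu=[mu])
            m8 = EBDModel(root_age=five_tip_tree.root_age,
                          lam=[lam] * 8, mu=[mu] * 8)
            assert ebd_loglik(five_tip_tree, m1) == pytest.approx(
                ebd_loglik(five_tip_tree, m8), abs=1e-10)

    def test_varying_rates_differ_from_constant(self, five_tip_tree):
        m = EBDModel(root_age=five_tip_tree.root_age,
                     lam=[0.1, 0.4], mu=[0.05, 0.05])
        c = EBDModel(root_age=five_tip_tree.root_age, lam=[0.1], mu=[0.05])
        assert ebd_loglik(five_tip_tree, m) != pytest.approx(
            ebd_loglik(five_tip_tree, c), abs=1e-6)

    def test_non_ultrametric_rejected(self):
        t = read_tree("(A:1,B:2);", ultrametric=False)
        with pytest.raises(ValueError, match="ultrametric"):
            ebd_loglik(t, EBDModel(root_age=2.0, lam=[0.2], mu=[0.1]))

    def test_clade_fraction_reduces_to_global_rho(self, five_tip_tree):
        """A single clade covering every tip equals the global-rho path."""
        m_global = EBDModel(root_age=five_tip_tree.root_age,
                            lam=[0.3], mu=[0.1], rho=0.5)
        m_clade = EBDModel(root_age=five_tip_tree.root_age,
                           lam=[0.3], mu=[0.1], rho=1.0,
                           clade_fractions=[({"A", "B", "C", "D", "E"}, 0.5)])
        assert ebd_loglik(five_tip_tree, m_clade) == pytest.approx(
            ebd_loglik(five_tip_tree, m_global), abs=1e-10)

    def test_parameter_recovery_by_ml_grid(self):
        """Grid maximum-likelihood on simulated trees lands near truth."""
        lam_t, mu_t = 0.25, 0.1
        grid_l = np.linspace(0.1, 0.45, 15)
        errs = []
        for rep in range(6):
            tree = simulate_tree(lam_t, mu_t, 300, 1000 + rep)
            lls = [ebd_loglik(tree, EBDModel(root_age=tree.root_age,
                                             lam=[l], mu=[mu_t]))
                   for l in grid_l]
            errs.append(abs(grid_l[int(np.argmax(lls))] - lam_t) / lam_t)
        assert np.mean(errs) < 0.2


class TestEBDPrior:
    def test_equal_rates_contribute_normal_at_zero(self):
        from scipy.stats import norm
        m = EBDModel(root_age=10, lam=[0.2] * 5, mu=[0.1] * 5)
        ld = ebd_prior_logdensity(m, sigma_lam=0.3, sigma_mu=0.5)
        expect = 4 * norm.logpdf(0, scale=0.3) + 4 * norm.logpdf(0, scale=0.5)
        assert ld == pytest.approx(expect, abs=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.05, 0.5, 6)
        mu = rng.uniform(0.01, 0.3, 6)
        m_fwd = EBDModel(root_age=10, lam=lam, mu=mu)
        m_rev = EBDModel(root_age=10, lam=lam[::-1], mu=mu[::-1])
        assert ebd_prior_logdensity(m_fwd, 0.4, 0.4) == pytest.approx(
            ebd_prior_logdensity(m_rev, 0.4, 0.4), abs=1e-12)

    def test_sigma_to_zero_with_unequal_rates_diverges(self):
        m = EBDModel(root_age=10, lam=[0.2, 0.3], mu=[0.1, 0.1])
        assert ebd_prior_logdensity(m, 1e-12, 1e-12) < -1e6

    def test_nonpositive_sigma_rejected(self):
        m = EBDModel(root_age=10, lam=[0.2], mu=[0.1])
        with pytest.raises(ValueError, match="sigma"):
            ebd_prior_logdensity(m, 0.0, 0.1)


def three_state_sse_loglik(tree, data, lam3, mu3, q33, root_freqs=None):
    """Independent 3-state SSE oracle (MuSSE-style), coded directly on
    the ODEs with scipy and no shared machinery with hisse_loglik."""
    lam3, mu3 = np.asarray(lam3, float), np.asarray(mu3, float)
    q33 = np.asarray(q33, float)
    qo = q33 - np.diag(np.diag(q33))
    qt = qo.sum(axis=1)
    pi = np.full(3, 1 / 3) if root_freqs is None else np.asarray(root_freqs)

    def e_rhs(t, E):
        return mu3 - (lam3 + mu3 + qt) * E + lam3 * E * E + qo @ E

    Esol = solve_ivp(e_rhs, (0, tree.root_age * (1 + 1e-9)), np.zeros(3),
                     dense_output=True, rtol=1e-10, atol=1e-12).sol

    def d_rhs(t, D):
        E = Esol(t)
        return -(lam3 + mu3 + qt) * D + 2 * lam3 * E * D + qo @ D

    logscale = 0.0
    D = {}
    for v in tree.postorder():
        if not tree.children[v]:
            init = np.zeros(3)
            for s in data[tree.labels[v]]:
                init[s] = 1.0
            D[v] = init
        else:
            acc = np.ones(3)
            for c in tree.children[v]:
                sol = solve_ivp(d_rhs, (float(tree.ages[c]),
                                        float(tree.ages[v])), D[c],
                                rtol=1e-10, atol=1e-12)
                acc = acc * sol.y[:, -1]
            acc = acc * lam3
            m = acc.max()
            D[v] = acc / m
            logscale += np.log(m)
    E_root = Esol(tree.root_age)
    val = np.sum(pi * D[tree.root] / (lam3 * (1 - E_root) ** 2))
    return float(np.log(val) + logscale)


class TestHiSSE:
    def test_collapse_to_constant_rate_bd(self):
        """All 6 states tied, q = 0: log L = BD log-likelihood + the
        tip-state root term."""
        tree = simulate_tree(0.2, 0.05, 40, 3)
        lam, mu = 0.21, 0.07
        m = HiSSEModel(lam=[lam] * 6, mu=[mu] * 6, q_biome=np.zeros((3, 3)))
        data = DiscreteCharacterData(
            BIOME_SPACE, {l: {0} for l in tree.tip_labels()})
        got = hisse_loglik(tree, data, m)
        want = bd_closed_form(tree, lam, mu, 1.0) + np.log(2 / 6)
        assert got == pytest.approx(want, abs=1e-4)

    def test_two_tip_tiny_q_limit(self):
        t = read_tree("(A:2,B:2);")
        lam, mu = 0.3, 0.1
        m = HiSSEModel(lam=[lam] * 6, mu=[mu] * 6,
                       q_biome=np.full((3, 3), 1e-9), hidden_switch=1e-9)
        d = DiscreteCharacterData(BIOME_SPACE, {"A": {1}, "B": {1}})
        got = hisse_loglik(t, d, m)
        want = bd_closed_form(t, lam, mu, 1.0) + np.log(2 / 6)
        assert got == pytest.approx(want, abs=1e-4)

    def test_hidden_tied_reduces_to_three_state_sse(self):
        """hidden_switch = 0 with hidden states tied == independent
        3-state SSE oracle (to 1e-6)."""
        tree = simulate_tree(0.25, 0.08, 25, 5)
        lam3 = np.array([0.3, 0.2, 0.15])
        mu3 = np.array([0.05, 0.1, 0.08])
        q = np.zeros((3, 3))
        q[0, 1] = q[1, 2] = 0.03
        q[1, 0] = q[2, 1] = 0.06
        m = HiSSEModel(lam=np.tile(lam3, 2), mu=np.tile(mu3, 2),
                       q_biome=q, hidden_switch=0.0)
        rng = np.random.default_rng(6)
        data = DiscreteCharacterData(
            BIOME_SPACE, {l: {int(rng.integers(3))}
                          for l in tree.tip_labels()})
        got = hisse_loglik(tree, data, m, rtol=1e-10, atol=1e-12)
        want = three_state_sse_loglik(tree, data, lam3, mu3, q)
        assert got == pytest.approx(want, abs=1e-6)

    def test_null_model_is_biome_symmetric(self):
        """The biome-independent null gives identical likelihood when all
        tip biome labels are permuted."""
        tree = simulate_tree(0.2, 0.05, 30, 7)
        null = biome_independent_model([0.25, 0.12], [0.06, 0.06],
                                       hidden_switch=0.02)
        rng = np.random.default_rng(8)
        states = {l: int(rng.integers(3)) for l in tree.tip_labels()}
        d1 = DiscreteCharacterData(BIOME_SPACE,
                                   {l: {s} for l, s in states.items()})
        # permuting biome identities relabels tips under a symmetric q
        perm = {0: 2, 1: 0, 2: 1}
        d2 = DiscreteCharacterData(BIOME_SPACE,
                                   {l: {perm[s]} for l, s in states.items()})
        q_sym = np.full((3, 3), 0.04)
        null_sym = biome_independent_model([0.25, 0.12], [0.06, 0.06],
                                           hidden_switch=0.02, q_biome=q_sym)
        assert hisse_loglik(tree, d1, null_sym) == pytest.approx(
            hisse_loglik(tree, d2, null_sym), abs=1e-6)

    def test_extinction_probability_bounded(self):
        from paleorange.diversification import _sse_extinction
        m = HiSSEModel.ordered(lam=[.2, .15, .3, .1, .08, .15],
                               mu=[.05, .2, .3, .05, .2, .3],
                               q_up=0.05, q_down=0.1, hidden_switch=0.02,
                               rho=0.7)
        sol = _sse_extinction(m, 80.0, 1e-8, 1e-10)
        E = sol(np.linspace(0, 80, 64))
        assert E.min() >= -1e-8 and E.max() <= 1 + 1e-8

    def test_extinction_monotone_under_complete_sampling(self):
        """With rho = 1 (E(0) = 0) and mu > 0, extinction probability is
        non-decreasing toward the past in every state."""
        from paleorange.diversification import _sse_extinction
        m = HiSSEModel.ordered(lam=[.2, .15, .3, .1, .08, .15],
                               mu=[.05, .2, .3, .05, .2, .3],
                               q_up=0.05, q_down=0.1, hidden_switch=0.02)
        sol = _sse_extinction(m, 80.0, 1e-8, 1e-10)
        E = sol(np.linspace(0, 80, 64))
        assert E.min() >= -1e-8 and E.max() <= 1 + 1e-8
        assert np.all(np.diff(E, axis=1) >= -1e-6)


class TestDerivedRatesAndCoding:
    def test_derived_rates_values(self):
        df = derived_rates([0.2, 0.3], [0.1, 0.3])
        assert df["net_diversification"].tolist() == pytest.approx([0.1, 0.0])
        assert df["turnover"].tolist() == pytest.approx([0.5, 1.0])

    def test_zero_speciation_rejected(self):
        with pytest.raises(ValueError, match="lam = 0"):
            derived_rates([0.0], [0.1])

    def test_posterior_mean_linearity(self):
        rng = np.random.default_rng(9)
        lam_draws = rng.uniform(0.1, 0.4, 200)
        mu_draws = rng.uniform(0.01, 0.09, 200)
        nets = [derived_rates([l], [m])["net_diversification"][0]
                for l, m in zip(lam_draws, mu_draws)]
        assert np.mean(nets) == pytest.approx(
            lam_draws.mean() - mu_draws.mean(), abs=1e-12)

    def test_coldest_biome_rule(self):
        d = coldest_biome_coding({
            "a": {"tropical", "warm-temperate"},
            "b": {"tropical"},
            "c": {"warm-temperate", "cold-temperate"},
            "d": set(),
        })
        assert d["a"] == frozenset({1})
        assert d["b"] == frozenset({0})
        assert d["c"] == frozenset({2})
        assert d["d"] == frozenset({0, 1, 2})
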