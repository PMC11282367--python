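"""Diversification likelihoods: episodic birth-death and biome HiSSE.

The episodic birth-death (EBD) model has piecewise-constant speciation
and extinction rates over equal-length intervals between the root and
the present, uniform incomplete sampling at the present, and an
autocorrelated (Brownian on the log scale, backward in time) prior
across intervals.

The HiSSE model couples a 3-state observed biome trait (tropical,
warm-temperate, cold-temperate) with a 2-state hidden trait absorbing
background rate heterogeneity; each of the 6 combined states carries its
own speciation and extinction rate.  The likelihood integrates the
standard state-dependent extinction/branch ODEs numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import norm

from .characters import BIOMES, DiscreteCharacterData, StateSpace
from .trees import TimeTree

__all__ = [
    "EBDModel", "ebd_loglik", "ebd_prior_logdensity",
    "HiSSEModel", "hisse_loglik", "biome_independent_model",
    "derived_rates", "coldest_biome_coding", "BIOME_SPACE",
]

BIOME_SPACE = StateSpace(BIOMES)


# ---------------------------------------------------------------------------
# Episodic birth-death


@dataclass
class EBDModel:
    """Piecewise-constant birth-death rates on equal-length intervals.

    Interval 0 is adjacent to the present; interval i covers ages
    ``(i, i+1) * root_age / n`` with rates ``lam[i]``, ``mu[i]`` in
    events/lineage/Myr.  ``rho`` is the uniform sampling probability of
    an extant species; ``clade_fractions`` optionally assigns separate
    fractions to named clades (applied from the stem of each clade).
    """

    root_age: float
    lam: np.ndarray
    mu: np.ndarray
    rho: float = 1.0
    clade_fractions: list = field(default_factory=list)  # [(tip labels, rho)]

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if self.lam.shape != self.mu.shape:
            raise ValueError("lam and mu must have equal length")
        if np.any(self.lam <= 0) or np.any(self.mu < 0):
            raise ValueError("require lam > 0 and mu >= 0")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if self.root_age <= 0:
            raise ValueError("root_age must be > 0")

    @property
    def n_intervals(self) -> int:
        return len(self.lam)

    def boundaries(self) -> np.ndarray:
        """Ascending ages 0 = t_0 < ... < t_n = root_age."""
        return np.linspace(0.0, self.root_age, self.n_intervals + 1)

    def interval_of(self, age: float) -> int:
        """Interval containing ``age`` for rate lookup (age t_i belongs to
        the older interval i, matching piecewise-constant left limits)."""
        b = self.boundaries()
        i = int(np.searchsorted(b, age, side="left")) - 1
        return min(max(i, 0), self.n_intervals - 1)

    def interval_above(self, age: float) -> int:
        """Interval immediately older than ``age`` (boundary age t_i maps
        to interval i), used when integrating toward the past."""
        b = self.boundaries()
        i = int(np.searchsorted(b, age, side="right")) - 1
        return min(max(i, 0), self.n_intervals - 1)


def _bd_step(y0: float, lam: float, mu: float, dt: float):
    """Propagate y = 1 - E over one constant-rate interval.

    y obeys the logistic ODE y' = (lam - mu) y - lam y^2.  Returns
    (y(dt), log Phi) where Phi is the per-lineage branch factor
    exp(r dt) (r / g)^2 with g = r + lam y0 (e^{r dt} - 1).
    """
    r = lam - mu
    if abs(r) < 1e-12:
        denom = 1.0 + lam * y0 * dt
        return y0 / denom, -2.0 * np.log(denom)
    erd = np.exp(r * dt)
    g = r + lam * y0 * (erd - 1.0)
    if g <= 0 if r > 0 else g >= 0:  # g and r share sign for valid y0
        return np.nan, -np.inf
    return r * y0 * erd / g, r * dt - 2.0 * (np.log(abs(g)) - np.log(abs(r)))


class _SurvivalTable:
    """y(t) = 1 - E(t) at interval boundaries for one sampling fraction."""

    def __init__(self, model: EBDModel, rho: float):
        self.model = model
        b = model.boundaries()
        self.y_at = np.empty(model.n_intervals + 1)
        self.y_at[0] = rho
        for i in range(model.n_intervals):
            y, _ = _bd_step(self.y_at[i], model.lam[i], model.mu[i], b[i + 1] - b[i])
            self.y_at[i + 1] = y

    def y(self, age: float) -> float:
        m = self.model
        i = m.interval_of(age) if age > 0 else 0
        t0 = m.boundaries()[i]
        y, _ = _bd_step(self.y_at[i], m.lam[i], m.mu[i], age - t0)
        return y

    def log_phi(self, young: float, old: float) -> float:
        """Log branch factor from age ``young`` up to age ``old``."""
        m = self.model
        b = m.boundaries()
        total = 0.0
        age = young
        y = self.y(young)
        while age < old - 1e-12 * max(old, 1.0):
            i = m.interval_above(age)
            stop = min(b[i + 1], old)
            y, lp = _bd_step(y, m.lam[i], m.mu[i], stop - age)
            total += lp
            age = stop
        return total


def _tip_rho(tree: TimeTree, model: EBDModel) -> dict:
    """Sampling fraction per branch (keyed by child node index).

    Each branch inherits the fraction of the innermost configured clade
    containing its whole subtree; branches outside every clade use the
    global rho.
    """
    out = {}
    if not model.clade_fractions:
        return {v: model.rho for v in range(tree.n_nodes)}
    clades = tree.clades()
    configured = sorted(((frozenset(labels), rho)
                         for labels, rho in model.clade_fractions),
                        key=lambda x: len(x[0]))
    for v in range(tree.n_nodes):
        sub = clades[v]
        rho = model.rho
        for cl, r in configured:
            if sub <= cl:
                rho = r
                break
        out[v] = rho
    return out


def ebd_loglik(tree: TimeTree, model: EBDModel) -> float:
    """Episodic birth-death log-likelihood of an ultrametric extant tree.

    Conditioned on the root age and on both root lineages surviving to
    be sampled.  Incomplete sampling is uniform at the present.
    """
    if not tree.is_ultrametric(tol=1e-6 * max(tree.root_age, 1.0)):
        raise ValueError("EBD likelihood requires an ultrametric extant tree")
    rho_of = _tip_rho(tree, model)
    tables = {r: _SurvivalTable(model, r) for r in set(rho_of.values())}
    ll = 0.0
    for t in tree.tips():
        ll += np.log(rho_of[t])
    for v, pa, na in tree.branches():
        ll += tables[rho_of[v]].log_phi(na, pa)
    root = tree.root
    for v in tree.postorder():
        if tree.children[v] and v != root:
            i = model.interval_of(float(tree.ages[v]))
            ll += np.log(model.lam[i])
    for c in tree.children[root]:
        y_root = tables[rho_of[c]].y(float(tree.ages[root]))
        if y_root <= 0:
            return -np.inf
        ll -= np.log(y_root)
    return float(ll)


def ebd_prior_logdensity(model: EBDModel, sigma_lam: float, sigma_mu: float,
                         first_logpdf=None, sigma_logpdf=None) -> float:
    """Autocorrelated log-rate prior: Brownian steps backward in time.

    Going backward from the present, each older interval's log rate is
    Normal around the previous (younger) interval's log rate.  Optional
    ``first_logpdf(lam0, mu0)`` and ``sigma_logpdf(sigma)`` hyperpriors;
    by default the first interval and the step sizes are unpenalized.
    """
    if sigma_lam <= 0 or sigma_mu <= 0:
        raise ValueError("sigma must be > 0")
    ld = 0.0
    loglam, logmu = np.log(model.lam), np.log(model.mu)
    ld += float(np.sum(norm.logpdf(np.diff(loglam), scale=sigma_lam)))
    ld += float(np.sum(norm.logpdf(np.diff(logmu), scale=sigma_mu)))
    if first_logpdf is not None:
        ld += first_logpdf(model.lam[0], model.mu[0])
    if sigma_logpdf is not None:
        ld += sigma_logpdf(sigma_lam) + sigma_logpdf(sigma_mu)
    return ld


# ---------------------------------------------------------------------------
# HiSSE


@dataclass
class HiSSEModel:
    """3 observed biomes x 2 hidden states, each with its own (lam, mu).

    Combined state index = ``hidden * 3 + biome`` with biomes ordered
    (tropical, warm-temperate, cold-temperate).  Biome shifts follow
    ``q_biome`` (ordered moves tropical<->warm<->cold by default);
    hidden-state switches occur at rate ``hidden_switch`` independently
    of biome.  No simultaneous biome+hidden jumps.
    """

    lam: np.ndarray
    mu: np.ndarray
    q_biome: np.ndarray
    hidden_switch: float = 0.0
    root_freqs: np.ndarray | None = None
    rho: np.ndarray | float = 1.0

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.q_biome = np.asarray(self.q_biome, dtype=float)
        if self.lam.shape != (6,) or self.mu.shape != (6,):
            raise ValueError("lam and mu must have 6 entries (2 hidden x 3 biomes)")
        if np.any(self.lam < 0) or np.any(self.mu < 0) or self.hidden_switch < 0:
            raise ValueError("rates must be >= 0")
        if not np.any(self.lam > 0):
            raise ValueError("at least one speciation rate must be > 0")
        if self.q_biome.shape != (3, 3) or np.any(
                self.q_biome - np.diag(np.diag(self.q_biome)) < 0):
            raise ValueError("q_biome must be 3x3 with non-negative off-diagonals")
        if self.root_freqs is None:
            self.root_freqs = np.full(6, 1 / 6)
        else:
            f = np.asarray(self.root_freqs, dtype=float)
            self.root_freqs = f / f.sum()
        self.rho6 = np.resize(np.asarray(self.rho, dtype=float), 3)
        self.rho6 = np.tile(self.rho6, 2)

    @classmethod
    def ordered(cls, lam, mu, q_up: float, q_down: float,
                hidden_switch: float = 0.0, **kw) -> "HiSSEModel":
        """Temperature-ordered biome moves only: tropical<->warm<->cold.

        ``q_up`` is the rate toward colder biomes, ``q_down`` toward
        warmer ones.
        """
        q = np.zeros((3, 3))
        q[0, 1] = q[1, 2] = q_up
        q[1, 0] = q[2, 1] = q_down
        return cls(lam=lam, mu=mu, q_biome=q, hidden_switch=hidden_switch, **kw)

    def q_matrix(self) -> np.ndarray:
        """Full 6x6 transition-rate generator among combined states."""
        Q = np.zeros((6, 6))
        for h in (0, 1):
            for b in range(3):
                for b2 in range(3):
                    if b != b2:
                        Q[h * 3 + b, h * 3 + b2] = self.q_biome[b, b2]
                Q[h * 3 + b, (1 - h) * 3 + b] = self.hidden_switch
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def biome_independent_model(lam2, mu2, hidden_switch: float,
                            q_biome=None, **kw) -> HiSSEModel:
    """Null model: diversification depends on the hidden state only.

    ``lam2``/``mu2`` give the two hidden-state rates, copied across
    biomes; biome shifts still occur (defaulting to a shared rate of 1
    between ordered neighbors) but carry no diversification signal.
    """
    lam = np.repeat(np.asarray(lam2, dtype=float), 3)
    mu = np.repeat(np.asarray(mu2, dtype=float), 3)
    if q_biome is None:
        q_biome = np.zeros((3, 3))
        q_biome[0, 1] = q_biome[1, 2] = q_biome[1, 0] = q_biome[2, 1] = 1.0
    return HiSSEModel(lam=lam, mu=mu, q_biome=q_biome,
                      hidden_switch=hidden_switch, **kw)


def _sse_extinction(model: HiSSEModel, t_max: float, rtol: float, atol: float):
    """Dense solution of the extinction ODE E(t) over [0, t_max]."""
    lam, mu = model.lam, model.mu
    Q = model.q_matrix()
    Qoff = Q - np.diag(np.diag(Q))
    qtot = Qoff.sum(axis=1)

    def rhs(_t, E):
        return mu - (lam + mu + qtot) * E + lam * E * E + Qoff @ E

    E0 = 1.0 - model.rho6
    sol = solve_ivp(rhs, (0.0, t_max * (1 + 1e-9)), E0, dense_output=True,
                    rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"extinction ODE failed: {sol.message}")
    # solver sanity check: probabilities stay in [0,1] and, with mu > 0,
    # never decrease toward the past
    Es = sol.sol(np.linspace(0, t_max, 32))
    if Es.min() < -1e-6 or Es.max() > 1 + 1e-6:
        raise RuntimeError("extinction probability left [0, 1]")
    return sol.sol


def hisse_loglik(tree: TimeTree, biome_states: DiscreteCharacterData,
                 model: HiSSEModel, rtol: float = 1e-8, atol: float = 1e-10,
                 condition_on_survival: bool = True) -> float:
    """HiSSE log-likelihood with the hidden state always ambiguous.

    Tip ambiguity sets are over the 3 observed biomes; a state's initial
    branch probability is its sampling fraction when the biome is in the
    tip's set, 0 otherwise (replicated over hidden states).  Branch D
    vectors are renormalized with log-scaler accumulation; the root is
    weighted by ``root_freqs`` and, by default, conditioned on survival
    via the lambda (1-E)^2 convention.
    """
    if not tree.is_ultrametric(tol=1e-6 * max(tree.root_age, 1.0)):
        raise ValueError("HiSSE likelihood requires an ultrametric extant tree")
    lam, mu = model.lam, model.mu
    Q = model.q_matrix()
    Qoff = Q - np.diag(np.diag(Q))
    qtot = Qoff.sum(axis=1)
    Esol = _sse_extinction(model, tree.root_age, rtol, atol)

    def rhs(t, D):
        E = Esol(t)
        return -(lam + mu + qtot) * D + 2.0 * lam * E * D + Qoff @ D

    n = tree.n_nodes
    D = np.zeros((n, 6))
    logscale = np.zeros(n)
    for v in tree.postorder():
        if not tree.children[v]:
            label = tree.labels[v]
            allowed = (biome_states[label] if label in biome_states
                       else frozenset(range(3)))
            init = np.zeros(6)
            for b in allowed:
                init[b] = model.rho6[b]
                init[3 + b] = model.rho6[3 + b]
            D[v] = init
        else:
            acc = np.ones(6)
            for c in tree.children[v]:
                sol = solve_ivp(rhs, (float(tree.ages[c]), float(tree.ages[v])),
                                D[c], rtol=rtol, atol=atol, method="RK45")
                if not sol.success:
                    raise RuntimeError(f"branch ODE failed: {sol.message}")
                acc = acc * np.clip(sol.y[:, -1], 0.0, None)
                logscale[v] += logscale[c]
            acc = acc * lam
            m = acc.max()
            if m <= 0:
                return -np.inf
            D[v] = acc / m
            logscale[v] += np.log(m)
    root = tree.root
    pi = model.root_freqs
    E_root = Esol(tree.root_age)
    if condition_on_survival:
        denom = lam * (1.0 - E_root) ** 2
        ok = denom > 0
        val = float(np.sum(pi[ok] * D[root][ok] / denom[ok]))
    else:
        # undo the root-node lambda factor to leave the plain joint density
        ok = lam > 0
        val = float(np.sum(pi[ok] * D[root][ok] / lam[ok]))
    if val <= 0:
        return -np.inf
    return float(np.log(val) + logscale[root])


# ---------------------------------------------------------------------------
# Derived quantities and codings


def derived_rates(lam, mu, labels=None) -> pd.DataFrame:
    """Net diversification (lam - mu) and turnover (mu / lam) per state."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if np.any(lam == 0):
        raise ValueError("turnover undefined at lam = 0")
    if labels is None:
        labels = [str(i) for i in range(len(lam))]
    return pd.DataFrame({
        "state": list(labels),
        "speciation": lam,
        "extinction": mu,
        "net_diversification": lam - mu,
        "turnover": mu / lam,
    })


def coldest_biome_coding(biome_sets: dict) -> DiscreteCharacterData:
    """Assign each taxon the coldest biome it occupies.

    ``biome_sets`` maps taxon -> set of biome names (or indices); the
    order cold-temperate > warm-temperate > tropical picks the coldest.
    Taxa with an empty set are unknown and coded ambiguous among all 3.
    """
    out = {}
    for taxon, biomes in biome_sets.items():
        idxs = set()
        for b in biomes:
            idxs.add(b if isinstance(b, int) else BIOME_SPACE.index[b])
        if not idxs:
            out[taxon] = frozenset(range(3))
        else:
            out[taxon] = frozenset([max(idxs)])
    return DiscreteCharacterData(BIOME_SPACE, out)
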