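"""Metropolis-Hastings MCMC, priors, posterior summaries, model comparison.

The sampler is a plain random-scan MH kernel over a dict-valued state
(scalars, simplex vectors, and dated trees).  Posterior summaries follow
the reporting conventions used throughout the package: posterior mean
(PM), shortest (HPD) intervals at 95% and 80%, and a maximum a
posteriori (MAP) summary tree.  Marginal likelihoods for model
comparison use stepping-stone integration over a Beta(0.3, 1) power
ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .trees import TimeTree

__all__ = [
    "TruncatedNormalPrior", "UniformPrior", "ExponentialPrior",
    "LogNormalPrior", "DirichletPrior",
    "ScaleMove", "SlideMove", "SimplexMove", "NodeAgeMove", "RootAgeMove",
    "NNIMove", "enforce_monophyly",
    "PosteriorTrace", "run_mcmc", "hpd_interval", "map_tree_summary",
    "marginal_likelihood", "effective_sample_size",
]


# ---------------------------------------------------------------------------
# Priors


class TruncatedNormalPrior:
    """Normal(mean, sd) truncated to [low, high]; e.g. the root-age prior
    TruncatedNormal(120, 20, [40, 240]) used for biogeographic dating."""

    def __init__(self, mean: float, sd: float, low: float, high: float):
        if not low < high:
            raise ValueError("truncation bounds must be ordered")
        if sd <= 0:
            raise ValueError("sd must be > 0")
        self.mean_, self.sd, self.low, self.high = mean, sd, low, high
        self._dist = stats.truncnorm((low - mean) / sd, (high - mean) / sd,
                                     loc=mean, scale=sd)

    def logpdf(self, x: float) -> float:
        return float(self._dist.logpdf(x))

    def sample(self, rng) -> float:
        return float(self._dist.ppf(rng.random()))

    @property
    def analytic_mean(self) -> float:
        return float(self._dist.mean())

    @property
    def analytic_var(self) -> float:
        return float(self._dist.var())

    def ppf(self, q):
        return self._dist.ppf(q)


class UniformPrior:
    def __init__(self, low: float, high: float):
        if not low < high:
            raise ValueError("bounds must be ordered")
        self.low, self.high = low, high

    def logpdf(self, x: float) -> float:
        return -math.log(self.high - self.low) if self.low <= x <= self.high \
            else -math.inf

    def sample(self, rng) -> float:
        return float(rng.uniform(self.low, self.high))

    @property
    def analytic_mean(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def analytic_var(self) -> float:
        return (self.high - self.low) ** 2 / 12.0


class ExponentialPrior:
    def __init__(self, rate: float):
        if rate <= 0:
            raise ValueError("rate must be > 0")
        self.rate = rate

    def logpdf(self, x: float) -> float:
        return math.log(self.rate) - self.rate * x if x >= 0 else -math.inf

    def sample(self, rng) -> float:
        return float(rng.exponential(1.0 / self.rate))

    @property
    def analytic_mean(self) -> float:
        return 1.0 / self.rate

    @property
    def analytic_var(self) -> float:
        return 1.0 / self.rate ** 2


class LogNormalPrior:
    def __init__(self, mean_log: float, sd_log: float):
        if sd_log <= 0:
            raise ValueError("sd_log must be > 0")
        self.mean_log, self.sd_log = mean_log, sd_log

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log(x) - self.mean_log) / self.sd_log
        return -0.5 * z * z - math.log(x * self.sd_log * math.sqrt(2 * math.pi))

    def sample(self, rng) -> float:
        return float(np.exp(self.mean_log + self.sd_log * rng.standard_normal()))

    @property
    def analytic_mean(self) -> float:
        return math.exp(self.mean_log + 0.5 * self.sd_log ** 2)

    @property
    def analytic_var(self) -> float:
        s2 = self.sd_log ** 2
        return (math.exp(s2) - 1) * math.exp(2 * self.mean_log + s2)


class DirichletPrior:
    def __init__(self, alpha):
        self.alpha = np.asarray(alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be > 0")

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0) or abs(x.sum() - 1.0) > 1e-8:
            return -math.inf
        return float(stats.dirichlet.logpdf(x / x.sum(), self.alpha))

    def sample(self, rng):
        return rng.dirichlet(self.alpha)

    @property
    def analytic_mean(self):
        return self.alpha / self.alpha.sum()


# ---------------------------------------------------------------------------
# Moves


class Move:
    """Base proposal: returns (updates dict, log Hastings ratio) or None
    for an immediate rejection (e.g. a violated hard constraint)."""

    name = "move"
    weight = 1.0

    def propose(self, state: dict, rng):  # pragma: no cover - interface
        raise NotImplementedError


class ScaleMove(Move):
    """Multiplicative proposal for a positive scalar; Jacobian log m."""

    def __init__(self, param: str, tuning: float = 1.0, weight: float = 1.0):
        self.param, self.tuning, self.weight = param, tuning, weight
        self.name = f"scale({param})"

    def propose(self, state, rng):
        m = math.exp(self.tuning * (rng.random() - 0.5))
        return {self.param: state[self.param] * m}, math.log(m)


class SlideMove(Move):
    def __init__(self, param: str, delta: float = 1.0, weight: float = 1.0):
        self.param, self.delta, self.weight = param, delta, weight
        self.name = f"slide({param})"

    def propose(self, state, rng):
        return {self.param: state[self.param]
                + self.delta * (rng.random() - 0.5)}, 0.0


class ElementScaleMove(Move):
    """Multiplicative proposal for one random element of a positive
    vector-valued parameter (e.g. per-interval birth-death rates)."""

    def __init__(self, param: str, tuning: float = 1.0, weight: float = 1.0):
        self.param, self.tuning, self.weight = param, tuning, weight
        self.name = f"element_scale({param})"

    def propose(self, state, rng):
        x = np.array(state[self.param], dtype=float)
        i = rng.integers(len(x))
        m = math.exp(self.tuning * (rng.random() - 0.5))
        x[i] *= m
        return {self.param: x}, math.log(m)


class SimplexMove(Move):
    """Dirichlet-centered proposal for a simplex-valued parameter."""

    def __init__(self, param: str, concentration: float = 50.0,
                 weight: float = 1.0, offset: float = 1.0):
        self.param, self.conc, self.weight = param, concentration, weight
        self.offset = offset
        self.name = f"simplex({param})"

    def propose(self, state, rng):
        w = np.asarray(state[self.param], dtype=float)
        a_fwd = self.conc * w + self.offset
        w_new = rng.dirichlet(a_fwd)
        if np.any(w_new <= 1e-12):
            return None
        a_rev = self.conc * w_new + self.offset
        logh = (stats.dirichlet.logpdf(w, a_rev)
                - stats.dirichlet.logpdf(w_new, a_fwd))
        return {self.param: w_new}, float(logh)


class NodeAgeMove(Move):
    """Uniform slide of one internal (non-root) node age within the
    window (oldest child age, parent age); symmetric, so log H = 0."""

    def __init__(self, tree_param: str = "tree", weight: float = 1.0):
        self.param, self.weight = tree_param, weight
        self.name = f"node_age({tree_param})"

    def propose(self, state, rng):
        tree: TimeTree = state[self.param]
        internal = [v for v in range(tree.n_nodes)
                    if tree.children[v] and tree.parent[v] >= 0]
        if not internal:
            return None
        v = internal[rng.integers(len(internal))]
        lo = max(float(tree.ages[c]) for c in tree.children[v])
        hi = float(tree.ages[tree.parent[v]])
        new = tree.copy()
        new.ages[v] = lo + (hi - lo) * rng.random()
        return {self.param: new}, 0.0


class RootAgeMove(Move):
    """Multiplicative scaling of the root age (children fixed)."""

    def __init__(self, tree_param: str = "tree", tuning: float = 0.3,
                 weight: float = 1.0):
        self.param, self.tuning, self.weight = tree_param, tuning, weight
        self.name = f"root_age({tree_param})"

    def propose(self, state, rng):
        tree: TimeTree = state[self.param]
        r = tree.root
        lo = max(float(tree.ages[c]) for c in tree.children[r])
        m = math.exp(self.tuning * (rng.random() - 0.5))
        new_age = float(tree.ages[r]) * m
        if new_age <= lo:
            return None
        new = tree.copy()
        new.ages[r] = new_age
        return {self.param: new}, math.log(m)


class NNIMove(Move):
    """Nearest-neighbor interchange on a rooted dated tree.

    Swaps a child of an internal node with that node's sibling, keeping
    all node ages; rejected when the swap would create a non-positive
    branch duration.
    """

    def __init__(self, tree_param: str = "tree", weight: float = 1.0):
        self.param, self.weight = tree_param, weight
        self.name = f"nni({tree_param})"

    def propose(self, state, rng):
        tree: TimeTree = state[self.param]
        cand = [v for v in range(tree.n_nodes)
                if tree.children[v] and tree.parent[v] >= 0
                and len(tree.children[tree.parent[v]]) == 2]
        if not cand:
            return None
        v = cand[rng.integers(len(cand))]
        p = int(tree.parent[v])
        sib = [c for c in tree.children[p] if c != v][0]
        child = tree.children[v][rng.integers(len(tree.children[v]))]
        # swap `child` (moves up to p) with `sib` (moves down to v)
        if tree.ages[sib] >= tree.ages[v]:
            return None
        new = tree.copy()
        new.children[v] = [c if c != child else sib for c in new.children[v]]
        new.children[p] = [c if c != sib else child for c in new.children[p]]
        new.parent[sib] = v
        new.parent[child] = p
        new._invalidate()
        return {self.param: new}, 0.0


def enforce_monophyly(moves, clade_labels, tree_param: str = "tree"):
    """Wrap moves so proposals breaking a clade constraint are rejected
    before any likelihood evaluation."""
    target = frozenset(clade_labels)

    class Constrained(Move):
        def __init__(self, inner):
            self.inner = inner
            self.name = f"monophyly[{inner.name}]"
            self.weight = inner.weight

        def propose(self, state, rng):
            tips = set(state[tree_param].tip_labels())
            if not target <= tips:
                raise ValueError("constraint tips not all present in tree")
            prop = self.inner.propose(state, rng)
            if prop is None:
                return None
            updates, logh = prop
            tree = updates.get(tree_param, state[tree_param])
            if not tree.is_monophyletic(target):
                return None
            return updates, logh

    return [Constrained(m) for m in moves]


# ---------------------------------------------------------------------------
# The sampler


@dataclass
class PosteriorTrace:
    """Labeled posterior samples: scalar parameters, optional trees,
    log-posterior/likelihood columns, move acceptance rates."""

    params: pd.DataFrame
    trees: list = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)
    burn_in: float = 0.25
    final_state: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.params)

    def posterior(self, column: str, discard_burn_in: bool = True) -> np.ndarray:
        x = self.params[column].to_numpy()
        if discard_burn_in:
            x = x[int(self.burn_in * len(x)):]
        return x

    def summary(self, columns=None) -> pd.DataFrame:
        cols = columns or [c for c in self.params.columns
                           if c not in ("iteration",)]
        rows = []
        for c in cols:
            x = self.posterior(c)
            lo95, hi95 = hpd_interval(x, 0.95)
            lo80, hi80 = hpd_interval(x, 0.80)
            rows.append({"param": c, "pm": x.mean(),
                         "hpd95_low": lo95, "hpd95_high": hi95,
                         "hpd80_low": lo80, "hpd80_high": hi80,
                         "ess": effective_sample_size(x)})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.params.to_csv(path, sep="\t", index=False)


def _flatten(state: dict) -> dict:
    out = {}
    for k, v in state.items():
        if isinstance(v, TimeTree):
            out[f"{k}.root_age"] = v.root_age
        elif isinstance(v, np.ndarray):
            for i, x in enumerate(np.ravel(v)):
                out[f"{k}[{i}]"] = float(x)
        elif isinstance(v, (int, float, np.floating)):
            out[k] = float(v)
    return out


def run_mcmc(log_likelihood, log_prior, init: dict, moves, n_iter: int,
             seed, thin: int = 1, beta: float = 1.0, tree_param=None,
             burn_in: float = 0.25, init_sampler=None,
             max_init_attempts: int = 100) -> PosteriorTrace:
    """Random-scan Metropolis-Hastings over a dict-valued state.

    The target is ``log_prior(state) + beta * log_likelihood(state)``
    (``beta`` supports power posteriors for stepping-stone).  The chain
    is reproducible under ``seed``; acceptance rates are tracked per
    move.  If the initial state has -inf posterior, ``init_sampler(rng)``
    is retried a bounded number of times.
    """
    rng = np.random.default_rng(seed)
    state = dict(init)
    lp = log_prior(state)
    ll = log_likelihood(state) if np.isfinite(lp) else -math.inf
    attempts = 0
    while not np.isfinite(lp + beta * ll):
        attempts += 1
        if init_sampler is None or attempts > max_init_attempts:
            raise RuntimeError("could not find an initial state with "
                               "finite posterior")
        state = dict(init_sampler(rng))
        lp = log_prior(state)
        ll = log_likelihood(state) if np.isfinite(lp) else -math.inf
    weights = np.array([m.weight for m in moves], dtype=float)
    weights /= weights.sum()
    tried = {m.name: 0 for m in moves}
    accepted = {m.name: 0 for m in moves}
    records, trees = [], []
    for it in range(n_iter):
        m = moves[rng.choice(len(moves), p=weights)]
        tried[m.name] += 1
        prop = m.propose(state, rng)
        if prop is not None:
            updates, logh = prop
            cand = dict(state)
            cand.update(updates)
            lp_c = log_prior(cand)
            if np.isfinite(lp_c):
                ll_c = log_likelihood(cand)
                log_ratio = (lp_c + beta * ll_c) - (lp + beta * ll) + logh
                if np.log(rng.random() + 1e-300) < log_ratio:
                    state, lp, ll = cand, lp_c, ll_c
                    accepted[m.name] += 1
        if it % thin == 0:
            rec = _flatten(state)
            rec["iteration"] = it
            rec["log_prior"] = lp
            rec["log_likelihood"] = ll
            rec["log_posterior"] = lp + ll
            records.append(rec)
            if tree_param is not None:
                trees.append(state[tree_param].copy())
    acc = {k: (accepted[k] / tried[k] if tried[k] else float("nan"))
           for k in tried}
    return PosteriorTrace(params=pd.DataFrame(records), trees=trees,
                          acceptance=acc, burn_in=burn_in,
                          final_state=dict(state))


# ---------------------------------------------------------------------------
# Summaries


def hpd_interval(samples, prob: float = 0.95) -> tuple:
    """Shortest contiguous interval holding ceil(prob * n) sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < prob <= 1:
        raise ValueError("prob must be in (0, 1]")
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[:n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def effective_sample_size(x) -> float:
    """ESS via the initial positive autocorrelation sequence."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


def map_tree_summary(trace: PosteriorTrace) -> TimeTree:
    """MAP summary: most frequent sampled topology with mean node ages.

    Ties are broken by the higher mean log-posterior among the tied
    topologies; ages are averaged per clade across that topology's
    samples.
    """
    if not trace.trees:
        raise ValueError("trace contains no sampled trees")
    start = int(trace.burn_in * len(trace.trees))
    trees = trace.trees[start:] or trace.trees
    lp = trace.params["log_posterior"].to_numpy()[start:][:len(trees)]
    groups: dict[frozenset, list[int]] = {}
    for i, t in enumerate(trees):
        groups.setdefault(t.topology_key(), []).append(i)
    best_key = max(groups, key=lambda k: (len(groups[k]),
                                          float(np.mean(lp[groups[k]]))))
    idxs = groups[best_key]
    rep = trees[idxs[0]].copy()
    clades = rep.clades()
    age_sum = {v: 0.0 for v in range(rep.n_nodes)}
    for i in idxs:
        t = trees[i]
        other = {s: v for v, s in t.clades().items()}
        for v in range(rep.n_nodes):
            age_sum[v] += float(t.ages[other[clades[v]]])
    for v in range(rep.n_nodes):
        rep.ages[v] = age_sum[v] / len(idxs)
    rep.validate()
    return rep


# ---------------------------------------------------------------------------
# Marginal likelihood (stepping stone)


def marginal_likelihood(log_likelihood, log_prior, init: dict, moves,
                        n_steps: int = 32, iters_per_step: int = 500,
                        burn_frac: float = 0.2, seed=0,
                        alpha: float = 0.3):
    """Stepping-stone log marginal likelihood over a Beta(alpha, 1) ladder.

    Runs a short power-posterior chain at each rung (reusing the last
    state as the next initialization) and accumulates
    ``sum_k log E_{beta_k}[exp((beta_{k+1}-beta_k) logL)]``.
    Returns (log marginal likelihood, per-step ESS list).
    """
    betas = (np.arange(n_steps + 1) / n_steps) ** (1.0 / alpha)
    state = dict(init)
    total = 0.0
    ess = []
    for k in range(n_steps):
        trace = run_mcmc(log_likelihood, log_prior, state, moves,
                         n_iter=iters_per_step, seed=(seed * 1009 + k) % (2**31),
                         beta=float(betas[k]), burn_in=burn_frac)
        lls = trace.posterior("log_likelihood")
        d_beta = betas[k + 1] - betas[k]
        contrib = logsumexp(d_beta * lls) - math.log(len(lls))
        if not np.isfinite(contrib):
            raise RuntimeError(f"non-finite stepping-stone contribution at "
                               f"power {betas[k]:.4f}")
        total += float(contrib)
        ess.append(effective_sample_size(lls))
        state = dict(trace.final_state)
    return total, ess
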