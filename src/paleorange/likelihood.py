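"""Phylogenetic likelihoods for time-heterogeneous discrete characters.

An :class:`EpochCTMC` holds one generator matrix per epoch.  Branches are
cut into segments at epoch boundaries; the transition probability over a
branch is the chronologically ordered product of per-segment matrix
exponentials.  On top of that propagator this module implements
Felsenstein pruning, marginal ancestral states, and stochastic character
mapping (endpoint-conditioned sampling by uniformization within each
epoch segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .characters import DiscreteCharacterData
from .geography import (BiomeShiftParams, DispersalParams, EpochGraphStack,
                        biome_region_rate_matrix, dispersal_rate_matrix)
from .trees import TimeTree

__all__ = [
    "EpochCTMC", "branch_segments", "branch_transition_matrix",
    "prune_loglik", "ancestral_marginals", "sample_stochastic_map",
    "StochasticMap", "BranchEvent", "write_stochastic_map",
]


def branch_segments(boundaries: np.ndarray, old_age: float, young_age: float):
    """Cut a branch [young_age, old_age] at epoch boundaries.

    Returns ``(start_age, end_age, epoch_index)`` triples, oldest first,
    each lying within a single epoch.  Ages older than the oldest
    boundary fall into epoch 0.
    """
    if old_age < young_age:
        raise ValueError("old_age must be >= young_age")
    cuts = [old_age]
    for b in boundaries[1:-1]:
        if young_age < b < old_age:
            cuts.append(float(b))
    cuts.append(young_age)
    n_epochs = len(boundaries) - 1
    segs = []
    for a0, a1 in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a0 + a1)
        if mid >= boundaries[0]:
            e = 0
        else:
            e = int(np.searchsorted(-boundaries, -mid, side="right")) - 1
            e = min(max(e, 0), n_epochs - 1)
        segs.append((a0, a1, e))
    return segs


class EpochCTMC:
    """A piecewise-constant CTMC: epoch boundaries + per-epoch generators.

    Symmetric generators (the usual case here: undirected dispersal and
    biome graphs) are spectrally decomposed once so that per-segment
    transition matrices are two small matrix products; non-symmetric
    generators fall back to scaling-and-squaring ``expm``.
    """

    def __init__(self, boundaries, rate_matrices):
        self.boundaries = np.asarray(boundaries, dtype=float)
        self.Q = [np.asarray(Q, dtype=float) for Q in rate_matrices]
        if len(self.Q) != len(self.boundaries) - 1:
            raise ValueError("need one rate matrix per epoch")
        S = self.Q[0].shape[0]
        for Q in self.Q:
            if Q.shape != (S, S):
                raise ValueError("rate matrices must share one square shape")
            off = Q - np.diag(np.diag(Q))
            if np.any(off < -1e-12):
                raise ValueError("negative off-diagonal rate")
            if np.max(np.abs(Q.sum(axis=1))) > 1e-9:
                raise ValueError("rate matrix rows must sum to 0")
        self.n_states = S
        self._eig = []
        for Q in self.Q:
            if np.allclose(Q, Q.T, atol=1e-12):
                w, V = np.linalg.eigh(Q)
                self._eig.append((w, V))
            else:
                self._eig.append(None)
        self._unif: list[dict] = [{} for _ in self.Q]

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(cls, Q, oldest_age: float) -> "EpochCTMC":
        return cls([oldest_age, 0.0], [Q])

    @classmethod
    def from_dispersal(cls, stack: EpochGraphStack,
                       params: DispersalParams) -> "EpochCTMC":
        Qs = [dispersal_rate_matrix(stack, e, params)
              for e in range(stack.n_epochs)]
        return cls(stack.boundaries, Qs)

    @classmethod
    def from_biome_shift(cls, stack: EpochGraphStack,
                         params: BiomeShiftParams) -> "EpochCTMC":
        Qs = [biome_region_rate_matrix(stack, e, params)
              for e in range(stack.n_epochs)]
        return cls(stack.boundaries, Qs)

    # -- propagation -------------------------------------------------------

    def segment_matrix(self, epoch: int, dt: float) -> np.ndarray:
        if dt < 0:
            raise ValueError("negative duration")
        if dt == 0:
            return np.eye(self.n_states)
        eig = self._eig[epoch]
        if eig is not None:
            w, V = eig
            P = (V * np.exp(w * dt)) @ V.T
        else:
            P = expm(self.Q[epoch] * dt)
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def segments(self, old_age: float, young_age: float):
        return branch_segments(self.boundaries, old_age, young_age)

    def branch_matrix(self, old_age: float, young_age: float) -> np.ndarray:
        """Transition matrix from the state at the old end to the young end."""
        P = np.eye(self.n_states)
        for a0, a1, e in self.segments(old_age, young_age):
            P = P @ self.segment_matrix(e, a0 - a1)
        return P

    def branch_matrices(self, spans) -> list:
        """Transition matrices for many branches at once.

        ``spans`` is a sequence of (old_age, young_age) pairs; segment
        exponentials are computed in one batch per epoch (via the cached
        spectral decomposition), which is what makes repeated likelihood
        evaluation over a fixed tree cheap.
        """
        plans = [self.segments(a, b) for a, b in spans]
        by_epoch: dict[int, list] = {}
        for bi, plan in enumerate(plans):
            for si, (a0, a1, e) in enumerate(plan):
                by_epoch.setdefault(e, []).append((bi, si, a0 - a1))
        seg_P: dict[tuple, np.ndarray] = {}
        for e, items in by_epoch.items():
            dts = np.array([dt for _, _, dt in items])
            eig = self._eig[e]
            if eig is not None:
                w, V = eig
                batch = np.einsum("ij,nj,kj->nik", V, np.exp(np.outer(dts, w)), V)
            else:
                batch = np.stack([expm(self.Q[e] * dt) for dt in dts])
            np.clip(batch, 0.0, 1.0, out=batch)
            batch /= batch.sum(axis=2, keepdims=True)
            for (bi, si, _), P in zip(items, batch):
                seg_P[(bi, si)] = P
        out = []
        for bi, plan in enumerate(plans):
            if len(plan) == 1:
                out.append(seg_P[(bi, 0)])
            else:
                P = seg_P[(bi, 0)]
                for si in range(1, len(plan)):
                    P = P @ seg_P[(bi, si)]
                out.append(P)
        return out


def branch_transition_matrix(plan, process: EpochCTMC) -> np.ndarray:
    """Ordered product of per-segment exponentials, oldest segment first.

    ``plan`` is a sequence of ``(start_age, end_age, epoch)`` triples as
    produced by :func:`branch_segments`.
    """
    P = np.eye(process.n_states)
    for a0, a1, e in plan:
        P = P @ process.segment_matrix(e, a0 - a1)
    return P


# ---------------------------------------------------------------------------
# Pruning and marginals


def _node_partials(tree: TimeTree, data: DiscreteCharacterData,
                   process: EpochCTMC):
    """Postorder conditional likelihoods with per-node log scalers.

    Returns (L, logscale, branch_P) where L[v] is the rescaled partial at
    node v, logscale[v] accumulates the scalers of v's subtree, and
    branch_P[v] is the transition matrix over the branch above v.
    """
    S = process.n_states
    n = tree.n_nodes
    L = np.zeros((n, S))
    logscale = np.zeros(n)
    nodes = [v for v, _, _ in tree.branches()]
    spans = [(float(tree.ages[tree.parent[v]]), float(tree.ages[v]))
             for v in nodes]
    branch_P = dict(zip(nodes, process.branch_matrices(spans)))
    for v in tree.postorder():
        if not tree.children[v]:
            label = tree.labels[v]
            if label not in data:
                L[v] = 1.0  # absent taxon: treated as missing
            else:
                L[v] = data.partial(label)
        else:
            L[v] = 1.0
            for c in tree.children[v]:
                L[v] *= branch_P[c] @ L[c]
                logscale[v] += logscale[c]
        m = L[v].max()
        if m <= 0:
            return L, np.full(n, -np.inf), branch_P
        L[v] /= m
        logscale[v] += np.log(m)
    return L, logscale, branch_P


def _root_frequencies(process: EpochCTMC, root_freqs) -> np.ndarray:
    if root_freqs is None:
        return np.full(process.n_states, 1.0 / process.n_states)
    f = np.asarray(root_freqs, dtype=float)
    if f.shape != (process.n_states,) or np.any(f < 0):
        raise ValueError("bad root frequencies")
    return f / f.sum()


def prune_loglik(tree: TimeTree, data: DiscreteCharacterData,
                 process: EpochCTMC, root_freqs=None) -> float:
    """Felsenstein-pruned log-likelihood of tip ambiguity sets.

    Root state frequencies default to uniform (no range prior beyond the
    CTMC itself).  Returns -inf when the data are impossible under the
    model.
    """
    pi = _root_frequencies(process, root_freqs)
    L, logscale, _ = _node_partials(tree, data, process)
    r = tree.root
    val = float(pi @ L[r])
    if val <= 0 or not np.isfinite(logscale[r]):
        return -np.inf
    return float(np.log(val) + logscale[r])


def ancestral_marginals(tree: TimeTree, data: DiscreteCharacterData,
                        process: EpochCTMC, root_freqs=None) -> np.ndarray:
    """Marginal posterior state probabilities for every node.

    Combines the postorder conditionals with a preorder "outside" pass;
    each returned row sums to 1.
    """
    pi = _root_frequencies(process, root_freqs)
    L, logscale, branch_P = _node_partials(tree, data, process)
    if not np.isfinite(logscale[tree.root]):
        raise ValueError("data impossible under the model")
    n, S = L.shape
    out = np.zeros((n, S))
    out[tree.root] = pi
    marg = np.zeros((n, S))
    for v in tree.preorder():
        m = out[v] * L[v]
        tot = m.sum()
        if tot <= 0:
            raise ValueError("zero marginal mass (impossible data)")
        marg[v] = m / tot
        kids = tree.children[v]
        if not kids:
            continue
        down = [branch_P[c] @ L[c] for c in kids]
        for idx, c in enumerate(kids):
            o = out[v].copy()
            for jdx, d in enumerate(down):
                if jdx != idx:
                    o = o * d
            out[c] = o @ branch_P[c]
            s = out[c].sum()
            if s > 0:
                out[c] /= s
    return marg


# ---------------------------------------------------------------------------
# Stochastic character mapping


@dataclass(frozen=True)
class BranchEvent:
    age: float
    from_state: int
    to_state: int


@dataclass
class StochasticMap:
    """A full, timed character history over a tree.

    ``node_state[v]`` is the state at node v; ``events[v]`` lists the
    transitions on the branch *above* v, ordered oldest to youngest.
    """

    tree: TimeTree
    node_state: np.ndarray
    events: dict = field(default_factory=dict)

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def validate(self, data: DiscreteCharacterData | None = None) -> None:
        for v, pa, na in self.tree.branches():
            s = int(self.node_state[self.tree.parent[v]])
            prev_age = pa
            for ev in self.events.get(v, ()):
                if not (na <= ev.age <= pa) or ev.age > prev_age:
                    raise ValueError(f"event age {ev.age} outside branch above {v}")
                if ev.from_state != s:
                    raise ValueError("event chain not contiguous")
                if ev.from_state == ev.to_state:
                    raise ValueError("self-transition recorded")
                s = ev.to_state
                prev_age = ev.age
            if s != int(self.node_state[v]):
                raise ValueError(f"branch endpoint state mismatch at node {v}")
        if data is not None:
            for t in self.tree.tips():
                label = self.tree.labels[t]
                if label in data and int(self.node_state[t]) not in data[label]:
                    raise ValueError(f"tip {label} state outside ambiguity set")

    def state_on_branch(self, v: int, age: float) -> int:
        """State on the branch above v at a given age (events at exactly
        ``age`` counted as having occurred)."""
        s = int(self.node_state[self.tree.parent[v]])
        for ev in self.events.get(v, ()):
            if ev.age >= age:
                s = ev.to_state
            else:
                break
        return s


def _unif_powers(process: EpochCTMC, epoch: int, n: int):
    """Cache of (mu, [R^0 ... R^n]) for uniformization in one epoch."""
    cache = process._unif[epoch]
    if "mu" not in cache:
        Q = process.Q[epoch]
        mu = float(np.max(-np.diag(Q)))
        cache["mu"] = mu
        if mu > 0:
            cache["R"] = [np.eye(process.n_states)]
            cache["Rmat"] = np.eye(process.n_states) + Q / mu
    mu = cache["mu"]
    if mu == 0:
        return mu, None
    R = cache["R"]
    while len(R) <= n:
        R.append(R[-1] @ cache["Rmat"])
    return mu, R


def _sample_segment_path(process: EpochCTMC, epoch: int, dt: float,
                         a: int, b: int, P_ab: float, rng) -> list:
    """Endpoint-conditioned CTMC path on one epoch segment by
    uniformization.  Returns (time-from-old-end, from, to) transitions."""
    mu, R = _unif_powers(process, epoch, 0)
    if mu == 0 or dt == 0:
        if a != b:
            raise RuntimeError("impossible endpoint pair under zero-rate process")
        return []
    # number of uniformized jumps
    u = rng.random() * P_ab
    lam = mu * dt
    logp = -lam
    n = 0
    cum = 0.0
    nmax = int(20 + 10 * lam + 20 * np.sqrt(lam))
    while True:
        mu, R = _unif_powers(process, epoch, n)
        cum += np.exp(logp) * R[n][a, b]
        if cum >= u:
            break
        n += 1
        logp += np.log(lam) - np.log(n)
        if n > nmax:
            break  # numerical tail: accept current n
    if n == 0:
        return []
    # jump chain states by forward sampling conditioned on the endpoint
    states = [a]
    for k in range(1, n):
        _, R = _unif_powers(process, epoch, n - k)
        w = R[1][states[-1], :] * R[n - k][:, b]
        tot = w.sum()
        if tot <= 0:
            raise RuntimeError("uniformization weight underflow")
        states.append(int(rng.choice(len(w), p=w / tot)))
    states.append(b)
    times = np.sort(rng.random(n)) * dt
    path = []
    for k in range(n):
        if states[k] != states[k + 1]:
            path.append((float(times[k]), states[k], states[k + 1]))
    return path


def sample_stochastic_map(tree: TimeTree, data: DiscreteCharacterData,
                          process: EpochCTMC, rng, root_freqs=None,
                          max_retries: int = 10_000) -> StochasticMap:
    """Draw one full history from the posterior of histories given tips.

    Node states are sampled exactly from their joint conditional
    distribution; branch paths are sampled endpoint-conditioned within
    each epoch segment by uniformization.  Reproducible given ``rng``
    (an int seed or a numpy Generator).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pi = _root_frequencies(process, root_freqs)
    L, logscale, branch_P = _node_partials(tree, data, process)
    if not np.isfinite(logscale[tree.root]):
        raise ValueError("data impossible under the model")
    n = tree.n_nodes
    node_state = np.full(n, -1, dtype=np.int64)
    w = pi * L[tree.root]
    node_state[tree.root] = int(rng.choice(len(w), p=w / w.sum()))
    for v in tree.preorder():
        for c in tree.children[v]:
            wc = branch_P[c][node_state[v], :] * L[c]
            tot = wc.sum()
            if tot <= 0:
                raise RuntimeError("zero-probability branch endpoint")
            node_state[c] = int(rng.choice(len(wc), p=wc / tot))
    events: dict[int, list] = {}
    for v, pa, na in tree.branches():
        segs = process.segments(pa, na)
        # intermediate states at segment boundaries, filtered forward
        seg_P = [process.segment_matrix(e, a0 - a1) for a0, a1, e in segs]
        states = [int(node_state[tree.parent[v]])]
        end = int(node_state[v])
        for k in range(len(segs) - 1):
            suffix = np.eye(process.n_states)
            for P in seg_P[k + 1:]:
                suffix = suffix @ P
            wk = seg_P[k][states[-1], :] * suffix[:, end]
            tot = wk.sum()
            if tot <= 0:
                raise RuntimeError("zero-probability segment boundary")
            states.append(int(rng.choice(len(wk), p=wk / tot)))
        states.append(end)
        ev: list[BranchEvent] = []
        for k, (a0, a1, e) in enumerate(segs):
            ok = False
            for _ in range(max_retries):
                try:
                    path = _sample_segment_path(
                        process, e, a0 - a1, states[k], states[k + 1],
                        float(seg_P[k][states[k], states[k + 1]]), rng)
                    ok = True
                    break
                except RuntimeError:
                    continue
            if not ok:
                raise RuntimeError(
                    f"stochastic-map sampling failed on branch above node {v}")
            for t, s0, s1 in path:
                ev.append(BranchEvent(age=a0 - t, from_state=s0, to_state=s1))
        if ev:
            events[v] = ev
    return StochasticMap(tree=tree, node_state=node_state, events=events)


def write_stochastic_map(smap: StochasticMap, space=None, path=None) -> str:
    """TSV event table: branch node index, age, from, to (names if a
    space is given)."""
    lines = ["branch\tage\tfrom\tto"]
    name = (lambda s: space.names[s]) if space is not None else str
    for v in sorted(smap.events):
        for ev in smap.events[v]:
            lines.append(f"{v}\t{ev.age:.9g}\t{name(ev.from_state)}\t{name(ev.to_state)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
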