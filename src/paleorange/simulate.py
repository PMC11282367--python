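"""Forward simulators for every input the analyses consume.

All generators are exact (Gillespie-style event simulation, no
tau-leaping) and deterministic under a seed.  The default desk-scale
recipe — 200 tips, 3 biomes x 4 regions, 4 epochs, 2 loci x 600 bp —
is sized so that the full pipeline (dating, diversification, biome
shift, event analytics) runs in minutes on one CPU while retaining the
statistical structure the likelihoods assume: a dated birth-death tree,
partitioned GTR+Gamma sequences, single-area tip ranges with ambiguity
for wide-ranging taxa, and biome-region tip states with missing codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .characters import (BIOMES, BiomeRegionSpace, DiscreteCharacterData,
                         PartitionedAlignment, StateSpace)
from .diversification import HiSSEModel
from .geography import (BiomeShiftParams, DispersalParams, EpochGraphStack,
                        write_graph_stack)
from .likelihood import BranchEvent, EpochCTMC, StochasticMap
from .molecular import GTRParams, _GTRPropagator, discrete_gamma_rates
from .trees import TimeTree

__all__ = [
    "SimulationRecipe", "simulate_tree", "simulate_history",
    "simulate_alignment", "simulate_sse", "make_area_stack",
    "make_biome_region_stack", "simulate_dataset", "tip_states_to_data",
    "simulate_tree_for_time",
]

DEFAULT_REGIONS = ("SEAs", "SAm", "NAm", "Afr")


@dataclass
class SimulationRecipe:
    """Everything needed to regenerate one synthetic dataset."""

    seed: int = 0
    n_tips: int = 200
    birth: float = 0.1
    death: float = 0.03
    rho: float = 1.0
    n_areas: int = 6
    biomes: tuple = BIOMES
    regions: tuple = DEFAULT_REGIONS
    epoch_boundaries: tuple = (120.0, 80.0, 40.0, 15.0, 0.0)
    adjacency_density: float = 0.5
    dispersal: DispersalParams = field(default_factory=lambda: DispersalParams(
        base=0.03, medium=0.1, long=0.01))
    biome_shift: BiomeShiftParams = field(default_factory=lambda: BiomeShiftParams(
        base=0.05, weights=(0.05, 0.05, 0.90), biome_shift_rel=1.0))
    gtr: GTRParams = field(default_factory=lambda: GTRParams(
        exch=(0.1, 0.25, 0.08, 0.07, 0.35, 0.15),
        freqs=(0.3, 0.2, 0.2, 0.3), alpha=0.5, clock=0.005))
    locus_lengths: tuple = (600, 600)
    frac_ambiguous: float = 0.15
    frac_missing: float = 0.05

    def to_metadata(self) -> dict:
        d = dict(self.__dict__)
        d["dispersal"] = dict(self.dispersal.__dict__)
        d["biome_shift"] = {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.biome_shift.__dict__.items()}
        d["gtr"] = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.gtr.__dict__.items()}
        return d

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationRecipe":
        raw = yaml.safe_load(text) or {}
        for key, klass in (("dispersal", DispersalParams),
                           ("biome_shift", BiomeShiftParams),
                           ("gtr", GTRParams)):
            if key in raw and isinstance(raw[key], dict):
                sub = {k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in raw[key].items()}
                raw[key] = klass(**sub)
        for key in ("biomes", "regions", "epoch_boundaries", "locus_lengths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Birth-death trees


def simulate_tree(birth: float, death: float, n_tips: int, seed,
                  rho: float = 1.0, max_retries: int = 1000) -> TimeTree:
    """Forward birth-death tree conditioned on >= 2 sampled extant tips.

    Simulation runs until ``n_tips`` lineages are simultaneously extant,
    then the present is placed uniformly inside the waiting time to the
    next event; extinct and unsampled lineages are pruned (uniform
    subsampling with probability ``rho``).  Retries on whole-tree
    extinction.
    """
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = _rng(seed)
    for _ in range(max_retries):
        # node bookkeeping: parent, birth time (forward), death time or None
        parent = [-1]
        t_birth = [0.0]
        t_end: list = [None]
        children: list[list[int]] = [[]]
        alive = [0]
        t = 0.0
        failed = False
        while len(alive) < n_tips:
            total = len(alive) * (birth + death)
            t += rng.exponential(1.0 / total)
            k = alive[rng.integers(len(alive))]
            if rng.random() < birth / (birth + death):
                for _c in range(2):
                    parent.append(k)
                    t_birth.append(t)
                    t_end.append(None)
                    children.append([])
                children[k].extend([len(parent) - 2, len(parent) - 1])
                t_end[k] = t
                alive.remove(k)
                alive.extend([len(parent) - 2, len(parent) - 1])
            else:
                t_end[k] = t
                alive.remove(k)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        total = len(alive) * (birth + death)
        present = t + rng.random() * rng.exponential(1.0 / total)
        sampled = [k for k in alive if rng.random() < rho]
        if len(sampled) < 2:
            continue
        for k in alive:
            t_end[k] = present
        tree = _prune_to_sampled(parent, t_birth, t_end, children,
                                 set(sampled), present)
        if tree is not None:
            return tree
    raise RuntimeError("tree simulation failed: repeated extinction")


def _prune_to_sampled(parent, t_birth, t_end, children, sampled, present):
    """Drop extinct/unsampled lineages, suppress unary nodes, build a
    TimeTree with the present at age 0.

    Tip labels are ``t<original lineage id>`` so callers can join
    simulated per-lineage attributes back onto the pruned tree.
    """
    import sys
    n = len(parent)
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 10 * n + 1000))
    keep = [False] * n
    for k in sampled:
        v = k
        while v >= 0 and not keep[v]:
            keep[v] = True
            v = parent[v]

    def build(v):
        kept_kids = [c for c in children[v] if keep[c]]
        if not kept_kids:
            return [("tip", v)]
        subs = []
        for c in kept_kids:
            subs.extend(build(c))
        if len(kept_kids) == 1:
            return subs  # suppress unary passage through v
        return [("node", v, subs)]

    top = build(0)
    if len(top) == 1 and top[0][0] == "tip":
        return None
    root_spec = top[0] if len(top) == 1 else ("node", 0, top)

    parents2, children2, ages2, labels2 = [], [], [], []

    def emit(spec, parent_idx):
        idx = len(parents2)
        parents2.append(parent_idx)
        children2.append([])
        if parent_idx >= 0:
            children2[parent_idx].append(idx)
        if spec[0] == "tip":
            v = spec[1]
            ages2.append(present - t_end[v])
            labels2.append(f"t{v}")
        else:
            v = spec[1]
            ages2.append(present - t_end[v])
            labels2.append(None)
            for sub in spec[2]:
                emit(sub, idx)
        return idx

    try:
        emit(root_spec, -1)
    finally:
        sys.setrecursionlimit(limit)
    for i in range(len(parents2)):
        ages2[i] = max(ages2[i], 0.0)
    tree = TimeTree(parents2, children2, ages2, labels2, validate=False)
    try:
        tree.validate()
    except ValueError:
        return None  # zero-duration edge from simultaneous events; retry
    return tree


def simulate_tree_for_time(birth: float, death: float, duration: float,
                           seed) -> int:
    """Count extant lineages after ``duration`` starting from one lineage
    (no tree construction; used for birth-death calibration checks)."""
    rng = _rng(seed)
    n, t = 1, 0.0
    while n > 0:
        t += rng.exponential(1.0 / (n * (birth + death))) if birth + death > 0 \
            else np.inf
        if t >= duration:
            break
        n += 1 if rng.random() < birth / (birth + death) else -1
    return n


# ---------------------------------------------------------------------------
# Character histories (Gillespie along branches)


def simulate_history(tree: TimeTree, process: EpochCTMC, seed,
                     root_state: int | None = None, root_freqs=None):
    """Exact forward simulation of an epoch-switching CTMC over a tree.

    Returns ``(StochasticMap, tip state dict)``; event waiting times are
    exponential with the current state's total rate, re-drawn at epoch
    boundaries (valid because the process is piecewise-homogeneous and
    the exponential is memoryless).
    """
    rng = _rng(seed)
    S = process.n_states
    if root_state is None:
        pi = (np.full(S, 1.0 / S) if root_freqs is None
              else np.asarray(root_freqs, dtype=float))
        root_state = int(rng.choice(S, p=pi / pi.sum()))
    node_state = np.full(tree.n_nodes, -1, dtype=np.int64)
    node_state[tree.root] = root_state
    events: dict[int, list] = {}
    for v in tree.preorder():
        for c in tree.children[v]:
            s = int(node_state[v])
            ev = []
            for a0, a1, e in process.segments(float(tree.ages[v]),
                                              float(tree.ages[c])):
                Q = process.Q[e]
                age = a0
                while True:
                    rate = -Q[s, s]
                    if rate <= 0:
                        break
                    age = age - rng.exponential(1.0 / rate)
                    if age <= a1:
                        break
                    probs = np.clip(Q[s], 0, None)
                    probs[s] = 0.0
                    nxt = int(rng.choice(S, p=probs / probs.sum()))
                    ev.append(BranchEvent(age=age, from_state=s, to_state=nxt))
                    s = nxt
            node_state[c] = s
            if ev:
                events[c] = ev
    smap = StochasticMap(tree=tree, node_state=node_state, events=events)
    tips = {tree.labels[t]: int(node_state[t]) for t in tree.tips()}
    return smap, tips


def tip_states_to_data(tips: dict, space: StateSpace, rng=None,
                       frac_ambiguous: float = 0.0,
                       frac_missing: float = 0.0,
                       neighbor=None) -> DiscreteCharacterData:
    """Wrap simulated tip states, optionally degrading some observations.

    A fraction of taxa become ambiguous between their true state and a
    neighbor state (emulating wide-ranging taxa), and a fraction become
    missing ('?'), emulating taxa whose range falls outside the modeled
    state space.
    """
    rng = _rng(rng if rng is not None else 0)
    data = {}
    for taxon, s in tips.items():
        u = rng.random()
        if u < frac_missing:
            data[taxon] = frozenset(range(space.size))
        elif u < frac_missing + frac_ambiguous:
            if neighbor is not None:
                other = neighbor(s, rng)
            else:
                other = int((s + 1) % space.size)
            data[taxon] = frozenset({s, other})
        else:
            data[taxon] = frozenset({s})
    return DiscreteCharacterData(space, data)


# ---------------------------------------------------------------------------
# Sequence data


def simulate_alignment(tree: TimeTree, gtr, locus_lengths, seed,
                       n_cat: int = 4) -> PartitionedAlignment:
    """Site-wise GTR+Gamma simulation with per-partition parameters.

    ``gtr`` is one GTRParams or a sequence matching ``locus_lengths``.
    Partition ids are ``locus1, locus2, ...``.
    """
    rng = _rng(seed)
    if isinstance(gtr, GTRParams):
        gtr = [gtr] * len(locus_lengths)
    seqs = {tree.labels[t]: [] for t in tree.tips()}
    partitions = {}
    offset = 0
    for li, (params, length) in enumerate(zip(gtr, locus_lengths), 1):
        partitions[f"locus{li}"] = np.arange(offset, offset + length)
        offset += length
        prop = _GTRPropagator(params)
        rates = discrete_gamma_rates(params.alpha, n_cat)
        cats = rng.integers(n_cat, size=length)
        states = {tree.root: rng.choice(4, size=length, p=prop.pi)}
        for v in tree.preorder():
            for c in tree.children[v]:
                bl = tree.branch_length(c) * params.clock * params.rate_mult
                child = np.empty(length, dtype=np.int64)
                for ci in range(n_cat):
                    mask = cats == ci
                    if not mask.any():
                        continue
                    P = prop.matrix(bl * rates[ci])
                    cum = np.cumsum(P, axis=1)
                    u = rng.random(int(mask.sum()))
                    rows = cum[states[v][mask]]
                    child[mask] = (u[:, None] > rows).sum(axis=1)
                states[c] = child
        letters = np.array(list("ACGT"))
        for t in tree.tips():
            seqs[tree.labels[t]].append("".join(letters[states[t]]))
    return PartitionedAlignment(
        sequences={k: "".join(v) for k, v in seqs.items()},
        partitions=partitions)


# ---------------------------------------------------------------------------
# State-dependent diversification (tree + trait jointly)


def simulate_sse(model: HiSSEModel, n_tips: int, seed,
                 root_state: int | None = None, rho: float = 1.0,
                 max_retries: int = 1000):
    """Joint forward simulation of tree and 6-state (biome x hidden)
    character; hidden states are discarded in the returned tip data.

    Conditioned on reaching ``n_tips`` extant lineages (with >= 2
    sampled); the present is placed uniformly within the waiting time to
    the next global event.
    """
    rng = _rng(seed)
    lam, mu = model.lam, model.mu
    Q = model.q_matrix()
    Qoff = np.clip(Q, 0, None)
    np.fill_diagonal(Qoff, 0.0)
    qtot = Qoff.sum(axis=1)
    for _ in range(max_retries):
        if root_state is None:
            pi = model.root_freqs
            s0 = int(rng.choice(6, p=pi / pi.sum()))
        else:
            s0 = int(root_state)
        parent = [-1]
        t_birth = [0.0]
        t_end: list = [None]
        children: list[list[int]] = [[]]
        state = [s0]
        alive = [0]
        t = 0.0
        failed = False
        while len(alive) < n_tips:
            rates = np.array([lam[state[k]] + mu[state[k]] + qtot[state[k]]
                              for k in alive])
            total = rates.sum()
            t += rng.exponential(1.0 / total)
            k = alive[int(rng.choice(len(alive), p=rates / total))]
            s = state[k]
            u = rng.random() * (lam[s] + mu[s] + qtot[s])
            if u < lam[s]:
                for _c in range(2):
                    parent.append(k)
                    t_birth.append(t)
                    t_end.append(None)
                    children.append([])
                    state.append(s)
                children[k].extend([len(parent) - 2, len(parent) - 1])
                t_end[k] = t
                alive.remove(k)
                alive.extend([len(parent) - 2, len(parent) - 1])
            elif u < lam[s] + mu[s]:
                t_end[k] = t
                alive.remove(k)
                if not alive:
                    failed = True
                    break
            else:
                state[k] = int(rng.choice(6, p=Qoff[s] / qtot[s]))
        if failed:
            continue
        rates = np.array([lam[state[k]] + mu[state[k]] + qtot[state[k]]
                          for k in alive])
        present = t + rng.random() * rng.exponential(1.0 / rates.sum())
        sampled = [k for k in alive if rng.random() < rho]
        if len(sampled) < 2:
            continue
        for k in alive:
            t_end[k] = present
        tree = _prune_to_sampled(parent, t_birth, t_end, children,
                                 set(sampled), present)
        if tree is None:
            continue
        space = StateSpace(BIOMES)
        tipdata = {f"t{k}": frozenset({state[k] % 3}) for k in sampled}
        return tree, DiscreteCharacterData(space, tipdata)
    raise RuntimeError("SSE simulation failed: repeated extinction")


# ---------------------------------------------------------------------------
# Fixture graph stacks


def make_area_stack(n_areas: int, boundaries, seed,
                    density: float = 0.5) -> EpochGraphStack:
    """Random area-dispersal stack honoring short <= medium <= long nesting.

    Each epoch draws a connected random graph at the given density for
    the short mode, then adds extra edges for medium and long reach.
    """
    rng = _rng(seed)
    boundaries = np.asarray(boundaries, dtype=float)
    E = len(boundaries) - 1
    names = [f"A{i+1}" for i in range(n_areas)]
    feats = {m: np.zeros((E, n_areas, n_areas), dtype=np.uint8)
             for m in ("short", "medium", "long")}
    iu = np.triu_indices(n_areas, k=1)
    for e in range(E):
        short = np.zeros((n_areas, n_areas), dtype=np.uint8)
        # spanning chain keeps every epoch's short graph connected
        perm = rng.permutation(n_areas)
        for a, b in zip(perm[:-1], perm[1:]):
            short[a, b] = short[b, a] = 1
        extra = rng.random(len(iu[0])) < density
        short[iu[0][extra], iu[1][extra]] = 1
        short[iu[1][extra], iu[0][extra]] = 1
        med = short.copy()
        more = rng.random(len(iu[0])) < density / 2
        med[iu[0][more], iu[1][more]] = 1
        med[iu[1][more], iu[0][more]] = 1
        lng = np.ones((n_areas, n_areas), dtype=np.uint8)
        np.fill_diagonal(short, 0)
        np.fill_diagonal(med, 0)
        np.fill_diagonal(lng, 0)
        feats["short"][e], feats["medium"][e], feats["long"][e] = short, med, lng
    return EpochGraphStack(space=StateSpace(names), boundaries=boundaries,
                           features=feats)


def make_biome_region_stack(boundaries, seed, biomes=BIOMES,
                            regions=DEFAULT_REGIONS,
                            region_density: float = 0.6,
                            availability_p: float = 0.75) -> EpochGraphStack:
    """Random paleobiome stack: land adjacency + per-epoch biome
    availability, expanded into full/geography/biome channels over the
    compound state space.

    * full: every single-component move allowed (uninformative).
    * geography: region moves need land adjacency; biome moves are free.
    * biome: region moves need the biome present in both regions and
      adjacency; biome moves need the target biome present locally.
    """
    rng = _rng(seed)
    boundaries = np.asarray(boundaries, dtype=float)
    E = len(boundaries) - 1
    sp = BiomeRegionSpace(biomes, regions)
    B, R, S = sp.n_biomes, sp.n_regions, sp.size
    feats = {f: np.zeros((E, S, S), dtype=np.uint8) for f in
             ("full", "geography", "biome")}
    avail = np.zeros((E, B, R), dtype=np.uint8)
    for e in range(E):
        adj = np.zeros((R, R), dtype=np.uint8)
        perm = rng.permutation(R)
        for a, b in zip(perm[:-1], perm[1:]):
            adj[a, b] = adj[b, a] = 1
        iu = np.triu_indices(R, k=1)
        extra = rng.random(len(iu[0])) < region_density
        adj[iu[0][extra], iu[1][extra]] = 1
        adj[iu[1][extra], iu[0][extra]] = 1
        av = (rng.random((B, R)) < availability_p).astype(np.uint8)
        av[:, rng.integers(R)] = 1  # at least one fully stocked region
        for r in range(R):
            if not av[:, r].any():
                av[rng.integers(B), r] = 1
        avail[e] = av
        for b in range(B):
            for r in range(R):
                i = sp.encode(b, r)
                for r2 in range(R):
                    if r2 == r:
                        continue
                    j = sp.encode(b, r2)
                    feats["full"][e, i, j] = 1
                    feats["geography"][e, i, j] = adj[r, r2]
                    feats["biome"][e, i, j] = adj[r, r2] & av[b, r] & av[b, r2]
                for b2 in range(B):
                    if b2 == b:
                        continue
                    j = sp.encode(b2, r)
                    feats["full"][e, i, j] = 1
                    feats["geography"][e, i, j] = 1
                    feats["biome"][e, i, j] = av[b2, r]
    return EpochGraphStack(space=sp, boundaries=boundaries, features=feats,
                           availability=avail)


# ---------------------------------------------------------------------------
# One-call dataset


def simulate_dataset(recipe: SimulationRecipe) -> dict:
    """Generate the full desk-scale dataset a pipeline run consumes.

    Returns a dict with the tree, area stack + tip ranges, biome-region
    stack + tip states + true history, alignment, and a metadata echo of
    the recipe (sufficient to regenerate everything).
    """
    rng = np.random.default_rng(recipe.seed)
    tree = simulate_tree(recipe.birth, recipe.death, recipe.n_tips,
                         rng, rho=recipe.rho)
    scale = max(tree.root_age * 1.25, recipe.epoch_boundaries[0])
    area_bounds = np.array([scale] + list(recipe.epoch_boundaries[1:]))
    area_stack = make_area_stack(recipe.n_areas, area_bounds, rng,
                                 density=recipe.adjacency_density)
    area_proc = EpochCTMC.from_dispersal(area_stack, recipe.dispersal)
    _, area_tips = simulate_history(tree, area_proc, rng)
    area_data = tip_states_to_data(
        area_tips, area_stack.space, rng,
        frac_ambiguous=recipe.frac_ambiguous, frac_missing=recipe.frac_missing)
    br_stack = make_biome_region_stack(area_bounds, rng,
                                       biomes=recipe.biomes,
                                       regions=recipe.regions)
    br_proc = EpochCTMC.from_biome_shift(br_stack, recipe.biome_shift)
    sp = br_stack.space

    def br_neighbor(s, rr):
        b, r = sp.decode(s)
        if rr.random() < 0.5:
            return sp.encode(b, (r + 1) % sp.n_regions)
        return sp.encode((b + 1) % sp.n_biomes, r)

    true_map, br_tips = simulate_history(tree, br_proc, rng)
    br_data = tip_states_to_data(br_tips, sp, rng,
                                 frac_ambiguous=recipe.frac_ambiguous,
                                 frac_missing=recipe.frac_missing,
                                 neighbor=br_neighbor)
    aln = simulate_alignment(tree, recipe.gtr, recipe.locus_lengths, rng)
    return {
        "tree": tree,
        "area_stack": area_stack,
        "area_data": area_data,
        "biome_region_stack": br_stack,
        "biome_region_data": br_data,
        "true_history": true_map,
        "alignment": aln,
        "metadata": recipe.to_metadata(),
    }
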