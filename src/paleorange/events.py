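"""Event and event-series analytics over sampled biome-region histories.

A stochastic map assigns every branch a timed sequence of (biome,
region) transitions; each transition changes exactly one component and
is classed as a *biome shift* or a *region shift*.  An *event series* is
an ordered pair of consecutive events on a lineage path (crossing
speciation nodes root-ward), classified as:

========================  ==================================================
biome/region reversal     two same-feature events returning to the start
biome/region flight       two same-feature events across three states
biome-first/region-first  mixed pair, named for the earlier event
========================  ==================================================

Lineage-state proportions, series tabulations, and biome-availability
mismatch are summarized across maps with posterior means and 80%/95%
HPD intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characters import BiomeRegionSpace
from .geography import EpochGraphStack
from .likelihood import StochasticMap
from .inference import hpd_interval

__all__ = [
    "EventRecord", "SERIES_CATEGORIES", "records_from_map",
    "classify_event_pair", "tabulate_event_series",
    "summarize_event_series", "lineage_state_proportions",
    "mismatch_proportion",
]

SERIES_CATEGORIES = ("biome_reversal", "biome_flight", "region_reversal",
                     "region_flight", "biome_first", "region_first")


@dataclass(frozen=True)
class EventRecord:
    """One biome- or region-shift on a branch; states are (biome, region)."""

    branch: int
    age: float
    from_state: tuple
    to_state: tuple

    def __post_init__(self):
        db = self.from_state[0] != self.to_state[0]
        dr = self.from_state[1] != self.to_state[1]
        if db == dr:
            raise ValueError("event must change exactly one of biome/region")

    @property
    def event_class(self) -> str:
        return "biome_shift" if self.from_state[0] != self.to_state[0] \
            else "region_shift"


def records_from_map(smap: StochasticMap,
                     space: BiomeRegionSpace) -> list:
    """Flatten a stochastic map into EventRecords (branch keyed by the
    child node index, events oldest first within a branch)."""
    out = []
    for v in sorted(smap.events):
        for ev in smap.events[v]:
            out.append(EventRecord(branch=v, age=ev.age,
                                   from_state=space.decode(ev.from_state),
                                   to_state=space.decode(ev.to_state)))
    return out


def classify_event_pair(first: EventRecord, second: EventRecord) -> str:
    """Classify a consecutive pair of events on one lineage path.

    Requires contiguity: the second event must start from the state the
    first produced.
    """
    if first.to_state != second.from_state:
        raise ValueError("events are not consecutive on a lineage path")
    c1, c2 = first.event_class, second.event_class
    if c1 == c2:
        feature = "biome" if c1 == "biome_shift" else "region"
        return (f"{feature}_reversal" if first.from_state == second.to_state
                else f"{feature}_flight")
    return "biome_first" if c1 == "biome_shift" else "region_first"


def _bin_of(age: float, bin_edges: np.ndarray) -> int:
    """Index of the time bin holding ``age``; edges descending to 0,
    bin i covering (edges[i+1], edges[i]]."""
    if age >= bin_edges[0]:
        return 0
    i = int(np.searchsorted(-bin_edges, -age, side="right")) - 1
    return min(max(i, 0), len(bin_edges) - 2)


def tabulate_event_series(smap: StochasticMap, space: BiomeRegionSpace,
                          bin_edges) -> pd.DataFrame:
    """Count event series per time bin for one map.

    Each event is paired with its nearest root-ward predecessor on the
    lineage path (crossing speciation nodes: an ancestral event can seed
    one series in each daughter path) and the pair is assigned to the
    bin of the *second* event.  Returns a (n_bins x categories) count
    frame indexed by the old edge of each bin.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges) - 1
    counts = np.zeros((n_bins, len(SERIES_CATEGORIES)), dtype=int)
    cat_idx = {c: i for i, c in enumerate(SERIES_CATEGORIES)}
    tree = smap.tree

    stack: list[tuple[int, EventRecord | None]] = [(tree.root, None)]
    while stack:
        v, prev = stack.pop()
        for c in tree.children[v]:
            last = prev
            for ev in smap.events.get(c, ()):
                rec = EventRecord(branch=c, age=ev.age,
                                  from_state=space.decode(ev.from_state),
                                  to_state=space.decode(ev.to_state))
                if last is not None:
                    cat = classify_event_pair(last, rec)
                    counts[_bin_of(rec.age, bin_edges), cat_idx[cat]] += 1
                last = rec
            stack.append((c, last))
    return pd.DataFrame(counts, columns=list(SERIES_CATEGORIES),
                        index=pd.Index(bin_edges[:-1], name="bin_old_edge"))


def summarize_event_series(maps, space: BiomeRegionSpace, bin_edges,
                           hpd_probs=(0.8, 0.95)) -> pd.DataFrame:
    """Posterior summaries of per-bin series-category proportions.

    For each map, counts in a bin are normalized over categories (bins
    with no pairs contribute nothing); means and HPD intervals are taken
    across maps.  Tidy output: one row per (bin, category).
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    per_map = []
    for smap in maps:
        counts = tabulate_event_series(smap, space, bin_edges).to_numpy()
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_map.append(np.where(tot > 0, counts / tot, np.nan))
    arr = np.array(per_map)  # (maps, bins, cats)
    rows = []
    for bi in range(len(bin_edges) - 1):
        for ci, cat in enumerate(SERIES_CATEGORIES):
            x = arr[:, bi, ci]
            x = x[~np.isnan(x)]
            row = {"bin_old_edge": bin_edges[bi],
                   "bin_young_edge": bin_edges[bi + 1],
                   "category": cat,
                   "n_maps_with_pairs": len(x),
                   "mean": float(np.mean(x)) if len(x) else np.nan}
            for p in hpd_probs:
                tag = f"hpd{int(round(p * 100))}"
                if len(x) >= 2:
                    lo, hi = hpd_interval(x, p)
                else:
                    lo = hi = np.nan
                row[f"{tag}_low"], row[f"{tag}_high"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


def _live_branches(tree, age: float):
    """Branches (child-node keyed) spanning ``age``: child age <= age <
    parent age; at age 0 these are the pendant tip branches."""
    out = []
    for v, pa, na in tree.branches():
        if na <= age < pa:
            out.append(v)
    return out


def lineage_state_proportions(maps, grid, space=None) -> pd.DataFrame:
    """Fraction of live lineages in each state at each grid age,
    averaged over maps; rows sum to 1."""
    maps = list(maps)
    tree = maps[0].tree
    grid = np.asarray(grid, dtype=float)
    if np.any(grid >= tree.root_age):
        raise ValueError("grid age at or older than the root")
    n_states = (space.size if space is not None
                else int(max(m.node_state.max() for m in maps)) + 1)
    acc = np.zeros((len(grid), n_states))
    for smap in maps:
        for gi, age in enumerate(grid):
            live = _live_branches(tree, age)
            states = [smap.state_on_branch(v, age) for v in live]
            for s in states:
                acc[gi, s] += 1.0 / len(states)
    acc /= len(maps)
    cols = list(space.names) if space is not None else list(range(n_states))
    return pd.DataFrame(acc, columns=cols, index=pd.Index(grid, name="age"))


def mismatch_proportion(maps, stack: EpochGraphStack, grid) -> pd.Series:
    """Fraction of live lineages whose biome is unavailable in their
    region at each grid age (availability from the paleobiome stack)."""
    maps = list(maps)
    tree = maps[0].tree
    sp = stack.space
    if not isinstance(sp, BiomeRegionSpace):
        raise ValueError("mismatch requires a biome-region stack")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid > stack.boundaries[0]) or np.any(grid < 0):
        raise ValueError("grid age outside the stack's span")
    if np.any(grid >= tree.root_age):
        raise ValueError("grid age at or older than the root")
    avail = stack.biome_availability()
    out = np.zeros(len(grid))
    for smap in maps:
        for gi, age in enumerate(grid):
            e = stack.epoch_index(age)
            live = _live_branches(tree, age)
            bad = 0
            for v in live:
                b, r = sp.decode(smap.state_on_branch(v, age))
                if not avail[e, b, r]:
                    bad += 1
            out[gi] += bad / len(live)
    out /= len(maps)
    return pd.Series(out, index=pd.Index(grid, name="age"),
                     name="mismatch_proportion")
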