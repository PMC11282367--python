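"""Time-stratified dispersal structure: epoch graph stacks and rate matrices.

Paleogeographic history is represented as an ordered stack of epochs,
each carrying one binary adjacency matrix per *feature channel* over a
discrete state space.  For the area-dispersal model the channels are the
three dispersal modes (``short``, ``medium``, ``long``), nested so that
any short-distance connection is also reachable by the medium and long
modes.  For the biome-region model the channels are the uninformative
``full`` graph, land adjacency (``geography``), and biome continuity
(``biome``), combined by simplex weights (w_U, w_G, w_B) estimated from
the data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .characters import BiomeRegionSpace, StateSpace

__all__ = [
    "EpochGraphStack", "DispersalParams", "BiomeShiftParams",
    "load_graph_stack", "write_graph_stack",
    "dispersal_rate_matrix", "biome_region_rate_matrix",
]

DISPERSAL_MODES = ("short", "medium", "long")
BIOME_FEATURES = ("full", "geography", "biome")


@dataclass
class EpochGraphStack:
    """Epoch boundary ages plus per-epoch, per-feature adjacency matrices.

    ``boundaries`` has length ``n_epochs + 1``, strictly decreasing and
    ending at 0 (present); epoch ``e`` covers ``(boundaries[e+1],
    boundaries[e]]``.  Ages older than ``boundaries[0]`` are assigned to
    the oldest epoch, so a root slightly older than the stack is handled
    by extending the oldest regime.
    """

    space: StateSpace
    boundaries: np.ndarray
    features: dict
    availability: np.ndarray | None = None  # (n_epochs, n_biomes, n_regions)

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.features = {k: np.asarray(v, dtype=np.uint8)
                         for k, v in self.features.items()}
        if self.availability is not None:
            self.availability = np.asarray(self.availability, dtype=np.uint8)
        self.validate()

    @property
    def n_epochs(self) -> int:
        return len(self.boundaries) - 1

    def validate(self) -> None:
        b = self.boundaries
        if len(b) < 2 or b[-1] != 0.0:
            raise ValueError("epoch boundaries must end at 0 (present)")
        if not np.all(np.diff(b) < 0):
            raise ValueError("epoch boundaries must be strictly decreasing "
                             "(gap-free tiling of [oldest, 0])")
        S = self.space.size
        for name, mats in self.features.items():
            if mats.shape != (self.n_epochs, S, S):
                raise ValueError(
                    f"feature {name!r}: expected shape {(self.n_epochs, S, S)}, "
                    f"got {mats.shape}")
            if not np.all((mats == 0) | (mats == 1)):
                raise ValueError(f"feature {name!r}: entries must be 0/1")
            if np.any(mats[:, np.arange(S), np.arange(S)] != 0):
                raise ValueError(f"feature {name!r}: diagonal must be zero")
        if all(m in self.features for m in DISPERSAL_MODES):
            s, m, l = (self.features[k] for k in DISPERSAL_MODES)
            if np.any(s > m) or np.any(m > l):
                raise ValueError("dispersal-mode nesting violated: require "
                                 "short <= medium <= long adjacency")
        if self.availability is not None:
            if not isinstance(self.space, BiomeRegionSpace):
                raise ValueError("availability requires a BiomeRegionSpace")
            want = (self.n_epochs, self.space.n_biomes, self.space.n_regions)
            if self.availability.shape != want:
                raise ValueError(f"availability: expected shape {want}, "
                                 f"got {self.availability.shape}")

    def epoch_index(self, age: float) -> int:
        """Epoch containing ``age``; epoch e covers (b[e+1], b[e]]."""
        if age < 0:
            raise ValueError("negative age")
        if age >= self.boundaries[0]:
            return 0
        # boundaries descending; find first e with boundaries[e+1] < age
        e = int(np.searchsorted(-self.boundaries, -age, side="right")) - 1
        return min(max(e, 0), self.n_epochs - 1)

    def biome_availability(self) -> np.ndarray:
        """(n_epochs, n_biomes, n_regions) biome presence, explicit or
        derived from the ``biome`` channel (a biome is present in a region
        if any biome-shift edge leads into it there)."""
        if self.availability is not None:
            return self.availability
        if "biome" not in self.features or not isinstance(self.space, BiomeRegionSpace):
            raise ValueError("no availability information in this stack")
        sp, E = self.space, self.n_epochs
        B, R = sp.n_biomes, sp.n_regions
        out = np.zeros((E, B, R), dtype=np.uint8)
        A = self.features["biome"]
        for e in range(E):
            for b in range(B):
                for r in range(R):
                    i = sp.encode(b, r)
                    incoming = [sp.encode(bb, r) for bb in range(B) if bb != b]
                    out[e, b, r] = 1 if any(A[e, j, i] for j in incoming) else 0
        return out


@dataclass
class DispersalParams:
    """Base dispersal rate (events/Myr) and relative mode multipliers.

    Oceanic barriers limit the modes differentially, so the multipliers
    are ordered ``long <= medium <= 1`` with the short mode at rate 1.
    """

    base: float = 1.0
    medium: float = 0.1
    long: float = 0.01

    def __post_init__(self):
        if self.base <= 0:
            raise ValueError("base dispersal rate must be > 0")
        if not (0 < self.long <= self.medium <= 1.0):
            raise ValueError("mode multipliers must satisfy 0 < long <= medium <= 1")


@dataclass
class BiomeShiftParams:
    """Event rate, simplex feature weights, and biome/region relative rate.

    ``weights`` = (w_U, w_G, w_B): uninformative, geography, and biome
    channels.  ``biome_shift_rel`` scales biome shifts relative to region
    shifts (which have relative rate 1).
    """

    base: float = 1.0
    weights: tuple = (1 / 3, 1 / 3, 1 / 3)
    biome_shift_rel: float = 1.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be 3 non-negative values summing to 1")
        self.weights = tuple(float(x) for x in w)
        if self.base <= 0 or self.biome_shift_rel <= 0:
            raise ValueError("rates must be > 0")


def _as_generator(Q: np.ndarray) -> np.ndarray:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def dispersal_rate_matrix(stack: EpochGraphStack, epoch: int,
                          params: DispersalParams) -> np.ndarray:
    """Dispersal generator for one epoch: q_ij = base x best-mode multiplier.

    A pair connected by the short mode moves at the base rate; pairs
    reachable only by medium or long modes are scaled by the respective
    multipliers; unconnected pairs have rate 0.  Rows sum to zero.
    """
    if not 0 <= epoch < stack.n_epochs:
        raise IndexError("epoch index out of range")
    s = stack.features["short"][epoch].astype(float)
    m = stack.features["medium"][epoch].astype(float)
    l = stack.features["long"][epoch].astype(float)
    mult = np.where(s == 1, 1.0,
                    np.where(m == 1, params.medium,
                             np.where(l == 1, params.long, 0.0)))
    return _as_generator(params.base * mult)


def biome_region_rate_matrix(stack: EpochGraphStack, epoch: int,
                             params: BiomeShiftParams) -> np.ndarray:
    """Biome-region generator: weighted feature graphs over single-component
    moves.

    Transitions change exactly one of (biome, region); composite moves
    have rate 0.  q_ij = base x class-rate x (w_U A_U + w_G A_G + w_B A_B)_ij
    where the class rate is ``biome_shift_rel`` for biome shifts and 1 for
    region shifts.
    """
    if not 0 <= epoch < stack.n_epochs:
        raise IndexError("epoch index out of range")
    sp = stack.space
    if not isinstance(sp, BiomeRegionSpace):
        raise ValueError("stack space must be a BiomeRegionSpace")
    w_u, w_g, w_b = params.weights
    W = (w_u * stack.features["full"][epoch].astype(float)
         + w_g * stack.features["geography"][epoch].astype(float)
         + w_b * stack.features["biome"][epoch].astype(float))
    S = sp.size
    biome_i, region_i = np.divmod(np.arange(S), sp.n_regions)
    same_biome = biome_i[:, None] == biome_i[None, :]
    same_region = region_i[:, None] == region_i[None, :]
    biome_move = (~same_biome) & same_region
    region_move = same_biome & (~same_region)
    classrate = np.where(biome_move, params.biome_shift_rel,
                         np.where(region_move, 1.0, 0.0))
    return _as_generator(params.base * classrate * W)


# ---------------------------------------------------------------------------
# Structured-text stack format


def write_graph_stack(stack: EpochGraphStack, path=None) -> str:
    """Serialize a stack to the package's line-oriented TSV block format."""
    buf = io.StringIO()
    buf.write("states\t" + "\t".join(stack.space.names) + "\n")
    buf.write("boundaries\t" + "\t".join(f"{b:g}" for b in stack.boundaries) + "\n")
    for name, mats in stack.features.items():
        for e in range(stack.n_epochs):
            buf.write(f"matrix\t{e}\t{name}\n")
            for row in mats[e]:
                buf.write("\t".join(str(int(x)) for x in row) + "\n")
    if stack.availability is not None:
        for e in range(stack.n_epochs):
            buf.write(f"availability\t{e}\n")
            for row in stack.availability[e]:
                buf.write("\t".join(str(int(x)) for x in row) + "\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _infer_space(names) -> StateSpace:
    """Recognize a biome-region layout from ``biome+region`` state names
    (biome-major order); otherwise fall back to a plain StateSpace."""
    if all("+" in n for n in names):
        pairs = [n.split("+", 1) for n in names]
        biomes = list(dict.fromkeys(b for b, _ in pairs))
        regions = list(dict.fromkeys(r for _, r in pairs))
        if len(biomes) * len(regions) == len(names):
            candidate = BiomeRegionSpace(biomes, regions)
            if candidate.names == tuple(names):
                return candidate
    return StateSpace(names)


def load_graph_stack(source, state_space: StateSpace | None = None) -> EpochGraphStack:
    """Load a stack from text or a file path; validates on construction.

    If ``state_space`` is provided, the file's state names must match it
    (and its type, e.g. BiomeRegionSpace, is preserved).
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    lines = [l.rstrip("\n") for l in text.splitlines() if l.strip()]
    if not lines or not lines[0].startswith("states\t"):
        raise ValueError("stack file must start with a 'states' line")
    names = lines[0].split("\t")[1:]
    if state_space is not None:
        if tuple(names) != state_space.names:
            raise ValueError("state names in file do not match supplied space")
        space = state_space
    else:
        space = _infer_space(names)
    if not lines[1].startswith("boundaries\t"):
        raise ValueError("second line must be 'boundaries'")
    boundaries = np.array([float(x) for x in lines[1].split("\t")[1:]])
    n_epochs = len(boundaries) - 1
    S = len(names)
    features: dict[str, dict] = {}
    avail: dict[int, np.ndarray] = {}
    i = 2
    while i < len(lines):
        header = lines[i].split("\t")
        if header[0] == "matrix":
            e, fname = int(header[1]), header[2]
            block = lines[i + 1:i + 1 + S]
            rows = [r.split("\t") for r in block]
            if len(rows) != S or any(len(r) != S for r in rows):
                raise ValueError(f"matrix block for feature {fname!r}, epoch {e}: "
                                 f"expected {S}x{S}")
            features.setdefault(fname, {})[e] = np.array(rows, dtype=np.uint8)
            i += 1 + S
        elif header[0] == "availability":
            e = int(header[1])
            if not isinstance(space, BiomeRegionSpace):
                raise ValueError("availability block requires a BiomeRegionSpace")
            B = space.n_biomes
            block = lines[i + 1:i + 1 + B]
            avail[e] = np.array([r.split("\t") for r in block], dtype=np.uint8)
            i += 1 + B
        else:
            raise ValueError(f"unexpected line: {lines[i]!r}")
    feat_arrays = {}
    for fname, blocks in features.items():
        if sorted(blocks) != list(range(n_epochs)):
            raise ValueError(f"feature {fname!r}: missing epoch blocks")
        feat_arrays[fname] = np.stack([blocks[e] for e in range(n_epochs)])
    availability = None
    if avail:
        if sorted(avail) != list(range(n_epochs)):
            raise ValueError("availability: missing epoch blocks")
        availability = np.stack([avail[e] for e in range(n_epochs)])
    return EpochGraphStack(space=space, boundaries=boundaries,
                           features=feat_arrays, availability=availability)
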