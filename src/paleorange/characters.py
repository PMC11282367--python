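"""Discrete character data: state spaces, tip-state tables, alignments.

Tip observations are ambiguity *sets* over a named state space.  A taxon
with a wide range is ambiguous among the states it occupies (e.g. a
rainforest species spanning Central and South America is coded as
``tropical+CAm, tropical+SAm``); a taxon with no usable data is coded
``?`` and treated as missing, i.e. ambiguous over the full space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .trees import TimeTree, normalize_label

__all__ = [
    "StateSpace", "BiomeRegionSpace", "DiscreteCharacterData",
    "PartitionedAlignment", "read_state_table", "write_state_table",
    "read_fasta", "read_partition_table", "validate_joint_inputs",
    "NUCLEOTIDES", "BIOMES",
]

BIOMES = ("tropical", "warm-temperate", "cold-temperate")

# IUPAC nucleotide ambiguity codes -> sets of ACGT indices
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT", "X": "ACGT",
}


class StateSpace:
    """An ordered, named set of discrete states."""

    def __init__(self, names):
        self.names = tuple(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate state names")
        self.index = {n: i for i, n in enumerate(self.names)}

    @property
    def size(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, StateSpace) and self.names == other.names

    def __repr__(self) -> str:  # pragma: no cover
        return f"StateSpace({len(self.names)} states)"


NUCLEOTIDES = StateSpace(("A", "C", "G", "T"))


class BiomeRegionSpace(StateSpace):
    """Compound (biome, region) states, indexed ``b * n_regions + r``.

    State names follow the ``biome+region`` convention, e.g.
    ``tropical+SAm``.
    """

    def __init__(self, biomes=BIOMES, regions=("SEAs", "EAs", "Eur", "SAm",
                                               "CAm", "NAm")):
        self.biomes = tuple(biomes)
        self.regions = tuple(regions)
        names = [f"{b}+{r}" for b in self.biomes for r in self.regions]
        super().__init__(names)

    @property
    def n_biomes(self) -> int:
        return len(self.biomes)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def encode(self, biome: int, region: int) -> int:
        return biome * self.n_regions + region

    def decode(self, state: int) -> tuple[int, int]:
        return divmod(state, self.n_regions)


class DiscreteCharacterData:
    """Per-taxon ambiguity sets of state indices over a shared space."""

    def __init__(self, space: StateSpace, data: dict):
        self.space = space
        self.data: dict[str, frozenset] = {}
        for taxon, states in data.items():
            states = frozenset(int(s) for s in states)
            if not states:
                raise ValueError(f"empty ambiguity set for taxon {taxon!r}")
            if any(s < 0 or s >= space.size for s in states):
                raise ValueError(f"state index out of range for taxon {taxon!r}")
            self.data[taxon] = states

    def taxa(self) -> list[str]:
        return list(self.data)

    def __getitem__(self, taxon: str) -> frozenset:
        return self.data[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.data

    def __len__(self) -> int:
        return len(self.data)

    def is_missing(self, taxon: str) -> bool:
        return len(self.data[taxon]) == self.space.size

    def partial(self, taxon: str) -> np.ndarray:
        """Indicator vector over states (the tip partial likelihood)."""
        v = np.zeros(self.space.size)
        v[list(self.data[taxon])] = 1.0
        return v

    def to_table(self) -> str:
        lines = []
        for taxon in sorted(self.data):
            states = self.data[taxon]
            if len(states) == self.space.size:
                lines.append(f"{taxon}\t?")
            else:
                names = ",".join(self.space.names[s] for s in sorted(states))
                lines.append(f"{taxon}\t{names}")
        return "\n".join(lines) + "\n"


def read_state_table(text: str, space: StateSpace) -> DiscreteCharacterData:
    """Parse a TSV ``taxon<TAB>state[,state...]`` table; ``?`` = missing."""
    data: dict[str, frozenset] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {ln}: expected 'taxon<TAB>states'")
        taxon = normalize_label(parts[0])
        if taxon in data:
            raise ValueError(f"line {ln}: duplicate taxon {taxon!r}")
        raw = parts[1].strip()
        if raw in ("?", "-"):
            data[taxon] = frozenset(range(space.size))
            continue
        states = set()
        for name in raw.split(","):
            name = name.strip()
            if name not in space.index:
                raise ValueError(f"line {ln}: unknown state label {name!r}")
            states.add(space.index[name])
        data[taxon] = frozenset(states)
    return DiscreteCharacterData(space, data)


def write_state_table(data: DiscreteCharacterData, path=None) -> str:
    text = data.to_table()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Partitioned alignments


@dataclass
class PartitionedAlignment:
    """Equal-length nucleotide sequences plus a site partition table.

    ``partitions`` maps a partition id to the 0-based site indices it
    owns; every site belongs to exactly one partition.
    """

    sequences: dict
    partitions: dict = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences of unequal length: {sorted(lengths)}")
        self.n_sites = lengths.pop() if lengths else 0
        if not self.partitions:
            self.partitions = {"all": np.arange(self.n_sites)}
        assigned = np.concatenate([np.asarray(v, dtype=int)
                                   for v in self.partitions.values()]) \
            if self.partitions else np.array([], dtype=int)
        counts = np.bincount(assigned, minlength=self.n_sites)
        if self.n_sites and not np.all(counts == 1):
            bad = np.flatnonzero(counts != 1)
            raise ValueError(f"sites not assigned to exactly one partition: "
                             f"{bad[:5].tolist()}...")

    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        """Bitmask-encode sequences: (n_taxa, n_sites) with bit b set iff
        nucleotide b is compatible with the observation."""
        out = np.zeros((self.n_taxa, self.n_sites), dtype=np.uint8)
        for i, seq in enumerate(self.sequences.values()):
            for j, ch in enumerate(seq.upper()):
                allowed = _IUPAC.get(ch)
                if allowed is None:
                    raise ValueError(f"unknown nucleotide code {ch!r}")
                mask = 0
                for nt in allowed:
                    mask |= 1 << NUCLEOTIDES.index[nt]
                out[i, j] = mask
        return out

    def to_fasta(self, path=None) -> str:
        buf = io.StringIO()
        for name, seq in self.sequences.items():
            buf.write(f">{name}\n{seq}\n")
        text = buf.getvalue()
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def read_fasta(text: str) -> dict:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = normalize_label(line[1:])
            if name in seqs:
                raise ValueError(f"duplicate sequence name {name!r}")
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_partition_table(text: str, n_sites: int | None = None) -> dict:
    """Parse a TSV partition table into {partition id: site index array}.

    Columns: partition, locus, codon_position, site_start, site_end
    (1-based inclusive).  codon_position in {1,2,3} selects every third
    site within the range; '-' (or empty) takes the whole range.
    """
    parts: dict[str, list] = {}
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if lines and lines[0].lower().startswith("partition"):
        lines = lines[1:]
    for ln, line in enumerate(lines, 1):
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 5:
            raise ValueError(f"partition row {ln}: expected 5 columns")
        pid, _locus, codon, start, end = cols
        start, end = int(start), int(end)
        if start < 1 or end < start:
            raise ValueError(f"partition row {ln}: bad site range {start}-{end}")
        codon = codon.strip()
        if codon in ("", "-", "0"):
            sites = np.arange(start - 1, end)
        else:
            pos = int(codon)
            if pos not in (1, 2, 3):
                raise ValueError(f"partition row {ln}: bad codon position {codon}")
            sites = np.arange(start - 1 + pos - 1, end, 3)
        parts.setdefault(pid, []).append(sites)
    out = {pid: np.sort(np.concatenate(chunks)) for pid, chunks in parts.items()}
    if n_sites is not None:
        allsites = np.concatenate(list(out.values()))
        counts = np.bincount(allsites, minlength=n_sites)
        if len(allsites) and (allsites.max() >= n_sites or not np.all(counts == 1)):
            raise ValueError("partition table does not tile the alignment")
    return out


# ---------------------------------------------------------------------------
# Joint validation


@dataclass
class ValidationReport:
    common: set
    missing: dict

    @property
    def ok(self) -> bool:
        return all(len(v) == 0 for v in self.missing.values())

    def __str__(self) -> str:
        if self.ok:
            return f"all sources agree on {len(self.common)} taxa"
        lines = [f"common taxa: {len(self.common)}"]
        for src, taxa in self.missing.items():
            if taxa:
                lines.append(f"{src}: not shared by all sources: {sorted(taxa)}")
        return "\n".join(lines)


def validate_joint_inputs(tree: TimeTree | None = None, **sources) -> ValidationReport:
    """Cross-check taxon sets across a tree and any named data sources.

    Reports, per source, the taxa it has that are absent from at least
    one other source.  Raises if the overall intersection is empty.
    """
    sets: dict[str, set] = {}
    if tree is not None:
        sets["tree"] = set(tree.tip_labels())
    for name, src in sources.items():
        if src is None:
            continue
        if isinstance(src, DiscreteCharacterData):
            sets[name] = set(src.taxa())
        elif isinstance(src, PartitionedAlignment):
            sets[name] = set(src.taxa())
        elif isinstance(src, dict):
            sets[name] = set(src)
        else:
            sets[name] = set(src)
    if not sets:
        raise ValueError("no inputs to validate")
    common = set.intersection(*sets.values())
    if not common:
        raise ValueError("empty taxon intersection across inputs")
    missing = {name: sorted(s - common) for name, s in sets.items()}
    return ValidationReport(common=common, missing=missing)
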