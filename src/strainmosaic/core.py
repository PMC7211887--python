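"""Shared containers for strain-level metagenomic data.

Coordinates follow the SAM/VCF convention (1-based, inclusive) in every
file format and in :class:`SNVProfile`; array-backed containers
(:class:`Pileup`, :class:`DepthTrack`) index positions 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class ReferenceSequence:
    """A reference genome for one species."""

    species_id: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty reference sequence")
        bad = set(self.sequence) - set(BASES + "N")
        if bad:
            raise ValueError(f"non-ACGTN characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_indices(self) -> np.ndarray:
        """Per-position index into ACGT; N positions get -1."""
        arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for base, idx in BASE_INDEX.items():
            out[arr == ord(base)] = idx
        return out


@dataclass
class DepthTrack:
    """Per-position read depth over one species' reference."""

    species_id: str
    depth: np.ndarray  # shape (L,), non-negative ints

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth track must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return int(self.depth.shape[0])

    @property
    def breadth(self) -> float:
        """Fraction of reference positions covered by at least one read."""
        return float((self.depth >= 1).sum()) / self.length

    @property
    def mean_depth(self) -> float:
        """Mean depth over the whole reference (uncovered positions count)."""
        return float(self.depth.sum()) / self.length


@dataclass
class Pileup:
    """Per-position allele counts (columns ordered A, C, G, T)."""

    species_id: str
    counts: np.ndarray  # shape (L, 4)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("pileup counts must have shape (L, 4)")
        if (self.counts < 0).any():
            raise ValueError("negative allele count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])

    def depth_track(self) -> DepthTrack:
        return DepthTrack(self.species_id, self.counts.sum(axis=1))

    def pooled_with(self, other: "Pileup") -> "Pileup":
        if other.species_id != self.species_id or other.length != self.length:
            raise ValueError("cannot pool pileups of different references")
        return Pileup(self.species_id, self.counts + other.counts)


@dataclass
class SNVProfile:
    """Consensus variant calls for one sample against one species.

    ``calls`` maps 1-based reference position to the called alternate
    base; positions absent from the map are reference or uncalled.
    """

    sample_id: str
    species_id: str
    calls: dict[int, str] = field(default_factory=dict)
    depth_at_call: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, base in self.calls.items():
            if base not in BASE_INDEX:
                raise ValueError(f"called base {base!r} at {pos} not in ACGT")
            if pos < 1:
                raise ValueError("positions are 1-based")


@dataclass
class AlignmentRecord:
    """One aligned read, as parsed from SAM.

    ``pos`` is the 1-based leftmost reference coordinate.  ``sequence``
    is the aligned portion of the read (may be None when the SAM omits
    it); pileups require it.
    """

    read_id: str
    species_id: str
    pos: int
    aligned_length: int
    edit_distance: int
    is_secondary: bool = False
    is_supplementary: bool = False
    sequence: str | None = None

    @property
    def identity(self) -> float:
        """Fraction of aligned bases matching the reference."""
        if self.aligned_length <= 0:
            return 0.0
        return (self.aligned_length - self.edit_distance) / self.aligned_length

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference coordinate."""
        return self.pos + self.aligned_length - 1
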