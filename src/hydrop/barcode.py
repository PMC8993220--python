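"""Split-pool barcode architecture and whitelist construction.

Droplet beads are barcoded in successive split-pool rounds: in each round
the bead pool is distributed over a plate of wells, each well appending one
short "sub-barcode" by linear amplification.  After ``k`` rounds over plates
of sizes ``n_1 .. n_k`` the full cell barcode is the concatenation of one
sub-barcode per round, giving ``n_1 * ... * n_k`` possible barcodes
(884,736 for the canonical three 96-well rounds of 10-mers).  This module
represents that architecture and materialises the whitelist of all valid
full barcodes, keeping the (round, well) provenance of every entry.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "SubBarcodePlate",
    "Segment",
    "BarcodeStructure",
    "BarcodeWhitelist",
    "build_whitelist",
    "barcode_space_size",
    "min_pairwise_hamming",
    "hamming",
]

_DNA = frozenset("ACGT")


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class SubBarcodePlate:
    """One split-pool round: an ordered plate of well sub-barcodes.

    Parameters
    ----------
    round_index : int
        1-based round of split-pool barcoding.
    sequences : tuple of str
        The well sub-barcodes in well order.  Must be unique, uniform
        length, over the DNA alphabet.
    """

    round_index: int
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index is 1-based and must be >= 1")
        seqs = tuple(self.sequences)
        object.__setattr__(self, "sequences", seqs)
        if not seqs:
            raise ValueError("plate must contain at least one sequence")
        length = len(seqs[0])
        if length < 1:
            raise ValueError("sub-barcodes must have length >= 1")
        for s in seqs:
            if len(s) != length:
                raise ValueError("sub-barcodes within a plate must share one length")
            if not set(s) <= _DNA:
                raise ValueError(f"non-ACGT character in sub-barcode {s!r}")
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sub-barcodes within a plate")

    @property
    def barcode_length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_file(cls, path_or_handle, round_index: int) -> "SubBarcodePlate":
        """Read a plate from plain text, one sequence per line; ``#`` comments
        and blank lines are ignored.  Gzip-transparent when given a path."""
        from .io import open_text

        if hasattr(path_or_handle, "read"):
            lines = path_or_handle.read().splitlines()
        else:
            with open_text(path_or_handle) as fh:
                lines = fh.read().splitlines()
        seqs = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seqs.append(line.upper())
        return cls(round_index=round_index, sequences=tuple(seqs))


@dataclass(frozen=True)
class Segment:
    """One block of the barcode read layout.

    ``kind`` is one of ``"subbarcode"`` (carries ``round_index`` and
    ``length``), ``"linker"`` (fixed ``sequence``) or ``"umi"`` (``length``).
    """

    kind: str
    length: int
    round_index: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("subbarcode", "linker", "umi"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "linker":
            if not self.sequence:
                raise ValueError("linker segment requires a sequence")
            object.__setattr__(self, "length", len(self.sequence))
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.kind == "subbarcode" and self.round_index is None:
            raise ValueError("subbarcode segment requires a round_index")

    @staticmethod
    def subbarcode(round_index: int, length: int) -> "Segment":
        return Segment("subbarcode", length=length, round_index=round_index)

    @staticmethod
    def linker(sequence: str) -> "Segment":
        return Segment("linker", length=len(sequence), sequence=sequence)

    @staticmethod
    def umi(length: int) -> "Segment":
        return Segment("umi", length=length)


@dataclass(frozen=True)
class BarcodeStructure:
    """Declarative layout of the barcode read.

    The read is a fixed-offset concatenation of sub-barcode blocks,
    inter-sub-barcode linkers introduced by the barcoding chemistry, and an
    optional UMI.  The number of sub-barcode blocks must match the number of
    split-pool rounds of the design.
    """

    blocks: tuple[Segment, ...]

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise ValueError("structure needs at least one block")
        rounds = [b.round_index for b in blocks if b.kind == "subbarcode"]
        if not rounds:
            raise ValueError("structure needs at least one subbarcode block")
        if sorted(rounds) != list(range(1, len(rounds) + 1)):
            raise ValueError("subbarcode rounds must be 1..k, each exactly once")
        if sum(b.kind == "umi" for b in blocks) > 1:
            raise ValueError("at most one UMI block")

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def n_rounds(self) -> int:
        return sum(b.kind == "subbarcode" for b in self.blocks)

    @property
    def barcode_length(self) -> int:
        """Length of the concatenated full barcode (sub-barcode blocks only)."""
        return sum(b.length for b in self.blocks if b.kind == "subbarcode")

    @property
    def umi_length(self) -> int:
        return sum(b.length for b in self.blocks if b.kind == "umi")

    @classmethod
    def from_dict(cls, doc: dict) -> "BarcodeStructure":
        """Build from a config mapping: ``{"blocks": [{"kind": ...}, ...]}``."""
        blocks = []
        for b in doc["blocks"]:
            kind = b["kind"]
            if kind == "subbarcode":
                blocks.append(Segment.subbarcode(b["round"], b["length"]))
            elif kind == "linker":
                blocks.append(Segment.linker(b["sequence"]))
            elif kind == "umi":
                blocks.append(Segment.umi(b["length"]))
            else:
                raise ValueError(f"unknown block kind {kind!r}")
        return cls(tuple(blocks))


@dataclass
class BarcodeWhitelist:
    """The enumerated set of valid full barcodes with per-round provenance.

    ``provenance`` maps each full barcode to its tuple of 0-based well
    indices, one per round; it is a bijection by construction.
    """

    barcodes: tuple[str, ...]
    provenance: dict[str, tuple[int, ...]]
    plate_sizes: tuple[int, ...]
    block_lengths: tuple[int, ...]
    _set: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._set = frozenset(self.barcodes)

    @property
    def size(self) -> int:
        return len(self.barcodes)

    @property
    def barcode_length(self) -> int:
        return sum(self.block_lengths)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._set

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def decompose(self, barcode: str) -> tuple[str, ...]:
        """Split a full barcode back into its per-round sub-barcodes."""
        parts = []
        offset = 0
        for length in self.block_lengths:
            parts.append(barcode[offset : offset + length])
            offset += length
        return tuple(parts)

    def write(self, path, provenance: bool = False) -> None:
        """Serialize one barcode per line (gzip-transparent by extension).

        With ``provenance=True`` writes a TSV ``barcode<TAB>round<TAB>well``
        with one row per (barcode, round)."""
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            if provenance:
                for bc in self.barcodes:
                    for rnd, well in enumerate(self.provenance[bc], start=1):
                        fh.write(f"{bc}\t{rnd}\t{well}\n")
            else:
                for bc in self.barcodes:
                    fh.write(bc + "\n")

    @classmethod
    def read(cls, path) -> "BarcodeWhitelist":
        """Read a one-barcode-per-line whitelist (no provenance recorded)."""
        from .io import open_text

        with open_text(path) as fh:
            barcodes = tuple(
                line.strip() for line in fh if line.strip() and not line.startswith("#")
            )
        if not barcodes:
            raise ValueError(f"empty whitelist: {path}")
        length = len(barcodes[0])
        if any(len(b) != length for b in barcodes):
            raise ValueError("whitelist entries must share one length")
        prov = {bc: (i,) for i, bc in enumerate(barcodes)}
        return cls(
            barcodes=barcodes,
            provenance=prov,
            plate_sizes=(len(barcodes),),
            block_lengths=(length,),
        )


def barcode_space_size(plate_sizes: Sequence[int]) -> int:
    """Total barcode complexity of a split-pool design: the product of the
    per-round plate sizes (96*96*96 = 884,736 for the canonical design)."""
    sizes = list(plate_sizes)
    if not sizes:
        raise ValueError("need at least one plate size")
    if any(s < 1 for s in sizes):
        raise ValueError("plate sizes must be >= 1")
    out = 1
    for s in sizes:
        out *= s
    return out


def build_whitelist(plates: Sequence[SubBarcodePlate]) -> BarcodeWhitelist:
    """Materialise the full-barcode whitelist as the Cartesian product of the
    plates, in round-major, well-index-ascending order.

    Raises
    ------
    ValueError
        If two different well tuples concatenate to the same full barcode
        (the error names the colliding tuples) — correction semantics
        require the product to be a bijection.
    """
    plates = list(plates)
    if not plates:
        raise ValueError("need at least one plate")
    plates = sorted(plates, key=lambda p: p.round_index)
    if [p.round_index for p in plates] != list(range(1, len(plates) + 1)):
        raise ValueError("plate round indices must be 1..k, each exactly once")

    barcodes: list[str] = []
    provenance: dict[str, tuple[int, ...]] = {}
    for wells in itertools.product(*(range(len(p)) for p in plates)):
        bc = "".join(p.sequences[w] for p, w in zip(plates, wells))
        if bc in provenance:
            raise ValueError(
                f"barcode collision: well tuples {provenance[bc]} and {wells} "
                f"both concatenate to {bc!r}"
            )
        provenance[bc] = wells
        barcodes.append(bc)
    return BarcodeWhitelist(
        barcodes=tuple(barcodes),
        provenance=provenance,
        plate_sizes=tuple(len(p) for p in plates),
        block_lengths=tuple(p.barcode_length for p in plates),
    )


def min_pairwise_hamming(plate: SubBarcodePlate | Iterable[str]) -> int:
    """Minimum Hamming distance over all pairs of sub-barcodes.

    A plate with minimum distance < 3 cannot guarantee unambiguous
    1-mismatch correction; callers should warn on such designs.
    """
    seqs = list(plate.sequences) if isinstance(plate, SubBarcodePlate) else list(plate)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must share one length")
    import numpy as np

    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length)
    best = length
    for i in range(len(seqs) - 1):
        d = (arr[i + 1 :] != arr[i]).sum(axis=1).min()
        if d < best:
            best = int(d)
            if best == 0:
                break
    return best
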