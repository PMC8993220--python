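"""Barcode-read parsing and tiered whitelist correction.

The barcode read carries the split-pool sub-barcodes separated by fixed
linker sequences (and, for the RNA design, a UMI).  Parsing is fixed-offset:
linkers are verified against their expected sequence within a small mismatch
budget, sub-barcodes are excised and concatenated in round order, and the
concatenated barcode is corrected against the whitelist by minimal Hamming
distance.  Correction is tiered: an exact (tier-0) hit short-circuits the
tier-1 search, and so on up to ``max_mismatch``; a read is assigned only
when exactly one whitelist entry sits at the minimal tier — ties are
rejected rather than broken, to avoid mixing cells.

Reads with a 1 bp synthesis frameshift shift every downstream linker out of
register and are rejected by the linker check; no indel rescue is attempted.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .barcode import BarcodeStructure, BarcodeWhitelist, hamming

__all__ = [
    "ParsedBarcodeRead",
    "CorrectionResult",
    "DemuxReport",
    "parse_barcode_read",
    "correct_barcode",
    "demultiplex",
    "UNASSIGNED",
]

UNASSIGNED = -1

_OTHER_BASES = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}


@dataclass(frozen=True)
class ParsedBarcodeRead:
    """Result of fixed-offset parsing of one barcode read."""

    raw_sequence: str
    concatenated_barcode: str | None
    umi: str | None
    parse_ok: bool
    fail_reason: str  # "none" | "too_short" | "linker_mismatch"


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of tiered whitelist correction for one observed barcode.

    ``tier`` is the minimal Hamming distance at which whitelist entries were
    found (``UNASSIGNED`` if none within ``max_mismatch``);
    ``assigned_barcode`` is set only when that tier held exactly one entry.
    """

    assigned_barcode: str | None
    tier: int
    n_candidates_at_tier: int

    @property
    def assigned(self) -> bool:
        return self.assigned_barcode is not None


@dataclass
class DemuxReport:
    """Partition of all input reads by demultiplexing outcome.

    ``total_reads == parse_failures + sum(tier_counts) + ambiguous +
    unassigned`` holds exactly.
    """

    total_reads: int = 0
    parse_failures: int = 0
    tier_counts: dict[int, int] = field(default_factory=dict)
    ambiguous: int = 0
    unassigned: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.tier_counts.values())

    def tier_fraction(self, tier: int) -> float:
        if self.total_reads == 0:
            raise ValueError("empty report")
        return self.tier_counts.get(tier, 0) / self.total_reads

    @property
    def assigned_fraction(self) -> float:
        return self.assigned / self.total_reads

    def check(self) -> None:
        total = self.parse_failures + self.assigned + self.ambiguous + self.unassigned
        if total != self.total_reads:
            raise AssertionError(
                f"report does not partition reads: {total} != {self.total_reads}"
            )

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "parse_failures": self.parse_failures,
            "tier_counts": {str(k): v for k, v in sorted(self.tier_counts.items())},
            "assigned": self.assigned,
            "ambiguous": self.ambiguous,
            "unassigned": self.unassigned,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def parse_barcode_read(
    read: str,
    structure: BarcodeStructure,
    linker_mismatch_budget: int = 1,
    check_linkers: bool = True,
) -> ParsedBarcodeRead:
    """Excise sub-barcodes and UMI from a barcode read at fixed offsets.

    Each linker is compared to its expected sequence; more than
    ``linker_mismatch_budget`` mismatches in any single linker fails the
    read with ``fail_reason="linker_mismatch"``.  A read shorter than the
    structure fails with ``"too_short"``.
    """
    read = read.upper()
    if len(read) < structure.total_length:
        return ParsedBarcodeRead(read, None, None, False, "too_short")
    offset = 0
    sub_parts: dict[int, str] = {}
    umi: str | None = None
    for block in structure.blocks:
        segment = read[offset : offset + block.length]
        if block.kind == "subbarcode":
            sub_parts[block.round_index] = segment
        elif block.kind == "umi":
            umi = segment
        elif check_linkers:
            if hamming(segment, block.sequence) > linker_mismatch_budget:
                return ParsedBarcodeRead(read, None, None, False, "linker_mismatch")
        offset += block.length
    barcode = "".join(sub_parts[r] for r in sorted(sub_parts))
    return ParsedBarcodeRead(read, barcode, umi, True, "none")


def _neighbors_at_distance(seq: str, distance: int) -> Iterator[str]:
    """All strings at exactly ``distance`` substitutions from ``seq``."""
    positions = range(len(seq))
    for combo in itertools.combinations(positions, distance):
        choices = [_OTHER_BASES.get(seq[p], "ACGT") for p in combo]
        for subs in itertools.product(*choices):
            out = list(seq)
            for p, b in zip(combo, subs):
                out[p] = b
            yield "".join(out)


def _block_boundaries(length: int, n_blocks: int) -> list[tuple[int, int]]:
    cuts = [round(i * length / n_blocks) for i in range(n_blocks + 1)]
    return [(cuts[i], cuts[i + 1]) for i in range(n_blocks)]


def _block_index(whitelist: BarcodeWhitelist, n_blocks: int):
    """Pigeonhole index: per block position, a dict from block substring to
    the entries carrying it.  Any entry within Hamming distance
    ``n_blocks - 1`` of a query matches the query exactly in at least one
    block, so the union of block-matches is a complete candidate set."""
    cache = whitelist.__dict__.setdefault("_block_index_cache", {})
    if n_blocks not in cache:
        bounds = _block_boundaries(whitelist.barcode_length, n_blocks)
        index: list[dict[str, list[str]]] = [{} for _ in bounds]
        for entry in whitelist.barcodes:
            for d, (s, e) in zip(index, bounds):
                d.setdefault(entry[s:e], []).append(entry)
        cache[n_blocks] = (bounds, index)
    return cache[n_blocks]


def correct_barcode(
    observed: str,
    whitelist: BarcodeWhitelist,
    max_mismatch: int = 1,
) -> CorrectionResult:
    """Correct an observed barcode by minimal-tier Hamming search.

    Finds the smallest tier ``t <= max_mismatch`` at which at least one
    whitelist entry lies at Hamming distance exactly ``t`` and assigns iff
    that tier holds exactly one candidate.  Tier 0 is a hash lookup and
    tier 1 enumerates the 1-substitution neighborhood; higher tiers use a
    pigeonhole block index.  Both routes are exactly equivalent to an
    exhaustive nearest-neighbor scan of the whitelist.
    """
    if not 0 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 0..3")
    if len(observed) != whitelist.barcode_length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist "
            f"entry length {whitelist.barcode_length}"
        )
    if observed in whitelist:
        return CorrectionResult(observed, 0, 1)
    if max_mismatch == 0:
        return CorrectionResult(None, UNASSIGNED, 0)
    hits = {v for v in _neighbors_at_distance(observed, 1) if v in whitelist}
    if hits:
        if len(hits) == 1:
            return CorrectionResult(next(iter(hits)), 1, 1)
        return CorrectionResult(None, 1, len(hits))
    if max_mismatch == 1:
        return CorrectionResult(None, UNASSIGNED, 0)
    bounds, index = _block_index(whitelist, max_mismatch + 1)
    candidates: set[str] = set()
    for d, (s, e) in zip(index, bounds):
        candidates.update(d.get(observed[s:e], ()))
    best, n_at_best, winner = None, 0, None
    for entry in candidates:
        dist = hamming(observed, entry)
        if dist > max_mismatch:
            continue
        if best is None or dist < best:
            best, n_at_best, winner = dist, 1, entry
        elif dist == best:
            n_at_best += 1
            winner = None
    if best is None:
        return CorrectionResult(None, UNASSIGNED, 0)
    return CorrectionResult(winner, best, n_at_best)


@dataclass(frozen=True)
class TaggedRead:
    """A mate read annotated with its corrected barcode (and UMI)."""

    name: str
    sequence: str
    quality: str
    barcode: str
    umi: str | None = None

    def to_fastq(self) -> str:
        comment = f"CB:Z:{self.barcode}"
        if self.umi is not None:
            comment += f" UB:Z:{self.umi}"
        return f"@{self.name} {comment}\n{self.sequence}\n+\n{self.quality}\n"


def demultiplex(
    barcode_reads: Iterable[tuple[str, str, str]],
    mate_reads: Iterable[tuple[str, str, str]] | None,
    structure: BarcodeStructure,
    whitelist: BarcodeWhitelist,
    max_mismatch: int = 1,
    linker_mismatch_budget: int = 1,
) -> tuple[Iterator[TaggedRead], DemuxReport]:
    """Demultiplex record-synchronized barcode/mate read streams.

    Parameters
    ----------
    barcode_reads, mate_reads
        Iterables of ``(name, sequence, quality)`` FASTQ records.  The two
        streams must be synchronized (same read names in the same order);
        desynchronization is a hard error at the offending record.  Pass
        ``mate_reads=None`` to demultiplex the barcode stream alone (report
        only).

    Returns
    -------
    tagged : iterator of TaggedRead
        Mate reads that were assigned a barcode, annotated with ``CB``
        (and ``UB`` when the structure carries a UMI).  Must be consumed to
        fully populate the report.
    report : DemuxReport
        Filled in as the tagged iterator is consumed.
    """
    report = DemuxReport()

    def _gen() -> Iterator[TaggedRead]:
        mates = iter(mate_reads) if mate_reads is not None else None
        for name, seq, qual in barcode_reads:
            if mates is not None:
                try:
                    m_name, m_seq, m_qual = next(mates)
                except StopIteration:
                    raise ValueError(
                        f"mate FASTQ exhausted before barcode FASTQ at read {name!r}"
                    ) from None
                if m_name.split("/")[0] != name.split("/")[0]:
                    raise ValueError(
                        f"desynchronized FASTQs: barcode read {name!r} vs mate {m_name!r}"
                    )
            report.total_reads += 1
            parsed = parse_barcode_read(
                seq, structure, linker_mismatch_budget=linker_mismatch_budget
            )
            if not parsed.parse_ok:
                report.parse_failures += 1
                continue
            result = correct_barcode(parsed.concatenated_barcode, whitelist, max_mismatch)
            if result.assigned:
                report.tier_counts[result.tier] = (
                    report.tier_counts.get(result.tier, 0) + 1
                )
                if mates is not None:
                    yield TaggedRead(m_name, m_seq, m_qual, result.assigned_barcode, parsed.umi)
            elif result.n_candidates_at_tier > 1:
                report.ambiguous += 1
            else:
                report.unassigned += 1
        if mates is not None:
            try:
                next(mates)
            except StopIteration:
                pass
            else:
                raise ValueError("barcode FASTQ exhausted before mate FASTQ")

    return _gen(), report
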