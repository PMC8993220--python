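"""Barcode parsing and tiered correction against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrop.barcode import (
    BarcodeStructure,
    BarcodeWhitelist,
    Segment,
    build_whitelist,
)
from hydrop.demux import (
    UNASSIGNED,
    correct_barcode,
    demultiplex,
    parse_barcode_read,
)
from hydrop.synth import SynthConfig, default_structure, make_barcode_fastq, make_plates


def _toy_structure(umi: int = 0) -> BarcodeStructure:
    blocks = [Segment.subbarcode(1, 2), Segment.linker("GG"), Segment.subbarcode(2, 2)]
    if umi:
        blocks.append(Segment.umi(umi))
    return BarcodeStructure(tuple(blocks))


def _wl(entries) -> BarcodeWhitelist:
    entries = tuple(entries)
    return BarcodeWhitelist(
        barcodes=entries,
        provenance={e: (i,) for i, e in enumerate(entries)},
        plate_sizes=(len(entries),),
        block_lengths=(len(entries[0]),),
    )


class TestParse:
    def test_extracts_barcode_across_linker(self):
        parsed = parse_barcode_read("ATGGCA", _toy_structure())
        assert parsed.parse_ok and parsed.concatenated_barcode == "ATCA"
        assert parsed.umi is None

    def test_linker_over_budget_fails(self):
        parsed = parse_barcode_read("ATTTCA", _toy_structure())
        assert not parsed.parse_ok and parsed.fail_reason == "linker_mismatch"

    def test_single_linker_mismatch_tolerated(self):
        assert parse_barcode_read("ATGTCA", _toy_structure()).parse_ok

    def test_umi_extraction(self):
        parsed = parse_barcode_read("ATGGCAAAA", _toy_structure(umi=3))
        assert parsed.concatenated_barcode == "ATCA" and parsed.umi == "AAA"

    def test_short_read_fails(self):
        parsed = parse_barcode_read("ATGG", _toy_structure())
        assert not parsed.parse_ok and parsed.fail_reason == "too_short"


class TestCorrect:
    def test_exact_match_is_tier_zero(self, small_whitelist):
        bc = small_whitelist.barcodes[5]
        res = correct_barcode(bc, small_whitelist, max_mismatch=1)
        assert res.assigned_barcode == bc and res.tier == 0

    def test_single_mismatch_assigned_at_tier_one(self, small_whitelist):
        bc = small_whitelist.barcodes[0]
        flipped = "T" if bc[4] != "T" else "G"
        observed = bc[:4] + flipped + bc[5:]
        res = correct_barcode(observed, small_whitelist, max_mismatch=1)
        assert res.assigned_barcode == bc and res.tier == 1 and res.n_candidates_at_tier == 1

    def test_tie_at_minimal_tier_rejected(self):
        wl = _wl(["AAAA", "AATT"])
        res = correct_barcode("AATA", wl, max_mismatch=1)
        assert res.assigned_barcode is None
        assert res.tier == 1 and res.n_candidates_at_tier == 2

    def test_out_of_reach_is_unassigned(self):
        wl = _wl(["AAAA"])
        res = correct_barcode("TTTT", wl, max_mismatch=3)
        assert res.tier == UNASSIGNED and res.n_candidates_at_tier == 0

    def test_length_mismatch_is_error(self, small_whitelist):
        with pytest.raises(ValueError):
            correct_barcode("ACGT", small_whitelist)

    @staticmethod
    def _oracle(observed: str, entries: list[str], max_mismatch: int):
        """Exhaustive nearest-neighbor scan over the whitelist."""
        arr = np.frombuffer("".join(entries).encode(), dtype=np.uint8).reshape(
            len(entries), len(observed)
        )
        q = np.frombuffer(observed.encode(), dtype=np.uint8)
        d = (arr != q).sum(axis=1)
        best = int(d.min())
        if best > max_mismatch:
            return None, UNASSIGNED, 0
        n = int((d == best).sum())
        winner = entries[int(np.argmin(d))] if n == 1 else None
        return winner, best, n

    def test_matches_exhaustive_scan(self, small_whitelist):
        """Neighborhood-enumeration correction equals the brute-force
        nearest-neighbor scan, including tie rejection."""
        rng = np.random.default_rng(5)
        entries = list(small_whitelist.barcodes)
        queries = []
        for n_err in (0, 1, 2, 3):
            for _ in range(40):
                bc = list(entries[rng.integers(len(entries))])
                for p in rng.choice(30, size=n_err, replace=False):
                    bc[p] = "ACGT"[rng.integers(4)]
                queries.append("".join(bc))
        for _ in range(20):  # far-away garbage
            queries.append("".join("ACGT"[b] for b in rng.integers(0, 4, 30)))
        for q in queries:
            got = correct_barcode(q, small_whitelist, max_mismatch=3)
            want_bc, want_tier, want_n = self._oracle(q, entries, 3)
            assert (got.assigned_barcode, got.tier) == (want_bc, want_tier)
            if want_tier != UNASSIGNED:
                assert got.n_candidates_at_tier == want_n

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_property_minimal_tier_equals_min_distance(self, seed):
        rng = np.random.default_rng(seed)
        entries = ["".join("ACGT"[b] for b in row) for row in rng.integers(0, 4, (12, 6))]
        entries = list(dict.fromkeys(entries))
        wl = _wl(entries)
        q = "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
        got = correct_barcode(q, wl, max_mismatch=3)
        want_bc, want_tier, want_n = self._oracle(q, entries, 3)
        assert got.tier == want_tier
        assert got.assigned_barcode == want_bc

    def test_raising_max_mismatch_never_loses_assignments(self, small_whitelist):
        rng = np.random.default_rng(9)
        entries = list(small_whitelist.barcodes)
        queries = []
        for _ in range(100):
            bc = list(entries[rng.integers(len(entries))])
            for p in rng.choice(30, size=rng.integers(0, 4), replace=False):
                bc[p] = "ACGT"[rng.integers(4)]
            queries.append("".join(bc))
        assigned = [
            sum(correct_barcode(q, small_whitelist, m).assigned for q in queries)
            for m in range(4)
        ]
        assert assigned == sorted(assigned)


class TestDemultiplex:
    def test_error_free_reads_all_tier_zero(self, structure, small_whitelist):
        cfg = SynthConfig(seed=1, n_cells=5, reads_per_cell=20,
                          substitution_rate=0.0, frameshift_fraction=0.0)
        reads, _ = make_barcode_fastq(cfg, structure, small_whitelist)
        tagged, report = demultiplex(reads, None, structure, small_whitelist)
        list(tagged)
        report.check()
        assert report.tier_fraction(0) == 1.0 and report.unassigned == 0

    def test_single_substitution_reads_all_tier_one(self, structure, small_whitelist):
        """With plates at min distance >= 3, one error inside a sub-barcode
        is always uniquely corrected at tier 1."""
        rng = np.random.default_rng(2)
        cfg = SynthConfig(seed=2, n_cells=5, reads_per_cell=20,
                          substitution_rate=0.0, frameshift_fraction=0.0)
        reads, truth = make_barcode_fastq(cfg, structure, small_whitelist)
        mutated = []
        for (name, seq, qual) in reads:
            pos = int(rng.integers(0, 10))  # inside the first sub-barcode block
            base = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
            mutated.append((name, seq[:pos] + base + seq[pos + 1 :], qual))
        tagged, report = demultiplex(mutated, None, structure, small_whitelist)
        list(tagged)
        assert report.tier_fraction(1) == 1.0

    def test_assignments_recover_true_barcodes(self, structure, small_whitelist):
        cfg = SynthConfig(seed=3, n_cells=8, reads_per_cell=50,
                          substitution_rate=0.01, frameshift_fraction=0.0)
        reads, truth = make_barcode_fastq(cfg, structure, small_whitelist)
        mates = [(n, "ACGT" * 10, "I" * 40) for n, _, _ in reads]
        tagged, report = demultiplex(reads, mates, structure, small_whitelist)
        by_name = dict(truth[["read", "true_barcode"]].itertuples(index=False))
        n_wrong = sum(t.barcode != by_name[t.name] for t in tagged)
        report.check()
        assert n_wrong == 0 and report.assigned > 0

    def test_report_partitions_all_reads(self, structure, small_whitelist):
        cfg = SynthConfig(seed=4, n_cells=10, reads_per_cell=30,
                          substitution_rate=0.02, frameshift_fraction=0.1)
        reads, _ = make_barcode_fastq(cfg, structure, small_whitelist)
        tagged, report = demultiplex(reads, None, structure, small_whitelist)
        list(tagged)
        report.check()
        assert report.total_reads == len(reads)

    def test_desynchronized_mates_raise(self, structure, small_whitelist):
        cfg = SynthConfig(seed=5, n_cells=2, reads_per_cell=5,
                          substitution_rate=0.0, frameshift_fraction=0.0)
        reads, _ = make_barcode_fastq(cfg, structure, small_whitelist)
        mates = [("WRONGNAME", "ACGT", "IIII")] * len(reads)
        tagged, _ = demultiplex(reads, mates, structure, small_whitelist)
        with pytest.raises(ValueError, match="desynchronized"):
            list(tagged)

    def test_tier_fractions_follow_binomial_law(self, structure):
        """Substitutions are i.i.d. per barcode base, so the tier-0/1
        fractions follow Binomial(30, eps) mass at 0 and 1 within 3 sigma."""
        plates = make_plates(3, 24, 10, seed=6)
        wl = build_whitelist(plates)
        eps = 0.02
        cfg = SynthConfig(seed=6, n_cells=50, reads_per_cell=80,
                          substitution_rate=eps, frameshift_fraction=0.0)
        reads, _ = make_barcode_fastq(cfg, structure, wl)
        tagged, report = demultiplex(reads, None, structure, wl)
        list(tagged)
        n = report.total_reads
        for tier, p in ((0, (1 - eps) ** 30), (1, 30 * eps * (1 - eps) ** 29)):
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(report.tier_fraction(tier) - p) < 3 * sigma
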