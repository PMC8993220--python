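"""ATAC QC metrics: hand-enumerated toys and generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from hydrop.atac import (
    FragmentRecord,
    call_cells,
    compute_qc,
    duplication_rate,
    frip,
    tss_enrichment,
)
from hydrop.synth import SynthConfig, make_fragments, toy_genome

COLS = ["chrom", "start", "end", "barcode", "count"]


def frame(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestDuplication:
    def test_single_fragment_count_four(self):
        assert duplication_rate(frame([("chr1", 0, 100, "b", 4)]))["b"] == 0.75

    def test_all_singletons_zero(self):
        rows = [("chr1", i * 10, i * 10 + 5, "b", 1) for i in range(8)]
        assert duplication_rate(frame(rows))["b"] == 0.0

    def test_mixed_counts_match_hand_tally(self):
        rows = [
            ("chr1", 0, 50, "b1", 3),
            ("chr1", 60, 110, "b1", 1),
            ("chr1", 0, 50, "b1", 2),  # same interval again: merges with row 0
            ("chr2", 5, 55, "b1", 4),
            ("chr1", 0, 50, "b2", 1),
            ("chr1", 100, 150, "b2", 1),
            ("chr1", 200, 250, "b2", 2),
            ("chr2", 0, 90, "b2", 1),
            ("chr2", 0, 90, "b2", 1),
            ("chr2", 300, 350, "b2", 5),
        ]
        # b1: 3 distinct intervals, 3+1+2+4 = 10 read pairs -> 0.7
        # b2: 5 distinct intervals, 1+1+2+1+1+5 = 11 read pairs -> 6/11
        rates = duplication_rate(frame(rows))
        assert rates["b1"] == pytest.approx(0.7)
        assert rates["b2"] == pytest.approx(1 - 5 / 11)

    def test_empty_barcode_absent_not_zero(self):
        rates = duplication_rate(frame([("chr1", 0, 9, "b1", 1)]))
        assert "b2" not in rates.index

    def test_record_validation(self):
        with pytest.raises(ValueError):
            FragmentRecord("chr1", 10, 10, "b")
        with pytest.raises(ValueError):
            FragmentRecord("chr1", 0, 10, "b", count=0)


class TestFrip:
    peaks = pd.DataFrame(
        [("chr1", 100, 200), ("chr1", 180, 300)], columns=["chrom", "start", "end"]
    )

    def test_all_inside_is_one(self):
        rows = [("chr1", 110, 150, "b", 1), ("chr1", 250, 290, "b", 1)]
        assert frip(frame(rows), self.peaks)["b"] == 1.0

    def test_disjoint_is_zero(self):
        rows = [("chr1", 400, 500, "b", 1), ("chr2", 100, 200, "b", 1)]
        assert frip(frame(rows), self.peaks)["b"] == 0.0

    def test_toy_case_matches_brute_force(self):
        rows = [
            ("chr1", 50, 101, "b", 1),   # 1 bp overlap at the merged peak start
            ("chr1", 50, 100, "b", 1),   # half-open: touching, no overlap
            ("chr1", 300, 360, "b", 1),  # starts at merged peak end: no overlap
            ("chr1", 299, 360, "b", 1),  # 1 bp overlap at the end
            ("chr1", 150, 260, "b", 1),  # inside
            ("chr2", 100, 200, "b", 1),  # wrong chromosome
        ]
        def brute(s, e, chrom):
            return any(
                chrom == pc and s < pe and ps < e
                for pc, ps, pe in self.peaks.itertuples(index=False)
            )
        expected = np.mean([brute(s, e, c) for c, s, e, _, _ in rows])
        assert frip(frame(rows), self.peaks)["b"] == pytest.approx(expected)


class TestTssEnrichment:
    def test_formula_identity_on_point_masses(self):
        """All signal insertions exactly at the TSS, flanks at a known
        depth: the score is smoothed-peak over flank depth by construction."""
        tss = pd.DataFrame([("chr1", 5000, "+")], columns=["chrom", "start", "strand"])
        rows = []
        k, m = 40, 6
        # distinct intervals (same interval twice would be a PCR duplicate);
        # far ends keep the second insertion site outside the +/-2000 window
        for i in range(k):  # start insertion exactly at the TSS
            rows.append(("chr1", 5000, 11000 + i, "b", 1))
        for j in range(m):  # start insertion on the upstream flank
            rows.append(("chr1", 3000 + j, 12000 + j, "b", 1))
        scores, profile = tss_enrichment(frame(rows), tss)
        center_smoothed = k / 51
        flank_depth = m / 200  # m insertions over the two 100 bp flanks
        assert scores["b"] == pytest.approx(center_smoothed / flank_depth)
        assert profile.loc[0] == k

    def test_minus_strand_flips_orientation(self):
        tss = pd.DataFrame([("chr1", 5000, "-")], columns=["chrom", "start", "strand"])
        rows = [("chr1", 5100, 5101, "b", 1)]  # +100 genomic -> -100 oriented
        _, profile = tss_enrichment(frame(rows), tss)
        assert profile.loc[-100] == 2 and profile.loc[100] == 0

    def test_uniform_insertions_score_near_one(self, genome):
        """The uniform-insertion null has no TSS structure: score ~ 1."""
        cfg = SynthConfig(seed=21, n_cells=1, n_background_barcodes=0,
                          n_frags_per_cell=25000, tss_signal_fraction=0.0)
        frags, _ = make_fragments(cfg, genome)
        scores, profile = tss_enrichment(frags, genome["tss"])
        assert scores.iloc[0] == pytest.approx(1.0, rel=0.10)
        # aggregate profile flat within Monte-Carlo noise
        inner = profile.to_numpy()[500:-500].astype(float)
        assert inner.std() < 3 * np.sqrt(inner.mean())

    def test_zero_flank_coverage_reports_missing(self):
        tss = pd.DataFrame([("chr1", 5000, "+")], columns=["chrom", "start", "strand"])
        rows = [("chr1", 5000, 5001, "b", 1)]  # center signal, empty flanks
        scores, _ = tss_enrichment(frame(rows), tss)
        assert np.isnan(scores["b"])

    def test_score_increases_with_signal_fraction(self, genome):
        means = []
        for lam in (0.0, 0.2, 0.45):
            cfg = SynthConfig(seed=22, n_cells=10, n_background_barcodes=0,
                              n_frags_per_cell=1500, tss_signal_fraction=lam)
            frags, _ = make_fragments(cfg, genome)
            scores, _ = tss_enrichment(frags, genome["tss"])
            means.append(scores.mean())
        assert means[0] < means[1] < means[2]

    def test_empty_tss_set_is_error(self, toy_fragments):
        with pytest.raises(ValueError):
            tss_enrichment(toy_fragments, pd.DataFrame(columns=["chrom", "start"]))


class TestCallCells:
    def qc(self, frags, tss):
        return pd.DataFrame(
            {"unique_fragments": frags, "tss_enrichment": tss},
            index=[f"b{i}" for i in range(len(frags))],
        )

    def test_inclusive_boundary_kept(self):
        out = call_cells(self.qc([1000], [7.0]), min_fragments=1000, min_tss=7)
        assert bool(out["is_cell"].iloc[0])

    def test_below_fragment_floor_rejected(self):
        out = call_cells(self.qc([999], [20.0]), min_fragments=1000, min_tss=7)
        assert not bool(out["is_cell"].iloc[0])

    def test_nan_score_rejected(self):
        out = call_cells(self.qc([5000], [np.nan]), min_fragments=1000, min_tss=5)
        assert not bool(out["is_cell"].iloc[0])

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        qc = self.qc(rng.integers(10, 5000, 200), rng.uniform(0, 20, 200))
        kept = [
            call_cells(qc, min_fragments=f, min_tss=t)["is_cell"].sum()
            for f, t in [(100, 2), (1000, 2), (1000, 7), (2000, 10)]
        ]
        assert kept == sorted(kept, reverse=True)


class TestPipeline:
    def test_planted_cells_recovered_exactly(self, genome):
        cfg = SynthConfig(seed=23, n_cells=40, n_background_barcodes=400)
        frags, truth = make_fragments(cfg, genome)
        qc, _ = compute_qc(frags, genome["tss"], genome["peaks"],
                           min_fragments=1000, min_tss=5)
        called = set(qc.index[qc["is_cell"]])
        planted = set(truth.loc[truth["is_cell"], "barcode"])
        assert called == planted

    def test_metrics_in_range_and_duplication_regime(self, genome):
        """Generator set for mean multiplicity 4 -> ~75% duplication; the
        observed aggregate rate is within 3 delta-method sigma."""
        cfg = SynthConfig(seed=24, n_cells=30, n_background_barcodes=100)
        frags, _ = make_fragments(cfg, genome)
        qc, _ = compute_qc(frags, genome["tss"], genome["peaks"])
        assert ((qc["duplication_rate"] >= 0) & (qc["duplication_rate"] <= 1)).all()
        assert ((qc["frip"] >= 0) & (qc["frip"] <= 1)).all()
        assert (qc["tss_enrichment"].dropna() >= 0).all()
        cells = qc[qc.index.str.startswith("CELL")]
        n = int(cells["unique_fragments"].sum())
        agg_dup = 1 - n / cells["total_read_pairs"].sum()
        mu = cfg.duplication_mean
        sigma = np.sqrt(mu * (mu - 1) / n) / mu**2  # delta method on 1 - n/T
        assert abs(agg_dup - (1 - 1 / mu)) < 3 * sigma

    def test_metrics_invariant_under_row_permutation(self, genome):
        cfg = SynthConfig(seed=25, n_cells=5, n_background_barcodes=20,
                          n_frags_per_cell=300)
        frags, _ = make_fragments(cfg, genome)
        qc1, _ = compute_qc(frags, genome["tss"], genome["peaks"])
        shuffled = frags.sample(frac=1.0, random_state=1).reset_index(drop=True)
        qc2, _ = compute_qc(shuffled, genome["tss"], genome["peaks"])
        pd.testing.assert_frame_equal(qc1.sort_index(), qc2.sort_index())
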