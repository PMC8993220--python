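"""Per-barcode scATAC-seq QC metrics from fragments files.

A fragments file is the standard BED-like scATAC intermediate: one row per
sequenced fragment with ``chrom, start, end, barcode, count`` where
``count`` is the PCR duplicate multiplicity of the distinct
``(chrom, start, end)`` interval for that barcode.  Coordinates are 0-based
half-open throughout; the Tn5 +4/-5 shift is assumed already applied
upstream and is not re-applied.

Metrics
-------
duplication rate
    ``1 - unique_fragments / total_read_pairs`` per barcode.
TSS enrichment
    Tn5 insertion sites (both fragment ends) are binned at single-bp
    resolution in a strand-oriented window around each transcription start
    site; the score is the smoothed insertion depth at the TSS divided by
    the mean depth over the two outermost flank windows — a per-cell
    signal-to-noise ratio that is ~1 for background barcodes.
FRIP
    Fraction of a barcode's unique fragments overlapping (>= 1 bp) any
    peak, after merging the peak set.

Cell calling applies explicit thresholds on unique fragments and TSS
enrichment (inclusive bounds); thresholds are never auto-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "FragmentRecord",
    "duplication_rate",
    "tss_enrichment",
    "frip",
    "call_cells",
    "compute_qc",
    "unique_fragments",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass(frozen=True)
class FragmentRecord:
    """One deduplicatable ATAC fragment: half-open interval + barcode +
    duplicate multiplicity."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _as_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        missing = set(FRAGMENT_COLUMNS) - set(fragments.columns)
        if missing:
            raise ValueError(f"fragments frame missing columns {sorted(missing)}")
        return fragments
    rows = [(f.chrom, f.start, f.end, f.barcode, f.count) for f in fragments]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _dedupe(frags: pd.DataFrame) -> pd.DataFrame:
    """Collapse to distinct (barcode, chrom, start, end), summing counts."""
    return (
        frags.groupby(["barcode", "chrom", "start", "end"], sort=False, observed=True)[
            "count"
        ]
        .sum()
        .reset_index()
    )


def unique_fragments(fragments) -> pd.Series:
    """Number of distinct (chrom, start, end) intervals per barcode."""
    uniq = _dedupe(_as_frame(fragments))
    return uniq.groupby("barcode", observed=True).size()


def duplication_rate(fragments) -> pd.Series:
    """Per-barcode duplication rate: 1 - distinct intervals / total read
    pairs (the sum of duplicate multiplicities).

    Barcodes absent from the input are simply absent from the result (a
    rate for an empty barcode is undefined, not 0).
    """
    uniq = _dedupe(_as_frame(fragments))
    grouped = uniq.groupby("barcode", observed=True)
    n_unique = grouped.size()
    total = grouped["count"].sum()
    return (1.0 - n_unique / total).rename("duplication_rate")


def _merge_intervals(bed: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge possibly-overlapping intervals; returns per-chrom sorted
    (starts, ends) arrays of disjoint intervals."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in bed.groupby("chrom", observed=True):
        ivals = sub[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivals:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def frip(fragments, peaks: pd.DataFrame) -> pd.Series:
    """Fraction of unique fragments overlapping >= 1 bp of any peak.

    ``peaks`` is a BED-like frame (chrom, start, end); overlapping peaks
    are merged internally.  Half-open interval semantics: fragment
    ``[s, e)`` overlaps peak ``[ps, pe)`` iff ``s < pe and ps < e``.
    """
    uniq = _dedupe(_as_frame(fragments))
    merged = _merge_intervals(peaks)
    in_peak = np.zeros(len(uniq), dtype=bool)
    for chrom, idx in uniq.groupby("chrom", observed=True).groups.items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        s = uniq.loc[idx, "start"].to_numpy()
        e = uniq.loc[idx, "end"].to_numpy()
        # rightmost merged peak starting before the fragment end; disjoint
        # sorted peaks make this the only overlap candidate
        i = np.searchsorted(starts, e, side="left") - 1
        ok = i >= 0
        hit = np.zeros(len(s), dtype=bool)
        hit[ok] = ends[i[ok]] > s[ok]
        in_peak[uniq.index.get_indexer(idx)] = hit
    uniq = uniq.assign(in_peak=in_peak)
    grouped = uniq.groupby("barcode", observed=True)
    return (grouped["in_peak"].sum() / grouped.size()).rename("frip")


def tss_enrichment(
    fragments,
    tss_sites: pd.DataFrame,
    window: int = 2000,
    flank: int = 100,
    smooth: int = 51,
) -> tuple[pd.Series, pd.Series]:
    """Per-barcode TSS enrichment score and the barcode-summed profile.

    Parameters
    ----------
    tss_sites : DataFrame
        BED-like with columns ``chrom, start`` (TSS position) and optional
        ``strand``; minus-strand sites are flipped so the profile is
        transcription-oriented.
    window : int
        Half-width in bp of the profile around each TSS (default 2000).
    flank : int
        Width in bp of the two outermost background windows (default 100).
    smooth : int
        Moving-average width in bp applied before reading off the center
        depth (default 51).

    Returns
    -------
    scores : Series indexed by barcode
        Smoothed center depth / mean flank depth; NaN when a barcode has no
        flank coverage (never infinite).
    profile : Series indexed by offset (-window..window)
        Aggregate unsmoothed insertion counts summed over barcodes.
    """
    if tss_sites.empty:
        raise ValueError("TSS set must be nonempty")
    uniq = _dedupe(_as_frame(fragments))
    barcodes = pd.Index(uniq["barcode"].unique())
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    width = 2 * window + 1
    mat = np.zeros((len(barcodes), width), dtype=np.int64)

    strands = (
        tss_sites["strand"] if "strand" in tss_sites.columns else pd.Series("+", index=tss_sites.index)
    )
    for chrom, sub in uniq.groupby("chrom", observed=True):
        sites = tss_sites[tss_sites["chrom"] == chrom]
        if sites.empty:
            continue
        # both fragment ends are Tn5 insertion sites ([s, e) -> s and e-1)
        pos = np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy() - 1])
        bcs = np.concatenate([sub["barcode"].map(bc_idx).to_numpy()] * 2)
        order = np.argsort(pos, kind="stable")
        pos, bcs = pos[order], bcs[order]
        for t, strand in zip(sites["start"].to_numpy(), strands.loc[sites.index]):
            lo = np.searchsorted(pos, t - window, side="left")
            hi = np.searchsorted(pos, t + window, side="right")
            if lo == hi:
                continue
            offsets = pos[lo:hi] - t
            if strand == "-":
                offsets = -offsets
            np.add.at(mat, (bcs[lo:hi], offsets + window), 1)

    smoothed = uniform_filter1d(mat.astype(float), size=smooth, axis=1, mode="nearest")
    center = smoothed[:, window]
    flank_depth = np.concatenate([mat[:, :flank], mat[:, -flank:]], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(flank_depth > 0, center / flank_depth, np.nan)
    score_series = pd.Series(scores, index=barcodes, name="tss_enrichment")
    profile = pd.Series(
        mat.sum(axis=0), index=pd.RangeIndex(-window, window + 1), name="insertions"
    )
    profile.index.name = "offset"
    return score_series, profile


def call_cells(
    qc: pd.DataFrame, min_fragments: int = 1000, min_tss: float = 5.0
) -> pd.DataFrame:
    """Flag barcodes as cells: ``unique_fragments >= min_fragments`` and
    ``tss_enrichment >= min_tss`` (inclusive bounds; NaN scores fail)."""
    is_cell = (qc["unique_fragments"] >= min_fragments) & (
        qc["tss_enrichment"] >= min_tss
    )
    return qc.assign(is_cell=is_cell.fillna(False))


def compute_qc(
    fragments,
    tss_sites: pd.DataFrame,
    peaks: pd.DataFrame | None = None,
    window: int = 2000,
    flank: int = 100,
    smooth: int = 51,
    min_fragments: int = 1000,
    min_tss: float = 5.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full per-barcode QC table plus the aggregate TSS profile.

    Returns a frame indexed by barcode with columns ``unique_fragments,
    total_read_pairs, duplication_rate, tss_enrichment, frip, is_cell``
    (``frip`` is NaN when no peaks are given).
    """
    frags = _as_frame(fragments)
    uniq = _dedupe(frags)
    grouped = uniq.groupby("barcode", observed=True)
    qc = pd.DataFrame(
        {
            "unique_fragments": grouped.size(),
            "total_read_pairs": grouped["count"].sum(),
        }
    )
    qc["duplication_rate"] = 1.0 - qc["unique_fragments"] / qc["total_read_pairs"]
    scores, profile = tss_enrichment(frags, tss_sites, window, flank, smooth)
    qc["tss_enrichment"] = scores
    qc["frip"] = frip(frags, peaks) if peaks is not None else np.nan
    qc = call_cells(qc, min_fragments=min_fragments, min_tss=min_tss)
    qc.index.name = "barcode"
    return qc, profile
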