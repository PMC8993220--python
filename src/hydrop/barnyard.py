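"""Species-mixing (barnyard) classification of barcodes.

In a deliberate two-species mixture, a barcode capturing material from a
single cell should map almost exclusively to one genome; barcodes with
substantial counts from both genomes indicate droplet doublets or barcode
mixing.  Each barcode is classified from its per-species unique-fragment
(ATAC) or UMI (RNA) counts: below a minimal total it is ``low_signal``;
otherwise it is called for the majority species when the majority fraction
(purity) reaches the threshold (>= , non-strict; default 0.95), else
``doublet``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

__all__ = ["BarnyardCall", "classify_species", "classify_table", "barnyard_summary"]

LOW_SIGNAL = "low_signal"
DOUBLET = "doublet"


@dataclass(frozen=True)
class BarnyardCall:
    """Classification of one barcode in a two-species mixture."""

    barcode: str
    label: str  # species A name | species B name | "doublet" | "low_signal"
    purity: float  # max species fraction; NaN when total == 0
    total: int


def classify_species(
    counts: dict[str, int],
    barcode: str = "",
    purity_threshold: float = 0.95,
    min_total: int = 1000,
) -> BarnyardCall:
    """Classify one barcode from its two per-species counts.

    The design is strictly pairwise: more than two species labels is an
    error.  ``purity`` is the larger species fraction (in [0.5, 1] whenever
    the total is positive).
    """
    if len(counts) != 2:
        raise ValueError(f"expected exactly two species labels, got {sorted(counts)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("species counts must be nonnegative")
    total = sum(counts.values())
    if total == 0:
        return BarnyardCall(barcode, LOW_SIGNAL, float("nan"), 0)
    top_species = max(sorted(counts), key=counts.__getitem__)
    purity = counts[top_species] / total
    if total < min_total:
        label = LOW_SIGNAL
    elif purity >= purity_threshold:
        label = top_species
    else:
        label = DOUBLET
    return BarnyardCall(barcode, label, purity, total)


def classify_table(
    counts: pd.DataFrame,
    purity_threshold: float = 0.95,
    min_total: int = 1000,
) -> pd.DataFrame:
    """Vectorised classification of a per-barcode species-count table.

    ``counts`` is indexed by barcode with exactly two count columns (one per
    species).  Returns a frame with ``label``, ``purity`` and ``total``.
    """
    if counts.shape[1] != 2:
        raise ValueError(
            f"expected exactly two species columns, got {list(counts.columns)}"
        )
    a, b = counts.columns
    total = counts[a] + counts[b]
    purity = counts[[a, b]].max(axis=1) / total
    top = counts[[a, b]].idxmax(axis=1)
    label = top.where(purity >= purity_threshold, DOUBLET)
    label = label.mask((total < min_total) | (total == 0), LOW_SIGNAL)
    out = pd.DataFrame({"label": label, "purity": purity, "total": total})
    out.index.name = "barcode"
    return out


def barnyard_summary(calls: pd.DataFrame) -> dict:
    """Tallies of pure-species cells and doublets plus the observed doublet
    rate ``doublets / (pure + doublets)`` (low-signal barcodes excluded)."""
    labels = calls["label"]
    species = sorted(set(labels) - {DOUBLET, LOW_SIGNAL})
    per_species = {s: int((labels == s).sum()) for s in species}
    n_doublet = int((labels == DOUBLET).sum())
    n_pure = sum(per_species.values())
    denom = n_pure + n_doublet
    return {
        "pure_counts": per_species,
        "n_pure": n_pure,
        "n_doublets": n_doublet,
        "n_low_signal": int((labels == LOW_SIGNAL).sum()),
        "doublet_rate": (n_doublet / denom) if denom else float("nan"),
    }


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
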