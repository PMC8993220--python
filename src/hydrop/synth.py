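"""Synthetic fixtures with ground truth for every pipeline stage.

Every generator takes an explicit seed (one PRNG stream per call) and
returns a machine-readable truth table next to its primary output, so each
downstream metric can be validated against planted values without any
reference download.  The emulated regimes follow the assay's observed data:
a 3 x 96-well split-pool barcode space, per-base substitution errors plus a
~9% frameshifted/garbage read fraction in the barcode read, TSS-enriched
fragment libraries sequenced to ~75% duplication, 50:50 two-species
mixtures with a small doublet fraction, and bead images where ~1/96 of
beads fluoresce for a single sub-barcode probe.

The synthetic "genome" is a couple of named toy chromosomes (<= 1 Mb
total) with evenly spaced TSSs; read-level sequence content (transcript
and genome sequence, quality modelling) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode import BarcodeStructure, BarcodeWhitelist, Segment, SubBarcodePlate

__all__ = [
    "SynthConfig",
    "default_structure",
    "make_plates",
    "make_barcode_fastq",
    "toy_genome",
    "make_fragments",
    "make_barnyard",
    "make_bead_images",
    "make_gene_assignments",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# placeholder inter-sub-barcode adapters (the real chemistry's linkers are a
# user config input); fixed so defaults are reproducible
DEFAULT_LINKERS = ("GTGACGCTAC", "CCTAGTCGAA")


@dataclass
class SynthConfig:
    """Study conditions for all generators.  All rates are in [0, 1]; the
    seed fully determines every output."""

    seed: int = 0
    # barcode reads
    n_cells: int = 200
    reads_per_cell: int = 100
    substitution_rate: float = 0.01
    frameshift_fraction: float = 0.09
    # fragments
    n_frags_per_cell: int = 2000
    n_background_barcodes: int = 2000
    frags_per_background: int = 30
    tss_signal_fraction: float = 0.45  # lambda: fraction of TSS-proximal insertions
    tss_sigma: float = 75.0  # bp spread of TSS-proximal insertion points
    duplication_mean: float = 4.0  # mean duplicate multiplicity (4 -> ~75% dup)
    # barnyard
    species_mix: tuple[float, float] = (0.5, 0.5)
    doublet_fraction: float = 0.05
    cross_contamination: float = 0.005
    mean_counts_per_cell: int = 5000
    species_names: tuple[str, str] = ("human", "mouse")
    # RNA assignments
    n_genes: int = 200
    transcripts_per_cell: int = 1000
    mapped_fraction: float = 0.55
    rna_duplication_mean: float = 2.5
    mito_expression_fraction: float = 0.005
    # beads
    n_beads: int = 960
    positive_probability: float = 1.0 / 96.0
    bead_radius_px: int = 9
    noise_sigma: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "frameshift_fraction",
            "tss_signal_fraction",
            "doublet_fraction",
            "cross_contamination",
            "positive_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


def default_structure(
    n_rounds: int = 3,
    sub_length: int = 10,
    linkers: tuple[str, ...] = DEFAULT_LINKERS,
    umi_length: int = 0,
) -> BarcodeStructure:
    """The default barcode-read layout: sub-barcode blocks separated by
    fixed linkers, optionally followed by a UMI (RNA design)."""
    if len(linkers) < n_rounds - 1:
        raise ValueError("need a linker between every pair of rounds")
    blocks: list[Segment] = []
    for r in range(1, n_rounds + 1):
        blocks.append(Segment.subbarcode(r, sub_length))
        if r < n_rounds:
            blocks.append(Segment.linker(linkers[r - 1]))
    if umi_length:
        blocks.append(Segment.umi(umi_length))
    return BarcodeStructure(tuple(blocks))


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    arr = rng.integers(0, 4, size=(n, length))
    return ["".join("ACGT"[b] for b in row) for row in arr]


def make_plates(
    n_rounds: int,
    n_wells: int,
    length: int,
    min_distance: int = 3,
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[SubBarcodePlate]:
    """Random sub-barcode plates with guaranteed pairwise Hamming distance
    >= ``min_distance`` within each plate (greedy rejection sampling)."""
    if min_distance > length:
        raise ValueError("min_distance cannot exceed sequence length")
    rng = np.random.default_rng((seed, 101))
    plates = []
    for r in range(1, n_rounds + 1):
        chosen: list[np.ndarray] = []
        tries = 0
        while len(chosen) < n_wells:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {n_wells} sequences of length {length} at "
                    f"min distance {min_distance} within {max_tries} tries"
                )
            cand = rng.integers(0, 4, size=length)
            if all((cand != c).sum() >= min_distance for c in chosen):
                chosen.append(cand)
        seqs = tuple("".join("ACGT"[b] for b in row) for row in chosen)
        plates.append(SubBarcodePlate(round_index=r, sequences=seqs))
    return plates


def make_barcode_fastq(
    config: SynthConfig,
    structure: BarcodeStructure,
    whitelist: BarcodeWhitelist,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate barcode reads with substitution errors and frameshifts.

    Per read: a true cell barcode is expanded into the full read layout
    (sub-barcodes, clean linkers, random UMI); substitutions are injected
    i.i.d. per base *within the sub-barcode blocks* (so assignment-tier
    statistics follow a Binomial(barcode_length, rate) law exactly); with
    probability ``frameshift_fraction`` one random base of the read is then
    deleted and a random base appended, emulating an oligo synthesis
    frameshift.

    Returns ``(reads, truth)`` where reads are ``(name, sequence, quality)``
    records and truth has one row per read: ``read, true_barcode,
    n_errors, frameshifted``.
    """
    rng = config.rng(salt=202)
    n_reads = config.n_cells * config.reads_per_cell
    cell_barcodes = rng.choice(
        np.asarray(whitelist.barcodes, dtype=object),
        size=config.n_cells,
        replace=False,
    )
    sub_slices = []
    offset = 0
    for length in whitelist.block_lengths:
        sub_slices.append((offset, offset + length))
        offset += length

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    bc_len = whitelist.barcode_length
    for i in range(n_reads):
        true_bc = str(cell_barcodes[i % config.n_cells])
        subs = whitelist.decompose(true_bc)
        # inject substitutions into the concatenated barcode
        n_err = 0
        bc_chars = list(true_bc)
        err_mask = rng.random(bc_len) < config.substitution_rate
        for p in np.flatnonzero(err_mask):
            bc_chars[p] = "ACGT"[(("ACGT".index(bc_chars[p])) + rng.integers(1, 4)) % 4]
            n_err += 1
        mutated = "".join(bc_chars)
        mut_subs = [mutated[s:e] for s, e in sub_slices]
        # assemble the full read
        parts = []
        sub_i = 0
        umi = None
        for block in structure.blocks:
            if block.kind == "subbarcode":
                parts.append(mut_subs[sub_i])
                sub_i += 1
            elif block.kind == "linker":
                parts.append(block.sequence)
            else:
                umi = "".join("ACGT"[b] for b in rng.integers(0, 4, size=block.length))
                parts.append(umi)
        seq = "".join(parts)
        frameshifted = bool(rng.random() < config.frameshift_fraction)
        if frameshifted:
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + seq[pos + 1 :] + "ACGT"[rng.integers(0, 4)]
        name = f"read{i:07d}"
        reads.append((name, seq, "I" * len(seq)))
        truth_rows.append((name, true_bc, n_err, frameshifted))
    truth = pd.DataFrame(
        truth_rows, columns=["read", "true_barcode", "n_errors", "frameshifted"]
    )
    return reads, truth


def toy_genome(
    n_chroms: int = 2,
    chrom_size: int = 500_000,
    tss_per_chrom: int = 100,
    peak_halfwidth: int = 250,
) -> dict:
    """A tiny named genome model: chrom sizes, evenly spaced TSSs
    (alternating strand) and peaks centered on each TSS."""
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chroms)}
    tss_rows, peak_rows = [], []
    spacing = chrom_size // (tss_per_chrom + 1)
    for chrom in chrom_sizes:
        for j in range(tss_per_chrom):
            pos = (j + 1) * spacing
            tss_rows.append((chrom, pos, "+" if j % 2 == 0 else "-"))
            peak_rows.append((chrom, pos - peak_halfwidth, pos + peak_halfwidth))
    return {
        "chrom_sizes": chrom_sizes,
        "tss": pd.DataFrame(tss_rows, columns=["chrom", "start", "strand"]),
        "peaks": pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]),
    }


def make_fragments(
    config: SynthConfig, genome: dict | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a fragments table of planted cells over diffuse background.

    Cells place a fraction lambda (``tss_signal_fraction``) of their Tn5
    insertion points at Normal(TSS, ``tss_sigma``) and the rest uniformly;
    a fragment extends from its insertion point by a typical ATAC insert
    length (uniform 80-140 bp).  Duplicate multiplicities are geometric
    with mean ``duplication_mean`` (mean 4 gives an expected ~75%
    duplication rate, since E[dup] ~ 1 - 1/mean).  Background barcodes
    place few fragments, all uniform.

    Returns ``(fragments, truth)``; truth has one row per barcode with
    ``barcode, is_cell, n_fragments``.
    """
    if genome is None:
        genome = toy_genome()
    rng = config.rng(salt=303)
    chroms = list(genome["chrom_sizes"])
    sizes = np.array([genome["chrom_sizes"][c] for c in chroms])
    total_size = sizes.sum()
    tss = genome["tss"]
    tss_by_chrom = {c: g["start"].to_numpy() for c, g in tss.groupby("chrom")}

    rows = []
    truth_rows = []
    geo_p = 1.0 / config.duplication_mean

    def _uniform_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
        ci = rng.choice(len(chroms), size=n, p=sizes / total_size)
        pos = rng.integers(0, sizes[ci] - 200)
        return ci, pos

    def _emit(barcode: str, n_frags: int, lam: float) -> None:
        n_tssward = rng.binomial(n_frags, lam)
        n_uniform = n_frags - n_tssward
        lengths = rng.integers(80, 141, size=n_frags)
        starts = np.empty(n_frags, dtype=np.int64)
        chrom_idx = np.empty(n_frags, dtype=np.int64)
        if n_tssward:
            ci = rng.choice(len(chroms), size=n_tssward, p=sizes / total_size)
            for k in range(n_tssward):
                sites = tss_by_chrom[chroms[ci[k]]]
                t = sites[rng.integers(0, len(sites))]
                starts[k] = int(t + rng.normal(0.0, config.tss_sigma))
            chrom_idx[:n_tssward] = ci
        if n_uniform:
            ci, pos = _uniform_positions(n_uniform)
            chrom_idx[n_tssward:] = ci
            starts[n_tssward:] = pos
        starts = np.clip(starts, 0, sizes[chrom_idx] - 200)
        counts = rng.geometric(geo_p, size=n_frags)
        for k in range(n_frags):
            rows.append(
                (
                    chroms[chrom_idx[k]],
                    int(starts[k]),
                    int(starts[k] + lengths[k]),
                    barcode,
                    int(counts[k]),
                )
            )

    for i in range(config.n_cells):
        bc = f"CELL{i:05d}"
        _emit(bc, config.n_frags_per_cell, config.tss_signal_fraction)
        truth_rows.append((bc, True, config.n_frags_per_cell))
    for i in range(config.n_background_barcodes):
        bc = f"BG{i:06d}"
        n = max(1, int(rng.poisson(config.frags_per_background)))
        _emit(bc, n, 0.0)
        truth_rows.append((bc, False, n))

    fragments = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "barcode", "count"]
    )
    truth = pd.DataFrame(truth_rows, columns=["barcode", "is_cell", "n_fragments"])
    return fragments, truth


def make_barnyard(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-species per-barcode count table.

    Pure cells draw their species by ``species_mix`` and leak a small
    ``cross_contamination`` fraction of counts to the other genome;
    doublets (fraction ``doublet_fraction``) split counts between genomes
    at a Beta(20, 20) ratio, which keeps their majority fraction well below
    any sensible purity threshold.

    Returns ``(counts, truth)``: counts indexed by barcode with one column
    per species; truth carries the planted label.
    """
    rng = config.rng(salt=404)
    a, b = config.species_names
    rows, truth_rows = [], []
    for i in range(config.n_cells):
        bc = f"BC{i:05d}"
        total = max(1, int(rng.poisson(config.mean_counts_per_cell)))
        if rng.random() < config.doublet_fraction:
            share = rng.beta(20, 20)
            ca = rng.binomial(total, share)
            rows.append((bc, ca, total - ca))
            truth_rows.append((bc, "doublet"))
        else:
            own = a if rng.random() < config.species_mix[0] else b
            leaked = rng.binomial(total, config.cross_contamination)
            ca = (total - leaked) if own == a else leaked
            rows.append((bc, ca, total - ca))
            truth_rows.append((bc, own))
    counts = pd.DataFrame(rows, columns=["barcode", a, b]).set_index("barcode")
    truth = pd.DataFrame(truth_rows, columns=["barcode", "label"]).set_index("barcode")
    return counts, truth


def make_gene_assignments(
    config: SynthConfig, umi_length: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Simulate a read-to-gene assignment table with PCR duplication.

    Per cell, per-gene molecule counts are Poisson with a small
    ``mito_expression_fraction`` of expression routed to a mitochondrial
    gene (named with the ``mt-`` prefix); each molecule carries a random
    UMI and is sequenced ``Geometric(1/rna_duplication_mean)`` times.
    Reads failing to map to a gene are emitted with ``mapped_ok=False`` so
    the mapped fraction is ``mapped_fraction``.

    Returns ``(assignments, truth, total_reads)``: truth has one row per
    distinct generated (barcode, gene, umi) molecule, so the ground-truth
    count matrix is its (barcode, gene) tally — exact even under UMI
    collisions.
    """
    rng = config.rng(salt=606)
    genes = [f"GENE{j:04d}" for j in range(config.n_genes - 1)] + ["mt-ND1"]
    rows = []
    molecule_rows = []
    per_gene_mean = np.full(config.n_genes, 1.0 - config.mito_expression_fraction)
    per_gene_mean /= config.n_genes - 1
    per_gene_mean[-1] = config.mito_expression_fraction
    per_gene_mean *= config.transcripts_per_cell
    geo_p = 1.0 / config.rna_duplication_mean
    for i in range(config.n_cells):
        bc = f"BC{i:05d}"
        n_mol = rng.poisson(per_gene_mean)
        for j in np.flatnonzero(n_mol):
            for _ in range(int(n_mol[j])):
                umi = "".join("ACGT"[b] for b in rng.integers(0, 4, size=umi_length))
                dup = int(rng.geometric(geo_p))
                rows.extend([(bc, umi, genes[j], True)] * dup)
                molecule_rows.append((bc, genes[j], umi))
    # pad with unmapped reads to hit the target mapped fraction
    n_mapped = len(rows)
    n_unmapped = int(round(n_mapped * (1.0 - config.mapped_fraction) / config.mapped_fraction))
    for k in range(n_unmapped):
        rows.append((f"BC{int(rng.integers(0, config.n_cells)):05d}", "", "", False))
    assignments = pd.DataFrame(rows, columns=["barcode", "umi", "gene_id", "mapped_ok"])
    truth = pd.DataFrame(
        molecule_rows, columns=["barcode", "gene_id", "umi"]
    ).drop_duplicates()
    return assignments, truth, len(rows)


def make_bead_images(
    config: SynthConfig,
    positive_level: int = 150,
    negative_level: int = 20,
    brightfield_level: int = 160,
    brightfield_background: int = 40,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a fluorescence/brightfield image pair of non-overlapping beads.

    Beads sit on a jittered grid.  In fluorescence, probe-positive beads
    (per-bead probability ``positive_probability``) are bright plateaus and
    negatives stay at background; in brightfield every bead is visible.
    Gaussian noise of sd ``noise_sigma`` is added to both 8-bit images.

    Returns ``(fluorescence, brightfield, truth)`` with truth rows
    ``row, col, radius, positive``.
    """
    rng = config.rng(salt=505)
    r = config.bead_radius_px
    pitch = int(2 * r + 8)
    n_cols = int(np.ceil(np.sqrt(config.n_beads)))
    n_rows = int(np.ceil(config.n_beads / n_cols))
    h = n_rows * pitch + pitch
    w = n_cols * pitch + pitch
    fluo = np.full((h, w), float(negative_level))
    bright = np.full((h, w), float(brightfield_background))

    positive = rng.random(config.n_beads) < config.positive_probability
    jitter_max = max(1, (pitch - 2 * r) // 2 - 1)
    truth_rows = []
    yy, xx = np.ogrid[: 2 * r + 1, : 2 * r + 1]
    disc = (yy - r) ** 2 + (xx - r) ** 2 <= r**2
    k = 0
    for gy in range(n_rows):
        for gx in range(n_cols):
            if k >= config.n_beads:
                break
            cy = pitch + gy * pitch + int(rng.integers(-jitter_max, jitter_max + 1))
            cx = pitch + gx * pitch + int(rng.integers(-jitter_max, jitter_max + 1))
            sl = (slice(cy - r, cy + r + 1), slice(cx - r, cx + r + 1))
            bright[sl][disc] = brightfield_level
            if positive[k]:
                fluo[sl][disc] = positive_level
            truth_rows.append((cy, cx, r, bool(positive[k])))
            k += 1

    if config.noise_sigma > 0:
        fluo = fluo + rng.normal(0.0, config.noise_sigma, fluo.shape)
        bright = bright + rng.normal(0.0, config.noise_sigma, bright.shape)
    fluo = np.clip(np.rint(fluo), 0, 255).astype(np.uint8)
    bright = np.clip(np.rint(bright), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(truth_rows, columns=["row", "col", "radius", "positive"])
    return fluo, bright, truth
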