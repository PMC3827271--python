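"""Frequency-spectrum summary statistics and their binned, flattened form.

The kernel-ABC step consumes a fixed-length vector of counts.  For autosomal
multi-locus data that vector concatenates, in frozen order: the brown-bear
SFS (binned), the polar-bear SFS (binned), and the two-dimensional haplotype
frequency spectrum (2D-HFS, row-major over binned axes with excluded cells
dropped).  For mtDNA the vector is a single binned 2D-SFS block over (derived
copies in brown bears, derived copies in polar bears).

Bin counts follow Sturges' rule, round(1 + log2(x)), and the default interval
layouts are: derived-allele bins 1-4, 5-8, 9-12, 13-16, 17-20, 21-24, 25-28,
29-36 (the last bin is wider) and haplotype-count bins 0, 1-6, 7-12, 13-18,
19-24, 25-30, 31-36, with the (0, 0) cell of the 2D-HFS excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import HaplotypeMatrix, LocusSet

__all__ = [
    "BinSpec",
    "SummaryVector",
    "sfs",
    "joint_sfs",
    "joint_hfs",
    "sturges_bins",
    "bin_and_flatten",
    "summarize_dataset",
    "adna_default_binspec",
    "mtdna_binspec",
]


def sturges_bins(x: int) -> int:
    """Sturges' rule: nearest integer to 1 + log2(x), ties rounding up."""
    if x < 1:
        raise ValueError("Sturges' formula needs x >= 1")
    return int(math.floor(1.0 + math.log2(x) + 0.5))


@dataclass(frozen=True)
class BinSpec:
    """Binning layout for one summary-vector flavour.

    ``mode`` is ``"aDNA"`` (SFS_uar | SFS_uma | 2D-HFS blocks) or ``"mtDNA"``
    (single 2D-SFS block).  Intervals are inclusive integer ranges on the
    attainable frequency axis; ``*_excluded`` lists cells in bin coordinates.
    """

    mode: str
    sfs_intervals: tuple[tuple[int, int], ...] = ()
    hfs_intervals: tuple[tuple[int, int], ...] = ()
    hfs_excluded: tuple[tuple[int, int], ...] = ()
    sfs2d_row_intervals: tuple[tuple[int, int], ...] = ()
    sfs2d_col_intervals: tuple[tuple[int, int], ...] = ()
    sfs2d_excluded: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("aDNA", "mtDNA"):
            raise ValueError(f"unknown binspec mode {self.mode!r}")
        for ivals in (self.sfs_intervals, self.hfs_intervals,
                      self.sfs2d_row_intervals, self.sfs2d_col_intervals):
            for (lo, hi) in ivals:
                if lo > hi:
                    raise ValueError("interval lower bound exceeds upper bound")

    @property
    def dimension(self) -> int:
        if self.mode == "aDNA":
            h = len(self.hfs_intervals)
            return (2 * len(self.sfs_intervals)
                    + h * h - len(self.hfs_excluded))
        r, c = len(self.sfs2d_row_intervals), len(self.sfs2d_col_intervals)
        return r * c - len(self.sfs2d_excluded)

    @property
    def blocks(self) -> tuple[tuple[str, int], ...]:
        if self.mode == "aDNA":
            k = len(self.sfs_intervals)
            h = len(self.hfs_intervals)
            return (("sfs_uar", k), ("sfs_uma", k),
                    ("hfs2d", h * h - len(self.hfs_excluded)))
        r, c = len(self.sfs2d_row_intervals), len(self.sfs2d_col_intervals)
        return (("sfs2d", r * c - len(self.sfs2d_excluded)),)


@dataclass
class SummaryVector:
    """Binned, flattened summary statistics (the s_i fed to the kernel)."""

    values: np.ndarray
    binspec: BinSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.binspec.dimension:
            raise ValueError("vector length must match the binspec dimension")
        if (self.values < 0).any():
            raise ValueError("summary counts must be non-negative")


def adna_default_binspec() -> BinSpec:
    """The 8 + 8 + 48 = 64-dimensional autosomal layout for 36+36 samples."""
    sfs = ((1, 4), (5, 8), (9, 12), (13, 16), (17, 20), (21, 24), (25, 28), (29, 36))
    hfs = ((0, 0), (1, 6), (7, 12), (13, 18), (19, 24), (25, 30), (31, 36))
    return BinSpec(mode="aDNA", sfs_intervals=sfs, hfs_intervals=hfs,
                   hfs_excluded=((0, 0),))


def mtdna_binspec(n_uar: int, n_uma: int,
                  col_intervals: tuple[tuple[int, int], ...] | None = None,
                  exclude_fixed: bool = False,
                  extra_excluded: tuple[tuple[int, int], ...] = ()) -> BinSpec:
    """2D-SFS layout for an mtDNA dataset.

    Rows are the full brown-bear spectrum 0..n_uar (one bin per count); the
    polar-bear axis is the full spectrum 0..n_uma unless ``col_intervals``
    supplies coarser bins.  Cell (0, 0) is always excluded; the fixed cell
    (n_uar, n_uma) is excluded when ``exclude_fixed``.  Further exclusions
    are configuration-driven because no closed rule reproduces every printed
    bin total.
    """
    rows = tuple((i, i) for i in range(n_uar + 1))
    cols = tuple((j, j) for j in range(n_uma + 1)) if col_intervals is None else tuple(col_intervals)
    excluded = {(0, 0)}
    if exclude_fixed:
        excluded.add((len(rows) - 1, len(cols) - 1))
    excluded.update(extra_excluded)
    return BinSpec(mode="mtDNA", sfs2d_row_intervals=rows, sfs2d_col_intervals=cols,
                   sfs2d_excluded=tuple(sorted(excluded)))


MTDNA_SET2_COL_INTERVALS = ((0, 0), (1, 3), (4, 6), (7, 9), (10, 12),
                            (13, 15), (16, 18), (19, 21), (22, 24), (25, 26))


# ---------------------------------------------------------------------------
# raw spectra

def _check_polarized(matrix: HaplotypeMatrix) -> None:
    if not matrix.polarized:
        raise ValueError("spectra require a polarized matrix")


def sfs(matrix: HaplotypeMatrix, population: str = "pooled") -> np.ndarray:
    """Site frequency spectrum xi_1..xi_n for the chosen population.

    ``xi_i`` is the number of sites whose derived allele is carried by exactly
    i chromosomes of that population; sites with zero derived copies there do
    not count.  Fixed-derived-flagged sites are excluded (they belong to the
    2D-SFS fixed cell only).
    """
    _check_polarized(matrix)
    if population == "uar":
        sub, n = matrix.uar, matrix.n_uar
    elif population == "uma":
        sub, n = matrix.uma, matrix.n_uma
    elif population == "pooled":
        sub, n = matrix.data, matrix.n_chromosomes
    else:
        raise ValueError(f"unknown population {population!r}")
    seg = ~matrix.fixed_derived
    counts = sub[seg].sum(axis=1)
    out = np.bincount(counts[counts > 0], minlength=n + 1)[1:n + 1]
    return out.astype(np.int64)


def joint_sfs(matrix: HaplotypeMatrix) -> np.ndarray:
    """2D-SFS: cell (i, j) counts sites with i derived copies in brown bears
    and j in polar bears.  Cell (0, 0) is structurally zero; fixed-derived
    sites (if flagged) land in (n_uar, n_uma)."""
    _check_polarized(matrix)
    out = np.zeros((matrix.n_uar + 1, matrix.n_uma + 1), dtype=np.int64)
    ci = matrix.uar.sum(axis=1)
    cj = matrix.uma.sum(axis=1)
    np.add.at(out, (ci, cj), 1)
    return out


def joint_hfs(locus_set: LocusSet) -> np.ndarray:
    """2D-HFS pooled across loci: each distinct haplotype at a locus adds one
    tally at (its copies among brown bears, its copies among polar bears)."""
    n_uar, n_uma = locus_set.n_uar, locus_set.n_uma
    out = np.zeros((n_uar + 1, n_uma + 1), dtype=np.int64)
    for matrix in locus_set.loci:
        _check_polarized(matrix)
        cols = matrix.data.T  # (chromosomes, sites)
        if matrix.n_sites == 0:
            out[n_uar, n_uma] += 1
            continue
        haplotypes: dict[bytes, list[int]] = {}
        for c in range(cols.shape[0]):
            key = cols[c].tobytes()
            tally = haplotypes.setdefault(key, [0, 0])
            tally[0 if c < n_uar else 1] += 1
        for (i, j) in haplotypes.values():
            out[i, j] += 1
    return out


# ---------------------------------------------------------------------------
# binning

def _bin_1d(raw: np.ndarray, intervals) -> np.ndarray:
    """raw[k] holds the count for frequency k+offset; intervals are inclusive
    frequency ranges.  Here raw is indexed by frequency directly."""
    return np.array([raw[lo:hi + 1].sum() for lo, hi in intervals], dtype=float)


def _bin_2d(table: np.ndarray, row_intervals, col_intervals, excluded) -> np.ndarray:
    binned = np.zeros((len(row_intervals), len(col_intervals)))
    for bi, (rlo, rhi) in enumerate(row_intervals):
        for bj, (clo, chi) in enumerate(col_intervals):
            binned[bi, bj] = table[rlo:rhi + 1, clo:chi + 1].sum()
    excluded = set(excluded)
    flat = [binned[bi, bj]
            for bi in range(len(row_intervals))
            for bj in range(len(col_intervals))
            if (bi, bj) not in excluded]
    return np.array(flat, dtype=float)


def bin_and_flatten(tables: dict[str, np.ndarray], binspec: BinSpec) -> SummaryVector:
    """Aggregate raw spectra into the fixed-order flattened vector.

    For aDNA, ``tables`` holds ``sfs_uar``/``sfs_uma`` (indexed by derived
    count 0..n) and ``hfs2d``; for mtDNA a single ``sfs2d`` table.
    """
    if binspec.mode == "aDNA":
        required = {"sfs_uar", "sfs_uma", "hfs2d"}
        if not required <= tables.keys():
            raise ValueError(f"aDNA summaries need tables {sorted(required)}")
        max_f = max(hi for _, hi in binspec.sfs_intervals)
        for key in ("sfs_uar", "sfs_uma"):
            if len(tables[key]) < max_f + 1:
                raise ValueError(f"{key} table shorter than the bin range")
        h = len(binspec.hfs_intervals)
        max_h = max(hi for _, hi in binspec.hfs_intervals)
        if tables["hfs2d"].shape[0] < max_h + 1 or tables["hfs2d"].shape[1] < max_h + 1:
            raise ValueError("hfs2d table smaller than the bin range")
        parts = [
            _bin_1d(tables["sfs_uar"], binspec.sfs_intervals),
            _bin_1d(tables["sfs_uma"], binspec.sfs_intervals),
            _bin_2d(tables["hfs2d"], binspec.hfs_intervals,
                    binspec.hfs_intervals, binspec.hfs_excluded),
        ]
        return SummaryVector(values=np.concatenate(parts), binspec=binspec)
    if "sfs2d" not in tables:
        raise ValueError("mtDNA summaries need an 'sfs2d' table")
    table = tables["sfs2d"]
    max_r = max(hi for _, hi in binspec.sfs2d_row_intervals)
    max_c = max(hi for _, hi in binspec.sfs2d_col_intervals)
    if table.shape[0] < max_r + 1 or table.shape[1] < max_c + 1:
        raise ValueError("sfs2d table smaller than the bin range")
    values = _bin_2d(table, binspec.sfs2d_row_intervals,
                     binspec.sfs2d_col_intervals, binspec.sfs2d_excluded)
    return SummaryVector(values=values, binspec=binspec)


def summarize_dataset(locus_set: LocusSet, binspec: BinSpec) -> SummaryVector:
    """Pool per-locus spectra across loci and bin into the summary vector."""
    n_uar, n_uma = locus_set.n_uar, locus_set.n_uma
    if binspec.mode == "aDNA":
        sfs_uar = np.zeros(n_uar + 1, dtype=np.int64)
        sfs_uma = np.zeros(n_uma + 1, dtype=np.int64)
        for matrix in locus_set.loci:
            sfs_uar[1:] += sfs(matrix, "uar")
            sfs_uma[1:] += sfs(matrix, "uma")
        tables = {
            "sfs_uar": sfs_uar,
            "sfs_uma": sfs_uma,
            "hfs2d": joint_hfs(locus_set),
        }
        return bin_and_flatten(tables, binspec)
    table = np.zeros((n_uar + 1, n_uma + 1), dtype=np.int64)
    for matrix in locus_set.loci:
        table += joint_sfs(matrix)
    return bin_and_flatten({"sfs2d": table}, binspec)
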