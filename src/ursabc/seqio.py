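"""Alignment I/O, outgroup polarization, and infinite-sites editing.

Sequence data enter as pre-aligned multi-FASTA with population labels for
brown bears (``uar``), polar bears (``uma``), and outgroups (a distant
``outg_panda`` and a pair of closer ``outg_blackbear`` sequences).  Sites are
polarized into ancestral (0) / derived (1) states against the outgroups, and
recurrent mutation is detected with the four-gamete test: two biallelic sites
showing all four haplotypes 00/01/10/11 cannot both fit a single
non-recombining genealogy under infinite sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "HaplotypeMatrix",
    "LocusSet",
    "read_alignment",
    "write_alignment",
    "read_popmap",
    "infer_populations",
    "polarize_sites",
    "four_gamete_scan",
    "build_mtdna_sets",
]

INGROUP_POPS = ("uar", "uma")
VALID_POPS = ("uar", "uma", "outg_panda", "outg_blackbear")
_ACGT = frozenset(b"ACGT")


@dataclass
class Alignment:
    """Equal-length nucleotide sequences with one population label each.

    ``positions`` are 1-based alignment coordinates, kept so that edited
    alignments (columns removed) remember their original coordinates.
    """

    ids: list[str]
    populations: list[str]
    sequences: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences} or {0}) > 1:
            raise ValueError("sequences must be equal length")
        if len(self.ids) != len(self.sequences) or len(self.ids) != len(self.populations):
            raise ValueError("ids, populations, sequences must align")
        for pop in self.populations:
            if pop not in VALID_POPS:
                raise ValueError(f"unknown population label {pop!r}")
        if self.positions is None:
            self.positions = np.arange(1, self.length + 1, dtype=np.int64)
        else:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if len(self.positions) != self.length:
                raise ValueError("positions must match alignment length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def indices(self, *pops: str) -> list[int]:
        return [i for i, p in enumerate(self.populations) if p in pops]

    def subset_sequences(self, keep: list[int]) -> "Alignment":
        return Alignment(
            ids=[self.ids[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            sequences=[self.sequences[i] for i in keep],
            positions=self.positions.copy(),
        )

    def subset_columns(self, keep_cols: np.ndarray) -> "Alignment":
        keep_cols = np.asarray(keep_cols)
        return Alignment(
            ids=list(self.ids),
            populations=list(self.populations),
            sequences=["".join(s[c] for c in keep_cols) for s in self.sequences],
            positions=self.positions[keep_cols],
        )

    def as_bytes(self) -> np.ndarray:
        """(n_sequences, length) uint8 view of the uppercased alignment."""
        return np.frombuffer(
            "".join(s.upper() for s in self.sequences).encode(), dtype=np.uint8
        ).reshape(self.n_sequences, self.length)


@dataclass
class HaplotypeMatrix:
    """Binary derived(1)/ancestral(0) states, sites x chromosomes.

    Columns 0..n_uar-1 are brown-bear chromosomes, the rest polar-bear.
    Every site must be segregating among the ingroup unless it is flagged in
    ``fixed_derived`` (derived in every ingroup chromosome relative to the
    outgroup), which is meaningful only for mtDNA 2D spectra.
    """

    data: np.ndarray
    site_positions: np.ndarray
    n_uar: int
    n_uma: int
    locus_id: str = ""
    polarized: bool = True
    fixed_derived: np.ndarray | None = None
    dropped_sites: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (sites x chromosomes)")
        if self.data.shape[1] != self.n_uar + self.n_uma:
            raise ValueError("column count must equal n_uar + n_uma")
        if self.data.shape[0] != len(self.site_positions):
            raise ValueError("one position per site required")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("entries must be 0/1")
        counts = self.data.sum(axis=1)
        n = self.data.shape[1]
        fixed = (np.zeros(len(counts), dtype=bool)
                 if self.fixed_derived is None else np.asarray(self.fixed_derived, dtype=bool))
        if len(fixed) != len(counts):
            raise ValueError("fixed_derived flag must have one entry per site")
        seg = ~fixed
        if n > 0 and ((counts[seg] == 0) | (counts[seg] == n)).any():
            raise ValueError("non-segregating site present without fixed_derived flag")
        if (counts[fixed] != n).any():
            raise ValueError("fixed_derived site must be derived on all chromosomes")
        self.fixed_derived = fixed

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.data.shape[1]

    @property
    def uar(self) -> np.ndarray:
        return self.data[:, : self.n_uar]

    @property
    def uma(self) -> np.ndarray:
        return self.data[:, self.n_uar:]


@dataclass
class LocusSet:
    """A multi-locus dataset with per-locus simulation/mutation settings."""

    loci: list[HaplotypeMatrix]
    configs: list  # list[coalsim.LocusConfig], kept untyped to avoid a cycle

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.configs):
            raise ValueError("one config per locus required")
        sizes = {(m.n_uar, m.n_uma) for m in self.loci}
        if len(sizes) > 1:
            raise ValueError("sample sizes must be uniform across loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_uar(self) -> int:
        return self.loci[0].n_uar

    @property
    def n_uma(self) -> int:
        return self.loci[0].n_uma


# ---------------------------------------------------------------------------
# I/O

def infer_populations(ids: list[str]) -> list[str]:
    """Map sequence ids to population labels from their name tags."""
    pops = []
    for sid in ids:
        low = sid.lower()
        if "panda" in low:
            pops.append("outg_panda")
        elif "blackbear" in low or "black_bear" in low:
            pops.append("outg_blackbear")
        elif low.startswith("uar"):
            pops.append("uar")
        elif low.startswith("uma"):
            pops.append("uma")
        else:
            raise ValueError(f"cannot infer population for sequence id {sid!r}")
    return pops


def read_popmap(path) -> dict[str, str]:
    """Two-column (id, population) whitespace/tab-separated mapping file."""
    mapping = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, pop = line.split()[:2]
            if pop not in VALID_POPS:
                raise ValueError(f"unknown population {pop!r} in popmap")
            mapping[sid] = pop
    return mapping


def read_alignment(path, popmap: dict[str, str] | None = None) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    pops = [popmap[i] for i in ids] if popmap is not None else infer_populations(ids)
    return Alignment(ids=ids, populations=pops, sequences=seqs)


def write_alignment(align: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(align.ids, align.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# polarization

def polarize_sites(align: Alignment, keep_fixed_derived: bool = False) -> HaplotypeMatrix:
    """Assign ancestral/derived states per segregating site using outgroups.

    The rules, applied per site: (1) if both black-bear outgroup sequences
    carry the same allele and it occurs among the ingroup alleles, that allele
    is ancestral; (2) otherwise, if the panda allele occurs among the ingroup
    alleles, the panda allele is ancestral; (3) otherwise the site is dropped
    and logged.  Sites with more than two ingroup alleles violate infinite
    sites and are dropped; sites with a gap or ambiguity code in any retained
    sequence are excluded up front.
    """
    uar_idx = align.indices("uar")
    uma_idx = align.indices("uma")
    bb_idx = align.indices("outg_blackbear")
    panda_idx = align.indices("outg_panda")
    if not bb_idx and not panda_idx:
        raise ValueError("at least one outgroup sequence is required")
    if not uar_idx and not uma_idx:
        raise ValueError("no ingroup sequences present")
    arr = align.as_bytes()
    ingroup = arr[uar_idx + uma_idx, :]
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    clean = acgt.all(axis=0)

    rows, positions, fixed_flags, dropped = [], [], [], []
    use_bb_rule = len(bb_idx) == 2
    for col in np.nonzero(clean)[0]:
        column = ingroup[:, col]
        alleles = np.unique(column)
        if len(alleles) > 2:
            dropped.append((int(align.positions[col]), "more than two ingroup alleles"))
            continue
        # for segregating sites the ancestral allele must occur in the
        # ingroup; for monomorphic sites the outgroup state stands alone
        monomorphic = len(alleles) == 1
        ancestral = None
        if use_bb_rule:
            b1, b2 = arr[bb_idx[0], col], arr[bb_idx[1], col]
            if b1 == b2 and (monomorphic or b1 in alleles):
                ancestral = b1
        if ancestral is None and panda_idx:
            pa = arr[panda_idx[0], col]
            if monomorphic or pa in alleles:
                ancestral = pa
        if ancestral is None:
            if not monomorphic:
                dropped.append((int(align.positions[col]), "no polarization rule applies"))
            continue
        if len(alleles) == 1:
            if keep_fixed_derived and alleles[0] != ancestral:
                rows.append(np.ones(len(column), dtype=np.uint8))
                positions.append(int(align.positions[col]))
                fixed_flags.append(True)
            continue
        rows.append((column != ancestral).astype(np.uint8))
        positions.append(int(align.positions[col]))
        fixed_flags.append(False)

    data = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, len(uar_idx) + len(uma_idx)), dtype=np.uint8)
    return HaplotypeMatrix(
        data=data,
        site_positions=np.array(positions, dtype=np.int64),
        n_uar=len(uar_idx),
        n_uma=len(uma_idx),
        fixed_derived=np.array(fixed_flags, dtype=bool),
        dropped_sites=dropped,
    )


# ---------------------------------------------------------------------------
# four-gamete test

def four_gamete_scan(matrix: HaplotypeMatrix) -> list[tuple[int, int]]:
    """All site-index pairs (i < j) exhibiting all four gametes 00/01/10/11."""
    a = matrix.data.astype(np.int32)
    s = a.shape[0]
    if s < 2:
        return []
    n11 = a @ a.T
    n10 = a @ (1 - a).T
    n01 = n10.T
    n00 = (1 - a) @ (1 - a).T
    bad = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    ii, jj = np.nonzero(np.triu(bad, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


# ---------------------------------------------------------------------------
# mtDNA dataset editing

def _incompatibility_degree(align: Alignment, matrix: HaplotypeMatrix,
                            pairs: list[tuple[int, int]]) -> dict[int, int]:
    """Count, per ingroup sequence, the incompatible pairs in which it carries
    a rarest gamete (removing all carriers of a rarest gamete resolves the
    pair)."""
    ingroup = align.indices(*INGROUP_POPS)
    degree = {i: 0 for i in ingroup}
    for si, sj in pairs:
        gi, gj = matrix.data[si], matrix.data[sj]
        gam = gi * 2 + gj
        counts = np.bincount(gam, minlength=4)
        rare = np.nonzero(counts == counts[counts > 0].min())[0]
        carriers = np.nonzero(np.isin(gam, rare))[0]
        for c in carriers:
            degree[ingroup[c]] += 1
    return degree


def longest_compatible_prefix(matrix: HaplotypeMatrix,
                              pairs: list[tuple[int, int]] | None = None) -> int:
    """Largest alignment position P such that no incompatible pair lies
    entirely within positions 1..P."""
    if pairs is None:
        pairs = four_gamete_scan(matrix)
    if not pairs:
        return int(matrix.site_positions.max()) if matrix.n_sites else 0
    # the later site of the earliest-ending incompatible pair caps the window
    cap = min(int(matrix.site_positions[max(si, sj)]) for si, sj in pairs)
    return cap - 1


def build_mtdna_sets(align: Alignment, mode: str,
                     max_removals: int | None = None) -> Alignment:
    """Edit an mtDNA alignment into an infinite-sites-compatible dataset.

    ``exclude-sequences``: iteratively remove the ingroup sequence implicated
    in the most four-gamete incompatibilities (ties broken by lowest id,
    lexicographically) until none remain — or until ``max_removals`` — and
    then, if incompatibilities persist, truncate to the longest prefix window
    free of them.  ``exclude-sites``: remove every column belonging to at
    least one incompatible pair.  Outgroup sequences are always retained.
    The result passes the four-gamete scan with no hits.
    """
    if mode not in ("exclude-sequences", "exclude-sites"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exclude-sites":
        matrix = polarize_sites(align)
        pairs = four_gamete_scan(matrix)
        bad_positions = {int(matrix.site_positions[s]) for pair in pairs for s in pair}
        keep = np.array([p not in bad_positions for p in align.positions])
        return align.subset_columns(np.nonzero(keep)[0])

    current = align
    removed = 0
    while max_removals is None or removed < max_removals:
        matrix = polarize_sites(current)
        pairs = four_gamete_scan(matrix)
        if not pairs:
            return current
        degree = _incompatibility_degree(current, matrix, pairs)
        worst = max(degree.values())
        victim = sorted(current.ids[i] for i, d in degree.items() if d == worst)[0]
        keep = [i for i, sid in enumerate(current.ids) if sid != victim]
        if not [i for i in keep if current.populations[i] in INGROUP_POPS]:
            raise ValueError("all ingroup sequences would be removed")
        current = current.subset_sequences(keep)
        removed += 1
    # removal budget exhausted with incompatibilities left: truncate instead
    matrix = polarize_sites(current)
    pairs = four_gamete_scan(matrix)
    if not pairs:
        return current
    cutoff = longest_compatible_prefix(matrix, pairs)
    return current.subset_columns(np.nonzero(current.positions <= cutoff)[0])
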