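"""Synthetic multi-locus datasets with the structure the inference assumes.

Generates coalescent data under the two-population divergence model, renders
it to nucleotide FASTA with outgroup sequences for polarization, and can
inject recurrent mutations to exercise the four-gamete filtering.  The
rendering maps the ancestral state at each segregating site to one base and
the derived state to another (chosen uniformly at random per site); the
sequence is otherwise the random ancestral background, i.e. infinite sites
except at injected recurrent sites.

Outgroups sit on the same genealogy extended beyond the ingroup root: a
distant panda-like outgroup at ``outgroup_divergence`` generations and a
pair of closer black-bear-like outgroups at one third of that distance.
Outgroup-path substitutions are placed on the outgroup branches at sites
that avoid the ingroup's segregating sites, so the recorded truth (the
ingroup root state) stays exact and no outgroup back-mutation occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import DemographicParams, LocusConfig, simulate_locus
from .seqio import Alignment, HaplotypeMatrix, LocusSet, polarize_sites, four_gamete_scan, write_alignment

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_dataset",
    "inject_recurrent_mutations",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults: 14 diploid autosomal loci of 500 bp with
    36 + 36 sampled chromosomes, mutation and (for autosomes) equal
    recombination at the calibrated per-site rates; the mtDNA mode is a
    single non-recombining locus with 9 + 26 haploid sequences."""

    n_loci: int = 14
    locus_length: int = 500
    n_uar: int = 36
    n_uma: int = 36
    mode: str = "diploid-aDNA"
    true_params: DemographicParams = field(
        default_factory=lambda: DemographicParams(40_000.0, 8_000.0, 120_000.0))
    mu_per_site: float = 1.314e-8
    recomb_equals_mu: bool = True
    n_recurrent: int = 0
    outgroup_divergence: float = 2_400_000.0  # generations (12 MYA at 10 y/gen)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 0 or self.n_recurrent < 0:
            raise ValueError("counts must be >= 0")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")
        if self.mu_per_site < 0:
            raise ValueError("mu_per_site must be >= 0")
        if self.mode not in ("diploid-aDNA", "haploid-mtDNA"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_uar == 0 or self.n_uma == 0:
            raise ValueError("both populations need at least one sample")

    def locus_config(self) -> LocusConfig:
        recomb = "equal-to-mu" if (self.recomb_equals_mu and self.mode == "diploid-aDNA") else "zero"
        return LocusConfig(length=self.locus_length, mu_per_site=self.mu_per_site,
                           recombination=recomb, ploidy_mode=self.mode,
                           n_uar=self.n_uar, n_uma=self.n_uma)


@dataclass
class TruthRecord:
    """Ground truth of a generated dataset: the generating parameters, each
    locus's TMRCA (generations), and the ancestral base at every segregating
    site (locus id -> {1-based position: base})."""

    true_params: DemographicParams
    tmrca: dict[str, float]
    ancestral: dict[str, dict[int, str]]
    recurrent_sites: dict[str, list[int]] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("record\tlocus\tposition\tvalue\n")
            for name, value in zip(("n_uar", "n_uma", "t_div"),
                                   self.true_params.as_array()):
                fh.write(f"param\t.\t.\t{value:.6g}\n")
            for locus, t in self.tmrca.items():
                fh.write(f"tmrca\t{locus}\t.\t{t:.6g}\n")
            for locus, sites in self.ancestral.items():
                for pos, base in sorted(sites.items()):
                    fh.write(f"ancestral\t{locus}\t{pos}\t{base}\n")
            for locus, sites in self.recurrent_sites.items():
                for pos in sites:
                    fh.write(f"recurrent\t{locus}\t{pos}\t.\n")


@dataclass
class SyntheticDataset:
    locus_set: LocusSet
    alignments: list[Alignment]
    truth: TruthRecord


def _render_locus(matrix: HaplotypeMatrix, locus: LocusConfig,
                  outgroup_divergence: float, mu: float,
                  rng: np.random.Generator):
    """Nucleotide rendering of one locus plus outgroup sequences."""
    length = locus.length
    n = matrix.n_chromosomes
    ancestral_seq = rng.choice(_BASES, size=length)
    seg_cols = matrix.site_positions - 1
    derived = np.empty(len(seg_cols), dtype=np.uint8)
    for k, col in enumerate(seg_cols):
        options = _BASES[_BASES != ancestral_seq[col]]
        derived[k] = rng.choice(options)

    rows = np.tile(ancestral_seq, (n, 1))
    for k, col in enumerate(seg_cols):
        rows[matrix.data[k].astype(bool), col] = derived[k]

    # outgroup substitutions avoid segregating columns (infinite sites)
    free_cols = np.setdiff1d(np.arange(length), seg_cols)

    def mutate(base_row: np.ndarray, branch_generations: float) -> np.ndarray:
        out = base_row.copy()
        n_sub = rng.poisson(mu * branch_generations * length)
        n_sub = min(n_sub, len(free_cols))
        if n_sub:
            cols = rng.choice(free_cols, size=n_sub, replace=False)
            for col in cols:
                options = _BASES[_BASES != out[col]]
                out[col] = rng.choice(options)
        return out

    d = outgroup_divergence
    panda = mutate(ancestral_seq, 2.0 * d)
    bb_stem = mutate(ancestral_seq, 2.0 * d / 3.0)
    bb1 = mutate(bb_stem, d / 30.0)
    bb2 = mutate(bb_stem, d / 30.0)

    ids = ([f"uar_{i:02d}" for i in range(matrix.n_uar)]
           + [f"uma_{i:02d}" for i in range(matrix.n_uma)]
           + ["outg_blackbear_1", "outg_blackbear_2", "outg_panda"])
    pops = (["uar"] * matrix.n_uar + ["uma"] * matrix.n_uma
            + ["outg_blackbear", "outg_blackbear", "outg_panda"])
    seqs = [bytes(r).decode() for r in rows] + [
        bytes(bb1).decode(), bytes(bb2).decode(), bytes(panda).decode()]
    align = Alignment(ids=ids, populations=pops, sequences=seqs)
    truth_anc = {int(p): chr(ancestral_seq[p - 1]) for p in matrix.site_positions}
    return align, truth_anc


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Simulate, render, and (optionally) corrupt a multi-locus dataset."""
    locus = config.locus_config()
    root = np.random.SeedSequence(config.seed)
    locus_seeds = root.spawn(config.n_loci)
    loci, alignments = [], []
    tmrca: dict[str, float] = {}
    ancestral: dict[str, dict[int, str]] = {}
    recurrent: dict[str, list[int]] = {}
    for li, child in enumerate(locus_seeds):
        rng = np.random.default_rng(child)
        matrix, genealogy = simulate_locus(config.true_params, locus, seed=rng)
        locus_id = f"locus_{li:02d}"
        matrix.locus_id = locus_id
        align, truth_anc = _render_locus(matrix, locus, config.outgroup_divergence,
                                         config.mu_per_site, rng)
        if config.n_recurrent and matrix.n_sites >= 2:
            align, altered = inject_recurrent_mutations(
                align, config.n_recurrent, seed=rng, return_sites=True)
            recurrent[locus_id] = altered
            matrix = polarize_sites(align)
            matrix.locus_id = locus_id
        loci.append(matrix)
        alignments.append(align)
        tmrca[locus_id] = genealogy.tmrca
        ancestral[locus_id] = truth_anc
    truth = TruthRecord(true_params=config.true_params, tmrca=tmrca,
                        ancestral=ancestral, recurrent_sites=recurrent)
    locus_set = LocusSet(loci=loci, configs=[locus] * config.n_loci)
    return SyntheticDataset(locus_set=locus_set, alignments=alignments, truth=truth)


def inject_recurrent_mutations(align: Alignment, k: int, seed=None,
                               return_sites: bool = False):
    """Strike k existing segregating sites with a second, independent
    mutation on a random lineage.

    Each altered site gains its derived base on one additional ingroup
    chromosome, chosen (when possible) so the site becomes four-gamete
    incompatible with some currently compatible partner site.  Returns the
    edited alignment (and, optionally, the altered 1-based positions).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k == 0:
        return (align, []) if return_sites else align
    matrix = polarize_sites(align)
    if matrix.n_sites < 2:
        raise ValueError("need at least two segregating sites to inject against")
    if k > matrix.n_sites:
        raise ValueError(f"k={k} exceeds the {matrix.n_sites} available sites")
    data = matrix.data.copy()
    incompatible = set(four_gamete_scan(matrix))
    # matrix columns are uar first, then uma, regardless of file order
    ingroup_rows = align.indices("uar") + align.indices("uma")
    seqs = [bytearray(s.encode()) for s in align.sequences]
    pos_to_col = {int(p): c for c, p in enumerate(align.positions)}

    targets = rng.choice(matrix.n_sites, size=k, replace=False)
    altered: list[int] = []
    for si in targets:
        col = pos_to_col[int(matrix.site_positions[si])]
        anc_carriers = np.nonzero(data[si] == 0)[0]
        derived_carrier = int(np.nonzero(data[si] == 1)[0][0])
        derived_base = seqs[ingroup_rows[derived_carrier]][col]
        chosen = None
        partners = rng.permutation(matrix.n_sites)
        for p in partners:
            if p == si or (min(si, p), max(si, p)) in incompatible:
                continue
            for c in rng.permutation(anc_carriers):
                trial = data[si].copy()
                trial[c] = 1
                gam = {(int(a), int(b)) for a, b in zip(trial, data[p])}
                if len(gam) == 4:
                    chosen = int(c)
                    break
            if chosen is not None:
                break
        if chosen is None and len(anc_carriers):
            chosen = int(rng.choice(anc_carriers))
        if chosen is None:
            continue  # site fixed-derived; nothing to strike
        data[si, chosen] = 1
        seqs[ingroup_rows[chosen]][col] = derived_base
        altered.append(int(matrix.site_positions[si]))
        # refresh incompatibilities involving si for later iterations
        for p in range(matrix.n_sites):
            if p == si:
                continue
            gam = {(int(a), int(b)) for a, b in zip(data[si], data[p])}
            if len(gam) == 4:
                incompatible.add((min(si, p), max(si, p)))
    edited = Alignment(ids=list(align.ids), populations=list(align.populations),
                       sequences=[bytes(s).decode() for s in seqs],
                       positions=align.positions.copy())
    return (edited, altered) if return_sites else edited


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """One FASTA per locus plus the tab-separated TruthRecord file."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for matrix, align in zip(dataset.locus_set.loci, dataset.alignments):
        write_alignment(align, outdir / f"{matrix.locus_id or 'locus'}.fasta")
    dataset.truth.write(outdir / "truth.tsv")
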