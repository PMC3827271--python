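"""Coalescent simulation under a two-population divergence model.

The model: two populations (brown bears, ``uar``; polar bears, ``uma``) of
constant effective sizes that split from a single ancestral population ``T``
generations ago.  Going backward in time, lineages coalesce within each
population at pairwise rate ``1/K`` per generation, where ``K`` is the
effective number of chromosomes (``2N`` for diploid autosomal loci, ``N`` for
haploid mtDNA), and the two populations merge into the ancestral population at
time ``T``.  Mutation follows the infinite-sites model at a per-site,
per-generation rate; intra-locus recombination, when enabled, places
crossovers at a per-site rate equal to the mutation rate, yielding an
ancestral recombination graph with marginal trees per segment.

Internally everything is parametrized by chromosome count ``K`` and time in
generations.  Conversion helpers to/from the Hudson ``ms`` scaling
(``theta = 4 N mu``, time in units of ``4 N0``) are provided because the
literature reports parameters in that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import HaplotypeMatrix

__all__ = [
    "DemographicParams",
    "LocusConfig",
    "Genealogy",
    "simulate_locus",
    "sample_tmrca",
    "watterson_expected_s",
    "expected_tmrca",
    "to_ms_scaling",
    "from_ms_scaling",
]


@dataclass(frozen=True)
class DemographicParams:
    """Effective sizes (diploid individuals) and split time (generations)."""

    n_uar: float
    n_uma: float
    t_div: float

    def __post_init__(self) -> None:
        if self.n_uar <= 0 or self.n_uma <= 0 or self.t_div <= 0:
            raise ValueError("all demographic parameters must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.n_uar, self.n_uma, self.t_div], dtype=float)


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus simulation settings.

    ``ploidy_mode`` controls the effective-chromosome conversion: for
    ``diploid-aDNA`` a population of N individuals carries K = 2N chromosomes;
    for ``haploid-mtDNA`` the sampled size parameter is used directly
    (K = N), mirroring the convention in which the mtDNA effective size is
    later reported as N/2.
    """

    length: int = 500
    mu_per_site: float = 1.314e-8
    recombination: str = "equal-to-mu"  # or "zero"
    ploidy_mode: str = "diploid-aDNA"  # or "haploid-mtDNA"
    n_uar: int = 36
    n_uma: int = 36

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("locus length must be >= 1 bp")
        if self.mu_per_site < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.recombination not in ("equal-to-mu", "zero"):
            raise ValueError(f"unknown recombination mode {self.recombination!r}")
        if self.ploidy_mode not in ("diploid-aDNA", "haploid-mtDNA"):
            raise ValueError(f"unknown ploidy mode {self.ploidy_mode!r}")
        if self.n_uar < 0 or self.n_uma < 0:
            raise ValueError("sample sizes must be >= 0")

    def chromosomes(self, n_individuals: float) -> float:
        """Effective chromosome count K for a population of the given size."""
        return 2.0 * n_individuals if self.ploidy_mode == "diploid-aDNA" else float(n_individuals)


@dataclass
class Genealogy:
    """A simulated genealogy: one explicit tree (no recombination) or the
    marginal-tree summaries of an ancestral recombination graph.

    For the tree case, nodes 0..n-1 are the sampled leaves (uar first, then
    uma) and internal nodes follow in coalescence order; ``parent[root] = -1``.
    Times are in generations.
    """

    n_leaves: int
    parent: np.ndarray | None = None
    node_time: np.ndarray | None = None
    # list of (left_bp, right_bp, tmrca_generations) marginal intervals
    marginal: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def has_tree(self) -> bool:
        return self.parent is not None

    @property
    def tmrca(self) -> float:
        """TMRCA in generations; length-weighted mean over marginal trees."""
        if self.has_tree:
            return float(self.node_time[-1])
        total = sum(r - l for l, r, _ in self.marginal)
        if total == 0:
            return 0.0
        return sum((r - l) * t for l, r, t in self.marginal) / total

    def tmrca_of(self, leaves: list[int] | np.ndarray) -> float:
        """TMRCA of a subset of leaves (explicit-tree genealogies only)."""
        if not self.has_tree:
            raise ValueError("subset TMRCA requires an explicit tree (no recombination)")
        leaves = list(leaves)
        if len(leaves) < 2:
            raise ValueError("need >= 2 leaves")
        if min(leaves) < 0 or max(leaves) >= self.n_leaves:
            raise ValueError("leaf index out of range")
        # ancestor sets are tiny (n <= ~100); walk paths to the root
        paths = []
        for leaf in leaves:
            anc = set()
            node = leaf
            while node != -1:
                anc.add(node)
                node = int(self.parent[node])
            paths.append(anc)
        common = set.intersection(*paths)
        return float(min(self.node_time[node] for node in common))

    def newick(self) -> str:
        """Debug rendering of an explicit tree in Newick format."""
        if not self.has_tree:
            raise ValueError("newick rendering requires an explicit tree")
        children: dict[int, list[int]] = {}
        for node, par in enumerate(self.parent):
            if par >= 0:
                children.setdefault(int(par), []).append(node)

        def render(node: int) -> str:
            if node < self.n_leaves:
                return f"n{node}"
            left, right = children[node]
            bl = self.node_time[node] - self.node_time[left], self.node_time[node] - self.node_time[right]
            return f"({render(left)}:{bl[0]:.6g},{render(right)}:{bl[1]:.6g})"

        root = int(np.where(self.parent == -1)[0][0])
        return render(root) + ";"


# ---------------------------------------------------------------------------
# analytic expectations (closed-form oracles)

def watterson_expected_s(theta_locus: float, n: int) -> float:
    """E[S] = theta * sum_{i=1}^{n-1} 1/i with theta = 2 K mu_locus."""
    return theta_locus * sum(1.0 / i for i in range(1, n))


def expected_tmrca(k_chromosomes: float, n: int) -> float:
    """E[TMRCA] = 2K(1 - 1/n) generations for a constant-size population."""
    return 2.0 * k_chromosomes * (1.0 - 1.0 / n)


# ---------------------------------------------------------------------------
# ms-convention conversion helpers

def to_ms_scaling(params: DemographicParams, locus: LocusConfig, n0: float | None = None):
    """Convert to Hudson ms scaling relative to N0 (default: N_uar).

    Returns a dict with ``theta`` (= 2 * K0 * mu_locus), ``rho``, population
    size ratios relative to N0, and the split time in units of K0*2 generations
    (ms measures time in 4N0 generations for diploids, i.e. 2*K0).
    """
    n0 = params.n_uar if n0 is None else n0
    k0 = locus.chromosomes(n0)
    mu_locus = locus.mu_per_site * locus.length
    theta = 2.0 * k0 * mu_locus
    rho = theta if locus.recombination == "equal-to-mu" else 0.0
    return {
        "theta": theta,
        "rho": rho,
        "size_uar": params.n_uar / n0,
        "size_uma": params.n_uma / n0,
        "t_div": params.t_div / (2.0 * k0),
    }


def from_ms_scaling(theta: float, t_div_ms: float, size_uar: float, size_uma: float,
                    locus: LocusConfig, n0: float) -> DemographicParams:
    """Inverse of :func:`to_ms_scaling` (theta is informative only via n0)."""
    k0 = locus.chromosomes(n0)
    return DemographicParams(
        n_uar=size_uar * n0,
        n_uma=size_uma * n0,
        t_div=t_div_ms * 2.0 * k0,
    )


# ---------------------------------------------------------------------------
# engine: explicit tree, no recombination

def _pick_pair(k: int, rng: np.random.Generator) -> tuple[int, int]:
    i = int(rng.integers(k))
    j = int(rng.integers(k - 1))
    if j >= i:
        j += 1
    return i, j


def _simulate_tree(n_uar: int, n_uma: int, k_uar: float, k_uma: float,
                   k_anc: float, t_div: float, rng: np.random.Generator):
    """Two-population Kingman coalescent; returns (parent, node_time) arrays."""
    n = n_uar + n_uma
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1, dtype=float)
    pops = [list(range(n_uar)), list(range(n_uar, n))]
    sizes = [k_uar, k_uma]
    next_node = n
    t = 0.0
    merged = False
    while len(pops[0]) + len(pops[1]) > 1:
        k0, k1 = len(pops[0]), len(pops[1])
        r0 = k0 * (k0 - 1) / (2.0 * sizes[0])
        r1 = k1 * (k1 - 1) / (2.0 * sizes[1])
        total = r0 + r1
        if total > 0.0:
            dt = rng.exponential(1.0 / total)
        if total == 0.0 or (not merged and t + dt >= t_div):
            t = t_div
            pops[0].extend(pops[1])
            pops[1] = []
            sizes[0] = k_anc
            merged = True
            continue
        t += dt
        pop = 0 if rng.random() * total < r0 else 1
        lineages = pops[pop]
        i, j = _pick_pair(len(lineages), rng)
        a, b = lineages[i], lineages[j]
        node_time[next_node] = t
        parent[a] = next_node
        parent[b] = next_node
        lineages[i] = next_node
        lineages.pop(j)
        next_node += 1
    return parent[:next_node], node_time[:next_node]


def _drop_mutations_tree(parent: np.ndarray, node_time: np.ndarray, n_leaves: int,
                         mu_locus: float, length: int, rng: np.random.Generator):
    """Poisson mutations on branches; returns (positions_bp, leaf-mask list)."""
    n_nodes = len(parent)
    par = parent
    branch_len = np.zeros(n_nodes)
    has_parent = par >= 0
    branch_len[has_parent] = node_time[par[has_parent]] - node_time[has_parent]
    total = branch_len.sum()
    n_mut = rng.poisson(total * mu_locus)
    if n_mut == 0:
        return np.empty(0), []
    # leaf bitmask under each node (children always precede parents)
    masks = [1 << i for i in range(n_leaves)] + [0] * (n_nodes - n_leaves)
    for node in range(n_nodes):
        if par[node] >= 0:
            masks[par[node]] |= masks[node]
    branches = rng.choice(n_nodes, size=n_mut, p=branch_len / total)
    pos = rng.uniform(0.0, length, size=n_mut)
    order = np.argsort(pos)
    return pos[order], [masks[branches[i]] for i in order]


# ---------------------------------------------------------------------------
# engine: ancestral recombination graph with segment tracking

def _simulate_arg(n_uar: int, n_uma: int, k_uar: float, k_uma: float, k_anc: float,
                  t_div: float, r_per_site: float, length: int,
                  rng: np.random.Generator):
    """Backward-in-time coalescent with crossover recombination.

    Each lineage carries a sorted list of ancestral segments
    ``(left, right, mask)`` on the continuous interval [0, length); ``mask``
    is the bitmask of sampled chromosomes descending from that segment.
    Returns (pieces, mrca_intervals) where pieces are
    (duration, left, right, mask) branch records for mutation placement and
    mrca_intervals are (left, right, time) records of fixed segments.
    """
    n = n_uar + n_uma
    full = (1 << n) - 1
    # lineage: [segs, birth_time]; segs: list of [left, right, mask]
    pops: list[list[list]] = [
        [[[[0.0, float(length), 1 << i]], 0.0] for i in range(n_uar)],
        [[[[0.0, float(length), 1 << i]], 0.0] for i in range(n_uar, n)],
    ]
    sizes = [k_uar, k_uma]
    pieces: list[tuple[float, float, float, int]] = []
    mrca: list[tuple[float, float, float]] = []
    t = 0.0
    merged = False

    def span(segs) -> float:
        return segs[-1][1] - segs[0][0]

    def retire(lin, t_now) -> None:
        dur = t_now - lin[1]
        if dur > 0.0:
            for left, right, mask in lin[0]:
                pieces.append((dur, left, right, mask))

    def merge_segs(sa, sb, t_now):
        """Union of two segment lists; overlapping masks OR together.

        Segments whose union mask covers every sample have found their MRCA:
        they are recorded and dropped.
        """
        bounds = sorted({s[0] for s in sa} | {s[1] for s in sa} |
                        {s[0] for s in sb} | {s[1] for s in sb})
        out = []
        ia = ib = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mask = 0
            while ia < len(sa) and sa[ia][1] <= lo:
                ia += 1
            if ia < len(sa) and sa[ia][0] <= lo < sa[ia][1]:
                mask |= sa[ia][2]
            while ib < len(sb) and sb[ib][1] <= lo:
                ib += 1
            if ib < len(sb) and sb[ib][0] <= lo < sb[ib][1]:
                mask |= sb[ib][2]
            if mask == 0:
                continue
            if mask == full:
                if mrca and mrca[-1][1] == lo and mrca[-1][2] == t_now:
                    mrca[-1] = (mrca[-1][0], hi, t_now)
                else:
                    mrca.append((lo, hi, t_now))
                continue
            if out and out[-1][1] == lo and out[-1][2] == mask:
                out[-1][1] = hi
            else:
                out.append([lo, hi, mask])
        return out

    def do_merge() -> None:
        nonlocal merged, t
        t = t_div
        pops[0].extend(pops[1])
        pops[1] = []
        sizes[0] = k_anc
        merged = True

    while len(pops[0]) + len(pops[1]) > 0:
        k0, k1 = len(pops[0]), len(pops[1])
        r_coal = [k0 * (k0 - 1) / (2.0 * sizes[0]),
                  k1 * (k1 - 1) / (2.0 * sizes[1])]
        rec_rates = [[r_per_site * span(l[0]) for l in pops[0]],
                     [r_per_site * span(l[0]) for l in pops[1]]]
        r_rec = [sum(rec_rates[0]), sum(rec_rates[1])]
        total = r_coal[0] + r_coal[1] + r_rec[0] + r_rec[1]
        if total == 0.0:
            if merged:  # single lineage with zero span and non-full mask: impossible
                raise RuntimeError("stalled ARG")  # pragma: no cover
            do_merge()
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= t_div:
            do_merge()
            continue
        t += dt
        u = rng.random() * total
        if u < r_coal[0] + r_coal[1]:
            pop = 0 if u < r_coal[0] else 1
            lins = pops[pop]
            i, j = _pick_pair(len(lins), rng)
            la, lb = lins[i], lins[j]
            retire(la, t)
            retire(lb, t)
            segs = merge_segs(la[0], lb[0], t)
            for idx2 in sorted((i, j), reverse=True):
                lins.pop(idx2)
            if segs:
                lins.append([segs, t])
        else:
            u -= r_coal[0] + r_coal[1]
            pop, idx = 0, 0
            if u < r_rec[0]:
                pop = 0
            else:
                pop = 1
                u -= r_rec[0]
            for idx, rr in enumerate(rec_rates[pop]):
                if u < rr:
                    break
                u -= rr
            lin = pops[pop][idx]
            segs = lin[0]
            bp = rng.uniform(segs[0][0], segs[-1][1])
            left_segs, right_segs = [], []
            for lo, hi, mask in segs:
                if hi <= bp:
                    left_segs.append([lo, hi, mask])
                elif lo >= bp:
                    right_segs.append([lo, hi, mask])
                else:
                    left_segs.append([lo, bp, mask])
                    right_segs.append([bp, hi, mask])
            if left_segs and right_segs:
                retire(lin, t)
                pops[pop].pop(idx)
                pops[pop].append([left_segs, t])
                pops[pop].append([right_segs, t])
            # else: breakpoint fell outside ancestral material; no event
    return pieces, mrca


def _drop_mutations_arg(pieces, mu_per_site: float, length: int,
                        rng: np.random.Generator):
    if not pieces:
        return np.empty(0), []
    weights = np.array([dur * (right - left) for dur, left, right, _ in pieces])
    total = weights.sum()
    n_mut = rng.poisson(total * mu_per_site)
    if n_mut == 0:
        return np.empty(0), []
    idx = rng.choice(len(pieces), size=n_mut, p=weights / total)
    pos = np.empty(n_mut)
    masks = []
    for k, i in enumerate(idx):
        _, left, right, mask = pieces[i]
        pos[k] = rng.uniform(left, right)
        masks.append(mask)
    order = np.argsort(pos)
    return pos[order], [masks[i] for i in order]


# ---------------------------------------------------------------------------

def _discretize_positions(pos: np.ndarray, length: int) -> np.ndarray:
    """Map sorted continuous positions in [0, L) to unique 1-based integers.

    When S <= L the positions stay within 1..L; a denser-than-renderable
    locus (S > L, possible under extreme parameter draws) overflows past L,
    which only matters for FASTA rendering, not for spectra.
    """
    out = np.floor(pos).astype(np.int64) + 1
    s = len(out)
    fits = s <= length
    for i in range(s):
        lo = 1 if i == 0 else out[i - 1] + 1
        out[i] = max(out[i], lo)
        if fits:
            out[i] = min(out[i], length - (s - 1 - i))
    return out


def _masks_to_matrix(masks: list[int], n: int) -> np.ndarray:
    mat = np.zeros((len(masks), n), dtype=np.uint8)
    for row, mask in enumerate(masks):
        while mask:
            low = mask & -mask
            mat[row, low.bit_length() - 1] = 1
            mask ^= low
    return mat


def simulate_locus(params: DemographicParams, locus: LocusConfig, seed=None,
                   k_anc: float | None = None) -> tuple[HaplotypeMatrix, Genealogy]:
    """Simulate one locus under the divergence model.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The ancestral
    population after the (backward-time) merge takes the brown-bear size by
    default; override with ``k_anc`` (in chromosomes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_uar, n_uma = locus.n_uar, locus.n_uma
    n = n_uar + n_uma
    if n == 0:
        raise ValueError("no samples requested")
    k_uar = locus.chromosomes(params.n_uar)
    k_uma = locus.chromosomes(params.n_uma)
    if k_anc is None:
        k_anc = k_uar
    mu_locus = locus.mu_per_site * locus.length

    if n == 1:
        genealogy = Genealogy(n_leaves=1, parent=np.array([-1]), node_time=np.zeros(1))
        matrix = HaplotypeMatrix(
            data=np.zeros((0, 1), dtype=np.uint8),
            site_positions=np.empty(0, dtype=np.int64),
            n_uar=n_uar, n_uma=n_uma,
        )
        return matrix, genealogy

    if locus.recombination == "zero":
        parent, node_time = _simulate_tree(n_uar, n_uma, k_uar, k_uma, k_anc,
                                           params.t_div, rng)
        genealogy = Genealogy(n_leaves=n, parent=parent, node_time=node_time,
                              marginal=[(0.0, float(locus.length), float(node_time[-1]))])
        pos, masks = _drop_mutations_tree(parent, node_time, n, mu_locus,
                                          locus.length, rng)
    else:
        r = locus.mu_per_site  # per site per generation, matched to mu
        pieces, mrca = _simulate_arg(n_uar, n_uma, k_uar, k_uma, k_anc,
                                     params.t_div, r, locus.length, rng)
        genealogy = Genealogy(n_leaves=n, marginal=[(l, r_, t) for l, r_, t in mrca])
        pos, masks = _drop_mutations_arg(pieces, locus.mu_per_site, locus.length, rng)

    site_positions = _discretize_positions(np.sort(pos), locus.length)
    matrix = HaplotypeMatrix(
        data=_masks_to_matrix(masks, n),
        site_positions=site_positions,
        n_uar=n_uar, n_uma=n_uma,
    )
    return matrix, genealogy


def sample_tmrca(n: int, k_chromosomes: float, seed=None) -> float:
    """Draw a TMRCA for n lineages in a constant-size population.

    T_MRCA = T_n + T_{n-1} + ... + T_2 where T_i ~ Exponential(i(i-1)/2) in
    coalescent units of K generations.
    """
    if n < 2:
        raise ValueError("TMRCA requires n >= 2 lineages")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i = np.arange(2, n + 1, dtype=float)
    rates = i * (i - 1) / 2.0
    return float(np.sum(rng.exponential(1.0 / rates)) * k_chromosomes)
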