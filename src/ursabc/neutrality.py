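"""Neutrality tests on a sample of haplotypes.

Implements Tajima's D, Fu & Li's D and F (outgroup versions, using the count
of derived singletons as the external-mutation class), and Fay & Wu's H.
Significance is assessed against the null distribution of the statistics
under a constant-size coalescent conditioned on the observed number of
segregating sites S (mutations placed multinomially on branches in
proportion to branch length), with two-tailed empirical p-values using the
+1 correction.

All statistics operate on a binary derived/ancestral matrix; Tajima's D uses
only pi and S (folded), while Fu & Li's tests and Fay & Wu's H require a
polarized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import HaplotypeMatrix

__all__ = [
    "NeutralityStats",
    "tajimas_d",
    "fu_li_tests",
    "fay_wu_h",
    "neutrality_pvalues",
    "compute_neutrality",
]


@dataclass
class NeutralityStats:
    d_tajima: float
    d_fuli: float
    f_fuli: float
    h_faywu: float
    n: int
    s: int
    pvalues: dict[str, float] | None = None

    def to_rows(self) -> list[tuple[str, float, float | None]]:
        """(statistic, value, p) rows for a tab-separated export."""
        p = self.pvalues or {}
        return [
            ("Tajima_D", self.d_tajima, p.get("d_tajima")),
            ("FuLi_D", self.d_fuli, p.get("d_fuli")),
            ("FuLi_F", self.f_fuli, p.get("f_fuli")),
            ("FayWu_H", self.h_faywu, p.get("h_faywu")),
        ]


def _site_counts(matrix_or_counts, n: int | None = None):
    """Accept a HaplotypeMatrix or a raw vector of per-site derived counts."""
    if isinstance(matrix_or_counts, HaplotypeMatrix):
        m = matrix_or_counts
        seg = ~m.fixed_derived
        return m.data[seg].sum(axis=1).astype(np.int64), m.n_chromosomes, m.polarized
    counts = np.asarray(matrix_or_counts, dtype=np.int64)
    if n is None:
        raise ValueError("sample size n required with raw counts")
    return counts, n, True


def _pi_from_counts(counts: np.ndarray, n: int) -> float:
    """Mean pairwise differences: sum_i 2 c_i (n - c_i) / (n (n-1))."""
    return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i ** 2))


def tajimas_d(matrix, n: int | None = None) -> float:
    """Tajima's D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))."""
    counts, n, _ = _site_counts(matrix, n)
    s = len(counts)
    if n < 2:
        raise ValueError("Tajima's D needs n >= 2")
    if s == 0:
        return float("nan")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    pi = _pi_from_counts(counts, n)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def fu_li_tests(matrix, n: int | None = None) -> tuple[float, float]:
    """Fu & Li's D and F with an outgroup.

    eta = S total mutations; eta_e = derived singletons (mutations on
    external branches).  Constants follow the published variance formulas.
    """
    counts, n, polarized = _site_counts(matrix, n)
    if not polarized:
        raise ValueError("Fu & Li's tests require a polarized matrix")
    if n < 3:
        raise ValueError("Fu & Li's tests need n >= 3")
    s = len(counts)
    if s == 0:
        return float("nan"), float("nan")
    eta_e = int(np.sum(counts == 1))
    a_n, b_n = _harmonics(n)
    c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a_n ** 2 / (b_n + a_n ** 2)) * (c_n - (n + 1.0) / (n - 1.0))
    u_d = a_n - 1.0 - v_d
    d = (s - a_n * eta_e) / np.sqrt(u_d * s + v_d * s ** 2)

    a_n1 = a_n + 1.0 / n  # a_{n+1}
    v_f = (c_n + 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) \
        / (a_n ** 2 + b_n)
    u_f = (1.0 + (n + 1.0) / (3.0 * (n - 1))
           - 4.0 * (n + 1.0) / (n - 1) ** 2 * (a_n1 - 2.0 * n / (n + 1))) / a_n - v_f
    pi = _pi_from_counts(counts, n)
    f = (pi - eta_e) / np.sqrt(u_f * s + v_f * s ** 2)
    return float(d), float(f)


def fay_wu_h(matrix, n: int | None = None) -> float:
    """Fay & Wu's H = pi - theta_H, theta_H = sum_i 2 xi_i i^2 / (n (n-1))."""
    counts, n, polarized = _site_counts(matrix, n)
    if not polarized:
        raise ValueError("Fay & Wu's H requires a polarized matrix")
    if n < 2:
        raise ValueError("Fay & Wu's H needs n >= 2")
    if len(counts) == 0:
        return float("nan")
    pi = _pi_from_counts(counts, n)
    theta_h = float(np.sum(2.0 * counts.astype(float) ** 2) / (n * (n - 1)))
    return pi - theta_h


# ---------------------------------------------------------------------------
# fixed-S coalescent null

def _sim_fixed_s_counts(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Derived counts of S mutations dropped on one constant-size Kingman
    genealogy, branches weighted by length."""
    # build the tree: sizes[i] = number of leaves under each active lineage
    sizes = [1] * n
    branch_sizes: list[int] = []
    branch_lengths: list[float] = []
    t = 0.0
    birth = [0.0] * n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        for idx in (i, j):
            branch_sizes.append(sizes[idx])
            branch_lengths.append(t - birth[idx])
        merged = sizes[i] + sizes[j]
        for idx in sorted((i, j), reverse=True):
            sizes.pop(idx)
            birth.pop(idx)
        sizes.append(merged)
        birth.append(t)
        k -= 1
    lengths = np.array(branch_lengths)
    picks = rng.choice(len(lengths), size=s, p=lengths / lengths.sum())
    return np.array([branch_sizes[p] for p in picks], dtype=np.int64)


def neutrality_pvalues(observed: dict[str, float], n: int, s: int,
                       n_sims: int = 10_000, seed=None) -> dict[str, float]:
    """Two-tailed empirical p-values under the fixed-S constant-size null.

    ``observed`` maps statistic names (``d_tajima``, ``d_fuli``, ``f_fuli``,
    ``h_faywu``) to observed values.  p = min(1, 2 * min(tail probabilities))
    with the +1 correction, bounded below by 1/(n_sims + 1).
    """
    if n_sims < 100:
        raise ValueError("need n_sims >= 100 for stable p-values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null: dict[str, list[float]] = {key: [] for key in observed}
    for _ in range(n_sims):
        counts = _sim_fixed_s_counts(n, s, rng)
        if "d_tajima" in null:
            null["d_tajima"].append(tajimas_d(counts, n=n))
        if "d_fuli" in null or "f_fuli" in null:
            d, f = fu_li_tests(counts, n=n)
            if "d_fuli" in null:
                null["d_fuli"].append(d)
            if "f_fuli" in null:
                null["f_fuli"].append(f)
        if "h_faywu" in null:
            null["h_faywu"].append(fay_wu_h(counts, n=n))
    out = {}
    for key, obs in observed.items():
        draws = np.array(null[key])
        lo = (1 + np.sum(draws <= obs)) / (n_sims + 1)
        hi = (1 + np.sum(draws >= obs)) / (n_sims + 1)
        out[key] = float(min(1.0, 2.0 * min(lo, hi)))
    return out


def compute_neutrality(matrix: HaplotypeMatrix, n_sims: int = 10_000,
                       seed=None) -> NeutralityStats:
    """All four statistics plus fixed-S null p-values for one matrix."""
    counts, n, _ = _site_counts(matrix)
    s = len(counts)
    d_t = tajimas_d(matrix)
    d_fl, f_fl = fu_li_tests(matrix)
    h = fay_wu_h(matrix)
    stats = NeutralityStats(d_tajima=d_t, d_fuli=d_fl, f_fuli=f_fl,
                            h_faywu=h, n=n, s=s)
    if s > 0:
        stats.pvalues = neutrality_pvalues(
            {"d_tajima": d_t, "d_fuli": d_fl, "f_fuli": f_fl, "h_faywu": h},
            n=n, s=s, n_sims=n_sims, seed=seed)
    return stats
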