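"""Significant cis and trans interaction calling at 10-kb resolution.

Cis pairs are tested against an equal-occupancy distance-stratified
background: within each stratum the expected per-read contact probability is
p_d = (stratum count sum) / (stratum pair count * N_cis), and each tested
pair gets an upper-tail binomial(N_cis, p_d) p-value at its observed count.
Trans pairs use one uniform expectation p_t = 1 / (number of possible trans
bin pairs). Benjamini-Hochberg q-values are computed over the tested pairs
(those with count >= 1; zero-count pairs still enter the stratum pair
totals). A call is retained iff read_count >= min_count ("ReadCount > 2"),
p <= p_max and q <= q_max; output is sorted by read_count descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contact_matrix import ContactMap

__all__ = [
    "InteractionCall",
    "call_cis_significant",
    "call_trans_significant",
    "shared_interactions",
    "bh_qvalues",
]


@dataclass(frozen=True)
class InteractionCall:
    chrom_a: str
    bin_a: int  # local bin on chrom_a
    chrom_b: str
    bin_b: int
    read_count: int
    p_value: float
    q_value: float
    kind: str  # cis | trans
    distance_bp: int | None = None

    def key(self) -> tuple:
        """Canonical pair identity for cross-condition set comparison."""
        a = (self.chrom_a, self.bin_a)
        b = (self.chrom_b, self.bin_b)
        return tuple(sorted((a, b)))


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-independent)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _binom_sf_at_least(k: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    """P(X >= k) for X ~ Binomial(n, p), vectorized over pairs."""
    return stats.binom.sf(k - 1, n, p)


def call_cis_significant(
    cmap: ContactMap,
    n_distance_strata: int = 100,
    min_count: int = 3,
    p_max: float = 0.01,
    q_max: float = 0.01,
    min_dist_bins: int = 2,
) -> list[InteractionCall]:
    """Distance-stratified binomial test for cis bin pairs.

    Pairs closer than ``min_dist_bins`` are excluded (adjacent-bin
    self-ligation artifacts). Strata are equal-occupancy in the number of
    possible pairs, computed over all distances genome-wide.
    """
    res = cmap.resolution
    # gather per-distance totals: possible pairs and observed counts
    max_d = 0
    for chrom in cmap.chroms:
        max_d = max(max_d, cmap.bins.n_bins_per_chrom[chrom] - 1)
    if max_d < min_dist_bins:
        return []
    n_pairs_at_d = np.zeros(max_d + 1)
    count_at_d = np.zeros(max_d + 1)
    records = []  # (chrom, i, j, count, d)
    n_cis = 0.0
    for chrom in cmap.chroms:
        m = cmap.cis_matrix(chrom)
        n = m.shape[0]
        for d in range(min_dist_bins, n):
            diag = np.diagonal(m, offset=d)
            n_pairs_at_d[d] += diag.size
            count_at_d[d] += diag.sum()
            n_cis += diag.sum()
            nz = np.nonzero(diag)[0]
            for i in nz:
                records.append((chrom, int(i), int(i + d), float(diag[i]), d))
    n_cis = int(round(n_cis))
    if n_cis == 0 or not records:
        return []
    # equal-occupancy strata over distances (weighted by possible pair count)
    dists = np.arange(min_dist_bins, max_d + 1)
    weights = n_pairs_at_d[dists]
    cum = np.cumsum(weights)
    total = cum[-1]
    n_strata = min(n_distance_strata, int((weights > 0).sum()))
    edges = np.searchsorted(cum, np.linspace(0, total, n_strata + 1)[1:-1], side="left")
    stratum_of_d = np.zeros(max_d + 1, dtype=int)
    stratum_of_d[dists] = np.searchsorted(edges, np.arange(dists.size), side="right")
    strat_pairs = np.zeros(n_strata)
    strat_counts = np.zeros(n_strata)
    for d in dists:
        s = stratum_of_d[d]
        strat_pairs[s] += n_pairs_at_d[d]
        strat_counts[s] += count_at_d[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_d = np.where(strat_pairs > 0, strat_counts / (strat_pairs * n_cis), 0.0)

    counts = np.array([r[3] for r in records])
    probs = np.array([p_d[stratum_of_d[r[4]]] for r in records])
    pvals = _binom_sf_at_least(counts, n_cis, probs)
    qvals = bh_qvalues(pvals)
    calls = []
    for (chrom, i, j, c, d), p, q in zip(records, pvals, qvals):
        if c >= min_count and p <= p_max and q <= q_max:
            calls.append(
                InteractionCall(
                    chrom_a=chrom,
                    bin_a=i,
                    chrom_b=chrom,
                    bin_b=j,
                    read_count=int(c),
                    p_value=float(p),
                    q_value=float(q),
                    kind="cis",
                    distance_bp=d * res,
                )
            )
    calls.sort(key=lambda c: (-c.read_count, c.chrom_a, c.bin_a, c.bin_b))
    return calls


def cis_pair_pvalues(
    cmap: ContactMap, n_distance_strata: int = 100, min_dist_bins: int = 2
) -> np.ndarray:
    """P-values of all tested cis pairs without the significance filters
    (used for null-calibration checks)."""
    calls = call_cis_significant(
        cmap,
        n_distance_strata=n_distance_strata,
        min_count=0,
        p_max=1.0,
        q_max=1.0,
        min_dist_bins=min_dist_bins,
    )
    return np.array([c.p_value for c in calls])


def call_trans_significant(
    cmap: ContactMap,
    min_count: int = 3,
    p_max: float = 0.01,
    q_max: float = 0.01,
) -> list[InteractionCall]:
    """Uniform-expectation binomial test for trans bin pairs."""
    n_trans = int(round(cmap.total_trans_pairs))
    if n_trans == 0 or not cmap.trans:
        return []
    chrom_bins = cmap.bins.n_bins_per_chrom
    chroms = list(cmap.bins.chrom_sizes)
    possible = 0
    for a in range(len(chroms)):
        for b in range(a + 1, len(chroms)):
            possible += chrom_bins[chroms[a]] * chrom_bins[chroms[b]]
    p_t = 1.0 / possible
    records = []
    for (ca, cb), store in cmap.trans.items():
        for (i, j), c in store.items():
            if c >= 1:
                records.append((ca, i, cb, j, float(c)))
    counts = np.array([r[4] for r in records])
    pvals = _binom_sf_at_least(counts, n_trans, np.full(counts.size, p_t))
    qvals = bh_qvalues(pvals)
    calls = []
    for (ca, i, cb, j, c), p, q in zip(records, pvals, qvals):
        if c >= min_count and p <= p_max and q <= q_max:
            calls.append(
                InteractionCall(
                    chrom_a=ca,
                    bin_a=i,
                    chrom_b=cb,
                    bin_b=j,
                    read_count=int(c),
                    p_value=float(p),
                    q_value=float(q),
                    kind="trans",
                )
            )
    calls.sort(key=lambda c: (-c.read_count, c.chrom_a, c.bin_a, c.chrom_b, c.bin_b))
    return calls


def shared_interactions(
    calls1: list[InteractionCall], calls2: list[InteractionCall]
) -> dict:
    """Counts of interaction pairs (exact canonical bin-pair identity) called
    significant in both conditions, split by kind."""
    out = {}
    for kind in ("cis", "trans"):
        k1 = {c.key() for c in calls1 if c.kind == kind}
        k2 = {c.key() for c in calls2 if c.kind == kind}
        out[f"shared_{kind}"] = len(k1 & k2)
    return out
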