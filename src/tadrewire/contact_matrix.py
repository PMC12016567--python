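"""Binned Hi-C contact map container and matrix-level transforms.

Raw counts are accepted as-is: matrix balancing (ICE etc.) is assumed done
upstream or absent. Cis matrices are stored dense per chromosome (symmetric);
trans counts are stored as sparse dictionaries keyed by ordered chromosome
pairs. This suits the matrix sizes this pipeline works at (<= a few thousand
bins per chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic_io import BinTable

__all__ = [
    "ContactMap",
    "read_contact_map",
    "write_contact_map",
    "smooth_map",
    "observed_expected",
    "distance_decay",
]


@dataclass
class ContactMap:
    """Symmetric binned cis counts per chromosome plus trans pair counts."""

    bins: BinTable
    cis: dict[str, np.ndarray] = field(default_factory=dict)
    # (chromA, chromB) with A before B in bin-table order -> {(iA, iB): count}
    trans: dict[tuple[str, str], dict[tuple[int, int], float]] = field(default_factory=dict)

    @property
    def resolution(self) -> int:
        return self.bins.resolution

    @property
    def chroms(self) -> list[str]:
        return list(self.bins.chrom_sizes)

    def cis_matrix(self, chrom: str) -> np.ndarray:
        if chrom not in self.cis:
            n = self.bins.n_bins_per_chrom[chrom]
            self.cis[chrom] = np.zeros((n, n))
        return self.cis[chrom]

    @property
    def total_cis_pairs(self) -> float:
        total = 0.0
        for m in self.cis.values():
            # upper triangle + diagonal counted once
            total += np.triu(m).sum()
        return total

    @property
    def total_trans_pairs(self) -> float:
        return float(sum(sum(d.values()) for d in self.trans.values()))

    def add_count(self, bin_a: int, bin_b: int, count: float) -> None:
        """Add ``count`` supporting the (global bin_a, global bin_b) pair."""
        if count < 0:
            raise ValueError("counts must be >= 0")
        ca = self.bins.chrom_of(bin_a)
        cb = self.bins.chrom_of(bin_b)
        if ca == cb:
            i = bin_a - self.bins.chrom_offsets[ca]
            j = bin_b - self.bins.chrom_offsets[cb]
            m = self.cis_matrix(ca)
            m[i, j] += count
            if i != j:
                m[j, i] += count
        else:
            order = list(self.bins.chrom_sizes)
            if order.index(ca) > order.index(cb):
                ca, cb = cb, ca
                bin_a, bin_b = bin_b, bin_a
            key = (ca, cb)
            i = bin_a - self.bins.chrom_offsets[ca]
            j = bin_b - self.bins.chrom_offsets[cb]
            store = self.trans.setdefault(key, {})
            store[(i, j)] = store.get((i, j), 0.0) + count


def read_contact_map(matrix_path, bins: BinTable) -> ContactMap:
    """Read a HiC-Pro-style triplet file ("binA binB count", 1-based bin ids)
    onto an existing :class:`~tadrewire.genomic_io.BinTable`."""
    cmap = ContactMap(bins=bins)
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{matrix_path}:{lineno}: expected 3 columns")
            a1, b1 = int(fields[0]), int(fields[1])
            try:
                count = int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{matrix_path}:{lineno}: non-integer count {fields[2]!r}"
                ) from exc
            a, b = a1 - 1, b1 - 1
            if not (0 <= a < bins.n_bins and 0 <= b < bins.n_bins):
                raise ValueError(f"{matrix_path}:{lineno}: bin id out of range")
            cmap.add_count(a, b, count)
    return cmap


def write_contact_map(cmap: ContactMap, matrix_path) -> None:
    """Write the upper triangle (and trans pairs) as a HiC-Pro triplet file."""
    bins = cmap.bins
    with open(matrix_path, "w") as fh:
        for chrom, m in cmap.cis.items():
            off = bins.chrom_offsets[chrom]
            ii, jj = np.nonzero(np.triu(m))
            for i, j in zip(ii, jj):
                fh.write(f"{off + i + 1}\t{off + j + 1}\t{int(round(m[i, j]))}\n")
        for (ca, cb), store in cmap.trans.items():
            offa, offb = bins.chrom_offsets[ca], bins.chrom_offsets[cb]
            for (i, j), c in sorted(store.items()):
                fh.write(f"{offa + i + 1}\t{offb + j + 1}\t{int(round(c))}\n")


def write_bins_bed(bins: BinTable, path) -> None:
    """HiC-Pro companion bins BED with 1-based bin ids in column 4."""
    with open(path, "w") as fh:
        for idx, chrom, start, end in bins.iter_bins():
            fh.write(f"{chrom}\t{start}\t{end}\t{idx + 1}\n")


def read_bins_bed(path) -> BinTable:
    """Reconstruct a BinTable from a HiC-Pro bins BED.

    The resolution is taken from the first bin's width; chromosome sizes
    from the last bin end per chromosome. Bin ids must be contiguous in
    file order.
    """
    chrom_sizes: dict[str, int] = {}
    resolution = None
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split("\t")[:3]
            start, end = int(start), int(end)
            if resolution is None:
                resolution = end - start
            chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), end)
    if resolution is None:
        raise ValueError(f"{path}: empty bins file")
    return BinTable(chrom_sizes=chrom_sizes, resolution=resolution)


def _smooth_matrix(m: np.ndarray, h: int) -> np.ndarray:
    """Mean over the (2h+1)x(2h+1) window, truncated at matrix edges."""
    if h == 0:
        return m.copy()
    # cumulative-sum box filter with edge truncation via a count matrix
    ones = np.ones_like(m)
    kernel_sum = _box_sum(m, h)
    kernel_n = _box_sum(ones, h)
    return kernel_sum / kernel_n


def _box_sum(m: np.ndarray, h: int) -> np.ndarray:
    """Sum over the (2h+1)x(2h+1) window clipped to the matrix."""
    n0, n1 = m.shape
    c = np.zeros((n0 + 1, n1 + 1))
    c[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
    i = np.arange(n0)
    j = np.arange(n1)
    lo0 = np.clip(i - h, 0, n0)
    hi0 = np.clip(i + h + 1, 0, n0)
    lo1 = np.clip(j - h, 0, n1)
    hi1 = np.clip(j + h + 1, 0, n1)
    return (
        c[np.ix_(hi0, hi1)]
        - c[np.ix_(lo0, hi1)]
        - c[np.ix_(hi0, lo1)]
        + c[np.ix_(lo0, lo1)]
    )


def smooth_map(cmap: ContactMap, h: int) -> ContactMap:
    """Window-mean smoothing of every cis matrix; ``h`` is the half-span in
    bins (h=0 is the identity). Trans counts are passed through unchanged."""
    if h < 0:
        raise ValueError("h must be >= 0")
    out = ContactMap(bins=cmap.bins)
    for chrom, m in cmap.cis.items():
        out.cis[chrom] = _smooth_matrix(m, h)
    out.trans = {k: dict(v) for k, v in cmap.trans.items()}
    return out


def distance_decay(cmap: ContactMap, chrom: str) -> np.ndarray:
    """Mean count per diagonal offset (offset 0 included) for one chromosome."""
    m = cmap.cis_matrix(chrom)
    n = m.shape[0]
    decay = np.zeros(n)
    for d in range(n):
        decay[d] = np.diagonal(m, offset=d).mean() if n - d > 0 else 0.0
    return decay


def observed_expected(cmap: ContactMap, chrom: str) -> np.ndarray:
    """O/E matrix: each entry divided by the mean count at its diagonal
    offset. Offsets with zero mean yield zeros."""
    m = cmap.cis_matrix(chrom)
    n = m.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    decay = distance_decay(cmap, chrom)
    i, j = np.indices(m.shape)
    exp = decay[np.abs(i - j)]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(exp > 0, m / np.where(exp > 0, exp, 1.0), 0.0)
    return oe
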