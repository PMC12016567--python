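"""Directionality-index TAD calling and cross-condition boundary comparison.

The directionality index (DI) contrasts, for each bin, the contact sum into
the upstream flank (A) against the downstream flank (B) within a fixed
window (2 Mb by default):

    E  = (A + B) / 2
    DI = sign(B - A) * [ (A - E)^2 / E + (B - E)^2 / E ]

DI is 0 wherever A = B (including A + B = 0). TADs are then called with a
deterministic run-based automaton: bins are labeled downstream-biased
(DI >= t), upstream-biased (DI <= -t) or neutral, with t a per-chromosome
multiple of the SD of nonzero DI, and a TAD spans from the first bin of a
downstream-biased run to the last bin of the next upstream-biased run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_matrix import ContactMap
from .genomic_io import BinTable, GeneModel, GenomicInterval, gc_content

__all__ = [
    "DirectionalityTrack",
    "Tad",
    "TadSet",
    "BoundarySet",
    "BoundaryDiff",
    "ReorgEvent",
    "directionality_index",
    "di_from_flanks",
    "call_tads",
    "boundaries_of",
    "compare_boundaries",
    "classify_reorganization",
    "region_class_stats",
]

DEFAULT_DI_WINDOW_BP = 2_000_000


def di_from_flanks(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Closed-form DI from upstream (A) and downstream (B) contact sums."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    E = (A + B) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(E > 0, (A - E) ** 2 / np.where(E > 0, E, 1.0)
                       + (B - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    return np.sign(B - A) * chi


@dataclass
class DirectionalityTrack:
    """Per-bin DI with its upstream/downstream flank sums, per chromosome."""

    bins: BinTable
    window_bp: int
    A: dict[str, np.ndarray] = field(default_factory=dict)
    B: dict[str, np.ndarray] = field(default_factory=dict)
    di: dict[str, np.ndarray] = field(default_factory=dict)

    def genome_vector(self) -> np.ndarray:
        """DI as one vector over the global bin index (for track export)."""
        out = np.zeros(self.bins.n_bins)
        for chrom, v in self.di.items():
            off = self.bins.chrom_offsets[chrom]
            out[off : off + len(v)] = v
        return out


def directionality_index(
    cmap: ContactMap, window_bp: int = DEFAULT_DI_WINDOW_BP
) -> DirectionalityTrack:
    """Compute the DI track from a (40-kb) contact map.

    A sums contacts from bin i to bins [i-w, i); B to (i, i+w]; flanks are
    truncated at chromosome edges.
    """
    if window_bp < cmap.resolution:
        raise ValueError("window_bp must be >= resolution")
    w = window_bp // cmap.resolution
    track = DirectionalityTrack(bins=cmap.bins, window_bp=window_bp)
    for chrom in cmap.chroms:
        m = cmap.cis_matrix(chrom)
        n = m.shape[0]
        A = np.zeros(n)
        B = np.zeros(n)
        c = np.zeros((n, n + 1))
        c[:, 1:] = np.cumsum(m, axis=1)
        idx = np.arange(n)
        lo = np.maximum(idx - w, 0)
        hi = np.minimum(idx + w + 1, n)
        A = c[idx, idx] - c[idx, lo]          # [i-w, i)
        B = c[idx, hi] - c[idx, idx + 1]      # (i, i+w]
        track.A[chrom] = A
        track.B[chrom] = B
        track.di[chrom] = di_from_flanks(A, B)
    return track


@dataclass(frozen=True)
class Tad:
    """A TAD as a half-open bin range on one chromosome."""

    chrom: str
    start_bin: int
    end_bin: int

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    def span_bp(self, resolution: int) -> int:
        return self.n_bins * resolution

    def contains_bin(self, b: int) -> bool:
        return self.start_bin <= b < self.end_bin


@dataclass
class TadSet:
    """Disjoint, sorted TADs at one resolution."""

    resolution: int
    tads: list[Tad]

    def __post_init__(self) -> None:
        self.tads = sorted(self.tads, key=lambda t: (t.chrom, t.start_bin))
        prev: Tad | None = None
        for t in self.tads:
            if t.end_bin <= t.start_bin:
                raise ValueError(f"empty TAD {t}")
            if prev and prev.chrom == t.chrom and t.start_bin < prev.end_bin:
                raise ValueError(f"overlapping TADs {prev} and {t}")
            prev = t

    def __len__(self) -> int:
        return len(self.tads)

    def __iter__(self):
        return iter(self.tads)

    def by_chrom(self, chrom: str) -> list[Tad]:
        return [t for t in self.tads if t.chrom == chrom]

    def tad_containing(self, chrom: str, local_bin: int) -> Tad | None:
        for t in self.tads:
            if t.chrom == chrom and t.contains_bin(local_bin):
                return t
        return None


@dataclass
class BoundarySet:
    """Boundary bins derived from a TadSet.

    One boundary per distinct TAD start bin and per TAD last bin
    (end_bin - 1); when two TADs share a junction (one ends where the next
    starts) the junction contributes a single boundary at the start bin.
    """

    resolution: int
    boundaries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.boundaries = sorted(set(self.boundaries))

    def __len__(self) -> int:
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)

    def by_chrom(self, chrom: str) -> list[int]:
        return [b for c, b in self.boundaries if c == chrom]


def call_tads(
    di: DirectionalityTrack,
    resolution: int | None = None,
    t_sd: float = 0.5,
    min_size_bins: int = 3,
) -> TadSet:
    """Run-based TAD calling from a DI track.

    Per chromosome the threshold is ``t = t_sd * SD(nonzero DI)``. A TAD
    opens at the first bin of a downstream-biased (DI >= t) run and closes
    at the last bin of the next upstream-biased (DI <= -t) run. TADs
    shorter than ``min_size_bins`` are discarded. Output is invariant to
    scaling all counts by a positive constant (DI scales, and so does its SD).
    """
    resolution = resolution if resolution is not None else di.bins.resolution
    tads: list[Tad] = []
    for chrom, v in di.di.items():
        nz = v[v != 0]
        if nz.size == 0:
            warnings.warn(f"chromosome {chrom}: all-zero DI, no TADs called")
            continue
        t = t_sd * nz.std()
        if t == 0:
            warnings.warn(f"chromosome {chrom}: zero DI spread, no TADs called")
            continue
        start: int | None = None
        in_neg_run = False
        last_neg_end: int | None = None
        for i, x in enumerate(v):
            if x >= t:
                if in_neg_run and start is not None:
                    # downstream-biased run after a closing upstream run:
                    # emit the TAD and open the next one here
                    tads.append(Tad(chrom, start, last_neg_end + 1))
                    start = i
                    in_neg_run = False
                elif start is None:
                    start = i
            elif x <= -t:
                if start is not None:
                    in_neg_run = True
                    last_neg_end = i
            # neutral bins extend whatever run we are in
        if in_neg_run and start is not None:
            tads.append(Tad(chrom, start, last_neg_end + 1))
    kept = [t for t in tads if t.n_bins >= min_size_bins]
    return TadSet(resolution=resolution, tads=kept)


def boundaries_of(tads: TadSet) -> BoundarySet:
    """Boundary bins of a TadSet (see :class:`BoundarySet` for the junction
    deduplication rule)."""
    starts = {(t.chrom, t.start_bin) for t in tads}
    bounds: set[tuple[str, int]] = set(starts)
    for t in tads:
        if (t.chrom, t.end_bin) in starts:
            continue  # junction already represented by the next TAD's start
        bounds.add((t.chrom, t.end_bin - 1))
    return BoundarySet(resolution=tads.resolution, boundaries=sorted(bounds))


@dataclass
class BoundaryDiff:
    """Greedy matched boundary comparison between two conditions."""

    resolution: int
    shared: list[tuple[tuple[str, int], tuple[str, int]]]
    lost: list[tuple[str, int]]    # only in condition 1
    gained: list[tuple[str, int]]  # only in condition 2
    shared_fraction_1: float
    shared_fraction_2: float


def _greedy_match(
    b1: list[int], b2: list[int], tol: int
) -> list[tuple[int, int]]:
    """Greedy nearest matching within ``tol``; each element matched once.

    Candidate pairs are taken in order of (distance, position) which makes
    the match deterministic and symmetric in |matches|.
    """
    cands = [
        (abs(x - y), x, y, i, j)
        for i, x in enumerate(b1)
        for j, y in enumerate(b2)
        if abs(x - y) <= tol
    ]
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    out = []
    for _d, _x, _y, i, j in cands:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        out.append((i, j))
    return out


def compare_boundaries(
    b1: BoundarySet, b2: BoundarySet, tol_bins: int = 1
) -> BoundaryDiff:
    """Match boundaries across conditions within ``tol_bins`` (greedy nearest,
    each boundary matched at most once); the rest are gained/lost."""
    if b1.resolution != b2.resolution:
        raise ValueError("boundary sets have different resolutions")
    shared: list[tuple[tuple[str, int], tuple[str, int]]] = []
    lost: list[tuple[str, int]] = []
    gained: list[tuple[str, int]] = []
    chroms = sorted({c for c, _ in b1.boundaries} | {c for c, _ in b2.boundaries})
    for chrom in chroms:
        x1 = b1.by_chrom(chrom)
        x2 = b2.by_chrom(chrom)
        matched = _greedy_match(x1, x2, tol_bins)
        m1 = {i for i, _ in matched}
        m2 = {j for _, j in matched}
        shared.extend(((chrom, x1[i]), (chrom, x2[j])) for i, j in matched)
        lost.extend((chrom, x) for i, x in enumerate(x1) if i not in m1)
        gained.extend((chrom, x) for j, x in enumerate(x2) if j not in m2)
    n1, n2 = len(b1), len(b2)
    return BoundaryDiff(
        resolution=b1.resolution,
        shared=shared,
        lost=sorted(lost),
        gained=sorted(gained),
        shared_fraction_1=len(shared) / n1 if n1 else 0.0,
        shared_fraction_2=len(shared) / n2 if n2 else 0.0,
    )


@dataclass(frozen=True)
class ReorgEvent:
    """A TAD reorganization event between condition 1 and condition 2."""

    kind: str  # fusion | separation | shift
    chrom: str
    boundary_bins: tuple[int, ...]  # defining boundary bin(s); shift: (from, to)


def _union_overlap(t: Tad, others: list[Tad]) -> tuple[float, float]:
    """(overlap/|t|, overlap/|union span of others|) for reciprocal test."""
    ov = sum(
        max(0, min(t.end_bin, o.end_bin) - max(t.start_bin, o.start_bin))
        for o in others
    )
    union = sum(o.n_bins for o in others)
    return ov / t.n_bins, ov / union if union else 0.0


def classify_reorganization(
    tads1: TadSet,
    tads2: TadSet,
    tol_bins: int = 1,
    ro_min: float = 0.8,
    shift_max: int = 5,
) -> list[ReorgEvent]:
    """Type boundary changes as fusion / separation / shift.

    separation: a condition-1 TAD reciprocally overlapped (>= ro_min) by the
    union of >= 2 condition-2 TADs, with a gained boundary strictly inside
    it. fusion: the mirror case with a lost boundary. shift: boundaries
    matched at a distance in (tol_bins, shift_max] whose flanks are not
    already consumed by a fusion/separation. Swapping the two inputs maps
    fusion <-> separation and preserves shifts.
    """
    if tads1.resolution != tads2.resolution:
        raise ValueError("TAD sets have different resolutions")
    b1 = boundaries_of(tads1)
    b2 = boundaries_of(tads2)
    diff = compare_boundaries(b1, b2, tol_bins)
    gained = set(diff.gained)
    lost = set(diff.lost)
    events: list[ReorgEvent] = []
    used_gained: set[tuple[str, int]] = set()
    used_lost: set[tuple[str, int]] = set()

    for t in tads1:
        partners = [
            o
            for o in tads2.by_chrom(t.chrom)
            if min(t.end_bin, o.end_bin) > max(t.start_bin, o.start_bin)
        ]
        if len(partners) < 2:
            continue
        r1, r2 = _union_overlap(t, partners)
        if r1 < ro_min or r2 < ro_min:
            continue
        inside = [
            (c, b)
            for (c, b) in gained
            if c == t.chrom and t.start_bin < b < t.end_bin - 1 and (c, b) not in used_gained
        ]
        for key in inside:
            used_gained.add(key)
            events.append(ReorgEvent("separation", t.chrom, (key[1],)))

    for t in tads2:
        partners = [
            o
            for o in tads1.by_chrom(t.chrom)
            if min(t.end_bin, o.end_bin) > max(t.start_bin, o.start_bin)
        ]
        if len(partners) < 2:
            continue
        r1, r2 = _union_overlap(t, partners)
        if r1 < ro_min or r2 < ro_min:
            continue
        inside = [
            (c, b)
            for (c, b) in lost
            if c == t.chrom and t.start_bin < b < t.end_bin - 1 and (c, b) not in used_lost
        ]
        for key in inside:
            used_lost.add(key)
            events.append(ReorgEvent("fusion", t.chrom, (key[1],)))

    # shift: re-match the leftover unmatched boundaries at the wider tolerance
    chroms = sorted({c for c, _ in lost} | {c for c, _ in gained})
    for chrom in chroms:
        l = sorted(b for c, b in lost if c == chrom and (c, b) not in used_lost)
        g = sorted(b for c, b in gained if c == chrom and (c, b) not in used_gained)
        for i, j in _greedy_match(l, g, shift_max):
            if abs(l[i] - g[j]) > tol_bins:
                events.append(ReorgEvent("shift", chrom, (l[i], g[j])))
    events.sort(key=lambda e: (e.chrom, e.boundary_bins, e.kind))
    return events


def region_class_stats(
    tads: TadSet,
    bins: BinTable,
    genes: list[GeneModel],
    genome=None,
    border_flank_bins: int = 1,
):
    """Gene density (TSS per Mb) and GC fraction for TAD border vs inner bins.

    border = boundary bins +/- border_flank_bins; inner = TAD bins minus
    border. Returns a dict keyed by region class.
    """
    res = tads.resolution
    border: set[tuple[str, int]] = set()
    tad_bins: set[tuple[str, int]] = set()
    for t in tads:
        for b in range(t.start_bin, t.end_bin):
            tad_bins.add((t.chrom, b))
    for chrom, b in boundaries_of(tads):
        n_chrom = bins.n_bins_per_chrom.get(chrom, 0)
        for k in range(b - border_flank_bins, b + border_flank_bins + 1):
            if 0 <= k < n_chrom:
                border.add((chrom, k))
    inner = tad_bins - border

    def stats(region: set[tuple[str, int]]) -> dict:
        length_bp = 0
        intervals: list[GenomicInterval] = []
        for chrom, b in region:
            start = b * res
            end = min(start + res, bins.chrom_sizes[chrom])
            length_bp += end - start
            intervals.append(GenomicInterval(chrom, start, end))
        n_tss = sum(
            1
            for g in genes
            if (g.chrom, g.tss // res) in region
        )
        out = {
            "length_bp": length_bp,
            "n_tss": n_tss,
            "gene_density_per_mb": n_tss / (length_bp / 1e6) if length_bp else 0.0,
        }
        if genome is not None and intervals:
            vals = gc_content(intervals, genome)
            lengths = np.array([len(iv) for iv in intervals], dtype=float)
            ok = ~np.isnan(vals)
            out["gc_fraction"] = (
                float(np.average(vals[ok], weights=lengths[ok])) if ok.any() else float("nan")
            )
        return out

    return {"border": stats(border), "inner": stats(inner)}
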