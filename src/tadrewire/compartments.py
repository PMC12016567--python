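"""A/B compartment calling at 100-kb resolution.

Per chromosome the smoothed contact matrix is converted to observed/expected,
a Pearson correlation matrix is computed over covered bins (main diagonal
excluded), and the first eigenvector (largest-magnitude eigenvalue) scores
each bin. The sign is fixed so that positive-score bins have the higher mean
gene density (or GC content when that basis is selected); the A label then
means score > 0 and B means score < 0. Bins without coverage are NA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contact_matrix import ContactMap, observed_expected, smooth_map
from .genomic_io import BinTable, GeneModel, GenomicInterval, gc_content
from .tad_architecture import TadSet

__all__ = [
    "CompartmentTrack",
    "CompartmentSegment",
    "compartment_eigenvector",
    "assign_tad_compartments",
    "compartment_segments",
    "compare_compartments",
]


@dataclass
class CompartmentTrack:
    bins: BinTable
    score: np.ndarray  # NaN for unscored bins
    orientation_basis: str = "gene_density"

    @property
    def label(self) -> np.ndarray:
        """'A' for score > 0, 'B' for score < 0, 'NA' otherwise."""
        lab = np.full(self.bins.n_bins, "NA", dtype=object)
        ok = ~np.isnan(self.score)
        lab[ok & (self.score > 0)] = "A"
        lab[ok & (self.score < 0)] = "B"
        return lab


@dataclass(frozen=True)
class CompartmentSegment:
    chrom: str
    start: int
    end: int
    label: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _orientation_weights(
    bins: BinTable,
    genes: list[GeneModel] | None,
    genome,
    basis: str,
) -> np.ndarray:
    w = np.zeros(bins.n_bins)
    if basis == "gene_density":
        if genes is None:
            raise ValueError("gene models required for gene_density orientation")
        for g in genes:
            if g.chrom in bins.chrom_sizes and g.tss < bins.chrom_sizes[g.chrom]:
                w[bins.bin_index(g.chrom, g.tss)] += 1
    elif basis == "gc":
        if genome is None:
            raise ValueError("genome FASTA required for gc orientation")
        intervals = [
            GenomicInterval(chrom, start, end)
            for _idx, chrom, start, end in bins.iter_bins()
        ]
        vals = gc_content(intervals, genome)
        w = np.nan_to_num(vals)
    else:
        raise ValueError(f"unknown orientation basis {basis!r}")
    return w


def compartment_eigenvector(
    cmap: ContactMap,
    h: int = 1,
    genes: list[GeneModel] | None = None,
    genome=None,
    orientation_basis: str = "gene_density",
) -> CompartmentTrack:
    """First-eigenvector compartment score per (100-kb) bin."""
    bins = cmap.bins
    weights = _orientation_weights(bins, genes, genome, orientation_basis)
    score = np.full(bins.n_bins, np.nan)
    smoothed = smooth_map(cmap, h)
    for chrom in cmap.chroms:
        raw = cmap.cis_matrix(chrom)
        off = bins.chrom_offsets[chrom]
        covered = np.where(raw.sum(axis=0) > 0)[0]
        if covered.size < 3:
            warnings.warn(f"chromosome {chrom}: fewer than 3 covered bins, all NA")
            continue
        oe = observed_expected(smoothed, chrom)
        sub = oe[np.ix_(covered, covered)]
        # exclude the main diagonal from the correlation computation
        np.fill_diagonal(sub, np.nan)
        col_mean = np.nanmean(sub, axis=0)
        filled = np.where(np.isnan(sub), col_mean[None, :], sub)
        sd = filled.std(axis=0)
        if np.all(sd == 0):
            warnings.warn(f"chromosome {chrom}: degenerate O/E (constant), all NA")
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(filled, rowvar=False)
        corr = np.nan_to_num(corr)
        eigvals, eigvecs = np.linalg.eigh(corr)
        k = int(np.argmax(np.abs(eigvals)))
        ev = eigvecs[:, k]
        # orient: positive class gets the higher mean orientation weight
        w = weights[off + covered]
        pos, neg = ev > 0, ev < 0
        if pos.any() and neg.any() and w[pos].mean() < w[neg].mean():
            ev = -ev
        score[off + covered] = ev
    return CompartmentTrack(bins=bins, score=score, orientation_basis=orientation_basis)


def assign_tad_compartments(track: CompartmentTrack, tads: TadSet) -> list[str]:
    """Label each TAD A/B by the mean eigenvector score of the (100-kb) bins
    it overlaps by bp; a mean of exactly 0 or no scored bins gives 'NA'."""
    res_c = track.bins.resolution
    labels: list[str] = []
    for t in tads:
        start_bp = t.start_bin * tads.resolution
        end_bp = t.end_bin * tads.resolution
        if t.chrom not in track.bins.chrom_sizes:
            labels.append("NA")
            continue
        off = track.bins.chrom_offsets[t.chrom]
        n_chrom = track.bins.n_bins_per_chrom[t.chrom]
        lo = start_bp // res_c
        hi = min(-(-end_bp // res_c), n_chrom)
        vals = track.score[off + lo : off + hi]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            labels.append("NA")
        else:
            m = vals.mean()
            labels.append("A" if m > 0 else "B" if m < 0 else "NA")
    return labels


def compartment_segments(track: CompartmentTrack) -> list[CompartmentSegment]:
    """Maximal runs of identical non-NA label; NA bins break runs."""
    segments: list[CompartmentSegment] = []
    labels = track.label
    for chrom in track.bins.chrom_sizes:
        off = track.bins.chrom_offsets[chrom]
        n = track.bins.n_bins_per_chrom[chrom]
        res = track.bins.resolution
        size = track.bins.chrom_sizes[chrom]
        run_label: str | None = None
        run_start = 0
        for local in range(n + 1):
            lab = labels[off + local] if local < n else None
            if lab != run_label:
                if run_label in ("A", "B"):
                    segments.append(
                        CompartmentSegment(
                            chrom,
                            run_start * res,
                            min(local * res, size),
                            run_label,
                        )
                    )
                run_label = lab if lab in ("A", "B") else None
                run_start = local
    return segments


def segment_length_summary(segments: list[CompartmentSegment]) -> dict:
    out = {}
    for lab in ("A", "B"):
        lengths = np.array([s.length_bp for s in segments if s.label == lab])
        out[lab] = {
            "count": int(lengths.size),
            "median_bp": float(np.median(lengths)) if lengths.size else float("nan"),
            "total_bp": int(lengths.sum()) if lengths.size else 0,
        }
    return out


def compare_compartments(track1: CompartmentTrack, track2: CompartmentTrack) -> dict:
    """Label agreement and Pearson r of scores over bins labeled in both."""
    if track1.bins.n_bins != track2.bins.n_bins:
        raise ValueError("tracks are on different bin tables")
    l1, l2 = track1.label, track2.label
    both = (l1 != "NA") & (l2 != "NA")
    n = int(both.sum())
    if n == 0:
        raise ValueError("no bins labeled in both tracks")
    agreement = float((l1[both] == l2[both]).mean())
    s1 = track1.score[both]
    s2 = track2.score[both]
    r = float(np.corrcoef(s1, s2)[0, 1]) if n > 1 else float("nan")
    return {"label_agreement": agreement, "score_correlation": r, "n_bins": n}
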