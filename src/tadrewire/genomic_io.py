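"""Core genomic types and plain-text format readers/writers.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based inclusive) is converted on read: starts shift by -1, ends are kept.
Chromosome names are taken verbatim; no ``chr`` prefix normalisation is
applied unless requested by the caller.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "BinTable",
    "GeneModel",
    "PeakSet",
    "read_intervals",
    "read_gene_models",
    "make_bins",
    "interval_overlap",
    "gc_content",
    "write_track",
    "read_track",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", tolerance: int = 0) -> bool:
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.chrom != other.chrom:
            return False
        return self.start - tolerance < other.end and other.start < self.end + tolerance

    def distance_to_point(self, pos: int) -> int:
        """Genomic distance from this interval's midpoint to ``pos``."""
        return abs(self.midpoint - pos)


@dataclass
class BinTable:
    """Fixed-width tiling of a genome; last bin per chromosome may be short.

    Global bin indices are assigned by chromosome insertion order then start,
    and the mapping index <-> (chrom, start) is a bijection.
    """

    chrom_sizes: dict[str, int]
    resolution: int
    chrom_offsets: dict[str, int] = field(init=False)
    n_bins_per_chrom: dict[str, int] = field(init=False)
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        offsets: dict[str, int] = {}
        counts: dict[str, int] = {}
        total = 0
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
            n = -(-size // self.resolution)  # ceil division
            offsets[chrom] = total
            counts[chrom] = n
            total += n
        self.chrom_offsets = offsets
        self.n_bins_per_chrom = counts
        self.n_bins = total

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base ``pos``."""
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < self.chrom_sizes[chrom]):
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offsets[chrom] + pos // self.resolution

    def bin_location(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with global ``index``."""
        if not (0 <= index < self.n_bins):
            raise IndexError(f"bin index {index} out of range")
        for chrom, off in self.chrom_offsets.items():
            n = self.n_bins_per_chrom[chrom]
            if off <= index < off + n:
                local = index - off
                start = local * self.resolution
                end = min(start + self.resolution, self.chrom_sizes[chrom])
                return chrom, start, end
        raise IndexError(index)  # pragma: no cover

    def chrom_of(self, index: int) -> str:
        return self.bin_location(index)[0]

    def iter_bins(self) -> Iterable[tuple[int, str, int, int]]:
        idx = 0
        for chrom, size in self.chrom_sizes.items():
            for local in range(self.n_bins_per_chrom[chrom]):
                start = local * self.resolution
                end = min(start + self.resolution, size)
                yield idx, chrom, start, end
                idx += 1

    def bin_midpoint_bp(self, chrom: str, local_bin: int) -> int:
        start = local_bin * self.resolution
        end = min(start + self.resolution, self.chrom_sizes[chrom])
        return (start + end) // 2


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS, genomic span and exonic length (for RPKM)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    span: GenomicInterval
    exonic_length: int

    def __post_init__(self) -> None:
        if self.exonic_length < 1:
            raise ValueError("exonic_length must be >= 1")
        expected = self.span.start if self.strand == "+" else self.span.end - 1
        if self.tss != expected:
            raise ValueError(
                f"tss {self.tss} inconsistent with strand {self.strand} span"
            )

    def promoter(self, halfwidth: int = 2000) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, max(0, self.tss - halfwidth), self.tss + halfwidth
        )


@dataclass
class PeakSet:
    """Sorted collection of peak intervals for one assay in one condition."""

    condition: str
    assay: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def overlapping(self, query: GenomicInterval, tolerance: int = 0) -> list[GenomicInterval]:
        return [p for p in self.peaks if p.overlaps(query, tolerance)]


def read_intervals(path, fmt: str = "BED", condition: str = "", assay: str = "") -> PeakSet:
    """Read a BED or narrowPeak file into a :class:`PeakSet`.

    narrowPeak column 7 (signalValue) is retained as ``score``; the summit
    column is ignored, peaks are treated purely as intervals.
    """
    if fmt not in ("BED", "narrowPeak"):
        raise ValueError(f"unknown format {fmt!r}")
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            score: float | None = None
            if fmt == "narrowPeak" and len(fields) >= 7:
                score = float(fields[6])
            elif len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                peaks.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(condition=condition, assay=assay, peaks=peaks)


def write_peaks(peakset: PeakSet, path) -> None:
    """Write a PeakSet as BED6 (score column empty-safe)."""
    with open(path, "w") as fh:
        for p in peakset:
            score = "0" if p.score is None else f"{p.score:g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t{score}\t{p.strand}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if " " in item:
            key, _, value = item.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def read_gene_models(path) -> list[GeneModel]:
    """Parse gene and exon features from a GTF file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    ``exonic_length`` is the length of the union of a gene's exons; a gene
    with no exon features falls back to its span length with a warning.
    """
    spans: dict[str, tuple[str, int, int, str, str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            start = int(start1) - 1  # GTF 1-based inclusive -> 0-based half-open
            end = int(end1)
            attrs = _parse_gtf_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                name = attrs.get("gene_name", gid)
                spans[gid] = (chrom, start, end, strand, name)
                order.append(gid)
            else:
                exons.setdefault(gid, []).append((start, end))
    genes: list[GeneModel] = []
    for gid in order:
        chrom, start, end, strand, name = spans[gid]
        if gid in exons:
            exonic = _union_length(exons[gid])
        else:
            exonic = end - start
            warnings.warn(f"gene {gid} has no exon features; using span length")
        tss = start if strand == "+" else end - 1
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=name,
                chrom=chrom,
                strand=strand,
                tss=tss,
                span=GenomicInterval(chrom, start, end, strand=strand),
                exonic_length=exonic,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as a minimal GTF (gene + one exon per gene span)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            base = (
                f"{g.chrom}\ttadrewire\t{{feat}}\t{g.span.start + 1}\t{g.span.end}\t."
                f"\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(base.format(feat="gene"))
            # single exon spanning exonic_length from the TSS-proximal end
            if g.strand == "+":
                es, ee = g.span.start, g.span.start + g.exonic_length
            else:
                es, ee = g.span.end - g.exonic_length, g.span.end
            fh.write(
                f"{g.chrom}\ttadrewire\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def make_bins(chrom_sizes: dict[str, int], resolution: int) -> BinTable:
    """Tile each chromosome with ``resolution``-bp bins (last bin may be short)."""
    return BinTable(chrom_sizes=dict(chrom_sizes), resolution=resolution)


def interval_overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    tolerance: int = 0,
) -> list[tuple[int, int]]:
    """All index pairs (i, j) where ``a[i]`` expanded by ``tolerance`` on each
    side intersects ``b[j]``.

    Sweep-line over per-chromosome sorted endpoints; equivalent to the O(n*m)
    all-pairs check.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom_b: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom_b.values():
        lst.sort()
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(a):
        cand = by_chrom_b.get(iv.chrom)
        if not cand:
            continue
        lo = iv.start - tolerance
        hi = iv.end + tolerance
        starts = [c[0] for c in cand]
        k = bisect.bisect_left(starts, hi)
        for s, e, j in cand[:k]:
            if e > lo:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def gc_content(intervals: Sequence[GenomicInterval], genome) -> np.ndarray:
    """GC fraction per interval from an indexed FASTA (pyfaidx.Fasta).

    N bases are excluded from the denominator; an all-N interval yields NaN.
    """
    out = np.empty(len(intervals))
    for k, iv in enumerate(intervals):
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} missing from genome FASTA")
        seq = str(genome[iv.chrom][iv.start : iv.end]).upper()
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        out[k] = gc / acgt if acgt else np.nan
    return out


def write_track(values: Sequence[float], bins: BinTable, path) -> None:
    """Write per-bin values as bedGraph; NaN values are omitted.

    Values round-trip through :func:`read_track` to 6 decimals.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != bins.n_bins:
        raise ValueError(
            f"value vector length {len(values)} != number of bins {bins.n_bins}"
        )
    with open(path, "w") as fh:
        for idx, chrom, start, end in bins.iter_bins():
            v = values[idx]
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.6f}\n")


def read_track(path, bins: BinTable) -> np.ndarray:
    """Read a bedGraph written by :func:`write_track` back onto ``bins``."""
    values = np.full(bins.n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, value = line.rstrip("\n").split("\t")
            values[bins.bin_index(chrom, int(start))] = float(value)
    return values
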