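"""Seeded two-condition multi-omics simulator with planted truth.

The generator emulates the data regime this pipeline targets: block-
structured cis contact maps with power-law distance decay and Poisson
counts; a condition-2 TAD layout derived from condition 1 by planted
fusion / separation / shift events; CTCF peaks at boundaries, present only
in the conditions where the boundary exists; ATAC promoter and enhancer
peaks; and an RNA count matrix with planted fold changes whose sign follows
the mechanism direction rules. Decoy genes violate exactly one candidate
criterion each (distance, accessibility, DEG status, or direction) so a
classifier failure localizes the broken rule.

All outputs are fully determined by (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .contact_matrix import ContactMap
from .expression import CountMatrix
from .genomic_io import BinTable, GeneModel, GenomicInterval, PeakSet, make_bins

__all__ = [
    "ScenarioSpec",
    "PlantedGene",
    "TruthManifest",
    "simulate_contact_map",
    "simulate_condition_pair",
    "simulate_regulome",
    "simulate_deg_counts",
    "simulate_checkerboard",
]


@dataclass
class ScenarioSpec:
    """Study conditions for the default planted scenario.

    Defaults: 2 chromosomes x 20 Mb at 40-kb bins, 1e5 cis pairs per
    chromosome, within-TAD enrichment 3 over a power-law decay with
    exponent 1, nominal 800-kb TADs (separation halves 400 kb, inside the
    200 kb - 1 Mb range typical of mammalian TADs); 4 mechanism-1 and 4 mechanism-2
    planted pairs, 8 one-violation decoys, and null filler genes. RNA
    counts are negative binomial (dispersion 0.1) around a 400-count
    baseline with 10-fold planted changes (single samples per condition at
    this dispersion need an order-of-magnitude effect to be unambiguous).
    """

    n_chroms: int = 2
    chrom_length_bp: int = 20_000_000
    resolution: int = 40_000
    tad_size_bins: int = 20
    depth: float = 100_000.0  # cis pairs per chromosome
    decay_exponent: float = 1.0
    block_enrichment: float = 3.0
    n_extra_fusion: int = 2
    n_extra_separation: int = 2
    n_extra_shift: int = 4
    shift_bins: int = 2
    include_planted_pairs: bool = True
    include_decoys: bool = True
    n_filler_genes: int = 42
    base_mean: float = 400.0
    planted_fc: float = 10.0
    rna_dispersion: float = 0.1
    gene_exonic_length: int = 2_000
    promoter_peak_halfwidth: int = 300
    enhancer_peak_halfwidth: int = 200
    ctcf_peak_halfwidth: int = 150
    seed: int = 42

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chrS{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}

    @property
    def n_bins_per_chrom(self) -> int:
        return -(-self.chrom_length_bp // self.resolution)


@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # fusion | separation | shift
    chrom: str
    bin: int  # defining boundary bin (separation: new; fusion: removed;
    # shift: condition-1 position)
    shift_to: int | None = None


@dataclass(frozen=True)
class PlantedGene:
    """A gene planted at an event locus, with its expected classification.

    ``violation`` is None for expected positives; decoys name the single
    criterion they break.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    enhancer_start: int
    enhancer_end: int
    mechanism: int  # 1 | 2 (intended geometry; decoys keep their intent)
    change: str  # gained | lost
    expression: str  # up | down | none
    expected_direction: str | None  # activation | deactivation | None
    expected_role: str | None  # oncogene | suppressor | None
    violation: str | None  # None | distance | accessibility | deg | direction
    event_bin: int


@dataclass
class TruthManifest:
    resolution: int
    chrom_sizes: dict[str, int]
    boundaries_1: dict[str, list[int]]  # interior junction bins, condition 1
    boundaries_2: dict[str, list[int]]
    events: list[PlantedEvent]
    planted_genes: list[PlantedGene] = field(default_factory=list)
    deg_truth: dict[str, str] = field(default_factory=dict)  # gene -> up|down|none

    @property
    def expected_pairs(self) -> list[PlantedGene]:
        return [g for g in self.planted_genes if g.violation is None]

    @property
    def decoys(self) -> list[PlantedGene]:
        return [g for g in self.planted_genes if g.violation is not None]

    def to_json(self, path) -> None:
        payload = {
            "resolution": self.resolution,
            "chrom_sizes": self.chrom_sizes,
            "boundaries_1": self.boundaries_1,
            "boundaries_2": self.boundaries_2,
            "events": [asdict(e) for e in self.events],
            "planted_genes": [asdict(g) for g in self.planted_genes],
            "deg_truth": self.deg_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            resolution=d["resolution"],
            chrom_sizes=d["chrom_sizes"],
            boundaries_1=d["boundaries_1"],
            boundaries_2=d["boundaries_2"],
            events=[PlantedEvent(**e) for e in d["events"]],
            planted_genes=[PlantedGene(**g) for g in d["planted_genes"]],
            deg_truth=d["deg_truth"],
        )


def _partition_from_boundaries(n_bins: int, interior: list[int]) -> list[tuple[int, int]]:
    """TAD intervals [start, end) from interior junction bins."""
    cuts = [0] + sorted(interior) + [n_bins]
    return [(cuts[k], cuts[k + 1]) for k in range(len(cuts) - 1)]


def simulate_contact_map(
    boundaries_by_chrom: dict[str, list[int]],
    chrom_sizes: dict[str, int],
    resolution: int,
    depth: float,
    decay_exponent: float = 1.0,
    block_enrichment: float = 3.0,
    seed: int = 0,
) -> ContactMap:
    """Poisson contact map with planted block-TAD structure.

    Expected count for bin pair (i, j) is proportional to
    ``(|i-j|+1)^(-decay_exponent) * block_enrichment^[same TAD]``, scaled so
    the upper triangle of each chromosome sums to ``depth`` in expectation.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    bins = make_bins(chrom_sizes, resolution)
    cmap = ContactMap(bins=bins)
    for chrom in chrom_sizes:
        n = bins.n_bins_per_chrom[chrom]
        interior = boundaries_by_chrom.get(chrom, [])
        tad_id = np.zeros(n, dtype=int)
        for k, (s, e) in enumerate(_partition_from_boundaries(n, interior)):
            tad_id[s:e] = k
        i, j = np.indices((n, n))
        lam = (np.abs(i - j) + 1.0) ** (-decay_exponent)
        lam *= np.where(tad_id[i] == tad_id[j], block_enrichment, 1.0)
        upper = np.triu(lam)
        lam *= depth / upper.sum()
        upper_counts = rng.poisson(np.triu(lam))
        m = upper_counts + np.triu(upper_counts, 1).T
        cmap.cis[chrom] = m.astype(float)
    return cmap


def _grid_boundaries(n_bins: int, tad_size: int) -> list[int]:
    return list(range(tad_size, n_bins - tad_size + 1, tad_size))


def _plan_scenario(spec: ScenarioSpec) -> TruthManifest:
    """Lay out condition-1 TADs, allocate events to spaced loci and place
    planted/decoy genes (deterministic given the scenario settings)."""
    res = spec.resolution
    n_bins = spec.n_bins_per_chrom
    chroms = list(spec.chrom_sizes)
    layout1 = {c: _grid_boundaries(n_bins, spec.tad_size_bins) for c in chroms}

    # event slots: every 2nd TAD, skipping the chromosome-end TADs. Loci
    # that carry a planted gene are kept outside the DI flank-truncation
    # zone (within window_bp of a chromosome end the truncated flank biases
    # the index); edge slots are still used for gene-free stress events.
    n_tads = n_bins // spec.tad_size_bins
    di_edge_bins = 2_000_000 // res
    interior: list[tuple[str, int]] = []
    edge: list[tuple[str, int]] = []
    for t in range(1, n_tads - 1, 2):
        for c in chroms:
            s, e = t * spec.tad_size_bins, (t + 1) * spec.tad_size_bins
            if s >= di_edge_bins and e <= n_bins - di_edge_bins:
                interior.append((c, t))
            else:
                edge.append((c, t))
    gene_slots = iter(interior)
    extra_slots = iter(edge)

    def take_slot(for_gene: bool = True) -> tuple[str, int]:
        source = gene_slots if for_gene else extra_slots
        try:
            return next(source)
        except StopIteration:
            pass
        if not for_gene:
            # extras fall back to unused interior slots
            try:
                return next(gene_slots)
            except StopIteration as exc:
                raise ValueError("scenario too dense: not enough event loci") from exc
        raise ValueError("scenario too dense: not enough gene loci")

    events: list[PlantedEvent] = []
    genes: list[PlantedGene] = []
    gene_no = 0

    def new_gene_id() -> str:
        nonlocal gene_no
        gene_no += 1
        return f"G{gene_no:04d}"

    def add_event(kind: str, for_gene: bool = True) -> PlantedEvent:
        chrom, t = take_slot(for_gene)
        s = t * spec.tad_size_bins
        e = s + spec.tad_size_bins
        if kind == "separation":
            ev = PlantedEvent("separation", chrom, (s + e) // 2)
        elif kind == "fusion":
            ev = PlantedEvent("fusion", chrom, e)
        else:
            ev = PlantedEvent("shift", chrom, e, shift_to=e + spec.shift_bins)
        events.append(ev)
        return ev

    def mid(b: int) -> int:
        return b * res + res // 2

    def place_gene(
        ev: PlantedEvent,
        mechanism: int,
        expression: str,
        violation: str | None,
        enhancer_offset: int | None = None,
    ) -> None:
        change = "gained" if ev.kind == "separation" else "lost"
        b = ev.bin
        if mechanism == 1:
            tss = mid(b) - 8_000
            enh_center = mid(b) + (enhancer_offset if enhancer_offset else 8_000)
        else:
            tss = mid(b - 2) if violation == "distance" else mid(b - 1)
            enh_center = mid(b + 1)
        if violation is None:
            direction = "activation" if expression == "up" else "deactivation"
            role = "oncogene" if expression == "up" else "suppressor"
        else:
            direction = role = None
        genes.append(
            PlantedGene(
                gene_id=new_gene_id(),
                chrom=ev.chrom,
                tss=tss,
                strand="+",
                enhancer_start=enh_center - spec.enhancer_peak_halfwidth,
                enhancer_end=enh_center + spec.enhancer_peak_halfwidth,
                mechanism=mechanism,
                change=change,
                expression=expression,
                expected_direction=direction,
                expected_role=role,
                violation=violation,
                event_bin=b,
            )
        )

    if spec.include_planted_pairs:
        # mechanism 1: boundary gain -> deactivation (down, suppressor);
        # boundary loss -> activation (up, oncogene)
        for _ in range(2):
            place_gene(add_event("separation"), 1, "down", None)
        for _ in range(2):
            place_gene(add_event("fusion"), 1, "up", None)
        # mechanism 2 (printed rules): gain -> activation; loss -> deactivation
        for _ in range(2):
            place_gene(add_event("separation"), 2, "up", None)
        for _ in range(2):
            place_gene(add_event("fusion"), 2, "down", None)

    if spec.include_decoys:
        place_gene(add_event("separation"), 1, "down", "distance", enhancer_offset=30_000)
        place_gene(add_event("fusion"), 2, "down", "distance")
        place_gene(add_event("separation"), 1, "down", "accessibility")
        place_gene(add_event("fusion"), 2, "down", "accessibility")
        place_gene(add_event("separation"), 1, "none", "deg")
        place_gene(add_event("fusion"), 2, "none", "deg")
        # wrong direction at inter-TAD distances (at intra-TAD distances any
        # direction satisfies one of the two mechanisms' rule tables)
        place_gene(add_event("separation"), 2, "down", "direction")
        place_gene(add_event("fusion"), 2, "up", "direction")

    for _ in range(spec.n_extra_separation):
        add_event("separation", for_gene=False)
    for _ in range(spec.n_extra_fusion):
        add_event("fusion", for_gene=False)
    for _ in range(spec.n_extra_shift):
        add_event("shift", for_gene=False)

    # derive the condition-2 layout from the planted events
    layout2 = {c: list(v) for c, v in layout1.items()}
    defined: set[tuple[str, int]] = set()
    for ev in events:
        touched = [ev.bin] if ev.shift_to is None else [ev.bin, ev.shift_to]
        for b in touched:
            if (ev.chrom, b) in defined:
                raise ValueError(f"overlapping planted events at {ev.chrom}:{b}")
            defined.add((ev.chrom, b))
        l2 = layout2[ev.chrom]
        if ev.kind == "separation":
            l2.append(ev.bin)
        elif ev.kind == "fusion":
            l2.remove(ev.bin)
        else:
            l2.remove(ev.bin)
            l2.append(ev.shift_to)
    for c in layout2:
        layout2[c] = sorted(layout2[c])

    return TruthManifest(
        resolution=res,
        chrom_sizes=dict(spec.chrom_sizes),
        boundaries_1={c: sorted(v) for c, v in layout1.items()},
        boundaries_2=layout2,
        events=events,
        planted_genes=genes,
    )


def simulate_condition_pair(
    spec: ScenarioSpec,
) -> tuple[ContactMap, ContactMap, TruthManifest]:
    """Contact maps for both conditions plus the planted-truth manifest."""
    manifest = _plan_scenario(spec)
    cmap1 = simulate_contact_map(
        manifest.boundaries_1,
        spec.chrom_sizes,
        spec.resolution,
        spec.depth,
        spec.decay_exponent,
        spec.block_enrichment,
        seed=spec.seed,
    )
    cmap2 = simulate_contact_map(
        manifest.boundaries_2,
        spec.chrom_sizes,
        spec.resolution,
        spec.depth,
        spec.decay_exponent,
        spec.block_enrichment,
        seed=spec.seed + 1,
    )
    return cmap1, cmap2, manifest


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_regulome(
    spec: ScenarioSpec, manifest: TruthManifest
) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet, list[GeneModel], CountMatrix]:
    """Peak sets, gene models and the RNA count matrix coupled to the
    planted events. Returns (ctcf1, ctcf2, atac1, atac2, genes, counts)."""
    rng = np.random.default_rng(spec.seed + 1000)
    res = manifest.resolution

    def ctcf_peaks(boundaries: dict[str, list[int]], condition: str) -> PeakSet:
        peaks = []
        for chrom, bs in boundaries.items():
            for b in bs:
                center = b * res + res // 2
                peaks.append(
                    GenomicInterval(
                        chrom,
                        center - spec.ctcf_peak_halfwidth,
                        center + spec.ctcf_peak_halfwidth,
                        name=f"ctcf_{chrom}_{b}",
                    )
                )
        return PeakSet(condition=condition, assay="CTCF", peaks=peaks)

    ctcf1 = ctcf_peaks(manifest.boundaries_1, "cond1")
    ctcf2 = ctcf_peaks(manifest.boundaries_2, "cond2")

    genes: list[GeneModel] = []
    atac1_peaks: list[GenomicInterval] = []
    atac2_peaks: list[GenomicInterval] = []
    expression: dict[str, str] = {}

    def add_gene(gene_id: str, chrom: str, tss: int, strand: str) -> None:
        length = 6_000
        if strand == "+":
            span = GenomicInterval(chrom, tss, tss + length, strand=strand)
        else:
            span = GenomicInterval(chrom, tss - length + 1, tss + 1, strand=strand)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_id,
                chrom=chrom,
                strand=strand,
                tss=tss,
                span=span,
                exonic_length=spec.gene_exonic_length,
            )
        )

    for pg in manifest.planted_genes:
        add_gene(pg.gene_id, pg.chrom, pg.tss, pg.strand)
        expression[pg.gene_id] = pg.expression
        prom = GenomicInterval(
            pg.chrom,
            pg.tss - spec.promoter_peak_halfwidth,
            pg.tss + spec.promoter_peak_halfwidth,
            name=f"prom_{pg.gene_id}",
        )
        enh = GenomicInterval(
            pg.chrom, pg.enhancer_start, pg.enhancer_end, name=f"enh_{pg.gene_id}"
        )
        atac1_peaks.append(prom)
        atac2_peaks.append(prom)
        atac1_peaks.append(enh)
        if pg.violation != "accessibility":
            atac2_peaks.append(enh)

    # filler genes: accessible promoters, no expression change, spread over
    # the genome away from any planted locus
    chroms = list(manifest.chrom_sizes)
    event_loci = {(e.chrom, e.bin) for e in manifest.events}
    n_bins = next(iter(manifest.chrom_sizes.values())) // res
    k = 0
    attempt = 0
    while k < spec.n_filler_genes:
        attempt += 1
        chrom = chroms[attempt % len(chroms)]
        b = int(rng.integers(2, n_bins - 2))
        if any(abs(b - eb) < 3 for ec, eb in event_loci if ec == chrom):
            continue
        tss = b * res + int(rng.integers(5_000, res - 5_000))
        gid = f"F{k + 1:04d}"
        add_gene(gid, chrom, tss, "+")
        expression[gid] = "none"
        prom = GenomicInterval(
            chrom,
            tss - spec.promoter_peak_halfwidth,
            tss + spec.promoter_peak_halfwidth,
            name=f"prom_{gid}",
        )
        atac1_peaks.append(prom)
        atac2_peaks.append(prom)
        k += 1

    counts = np.zeros((len(genes), 2), dtype=int)
    for gi, g in enumerate(genes):
        base = float(rng.uniform(0.75, 1.25) * spec.base_mean)
        status = expression[g.gene_id]
        mean1 = base
        if status == "up":
            mean2 = base * spec.planted_fc
        elif status == "down":
            mean2 = base / spec.planted_fc
        else:
            mean2 = base
        counts[gi, 0] = _nb_draw(rng, mean1, spec.rna_dispersion)
        counts[gi, 1] = _nb_draw(rng, mean2, spec.rna_dispersion)

    manifest.deg_truth = expression
    count_matrix = CountMatrix(
        gene_ids=[g.gene_id for g in genes],
        samples=["cond1", "cond2"],
        counts=counts,
        exonic_lengths=np.full(len(genes), spec.gene_exonic_length),
    )
    return (
        ctcf1,
        ctcf2,
        PeakSet(condition="cond1", assay="ATAC", peaks=atac1_peaks),
        PeakSet(condition="cond2", assay="ATAC", peaks=atac2_peaks),
        genes,
        count_matrix,
    )


def simulate_deg_counts(
    n_null: int = 1000,
    n_de: int = 50,
    fold: float = 8.0,
    base_mean: float = 400.0,
    dispersion: float = 0.1,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Two-condition NB count matrix with ``n_de`` planted fold changes
    (half up, half down).

    Each condition is sequenced as ``n_replicates`` library replicates with
    per-replicate NB noise at the given dispersion, summed per condition —
    matching the differential caller's pooled-replicate contract. Returns
    (counts, is_de truth vector).
    """
    rng = np.random.default_rng(seed)
    n = n_null + n_de
    is_de = np.zeros(n, dtype=bool)
    is_de[:n_de] = True
    means1 = rng.uniform(0.5, 1.5, n) * base_mean
    means2 = means1.copy()
    means2[: n_de // 2] *= fold
    means2[n_de // 2 : n_de] /= fold
    perm = rng.permutation(n)
    means1, means2, is_de = means1[perm], means2[perm], is_de[perm]
    r = 1.0 / dispersion
    col1 = sum(
        rng.negative_binomial(r, r / (r + means1)) for _ in range(n_replicates)
    )
    col2 = sum(
        rng.negative_binomial(r, r / (r + means2)) for _ in range(n_replicates)
    )
    counts = np.stack([col1, col2], axis=1)
    cm = CountMatrix(
        gene_ids=[f"G{i:04d}" for i in range(n)],
        samples=["cond1", "cond2"],
        counts=counts,
        exonic_lengths=np.full(n, 1_000),
    )
    return cm, is_de


def simulate_checkerboard(
    n_bins: int = 200,
    block_bins: int = 10,
    resolution: int = 100_000,
    depth: float = 500_000.0,
    within_enrichment: float = 2.0,
    seed: int = 0,
    chrom: str = "chrS1",
) -> tuple[ContactMap, np.ndarray, list[GeneModel]]:
    """Two-compartment checkerboard map with planted A/B labels.

    Same-label bin pairs are enriched ``within_enrichment``-fold over the
    distance decay. Gene models (denser in A bins) are returned for
    eigenvector orientation. Returns (map, labels, genes) with labels in
    {'A', 'B'} per bin.
    """
    rng = np.random.default_rng(seed)
    labels = np.where((np.arange(n_bins) // block_bins) % 2 == 0, "A", "B")
    chrom_sizes = {chrom: n_bins * resolution}
    bins = make_bins(chrom_sizes, resolution)
    cmap = ContactMap(bins=bins)
    i, j = np.indices((n_bins, n_bins))
    lam = (np.abs(i - j) + 1.0) ** -1.0
    lam *= np.where(labels[i] == labels[j], within_enrichment, 1.0)
    lam *= depth / np.triu(lam).sum()
    upper = rng.poisson(np.triu(lam))
    cmap.cis[chrom] = (upper + np.triu(upper, 1).T).astype(float)
    genes: list[GeneModel] = []
    gid = 0
    for b in range(n_bins):
        n_genes = 3 if labels[b] == "A" else 1
        for k in range(n_genes):
            gid += 1
            tss = b * resolution + (k + 1) * resolution // (n_genes + 1)
            genes.append(
                GeneModel(
                    gene_id=f"C{gid:04d}",
                    gene_name=f"C{gid:04d}",
                    chrom=chrom,
                    strand="+",
                    tss=tss,
                    span=GenomicInterval(chrom, tss, tss + 1_000),
                    exonic_length=1_000,
                )
            )
    return cmap, labels, genes
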