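"""CTCF-mediated boundary-alteration events and mechanism-1/2 pair calling.

The pipeline's terminal stage. Condition 2 is conventionally the tumor:

* step 1 — differential TAD boundaries that co-occur with condition-specific
  CTCF peaks become :class:`BoundaryAlterationEvent` records;
* step 2 — differentially expressed genes near an event whose promoter is
  ATAC-accessible in both conditions become candidate genes;
* step 3 — promoter-distal, both-condition-accessible ATAC peaks are paired
  with candidate genes under the intra-TAD (mechanism 1, < 20 kb, boundary
  between peak and TSS) or inter-TAD (mechanism 2, < 100 kb, peak/TSS TAD
  co-membership changes between conditions) model, with the direction rules
  applied from a named preset.

Direction presets: ``printed`` (mechanism 1: boundary gain -> deactivation,
loss -> activation; mechanism 2: gain -> activation, loss -> deactivation)
and ``worked_example`` (mechanism 2 reversed, matching the fusion->activation
geometry of the tool's flagship locus). A gene up-regulated in condition 2
is tagged an oncogene candidate, down-regulated a suppressor candidate —
a labeling convention, not a biological assertion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expression import ExpressionResult
from .genomic_io import GeneModel, GenomicInterval, PeakSet
from .tad_architecture import BoundaryDiff, TadSet

__all__ = [
    "BoundaryAlterationEvent",
    "CandidatePair",
    "DIRECTION_PRESETS",
    "ctcf_boundary_events",
    "candidate_genes",
    "accessible_peaks",
    "classify_mechanism1",
    "classify_mechanism2",
    "classify_pairs",
]

# mechanism -> boundary change -> pair direction
DIRECTION_PRESETS: dict[str, dict[int, dict[str, str]]] = {
    "printed": {
        1: {"gained": "deactivation", "lost": "activation"},
        2: {"gained": "activation", "lost": "deactivation"},
    },
    "worked_example": {
        1: {"gained": "deactivation", "lost": "activation"},
        2: {"gained": "deactivation", "lost": "activation"},
    },
}

_DIRECTION_FLAG = {"activation": "up", "deactivation": "down"}


@dataclass(frozen=True)
class BoundaryAlterationEvent:
    """A differential TAD boundary co-occurring with a condition-specific
    CTCF peak that agrees in direction (gained with gained, lost with lost)."""

    chrom: str
    boundary_bin: int
    boundary_bp: int  # bin midpoint
    change: str  # gained | lost (condition 2 vs condition 1)

    @property
    def ctcf_change(self) -> str:
        return self.change


@dataclass(frozen=True)
class CandidatePair:
    gene_id: str
    gene_name: str
    peak: GenomicInterval
    event: BoundaryAlterationEvent
    mechanism: int
    direction: str  # activation | deactivation
    role: str  # oncogene | suppressor
    distance_bp: int
    log2_fc: float
    fdr: float


def ctcf_boundary_events(
    bdiff: BoundaryDiff,
    ctcf1: PeakSet,
    ctcf2: PeakSet,
    tol_bp: int = 40_000,
) -> list[BoundaryAlterationEvent]:
    """Retain differential boundaries supported by a condition-specific CTCF
    peak.

    A gained boundary is kept iff some condition-2 CTCF peak overlaps the
    boundary bin expanded by ``tol_bp`` and no condition-1 peak does
    (condition-2-specific occupancy); lost boundaries mirror the rule with
    condition-1-specific peaks.
    """
    res = bdiff.resolution
    events: list[BoundaryAlterationEvent] = []

    def window(chrom: str, b: int) -> GenomicInterval:
        return GenomicInterval(chrom, max(0, b * res - tol_bp), (b + 1) * res + tol_bp)

    for chrom, b in bdiff.gained:
        win = window(chrom, b)
        if ctcf2.overlapping(win) and not ctcf1.overlapping(win):
            events.append(
                BoundaryAlterationEvent(chrom, b, b * res + res // 2, "gained")
            )
    for chrom, b in bdiff.lost:
        win = window(chrom, b)
        if ctcf1.overlapping(win) and not ctcf2.overlapping(win):
            events.append(
                BoundaryAlterationEvent(chrom, b, b * res + res // 2, "lost")
            )
    events.sort(key=lambda e: (e.chrom, e.boundary_bin))
    return events


def candidate_genes(
    events: list[BoundaryAlterationEvent],
    genes: list[GeneModel],
    expr: ExpressionResult,
    atac1: PeakSet,
    atac2: PeakSet,
    promoter_halfwidth: int = 2_000,
    search_radius: int = 1_000_000,
) -> list[GeneModel]:
    """Differentially expressed genes near an event whose promoter is
    accessible in both conditions."""
    out: list[GeneModel] = []
    for g in genes:
        if expr.flag_of(g.gene_id) == "none":
            continue
        prom = g.promoter(promoter_halfwidth)
        near = any(
            e.chrom == g.chrom and abs(e.boundary_bp - g.tss) <= search_radius
            for e in events
        )
        if not near:
            continue
        if atac1.overlapping(prom) and atac2.overlapping(prom):
            out.append(g)
    return out


def accessible_peaks(atac1: PeakSet, atac2: PeakSet) -> list[GenomicInterval]:
    """Peaks accessible in both conditions (condition-1 peaks that overlap a
    condition-2 peak)."""
    return [p for p in atac1 if atac2.overlapping(p)]


def _promoter_distal(peak: GenomicInterval, gene: GeneModel, halfwidth: int) -> bool:
    return not peak.overlaps(gene.promoter(halfwidth))


def _boundary_between(
    event: BoundaryAlterationEvent,
    gene: GeneModel,
    peak: GenomicInterval,
    slack_bp: int,
) -> bool:
    if event.chrom != gene.chrom:
        return False
    lo = min(gene.tss, peak.midpoint) - slack_bp
    hi = max(gene.tss, peak.midpoint) + slack_bp
    return lo < event.boundary_bp < hi


def classify_mechanism1(
    gene: GeneModel,
    expr: ExpressionResult,
    events: list[BoundaryAlterationEvent],
    shared_peaks: list[GenomicInterval],
    max_dist: int = 20_000,
    promoter_halfwidth: int = 2_000,
    boundary_slack_bp: int = 40_000,
    preset: str = "printed",
) -> list[CandidatePair]:
    """Intra-TAD (loop alteration) pairs for one candidate gene."""
    rules = DIRECTION_PRESETS[preset][1]
    flag = expr.flag_of(gene.gene_id)
    idx = expr.gene_ids.index(gene.gene_id)
    pairs: list[CandidatePair] = []
    for peak in shared_peaks:
        if peak.chrom != gene.chrom:
            continue
        dist = peak.distance_to_point(gene.tss)
        if dist >= max_dist:
            continue
        if not _promoter_distal(peak, gene, promoter_halfwidth):
            continue
        matching = [
            e
            for e in events
            if _boundary_between(e, gene, peak, boundary_slack_bp)
            and _DIRECTION_FLAG[rules[e.change]] == flag
        ]
        if not matching:
            continue
        event = min(matching, key=lambda e: abs(e.boundary_bp - gene.tss))
        pairs.append(
            CandidatePair(
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
                peak=peak,
                event=event,
                mechanism=1,
                direction=rules[event.change],
                role="oncogene" if flag == "up" else "suppressor",
                distance_bp=dist,
                log2_fc=float(expr.log2_fc[idx]),
                fdr=float(expr.fdr[idx]),
            )
        )
    return pairs


def _same_tad(tads: TadSet, chrom: str, pos_a: int, pos_b: int) -> bool:
    res = tads.resolution
    ta = tads.tad_containing(chrom, pos_a // res)
    tb = tads.tad_containing(chrom, pos_b // res)
    return ta is not None and ta == tb


def classify_mechanism2(
    gene: GeneModel,
    expr: ExpressionResult,
    events: list[BoundaryAlterationEvent],
    shared_peaks: list[GenomicInterval],
    tads1: TadSet,
    tads2: TadSet,
    max_dist: int = 100_000,
    promoter_halfwidth: int = 2_000,
    boundary_slack_bp: int = 40_000,
    preset: str = "printed",
) -> list[CandidatePair]:
    """Inter-TAD (TAD reorganization) pairs for one candidate gene.

    Requires the peak and the TSS to share a TAD in exactly one condition,
    with an event of the geometry-implied change (same TAD only in
    condition 1 -> a boundary was gained; only in condition 2 -> lost)
    lying between them.
    """
    rules = DIRECTION_PRESETS[preset][2]
    flag = expr.flag_of(gene.gene_id)
    idx = expr.gene_ids.index(gene.gene_id)
    pairs: list[CandidatePair] = []
    for peak in shared_peaks:
        if peak.chrom != gene.chrom:
            continue
        dist = peak.distance_to_point(gene.tss)
        if dist >= max_dist:
            continue
        if not _promoter_distal(peak, gene, promoter_halfwidth):
            continue
        same1 = _same_tad(tads1, gene.chrom, gene.tss, peak.midpoint)
        same2 = _same_tad(tads2, gene.chrom, gene.tss, peak.midpoint)
        if same1 == same2:
            continue
        implied_change = "gained" if same1 else "lost"
        matching = [
            e
            for e in events
            if e.change == implied_change
            and _boundary_between(e, gene, peak, boundary_slack_bp)
            and _DIRECTION_FLAG[rules[e.change]] == flag
        ]
        if not matching:
            continue
        event = min(matching, key=lambda e: abs(e.boundary_bp - gene.tss))
        pairs.append(
            CandidatePair(
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
                peak=peak,
                event=event,
                mechanism=2,
                direction=rules[event.change],
                role="oncogene" if flag == "up" else "suppressor",
                distance_bp=dist,
                log2_fc=float(expr.log2_fc[idx]),
                fdr=float(expr.fdr[idx]),
            )
        )
    return pairs


def classify_pairs(
    genes: list[GeneModel],
    expr: ExpressionResult,
    events: list[BoundaryAlterationEvent],
    atac1: PeakSet,
    atac2: PeakSet,
    tads1: TadSet,
    tads2: TadSet,
    mech1_max_dist: int = 20_000,
    mech2_max_dist: int = 100_000,
    promoter_halfwidth: int = 2_000,
    search_radius: int = 1_000_000,
    boundary_slack_bp: int = 40_000,
    preset: str = "printed",
) -> list[CandidatePair]:
    """Steps 2-3 over all genes; output sorted by (gene_id, distance)."""
    cands = candidate_genes(
        events, genes, expr, atac1, atac2, promoter_halfwidth, search_radius
    )
    shared = accessible_peaks(atac1, atac2)
    pairs: list[CandidatePair] = []
    for g in cands:
        pairs.extend(
            classify_mechanism1(
                g, expr, events, shared, mech1_max_dist, promoter_halfwidth,
                boundary_slack_bp, preset,
            )
        )
        pairs.extend(
            classify_mechanism2(
                g, expr, events, shared, tads1, tads2, mech2_max_dist,
                promoter_halfwidth, boundary_slack_bp, preset,
            )
        )
    pairs.sort(key=lambda p: (p.gene_id, p.distance_bp, p.mechanism))
    return pairs


def summarize_pairs(pairs: list[CandidatePair]) -> dict[str, int]:
    """Counts of oncogene/suppressor candidates per mechanism."""
    out = {"mech1_onco": 0, "mech1_supp": 0, "mech2_onco": 0, "mech2_supp": 0}
    seen: set[tuple[str, int]] = set()
    for p in pairs:
        key = (p.gene_id, p.mechanism)
        if key in seen:
            continue
        seen.add(key)
        tag = "onco" if p.role == "oncogene" else "supp"
        out[f"mech{p.mechanism}_{tag}"] += 1
    return out
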