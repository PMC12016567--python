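"""End-to-end orchestration of the two-condition analysis.

Runs the full flow on in-memory objects: directionality index -> TAD and
boundary calls per condition -> differential boundaries -> CTCF-supported
boundary-alteration events -> expression normalization and differential
calling -> mechanism-1/2 candidate pair classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import (
    BoundaryAlterationEvent,
    CandidatePair,
    classify_pairs,
    ctcf_boundary_events,
    summarize_pairs,
)
from .contact_matrix import ContactMap
from .expression import CountMatrix, ExpressionResult, call_degs
from .genomic_io import GeneModel, PeakSet
from .tad_architecture import (
    BoundaryDiff,
    TadSet,
    boundaries_of,
    call_tads,
    compare_boundaries,
    directionality_index,
)

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineParams:
    di_window_bp: int = 2_000_000
    t_sd: float = 0.5
    min_tad_size_bins: int = 3
    boundary_tol_bins: int = 1
    ctcf_tol_bp: int = 40_000
    promoter_halfwidth: int = 2_000
    search_radius: int = 1_000_000
    mech1_max_dist: int = 20_000
    mech2_max_dist: int = 100_000
    boundary_slack_bp: int | None = None  # None -> one bin
    dispersion: float = 0.1
    fc_min: float = 2.0
    fdr_max: float = 0.05
    rpkm_threshold: float = 1.0
    direction_preset: str = "printed"


@dataclass
class PipelineResult:
    tads1: TadSet
    tads2: TadSet
    boundary_diff: BoundaryDiff
    events: list[BoundaryAlterationEvent]
    expression: ExpressionResult
    pairs: list[CandidatePair]
    summary: dict[str, int] = field(default_factory=dict)

    def pairs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": p.gene_id,
                "gene_name": p.gene_name,
                "mechanism": p.mechanism,
                "role": p.role,
                "direction": p.direction,
                "peak_chrom": p.peak.chrom,
                "peak_start": p.peak.start,
                "peak_end": p.peak.end,
                "boundary_bp": p.event.boundary_bp,
                "event_change": p.event.change,
                "distance_bp": p.distance_bp,
                "log2_fc": p.log2_fc,
                "fdr": p.fdr,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "gene_name", "mechanism", "role", "direction",
                "peak_chrom", "peak_start", "peak_end", "boundary_bp",
                "event_change", "distance_bp", "log2_fc", "fdr",
            ],
        )


def run_pipeline(
    cmap1: ContactMap,
    cmap2: ContactMap,
    ctcf1: PeakSet,
    ctcf2: PeakSet,
    atac1: PeakSet,
    atac2: PeakSet,
    genes: list[GeneModel],
    counts: CountMatrix,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Execute the full two-condition flow and classify candidate pairs."""
    params = params or PipelineParams()
    if cmap1.resolution != cmap2.resolution:
        raise ValueError("contact maps have different resolutions")
    slack = (
        params.boundary_slack_bp
        if params.boundary_slack_bp is not None
        else cmap1.resolution
    )
    di1 = directionality_index(cmap1, params.di_window_bp)
    di2 = directionality_index(cmap2, params.di_window_bp)
    tads1 = call_tads(di1, cmap1.resolution, params.t_sd, params.min_tad_size_bins)
    tads2 = call_tads(di2, cmap2.resolution, params.t_sd, params.min_tad_size_bins)
    diff = compare_boundaries(
        boundaries_of(tads1), boundaries_of(tads2), params.boundary_tol_bins
    )
    events = ctcf_boundary_events(diff, ctcf1, ctcf2, params.ctcf_tol_bp)
    expr = call_degs(
        counts,
        dispersion=params.dispersion,
        fc_min=params.fc_min,
        fdr_max=params.fdr_max,
        rpkm_threshold=params.rpkm_threshold,
    )
    pairs = classify_pairs(
        genes,
        expr,
        events,
        atac1,
        atac2,
        tads1,
        tads2,
        mech1_max_dist=params.mech1_max_dist,
        mech2_max_dist=params.mech2_max_dist,
        promoter_halfwidth=params.promoter_halfwidth,
        search_radius=params.search_radius,
        boundary_slack_bp=slack,
        preset=params.direction_preset,
    )
    return PipelineResult(
        tads1=tads1,
        tads2=tads2,
        boundary_diff=diff,
        events=events,
        expression=expr,
        pairs=pairs,
        summary=summarize_pairs(pairs),
    )
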