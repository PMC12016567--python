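"""Boundary-alteration events, candidate filters, mechanism rules, and
brute-force equivalence of the full classifier."""

import numpy as np
import pytest

from tadrewire.classify import (
    DIRECTION_PRESETS,
    BoundaryAlterationEvent,
    candidate_genes,
    classify_mechanism1,
    classify_mechanism2,
    classify_pairs,
    ctcf_boundary_events,
)
from tadrewire.expression import ExpressionResult
from tadrewire.genomic_io import GeneModel, GenomicInterval, PeakSet
from tadrewire.pipeline import PipelineParams, run_pipeline
from tadrewire.tad_architecture import BoundaryDiff, Tad, TadSet

RES = 40_000


def _expr(flags: dict[str, str]) -> ExpressionResult:
    ids = list(flags)
    n = len(ids)
    return ExpressionResult(
        gene_ids=ids,
        rpkm=np.full((n, 2), 10.0),
        log2_fc=np.array([3.0 if f == "up" else -3.0 if f == "down" else 0.0 for f in flags.values()]),
        fdr=np.array([1e-6 if f != "none" else 0.9 for f in flags.values()]),
        deg_flag=np.array(list(flags.values()), dtype=object),
        low_abundance=np.zeros(n, dtype=bool),
    )


def _gene(gene_id: str, tss: int, chrom: str = "c") -> GeneModel:
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        chrom=chrom,
        strand="+",
        tss=tss,
        span=GenomicInterval(chrom, tss, tss + 5_000),
        exonic_length=1_000,
    )


def _peaks(intervals, condition="x", assay="ATAC") -> PeakSet:
    return PeakSet(condition=condition, assay=assay, peaks=list(intervals))


class TestCtcfBoundaryEvents:
    def _diff(self, gained=(), lost=()):
        return BoundaryDiff(
            resolution=RES,
            shared=[],
            lost=[("c", b) for b in lost],
            gained=[("c", b) for b in gained],
            shared_fraction_1=0.0,
            shared_fraction_2=0.0,
        )

    def test_condition2_specific_peak_supports_gained(self):
        peak = GenomicInterval("c", 10 * RES, 10 * RES + 300)
        events = ctcf_boundary_events(self._diff(gained=[10]), _peaks([]), _peaks([peak]))
        assert [(e.change, e.boundary_bin) for e in events] == [("gained", 10)]

    def test_peak_in_both_conditions_discards_boundary(self):
        peak = GenomicInterval("c", 10 * RES, 10 * RES + 300)
        events = ctcf_boundary_events(
            self._diff(gained=[10]), _peaks([peak]), _peaks([peak])
        )
        assert events == []

    def test_lost_boundary_mirrors_with_condition1_peak(self):
        peak = GenomicInterval("c", 7 * RES + 100, 7 * RES + 400)
        events = ctcf_boundary_events(self._diff(lost=[7]), _peaks([peak]), _peaks([]))
        assert [(e.change, e.boundary_bin) for e in events] == [("lost", 7)]

    def test_empty_ctcf_sets_no_events(self):
        assert ctcf_boundary_events(self._diff(gained=[5], lost=[9]), _peaks([]), _peaks([])) == []

    def test_boundary_midpoint_position(self):
        peak = GenomicInterval("c", 10 * RES, 10 * RES + 300)
        (ev,) = ctcf_boundary_events(self._diff(gained=[10]), _peaks([]), _peaks([peak]))
        assert ev.boundary_bp == 10 * RES + RES // 2


class TestCandidateGenes:
    EVENT = BoundaryAlterationEvent("c", 10, 10 * RES + RES // 2, "gained")

    def test_full_criteria_retained(self):
        g = _gene("g1", 10 * RES + 520_000)  # 0.5 Mb from the event
        prom_peak = GenomicInterval("c", g.tss - 200, g.tss + 200)
        out = candidate_genes(
            [self.EVENT], [g], _expr({"g1": "down"}), _peaks([prom_peak]), _peaks([prom_peak])
        )
        assert [x.gene_id for x in out] == ["g1"]

    def test_one_sided_promoter_accessibility_excluded(self):
        g = _gene("g1", 10 * RES + 520_000)
        prom_peak = GenomicInterval("c", g.tss - 200, g.tss + 200)
        out = candidate_genes(
            [self.EVENT], [g], _expr({"g1": "down"}), _peaks([prom_peak]), _peaks([])
        )
        assert out == []

    def test_non_deg_excluded(self):
        g = _gene("g1", 10 * RES + 100_000)
        prom_peak = GenomicInterval("c", g.tss - 200, g.tss + 200)
        out = candidate_genes(
            [self.EVENT], [g], _expr({"g1": "none"}), _peaks([prom_peak]), _peaks([prom_peak])
        )
        assert out == []

    def test_beyond_search_radius_excluded(self):
        g = _gene("g1", 10 * RES + 1_500_000)
        prom_peak = GenomicInterval("c", g.tss - 200, g.tss + 200)
        out = candidate_genes(
            [self.EVENT], [g], _expr({"g1": "down"}), _peaks([prom_peak]), _peaks([prom_peak])
        )
        assert out == []


class TestMechanism1:
    """Peak < 20 kb from the TSS, promoter-distal, boundary in between,
    gain->deactivation / loss->activation."""

    def _setup(self, change: str, flag: str, peak_offset: int = 10_000):
        boundary_bp = 100 * RES + RES // 2
        tss = boundary_bp - 6_000
        gene = _gene("g1", tss)
        event = BoundaryAlterationEvent("c", 100, boundary_bp, change)
        peak = GenomicInterval("c", tss + peak_offset - 200, tss + peak_offset + 200)
        expr = _expr({"g1": flag})
        return gene, expr, event, peak

    def test_gained_boundary_downregulated_gene_pairs(self):
        gene, expr, event, peak = self._setup("gained", "down")
        pairs = classify_mechanism1(gene, expr, [event], [peak], boundary_slack_bp=0)
        assert len(pairs) == 1
        assert pairs[0].direction == "deactivation" and pairs[0].role == "suppressor"

    def test_same_geometry_upregulated_gene_rejected(self):
        gene, expr, event, peak = self._setup("gained", "up")
        assert classify_mechanism1(gene, expr, [event], [peak], boundary_slack_bp=0) == []

    def test_peak_beyond_20kb_rejected(self):
        gene, expr, event, peak = self._setup("gained", "down", peak_offset=25_000)
        assert classify_mechanism1(gene, expr, [event], [peak], boundary_slack_bp=0) == []

    def test_promoter_overlapping_peak_rejected(self):
        gene, expr, event, _ = self._setup("gained", "down")
        prom_peak = GenomicInterval("c", gene.tss - 100, gene.tss + 100)
        assert classify_mechanism1(gene, expr, [event], [prom_peak], boundary_slack_bp=0) == []

    def test_boundary_not_between_rejected_without_slack(self):
        gene, expr, _event, peak = self._setup("gained", "down")
        far = BoundaryAlterationEvent("c", 120, 120 * RES + RES // 2, "gained")
        assert classify_mechanism1(gene, expr, [far], [peak], boundary_slack_bp=0) == []

    def test_lost_boundary_upregulated_gene_is_activation(self):
        gene, expr, event, peak = self._setup("lost", "up")
        (pair,) = classify_mechanism1(gene, expr, [event], [peak], boundary_slack_bp=0)
        assert pair.direction == "activation" and pair.role == "oncogene"


class TestMechanism2:
    """Peak < 100 kb, TAD co-membership changes between conditions."""

    def _setup(self, change: str, flag: str):
        b = 100
        boundary_bp = b * RES + RES // 2
        tss = (b - 1) * RES + RES // 2
        gene = _gene("g1", tss)
        peak_mid = (b + 1) * RES + RES // 2
        peak = GenomicInterval("c", peak_mid - 200, peak_mid + 200)
        split = TadSet(RES, [Tad("c", 90, b), Tad("c", b, 110)])
        merged = TadSet(RES, [Tad("c", 90, 110)])
        tads1, tads2 = (merged, split) if change == "gained" else (split, merged)
        event = BoundaryAlterationEvent("c", b, boundary_bp, change)
        return gene, _expr({"g1": flag}), event, peak, tads1, tads2

    def test_gained_boundary_upregulated_printed_rules(self):
        gene, expr, event, peak, t1, t2 = self._setup("gained", "up")
        (pair,) = classify_mechanism2(gene, expr, [event], [peak], t1, t2)
        assert pair.mechanism == 2 and pair.direction == "activation"

    def test_lost_boundary_upregulated_worked_example_rules(self):
        gene, expr, event, peak, t1, t2 = self._setup("lost", "up")
        assert classify_mechanism2(gene, expr, [event], [peak], t1, t2) == []
        (pair,) = classify_mechanism2(
            gene, expr, [event], [peak], t1, t2, preset="worked_example"
        )
        assert pair.direction == "activation" and pair.role == "oncogene"

    def test_same_tad_in_both_conditions_rejected(self):
        gene, expr, event, peak, _t1, t2 = self._setup("gained", "up")
        merged = TadSet(RES, [Tad("c", 90, 110)])
        assert classify_mechanism2(gene, expr, [event], [peak], merged, merged) == []

    def test_distance_gate(self):
        gene, expr, event, peak, t1, t2 = self._setup("gained", "up")
        far_mid = gene.tss + 150_000
        far = GenomicInterval("c", far_mid - 200, far_mid + 200)
        assert classify_mechanism2(gene, expr, [event], [far], t1, t2) == []


def brute_force_pairs(
    genes, expr, events, atac1, atac2, tads1, tads2, slack_bp, preset="printed"
):
    """Independent exhaustive filter over genes x peaks x events applying
    the candidate criteria literally."""
    rules = DIRECTION_PRESETS[preset]
    flag_for = {"activation": "up", "deactivation": "down"}
    out = set()
    shared = [
        p
        for p in atac1
        if any(q.chrom == p.chrom and q.start < p.end and p.start < q.end for q in atac2)
    ]
    for gene in genes:
        flag = expr.flag_of(gene.gene_id)
        if flag == "none":
            continue
        ps, pe = gene.tss - 2_000, gene.tss + 2_000
        acc1 = any(p.chrom == gene.chrom and p.start < pe and ps < p.end for p in atac1)
        acc2 = any(p.chrom == gene.chrom and p.start < pe and ps < p.end for p in atac2)
        if not (acc1 and acc2):
            continue
        if not any(
            e.chrom == gene.chrom and abs(e.boundary_bp - gene.tss) <= 1_000_000
            for e in events
        ):
            continue
        for peak in shared:
            if peak.chrom != gene.chrom:
                continue
            pm = (peak.start + peak.end) // 2
            dist = abs(pm - gene.tss)
            distal = not (peak.start < pe and ps < peak.end)
            if not distal:
                continue
            lo, hi = min(gene.tss, pm) - slack_bp, max(gene.tss, pm) + slack_bp
            for ev in events:
                if ev.chrom != gene.chrom or not (lo < ev.boundary_bp < hi):
                    continue
                if dist < 20_000 and flag == flag_for[rules[1][ev.change]]:
                    role = "oncogene" if flag == "up" else "suppressor"
                    out.add(
                        (gene.gene_id, peak.start, peak.end, 1, rules[1][ev.change], role)
                    )
                if dist < 100_000:
                    def same(tads):
                        ta = tads.tad_containing(gene.chrom, gene.tss // tads.resolution)
                        tb = tads.tad_containing(gene.chrom, pm // tads.resolution)
                        return ta is not None and ta == tb

                    s1, s2 = same(tads1), same(tads2)
                    implied = "gained" if s1 else "lost"
                    if (
                        s1 != s2
                        and ev.change == implied
                        and flag == flag_for[rules[2][ev.change]]
                    ):
                        role = "oncogene" if flag == "up" else "suppressor"
                        out.add(
                            (gene.gene_id, peak.start, peak.end, 2, rules[2][ev.change], role)
                        )
    return out


class TestPipelineEquivalenceAndDuality:
    def _pair_keys(self, pairs):
        return {
            (p.gene_id, p.peak.start, p.peak.end, p.mechanism, p.direction, p.role)
            for p in pairs
        }

    def test_matches_brute_force_on_default_scenario(
        self, default_scenario, default_regulome, default_pipeline_result
    ):
        spec, _cm1, _cm2, _man = default_scenario
        _ctcf1, _ctcf2, atac1, atac2, genes, _counts = default_regulome
        res = default_pipeline_result
        brute = brute_force_pairs(
            genes, res.expression, res.events, atac1, atac2,
            res.tads1, res.tads2, slack_bp=spec.resolution,
        )
        assert self._pair_keys(res.pairs) == brute

    def test_matches_brute_force_without_decoys(self):
        from tadrewire.simulate import (
            ScenarioSpec, simulate_condition_pair, simulate_regulome,
        )

        spec = ScenarioSpec(include_decoys=False, seed=7)
        cm1, cm2, man = simulate_condition_pair(spec)
        ctcf1, ctcf2, atac1, atac2, genes, counts = simulate_regulome(spec, man)
        res = run_pipeline(cm1, cm2, ctcf1, ctcf2, atac1, atac2, genes, counts)
        brute = brute_force_pairs(
            genes, res.expression, res.events, atac1, atac2,
            res.tads1, res.tads2, slack_bp=spec.resolution,
        )
        assert self._pair_keys(res.pairs) == brute

    def test_condition_swap_duality(self, default_scenario, default_regulome,
                                    default_pipeline_result):
        spec, cm1, cm2, _man = default_scenario
        ctcf1, ctcf2, atac1, atac2, genes, counts = default_regulome
        fwd = default_pipeline_result
        from tadrewire.expression import CountMatrix

        swapped_counts = CountMatrix(
            gene_ids=list(counts.gene_ids),
            samples=list(reversed(counts.samples)),
            counts=counts.counts[:, ::-1],
            exonic_lengths=counts.exonic_lengths,
        )
        rev = run_pipeline(
            cm2, cm1, ctcf2, ctcf1, atac2, atac1, genes, swapped_counts,
            params=PipelineParams(),
        )
        flip_change = {"gained": "lost", "lost": "gained"}
        flip_role = {"oncogene": "suppressor", "suppressor": "oncogene"}
        flip_dir = {"activation": "deactivation", "deactivation": "activation"}
        fwd_keys = {
            (p.gene_id, p.mechanism, flip_change[p.event.change],
             flip_role[p.role], flip_dir[p.direction])
            for p in fwd.pairs
        }
        rev_keys = {
            (p.gene_id, p.mechanism, p.event.change, p.role, p.direction)
            for p in rev.pairs
        }
        assert fwd_keys == rev_keys

    def test_output_invariant_to_input_ordering(self, default_scenario,
                                                default_regulome,
                                                default_pipeline_result):
        spec, cm1, cm2, _man = default_scenario
        ctcf1, ctcf2, atac1, atac2, genes, counts = default_regulome
        shuffled_genes = list(reversed(genes))
        res = run_pipeline(
            cm1, cm2, ctcf1, ctcf2,
            PeakSet("cond1", "ATAC", list(reversed(atac1.peaks))),
            PeakSet("cond2", "ATAC", list(reversed(atac2.peaks))),
            shuffled_genes,
            counts,
        )
        assert self._pair_keys(res.pairs) == self._pair_keys(
            default_pipeline_result.pairs
        )
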