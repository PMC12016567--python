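"""Directionality index, TAD calling, boundary diff and reorganization."""

import numpy as np
import pytest

from tadrewire.contact_matrix import ContactMap
from tadrewire.genomic_io import GeneModel, GenomicInterval, make_bins
from tadrewire.tad_architecture import (
    BoundarySet,
    DirectionalityTrack,
    Tad,
    TadSet,
    boundaries_of,
    call_tads,
    classify_reorganization,
    compare_boundaries,
    di_from_flanks,
    directionality_index,
    region_class_stats,
)

RES = 40_000


def _map_from(matrix: np.ndarray, chrom: str = "chrA") -> ContactMap:
    n = matrix.shape[0]
    cmap = ContactMap(bins=make_bins({chrom: n * RES}, RES))
    cmap.cis[chrom] = np.asarray(matrix, dtype=float)
    return cmap


def _track(values, chrom: str = "chrA") -> DirectionalityTrack:
    values = np.asarray(values, dtype=float)
    bins = make_bins({chrom: len(values) * RES}, RES)
    t = DirectionalityTrack(bins=bins, window_bp=2_000_000)
    t.di[chrom] = values
    return t


class TestDirectionalityFormula:
    def test_symmetric_flanks_give_zero(self):
        assert di_from_flanks([10.0], [10.0])[0] == 0.0

    def test_known_values(self):
        # A=0, B=20: E=10, DI = +((0-10)^2/10 + (20-10)^2/10) = +20
        assert di_from_flanks([0.0], [20.0])[0] == pytest.approx(20.0)
        assert di_from_flanks([20.0], [0.0])[0] == pytest.approx(-20.0)

    def test_matches_closed_form_on_random_pairs(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(0, 500, 1000)
        B = rng.uniform(0, 500, 1000)
        expected = np.array(
            [
                0.0
                if a == b
                else np.sign(b - a)
                * ((a - (a + b) / 2) ** 2 / ((a + b) / 2) + (b - (a + b) / 2) ** 2 / ((a + b) / 2))
                for a, b in zip(A, B)
            ]
        )
        np.testing.assert_allclose(di_from_flanks(A, B), expected, atol=1e-10)

    def test_zero_coverage_gives_zero(self):
        assert di_from_flanks([0.0], [0.0])[0] == 0.0

    def test_flank_sums_respect_window(self):
        n = 120
        m = np.zeros((n, n))
        m[60, 61] = 5.0
        m[61, 60] = 5.0
        track = directionality_index(_map_from(m), window_bp=2_000_000)
        # bin 60 sees 5 downstream, bin 61 sees 5 upstream, nothing else
        assert track.B["chrA"][60] == 5.0 and track.A["chrA"][60] == 0.0
        assert track.A["chrA"][61] == 5.0 and track.B["chrA"][61] == 0.0

    def test_antisymmetry_under_bin_reversal(self):
        rng = np.random.default_rng(11)
        m = rng.poisson(2.0, (200, 200)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        di = directionality_index(_map_from(m)).di["chrA"]
        di_rev = directionality_index(_map_from(m[::-1, ::-1])).di["chrA"]
        np.testing.assert_allclose(di, -di_rev[::-1], atol=1e-9)

    def test_constant_matrix_zero_di_at_interior(self):
        m = np.full((200, 200), 3.0)
        di = directionality_index(_map_from(m)).di["chrA"]
        w = 2_000_000 // RES
        np.testing.assert_allclose(di[w:-w], 0.0, atol=1e-12)


class TestCallTads:
    def test_single_plus_minus_block(self):
        # nonzero-DI SD is 5, so t_sd=0.5 gives threshold 2.5 < 5
        tads = call_tads(_track([5, 5, -5, -5]), RES, t_sd=0.5, min_size_bins=2)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(0, 4)]

    def test_all_zero_di_warns_no_tads(self):
        with pytest.warns(UserWarning, match="all-zero"):
            tads = call_tads(_track([0, 0, 0, 0]), RES)
        assert len(tads) == 0

    def test_two_consecutive_blocks(self):
        tads = call_tads(_track([5, 5, -5, -5, 5, 5, -5, -5]), RES, min_size_bins=2)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(0, 4), (4, 8)]

    def test_min_size_filter(self):
        tads = call_tads(_track([5, -5, 0, 0, 5, 5, -5, -5]), RES, min_size_bins=3)
        assert [(t.start_bin, t.end_bin) for t in tads] == [(4, 8)]

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.poisson(2.0, (200, 200)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        t1 = call_tads(directionality_index(_map_from(m)), RES)
        t2 = call_tads(directionality_index(_map_from(m * 7.0)), RES)
        assert [(t.start_bin, t.end_bin) for t in t1] == [
            (t.start_bin, t.end_bin) for t in t2
        ]


class TestBoundaries:
    def test_single_tad_endpoints(self):
        bs = boundaries_of(TadSet(RES, [Tad("c", 10, 20)]))
        assert bs.boundaries == [("c", 10), ("c", 19)]

    def test_adjacent_tads_share_junction(self):
        bs = boundaries_of(TadSet(RES, [Tad("c", 10, 20), Tad("c", 20, 30)]))
        assert bs.boundaries == [("c", 10), ("c", 20), ("c", 29)]

    def test_empty(self):
        assert len(boundaries_of(TadSet(RES, []))) == 0


class TestCompareBoundaries:
    def test_identical_sets_fully_shared(self):
        b = BoundarySet(RES, [("c", 5), ("c", 10)])
        diff = compare_boundaries(b, b)
        assert len(diff.shared) == 2 and not diff.lost and not diff.gained
        assert diff.shared_fraction_1 == diff.shared_fraction_2 == 1.0

    def test_disjoint_far_sets(self):
        diff = compare_boundaries(
            BoundarySet(RES, [("c", 0)]), BoundarySet(RES, [("c", 50)])
        )
        assert not diff.shared and diff.lost == [("c", 0)] and diff.gained == [("c", 50)]

    def test_within_tolerance_match(self):
        diff = compare_boundaries(
            BoundarySet(RES, [("c", 10)]), BoundarySet(RES, [("c", 11)]), tol_bins=1
        )
        assert diff.shared == [(("c", 10), ("c", 11))]

    def test_swap_symmetry(self):
        b1 = BoundarySet(RES, [("c", 3), ("c", 10), ("c", 30)])
        b2 = BoundarySet(RES, [("c", 4), ("c", 22)])
        d12 = compare_boundaries(b1, b2)
        d21 = compare_boundaries(b2, b1)
        assert len(d12.shared) == len(d21.shared)
        assert d12.lost == d21.gained and d12.gained == d21.lost

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_boundaries(BoundarySet(RES, []), BoundarySet(10_000, []))


class TestReorganization:
    def test_separation(self):
        t1 = TadSet(RES, [Tad("c", 0, 10)])
        t2 = TadSet(RES, [Tad("c", 0, 5), Tad("c", 5, 10)])
        events = classify_reorganization(t1, t2)
        assert [(e.kind, e.boundary_bins) for e in events] == [("separation", (5,))]

    def test_fusion_by_duality(self):
        t1 = TadSet(RES, [Tad("c", 0, 5), Tad("c", 5, 10)])
        t2 = TadSet(RES, [Tad("c", 0, 10)])
        events = classify_reorganization(t1, t2)
        assert [(e.kind, e.boundary_bins) for e in events] == [("fusion", (5,))]

    def test_shift(self):
        t1 = TadSet(RES, [Tad("c", 0, 10), Tad("c", 10, 20)])
        t2 = TadSet(RES, [Tad("c", 0, 12), Tad("c", 12, 20)])
        events = classify_reorganization(t1, t2)
        assert [(e.kind, e.boundary_bins) for e in events] == [("shift", (10, 12))]

    def test_swap_duality_on_simulated_tads(self, default_scenario):
        from tadrewire.tad_architecture import directionality_index as di_fn

        _spec, cm1, cm2, _man = default_scenario
        t1 = call_tads(di_fn(cm1), cm1.resolution)
        t2 = call_tads(di_fn(cm2), cm2.resolution)
        fwd = classify_reorganization(t1, t2)
        rev = classify_reorganization(t2, t1)
        flip = {"fusion": "separation", "separation": "fusion", "shift": "shift"}

        def norm(events):
            return sorted(
                (e.chrom, tuple(sorted(e.boundary_bins)), e.kind) for e in events
            )

        assert norm(rev) == sorted(
            (c, b, flip[k]) for c, b, k in norm(fwd)
        )


class TestRegionClassStats:
    def _genes(self, positions):
        return [
            GeneModel(
                gene_id=f"g{i}",
                gene_name=f"g{i}",
                chrom="chrA",
                strand="+",
                tss=p,
                span=GenomicInterval("chrA", p, p + 100),
                exonic_length=100,
            )
            for i, p in enumerate(positions)
        ]

    def test_no_genes_zero_density(self):
        bins = make_bins({"chrA": 40 * RES}, RES)
        tads = TadSet(RES, [Tad("chrA", 0, 20)])
        stats = region_class_stats(tads, bins, [])
        assert stats["inner"]["gene_density_per_mb"] == 0.0
        assert stats["border"]["gene_density_per_mb"] == 0.0

    def test_density_arithmetic(self):
        bins = make_bins({"chrA": 40 * RES}, RES)
        tads = TadSet(RES, [Tad("chrA", 0, 29)])
        # inner = 29 bins minus 6 border bins (0,1 and 27,28,29 clipped) -> put
        # one TSS mid-TAD and check per-Mb scaling directly
        stats = region_class_stats(tads, bins, self._genes([15 * RES + 100]))
        inner_mb = stats["inner"]["length_bp"] / 1e6
        assert stats["inner"]["gene_density_per_mb"] == pytest.approx(1 / inner_mb)
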