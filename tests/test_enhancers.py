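"""Coverage normalization, peak/stitch/SE calling and differential surfaces."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrnmes import (
    InputError,
    assign_region_genes,
    call_peaks,
    call_superenhancers,
    differential_surface,
    normalize_track,
    poisson_direction_filter,
    select_induced_regions,
    stitch_peaks,
)
from adrnmes.containers import CoverageTrack, DifferentialRegion, EnhancerRegion
from adrnmes.simulate import Gene, SimulationConfig, default_genome, simulate_chip_landscape
from _oracles import (
    assign_genes_oracle,
    elbow_cutoff_oracle,
    run_length_peaks_oracle,
    stitch_oracle,
)


def track(counts, total=2.0e7, bin_width=50):
    return CoverageTrack("chrS", bin_width, 0, np.asarray(counts, float), total)


class TestNormalize:
    def test_target_library_is_identity(self):
        t = track([1, 2, 3], total=2.0e7)
        assert np.array_equal(normalize_track(t).counts, t.counts)

    def test_double_library_halves_bins(self):
        t = track(np.arange(10, dtype=float), total=4.0e7)
        assert np.allclose(normalize_track(t).counts, np.arange(10) / 2)

    def test_total_signal_conserved(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, 100).astype(float)
        t = track(counts, total=3.7e6)
        norm = normalize_track(t)
        assert norm.counts.sum() == pytest.approx(counts.sum() * 2e7 / 3.7e6)

    def test_library_factors_cancel(self):
        """Same landscape at 0.5x and 2x depth: normalized means agree within 3 Poisson sd."""
        genome = default_genome(n_typical=30)
        cfg = SimulationConfig(seed=21)
        _, b_half, _, _ = simulate_chip_landscape(cfg, genome, lib_factor_b=0.5)
        cfg2 = SimulationConfig(seed=22)
        _, b_double, _, _ = simulate_chip_landscape(cfg2, genome, lib_factor_b=2.0)
        n1, n2 = normalize_track(b_half), normalize_track(b_double)
        s, e = genome.intervals("MES-SE")[0]
        sl = n1.bin_slice(s, e)
        m1, m2 = n1.counts[sl].mean(), n2.counts[sl].mean()
        # Poisson sd of the per-bin mean, propagated through normalization
        nbins = sl.stop - sl.start
        sd = np.sqrt(m1 * (2e7 / b_half.total_mapped_reads) / nbins + m2 * (2e7 / b_double.total_mapped_reads) / nbins)
        assert abs(m1 - m2) < 3 * sd


class TestPeaks:
    def test_all_zero_track_has_no_peaks(self):
        assert call_peaks(track(np.zeros(30)), 1.0) == []

    def test_single_block(self):
        counts = np.zeros(30)
        counts[5:15] = 9.0
        assert call_peaks(track(counts), 5.0, 50) == [(250, 750)]

    def test_min_width_filters_short_runs(self):
        counts = np.zeros(30)
        counts[3] = 9.0
        counts[10:14] = 9.0
        assert call_peaks(track(counts), 5.0, 200) == [(500, 700)]

    def test_matches_run_length_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.poisson(2, 200).astype(float)
            thr = float(rng.uniform(1, 5))
            t = track(counts)
            got = call_peaks(t, thr, 100)
            assert got == run_length_peaks_oracle(counts, thr, 50, 100)

    def test_negative_threshold_rejected(self):
        with pytest.raises(InputError):
            call_peaks(track([1.0, 2.0]), -1)


class TestStitch:
    def test_gap_below_distance_merges(self):
        regions = stitch_peaks([(100, 200), (300, 400)], 150)
        assert [(r.start, r.end, r.constituent_count) for r in regions] == [(100, 400, 2)]

    def test_gap_above_distance_keeps_separate(self):
        regions = stitch_peaks([(100, 200), (300, 400)], 50)
        assert [(r.start, r.end) for r in regions] == [(100, 200), (300, 400)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(InputError):
            stitch_peaks([(300, 400), (100, 200)], 50)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            starts = np.cumsum(rng.integers(1, 300, size=40))
            peaks = [(int(s), int(s + rng.integers(1, 80))) for s in starts]
            peaks = [
                p for i, p in enumerate(peaks) if i == 0 or p[0] > peaks[i - 1][1]
            ]
            dist = int(rng.integers(0, 200))
            got = [(r.start, r.end, r.constituent_count) for r in stitch_peaks(peaks, dist)]
            assert got == stitch_oracle(peaks, dist)


class TestSuperEnhancers:
    def test_single_dominant_region(self):
        counts = np.zeros(2000)
        regions = []
        for i in range(20):
            s = i * 4000
            regions.append(EnhancerRegion(s, s + 500))
        counts = np.zeros(80000 // 50)
        counts[(19 * 4000) // 50 : (19 * 4000 + 500) // 50] = 10.0
        t = track(counts)
        call = call_superenhancers(regions, t)
        assert int(call.is_super.sum()) == 1
        assert call.superenhancers[0].start == 19 * 4000

    def test_linear_signals_give_no_superenhancers(self):
        regions = [EnhancerRegion(i * 1000, i * 1000 + 500) for i in range(10)]
        counts = np.zeros(10 * 1000 // 50)
        for i in range(10):
            counts[i * 20 : i * 20 + 10] = float(i)
        call = call_superenhancers(regions, track(counts))
        assert int(call.is_super.sum()) == 0

    def test_flat_signals_warn_and_call_nothing(self):
        regions = [EnhancerRegion(i * 1000, i * 1000 + 500) for i in range(5)]
        counts = np.ones(100)
        with pytest.warns(UserWarning):
            call = call_superenhancers(regions, track(counts))
        assert int(call.is_super.sum()) == 0

    def test_cutoff_matches_slope_oracle_on_default_landscape(self, landscape_calls):
        call = landscape_calls["B"]["call"]
        signals = [r.signal for r in call.regions]
        assert call.cutoff_rank == elbow_cutoff_oracle(signals)

    def test_adding_low_region_keeps_super_set(self, landscape_calls):
        call = landscape_calls["B"]["call"]
        norm = landscape_calls["B"]["norm"]
        before = {r.interval for r in call.superenhancers}
        extra = EnhancerRegion(0, 1000)  # leftmost margin: background signal
        call2 = call_superenhancers(list(call.regions) + [extra], norm)
        after = {r.interval for r in call2.superenhancers}
        assert before == after


class TestAssignGenes:
    GENES = [
        Gene("g_a", 1000, 2000, "+", 1000),
        Gene("g_b", 5000, 6000, "-", 5999),
        Gene("g_c", 9000, 9500, "+", 9000),
    ]

    def test_region_inside_gene_body(self):
        out = assign_region_genes([EnhancerRegion(1200, 1300)], self.GENES)
        assert out[(1200, 1300)] == ["g_a"]

    def test_equidistant_tss_breaks_to_smaller_id(self):
        genes = [Gene("g_x", 0, 10, "+", 0), Gene("g_w", 200, 210, "+", 200)]
        out = assign_region_genes([EnhancerRegion(100, 101)], genes)
        assert out[(100, 101)] == ["g_w"]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        genes = [
            Gene(f"g{i:02d}", int(s), int(s) + 300, "+", int(s))
            for i, s in enumerate(np.sort(rng.choice(50000, 12, replace=False)))
        ]
        regions = [
            EnhancerRegion(int(s), int(s) + 200)
            for s in np.sort(rng.choice(50000, 30, replace=False))
        ]
        got = {
            iv: genes_ for iv, genes_ in assign_region_genes(regions, genes).items()
        }
        assert got == assign_genes_oracle([r.interval for r in regions], genes)


class TestDifferentialSurface:
    def test_identical_tracks_all_unchanged(self):
        t = track(np.arange(40, dtype=float))
        diffs = differential_surface(t, t, [EnhancerRegion(0, 500), EnhancerRegion(1000, 1500)])
        assert all(d.surface == 0 and d.direction == "unchanged" for d in diffs)

    def test_closed_form_surface(self):
        a = track(np.zeros(10))
        b = track(np.full(10, 2.0))
        diffs = differential_surface(a, b, [EnhancerRegion(0, 500)])
        assert diffs[0].surface == pytest.approx(1000.0)
        assert diffs[0].direction == "increased"

    def test_swap_negates_exactly(self, default_landscape, landscape_calls):
        _, _, _, truth = default_landscape
        na, nb = landscape_calls["A"]["norm"], landscape_calls["B"]["norm"]
        regions = [
            EnhancerRegion(s, e)
            for cls in ("MES-SE", "ADRN-SE", "typical")
            for s, e in truth.planted_se[cls]
        ]
        fwd = differential_surface(na, nb, regions)
        rev = differential_surface(nb, na, regions)
        for f, r in zip(fwd, rev):
            assert r.surface == -f.surface

    def test_incongruent_bins_rejected(self):
        with pytest.raises(InputError):
            differential_surface(track(np.zeros(10)), track(np.zeros(12)), [])


class TestSelectInduced:
    def _diffs(self, surfaces):
        return [
            DifferentialRegion(i * 1000, i * 1000 + 500, s, "increased" if s > 0 else "decreased")
            for i, s in enumerate(surfaces)
        ]

    def test_single_top_region(self):
        out = select_induced_regions(self._diffs([5.0, 50.0, 7.0]), 1)
        assert out == [(1000, 1500)]

    def test_no_positive_surfaces_warns_empty(self):
        with pytest.warns(UserWarning):
            assert select_induced_regions(self._diffs([-1.0, -2.0]), 5) == []

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(13)
        surfaces = rng.normal(0, 100, 400).tolist()
        diffs = self._diffs(surfaces)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = select_induced_regions(diffs, 50)
        expected = [
            d.interval
            for d in sorted(
                (d for d in diffs if d.surface > 0), key=lambda d: (-d.surface, d.start)
            )[:50]
        ]
        assert got == expected

    def test_poisson_filter_keeps_planted_changes_only(
        self, default_landscape, landscape_calls
    ):
        genome_seq, track_a, track_b, truth = default_landscape
        na, nb = landscape_calls["A"]["norm"], landscape_calls["B"]["norm"]
        regions = [
            EnhancerRegion(s, e)
            for cls in ("MES-SE", "ADRN-SE", "typical")
            for s, e in sorted(truth.planted_se[cls])
        ]
        diffs = poisson_direction_filter(
            differential_surface(na, nb, regions), track_a, track_b
        )
        by_cls = {}
        mes = set(map(tuple, truth.planted_se["MES-SE"]))
        adrn = set(map(tuple, truth.planted_se["ADRN-SE"]))
        for d in diffs:
            if d.interval in mes:
                by_cls.setdefault("MES", set()).add(d.direction)
            elif d.interval in adrn:
                by_cls.setdefault("ADRN", set()).add(d.direction)
            else:
                by_cls.setdefault("typical", set()).add(d.direction)
        assert by_cls["MES"] == {"increased"}
        assert by_cls["ADRN"] == {"decreased"}
        assert by_cls["typical"] == {"unchanged"}


@settings(deadline=None, max_examples=40)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 400)), min_size=0, max_size=25
    ),
    d1=st.integers(0, 500),
    d2=st.integers(0, 500),
)
def test_stitching_idempotent_and_monotone(data, d1, d2):
    """Stitching is idempotent; region count is non-increasing in distance."""
    peaks = []
    last_end = -1
    for start, width in sorted(data):
        s = max(start, last_end + 1)
        peaks.append((s, s + width))
        last_end = s + width
    lo, hi = min(d1, d2), max(d1, d2)
    r_lo = stitch_peaks(peaks, lo)
    r_hi = stitch_peaks(peaks, hi)
    assert len(r_hi) <= len(r_lo)
    again = stitch_peaks([r.interval for r in r_lo], lo)
    assert [r.interval for r in again] == [r.interval for r in r_lo]
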