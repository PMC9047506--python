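"""delta(SNP index), the simulated null band, and region merging."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from bulkscan.qtl_scan import (
    CandidateRegion,
    NullBandSimulator,
    ScanResult,
    call_candidates_and_merge,
    delta_snp_index,
    scan_records,
    simulate_null_band,
    _null_deltas,
)
from bulkscan.variant_filtering import SnpIndexRecord, compute_snp_index


def exact_null_band(n_bulk, depth_by, depth_ky, level=0.95):
    """Brute-force enumeration of the two-stage binomial null distribution.

    Independent oracle for the Monte-Carlo band: enumerates every (allele
    count, read count) outcome, accumulates the exact delta distribution,
    and applies the same inverse-CDF quantile rule.
    """
    chroms = 2 * n_bulk

    def index_dist(depth):
        dist = {}
        for k in range(chroms + 1):
            pk = stats.binom.pmf(k, chroms, 0.5)
            f = k / chroms
            for r in range(depth + 1):
                dist[r / depth] = dist.get(r / depth, 0.0) + pk * stats.binom.pmf(
                    r, depth, f
                )
        return dist

    d_by, d_ky = index_dist(depth_by), index_dist(depth_ky)
    delta = {}
    for i_by, p_by in d_by.items():
        for i_ky, p_ky in d_ky.items():
            key = round(i_by - i_ky, 12)
            delta[key] = delta.get(key, 0.0) + p_by * p_ky
    support = sorted(delta)
    cdf = np.cumsum([delta[x] for x in support])
    tail = (1 - level) / 2
    lo = support[int(np.searchsorted(cdf, tail))]
    hi = support[int(np.searchsorted(cdf, 1 - tail))]
    return lo, hi


def _record(index_by, index_ky, depth_by=30, depth_ky=30, chrom="chr1", pos=100,
            make_site=None):
    site = make_site(chrom=chrom, pos=pos)
    return SnpIndexRecord(
        site=site, high_parent="AYP1", index_by=index_by, index_ky=index_ky,
        depth_by=depth_by, depth_ky=depth_ky,
    )


class TestDelta:
    def test_recessive_expectation_two_thirds(self, make_site):
        rec = _record(1.0, 1 / 3, make_site=make_site)
        assert delta_snp_index(rec) == pytest.approx(2 / 3)

    def test_equal_indices_give_zero(self, make_site):
        assert delta_snp_index(_record(0.4, 0.4, make_site=make_site)) == 0.0

    def test_bounds_attained(self, make_site):
        assert delta_snp_index(_record(0.0, 1.0, make_site=make_site)) == -1.0

    def test_undefined_without_coverage(self, make_site):
        rec = _record(None, 0.5, make_site=make_site)
        with pytest.raises(ValueError, match="coverage"):
            delta_snp_index(rec)


class TestNullBand:
    @pytest.mark.parametrize(
        "n_bulk,depth_by,depth_ky",
        [(1, 1, 1), (1, 2, 3), (2, 1, 1), (2, 2, 2), (2, 3, 3), (2, 3, 1)],
    )
    def test_band_matches_exact_enumeration(self, n_bulk, depth_by, depth_ky):
        exact = exact_null_band(n_bulk, depth_by, depth_ky)
        sampled = simulate_null_band(
            n_bulk, depth_by, depth_ky, n_reps=200_000, seed=5
        )
        assert sampled == pytest.approx(exact)

    def test_signed_extreme_probability_quarter_at_depth_one(self):
        # large-bulk limit at depth 1: each index is a fair coin, so each
        # signed extreme delta (+1 or -1) has probability 1/4
        rng = np.random.default_rng(0)
        deltas = _null_deltas(10_000, 1, 1, 200_000, rng)
        assert np.mean(deltas == 1.0) == pytest.approx(0.25, abs=0.01)
        assert np.mean(deltas == -1.0) == pytest.approx(0.25, abs=0.01)

    def test_band_shrinks_with_depth_and_bulk_size(self):
        lo1, hi1 = simulate_null_band(30, 5, 5, n_reps=20_000, seed=1)
        lo2, hi2 = simulate_null_band(30, 100, 100, n_reps=20_000, seed=1)
        lo3, hi3 = simulate_null_band(500, 100, 100, n_reps=20_000, seed=1)
        assert hi2 - lo2 < hi1 - lo1
        assert hi3 - lo3 < hi2 - lo2

    def test_band_brackets_zero(self):
        for depths in [(7, 12), (30, 30), (60, 25)]:
            lo, hi = simulate_null_band(30, *depths, seed=3)
            assert lo <= 0.0 <= hi

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            simulate_null_band(30, 10, 10, level=1.5)

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning, match="noisy"):
            simulate_null_band(30, 10, 10, n_reps=50)

    def test_cached_band_is_order_independent(self):
        a = NullBandSimulator(30, seed=4)
        b = NullBandSimulator(30, seed=4)
        a.band(30, 30)
        a.band(25, 35)
        b.band(25, 35)
        b.band(30, 30)
        assert a.band(30, 30) == b.band(30, 30)
        assert a.band(25, 35) == b.band(25, 35)


class TestScanAndMerge:
    def test_candidate_iff_outside_band(self, make_site):
        class FixedBand(NullBandSimulator):
            def band(self, depth_by, depth_ky):
                return (-0.3, 0.3)

        records = [
            _record(0.9, 0.1, pos=100, make_site=make_site),   # delta 0.8
            _record(0.5, 0.45, pos=200, make_site=make_site),  # delta 0.05
        ]
        results = scan_records(records, n_bulk=30, band_simulator=FixedBand(30))
        assert [r.is_candidate for r in results] == [True, False]

    def test_label_swap_negates_delta_and_flags_match_symmetric_band(self, make_site):
        class FixedBand(NullBandSimulator):
            def band(self, depth_by, depth_ky):
                return (-0.25, 0.25)

        rng = np.random.default_rng(7)
        records, swapped = [], []
        for pos in range(100, 400, 10):
            iby, iky = rng.random(), rng.random()
            records.append(_record(iby, iky, pos=pos, make_site=make_site))
            swapped.append(_record(iky, iby, pos=pos, make_site=make_site))
        a = scan_records(records, n_bulk=30, band_simulator=FixedBand(30))
        b = scan_records(swapped, n_bulk=30, band_simulator=FixedBand(30))
        for ra, rb in zip(a, b):
            assert ra.delta == pytest.approx(-rb.delta)
            assert ra.is_candidate == rb.is_candidate

    def test_gap_merging_and_min_sites(self, make_site):
        def result(pos, candidate=True):
            rec = _record(0.9, 0.1, pos=pos, make_site=make_site)
            return ScanResult(rec, 0.8, -0.3, 0.3, candidate)

        results = [result(100), result(200), result(2_000_100)]
        assert call_candidates_and_merge(results, min_sites=3) == []
        regions = call_candidates_and_merge(results, min_sites=1)
        assert [(r.start, r.end, r.n_sites) for r in regions] == [
            (100, 200, 2), (2_000_100, 2_000_100, 1)
        ]

    def test_no_candidates_gives_empty_list(self, make_site):
        rec = _record(0.5, 0.5, make_site=make_site)
        results = [ScanResult(rec, 0.0, -0.3, 0.3, False)]
        assert call_candidates_and_merge(results) == []

    def test_unsorted_input_sorted_internally(self, make_site):
        def result(pos):
            rec = _record(0.9, 0.1, pos=pos, make_site=make_site)
            return ScanResult(rec, 0.8, -0.3, 0.3, True)

        regions = call_candidates_and_merge(
            [result(300), result(100), result(200)], min_sites=3
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 300)

    def test_region_invariants(self):
        region = CandidateRegion("chr1", 100, 300)
        assert region.contains(100) and region.contains(300)
        assert not region.contains(99)


class TestEndToEndScan:
    def test_causal_locus_recovered_on_default_experiment(self, default_experiment):
        cfg = default_experiment.config
        records = [
            compute_snp_index(s, cfg.causal_origin) for s in default_experiment.sites
        ]
        from bulkscan.variant_filtering import apply_filters

        retained = apply_filters(records).retained
        results = scan_records(retained, n_bulk=cfg.n_bulk, seed=cfg.rng_seed)
        regions = call_candidates_and_merge(results)
        assert any(
            r.chrom == cfg.causal_chrom and r.contains(cfg.causal_pos)
            for r in regions
        )
        causal = next(
            r for r in results
            if r.chrom == cfg.causal_chrom and r.pos == cfg.causal_pos
        )
        assert causal.is_candidate
        assert causal.delta > 0.4
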