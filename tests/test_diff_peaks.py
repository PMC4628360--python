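import math

import numpy as np
import pytest

from diffmark.diff_peaks import (
    ReplicatePeakSets,
    build_consensus,
    call_differential,
    quantify,
    quantile_filter,
    reproducible_peaks,
    run_differential_pipeline,
)
from diffmark.genome_io import GenomicInterval, Peak, merge_intervals
from diffmark.stats_core import CountMatrix, log_transform, scale_normalize

from conftest import random_peaks


def mk_peaks(spans, chrom="chr1", prefix="p"):
    return [
        Peak(GenomicInterval(chrom, s, e), f"{prefix}{i}") for i, (s, e) in enumerate(spans)
    ]


class TestReproduciblePeaks:
    def test_identical_sets_all_kept(self):
        peaks = mk_peaks([(100, 300), (500, 700)])
        kept = reproducible_peaks(peaks, peaks)
        assert [p.interval for p in kept] == [p.interval for p in peaks]

    def test_disjoint_sets_empty(self):
        a = mk_peaks([(100, 200)])
        b = mk_peaks([(300, 400)])
        assert reproducible_peaks(a, b) == []

    def test_kept_peak_extends_to_union_span(self):
        a = mk_peaks([(100, 300)])
        b = mk_peaks([(250, 400)])
        (kept,) = reproducible_peaks(a, b)
        assert kept.interval == GenomicInterval("chr1", 100, 400)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 60, chrom_names=("chr1",), max_pos=8000, max_len=300)
        b = random_peaks(rng, 60, chrom_names=("chr1",), max_pos=8000, max_len=300)
        kept = {p.peak_id: p.interval for p in reproducible_peaks(a, b)}
        for pa in a:
            matches = [
                pb.interval
                for pb in b
                if pa.interval.overlap_bp(pb.interval) >= 1
            ]
            if not matches:
                assert pa.peak_id not in kept
            else:
                start = min([pa.interval.start] + [m.start for m in matches])
                end = max([pa.interval.end] + [m.end for m in matches])
                assert kept[pa.peak_id] == GenomicInterval("chr1", start, end)


def make_sets(ctrl1, ctrl2, trt1, trt2):
    return ReplicatePeakSets(
        [ctrl1, ctrl2, trt1, trt2],
        ["control", "control", "treated", "treated"],
        [1e6] * 4,
    )


class TestBuildConsensus:
    def test_condition_specific_sources(self):
        trt = mk_peaks([(100, 300)])
        sets = make_sets(mk_peaks([(900, 1000)]), mk_peaks([(900, 1000)]), trt, trt)
        cons = build_consensus(sets)
        by_source = {c.source: c for c in cons}
        assert by_source["treated-reproducible"].interval == GenomicInterval("chr1", 100, 300)
        assert by_source["control-reproducible"].interval == GenomicInterval("chr1", 900, 1000)

    def test_shared_region_merged_as_both(self):
        peaks = mk_peaks([(100, 300)])
        sets = make_sets(peaks, peaks, mk_peaks([(200, 400)]), mk_peaks([(200, 400)]))
        cons = build_consensus(sets)
        assert len(cons) == 1
        assert cons[0].source == "both"
        assert cons[0].interval == GenomicInterval("chr1", 100, 400)

    def test_requires_two_replicates_per_condition(self):
        with pytest.raises(ValueError):
            ReplicatePeakSets(
                [mk_peaks([(1, 2)])] * 3, ["control", "treated", "treated"], [1e6] * 3
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reps = [
            random_peaks(rng, 40, chrom_names=("toy",), max_pos=9000, max_len=300)
            for _ in range(4)
        ]
        sets = make_sets(*reps)
        cons = build_consensus(sets)

        # oracle: union-span reproducible sets per condition, merged by base mask
        def repro_spans(r1, r2):
            spans = []
            for pa in r1:
                ms = [pb.interval for pb in r2 if pa.interval.overlap_bp(pb.interval) >= 1]
                if ms:
                    spans.append(
                        GenomicInterval(
                            "toy",
                            min([pa.interval.start] + [m.start for m in ms]),
                            max([pa.interval.end] + [m.end for m in ms]),
                        )
                    )
            return spans

        want = merge_intervals(repro_spans(reps[0], reps[1]) + repro_spans(reps[2], reps[3]))
        assert [c.interval for c in cons] == want


class TestQuantify:
    def test_counts_inside_and_library_total(self):
        cons = build_consensus(
            make_sets(*[mk_peaks([(100, 200)])] * 4)
        )
        tags = {"chr1": np.array([100, 150, 199, 200, 500])}  # 3 in, 2 out
        cm = quantify(cons, [tags] * 4, ["control", "control", "treated", "treated"])
        assert cm.counts[0, 0] == 3
        assert cm.library_sizes[0] == 5

    def test_empty_consensus_keeps_libraries(self):
        tags = {"chr1": np.array([10, 20])}
        cm = quantify([], [tags] * 4, ["control", "control", "treated", "treated"])
        assert cm.counts.shape == (0, 4)
        assert np.all(cm.library_sizes == 2)

    def test_interval_list_input_equals_dict_input(self):
        cons = build_consensus(make_sets(*[mk_peaks([(100, 200), (300, 400)])] * 4))
        ivs = [GenomicInterval("chr1", p, p + 1) for p in (120, 350, 900)]
        cm_list = quantify(cons, [ivs] * 4, ["control", "control", "treated", "treated"])
        cm_dict = quantify(
            cons,
            [{"chr1": np.array([120, 350, 900])}] * 4,
            ["control", "control", "treated", "treated"],
        )
        assert np.array_equal(cm_list.counts, cm_dict.counts)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, 30, chrom_names=("chr1", "chr2"), max_pos=5000, max_len=200)
        sets = make_sets(peaks, peaks, peaks, peaks)
        cons = build_consensus(sets)
        tag_pos = np.sort(rng.integers(0, 6000, size=400))
        tags = {"chr1": tag_pos[:200], "chr2": tag_pos[200:]}
        cm = quantify(cons, [tags] * 4, ["control", "control", "treated", "treated"])
        for j, c in enumerate(cons):
            pos = tags[c.interval.chrom]
            want = int(((pos >= c.interval.start) & (pos < c.interval.end)).sum())
            idx = cm.feature_ids.index(c.peak_id)
            assert cm.counts[idx, 0] == want


def ladder_nm(means):
    counts = np.tile(np.asarray(means, dtype=float)[:, None], (1, 4))
    cm = CountMatrix(
        [f"f{i}" for i in range(len(means))],
        list("abcd"),
        counts.astype(int),
        [1000.0] * 4,
        ["control", "control", "treated", "treated"],
    )
    scaled, t = scale_normalize(cm, target=1000.0)
    # use raw means as values directly for exact ladder arithmetic
    nm = log_transform(scaled, cm, pseudocount=1.0, target=t)
    nm.values = counts
    return nm


class TestQuantileFilter:
    def test_nearest_rank_ladder(self):
        nm = ladder_nm(list(range(1, 101)))
        retained = quantile_filter(nm, q=0.05)
        assert len(retained) == 95
        assert "f4" not in retained and "f5" in retained  # threshold is the 5th value

    def test_median_on_four(self):
        nm = ladder_nm([1, 2, 3, 4])
        assert quantile_filter(nm, q=0.5) == ["f2", "f3"]

    def test_all_tied_means_guarded(self):
        nm = ladder_nm([7, 7, 7])
        with pytest.raises(ValueError, match="lower q|inspect"):
            quantile_filter(nm, q=0.05)

    def test_too_few_features_rejected(self):
        nm = ladder_nm([1])
        with pytest.raises(ValueError):
            quantile_filter(nm, q=0.05)


class TestCallDifferential:
    def test_infinite_fc_cut_blocks_all_calls(self, rng):
        values = rng.normal(size=(100, 4))
        values[:10, 2:] += 5.0
        nm = ladder_nm([1] * 100)
        nm.values = values
        results = call_differential(nm, list(nm.feature_ids), fc_cut=math.inf)
        assert all(r.direction == "ns" for r in results)

    def test_strong_single_injection_recovered(self):
        rng = np.random.default_rng(0)
        n = 300
        base = np.log2(100 + rng.normal(0, 1.0, size=(n, 4)))
        base[0, 2:] += 2.0  # 4-fold on one peak
        nm = ladder_nm([1] * n)
        nm.values = base
        results = call_differential(nm, list(nm.feature_ids))
        assert results[0].direction == "up"
        assert all(r.direction == "ns" for r in results[1:])

    def test_partition_counts(self):
        rng = np.random.default_rng(3)
        nm = ladder_nm([1] * 50)
        nm.values = rng.normal(size=(50, 4))
        results = call_differential(nm, list(nm.feature_ids))
        n_up = sum(r.direction == "up" for r in results)
        n_down = sum(r.direction == "down" for r in results)
        n_ns = sum(r.direction == "ns" for r in results)
        assert n_up + n_down + n_ns == 50


class TestPipelineStructure:
    def _toy_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        peaks = mk_peaks([(i * 1000, i * 1000 + 500) for i in range(30)])
        sets = make_sets(peaks, peaks, peaks, peaks)
        counts = rng.integers(5, 200, size=(30, 4))
        return sets, counts

    def test_deterministic_given_inputs(self):
        sets, counts = self._toy_inputs()
        out1 = run_differential_pipeline(sets, counts=counts)
        out2 = run_differential_pipeline(sets, counts=counts)
        r1, r2 = out1[0].results, out2[0].results
        assert [(r.feature_id, r.log_fc, r.p_value, r.q_value, r.direction) for r in r1] == [
            (r.feature_id, r.log_fc, r.p_value, r.q_value, r.direction) for r in r2
        ]

    def test_quantile_threshold_computed_over_consensus_only(self):
        # the filter sees only reproducible peaks: a low-signal peak present in
        # one replicate only must not shift the quantile threshold
        strong = [(i * 1000, i * 1000 + 500) for i in range(1, 21)]
        ctrl1 = mk_peaks(strong + [(50_000, 50_400)])  # extra peak, rep1 only
        ctrl2 = mk_peaks(strong)
        sets = make_sets(ctrl1, ctrl2, mk_peaks(strong), mk_peaks(strong))
        cons = build_consensus(sets)
        assert len(cons) == 20  # irreproducible peak never reaches quantification

    def test_up_down_sum_equals_called(self):
        sets, counts = self._toy_inputs(seed=5)
        dps, _, _ = run_differential_pipeline(sets, counts=counts)
        assert dps.n_up + dps.n_down == len(dps.called)
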