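import numpy as np
import pandas as pd
import pytest

from enhancerscape.enhancers import (
    DistalFilterRules,
    StitchedEnhancer,
    call_super,
    filter_active,
    filter_distal,
    quantify,
    stitch,
)
from enhancerscape.genome_io import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SignalTrack,
)

from conftest import random_intervals, random_track


def annotation_at(tss_list):
    rows = [dict(gene_id=f"g{i}", chrom="chr1", start=t, end=t + 1000,
                 strand="+") for i, t in enumerate(tss_list)]
    return GeneAnnotation(pd.DataFrame.from_records(rows))


def brute_force_distal(peaks, genes, rules):
    """All-pairs distance check, the oracle for the retained/removed call."""
    kept = []
    for iv in peaks:
        ok_all = True
        for row in genes.genes.itertuples():
            if row.chrom != iv.chrom:
                continue
            tss = row.tss
            if iv.start <= tss <= iv.end:
                bdist = 0
            else:
                bdist = min(abs(tss - iv.start), abs(tss - iv.end))
            cdist = abs((iv.start + iv.end) / 2 - tss)
            ok_b = bdist >= rules.boundary_min_dist
            ok_c = cdist >= rules.center_min_dist
            ok = (ok_b or ok_c) if rules.combine == "or" else (ok_b and ok_c)
            if not ok:
                ok_all = False
                break
        if ok_all:
            kept.append(iv)
    return kept


class TestDistalFilter:
    def test_far_peak_retained(self):
        peaks = PeakSet([GenomicInterval("chr1", 5000, 5200)])
        out = filter_distal(peaks, annotation_at([10_000]))
        assert len(out) == 1  # boundary distance 4800 >= 1500

    def test_tss_inside_peak_removed(self):
        peaks = PeakSet([GenomicInterval("chr1", 5000, 5200)])
        out = filter_distal(peaks, annotation_at([5100]))
        assert len(out) == 0

    def test_combine_switch_on_ambiguous_peak(self):
        # boundary 1400 bp from TSS but center 3100 bp away
        peak = GenomicInterval("chr1", 11_400, 14_800)  # center 13_100
        peaks = PeakSet([peak])
        genes = annotation_at([10_000])
        assert len(filter_distal(peaks, genes,
                                 DistalFilterRules(combine="or"))) == 1
        assert len(filter_distal(peaks, genes,
                                 DistalFilterRules(combine="and"))) == 0

    def test_empty_annotation_rejected(self):
        ann = annotation_at([100])
        ann.genes = ann.genes.iloc[0:0]
        with pytest.raises(ValueError, match="empty"):
            filter_distal(PeakSet([GenomicInterval("chr1", 0, 10)]), ann)

    @pytest.mark.parametrize("combine", ["or", "and"])
    def test_matches_brute_force(self, combine):
        rng = np.random.default_rng(17)
        peaks = PeakSet(random_intervals(rng, 200, chroms=("chr1",),
                                         max_pos=500_000, max_len=4000))
        genes = annotation_at(sorted(rng.integers(0, 500_000, size=50)
                                     .tolist()))
        rules = DistalFilterRules(combine=combine)
        got = {iv.sort_key() for iv in filter_distal(peaks, genes, rules)}
        want = {iv.sort_key() for iv in brute_force_distal(peaks, genes,
                                                           rules)}
        assert got == want

    def test_idempotent(self):
        rng = np.random.default_rng(23)
        peaks = PeakSet(random_intervals(rng, 100, chroms=("chr1",),
                                         max_pos=300_000))
        genes = annotation_at(sorted(rng.integers(0, 300_000, 20).tolist()))
        once = filter_distal(peaks, genes)
        twice = filter_distal(once, genes)
        assert [i.sort_key() for i in once] == [i.sort_key() for i in twice]


def brute_force_partition(intervals, gap):
    """O(n^2) transitive closure over the 'distance < gap' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            dist = max(b.start - a.end, a.start - b.end)
            if dist < gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    return {frozenset(iv.sort_key() for iv in g) for g in groups.values()}


class TestStitch:
    def test_gap_just_below_threshold_merges(self):
        peaks = PeakSet([GenomicInterval("chr1", 100, 200),
                         GenomicInterval("chr1", 12_699, 12_800)])
        out = stitch(peaks)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (100, 12_800)

    def test_gap_at_threshold_splits(self):
        peaks = PeakSet([GenomicInterval("chr1", 100, 200),
                         GenomicInterval("chr1", 12_700, 12_800)])
        assert len(stitch(peaks)) == 2

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(29)
        peaks = PeakSet(random_intervals(rng, 300, max_pos=2_000_000))
        result = stitch(peaks)
        got = {frozenset(iv.sort_key() for iv in e.constituents)
               for e in result}
        assert got == brute_force_partition(peaks.intervals, 12_500)

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        peaks = PeakSet(random_intervals(rng, 200))
        first = stitch(peaks)
        spans = PeakSet([e.interval for e in first])
        second = stitch(spans)
        assert [e.interval.sort_key() for e in first] == [
            e.interval.sort_key() for e in second]


class TestActiveFilter:
    def test_requires_h3k4me1_support(self):
        k27 = PeakSet([GenomicInterval("chr1", 0, 100),
                       GenomicInterval("chr1", 1000, 1100)])
        k4 = PeakSet([GenomicInterval("chr1", 99, 150)])
        out = filter_active(k27, k4)
        assert [(i.start, i.end) for i in out] == [(0, 100)]

    def test_overlap_fraction_knob(self):
        k27 = PeakSet([GenomicInterval("chr1", 0, 100)])
        k4 = PeakSet([GenomicInterval("chr1", 90, 200)])  # 10% overlap
        assert len(filter_active(k27, k4, min_overlap_fraction=0.5)) == 0
        assert len(filter_active(k27, k4, min_overlap_fraction=0.05)) == 1


def make_enhancers(signals):
    out = []
    pos = 0
    for s in signals:
        iv = GenomicInterval("chr1", pos, pos + 1000)
        e = StitchedEnhancer(interval=iv, constituents=[iv])
        e.signal["H3K27ac"] = {"raw": float(s), "rpkm": float(s)}
        out.append(e)
        pos += 20_000
    return out


class TestQuantify:
    def test_rpkm_worked_example(self):
        iv = GenomicInterval("chr1", 0, 2000)
        enh = [StitchedEnhancer(interval=iv, constituents=[iv])]
        track = SignalTrack({"chr1": ([0], [2000], [0.2])},
                            library_size=1e6)  # 400 reads over 2 kb
        quantify(enh, track)
        assert enh[0].signal["H3K27ac"]["raw"] == pytest.approx(400.0,
                                                                abs=1e-9)
        assert enh[0].signal["H3K27ac"]["rpkm"] == pytest.approx(200.0,
                                                                 abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(37)
        track = random_track(rng)
        iv = GenomicInterval("chr1", 1000, 9000)
        e1 = [StitchedEnhancer(interval=iv, constituents=[iv])]
        quantify(e1, track)
        doubled = SignalTrack(
            {c: (s, e, v * 2) for c, (s, e, v) in track.runs.items()},
            library_size=track.library_size * 2)
        e2 = [StitchedEnhancer(interval=iv, constituents=[iv])]
        quantify(e2, doubled)
        assert e2[0].signal["H3K27ac"]["rpkm"] == pytest.approx(
            e1[0].signal["H3K27ac"]["rpkm"], rel=1e-12)

    def test_block_sum_matches_per_bp_oracle(self):
        rng = np.random.default_rng(41)
        track = random_track(rng)
        for _ in range(10):
            s = int(rng.integers(0, 80_000))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 15_000)))
            enh = [StitchedEnhancer(interval=iv, constituents=[iv])]
            quantify(enh, track)
            brute = track.values_per_bp("chr1", iv.start, iv.end).sum()
            assert enh[0].signal["H3K27ac"]["raw"] == pytest.approx(
                brute, rel=1e-9)

    def test_zero_library_rejected(self):
        iv = GenomicInterval("chr1", 0, 100)
        with pytest.raises(ValueError):
            quantify([StitchedEnhancer(interval=iv, constituents=[iv])],
                     SignalTrack({"chr1": ([0], [10], [1.0])},
                                 library_size=0.0))


class TestCallSuper:
    def test_cubic_curve_analytic_tangent(self):
        # y = x^3: slope-1 tangent at x = 3^(-1/2) ~ 0.5774
        x = np.arange(1001) / 1000
        enh = make_enhancers(x ** 3 * 1e4)
        curve = call_super(enh)
        assert 0.57 <= curve.cutoff_index / 1000 <= 0.59
        frac_super = np.mean([e.is_super for e in enh])
        assert 0.40 <= frac_super <= 0.44  # analytic 1 - 3^(-1/2) ~ 0.423

    def test_linear_curve_has_no_supers(self):
        enh = make_enhancers(np.arange(101, dtype=float))
        with pytest.warns(UserWarning):
            curve = call_super(enh)
        assert curve.cutoff_index is None
        assert not any(e.is_super for e in enh)

    def test_all_equal_signals_no_supers(self):
        enh = make_enhancers([5.0] * 10)
        with pytest.warns(UserWarning):
            call_super(enh)
        assert not any(e.is_super for e in enh)

    def test_boosting_top_enhancer_never_demotes_it(self):
        rng = np.random.default_rng(43)
        base = rng.random(200) * 10
        base[base.argmax()] += 50  # clear super tail
        enh = make_enhancers(base)
        call_super(enh)
        top = max(enh, key=lambda e: e.signal["H3K27ac"]["raw"])
        assert top.is_super
        boosted = base.copy()
        boosted[base.argmax()] += 100
        enh2 = make_enhancers(boosted)
        call_super(enh2)
        top2 = max(enh2, key=lambda e: e.signal["H3K27ac"]["raw"])
        assert top2.is_super

    def test_partition_monotone_in_signal(self):
        rng = np.random.default_rng(47)
        sig = np.concatenate([rng.random(150), 20 + rng.random(10) * 10])
        enh = make_enhancers(sig)
        call_super(enh)
        supers = [e.signal["H3K27ac"]["raw"] for e in enh if e.is_super]
        typicals = [e.signal["H3K27ac"]["raw"] for e in enh if not e.is_super]
        if supers and typicals:
            assert min(supers) > max(typicals)

    def test_too_few_enhancers_rejected(self):
        with pytest.raises(ValueError):
            call_super(make_enhancers([1.0, 2.0]))
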