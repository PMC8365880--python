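import numpy as np
import pytest

from enhancerscape.differential import (
    build_union_catalog,
    call_degs,
    call_vels,
    call_vsels,
    normalize_fpkm,
    pool_replicates,
)
from enhancerscape.enhancers import StitchedEnhancer, quantify, stitch
from enhancerscape.genome_io import (
    CountMatrix,
    GenomicInterval,
    PeakSet,
    SignalTrack,
)

from conftest import random_intervals, random_track


def flat_track(value, length=10_000, library=1e6):
    return SignalTrack({"chr1": ([0], [length], [value])},
                       library_size=library)


def enh_at(start, end, chrom="chr1"):
    iv = GenomicInterval(chrom, start, end)
    return StitchedEnhancer(interval=iv, constituents=[iv])


class TestPoolReplicates:
    def test_identical_tracks_double(self):
        rng = np.random.default_rng(5)
        t = random_track(rng)
        pooled = pool_replicates([t, t])
        assert pooled.library_size == pytest.approx(2 * t.library_size)
        assert pooled.total_signal == pytest.approx(2 * t.total_signal)

    def test_single_track_identity(self):
        rng = np.random.default_rng(6)
        t = random_track(rng)
        assert pool_replicates([t]) is t

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_replicates([])

    def test_pool_then_quantify_is_linear(self):
        # pooled raw quantification equals the sum of per-replicate raws,
        # even when replicates have different run breakpoints
        rng = np.random.default_rng(7)
        tracks = [random_track(rng) for _ in range(3)]
        pooled = pool_replicates(tracks)
        iv = GenomicInterval("chr1", 2000, 60_000)
        pooled_raw = pooled.interval_sum("chr1", iv.start, iv.end)
        per_rep = sum(t.interval_sum("chr1", iv.start, iv.end)
                      for t in tracks)
        assert pooled_raw == pytest.approx(per_rep, rel=1e-9)


class TestUnionCatalog:
    def test_disjoint_catalogs_concatenate(self):
        a = [enh_at(i * 100_000, i * 100_000 + 500) for i in range(3)]
        b = [enh_at(i * 100_000 + 50_000, i * 100_000 + 50_500)
             for i in range(4)]
        assert len(build_union_catalog(a, b)) == 7

    def test_identical_catalogs_collapse(self):
        a = [enh_at(0, 500), enh_at(50_000, 50_500)]
        b = [enh_at(0, 500), enh_at(50_000, 50_500)]
        union = build_union_catalog(a, b)
        assert [(e.interval.start, e.interval.end) for e in union] == [
            (0, 500), (50_000, 50_500)]
        for e in union:
            prov = e.signal["provenance"]
            assert prov["in_normal"] and prov["in_tumor"]

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(8)
        a = [enh_at(s.start, s.end, s.chrom)
             for s in random_intervals(rng, 80, max_pos=300_000)]
        b = [enh_at(s.start, s.end, s.chrom)
             for s in random_intervals(rng, 80, max_pos=300_000)]
        union = build_union_catalog(a, b)
        # overlap >= 1 bp joins == stitching with gap threshold 1
        all_spans = PeakSet([e.interval for e in a + b])
        oracle = stitch(all_spans, stitch_gap=1)
        assert [(e.interval.sort_key()) for e in union] == [
            (e.interval.sort_key()) for e in oracle]


class TestCallVels:
    def test_fold_change_worked_example(self):
        cat = [enh_at(0, 1000)]
        tumor = flat_track(0.01)    # raw 10 over 1 kb -> RPKM 10
        normal = flat_track(0.004)  # raw 4 -> RPKM 4
        [rec] = call_vels(cat, tumor, normal, pseudocount=1.0)
        assert rec.fold_change == pytest.approx(11 / 5)
        assert rec.status == "gain"

    def test_equal_signal_is_stable(self):
        cat = [enh_at(0, 1000)]
        [rec] = call_vels(cat, flat_track(0.01), flat_track(0.01))
        assert rec.fold_change == pytest.approx(1.0)
        assert rec.status == "stable"

    def test_gain_lost_symmetry(self):
        # swapping tumor and normal inverts every fold change, so
        # gain(t, n) == lost(n, t) under inverted thresholds; exact
        # reciprocity needs a vanishing pseudocount
        rng = np.random.default_rng(9)
        cat_spans = [(i * 20_000, i * 20_000 + 1000) for i in range(10)]
        t = random_track(rng, max_pos=300_000)
        n = random_track(rng, max_pos=300_000)
        fwd = call_vels([enh_at(s, e) for s, e in cat_spans], t, n,
                        pseudocount=1e-9)
        rev = call_vels([enh_at(s, e) for s, e in cat_spans], n, t,
                        pseudocount=1e-9)
        f = {r.enhancer.interval.sort_key(): r for r in fwd}
        r_ = {r.enhancer.interval.sort_key(): r for r in rev}
        swap = {"gain": "lost", "lost": "gain", "stable": "stable"}
        for key in f:
            assert f[key].fold_change == pytest.approx(
                1 / r_[key].fold_change, rel=1e-6)
            assert swap[f[key].status] == r_[key].status

    def test_scale_invariance(self):
        cat1 = [enh_at(0, 1000)]
        cat2 = [enh_at(0, 1000)]
        t, n = flat_track(0.03), flat_track(0.01)
        t2 = SignalTrack({"chr1": ([0], [10_000], [0.3])}, library_size=1e7)
        n2 = SignalTrack({"chr1": ([0], [10_000], [0.1])}, library_size=1e7)
        [a] = call_vels(cat1, t, n)
        [b] = call_vels(cat2, t2, n2)
        assert a.fold_change == pytest.approx(b.fold_change, rel=1e-12)
        assert a.status == b.status

    def test_bad_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            call_vels([enh_at(0, 1000)], flat_track(1), flat_track(1),
                      pseudocount=0.0)


class TestCallVsels:
    def _catalog(self, super_normal, super_tumor):
        e = enh_at(0, 1000)
        e.signal["provenance"] = dict(
            in_normal=True, in_tumor=True,
            super_in_normal=super_normal, super_in_tumor=super_tumor)
        return [e]

    def test_super_in_tumor_gain(self):
        cat = self._catalog(False, True)
        [rec] = call_vsels(cat, flat_track(0.03), flat_track(0.01))
        assert rec.status == "gain"
        assert rec.condition_of_super == "tumor"

    def test_gain_requires_super_in_tumor(self):
        cat = self._catalog(True, False)
        [rec] = call_vsels(cat, flat_track(0.03), flat_track(0.01))
        assert rec.status == "stable"  # directional rule blocks the gain

    def test_non_directional_mode(self):
        cat = self._catalog(True, False)
        [rec] = call_vsels(cat, flat_track(0.03), flat_track(0.01),
                           directional=False)
        assert rec.status == "gain"

    def test_non_super_loci_excluded(self):
        cat = self._catalog(False, False)
        assert call_vsels(cat, flat_track(0.03), flat_track(0.01)) == []


class TestFpkm:
    def _matrix(self, counts, lengths):
        counts = np.asarray(counts)
        n = counts.shape[1]
        ids = [f"s{i}" for i in range(n)]
        groups = {s: ("normal" if i < n // 2 else "tumor")
                  for i, s in enumerate(ids)}
        return CountMatrix([f"g{i}" for i in range(counts.shape[0])],
                           ids, counts, np.asarray(lengths, float), groups)

    def test_worked_example(self):
        # gene of 2 kb with 100 reads in a 1e6-read library -> FPKM 50
        cm = self._matrix([[100, 100], [999_900, 999_900]], [2000, 1000])
        fpkm = normalize_fpkm(cm)
        assert fpkm[0, 0] == pytest.approx(50.0, abs=1e-9)

    def test_depth_invariance(self):
        cm1 = self._matrix([[100, 200], [900, 1800]], [2000, 1000])
        fpkm = normalize_fpkm(cm1)
        assert fpkm[0, 0] == pytest.approx(fpkm[0, 1], rel=1e-12)

    def test_matches_scalar_formula(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 1000, size=(20, 4))
        lengths = rng.integers(200, 5000, size=20)
        cm = self._matrix(counts, lengths)
        fpkm = normalize_fpkm(cm)
        totals = counts.sum(axis=0)
        for g in range(20):
            for s in range(4):
                want = counts[g, s] / ((lengths[g] / 1000)
                                       * (totals[s] / 1e6))
                assert fpkm[g, s] == pytest.approx(want, rel=1e-12)

    def test_zero_library_rejected(self):
        cm = self._matrix([[0, 5], [0, 5]], [1000, 1000])
        with pytest.raises(ValueError, match="zero library"):
            normalize_fpkm(cm)


class TestCallDegs:
    def _matrix(self, normal, tumor, lengths=None):
        normal, tumor = np.asarray(normal), np.asarray(tumor)
        counts = np.hstack([normal, tumor])
        ids = ([f"n{i}" for i in range(normal.shape[1])]
               + [f"t{i}" for i in range(tumor.shape[1])])
        groups = {s: ("normal" if s.startswith("n") else "tumor")
                  for s in ids}
        n_genes = counts.shape[0]
        if lengths is None:
            lengths = np.full(n_genes, 1000.0)
        return CountMatrix([f"g{i}" for i in range(n_genes)], ids, counts,
                           lengths, groups)

    def test_identical_groups_null(self):
        block = [[100, 110, 90], [500, 480, 520]]
        cm = self._matrix(block, block)
        for rec in call_degs(cm):
            assert rec.log2fc == pytest.approx(0.0, abs=1e-9)
            assert rec.status == "null"

    def test_strong_planted_gene_called_up(self):
        cm = self._matrix(
            [[100, 105, 95], [1000, 1010, 990], [1000, 990, 1010]],
            [[405, 420, 380], [1000, 1020, 980], [1000, 1010, 990]],
        )
        recs = {r.gene_id: r for r in call_degs(cm)}
        assert recs["g0"].status == "up"
        assert recs["g1"].status == "null"

    def test_small_groups_rejected(self):
        cm = self._matrix([[1], [2]], [[3], [4]])
        with pytest.raises(ValueError, match="2 samples"):
            call_degs(cm)

    def test_concordant_with_negative_binomial_fitter(self, sim_bundle):
        # independent route: a DESeq2-style NB GLM (pydeseq2) should call
        # essentially the same up-regulated set as the Welch stand-in on
        # simulated counts with strong planted effects
        import pandas as pd
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cm = sim_bundle["counts"]
        counts = pd.DataFrame(cm.counts.T, index=cm.sample_ids,
                              columns=cm.gene_ids)
        meta = pd.DataFrame(
            {"condition": [cm.groups[s] for s in cm.sample_ids]},
            index=cm.sample_ids)
        dds = DeseqDataSet(counts=counts, metadata=meta,
                           design="~condition", quiet=True)
        dds.deseq2()
        st = DeseqStats(dds, contrast=["condition", "tumor", "normal"],
                        quiet=True)
        st.summary()
        res = st.results_df
        nb_up = set(res[(res.padj < 0.05) & (res.log2FoldChange >= 1)].index)
        welch_up = {d.gene_id for d in call_degs(cm) if d.status == "up"}
        jaccard = len(nb_up & welch_up) / max(len(nb_up | welch_up), 1)
        assert jaccard >= 0.9
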