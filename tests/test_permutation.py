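import numpy as np
import pandas as pd
import pytest

from crelink import permutation as perm
from crelink.intervals import CREClass, GeneAnnotation, GenomicInterval, Peak
from crelink.network import EGNetwork


def _variants(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])


def _peak(chrom, start, length):
    return Peak(GenomicInterval(chrom, start, start + length), start + length // 2, 1.0)


GENES = [GeneAnnotation("g1", "chr1", 50_000), GeneAnnotation("g2", "chr1", 500_000)]


class TestObservedOverlap:
    def test_boundary_and_uniqueness(self):
        cres = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 250)]
        v = _variants([
            ("chr1", 100, "at_start"),       # 0-based start is inside
            ("chr1", 199, "just_inside"),
            ("chr1", 200, "at_end"),         # exclusive end: outside first CRE
            ("chr1", 175, "in_two_cres"),    # counts once
            ("chr1", 175, "in_two_cres"),    # duplicate row collapses
        ])
        assert perm.observed_variant_overlap(v, cres) == 4

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        cres = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
            for s in rng.integers(0, 900_000, size=100)
        ]
        v = _variants([
            ("chr1", int(p), f"v{i}")
            for i, p in enumerate(rng.integers(0, 1_000_000, size=1_000))
        ])
        want = sum(
            1
            for row in v.itertuples(index=False)
            if any(c.start <= row.pos < c.end for c in cres)
        )
        assert perm.observed_variant_overlap(v, cres) == want


class TestMatchIndex:
    def test_one_peak_occupies_one_bin(self):
        idx = perm.build_match_index(
            [_peak("chr1", 10_000, 300)], GENES,
            len_edges=np.array([200.0, 400.0]), dist_edges=np.array([1_000.0]),
        )
        assert len(idx.bins) == 1

    def test_value_on_edge_falls_in_right_bin(self):
        # lengths 400 exactly on the edge -> right-hand (upper) bin
        idx = perm.build_match_index(
            [_peak("chr1", 10_000, 400), _peak("chr1", 20_000, 399)], GENES,
            len_edges=np.array([400.0]), dist_edges=np.array([1e9]),
        )
        keys = sorted(idx.bins)
        assert len(keys) == 2
        assert keys[0][1] == 0 and keys[1][1] == 1  # below / at-or-above edge

    def test_membership_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        peaks = [
            _peak("chr1", int(s), int(rng.integers(100, 2_000)))
            for s in rng.integers(0, 900_000, size=200)
        ]
        len_edges = np.array([300.0, 600.0, 1_200.0])
        dist_edges = np.array([5_000.0, 50_000.0])
        idx = perm.build_match_index(peaks, GENES, len_edges, dist_edges)
        for key, members in idx.bins.items():
            for i in members:
                p = peaks[i]
                lb = int(np.digitize(p.interval.length, len_edges))
                d = min(abs(p.interval.midpoint - g.tss) for g in GENES)
                db = int(np.digitize(d, dist_edges))
                assert key == ("chr1", lb, db)

    def test_strictly_increasing_edges_required(self):
        with pytest.raises(ValueError):
            perm.build_match_index(
                [_peak("chr1", 0, 100)], GENES,
                len_edges=np.array([5.0, 5.0]), dist_edges=np.array([1.0]),
            )


class TestSampleMatched:
    def test_exact_bin_returns_its_only_peak(self):
        p = _peak("chr1", 40_000, 300)
        idx = perm.build_match_index([p], GENES)
        got, r = perm.sample_matched(idx, "chr1", 300, 10_150 - 0,
                                     np.random.default_rng(0))
        assert got == p and r == 0

    def test_relaxes_to_adjacent_bin(self):
        # only peak is long; query is short -> relaxation needed
        p = _peak("chr1", 40_000, 1_900)
        idx = perm.build_match_index(
            [p], GENES, len_edges=np.array([500.0, 1_000.0]),
            dist_edges=np.array([1e9]),
        )
        got, r = perm.sample_matched(idx, "chr1", 600, 100, np.random.default_rng(0))
        assert got == p and r == 1

    def test_missing_chromosome_raises(self):
        idx = perm.build_match_index([_peak("chr1", 0, 100)], GENES)
        with pytest.raises(ValueError):
            perm.sample_matched(idx, "chrZ", 100, 100, np.random.default_rng(0))

    def test_sampling_is_uniform_within_bin(self):
        peaks = [_peak("chr1", 40_000 + 1_000 * i, 300) for i in range(3)]
        idx = perm.build_match_index(
            peaks, GENES, len_edges=np.array([1e9]), dist_edges=np.array([1e9])
        )
        rng = np.random.default_rng(7)
        counts = {i: 0 for i in range(3)}
        for _ in range(10_000):
            got, _ = perm.sample_matched(idx, "chr1", 300, 5_000, rng)
            counts[peaks.index(got)] += 1
        for c in counts.values():
            # binomial(10000, 1/3): 5 sigma ~ 236
            assert abs(c - 10_000 / 3) < 250


class TestVariantPermutation:
    def _setup(self, rng):
        peaks = [
            _peak("chr1", int(s), int(rng.integers(200, 800)))
            for s in rng.integers(0, 900_000, size=300)
        ]
        net_cres = {
            f"c{i}": peaks[i].interval for i in rng.choice(300, size=30, replace=False)
        }
        return peaks, net_cres

    def test_p_value_identities(self):
        rng = np.random.default_rng(3)
        peaks, net_cres = self._setup(rng)
        # observed below every null -> p = 1
        v = _variants([("chr1", 999_999, "far")])
        res = perm.permutation_test_variants(v, net_cres, peaks, GENES,
                                             n_perm=50, seed=0)
        assert res.observed == 0
        assert res.p_empirical == 1.0
        # direct-count identity on the stored null vector
        k = int(np.sum(res.null_values >= res.observed))
        assert res.p_empirical == (k + 1) / (res.n_perm + 1)

    def test_null_count_example(self):
        # null {1,2,3,4}, observed 3 -> p = (2+1)/5
        null = np.array([1, 2, 3, 4])
        p = (int(np.sum(null >= 3)) + 1) / (len(null) + 1)
        assert p == pytest.approx(0.6)

    def test_bit_reproducible(self):
        rng = np.random.default_rng(4)
        peaks, net_cres = self._setup(rng)
        v = _variants([
            ("chr1", int(p), f"v{i}")
            for i, p in enumerate(rng.integers(0, 1_000_000, size=200))
        ])
        a = perm.permutation_test_variants(v, net_cres, peaks, GENES, n_perm=100, seed=9)
        b = perm.permutation_test_variants(v, net_cres, peaks, GENES, n_perm=100, seed=9)
        assert a.observed == b.observed
        assert np.array_equal(a.null_values, b.null_values)
        assert a.p_empirical == b.p_empirical and a.fold_enrichment == b.fold_enrichment

    def test_p_floor_when_observed_beats_every_null(self):
        rng = np.random.default_rng(5)
        peaks, net_cres = self._setup(rng)
        # every variant inside network CREs -> observed is maximal
        v_rows = []
        for i, iv in enumerate(list(net_cres.values()) * 4):
            v_rows.append(("chr1", int((iv.start + iv.end) // 2), f"v{i}"))
        res = perm.permutation_test_variants(
            _variants(v_rows), net_cres, peaks, GENES, n_perm=200, seed=1
        )
        assert res.p_empirical >= 1 / (res.n_perm + 1)
        assert res.fold_enrichment > 1


class TestEqtlOps:
    CRES = {
        "c1": GenomicInterval("chr1", 100, 200),
        "c2": GenomicInterval("chr1", 150, 260),
    }
    NET = EGNetwork(edges=pd.DataFrame(
        {"cre_id": ["c1", "c2"], "gene_id": ["g1", "g2"], "score": [0.9, 0.9]}
    ))

    def test_variant_in_cre_with_wrong_target_not_counted(self):
        eq = pd.DataFrame([("chr1", 120, "e1", "g2")],
                          columns=["chrom", "pos", "id", "gene_id"])
        # pos 120 only inside c1, whose sole edge targets g1
        assert perm.observed_eqtl_concordance(eq, self.NET, self.CRES) == 0

    def test_pair_supported_by_two_cres_counts_once(self):
        net = EGNetwork(edges=pd.DataFrame(
            {"cre_id": ["c1", "c2"], "gene_id": ["g1", "g1"], "score": [0.9, 0.9]}
        ))
        eq = pd.DataFrame([("chr1", 175, "e1", "g1")],
                          columns=["chrom", "pos", "id", "gene_id"])
        assert perm.observed_eqtl_concordance(eq, net, self.CRES) == 1

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(6)
        cres = {
            f"c{i}": GenomicInterval("chr1", int(s), int(s) + 200)
            for i, s in enumerate(rng.integers(0, 90_000, size=40))
        }
        edges = pd.DataFrame({
            "cre_id": [f"c{rng.integers(40)}" for _ in range(60)],
            "gene_id": [f"g{rng.integers(10)}" for _ in range(60)],
            "score": 1.0,
        }).drop_duplicates(["cre_id", "gene_id"])
        network = EGNetwork(edges=edges)
        eq = pd.DataFrame(
            [("chr1", int(p), f"e{i}", f"g{rng.integers(10)}")
             for i, p in enumerate(rng.integers(0, 100_000, size=300))],
            columns=["chrom", "pos", "id", "gene_id"],
        )
        edge_set = set(zip(edges["cre_id"], edges["gene_id"]))
        want = len({
            (r.chrom, r.pos, r.id, r.gene_id)
            for r in eq.itertuples(index=False)
            for cid, iv in cres.items()
            if iv.start <= r.pos < iv.end and (cid, r.gene_id) in edge_set
        })
        assert perm.observed_eqtl_concordance(eq, network, cres) == want

    def test_identity_sampling_gives_degenerate_null(self):
        # a universe where each CRE's bin contains only itself
        peaks = [_peak("chr1", 100, 100), _peak("chr1", 150, 110)]
        cres = {"peak_0": peaks[0].interval, "peak_1": peaks[1].interval}
        network = EGNetwork(edges=pd.DataFrame(
            {"cre_id": ["peak_0", "peak_1"], "gene_id": ["g1", "g2"],
             "score": [0.9, 0.9]}
        ), threshold=0.5)
        peak_edges = pd.DataFrame(
            {"peak_id": ["peak_0", "peak_1"], "gene_id": ["g1", "g2"],
             "score": [0.9, 0.9]}
        )
        eq = pd.DataFrame([("chr1", 120, "e1", "g1"), ("chr1", 200, "e2", "g2")],
                          columns=["chrom", "pos", "id", "gene_id"])
        res = perm.permutation_test_eqtl(
            eq, network, peaks, GENES, peak_edges,
            peak_classes=[CREClass.INTERGENIC_ENHANCER] * 2,
            n_perm=30, seed=0,
            len_edges=np.array([105.0]), dist_edges=np.array([1e9]),
            cre_intervals=cres,
        )
        assert res.observed == 2
        assert np.all(res.null_values == res.observed)
        assert res.p_empirical == 1.0

    def test_recovers_planted_concordance_enrichment(self):
        """eQTLs planted concordant with one CRE set: the permutation FE
        should exceed 1 and the observed statistic should sit far in the
        null's upper tail."""
        rng = np.random.default_rng(8)
        peaks = [
            _peak("chr1", int(s), int(rng.integers(200, 600)))
            for s in rng.integers(0, 900_000, size=400)
        ]
        peak_ids = [f"peak_{i}" for i in range(400)]
        # every peak predicts 1-2 targets
        rows = []
        for pid in peak_ids:
            for g in rng.choice(10, size=int(rng.integers(1, 3)), replace=False):
                rows.append((pid, f"g{g}", 0.9))
        peak_edges = pd.DataFrame(rows, columns=["peak_id", "gene_id", "score"])
        net_ids = [peak_ids[i] for i in rng.choice(400, size=40, replace=False)]
        edges = peak_edges[peak_edges["peak_id"].isin(net_ids)].rename(
            columns={"peak_id": "cre_id"})
        network = EGNetwork(edges=edges, threshold=0.5)
        cres = {pid: peaks[int(pid.split("_")[1])].interval for pid in peak_ids}
        # plant concordant eqtls inside network CREs, plus uniform noise
        eq_rows = []
        for i, (cid, g) in enumerate(zip(edges["cre_id"], edges["gene_id"])):
            iv = cres[cid]
            eq_rows.append((iv.chrom, int((iv.start + iv.end) // 2), f"pe{i}", g))
        for i, p in enumerate(rng.integers(0, 1_000_000, size=200)):
            eq_rows.append(("chr1", int(p), f"ne{i}", f"g{rng.integers(10)}"))
        eq = pd.DataFrame(eq_rows, columns=["chrom", "pos", "id", "gene_id"])
        res = perm.permutation_test_eqtl(
            eq, network, peaks, GENES, peak_edges,
            peak_classes=[CREClass.INTERGENIC_ENHANCER] * 400,
            n_perm=100, seed=2, cre_intervals=cres, peak_ids=peak_ids,
        )
        assert res.fold_enrichment > 1.5
        assert res.p_empirical <= 0.05
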