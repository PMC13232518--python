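import numpy as np
import pandas as pd
import pytest

from crelink import features as feat
from crelink.intervals import GeneAnnotation, GenomicInterval, Peak
from oracles import abc_loop

SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


def mk_peak(chrom, start, length, rc, summit=None):
    iv = GenomicInterval(chrom, start, start + length)
    return Peak(iv, summit if summit is not None else start + length // 2, rc)


class TestSelectCandidates:
    def test_counts_peaks_plus_promoters(self):
        peaks = [mk_peak("chr1", 1_000 * i + 10_000, 300, 10 + i) for i in range(10)]
        genes = [GeneAnnotation("g1", "chr1", 500_000), GeneAnnotation("g2", "chr1", 600_000)]
        out = feat.select_candidates(peaks, genes, SIZES, n_top=3)
        assert sum(c.source == "dnase_peak" for c in out) == 3
        assert sum(c.source == "promoter" for c in out) == 2
        assert all(
            c.interval.length == feat.CRE_SCORING_WIDTH
            for c in out if c.source == "dnase_peak"
        )

    def test_read_count_ties_break_by_position(self):
        peaks = [
            mk_peak("chr1", 50_000, 300, 5.0),
            mk_peak("chr1", 10_000, 300, 5.0),
            mk_peak("chr1", 30_000, 300, 5.0),
        ]
        out = feat.select_candidates(peaks, [], SIZES, n_top=2)
        starts = [c.interval.start for c in out]
        assert starts == sorted(starts)
        assert out[0].interval.midpoint == 10_150

    def test_top_k_dominates_discarded(self):
        rng = np.random.default_rng(0)
        peaks = [
            mk_peak("chr1", int(s), 200, float(rc))
            for s, rc in zip(
                rng.integers(0, 900_000, size=1_000), rng.gamma(2, 30, size=1_000)
            )
        ]
        out = feat.select_candidates(peaks, [], SIZES, n_top=150)
        kept = sorted((c.read_count for c in out), reverse=True)
        discarded_max = sorted((p.read_count for p in peaks), reverse=True)[150]
        assert min(kept) >= discarded_max

    def test_keeps_original_peak_coordinates(self):
        p = mk_peak("chr1", 10_000, 900, 3.0)
        out = feat.select_candidates([p], [], SIZES, n_top=1)
        assert out[0].region == p.interval
        assert out[0].interval.length == 500


class TestEnumeratePairs:
    GENES = [GeneAnnotation("g1", "chr1", 500_000), GeneAnnotation("g2", "chr2", 500_000)]

    def _cre(self, chrom, mid):
        iv = GenomicInterval(chrom, mid - 250, mid + 250)
        return feat.CandidateCRE("c_" + chrom + str(mid), iv, "dnase_peak", mid, 1.0)

    def test_window_boundary_inclusive(self):
        sizes = {"chr1": 10_000_000}
        genes = [GeneAnnotation("g1", "chr1", 5_500_000)]
        at = feat.CandidateCRE(
            "at", GenomicInterval("chr1", 499_750, 500_250), "dnase_peak", 500_000, 1.0
        )
        beyond = feat.CandidateCRE(
            "beyond", GenomicInterval("chr1", 499_749, 500_249), "dnase_peak", 499_999, 1.0
        )
        df = feat.enumerate_pairs([at, beyond], genes)
        assert set(df["cre_id"]) == {"at"}
        assert df["distance"].iloc[0] == 5_000_000

    def test_cross_chromosome_excluded(self):
        df = feat.enumerate_pairs([self._cre("chr1", 400_000)], self.GENES)
        assert set(df["gene_id"]) == {"g1"}

    def test_matches_all_pairs_bruteforce_and_window_monotone(self):
        rng = np.random.default_rng(2)
        cres = [
            self._cre(f"chr{rng.integers(1, 3)}", int(m))
            for m in rng.integers(1_000, 999_000, size=40)
        ]
        genes = [
            GeneAnnotation(f"g{i}", f"chr{rng.integers(1, 3)}", int(t))
            for i, t in enumerate(rng.integers(1_000, 999_000, size=15))
        ]
        prev = 0
        for window in (10_000, 100_000, 600_000):
            df = feat.enumerate_pairs(cres, genes, window=window)
            want = {
                (c.cre_id, g.gene_id)
                for c in cres
                for g in genes
                if c.interval.chrom == g.chrom
                and abs(c.interval.midpoint - g.tss) <= window
            }
            assert set(zip(df["cre_id"], df["gene_id"])) == want
            assert len(df) >= prev
            prev = len(df)


class TestAbcScore:
    def test_single_candidate_scores_one(self):
        pairs = pd.DataFrame({"cre_id": ["c1"], "gene_id": ["g1"], "distance": [100]})
        act = pd.DataFrame({"cre_id": ["c1"], "dnase": [4.0], "h3k27ac": [9.0]})
        s = feat.abc_score(pairs, act, {("c1", "g1"): 2.0})
        assert s.iloc[0] == pytest.approx(1.0)

    def test_three_to_one_ratio(self):
        pairs = pd.DataFrame(
            {"cre_id": ["c1", "c2"], "gene_id": ["g1", "g1"], "distance": [1, 2]}
        )
        act = pd.DataFrame(
            {"cre_id": ["c1", "c2"], "dnase": [9.0, 1.0], "h3k27ac": [1.0, 1.0]}
        )
        s = feat.abc_score(pairs, act, {("c1", "g1"): 1.0, ("c2", "g1"): 1.0})
        assert list(s) == pytest.approx([0.75, 0.25])

    def test_zero_total_gene_scores_zero(self):
        pairs = pd.DataFrame({"cre_id": ["c1"], "gene_id": ["g1"], "distance": [1]})
        act = pd.DataFrame({"cre_id": ["c1"], "dnase": [0.0], "h3k27ac": [0.0]})
        s = feat.abc_score(pairs, act, {})
        assert s.iloc[0] == 0.0

    def test_matches_loop_oracle_and_invariances(self):
        rng = np.random.default_rng(3)
        cres = [f"c{i}" for i in range(20)]
        genes = [f"g{j}" for j in range(3)]
        pairs = pd.DataFrame(
            [(c, g, int(rng.integers(1, 10_000))) for c in cres for g in genes],
            columns=["cre_id", "gene_id", "distance"],
        )
        act = pd.DataFrame({
            "cre_id": cres,
            "dnase": rng.gamma(2, 10, size=20),
            "h3k27ac": rng.gamma(2, 10, size=20),
        })
        contact = {
            (c, g): float(rng.random()) for c in cres for g in genes
        }
        s = feat.abc_score(pairs, act, contact)
        np.testing.assert_allclose(s, abc_loop(pairs, act, contact), rtol=1e-12)
        sums = s.groupby(pairs["gene_id"]).sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)
        # uniform rescaling of one gene's contacts leaves its scores unchanged
        contact2 = {
            k: (v * 7.5 if k[1] == "g1" else v) for k, v in contact.items()
        }
        np.testing.assert_allclose(feat.abc_score(pairs, act, contact2), s, rtol=1e-12)


class TestElementwiseOps:
    def test_orientation_mean(self):
        assert feat.average_orientations(0.4, 0.6) == pytest.approx(0.5)
        assert feat.average_orientations(1.3, 1.3) == pytest.approx(1.3)
        rng = np.random.default_rng(0)
        f, r = rng.normal(size=100), rng.normal(size=100)
        np.testing.assert_allclose(
            feat.average_orientations(f, r), [(a + b) / 2 for a, b in zip(f, r)]
        )
        with pytest.raises(ValueError):
            feat.average_orientations(np.nan, 0.5)

    def test_ensemble_mean(self):
        assert feat.ensemble_mean([1.3] * 10) == pytest.approx(1.3)
        assert feat.ensemble_mean([0.0, 1.0]) == pytest.approx(0.5)  # warns
        rng = np.random.default_rng(1)
        v = rng.normal(size=10)
        assert feat.ensemble_mean(v) == pytest.approx(sum(v) / 10)
        with pytest.raises(ValueError):
            feat.ensemble_mean([])

    def test_collapse_duplicate_columns(self):
        df = pd.DataFrame({"x|1": [0.2, 0.5], "x|2": [0.4, 0.1], "y|1": [1.0, 2.0]})
        out = feat.collapse_duplicate_columns(df, {"x": ["x|1", "x|2"], "y": ["y|1"]})
        np.testing.assert_allclose(out["x"], [0.3, 0.3])
        np.testing.assert_allclose(out["y"], [1.0, 2.0])
        rng = np.random.default_rng(2)
        big = pd.DataFrame(rng.random((1000, 5)), columns=[f"f|{i}" for i in range(5)])
        got = feat.collapse_duplicate_columns(big, {"f": list(big.columns)})["f"]
        np.testing.assert_allclose(got, big.to_numpy().mean(axis=1))


class TestAssemble:
    PAIRS = pd.DataFrame({
        "cre_id": ["c1", "c1", "c2"],
        "gene_id": ["g1", "g2", "g1"],
        "distance": [100, 200, 300],
    })

    def test_schema_and_manifest(self):
        re2g = self.PAIRS[["cre_id", "gene_id"]].assign(f1=[1.0, 2.0, 3.0])
        mpra = pd.DataFrame({"cre_id": ["c1", "c2"], "mpra": [0.1, 0.2]})
        sei = pd.DataFrame({"cre_id": ["c1", "c2"], "sei_dnase": [0.5, 0.6]})
        fm = feat.assemble(self.PAIRS, re2g, mpra, sei, abc=pd.Series([0.9, 0.1, 1.0]))
        assert set(fm.feature_columns) == {"distance", "abc_score", "f1", "mpra", "sei_dnase"}
        assert fm.manifest["mpra"] == "mpralegnet"
        assert fm.manifest["sei_dnase"] == "sei"
        assert fm.manifest["abc_score"] == "abc"

    def test_missing_value_imputed_with_flag(self):
        sei = pd.DataFrame({"cre_id": ["c1"], "sei_dnase": [0.5]})  # c2 absent
        fm = feat.assemble(self.PAIRS, sei_features=sei)
        row = fm.data[fm.data["cre_id"] == "c2"].iloc[0]
        assert row["sei_dnase"] == pytest.approx(0.5)  # column median
        assert row["sei_dnase_missing"] == 1.0
        assert fm.data["sei_dnase_missing"].sum() == 1.0

    def test_unknown_id_raises(self):
        mpra = pd.DataFrame({"cre_id": ["c1", "cX"], "mpra": [0.1, 0.2]})
        with pytest.raises(ValueError, match="cX"):
            feat.assemble(self.PAIRS, mpra_activity=mpra)

    def test_row_order_invariant(self):
        re2g = self.PAIRS[["cre_id", "gene_id"]].assign(f1=[1.0, 2.0, 3.0])
        a = feat.assemble(self.PAIRS, re2g)
        b = feat.assemble(
            self.PAIRS.sample(frac=1, random_state=4).reset_index(drop=True),
            re2g.sample(frac=1, random_state=5).reset_index(drop=True),
        )
        pd.testing.assert_frame_equal(a.data, b.data)
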