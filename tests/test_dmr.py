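import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bpmeth import dmr


class TestStoufferLiptak:
    def test_independent_combination_matches_normal_cdf_oracle(self):
        p = dmr.stouffer_liptak([0.05, 0.05, 0.05], np.eye(3))
        oracle = stats.norm.sf(3 * stats.norm.isf(0.05) / np.sqrt(3))
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(0.00219, abs=2e-5)

    def test_perfect_correlation_returns_input_p(self):
        p = dmr.stouffer_liptak([0.05, 0.05, 0.05], np.ones((3, 3)))
        assert p == pytest.approx(0.05, rel=1e-9)

    def test_single_p_unchanged(self):
        assert dmr.stouffer_liptak([0.2]) == pytest.approx(0.2, rel=1e-9)

    def test_extreme_p_clipped_not_crashing(self):
        assert 0.0 < dmr.stouffer_liptak([0.0, 1.0], np.eye(2)) < 1.0

    def test_non_psd_matrix_repaired(self):
        sigma = np.array([[1.0, 0.9, -0.9],
                          [0.9, 1.0, 0.9],
                          [-0.9, 0.9, 1.0]])   # indefinite
        p = dmr.stouffer_liptak([0.01, 0.01, 0.01], sigma)
        assert 0.0 < p < 1.0


class TestCorrelationEstimation:
    @staticmethod
    def _clustered_positions(n_pairs, gap, rng):
        pos, p0 = [], 10_000
        for _ in range(n_pairs):
            pos += [p0, p0 + gap]
            p0 += 10_000
        return np.array(pos, dtype=float)

    def test_independent_p_gives_near_zero_bins(self, rng):
        pos = self._clustered_positions(5000, 100, rng)
        p = rng.uniform(size=len(pos))
        tab = dmr.estimate_p_correlation(p, np.repeat("chr1", len(pos)), pos)
        assert (tab["corr"] <= 0.05).all()      # clipped below at 0

    def test_planted_correlation_recovered(self, rng):
        pos = self._clustered_positions(5000, 100, rng)
        shared = rng.standard_normal(5000)
        z = np.empty(len(pos))
        noise = rng.standard_normal((5000, 2))
        z[0::2] = np.sqrt(0.5) * shared + np.sqrt(0.5) * noise[:, 0]
        z[1::2] = np.sqrt(0.5) * shared + np.sqrt(0.5) * noise[:, 1]
        p = stats.norm.sf(z)
        tab = dmr.estimate_p_correlation(p, np.repeat("chr1", len(pos)), pos)
        first = tab.iloc[0]
        assert first["lo"] <= 100 < first["hi"] or first["hi"] <= 200
        assert 0.4 <= first["corr"] <= 0.6

    def test_single_probe_flat_fallback(self):
        tab = dmr.estimate_p_correlation(np.array([0.5]),
                                         np.array(["chr1"]),
                                         np.array([100.0]))
        assert (tab["corr"] == 0.0).all()


def _make_ewas(pos, p, chrom="chr1"):
    return (pd.DataFrame({"probe_id": [f"cg{i}" for i in range(len(pos))],
                          "p": p, "effect_beta_per10": 0.01}),
            pd.DataFrame({"probe_id": [f"cg{i}" for i in range(len(pos))],
                          "chrom": chrom, "pos": pos}))


class TestCallRegions:
    def test_two_distant_blocks_never_merged(self, rng):
        # two 5-probe blocks of tiny p separated by 2000 bp, plus far nulls
        pos = np.concatenate([
            10_000 + np.arange(5) * 100,
            12_400 + np.arange(5) * 100,
            100_000 + np.arange(200) * 5_000])
        p = np.concatenate([np.full(10, 1e-12), rng.uniform(size=200)])
        ew, ann = _make_ewas(pos, p)
        regs = dmr.call_regions(ew, ann, significance=None)
        strong = regs[regs["p_region"] < 1e-6]
        assert len(strong) == 2
        assert strong["end"].iloc[0] < 12_400
        assert strong["start"].iloc[1] >= 12_400

    def test_no_seeds_returns_empty(self, rng):
        pos = 10_000 + np.arange(50) * 5_000
        ew, ann = _make_ewas(pos, np.full(50, 0.5))
        regs = dmr.call_regions(ew, ann)
        assert regs.empty

    def test_sidak_dominates_region_p(self, rng):
        pos = np.concatenate([10_000 + np.arange(6) * 100,
                              50_000 + np.arange(300) * 3_000])
        p = np.concatenate([np.full(6, 1e-10), rng.uniform(size=300)])
        ew, ann = _make_ewas(pos, p)
        regs = dmr.call_regions(ew, ann, significance=None)
        assert (regs["p_sidak"] >= regs["p_region"] - 1e-15).all()
        assert (regs["n_probes"] >= 3).all()

    def test_invariant_to_input_row_order(self, rng):
        pos = np.concatenate([10_000 + np.arange(6) * 100,
                              50_000 + np.arange(200) * 4_000])
        p = np.concatenate([np.full(6, 1e-10), rng.uniform(size=200)])
        ew, ann = _make_ewas(pos, p)
        regs1 = dmr.call_regions(ew, ann, significance=None)
        perm = rng.permutation(len(ew))
        regs2 = dmr.call_regions(ew.iloc[perm], ann, significance=None)
        pd.testing.assert_frame_equal(regs1, regs2)


class TestAnnotateRegions:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [1_000, 20_000, 30_000],
            "end": [5_000, 25_000, 35_000],
            "name": ["GENEB", "GENEA", "GENEC"]})

    def test_overlap_wins(self, genes):
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [2_000],
                             "end": [2_500]})
        out = dmr.annotate_regions(regs, genes)
        assert out["gene_label"].iloc[0] == "GENEB"

    def test_far_region_is_intergenic(self, genes):
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [500_000],
                             "end": [500_300]})
        out = dmr.annotate_regions(regs, genes)
        assert out["gene_label"].iloc[0] == "intergenic"

    def test_equidistant_tie_broken_lexicographically(self, genes):
        # midpoint between GENEA (ends 25,000) and GENEC (starts 30,000)
        regs = pd.DataFrame({"chrom": ["chr1"], "start": [27_400],
                             "end": [27_600]})
        out = dmr.annotate_regions(regs, genes)
        assert out["gene_label"].iloc[0] == "GENEA"

    def test_unknown_chrom_is_intergenic(self, genes):
        regs = pd.DataFrame({"chrom": ["chr9"], "start": [2_000],
                             "end": [2_500]})
        out = dmr.annotate_regions(regs, genes)
        assert out["gene_label"].iloc[0] == "intergenic"


class TestLocationEnrichment:
    def test_odds_ratio_exact_arithmetic(self):
        # 2x2 table (10, 90; 10, 890) -> OR = (10*890)/(90*10)
        probes = [f"cg{i}" for i in range(1000)]
        ann = pd.DataFrame({
            "probe_id": probes,
            "location_class": ["TSS-region"] * 10 + ["other"] * 90
            + ["TSS-region"] * 10 + ["other"] * 890})
        dmr_probes = set(probes[:100])
        out = dmr.location_enrichment(dmr_probes, probes, ann)
        tss = out.set_index("location_class").loc["TSS-region"]
        assert tss["odds_ratio"] == pytest.approx(9.888888888, rel=1e-9)

    def test_empty_class_skipped(self):
        probes = ["cg0", "cg1"]
        ann = pd.DataFrame({"probe_id": probes,
                            "location_class": ["body", "body"]})
        out = dmr.location_enrichment({"cg0"}, probes, ann)
        assert list(out["location_class"]) == ["body"]


def test_bed_export_is_zero_based_half_open():
    regs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [250],
                         "p_region": [1e-5]})
    bed = dmr.to_bed(regs)
    assert bed["start"].iloc[0] == 99
    assert bed["end"].iloc[0] == 250
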