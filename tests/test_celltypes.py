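import numpy as np
import pandas as pd
import pytest

from bpmeth import celltypes, synthetic as syn
from bpmeth.compositional import CELL_TYPES, ILR_BASIS


class TestProbeSelection:
    def test_recovers_planted_discriminators(self, reference_profiles):
        planted = {p for ps in
                   reference_profiles.attrs["discriminating"].values()
                   for p in ps}
        picked = celltypes.select_discriminating_probes(reference_profiles,
                                                        50)
        assert set(picked) == planted

    def test_zero_per_type_rejected(self, reference_profiles):
        with pytest.raises(ValueError):
            celltypes.select_discriminating_probes(reference_profiles, 0)

    def test_deduplicated_upper_bound(self, reference_profiles):
        picked = celltypes.select_discriminating_probes(reference_profiles,
                                                        30)
        assert len(picked) == len(set(picked)) <= 180


class TestDeconvolve:
    def test_pure_reference_sample(self, reference_profiles):
        refs = reference_profiles
        bulk = pd.DataFrame(refs.loc["Stromal"].to_numpy()[:, None],
                            index=refs.columns, columns=["pure"])
        w = celltypes.deconvolve(bulk, refs).iloc[0]
        expected = pd.Series(0.0, index=list(CELL_TYPES))
        expected["Stromal"] = 1.0
        assert np.abs(w - expected).max() < 1e-6

    def test_equal_mixture_of_two_types(self, reference_profiles):
        refs = reference_profiles
        mix = 0.5 * (refs.loc["Stromal"] + refs.loc["Hofbauer"])
        bulk = pd.DataFrame(mix.to_numpy()[:, None], index=refs.columns,
                            columns=["mix"])
        w = celltypes.deconvolve(bulk, refs).iloc[0]
        assert w["Stromal"] == pytest.approx(0.5, abs=1e-6)
        assert w["Hofbauer"] == pytest.approx(0.5, abs=1e-6)

    def test_too_few_probes_rejected(self, reference_profiles):
        refs = reference_profiles
        bulk = pd.DataFrame(refs.iloc[:, :10].to_numpy().T.mean(1)[:, None],
                            index=refs.columns[:10], columns=["s"])
        with pytest.raises(ValueError):
            celltypes.deconvolve(bulk, refs, list(refs.columns[:10]))

    def test_output_on_simplex_even_with_heavy_noise(self, reference_profiles,
                                                     rng):
        refs = reference_profiles
        noisy = np.clip(refs.to_numpy().mean(0)
                        + rng.normal(0, 0.2, refs.shape[1]), 0.01, 0.99)
        bulk = pd.DataFrame(noisy[:, None], index=refs.columns,
                            columns=["n"])
        w = celltypes.deconvolve(bulk, refs).iloc[0]
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_recovery_error_shrinks_with_more_probes(self, reference_profiles,
                                                     rng):
        refs = reference_profiles
        z = np.log(syn.DEFAULT_COMPOSITION)[None, :] + rng.normal(
            0, 0.25, (40, 6))
        w = np.exp(z)
        w /= w.sum(1, keepdims=True)
        bulk = np.clip(w @ refs.to_numpy(), 1e-6, 1 - 1e-6)
        m = np.log2(bulk / (1 - bulk)) + rng.normal(0, 0.05, bulk.shape)
        beta = pd.DataFrame((np.exp2(m) / (1 + np.exp2(m))).T,
                            index=refs.columns,
                            columns=[f"s{i}" for i in range(40)])
        errs = []
        for k in (10, 25, 50):
            probes = celltypes.select_discriminating_probes(refs, k)
            est = celltypes.deconvolve(beta, refs, probes)
            errs.append(np.sqrt(((est.to_numpy() - w) ** 2).mean()))
        assert errs[2] < errs[0]
        assert errs[2] < 0.05


class TestAssociation:
    @staticmethod
    def _cohort(gamma, n, seed):
        rng = np.random.default_rng(seed)
        bp = rng.normal(0, 6, n)
        comp = syn.generate_compositions(bp, gamma, seed=seed + 1)
        idx = [f"S{i}" for i in range(n)]
        comp.index = idx
        return pd.Series(bp, index=idx), comp

    def test_power_under_strong_composition_shift(self):
        bp, comp = self._cohort(-0.03, 600, 0)
        assert celltypes.test_global_association(comp, bp) < 0.05

    def test_null_p_not_extreme(self):
        ps = []
        for s in range(10):
            bp, comp = self._cohort(0.0, 200, 100 + s)
            ps.append(celltypes.test_global_association(comp, bp))
        assert min(ps) > 1e-4           # no wild anti-conservatism
        assert max(ps) > 0.2            # spread over the unit interval

    def test_constant_bp_returns_p_one(self):
        bp, comp = self._cohort(0.0, 100, 3)
        assert celltypes.test_global_association(
            comp, pd.Series(80.0, index=bp.index)) == 1.0

    def test_invariant_to_ilr_basis_rotation(self):
        bp, comp = self._cohort(-0.02, 300, 4)
        p1 = celltypes.test_global_association(comp, bp)
        # likelihood-ratio statistic is invariant under orthonormal rotation
        # of the response coordinates, so any valid ilr basis gives same p
        from bpmeth import compositional as co
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        rotated = q @ co.ILR_BASIS
        Y1 = co.ilr(co.zero_replace(comp.to_numpy()))
        Y2 = co.ilr(co.zero_replace(comp.to_numpy()), basis=rotated)
        assert np.allclose(Y2, Y1 @ q.T, atol=1e-10)

    def test_ratio_model_recovers_gamma(self):
        bp, comp = self._cohort(-0.02, 600, 5)
        eff, (lo, hi), p = celltypes.fit_ratio_model(comp, bp)
        se = (hi - lo) / (2 * 1.96)
        assert abs(eff - (-0.02)) < 2 * se
        assert p < 0.05

    def test_ratio_model_zero_when_ratio_constant(self):
        n = 50
        comp = pd.DataFrame(
            np.tile([0.3, 0.3, 0.1, 0.1, 0.1, 0.1], (n, 1)),
            columns=list(CELL_TYPES))
        bp = pd.Series(np.random.default_rng(0).normal(0, 5, n))
        eff, _, _ = celltypes.fit_ratio_model(comp, bp)
        assert eff == pytest.approx(0.0, abs=1e-10)

    def test_per_celltype_table_shape(self):
        bp, comp = self._cohort(-0.02, 200, 6)
        out = celltypes.per_celltype_association(comp, bp)
        assert list(out["cell_type"]) == list(CELL_TYPES)


class TestCompositionalPCA:
    def test_rank_one_curve_explained_by_pc1(self):
        t = np.linspace(-1, 1, 60)
        base = np.log(np.array(syn.DEFAULT_COMPOSITION))
        z = base[None, :] + t[:, None] * np.array([1, -1, 0, 0, 0, 0]) * 0.4
        w = np.exp(z)
        w /= w.sum(1, keepdims=True)
        comp = pd.DataFrame(w, columns=list(CELL_TYPES))
        out = celltypes.compositional_pca(comp)
        assert out["explained_variance_ratio"][0] > 0.99

    def test_anticorrelated_stromal_sct_loadings(self):
        rng = np.random.default_rng(1)
        bp = rng.normal(0, 6, 300)
        comp = syn.generate_compositions(bp, -0.05, seed=2, comp_sd=0.05)
        out = celltypes.compositional_pca(comp)
        l1 = out["loadings"]["PC1"]
        assert l1["Stromal"] * l1["Syncytiotrophoblast"] < 0

    def test_sample_permutation_leaves_loadings_unchanged(self, rng):
        comp = syn.generate_compositions(rng.normal(0, 6, 80), -0.02, seed=3)
        out1 = celltypes.compositional_pca(comp)
        perm = rng.permutation(len(comp))
        out2 = celltypes.compositional_pca(comp.iloc[perm])
        assert np.allclose(np.abs(out1["loadings"].to_numpy()),
                           np.abs(out2["loadings"].to_numpy()), atol=1e-8)
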