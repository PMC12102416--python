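import numpy as np
import pandas as pd
import pytest

from osmogill.coexpression import (
    ModuleAssignment,
    membership_and_significance,
    merge_close_modules,
    module_eigengene,
    module_trait_correlation,
    select_hub_genes,
    tissue_trait_matrix,
    tom_edge_list,
    tom_matrix,
)
from osmogill.expression import ValidationError

TISSUE_DESIGN = ["gills"] * 3 + ["nerve"] * 3 + ["eyes"] * 3


def assignment(mapping, min_size=2):
    return ModuleAssignment(mapping, min_size=min_size)


class TestModuleAssignment:
    def test_min_size_enforced(self):
        with pytest.raises(ValidationError, match="m1"):
            ModuleAssignment({"g0": "m1"}, min_size=2)

    def test_tsv_roundtrip(self, tmp_path):
        a = assignment({"g0": "m1", "g1": "m1", "g2": "m2", "g3": "m2"})
        p = tmp_path / "modules.tsv"
        a.to_tsv(p)
        b = ModuleAssignment.from_tsv(p, min_size=2)
        assert b.labels == a.labels


class TestModuleEigengene:
    def test_rank_one_module(self, make_ds):
        rng = np.random.default_rng(0)
        v = rng.normal(size=9)
        ds = make_ds(np.tile(v, (4, 1)), TISSUE_DESIGN, scale="log")
        eig = module_eigengene(ds, assignment({g: "m" for g in ds.genes}))
        assert eig.explained_variance["m"] == pytest.approx(1.0)
        e = eig.eigengenes.loc["m"].to_numpy()
        z = (v - v.mean()) / v.std()
        np.testing.assert_allclose(e * np.linalg.norm(z), z, atol=1e-8)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_two_block_matrix_matches_pca_oracle(self, make_ds):
        rng = np.random.default_rng(1)
        p1 = np.array([3.0, 3, 3, 0, 0, 0, 0, 0, 0])
        p2 = np.array([0.0, 0, 0, 0, 0, 0, 3, 3, 3])
        x = np.vstack(
            [p1 + rng.normal(0, 0.05, 9) for _ in range(10)]
            + [p2 + rng.normal(0, 0.05, 9) for _ in range(10)]
        )
        ds = make_ds(x, TISSUE_DESIGN, scale="log")
        lab = {f"g{i}": ("m1" if i < 10 else "m2") for i in range(20)}
        eig = module_eigengene(ds, assignment(lab))
        for module, profile in (("m1", p1), ("m2", p2)):
            e = eig.eigengenes.loc[module].to_numpy()
            z = (profile - profile.mean()) / profile.std()
            r = np.corrcoef(e, z)[0, 1]
            assert abs(r) > 0.999
            assert r > 0  # sign orientation: positive mean member correlation

    def test_gene_order_invariance(self, make_ds):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 9))
        ds = make_ds(x, TISSUE_DESIGN, scale="log")
        lab = {g: "m" for g in ds.genes}
        e1 = module_eigengene(ds, assignment(lab)).eigengenes
        shuffled = ds.subset_genes(list(rng.permutation(ds.genes)))
        e2 = module_eigengene(shuffled, assignment(lab)).eigengenes
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-10)

    def test_too_small_module_rejected(self, make_ds):
        ds = make_ds(np.random.default_rng(0).normal(size=(2, 9)), TISSUE_DESIGN, scale="log")
        with pytest.raises(ValidationError):
            module_eigengene(ds, assignment({"g0": "m"}, min_size=1))


class TestMergeCloseModules:
    def build(self, make_ds, profiles, sizes, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], {}
        i = 0
        for p, (m, k) in zip(profiles, sizes.items()):
            for _ in range(k):
                rows.append(p + rng.normal(0, noise, len(p)))
                labels[f"g{i}"] = m
                i += 1
        ds = make_ds(np.vstack(rows), TISSUE_DESIGN, scale="log")
        return ds, assignment(labels)

    def test_identical_eigengene_modules_merge(self, make_ds):
        p = np.array([5.0, 5, 5, 0, 0, 0, 0, 0, 0])
        ds, a = self.build(make_ds, [p, p], {"m1": 5, "m2": 5})
        merged = merge_close_modules(ds, a, height_cutoff=0.2)
        assert len(merged.modules()) == 1

    def test_distant_modules_stay_separate(self, make_ds):
        p1 = np.array([5.0, 5, 5, 0, 0, 0, 0, 0, 0])
        p2 = np.array([0.0, 0, 0, 0, 0, 0, 5, 5, 5])  # eigengene corr ~ -0.5
        ds, a = self.build(make_ds, [p1, p2], {"m1": 5, "m2": 5})
        merged = merge_close_modules(ds, a, height_cutoff=0.2)
        assert len(merged.modules()) == 2

    def test_three_identical_modules_converge_to_one(self, make_ds):
        p = np.array([5.0, 5, 5, 0, 0, 0, 0, 0, 0])
        ds, a = self.build(make_ds, [p, p, p], {"m1": 4, "m2": 4, "m3": 4})
        merged = merge_close_modules(ds, a, height_cutoff=0.2)
        assert len(merged.modules()) == 1

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_cutoff_validated(self, make_ds, bad):
        p = np.array([5.0, 5, 5, 0, 0, 0, 0, 0, 0])
        ds, a = self.build(make_ds, [p, p], {"m1": 5, "m2": 5})
        with pytest.raises(ValidationError):
            merge_close_modules(ds, a, height_cutoff=bad)


class TestModuleTraitCorrelation:
    def eigen_fixture(self, make_ds, profiles):
        rng = np.random.default_rng(3)
        rows, labels = [], {}
        for j, p in enumerate(profiles):
            for k in range(5):
                rows.append(p + rng.normal(0, 0.01, len(p)))
                labels[f"g{j}_{k}"] = f"m{j}"
        ds = make_ds(
            np.vstack(rows), TISSUE_DESIGN,
            genes=list(labels), scale="log",
        )
        eig = module_eigengene(ds, assignment(labels))
        return ds, eig

    def test_indicator_profile_correlates_fully(self, make_ds):
        gill_profile = np.array([1.0, 1, 1, 0, 0, 0, 0, 0, 0])
        ds, eig = self.eigen_fixture(make_ds, [gill_profile])
        r, p = module_trait_correlation(eig, tissue_trait_matrix(ds))
        assert r.loc["m0", "gills"] == pytest.approx(1.0, abs=1e-3)
        assert p.loc["m0", "gills"] < 1e-6

    def test_orthogonal_trait_near_zero(self, make_ds):
        profile = np.array([1.0, -1, 0, 1, -1, 0, 1, -1, 0])  # balanced per tissue
        ds, eig = self.eigen_fixture(make_ds, [profile])
        r, p = module_trait_correlation(eig, tissue_trait_matrix(ds))
        assert abs(r.loc["m0", "gills"]) < 0.05
        assert p.loc["m0", "gills"] > 0.5

    def test_constant_trait_rejected(self, make_ds):
        profile = np.array([1.0, 1, 1, 0, 0, 0, 0, 0, 0])
        ds, eig = self.eigen_fixture(make_ds, [profile])
        traits = tissue_trait_matrix(ds)
        traits["flat"] = 1.0
        with pytest.raises(ValidationError, match="flat"):
            module_trait_correlation(eig, traits)


class TestMembershipAndHubs:
    def fixture(self, make_ds, n_noise=0):
        rng = np.random.default_rng(4)
        gill_profile = np.array([4.0, 4, 4, 0, 0, 0, 0, 0, 0])
        rows = [gill_profile + rng.normal(0, 0.01, 9) for _ in range(6)]
        labels = {f"g{i}": "m" for i in range(6)}
        for i in range(n_noise):
            rows.append(rng.normal(0, 1, 9))
            labels[f"n{i}"] = "noise"
        genes = list(labels)
        ds = make_ds(np.vstack(rows), TISSUE_DESIGN, genes=genes, scale="log")
        a = assignment(labels)
        eig = module_eigengene(ds, a)
        traits = tissue_trait_matrix(ds)
        return ds, a, eig, traits

    def test_member_identical_to_eigengene_has_full_mm(self, make_ds):
        ds, a, eig, traits = self.fixture(make_ds)
        rep = membership_and_significance(ds, a, eig, traits, "gills")
        assert (rep["MM"] > 0.999).all()

    def test_gill_only_gene_positive_gs(self, make_ds):
        ds, a, eig, traits = self.fixture(make_ds)
        rep = membership_and_significance(ds, a, eig, traits, "gills")
        assert (rep["GS"] > 0.9).all()

    def test_noise_genes_small_mean_gs(self, make_ds):
        # at the ~29-sample design scale, trait-independent genes have
        # mean |GS| well below the 0.2 hub cutoff
        rng = np.random.default_rng(4)
        design = [t for t in ("gills", "nerve", "eyes", "ant", "per") for _ in range(6)]
        gill_profile = np.array([4.0] * 6 + [0.0] * 24)
        rows = [gill_profile + rng.normal(0, 0.01, 30) for _ in range(6)]
        labels = {f"g{i}": "m" for i in range(6)}
        for i in range(1000):
            rows.append(rng.normal(0, 1, 30))
            labels[f"n{i}"] = "noise"
        ds = make_ds(np.vstack(rows), design, genes=list(labels), scale="log")
        a = assignment(labels)
        eig = module_eigengene(ds, a)
        traits = tissue_trait_matrix(ds)
        rep = membership_and_significance(ds, a, eig, traits, "gills")
        noise_gs = rep.loc[rep["module"] == "noise", "GS"].abs()
        assert noise_gs.mean() < 0.2

    @pytest.mark.parametrize(
        "mm,gs,expected",
        [(0.9, 0.5, True), (0.9, -0.3, True), (0.7, 0.9, False), (0.9, 0.1, False)],
    )
    def test_hub_rule(self, mm, gs, expected):
        rep = pd.DataFrame(
            {"module": ["m"], "MM": [mm], "GS": [gs], "undefined": [False]},
            index=["g"],
        )
        out = select_hub_genes(rep, mm_threshold=0.8, gs_threshold=0.2)
        assert bool(out["hub"].iloc[0]) is expected

    def test_thresholds_validated(self):
        rep = pd.DataFrame(
            {"module": ["m"], "MM": [0.9], "GS": [0.5], "undefined": [False]},
            index=["g"],
        )
        with pytest.raises(ValidationError):
            select_hub_genes(rep, mm_threshold=1.5)


class TestTOM:
    def test_two_perfectly_correlated_genes(self, make_ds):
        v = np.arange(9.0)
        ds = make_ds(np.vstack([v, 2 * v + 1]), TISSUE_DESIGN, scale="log")
        tom = tom_matrix(ds, ds.genes)
        assert tom.iloc[0, 1] == pytest.approx(1.0)
        edges = tom_edge_list(ds, ds.genes, weight_cutoff=0.3)
        assert len(edges) == 1 and edges["weight"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_genes_no_edges(self, make_ds):
        # mutually uncorrelated constructed vectors
        x = np.array(
            [
                [1, -1, 1, -1, 1, -1, 1, -1, 0.0],
                [1, 1, -1, -1, 1, 1, -1, -1, 0.0],
                [1, -1, -1, 1, 1, -1, -1, 1, 0.0],
            ]
        )
        ds = make_ds(x, TISSUE_DESIGN, scale="log")
        edges = tom_edge_list(ds, ds.genes, weight_cutoff=0.3)
        assert len(edges) == 0

    def test_tom_symmetric_unit_interval(self, make_ds):
        rng = np.random.default_rng(5)
        ds = make_ds(rng.normal(size=(15, 9)), TISSUE_DESIGN, scale="log")
        tom = tom_matrix(ds, ds.genes).to_numpy()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        assert (tom >= 0).all() and (tom <= 1).all()

    def test_zero_variance_gene_excluded(self, make_ds):
        x = np.vstack([np.arange(9.0), np.arange(9.0) * 2, np.full(9, 3.0)])
        ds = make_ds(x, TISSUE_DESIGN, scale="log")
        tom = tom_matrix(ds, ds.genes)
        assert "g2" not in tom.index
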