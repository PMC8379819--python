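import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexflow import synthetic_data as sd
from coexflow import trait_stats as ts
from coexflow import wgcna_modules as wm


def _meta(n_breeds=2, n_groups=2, n_tissues=3, reps=3):
    breeds = [f"b{i}" for i in range(n_breeds)]
    groups = ["High", "Low"][:n_groups]
    tissues = [f"t{i}" for i in range(n_tissues)]
    _, meta = sd.make_design(breeds, groups, tissues, reps)
    return meta


class TestTraitDesignMatrix:
    def test_level_count_columns(self):
        design = ts.trait_design_matrix(_meta())
        assert design.shape == (36, 7)  # 2 breeds + 2 groups + 3 tissues

    def test_factor_columns_partition(self):
        design = ts.trait_design_matrix(_meta())
        for factor, k in (("breed", 2), ("group", 2), ("tissue", 3)):
            cols = [c for c in design.columns if c.startswith(factor + "_")]
            assert len(cols) == k
            np.testing.assert_array_equal(design[cols].sum(axis=1).to_numpy(), 1)

    def test_single_level_factor_flagged(self):
        meta = _meta(n_breeds=1)
        with pytest.warns(UserWarning, match="constant"):
            design = ts.trait_design_matrix(meta)
        assert design["breed_b0"].nunique() == 1

    def test_missing_column_error(self):
        meta = _meta().drop(columns="tissue")
        with pytest.raises(ValueError):
            ts.trait_design_matrix(meta)


class TestModuleTraitCorrelation:
    def _eig(self, vals, samples):
        eig = pd.DataFrame(vals, columns=samples)
        eig.index = pd.Index(range(1, len(vals) + 1), name="module")
        return eig

    def test_identity_trait(self):
        meta = _meta()
        design = ts.trait_design_matrix(meta)
        t = design["group_High"].to_numpy(float)
        me = (t - t.mean()) / t.std()
        table = ts.module_trait_correlation(
            self._eig([me], design.index), design
        )
        assert table.r.loc[1, "group_High"] == pytest.approx(1.0)
        assert table.p.loc[1, "group_High"] == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_pearsonr_oracle(self):
        # construct data with sample correlation exactly 0.49 at n = 36
        rng = np.random.default_rng(5)
        n = 36
        t = rng.normal(size=n)
        z = rng.normal(size=n)
        t_std = (t - t.mean()) / t.std()
        z_res = z - z.mean()
        z_res -= t_std * (z_res @ t_std) / (t_std @ t_std)
        z_std = z_res / np.sqrt((z_res**2).mean())
        r_target = 0.49
        me = r_target * t_std + np.sqrt(1 - r_target**2) * z_std
        samples = [f"s{i}" for i in range(n)]
        design = pd.DataFrame({"trait": t}, index=samples)
        table = ts.module_trait_correlation(self._eig([me], samples), design)
        r_oracle, p_oracle = stats.pearsonr(me, t)
        assert table.r.loc[1, "trait"] == pytest.approx(r_target, abs=1e-12)
        assert table.p.loc[1, "trait"] == pytest.approx(p_oracle, abs=1e-10)

    def test_consistent_permutation_invariance(self, rng):
        n = 12
        samples = [f"s{i}" for i in range(n)]
        me = rng.normal(size=(2, n))
        design = pd.DataFrame(
            {"trait": rng.integers(0, 2, n)}, index=samples
        ).astype(float)
        t1 = ts.module_trait_correlation(self._eig(me, samples), design)
        perm = rng.permutation(n)
        t2 = ts.module_trait_correlation(
            self._eig(me[:, perm], [samples[i] for i in perm]),
            design.iloc[perm],
        )
        pd.testing.assert_frame_equal(t1.r, t2.r)

    def test_constant_trait_missing(self, rng):
        samples = [f"s{i}" for i in range(10)]
        design = pd.DataFrame({"flat": np.ones(10)}, index=samples)
        with pytest.warns(UserWarning):
            table = ts.module_trait_correlation(
                self._eig(rng.normal(size=(1, 10)), samples), design
            )
        assert np.isnan(table.r.loc[1, "flat"])


class TestGeneStatistics:
    def test_gs_identity_and_absolute(self, rng):
        t = rng.integers(0, 2, 10).astype(float)
        t[0] = 1 - t[0] if t.std() == 0 else t[0]
        expr = pd.DataFrame([t, -t], index=["pos", "neg"])
        gs = ts.gene_significance(expr, t)
        assert gs["pos"] == pytest.approx(1.0)
        assert gs["neg"] == pytest.approx(1.0)

    def test_gs_signed_variant(self, rng):
        t = np.array([0.0, 1, 0, 1, 0, 1])
        expr = pd.DataFrame([-t], index=["neg"])
        gs = ts.gene_significance(expr, t, signed=True)
        assert gs["neg"] == pytest.approx(-1.0)

    def test_gs_oracle_five_genes(self, rng):
        vals = rng.normal(size=(5, 12))
        t = rng.normal(size=12)
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(5)])
        gs = ts.gene_significance(expr, t)
        for i in range(5):
            assert gs.iloc[i] == pytest.approx(
                abs(stats.pearsonr(vals[i], t)[0]), abs=1e-12
            )

    def test_ms_constant_and_bounds(self, rng):
        gs = pd.Series([0.5, 0.5, 0.9, 0.1], index=list("abcd"))
        asg = wm.ModuleAssignment(
            labels=pd.Series([1, 1, 2, 2], index=list("abcd"))
        )
        ms = ts.module_significance(gs, asg)
        assert ms[1] == pytest.approx(0.5)
        assert gs[["c", "d"]].min() <= ms[2] <= gs[["c", "d"]].max()

    def test_ms_trait_module_above_neutral(self):
        _, meta, counts, truth = sd.benchmark_dataset(seed=2)
        from coexflow import preprocess as pp

        counts_f = pp.filter_low_expression(counts)
        sf = pp.size_factors(counts_f)
        expr = pp.vst_transform(counts_f, sf, pp.fit_dispersion_trend(counts_f, sf))
        t = (meta["group"] == "High").to_numpy(float)
        gs = ts.gene_significance(expr, t)
        asg = wm.ModuleAssignment(labels=truth.module_of_gene.loc[expr.index])
        ms = ts.module_significance(gs, asg)
        assert ms[3] > ms[4]  # planted trait module vs neutral module

    def test_mm_oracle(self, rng):
        vals = rng.normal(size=(6, 10))
        me = pd.DataFrame(rng.normal(size=(2, 10)))
        me.index = pd.Index([1, 2], name="module")
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(6)])
        me.columns = expr.columns
        mm = ts.module_membership(expr, me)
        for i in range(6):
            for m in (1, 2):
                assert mm.iloc[i][m] == pytest.approx(
                    stats.pearsonr(vals[i], me.loc[m])[0], abs=1e-12
                )

    def test_mm_rank_one_module(self, rng):
        profile = rng.normal(size=10)
        expr = pd.DataFrame(
            np.tile(profile, (4, 1)) * rng.uniform(0.5, 2, 4)[:, None],
            index=[f"g{i}" for i in range(4)],
        )
        asg = wm.ModuleAssignment(labels=pd.Series([1] * 4, index=expr.index))
        eig = wm.module_eigengenes(expr, asg)
        mm = ts.module_membership(expr, eig)
        assert np.all(np.abs(mm[1].to_numpy()) > 0.999)

    def test_gs_mm_correlated_on_trait_module(self):
        _, meta, counts, truth = sd.benchmark_dataset(seed=1)
        from coexflow import preprocess as pp

        counts_f = pp.filter_low_expression(counts)
        sf = pp.size_factors(counts_f)
        expr = pp.vst_transform(counts_f, sf, pp.fit_dispersion_trend(counts_f, sf))
        asg = wm.ModuleAssignment(labels=truth.module_of_gene.loc[expr.index])
        eig = wm.module_eigengenes(expr, asg)
        t = (meta["group"] == "High").to_numpy(float)
        gs = ts.gene_significance(expr, t)
        mm = ts.module_membership(expr, eig)
        genes = asg.genes_in(3)
        r = np.corrcoef(gs.loc[genes], np.abs(mm.loc[genes, 3]))[0, 1]
        assert r > 0.5


class TestConnectivityAndHubs:
    def _adj(self, rng, n):
        raw = rng.uniform(0, 1, size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        return pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                            columns=[f"g{i}" for i in range(n)])

    def test_singleton_module_zero_within(self, rng):
        adj = self._adj(rng, 5)
        asg = wm.ModuleAssignment(
            labels=pd.Series([1, 0, 0, 0, 0], index=adj.index)
        )
        conn = ts.intramodular_connectivity(adj, asg)
        assert conn.loc["g0", "kWithin"] == 0.0

    def test_single_module_saturation(self, rng):
        adj = self._adj(rng, 6)
        asg = wm.ModuleAssignment(labels=pd.Series([1] * 6, index=adj.index))
        conn = ts.intramodular_connectivity(adj, asg)
        np.testing.assert_allclose(conn["kWithin"], conn["kTotal"])

    def test_brute_force_oracle(self, rng):
        adj = self._adj(rng, 15)
        labels = pd.Series(rng.integers(0, 3, 15), index=adj.index)
        asg = wm.ModuleAssignment(labels=labels)
        conn = ts.intramodular_connectivity(adj, asg)
        a = adj.to_numpy()
        for i, g in enumerate(adj.index):
            kt = sum(a[i, j] for j in range(15) if j != i)
            kw = sum(
                a[i, j]
                for j in range(15)
                if j != i and labels.iloc[j] == labels.iloc[i]
            )
            assert conn.loc[g, "kTotal"] == pytest.approx(kt, abs=1e-10)
            assert conn.loc[g, "kWithin"] == pytest.approx(kw, abs=1e-10)

    def test_dimension_mismatch(self, rng):
        adj = self._adj(rng, 4)
        asg = wm.ModuleAssignment(labels=pd.Series([1, 1], index=["g0", "g1"]))
        with pytest.raises(ValueError):
            ts.intramodular_connectivity(adj, asg)

    def test_hub_truncation_and_order(self, rng):
        adj = self._adj(rng, 10)
        asg = wm.ModuleAssignment(labels=pd.Series([1] * 10, index=adj.index))
        conn = ts.intramodular_connectivity(adj, asg)
        hubs = ts.select_hub_genes(conn, asg, n=30)
        assert len(hubs[1]) == 10
        kw = hubs[1]["kWithin"].to_numpy()
        assert np.all(np.diff(kw) <= 1e-12)

    def test_hub_order_invariant_to_gene_order(self, rng):
        adj = self._adj(rng, 12)
        asg = wm.ModuleAssignment(labels=pd.Series([1] * 12, index=adj.index))
        conn = ts.intramodular_connectivity(adj, asg)
        hubs1 = ts.select_hub_genes(conn, asg, n=5)
        perm = rng.permutation(12)
        adj2 = adj.iloc[perm, perm]
        asg2 = wm.ModuleAssignment(labels=asg.labels.iloc[perm])
        conn2 = ts.intramodular_connectivity(adj2, asg2)
        hubs2 = ts.select_hub_genes(conn2, asg2, n=5)
        assert list(hubs1[1].index) == list(hubs2[1].index)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_planted_hub_recovered(self, seed):
        # one gene with maximal loading should rank among its module's hubs
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=40)
        lam = np.full(25, 0.5)
        lam[0] = 1.5
        vals = lam[:, None] * latent[None, :] + rng.normal(size=(25, 40)) * 0.4
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(25)])
        from coexflow import wgcna_network as wn

        adj = wn.adjacency(wn.correlation_matrix(expr), 6)
        asg = wm.ModuleAssignment(labels=pd.Series([1] * 25, index=expr.index))
        conn = ts.intramodular_connectivity(adj, asg)
        hubs = ts.select_hub_genes(conn, asg, n=5)
        assert "g0" in hubs[1].index


class TestExportHubNetwork:
    def test_edge_count(self, rng):
        n = 8
        raw = rng.uniform(0, 1, size=(n, n))
        a = pd.DataFrame(
            (raw + raw.T) / 2,
            index=[f"g{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(n)],
        )
        edges = ts.export_hub_network(a, [f"g{i}" for i in range(n)])
        assert len(edges) == n * (n - 1) // 2

    def test_thirty_hubs_435_edges(self, rng):
        n = 30
        raw = rng.uniform(0, 1, size=(n, n))
        genes = [f"g{i}" for i in range(n)]
        a = pd.DataFrame((raw + raw.T) / 2, index=genes, columns=genes)
        edges = ts.export_hub_network(a, genes)
        assert len(edges) == 435

    def test_weights_match_adjacency(self, rng):
        n = 5
        raw = rng.uniform(0, 1, size=(n, n))
        genes = [f"g{i}" for i in range(n)]
        a = pd.DataFrame((raw + raw.T) / 2, index=genes, columns=genes)
        edges = ts.export_hub_network(a, genes)
        for _, row in edges.iterrows():
            assert row["weight"] == a.loc[row["source"], row["target"]]
            assert row["source"] < row["target"]

    def test_empty_hub_list(self, rng):
        a = pd.DataFrame(np.eye(2), index=["g0", "g1"], columns=["g0", "g1"])
        with pytest.raises(ValueError):
            ts.export_hub_network(a, [])
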