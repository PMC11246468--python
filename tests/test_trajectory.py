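"""Backbone pseudotime, lineage genes, modules, connectivity and fates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from lungdyn import trajectory
from lungdyn.trajectory import (connectivity_ratio, fate_probabilities,
                                gene_modules, infer_backbone,
                                natural_spline_basis, vignette_connectivity)


class TestInferBackbone:
    def test_collinear_clusters_give_coordinate_pseudotime(self, rng):
        # three collinear centroids; cells exactly on the line
        x = np.sort(rng.uniform(0, 30, 120))
        emb = np.column_stack([x, np.zeros(120)])
        lab = np.digitize(x, [10, 20])
        model = infer_backbone(emb, lab, root_cluster=0)
        rho = stats.spearmanr(model.pseudotime, x).statistic
        assert rho == pytest.approx(1.0)

    def test_root_centroid_cells_have_zero_tau(self):
        emb = np.array([[0.0, 0.0]] * 5 + [[10.0, 0.0]] * 5)
        lab = np.array([0] * 5 + [1] * 5)
        model = infer_backbone(emb, lab, root_cluster=0)
        assert np.allclose(model.pseudotime[:5], 0.0, atol=1e-12)

    def test_y_topology_matches_bruteforce_mst(self, rng):
        # A -> B -> {C, D}: compare the edge set to a brute-force MST over
        # the four centroids (enumerate all 16 spanning trees via networkx)
        import itertools

        import networkx as nx

        cents = {"A": (0, 0), "B": (10, 0), "C": (20, 8), "D": (20, -8)}
        emb, lab = [], []
        for name, (cx, cy) in cents.items():
            emb.append(rng.normal(scale=0.1, size=(30, 2)) + [cx, cy])
            lab += [name] * 30
        emb = np.vstack(emb)
        lab = np.array(lab)
        model = infer_backbone(emb, lab, root_cluster="A")
        got = {tuple(sorted(e)) for e in model.mst_edges}

        # oracle: exhaustive minimum spanning tree over cluster centroids
        names = sorted(cents)
        cent_arr = {n: emb[lab == n].mean(axis=0) for n in names}
        best, best_w = None, np.inf
        for edges in itertools.combinations(
                itertools.combinations(names, 2), 3):
            g = nx.Graph(edges)
            if g.number_of_nodes() == 4 and nx.is_connected(g):
                w = sum(np.linalg.norm(cent_arr[a] - cent_arr[b])
                        for a, b in edges)
                if w < best_w:
                    best, best_w = edges, w
        oracle = {tuple(sorted(e)) for e in best}
        assert got == oracle == {("A", "B"), ("B", "C"), ("B", "D")}
        assert sorted(tuple(p) for p in model.lineages) == [
            ("A", "B", "C"), ("A", "B", "D")]

    def test_tau_invariant_under_rotation(self, rng):
        emb = rng.normal(size=(150, 3)) + np.linspace(0, 20, 150)[:, None]
        lab = np.digitize(np.arange(150), [50, 100])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m0 = infer_backbone(emb, lab, root_cluster=0)
        m1 = infer_backbone(emb @ q.T, lab, root_cluster=0)
        assert np.allclose(m0.pseudotime, m1.pseudotime, atol=1e-8)

    def test_missing_root_raises(self, rng):
        emb = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="root"):
            infer_backbone(emb, np.zeros(20, int), root_cluster=7)

    def test_lineage_weights_normalised(self, atlas, backbone):
        _, model = backbone
        sums = model.lineage_weights.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestAssociationTest:
    def _model_on_line(self, n, rng):
        x = np.sort(rng.uniform(0, 30, n))
        emb = np.column_stack([x, np.zeros(n)])
        lab = np.digitize(x, [15])
        return infer_backbone(emb, lab, root_cluster=0), x

    def test_planted_logistic_gene_detected_and_null_controlled(self, rng):
        model, x = self._model_on_line(400, rng)
        tau01 = (x - x.min()) / np.ptp(x)
        n_null = 300
        null = np.log1p(rng.poisson(1.5, size=(400, n_null)).astype(float))
        planted = np.log1p(rng.poisson(
            1.5 * np.exp(2.0 / (1 + np.exp(-(tau01 - 0.5) / 0.1)))).astype(float))
        vals = np.column_stack([planted, null])
        genes = pd.Index(["planted"] + [f"N{i}" for i in range(n_null)])
        res = trajectory.association_test(vals, genes, model, min_cells=30)
        assert len(res) == 1
        tab = next(iter(res.values())).set_index("gene")
        assert tab.loc["planted", "selected"]
        assert tab.drop(index="planted")["selected"].mean() <= 0.02

    def test_fdr_is_per_lineage(self, atlas, processed, backbone):
        """BH is applied within each lineage separately: a gene's adjusted
        p in one lineage is unaffected by genes tested in the other."""
        qc, expr, _, _ = processed
        mask, model = backbone
        res = trajectory.association_test(expr.values[mask], expr.gene_ids,
                                          model)
        assert set(res) == {"ciliated", "neuroendocrine"}
        for name, tab in res.items():
            sub = (model.lineage_weights[name] >= 0.4).to_numpy()
            tau = model.pseudotime.to_numpy()[sub]
            B = natural_spline_basis(tau, df=10)
            Q, _ = np.linalg.qr(B)
            _, p = trajectory._spline_ftest(expr.values[mask][sub], Q,
                                            B.shape[1])
            from statsmodels.stats.multitest import multipletests

            adj = multipletests(p, method="fdr_bh")[1]
            got = tab.set_index("gene").loc[expr.gene_ids, "adj_p"].to_numpy()
            assert np.allclose(got, adj, atol=1e-12)

    def test_small_lineage_skipped(self, rng):
        model, _ = self._model_on_line(40, rng)
        vals = rng.normal(size=(40, 5)) ** 2
        with pytest.warns(UserWarning, match="skipped"):
            res = trajectory.association_test(vals, pd.Index(list("abcde")),
                                              model, min_cells=50)
        assert res == {}


class TestGeneModules:
    def test_identical_profiles_share_a_module(self, rng):
        tau = np.sort(rng.uniform(0, 1, 100))
        base = np.sin(2 * np.pi * tau)
        vals = np.column_stack([base, base, -base, -base])
        gm = gene_modules(vals, pd.Index(list("abcd")), tau, n_modules=2)
        assert gm.assignment["a"] == gm.assignment["b"]
        assert gm.assignment["c"] == gm.assignment["d"]
        assert gm.assignment["a"] != gm.assignment["c"]

    def test_block_structure_matches_ward_oracle(self, rng):
        tau = np.sort(rng.uniform(0, 1, 200))
        f1, f2, f3 = tau, np.cos(3 * tau), (tau - 0.5) ** 2
        vals = np.column_stack([
            f1 + rng.normal(0, 0.05, 200), f1 + rng.normal(0, 0.05, 200),
            f2 + rng.normal(0, 0.05, 200), f2 + rng.normal(0, 0.05, 200),
            f3 + rng.normal(0, 0.05, 200), f3 + rng.normal(0, 0.05, 200)])
        genes = pd.Index([f"g{i}" for i in range(6)])
        gm = gene_modules(vals, genes, tau, n_modules=3)
        # oracle: hand-computed correlation -> Ward -> fcluster
        c = np.corrcoef(vals[np.argsort(tau, kind="stable")].T)
        d = 1 - c
        np.fill_diagonal(d, 0)
        z = hierarchy.ward(squareform(d, checks=False))
        oracle = hierarchy.fcluster(z, t=3, criterion="maxclust")
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(oracle, gm.assignment.to_numpy()) == 1.0

    def test_constant_gene_removed_with_warning(self, rng):
        tau = np.sort(rng.uniform(0, 1, 50))
        vals = np.column_stack([tau, np.ones(50), -tau])
        with pytest.warns(UserWarning, match="constant"):
            gm = gene_modules(vals, pd.Index(list("abc")), tau, n_modules=2)
        assert list(gm.assignment.index) == ["a", "c"]

    def test_smoothed_matrix_shape_and_monotone_trend(self, rng):
        tau = np.sort(rng.uniform(0, 1, 150))
        vals = np.column_stack([3 * tau + rng.normal(0, 0.1, 150),
                                1 - tau + rng.normal(0, 0.1, 150)])
        gm = gene_modules(vals, pd.Index(["up", "down"]), tau, n_modules=2,
                          grid_size=40)
        assert gm.smoothed.shape == (2, 40)
        assert gm.smoothed.loc["up"].iloc[-1] > gm.smoothed.loc["up"].iloc[0]


class TestVignetteConnectivity:
    def test_gw_binning(self):
        from lungdyn.vignettes import TRAJECTORY_VIGNETTES, assign_vignette

        v = assign_vignette([12, 15, 18], TRAJECTORY_VIGNETTES)
        assert list(v) == ["early", "mid", "late"]

    def test_separated_clusters_zero_connectivity(self, rng):
        emb = np.vstack([rng.normal(size=(40, 2)),
                         rng.normal(size=(40, 2)) + 1000])
        lab = np.array([0] * 40 + [1] * 40)
        gw = np.full(80, 12)
        tau = np.arange(80, dtype=float)
        vg = vignette_connectivity(emb, lab, gw, tau, k_neighbors=5)
        assert vg.connectivity["early"].loc[0, 1] == 0.0

    def test_ratio_matches_bruteforce_edge_count(self, rng):
        emb = rng.normal(size=(90, 2))
        lab = rng.integers(0, 3, 90)
        edges = trajectory._knn_undirected_edges(emb, 6)
        got = connectivity_ratio(edges, lab)
        # oracle: count inter-cluster edges by hand from the distance matrix
        D = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        knn = np.argsort(D, axis=1, kind="stable")[:, :6]
        eset = set()
        for i in range(90):
            for j in knn[i]:
                eset.add((min(i, j), max(i, j)))
        m = len(eset)
        assert m == len(edges)
        sizes = np.bincount(lab)
        for a in range(3):
            for b in range(a + 1, 3):
                obs = sum(1 for i, j in eset if {lab[i], lab[j]} == {a, b})
                exp = m * sizes[a] * sizes[b] / (90 * 89 / 2)
                assert got.loc[a, b] == pytest.approx(min(obs / exp, 1.0))

    def test_orientation_follows_mean_pseudotime(self, rng):
        emb = np.vstack([rng.normal(size=(40, 2)),
                         rng.normal(size=(40, 2)) + 2.0])
        lab = np.array(["lo"] * 40 + ["hi"] * 40)
        gw = np.full(80, 15)
        tau = np.concatenate([np.zeros(40), np.ones(40)])
        vg = vignette_connectivity(emb, lab, gw, tau, k_neighbors=10)
        edges = vg.edges
        row = edges[(edges["vignette"] == "mid")].iloc[0]
        assert (row["from"], row["to"]) == ("lo", "hi")


class TestFateProbabilities:
    def _toy(self, rng, n=120):
        x = np.sort(rng.uniform(0, 10, n))
        emb = np.column_stack([x, rng.normal(0, 0.2, n)])
        tau = x.copy()
        lab = np.where(x < 8, "transit", "end")
        return emb, tau, lab

    def test_terminal_cells_are_absorbing(self, rng):
        emb, tau, lab = self._toy(rng)
        F = fate_probabilities(emb, tau, ["end"], lab, k_neighbors=8)
        term = lab == "end"
        assert np.allclose(F.to_numpy()[term, 0], 1.0)

    def test_rows_sum_to_one(self, rng):
        emb, tau, lab = self._toy(rng)
        F = fate_probabilities(emb, tau, ["end"], lab, k_neighbors=8)
        assert np.allclose(F.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_dense_absorption_oracle(self, rng):
        """Independent oracle: rebuild the transition matrix row by row and
        solve the absorbing-chain system with dense linear algebra."""
        from scipy.special import expit as sigmoid
        from sklearn.neighbors import NearestNeighbors

        n = 150
        emb = rng.normal(size=(n, 3))
        tau = rng.uniform(0, 1, n)
        lab = rng.choice(["a", "b", "t"], n, p=[0.2, 0.2, 0.6])
        k, scale = 10, 0.3
        F = fate_probabilities(emb, tau, ["a", "b"], lab, k_neighbors=k,
                               kernel_scale=scale)
        idx = NearestNeighbors(n_neighbors=k).fit(emb).kneighbors(
            return_distance=False)
        P = np.zeros((n, n))
        for i in range(n):
            for j in idx[i]:
                P[i, j] = sigmoid((tau[j] - tau[i]) / scale)
            P[i] /= P[i].sum()
        term = np.isin(lab, ["a", "b"])
        P[term] = 0.0
        P[term, np.arange(n)[term]] = 1.0
        # absorb: F = (I - Q)^-1 R grouped by terminal cluster
        trans = ~term
        Q = P[np.ix_(trans, trans)]
        Fo = np.linalg.solve(np.eye(trans.sum()) - Q,
                             np.column_stack([
                                 P[np.ix_(trans, (lab == "a"))].sum(axis=1),
                                 P[np.ix_(trans, (lab == "b"))].sum(axis=1)]))
        assert np.allclose(F.to_numpy()[trans], Fo, atol=1e-6)

    def test_y_trajectory_branch_fates(self, atlas, processed, backbone):
        qc, _, emb, _ = processed
        mask, model = backbone
        lab = qc.cell_meta["true_type"][mask].to_numpy()
        tau = model.pseudotime.to_numpy()
        F = fate_probabilities(emb[mask], tau, ["ciliated", "neuroendocrine"],
                               lab, k_neighbors=15)
        truth = qc.cell_meta["true_branch"][mask]
        past = truth.isin(["ciliated", "neuroendocrine"]).to_numpy()
        correct = (F.to_numpy()[past].argmax(axis=1) ==
                   (truth[past] == "neuroendocrine").to_numpy().astype(int))
        assert correct.mean() >= 0.9


class TestNaturalSplineBasis:
    def test_linear_beyond_boundaries_and_df(self, rng):
        x = rng.uniform(0, 1, 300)
        B = natural_spline_basis(x, df=10)
        assert B.shape == (300, 10)
        # natural basis is linear outside the boundary knots: second
        # differences along a fine grid outside the data range vanish
        knots = np.quantile(x, np.linspace(0, 1, 11))
        g = np.linspace(x.max() + 0.1, x.max() + 0.5, 20)
        Bg = natural_spline_basis(g, df=10, knots=knots)
        second = np.diff(Bg, n=2, axis=0)
        assert np.abs(second).max() < 1e-8
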