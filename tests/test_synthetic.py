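"""Generator contracts: determinism, planted structure, spatial geometry."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from lungdyn import synthetic
from lungdyn.datatypes import ConfigError
from lungdyn.synthetic import (CompositionTrend, NicheSpec, SimConfig,
                               SpatialSpec, TrajectorySpec)


def small_config(**kw):
    base = dict(n_samples=6, n_cells_per_sample=100, n_genes=300, seed=7)
    base.update(kw)
    return SimConfig(**base)


class TestMakeAtlas:
    def test_same_seed_is_byte_identical(self):
        a = synthetic.make_atlas(small_config())
        b = synthetic.make_atlas(small_config())
        assert np.array_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.counts.cell_meta, b.counts.cell_meta)
        pd.testing.assert_frame_equal(a.spatial.table, b.spatial.table)
        pd.testing.assert_frame_equal(a.spot_weights.weights,
                                      b.spot_weights.weights)

    def test_different_seed_differs(self):
        a = synthetic.make_atlas(small_config())
        b = synthetic.make_atlas(small_config(seed=8))
        assert not np.array_equal(a.counts.counts, b.counts.counts)

    def test_invariants(self, atlas):
        meta = atlas.counts.cell_meta
        lo, hi = atlas.config.gw_range
        assert meta["gestational_week"].between(lo, hi).all()
        tau = atlas.truth_pseudotime.dropna()
        assert ((tau >= 0) & (tau <= 1)).all()
        assert np.issubdtype(atlas.counts.counts.dtype, np.integer)
        assert (atlas.counts.counts >= 0).all()
        # marker sets are disjoint across types
        all_markers = [g for gs in atlas.truth_markers.values() for g in gs]
        assert len(all_markers) == len(set(all_markers))

    def test_null_marker_effect_levels_marker_means(self):
        cfg = small_config(marker_effect=0.0, n_cells_per_sample=400)
        a = synthetic.make_atlas(cfg)
        ct = a.counts.cell_meta["true_type"]
        for t, genes in a.truth_markers.items():
            cols = a.counts.gene_ids.get_indexer(genes)
            own = a.counts.counts[np.ix_((ct == t).to_numpy(), cols)].mean()
            other = a.counts.counts[np.ix_((ct != t).to_numpy(), cols)].mean()
            # library/depth noise only: means agree within a few percent
            assert own == pytest.approx(other, rel=0.10)

    @staticmethod
    def _raw_logit(cfg, focal, prop):
        """Invert the cross-type renormalisation: recover the focal type's
        pre-normalisation logit from observed proportions, using the known
        trends of the other types (refitting the generating model)."""
        t = prop["gw"].to_numpy() - (cfg.gw_range[0] + cfg.gw_range[1]) / 2.0
        s_other = sum(expit(cfg.composition_spec[u].logit(t))
                      for u in cfg.cell_types if u != focal)
        p = prop["p"].to_numpy()
        raw = s_other * p / (1.0 - p)
        return t, logit(np.clip(raw, 1e-9, 1 - 1e-9))

    def test_quadratic_composition_recovers_concavity(self):
        """Refitting the generating polynomial to simulated per-sample
        proportions recovers the planted negative curvature."""
        spec = dict(synthetic._default_composition())
        spec["neuroendocrine"] = CompositionTrend("quadratic", (-1.0, 0.0, -0.3))
        cfg = SimConfig(n_samples=19, n_cells_per_sample=2000, seed=3,
                        composition_spec=spec, spatial_spec=None)
        a = synthetic.make_atlas(cfg)
        meta = a.counts.cell_meta
        prop = (meta.assign(is_t=meta["true_type"] == "neuroendocrine")
                .groupby("sample_id")
                .agg(gw=("gestational_week", "first"), p=("is_t", "mean")))
        prop["p"] = prop["p"].clip(lower=0.5 / 2000)
        t, y = self._raw_logit(cfg, "neuroendocrine", prop)
        beta = np.polyfit(t, y, 2)
        assert beta[0] < -0.1  # concave on the logit scale

    def test_expected_proportions_renormalised_inverse_logit(self):
        cfg = small_config()
        gw = np.array([12, 15])
        props = synthetic.expected_proportions(cfg, gw)
        assert np.allclose(props.sum(axis=1), 1.0)
        raw = np.array([[expit(cfg.composition_spec[t].logit(w - 14.5))
                         for t in cfg.cell_types] for w in gw])
        assert np.allclose(props.to_numpy(), raw / raw.sum(1, keepdims=True))

    def test_linear_composition_slope_recovery(self):
        """Logit per-sample proportions regressed on GW recover the planted
        slope within 3 SE at n_cells_per_sample = 2000."""
        cfg = SimConfig(n_samples=19, n_cells_per_sample=2000, seed=4,
                        spatial_spec=None)
        a = synthetic.make_atlas(cfg)
        meta = a.counts.cell_meta
        for t, slope in [("progenitor", -0.35), ("ciliated", 0.35)]:
            prop = (meta.assign(is_t=meta["true_type"] == t)
                    .groupby("sample_id")
                    .agg(gw=("gestational_week", "first"), p=("is_t", "mean")))
            x, y = self._raw_logit(cfg, t, prop)
            X = np.column_stack([np.ones(len(x)), x])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(x) - 2
            sigma2 = float(res[0]) / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert abs(coef[1] - slope) < 3 * se

    def test_pseudotime_genes_monotone_in_truth(self, atlas):
        """A shared activating pseudotime gene increases along truth tau."""
        pt = atlas.truth_pt_genes
        g = pt[(pt["sign"] == 1) & (pt["branch"] == "all")].iloc[0]
        col = atlas.counts.gene_ids.get_loc(g["gene"])
        tau = atlas.truth_pseudotime
        on = tau.notna().to_numpy()
        lo = atlas.counts.counts[on & (tau < 0.3).to_numpy(), col].mean()
        hi = atlas.counts.counts[on & (tau > 0.7).to_numpy(), col].mean()
        assert hi > lo * 2

    def test_marker_separability_auroc(self):
        """With a unit log-effect every marker gene separates its own type
        with AUROC above 0.8."""
        from sklearn.metrics import roc_auc_score

        a = synthetic.make_atlas(small_config(marker_effect=1.0,
                                              n_cells_per_sample=300,
                                              n_samples=12))
        ct = a.counts.cell_meta["true_type"]
        for t, genes in a.truth_markers.items():
            y = (ct == t).astype(int)
            for g in genes:
                col = a.counts.gene_ids.get_loc(g)
                assert roc_auc_score(y, a.counts.counts[:, col]) > 0.8

    def test_invalid_configs_name_the_field(self):
        with pytest.raises(ConfigError, match="mixture"):
            synthetic.make_atlas(small_config(spatial_spec=SpatialSpec(
                niches=(NicheSpec((0, 0), 10, {"progenitor": 0.7}),))))
        with pytest.raises(ConfigError, match="gw_range"):
            synthetic.make_atlas(small_config(gw_range=(8, 19)))
        with pytest.raises(ConfigError, match="n_genes"):
            synthetic.make_atlas(small_config(n_genes=20))


class TestMakeSpatial:
    def test_segregated_niches_confine_types(self):
        spec = SpatialSpec(
            niches=(NicheSpec((200.0, 200.0), 100.0, {"progenitor": 1.0}),
                    NicheSpec((800.0, 800.0), 100.0, {"stromal": 1.0})),
            n_cells_per_niche=200, n_background=0)
        a = synthetic.make_atlas(small_config(spatial_spec=spec))
        tab = a.spatial.table
        x = tab[tab["type"] == "progenitor"]
        d = np.hypot(x["x"] - 200, x["y"] - 200)
        assert (d <= 100.0 + 1e-9).all()
        assert len(x) > 0

    def test_spot_weight_rows_sum_to_one(self, atlas):
        sums = atlas.spot_weights.weights.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_two_type_spot_weights_anticorrelate(self):
        """In a two-type system w_Y = 1 - w_X, so corr(X, Y) = -1."""
        cfg = small_config(
            cell_types=("progenitor", "stromal"),
            composition_spec={
                "progenitor": CompositionTrend("constant", (0.0,)),
                "stromal": CompositionTrend("constant", (0.0,))},
            trajectory_spec=TrajectorySpec(paths=(("progenitor",),), n_genes=10),
            spatial_spec=SpatialSpec(
                niches=(NicheSpec((300.0, 300.0), 250.0,
                                  {"progenitor": 0.8, "stromal": 0.2}),
                        NicheSpec((700.0, 700.0), 250.0,
                                  {"progenitor": 0.2, "stromal": 0.8})),
                n_cells_per_niche=400, n_background=100),
            lr_spec=synthetic.LRSpec(pairs=(), n_decoys=0))
        a = synthetic.make_atlas(cfg)
        W = a.spot_weights.weights
        r = np.corrcoef(W["progenitor"], W["stromal"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_empty_niche_mixture_raises(self, atlas):
        cfg = small_config()
        cfg.spatial_spec = SpatialSpec(niches=(NicheSpec((0, 0), 10, {}),))
        with pytest.raises(ConfigError, match="mixture"):
            synthetic.make_spatial(atlas, cfg)


class TestMakeQuery:
    def test_deterministic_and_gene_compatible(self, atlas):
        q1 = synthetic.make_query(atlas.config, 50, gw=12, seed=3)
        q2 = synthetic.make_query(atlas.config, 50, gw=12, seed=3)
        assert np.array_equal(q1.counts, q2.counts)
        assert q1.gene_ids.equals(atlas.counts.gene_ids)

    def test_tau_range_clips_trajectory(self, atlas):
        q = synthetic.make_query(atlas.config, 200, gw=11,
                                 type_weights={"progenitor": 1.0},
                                 tau_range=(0.0, 0.2), seed=0)
        tau = q.cell_meta["true_pseudotime"]
        assert tau.notna().all() and (tau <= 0.2 + 1e-12).all()
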