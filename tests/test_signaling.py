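"""Ligand-receptor inference: Hill probabilities, permutation significance,
temporal contrasts and pathway information flow."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lungdyn import signaling
from lungdyn.datatypes import ExprMatrix
from lungdyn.signaling import (LRPair, information_flow,
                               interaction_probability,
                               permutation_significance, signed_rank_exact_p,
                               temporal_compare, vignette_tables)


def _expr(values, genes, labels, gw=None, sample=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    idx = pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    meta = pd.DataFrame({"sample_id": sample if sample is not None else "S"},
                        index=idx)
    if gw is not None:
        meta["gestational_week"] = gw
    return (ExprMatrix(values, meta, pd.Index(genes)),
            pd.Series(labels, index=idx))


PAIR = LRPair("L", ("R",), "P")


class TestInteractionProbability:
    def test_zero_ligand_gives_zero(self, rng):
        vals = np.zeros((20, 2))
        vals[10:, 1] = 2.0  # receptor in receiver only
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 10 + ["r"] * 10)
        tab = interaction_probability(expr, lab, [PAIR])
        row = tab.set_index(["sender", "receiver"]).loc[("s", "r")]
        assert row["probability"] == 0.0

    def test_half_max_at_hill_k(self):
        # constant expression makes the trimmed means exact
        vals = np.column_stack([np.full(20, 2.0), np.full(20, 0.25)])
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 10 + ["r"] * 10)
        tab = interaction_probability(expr, lab, [PAIR], hill_k=0.5)
        row = tab.set_index(["sender", "receiver"]).loc[("s", "r")]
        assert row["probability"] == pytest.approx(0.5)  # L*R = 0.5 = k

    def test_saturates_toward_one(self):
        vals = np.column_stack([np.full(20, 50.0), np.full(20, 50.0)])
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 10 + ["r"] * 10)
        tab = interaction_probability(expr, lab, [PAIR])
        assert tab["probability"].iloc[0] > 0.99

    def test_monotone_in_ligand_expression(self, rng):
        probs = []
        for lig in (0.5, 1.0, 2.0, 4.0):
            vals = np.column_stack([np.full(30, lig), np.full(30, 1.0)])
            expr, lab = _expr(vals, ["L", "R"], ["s"] * 15 + ["r"] * 15)
            tab = interaction_probability(expr, lab, [PAIR])
            row = tab.set_index(["sender", "receiver"]).loc[("s", "r")]
            probs.append(row["probability"])
        assert all(a < b for a, b in zip(probs, probs[1:]))

    def test_multi_subunit_geometric_mean(self):
        pair = LRPair("L", ("R1", "R2"), "P")
        vals = np.column_stack([np.full(20, 1.0), np.full(20, 4.0),
                                np.full(20, 1.0)])
        expr, lab = _expr(vals, ["L", "R1", "R2"], ["s"] * 10 + ["r"] * 10)
        tab = interaction_probability(expr, lab, [pair], hill_k=0.5)
        row = tab.set_index(["sender", "receiver"]).loc[("s", "r")]
        x = 1.0 * np.sqrt(4.0 * 1.0)
        assert row["probability"] == pytest.approx(x / (0.5 + x))

    def test_missing_gene_pair_skipped_with_warning(self, rng):
        vals = rng.uniform(size=(10, 1))
        expr, lab = _expr(vals, ["L"], ["s"] * 5 + ["r"] * 5)
        with pytest.warns(UserWarning, match="skipped"):
            tab = interaction_probability(expr, lab, [PAIR])
        assert tab.empty


class TestPermutationSignificance:
    def test_p_bounded_below_by_permutation_floor(self, rng):
        vals = rng.uniform(1, 2, size=(60, 2))
        vals[:30, 0] += 5.0  # strong ligand in sender
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 30 + ["r"] * 30)
        tab = permutation_significance(expr, lab, [PAIR], n_perms=50, seed=0)
        assert (tab["p_value"] >= 1 / 51 - 1e-12).all()

    def test_too_few_permutations_rejected(self, rng):
        vals = rng.uniform(size=(20, 2))
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 10 + ["r"] * 10)
        with pytest.raises(ValueError, match="n_perms"):
            permutation_significance(expr, lab, [PAIR], n_perms=10)

    def test_planted_pair_significant(self, rng):
        vals = np.exp(rng.normal(0, 0.2, size=(80, 2)))
        vals[:40, 0] *= 10.0
        vals[40:, 1] *= 4.0
        expr, lab = _expr(vals, ["L", "R"], ["s"] * 40 + ["r"] * 40)
        tab = permutation_significance(expr, lab, [PAIR], n_perms=100, seed=0)
        row = tab.set_index(["sender", "receiver"]).loc[("s", "r")]
        assert bool(row["significant"])

    def test_null_type_one_error_controlled(self, rng):
        """Exchangeable labels: the fraction of significant calls stays
        near the nominal level across seeds."""
        n_hits = n_tests = 0
        for seed in range(3):
            r = np.random.default_rng(seed)
            vals = np.exp(r.normal(0, 0.3, size=(120, 12)))
            genes = [f"L{i}" for i in range(6)] + [f"R{i}" for i in range(6)]
            pairs = [LRPair(f"L{i}", (f"R{i}",), "P") for i in range(6)]
            expr, lab = _expr(vals, genes, r.choice(["a", "b", "c"], 120))
            tab = permutation_significance(expr, lab, pairs, n_perms=100,
                                           seed=seed)
            n_hits += int(tab["significant"].sum())
            n_tests += len(tab)
        assert n_hits / n_tests <= 0.02


class TestSignedRankExact:
    def test_all_zero_differences_give_p_one(self):
        assert signed_rank_exact_p(np.zeros(8)) == 1.0

    def test_unit_shift_of_eight_pathways(self):
        # all 8 differences positive and tied: two-sided exact p = 2/256
        assert signed_rank_exact_p(np.ones(8)) == pytest.approx(2 / 256)

    def test_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=10)
            d = d[d != 0]
            ref = stats.wilcoxon(d, alternative="two-sided",
                                 method="exact").pvalue
            assert signed_rank_exact_p(d) == pytest.approx(ref, abs=1e-12)

    def test_matches_bruteforce_with_ties(self, rng):
        # independent oracle: enumerate every sign assignment explicitly
        import itertools

        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -3.0, 0.5])
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([False, True], repeat=len(d))]
        ws = np.array(ws)
        p_ge = (ws >= w_obs - 1e-12).mean()
        p_le = (ws <= w_obs + 1e-12).mean()
        oracle = min(1.0, 2.0 * min(p_ge, p_le))
        assert signed_rank_exact_p(d) == pytest.approx(oracle, abs=1e-12)


class TestInformationFlow:
    def _table(self, flows, sig=True):
        return pd.DataFrame({
            "sender": "s", "receiver": "r",
            "pair": [f"p{i}" for i in range(len(flows))],
            "pathway": [f"pw{i}" for i in range(len(flows))],
            "probability": flows, "p_value": 0.001,
            "significant": sig})

    def test_identical_flows_give_p_one(self):
        t = self._table([0.5, 0.2, 0.7, 0.1, 0.9])
        flows, tests = information_flow({"early": t, "late": t.copy()})
        assert (tests["p_value"] == 1.0).all()

    def test_flow_zero_without_significant_interactions(self):
        t1 = self._table([0.5] * 5)
        t2 = self._table([0.5] * 5, sig=False)
        flows, _ = information_flow({"early": t1, "late": t2})
        assert (flows["late"] == 0).all()
        assert (flows["early"] == 0.5).all()

    def test_few_pathways_warn(self):
        t = self._table([0.5, 0.2])
        with pytest.warns(UserWarning, match="underpowered"):
            information_flow({"early": t, "late": t.copy()})


class TestTemporalCompare:
    def _vignette_setup(self, rng, switch=True):
        """Cells over 15 samples spanning the three vignettes; ligand L is
        elevated in sender cells of early samples when ``switch``. Enough
        samples that the sample-permutation null has fine resolution."""
        gws = [10, 10, 11, 12, 13, 14, 14, 15, 16, 16, 18, 18, 19, 19, 19]
        vals, labs, gw_col, samp = [], [], [], []
        for si, gw in enumerate(gws):
            n = 60
            block = np.exp(rng.normal(0, 0.2, size=(n, 2)))
            lab = np.array(["s"] * 30 + ["r"] * 30)
            if switch and gw <= 13:
                block[:30, 0] *= 8.0  # ligand up in sender, early only
            else:
                block[:30, 0] *= 1.0
            block[30:, 1] *= 3.0  # receptor always on in receiver
            vals.append(block)
            labs.append(lab)
            gw_col += [gw] * n
            samp += [f"S{si}"] * n
        expr, lab = _expr(np.vstack(vals), ["L", "R"], np.concatenate(labs),
                          gw=gw_col, sample=samp)
        return expr, lab

    def _tables(self, expr, lab, seed=0):
        return vignette_tables(expr, lab, [PAIR], n_perms=150, seed=seed)

    def test_planted_early_switch_called(self, rng):
        expr, lab = self._vignette_setup(rng, switch=True)
        tabs = self._tables(expr, lab)
        calls = temporal_compare(expr, lab, [PAIR], tabs, n_perms=5000,
                                 seed=0)
        row = calls.set_index(["sender", "receiver"]).loc[("s", "r")]
        assert bool(row["early_up"]) and not bool(row["late_up"])

    def test_identical_vignettes_make_no_calls(self, rng):
        """With per-sample expression identical in distribution and the
        statistic identical across permutations, p = 1 for both sides."""
        gws = [10, 11, 12, 14, 15, 16, 18, 18, 19]
        block = np.exp(np.random.default_rng(5).normal(0, 0.2, size=(60, 2)))
        vals = np.vstack([block] * 9)  # every sample literally identical
        labs = np.tile(["s"] * 30 + ["r"] * 30, 9)
        gw_col = np.repeat(gws, 60)
        samp = np.repeat([f"S{i}" for i in range(9)], 60)
        expr, lab = _expr(vals, ["L", "R"], labs, gw=gw_col, sample=samp)
        tabs = self._tables(expr, lab)
        calls = temporal_compare(expr, lab, [PAIR], tabs, n_perms=400, seed=0)
        if not calls.empty:
            assert (calls["p_early"] == 1.0).all()
            assert (calls["p_late"] == 1.0).all()
            assert not calls["early_up"].any()

    def test_sender_restriction_excludes_triples(self, rng):
        expr, lab = self._vignette_setup(rng, switch=True)
        tabs = self._tables(expr, lab)
        calls = temporal_compare(expr, lab, [PAIR], tabs,
                                 restrict_senders={"r"}, n_perms=500, seed=0)
        assert "s" not in set(calls["sender"])

    def test_candidates_require_significance_somewhere(self, rng):
        expr, lab = self._vignette_setup(rng, switch=True)
        tabs = {k: t.assign(significant=False)
                for k, t in self._tables(expr, lab).items()}
        calls = temporal_compare(expr, lab, [PAIR], tabs, n_perms=200, seed=0)
        assert calls.empty


class TestAtlasRecovery:
    def test_planted_vignette_switches_recovered(self, atlas, processed):
        """On the default atlas the early FGF ligand is called early-up
        from its stromal sender and no decoy pair is called."""
        _, expr, _, _ = processed
        truth = expr.cell_meta["true_type"]
        tabs = vignette_tables(expr, truth, atlas.lr_database, n_perms=100,
                               seed=0)
        calls = temporal_compare(expr, truth, atlas.lr_database, tabs,
                                 n_perms=20000, seed=0)
        called = calls[calls["early_up"]]
        assert (called["pair"].str.startswith("FGF7")).all()
        sent = calls.set_index(["sender", "receiver", "pair"])
        assert sent.loc[("stromal", "progenitor", "FGF7->FGFR2"),
                        "early_up"].item()
        decoys = calls[calls["pair"].str.startswith("LIG")]
        assert not decoys["early_up"].any()
        assert not decoys["late_up"].any()
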