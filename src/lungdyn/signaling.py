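"""Ligand-receptor signalling: interaction probabilities, permutation
significance, spatially-restricted temporal contrasts, and pathway
information flow.

The interaction model is a minimal mass-action Hill form: with L the 25%
trimmed mean of ligand expression in the sender type and R the geometric
mean over receptor subunits of their trimmed means in the receiver type,
probability = L*R / (hill_k + L*R). Significance permutes cell-type
labels (p = (1 + #{null >= obs}) / (1 + n_perms), significant at p < 0.01).
Temporal early-vs-late calls contrast log vignette intensities against a
sample-permutation null with Holm familywise control, and are made only
for interactions that are significant in at least one vignette and whose
sender is spatially close to the receiver.
Information flow per pathway is the sum of significant interaction
probabilities; vignettes are compared by an exact paired Wilcoxon
signed-rank test across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExprMatrix
from .vignettes import SIGNALING_VIGNETTES, VIGNETTE_ORDER, assign_vignette

HILL_K = 0.5
TRIM = 0.25


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor_subunits: tuple[str, ...]
    pathway: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor_subunits:
            raise ValueError("ligand and receptor genes must be nonempty")
        if not self.pathway:
            raise ValueError("pathway must be nonempty")

    @property
    def label(self) -> str:
        return f"{self.ligand}->{'+'.join(self.receptor_subunits)}"


def pairs_from_frame(db: pd.DataFrame) -> list[LRPair]:
    """Parse an LR database table (ligand, receptor_subunits ;-sep, pathway)."""
    return [LRPair(r["ligand"], tuple(r["receptor_subunits"].split(";")),
                   r["pathway"]) for _, r in db.iterrows()]


def _trimmed_means(X: np.ndarray, groups: np.ndarray, order: list,
                   trim: float = TRIM) -> np.ndarray:
    """(len(order), n_genes) trimmed mean of X within each group."""
    out = np.zeros((len(order), X.shape[1]))
    for i, g in enumerate(order):
        sub = X[groups == g]
        if len(sub):
            out[i] = stats.trim_mean(sub, trim, axis=0)
    return out


def _probabilities(tm: np.ndarray, type_index: dict, gene_index: dict,
                   pairs: list[LRPair], senders: list, receivers: list,
                   hill_k: float) -> np.ndarray:
    """(n_senders, n_receivers, n_pairs) Hill interaction probabilities."""
    P = np.zeros((len(senders), len(receivers), len(pairs)))
    for k, pair in enumerate(pairs):
        lig = tm[:, gene_index[pair.ligand]]
        sub = np.array([tm[:, gene_index[s]] for s in pair.receptor_subunits])
        rec = np.exp(np.log(np.maximum(sub, 1e-300)).mean(axis=0))
        rec[np.any(sub == 0, axis=0)] = 0.0
        for i, s in enumerate(senders):
            L = lig[type_index[s]]
            for j, r in enumerate(receivers):
                x = L * rec[type_index[r]]
                P[i, j, k] = x / (hill_k + x)
    return P


def _usable_pairs(pairs: list[LRPair], gene_ids: pd.Index) -> list[LRPair]:
    out = []
    for p in pairs:
        genes = (p.ligand, *p.receptor_subunits)
        if all(g in gene_ids for g in genes):
            out.append(p)
        else:
            warnings.warn(f"pair {p.label} skipped: gene(s) missing from matrix")
    return out


def interaction_probability(expr: ExprMatrix, labels: pd.Series,
                            lr_db: list[LRPair] | pd.DataFrame,
                            hill_k: float = HILL_K,
                            senders: list | None = None,
                            receivers: list | None = None) -> pd.DataFrame:
    """Long table of sender x receiver x pair interaction probabilities."""
    pairs = pairs_from_frame(lr_db) if isinstance(lr_db, pd.DataFrame) else list(lr_db)
    pairs = _usable_pairs(pairs, expr.gene_ids)
    lab = labels.reindex(expr.cell_ids).to_numpy()
    types = sorted(pd.unique(pd.Series(lab).dropna()))
    senders = list(senders) if senders is not None else types
    receivers = list(receivers) if receivers is not None else types
    for t in [*senders, *receivers]:
        if t not in types:
            warnings.warn(f"type {t!r} has no cells; its rows are omitted")
    senders = [t for t in senders if t in types]
    receivers = [t for t in receivers if t in types]
    genes = sorted({g for p in pairs for g in (p.ligand, *p.receptor_subunits)})
    gidx = {g: i for i, g in enumerate(genes)}
    X = expr.values[:, expr.gene_index(genes)] if genes else np.zeros((len(lab), 0))
    tm = _trimmed_means(X, lab, types)
    tindex = {t: i for i, t in enumerate(types)}
    P = _probabilities(tm, tindex, gidx, pairs, senders, receivers, hill_k)
    rows = []
    for i, s in enumerate(senders):
        for j, r in enumerate(receivers):
            for k, pair in enumerate(pairs):
                rows.append({"sender": s, "receiver": r, "pair": pair.label,
                             "ligand": pair.ligand,
                             "receptor": "+".join(pair.receptor_subunits),
                             "pathway": pair.pathway,
                             "probability": P[i, j, k]})
    return pd.DataFrame(rows)


def permutation_significance(expr: ExprMatrix, labels: pd.Series,
                             lr_db: list[LRPair] | pd.DataFrame,
                             n_perms: int = 100, alpha: float = 0.01,
                             hill_k: float = HILL_K, seed: int = 0,
                             senders: list | None = None,
                             receivers: list | None = None) -> pd.DataFrame:
    """Interaction table with cell-label permutation p-values.

    p = (1 + #{null probability >= observed}) / (1 + n_perms); the
    ``significant`` flag applies p < alpha.
    """
    if n_perms < 19:
        raise ValueError("n_perms < 19 cannot resolve alpha = 0.01")
    pairs = pairs_from_frame(lr_db) if isinstance(lr_db, pd.DataFrame) else list(lr_db)
    pairs = _usable_pairs(pairs, expr.gene_ids)
    lab = labels.reindex(expr.cell_ids).to_numpy()
    types = sorted(pd.unique(pd.Series(lab).dropna()))
    senders = [t for t in (senders if senders is not None else types) if t in types]
    receivers = [t for t in (receivers if receivers is not None else types)
                 if t in types]
    genes = sorted({g for p in pairs for g in (p.ligand, *p.receptor_subunits)})
    gidx = {g: i for i, g in enumerate(genes)}
    X = expr.values[:, expr.gene_index(genes)] if genes else np.zeros((len(lab), 0))
    tindex = {t: i for i, t in enumerate(types)}
    obs = _probabilities(_trimmed_means(X, lab, types), tindex, gidx, pairs,
                         senders, receivers, hill_k)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perms):
        perm = rng.permutation(lab)
        null = _probabilities(_trimmed_means(X, perm, types), tindex, gidx,
                              pairs, senders, receivers, hill_k)
        exceed += null >= obs - 1e-12
    pval = (1.0 + exceed) / (1.0 + n_perms)
    rows = []
    for i, s in enumerate(senders):
        for j, r in enumerate(receivers):
            for k, pair in enumerate(pairs):
                rows.append({"sender": s, "receiver": r, "pair": pair.label,
                             "pathway": pair.pathway,
                             "probability": obs[i, j, k],
                             "p_value": pval[i, j, k],
                             "significant": pval[i, j, k] < alpha})
    return pd.DataFrame(rows)


def vignette_tables(expr: ExprMatrix, labels: pd.Series,
                    lr_db: list[LRPair] | pd.DataFrame,
                    bounds: dict[str, tuple[int, int]] | None = None,
                    n_perms: int = 100, alpha: float = 0.01,
                    hill_k: float = HILL_K, seed: int = 0,
                    senders: list | None = None,
                    receivers: list | None = None) -> dict[str, pd.DataFrame]:
    """Per-vignette interaction tables with permutation significance."""
    bounds = bounds if bounds is not None else SIGNALING_VIGNETTES
    vig = assign_vignette(expr.cell_meta["gestational_week"], bounds)
    out = {}
    for i, name in enumerate(v for v in VIGNETTE_ORDER if v in bounds):
        mask = (vig == name).to_numpy()
        sub = ExprMatrix(expr.values[mask], expr.cell_meta.loc[mask],
                         expr.gene_ids)
        out[name] = permutation_significance(
            sub, labels.loc[sub.cell_ids], lr_db, n_perms=n_perms,
            alpha=alpha, hill_k=hill_k, seed=seed + i,
            senders=senders, receivers=receivers)
    return out


def temporal_compare(expr: ExprMatrix, labels: pd.Series,
                     lr_db: list[LRPair] | pd.DataFrame,
                     tables: dict[str, pd.DataFrame],
                     restrict_senders: set[str] | None = None,
                     bounds: dict[str, tuple[int, int]] | None = None,
                     n_perms: int = 20000, alpha: float = 0.01,
                     hill_k: float = HILL_K, seed: int = 0) -> pd.DataFrame:
    """Early-up / late-up calls for spatially-restricted interactions.

    Candidates are the (sender, receiver, pair) triples that are significant
    in at least one vignette (and whose sender is in ``restrict_senders``,
    when given). For each candidate the vignette-level interaction intensity
    is L_v * R_v, where L_v (R_v) is the mean over the vignette's samples of
    the per-sample 25%-trimmed ligand (receptor) expression in the sender
    (receiver) type; the contrast is delta = log intensity(early) - max of
    log intensity(mid/late). The log scale - equivalently the logit of the
    Hill probability - undoes saturation so strong switches are not
    compressed near probability 1.

    The null permutes the sample-to-vignette assignment: the vignette is a
    sample-level covariate, so samples are the exchangeable unit (permuting
    cells would understate the null variance). One-sided permutation
    p-values for both directions are Holm-adjusted across the whole
    candidate family; ``early_up`` / ``late_up`` require adjusted p < alpha.
    """
    bounds = bounds if bounds is not None else SIGNALING_VIGNETTES
    vnames = [v for v in VIGNETTE_ORDER if v in bounds]
    if len(vnames) < 2:
        raise ValueError("temporal contrast needs >= 2 vignettes")
    pairs = pairs_from_frame(lr_db) if isinstance(lr_db, pd.DataFrame) else list(lr_db)
    pairs = _usable_pairs(pairs, expr.gene_ids)
    pair_by_label = {p.label: p for p in pairs}

    cand: list[tuple[str, str, str]] = []
    for name in vnames:
        tab = tables.get(name)
        if tab is None or tab.empty:
            continue
        for _, row in tab[tab["significant"]].iterrows():
            trip = (row["sender"], row["receiver"], row["pair"])
            if restrict_senders is not None and row["sender"] not in restrict_senders:
                continue
            if trip not in cand and row["pair"] in pair_by_label:
                cand.append(trip)
    if not cand:
        return pd.DataFrame(columns=[
            "sender", "receiver", "pair", "pathway",
            *[f"prob_{v}" for v in vnames], "delta", "p_early", "p_late",
            "adj_p_early", "adj_p_late", "early_up", "late_up"])

    lab = labels.reindex(expr.cell_ids).to_numpy()
    vig = assign_vignette(expr.cell_meta["gestational_week"], bounds) \
        .fillna("").astype(str).to_numpy()
    sample_id = expr.cell_meta["sample_id"].to_numpy()
    samp = pd.DataFrame({"sample_id": sample_id, "vig": vig}) \
        .drop_duplicates("sample_id")
    binned = samp[samp["vig"] != ""]
    samples = binned["sample_id"].to_numpy()
    samp_vig = binned["vig"].to_numpy()
    n_samp = len(samples)
    if n_samp < len(vnames) + 1:
        raise ValueError("too few samples for a sample-level permutation null")

    genes = sorted({g for p in pairs for g in (p.ligand, *p.receptor_subunits)})
    gidx = {g: i for i, g in enumerate(genes)}
    X = expr.values[:, expr.gene_index(genes)]
    types = sorted({s for s, _, _ in cand} | {r for _, r, _ in cand})
    # per-(sample, type) trimmed means of every pair gene, NaN when absent
    tm = np.full((n_samp, len(types), len(genes)), np.nan)
    for si, s in enumerate(samples):
        in_s = sample_id == s
        for ti, t in enumerate(types):
            cells = in_s & (lab == t)
            if cells.any():
                tm[si, ti] = stats.trim_mean(X[cells], TRIM, axis=0)
    type_index = {t: i for i, t in enumerate(types)}

    rng = np.random.default_rng(seed)
    perm_idx = np.vstack([np.arange(n_samp)] + [rng.permutation(n_samp)
                                                for _ in range(n_perms)])
    vmasks = [samp_vig == v for v in vnames]
    eps = 1e-12

    def vignette_values(per_sample: np.ndarray) -> np.ndarray:
        """(n_perms+1, n_vignettes) vignette means; NaN-free (0 if empty)."""
        permuted = per_sample[perm_idx]  # rows: identity first, then perms
        out = np.zeros((permuted.shape[0], len(vnames)))
        for vi, mask in enumerate(vmasks):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[:, vi] = np.nanmean(permuted[:, mask], axis=1)
        return np.nan_to_num(out, nan=0.0)

    rows = []
    all_p: list[float] = []
    for sender, receiver, plabel in cand:
        pair = pair_by_label[plabel]
        Ls = tm[:, type_index[sender], gidx[pair.ligand]]
        Lv = vignette_values(Ls)
        subs = np.stack([vignette_values(tm[:, type_index[receiver], gidx[g]])
                         for g in pair.receptor_subunits])
        Rv = np.exp(np.log(np.maximum(subs, eps)).mean(axis=0))
        Rv[np.any(subs <= 0, axis=0)] = 0.0
        x = Lv * Rv
        z = np.log(np.maximum(x, eps) / hill_k)
        delta = z[:, 0] - z[:, 1:].max(axis=1)
        d_obs, d_null = delta[0], delta[1:]
        p_early = (1.0 + (d_null >= d_obs - 1e-12).sum()) / (1.0 + n_perms)
        p_late = (1.0 + (d_null <= d_obs + 1e-12).sum()) / (1.0 + n_perms)
        probs = x[0] / (hill_k + x[0])
        rows.append({"sender": sender, "receiver": receiver, "pair": plabel,
                     "pathway": pair.pathway,
                     **{f"prob_{v}": probs[i] for i, v in enumerate(vnames)},
                     "delta": d_obs, "p_early": p_early, "p_late": p_late})
        all_p.extend([p_early, p_late])

    adj = multipletests(all_p, method="holm")[1] if all_p else []
    out = pd.DataFrame(rows)
    out["adj_p_early"] = adj[0::2]
    out["adj_p_late"] = adj[1::2]
    out["early_up"] = out["adj_p_early"] < alpha
    out["late_up"] = out["adj_p_late"] < alpha
    return out


# ---------------------------------------------------------------------------
# pathway information flow


def signed_rank_exact_p(diffs: np.ndarray, max_exact_n: int = 25) -> float:
    """Two-sided exact Wilcoxon signed-rank p (tie-aware, zeros dropped).

    Zero differences are discarded; if none remain the test is degenerate
    and p = 1. The exact null distribution of W+ (sum of positive signed
    ranks) over all sign assignments is computed by dynamic programming on
    doubled midranks, so ties are handled exactly. Falls back to a normal
    approximation above ``max_exact_n`` non-zero differences.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    if m > max_exact_n:
        mu = m * (m + 1) / 4.0
        # tie-corrected variance of W+
        _, counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 \
            - ((counts ** 3 - counts).sum()) / 48.0
        z = (w_obs - mu) / np.sqrt(var)
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    r2 = np.rint(2 * ranks).astype(int)  # midranks are multiples of 1/2
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[:-r]
        dist = nxt
    dist /= 2.0 ** m
    w2 = int(round(2 * w_obs))
    p_ge = dist[w2:].sum()
    p_le = dist[: w2 + 1].sum()
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def information_flow(tables: dict[str, pd.DataFrame],
                     min_pathways: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway information flow per vignette and paired signed-rank tests.

    Flow = sum of significant interaction probabilities within a pathway;
    each pair of vignettes is compared by an exact paired Wilcoxon
    signed-rank test over pathways.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 vignettes to compare information flow")
    pathways = sorted({pw for tab in tables.values() if not tab.empty
                       for pw in tab["pathway"].unique()})
    flows = pd.DataFrame(0.0, index=pd.Index(pathways, name="pathway"),
                         columns=list(tables))
    for name, tab in tables.items():
        if tab.empty:
            continue
        sig = tab[tab["significant"]]
        agg = sig.groupby("pathway")["probability"].sum()
        flows.loc[agg.index, name] = agg.to_numpy()
    if len(pathways) < min_pathways:
        warnings.warn(f"only {len(pathways)} pathways; the paired test is "
                      "underpowered")
    names = list(tables)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = (flows[names[j]] - flows[names[i]]).to_numpy()
            rows.append({"vignette_a": names[i], "vignette_b": names[j],
                         "p_value": signed_rank_exact_p(d)})
    return flows, pd.DataFrame(rows)
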