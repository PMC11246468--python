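"""Seeded synthetic developing-lung atlas generator.

Emulates the statistical structure the downstream analyses assume, with
full ground truth for recovery tests:

* cell types with planted marker genes (disjoint marker sets, log-scale
  mean shifts);
* per-sample cell-type composition following constant / linear / quadratic
  trends in gestational week on the logit scale, renormalised across types;
* a branching latent trajectory (ordered cluster paths, e.g.
  progenitor -> transitional -> {ciliated, neuroendocrine}) with
  pseudotime-dependent genes shaped as logistic activations on [0, 1];
* spatially organised niches of cell types on a [0, extent]^2 plane, plus
  grid-spot deconvolution-style weight tables;
* ligand-receptor pairs whose sender-side ligand is active only in a
  chosen gestational vignette.

Counts are negative binomial with gene-specific means and per-sample depth
scaling. Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ConfigError, CountMatrix
from .vignettes import SIGNALING_VIGNETTES, assign_vignette

# ---------------------------------------------------------------------------
# configuration


@dataclass
class CompositionTrend:
    """Logit-scale trend of one type's expected proportion vs centred GW."""

    family: str  # constant | linear | quadratic
    coef: tuple[float, ...]

    def __post_init__(self) -> None:
        n = {"constant": 1, "linear": 2, "quadratic": 3}.get(self.family)
        if n is None:
            raise ConfigError(f"composition_spec: unknown family {self.family!r}")
        if len(self.coef) != n:
            raise ConfigError(
                f"composition_spec: family {self.family!r} needs {n} coefficients")

    def logit(self, t_centered: np.ndarray) -> np.ndarray:
        c = np.zeros(3)
        c[: len(self.coef)] = self.coef
        t = np.asarray(t_centered, dtype=float)
        return c[0] + c[1] * t + c[2] * t ** 2


@dataclass
class TrajectorySpec:
    """Ordered root-to-leaf type paths plus pseudotime-dependent genes."""

    paths: tuple[tuple[str, ...], ...] = (
        ("progenitor", "transitional", "ciliated"),
        ("progenitor", "transitional", "neuroendocrine"),
    )
    n_genes: int = 60
    amplitude: float = 2.0  # log-scale swing of the logistic activation
    width: float = 0.08     # logistic activation width on [0,1] pseudotime


@dataclass
class NicheSpec:
    center: tuple[float, float]
    radius: float
    mixture: dict[str, float]


@dataclass
class SpatialSpec:
    """Niche geometry on a [0, extent]^2 plane (platform-like units)."""

    niches: tuple[NicheSpec, ...] = ()
    n_cells_per_niche: int = 600
    n_background: int = 300
    extent: float = 1000.0
    spot_spacing: float = 100.0
    spot_radius: float = 75.0


@dataclass
class PlantedLR:
    ligand: str
    receptor_subunits: tuple[str, ...]
    pathway: str
    sender: str
    receiver: str
    active_vignette: str | None = None  # None = active in every vignette


@dataclass
class LRSpec:
    pairs: tuple[PlantedLR, ...] = ()
    effect: float = 2.0        # log-scale elevation of planted ligand genes
    receptor_effect: float = 1.5
    n_decoys: int = 8          # unplanted pairs with flat expression


def _default_composition() -> dict[str, CompositionTrend]:
    # coefficients on GW centred at the midpoint of gw_range
    return {
        "progenitor": CompositionTrend("linear", (-1.0, -0.35)),
        "transitional": CompositionTrend("constant", (-1.3,)),
        "ciliated": CompositionTrend("linear", (-1.8, 0.35)),
        "neuroendocrine": CompositionTrend("quadratic", (-1.4, 0.0, -0.08)),
        "stromal": CompositionTrend("constant", (-0.3,)),
    }


def _default_spatial() -> SpatialSpec:
    return SpatialSpec(niches=(
        NicheSpec((300.0, 300.0), 220.0,
                  {"progenitor": 0.45, "transitional": 0.25, "stromal": 0.30}),
        NicheSpec((700.0, 700.0), 220.0,
                  {"ciliated": 0.40, "neuroendocrine": 0.25, "stromal": 0.35}),
    ))


def _default_lr() -> LRSpec:
    return LRSpec(pairs=(
        PlantedLR("FGF7", ("FGFR2",), "FGF", "stromal", "progenitor", "early"),
        PlantedLR("FGF18", ("FGFR2",), "FGF", "stromal", "progenitor", "late"),
        PlantedLR("WNT2", ("FZD2", "LRP5"), "WNT", "stromal", "transitional", None),
        PlantedLR("DLL3", ("NOTCH1",), "NOTCH", "neuroendocrine", "progenitor", None),
    ))


@dataclass
class SimConfig:
    """Study-condition knobs of the synthetic atlas.

    Defaults mirror the design of the emulated study where it states one
    (19 samples spanning integer gestational weeks 10-19; one week per
    sample), and are otherwise sized for fast, well-powered recovery tests.
    """

    n_samples: int = 19
    gw_range: tuple[int, int] = (10, 19)
    n_cells_per_sample: int = 300
    n_genes: int = 600
    cell_types: tuple[str, ...] = (
        "progenitor", "transitional", "ciliated", "neuroendocrine", "stromal")
    markers_per_type: int = 10
    marker_effect: float = 1.5
    composition_spec: dict[str, CompositionTrend] = field(
        default_factory=_default_composition)
    trajectory_spec: TrajectorySpec = field(default_factory=TrajectorySpec)
    spatial_spec: SpatialSpec | None = field(default_factory=_default_spatial)
    lr_spec: LRSpec = field(default_factory=_default_lr)
    n_gw_genes: int = 40       # maturation genes with week-dependent means
    gw_effect: float = 0.5     # log-scale swing of maturation genes over the range
    dispersion: float = 10.0   # NB size parameter; Var = mu + mu^2/dispersion
    depth_sd: float = 0.15     # lognormal sd of per-sample depth factors
    vignette_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(SIGNALING_VIGNETTES))
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name in ("n_samples", "n_cells_per_sample", "n_genes",
                     "markers_per_type"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.gw_range
        if not (10 <= lo <= hi <= 19):
            raise ConfigError("gw_range must lie within 10-19")
        if self.marker_effect < 0:
            raise ConfigError("marker_effect must be >= 0")
        unknown = set(self.composition_spec) - set(self.cell_types)
        if unknown:
            raise ConfigError(f"composition_spec: unknown types {sorted(unknown)}")
        missing = set(self.cell_types) - set(self.composition_spec)
        if missing:
            raise ConfigError(f"composition_spec: missing types {sorted(missing)}")
        for path in self.trajectory_spec.paths:
            for t in path:
                if t not in self.cell_types:
                    raise ConfigError(f"trajectory_spec: unknown type {t!r}")
        if self.spatial_spec is not None:
            for i, niche in enumerate(self.spatial_spec.niches):
                if not niche.mixture:
                    raise ConfigError(f"spatial_spec: niche {i} mixture is empty")
                tot = sum(niche.mixture.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ConfigError(
                        f"spatial_spec: niche {i} mixture sums to {tot}, not 1")
                for t in niche.mixture:
                    if t not in self.cell_types:
                        raise ConfigError(f"spatial_spec: unknown type {t!r}")
        for p in self.lr_spec.pairs:
            if p.sender not in self.cell_types or p.receiver not in self.cell_types:
                raise ConfigError(
                    f"lr_spec: unknown sender/receiver in pair {p.ligand}->{p.receptor_subunits}")
            if p.active_vignette is not None and p.active_vignette not in self.vignette_bounds:
                raise ConfigError(
                    f"lr_spec: unknown vignette {p.active_vignette!r}")
        # marker sets are assigned disjointly by construction, but the gene
        # budget must accommodate them plus trajectory and LR genes
        if self._n_reserved() > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for "
                f"{self._n_reserved()} reserved (marker/trajectory/LR) genes")

    def _lr_gene_names(self) -> list[str]:
        names: list[str] = []
        for p in self.lr_spec.pairs:
            for g in (p.ligand, *p.receptor_subunits):
                if g not in names:
                    names.append(g)
        for i in range(self.lr_spec.n_decoys):
            names.extend([f"LIG{i + 1}", f"REC{i + 1}"])
        return names

    def _n_reserved(self) -> int:
        return (len(self.cell_types) * self.markers_per_type
                + self.trajectory_spec.n_genes + self.n_gw_genes
                + len(self._lr_gene_names()))


# ---------------------------------------------------------------------------
# atlas containers


@dataclass
class SpatialMap:
    """Cell centroids with type labels on the spatial plane."""

    table: pd.DataFrame  # columns: cell_id, x, y, type


@dataclass
class SpotWeights:
    """Spot-level type proportions (rows sum to 1) with spot coordinates."""

    weights: pd.DataFrame  # index spot_id, columns = types
    coords: pd.DataFrame   # index spot_id, columns x, y


@dataclass
class SyntheticAtlas:
    counts: CountMatrix
    truth_markers: dict[str, list[str]]
    truth_pseudotime: pd.Series
    truth_branch: pd.Series
    truth_composition: dict[str, CompositionTrend]
    truth_pt_genes: pd.DataFrame  # gene, sign, midpoint, branch
    truth_gw_genes: pd.DataFrame  # gene, slope (maturation trend)
    lr_truth: pd.DataFrame        # planted pairs incl. active vignette
    lr_database: pd.DataFrame     # planted + decoy pairs (analysis input)
    config: SimConfig
    spatial: SpatialMap | None = None
    spot_weights: SpotWeights | None = None


# ---------------------------------------------------------------------------
# gene architecture


@dataclass
class _GeneModel:
    gene_ids: pd.Index
    base_mean: np.ndarray
    markers: dict[str, list[str]]
    pt_genes: pd.DataFrame        # index gene, columns sign, midpoint, branch
    gw_genes: pd.DataFrame        # index gene, column slope (log per unit z)
    lr_gene_idx: dict[str, int]


def _build_genes(config: SimConfig, rng: np.random.Generator) -> _GeneModel:
    names: list[str] = []
    markers: dict[str, list[str]] = {}
    for t in config.cell_types:
        markers[t] = [f"MK-{t}-{i + 1}" for i in range(config.markers_per_type)]
        names.extend(markers[t])
    pt_names = [f"PT-{i + 1}" for i in range(config.trajectory_spec.n_genes)]
    names.extend(pt_names)
    gw_names = [f"GW-{i + 1}" for i in range(config.n_gw_genes)]
    names.extend(gw_names)
    lr_names = config._lr_gene_names()
    names.extend(lr_names)
    n_bg = config.n_genes - len(names)
    names.extend(f"G{i + 1:04d}" for i in range(n_bg))
    gene_ids = pd.Index(names, name="gene_id")

    # baseline means: background genes around 0.6 counts/cell so median
    # library depth clears the 200-detected-gene QC floor with margin;
    # marker/trajectory/receptor genes are well-expressed (median 1.5) so
    # their signal survives shallow sampling; ligand genes sit lower
    # (median 0.8) so a vignette-specific elevation shifts the cell's total
    # library by ~1%, keeping normalisation closure effects negligible
    base = np.exp(rng.normal(np.log(0.6), 0.8, size=config.n_genes))
    is_reserved = np.zeros(config.n_genes, dtype=bool)
    is_reserved[: config._n_reserved()] = True
    base[is_reserved] = np.exp(rng.normal(np.log(1.5), 0.25, size=is_reserved.sum()))
    # markers model canonical, robustly expressed genes: tight baseline around
    # 3 counts/cell so a unit log-effect is detectable in single cells even
    # for cells sitting in the smooth on/off transition zones
    n_marker_genes = len(config.cell_types) * config.markers_per_type
    base[:n_marker_genes] = np.exp(
        rng.normal(np.log(3.0), 0.15, size=n_marker_genes))
    ligands = [p.ligand for p in config.lr_spec.pairs]
    ligands += [f"LIG{i + 1}" for i in range(config.lr_spec.n_decoys)]
    lig_idx = gene_ids.get_indexer(pd.Index(ligands).unique())
    base[lig_idx] = np.exp(rng.normal(np.log(0.8), 0.25, size=len(lig_idx)))

    n_pt = len(pt_names)
    signs = np.where(np.arange(n_pt) % 2 == 0, 1.0, -1.0)
    midpoints = np.linspace(0.15, 0.85, n_pt) if n_pt > 1 else np.array([0.5])
    # genes activating past the bifurcation are branch-specific, so the
    # branches diverge in expression space (a Y, not a chain)
    leaves = list(dict.fromkeys(p[-1] for p in config.trajectory_spec.paths))
    branch = np.array(["all"] * n_pt, dtype=object)
    late = np.flatnonzero(midpoints > 0.55)
    if len(leaves) > 1:
        for i, gi in enumerate(late):
            branch[gi] = leaves[i % len(leaves)]
            signs[gi] = 1.0  # branch genes are activations within their branch
    pt_genes = pd.DataFrame({"sign": signs, "midpoint": midpoints,
                             "branch": branch},
                            index=pd.Index(pt_names, name="gene"))
    # maturation genes: smooth log-linear dependence on gestational week in
    # every cell; alternating signs keep the total library roughly flat
    n_gw = config.n_gw_genes
    gw_slopes = (np.where(np.arange(n_gw) % 2 == 0, 1.0, -1.0)
                 * config.gw_effect
                 * np.linspace(0.5, 1.5, n_gw if n_gw else 1)[:n_gw])
    gw_genes = pd.DataFrame({"slope": gw_slopes},
                            index=pd.Index(gw_names, name="gene"))
    lr_idx = {g: gene_ids.get_loc(g) for g in lr_names}
    return _GeneModel(gene_ids, base, markers, pt_genes, gw_genes, lr_idx)


MARKER_RAMP_WIDTH = 0.02  # pseudotime width of marker on/off transitions


def _log_mean_matrix(config: SimConfig, genes: _GeneModel,
                     cell_type: np.ndarray, tau: np.ndarray,
                     vignette: np.ndarray, cell_branch: np.ndarray,
                     gw: np.ndarray) -> np.ndarray:
    """Per-cell per-gene log mean (before depth scaling).

    Trajectory-type markers ramp on and off smoothly in pseudotime around
    the type's interval (differentiation is a continuum, so expression must
    not jump at the discretised type boundaries); markers of types off the
    trajectory switch with the type label.
    """
    n = len(cell_type)
    logmu = np.tile(np.log(genes.base_mean), (n, 1))
    # maturation genes: log-linear in standardised gestational week
    if len(genes.gw_genes):
        lo, hi = config.gw_range
        z = (np.asarray(gw, dtype=float) - (lo + hi) / 2.0) / max((hi - lo) / 2.0, 1)
        cols = genes.gene_ids.get_indexer(genes.gw_genes.index)
        logmu[:, cols] += z[:, None] * genes.gw_genes["slope"].to_numpy()[None, :]
    type_arr = np.asarray(cell_type)
    intervals = _type_intervals(config.trajectory_spec)
    on_traj = np.isfinite(tau)
    cbranch = np.asarray(cell_branch, dtype=object)
    w = MARKER_RAMP_WIDTH
    for t, mk in genes.markers.items():
        cols = genes.gene_ids.get_indexer(mk)
        if t in intervals:
            a, b, br = intervals[t]
            eligible = on_traj & ((cbranch == br) | (cbranch == "trunk")
                                  | (br == "trunk"))
            if not eligible.any():
                continue
            ramp = np.ones(int(eligible.sum()))
            tt = tau[eligible]
            if a > 0:
                ramp = ramp * expit((tt - a) / w)
            if b < 1:
                ramp = ramp * expit((b - tt) / w)
            logmu[np.ix_(eligible, cols)] += config.marker_effect * ramp[:, None]
        else:
            rows = type_arr == t
            if rows.any():
                logmu[np.ix_(rows, cols)] += config.marker_effect
    # pseudotime-dependent genes: logistic activation along [0,1]; genes
    # tagged with a branch activate on that branch and, by continuity of
    # the logistic profile, also in the shared trunk
    spec = config.trajectory_spec
    if on_traj.any() and len(genes.pt_genes):
        cols = genes.gene_ids.get_indexer(genes.pt_genes.index)
        z = (tau[on_traj, None] - genes.pt_genes["midpoint"].to_numpy()[None, :])
        act = expit(genes.pt_genes["sign"].to_numpy()[None, :] * z / spec.width)
        gbranch = genes.pt_genes["branch"].to_numpy()[None, :]
        cb = cbranch[on_traj, None]
        act = act * ((gbranch == "all") | (gbranch == cb) | (cb == "trunk"))
        logmu[np.ix_(on_traj, cols)] += spec.amplitude * act
    # planted ligand/receptor elevation
    vig = pd.Series(vignette).fillna("").astype(str).to_numpy()
    for p in config.lr_spec.pairs:
        send = type_arr == p.sender
        if p.active_vignette is not None:
            send = send & (vig == p.active_vignette)
        if send.any():
            logmu[send, genes.lr_gene_idx[p.ligand]] += config.lr_spec.effect
        recv = type_arr == p.receiver
        if recv.any():
            for sub in p.receptor_subunits:
                logmu[recv, genes.lr_gene_idx[sub]] += config.lr_spec.receptor_effect
    return logmu


def _sample_counts(logmu: np.ndarray, dispersion: float,
                   rng: np.random.Generator) -> np.ndarray:
    mu = np.exp(logmu)
    lam = rng.gamma(dispersion, mu / dispersion)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# trajectory truth


def _type_intervals(spec: TrajectorySpec) -> dict[str, tuple[float, float, str]]:
    """Pseudotime interval and branch label for every type on the trajectory.

    Types on a single path take that path's leaf as branch label; types
    shared by several paths are labelled 'trunk'.
    """
    out: dict[str, tuple[float, float, str]] = {}
    membership: dict[str, set[str]] = {}
    for path in spec.paths:
        for t in path:
            membership.setdefault(t, set()).add(path[-1])
    for path in spec.paths:
        L = len(path)
        for d, t in enumerate(path):
            if t in out:
                continue
            branch = path[-1] if len(membership[t]) == 1 else "trunk"
            out[t] = (d / L, (d + 1) / L, branch)
    return out


# ---------------------------------------------------------------------------
# public operations


def expected_proportions(config: SimConfig, gw: np.ndarray) -> pd.DataFrame:
    """Expected (renormalised) type proportions at the given weeks."""
    lo, hi = config.gw_range
    center = (lo + hi) / 2.0
    t = np.asarray(gw, dtype=float) - center
    raw = np.column_stack([
        expit(config.composition_spec[ct].logit(t)) for ct in config.cell_types])
    raw /= raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(raw, columns=list(config.cell_types), index=gw)


def make_atlas(config: SimConfig | None = None) -> SyntheticAtlas:
    """Generate the full synthetic atlas (deterministic given config.seed)."""
    config = config if config is not None else SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _build_genes(config, rng)

    lo, hi = config.gw_range
    weeks = np.arange(lo, hi + 1)
    sample_gw = np.sort(weeks[np.arange(config.n_samples) % len(weeks)])
    props = expected_proportions(config, sample_gw).to_numpy()
    intervals = _type_intervals(config.trajectory_spec)

    blocks, metas = [], []
    for s in range(config.n_samples):
        gw = int(sample_gw[s])
        sid = f"S{s + 1:02d}"
        n_by_type = rng.multinomial(config.n_cells_per_sample, props[s])
        ctype = np.repeat(list(config.cell_types), n_by_type)
        rng.shuffle(ctype)
        n = len(ctype)
        tau = np.full(n, np.nan)
        branch = np.array([""] * n, dtype=object)
        for t, (a, b, br) in intervals.items():
            rows = ctype == t
            tau[rows] = rng.uniform(a, b, rows.sum())
            branch[rows] = br
        vig = assign_vignette(np.full(n, gw), config.vignette_bounds).to_numpy()
        logmu = _log_mean_matrix(config, genes, ctype, tau, vig, branch,
                                 np.full(n, gw))
        depth = rng.lognormal(0.0, config.depth_sd)
        blocks.append(_sample_counts(logmu + np.log(depth), config.dispersion, rng))
        metas.append(pd.DataFrame({
            "sample_id": sid,
            "gestational_week": gw,
            "true_type": ctype,
            "true_pseudotime": tau,
            "true_branch": branch,
        }, index=pd.Index([f"{sid}-c{i + 1:04d}" for i in range(n)], name="cell_id")))

    counts = CountMatrix(np.vstack(blocks), pd.concat(metas), genes.gene_ids)
    lr_truth = pd.DataFrame([dataclasses.asdict(p) for p in config.lr_spec.pairs])
    atlas = SyntheticAtlas(
        counts=counts,
        truth_markers=genes.markers,
        truth_pseudotime=counts.cell_meta["true_pseudotime"],
        truth_branch=counts.cell_meta["true_branch"],
        truth_composition=dict(config.composition_spec),
        truth_pt_genes=genes.pt_genes.reset_index(),
        truth_gw_genes=genes.gw_genes.reset_index(),
        lr_truth=lr_truth,
        lr_database=lr_database(config),
        config=config,
    )
    if config.spatial_spec is not None and config.spatial_spec.niches:
        atlas.spatial, atlas.spot_weights = make_spatial(atlas, config)
    return atlas


def lr_database(config: SimConfig) -> pd.DataFrame:
    """Ligand-receptor-pathway table: planted pairs plus flat decoy pairs."""
    rows = [{"ligand": p.ligand,
             "receptor_subunits": ";".join(p.receptor_subunits),
             "pathway": p.pathway} for p in config.lr_spec.pairs]
    decoy_paths = ["BMP", "TGFb", "SHH", "EGF"]
    for i in range(config.lr_spec.n_decoys):
        rows.append({"ligand": f"LIG{i + 1}",
                     "receptor_subunits": f"REC{i + 1}",
                     "pathway": decoy_paths[i % len(decoy_paths)]})
    return pd.DataFrame(rows)


def make_spatial(atlas: SyntheticAtlas, config: SimConfig | None = None
                 ) -> tuple[SpatialMap, SpotWeights]:
    """Place typed cells in niches and derive grid-spot weight tables.

    Cells of niche-enriched types are dense inside their niche (uniform on
    the niche disc); background cells are uniform over the plane with a
    uniform type mixture. Spot weights are local type proportions within
    ``spot_radius`` of each grid spot; empty spots are dropped.
    """
    config = config if config is not None else atlas.config
    spec = config.spatial_spec
    if spec is None or not spec.niches:
        raise ConfigError("spatial_spec: no niches configured")
    for i, niche in enumerate(spec.niches):
        if not niche.mixture:
            raise ConfigError(f"spatial_spec: niche {i} mixture is empty")
    rng = np.random.default_rng([config.seed, 7919])

    xs, ys, types = [], [], []
    for niche in spec.niches:
        tnames = list(niche.mixture)
        probs = np.array([niche.mixture[t] for t in tnames])
        draws = rng.choice(len(tnames), size=spec.n_cells_per_niche, p=probs)
        r = niche.radius * np.sqrt(rng.uniform(size=spec.n_cells_per_niche))
        th = rng.uniform(0, 2 * np.pi, size=spec.n_cells_per_niche)
        xs.append(niche.center[0] + r * np.cos(th))
        ys.append(niche.center[1] + r * np.sin(th))
        types.append(np.array(tnames, dtype=object)[draws])
    if spec.n_background > 0:
        xs.append(rng.uniform(0, spec.extent, spec.n_background))
        ys.append(rng.uniform(0, spec.extent, spec.n_background))
        types.append(rng.choice(np.array(config.cell_types, dtype=object),
                                size=spec.n_background))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ctype = np.concatenate(types)
    table = pd.DataFrame({
        "cell_id": [f"sp-c{i + 1:05d}" for i in range(len(x))],
        "x": x, "y": y, "type": ctype})
    smap = SpatialMap(table)

    # grid spots: local type proportions within spot_radius
    grid = np.arange(spec.spot_spacing / 2, spec.extent, spec.spot_spacing)
    gx, gy = np.meshgrid(grid, grid)
    gx, gy = gx.ravel(), gy.ravel()
    tlist = list(config.cell_types)
    tcode = pd.Categorical(ctype, categories=tlist).codes
    rows, coords, ids = [], [], []
    for i in range(len(gx)):
        d2 = (x - gx[i]) ** 2 + (y - gy[i]) ** 2
        near = d2 <= spec.spot_radius ** 2
        if not near.any():
            continue
        cnt = np.bincount(tcode[near], minlength=len(tlist)).astype(float)
        rows.append(cnt / cnt.sum())
        coords.append((gx[i], gy[i]))
        ids.append(f"spot-{i + 1:04d}")
    idx = pd.Index(ids, name="spot_id")
    weights = SpotWeights(
        weights=pd.DataFrame(rows, index=idx, columns=tlist),
        coords=pd.DataFrame(coords, index=idx, columns=["x", "y"]))
    return smap, weights


def make_query(config: SimConfig, n_cells: int, gw: int,
               type_weights: dict[str, float] | None = None,
               tau_range: tuple[float, float] | None = None,
               seed: int = 0, sample_id: str = "query") -> CountMatrix:
    """Draw a query (organoid-like) dataset from the reference generative model.

    ``type_weights`` fixes the type mixture (default: the reference's expected
    mixture at ``gw``); ``tau_range`` optionally clips trajectory pseudotimes
    to a window, emulating cultures that only reach part of the trajectory.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 104729, seed])
    genes = _build_genes(config, np.random.default_rng(config.seed))
    if type_weights is None:
        w = expected_proportions(config, np.array([gw])).iloc[0]
        type_weights = w.to_dict()
    tnames = list(type_weights)
    probs = np.array([type_weights[t] for t in tnames], dtype=float)
    probs /= probs.sum()
    ctype = np.array(tnames, dtype=object)[rng.choice(len(tnames), n_cells, p=probs)]
    intervals = _type_intervals(config.trajectory_spec)
    tau = np.full(n_cells, np.nan)
    branch = np.array([""] * n_cells, dtype=object)
    for t, (a, b, br) in intervals.items():
        rows = ctype == t
        if tau_range is not None:
            a, b = max(a, tau_range[0]), min(b, tau_range[1])
            if a >= b:
                a, b = tau_range
        tau[rows] = rng.uniform(a, b, rows.sum())
        branch[rows] = br
    vig = assign_vignette(np.full(n_cells, gw), config.vignette_bounds).to_numpy()
    logmu = _log_mean_matrix(config, genes, ctype, tau, vig, branch,
                             np.full(n_cells, gw))
    counts = _sample_counts(logmu, config.dispersion, rng)
    meta = pd.DataFrame({
        "sample_id": sample_id, "gestational_week": gw,
        "true_type": ctype, "true_pseudotime": tau,
    }, index=pd.Index([f"{sample_id}-c{i + 1:05d}" for i in range(n_cells)],
                      name="cell_id"))
    return CountMatrix(counts, meta, genes.gene_ids)


def simulate_composition_counts(family: str, coef: tuple[float, ...],
                                n_samples: int = 19,
                                gw_range: tuple[int, int] = (10, 19),
                                n_total: int = 5000,
                                seed: int = 0) -> pd.DataFrame:
    """Binomial counts of one focal type under a planted logit trend.

    Weeks are assigned round-robin over ``gw_range``; coefficients act on GW
    centred at the midpoint of the range. Returns columns
    (sample_id, gestational_week, n_type, n_total).
    """
    rng = np.random.default_rng(seed)
    trend = CompositionTrend(family, tuple(coef))
    lo, hi = gw_range
    weeks = np.arange(lo, hi + 1)
    gw = np.sort(weeks[np.arange(n_samples) % len(weeks)])
    p = expit(trend.logit(gw - (lo + hi) / 2.0))
    y = rng.binomial(n_total, p)
    return pd.DataFrame({
        "sample_id": [f"S{i + 1:02d}" for i in range(n_samples)],
        "gestational_week": gw, "n_type": y, "n_total": n_total})
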