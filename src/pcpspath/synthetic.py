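"""Synthetic biogeographic worlds with known causal structure.

The generator emulates the data model of a continental-scale threatened
species analysis: a pure-birth phylogeny whose tips carry climatic niche
optima evolved by Brownian motion, a latitudinal climate gradient with
per-site mean/range summaries, Dirichlet land-use (anthrome) covers
coupled to climate, incidence ranges drawn from Gaussian niche kernels,
and IUCN threat categories produced by thresholding a latent threat
score with known coefficients for endemism, village-cover exposure and
richness. Because the generating coefficients are known, the full
pipeline can be exercised end-to-end as a parameter-recovery experiment.

The whole world is a pure function of ``(WorldConfig, seed)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .datatypes import (
    ANTHROME_COLUMNS,
    CLIMATE_VARIABLES,
    CompositionMatrix,
    PhylogenyBundle,
    SiteAttributes,
    ThreatTable,
    ValidationError,
)

#: latitudinal-gradient loading of each of the nine climate variables
_GRADIENT_LOADINGS = {
    "altitude": 0.3,
    "annual_mean_temperature": -1.0,
    "temperature_seasonality": 0.9,
    "max_temperature_warmest_month": -0.7,
    "min_temperature_coldest_month": -1.0,
    "annual_mean_rainfall": -0.8,
    "rainfall_seasonality": 0.4,
    "precipitation_wettest_month": -0.7,
    "precipitation_driest_month": -0.6,
}

#: baseline Dirichlet concentrations, urban .. wild
_ANTHROME_BASE = np.array([0.05, 0.13, 0.13, 0.13, 0.2, 0.3])

#: bounds of the log-uniform expected-range-size scale (in sites)
_TARGET_SITES_MIN = 0.25
_TARGET_SITES_MAX_FRACTION = 0.5

#: below this expected range size (sites) a species counts as narrow-ranged
_NARROW_SITES = 6.0

#: niche breadth multiplier floor for the narrowest-ranged species;
#: smaller values concentrate endemism into sharper hotspots
_NARROW_BREADTH_FLOOR = 0.15

#: log-scale sd of the per-site suitability (richness) lognormal;
#: continental richness spans orders of magnitude, so this is large
_RICHNESS_LOGSD = 0.7

#: microendemism hotspots ride the suitability gradient (rich regions
#: also hold the narrow-ranged species) with an extra lognormal factor
#: for topographic complexity
_HOTSPOT_SUITABILITY_EXP = 1.8
_HOTSPOT_LOGSD = 1.4


@dataclass(frozen=True)
class WorldConfig:
    """Generating conditions of a synthetic world.

    Effect sizes are on the unit-noise latent threat scale; the defaults
    are the strong-effect conditions used by the recovery experiments.
    """

    n_sites: int = 120
    n_species: int = 400
    n_genera: int = 40
    climate_gradient_strength: float = 1.0
    niche_breadth: float = 1.0
    phylo_signal: float = 1.0
    landuse_coupling: float = 1.0
    b_endemic: float = 10.0
    b_village: float = 26.0
    b_richness: float = 1.2
    category_thresholds: tuple[float, ...] = (7.4, 8.2, 9.0, 9.8)
    deep_split: float = 0.5
    n_subsamples: int = 8
    max_redraws: int = 200

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_species < 2 or self.n_genera < 2:
            raise ValidationError("all counts must be >= 2")
        if self.n_genera > self.n_species:
            raise ValidationError("n_genera must not exceed n_species")
        t = self.category_thresholds
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValidationError("category thresholds must be strictly increasing")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated world, for parameter-recovery tests."""

    config: WorldConfig
    seed: int | None
    niche_optima: pd.Series = field(default_factory=pd.Series)
    latent_threat: pd.Series = field(default_factory=pd.Series)
    village_exposure: pd.Series = field(default_factory=pd.Series)
    site_warmth: pd.Series = field(default_factory=pd.Series)


@dataclass
class SyntheticWorld:
    W: CompositionMatrix
    phylogeny: PhylogenyBundle
    attributes: SiteAttributes
    threats: ThreatTable
    truth: SyntheticTruth


def _species_labels(n: int) -> list[str]:
    return [f"sp_{i + 1:04d}" for i in range(n)]


def simulate_tree(cfg: WorldConfig, rng: np.random.Generator) -> PhylogenyBundle:
    """Pure-birth (Yule) topology with unit branch lengths.

    Tips in ladderized leaf order are partitioned into ``n_genera``
    contiguous blocks serving as the genus/clade map.
    """
    # grow a binary topology by splitting uniformly chosen leaves
    children: dict[int, list[int]] = {0: []}
    leaves = [0]
    next_id = 1
    while len(leaves) < cfg.n_species:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        kids = [next_id, next_id + 1]
        next_id += 2
        children[node] = kids
        for k in kids:
            children[k] = []
        leaves.extend(kids)

    labels = _species_labels(cfg.n_species)
    label_of: dict[int, str] = {}
    order: list[int] = []

    def _collect(node: int) -> None:
        if not children[node]:
            order.append(node)
        else:
            for k in children[node]:
                _collect(k)

    _collect(0)
    for node, lbl in zip(order, labels):
        label_of[node] = lbl

    def _newick(node: int) -> str:
        if not children[node]:
            return f"{label_of[node]}:1"
        inner = ",".join(_newick(k) for k in children[node])
        return f"({inner}):1"

    newick = _newick(0) + ";"
    # contiguous blocks of tips in leaf order become genera
    bounds = np.linspace(0, cfg.n_species, cfg.n_genera + 1).astype(int)
    clade_map = {}
    for g in range(cfg.n_genera):
        for i in range(bounds[g], bounds[g + 1]):
            clade_map[labels[i]] = f"genus_{g + 1:03d}"
    return pio.read_tree_string(newick, clade_map)


def simulate_sites_and_climate(
    cfg: WorldConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Site geography plus 18 climate summaries.

    Latitudes sit on a jittered grid; nine latent climate variables are
    linear latitudinal gradients plus an independent continentality
    factor and site noise; per-site subsamples yield mean and range.
    Returns the attribute columns (without anthromes) and the latent
    warmth score used to couple land use and niches to climate.
    """
    if cfg.n_sites < 5:
        raise ValidationError("need at least 5 sites")
    sites = [f"site_{i + 1:03d}" for i in range(cfg.n_sites)]
    lat = np.linspace(-55, 55, cfg.n_sites) + rng.uniform(-1, 1, cfg.n_sites)
    lon = rng.uniform(-120, -35, cfg.n_sites)
    area = np.exp(rng.normal(11.0, 1.0, cfg.n_sites))
    latn = lat / 55.0
    continentality = rng.normal(0, 1, cfg.n_sites)

    cols: dict[str, np.ndarray] = {}
    latent: dict[str, np.ndarray] = {}
    # within-site spread grows toward the poles (stronger seasonality)
    within_sd = np.exp(-0.7 + 0.6 * np.abs(latn) + 0.3 * rng.normal(0, 1, cfg.n_sites))
    for var in CLIMATE_VARIABLES:
        g = _GRADIENT_LOADINGS[var]
        base = (
            g * cfg.climate_gradient_strength * latn
            + 0.3 * continentality
            + 0.25 * rng.normal(0, 1, cfg.n_sites)
        )
        latent[var] = base
        sub = base[:, None] + within_sd[:, None] * rng.normal(
            0, 1, (cfg.n_sites, cfg.n_subsamples)
        )
        cols[f"{var}_mean"] = sub.mean(axis=1)
        cols[f"{var}_range"] = sub.max(axis=1) - sub.min(axis=1)

    table = pd.DataFrame(
        {"latitude": lat, "longitude": lon, "area": area, **cols}, index=sites
    )
    warm = latent["annual_mean_temperature"] - latent["temperature_seasonality"]
    warm = (warm - warm.mean()) / max(warm.std(), 1e-12)
    return table, pd.Series(warm, index=sites, name="warmth")


def _brownian_optima(
    phy: PhylogenyBundle, rate: float, rng: np.random.Generator
) -> pd.Series:
    """Brownian-motion tip values on the unit-branch-length tree."""
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            step = rng.normal(0.0, np.sqrt(max(rate, 0.0)))
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out)


def simulate_ranges(
    cfg: WorldConfig,
    phy: PhylogenyBundle,
    site_climate: pd.Series,
    rng: np.random.Generator,
) -> tuple[CompositionMatrix, pd.Series]:
    """Incidence matrix from Gaussian niche kernels around evolved optima.

    Each species' climatic optimum evolves by Brownian motion on the
    tree; its occurrence probability at a site is a Gaussian kernel of
    the site's (standardized) climate around the (standardized) optimum,
    scaled by a species-specific prevalence. Prevalence itself evolves on
    the tree (an independent Brownian trait rank-mapped onto a
    log-uniform scale), so whole clades of narrow-ranged species share
    similar niche optima and endemism concentrates in hotspots, as in
    real assemblages. Empty rows/columns are re-drawn up to
    ``max_redraws`` times.
    """
    taxa = phy.taxa
    optima = _brownian_optima(phy, cfg.phylo_signal, rng).loc[taxa]
    o = optima.to_numpy()
    o_std = o.std()
    oz = (o - o.mean()) / o_std if o_std > 1e-12 else np.zeros_like(o)
    # deep climatic divergence between the two root clades (think
    # anurans vs salamanders): ``deep_split`` is the fraction of niche
    # optimum variance carried by the root split, so the broadest
    # phylogenetic gradient tracks climate turnover
    if cfg.deep_split > 0:
        root_kids = phy.tree.seed_node.child_nodes()
        if len(root_kids) >= 2:
            first_clade = {
                leaf.taxon.label for leaf in root_kids[0].leaf_iter()
            }
            side = np.where(
                optima.index.to_series().isin(first_clade), 1.0, -1.0
            )
            side -= side.mean()
            s_std = side.std()
            if s_std > 1e-12:
                oz = (
                    np.sqrt(cfg.deep_split) * side / s_std
                    + np.sqrt(1.0 - cfg.deep_split) * oz
                )
    c = site_climate.to_numpy()
    cz = (c - c.mean()) / max(c.std(), 1e-12)

    prev_trait = _brownian_optima(phy, 1.0, rng).loc[taxa]
    u = prev_trait.rank(method="first").to_numpy() / (len(taxa) + 1)
    # expected range size (in sites) is log-uniform between a fraction of
    # one site and half the landscape, independent of landscape size
    sites_target = np.exp(
        np.log(_TARGET_SITES_MIN)
        + u * (np.log(_TARGET_SITES_MAX_FRACTION * len(cz)) - np.log(_TARGET_SITES_MIN))
    )
    prevalence = sites_target / len(cz)
    # narrow-ranged species are also climate specialists: niche breadth
    # shrinks with prevalence, concentrating endemism into hotspots
    breadth = cfg.niche_breadth * (
        _NARROW_BREADTH_FLOOR + (1.0 - _NARROW_BREADTH_FLOOR) * u
    )
    kernel = np.exp(
        -((cz[:, None] - oz[None, :]) ** 2) / (2 * breadth[None, :] ** 2)
    )
    probs = prevalence[None, :] * kernel
    # Widespread species are rescaled by a log-normal per-site suitability,
    # so richness is not confounded with the climatic turnover gradient;
    # narrow-ranged species keep their raw kernel probabilities, so
    # endemism hotspots follow clade niche clustering, not site richness.
    wide = sites_target >= _NARROW_SITES
    target_richness = np.exp(
        rng.normal(np.log(0.08 * len(taxa)), _RICHNESS_LOGSD, len(cz))
    )
    wide_sum = np.maximum(probs[:, wide].sum(axis=1), 1e-12)
    probs[:, wide] *= (target_richness / wide_sum)[:, None]
    # microendemism hotspots: narrow species co-occur at rich,
    # high-complexity sites, so per-site endemism is overdispersed and
    # concentrated where richness is high, as in real assemblages
    rel_suit = target_richness / np.exp(np.log(target_richness).mean())
    hotspot = rel_suit**_HOTSPOT_SUITABILITY_EXP * np.exp(
        rng.normal(-0.5 * _HOTSPOT_LOGSD**2, _HOTSPOT_LOGSD, len(cz))
    )
    probs[:, ~wide] *= hotspot[:, None]
    probs = np.clip(probs, 0.0, 0.95)

    inc = (rng.random(probs.shape) < probs).astype(float)
    for it in range(cfg.max_redraws + 1):
        empty_cols = np.flatnonzero(inc.sum(axis=0) == 0)
        empty_rows = np.flatnonzero(inc.sum(axis=1) == 0)
        if empty_cols.size == 0 and empty_rows.size == 0:
            break
        if it == cfg.max_redraws:
            # a species whose optimum sits at the climatic margin may have
            # vanishing total occupancy probability: anchor it at one site
            # drawn in proportion to its probability profile
            for j in empty_cols:
                total = probs[:, j].sum()
                if total <= 0:
                    raise ValidationError(
                        "species with zero occupancy probability everywhere; "
                        "increase niche_breadth or prevalence"
                    )
                site = rng.choice(inc.shape[0], p=probs[:, j] / total)
                inc[site, j] = 1.0
            if np.flatnonzero(inc.sum(axis=1) == 0).size:
                raise ValidationError(
                    "could not fill empty sites within the redraw bound; "
                    "increase niche_breadth or prevalence"
                )
            break
        if empty_cols.size:
            inc[:, empty_cols] = (
                rng.random((inc.shape[0], empty_cols.size)) < probs[:, empty_cols]
            ).astype(float)
        if empty_rows.size:
            inc[empty_rows, :] = (
                rng.random((empty_rows.size, inc.shape[1])) < probs[empty_rows, :]
            ).astype(float)
    W = CompositionMatrix(
        pd.DataFrame(inc, index=site_climate.index, columns=taxa)
    )
    return W, optima


def simulate_landuse(
    cfg: WorldConfig, warmth: pd.Series, rng: np.random.Generator
) -> pd.DataFrame:
    """Dirichlet anthrome covers tilted toward villages/croplands when warm.

    The concentration of the villages and croplands components is
    multiplied by ``exp(landuse_coupling * warmth)`` (and the wild
    component by its inverse), so covers are coupled to climate with the
    configured strength; each site's six proportions sum to 1 exactly.
    """
    w = warmth.to_numpy()
    alpha = np.tile(_ANTHROME_BASE, (len(w), 1))
    tilt = np.exp(cfg.landuse_coupling * w)
    alpha[:, 1] *= tilt                 # villages
    alpha[:, 2] *= np.sqrt(tilt)        # croplands, weaker coupling
    alpha[:, 5] /= tilt                 # wild
    covers = np.vstack([rng.dirichlet(a) for a in alpha])
    return pd.DataFrame(covers, index=warmth.index, columns=list(ANTHROME_COLUMNS))


def assign_threat(
    cfg: WorldConfig,
    W: CompositionMatrix,
    landuse: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ThreatTable, pd.DataFrame]:
    """Threshold a latent threat score into IUCN categories.

    latent_i = b_endemic * 1[range size = 1]
             + b_village * mean village cover over occupied sites
             + b_richness * z(mean richness over occupied sites)
             + N(0, 1)

    The score is cut at ``category_thresholds`` into LC < NT < VU < EN <
    CR; EW and EX are not generated by default.
    """
    inc = W.values.to_numpy()
    range_size = inc.sum(axis=0)
    endemic = (range_size == 1).astype(float)
    village = landuse["villages"].to_numpy()
    richness = inc.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vill_exp = (inc * village[:, None]).sum(axis=0) / range_size
        rich_exp = (inc * richness[:, None]).sum(axis=0) / range_size
    rz = (rich_exp - rich_exp.mean()) / max(rich_exp.std(), 1e-12)
    noise = rng.normal(0, 1, inc.shape[1])
    latent = (
        cfg.b_endemic * endemic
        + cfg.b_village * vill_exp
        + cfg.b_richness * rz
        + noise
    )
    cats = np.full(inc.shape[1], "CR", dtype=object)
    names = ("LC", "NT", "VU", "EN")
    for name, cut in zip(names[::-1], cfg.category_thresholds[::-1]):
        cats[latent < cut] = name
    table = ThreatTable.from_series(pd.Series(cats, index=W.taxa))
    detail = pd.DataFrame(
        {"latent": latent, "endemic": endemic, "village_exposure": vill_exp,
         "richness_exposure": rz, "category": cats},
        index=W.taxa,
    )
    return table, detail


def generate_world(cfg: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete world; a pure function of ``(cfg, seed)``."""
    cfg = cfg or WorldConfig()
    rng = np.random.default_rng(seed)
    phy = simulate_tree(cfg, rng)
    attr_table, warmth = simulate_sites_and_climate(cfg, rng)
    W, optima = simulate_ranges(cfg, phy, warmth, rng)
    landuse = simulate_landuse(cfg, warmth, rng)
    threats, detail = assign_threat(cfg, W, landuse, rng)
    attrs = SiteAttributes.from_dataframe(attr_table.join(landuse))
    truth = SyntheticTruth(
        config=cfg,
        seed=seed,
        niche_optima=optima,
        latent_threat=detail["latent"],
        village_exposure=detail["village_exposure"],
        site_warmth=warmth,
    )
    return SyntheticWorld(W, phy, attrs, threats, truth)


def write_world(world: SyntheticWorld, out_dir) -> dict[str, str]:
    """Write a world in the canonical input formats (CSV + newick)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "composition": os.path.join(out_dir, "composition.csv"),
        "tree": os.path.join(out_dir, "tree.nwk"),
        "threats": os.path.join(out_dir, "threats.csv"),
        "site_attributes": os.path.join(out_dir, "site_attributes.csv"),
        "clade_map": os.path.join(out_dir, "clade_map.csv"),
    }
    pio.write_composition(world.W, paths["composition"])
    pio.write_tree(world.phylogeny, paths["tree"])
    pio.write_threats(world.threats, paths["threats"])
    pio.write_site_attributes(world.attributes, paths["site_attributes"])
    pio.write_clade_map(world.phylogeny.taxon_to_clade, paths["clade_map"])
    return paths
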