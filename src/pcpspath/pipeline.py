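"""End-to-end orchestration: diversity -> PCPS -> climate -> path analysis.

One run takes the four validated inputs (composition, phylogeny, site
attributes, threat table), computes the per-site diversity summaries,
the phylogenetic ordination and the climate axes, residualizes every
variable on geography, and fits one hierarchical path model per threat
scenario. All tables can be written as CSV together with a JSON run
manifest recording inputs, seeds and digests.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .climate import ClimatePCA
from .datatypes import (
    ANTHROME_COLUMNS,
    CompositionMatrix,
    PhylogenyBundle,
    SiteAttributes,
    ThreatTable,
)
from .diversity import SCENARIO_ORDER, diversity_summary
from .path import GeographicResidualizer, PathAnalysis
from .pcps import PCPSOrdination

logger = logging.getLogger("pcpspath")


@dataclass
class PipelineResult:
    diversity: pd.DataFrame
    pcps: PCPSOrdination
    climate: ClimatePCA
    variables: pd.DataFrame                     # residualized site x variable table
    ranks: dict[str, int]
    groups: dict[str, list[str]]
    scenario_models: dict[str, PathAnalysis]
    manifest: dict = field(default_factory=dict)


def causal_ranks(
    climate_cols, anthrome_cols, pcps_cols, response_cols
) -> dict[str, int]:
    """Default causal hierarchy: climate 0; land use & PCPS 1; richness
    and endemism 2; threat responses 3."""
    ranks = {c: 0 for c in climate_cols}
    ranks.update({c: 1 for c in anthrome_cols})
    ranks.update({c: 1 for c in pcps_cols})
    ranks.update({"richness": 2, "endemism": 2})
    ranks.update({c: 3 for c in response_cols})
    return ranks


def run_pipeline(
    W: CompositionMatrix,
    phylogeny: PhylogenyBundle,
    attributes: SiteAttributes,
    threats: ThreatTable,
    *,
    scenarios: tuple[str, ...] = SCENARIO_ORDER,
    n_pcps: int = 3,
    n_climate_axes: int = 2,
    n_perm: int = 999,
    seed: int = 0,
    aicc: bool = False,
) -> PipelineResult:
    """Run the full analysis once per threat scenario."""
    t0 = time.time()
    timings: dict[str, float] = {}
    attributes = attributes.aligned_to(W.sites)

    div = diversity_summary(W, threats)
    timings["diversity"] = time.time() - t0

    t = time.time()
    pcps = PCPSOrdination(n_axes=n_pcps).fit(W, phylogeny)
    pcps_scores = pcps.transform()
    timings["pcps"] = time.time() - t

    t = time.time()
    clim = ClimatePCA(n_axes=n_climate_axes).fit(attributes.climate)
    climate_scores = clim.transform()
    timings["climate"] = time.time() - t

    t = time.time()
    responses = [f"threat_{s}" for s in scenarios]
    raw = pd.concat(
        [climate_scores, attributes.anthromes, pcps_scores,
         div[["richness", "endemism"]], div[responses]],
        axis=1,
    )
    resid = GeographicResidualizer().fit_transform(raw, attributes.geography)
    timings["residualize"] = time.time() - t

    climate_cols = list(climate_scores.columns)
    pcps_cols = list(pcps_scores.columns)
    anthrome_cols = list(ANTHROME_COLUMNS)
    ranks = causal_ranks(climate_cols, anthrome_cols, pcps_cols, responses)
    groups = {
        "climate": climate_cols,
        "anthromes": anthrome_cols,
        "pcps": pcps_cols,
    }

    seeds = np.random.SeedSequence(seed).spawn(len(scenarios))
    models: dict[str, PathAnalysis] = {}
    for scen, ss in zip(scenarios, seeds):
        t = time.time()
        response = f"threat_{scen}"
        cols = climate_cols + anthrome_cols + pcps_cols + ["richness", "endemism", response]
        pa = PathAnalysis(
            n_perm=n_perm, aicc=aicc, random_state=np.random.default_rng(ss)
        )
        pa.fit(resid[cols], ranks, response, groups=groups, scenario=scen)
        models[scen] = pa
        timings[f"path_{scen}"] = time.time() - t
        logger.info(
            "scenario %s: %d edges (%d significant at 0.05)",
            scen, len(pa.edges_), int(pa.edges_["significant"].sum()),
        )

    manifest = {
        "version": __version__,
        "seed": seed,
        "n_perm": n_perm,
        "scenarios": list(scenarios),
        "n_sites": len(W.sites),
        "n_taxa": len(W.taxa),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return PipelineResult(div, pcps, clim, resid, ranks, groups, models, manifest)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def write_results(result: PipelineResult, out_dir: str) -> dict:
    """Write all result tables plus the run manifest; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    def _save(df: pd.DataFrame, name: str, **kw) -> None:
        path = os.path.join(out_dir, name)
        df.to_csv(path, **kw)
        outputs[name] = path

    _save(result.diversity, "diversity.csv", index_label="site")
    _save(result.pcps.P_.values, "P_matrix.csv", index_label="site")
    eig = pd.DataFrame({"eigenvalue": result.pcps.eigenvalues_})
    npos = len(result.pcps.variance_fractions_)
    eig["variance_fraction"] = np.concatenate(
        [result.pcps.variance_fractions_, np.full(len(eig) - npos, np.nan)]
    )
    _save(eig, "pcps_eigenvalues.csv", index_label="axis")
    _save(result.pcps.site_scores_, "pcps_scores.csv", index_label="site")
    _save(result.pcps.clade_correlations_, "clade_correlations.csv", index=False)
    _save(result.climate.loading_table(), "climate_loadings.csv", index=False)
    _save(result.climate.site_scores_, "climate_scores.csv", index_label="site")
    _save(result.variables, "residual_variables.csv", index_label="site")

    for scen, pa in result.scenario_models.items():
        sdir = os.path.join(out_dir, scen)
        os.makedirs(sdir, exist_ok=True)
        pa.edges_.to_csv(os.path.join(sdir, "edges.csv"), index=False)
        pa.effects_.to_csv(os.path.join(sdir, "effects.csv"), index=False)
        with open(os.path.join(sdir, "model.dot"), "w") as fh:
            fh.write(pa.model_.to_dot())
        outputs[f"{scen}/edges.csv"] = os.path.join(sdir, "edges.csv")
        outputs[f"{scen}/effects.csv"] = os.path.join(sdir, "effects.csv")
        outputs[f"{scen}/model.dot"] = os.path.join(sdir, "model.dot")

    manifest = dict(result.manifest)
    manifest["outputs"] = {
        name: _digest(path) for name, path in sorted(outputs.items())
    }
    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.manifest = manifest
    return manifest
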