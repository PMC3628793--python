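"""Per-site diversity summaries and nested threat scenarios.

Richness is the number of taxa in a site; a taxon is endemic when it
occurs in exactly one site of the matrix. Threatened-species counts are
computed under three nested scenarios of conservation urgency that pool
increasingly many IUCN categories:

* ``urgent``    — CR, EW, EX
* ``moderate``  — urgent plus EN
* ``inclusive`` — moderate plus VU
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CompositionMatrix, ThreatTable, ValidationError


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    included_categories: frozenset[str]


SCENARIOS: dict[str, ScenarioSpec] = {
    "urgent": ScenarioSpec("urgent", frozenset({"CR", "EW", "EX"})),
    "moderate": ScenarioSpec("moderate", frozenset({"CR", "EW", "EX", "EN"})),
    "inclusive": ScenarioSpec("inclusive", frozenset({"CR", "EW", "EX", "EN", "VU"})),
}

SCENARIO_ORDER: tuple[str, ...] = ("urgent", "moderate", "inclusive")


def richness(W: CompositionMatrix) -> pd.Series:
    """Number of taxa present per site (row sums of the incidence matrix)."""
    return (W.values > 0).sum(axis=1).rename("richness")


def endemism(W: CompositionMatrix) -> pd.Series:
    """Number of endemic taxa per site.

    A taxon is endemic when its column sum equals 1: it occurs in exactly
    one site, and that site gets the credit.
    """
    inc = (W.values > 0).astype(int)
    endemic_taxa = inc.sum(axis=0) == 1
    return inc.loc[:, endemic_taxa].sum(axis=1).rename("endemism")


def scenario_counts(
    W: CompositionMatrix, threats: ThreatTable, spec: ScenarioSpec
) -> tuple[pd.Series, int]:
    """Per-site threatened counts plus the pooled global species total.

    The global total counts distinct taxa of the matrix whose category is
    pooled by the scenario; taxa in the threat table but absent from the
    matrix do not contribute.
    """
    cats = threats.category_for(W.taxa)
    in_scenario = cats.isin(spec.included_categories).to_numpy()
    inc = (W.values > 0).to_numpy()
    per_site = pd.Series(
        inc[:, in_scenario].sum(axis=1),
        index=W.values.index,
        name=f"threat_{spec.name}",
    )
    global_total = int(in_scenario.sum())
    return per_site, global_total


def diversity_summary(W: CompositionMatrix, threats: ThreatTable) -> pd.DataFrame:
    """Site table of richness, endemism and the three scenario counts.

    Asserts scenario nestedness (urgent <= moderate <= inclusive per site)
    on every call.
    """
    out = pd.DataFrame({"richness": richness(W), "endemism": endemism(W)})
    totals = {}
    for name in SCENARIO_ORDER:
        per_site, total = scenario_counts(W, threats, SCENARIOS[name])
        out[f"threat_{name}"] = per_site
        totals[name] = total
    if not (
        (out["threat_urgent"] <= out["threat_moderate"]).all()
        and (out["threat_moderate"] <= out["threat_inclusive"]).all()
    ):
        raise ValidationError("scenario counts are not nested urgent <= moderate <= inclusive")
    if (out["endemism"] > out["richness"]).any():
        raise ValidationError("endemism exceeded richness for some site")
    out.attrs["global_totals"] = totals
    return out


def global_scenario_totals(W: CompositionMatrix, threats: ThreatTable) -> dict[str, int]:
    """Pooled species totals per scenario over the taxa of the matrix."""
    return {
        name: scenario_counts(W, threats, SCENARIOS[name])[1]
        for name in SCENARIO_ORDER
    }
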