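"""Hierarchical path analysis with AIC model selection and randomization tests.

Workflow: every variable (predictors and the threatened-species response
alike) is first residualized on latitude, longitude and area, so the
causal model describes geography-free variation. Variables then carry a
causal rank — climate axes are exogenous (rank 0); land-use covers and
phylogenetic axes rank 1; richness and endemism rank 2; the threat count
is the response (rank 3) — and edges may only point from lower to higher
rank. Model building starts at the response: its direct predictors are
found by exhaustive AIC best-subset selection among admissible variables,
each selected endogenous predictor is then resolved the same way, and so
on until only exogenous variables remain. Path coefficients are
standardized regression coefficients (one multiple OLS per endogenous
node on its parents); their p-values come from a permutation test that
shuffles the node's values across sites and refits.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ValidationError

logger = logging.getLogger("pcpspath")

#: default causal ranks by variable-name prefix
RANK_OF_GROUP = {"climate": 0, "anthrome": 1, "pcps": 1, "diversity": 2, "response": 3}

AIC_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# residualization on geography

def residualize(values: pd.Series | pd.DataFrame, geo: pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Residuals of an OLS of each variable on intercept + lat + lon + area."""
    y = pd.DataFrame(values)
    if len(y) < 5:
        raise ValidationError("residualization needs at least 5 sites")
    if not y.index.equals(geo.index):
        raise ValidationError("variable and geography tables are not aligned")
    X = np.column_stack([np.ones(len(geo)), geo.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "geography columns are collinear; drop one of lat/lon/area"
        )
    coef, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - X @ coef
    out = pd.DataFrame(resid, index=y.index, columns=y.columns)
    return out[values.name] if isinstance(values, pd.Series) else out


class GeographicResidualizer(BaseEstimator, TransformerMixin):
    """Transformer removing latitude, longitude and area from variables.

    ``fit`` learns one OLS per column of X against the site geography;
    ``transform`` returns the residuals (mean zero, orthogonal to the
    geography columns).
    """

    def fit(self, X: pd.DataFrame, geo: pd.DataFrame) -> "GeographicResidualizer":
        X = pd.DataFrame(X)
        if len(X) < 5:
            raise ValidationError("residualization needs at least 5 sites")
        D = np.column_stack([np.ones(len(geo)), geo.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValidationError("geography columns are collinear; drop one of lat/lon/area")
        self.geo_columns_ = list(geo.columns)
        self.design_ = D
        self.coef_, *_ = np.linalg.lstsq(D, X.to_numpy(dtype=float), rcond=None)
        self.feature_names_in_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).loc[:, self.feature_names_in_]
        resid = X.to_numpy(dtype=float) - self.design_ @ self.coef_
        return pd.DataFrame(resid, index=X.index, columns=X.columns)

    def fit_transform(self, X: pd.DataFrame, geo: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, geo).transform(X)


# ---------------------------------------------------------------------------
# AIC and best-subset selection

def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, rss, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValidationError("singular design matrix in OLS fit")
    if rss.size:
        return float(rss[0])
    fitted = design @ coef
    return float(((y - fitted) ** 2).sum())


def ols_aic(y, X=None, *, aicc: bool = False) -> float:
    """Gaussian-OLS AIC: ``n ln(RSS/n) + 2 (k + 2)``.

    ``k`` counts the predictors; the intercept and the error variance
    contribute the +2. An (essentially) perfect fit returns -inf with a
    warning so degenerate designs are visible rather than fatal.
    """
    y = np.asarray(y, dtype=float)
    Xa = (np.empty((len(y), 0)) if X is None
          else np.asarray(pd.DataFrame(X), dtype=float))
    n, k = len(y), Xa.shape[1]
    if n <= k + 2:
        raise ValidationError(f"need n > k + 2 (n={n}, k={k})")
    rss = _ols_rss(y, Xa)
    scale = max(float((y - y.mean()) @ (y - y.mean())), 1.0)
    if rss / n <= 1e-14 * scale:
        logger.warning("perfect fit (RSS ~ 0) with %d predictors; AIC = -inf", k)
        return float("-inf")
    aic = n * np.log(rss / n) + 2 * (k + 2)
    if aicc:
        p = k + 2
        if n - p - 1 <= 0:
            raise ValidationError("sample too small for the AICc correction")
        aic += 2 * p * (p + 1) / (n - p - 1)
    return float(aic)


@dataclass(frozen=True)
class SubsetSelection:
    selected: tuple[str, ...]
    aic: float
    n_models: int
    tie: bool = False


def select_subset(y, candidates: pd.DataFrame, *, aicc: bool = False) -> SubsetSelection:
    """Exhaustive AIC best-subset selection, including the null model.

    All 2^m predictor subsets are scored; the minimum AIC wins, with ties
    (within 1e-9) broken toward fewer predictors and then lexicographic
    variable order.
    """
    candidates = pd.DataFrame(candidates)
    names = sorted(candidates.columns)
    m = len(names)
    if m > 20:
        raise ValidationError(
            f"{m} candidates exceeds the exhaustive-search bound of 20; "
            "pre-select within groups first"
        )
    y = np.asarray(y, dtype=float)
    cols = {nm: candidates[nm].to_numpy(dtype=float) for nm in names}
    best: SubsetSelection | None = None
    n_models = 0
    tie_seen = False
    n_singular = 0
    for size in range(m + 1):
        for combo in itertools.combinations(names, size):
            X = np.column_stack([cols[nm] for nm in combo]) if combo else None
            try:
                aic = ols_aic(y, X, aicc=aicc)
            except ValidationError:
                # e.g. compositional covers: the full set is collinear
                n_singular += 1
                continue
            n_models += 1
            if best is None or aic < best.aic - AIC_TIE_TOL:
                best = SubsetSelection(combo, aic, 0)
            elif abs(aic - best.aic) <= AIC_TIE_TOL:
                tie_seen = True  # enumeration order already prefers the incumbent
    if tie_seen:
        logger.info("AIC tie within %.0e during subset selection; kept the smaller/earlier subset", AIC_TIE_TOL)
    if n_singular:
        logger.info("skipped %d singular candidate subsets", n_singular)
    return replace(best, n_models=n_models, tie=tie_seen)


def group_preselect(
    response, groups: dict[str, pd.DataFrame], *, aicc: bool = False
) -> dict[str, tuple[str, ...]]:
    """Best-subset selection run separately within each predictor group.

    The union of per-group winners is the variable pool carried into the
    hypothetical path model.
    """
    seen: set[str] = set()
    for g, df in groups.items():
        overlap = seen & set(df.columns)
        if overlap:
            raise ValidationError(f"groups are not disjoint: {sorted(overlap)}")
        seen |= set(df.columns)
    return {
        g: select_subset(response, df, aicc=aicc).selected
        for g, df in groups.items()
    }


# ---------------------------------------------------------------------------
# path model

@dataclass
class PathEdge:
    parent: str
    child: str
    beta: float | None = None
    p_value: float | None = None


@dataclass
class PathModel:
    """Directed acyclic graph of causal links with per-edge statistics."""

    ranks: dict[str, int]
    response: str
    edges: list[PathEdge] = field(default_factory=list)
    scenario: str | None = None

    def __post_init__(self) -> None:
        for e in self.edges:
            if self.ranks[e.parent] >= self.ranks[e.child]:
                raise ValidationError(
                    f"edge {e.parent}->{e.child} violates the causal rank order"
                )
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValidationError("path model contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.ranks)
        for e in self.edges:
            g.add_edge(e.parent, e.child, beta=e.beta, p_value=e.p_value)
        return g

    def parents_of(self, node: str) -> list[str]:
        return [e.parent for e in self.edges if e.child == node]

    def to_edge_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = [
            {"parent": e.parent, "child": e.child, "beta": e.beta,
             "p_value": e.p_value,
             "significant": (e.p_value is not None and e.p_value < alpha)}
            for e in self.edges
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "beta", "p_value", "significant"])

    def to_dot(self, alpha: float = 0.05) -> str:
        lines = ["digraph path_model {", "  rankdir=LR;"]
        for node in self.ranks:
            lines.append(f'  "{node}";')
        for e in self.edges:
            sig = e.p_value is not None and e.p_value < alpha
            style = "solid" if sig else "dashed"
            label = "" if e.beta is None else f"{e.beta:+.2f}"
            if e.p_value is not None:
                label += f" (p={e.p_value:.3f})"
            lines.append(
                f'  "{e.parent}" -> "{e.child}" [label="{label}", style={style}];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_path_model(
    data: pd.DataFrame,
    ranks: dict[str, int],
    response: str,
    *,
    retained: list[str] | None = None,
    aicc: bool = False,
    scenario: str | None = None,
) -> PathModel:
    """Iterative construction of the path DAG, starting at the response.

    Breadth-first: the response's predictors are chosen by best-subset
    AIC among all retained variables of strictly lower rank; each
    selected endogenous variable is then itself resolved against its own
    admissible set. Terminates because ranks strictly decrease along
    every edge.
    """
    universe = list(retained) if retained is not None else [
        c for c in data.columns if c != response
    ]
    for v in universe + [response]:
        if v not in ranks:
            raise ValidationError(f"no causal rank for variable {v!r}")
        if v != response and ranks[v] >= ranks[response]:
            raise ValidationError(
                f"{v!r} has rank >= the response; inadmissible predictor"
            )
    edges: list[PathEdge] = []
    resolved: set[str] = set()
    queue = [response]
    node_ranks = {v: ranks[v] for v in universe + [response]}
    while queue:
        node = queue.pop(0)
        if node in resolved:
            continue
        resolved.add(node)
        cands = [v for v in universe if ranks[v] < ranks[node]]
        if not cands:
            continue
        sel = select_subset(data[node], data[cands], aicc=aicc)
        for parent in sel.selected:
            edges.append(PathEdge(parent, node))
            if ranks[parent] >= 1 and parent not in resolved:
                queue.append(parent)
    return PathModel(node_ranks, response, edges, scenario)


# ---------------------------------------------------------------------------
# coefficients, permutation p-values, effects

def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant variable cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def path_coefficients(model: PathModel, data: pd.DataFrame) -> PathModel:
    """Standardized regression coefficients (path coefficients) per edge.

    One multiple OLS per endogenous node of the node on its parents,
    both z-scored; with a single parent the coefficient equals the
    Pearson correlation.
    """
    for node in {e.child for e in model.edges}:
        parents = model.parents_of(node)
        y = _zscore(data[node].to_numpy(dtype=float))
        X = _zscore(data[parents].to_numpy(dtype=float))
        design = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError(f"singular fit for node {node!r}")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        betas = dict(zip(parents, coef[1:]))
        for e in model.edges:
            if e.child == node:
                e.beta = float(betas[e.parent])
    return model


def randomization_pvalues(
    model: PathModel,
    data: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PathModel:
    """Permutation p-values for every path coefficient.

    For each endogenous node, the node's values are permuted across
    sites ``n_perm`` times and the parent regression refit; the
    two-tailed p-value of an edge is ``(1 + #{|b*| >= |b|}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for node in sorted({e.child for e in model.edges}):
        parents = model.parents_of(node)
        y = _zscore(data[node].to_numpy(dtype=float))
        X = _zscore(data[parents].to_numpy(dtype=float))
        design = np.column_stack([np.ones(len(y)), X])
        pinv = np.linalg.pinv(design)
        beta_obs = pinv @ y
        perm_idx = np.argsort(rng.random((n_perm, len(y))), axis=1)
        B = pinv @ y[perm_idx].T                      # (k+1) x n_perm
        exceed = (np.abs(B[1:]) >= np.abs(beta_obs[1:, None]) - 1e-12).sum(axis=1)
        pvals = (1 + exceed) / (n_perm + 1)
        lookup = dict(zip(parents, pvals))
        for e in model.edges:
            if e.child == node:
                e.p_value = float(lookup[e.parent])
    return model


@dataclass(frozen=True)
class EffectDecomposition:
    effects: pd.DataFrame  # variable, direct, indirect, total


def effect_decomposition(model: PathModel) -> EffectDecomposition:
    """Direct, indirect and total effects of every variable on the response.

    Direct effect: the coefficient of the single edge into the response
    (0 if absent). Indirect effect: the sum over all directed paths of
    length >= 2 of the product of coefficients along the path.
    """
    g = model.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise ValidationError("path model contains a cycle")
    rows = []
    for node in model.ranks:
        if node == model.response:
            continue
        direct = 0.0
        if g.has_edge(node, model.response):
            direct = g[node][model.response]["beta"] or 0.0
        indirect = 0.0
        for path in nx.all_simple_paths(g, node, model.response):
            if len(path) <= 2:
                continue
            prod = 1.0
            for a, b in zip(path[:-1], path[1:]):
                prod *= g[a][b]["beta"] or 0.0
            indirect += prod
        rows.append(
            {"variable": node, "direct": direct, "indirect": indirect,
             "total": direct + indirect}
        )
    return EffectDecomposition(pd.DataFrame(rows, columns=["variable", "direct", "indirect", "total"]))


# ---------------------------------------------------------------------------
# estimator facade

class PathAnalysis(BaseEstimator):
    """Hierarchical AIC path analysis with randomization-test p-values.

    Parameters
    ----------
    n_perm : int, default 999
        Permutations per endogenous node for edge p-values.
    alpha : float, default 0.05
        Significance level used when flagging edges in reports.
    aicc : bool, default False
        Use the small-sample AIC correction in all subset selections.
    random_state : int or Generator, default 0
        Seed for the permutation generator.

    ``fit`` expects a sites x variables table of *residualized* values, a
    rank map, the response name and optionally a ``groups`` mapping for
    the per-group AIC pre-selection step.

    Attributes
    ----------
    retained_ : dict of group -> selected variables (empty if no groups)
    model_ : PathModel with beta and p-value on every edge
    edges_ : DataFrame (parent, child, beta, p_value, significant)
    effects_ : DataFrame (variable, direct, indirect, total)
    """

    def __init__(self, n_perm: int = 999, alpha: float = 0.05,
                 aicc: bool = False, random_state: int | np.random.Generator = 0):
        self.n_perm = n_perm
        self.alpha = alpha
        self.aicc = aicc
        self.random_state = random_state

    def fit(
        self,
        X: pd.DataFrame,
        ranks: dict[str, int],
        response: str,
        groups: dict[str, list[str]] | None = None,
        scenario: str | None = None,
    ) -> "PathAnalysis":
        X = pd.DataFrame(X)
        if response not in X.columns:
            raise ValidationError(f"response {response!r} not in data")
        if groups:
            self.retained_ = group_preselect(
                X[response],
                {g: X[list(cols)] for g, cols in groups.items()},
                aicc=self.aicc,
            )
            grouped = {v for cols in groups.values() for v in cols}
            pool = [v for cols in self.retained_.values() for v in cols]
            pool += [v for v in X.columns if v not in grouped and v != response]
        else:
            self.retained_ = {}
            pool = [v for v in X.columns if v != response]
        model = build_path_model(
            X, ranks, response, retained=pool, aicc=self.aicc, scenario=scenario
        )
        model = path_coefficients(model, X)
        model = randomization_pvalues(model, X, self.n_perm, self.random_state)
        self.model_ = model
        self.edges_ = model.to_edge_frame(self.alpha)
        self.effects_ = effect_decomposition(model).effects
        return self
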