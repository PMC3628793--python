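"""Phylogenetic fuzzy-weighting and Principal Coordinates of Phylogenetic Structure.

The chain implemented here scales phylogenetic relationships up to the
site level:

1. pairwise node-count distances D between tips of a unit-branch-length
   tree;
2. their scaled complement S = 1 - D / max(D), a similarity in [0, 1];
3. column standardization of S into the belonging matrix Q (columns sum
   to 1), and the phylogeny-weighted composition P = W Q^T. Because Q is
   column-stochastic, each site's row sum (its richness) is preserved
   exactly while presences are redistributed toward close relatives;
4. a principal coordinates analysis of square-rooted Bray-Curtis
   dissimilarities between the rows of P. The resulting axes (PCPS)
   describe independent phylogenetic gradients across sites; the axis
   with the largest eigenvalue captures the deepest splits of the tree.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .datatypes import CompositionMatrix, PhylogenyBundle, ValidationError

logger = logging.getLogger("pcpspath")


def node_count_distances(phy: PhylogenyBundle, taxa=None) -> pd.DataFrame:
    """Tip-to-tip path lengths, in edges, on the unit-branch-length tree.

    Parameters
    ----------
    phy
        Phylogeny with branch lengths already normalized to 1.
    taxa
        Optional taxon order for the output; defaults to tip order.
        Taxa absent from the tree raise a validation error.
    """
    tip_labels = [leaf.taxon.label for leaf in phy.tree.leaf_node_iter()]
    if taxa is None:
        taxa = tip_labels
    index = {lbl: i for i, lbl in enumerate(tip_labels)}
    missing = [t for t in taxa if t not in index]
    if missing:
        raise ValidationError(f"taxa absent from the tree: {missing}")
    n = len(tip_labels)
    D = np.zeros((n, n))
    # postorder merge: each node carries its subtree's tip indices and
    # their depths (edge counts) below it; tip pairs meeting at a node
    # are at depth_i + depth_j
    stash: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            stash[id(node)] = (
                np.array([index[node.taxon.label]]), np.zeros(1)
            )
            continue
        parts = [stash.pop(id(ch)) for ch in node.child_nodes()]
        parts = [(tips, depths + 1.0) for tips, depths in parts]
        for a in range(len(parts)):
            for b in range(a + 1, len(parts)):
                ti, di = parts[a]
                tj, dj = parts[b]
                block = di[:, None] + dj[None, :]
                D[np.ix_(ti, tj)] = block
                D[np.ix_(tj, ti)] = block.T
        stash[id(node)] = (
            np.concatenate([p[0] for p in parts]),
            np.concatenate([p[1] for p in parts]),
        )
    full = pd.DataFrame(D, index=tip_labels, columns=tip_labels)
    return full.loc[list(taxa), list(taxa)]


def similarity_complement(D: pd.DataFrame, *, scale: float | None = None) -> pd.DataFrame:
    """Similarities S = 1 - D / scale, with scale defaulting to max(D).

    The default scaling guarantees S in [0, 1] with the most distant pair
    at exactly 0 and the diagonal at exactly 1.
    """
    arr = D.to_numpy(dtype=float)
    dmax = float(arr.max())
    if dmax <= 0 and len(D) > 1:
        raise ValidationError("degenerate distance matrix: all distances are zero")
    denom = dmax if scale is None else float(scale)
    S = 1.0 - arr / denom if len(D) > 1 else np.ones_like(arr)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=D.index, columns=D.columns)


def belonging_matrix(S: pd.DataFrame) -> pd.DataFrame:
    """Column-standardized similarities Q: q_ij = s_ij / sum_k s_kj."""
    arr = S.to_numpy(dtype=float)
    colsums = arr.sum(axis=0)
    if (colsums <= 0).any():
        raise ValidationError("similarity matrix has a non-positive column sum")
    return pd.DataFrame(arr / colsums, index=S.index, columns=S.columns)


def fuzzy_weight(W: CompositionMatrix, S: pd.DataFrame) -> CompositionMatrix:
    """Phylogeny-weighted composition P = W Q^T.

    ``P(site, i) = sum_j W(site, j) * q_ij`` redistributes each presence
    across phylogenetic neighbours; row sums of P equal row sums of W.
    """
    if list(W.taxa) != list(S.index) or list(S.index) != list(S.columns):
        raise ValidationError("taxa of the composition matrix and similarity matrix are not aligned")
    Q = belonging_matrix(S).to_numpy()
    P = W.values.to_numpy() @ Q.T
    dfP = pd.DataFrame(P, index=W.values.index, columns=W.values.columns)
    return CompositionMatrix(dfP)


def sqrt_bray_curtis(P: CompositionMatrix) -> pd.DataFrame:
    """Square-rooted Bray-Curtis dissimilarities between sites (rows of P)."""
    arr = P.values.to_numpy(dtype=float)
    rowsums = arr.sum(axis=1)
    if (rowsums <= 0).any():
        bad = P.values.index[rowsums <= 0][0]
        raise ValidationError(f"site {bad!r} has zero total composition")
    bc = squareform(pdist(arr, metric="braycurtis"))
    return pd.DataFrame(np.sqrt(bc), index=P.values.index, columns=P.values.index)


@dataclass(frozen=True)
class PcoaResult:
    """Eigenstructure of a principal coordinates analysis."""

    eigenvalues: np.ndarray            # all eigenvalues, non-increasing
    site_scores: pd.DataFrame          # sites x positive axes
    variance_fractions: np.ndarray     # per positive axis, sums to 1

    @property
    def n_negative(self) -> int:
        return int((self.eigenvalues < -1e-8 * max(abs(self.eigenvalues).max(), 1.0)).sum())


def pcoa(D: pd.DataFrame, *, correction: str = "none") -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    ``B = -1/2 J D^2 J`` is eigendecomposed; site scores on axis k are
    ``eigvec_k * sqrt(eigval_k)`` for positive eigenvalues. Negative
    eigenvalues (non-Euclidean input) are reported but their axes are
    discarded with a warning; ``correction='lingoes'`` instead adds the
    Lingoes constant to off-diagonal squared distances first.
    """
    arr = D.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix is not symmetric")
    n = arr.shape[0]

    def _center(d2: np.ndarray) -> np.ndarray:
        J = np.eye(n) - np.ones((n, n)) / n
        return -0.5 * J @ d2 @ J

    B = _center(arr ** 2)
    evals, evecs = scipy.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if correction == "lingoes" and evals[-1] < -1e-12:
        c = -evals[-1]
        d2 = arr ** 2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        B = _center(d2)
        evals, evecs = scipy.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    elif correction not in ("none", "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")

    tol = 1e-10 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    n_neg = int((evals < -tol).sum())
    if n_neg:
        logger.warning(
            "PCoA produced %d negative eigenvalues (smallest %.3g); axes discarded",
            n_neg, float(evals.min()),
        )
    scores = evecs[:, pos] * np.sqrt(evals[pos])
    # deterministic orientation: largest-|score| site positive on each axis
    for k in range(scores.shape[1]):
        imax = np.argmax(np.abs(scores[:, k]))
        if scores[imax, k] < 0:
            scores[:, k] *= -1
    cols = [f"pcps_{k + 1}" for k in range(scores.shape[1])]
    site_scores = pd.DataFrame(scores, index=D.index, columns=cols)
    fractions = evals[pos] / evals[pos].sum()
    return PcoaResult(evals, site_scores, fractions)


def clade_axis_correlations(
    P: CompositionMatrix,
    scores: pd.DataFrame,
    clade_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each taxon (and clade) of P with each axis.

    Returns a long table with columns ``taxon, clade, level, axis, r,
    degenerate``. Constant columns of P have undefined correlation and
    are reported as r = 0 with ``degenerate=True``. Clade rows correlate
    the summed composition of all member taxa with each axis.
    """
    if list(P.values.index) != list(scores.index):
        raise ValidationError("sites of P and site scores are not aligned")
    if len(scores) < 3:
        raise ValidationError("need at least 3 sites for correlations")
    clade_map = clade_map or {}

    def _corr_block(cols: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        X = cols.to_numpy(dtype=float)
        Y = scores.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        xs = Xc.std(axis=0)
        ys = Yc.std(axis=0)
        degenerate = xs == 0
        xs_safe = np.where(degenerate, 1.0, xs)
        r = (Xc.T @ Yc) / len(X) / np.outer(xs_safe, ys)
        r[degenerate, :] = 0.0
        return r, degenerate

    rows = []
    r_tax, deg_tax = _corr_block(P.values)
    for i, taxon in enumerate(P.taxa):
        for k, axis in enumerate(scores.columns):
            rows.append(
                {"taxon": taxon, "clade": clade_map.get(taxon, ""),
                 "level": "taxon", "axis": axis,
                 "r": float(r_tax[i, k]), "degenerate": bool(deg_tax[i])}
            )
    if clade_map:
        grouped = P.values.T.groupby(
            pd.Series({t: clade_map.get(t, "") for t in P.taxa})
        ).sum().T
        grouped = grouped.loc[:, [c for c in grouped.columns if c != ""]]
        if grouped.shape[1]:
            r_cl, deg_cl = _corr_block(grouped)
            for i, clade in enumerate(grouped.columns):
                for k, axis in enumerate(scores.columns):
                    rows.append(
                        {"taxon": "", "clade": clade, "level": "clade",
                         "axis": axis, "r": float(r_cl[i, k]),
                         "degenerate": bool(deg_cl[i])}
                    )
    return pd.DataFrame(rows)


class PCPSOrdination(BaseEstimator):
    """Principal Coordinates of Phylogenetic Structure.

    A transformer mapping a site x taxon incidence matrix, together with
    a phylogeny, to per-site scores on the leading phylogenetic axes.

    Parameters
    ----------
    n_axes : int, default 3
        Number of leading axes retained by :meth:`transform` (the full
        eigenstructure remains available in the fitted attributes).
    similarity : {"scaled_complement"}, default "scaled_complement"
        How node-count distances are turned into similarities.
    genus_aggregate : bool, default False
        If True, species columns of W are summed per clade-map genus
        before fuzzy-weighting (the tree must then carry genus tips).
    correction : {"none", "lingoes"}, default "none"
        Negative-eigenvalue handling in the PCoA.

    Attributes
    ----------
    distances_ : DataFrame
        Node-count distance matrix D over taxa.
    similarities_ : DataFrame
        Scaled-complement similarity matrix S.
    P_ : CompositionMatrix
        Phylogeny-weighted composition.
    eigenvalues_ : ndarray
    site_scores_ : DataFrame
        Sites x all positive axes.
    variance_fractions_ : ndarray
    clade_correlations_ : DataFrame
    """

    def __init__(self, n_axes: int = 3, similarity: str = "scaled_complement",
                 genus_aggregate: bool = False, correction: str = "none"):
        self.n_axes = n_axes
        self.similarity = similarity
        self.genus_aggregate = genus_aggregate
        self.correction = correction

    def fit(self, W: CompositionMatrix, phy: PhylogenyBundle) -> "PCPSOrdination":
        if self.similarity != "scaled_complement":
            raise ValueError(f"unknown similarity {self.similarity!r}")
        if self.genus_aggregate:
            if not phy.taxon_to_clade:
                raise ValidationError("genus aggregation requires a clade map")
            grouped = W.values.T.groupby(
                pd.Series({t: phy.taxon_to_clade[t] for t in W.taxa})
            ).sum().T
            W = CompositionMatrix(grouped)
        self.W_ = W
        self.distances_ = node_count_distances(phy, W.taxa)
        self.similarities_ = similarity_complement(self.distances_)
        self.P_ = fuzzy_weight(W, self.similarities_)
        self.dissimilarities_ = sqrt_bray_curtis(self.P_)
        res = pcoa(self.dissimilarities_, correction=self.correction)
        self.eigenvalues_ = res.eigenvalues
        self.site_scores_ = res.site_scores
        self.variance_fractions_ = res.variance_fractions
        self.clade_correlations_ = clade_axis_correlations(
            self.P_, self.site_scores_, phy.taxon_to_clade
        )
        return self

    def transform(self, W=None) -> pd.DataFrame:
        """Leading ``n_axes`` site scores from the fitted ordination."""
        k = min(self.n_axes, self.site_scores_.shape[1])
        return self.site_scores_.iloc[:, :k]

    def fit_transform(self, W: CompositionMatrix, phy: PhylogenyBundle) -> pd.DataFrame:
        return self.fit(W, phy).transform()
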