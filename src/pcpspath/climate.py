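"""Climate summarization and reduction to two principal axes.

Each of the nine environmental variables is summarized per site by its
mean and its range (max - min), giving 18 columns on wildly different
scales. A correlation-matrix PCA (variables standardized) reduces them
to two orthogonal climate axes; loadings are reported as Pearson
correlations between each original variable and each axis.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator

from .datatypes import ValidationError

logger = logging.getLogger("pcpspath")


def mean_range_decompose(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean and range of each climate variable.

    Parameters
    ----------
    samples
        Long-format table with columns ``site``, ``variable``, ``value``
        holding within-site samples (e.g. raster cells) of each variable.

    Returns
    -------
    DataFrame
        Wide table indexed by site with ``{variable}_mean`` and
        ``{variable}_range`` columns.
    """
    required = {"site", "variable", "value"}
    if not required.issubset(samples.columns):
        raise ValidationError(f"samples table needs columns {sorted(required)}")
    if samples.empty:
        raise ValidationError("empty sample table")
    g = samples.groupby(["site", "variable"])["value"]
    agg = g.agg(["mean", "max", "min"])
    agg["range"] = agg["max"] - agg["min"]
    wide = agg[["mean", "range"]].unstack("variable")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValidationError(f"sites with no samples for: {missing}")
    wide.columns = [f"{var}_{stat}" for stat, var in wide.columns]
    order = sorted(wide.columns, key=lambda c: (c.rsplit("_", 1)[0], c.rsplit("_", 1)[1]))
    return wide.loc[:, order]


class ClimatePCA(BaseEstimator):
    """Correlation-matrix PCA of per-site climate summaries.

    Variables are z-scored before the eigendecomposition, so loadings
    are the Pearson correlations of each variable with each axis and
    the squared loadings of a variable sum to 1 across all axes. The
    sign of each axis is fixed so that its largest-|loading| variable
    loads positively.

    Attributes
    ----------
    eigenvalues_ : ndarray, non-increasing
    variance_fractions_ : ndarray, per-axis share of total variance
    loadings_ : DataFrame, variables x retained axes (Pearson r)
    site_scores_ : DataFrame, sites x retained axes
    variance_fraction_retained_ : float, share captured by retained axes
    dropped_columns_ : list of constant columns removed before the PCA
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X: pd.DataFrame, y=None) -> "ClimatePCA":
        X = pd.DataFrame(X).astype(float)
        if len(X) < 3:
            raise ValidationError("climate PCA needs at least 3 sites")
        std = X.std(ddof=1)
        constant = std == 0
        self.dropped_columns_ = X.columns[constant].tolist()
        if self.dropped_columns_:
            logger.warning("dropping constant climate columns: %s", self.dropped_columns_)
            X = X.loc[:, ~constant]
            std = std[~constant]
        self.feature_names_in_ = X.columns.to_numpy()
        self.mean_ = X.mean()
        self.scale_ = std
        Z = (X - self.mean_) / self.scale_
        n = len(Z)
        R = Z.to_numpy().T @ Z.to_numpy() / (n - 1)
        evals, evecs = scipy.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
        k = min(self.n_axes, (evals > 1e-12).sum())
        # orient each axis: dominant variable loads positively
        load_full = evecs * np.sqrt(evals)
        for j in range(evecs.shape[1]):
            imax = np.argmax(np.abs(load_full[:, j]))
            if load_full[imax, j] < 0:
                evecs[:, j] *= -1
                load_full[:, j] *= -1
        self.eigenvalues_ = evals
        self.variance_fractions_ = evals / evals.sum()
        self.components_ = evecs[:, :k]
        axis_names = [f"climate_{j + 1}" for j in range(k)]
        self.loadings_ = pd.DataFrame(
            load_full[:, :k], index=X.columns, columns=axis_names
        )
        self.site_scores_ = pd.DataFrame(
            Z.to_numpy() @ evecs[:, :k], index=X.index, columns=axis_names
        )
        self.variance_fraction_retained_ = float(self.variance_fractions_[:k].sum())
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Scores on the retained climate axes."""
        if X is None:
            return self.site_scores_
        X = pd.DataFrame(X).astype(float).loc[:, self.feature_names_in_]
        Z = (X - self.mean_) / self.scale_
        return pd.DataFrame(
            Z.to_numpy() @ self.components_,
            index=X.index,
            columns=self.site_scores_.columns,
        )

    def loading_table(self) -> pd.DataFrame:
        """Loadings in report layout: variable, (M)/(R), one column per axis."""
        rows = []
        for name, r in self.loadings_.iterrows():
            var, stat = name.rsplit("_", 1)
            rows.append(
                {"variable": var, "summary": "M" if stat == "mean" else "R",
                 **{ax: float(r[ax]) for ax in self.loadings_.columns}}
            )
        return pd.DataFrame(rows)


def climate_pca(X: pd.DataFrame, n_axes: int = 2) -> ClimatePCA:
    """Convenience wrapper: fit a :class:`ClimatePCA` on ``X``."""
    return ClimatePCA(n_axes=n_axes).fit(X)
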