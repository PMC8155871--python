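"""Sensory-instrumental integration: stage summaries, correlations, PCA biplot.

Per-stage mean matrices (five maturity stages x instrumental and sensory
variables) are correlated (Pearson), pruned of redundant variables
(|r| > 0.80 keeps the more interpretable member of each pair), and projected
by a standardized PCA with Kaiser's eigenvalue > 1 retention rule.  With five
stage means the centered matrix has rank at most four, so at most four
non-null components carry all the variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _PCA

from ._util import round_half_up, stage_index, stage_label

__all__ = [
    "IntegrationError",
    "INSTRUMENTAL_VARIABLES",
    "SENSORY_VARIABLES",
    "DEFAULT_PRIORITY",
    "StageSummary",
    "CorrelationMatrix",
    "PcaBiplotResult",
    "stage_summary",
    "correlation_matrix",
    "prune_redundant",
    "pca_biplot",
    "plot_biplot",
]

logger = logging.getLogger(__name__)

INSTRUMENTAL_VARIABLES = ("Np", "Bf", "Bdc", "E", "Be", "De", "Th", "Bd", "Si", "Ar")
SENSORY_VARIABLES = ("color", "hardness", "cracking", "vegetal", "bitterness", "astringency")

#: Preference order used when pruning redundant pairs: earlier = kept.  The
#: derived energies Be and the ratio Ar rank last because the primary force
#: and distance readings they duplicate are easier to interpret.
DEFAULT_PRIORITY = (
    "Np", "Bf", "Bdc", "E", "De", "Th", "Bd", "Si",
    "color", "hardness", "cracking", "vegetal", "bitterness", "astringency",
    "Be", "Ar",
)


class IntegrationError(ValueError):
    """Invalid integration input."""


@dataclass
class StageSummary:
    """Per-stage means/SDs/counts for instrumental and sensory variables."""

    means: pd.DataFrame  # stages x variables
    sds: pd.DataFrame
    n: pd.DataFrame


@dataclass
class CorrelationMatrix:
    frame: pd.DataFrame  # square, symmetric, unit diagonal

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Report form: half-up rounding as printed correlation tables use."""
        return self.frame.map(
            lambda v: np.nan if pd.isna(v) else round_half_up(v, decimals)
        )


@dataclass
class PcaBiplotResult:
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    n_retained: int  # Kaiser: eigenvalues > 1
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations (stages) x components
    dropped_variables: list = field(default_factory=list)


def stage_summary(
    texture_frame: Optional[pd.DataFrame] = None,
    score_table: Optional[pd.DataFrame] = None,
) -> StageSummary:
    """Per-stage arithmetic means and SDs of texture parameters and/or
    sensory attributes.

    ``texture_frame`` needs a ``stage`` column plus the ten parameter columns;
    ``score_table`` is the long-format sensory table (per-stage statistics are
    taken over all judge x session scores).  Stages present in one source
    must be present in the other.
    """
    if texture_frame is None and score_table is None:
        raise IntegrationError("need at least one data source")

    means_parts, sd_parts, n_parts, stage_sets = [], [], [], []
    if texture_frame is not None:
        if "stage" not in texture_frame.columns:
            raise IntegrationError("texture frame needs a 'stage' column")
        cols = [c for c in INSTRUMENTAL_VARIABLES if c in texture_frame.columns]
        if not cols:
            raise IntegrationError("texture frame has no instrumental columns")
        g = texture_frame.groupby(texture_frame["stage"].map(stage_index))[cols]
        means_parts.append(g.mean())
        sd_parts.append(g.std(ddof=1).fillna(0.0))
        n_parts.append(g.count())
        stage_sets.append(set(g.mean().index))
    if score_table is not None:
        pv = score_table.pivot_table(
            index=score_table["sample"].map(stage_index),
            columns="attribute", values="score",
            aggfunc=["mean", "std", "count"], dropna=False,
        )
        m = pv["mean"].reindex(columns=[a for a in SENSORY_VARIABLES if a in pv["mean"].columns])
        means_parts.append(m)
        sd_parts.append(pv["std"].reindex(columns=m.columns).fillna(0.0))
        n_parts.append(pv["count"].reindex(columns=m.columns))
        stage_sets.append(set(m.index))

    stages = stage_sets[0]
    for s in stage_sets[1:]:
        if s != stages:
            raise IntegrationError(
                f"stage mismatch between sources: {sorted(stages)} vs {sorted(s)}"
            )
    if any((n_parts[i] == 0).any().any() for i in range(len(n_parts))):
        raise IntegrationError("empty stage cell")

    idx = [stage_label(s) for s in sorted(stages)]
    means = pd.concat(means_parts, axis=1)
    sds = pd.concat(sd_parts, axis=1)
    n = pd.concat(n_parts, axis=1)
    for df in (means, sds, n):
        df.index = idx
        df.index.name = "stage"
    return StageSummary(means=means, sds=sds, n=n)


def correlation_matrix(data) -> CorrelationMatrix:
    """Pearson correlations over the columns of a matrix.

    ``data`` is either a :class:`StageSummary` (correlations over the five
    stage means, as headline report tables use) or any observations x
    variables DataFrame (e.g. per-seed values).  Zero-variance variables get
    NaN correlations with a warning.
    """
    frame = data.means if isinstance(data, StageSummary) else pd.DataFrame(data)
    if frame.shape[0] < 3:
        raise IntegrationError("need at least 3 observations per variable pair")
    constant = frame.columns[frame.std(ddof=1) == 0].tolist()
    if constant:
        warnings.warn(
            f"zero-variance variables, correlations undefined: {constant}",
            stacklevel=2,
        )
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    return CorrelationMatrix(frame=corr)


def prune_redundant(
    matrix: CorrelationMatrix,
    threshold: float = 0.80,
    priorities: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple:
    """Drop the less interpretable member of every highly correlated pair.

    Pairs with |r| > ``threshold`` are processed greedily in decreasing |r|
    (ties broken by label order); in each pair the variable ranked later in
    ``priorities`` (unlisted variables rank last, in column order) is dropped
    unless already dropped.  Returns (kept labels, list of
    (dropped, kept, r)).
    """
    frame = matrix.frame if isinstance(matrix, CorrelationMatrix) else pd.DataFrame(matrix)
    labels = list(frame.columns)
    rank = {}
    for i, name in enumerate(priorities):
        rank[name] = i
    for j, name in enumerate(labels):
        rank.setdefault(name, len(priorities) + j)

    pairs = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            r = frame.iloc[i, j]
            if pd.notna(r) and abs(r) > threshold:
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))

    dropped_set: set = set()
    dropped_log = []
    for a, b, r in pairs:
        if a in dropped_set or b in dropped_set:
            continue
        loser, keeper = (a, b) if rank[a] > rank[b] else (b, a)
        dropped_set.add(loser)
        dropped_log.append((loser, keeper, r))
    kept = [v for v in labels if v not in dropped_set]
    return kept, dropped_log


def pca_biplot(data, standardize: bool = True) -> PcaBiplotResult:
    """Standardized PCA of a stage x variable mean matrix with Kaiser retention.

    Eigenvalues are those of the correlation matrix (sample covariance of the
    column-standardized data, ddof=1); components with eigenvalue > 1 are
    retained under Kaiser's criterion.  Constant columns are dropped with a
    warning.  Loadings are component vectors scaled by the square root of
    their eigenvalue (variable-component correlations for standardized data).
    """
    frame = data.means if isinstance(data, StageSummary) else pd.DataFrame(data)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise IntegrationError("need at least 2 observations and 2 variables")
    sd = frame.std(ddof=1)
    dropped = frame.columns[sd == 0].tolist()
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        frame = frame.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    if frame.shape[1] < 2:
        raise IntegrationError("fewer than 2 variables with variance")
    X = frame.to_numpy(float)
    if standardize:
        X = (X - X.mean(axis=0)) / sd.to_numpy()
    else:
        X = X - X.mean(axis=0)

    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = _PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    eig = pca.explained_variance_
    explained = pca.explained_variance_ratio_ * 100.0
    loadings = pca.components_.T * np.sqrt(eig)
    comps = [f"PC{i+1}" for i in range(n_comp)]
    return PcaBiplotResult(
        eigenvalues=eig,
        explained_variance_pct=explained,
        n_retained=int(np.sum(eig > 1.0)),
        loadings=pd.DataFrame(loadings, index=frame.columns, columns=comps),
        scores=pd.DataFrame(scores, index=frame.index, columns=comps),
        dropped_variables=dropped,
    )


def plot_biplot(result: PcaBiplotResult, path, scale_arrows: float = 1.0):
    """Render a two-component biplot (stage scores + variable loading arrows)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    sc = result.scores
    ax.scatter(sc.iloc[:, 0], sc.iloc[:, 1], c="tab:red", zorder=3)
    for name, row in sc.iterrows():
        ax.annotate(str(name), (row.iloc[0], row.iloc[1]), fontsize=9,
                    xytext=(4, 4), textcoords="offset points")
    span = max(np.abs(sc.iloc[:, :2].to_numpy()).max(), 1e-9)
    load = result.loadings.iloc[:, :2].to_numpy()
    lmax = max(np.abs(load).max(), 1e-9)
    k = scale_arrows * span / lmax
    for name, (x, y) in zip(result.loadings.index, load):
        ax.annotate("", xy=(k * x, k * y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue", lw=1))
        ax.annotate(str(name), (k * x, k * y), color="tab:blue", fontsize=8)
    ev = result.explained_variance_pct
    ax.set_xlabel(f"PC1 ({ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1]:.1f}%)" if len(ev) > 1 else "PC2")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
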