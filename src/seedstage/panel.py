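"""Sensory-panel performance statistics.

A trained panel scores seed samples (one per maturity stage) on a structured
0-10 scale for six attributes across repeated sessions.  Panel quality is
assessed with a fixed-effects three-way ANOVA (sample, session, judge and
their two-way interactions; with one observation per cell the three-way
interaction is the error term), Student-Newman-Keuls multiple comparisons,
and a judges-as-variables PCA that separates mere scale effects (all judges
load with one sign on the first component) from genuine disagreement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.decomposition import PCA as _PCA

from ._util import stage_index

__all__ = [
    "ATTRIBUTES",
    "PanelError",
    "BalancedDesignError",
    "AnovaTable",
    "SnkGrouping",
    "PanelPcaResult",
    "StageRegression",
    "validate_score_table",
    "three_way_anova",
    "snk_test",
    "panel_homogeneity_pca",
    "judge_screening",
    "attribute_stage_regression",
]

logger = logging.getLogger(__name__)

#: The six attributes scored by the panel.
ATTRIBUTES = ("color", "hardness", "cracking", "vegetal", "bitterness", "astringency")

_REQUIRED_COLUMNS = ("judge", "session", "sample", "attribute", "score")


class PanelError(ValueError):
    """Invalid sensory-score input."""


class BalancedDesignError(PanelError):
    """The judge x session x sample design has missing or duplicated cells."""


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table (judge, session, sample, attribute, score)."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise PanelError(f"score table missing columns: {missing}")
    unknown = set(table["attribute"].unique()) - set(ATTRIBUTES)
    if unknown:
        raise PanelError(f"unknown attributes: {sorted(unknown)} (expected {ATTRIBUTES})")
    scores = pd.to_numeric(table["score"], errors="coerce")
    if scores.isna().any():
        raise PanelError("non-numeric scores present")
    if scores.min() < 0 or scores.max() > 10:
        raise PanelError("scores must lie on the structured 0-10 scale")
    return table


@dataclass
class AnovaTable:
    """Fixed-effects ANOVA summary: one row per effect plus residual and total."""

    frame: pd.DataFrame  # index: effect; columns: SS, df, MS, F, p
    attribute: str

    def p_value(self, effect: str) -> float:
        return float(self.frame.loc[effect, "p"])


@dataclass
class SnkGrouping:
    """Student-Newman-Keuls letters display.

    ``letters[i]`` is the letter set of group i (input order); groups sharing
    a letter are not significantly different at ``alpha``.
    """

    means: np.ndarray
    letters: list
    alpha: float
    different: np.ndarray  # boolean matrix in input order


@dataclass
class PanelPcaResult:
    """Judges-as-variables PCA of the sample x judge mean-score matrix."""

    loadings: pd.DataFrame  # judges x components
    explained_variance_pct: np.ndarray
    diagnosis: str  # 'scale_effects' | 'disagreement'
    dropped_judges: list = field(default_factory=list)


@dataclass
class StageRegression:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def _score_cube(table: pd.DataFrame, attribute: str):
    """Pivot one attribute to a (judge, session, sample) array; enforce balance."""
    sub = table[table["attribute"] == attribute]
    if sub.empty:
        raise PanelError(f"no rows for attribute {attribute!r}")
    judges = np.sort(sub["judge"].unique())
    sessions = np.sort(sub["session"].unique())
    samples = sorted(sub["sample"].unique(), key=stage_index)
    counts = sub.groupby(["judge", "session", "sample"]).size()
    expected = pd.MultiIndex.from_product([judges, sessions, samples])
    counts = counts.reindex(expected, fill_value=0)
    bad = counts[counts != 1]
    if len(bad):
        cells = list(bad.index[:5])
        raise BalancedDesignError(
            f"{attribute}: {len(bad)} judge x session x sample cells are missing "
            f"or duplicated, e.g. {cells}"
        )
    cube = (
        sub.set_index(["judge", "session", "sample"])["score"]
        .astype(float)
        .reindex(expected)
        .to_numpy()
        .reshape(len(judges), len(sessions), len(samples))
    )
    return cube, judges, sessions, samples


def _balanced_anova(cube: np.ndarray) -> pd.DataFrame:
    """Closed-form SS decomposition for a balanced three-way layout, one
    observation per cell; the three-way interaction is the residual."""
    J, S, M = cube.shape
    g = cube.mean()
    mj = cube.mean(axis=(1, 2))
    ms = cube.mean(axis=(0, 2))
    mm = cube.mean(axis=(0, 1))
    mjs = cube.mean(axis=2)
    mjm = cube.mean(axis=1)
    msm = cube.mean(axis=0)

    ss = {
        "judge": S * M * float(((mj - g) ** 2).sum()),
        "session": J * M * float(((ms - g) ** 2).sum()),
        "sample": J * S * float(((mm - g) ** 2).sum()),
        "judge x session": M * float(((mjs - mj[:, None] - ms[None, :] + g) ** 2).sum()),
        "judge x sample": S * float(((mjm - mj[:, None] - mm[None, :] + g) ** 2).sum()),
        "session x sample": J * float(((msm - ms[:, None] - mm[None, :] + g) ** 2).sum()),
    }
    df = {
        "judge": J - 1,
        "session": S - 1,
        "sample": M - 1,
        "judge x session": (J - 1) * (S - 1),
        "judge x sample": (J - 1) * (M - 1),
        "session x sample": (S - 1) * (M - 1),
    }
    ss_total = float(((cube - g) ** 2).sum())
    ss_resid = ss_total - sum(ss.values())
    ss_resid = max(ss_resid, 0.0)
    df_resid = (J - 1) * (S - 1) * (M - 1)

    rows = []
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    for eff in ("sample", "session", "judge", "session x sample",
                "judge x sample", "judge x session"):
        msq = ss[eff] / df[eff] if df[eff] > 0 else np.nan
        if ms_resid and ms_resid > 0 and df[eff] > 0:
            F = msq / ms_resid
            p = float(_stats.f.sf(F, df[eff], df_resid))
        elif msq and msq > 0:
            F, p = np.inf, 0.0
        else:
            F, p = np.nan, np.nan  # not applicable: no variation anywhere
        rows.append((eff, ss[eff], df[eff], msq, F, p))
    rows.append(("residual", ss_resid, df_resid, ms_resid, np.nan, np.nan))
    rows.append(("total", ss_total, J * S * M - 1, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["effect", "SS", "df", "MS", "F", "p"]).set_index("effect")


def three_way_anova(table: pd.DataFrame, attribute: str) -> AnovaTable:
    """Fixed-effects sample/session/judge ANOVA for one attribute.

    Requires a balanced complete design with exactly one score per
    judge x session x sample cell; the (confounded) three-way interaction
    serves as the error term, so only the two-way interactions are testable.
    """
    cube, *_ = _score_cube(table, attribute)
    return AnovaTable(frame=_balanced_anova(cube), attribute=attribute)


def _groups_to_stats(groups):
    """Normalise SNK input to (means, pooled MS, df_error, harmonic n)."""
    first = groups[0]
    if isinstance(first, (tuple, list)) and len(first) == 3 and np.isscalar(first[0]):
        means = np.array([float(m) for m, _, _ in groups])
        sds = np.array([float(s) for _, s, _ in groups])
        ns = np.array([int(n) for _, _, n in groups])
        if np.any(ns < 2):
            raise PanelError("each group needs n >= 2")
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        if any(a.size < 2 for a in arrays):
            raise PanelError("each group needs at least 2 raw scores")
        means = np.array([a.mean() for a in arrays])
        sds = np.array([a.std(ddof=1) for a in arrays])
        ns = np.array([a.size for a in arrays])
    df_err = int((ns - 1).sum())
    ms_err = float((sds**2 * (ns - 1)).sum() / df_err)
    n_h = len(ns) / float((1.0 / ns).sum())  # harmonic mean for unequal n
    return means, ms_err, df_err, n_h


@lru_cache(maxsize=512)
def _studentized_range_quantile(alpha: float, p: int, df: int) -> float:
    """Upper-alpha studentized-range quantile q(alpha, p, df).

    Evaluating the distribution is expensive, so quantiles are memoised; the
    same (p, df) pairs recur throughout a stepwise procedure.
    """
    return float(_stats.studentized_range.ppf(1 - alpha, p, df))


def snk_test(groups: Sequence, alpha: float = 0.05) -> SnkGrouping:
    """Student-Newman-Keuls stepwise comparison with a letters display.

    ``groups`` is either a list of raw score arrays or of (mean, sd, n)
    tuples.  Means are sorted and ranges tested against studentized-range
    critical values q(alpha, p, df) that shrink with the stretch p; ranges
    inside a non-significant stretch are never declared different (the usual
    protection rule).  Letters are assigned in ascending-mean order.
    """
    if len(groups) < 2:
        raise PanelError("need at least 2 groups")
    means, ms_err, df_err, n_h = _groups_to_stats(groups)
    k = len(means)
    order = np.argsort(means, kind="stable")
    sorted_means = means[order]
    se = np.sqrt(ms_err / n_h)

    ns_intervals: list = []

    def crit(p: int) -> float:
        return _studentized_range_quantile(alpha, p, df_err)

    def rec(i: int, j: int) -> None:
        if j <= i:
            return
        diff = sorted_means[j] - sorted_means[i]
        if se == 0:
            significant = diff > 0
        else:
            significant = diff / se > crit(j - i + 1)
        if not significant:
            ns_intervals.append((i, j))
            return
        rec(i + 1, j)
        rec(i, j - 1)

    rec(0, k - 1)

    # Keep maximal non-significance intervals; uncovered groups get singletons.
    maximal = [
        (a, b) for (a, b) in set(ns_intervals)
        if not any((c <= a and b <= d) and (c, d) != (a, b) for (c, d) in ns_intervals)
    ]
    covered = set()
    for a, b in maximal:
        covered.update(range(a, b + 1))
    for i in range(k):
        if i not in covered:
            maximal.append((i, i))
    maximal.sort()

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters_sorted = [""] * k
    for letter, (a, b) in zip(alphabet, maximal):
        for i in range(a, b + 1):
            letters_sorted[i] += letter

    different = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            share = any(a <= i and j <= b for (a, b) in maximal)
            different[i, j] = different[j, i] = not share

    letters = [""] * k
    diff_input = np.zeros((k, k), dtype=bool)
    for si, gi in enumerate(order):
        letters[gi] = letters_sorted[si]
        for sj, gj in enumerate(order):
            diff_input[gi, gj] = different[si, sj]
    return SnkGrouping(means=means, letters=letters, alpha=alpha, different=diff_input)


def panel_homogeneity_pca(
    table: pd.DataFrame,
    attribute: str,
    variance_threshold: float = 60.0,
) -> PanelPcaResult:
    """Diagnose a judge x sample interaction as scale effects or disagreement.

    The samples x judges matrix of session-averaged scores is column
    standardized and decomposed by PCA.  When every judge loads with the same
    sign on the first component and that component explains at least
    ``variance_threshold`` percent, the judges agree on the sample ordering
    and differ only in how they use the scale ('scale_effects'); otherwise the
    interaction reflects genuine 'disagreement'.
    """
    sub = table[table["attribute"] == attribute]
    if sub.empty:
        raise PanelError(f"no rows for attribute {attribute!r}")
    mat = sub.pivot_table(index="sample", columns="judge", values="score", aggfunc="mean")
    mat = mat.reindex(sorted(mat.index, key=stage_index))
    if mat.shape[0] < 3 or mat.shape[1] < 3:
        raise PanelError("need at least 3 samples and 3 judges")

    sd = mat.std(axis=0, ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance judges: {dropped}", stacklevel=2)
        mat = mat.drop(columns=dropped)
        sd = sd.drop(index=dropped)
        if mat.shape[1] < 3:
            raise PanelError("fewer than 3 judges with score variance")
    Z = (mat - mat.mean(axis=0)) / sd

    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = _PCA(n_components=n_comp)
    pca.fit(Z.to_numpy())
    loadings = pca.components_.T * np.sqrt(pca.explained_variance_)
    explained = pca.explained_variance_ratio_ * 100.0

    first = loadings[:, 0]
    signs = np.sign(np.where(np.abs(first) < 1e-12, 0.0, first))
    nonzero = signs[signs != 0]
    same_sign = nonzero.size > 0 and (np.all(nonzero > 0) or np.all(nonzero < 0))
    diagnosis = (
        "scale_effects"
        if same_sign and explained[0] >= variance_threshold
        else "disagreement"
    )
    return PanelPcaResult(
        loadings=pd.DataFrame(
            loadings, index=mat.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
        ),
        explained_variance_pct=explained,
        diagnosis=diagnosis,
        dropped_judges=dropped,
    )


def judge_screening(
    table: pd.DataFrame,
    multiple: float = 1.5,
    min_remaining: int = 3,
) -> list:
    """Flag judges with outlying score dispersion; return the retained judges.

    For every judge, the within-(sample, attribute) variance of scores across
    sessions is averaged into a single repeatability statistic.  Judges whose
    statistic exceeds the panel mean by more than ``multiple`` panel standard
    deviations are discarded.  Refuses to screen below ``min_remaining``
    judges.
    """
    validate_score_table(table)
    per_cell = (
        table.groupby(["judge", "sample", "attribute"])["score"]
        .var(ddof=1)
        .dropna()
    )
    per_judge = per_cell.groupby("judge").mean()
    if per_judge.empty:
        raise PanelError("cannot compute per-judge dispersion (single session?)")
    center = per_judge.mean()
    spread = per_judge.std(ddof=1)
    if not np.isfinite(spread) or spread == 0:
        retained = per_judge.index.tolist()
    else:
        retained = per_judge.index[per_judge <= center + multiple * spread].tolist()
    flagged = sorted(set(per_judge.index) - set(retained))
    if flagged:
        logger.warning("screened out judges %s (dispersion rule %.2f x SD)", flagged, multiple)
    if len(retained) < min_remaining:
        raise PanelError(
            f"screening would leave {len(retained)} < {min_remaining} judges"
        )
    return sorted(retained)


def attribute_stage_regression(table: pd.DataFrame, attribute: str) -> StageRegression:
    """OLS of per-stage mean score on the ordinal stage index (1..k)."""
    sub = table[table["attribute"] == attribute]
    if sub.empty:
        raise PanelError(f"no rows for attribute {attribute!r}")
    means = sub.groupby("sample")["score"].mean()
    idx = np.array([stage_index(s) for s in means.index], dtype=float)
    if idx.size < 3:
        raise PanelError("need at least 3 stages")
    y = means.to_numpy(float)
    order = np.argsort(idx)
    idx, y = idx[order], y[order]
    if np.ptp(y) == 0:
        return StageRegression(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                               degenerate=True)
    res = _stats.linregress(idx, y)
    return StageRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
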