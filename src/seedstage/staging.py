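"""Percentile-based allocation of seeds to maturity stages.

Seed coats darken and lose chroma as grapes ripen, so lightness L* and chroma
C*ab are used as the staging criteria.  Seeds are ranked on a one-dimensional
ripeness score and split into k equally sized ordinal stages (MS1 = least
mature) by percentiles, which guarantees homogeneous group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import stage_label

__all__ = [
    "StagingError",
    "MaturityStage",
    "StageAssignment",
    "ripeness_score",
    "classify_by_percentiles",
    "split_sets",
]


class StagingError(ValueError):
    """Invalid staging input."""


@dataclass(frozen=True)
class MaturityStage:
    """Ordinal ripeness group, 1-based ('MS1' = least mature)."""

    index: int

    @property
    def label(self) -> str:
        return stage_label(self.index)


@dataclass(frozen=True)
class StageAssignment:
    seed_id: object
    stage: MaturityStage
    score: float


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "seed_id" not in df.columns:
            raise StagingError("record frame needs a seed_id column")
        if "C_ab" not in df.columns and {"a", "b"}.issubset(df.columns):
            df["C_ab"] = np.hypot(df["a"], df["b"])
        return df
    rows = []
    for r in records:
        rows.append({"seed_id": r.seed_id, "L": r.L_star, "C_ab": r.C_ab})
    return pd.DataFrame(rows)


def ripeness_score(records, mode: str = "composite") -> list:
    """One-dimensional ripeness coordinate per seed.

    mode='composite' (default) projects standardized (L*, C*ab) onto their
    first principal axis, signed so that the score increases with ripeness
    (i.e. with decreasing L*).  mode='L' and mode='C' use a single coordinate
    (negated L*, negated C*ab respectively, both of which fall with ripening).

    Returns a list of (seed_id, score) in input order.
    """
    df = _records_to_frame(records)
    if len(df) < 2:
        raise StagingError("need at least 2 records")
    L = df["L"].to_numpy(float)
    C = df["C_ab"].to_numpy(float)

    if mode == "L":
        return list(zip(df["seed_id"], (-L).tolist()))
    if mode == "C":
        return list(zip(df["seed_id"], (-C).tolist()))
    if mode != "composite":
        raise StagingError(f"unknown mode: {mode!r}")

    X = np.column_stack([L, C])
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise StagingError("degenerate input: zero variance in both L* and C*ab")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # First principal axis of the standardized coordinates.
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    axis = vt[0]
    score = Z @ axis
    # Polarity: ripeness rises as L* falls (and as chroma falls).  The L*
    # loading must be negative; if L* carried no variance, fall back to C*ab.
    kept_names = [n for n, k in zip(("L", "C"), keep) if k]
    ref = kept_names.index("L") if "L" in kept_names else kept_names.index("C")
    if axis[ref] > 0:
        score = -score
    return list(zip(df["seed_id"], score.tolist()))


def classify_by_percentiles(scores: Sequence, k: int = 5) -> list:
    """Split scored seeds into k contiguous, (near-)equal ordinal stages.

    Seeds are sorted by score with a stable tie-break on seed_id, then divided
    into k contiguous groups whose sizes differ by at most one (exactly equal
    when k divides n).  Stage 1 holds the lowest scores (least mature seeds).
    """
    items = list(scores)
    n = len(items)
    if k < 1:
        raise StagingError("k must be >= 1")
    if n < k:
        raise StagingError(f"cannot form {k} stages from {n} seeds")
    order = sorted(range(n), key=lambda i: (items[i][1], str(items[i][0])))
    bounds = np.array_split(np.arange(n), k)
    assignments = [None] * n
    for stage_idx, chunk in enumerate(bounds, start=1):
        stage = MaturityStage(stage_idx)
        for pos in chunk:
            i = order[pos]
            sid, sc = items[i]
            assignments[i] = StageAssignment(sid, stage, float(sc))
    return assignments


def split_sets(
    assignments: Iterable[StageAssignment],
    texture_size: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Stratified random split into a sensory set and a texture set.

    ``texture_size`` seeds are drawn preserving stage proportions (largest
    remainder allocation); the rest form the sensory set.  Reproducible given
    ``seed`` (or an explicit numpy Generator).
    """
    assignments = list(assignments)
    n = len(assignments)
    if texture_size < 0 or texture_size > n:
        raise StagingError(f"requested {texture_size} of {n} available seeds")
    if rng is None:
        rng = np.random.default_rng(seed)

    by_stage: dict = {}
    for a in assignments:
        by_stage.setdefault(a.stage.index, []).append(a)
    stages = sorted(by_stage)
    sizes = np.array([len(by_stage[s]) for s in stages], float)
    quota = sizes / n * texture_size
    counts = np.floor(quota).astype(int)
    remainder = texture_size - counts.sum()
    # Largest-remainder rounding, ties broken by stage order.
    frac_order = np.argsort(-(quota - counts), kind="stable")
    for j in frac_order[:remainder]:
        counts[j] += 1
    for s, c in zip(stages, counts):
        if c > len(by_stage[s]):
            raise StagingError(f"stage {s} has only {len(by_stage[s])} seeds, need {c}")

    texture, sensory = [], []
    for s, c in zip(stages, counts):
        members = by_stage[s]
        pick = set(rng.choice(len(members), size=c, replace=False).tolist())
        for i, a in enumerate(members):
            (texture if i in pick else sensory).append(a)
    return sensory, texture
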