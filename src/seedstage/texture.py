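"""Compression-test force-distance curve analysis for whole seeds.

A flat cylindrical probe compresses a lyophilised seed at constant speed
(default 1.0 mm/s, 500 samples/s) until the seed is squeezed to half of its
height.  The trace rises roughly linearly until the coat cracks (the break),
the force collapses, then rises again with successive subfragmentation peaks.
Ten parameters summarise each curve:

====  =====================  ===========================================
Np    count                  peaks registered during the assay
Bf    N                      force just before the first break
Bdc   N                      force drop across the break (brittleness)
E     N/mm                   slope of the pre-break rise (from 10 N on)
Be    mJ                     area under the curve up to the break
De    mJ                     area under the entire curve
Th    mm                     seed thickness = 2 x total probe travel
Bd    mm                     probe travel at the break
Si    fraction (<= 0.5)      Bd / Th
Ar    fraction (0, 1]        Be / De
====  =====================  ===========================================

Si and Ar are stored as fractions of 1 (0.24, not 24) to match how stage
summary tables are usually printed, even though both are ratio "percentages"
conceptually.

Events (peaks, the break) are located on a lightly smoothed copy of the trace
to suppress sensor flutter; the parameter values themselves (forces, energies,
slope) are measured on the raw trace at those locations, so that noise-free
curves are recovered exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "CurveError",
    "NoBreakError",
    "ForceDistanceCurve",
    "BreakEvent",
    "TextureProfile",
    "read_curve",
    "smooth_curve",
    "detect_peaks",
    "detect_break",
    "elasticity",
    "integrate_energy",
    "texture_profile",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

#: grams-force expressed in newtons: the 5.0 g trigger threshold.
DEFAULT_ACTIVATION_FORCE_N = 0.049


class CurveError(ValueError):
    """Malformed force-distance input."""


class NoBreakError(RuntimeError):
    """No peak qualifies as a break; the curve is flagged, no profile emitted."""


@dataclass
class ForceDistanceCurve:
    """Ordered (distance mm, force N) samples with acquisition metadata."""

    distance: np.ndarray
    force: np.ndarray
    sample_rate: float = 500.0
    probe_speed: float = 1.0
    activation_force: float = DEFAULT_ACTIVATION_FORCE_N

    def __post_init__(self) -> None:
        d = np.asarray(self.distance, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise CurveError("distance and force must be 1-D arrays of equal length")
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(d)):
            raise CurveError("non-finite samples in curve")
        if np.any(np.diff(d) < 0):
            raise CurveError("distances must be non-decreasing")
        self.distance, self.force = d, f

    def __len__(self) -> int:
        return len(self.distance)


@dataclass(frozen=True)
class BreakEvent:
    """First structural failure: the peak index and the force drop after it."""

    index: int
    distance: float
    force_before: float
    force_after_min: float

    def __post_init__(self):
        if not self.force_before > self.force_after_min:
            raise CurveError("break must drop the force")

    @property
    def drop(self) -> float:
        return self.force_before - self.force_after_min


@dataclass
class TextureProfile:
    """The ten per-seed compression parameters (see module docstring)."""

    Np: int
    Bf: float
    Bdc: float
    E: float
    Be: float
    De: float
    Th: float
    Bd: float
    Si: float
    Ar: float
    seed_id: Optional[object] = None

    def as_dict(self) -> dict:
        return {
            "Np": self.Np, "Bf": self.Bf, "Bdc": self.Bdc, "E": self.E,
            "Be": self.Be, "De": self.De, "Th": self.Th, "Bd": self.Bd,
            "Si": self.Si, "Ar": self.Ar,
        }


def read_curve(
    path,
    dialect: Optional[str] = None,
    probe_speed: float = 1.0,
    sample_rate: float = 500.0,
    activation_force: float = DEFAULT_ACTIVATION_FORCE_N,
) -> ForceDistanceCurve:
    """Read a CSV/TSV force trace and trim it to the triggered compression.

    Accepts either ``distance_mm,force_N`` columns or ``time_s,force_N`` (in
    which case distance = time x probe speed).  Leading samples below the
    activation force are trimmed and the distance re-zeroed at the trigger;
    any retract tail (distance decreasing after the maximum) is discarded.
    """
    path = Path(path)
    if not path.exists():
        raise CurveError(f"no such curve file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CurveError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "force_n" not in cols:
        raise CurveError(f"{path}: missing force_N column (found {list(df.columns)})")
    force = pd.to_numeric(df[cols["force_n"]], errors="coerce")
    if "distance_mm" in cols:
        dist = pd.to_numeric(df[cols["distance_mm"]], errors="coerce")
    elif "time_s" in cols:
        dist = pd.to_numeric(df[cols["time_s"]], errors="coerce") * probe_speed
    else:
        raise CurveError(f"{path}: need a distance_mm or time_s column")
    if force.isna().any() or dist.isna().any():
        bad = int((force.isna() | dist.isna()).sum())
        raise CurveError(f"{path}: {bad} non-numeric rows")

    d = dist.to_numpy(float)
    f = force.to_numpy(float)
    # Truncate the post-test retract (probe withdrawal reverses the distance).
    stop = int(np.argmax(d)) + 1
    d, f = d[:stop], f[:stop]
    # Trigger trim: drop the approach, re-zero distance where force first
    # reaches the activation threshold.
    above = np.nonzero(f >= activation_force)[0]
    if above.size == 0:
        raise CurveError(f"{path}: force never reaches the activation threshold")
    start = int(above[0])
    d, f = d[start:] - d[start], f[start:]
    if len(d) < 10:
        raise CurveError(f"{path}: only {len(d)} samples after trigger trimming")
    return ForceDistanceCurve(d, f, sample_rate=sample_rate,
                              probe_speed=probe_speed,
                              activation_force=activation_force)


def smooth_curve(curve: ForceDistanceCurve, window: int = 5) -> ForceDistanceCurve:
    """Centered moving average on the force channel; distances unchanged.

    ``window`` must be odd; endpoints use shrinking (one-sided) windows so the
    output has the same length.  window=1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise CurveError("window must be an odd count >= 1")
    if window > len(curve):
        raise CurveError(f"window {window} exceeds curve length {len(curve)}")
    if window == 1:
        return replace(curve, distance=curve.distance.copy(), force=curve.force.copy())
    sm = (
        pd.Series(curve.force)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return replace(curve, distance=curve.distance.copy(), force=sm)


def detect_peaks(curve: ForceDistanceCurve, min_prominence: float = 2.0) -> np.ndarray:
    """Indices of local force maxima with prominence >= ``min_prominence`` N.

    Intended to run on a smoothed curve.  Endpoints (including a final rising
    plateau) are never counted.  Np is the length of the returned list.
    """
    peaks, _ = _signal.find_peaks(curve.force, prominence=min_prominence)
    return peaks


def detect_break(
    curve: ForceDistanceCurve,
    peaks: np.ndarray,
    drop_fraction: float = 0.2,
) -> BreakEvent:
    """First peak followed by a rapid force collapse.

    The break is the first detected peak whose force falls, before the next
    peak (or the end of the trace), by at least ``drop_fraction`` of the peak
    force.  Raises :class:`NoBreakError` when no peak qualifies.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise NoBreakError("no peaks detected; cannot locate a break")
    f = curve.force
    for j, p in enumerate(peaks):
        end = peaks[j + 1] if j + 1 < peaks.size else len(f)
        if end <= p + 1:
            continue
        seg = f[p:end]
        fmin = float(seg.min())
        if f[p] - fmin >= drop_fraction * f[p]:
            return BreakEvent(
                index=int(p),
                distance=float(curve.distance[p]),
                force_before=float(f[p]),
                force_after_min=fmin,
            )
    raise NoBreakError(
        f"no peak shows a relative force drop >= {drop_fraction:.0%}"
    )


def elasticity(
    curve: ForceDistanceCurve,
    break_event: BreakEvent,
    force_floor: float = 10.0,
) -> float:
    """Pre-break stiffness: OLS slope of force vs distance, in N/mm.

    The regression runs from the first sample at or above ``force_floor``
    (default 10 N, skipping contact-settling flutter) through the break
    sample.
    """
    ib = break_event.index
    qualifying = np.nonzero(curve.force[: ib + 1] >= force_floor)[0]
    if qualifying.size == 0:
        raise CurveError(
            f"break force {break_event.force_before:.2f} N never reaches the "
            f"{force_floor} N floor"
        )
    i0 = int(qualifying[0])
    d = curve.distance[i0: ib + 1]
    f = curve.force[i0: ib + 1]
    if len(d) < 2 or np.ptp(d) == 0:
        raise CurveError("elasticity segment has no distance extent")
    res = _stats.linregress(d, f)
    return float(res.slope)


def integrate_energy(curve: ForceDistanceCurve, from_idx: int, to_idx: int) -> float:
    """Trapezoidal work integral over [from_idx, to_idx], in mJ (= N.mm)."""
    if not 0 <= from_idx < to_idx < len(curve):
        raise CurveError(f"invalid index range [{from_idx}, {to_idx}]")
    sl = slice(from_idx, to_idx + 1)
    return float(np.trapezoid(curve.force[sl], curve.distance[sl]))


def texture_profile(
    curve: ForceDistanceCurve,
    window: int = 5,
    min_prominence: float = 2.0,
    drop_fraction: float = 0.2,
    force_floor: float = 10.0,
    seed_id=None,
) -> TextureProfile:
    """Extract the full ten-parameter profile from one triggered curve.

    Peak and break locations come from the smoothed trace; forces, the slope
    and the energies are then measured on the raw trace, with the break index
    refined to the raw local maximum within half a smoothing window.
    """
    if len(curve) < 10:
        raise CurveError("curve too short")
    sm = smooth_curve(curve, window)
    peaks = detect_peaks(sm, min_prominence)
    event_sm = detect_break(sm, peaks, drop_fraction)

    half = window // 2
    lo = max(event_sm.index - half, 0)
    hi = min(event_sm.index + half + 1, len(curve))
    ib = lo + int(np.argmax(curve.force[lo:hi]))

    later = peaks[peaks > event_sm.index]
    valley_end = int(later[0]) if later.size else len(curve)
    if valley_end <= ib + 1:
        valley_end = min(ib + 2, len(curve))
    fmin = float(curve.force[ib + 1: valley_end].min()) if valley_end > ib + 1 else float(curve.force[ib])
    event = BreakEvent(
        index=ib,
        distance=float(curve.distance[ib]),
        force_before=float(curve.force[ib]),
        force_after_min=min(fmin, float(curve.force[ib]) - 1e-12),
    )

    Np = int(peaks.size)
    Bf = event.force_before
    Bdc = event.drop
    E = elasticity(curve, event, force_floor)
    Be = integrate_energy(curve, 0, ib)
    De = integrate_energy(curve, 0, len(curve) - 1)
    Th = 2.0 * float(curve.distance[-1])
    Bd = event.distance
    if Th <= 0:
        raise CurveError("zero probe travel")
    return TextureProfile(
        Np=Np, Bf=Bf, Bdc=Bdc, E=E, Be=Be, De=De, Th=Th, Bd=Bd,
        Si=Bd / Th, Ar=Be / De, seed_id=seed_id,
    )


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame with a leading seed_id column."""
    rows = []
    for p in profiles:
        row = {"seed_id": p.seed_id}
        row.update(p.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
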