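"""Synthetic cohorts with known ground truth: images, curves, panel scores.

Every pipeline stage can be exercised without instrument data.  The generator
emulates:

* cabinet photographs — ellipses on a 12 x 8 grid over a light-gray plate,
  colored per maturity stage along the greenish-light to dark-brown ripening
  trajectory in CIELAB (falling L* and C*ab), plus per-seed palette scatter
  and per-pixel sensor noise;
* compression traces — piecewise-linear rise at slope E to the break
  (Bd, Bf), a rapid drop of Bdc, then subfragmentation bumps until the probe
  reaches half the seed thickness; knots snap to the 0.002 mm acquisition
  grid so the analytic parameter values are exact on the sampled curve;
* sensory scores — score = clip(gain_j x stage_mean + bias_j + noise, 0, 10)
  with a real sample effect, a null session effect and per-judge scale
  effects (positive gains), the structure a well-trained but
  scale-heterogeneous panel produces.

Default stage trends follow the published Syrah stage-summary table
(:mod:`seedstage.reference`) for texture and the reported monotone attribute
directions for the sensory scores (color/hardness/cracking rise with
maturity; vegetal/bitterness/astringency fall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import draw as _skdraw

from .imaging import SeedImage
from .texture import ForceDistanceCurve, TextureProfile, DEFAULT_ACTIVATION_FORCE_N
from ._util import stage_label

__all__ = [
    "SynthError",
    "CohortSpec",
    "ImageGroundTruth",
    "PanelGroundTruth",
    "generate_seed_image",
    "generate_curve",
    "generate_panel_scores",
    "simulate_run",
]

_GRID_STEP_MM = 0.002  # 500 samples/s at 1.0 mm/s


class SynthError(ValueError):
    """Inconsistent cohort specification."""


# Stage palette: (L*, C*ab, hue deg) means walking from greenish-light to
# dark brown, the direction seed coats take during ripening.
_DEFAULT_PALETTE = (
    (62.0, 36.0, 95.0),
    (54.5, 30.0, 85.0),
    (47.0, 25.0, 75.0),
    (39.5, 19.0, 66.0),
    (32.0, 14.0, 58.0),
)
_DEFAULT_PALETTE_SD = (2.0, 1.5, 3.0)

# Per-stage texture trend means/SDs (Bf N, E N/mm, Th mm, Bdc N, Np count).
_DEFAULT_TEXTURE_TRENDS = {
    "Bf": ((50.42, 54.24, 58.18, 59.82, 56.78), (11.30, 9.14, 9.67, 12.49, 14.29)),
    "E": ((98.11, 104.92, 105.68, 111.32, 103.70), (16.90, 15.04, 13.20, 18.59, 17.84)),
    "Th": ((2.19, 3.17, 3.22, 3.24, 3.27), (0.26, 0.27, 0.26, 0.34, 0.33)),
    "Bdc": ((20.04, 20.88, 20.21, 22.93, 18.82), (8.10, 7.18, 6.65, 9.23, 8.66)),
    "Np": ((3.66, 3.92, 4.40, 4.58, 4.18), (1.39, 1.26, 1.48, 1.65, 1.29)),
}

# Per-stage sensory attribute means on the 0-10 scale; color/hardness/cracking
# rise with maturity, vegetal/bitterness/astringency fall.
_DEFAULT_SENSORY_TRENDS = {
    "color": (1.8, 3.0, 4.2, 5.4, 6.6),
    "hardness": (4.0, 4.8, 5.6, 6.4, 7.0),
    "cracking": (3.6, 4.4, 5.2, 6.0, 6.8),
    "vegetal": (7.0, 6.0, 5.0, 4.0, 3.2),
    "bitterness": (6.6, 5.9, 5.2, 4.5, 3.9),
    "astringency": (6.4, 5.8, 5.2, 4.6, 4.0),
}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_seeds: int = 96
    k_stages: int = 5
    stage_color_palette: tuple = _DEFAULT_PALETTE
    palette_sd: tuple = _DEFAULT_PALETTE_SD
    texture_trends: dict = field(default_factory=lambda: dict(_DEFAULT_TEXTURE_TRENDS))
    sensory_trends: dict = field(default_factory=lambda: dict(_DEFAULT_SENSORY_TRENDS))
    judge_gain_sd: float = 0.12
    judge_bias_sd: float = 0.5
    score_noise_sd: float = 0.8
    pixel_noise_sd: float = 2.5
    force_noise_sd: float = 1.0
    cell_px: int = 40
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_seeds < self.k_stages:
            raise SynthError("n_seeds must be >= k_stages")
        if len(self.stage_color_palette) < self.k_stages:
            raise SynthError("palette must cover every stage")
        for name, (means, sds) in self.texture_trends.items():
            if any(s < 0 for s in sds):
                raise SynthError(f"negative SD for {name}")
        # Monotone-direction sanity for the declared sensory trends.
        for attr in ("color", "hardness", "cracking"):
            m = self.sensory_trends[attr]
            if any(b < a for a, b in zip(m, m[1:])):
                raise SynthError(f"{attr} trend must be non-decreasing")
        for attr in ("vegetal", "bitterness", "astringency"):
            m = self.sensory_trends[attr]
            if any(b > a for a, b in zip(m, m[1:])):
                raise SynthError(f"{attr} trend must be non-increasing")


@dataclass
class ImageGroundTruth:
    """True stage and palette color of every grid cell."""

    stages: dict  # (row, col) -> stage index (1-based)
    lab_colors: dict  # (row, col) -> (L*, a*, b*)


@dataclass
class PanelGroundTruth:
    """True effect components behind a generated score table."""

    stage_means: dict  # attribute -> per-stage mean
    judge_gains: dict
    judge_biases: dict
    sample_effect: bool


def _balanced_stage_layout(n: int, k: int) -> np.ndarray:
    """Contiguous near-equal stage blocks (stage 1 first), sizes differ <= 1."""
    chunks = np.array_split(np.arange(n), k)
    out = np.empty(n, dtype=int)
    for s, c in enumerate(chunks, start=1):
        out[c] = s
    return out


def _lab_to_rgb8(lab: np.ndarray) -> np.ndarray:
    rgb = _skcolor.lab2rgb(lab.reshape(1, -1, 3)).reshape(-1, 3)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def generate_seed_image(
    spec: CohortSpec,
    rows: int = 8,
    cols: int = 12,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Render one cabinet image of rows x cols non-touching elliptical seeds.

    Stage assignment walks the grid row-major in contiguous near-equal blocks
    (stage 1 first).  Returns (SeedImage, ImageGroundTruth).  Deterministic
    given the spec's rng_seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    cell = spec.cell_px
    max_r = 0.42 * cell
    if max_r < 3:
        raise SynthError("cell_px too small for visible seeds")
    h, w = rows * cell, cols * cell
    img = np.full((h, w, 3), 235.0)
    img += rng.normal(0.0, spec.pixel_noise_sd * 0.4, size=img.shape)

    stages = _balanced_stage_layout(rows * cols, spec.k_stages)
    sdL, sdC, sdH = spec.palette_sd
    truth_stage, truth_lab = {}, {}
    i = 0
    for r in range(rows):
        for c in range(cols):
            stage = int(stages[i])
            i += 1
            L0, C0, H0 = spec.stage_color_palette[stage - 1]
            L = L0 + rng.normal(0, sdL)
            C = max(C0 + rng.normal(0, sdC), 0.0)
            Hdeg = H0 + rng.normal(0, sdH)
            a = C * np.cos(np.radians(Hdeg))
            b = C * np.sin(np.radians(Hdeg))
            rgb = _lab_to_rgb8(np.array([L, a, b], float))[0]

            cy = r * cell + cell / 2 + rng.uniform(-2, 2)
            cx = c * cell + cell / 2 + rng.uniform(-2, 2)
            ry = 0.24 * cell * rng.uniform(0.9, 1.1)
            rx = 0.34 * cell * rng.uniform(0.9, 1.1)
            if max(rx, ry) > max_r:
                raise SynthError("seed ellipse too large for grid cell")
            rr, cc = _skdraw.ellipse(
                cy, cx, ry, rx, shape=(h, w), rotation=rng.uniform(-0.4, 0.4)
            )
            img[rr, cc] = rgb.astype(float)
            img[rr, cc] += rng.normal(0, spec.pixel_noise_sd, size=(len(rr), 3))
            truth_stage[(r, c)] = stage
            truth_lab[(r, c)] = (float(L), float(a), float(b))

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = SeedImage(pixels=pixels, grid_rows=rows, grid_cols=cols)
    return image, ImageGroundTruth(stages=truth_stage, lab_colors=truth_lab)


def _snap(x: float) -> float:
    return round(x / _GRID_STEP_MM) * _GRID_STEP_MM


def _template_knots(Bf, E, Th, Bdc, Np, rng) -> list:
    """Piecewise-linear (distance, force) knots of one compression trace.

    Rise from the trigger force at slope E to (Bd, Bf); drop to Bf - Bdc over
    0.04 mm; then Np - 1 subfragmentation bumps climbing back toward Bf until
    the probe stops at Th / 2.  All knot distances snap to the sampling grid.
    """
    f0 = 0.5  # just above the 5 g trigger
    travel = _snap(Th / 2.0)
    Bd = _snap((Bf - f0) / E)
    if not 0 < Bd < travel - 0.15:
        raise SynthError(f"break distance {Bd:.3f} mm inconsistent with travel {travel:.3f} mm")
    Bf_eff = f0 + E * Bd  # force at the snapped break knot

    knots = [(0.0, f0), (Bd, Bf_eff)]
    drop_w = _snap(0.04)
    valley_f = Bf_eff - Bdc
    if valley_f <= 0:
        raise SynthError("break decline exceeds break force")
    d = Bd + drop_w
    knots.append((_snap(d), valley_f))
    # flat-ish valley floor before the load picks up again
    d = _snap(d + 0.03)
    knots.append((d, valley_f + 1.0))

    n_bumps = max(int(Np) - 1, 0)
    end_f = Bf_eff * rng.uniform(0.95, 1.1)
    if n_bumps:
        span = travel - d
        seg = span / (n_bumps + 1)
        level = valley_f
        for i in range(1, n_bumps + 1):
            peak_d = _snap(d + seg * i)
            dip_d = _snap(peak_d + 0.4 * seg)
            frac = i / (n_bumps + 1)
            peak_f = level + (end_f - valley_f) * frac + rng.uniform(5.0, 9.0)
            peak_f = min(peak_f, Bf_eff - 1.0)  # first peak stays the tallest
            dip_f = peak_f - rng.uniform(6.0, 10.0)
            if dip_d >= travel:
                break
            knots.append((peak_d, peak_f))
            knots.append((dip_d, dip_f))
            level = dip_f
    knots.append((travel, end_f))

    # De-duplicate snapped distances while keeping order strict.
    out = []
    for dd, ff in knots:
        if out and dd <= out[-1][0]:
            continue
        out.append((dd, ff))
    return out


def _sample_piecewise(knots) -> tuple:
    d_end = knots[-1][0]
    n = int(round(d_end / _GRID_STEP_MM)) + 1
    dist = np.arange(n) * _GRID_STEP_MM
    kd = np.array([k[0] for k in knots])
    kf = np.array([k[1] for k in knots])
    force = np.interp(dist, kd, kf)
    return dist, force


def _analytic_profile(knots, min_prominence: float) -> TextureProfile:
    """Closed-form parameters of a knot template (the generator's oracle)."""
    kd = np.array([k[0] for k in knots])
    kf = np.array([k[1] for k in knots])
    interior = [
        i for i in range(1, len(knots) - 1)
        if kf[i] > kf[i - 1] and kf[i] > kf[i + 1]
    ]
    # Adjacent knots are the local valleys, so min(rise, fall) is a
    # conservative lower bound on the peak prominence.
    peaks = [
        i for i in interior
        if min(kf[i] - kf[i - 1], kf[i] - kf[i + 1]) >= min_prominence
    ]
    ib = peaks[0]
    Bf = float(kf[ib])
    Bd = float(kd[ib])
    after = kf[ib:]
    # drop to the next template peak (or end)
    nxt = peaks[1] if len(peaks) > 1 else len(kf) - 1
    fmin = float(kf[ib:nxt + 1].min()) if nxt > ib else Bf
    Bdc = Bf - fmin
    Th = 2.0 * float(kd[-1])
    area = float(np.trapezoid(kf, kd))
    area_break = float(np.trapezoid(kf[: ib + 1], kd[: ib + 1]))
    E = (Bf - kf[0]) / Bd
    return TextureProfile(
        Np=len(peaks), Bf=Bf, Bdc=Bdc, E=float(E), Be=area_break, De=area,
        Th=Th, Bd=Bd, Si=Bd / Th, Ar=area_break / area,
    )


def generate_curve(
    spec: CohortSpec,
    stage: int,
    rng: Optional[np.random.Generator] = None,
    noise_sd: Optional[float] = None,
    min_prominence: float = 2.0,
) -> tuple:
    """One synthetic force-distance curve for a seed of the given stage.

    Returns (ForceDistanceCurve, TextureProfile ground truth).  With
    ``noise_sd=0`` the sampled curve passes exactly through the template, so
    extraction must recover the ground truth up to grid resolution.
    """
    if not 1 <= stage <= spec.k_stages:
        raise SynthError(f"stage {stage} outside 1..{spec.k_stages}")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if noise_sd is None:
        noise_sd = spec.force_noise_sd
    s = stage - 1
    t = spec.texture_trends
    Bf = float(np.clip(rng.normal(t["Bf"][0][s], t["Bf"][1][s]), 25.0, 95.0))
    E = float(np.clip(rng.normal(t["E"][0][s], t["E"][1][s]), 60.0, 160.0))
    Th = float(np.clip(rng.normal(t["Th"][0][s], t["Th"][1][s]), 1.6, 4.2))
    Bdc = float(np.clip(rng.normal(t["Bdc"][0][s], t["Bdc"][1][s]), 0.3 * Bf, 0.85 * Bf))
    Np = int(np.clip(round(rng.normal(t["Np"][0][s], t["Np"][1][s])), 2, 8))
    # keep the break well inside the stroke (template needs room for bumps)
    bd_max = min(0.45 * Th, Th / 2.0 - 0.16)
    E = max(E, (Bf - 0.5) / bd_max)

    knots = _template_knots(Bf, E, Th, Bdc, Np, rng)
    truth = _analytic_profile(knots, min_prominence)
    dist, force = _sample_piecewise(knots)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    curve = ForceDistanceCurve(
        dist, force, sample_rate=500.0, probe_speed=1.0,
        activation_force=DEFAULT_ACTIVATION_FORCE_N,
    )
    return curve, truth


def generate_panel_scores(
    spec: CohortSpec,
    n_judges: int = 17,
    n_sessions: int = 8,
    sample_effect: bool = True,
    gains: Optional[np.ndarray] = None,
    biases: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Long-format sensory score table with known effect components.

    score = clip(gain_j x stage_mean + bias_j + noise, 0, 10).  The session
    main effect is zero by construction; heterogeneous positive gains induce
    a judge x sample interaction of the pure scale-effect kind.  With
    ``sample_effect=False`` every stage shares one mean (the ANOVA null).
    Mixed-sign ``gains`` can be supplied to build a disagreeing panel.
    """
    if n_judges < 3 or n_sessions < 2:
        raise SynthError("need n_judges >= 3 and n_sessions >= 2")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    k = spec.k_stages
    if gains is None:
        gains = np.clip(rng.normal(1.0, spec.judge_gain_sd, size=n_judges), 0.6, 1.4)
    else:
        gains = np.asarray(gains, dtype=float)
        if gains.shape != (n_judges,):
            raise SynthError("gains must have one entry per judge")
    if biases is None:
        biases = rng.normal(0.0, spec.judge_bias_sd, size=n_judges)
    else:
        biases = np.asarray(biases, dtype=float)
        if biases.shape != (n_judges,):
            raise SynthError("biases must have one entry per judge")

    stage_means = {}
    cells = n_judges * n_sessions * k
    judge_col = np.repeat(np.arange(1, n_judges + 1), n_sessions * k)
    session_col = np.tile(np.repeat(np.arange(1, n_sessions + 1), k), n_judges)
    sample_col = np.tile([stage_label(m + 1) for m in range(k)], n_judges * n_sessions)
    parts = []
    for attr, trend in spec.sensory_trends.items():
        means = np.asarray(trend[:k], dtype=float)
        if not sample_effect:
            means = np.full(k, float(np.mean(trend[:k])))
        stage_means[attr] = means.tolist()
        noise = rng.normal(0.0, spec.score_noise_sd, size=(n_judges, n_sessions, k))
        raw = gains[:, None, None] * means[None, None, :] + biases[:, None, None] + noise
        scores = np.clip(raw, 0.0, 10.0)
        parts.append(
            pd.DataFrame(
                {
                    "judge": judge_col,
                    "session": session_col,
                    "sample": sample_col,
                    "attribute": attr,
                    "score": scores.reshape(cells),
                }
            )
        )
    table = pd.concat(parts, ignore_index=True)
    truth = PanelGroundTruth(
        stage_means=stage_means,
        judge_gains={j + 1: float(g) for j, g in enumerate(gains)},
        judge_biases={j + 1: float(b) for j, b in enumerate(biases)},
        sample_effect=sample_effect,
    )
    return table, truth


def simulate_run(
    spec: CohortSpec,
    outdir,
    n_texture_per_stage: int = 10,
    n_judges: int = 17,
    n_sessions: int = 8,
) -> dict:
    """Write a complete simulated study to ``outdir``.

    Produces ``images/cabinet_01.png``, ``curves/*.csv`` with a
    ``curves/manifest.csv`` (file, seed_id, stage), ``scores.csv`` and
    ``ground_truth.json``.  Returns a manifest dict of everything written.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    image, img_truth = generate_seed_image(spec, rng=rng)
    img_path = outdir / "images" / "cabinet_01.png"
    iio.imwrite(img_path, image.pixels)

    manifest_rows = []
    curve_truths = {}
    for stage in range(1, spec.k_stages + 1):
        for i in range(n_texture_per_stage):
            curve, truth = generate_curve(spec, stage, rng=rng)
            name = f"stage{stage}_seed{i+1:02d}.csv"
            pd.DataFrame(
                {"distance_mm": curve.distance, "force_N": curve.force}
            ).to_csv(outdir / "curves" / name, index=False)
            seed_id = f"T{stage}-{i+1:02d}"
            manifest_rows.append({"file": name, "seed_id": seed_id, "stage": stage})
            curve_truths[seed_id] = truth.as_dict()
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "curves" / "manifest.csv", index=False)

    scores, panel_truth = generate_panel_scores(
        spec, n_judges=n_judges, n_sessions=n_sessions, rng=rng
    )
    scores.to_csv(outdir / "scores.csv", index=False)

    truth_payload = {
        "rng_seed": spec.rng_seed,
        "image_stages": {f"{r},{c}": s for (r, c), s in img_truth.stages.items()},
        "curve_profiles": curve_truths,
        "panel": {
            "stage_means": panel_truth.stage_means,
            "judge_gains": panel_truth.judge_gains,
            "judge_biases": panel_truth.judge_biases,
            "sample_effect": panel_truth.sample_effect,
        },
    }
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=1, sort_keys=True))

    return {
        "images": [str(img_path)],
        "curves_dir": str(outdir / "curves"),
        "scores": str(outdir / "scores.csv"),
        "ground_truth": str(truth_path),
    }
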