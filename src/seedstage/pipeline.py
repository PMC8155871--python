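"""End-to-end orchestration: images -> staging -> texture -> panel -> integration.

One :func:`run_pipeline` call executes every stage on a directory layout like
the one :func:`seedstage.synth.simulate_run` writes, saving per-stage CSVs,
the correlation matrix, SNK letter tables, PCA outputs and a machine-readable
``summary.json`` (config hash, seed, every output file, headline numbers).
Re-running with the same config and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import imaging, staging, texture, panel, integrate
from ._util import stage_label, stage_index

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Paths and parameters of one reproducible run."""

    images_dir: str
    curves_dir: str
    scores_file: str
    output_dir: str
    ground_truth: Optional[str] = None

    k_stages: int = 5
    staging_mode: str = "composite"
    grid_rows: int = 8
    grid_cols: int = 12
    min_area_px: int = 30
    threshold_mode: str = "fixed"
    background_threshold: float = 0.75

    smooth_window: int = 5
    min_prominence: float = 2.0
    drop_fraction: float = 0.2
    force_floor: float = 10.0

    alpha: float = 0.05
    screening_multiple: float = 1.5

    corr_threshold: float = 0.80
    priorities: tuple = integrate.DEFAULT_PRIORITY

    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("images_dir", "curves_dir"):
            if not Path(getattr(self, name)).is_dir():
                raise PipelineError(f"pre-flight: {name} does not exist: {getattr(self, name)}")
        if not Path(self.scores_file).is_file():
            raise PipelineError(f"pre-flight: scores_file does not exist: {self.scores_file}")
        if self.k_stages < 2:
            raise PipelineError("pre-flight: k_stages must be >= 2")
        if not 0 < self.alpha < 1:
            raise PipelineError("pre-flight: alpha must lie in (0, 1)")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _read_images(cfg: RunConfig) -> list:
    import imageio.v3 as iio

    paths = sorted(Path(cfg.images_dir).glob("*.png")) + sorted(
        Path(cfg.images_dir).glob("*.tif*")
    )
    if not paths:
        raise PipelineError(f"imaging: no PNG/TIFF images in {cfg.images_dir}")
    out = []
    for p in paths:
        px = iio.imread(p)
        if px.ndim == 3 and px.shape[2] == 4:
            px = px[:, :, :3]
        out.append((p.name, imaging.SeedImage(px, cfg.grid_rows, cfg.grid_cols)))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; return the summary dict (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    summary: dict = {
        "config_hash": config.digest(),
        "rng_seed": config.rng_seed,
        "outputs": outputs,
    }

    # -- imaging + staging ------------------------------------------------
    try:
        records, areas, image_of_seed = [], [], {}
        for name, img in _read_images(config):
            regions = imaging.segment_seed_grid(
                img, config.min_area_px, config.threshold_mode, config.background_threshold
            )
            for reg in regions:
                rec = imaging.summarize_seed_color(reg, img)
                sid = f"{name}:{reg.seed_id[0]},{reg.seed_id[1]}"
                records.append((sid, rec))
                areas.append(reg.area_px)
                image_of_seed[sid] = name
    except Exception as exc:
        raise PipelineError(f"imaging stage failed: {exc}") from exc

    colors = pd.DataFrame(
        [
            {
                "seed_id": sid, "area_px": area,
                "L": r.L_star, "a": r.a_star, "b": r.b_star,
                "C_ab": r.C_ab, "h_ab": r.h_ab,
            }
            for (sid, r), area in zip(records, areas)
        ]
    )
    colors_path = outdir / "seed_colors.csv"
    colors.to_csv(colors_path, index=False)
    outputs["seed_colors"] = colors_path.name

    try:
        scored = staging.ripeness_score(
            colors.rename(columns={"seed_id": "seed_id"}), mode=config.staging_mode
        )
        assignments = staging.classify_by_percentiles(scored, k=config.k_stages)
    except Exception as exc:
        raise PipelineError(f"staging stage failed: {exc}") from exc
    assign_df = pd.DataFrame(
        [
            {"seed_id": a.seed_id, "score": a.score, "stage": a.stage.label}
            for a in assignments
        ]
    )
    assign_path = outdir / "stage_assignments.csv"
    assign_df.to_csv(assign_path, index=False)
    outputs["stage_assignments"] = assign_path.name

    # Optional ground-truth agreement
    if config.ground_truth and Path(config.ground_truth).is_file():
        truth = json.loads(Path(config.ground_truth).read_text())
        true_stages = truth.get("image_stages", {})
        hits = total = 0
        for a in assignments:
            cell = a.seed_id.split(":", 1)[1]
            if cell in true_stages:
                total += 1
                hits += int(true_stages[cell] == a.stage.index)
        summary["stage_recovery_agreement"] = hits / total if total else None

    # -- texture ----------------------------------------------------------
    try:
        curves_dir = Path(config.curves_dir)
        manifest_path = curves_dir / "manifest.csv"
        manifest = pd.read_csv(manifest_path) if manifest_path.exists() else None
        profiles, flagged = [], []
        files = (
            [curves_dir / f for f in manifest["file"]]
            if manifest is not None
            else sorted(p for p in curves_dir.glob("*.csv") if p.name != "manifest.csv")
        )
        for i, fp in enumerate(files):
            sid = manifest["seed_id"].iloc[i] if manifest is not None else fp.stem
            try:
                curve = texture.read_curve(fp)
                prof = texture.texture_profile(
                    curve,
                    window=config.smooth_window,
                    min_prominence=config.min_prominence,
                    drop_fraction=config.drop_fraction,
                    force_floor=config.force_floor,
                    seed_id=sid,
                )
                profiles.append((sid, i, prof))
            except texture.NoBreakError as exc:
                logger.warning("texture: %s flagged (no break): %s", fp.name, exc)
                flagged.append(str(fp.name))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"texture stage failed: {exc}") from exc
    if not profiles:
        raise PipelineError("texture stage failed: no curve yielded a profile")

    prof_df = texture.profiles_to_frame([p for _, _, p in profiles])
    if manifest is not None:
        stage_map = dict(zip(manifest["seed_id"].astype(str), manifest["stage"]))
        prof_df["stage"] = [int(stage_map[str(s)]) for s in prof_df["seed_id"]]
    prof_path = outdir / "texture_profiles.csv"
    prof_df.to_csv(prof_path, index=False)
    outputs["texture_profiles"] = prof_path.name
    summary["curves_flagged_no_break"] = flagged

    # -- panel ------------------------------------------------------------
    try:
        scores = pd.read_csv(config.scores_file)
        panel.validate_score_table(scores)
        anova_rows, snk_rows, pca_rows, regress_rows = [], [], {}, []
        for attr in panel.ATTRIBUTES:
            if attr not in set(scores["attribute"]):
                continue
            at = panel.three_way_anova(scores, attr)
            f = at.frame.reset_index()
            f.insert(0, "attribute", attr)
            anova_rows.append(f)

            sub = scores[scores["attribute"] == attr]
            stages_present = sorted(sub["sample"].unique(), key=stage_index)
            groups = [sub[sub["sample"] == s]["score"].to_numpy() for s in stages_present]
            snk = panel.snk_test(groups, alpha=config.alpha)
            for s, m, letters in zip(stages_present, snk.means, snk.letters):
                snk_rows.append(
                    {"attribute": attr, "stage": s, "mean": m, "letters": letters}
                )

            pca = panel.panel_homogeneity_pca(scores, attr)
            pca_rows[attr] = {
                "diagnosis": pca.diagnosis,
                "pc1_pct": float(pca.explained_variance_pct[0]),
            }
            reg = panel.attribute_stage_regression(scores, attr)
            regress_rows.append(
                {
                    "attribute": attr, "slope": reg.slope,
                    "intercept": reg.intercept, "r_squared": reg.r_squared,
                }
            )
        retained = panel.judge_screening(scores, multiple=config.screening_multiple)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"panel stage failed: {exc}") from exc

    anova_path = outdir / "panel_anova.csv"
    pd.concat(anova_rows, ignore_index=True).to_csv(anova_path, index=False)
    outputs["panel_anova"] = anova_path.name
    snk_path = outdir / "sensory_snk_letters.csv"
    pd.DataFrame(snk_rows).to_csv(snk_path, index=False)
    outputs["sensory_snk_letters"] = snk_path.name
    reg_path = outdir / "attribute_stage_regression.csv"
    pd.DataFrame(regress_rows).to_csv(reg_path, index=False)
    outputs["attribute_stage_regression"] = reg_path.name
    summary["panel_homogeneity"] = pca_rows
    summary["judges_retained"] = [int(j) for j in retained]

    # -- integration ------------------------------------------------------
    try:
        tex_for_summary = prof_df if "stage" in prof_df.columns else None
        summ = integrate.stage_summary(tex_for_summary, scores)
        corr = integrate.correlation_matrix(summ)
        kept, dropped_pairs = integrate.prune_redundant(
            corr, threshold=config.corr_threshold, priorities=config.priorities
        )
        pca_res = integrate.pca_biplot(summ)
    except Exception as exc:
        raise PipelineError(f"integration stage failed: {exc}") from exc

    means_path = outdir / "stage_means.csv"
    summ.means.to_csv(means_path)
    outputs["stage_means"] = means_path.name
    sds_path = outdir / "stage_sds.csv"
    summ.sds.to_csv(sds_path)
    outputs["stage_sds"] = sds_path.name
    corr_path = outdir / "correlation_matrix.csv"
    corr.rounded().to_csv(corr_path)
    outputs["correlation_matrix"] = corr_path.name
    load_path = outdir / "pca_loadings.csv"
    pca_res.loadings.to_csv(load_path)
    outputs["pca_loadings"] = load_path.name
    scores_path = outdir / "pca_scores.csv"
    pca_res.scores.to_csv(scores_path)
    outputs["pca_scores"] = scores_path.name
    biplot_path = outdir / "pca_biplot.svg"
    integrate.plot_biplot(pca_res, biplot_path)
    outputs["pca_biplot"] = biplot_path.name

    summary["n_seeds_imaged"] = int(len(colors))
    summary["n_profiles"] = int(len(prof_df))
    summary["variables_kept_after_pruning"] = kept
    summary["redundant_pairs_dropped"] = [
        {"dropped": d, "kept": k2, "r": round(r, 4)} for d, k2, r in dropped_pairs
    ]
    summary["pca_components_retained_kaiser"] = pca_res.n_retained
    summary["pca_explained_pct"] = [round(float(v), 4) for v in pca_res.explained_variance_pct]

    summary_path = outdir / "summary.json"
    outputs["summary"] = summary_path.name
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", summary_path)
    return summary
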