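"""End-to-end study orchestration.

Two reproduction pipelines built from the library modules:

* :func:`run_afm_study` — simulate AFM images for a "reduced" and an
  "untreated" conformer population (351 and 352 molecules by default),
  measure and classify every particle, and compare the two conditions;
* :func:`run_flexibility_study` — simulate a flexible and a rigid
  two-state dihedral trajectory, run dPCA + free-energy-surface +
  basin analysis on each.

All randomness flows from one top-level seed; a provenance block
(config hash, seed, version) makes deterministic stages reproducible
bit-identically.
"""

from __future__ import annotations

import logging
import time
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .afm_image import analyze_heightmap, write_heightmap
from .conform_stats import (compare_distributions, compare_open_fractions,
                            summarize)
from .dpca_landscape import dpca, fes_histogram, find_basins, sincos_embed
from .report import (AfmStudyReport, ComparisonReport, ConditionReport,
                     FlexibilityFixtureReport, FlexibilityStudyReport,
                     Provenance, StudyReport, SummaryBlock, config_sha256)
from .synthetic_afm import (NAMED_MODELS, AspectRatioModel, ScanConfig,
                            render_heightmap, sample_population)
from .synthetic_traj import TrajectoryConfig, simulate_trajectory

logger = logging.getLogger("conformetry")

__all__ = ["PipelineConfig", "run_afm_study", "run_flexibility_study",
           "reproduce_study", "load_config"]


class ScanModel(BaseModel):
    image_px: int = 512
    pixel_nm: float = 1.0
    tip_radius_nm: float = 8.0
    noise_sigma_nm: float = 0.06
    line_offset_sigma_nm: float = 0.15
    plane_tilt: tuple[float, float] = (0.02, 0.01)

    def to_scan(self) -> ScanConfig:
        return ScanConfig(**self.model_dump())


class TrajFixtureModel(BaseModel):
    n_frames: int = 200_000
    n_dihedrals: int = 10
    p_ab: float = 0.005
    p_ba: float = 0.010
    kappa: float = 40.0


class DpcaModel(BaseModel):
    bins: int = 60
    temperature_K: float = 300.0


class PipelineConfig(BaseModel):
    """Configuration of the end-to-end reproduction run."""

    seed: int = 0
    n_reduced: int = 351
    n_untreated: int = 352
    particles_per_image: int = 50
    scan: ScanModel = Field(default_factory=ScanModel)
    open_threshold: float = 3.0
    exclude_above: float = 10.0
    frac_thresholds: list[float] = Field(default_factory=lambda: [3.0, 5.0])
    dpca: DpcaModel = Field(default_factory=DpcaModel)
    flexible: TrajFixtureModel = Field(default_factory=TrajFixtureModel)
    rigid: TrajFixtureModel = Field(
        default_factory=lambda: TrajFixtureModel(p_ab=0.0, p_ba=0.0, kappa=120.0))
    save_images: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.n_reduced < 1 or self.n_untreated < 1:
            raise ValueError("each condition needs at least one molecule")
        if self.particles_per_image < 1:
            raise ValueError("particles_per_image must be >= 1")
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from a TOML file."""
    with open(path, "rb") as fh:
        return PipelineConfig.model_validate(tomllib.load(fh))


def _summary_block(summary) -> SummaryBlock:
    return SummaryBlock(**summary.to_dict())


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-28s %.1f s", name, t1 - t0)
    return t1


def simulate_condition(
    name: str,
    n: int,
    model: AspectRatioModel,
    scan: ScanConfig,
    particles_per_image: int,
    base_seed: int,
    out_dir: Optional[Path] = None,
) -> tuple[list, list[pd.DataFrame]]:
    """Render one condition as a batch of images; returns (maps, truths)."""
    maps, truths = [], []
    offset = 0
    batch = 0
    while offset < n:
        take = min(particles_per_image, n - offset)
        seed = base_seed + batch
        m = AspectRatioModel(model.family, model.parameters, seed=seed)
        specs = sample_population(take, m, geometry_defaults=scan)
        hmap, truth = render_heightmap(specs, scan, seed=seed + 10_000)
        truth = truth.copy()
        truth["id"] = truth["id"] + offset
        truth["image"] = batch
        maps.append(hmap)
        truths.append(truth)
        if out_dir is not None:
            write_heightmap(hmap, out_dir / f"{name}_{batch:02d}.tif")
            truth.to_csv(out_dir / f"{name}_{batch:02d}_truth.csv", index=False)
        offset += take
        batch += 1
    return maps, truths


def run_afm_study(cfg: PipelineConfig, out_dir: str | Path | None = None
                  ) -> AfmStudyReport:
    """Simulate, measure and compare the two imaging conditions."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    scan = cfg.scan.to_scan()
    t0 = time.perf_counter()

    conditions: dict[str, ConditionReport] = {}
    records_by_cond: dict[str, pd.DataFrame] = {}
    plan = [("reduced", cfg.n_reduced, 0), ("untreated", cfg.n_untreated, 500)]
    for name, n, seed_block in plan:
        model = NAMED_MODELS[name](seed=0)
        maps, truths = simulate_condition(
            name, n, model, scan, cfg.particles_per_image,
            base_seed=cfg.seed * 1000 + seed_block,
            out_dir=out if cfg.save_images else None)
        t0 = _stage(f"simulate[{name}]", t0)
        frames = []
        for i, hmap in enumerate(maps):
            rec = analyze_heightmap(
                hmap, tip_radius_nm=scan.tip_radius_nm,
                open_threshold=cfg.open_threshold,
                exclude_above=cfg.exclude_above)
            rec["image"] = i
            frames.append(rec)
        records = pd.concat(frames, ignore_index=True)
        truth = pd.concat(truths, ignore_index=True)
        records_by_cond[name] = records
        t0 = _stage(f"analyze[{name}]", t0)

        labeled = records[records["label"].isin(["closed", "open"])]
        meas = summarize(records, thresholds=cfg.frac_thresholds,
                         open_threshold=cfg.open_threshold)
        truth_sum = summarize(np.asarray(truth["R_true"]),
                              thresholds=cfg.frac_thresholds,
                              open_threshold=cfg.open_threshold)
        conditions[name] = ConditionReport(
            condition=name,
            n_molecules=n,
            n_detected=int(len(records)),
            n_labeled=int(len(labeled)),
            n_excluded=int((records["label"] == "excluded").sum()),
            summary=_summary_block(meas),
            truth_summary=_summary_block(truth_sum),
            open_fraction_error=float(meas.frac_open - truth_sum.frac_open),
        )
        if out is not None:
            records.to_csv(out / f"{name}_particles.csv", index=False)
            truth.to_csv(out / f"{name}_truth.csv", index=False)

    red, unt = conditions["reduced"], conditions["untreated"]
    z, pz = compare_open_fractions(
        red.summary.n_open, red.summary.n, unt.summary.n_open, unt.summary.n,
        method="proportion_z")
    orat, pf = compare_open_fractions(
        red.summary.n_open, red.summary.n, unt.summary.n_open, unt.summary.n,
        method="fisher")
    r_red = records_by_cond["reduced"]
    r_unt = records_by_cond["untreated"]
    U, pu = compare_distributions(
        r_red.loc[r_red["label"].isin(["closed", "open"]), "aspect_ratio"],
        r_unt.loc[r_unt["label"].isin(["closed", "open"]), "aspect_ratio"])
    comparison = ComparisonReport(
        open_counts=[red.summary.n_open, unt.summary.n_open],
        group_sizes=[red.summary.n, unt.summary.n],
        open_percent=[round(100.0 * red.summary.frac_open, 1),
                      round(100.0 * unt.summary.frac_open, 1)],
        proportion_z=z, proportion_z_p=pz,
        fisher_odds_ratio=orat, fisher_p=pf,
        mannwhitney_U=U, mannwhitney_p=pu,
    )
    report = AfmStudyReport(conditions=conditions, comparison=comparison)
    if out is not None:
        from .plots import boxplot_figure
        boxplot_figure(
            {k: records_by_cond[k] for k in ("reduced", "untreated")},
            out / "aspect_ratio_boxplot.png")
    _stage("compare", t0)
    return report


def run_flexibility_study(cfg: PipelineConfig,
                          out_dir: str | Path | None = None
                          ) -> FlexibilityStudyReport:
    """dPCA + free-energy-landscape analysis of two trajectory fixtures."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    fixtures: dict[str, FlexibilityFixtureReport] = {}
    t0 = time.perf_counter()
    for name, fx, seed_block in (("flexible", cfg.flexible, 7),
                                 ("rigid", cfg.rigid, 8)):
        tcfg = TrajectoryConfig(
            n_frames=fx.n_frames, n_dihedrals=fx.n_dihedrals,
            p_ab=fx.p_ab, p_ba=fx.p_ba, kappa=fx.kappa,
            seed=cfg.seed * 1000 + seed_block)
        traj = simulate_trajectory(tcfg)
        result = dpca(sincos_embed(traj))
        fes = fes_histogram(result.projections, bins=cfg.dpca.bins,
                            temperature_K=cfg.dpca.temperature_K)
        basins = find_basins(fes, max_basins=2)
        truth_ratio = None
        if traj.truth_states is not None and traj.truth_states.max() > 0:
            occ_a = float(np.mean(traj.truth_states == 0))
            hi, lo = max(occ_a, 1 - occ_a), min(occ_a, 1 - occ_a)
            truth_ratio = hi / lo if lo > 0 else None
        fixtures[name] = FlexibilityFixtureReport(
            fixture=name,
            n_frames=tcfg.n_frames,
            n_basins=len(basins.minima),
            basins=[{"delta_g_kj_mol": b.delta_g_kj_mol,
                     "occupancy": b.occupancy} for b in basins.minima],
            occupancy_ratio=basins.occupancy_ratio,
            barrier_kj_mol=basins.barrier_kj_mol,
            pc1_variance_fraction=float(
                result.eigenvalues[0] / result.total_variance)
            if result.total_variance > 0 else 0.0,
            truth_occupancy_ratio=truth_ratio,
        )
        if out is not None:
            from .plots import fes_figure
            np.savetxt(out / f"{name}_fes.csv",
                       fes.grid.filled(np.nan), delimiter=",", fmt="%.6f")
            fes_figure(fes, out / f"{name}_fes.png")
        t0 = _stage(f"flexibility[{name}]", t0)
    return FlexibilityStudyReport(fixtures=fixtures)


def reproduce_study(cfg: PipelineConfig,
                    out_dir: str | Path | None = None) -> StudyReport:
    """Run both studies and assemble the full validated report."""
    prov = Provenance(
        seed=cfg.seed,
        config_sha256=config_sha256(cfg.model_dump()),
        package_version=__version__,
    )
    report = StudyReport(
        provenance=prov,
        afm=run_afm_study(cfg, out_dir=out_dir),
        flexibility=run_flexibility_study(cfg, out_dir=out_dir),
    )
    if out_dir is not None:
        path = Path(out_dir) / "report.json"
        path.write_text(report.to_json())
        logger.info("report written to %s", path)
    return report
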