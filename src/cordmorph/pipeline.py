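"""End-to-end pipeline: generate → deform → straighten → register →
measure → reconstruct → stats, with per-stage logging and deterministic,
byte-stable artifacts for a fixed config and seed.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import geometry, io, morphometry, phantom, reconstruct, stats
from .volume import CORD_LABELS, VoxelLabelVolume, cord_extents, pad_volume

STAGE_ORDER = ("generate", "deform", "straighten", "register", "measure",
               "reconstruct", "stats")

#: lofted solids: name -> labels forming the (envelope) mask
LOFT_TARGETS: dict[str, tuple[str, ...]] = {
    "white_matter": ("white_matter",),
    "gray_matter": ("gray_matter",),
    "csf": ("white_matter", "gray_matter", "csf"),
    "dura": ("white_matter", "gray_matter", "csf", "dura"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 1
    spacing: float = 0.1
    n_profiles: int = 200
    n_points: int = 40
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    segments: list | None = None          # subset of segment names, None = all
    segment_length: float | None = None   # override per-segment length (mm)
    bend_amplitude: float = 1.5
    bend_wavelength: float = 120.0
    shrink: tuple = (10.0, 10.0, 45.0)
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        full = {s: True for s in STAGE_ORDER}
        full.update(self.stages or {})
        unknown = set(full) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = full
        self.shrink = tuple(float(v) for v in self.shrink)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _setup_logger(out_dir: Path, level: str) -> logging.Logger:
    logger = logging.getLogger("cordmorph.pipeline")
    logger.setLevel(getattr(logging, level.upper()))
    for h in list(logger.handlers):
        logger.removeHandler(h)
        h.close()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log", mode="a")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    logger.propagate = False
    return logger


def run_pipeline(config: PipelineConfig) -> int:
    """Execute the enabled stages in order; returns 0 on success.

    The first failing stage aborts with a :class:`StageError` naming it.
    Artifacts are written under ``config.out_dir``; reruns with the same
    config and seed produce byte-identical CSV/STL/NIfTI outputs.
    """
    out = Path(config.out_dir)
    log = _setup_logger(out, config.log_level)
    force = config.force

    state: dict = {}

    def load_volume(name: str) -> VoxelLabelVolume:
        if name in state:
            return state[name]
        p = out / f"{name}.nii"
        if not p.exists():
            raise FileNotFoundError(
                f"{name}.nii not found; run its producing stage first")
        vol = io.read_label_volume(p)
        state[name] = vol
        return vol

    def stage(name):
        def deco(fn):
            if not config.stages.get(name, False):
                log.info("stage %s: skipped", name)
                return
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
        return deco

    @stage("generate")
    def _generate():
        cfg = phantom.build_default_config(seed=config.seed,
                                           spacing=config.spacing)
        if config.segments:
            cfg = phantom.subset_config(cfg, list(config.segments),
                                        length=config.segment_length)
        log.info("generate: %d segments at %.3f mm, seed %d",
                 len(cfg.segments), config.spacing, config.seed)
        vol, truth = phantom.render_phantom(cfg)
        state["phantom"] = vol
        state["config"] = cfg
        io.write_label_volume(vol, out / "phantom.nii", force=force)
        io.write_csv(truth, out / "ground_truth.csv", force=force)
        io.write_csv(cfg.segment_table(), out / "segments.csv", force=force)
        io.write_manifest(out / "manifest.json", seed=config.seed, force=force,
                          spacing=config.spacing,
                          n_segments=len(cfg.segments),
                          shape=list(vol.shape),
                          stages={k: bool(v) for k, v in config.stages.items()})

    @stage("deform")
    def _deform():
        vol = load_volume("phantom")
        f = geometry.ScaleFactors(*config.shrink)
        shrunk = phantom.shrink_volume(vol, f)
        log.info("deform: shrink by (%g, %g, %g)%%, bend %g mm / %g mm",
                 *config.shrink, config.bend_amplitude, config.bend_wavelength)
        padded = pad_volume(shrunk, config.bend_amplitude + 0.5, axes=(0,))
        bent = phantom.bend_volume(padded, config.bend_amplitude,
                                   config.bend_wavelength)
        bent.meta.pop("true_centerline", None)
        state["deformed"] = bent
        io.write_label_volume(bent, out / "deformed.nii", force=force)

    @stage("straighten")
    def _straighten():
        try:
            vol = load_volume("deformed")
        except FileNotFoundError:
            vol = load_volume("phantom")
        cl = geometry.extract_centerline(vol, CORD_LABELS)
        log.info("straighten: centerline length %.1f mm, %d samples",
                 cl.total_length, len(cl.points))
        straight = geometry.straighten_volume(vol, cl)
        state["straightened"] = straight
        io.write_label_volume(straight, out / "straightened.nii", force=force)

    @stage("register")
    def _register():
        ref = load_volume("phantom")
        try:
            moving = load_volume("straightened")
        except FileNotFoundError:
            moving = load_volume("phantom")
        ref_ext = cord_extents(ref)
        factors = geometry.estimate_scale(moving, ref_ext)
        log.info("register: estimated elongation (%.1f, %.1f, %.1f)%%",
                 factors.ex, factors.ey, factors.ez)
        registered = geometry.apply_scale(moving, factors)
        # re-anchor z so segment boundaries line up with the reference
        ref_z0 = _cord_z_start(ref)
        reg_z0 = _cord_z_start(registered)
        registered.origin = (registered.origin[0], registered.origin[1],
                             registered.origin[2] + (ref_z0 - reg_z0))
        state["registered"] = registered
        io.write_label_volume(registered, out / "registered.nii", force=force)
        io.write_json({"ex": factors.ex, "ey": factors.ey, "ez": factors.ez},
                      out / "scale.json", force=force)

    @stage("measure")
    def _measure():
        vol = None
        for name in ("registered", "straightened", "phantom"):
            try:
                vol = load_volume(name)
                break
            except FileNotFoundError:
                continue
        if vol is None:
            raise FileNotFoundError("no volume available to measure")
        seg_table = io.read_csv(out / "segments.csv")
        log.info("measure: %d segments on %s", len(seg_table), name)
        table = morphometry.measure_all(vol, seg_table)
        io.write_csv(table, out / "morphometry.csv", force=force)
        truth_path = out / "ground_truth.csv"
        if truth_path.exists():
            truth = io.read_csv(truth_path)
            io.write_csv(morphometry.compare_to_truth(table, truth),
                         out / "recovery.csv", force=force)

    @stage("reconstruct")
    def _reconstruct():
        vol = load_volume("phantom")
        metrics_rows = []
        for name, labels in LOFT_TARGETS.items():
            stack = reconstruct.extract_profiles(vol, labels,
                                                 n_profiles=config.n_profiles,
                                                 n_points=config.n_points)
            mesh = reconstruct.loft_profiles(stack, provenance=name)
            mm = reconstruct.mesh_metrics(mesh)
            log.info("reconstruct: %s volume %.1f mm3, watertight=%s",
                     name, mm.volume, mm.watertight)
            io.write_stl(mesh, out / f"{name}.stl", force=force)
            if name == "white_matter":
                io.write_profiles_csv(stack, out / "white_matter_profiles.csv",
                                      force=force)
            metrics_rows.append({"solid": name, "volume_mm3": mm.volume,
                                 "surface_area_mm2": mm.surface_area,
                                 "watertight": mm.watertight,
                                 "n_faces": mm.n_faces})
        import pandas as pd
        io.write_csv(pd.DataFrame(metrics_rows), out / "mesh_metrics.csv",
                     force=force)

    @stage("stats")
    def _stats():
        table = io.read_csv(out / "morphometry.csv")
        report: dict = {}
        for quantity in ("dura_thickness", "csf_thickness"):
            sub = table[table["quantity"] == quantity].pivot_table(
                index="segment", columns="side_or_view", values="value")
            sub = sub.dropna()
            if len(sub) < 2 or sub.shape[1] < 2:
                log.warning("stats: not enough data for %s", quantity)
                continue
            data = stats.RepeatedMeasures(
                values=sub.to_numpy(float),
                block_ids=[str(i) for i in sub.index],
                treatment_ids=[str(c) for c in sub.columns])
            fr = stats.friedman_test(data)
            entry = {"chi2": fr.chi2, "df": fr.df, "p_value": fr.p_value,
                     "rank_sums": {t: float(v) for t, v in
                                   zip(data.treatment_ids, fr.rank_sums)}}
            if data.k >= 3:
                ph = stats.pairwise_posthoc(data)
                entry["pairwise"] = [
                    {"pair": list(pair), "z": float(z), "p_raw": float(pr),
                     "p_adjusted": float(pa)}
                    for pair, z, pr, pa in zip(ph.pairs, ph.z_statistics,
                                               ph.p_raw, ph.p_adjusted)]
            report[quantity] = entry
            log.info("stats: %s Friedman chi2=%.3f p=%.4f",
                     quantity, fr.chi2, fr.p_value)
        io.write_json(report, out / "stats.json", force=force)
        io.write_csv(stats.segment_summary(table), out / "summary.csv",
                     force=force)

    log.info("pipeline complete: %s", out)
    return 0


def _cord_z_start(volume: VoxelLabelVolume) -> float:
    mask = np.isin(volume.array, CORD_LABELS)
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("degenerate: no cord labels present")
    return volume.origin[2] + zs[0] * volume.spacing[2]
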