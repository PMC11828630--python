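"""Run configuration and the end-to-end pipeline driver.

A :class:`RunConfig` captures everything needed to reproduce a full
sweep-and-recommend run: the head model, wavelength, ground-truth CSF
assumption, sweep grid, photon budget, seed, and solver settings.  The
pipeline writes every artifact (reference fields, metric tables, error
surfaces, contours, recommendation) into an output directory together
with a manifest of content hashes, so a persisted config re-runs to
identical DA outputs and statistically identical (same-seed: identical)
MC outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import da, mc
from .fields import mirror_average
from .head_models import (
    DEFAULT_THICKNESSES_MM,
    build_concentric_spheres,
    build_layered_slab,
    place_probe,
)
from .metrics import DetectorSampler, compute_metric_set
from .optics import csf_sweep_grid, reference_properties
from .sweep import (
    aggregate_recommendation,
    extract_zero_contours,
    run_csf_sweep,
    save_contours_json,
    save_surfaces_csv,
)

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    model: str = "slab"  # "slab" | "spheres"
    wavelength: int = 830
    csf_ground_truth: str = "low"  # "low" | "semidiffusive"
    spacing: float = 1.0
    lateral_size: float = 120.0
    total_depth: float = 40.0
    sphere_radii: tuple[float, ...] = (80.0, 68.75, 66.02, 62.73)
    thicknesses: tuple[float, ...] = DEFAULT_THICKNESSES_MM
    separations: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0)
    short_separation: float = 8.4
    detector_radius: float = 1.5
    sweep_separations: tuple[float, ...] = (35.0,)
    metrics: tuple[str, ...] = ("Egm", "Phi", "Sgm", "Fgm")
    mua_max: float = 0.04
    mua_step: float = 0.002
    musp_max: float = 0.4
    musp_step: float = 0.02
    n_photons: int = 10_000_000
    seed: int = 1
    da_rtol: float = 1e-10
    da_csf_override: tuple[float, float] | None = None
    fold_symmetry: bool = True
    output_dir: str = "csfequiv_out"

    def validate(self) -> None:
        if self.model not in ("slab", "spheres"):
            raise ConfigError(f"unknown model {self.model!r}")
        if self.wavelength not in (690, 830):
            raise ConfigError(f"unsupported wavelength {self.wavelength}")
        if self.csf_ground_truth not in ("low", "semidiffusive"):
            raise ConfigError(f"unknown csf_ground_truth {self.csf_ground_truth!r}")
        if self.spacing <= 0 or self.n_photons < 1:
            raise ConfigError("spacing must be > 0 and n_photons >= 1")
        bad = set(self.metrics) - {"Egm", "Phi", "Sgm", "Fgm"}
        if bad:
            raise ConfigError(f"unknown metrics {sorted(bad)}")

    def build_model(self):
        if self.model == "slab":
            return build_layered_slab(
                thicknesses=self.thicknesses,
                lateral_size=self.lateral_size,
                total_depth=self.total_depth,
                spacing=self.spacing,
            )
        return build_concentric_spheres(self.sphere_radii, spacing=self.spacing)

    def build_probe(self, model):
        kwargs = {}
        if self.model == "spheres":
            kwargs = {"geometry": "sphere", "sphere_radius": self.sphere_radii[0]}
        return place_probe(
            model,
            separations=self.separations,
            short_separation=self.short_separation,
            detector_radius=self.detector_radius,
            **kwargs,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Unknown keys are an error (they are usually typos of real knobs);
    missing keys take their defaults.
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a JSON object")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("thicknesses", "separations", "sweep_separations", "metrics",
                "sphere_radii", "da_csf_override"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cfg), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig, progress: bool = False) -> dict:
    """Execute the full protocol and write all outputs plus a manifest.

    Stages: build geometry, Monte Carlo reference (forward + one adjoint
    per sweep separation) at the ground-truth CSF, DA sweep over the CSF
    grid, zero-error contours, and the pooled recommendation.  Returns
    the manifest dict (also written to ``manifest.json``).
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: dict = {"config": asdict(cfg), "stages": [], "files": {}}

    def log_stage(name, **info):
        manifest["stages"].append(
            {"stage": name, "t_elapsed_s": round(time.time() - t_start, 2), **info}
        )
        if progress:
            print(f"[{time.strftime('%T')}] {name} {info}", flush=True)

    model = cfg.build_model()
    probe = cfg.build_probe(model)
    model.save(out / "model")
    log_stage("model", shape=list(model.shape), spacing=cfg.spacing)

    props = reference_properties(cfg.wavelength, cfg.csf_ground_truth)
    fold_fwd = (0, 1) if (cfg.fold_symmetry and cfg.model == "slab") else ()
    fold_adj = (1,) if (cfg.fold_symmetry and cfg.model == "slab") else ()

    src = mc.Source(position=probe.source_position, direction=probe.source_direction)
    fwd_mc, stats = mc.run_forward_mc(
        model, props, src, n_photons=cfg.n_photons, seed=cfg.seed
    )
    if fold_fwd:
        fwd_mc.values = mirror_average(fwd_mc.values, fold_fwd)
    log_stage(
        "mc_forward",
        n_photons=cfg.n_photons,
        seed=cfg.seed,
        escaped=stats.escaped_weight,
        conservation_residual=stats.conservation_residual(),
    )
    adjoints_mc = {}
    for k, sep in enumerate(cfg.sweep_separations):
        det = probe.detector(sep)
        adj, astats = mc.run_adjoint_mc(
            model, props, det.position, n_photons=cfg.n_photons, seed=cfg.seed + 1 + k
        )
        if fold_adj:
            adj.values = mirror_average(adj.values, fold_adj)
        adjoints_mc[sep] = adj
        log_stage("mc_adjoint", separation=sep, seed=cfg.seed + 1 + k)

    sampler = DetectorSampler(radius=cfg.detector_radius)
    reference = compute_metric_set(
        model, props, probe, fwd_mc, adjoints_mc, sampler=sampler,
        meta={"seed": cfg.seed, "n_photons": cfg.n_photons, "csf": "ground-truth"},
    )
    import pandas as pd

    pd.DataFrame(reference.to_rows()).to_csv(
        out / "reference_metrics.csv", index=False
    )
    ref_path = out / "reference_metrics.json"
    ref_path.write_text(
        json.dumps(
            {
                "Egm": reference.Egm,
                "Phi_d": {str(k): v for k, v in reference.Phi_d.items()},
                "Sgm": {str(k): v for k, v in reference.Sgm.items()},
                "Fgm": {str(k): v for k, v in reference.Fgm.items()},
                "solver_tag": reference.solver_tag,
                "meta": reference.meta,
            },
            indent=1,
        )
    )
    log_stage("reference_metrics", Egm=reference.Egm)

    grid = csf_sweep_grid(cfg.mua_max, cfg.mua_step, cfg.musp_max, cfg.musp_step)
    base_props = props
    if cfg.da_csf_override is not None:
        base_props = props.with_csf(*cfg.da_csf_override)
    surfaces = run_csf_sweep(
        model,
        base_props,
        probe,
        grid,
        reference,
        metrics=cfg.metrics,
        separations=cfg.sweep_separations,
        sampler=sampler,
        rtol=cfg.da_rtol,
        progress=progress,
    )
    save_surfaces_csv(surfaces, out / "error_surfaces.csv")
    log_stage("sweep", cells=grid.n_cells, surfaces=len(surfaces))

    contour_sets = [extract_zero_contours(s) for s in surfaces if s.is_complete()]
    recommendation = (
        aggregate_recommendation(contour_sets, surfaces=surfaces)
        if len(contour_sets) >= 2
        else None
    )
    save_contours_json(contour_sets, out / "contours.json", recommendation)
    if recommendation is not None:
        log_stage("recommendation", centroid=recommendation.centroid,
                  exact=recommendation.exact)

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["files"][p.name] = _sha256(p)
    manifest["wall_time_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
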