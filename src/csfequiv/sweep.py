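"""CSF property sweep: error surfaces, zero contours, recommendations.

The optimization protocol: fix a Monte Carlo reference computed once at
the ground-truth CSF properties, then re-run the diffusion solver over a
(mua, musp) grid of candidate CSF equivalent properties, recording the
signed percentage error of each metric at each grid cell.  The locus
where a metric's error surface crosses zero -- the "zero-error contour"
-- is the family of CSF property pairs for which the diffusion model
exactly matches the reference for that metric; intersections of two
contours match two metrics at once, and the centroid of the pooled
intersections is the single recommended property pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString
from skimage import measure

from .da import assemble_system, run_adjoint_da, run_forward_da
from .head_models import HeadModel, Probe
from .metrics import MetricSet, compute_metric_set, signed_percent_error
from .optics import SweepGrid

__all__ = [
    "ErrorSurface",
    "ContourSet",
    "IntersectionReport",
    "run_csf_sweep",
    "compute_error_surface",
    "extract_zero_contours",
    "intersect_contours",
    "aggregate_recommendation",
]


@dataclass
class ErrorSurface:
    """Signed % error of one metric over the CSF sweep grid.

    ``eps[i, j]`` corresponds to ``grid.mua_values[i]``,
    ``grid.musp_values[j]``.
    """

    metric: str
    separation: float | None
    grid: SweepGrid
    eps: np.ndarray
    wavelength: float | None = None
    model_id: str | None = None
    reference_meta: dict = field(default_factory=dict)

    @property
    def tag(self) -> str:
        if self.separation is None:
            return self.metric
        return f"{self.metric}@{self.separation:g}mm"

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.eps).all())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (mua, musp) cell."""
        mua, musp = np.meshgrid(
            self.grid.mua_values, self.grid.musp_values, indexing="ij"
        )
        return pd.DataFrame(
            {
                "mua": mua.ravel(),
                "musp": musp.ravel(),
                "metric": self.metric,
                "separation": (
                    np.nan if self.separation is None else self.separation
                ),
                "eps_percent": self.eps.ravel(),
            }
        )


@dataclass
class ContourSet:
    """Zero-error polylines (or the error minimizer) for one surface."""

    polylines: list[np.ndarray]  # each (N, 2): columns (mua, musp)
    minimizer: tuple[float, float, float] | None  # (mua, musp, |eps|)
    metric: str
    separation: float | None
    wavelength: float | None = None
    model_id: str | None = None

    @property
    def tag(self) -> str:
        if self.separation is None:
            return self.metric
        return f"{self.metric}@{self.separation:g}mm"

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "separation": self.separation,
            "wavelength": self.wavelength,
            "model_id": self.model_id,
            "polylines": [p.tolist() for p in self.polylines],
            "minimizer": list(self.minimizer) if self.minimizer else None,
        }


@dataclass
class IntersectionReport:
    """Pairwise zero-contour intersections and their cluster center."""

    points: list[tuple[float, float]]
    pair_tags: list[tuple[str, str]]
    centroid: tuple[float, float] | None
    exact: bool = True  # False when no intersections existed anywhere

    def to_dict(self) -> dict:
        return {
            "points": [list(p) for p in self.points],
            "pair_tags": [list(t) for t in self.pair_tags],
            "centroid": list(self.centroid) if self.centroid else None,
            "exact": self.exact,
        }


def compute_metric_set_da(
    model: HeadModel,
    props,
    probe: Probe,
    separations: tuple[float, ...] = (35.0,),
    need_adjoint: bool = True,
    sampler=None,
    rtol: float = 1e-10,
    meta: dict | None = None,
) -> MetricSet:
    """One full DA metric evaluation (forward + adjoints, one property set)."""
    system = assemble_system(model, props, rtol=rtol)
    fwd = run_forward_da(model, props, probe.source_position, system=system)
    adjoints = {}
    if need_adjoint:
        for sep in separations:
            det = probe.detector(sep)
            adjoints[sep] = run_adjoint_da(model, props, det.position, system=system)
    return compute_metric_set(
        model, props, probe, fwd, adjoints, sampler=sampler, meta=meta
    )


def run_csf_sweep(
    model: HeadModel,
    base_props,
    probe: Probe,
    grid: SweepGrid,
    reference: MetricSet,
    metrics: tuple[str, ...] = ("Egm", "Phi", "Sgm", "Fgm"),
    separations: tuple[float, ...] = (35.0,),
    sampler=None,
    rtol: float = 1e-10,
    da_runner=None,
    progress: bool = False,
) -> list[ErrorSurface]:
    """Sweep CSF (mua, musp) and build one error surface per metric.

    ``reference`` is the fixed (normally Monte Carlo) metric set computed
    at the ground-truth CSF properties; only the diffusion inputs vary
    across the sweep.  ``da_runner`` may override the per-cell metric
    evaluation (signature ``(props) -> MetricSet``), which the tests use
    for self-reference and analytic checks.
    """
    need_adjoint = any(m in metrics for m in ("Sgm", "Fgm"))
    if da_runner is None:

        def da_runner(props):
            return compute_metric_set_da(
                model,
                props,
                probe,
                separations=separations,
                need_adjoint=need_adjoint,
                sampler=sampler,
                rtol=rtol,
            )

    surfaces = {
        (m, None if m == "Egm" else sep): np.full(grid.shape, np.nan)
        for m in metrics
        for sep in (separations if m != "Egm" else (None,))
    }
    for (i, j), (mua, musp) in grid.cells():
        props = base_props.with_csf(mua, musp)
        try:
            mset = da_runner(props)
        except Exception:
            continue  # cell stays NaN; surface marked incomplete
        for (m, sep), eps in surfaces.items():
            eps[i, j] = signed_percent_error(
                mset.value(m, sep), reference.value(m, sep)
            )
        if progress:
            print(f"sweep cell ({i},{j}) mua={mua:g} musp={musp:g} done", flush=True)

    return [
        ErrorSurface(
            metric=m,
            separation=sep,
            grid=grid,
            eps=eps,
            wavelength=getattr(base_props, "wavelength_nm", None),
            reference_meta=dict(reference.meta),
        )
        for (m, sep), eps in surfaces.items()
    ]


def compute_error_surface(
    model: HeadModel,
    probe: Probe,
    base_props,
    grid: SweepGrid,
    reference: MetricSet,
    metric: str = "Phi",
    separation: float = 35.0,
    **kwargs,
) -> ErrorSurface:
    """Single-metric convenience wrapper around :func:`run_csf_sweep`."""
    seps = (separation,) if metric != "Egm" else (35.0,)
    (surface,) = run_csf_sweep(
        model,
        base_props,
        probe,
        grid,
        reference,
        metrics=(metric,),
        separations=seps,
        **kwargs,
    )
    return surface


def _index_to_grid(points_ij: np.ndarray, grid: SweepGrid) -> np.ndarray:
    """Map fractional (row, col) indices to (mua, musp) coordinates."""
    mua = np.interp(
        points_ij[:, 0], np.arange(len(grid.mua_values)), grid.mua_values
    )
    musp = np.interp(
        points_ij[:, 1], np.arange(len(grid.musp_values)), grid.musp_values
    )
    return np.column_stack([mua, musp])


def _refine_minimizer(surface: ErrorSurface) -> tuple[float, float, float]:
    """|eps|-minimizing point, refined by a local quadratic fit.

    Fits a quadratic to |eps| over the 3x3 neighborhood of the argmin
    cell and returns its stationary point when it is a proper minimum
    inside the neighborhood; otherwise falls back to the cell center.
    """
    a = np.abs(surface.eps)
    i0, j0 = np.unravel_index(np.nanargmin(a), a.shape)
    ni, nj = a.shape
    i1, i2 = max(i0 - 1, 0), min(i0 + 2, ni)
    j1, j2 = max(j0 - 1, 0), min(j0 + 2, nj)
    ii, jj = np.meshgrid(np.arange(i1, i2), np.arange(j1, j2), indexing="ij")
    x = (ii - i0).ravel().astype(float)
    y = (jj - j0).ravel().astype(float)
    z = a[i1:i2, j1:j2].ravel()
    best = (float(i0), float(j0))
    if len(z) >= 6 and np.isfinite(z).all():
        A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        c0, cx, cy, cxx, cxy, cyy = coef
        H = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
        if np.all(np.linalg.eigvalsh(H) > 0):
            sol = np.linalg.solve(H, -np.array([cx, cy]))
            if np.all(np.abs(sol) <= 1.0):
                best = (float(i0 + sol[0]), float(j0 + sol[1]))
    pt = _index_to_grid(np.array([best]), surface.grid)[0]
    return (float(pt[0]), float(pt[1]), float(a[i0, j0]))


def extract_zero_contours(surface: ErrorSurface) -> ContourSet:
    """Marching-squares zero-level polylines of an error surface.

    When the surface does not change sign anywhere, no polyline exists
    and the |eps|-minimizing property pair is returned instead.
    """
    if not surface.is_complete():
        raise ValueError("error surface has unfinished cells")
    contours = measure.find_contours(surface.eps, level=0.0)
    polylines = [_index_to_grid(c, surface.grid) for c in contours if len(c) >= 2]
    minimizer = None if polylines else _refine_minimizer(surface)
    return ContourSet(
        polylines=polylines,
        minimizer=minimizer,
        metric=surface.metric,
        separation=surface.separation,
        wavelength=surface.wavelength,
        model_id=surface.model_id,
    )


def _pair_intersections(a: ContourSet, b: ContourSet) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    for pa in a.polylines:
        la = LineString(pa)
        for pb in b.polylines:
            geom = la.intersection(LineString(pb))
            if geom.is_empty:
                continue
            if geom.geom_type == "Point":
                pts.append((geom.x, geom.y))
            elif geom.geom_type in ("MultiPoint", "GeometryCollection"):
                for g in geom.geoms:
                    if g.geom_type == "Point":
                        pts.append((g.x, g.y))
                    else:
                        c = g.centroid
                        pts.append((c.x, c.y))
            else:  # collinear overlap: represent by its midpoint
                c = geom.centroid
                pts.append((c.x, c.y))
    # deduplicate within tolerance
    out: list[tuple[float, float]] = []
    for p in pts:
        if not any(abs(p[0] - q[0]) < 1e-9 and abs(p[1] - q[1]) < 1e-9 for q in out):
            out.append(p)
    return out


def intersect_contours(a: ContourSet, b: ContourSet) -> IntersectionReport:
    """All intersection points between two contour sets' polylines."""
    pts = _pair_intersections(a, b)
    centroid = tuple(np.mean(pts, axis=0)) if pts else None
    return IntersectionReport(
        points=pts,
        pair_tags=[(a.tag, b.tag)] * len(pts),
        centroid=centroid,
    )


def aggregate_recommendation(
    contour_sets: list[ContourSet],
    surfaces: list[ErrorSurface] | None = None,
    weights: dict[str, float] | None = None,
) -> IntersectionReport:
    """Pool pairwise contour intersections into one recommended pair.

    The recommendation is the (optionally weighted) centroid of all
    pairwise intersection points.  When no pair of contours intersects
    anywhere -- including because some metrics have no zero contour at
    all -- the fallback is the minimizer of the pooled |eps| surfaces
    (weighted sum), flagged ``exact=False``.
    """
    if len(contour_sets) < 2:
        raise ValueError("need at least two contour sets to aggregate")
    points: list[tuple[float, float]] = []
    tags: list[tuple[str, str]] = []
    wts: list[float] = []
    for a, b in combinations(contour_sets, 2):
        for p in _pair_intersections(a, b):
            points.append(p)
            tags.append((a.tag, b.tag))
            if weights:
                wts.append(
                    weights.get(a.metric, 1.0) * weights.get(b.metric, 1.0)
                )
            else:
                wts.append(1.0)
    if points:
        arr = np.asarray(points)
        w = np.asarray(wts)
        centroid = tuple(np.average(arr, axis=0, weights=w))
        return IntersectionReport(points=points, pair_tags=tags, centroid=centroid)
    if surfaces:
        total = None
        for s in surfaces:
            wgt = weights.get(s.metric, 1.0) if weights else 1.0
            contrib = wgt * np.abs(s.eps)
            total = contrib if total is None else total + contrib
        pooled = ErrorSurface(
            metric="pooled",
            separation=None,
            grid=surfaces[0].grid,
            eps=total,
        )
        mua, musp, _ = _refine_minimizer(pooled)
        return IntersectionReport(
            points=[], pair_tags=[], centroid=(mua, musp), exact=False
        )
    return IntersectionReport(points=[], pair_tags=[], centroid=None, exact=False)


def save_surfaces_csv(surfaces: list[ErrorSurface], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in surfaces], ignore_index=True).to_csv(
        path, index=False
    )


def save_contours_json(
    contour_sets: list[ContourSet],
    path: str | Path,
    recommendation: IntersectionReport | None = None,
) -> None:
    payload: dict = {"contours": [c.to_dict() for c in contour_sets]}
    if recommendation is not None:
        payload["recommendation"] = recommendation.to_dict()
    Path(path).write_text(json.dumps(payload, indent=1))
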