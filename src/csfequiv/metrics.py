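"""fNIRS / photobiomodulation metrics from Green's-function fluence.

Four quantities summarise a forward model for brain applications:

* ``Egm``   -- energy deposited in gray matter per unit injected power:
  the integral of fluence x mua over the GM region (photobiomodulation
  dose metric).
* ``Phi_d`` -- detected fluence at a source-detector separation,
  trilinearly sampled at the detector coordinate.
* ``Sgm``   -- total gray-matter sensitivity: the absorption Jacobian
  J(r) = -Phi(r, r_s) Phi(r, r_d) / Phi(r_d, r_s) integrated over GM;
  non-positive by construction (raising mua lowers the reading).
* ``Fgm``   -- the GM fraction of whole-head sensitivity, in (0, 1].

The signed percentage error of a diffusion-model metric against its
Monte Carlo reference, (M_DA - M_MC) / M_MC x 100, is negative whenever
the diffusion model underestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import FluenceField, sample_trilinear
from .head_models import GM, HeadModel, Probe

__all__ = [
    "DetectorSampler",
    "POINT_SAMPLER",
    "DEFAULT_SAMPLER",
    "DetectorReading",
    "JacobianField",
    "MetricSet",
    "EmptyRegionError",
    "energy_deposition",
    "detector_fluence",
    "jacobian",
    "region_sensitivity",
    "sensitivity_fraction",
    "signed_percent_error",
    "voxelwise_percent_error",
    "compute_metric_set",
]


class EmptyRegionError(ValueError):
    """Requested tissue region has no voxels in the model."""


@dataclass(frozen=True)
class DetectorSampler:
    """Detector-reading convention shared by both solvers.

    The reading is the fluence interpolated at the detector coordinate.
    Because the fields live at voxel centers, a surface detector sits
    half a voxel above the first center plane; with
    ``surface_extrapolate`` the value at the true boundary is obtained
    by linear extrapolation from the first two center planes (matching a
    solver with surface nodes).  With ``radius > 0`` the reading is
    averaged over the detector disk on a fixed sub-grid -- the physical
    reading of a disk-shaped detector, and a large variance reducer for
    the Monte Carlo field.  Applying the identical rule to both solvers
    is what keeps their readings comparable.
    """

    radius: float = 1.5
    step: float = 0.375
    surface_extrapolate: bool = True

    def _plane(self, field: FluenceField, point) -> float:
        if self.radius <= 0:
            return sample_trilinear(field.values, field.model, point)
        n = int(self.radius / self.step)
        vals = []
        r2 = self.radius**2
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                dx, dy = i * self.step, j * self.step
                if dx * dx + dy * dy <= r2:
                    vals.append(
                        sample_trilinear(
                            field.values,
                            field.model,
                            (point[0] + dx, point[1] + dy, point[2]),
                        )
                    )
        return float(np.mean(vals))

    def __call__(self, field: FluenceField, position, inward=(0.0, 0.0, 1.0)) -> float:
        h = field.model.spacing
        pos = np.asarray(position, dtype=float)
        if not self.surface_extrapolate:
            return self._plane(field, pos)
        # extrapolate the first two voxel-center planes along the inward
        # normal back to the boundary point itself
        nrm = np.asarray(inward, dtype=float)
        p0 = self._plane(field, pos + 0.5 * h * nrm)
        p1 = self._plane(field, pos + 1.5 * h * nrm)
        return 1.5 * p0 - 0.5 * p1


#: Point sampling at the voxel-center hull (clamped trilinear).
POINT_SAMPLER = DetectorSampler(radius=0.0, surface_extrapolate=False)

#: Default reading: 1.5-mm disk average, surface-extrapolated.
DEFAULT_SAMPLER = DetectorSampler()


class DivisionGuardError(ZeroDivisionError):
    """A normalizing quantity (detector reading, reference metric) is zero."""


@dataclass(frozen=True)
class DetectorReading:
    value: float
    separation: float
    position: tuple[float, float, float]

    def __float__(self) -> float:
        return self.value


@dataclass
class JacobianField:
    """Per-voxel absorption sensitivity, units mm (per mua, per volume)."""

    values: np.ndarray
    model: HeadModel
    detector_separation: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class MetricSet:
    """All four metrics for one model / property / probe configuration."""

    Egm: float
    Phi_d: dict[float, float]
    Sgm: dict[float, float]
    Fgm: dict[float, float]
    solver_tag: str
    meta: dict = field(default_factory=dict)

    def value(self, metric: str, separation: float | None = None) -> float:
        if metric == "Egm":
            return self.Egm
        table = {"Phi": self.Phi_d, "Sgm": self.Sgm, "Fgm": self.Fgm}[metric]
        return table[separation]

    def to_rows(self) -> list[dict]:
        """One record per (metric, separation), with provenance columns."""
        rows = [
            {"metric": "Egm", "separation": None, "value": self.Egm,
             "solver_tag": self.solver_tag, **self.meta}
        ]
        for name, table in (("Phi", self.Phi_d), ("Sgm", self.Sgm),
                            ("Fgm", self.Fgm)):
            for sep, val in sorted(table.items()):
                rows.append(
                    {"metric": name, "separation": sep, "value": val,
                     "solver_tag": self.solver_tag, **self.meta}
                )
        return rows


def _check_region(model: HeadModel, region: int, allow_empty: bool) -> np.ndarray:
    mask = model.labels == region
    if not mask.any() and not allow_empty:
        raise EmptyRegionError(f"region label {region} absent from the model")
    return mask


def energy_deposition(
    fluence: FluenceField,
    model: HeadModel,
    props,
    region: int = GM,
    allow_empty: bool = False,
) -> float:
    """Absorbed power fraction in one region: sum Phi * mua * voxel volume."""
    mask = _check_region(model, region, allow_empty)
    if not mask.any():
        return 0.0
    mua = props[region].mua
    return float(fluence.values[mask].sum() * mua * model.voxel_volume)


def detector_fluence(fluence: FluenceField, position) -> float:
    """Fluence sampled at the detector coordinate (trilinear, clamped)."""
    return sample_trilinear(fluence.values, fluence.model, position)


def jacobian(
    forward: FluenceField,
    adjoint: FluenceField,
    det_reading: float,
    separation: float | None = None,
) -> JacobianField:
    """Absorption Jacobian J(r) = -Phi_fwd(r) Phi_adj(r) / Phi_d.

    Symmetric in (forward, adjoint); everywhere <= 0.
    """
    det = float(det_reading)
    if det <= 0.0:
        raise DivisionGuardError("detector reading must be positive")
    if forward.values.shape != adjoint.values.shape:
        raise ValueError("forward and adjoint fields must share one grid")
    return JacobianField(
        values=-(forward.values * adjoint.values) / det,
        model=forward.model,
        detector_separation=separation,
    )


def region_sensitivity(
    J: JacobianField,
    model: HeadModel,
    region: int = GM,
    allow_empty: bool = False,
) -> float:
    """Summed sensitivity over one region (<= 0), units mm^3 x mm^-1... -> mm."""
    mask = _check_region(model, region, allow_empty)
    if not mask.any():
        return 0.0
    return float(J.values[mask].sum() * model.voxel_volume)


def total_sensitivity(J: JacobianField, model: HeadModel) -> float:
    """Whole-domain summed sensitivity (all tissue labels)."""
    mask = model.labels > 0
    return float(J.values[mask].sum() * model.voxel_volume)


def sensitivity_fraction(
    J: JacobianField, model: HeadModel, region: int = GM
) -> float:
    """Region share of total sensitivity, in (0, 1] for tissue subregions."""
    total = total_sensitivity(J, model)
    if total == 0.0:
        raise DivisionGuardError("total sensitivity is zero")
    return region_sensitivity(J, model, region, allow_empty=True) / total


def signed_percent_error(m_da: float, m_mc: float) -> float:
    """(M_DA - M_MC) / M_MC x 100; negative when DA underestimates."""
    if m_mc == 0.0:
        raise DivisionGuardError("reference metric is zero")
    return (m_da - m_mc) / m_mc * 100.0


def voxelwise_percent_error(
    da: FluenceField,
    mc: FluenceField,
    mc_floor: float = 0.0,
) -> np.ndarray:
    """Per-voxel signed percentage error map, NaN where MC lacks signal.

    ``mc_floor`` masks voxels whose MC fluence is at or below the given
    noise floor (absolute, mm^-2); those cells carry no reliable
    reference and are excluded from spatial error statistics.
    """
    out = np.full(mc.values.shape, np.nan)
    ok = mc.values > mc_floor
    out[ok] = (da.values[ok] - mc.values[ok]) / mc.values[ok] * 100.0
    return out


def compute_metric_set(
    model: HeadModel,
    props,
    probe: Probe,
    forward: FluenceField,
    adjoints: dict[float, FluenceField],
    solver_tag: str | None = None,
    sampler: DetectorSampler | None = None,
    meta: dict | None = None,
) -> MetricSet:
    """Assemble the full metric set from precomputed fields.

    ``adjoints`` maps separation (mm) to the detector-sourced field;
    Phi_d is computed for every probe detector, Sgm/Fgm only for
    separations with an adjoint field.  ``sampler`` sets the detector-
    reading convention (default: 1.5-mm disk, surface-extrapolated),
    applied identically regardless of the solver that made the fields.
    """
    if sampler is None:
        sampler = DEFAULT_SAMPLER
    phi_d = {
        d.separation: sampler(forward, d.position)
        for d in probe.detectors
    }
    sgm = {}
    fgm = {}
    for sep, adj in adjoints.items():
        J = jacobian(forward, adj, phi_d[sep], separation=sep)
        sgm[sep] = region_sensitivity(J, model, GM)
        fgm[sep] = sensitivity_fraction(J, model, GM)
    return MetricSet(
        Egm=energy_deposition(forward, model, props, GM),
        Phi_d=phi_d,
        Sgm=sgm,
        Fgm=fgm,
        solver_tag=solver_tag or forward.solver_tag,
        meta=meta or {},
    )
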