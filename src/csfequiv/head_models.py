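"""Synthetic head geometries and probe layouts.

The study geometry is a five-layer head model: a slab with combined
scalp/skull, cerebrospinal fluid (CSF), gray matter (GM) and white matter
(WM) stacked along depth, surrounded by a non-scattering exterior.  A
concentric-sphere analog provides a curved-surface variant with the same
layer thicknesses.  Both are realised on a single structured voxel grid
that is shared verbatim by the Monte Carlo and diffusion solvers, so that
any DA-vs-MC discrepancy is attributable to the physics and not to the
discretization.

Conventions
-----------
* World units are mm; the grid is isotropic with spacing ``h``.
* Voxel ``(i, j, k)`` spans the half-open cell
  ``[i*h, (i+1)*h) x [j*h, (j+1)*h) x [k*h, (k+1)*h)`` relative to the
  origin; field values live at voxel centers.
* Labels: 0 = exterior, 1 = scalp/skull, 2 = CSF, 3 = GM, 4 = WM.
* For the slab the depth axis is ``z`` (axis 2) and the tissue-air
  surface is the plane ``z = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EXTERIOR",
    "SCALP_SKULL",
    "CSF",
    "GM",
    "WM",
    "REGION_MAP",
    "DEFAULT_THICKNESSES_MM",
    "InvalidGeometryError",
    "HeadModel",
    "Detector",
    "Probe",
    "build_layered_slab",
    "build_concentric_spheres",
    "place_probe",
]

EXTERIOR = 0
SCALP_SKULL = 1
CSF = 2
GM = 3
WM = 4

REGION_MAP = {
    EXTERIOR: "exterior",
    SCALP_SKULL: "scalp_skull",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
}

#: Mean layer thicknesses (mm) of the head model: scalp/skull, CSF, GM
#: and the minimum WM depth below GM.
DEFAULT_THICKNESSES_MM = (11.25, 2.73, 3.29, 4.23)


class InvalidGeometryError(ValueError):
    """Raised for non-physical geometry parameters."""


class OutOfBoundsError(ValueError):
    """Raised when a probe element does not fit on the model surface."""


@dataclass
class HeadModel:
    """Labeled voxel volume shared by the MC and DA solvers.

    Attributes
    ----------
    labels : ndarray of uint8, shape (nx, ny, nz)
        Per-voxel tissue label.
    spacing : float
        Isotropic voxel edge length in mm.
    origin : tuple of float
        World coordinate of the corner of voxel (0, 0, 0).
    region_map : dict
        Label -> tissue-name mapping.
    """

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_map: dict[int, str] = field(default_factory=lambda: dict(REGION_MAP))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing**3)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_volume(self, label: int) -> float:
        """Total volume (mm^3) of all voxels carrying ``label``."""
        return float(np.count_nonzero(self.labels == label)) * self.voxel_volume

    def world_extent(self) -> tuple[float, float, float]:
        return tuple(n * self.spacing for n in self.shape)

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Center coordinates (mm) of voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    # -- serialization: JSON header + raw little-endian uint8 volume -------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "shape": list(self.shape),
            "spacing": self.spacing,
            "origin": list(self.origin),
            "region_map": {str(k): v for k, v in self.region_map.items()},
            "dtype": "uint8",
            "order": "C",
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        self.labels.astype("<u1").tofile(path.with_suffix(".raw"))

    @classmethod
    def load(cls, path: str | Path) -> "HeadModel":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        labels = np.fromfile(path.with_suffix(".raw"), dtype="<u1").reshape(
            header["shape"]
        )
        return cls(
            labels=labels,
            spacing=float(header["spacing"]),
            origin=tuple(header["origin"]),
            region_map={int(k): v for k, v in header["region_map"].items()},
        )


@dataclass(frozen=True)
class Detector:
    position: tuple[float, float, float]
    radius: float
    separation: float


@dataclass(frozen=True)
class Probe:
    """Pencil-beam source plus a linear detector array on the surface."""

    source_position: tuple[float, float, float]
    source_direction: tuple[float, float, float]
    detectors: tuple[Detector, ...]

    def detector(self, separation: float) -> Detector:
        for d in self.detectors:
            if abs(d.separation - separation) < 1e-9:
                return d
        raise KeyError(f"no detector at separation {separation} mm")

    @property
    def separations(self) -> tuple[float, ...]:
        return tuple(d.separation for d in self.detectors)


def build_layered_slab(
    thicknesses: tuple[float, ...] = DEFAULT_THICKNESSES_MM,
    lateral_size: float = 120.0,
    total_depth: float = 40.0,
    spacing: float = 1.0,
) -> HeadModel:
    """Build the layered slab head model.

    Layers are stacked along ``z`` in the order scalp/skull, CSF, GM, WM;
    WM fills the remaining depth below the GM (the last entry of
    ``thicknesses`` is its minimum thickness).  A voxel takes the label of
    the layer containing its center.  A zero thickness produces a model
    without that layer.

    Parameters
    ----------
    thicknesses : (scalp_skull, csf, gm, wm_min) in mm
    lateral_size : edge length (mm) of the square x-y cross-section
    total_depth : slab depth (mm); must cover the cumulative thicknesses
    spacing : voxel size in mm
    """
    thicknesses = tuple(float(t) for t in thicknesses)
    if len(thicknesses) != 4:
        raise InvalidGeometryError("expected 4 layer thicknesses")
    if any(t < 0 for t in thicknesses) or spacing <= 0:
        raise InvalidGeometryError("thicknesses must be >= 0 and spacing > 0")
    if lateral_size <= 0 or total_depth <= 0:
        raise InvalidGeometryError("lateral_size and total_depth must be > 0")
    interfaces = np.cumsum(thicknesses[:3])
    if total_depth < interfaces[-1] + thicknesses[3]:
        raise InvalidGeometryError(
            f"total_depth {total_depth} mm does not contain the layers "
            f"(need >= {interfaces[-1] + thicknesses[3]} mm)"
        )
    nx = ny = int(round(lateral_size / spacing))
    nz = int(round(total_depth / spacing))
    z = (np.arange(nz) + 0.5) * spacing
    layer_of_z = np.full(nz, WM, dtype=np.uint8)
    layer_of_z[z < interfaces[2]] = GM
    layer_of_z[z < interfaces[1]] = CSF
    layer_of_z[z < interfaces[0]] = SCALP_SKULL
    labels = np.broadcast_to(layer_of_z, (nx, ny, nz)).copy()
    return HeadModel(labels=labels, spacing=float(spacing))


def build_concentric_spheres(
    radii: tuple[float, ...],
    spacing: float = 1.0,
    margin: float = 2.0,
) -> HeadModel:
    """Concentric-sphere head analog (curved-surface variant of the slab).

    ``radii[i]`` is the outer boundary of region ``i`` in the order
    scalp/skull, CSF, GM, WM; the last listed region fills the core.
    Four radii give the full head analog with a WM center; a single
    radius gives a homogeneous scalp/skull sphere.
    """
    radii = tuple(float(r) for r in radii)
    if not radii or any(r <= 0 for r in radii):
        raise InvalidGeometryError("radii must be positive")
    if not all(radii[i] > radii[i + 1] for i in range(len(radii) - 1)):
        raise InvalidGeometryError("radii must be strictly decreasing")
    if spacing <= 0:
        raise InvalidGeometryError("spacing must be > 0")
    extent = 2.0 * (radii[0] + margin)
    n = int(np.ceil(extent / spacing))
    c = n * spacing / 2.0
    ax = (np.arange(n) + 0.5) * spacing - c
    r = np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )
    # outside-in: radii[i] is the outer boundary of region i, so the
    # innermost region is the ball inside radii[-1] (WM for four radii)
    shell_labels = (SCALP_SKULL, CSF, GM, WM)
    labels = np.zeros((n, n, n), dtype=np.uint8)
    for i, radius in enumerate(radii):
        labels[r < radius] = shell_labels[min(i, 3)]
    return HeadModel(labels=labels, spacing=float(spacing))


def _slab_surface_point(model: HeadModel, x: float, y: float) -> tuple[float, float, float]:
    ex, ey, _ = model.world_extent()
    if not (0.0 <= x <= ex and 0.0 <= y <= ey):
        raise OutOfBoundsError(f"surface point ({x}, {y}) outside the {ex}x{ey} mm face")
    return (x, y, 0.0)


def place_probe(
    model: HeadModel,
    separations: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0),
    short_separation: float = 8.4,
    detector_radius: float = 1.5,
    geometry: str = "slab",
    sphere_radius: float | None = None,
) -> Probe:
    """Place the fNIRS probe: centered source plus a linear detector array.

    On the slab the source sits at the center of the ``z = 0`` face and
    detectors extend along ``+x``; geodesic distance equals the straight
    surface distance.  On the sphere the source is at the top pole
    (minimum ``z``) and a geodesic separation ``s`` maps to the polar
    angle ``s / R``.

    Detector separations are sorted ascending (short separation included)
    in the returned probe.
    """
    seps = sorted(set(float(s) for s in separations) | {float(short_separation)})
    if geometry == "slab":
        ex, ey, _ = model.world_extent()
        sx, sy = ex / 2.0, ey / 2.0
        src = _slab_surface_point(model, sx, sy)
        dets = []
        for s in seps:
            px = sx + s
            if px > ex:
                raise OutOfBoundsError(
                    f"separation {s} mm exceeds the surface extent ({ex} mm)"
                )
            dets.append(Detector(position=(px, sy, 0.0), radius=detector_radius, separation=s))
        return Probe(source_position=src, source_direction=(0.0, 0.0, 1.0), detectors=tuple(dets))
    elif geometry == "sphere":
        if sphere_radius is None:
            raise ValueError("sphere geometry requires sphere_radius")
        R = float(sphere_radius)
        ex, ey, ez = model.world_extent()
        cx, cy, cz = ex / 2.0, ey / 2.0, ez / 2.0
        src = (cx, cy, cz - R)
        dets = []
        for s in seps:
            theta = s / R
            if theta >= np.pi:
                raise OutOfBoundsError(f"arc {s} mm exceeds the hemisphere")
            pos = (cx + R * np.sin(theta), cy, cz - R * np.cos(theta))
            dets.append(Detector(position=pos, radius=detector_radius, separation=s))
        return Probe(source_position=src, source_direction=(0.0, 0.0, 1.0), detectors=tuple(dets))
    raise ValueError(f"unknown geometry {geometry!r}")
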