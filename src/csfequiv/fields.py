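"""Fluence fields on the shared voxel grid.

Both solvers emit the same container: the continuous-wave Green's
function fluence per unit injected power, in mm^-2, defined at voxel
centers.  Because the normalization contract is identical, MC and DA
fields can be compared voxel by voxel and sampled with the same
trilinear rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from .head_models import HeadModel

__all__ = ["FluenceField", "sample_trilinear", "mirror_average"]


@dataclass
class FluenceField:
    """Green's-function fluence Phi(r, r_src) on the model grid.

    ``values`` has the model's voxel shape, units mm^-2 per unit source
    power.  ``source_descriptor`` records the emitting probe point
    (position, direction, kind); ``solver_tag`` is "MC" or "DA".
    """

    values: np.ndarray
    model: HeadModel
    source_descriptor: dict
    solver_tag: str
    n_photons: int | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def sample(self, position) -> float:
        """Trilinear fluence at a world position (mm)."""
        return sample_trilinear(self.values, self.model, position)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "shape": list(self.values.shape),
            "spacing": self.model.spacing,
            "origin": list(self.model.origin),
            "dtype": "float64",
            "order": "C",
            "solver_tag": self.solver_tag,
            "source_descriptor": self.source_descriptor,
            "n_photons": self.n_photons,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        self.values.astype("<f8").tofile(path.with_suffix(".raw"))


def sample_trilinear(values: np.ndarray, model: HeadModel, position) -> float:
    """Trilinear interpolation among the 8 nearest voxel centers.

    Positions outside the hull of voxel centers (e.g. detectors on the
    tissue-air plane, half a voxel above the first center plane) are
    clamped onto the hull, so surface samples read the boundary-adjacent
    voxel layer.  Both solvers are sampled identically, which is what
    makes their detector readings comparable.
    """
    pos = np.asarray(position, dtype=float)
    idx = (pos - np.asarray(model.origin)) / model.spacing - 0.5
    return float(
        map_coordinates(values, idx.reshape(3, 1), order=1, mode="nearest")[0]
    )


def mirror_average(values: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Average a field with its mirror image about the grid mid-planes.

    Valid as a variance reducer only when the configuration really is
    mirror-symmetric about those planes (e.g. the slab with a centered
    normal source is symmetric in both lateral axes; a detector-sourced
    adjoint field only in the axis transverse to the probe line).
    """
    out = np.array(values, dtype=float, copy=True)
    for ax in axes:
        out += np.flip(out, axis=ax)
        out *= 0.5
    return out
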