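"""Tissue optical properties and the CSF property sweep grid.

Ground-truth per-tissue absorption (mua, mm^-1), reduced scattering
(musp, mm^-1) and anisotropy (g) at 690 and 830 nm for the four head
tissues, together with the derived transport quantities used by the
solvers:

* scattering coefficient  mus  = musp / (1 - g)
* diffusion coefficient   D    = 1 / (3 (mua + musp))
* effective attenuation   mueff = sqrt(mua / D)

The CSF entry is the contested one: its physiological ("low") reduced
scattering is 0.001 mm^-1, with a semidiffusive alternative of
0.16 mm^-1 at 830 nm reflecting subarachnoid trabeculae.  The sweep grid
spans the (mua, musp) search space over which the diffusion solver is
re-run when hunting for CSF equivalent properties.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .head_models import CSF, GM, REGION_MAP, SCALP_SKULL, WM

__all__ = [
    "Tissue",
    "OpticalProperties",
    "SweepGrid",
    "UnsupportedConfigurationError",
    "InvalidGridError",
    "reference_properties",
    "csf_sweep_grid",
]


class UnsupportedConfigurationError(ValueError):
    """Raised for wavelength / ground-truth combinations not tabulated."""


class InvalidGridError(ValueError):
    """Raised when sweep-grid steps do not divide the requested ranges."""


@dataclass(frozen=True)
class Tissue:
    """Optical properties of one tissue type.

    mua, musp in mm^-1; anisotropy g dimensionless in [0, 1); refractive
    index n >= 1.
    """

    mua: float
    musp: float
    g: float
    n: float = 1.37

    def __post_init__(self):
        if self.mua < 0 or self.musp < 0:
            raise ValueError("mua and musp must be >= 0")
        if not (0.0 <= self.g < 1.0):
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mus(self) -> float:
        """Scattering coefficient mus = musp / (1 - g), mm^-1."""
        return self.musp / (1.0 - self.g)

    @property
    def mut(self) -> float:
        """Total interaction coefficient mua + mus, mm^-1."""
        return self.mua + self.mus

    def D(self, include_mua: bool = True) -> float:
        """Diffusion coefficient in mm: 1/(3(mua+musp)), or 1/(3 musp)."""
        denom = self.mua + self.musp if include_mua else self.musp
        if denom <= 0:
            raise ValueError("mua + musp must be > 0 for a diffusion coefficient")
        return 1.0 / (3.0 * denom)

    @property
    def mueff(self) -> float:
        """Effective attenuation coefficient sqrt(mua / D), mm^-1."""
        return math.sqrt(self.mua / self.D())


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue optical properties for one wavelength.

    Maps the head-model labels to :class:`Tissue`; the exterior is a
    non-participating medium characterised only by its refractive index
    (``n_exterior``), which sets the Fresnel mismatch at the surface.
    """

    tissues: tuple[tuple[int, Tissue], ...]
    wavelength_nm: float
    n_exterior: float = 1.0

    def __getitem__(self, label: int) -> Tissue:
        for lab, t in self.tissues:
            if lab == label:
                return t
        raise KeyError(f"no tissue with label {label}")

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(lab for lab, _ in self.tissues)

    def with_tissue(self, label: int, **changes) -> "OpticalProperties":
        """Return a copy with one tissue's properties replaced."""
        new = tuple(
            (lab, replace(t, **changes) if lab == label else t)
            for lab, t in self.tissues
        )
        return replace(self, tissues=new)

    def with_csf(self, mua: float, musp: float) -> "OpticalProperties":
        """Copy with the CSF absorption / reduced scattering overridden."""
        return self.with_tissue(CSF, mua=mua, musp=musp)

    def as_arrays(self, n_labels: int | None = None):
        """(mua, mus, g, n) arrays indexed by tissue label, for the solvers.

        Label 0 (exterior) rows are zero apart from n = n_exterior.
        """
        if n_labels is None:
            n_labels = max(5, max(self.labels) + 1)
        mua = np.zeros(n_labels)
        mus = np.zeros(n_labels)
        g = np.zeros(n_labels)
        n = np.full(n_labels, self.n_exterior)
        for lab, t in self.tissues:
            mua[lab], mus[lab], g[lab], n[lab] = t.mua, t.mus, t.g, t.n
        return mua, mus, g, n

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "n_exterior": self.n_exterior,
            "tissues": {
                REGION_MAP.get(lab, str(lab)): {
                    "mua": t.mua, "musp": t.musp, "g": t.g, "n": t.n
                }
                for lab, t in self.tissues
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalProperties":
        name_to_label = {v: k for k, v in REGION_MAP.items()}
        tissues = tuple(
            (name_to_label[name], Tissue(**vals))
            for name, vals in d["tissues"].items()
        )
        return cls(
            tissues=tissues,
            wavelength_nm=float(d["wavelength_nm"]),
            n_exterior=float(d.get("n_exterior", 1.0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "OpticalProperties":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Ground-truth table: {wavelength: {label: (mua, musp, g)}}
_TABLE = {
    690: {
        SCALP_SKULL: (0.0159, 1.00, 0.89),
        CSF: (0.0004, 0.001, 0.89),
        GM: (0.02, 0.88, 0.89),
        WM: (0.07, 6.00, 0.85),
    },
    830: {
        SCALP_SKULL: (0.0191, 0.86, 0.89),
        CSF: (0.0026, 0.001, 0.89),
        GM: (0.03, 0.70, 0.90),
        WM: (0.09, 4.29, 0.87),
    },
}

#: Semidiffusive alternative CSF reduced scattering (mm^-1), 830 nm:
#: accounts for scattering by subarachnoid trabeculae.
CSF_MUSP_SEMIDIFFUSIVE = 0.16

#: Widely used literature recommendation for the CSF equivalent reduced
#: scattering coefficient in diffusion models (mm^-1).
CSF_MUSP_LITERATURE_RECOMMENDED = 0.3

#: Updated recommendation derived from the zero-error-contour analysis.
CSF_MUSP_UPDATED_RECOMMENDED = 0.15

#: External reference anchor (not reproducible at desk scale): in an
#: adult-atlas head model at 830 nm, the zero-error contours of total
#: brain sensitivity for the 30- and 35-mm separations intersect at this
#: (mua, musp) pair, the optimum when matching both simultaneously.
#: Recorded as metadata; reproducing it requires the external atlas
#: mesh toolchain.
ATLAS_SGM_INTERSECTION_830 = (0.00173, 0.138)


def reference_properties(
    wavelength_nm: int,
    csf_ground_truth: str = "low",
    n_tissue: float = 1.0,
    n_exterior: float = 1.0,
) -> OpticalProperties:
    """Ground-truth optical properties of the four head tissues.

    Parameters
    ----------
    wavelength_nm : 690 or 830
    csf_ground_truth : "low" or "semidiffusive"
        "low" uses the physiological ex-vivo CSF musp of 0.001 mm^-1;
        "semidiffusive" uses 0.16 mm^-1 (tabulated at 830 nm only).
    n_tissue, n_exterior :
        Refractive indices.  The property tables carry no indices; the
        default is the index-matched convention (n_tissue = n_exterior
        = 1: no Fresnel trapping at the surface, Robin coefficient
        A = 1), under which the published layered-model error figures
        are reproduced.  Set ``n_tissue=1.37`` for the common
        mismatched-tissue convention; the surface trapping it adds
        enhances lateral transport through the scalp/skull and visibly
        shrinks the CSF-related errors.
    """
    wl = int(wavelength_nm)
    if wl not in _TABLE:
        raise UnsupportedConfigurationError(
            f"wavelength {wavelength_nm} nm not tabulated (use 690 or 830)"
        )
    if csf_ground_truth not in ("low", "semidiffusive"):
        raise UnsupportedConfigurationError(
            f"unknown csf_ground_truth {csf_ground_truth!r}"
        )
    if csf_ground_truth == "semidiffusive" and wl != 830:
        raise UnsupportedConfigurationError(
            "the semidiffusive CSF ground truth is tabulated at 830 nm only"
        )
    tissues = []
    for lab, (mua, musp, g) in _TABLE[wl].items():
        if lab == CSF and csf_ground_truth == "semidiffusive":
            musp = CSF_MUSP_SEMIDIFFUSIVE
        tissues.append((lab, Tissue(mua=mua, musp=musp, g=g, n=n_tissue)))
    return OpticalProperties(
        tissues=tuple(tissues), wavelength_nm=float(wl), n_exterior=n_exterior
    )


@dataclass(frozen=True)
class SweepGrid:
    """Inclusive (mua, musp) grid for the CSF property sweep.

    The degenerate cell (mua=0, musp=0), where the diffusion equation is
    singular, carries a small substitute musp instead (stored in
    ``degenerate_substitution``); :meth:`cell_properties` applies it.
    """

    mua_values: tuple[float, ...]
    musp_values: tuple[float, ...]
    degenerate_substitution: float = 0.001

    def __post_init__(self):
        for vals in (self.mua_values, self.musp_values):
            arr = np.asarray(vals)
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise InvalidGridError("grid values must be non-negative, increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.mua_values), len(self.musp_values))

    @property
    def n_cells(self) -> int:
        return len(self.mua_values) * len(self.musp_values)

    def cell_properties(self, i: int, j: int) -> tuple[float, float]:
        """(mua, musp) actually simulated at cell (i, j)."""
        mua = self.mua_values[i]
        musp = self.musp_values[j]
        if mua == 0.0 and musp == 0.0:
            musp = self.degenerate_substitution
        return (mua, musp)

    def cells(self):
        """Iterate ((i, j), (mua, musp)) over the grid, row-major in mua."""
        for i in range(len(self.mua_values)):
            for j in range(len(self.musp_values)):
                yield (i, j), self.cell_properties(i, j)


def csf_sweep_grid(
    mua_max: float = 0.04,
    mua_step: float = 0.002,
    musp_max: float = 0.4,
    musp_step: float = 0.02,
    degenerate_substitution: float = 0.001,
) -> SweepGrid:
    """Build the CSF (mua, musp) search grid: inclusive 0..max by step."""
    if mua_step <= 0 or musp_step <= 0:
        raise InvalidGridError("steps must be positive")

    def axis(vmax: float, step: float) -> tuple[float, ...]:
        n = vmax / step
        if abs(n - round(n)) > 1e-9:
            raise InvalidGridError(f"step {step} does not divide max {vmax}")
        return tuple(np.round(np.arange(round(n) + 1) * step, 12))

    return SweepGrid(
        mua_values=axis(mua_max, mua_step),
        musp_values=axis(musp_max, musp_step),
        degenerate_substitution=degenerate_substitution,
    )
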