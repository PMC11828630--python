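"""Continuous-wave Monte Carlo photon transport on the voxel grid.

Reference ("gold standard") solver: weighted photon packets random-walk
through the labeled voxel volume with exponential free paths
(-ln(xi)/mut), Henyey-Greenstein scattering with the local anisotropy,
absorption by weight attenuation (albedo mus/mut per collision) and
Russian roulette below a weight threshold.  Fluence is accumulated with
the track-length estimator -- sum of weight x path length per voxel,
divided by voxel volume and photon count -- which stays unbiased as
mua -> 0, a requirement here because CSF absorption is nearly zero and
the sweep includes mua = 0 exactly.

A single Fresnel-mismatched interface exists at the tissue-air boundary
(internal interfaces are index-matched); packets transmitted into the
exterior are terminated and tallied as escaped.  The result is
normalized to unit injected power, so the output is the Green's-function
fluence in mm^-2, directly comparable to the diffusion solution.

Randomness comes from a per-photon splitmix64 counter stream keyed on
(seed, photon index): runs are bit-reproducible and independent of
photon execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .fields import FluenceField
from .head_models import HeadModel, Probe

__all__ = [
    "Source",
    "McRunStats",
    "DegenerateMediumError",
    "run_forward_mc",
    "run_adjoint_mc",
]

#: Russian-roulette weight threshold (fraction of launch weight) and
#: survival probability.  Packets three decades below the launch weight
#: contribute negligibly to every reported metric here, so they are
#: terminated unbiasedly rather than tracked to exhaustion.
ROULETTE_THRESHOLD = 1.0e-3
ROULETTE_SURVIVE = 0.1

_MAX_EVENTS_PER_PHOTON = 5_000_000


class DegenerateMediumError(ValueError):
    """Raised when the launch tissue has zero interaction coefficient."""


@dataclass(frozen=True)
class Source:
    """A probe emission point: pencil beam or isotropic point source."""

    position: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kind: str = "pencil"  # "pencil" | "isotropic"

    def descriptor(self) -> dict:
        return {
            "position": list(self.position),
            "direction": list(self.direction),
            "kind": self.kind,
        }


@dataclass(frozen=True)
class McRunStats:
    """Energy bookkeeping of one run, as fractions of injected energy."""

    launched_weight: float
    absorbed_weight: dict[int, float]
    escaped_weight: float
    roulette_discrepancy: float
    lost_weight: float

    @property
    def total_absorbed(self) -> float:
        return float(sum(self.absorbed_weight.values()))

    def conservation_residual(self) -> float:
        """|absorbed + escaped + roulette - launched| / launched."""
        bal = (
            self.total_absorbed
            + self.escaped_weight
            + self.roulette_discrepancy
            + self.lost_weight
            - self.launched_weight
        )
        return abs(bal) / self.launched_weight


@njit(inline="always")
def _splitmix64(state):
    # uint64 arithmetic wraps modulo 2^64
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(inline="always")
def _rand(state):
    state, z = _splitmix64(state)
    return state, (z >> np.uint64(11)) * 1.1102230246251565e-16  # / 2^53


@njit(inline="always", fastmath=True)
def _fresnel_reflectance(cos_i, n1, n2):
    if n1 == n2:
        return 0.0
    sin2_t = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin2_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin2_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False, fastmath=True, error_model="numpy")
def _transport(
    labels,
    mua_t,
    mus_t,
    g_t,
    n_t,
    n_ext,
    h,
    src_x,
    src_y,
    src_z,
    src_ux,
    src_uy,
    src_uz,
    isotropic,
    apply_specular,
    n_photons,
    seed,
    fluence,
    absorbed,
):
    """Trace ``n_photons`` packets; returns (escaped, roulette, lost).

    ``fluence`` accumulates weight x path length per voxel (caller
    normalizes); ``absorbed`` accumulates collision-estimator absorbed
    weight per tissue label.
    """
    nx, ny, nz = labels.shape
    escaped = 0.0
    roulette_net = 0.0
    lost = 0.0
    inv = 1.0 / h

    n_labels = mua_t.shape[0]
    mut_t = np.empty(n_labels)
    albedo_t = np.empty(n_labels)
    absfrac_t = np.empty(n_labels)
    for lab in range(n_labels):
        mut_t[lab] = mua_t[lab] + mus_t[lab]
        if mut_t[lab] > 0.0:
            albedo_t[lab] = mus_t[lab] / mut_t[lab]
            absfrac_t[lab] = mua_t[lab] / mut_t[lab]
        else:
            albedo_t[lab] = 1.0
            absfrac_t[lab] = 0.0

    for iph in range(n_photons):
        state = np.uint64(seed) * np.uint64(0x5DEECE66D) + np.uint64(iph)
        # warm up the stream so nearby photon ids decorrelate
        state, _ = _splitmix64(state)
        state, _ = _splitmix64(state)

        x, y, z = src_x, src_y, src_z
        if isotropic:
            state, r1 = _rand(state)
            state, r2 = _rand(state)
            uz = 2.0 * r1 - 1.0
            st = np.sqrt(max(0.0, 1.0 - uz * uz))
            phi = 2.0 * np.pi * r2
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
        else:
            ux, uy, uz = src_ux, src_uy, src_uz

        w = 1.0
        if apply_specular:
            # normal-incidence specular loss at the air->tissue interface
            ix0 = min(max(int(np.floor(x * inv)), 0), nx - 1)
            iy0 = min(max(int(np.floor(y * inv)), 0), ny - 1)
            iz0 = min(max(int(np.floor(z * inv)), 0), nz - 1)
            lab0 = labels[ix0, iy0, iz0]
            rsp = _fresnel_reflectance(1.0, n_ext, n_t[lab0])
            escaped += w * rsp
            w *= 1.0 - rsp

        ix = int(np.floor(x * inv))
        iy = int(np.floor(y * inv))
        iz = int(np.floor(z * inv))
        # a surface launch at z = 0 with uz > 0 starts in voxel layer 0
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            lost += w
            continue

        state, r = _rand(state)
        tau = -np.log(r)
        aux = abs(ux)
        auy = abs(uy)
        auz = abs(uz)
        alive = True
        events = 0

        while alive:
            events += 1
            if events > _MAX_EVENTS_PER_PHOTON:
                lost += w
                break
            lab = labels[ix, iy, iz]
            mut = mut_t[lab]

            # positive distances to the forward voxel face along each axis
            dx_rem = ((ix + 1) * h - x) if ux > 0.0 else (x - ix * h)
            dy_rem = ((iy + 1) * h - y) if uy > 0.0 else (y - iy * h)
            dz_rem = ((iz + 1) * h - z) if uz > 0.0 else (z - iz * h)

            d_coll = tau / mut if mut > 0.0 else 1.0e30

            # collision occurs before any face when d_coll*|u| <= d_rem
            # on all axes (product form avoids divisions in the common,
            # collision-dominated case)
            if (
                d_coll * aux <= dx_rem
                and d_coll * auy <= dy_rem
                and d_coll * auz <= dz_rem
            ):
                # collision inside the current voxel
                x += ux * d_coll
                y += uy * d_coll
                z += uz * d_coll
                fluence[ix, iy, iz] += w * d_coll
                absorbed[lab] += w * absfrac_t[lab]
                w *= albedo_t[lab]
                # Henyey-Greenstein deflection
                g = g_t[lab]
                state, r1 = _rand(state)
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * r1)
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    ct = 2.0 * r1 - 1.0
                st = np.sqrt(1.0 - ct * ct)
                # azimuth by rejection on the unit disk (no sin/cos)
                while True:
                    state, ra = _rand(state)
                    state, rb = _rand(state)
                    pa = 2.0 * ra - 1.0
                    pb = 2.0 * rb - 1.0
                    ps = pa * pa + pb * pb
                    if 1.0e-12 < ps <= 1.0:
                        break
                cp = (pa * pa - pb * pb) / ps
                sp = 2.0 * pa * pb / ps
                if auz > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -st * cp * den + uz * ct
                    norm = 1.0 / np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                    ux = ux_n * norm
                    uy = uy_n * norm
                    uz = uz_n * norm
                aux = abs(ux)
                auy = abs(uy)
                auz = abs(uz)
                state, r3 = _rand(state)
                tau = -np.log(r3)
                # Russian roulette
                if w < ROULETTE_THRESHOLD:
                    state, r4 = _rand(state)
                    if r4 < ROULETTE_SURVIVE:
                        roulette_net -= w * (1.0 / ROULETTE_SURVIVE - 1.0)
                        w /= ROULETTE_SURVIVE
                    else:
                        roulette_net += w
                        alive = False
            else:
                # a face is hit first (rare branch: divisions are fine);
                # zero direction components never cross their faces
                tx = dx_rem / aux if aux > 0.0 else 1.0e30
                ty = dy_rem / auy if auy > 0.0 else 1.0e30
                tz = dz_rem / auz if auz > 0.0 else 1.0e30
                axis = 0
                d_face = tx
                if ty < d_face:
                    d_face = ty
                    axis = 1
                if tz < d_face:
                    d_face = tz
                    axis = 2
                if d_face < 0.0:
                    d_face = 0.0

                x += ux * d_face
                y += uy * d_face
                z += uz * d_face
                fluence[ix, iy, iz] += w * d_face
                if mut > 0.0:
                    tau -= mut * d_face
                    if tau < 0.0:
                        tau = 0.0

                if axis == 0:
                    step = 1 if ux > 0.0 else -1
                    jx, jy, jz = ix + step, iy, iz
                    x = (ix + (1 if step > 0 else 0)) * h  # snap to face
                elif axis == 1:
                    step = 1 if uy > 0.0 else -1
                    jx, jy, jz = ix, iy + step, iz
                    y = (iy + (1 if step > 0 else 0)) * h
                else:
                    step = 1 if uz > 0.0 else -1
                    jx, jy, jz = ix, iy, iz + step
                    z = (iz + (1 if step > 0 else 0)) * h

                outside = (
                    jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
                )
                if not outside and labels[jx, jy, jz] == 0:
                    outside = True
                if outside:
                    # tissue-air interface: Fresnel reflect or escape
                    if axis == 0:
                        ci = aux
                    elif axis == 1:
                        ci = auy
                    else:
                        ci = auz
                    R = _fresnel_reflectance(ci, n_t[lab], n_ext)
                    state, r5 = _rand(state)
                    if r5 < R:
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                    else:
                        escaped += w
                        alive = False
                else:
                    ix, iy, iz = jx, jy, jz

    return escaped, roulette_net, lost


def run_forward_mc(
    model: HeadModel,
    props,
    source: Source,
    n_photons: int = 10_000_000,
    seed: int = 0,
) -> tuple[FluenceField, McRunStats]:
    """Trace photon packets from ``source`` and return the fluence field.

    The source is a pencil beam on the tissue-air boundary aimed along
    the inward normal (the fNIRS fiber model) or an isotropic interior
    point (used for analytic validations).  ``seed`` fully determines
    the result: same inputs + same seed give a bit-identical field.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    labels = np.ascontiguousarray(model.labels)
    mua_t, mus_t, g_t, n_t = props.as_arrays()

    pos = np.asarray(source.position, dtype=float)
    direction = np.asarray(source.direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("source direction must be non-zero")
    direction = direction / nrm

    # reject a source sitting in a zero-interaction medium
    idx = np.clip(
        np.floor(pos / model.spacing).astype(int),
        0,
        np.asarray(labels.shape) - 1,
    )
    lab0 = labels[tuple(idx)]
    if lab0 != 0 and mua_t[lab0] + mus_t[lab0] <= 0.0:
        raise DegenerateMediumError(
            f"tissue {lab0} at the source has zero interaction coefficient"
        )

    fluence_accum = np.zeros(labels.shape, dtype=np.float64)
    absorbed = np.zeros(len(mua_t), dtype=np.float64)
    isotropic = source.kind == "isotropic"
    apply_specular = not isotropic

    escaped, roulette_net, lost = _transport(
        labels,
        mua_t,
        mus_t,
        g_t,
        n_t,
        float(props.n_exterior),
        float(model.spacing),
        float(pos[0]),
        float(pos[1]),
        float(pos[2]),
        float(direction[0]),
        float(direction[1]),
        float(direction[2]),
        isotropic,
        apply_specular,
        int(n_photons),
        int(seed) & 0x7FFFFFFF,
        fluence_accum,
        absorbed,
    )
    if not np.isfinite(fluence_accum).all():
        raise FloatingPointError("non-finite fluence accumulation")

    norm = 1.0 / (n_photons * model.voxel_volume)
    field = FluenceField(
        values=fluence_accum * norm,
        model=model,
        source_descriptor=source.descriptor(),
        solver_tag="MC",
        n_photons=int(n_photons),
        seed=int(seed),
    )
    stats = McRunStats(
        launched_weight=1.0,
        absorbed_weight={
            lab: absorbed[lab] / n_photons for lab in range(len(absorbed))
        },
        escaped_weight=escaped / n_photons,
        roulette_discrepancy=roulette_net / n_photons,
        lost_weight=lost / n_photons,
    )
    return field, stats


def run_adjoint_mc(
    model: HeadModel,
    props,
    detector_position,
    n_photons: int = 10_000_000,
    seed: int = 0,
    direction=(0.0, 0.0, 1.0),
) -> tuple[FluenceField, McRunStats]:
    """Adjoint fluence: a pencil source launched at the detector position.

    Same code path as the forward run -- the adjoint of the transport
    operator under these boundary conditions is transport from the
    detector -- so reciprocity Phi(r_d, r_s) = Phi(r_s, r_d) holds to
    stochastic error.
    """
    src = Source(position=tuple(detector_position), direction=tuple(direction), kind="pencil")
    return run_forward_mc(model, props, src, n_photons=n_photons, seed=seed)
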