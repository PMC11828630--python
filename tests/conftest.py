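"""Shared fixtures: expensive solver runs computed once per session.

The heavy fixtures are deliberately scaled down from the reference
configuration (fewer photons, and 1-mm spacing where layer-thickness
fidelity is not the quantity under test) so the whole suite stays
within a desk-scale budget; each test's tolerance accounts for the
residual stochastic error.
"""

import numpy as np
import pytest

from csfequiv.da import assemble_system, run_adjoint_da, run_forward_da
from csfequiv.fields import mirror_average
from csfequiv.head_models import GM, build_layered_slab, place_probe
from csfequiv.mc import Source, run_adjoint_mc, run_forward_mc
from csfequiv.metrics import (
    DetectorSampler,
    energy_deposition,
    jacobian,
    region_sensitivity,
    sensitivity_fraction,
    signed_percent_error,
)
from csfequiv.optics import reference_properties

HEADLINE_SEPARATION = 35.0
CSF_PHYSIOLOGICAL = (0.0026, 0.001)
CSF_LITERATURE = (0.0026, 0.3)


def headline_comparison(spacing, n_photons, seed):
    """DA (literature CSF) vs MC (physiological CSF) at 830 nm, 35 mm.

    Returns the four signed percent errors keyed Egm/Phi/Sgm/Fgm --
    the same computation the acceptance script performs.
    """
    model = build_layered_slab(spacing=spacing)
    probe = place_probe(model)
    det = probe.detector(HEADLINE_SEPARATION)
    sampler = DetectorSampler(radius=det.radius)
    props_mc = reference_properties(830)
    props_da = props_mc.with_csf(*CSF_LITERATURE)

    fwd_mc, stats = run_forward_mc(
        model, props_mc,
        Source(position=probe.source_position),
        n_photons=n_photons, seed=seed,
    )
    adj_mc, _ = run_adjoint_mc(
        model, props_mc, det.position, n_photons=n_photons, seed=seed + 1
    )
    fwd_mc.values = mirror_average(fwd_mc.values, (0, 1))
    adj_mc.values = mirror_average(adj_mc.values, (1,))

    system = assemble_system(model, props_da)
    fwd_da = run_forward_da(model, props_da, probe.source_position, system=system)
    adj_da = run_adjoint_da(model, props_da, det.position, system=system)

    def metrics_of(fwd, adj, props):
        phi = 0.5 * (
            sampler(fwd, det.position) + sampler(adj, probe.source_position)
        )
        J = jacobian(fwd, adj, phi)
        return {
            "Egm": energy_deposition(fwd, model, props, GM),
            "Phi": phi,
            "Sgm": region_sensitivity(J, model, GM),
            "Fgm": sensitivity_fraction(J, model, GM),
        }

    m_mc = metrics_of(fwd_mc, adj_mc, props_mc)
    m_da = metrics_of(fwd_da, adj_da, props_da)
    return {
        k: signed_percent_error(m_da[k], m_mc[k]) for k in ("Egm", "Phi", "Sgm", "Fgm")
    }


@pytest.fixture(scope="session")
def headline_errors():
    """Scaled-down headline comparison: 0.5-mm grid, 7e6 photons/run."""
    return headline_comparison(spacing=0.5, n_photons=7_000_000, seed=210)


@pytest.fixture(scope="session")
def mc_reference_h1():
    """1-mm slab MC reference at physiological CSF (forward + 35-mm adjoint)."""
    model = build_layered_slab(spacing=1.0)
    probe = place_probe(model)
    det = probe.detector(HEADLINE_SEPARATION)
    props = reference_properties(830)
    fwd, _ = run_forward_mc(
        model, props, Source(position=probe.source_position),
        n_photons=1_200_000, seed=77,
    )
    adj, _ = run_adjoint_mc(model, props, det.position, n_photons=1_200_000, seed=78)
    fwd.values = mirror_average(fwd.values, (0, 1))
    adj.values = mirror_average(adj.values, (1,))
    return {"model": model, "probe": probe, "det": det, "props": props,
            "fwd": fwd, "adj": adj}
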