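"""Metric definitions: energy deposition, readings, Jacobian, errors."""

import numpy as np
import pytest

from csfequiv.fields import FluenceField, sample_trilinear
from csfequiv.head_models import CSF, GM, SCALP_SKULL, WM, HeadModel, build_layered_slab, place_probe
from csfequiv.metrics import (
    DivisionGuardError,
    EmptyRegionError,
    energy_deposition,
    detector_fluence,
    jacobian,
    region_sensitivity,
    sensitivity_fraction,
    signed_percent_error,
    total_sensitivity,
    voxelwise_percent_error,
)
from csfequiv.optics import OpticalProperties, Tissue, reference_properties


@pytest.fixture()
def small_slab():
    return build_layered_slab(
        thicknesses=(4.0, 2.0, 3.0, 3.0),
        lateral_size=20.0,
        total_depth=12.0,
        spacing=1.0,
    )


def _field(model, values, tag="MC"):
    return FluenceField(
        values=np.asarray(values, dtype=float),
        model=model,
        source_descriptor={},
        solver_tag=tag,
    )


class TestEnergyDeposition:
    def test_uniform_field_times_mua_volume(self, small_slab):
        props = reference_properties(830)
        f = _field(small_slab, np.full(small_slab.shape, 2.5))
        v_gm = small_slab.region_volume(GM)
        expected = 2.5 * props[GM].mua * v_gm
        assert energy_deposition(f, small_slab, props, GM) == pytest.approx(expected)

    def test_zero_absorption_region(self, small_slab):
        props = reference_properties(830).with_tissue(GM, mua=0.0)
        f = _field(small_slab, np.ones(small_slab.shape))
        assert energy_deposition(f, small_slab, props, GM) == 0.0

    def test_missing_region_raises_unless_allowed(self, small_slab):
        no_csf = build_layered_slab(
            thicknesses=(4.0, 0.0, 3.0, 3.0),
            lateral_size=20.0,
            total_depth=12.0,
            spacing=1.0,
        )
        props = reference_properties(830)
        f = _field(no_csf, np.ones(no_csf.shape))
        with pytest.raises(EmptyRegionError):
            energy_deposition(f, no_csf, props, CSF)
        assert energy_deposition(f, no_csf, props, CSF, allow_empty=True) == 0.0


class TestDetectorFluence:
    def test_constant_field(self, small_slab):
        f = _field(small_slab, np.full(small_slab.shape, 7.0))
        assert detector_fluence(f, (3.3, 4.4, 5.5)) == pytest.approx(7.0)

    def test_voxel_center_returns_voxel_value(self, small_slab):
        vals = np.random.default_rng(0).random(small_slab.shape)
        f = _field(small_slab, vals)
        assert detector_fluence(f, (2.5, 3.5, 4.5)) == pytest.approx(vals[2, 3, 4])

    def test_trilinear_exact_on_linear_field(self, small_slab):
        x = small_slab.voxel_centers(0)
        vals = np.broadcast_to(
            (2.0 * x + 1.0)[:, None, None], small_slab.shape
        ).copy()
        f = _field(small_slab, vals)
        for xq in (2.0, 5.25, 9.9):
            assert detector_fluence(f, (xq, 8.0, 6.0)) == pytest.approx(2 * xq + 1)


class TestJacobian:
    def test_unit_fields_give_minus_one(self, small_slab):
        ones = np.ones(small_slab.shape)
        J = jacobian(_field(small_slab, ones), _field(small_slab, ones), 1.0)
        assert np.all(J.values == -1.0)

    def test_symmetric_in_forward_adjoint(self, small_slab):
        rng = np.random.default_rng(1)
        a = rng.random(small_slab.shape)
        b = rng.random(small_slab.shape)
        J1 = jacobian(_field(small_slab, a), _field(small_slab, b), 0.5)
        J2 = jacobian(_field(small_slab, b), _field(small_slab, a), 0.5)
        np.testing.assert_allclose(J1.values, J2.values)

    def test_nonpositive_everywhere(self, small_slab):
        rng = np.random.default_rng(2)
        J = jacobian(
            _field(small_slab, rng.random(small_slab.shape)),
            _field(small_slab, rng.random(small_slab.shape)),
            2.0,
        )
        assert (J.values <= 0).all()

    def test_zero_reading_guard(self, small_slab):
        ones = np.ones(small_slab.shape)
        with pytest.raises(DivisionGuardError):
            jacobian(_field(small_slab, ones), _field(small_slab, ones), 0.0)


class TestRegionSensitivity:
    def test_additivity_over_regions(self, small_slab):
        rng = np.random.default_rng(3)
        J = jacobian(
            _field(small_slab, rng.random(small_slab.shape)),
            _field(small_slab, rng.random(small_slab.shape)),
            1.0,
        )
        parts = sum(
            region_sensitivity(J, small_slab, lab)
            for lab in (SCALP_SKULL, CSF, GM, WM)
        )
        assert parts == pytest.approx(total_sensitivity(J, small_slab))

    def test_fraction_bounds_and_whole_domain(self, small_slab):
        rng = np.random.default_rng(4)
        J = jacobian(
            _field(small_slab, rng.random(small_slab.shape) + 0.1),
            _field(small_slab, rng.random(small_slab.shape) + 0.1),
            1.0,
        )
        f = sensitivity_fraction(J, small_slab, GM)
        assert 0.0 < f < 1.0
        fractions = [
            sensitivity_fraction(J, small_slab, lab)
            for lab in (SCALP_SKULL, CSF, GM, WM)
        ]
        assert sum(fractions) == pytest.approx(1.0)


class TestSignedPercentError:
    @pytest.mark.parametrize(
        "da,mc,expected", [(0.8, 1.0, -20.0), (3.0, 3.0, 0.0), (1.5, 1.0, 50.0)]
    )
    def test_values(self, da, mc, expected):
        assert signed_percent_error(da, mc) == pytest.approx(expected)

    def test_zero_reference_guard(self):
        with pytest.raises(DivisionGuardError):
            signed_percent_error(1.0, 0.0)

    def test_scale_invariance(self):
        # common rescaling of both solutions leaves the error unchanged
        assert signed_percent_error(0.8 * 3.7, 1.0 * 3.7) == pytest.approx(-20.0)


class TestVoxelwiseError:
    def test_masking_below_floor(self, small_slab):
        mc = np.zeros(small_slab.shape)
        mc[0, 0, 0] = 1.0
        da = np.full(small_slab.shape, 0.5)
        err = voxelwise_percent_error(
            _field(small_slab, da, "DA"), _field(small_slab, mc)
        )
        assert err[0, 0, 0] == pytest.approx(-50.0)
        assert np.isnan(err[1, 1, 1])


class TestAdjointVsPerturbation:
    def test_jacobian_predicts_single_voxel_mua_perturbation(self, small_slab):
        """The adjoint-product Jacobian must predict the change of the
        detector reading under a small single-voxel absorption bump:
        d(ln Phi_d) ~= J(r) * dmua * V / Phi_d  (finite-difference oracle).
        """
        from csfequiv.da import assemble_system, run_adjoint_da, run_forward_da
        from csfequiv.metrics import POINT_SAMPLER, jacobian as make_jacobian

        props = reference_properties(830)
        src = (6.0, 10.0, 0.0)
        det = (14.0, 10.0, 0.0)
        sys_ = assemble_system(small_slab, props, rtol=1e-12)
        fwd = run_forward_da(small_slab, props, src, system=sys_)
        adj = run_adjoint_da(small_slab, props, det, system=sys_)
        # read at a voxel center so the reading is a single nodal value
        det_read_pt = (14.5, 10.5, 0.5)
        phi_d = POINT_SAMPLER(fwd, det_read_pt)
        # adjoint source must sit at the detector *reading* point for the
        # product formula to predict d(reading); re-solve accordingly
        adj = run_forward_da(small_slab, props, det_read_pt, system=sys_, sink=False)
        J = make_jacobian(fwd, adj, phi_d)

        voxel = (10, 10, 7)  # a GM voxel under the midpoint
        assert small_slab.labels[voxel] == GM
        delta = 1e-4  # mm^-1
        centers = tuple((i + 0.5) * small_slab.spacing for i in voxel)

        labels2 = small_slab.labels.copy()
        free_label = 5  # give the perturbed voxel its own tissue entry
        labels2[voxel] = free_label
        model2 = HeadModel(labels=labels2, spacing=small_slab.spacing)
        gm = props[GM]

        readings = {}
        for sgn in (+1, -1):
            props2 = OpticalProperties(
                tissues=props.tissues
                + ((free_label, Tissue(mua=gm.mua + sgn * delta, musp=gm.musp, g=gm.g)),),
                wavelength_nm=props.wavelength_nm,
            )
            sys2 = assemble_system(model2, props2, rtol=1e-12)
            f2 = run_forward_da(model2, props2, src, system=sys2)
            readings[sgn] = POINT_SAMPLER(f2, det_read_pt)

        observed = (np.log(readings[+1]) - np.log(readings[-1])) / 2.0
        # J already carries the 1/Phi_d normalization, so the relative
        # reading change is J * dmua * V
        predicted = J.values[voxel] * delta * small_slab.voxel_volume
        assert observed == pytest.approx(predicted, rel=0.05)
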