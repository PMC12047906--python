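import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from cervimetry.biometry import (
    BiometryError,
    canal_diameter,
    canal_midpoint,
    cervical_length,
    extract_interfaces,
    measure,
)
from cervimetry.phantom import PhantomSpec, generate_phantom
from cervimetry.volumes import (
    CANAL,
    CYST,
    INNER_STROMA,
    LabelVolume,
    VoxelGeometry,
    voxel_to_world,
)


def _tube(shape=(13, 13, 31), radius=3, capped=False):
    """Hand-built straight canal tube (z axis) in inner stroma, 1 mm spacing.

    Open at z = 2 and z = 28 with background beyond, as after cropping a
    parcellation around the cervix.
    """
    data = np.zeros(shape, dtype=np.int16)
    c = (shape[0] - 1) / 2
    ii = np.indices(shape[:2])
    r2 = (ii[0] - c) ** 2 + (ii[1] - c) ** 2
    stroma = r2 <= (radius + 2) ** 2
    canal = r2 <= radius**2
    for z in range(2, 29):
        data[:, :, z][stroma] = INNER_STROMA
        data[:, :, z][canal] = CANAL
    if capped:
        for z in (2, 28):
            sl = data[:, :, z]
            sl[sl == CANAL] = INNER_STROMA
    geom = VoxelGeometry(spacing=np.ones(3))
    return LabelVolume(data, geom)


class TestCervicalLength:
    def test_collinear(self):
        assert cervical_length((0, 0, 0), (0, 0, 17.5), (0, 0, 35)) == pytest.approx(35.0)

    def test_two_segment_closed_form(self):
        # 2 * sqrt(10^2 + 20^2) by hand
        v = cervical_length((0, 0, 0), (0, 10, 20), (0, 0, 40))
        assert v == pytest.approx(2 * np.sqrt(500), abs=1e-6)
        assert v == pytest.approx(44.721, abs=1e-3)

    def test_degenerate_midpoint(self):
        assert cervical_length((0, 0, 0), (0, 0, 0), (0, 0, 12)) == pytest.approx(12.0)

    def test_non_finite_rejected(self):
        with pytest.raises(BiometryError):
            cervical_length((0, 0, np.nan), (0, 0, 1), (0, 0, 2))

    @settings(max_examples=50, deadline=None)
    @given(pts=st.lists(st.floats(-50, 50), min_size=9, max_size=9))
    def test_triangle_inequality(self, pts):
        i, m, o = np.asarray(pts).reshape(3, 3)
        assert cervical_length(i, m, o) >= np.linalg.norm(i - o) - 1e-9


class TestMidpoint:
    def test_symmetric_tube_midpoint(self):
        lab = _tube()
        mid = canal_midpoint(lab)
        centre = voxel_to_world((6, 6, 15), lab.geometry)
        assert np.allclose(mid, centre, atol=0.5)

    def test_single_voxel(self):
        data = np.zeros((5, 5, 5), dtype=np.int16)
        data[2, 3, 1] = CANAL
        lab = LabelVolume(data, VoxelGeometry(spacing=np.ones(3)))
        assert np.allclose(canal_midpoint(lab), voxel_to_world((2, 3, 1), lab.geometry))

    def test_l_bend_matches_exhaustive_mean(self):
        data = np.zeros((9, 20, 20), dtype=np.int16)
        data[4, 2:18, 2] = CANAL   # arm along y
        data[4, 2, 2:12] = CANAL   # arm along z
        lab = LabelVolume(data, VoxelGeometry(spacing=np.full(3, 0.8)))
        expected = np.mean(
            [voxel_to_world(idx, lab.geometry) for idx in np.argwhere(data == CANAL)],
            axis=0,
        )
        assert np.allclose(canal_midpoint(lab), expected, atol=1e-12)

    def test_empty_canal(self):
        lab = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16))
        with pytest.raises(BiometryError, match="empty canal"):
            canal_midpoint(lab)


class TestInterfaces:
    def test_open_tube_has_two_components(self):
        inlet, outlet = extract_interfaces(_tube())
        assert inlet.end == "inlet" and outlet.end == "outlet"
        # each ROI is one end disc of the canal
        for roi in (inlet, outlet):
            zs = np.unique(roi.voxels[:, 2])
            assert len(zs) == 1
            assert int(zs[0]) in (2, 28)
        assert inlet.voxels[0, 2] != outlet.voxels[0, 2]

    def test_capped_tube_raises(self):
        with pytest.raises(BiometryError, match="capped|interface"):
            extract_interfaces(_tube(capped=True))

    def test_inlet_cyst_included_in_interface(self):
        lab = _tube()
        # replace half of one opening's canal voxels by cyst-coded voxels
        data = lab.data.copy()
        opening = (data[:, :, 28] == CANAL) & (np.indices((13, 13))[0] >= 6)
        data[:, :, 28][opening] = CYST
        lab2 = LabelVolume(data, lab.geometry)
        inlet, outlet = extract_interfaces(lab2)
        roi = inlet if inlet.voxels[0, 2] == 28 else outlet
        codes = {int(lab2.data[tuple(v)]) for v in roi.voxels}
        assert CYST in codes and CANAL in codes

    def test_empty_canal_raises(self):
        lab = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16))
        with pytest.raises(BiometryError):
            extract_interfaces(lab)


class TestDiameter:
    def test_straight_phantom_inlet_diameter(self, straight_phantom):
        spec, _, lab, truth = straight_phantom
        res = measure(lab)
        assert res.inlet_diameter == pytest.approx(8.0, abs=0.8)
        assert res.outlet_diameter == pytest.approx(8.0, abs=0.8)

    def test_one_voxel_canal(self):
        data = np.zeros((9, 9, 9), dtype=np.int16)
        data[2:7, 2:7, 2:7] = INNER_STROMA
        data[4, 4, 2:7] = CANAL
        lab = LabelVolume(data, VoxelGeometry(spacing=np.ones(3)))
        d, qc = canal_diameter(lab, voxel_to_world((4, 4, 4), lab.geometry), (0, 0, 1.0))
        assert d == pytest.approx(1.0, abs=0.5)

    def test_centre_outside_canal_rejected(self):
        lab = _tube()
        with pytest.raises(BiometryError, match="not inside the canal"):
            canal_diameter(lab, voxel_to_world((0, 0, 15), lab.geometry), (0, 0, 1.0))

    def test_translation_invariance(self, straight_phantom):
        spec, _, lab, _ = straight_phantom
        res1 = measure(lab)
        shifted = LabelVolume(
            lab.data, lab.geometry.with_origin(lab.geometry.origin + [13.0, -7.0, 4.0])
        )
        res2 = measure(shifted)
        assert res2.cervical_length == pytest.approx(res1.cervical_length, abs=1e-9)
        assert res2.inlet_diameter == pytest.approx(res1.inlet_diameter, abs=1e-9)
        assert res2.outlet_diameter == pytest.approx(res1.outlet_diameter, abs=1e-9)


class TestMeasure:
    def test_straight_phantom_length(self, straight_phantom):
        spec, _, lab, truth = straight_phantom
        res = measure(lab)
        assert res.cervical_length == pytest.approx(truth.true_cervical_length, abs=1.6)

    def test_bent_phantom_length_and_strict_inequality(self, bent_phantom):
        # error budget at a 30 degree bend: ~1 voxel of end-face rasterisation
        # inset plus the inherent canal-centroid-vs-vertex bias of the
        # two-line protocol (L * (1 - sqrt(1 - 0.75 sin^2(b/2))) ~ 0.9 mm)
        spec, _, lab, truth = bent_phantom
        res = measure(lab)
        assert res.cervical_length == pytest.approx(truth.true_cervical_length, abs=2.0)
        chord = np.linalg.norm(res.inlet_centre - res.outlet_centre)
        assert res.cervical_length > chord + 0.1

    def test_full_phantom_measurement(self, default_phantom):
        spec, _, lab, truth = default_phantom
        res = measure(lab)
        assert res.cervical_length == pytest.approx(truth.true_cervical_length, abs=1.6)
        assert res.inlet_diameter == pytest.approx(truth.true_inlet_diameter, abs=1.2)
        assert res.outlet_diameter == pytest.approx(truth.true_outlet_diameter, abs=1.2)

    def test_elongation_monotonicity(self):
        lengths = [25.0, 33.0, 41.0]
        measured = []
        for L in lengths:
            spec = PhantomSpec(
                canal_length=L, bend_angle=15.0, n_cysts=0, include_bladder=False, seed=6
            )
            _, lab, _ = generate_phantom(spec)
            measured.append(measure(lab).cervical_length)
        deltas = np.diff(measured)
        for d, dtrue in zip(deltas, np.diff(lengths)):
            assert d == pytest.approx(dtrue, abs=1.6)

    def test_sagittal_rotation_invariance(self, bent_phantom):
        spec, _, lab, _ = bent_phantom
        res1 = measure(lab)
        ang = np.radians(20.0)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, np.cos(ang), -np.sin(ang)],
                [0.0, np.sin(ang), np.cos(ang)],
            ]
        )
        centre = (np.asarray(lab.data.shape) - 1) / 2.0
        rotated = ndimage.affine_transform(
            lab.data, rot.T, offset=centre - rot.T @ centre, order=0
        )
        res2 = measure(LabelVolume(rotated, lab.geometry))
        # one-voxel contract plus nearest-neighbour regridding of the mask
        tol = 1.0
        assert res2.cervical_length == pytest.approx(res1.cervical_length, abs=tol)
        assert res2.inlet_diameter == pytest.approx(res1.inlet_diameter, abs=tol)
        assert res2.outlet_diameter == pytest.approx(res1.outlet_diameter, abs=tol)

    def test_failure_is_flagged_not_silent(self):
        res = measure(_tube(capped=True))
        assert res.cervical_length is None
        assert any("interfaces_failed" in f for f in res.qc_flags)

    def test_non_sagittal_bend_flagged(self, bent_phantom):
        # tip the bend plane 25 degrees out of the sagittal plane
        spec, _, lab, _ = bent_phantom
        ang = np.radians(25.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        centre = (np.asarray(lab.data.shape) - 1) / 2.0
        rotated = ndimage.affine_transform(
            lab.data, rot.T, offset=centre - rot.T @ centre, order=0
        )
        res = measure(LabelVolume(rotated, lab.geometry))
        assert any("non_sagittal" in f for f in res.qc_flags)
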