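"""Trabecular panel against analytic phantoms and brute-force oracles."""

import numpy as np
import pytest
from skimage.measure import euler_number

from cartiqus.morphometry import (
    TrabecularVolume,
    betti_numbers,
    compute_bvtv,
    compute_connd,
    compute_local_thickness,
    compute_morphometry,
    compute_smi,
    compute_tbn,
    euler_characteristic,
)
from cartiqus.synthetic import TrabecularPhantomSpec, generate_trabecular_phantom

VOX = 12.0  # µm


def _plates(t=5, p=25, shape=(100, 30, 30)):
    return generate_trabecular_phantom(
        TrabecularPhantomSpec(
            shape_kind="parallel_plates", volume_shape=shape, plate_thickness=t, plate_period=p
        )
    )


class TestBVTV:
    def test_solid(self):
        assert compute_bvtv(TrabecularVolume(np.ones((6, 6, 6), bool))) == 1.0

    def test_half_filled(self):
        v = np.zeros((8, 8, 8), bool)
        v[:4] = True
        assert compute_bvtv(TrabecularVolume(v)) == 0.5

    def test_plate_phantom_exact(self):
        assert compute_bvtv(_plates()) == 0.2

    def test_empty_voi_rejected(self):
        v = TrabecularVolume(np.ones((4, 4, 4), bool), mask=np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError):
            compute_bvtv(v)


class TestLocalThickness:
    def test_slab_thickness_recovered(self):
        # slab spanning the cross-section: in-plane boundary acts as mirror
        v = np.zeros((30, 20, 20), bool)
        v[10:20] = True
        th = compute_local_thickness(TrabecularVolume(v, voxel_size_um=VOX))
        assert th / (VOX * 1e-3) == pytest.approx(10.0, abs=1.0)

    def test_cylinder_diameter_recovered(self):
        # voxel-centred so the medial axis falls on voxel centres (the
        # maximal-sphere search only places sphere centres there)
        r = 8.0
        y, x = np.meshgrid(np.arange(31), np.arange(31), indexing="ij")
        disk = (y - 15) ** 2 + (x - 15) ** 2 <= r * r
        v = np.broadcast_to(disk, (40, 31, 31)).copy()
        th = compute_local_thickness(TrabecularVolume(v, voxel_size_um=VOX))
        assert th / (VOX * 1e-3) == pytest.approx(2 * r, abs=1.0)

    def test_plate_separation_recovered(self):
        v = _plates()
        sp = compute_local_thickness(v, phase="background")
        assert sp / (VOX * 1e-3) == pytest.approx(20.0, abs=1.0)

    def test_empty_phase_rejected(self):
        v = TrabecularVolume(np.ones((6, 6, 6), bool))
        with pytest.raises(ValueError):
            compute_local_thickness(v, phase="background")


class TestTbN:
    def test_plate_phantom_inverse_period(self):
        tbn = compute_tbn(_plates())  # mm^-1
        assert tbn * (VOX * 1e-3) * 25 == pytest.approx(1.0, rel=0.06)

    def test_doubling_period_roughly_halves_tbn(self):
        a = compute_tbn(_plates(t=5, p=25, shape=(100, 24, 24)))
        b = compute_tbn(_plates(t=5, p=50, shape=(100, 24, 24)))
        assert a / b == pytest.approx(2.0, rel=0.15)

    def test_solid_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_tbn(TrabecularVolume(np.ones((6, 6, 6), bool)))

    def test_plate_model_variant(self):
        v = _plates()
        tbn = compute_tbn(v, model="plate")  # (BV/TV)/Tb.Th = (t/p)/t = 1/p
        assert tbn * (VOX * 1e-3) * 25 == pytest.approx(1.0, rel=0.06)


def _brute_euler(mask):
    """Oracle: explicit cell enumeration of the closed cubical complex."""
    vs, es, fs, c = set(), set(), set(), 0
    for i, j, k in zip(*np.nonzero(mask)):
        c += 1
        for a in (0, 1):
            for b in (0, 1):
                for d in (0, 1):
                    vs.add((i + a, j + b, k + d))
                es.add(("ex", i, j + a, k + b))
                es.add(("ey", i + a, j, k + b))
                es.add(("ez", i + a, j + b, k))
        fs.update(
            [("fx", i, j, k), ("fx", i + 1, j, k), ("fy", i, j, k), ("fy", i, j + 1, k),
             ("fz", i, j, k), ("fz", i, j, k + 1)]
        )
    return len(vs) - len(es) + len(fs) - c


class TestTopology:
    def test_euler_agrees_with_brute_force_on_random_volumes(self, rng):
        for _ in range(20):
            mask = rng.random((8, 8, 8)) < rng.uniform(0.2, 0.8)
            assert euler_characteristic(mask) == _brute_euler(mask)

    def test_euler_agrees_with_skimage_26_connectivity(self, rng):
        for _ in range(10):
            mask = rng.random((8, 8, 8)) < 0.5
            assert euler_characteristic(mask) == euler_number(mask, connectivity=3)

    def test_betti_of_simple_solids(self):
        cube = np.ones((5, 5, 5), bool)
        assert betti_numbers(cube) == (1, 0, 0)
        hollow = np.pad(cube, 1, constant_values=True)
        hollow[3, 3, 3] = False  # one enclosed cavity
        assert betti_numbers(hollow) == (1, 0, 1)

    def test_solid_cube_has_zero_connectivity_density(self):
        v = TrabecularVolume(np.pad(np.ones((5, 5, 5), bool), 1), voxel_size_um=VOX)
        assert compute_connd(v) == 0.0

    def test_torus_connectivity_density_is_one_per_tv(self):
        v = generate_trabecular_phantom(
            TrabecularPhantomSpec(shape_kind="torus", volume_shape=(32, 52, 52))
        )
        assert compute_connd(v) == pytest.approx(1.0 / v.total_volume_mm3)

    def test_rod_lattice_loops_match_graph_count(self):
        # dual route: voxel Euler characteristic vs the rod-graph cycle count
        for dropout, seed in [(0.0, 0), (0.15, 3)]:
            v = generate_trabecular_phantom(
                TrabecularPhantomSpec(
                    shape_kind="rod_lattice", volume_shape=(64, 64, 64), rod_dropout=dropout,
                    seed=seed,
                )
            )
            measured_b1 = compute_connd(v) * v.total_volume_mm3
            assert measured_b1 == pytest.approx(v.metadata["expected_loops"])

    def test_disconnected_foreground_warns_and_uses_largest(self):
        m = np.zeros((10, 10, 10), bool)
        m[1:5, 1:5, 1:5] = True
        m[7:9, 7:9, 7:9] = True
        with pytest.warns(UserWarning, match="largest"):
            compute_connd(TrabecularVolume(m))


class TestSMI:
    def test_sphere_near_four(self):
        n, c = 52, 25.5
        z, y, x = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        sphere = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= 20.0**2
        assert compute_smi(TrabecularVolume(sphere)) == pytest.approx(4.0, abs=0.3)

    def test_long_cylinder_near_three(self):
        r = 8.0
        y, x = np.meshgrid(np.arange(22), np.arange(22), indexing="ij")
        disk = (y - 10.5) ** 2 + (x - 10.5) ** 2 <= r * r
        v = np.zeros((400, 22, 22), bool)
        v[2:398] = disk
        # ideal infinite cylinder is 3; end caps raise it slightly
        assert compute_smi(TrabecularVolume(v)) == pytest.approx(3.0, abs=0.3)

    def test_wide_thin_plate_near_zero(self):
        v = np.zeros((15, 300, 300), bool)
        v[6:9, 10:290, 10:290] = True
        assert compute_smi(TrabecularVolume(v)) == pytest.approx(0.0, abs=0.3)

    def test_monotone_along_plate_to_rod_morph(self):
        values = []
        for a, b in [(3, 160), (6, 80), (12, 40), (22, 22)]:
            v = np.zeros((a + 10, b + 10, 170), bool)
            v[5 : 5 + a, 5 : 5 + b, 5:165] = True
            values.append(compute_smi(TrabecularVolume(v)))
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_foreground_touching_all_faces_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            compute_smi(TrabecularVolume(np.ones((8, 8, 8), bool)))


def test_full_panel_on_rod_lattice_is_physiologically_ordered():
    v = generate_trabecular_phantom(TrabecularPhantomSpec(seed=1))
    m = compute_morphometry(v)
    assert 0.05 < m.bv_tv < 0.3
    assert m.tb_th_mm < m.tb_sp_mm
    assert m.conn_d_per_mm3 > 0
    assert 0 < m.smi < 4
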