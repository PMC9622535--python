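"""Junction construction, voxelization and STL round trips."""

import os

import numpy as np
import pytest

from fontanflow import (GeometryError, LimbSpec, ResolutionError,
                        build_junction, export_stl, load_stl, straight_tube,
                        voxelize, voxelize_mesh)
from fontanflow.errors import FormatError


class TestBuildJunction:
    def test_glenn_preset_has_three_ports(self):
        geo = build_junction("glenn")
        assert {l.name for l in geo.limbs} == {"SVC", "LPA", "RPA"}
        assert [l.name for l in geo.inlets] == ["SVC"]
        assert {l.name for l in geo.outlets} == {"LPA", "RPA"}

    def test_tcpc_preset_has_four_ports_and_offset(self):
        geo = build_junction("tcpc", caval_offset=0.004)
        assert {l.name for l in geo.inlets} == {"IVC", "SVC"}
        assert {l.name for l in geo.outlets} == {"LPA", "RPA"}
        assert geo.limb("IVC").anchor[0] == pytest.approx(0.004)

    def test_disconnected_limb_rejected_by_name(self):
        far = LimbSpec("LPA", 0.01, 0.03, (1.0, 0.0, 0.0),
                       (0.5, 0.5, 0.5), "outlet")
        near = [
            LimbSpec("SVC", 0.012, 0.036, (0.0, 1.0, 0.0), (0, 0, 0), "inlet"),
            LimbSpec("RPA", 0.01, 0.03, (-1.0, 0.0, 0.0), (0, 0, 0), "outlet"),
        ]
        with pytest.raises(GeometryError, match="LPA"):
            build_junction(limbs=near + [far])

    def test_role_invariants_enforced(self):
        limbs = [
            LimbSpec("SVC", 0.012, 0.036, (0.0, 1.0, 0.0), (0, 0, 0), "inlet"),
            LimbSpec("LPA", 0.01, 0.03, (1.0, 0.0, 0.0), (0, 0, 0), "outlet"),
        ]
        with pytest.raises(GeometryError, match="outlet"):
            build_junction(limbs=limbs)

    def test_limb_spec_invariants(self):
        with pytest.raises(GeometryError):
            LimbSpec("X", 0.01, 0.01, (0, 0, 1))          # too short
        with pytest.raises(GeometryError):
            LimbSpec("X", 0.01, 0.03, (0, 0, 2))          # non-unit axis


class TestVoxelize:
    def test_tube_volume_converges_to_cylinder(self):
        D, L = 0.010, 0.04
        tube = straight_tube(D, L)
        exact = np.pi * D ** 2 / 4 * L
        coarse = abs(voxelize(tube, D / 8).fluid_volume / exact - 1)
        fine = abs(voxelize(tube, D / 48).fluid_volume / exact - 1)
        # fine voxel count reproduces the analytic volume within 0.5 %,
        # decaying at least first order from the coarse level
        assert fine < 0.005
        assert fine < 0.5 * coarse

    def test_port_area_converges_to_disc(self):
        D = 0.010
        tube = straight_tube(D, 0.04)
        exact = np.pi * D ** 2 / 4
        errs = [abs(voxelize(tube, D / f).port("OUT").area / exact - 1)
                for f in (6, 12, 24)]
        assert errs[-1] < 0.02
        assert errs[0] >= errs[-1]

    def test_resolution_guard(self):
        geo = build_junction("tcpc")
        dmin = min(l.diameter for l in geo.limbs)
        voxelize(geo, dmin / 5)  # accepted at the limit
        with pytest.raises(ResolutionError):
            voxelize(geo, 0.3 * dmin)

    def test_recommended_fraction_reported(self):
        geo = build_junction("glenn")
        grid = voxelize(geo, 0.10 * geo.reference_diameter)
        assert grid.dx_fraction() == pytest.approx(0.10, rel=1e-6)

    def test_rotation_by_quarter_turn_preserves_cell_count(self):
        D, L = 0.010, 0.040  # multiples of dx so lattice alignment matches
        dx = D / 8
        n_z = voxelize(straight_tube(D, L, axis=(0, 0, 1)), dx).n_fluid
        n_x = voxelize(straight_tube(D, L, axis=(1, 0, 0)), dx).n_fluid
        assert n_z == n_x

    def test_deterministic(self):
        geo = build_junction("glenn")
        a = voxelize(geo, 0.0015)
        b = voxelize(geo, 0.0015)
        assert np.array_equal(a.fluid_mask, b.fluid_mask)
        assert a.ports.keys() == b.ports.keys()
        for k in a.ports:
            assert np.array_equal(a.ports[k].face_index, b.ports[k].face_index)

    def test_single_connected_component_for_presets(self):
        for preset in ("glenn", "tcpc"):
            grid = voxelize(build_junction(preset), 0.0015)
            assert grid.connected_components() == 1

    def test_ports_are_planar_patches(self):
        grid = voxelize(build_junction("tcpc"), 0.0015)
        for port in grid.ports.values():
            # all faces share one index along the port axis
            assert len(set(port.face_index[:, port.axis])) == 1
            assert port.area > 0


@pytest.fixture(scope="module")
def roundtrip(tmp_path_factory):
    d = tmp_path_factory.mktemp("stl")
    geo = build_junction("tcpc")
    dx = 0.0015
    grid = voxelize(geo, dx)
    ports = [{"name": l.name, "role": l.role,
              "center": list(l.cap_center),
              "normal": list(np.asarray(l.axis)), "diameter": l.diameter}
             for l in grid.geometry.limbs]
    paths = {}
    for name, binary in (("bin.stl", True), ("asc.stl", False)):
        p = str(d / name)
        export_stl(geo, p, binary=binary, resolution=dx / 3)
        paths[name] = p
    return grid, dx, ports, paths


class TestStlRoundTrip:
    def test_both_dialects_voxelize_identically(self, roundtrip):
        grid, dx, ports, paths = roundtrip
        gb = voxelize_mesh(load_stl(paths["bin.stl"]), dx, ports)
        ga = voxelize_mesh(load_stl(paths["asc.stl"]), dx, ports)
        assert np.array_equal(gb.fluid_mask, ga.fluid_mask)

    def test_roundtrip_matches_parametric_voxelization(self, roundtrip):
        grid, dx, ports, paths = roundtrip
        gb = voxelize_mesh(load_stl(paths["bin.stl"]), dx, ports)
        assert gb.n_fluid == grid.n_fluid
        for k in grid.ports:
            assert gb.ports[k].n_faces == grid.ports[k].n_faces

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_text("")
        with pytest.raises(FormatError):
            load_stl(str(p))

    def test_missing_file_rejected(self):
        with pytest.raises(FormatError):
            load_stl("/nonexistent/file.stl")
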