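"""Voxel domains: rasterisation, fixtures, unit cells, connectivity."""

import math
from dataclasses import replace

import numpy as np
import pytest

from scaffoldflow.geometry import (
    BoxEnvelope,
    Filament,
    ScaffoldSpec,
    SolidGeometry,
    build_rectangular_scaffold,
)
from scaffoldflow.voxel import (
    VoxelDomain,
    connectivity_filter,
    extract_unit_cell,
    make_channel_fixture,
    unit_cell_domain,
    voxelize,
    write_vtk_image,
)


def _filament_geometry(diameter=0.5, spacing=0.05, length=4.0):
    f = Filament(axis=0, transverse=1.0, z=1.0, radius=diameter / 2, span=(0.0, length))
    return SolidGeometry([f], BoxEnvelope(length, 2.0, 2.0))


class TestVoxelize:
    def test_cylinder_cross_section_area_close_to_disc(self):
        h = 0.05
        g = _filament_geometry(diameter=10 * h, spacing=h)
        dom = voxelize(g, spacing=h, entry_length=0.1, exit_length=0.1)
        k0, k1 = dom.scaffold_range
        # count solid voxels in one interior x-slab column
        per_slice = dom.scaffold[20, :, k0:k1].sum()
        area = per_slice * h * h
        assert area == pytest.approx(math.pi * (5 * h) ** 2, rel=0.05)

    def test_empty_geometry_is_all_fluid(self):
        dom = voxelize(SolidGeometry([], BoxEnvelope(1, 1, 1)), spacing=0.1)
        assert not dom.scaffold.any()
        assert dom.fluid.all()

    def test_full_scaffold_voxel_porosity_close_to_constructive(self):
        g = build_rectangular_scaffold(ScaffoldSpec.case_1a())
        exact = 1.0 - g.volume() / g.envelope.volume
        dom = voxelize(g, spacing=0.055, entry_length=0.22, exit_length=0.22)
        assert dom.porosity() == pytest.approx(exact, abs=0.01)

    def test_voxel_porosity_error_shrinks_with_resolution(self):
        # first-order surface convergence holds asymptotically; individual
        # spacings fluctuate with rasterisation phase, so compare across a
        # 4x refinement
        g = build_rectangular_scaffold(ScaffoldSpec.case_1a())
        exact = 1.0 - g.volume() / g.envelope.volume
        errs = [
            abs(voxelize(g, spacing=h, entry_length=0.1, exit_length=0.1).porosity() - exact)
            for h in (0.1, 0.025)
        ]
        assert errs[1] < errs[0]
        assert errs[1] < 0.004

    def test_coarse_spacing_rejected_with_floor_message(self):
        g = build_rectangular_scaffold(ScaffoldSpec.case_1a())
        with pytest.raises(ValueError, match="3 voxels"):
            voxelize(g, spacing=0.102)
        with pytest.raises(ValueError, match="fibre_diameter/3"):
            voxelize(g, spacing=0.2)

    def test_counts_and_relabelling_invariants(self):
        g = _filament_geometry()
        dom = voxelize(g, spacing=0.05, entry_length=0.2, exit_length=0.2)
        assert dom.fluid.sum() + dom.solid.sum() == np.prod(dom.shape)
        relabelled = replace(dom, lateral={"x": "periodic", "y": "periodic"})
        assert np.array_equal(relabelled.solid, dom.solid)


class TestChannelFixtures:
    def test_parallel_plate_gap_resolution(self):
        dom = make_channel_fixture("parallel_plate", 0.3, length=1.0, spacing=0.015)
        k = dom.shape[2] // 2
        assert dom.fluid[:, 0, k].sum() == 20  # voxels across the gap

    def test_tube_cross_section_area(self):
        R = 0.5
        dom = make_channel_fixture("circular_tube", R, length=0.5, spacing=1 / 30.0)
        k = dom.shape[2] // 2
        area = dom.fluid[:, :, k].sum() * dom.spacing**2
        assert area == pytest.approx(math.pi * R * R, rel=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_channel_fixture("parallel_plate", 0.3, length=0.0, spacing=0.015)
        with pytest.raises(ValueError, match="under-resolved"):
            make_channel_fixture("circular_tube", 0.05, length=1.0, spacing=0.02)
        with pytest.raises(ValueError, match="kind"):
            make_channel_fixture("triangle", 0.3, length=1.0, spacing=0.015)


class TestConnectivity:
    def test_sealed_pocket_is_excluded_and_filter_idempotent(self):
        solid = np.zeros((7, 7, 9), dtype=bool)
        solid[2:5, 2:5, 3:6] = True
        solid[3, 3, 4] = False  # sealed cavity
        dom = VoxelDomain(solid=solid, spacing=0.1, scaffold=solid.copy(), scaffold_range=(3, 6))
        filtered = connectivity_filter(dom)
        assert filtered.n_excluded == 1
        assert filtered.solid[3, 3, 4]
        again = connectivity_filter(filtered)
        assert again.n_excluded == filtered.n_excluded
        assert np.array_equal(again.solid, filtered.solid)


class TestUnitCell:
    def test_period_lengths_match_design(self):
        uc_a = unit_cell_domain(ScaffoldSpec.case_1a(), 0.0525, entry_length=0.21, exit_length=0.21)
        assert uc_a.shape[0] * uc_a.spacing == pytest.approx(0.63)
        uc_c = unit_cell_domain(ScaffoldSpec.case_1c(), 0.065, entry_length=0.26, exit_length=0.26)
        assert uc_c.shape[0] * uc_c.spacing == pytest.approx(0.78)
        assert uc_a.lateral == {"x": "periodic", "y": "periodic"}

    def test_extracted_cell_matches_full_interior_porosity(self):
        spec = ScaffoldSpec.case_1a()
        g = build_rectangular_scaffold(spec)
        dom = voxelize(g, spacing=0.0525, entry_length=0.21, exit_length=0.21)
        cell = extract_unit_cell(dom, spec)
        assert cell.shape[0] == cell.shape[1] == 12
        assert cell.porosity() == pytest.approx(dom.porosity(), abs=0.02)

    def test_extraction_rejects_graded_and_misaligned(self):
        spec = ScaffoldSpec.case_1a()
        g = build_rectangular_scaffold(spec)
        dom = voxelize(g, spacing=0.06, entry_length=0.24, exit_length=0.24)
        with pytest.raises(ValueError, match="integer"):
            extract_unit_cell(dom, spec)
        with pytest.raises(ValueError, match="period"):
            extract_unit_cell(dom, ScaffoldSpec.case_2())


def test_vtk_export_roundtrips_header(tmp_path):
    dom = make_channel_fixture("parallel_plate", 0.3, length=0.5, spacing=0.03)
    path = tmp_path / "dom.vtk"
    write_vtk_image(path, dom, fields={"p": np.zeros(dom.shape)})
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    nx, ny, nz = dom.shape
    assert f"DIMENSIONS {nx} {ny} {nz}" in text
    assert any(line.startswith("SCALARS p") for line in text)
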