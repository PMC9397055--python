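"""Scaffold construction and geometric metrics."""

import math

import numpy as np
import pytest
import trimesh

from scaffoldflow.geometry import (
    BoxEnvelope,
    Filament,
    ScaffoldSpec,
    SolidGeometry,
    Sphere,
    build_graded_ring_scaffold,
    build_rectangular_scaffold,
    compute_geometry_metrics,
    export_stl,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(fibre_diameter=-0.3), "fibre_diameter"),
            (dict(pore_sizes=(0.0,)), "pore_sizes"),
            (dict(n_layers=0), "n_layers"),
            (dict(layer_pitch=0.5), "layer_pitch"),
            (dict(lay_down_angle_increment=45.0), "lay_down_angle_increment"),
            (dict(pore_sizes=(0.3, 0.4)), "pore_sizes"),
        ],
    )
    def test_invalid_rectangular_fields_are_named(self, kwargs, match):
        base = dict(
            kind="rectangular", length=20.0, width=20.0, height=3.1,
            n_layers=10, fibre_diameter=0.33, pore_sizes=(0.3,),
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=match):
            ScaffoldSpec(**base)

    def test_graded_ring_requires_increasing_pores_and_matching_count(self):
        base = dict(
            kind="graded_ring", length=31.0, width=26.7, height=3.1,
            n_layers=10, fibre_diameter=0.33,
        )
        with pytest.raises(ValueError, match="increasing"):
            ScaffoldSpec(pore_sizes=(0.9, 0.5), **base)
        with pytest.raises(ValueError, match="ring_count"):
            ScaffoldSpec(pore_sizes=(0.5, 0.9), ring_count=3, **base)

    def test_catalogue_designs_carry_published_parameters(self):
        b = ScaffoldSpec.case_1b()
        assert b.pore_sizes == (0.350,)
        assert b.fibre_diameter == 0.33
        assert b.layer_pitch == pytest.approx(0.31)
        c2 = ScaffoldSpec.case_2()
        assert c2.pore_sizes == (0.476, 0.629, 0.670, 0.730, 0.803, 0.979)
        assert c2.ring_count == 6

    def test_builders_reject_wrong_kind(self):
        with pytest.raises(ValueError, match="kind"):
            build_rectangular_scaffold(ScaffoldSpec.case_2())
        with pytest.raises(ValueError, match="kind"):
            build_graded_ring_scaffold(ScaffoldSpec.case_1a())


class TestRectangular:
    def test_filament_count_follows_pore_spacing(self):
        # floor(width / (pore + diameter)) + 1 filaments per layer
        g_a = build_rectangular_scaffold(ScaffoldSpec.case_1a())
        g_c = build_rectangular_scaffold(ScaffoldSpec.case_1c())
        per_layer_a = len(g_a.filaments) / 10
        per_layer_c = len(g_c.filaments) / 10
        assert per_layer_a == math.floor(20.0 / 0.63) + 1 == 32
        assert per_layer_c == math.floor(20.0 / 0.78) + 1 == 26
        assert per_layer_c < per_layer_a

    def test_porosity_increases_with_pore_size(self):
        por = [
            compute_geometry_metrics(build_rectangular_scaffold(ScaffoldSpec.rectangular_case(p))).porosity
            for p in (0.300, 0.350, 0.45)
        ]
        assert por[0] < por[1] < por[2]

    def test_single_filament_volume_is_trimmed_cylinder(self):
        spec = ScaffoldSpec(
            kind="rectangular", length=5.0, width=5.0, height=0.33,
            n_layers=1, fibre_diameter=0.33, pore_sizes=(10.0,), layer_pitch=0.33,
        )
        g = build_rectangular_scaffold(spec)
        assert len(g.filaments) == 1
        r = 0.165
        assert g.volume() == pytest.approx(math.pi * r * r * 5.0, rel=1e-6)

    def test_volume_matches_independent_overlap_decomposition(self):
        # sum of cylinders minus analytic small-overlap crossings
        spec = ScaffoldSpec.case_1a()
        g = build_rectangular_scaffold(spec)
        r = spec.fibre_diameter / 2
        pitch = spec.layer_pitch
        n_per = 32
        cyl = 10 * n_per * math.pi * r * r * 20.0
        # crossing overlap of perpendicular cylinders, centre planes `pitch`
        # apart, small-overlap closed form pi*r*(2r-pitch)^2
        lens = math.pi * r * (2 * r - pitch) ** 2
        overlap = 9 * n_per * n_per * lens
        # top/bottom trim: circular segment of height (stack - H)/2 per face
        hseg = (9 * pitch + 2 * r - spec.height) / 2
        seg = r * r * math.acos((r - hseg) / r) - (r - hseg) * math.sqrt(2 * r * hseg - hseg * hseg)
        trim = 2 * n_per * seg * 20.0
        assert g.volume() == pytest.approx(cyl - overlap - trim, rel=2e-3)


class TestGradedRing:
    def test_single_ring_reduces_to_uniform_circular_grid(self):
        spec = ScaffoldSpec(
            kind="graded_ring", length=10.0, width=10.0, height=0.93,
            n_layers=3, fibre_diameter=0.33, pore_sizes=(0.5,), ring_count=1,
        )
        g = build_graded_ring_scaffold(spec)
        # every filament is a single full chord (no annulus splitting)
        spans = [f.span for f in g.filaments]
        assert all(lo < 0 < hi for lo, hi in spans)

    def test_porosity_monotone_in_outermost_pore(self):
        base = dict(
            kind="graded_ring", length=12.0, width=10.0, height=1.55,
            n_layers=5, fibre_diameter=0.33, ring_count=2,
        )
        g_small = build_graded_ring_scaffold(ScaffoldSpec(pore_sizes=(0.5, 0.7), **base))
        g_large = build_graded_ring_scaffold(ScaffoldSpec(pore_sizes=(0.5, 0.9), **base))
        v_small, v_large = g_small.volume(), g_large.volume()
        assert v_large < v_small  # larger pores, less material

    def test_graded_design_beats_every_rectangular_porosity(self):
        por2 = compute_geometry_metrics_porosity_only(build_graded_ring_scaffold(ScaffoldSpec.case_2()))
        for name in ("1A", "1B", "1C"):
            g = build_rectangular_scaffold(ScaffoldSpec.named(name))
            assert por2 > compute_geometry_metrics_porosity_only(g)


def compute_geometry_metrics_porosity_only(geometry) -> float:
    return 1.0 - geometry.volume() / geometry.envelope.volume


class TestMetrics:
    def test_sphere_volume_and_specific_surface_closed_form(self):
        g = SolidGeometry([Sphere((0.5, 0.5, 0.5), 0.1)], BoxEnvelope(1, 1, 1))
        m = compute_geometry_metrics(g)
        assert m.V_material == pytest.approx(4 / 3 * math.pi * 0.1**3, rel=1e-12)
        assert m.specific_surface == pytest.approx(4 * math.pi * 0.1**2, rel=1e-12)

    def test_empty_geometry_is_all_void(self):
        m = compute_geometry_metrics(SolidGeometry([], BoxEnvelope(1, 1, 1)))
        assert m.porosity == 1.0
        assert m.SA == 0.0
        assert m.specific_surface == 0.0

    def test_porosity_invariant_under_in_plane_translation(self):
        # same filament, shifted within a larger envelope
        def build(offset):
            f = Filament(axis=0, transverse=1.0 + offset, z=0.5, radius=0.165, span=(0.0, 4.0))
            return SolidGeometry([f], BoxEnvelope(4.0, 4.0, 1.0))

        m0 = compute_geometry_metrics(build(0.0))
        m1 = compute_geometry_metrics(build(1.3))
        assert m1.porosity == pytest.approx(m0.porosity, rel=1e-9)

    def test_watertight_mesh_path_and_defect_error(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        m = compute_geometry_metrics(box, envelope=BoxEnvelope(2.0, 2.0, 2.0))
        assert m.V_material == pytest.approx(1.0)
        assert m.porosity == pytest.approx(1 - 1.0 / 8.0)
        holed = trimesh.Trimesh(
            vertices=box.vertices, faces=box.faces[:-2], process=False
        )
        with pytest.raises(ValueError, match="watertight"):
            compute_geometry_metrics(holed, envelope=BoxEnvelope(2.0, 2.0, 2.0))

    def test_stl_export_writes_mesh(self, tmp_path):
        spec = ScaffoldSpec(
            kind="rectangular", length=3.0, width=3.0, height=0.62,
            n_layers=2, fibre_diameter=0.33, pore_sizes=(1.0,),
        )
        path = tmp_path / "cell.stl"
        export_stl(build_rectangular_scaffold(spec), path)
        again = trimesh.load(str(path))
        assert len(again.faces) > 0
        assert path.stat().st_size > 84
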