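"""Scene composition, label placement, ribbons and deterministic export."""

import math

import pytest

from circleplot import fixtures, formats_io as fio
from circleplot.formats_io import ColorSpec, LinkRecord, RegionTagRecord, SkeletonRecord
from circleplot.layout import build_layout, genomic_to_theta
from circleplot.project import Project
from circleplot.render import (
    compose,
    export,
    place_labels,
    render_links,
    render_skeleton,
    scene_to_svg,
)
from circleplot.tracks import TrackSpec


@pytest.fixture(scope="module")
def layout():
    return build_layout([SkeletonRecord(f"Chr{i+1}", 1_000_000) for i in range(4)])


def directed_u(layout, theta):
    return (layout.start_angle - theta) if layout.clockwise else (theta - layout.start_angle)


class TestRenderSkeleton:
    def test_band_label_tick_counts(self, layout):
        prims = render_skeleton(layout)
        assert sum(p.kind == "arc_band" for p in prims) == 4
        assert sum(p.kind == "text" for p in prims) == 4

    def test_band_fill_from_skeleton_colors(self):
        skel = [SkeletonRecord("Chr1", 100, ColorSpec(9, 8, 7))]
        prims = render_skeleton(build_layout(skel))
        band = next(p for p in prims if p.kind == "arc_band")
        assert band.fill == ColorSpec(9, 8, 7)


class TestRenderLinks:
    def test_ribbon_per_link(self, layout):
        links = [
            LinkRecord("Chr1", 1, 1000, "Chr2", 1, 1000),
            LinkRecord("Chr3", 5, 50, "Chr4", 5, 50),
        ]
        prims, warnings = render_links(links, layout)
        assert len(prims) == 2 and not warnings

    def test_degenerate_self_link_skipped(self, layout):
        links = [LinkRecord("Chr1", 10, 20, "Chr1", 10, 20)]
        prims, warnings = render_links(links, layout)
        assert prims == [] and len(warnings) == 1

    def test_anchors_equal_layout_transform(self, layout):
        lk = LinkRecord("Chr1", 123, 4567, "Chr3", 89, 101112)
        (rib,), _ = render_links([lk], layout, radius=40.0)
        expected = [
            genomic_to_theta(layout, "Chr1", 123),
            genomic_to_theta(layout, "Chr1", 4567),
            genomic_to_theta(layout, "Chr3", 89),
            genomic_to_theta(layout, "Chr3", 101112),
        ]
        for (theta, r), want in zip(rib.points[:4], expected):
            assert theta == pytest.approx(want, abs=1e-9)
            assert r == 40.0


class TestPlaceLabels:
    def overlaps(self, placement, layout):
        """Count overlapping label pairs using bounding intervals in u-space."""
        ivs = sorted(
            (directed_u(layout, pl.placed_theta) - pl.width_deg / 2,
             directed_u(layout, pl.placed_theta) + pl.width_deg / 2)
            for pl in placement.labels
        )
        return sum(ivs[i][1] > ivs[i + 1][0] + 1e-9 for i in range(len(ivs) - 1))

    def test_distant_labels_not_displaced(self, layout):
        tags = [
            RegionTagRecord("Chr1", "A", 100, 200),
            RegionTagRecord("Chr3", "B", 100, 200),
        ]
        lp = place_labels(tags, layout)
        for pl in lp.labels:
            assert pl.placed_theta == pytest.approx(pl.anchor_theta, abs=1e-12)

    def test_coincident_pair_symmetric(self, layout):
        tags = [RegionTagRecord("Chr1", "AA", 500, 500),
                RegionTagRecord("Chr1", "BB", 500, 500)]
        lp = place_labels(tags, layout)
        a, b = lp.labels
        da = directed_u(layout, a.placed_theta) - directed_u(layout, a.anchor_theta)
        db = directed_u(layout, b.placed_theta) - directed_u(layout, b.anchor_theta)
        assert da == pytest.approx(-db)
        assert self.overlaps(lp, layout) == 0

    @pytest.mark.parametrize("weight", [-6, -4, -2, 0])
    def test_twenty_coincident_resolved(self, layout, weight):
        tags = [RegionTagRecord("Chr2", f"GENE{i:02d}", 500_000, 500_000)
                for i in range(20)]
        lp = place_labels(tags, layout, overlap_weight=weight)
        assert self.overlaps(lp, layout) == 0
        assert lp.iterations <= 500
        # input order preserved along the plotting direction
        us = [directed_u(layout, pl.placed_theta) for pl in lp.labels]
        assert us == sorted(us)

    def test_larger_weight_spreads_more(self, layout):
        tags = [RegionTagRecord("Chr2", f"G{i}", 500_000, 500_000) for i in range(5)]
        def spread(w):
            lp = place_labels(tags, layout, overlap_weight=w)
            us = [directed_u(layout, pl.placed_theta) for pl in lp.labels]
            return max(us) - min(us)
        assert spread(0) > spread(-4) > 0

    def test_deterministic(self, layout):
        tags = [RegionTagRecord("Chr1", f"X{i}", 1000 * i + 1, 1000 * i + 10)
                for i in range(10)]
        a = place_labels(tags, layout)
        b = place_labels(tags, layout)
        assert [pl.placed_theta for pl in a.labels] == [pl.placed_theta for pl in b.labels]

    def test_overflow_warns(self, layout):
        tags = [RegionTagRecord("Chr1", "LONGLABELNAME" * 4, 1, 10) for _ in range(200)]
        lp = place_labels(tags, layout)
        assert lp.warnings


def demo_project(genome, skeleton):
    """Seven-track project exercising every glyph family."""
    from circleplot.stats_prep import WindowSpec, window_composition
    import tempfile, os

    d = tempfile.mkdtemp()
    fa = genome.write_fasta(os.path.join(d, "g.fa"))
    comp = window_composition(fa, WindowSpec(2000))
    links_text, _ = fixtures.make_links(genome, 8, seed=4)
    qtl_text, _ = fixtures.make_qtl_table(genome, 10, seed=5, reversed_fraction=0.3)
    tags = [RegionTagRecord("Chr1", f"gene{i}", 5000 * i + 1, 5000 * i + 100)
            for i in range(5)]
    return Project(
        skeleton=skeleton,
        tags=tags,
        links=fio.parse_links(links_text),
        tracks=[
            (comp.n_ratio, TrackSpec("point", 78, 88)),
            (comp.gc_skew, TrackSpec("line", 66, 76, sep_line_value=0.0)),
            (comp.gc_content, TrackSpec("heatmap", 54, 64, name="GC")),
            (comp.gc_content, TrackSpec("bar", 42, 52, color_by_chr=True,
                                        bar_fill=ColorSpec(230, 230, 230))),
            (comp.n_ratio, TrackSpec("bar", 30, 40, invert=True)),
            (fio.parse_discrete(qtl_text), TrackSpec("tile", 90, 100, bar_border=None)),
            (fio.parse_discrete(qtl_text), TrackSpec("arrow", 20, 26)),
        ],
    )


class TestCompose:
    def test_skeleton_only_scene(self, skeleton):
        scene = compose(Project(skeleton=skeleton))
        census = scene.census()
        assert set(census) == {"arc_band", "text", "polyline"}
        assert census["arc_band"] == len(skeleton)

    def test_adding_heatmap_adds_sectors_and_legend(self, genome, skeleton):
        from circleplot.stats_prep import WindowSpec, window_composition
        import tempfile, os
        fa = genome.write_fasta(os.path.join(tempfile.mkdtemp(), "g.fa"))
        comp = window_composition(fa, WindowSpec(5000))
        base = compose(Project(skeleton=skeleton))
        plus = compose(Project(skeleton=skeleton,
                               tracks=[(comp.gc_content, TrackSpec("heatmap", 50, 60))]))
        assert plus.census().get("sector", 0) == len(comp.gc_content)
        assert plus.census().get("legend_box", 0) == 1
        assert base.census().get("sector", 0) == 0

    def test_mode_equivalence_census(self, genome, skeleton):
        proj = demo_project(genome, skeleton)
        circ = compose(proj)
        proj.settings["circularized"] = False
        straight = compose(proj)
        assert circ.census() == straight.census()
        assert circ.mode == "circular" and straight.mode == "straight"


class TestExport:
    def test_svg_deterministic(self, genome, skeleton, tmp_path):
        proj = demo_project(genome, skeleton)
        a = scene_to_svg(compose(proj))
        b = scene_to_svg(compose(proj))
        assert a == b

    def test_svg_wellformed_xml(self, skeleton, tmp_path):
        import xml.etree.ElementTree as ET
        p = export(compose(Project(skeleton=skeleton)), tmp_path / "s.svg")
        root = ET.parse(p).getroot()
        assert root.tag.endswith("svg")

    def test_svg_element_count_tracks_primitives(self, skeleton, tmp_path):
        import xml.etree.ElementTree as ET
        scene = compose(Project(skeleton=skeleton))
        p = export(scene, tmp_path / "s.svg")
        n_elements = sum(1 for _ in ET.parse(p).getroot().iter()) - 1  # minus root
        assert n_elements >= len(scene.primitives)

    def test_png_dpi_scales_pixels(self, skeleton, tmp_path):
        from PIL import Image
        scene = compose(Project(skeleton=skeleton))
        p1 = export(scene, tmp_path / "a.png", dpi=50)
        p2 = export(scene, tmp_path / "b.png", dpi=100)
        w1 = Image.open(p1).size[0]
        w2 = Image.open(p2).size[0]
        assert w2 == 2 * w1

    def test_unknown_format_rejected(self, skeleton, tmp_path):
        with pytest.raises(ValueError):
            export(compose(Project(skeleton=skeleton)), tmp_path / "x.pdf")
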