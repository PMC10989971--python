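"""Portable project bundles.

A :class:`Project` collects everything a figure needs — the chromosome
skeleton, optional region tags and association links, an ordered list of
(records, :class:`~circleplot.tracks.TrackSpec`) tracks, and the global plot
settings. ``save_project`` writes a directory holding ``project.json`` (all
settings, schema-versioned) plus a ``data/`` subdirectory with the input
tables re-serialized in their canonical TSV dialects; only relative paths
are stored, so the directory can be moved or shared and
``load_project(save_project(p))`` reproduces ``p`` record-for-record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from . import formats_io as fio
from .stats_prep import WindowSpec
from .tracks import TrackSpec

__all__ = ["Project", "ProjectError", "save_project", "load_project", "DEFAULT_SETTINGS"]

SCHEMA_VERSION = 1

_CONTINUOUS_GLYPHS = {"heatmap", "bar", "line", "point"}
_DISCRETE_GLYPHS = {"tile", "triangle", "arrow"}

DEFAULT_SETTINGS: dict = {
    "gap_fraction": 0.005,
    "start_angle": 90.0,
    "clockwise": True,
    "circularized": True,
    "canvas": {"width": 800.0, "height": 800.0, "background": "255,255,255"},
    "skeleton_span": [92.0, 97.0],
    "tick_target_major_count": 5,
    "label": {"overlap_weight": -4.0, "font_size": 10.0, "radius": 99.0},
    "legend_anchors": [],
}


class ProjectError(ValueError):
    pass


@dataclass
class Project:
    skeleton: list[fio.SkeletonRecord]
    tags: list[fio.RegionTagRecord] = field(default_factory=list)
    links: list[fio.LinkRecord] = field(default_factory=list)
    tracks: list[tuple[list, TrackSpec]] = field(default_factory=list)
    settings: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_SETTINGS)))
    schema_version: int = SCHEMA_VERSION

    def setting(self, *keys, default=None):
        node = self.settings
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node


def _color_to_json(c: Optional[fio.ColorSpec]):
    return None if c is None else c.text


def _color_from_json(text) -> Optional[fio.ColorSpec]:
    return None if text is None else fio.parse_color(text)


def _spec_to_json(spec: TrackSpec) -> dict:
    return {
        "glyph": spec.glyph,
        "start_pos": spec.start_pos,
        "end_pos": spec.end_pos,
        "bin": None if spec.bin is None else {"window": spec.bin.window, "step": spec.bin.step},
        "bin_mode": spec.bin_mode,
        "palette": (
            spec.palette
            if spec.palette is None or isinstance(spec.palette, str)
            else [c.text for c in spec.palette]
        ),
        "color_by_chr": spec.color_by_chr,
        "sep_line_value": spec.sep_line_value,
        "above_color": spec.above_color.text,
        "below_color": spec.below_color.text,
        "bar_fill": _color_to_json(spec.bar_fill),
        "bar_border": _color_to_json(spec.bar_border),
        "fill": _color_to_json(spec.fill),
        "value_range": list(spec.value_range) if spec.value_range else None,
        "heat_scale": spec.heat_scale,
        "invert": spec.invert,
        "name": spec.name,
    }


def _spec_from_json(d: dict) -> TrackSpec:
    palette = d.get("palette")
    if isinstance(palette, list):
        palette = tuple(fio.parse_color(t) for t in palette)
    return TrackSpec(
        glyph=d["glyph"],
        start_pos=d["start_pos"],
        end_pos=d["end_pos"],
        bin=None if d.get("bin") is None else WindowSpec(d["bin"]["window"], d["bin"]["step"]),
        bin_mode=d.get("bin_mode", "none"),
        palette=palette,
        color_by_chr=d.get("color_by_chr", False),
        sep_line_value=d.get("sep_line_value"),
        above_color=fio.parse_color(d.get("above_color", "214,39,40")),
        below_color=fio.parse_color(d.get("below_color", "31,119,180")),
        bar_fill=_color_from_json(d.get("bar_fill")),
        bar_border=_color_from_json(d.get("bar_border")),
        fill=_color_from_json(d.get("fill")),
        value_range=tuple(d["value_range"]) if d.get("value_range") else None,
        heat_scale=d.get("heat_scale", "linear"),
        invert=d.get("invert", False),
        name=d.get("name", ""),
    )


def save_project(project: Project, directory: Union[str, Path]) -> Path:
    """Write the project bundle; returns the directory path."""
    directory = Path(directory)
    data_dir = directory / "data"
    data_dir.mkdir(parents=True, exist_ok=True)

    (data_dir / "skeleton.tsv").write_text(fio.write_skeleton(project.skeleton))
    manifest: dict = {
        "schema_version": project.schema_version,
        "settings": project.settings,
        "skeleton": "data/skeleton.tsv",
        "tags": None,
        "links": None,
        "tracks": [],
    }
    if project.tags:
        (data_dir / "tags.tsv").write_text(fio.write_region_tags(project.tags))
        manifest["tags"] = "data/tags.tsv"
    if project.links:
        (data_dir / "links.tsv").write_text(fio.write_links(project.links))
        manifest["links"] = "data/links.tsv"
    for i, (records, spec) in enumerate(project.tracks):
        fname = f"track{i:02d}.tsv"
        if spec.glyph in _DISCRETE_GLYPHS:
            text, kind = fio.write_discrete(records), "discrete"
        else:
            text, kind = fio.write_continuous(records), "continuous"
        (data_dir / fname).write_text(text)
        manifest["tracks"].append(
            {"data": f"data/{fname}", "kind": kind, "spec": _spec_to_json(spec)}
        )
    (directory / "project.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return directory


def load_project(directory: Union[str, Path]) -> Project:
    """Reload a saved bundle; inverse of :func:`save_project`."""
    directory = Path(directory)
    settings_path = directory / "project.json"
    if not settings_path.is_file():
        raise ProjectError(f"no project.json in {directory}")
    try:
        manifest = json.loads(settings_path.read_text())
    except json.JSONDecodeError as e:
        raise ProjectError(f"corrupted project.json in {directory}: {e}") from None
    for key in ("schema_version", "settings", "skeleton", "tracks"):
        if key not in manifest:
            raise ProjectError(f"project.json missing required key {key!r}")

    def read(rel: str) -> str:
        path = directory / rel
        if not path.is_file():
            raise ProjectError(f"referenced data file {rel!r} absent from project")
        return path.read_text()

    skeleton = fio.parse_skeleton(read(manifest["skeleton"]))
    tags = fio.parse_region_tags(read(manifest["tags"])) if manifest.get("tags") else []
    links = fio.parse_links(read(manifest["links"])) if manifest.get("links") else []
    tracks = []
    for t in manifest["tracks"]:
        text = read(t["data"])
        records = fio.parse_discrete(text) if t["kind"] == "discrete" else fio.parse_continuous(text)
        tracks.append((records, _spec_from_json(t["spec"])))
    return Project(
        skeleton=skeleton,
        tags=tags,
        links=links,
        tracks=tracks,
        settings=manifest["settings"],
        schema_version=manifest["schema_version"],
    )
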