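"""Readers/writers for scenes, spot tables and skeleton graphs.

Scenes go to multi-page TIFF (one page per channel), spot tables to CSV,
graphs to GraphML (node positions and classes, edge lengths and radii).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .detection import SpotRecord
from .graph import SkeletonGraph
from .synthetic import SpotTruth, SyntheticScene

CHANNEL_ORDER = ("hook", "anchor", "matrix")


def write_scene_tiff(scene: SyntheticScene, path: Path) -> None:
    stack = np.stack([scene.channels[c] for c in CHANNEL_ORDER])
    tifffile.imwrite(path, stack.astype(np.float32),
                     metadata={"axes": "CYX",
                               "channels": ",".join(CHANNEL_ORDER),
                               "pixel_size_nm": scene.pixel_size_nm})


def read_scene_tiff(path: Path) -> dict[str, np.ndarray]:
    stack = tifffile.imread(path)
    return {c: stack[i] for i, c in enumerate(CHANNEL_ORDER)}


def truth_spots_to_csv(spots: list[SpotTruth], path: Path) -> None:
    pd.DataFrame(
        {"x_nm": [s.position_nm[0] for s in spots],
         "y_nm": [s.position_nm[1] for s in spots],
         "class": [s.true_class for s in spots]}
    ).to_csv(path, index=False)


def detected_spots_to_csv(spots: list[SpotRecord], path: Path,
                          labels: list[str] | None = None) -> None:
    df = pd.DataFrame(
        {"x_px": [s.centroid_px[0] for s in spots],
         "y_px": [s.centroid_px[1] for s in spots],
         "x_nm": [s.centroid_nm[0] for s in spots],
         "y_nm": [s.centroid_nm[1] for s in spots],
         "area_um2": [s.area_um2 for s in spots],
         "circularity": [s.circularity for s in spots],
         "is_free": [s.is_free for s in spots]})
    if labels is not None:
        df["location_class"] = labels
    df.to_csv(path, index=False)


def graph_to_graphml(graph: SkeletonGraph, path: Path) -> None:
    g = nx.MultiGraph()
    for n in graph.nodes:
        g.add_node(n.id, x_nm=float(n.position_nm[0]),
                   y_nm=float(n.position_nm[1]), node_class=n.node_class)
    for e in graph.edges:
        g.add_edge(e.u, e.v, length_nm=float(e.length_nm),
                   radius_nm=float(e.radius_nm),
                   polyline=json.dumps(np.asarray(e.polyline_nm).round(2)
                                       .tolist()))
    nx.write_graphml(g, path)


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
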