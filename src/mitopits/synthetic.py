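"""Ground-truthed synthetic scenes for the MitoPit analyses.

Emulates what the downstream operators assume about real data: tubular
mitochondrial networks (tube radius ~250 nm, i.e. ~500 nm width) with
endpoints and branchpoints, diffraction-limited puncta placed with
class-dependent propensity per unit surface area plus a detached "free"
fraction, Poisson + Gaussian camera noise, triplets of 1-D Gaussian
channel profiles with inter-channel peak offsets, and double-membrane
vesicle contour pairs.  Every generator is deterministic for a fixed
seed, and every planted quantity is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage
from scipy.spatial import cKDTree

from .graph import (BRANCHPOINT, EDGE, ENDPOINT, FREE, GraphEdge, GraphNode,
                    GroundTruthGraph, polyline_length, surface_areas)
from .profiles import ContourPair, LineProfile

__all__ = [
    "NetworkSpec",
    "PlacementModel",
    "ImagingModel",
    "ProfileSpec",
    "ContourSpec",
    "SpotTruth",
    "SyntheticScene",
    "PlacementError",
    "generate_network",
    "sample_spot_locations",
    "render_scene",
    "generate_profile_set",
    "generate_contour_pairs",
]


class PlacementError(RuntimeError):
    """Raised when a component or spot cannot be placed in the field."""


class NetworkSpec(BaseModel):
    """Parameters of a synthetic tubular network.

    The 45 nm/px default makes a 3-pixel detection kernel equal 135 nm;
    the 250 nm tube radius gives the ~500 nm tube width of a
    mitochondrion.
    """

    model_config = ConfigDict(extra="forbid")

    n_components: int = Field(default=1, ge=1)
    tube_radius_nm: float = Field(default=250.0, gt=0)
    mean_edge_length_nm: float = Field(default=3000.0, gt=0)
    branch_probability: float = Field(default=0.0, ge=0, lt=1)
    field_size_px: tuple[int, int] = (512, 512)  # (width, height)
    pixel_size_nm: float = Field(default=45.0, gt=0)
    seed: int

    @property
    def field_size_nm(self) -> tuple[float, float]:
        return (self.field_size_px[0] * self.pixel_size_nm,
                self.field_size_px[1] * self.pixel_size_nm)


class PlacementModel(BaseModel):
    """Class-dependent spot placement propensities (per unit area).

    The edge weight is the reference (1); a weight w on endpoints means
    spots are w times more likely per unit surface area at endpoints.
    ``free_fraction`` of spots detach from the network entirely.
    """

    model_config = ConfigDict(extra="forbid")

    weight_endpoint: float = Field(default=47.5, ge=0)
    weight_edge: float = Field(default=1.0, ge=0)
    weight_branchpoint: float = Field(default=0.0, ge=0)
    free_fraction: float = Field(default=0.2, ge=0, le=1)
    n_spots: int = Field(default=100, ge=0)
    seed: int


class ImagingModel(BaseModel):
    """Camera/optics model: PSF blur, photon (Poisson) noise, read noise."""

    model_config = ConfigDict(extra="forbid")

    psf_sigma_nm: float = Field(default=90.0, gt=0)
    spot_amplitude: float = Field(default=200.0, ge=0)
    tube_amplitude: float = Field(default=120.0, ge=0)
    poisson_scale: float = Field(default=1.0, ge=0)  # photons per unit
    read_noise_sd: float = Field(default=2.0, ge=0)
    background: float = Field(default=10.0, ge=0)


class ProfileSpec(BaseModel):
    """Triplets of 1-D Gaussian channel profiles with planted offsets.

    Default offsets mirror the spatial ordering matrix -> anchor -> hook:
    the anchor peak precedes the hook by ~80 nm and the matrix by ~180 nm.
    """

    model_config = ConfigDict(extra="forbid")

    offsets_nm: dict[str, float] = {"hook": 0.0, "anchor": -80.0,
                                    "matrix": -180.0}
    sigmas_nm: dict[str, float] = {"hook": 100.0, "anchor": 140.0,
                                   "matrix": 160.0}
    amplitudes: dict[str, float] = {"hook": 100.0, "anchor": 80.0,
                                    "matrix": 80.0}
    baseline: float = 10.0
    sample_spacing_nm: float = Field(default=20.0, gt=0)
    half_window_nm: float = 600.0
    center_jitter_sd_nm: float = Field(default=40.0, ge=0)
    noise_sd: float = Field(default=0.0, ge=0)
    n_profiles: int = Field(default=50, ge=0)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ProfileSpec":
        if set(self.sigmas_nm) != set(self.offsets_nm) or \
           set(self.amplitudes) != set(self.offsets_nm):
            raise ValueError("channel names must match across fields")
        if any(s <= 0 for s in self.sigmas_nm.values()):
            raise ValueError("sigmas must be positive")
        if self.half_window_nm < 3.0 * max(self.sigmas_nm.values()):
            raise ValueError("half_window must be >= 3x the largest sigma")
        return self


class ContourSpec(BaseModel):
    """Elliptical double-membrane vesicle cross-sections."""

    model_config = ConfigDict(extra="forbid")

    outer_diameter_mean_nm: float = Field(default=120.0, gt=0)
    intermembrane_distance_mean_nm: float = Field(default=15.0, gt=0)
    axis_ratio: float = Field(default=1.2, ge=1.0)
    orientation: Optional[float] = None  # radians; None -> random per vesicle
    point_noise_sd_nm: float = Field(default=0.0, ge=0)
    n_vesicles: int = Field(default=36, ge=0)
    n_points: int = Field(default=100, ge=8)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "ContourSpec":
        if not self.outer_diameter_mean_nm > 2.0 * self.intermembrane_distance_mean_nm:
            raise ValueError("outer diameter must exceed twice the "
                             "intermembrane distance")
        return self


@dataclass
class SpotTruth:
    """A planted punctum with its ground-truth location class."""

    position_nm: np.ndarray  # (x, y)
    true_class: str  # endpoint | branchpoint | edge | free


@dataclass
class SyntheticScene:
    channels: dict[str, np.ndarray]  # hook, anchor, matrix
    truth_graph: GroundTruthGraph
    truth_spots: list[SpotTruth]
    pixel_size_nm: float


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

_STEP_NM = 100.0  # polyline sampling step
_HEADING_JITTER = 0.12  # rad per step, gentle tube curvature
_MAX_SEGMENTS = 7  # per component


def generate_network(spec: NetworkSpec) -> GroundTruthGraph:
    """Grow a random tree-shaped tubular network inside the field.

    Each component starts from an endpoint and grows gently curved
    segments; at a segment end, branching (probability
    ``branch_probability``) creates a degree-3 branchpoint with two
    children, otherwise an endpoint.  A component whose tube leaves the
    field is rejected and resampled (up to 100 tries); persistent failure
    raises :class:`PlacementError`.
    """
    rng = np.random.default_rng(spec.seed)
    margin = spec.tube_radius_nm + 2.0 * spec.pixel_size_nm
    separation = 3.0 * spec.tube_radius_nm  # axis-to-axis between components
    w_nm, h_nm = spec.field_size_nm
    if w_nm <= 2 * margin or h_nm <= 2 * margin:
        raise PlacementError("field too small for the tube radius")

    nodes: list[GraphNode] = []
    edges: list[GraphEdge] = []
    placed_pts: list[np.ndarray] = []
    next_id = 0

    for _comp in range(spec.n_components):
        tree = cKDTree(np.vstack(placed_pts)) if placed_pts else None
        for _attempt in range(100):
            comp_nodes, comp_edges = _grow_component(spec, rng, next_id)
            pts = np.vstack([e.polyline_nm for e in comp_edges])
            inside = (pts[:, 0].min() >= margin
                      and pts[:, 0].max() <= w_nm - margin
                      and pts[:, 1].min() >= margin
                      and pts[:, 1].max() <= h_nm - margin)
            clear = (tree is None
                     or tree.query(pts, k=1)[0].min() >= separation)
            if inside and clear:
                nodes.extend(comp_nodes)
                edges.extend(comp_edges)
                placed_pts.append(pts)
                next_id += len(comp_nodes)
                break
        else:
            raise PlacementError(
                f"could not place component {_comp} in the field "
                f"after 100 attempts")

    graph = GroundTruthGraph(nodes=nodes, edges=edges,
                             field_size_nm=(w_nm, h_nm),
                             pixel_size_nm=spec.pixel_size_nm)
    graph.validate()
    return graph


def _grow_component(spec: NetworkSpec, rng: np.random.Generator,
                    id_offset: int):
    w_nm, h_nm = spec.field_size_nm
    margin = spec.tube_radius_nm + 2.0 * spec.pixel_size_nm
    start = np.array([rng.uniform(margin, w_nm - margin),
                      rng.uniform(margin, h_nm - margin)])
    heading = rng.uniform(0.0, 2.0 * np.pi)

    nodes: list[GraphNode] = []
    edges: list[GraphEdge] = []

    def new_node(pos: np.ndarray, cls: str) -> int:
        nid = id_offset + len(nodes)
        nodes.append(GraphNode(id=nid, position_nm=pos.copy(), node_class=cls))
        return nid

    root = new_node(start, ENDPOINT)
    stack = [(root, start, heading, 0)]
    n_segments = 1
    while stack:
        parent, pos, ang, depth = stack.pop()
        length = spec.mean_edge_length_nm * rng.uniform(0.7, 1.3)
        n_steps = max(int(round(length / _STEP_NM)), 2)
        pts = [pos.copy()]
        a = ang
        for _ in range(n_steps):
            a += rng.normal(0.0, _HEADING_JITTER)
            pos = pos + (length / n_steps) * np.array([np.cos(a), np.sin(a)])
            pts.append(pos.copy())
        poly = np.asarray(pts)
        branch = (rng.random() < spec.branch_probability
                  and n_segments + 2 <= _MAX_SEGMENTS)
        end_cls = BRANCHPOINT if branch else ENDPOINT
        end_id = new_node(pos, end_cls)
        edges.append(GraphEdge(u=parent, v=end_id, polyline_nm=poly,
                               length_nm=polyline_length(poly),
                               radius_nm=spec.tube_radius_nm))
        if branch:
            spread = rng.uniform(0.5, 1.2)
            for sgn in (+1.0, -1.0):
                stack.append((end_id, pos.copy(), a + sgn * spread, depth + 1))
            n_segments += 2
    return nodes, edges


# ---------------------------------------------------------------------------
# spot placement
# ---------------------------------------------------------------------------

# Generator tolerances keeping planted class labels unambiguous under the
# nearest-node assignment rule (node jitter + localisation error stays
# inside one tube radius; edge spots stay well outside it):
_NODE_JITTER_FACTOR = 0.3  # node-spot jitter, in tube radii
_EDGE_EXCLUSION_FACTOR = 1.8  # node-free zone along edges, in tube radii
_EDGE_LATERAL_FACTOR = 0.4  # lateral jitter of edge spots, in tube radii
_FREE_CLEARANCE_FACTOR = 2.5  # min distance of free spots from tube axes


def sample_spot_locations(graph: GroundTruthGraph,
                          placement: PlacementModel) -> list[SpotTruth]:
    """Plant spots with class probability proportional to weight x area.

    On-network classes use the tube-model areas (endpoints: hemispherical
    caps; edges: cylinder sides; branchpoints: a nominal cap each);
    positions are sampled uniformly within the chosen class's region.
    Each spot is free with probability ``free_fraction``, placed away from
    the network.
    """
    rng = np.random.default_rng(placement.seed)
    has_graph = bool(graph.edges or graph.nodes)
    if placement.free_fraction < 1.0 and not has_graph:
        raise ValueError("graph is empty but free_fraction < 1")

    if has_graph and graph.edges:
        r = graph.mean_radius_nm()
        areas = surface_areas(graph)
        area_end, area_edge = areas.area_endpoint_nm2, areas.area_edge_nm2
        area_branch = graph.n_branchpoints * 2.0 * np.pi * r**2
    elif has_graph:
        r = 250.0
        area_end = graph.n_endpoints * 2.0 * np.pi * r**2
        area_edge = 0.0
        area_branch = graph.n_branchpoints * 2.0 * np.pi * r**2
    else:
        r = area_end = area_edge = area_branch = 0.0

    class_weights = np.array([
        placement.weight_endpoint * area_end,
        placement.weight_edge * area_edge,
        placement.weight_branchpoint * area_branch,
    ])
    total_w = class_weights.sum()
    if placement.free_fraction == 0.0 and total_w <= 0:
        raise ValueError("all class weights are zero and free_fraction is 0")

    ends = graph.node_positions(ENDPOINT) if has_graph else np.empty((0, 2))
    branches = (graph.node_positions(BRANCHPOINT) if has_graph
                else np.empty((0, 2)))
    edge_geom = _edge_sampling_geometry(graph, r) if graph.edges else None
    tube_tree = _tube_point_tree(graph) if graph.edges or len(ends) else None

    spots: list[SpotTruth] = []
    for _ in range(placement.n_spots):
        if rng.random() < placement.free_fraction:
            spots.append(SpotTruth(
                position_nm=_sample_free(graph, rng, tube_tree, r),
                true_class=FREE))
            continue
        if total_w <= 0:
            raise ValueError("no on-network placement measure")
        cls = rng.choice(3, p=class_weights / total_w)
        if cls == 0:
            node = ends[rng.integers(len(ends))]
            spots.append(SpotTruth(
                position_nm=node + _disk_jitter(rng, _NODE_JITTER_FACTOR * r),
                true_class=ENDPOINT))
        elif cls == 2:
            node = branches[rng.integers(len(branches))]
            spots.append(SpotTruth(
                position_nm=node + _disk_jitter(rng, _NODE_JITTER_FACTOR * r),
                true_class=BRANCHPOINT))
        else:
            spots.append(SpotTruth(
                position_nm=_sample_edge_point(edge_geom, rng, r),
                true_class=EDGE))
    return spots


def _disk_jitter(rng: np.random.Generator, radius: float) -> np.ndarray:
    rho = radius * np.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return rho * np.array([np.cos(phi), np.sin(phi)])


def _edge_sampling_geometry(graph: GroundTruthGraph, r: float):
    """Per-edge cumulative arc lengths and the node-free sampling windows."""
    m = _EDGE_EXCLUSION_FACTOR * r
    geoms = []
    weights = []
    for e in graph.edges:
        seg = np.linalg.norm(np.diff(e.polyline_nm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        allowed = max(e.length_nm - 2.0 * m, 0.0)
        geoms.append((e.polyline_nm, cum, m))
        weights.append(allowed)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        # every edge shorter than the exclusion zones: fall back to midpoints
        weights = np.array([e.length_nm for e in graph.edges], dtype=float)
        geoms = [(p, c, 0.45 * c[-1]) for (p, c, _m) in geoms]
    return geoms, weights / weights.sum()


def _sample_edge_point(edge_geom, rng: np.random.Generator,
                       r: float) -> np.ndarray:
    geoms, probs = edge_geom
    poly, cum, m = geoms[rng.choice(len(geoms), p=probs)]
    t = rng.uniform(m, cum[-1] - m)
    i = int(np.searchsorted(cum, t, side="right") - 1)
    i = min(i, len(poly) - 2)
    frac = (t - cum[i]) / max(cum[i + 1] - cum[i], 1e-12)
    point = poly[i] + frac * (poly[i + 1] - poly[i])
    tangent = poly[i + 1] - poly[i]
    tangent = tangent / max(np.linalg.norm(tangent), 1e-12)
    normal = np.array([-tangent[1], tangent[0]])
    lateral = rng.uniform(-_EDGE_LATERAL_FACTOR, _EDGE_LATERAL_FACTOR) * r
    return point + lateral * normal


def _tube_point_tree(graph: GroundTruthGraph) -> cKDTree:
    pts = [n.position_nm for n in graph.nodes]
    for e in graph.edges:
        # resample at 50 nm so distances to the axis are accurate
        seg = np.linalg.norm(np.diff(e.polyline_nm, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        s = np.arange(0.0, cum[-1], 50.0)
        pts.append(np.column_stack([np.interp(s, cum, e.polyline_nm[:, 0]),
                                    np.interp(s, cum, e.polyline_nm[:, 1])]))
    return cKDTree(np.vstack([np.atleast_2d(p) for p in pts]))


def _sample_free(graph: GroundTruthGraph, rng: np.random.Generator,
                 tube_tree: Optional[cKDTree], r: float) -> np.ndarray:
    if graph.field_size_nm is None:
        raise ValueError("graph carries no field size; cannot place free spots")
    w_nm, h_nm = graph.field_size_nm
    pad = 2.0 * (graph.pixel_size_nm or 45.0)
    clearance = _FREE_CLEARANCE_FACTOR * r if tube_tree is not None else 0.0
    for _ in range(5000):
        p = np.array([rng.uniform(pad, w_nm - pad),
                      rng.uniform(pad, h_nm - pad)])
        if tube_tree is None or tube_tree.query(p)[0] >= clearance:
            return p
    raise PlacementError("could not place a free spot away from the network")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_MATRIX_RADIUS_FACTOR = 0.8  # matrix tube lies inside the membrane tube
_HOOK_TUBE_FRACTION = 0.15  # dim rerouted-hook signal along the tube


def render_scene(graph: GroundTruthGraph, spots: list[SpotTruth],
                 imaging: ImagingModel, pixel_size_nm: float | None = None,
                 seed: int = 0) -> SyntheticScene:
    """Rasterize a network + spots into hook/anchor/matrix channels.

    The anchor channel carries the membrane tube (radius r), the matrix
    channel a thinner core (0.8 r), both PSF-blurred.  The hook channel
    carries analytic PSF-shaped puncta plus a dim tube term.  Poisson
    photon noise and Gaussian read noise follow the imaging model.
    """
    px = float(pixel_size_nm or graph.pixel_size_nm or 45.0)
    if graph.field_size_nm is None:
        raise ValueError("graph carries no field size")
    w_nm, h_nm = graph.field_size_nm
    shape = (int(round(h_nm / px)), int(round(w_nm / px)))
    rng = np.random.default_rng(seed)

    for s in spots:
        x, y = s.position_nm
        if not (0 <= x < w_nm and 0 <= y < h_nm):
            raise ValueError("spot position outside the field")

    psf_px = imaging.psf_sigma_nm / px
    if graph.edges:
        center = np.zeros(shape, dtype=bool)
        for e in graph.edges:
            seg = np.linalg.norm(np.diff(e.polyline_nm, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            s_arc = np.arange(0.0, cum[-1] + 0.01, 0.3 * px)
            xs = np.interp(s_arc, cum, e.polyline_nm[:, 0]) / px
            ys = np.interp(s_arc, cum, e.polyline_nm[:, 1]) / px
            rr = np.clip(np.round(ys).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.round(xs).astype(int), 0, shape[1] - 1)
            center[rr, cc] = True
        dist = ndimage.distance_transform_edt(~center)
        r_px = graph.mean_radius_nm() / px
        tube = (dist <= r_px).astype(float)
        matrix_tube = (dist <= _MATRIX_RADIUS_FACTOR * r_px).astype(float)
    else:
        tube = np.zeros(shape)
        matrix_tube = np.zeros(shape)

    anchor = ndimage.gaussian_filter(imaging.tube_amplitude * tube, psf_px)
    matrix = ndimage.gaussian_filter(imaging.tube_amplitude * matrix_tube,
                                     psf_px)
    hook = ndimage.gaussian_filter(
        _HOOK_TUBE_FRACTION * imaging.tube_amplitude * tube, psf_px)
    hook = hook + _render_spots(spots, imaging.spot_amplitude, psf_px, px,
                                shape)

    channels = {}
    for name, img in (("hook", hook), ("anchor", anchor), ("matrix", matrix)):
        img = img + imaging.background
        if imaging.poisson_scale > 0:
            img = rng.poisson(np.clip(img, 0, None)
                              * imaging.poisson_scale) / imaging.poisson_scale
        if imaging.read_noise_sd > 0:
            img = img + rng.normal(0.0, imaging.read_noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, None)

    return SyntheticScene(channels=channels, truth_graph=graph,
                          truth_spots=spots, pixel_size_nm=px)


def _render_spots(spots, amplitude: float, psf_px: float, px: float,
                  shape: tuple[int, int]) -> np.ndarray:
    img = np.zeros(shape)
    half = int(np.ceil(4.0 * psf_px))
    for s in spots:
        x_px, y_px = s.position_nm[0] / px, s.position_nm[1] / px
        r0 = max(int(np.floor(y_px)) - half, 0)
        r1 = min(int(np.ceil(y_px)) + half + 1, shape[0])
        c0 = max(int(np.floor(x_px)) - half, 0)
        c1 = min(int(np.ceil(x_px)) + half + 1, shape[1])
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((xx - x_px) ** 2 + (yy - y_px) ** 2) / (2.0 * psf_px**2))
    return img


# ---------------------------------------------------------------------------
# profiles and contours
# ---------------------------------------------------------------------------


def generate_profile_set(spec: ProfileSpec) -> list[LineProfile]:
    """Triplets of Gaussian channel traces with planted peak offsets.

    Each profile's hook center jitters around 0; every other channel peaks
    at hook center + its planted offset.
    """
    rng = np.random.default_rng(spec.seed)
    n_half = int(np.floor(spec.half_window_nm / spec.sample_spacing_nm))
    grid = np.arange(-n_half, n_half + 1) * spec.sample_spacing_nm
    profiles = []
    for _ in range(spec.n_profiles):
        c0 = rng.normal(0.0, spec.center_jitter_sd_nm) \
            if spec.center_jitter_sd_nm > 0 else 0.0
        traces = {}
        for ch, off in spec.offsets_nm.items():
            mu = c0 + off
            y = spec.baseline + spec.amplitudes[ch] * np.exp(
                -((grid - mu) ** 2) / (2.0 * spec.sigmas_nm[ch] ** 2))
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=grid.shape)
            traces[ch] = y
        profiles.append(LineProfile(distance_nm=grid.copy(),
                                    intensities=traces))
    return profiles


def generate_contour_pairs(spec: ContourSpec) -> list[ContourPair]:
    """Elliptical outer contours with an inner contour offset inward.

    The outer ellipse has mean extent (2a + 2b)/2 equal to the spec's
    diameter; the inner contour sits one intermembrane distance inside,
    along the inward normal.  A distance exceeding the smallest radius of
    curvature (b^2/a) would collapse the inner contour and is an error.
    """
    q = spec.axis_ratio
    d_mean = spec.outer_diameter_mean_nm
    a = q * d_mean / (1.0 + q)
    b = d_mean / (1.0 + q)
    dist = spec.intermembrane_distance_mean_nm
    if dist >= b**2 / a:
        raise ValueError("intermembrane distance exceeds the minimum radius "
                         "of curvature; inner contour would collapse")
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_points, endpoint=False)
    pairs = []
    for _ in range(spec.n_vesicles):
        phi = (spec.orientation if spec.orientation is not None
               else rng.uniform(0.0, np.pi))
        rot = np.array([[np.cos(phi), -np.sin(phi)],
                        [np.sin(phi), np.cos(phi)]])
        outer = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        normal = np.column_stack([b * np.cos(theta), a * np.sin(theta)])
        normal = normal / np.linalg.norm(normal, axis=1, keepdims=True)
        inner = outer - dist * normal
        outer = outer @ rot.T
        inner = inner @ rot.T
        if spec.point_noise_sd_nm > 0:
            outer = outer + rng.normal(0.0, spec.point_noise_sd_nm,
                                       size=outer.shape)
            inner = inner + rng.normal(0.0, spec.point_noise_sd_nm,
                                       size=inner.shape)
        pairs.append(ContourPair(outer=outer, inner=inner))
    return pairs
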