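"""Skeleton-graph geometry of mitochondrial networks.

A segmented mitochondrial network is reduced to a graph whose nodes are
endpoints (tube tips, degree 1) and branchpoints (junctions, degree >= 3)
and whose edges are the tubular segments between them.  Surface areas
follow the tube model: an edge of length ``l`` and radius ``r`` carries
lateral area ``2*pi*r*l``; each endpoint carries a hemispherical cap
``2*pi*r**2``.  Branchpoints lie on edge tubing and carry no area of
their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .detection import SegmentationMask

__all__ = [
    "GraphNode",
    "GraphEdge",
    "SkeletonGraph",
    "AreaFractions",
    "skeleton_graph",
    "surface_areas",
    "assign_spot_locations",
]

ENDPOINT = "endpoint"
BRANCHPOINT = "branchpoint"
EDGE = "edge"
FREE = "free"


@dataclass(frozen=True)
class GraphNode:
    id: int
    position_nm: np.ndarray  # (x, y)
    node_class: str  # "endpoint" | "branchpoint"


@dataclass
class GraphEdge:
    u: int
    v: int
    polyline_nm: np.ndarray  # (N, 2) of (x, y)
    length_nm: float
    radius_nm: float


@dataclass
class SkeletonGraph:
    """Node/edge representation of a tubular network, in nm coordinates."""

    nodes: list[GraphNode]
    edges: list[GraphEdge]
    field_size_nm: tuple[float, float] | None = None
    pixel_size_nm: float | None = None

    def node_positions(self, node_class: str | None = None) -> np.ndarray:
        pts = [n.position_nm for n in self.nodes
               if node_class is None or n.node_class == node_class]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n in self.nodes if n.node_class == ENDPOINT)

    @property
    def n_branchpoints(self) -> int:
        return sum(1 for n in self.nodes if n.node_class == BRANCHPOINT)

    @property
    def total_edge_length_nm(self) -> float:
        return float(sum(e.length_nm for e in self.edges))

    def mean_radius_nm(self) -> float:
        """Length-weighted mean tube radius over all edges."""
        if not self.edges:
            raise ValueError("graph has no edges; no radius information")
        lengths = np.array([e.length_nm for e in self.edges])
        radii = np.array([e.radius_nm for e in self.edges])
        return float(np.average(radii, weights=lengths))

    def validate(self) -> None:
        degree: dict[int, int] = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            degree[e.u] += 1
            degree[e.v] += 1
            if e.length_nm <= 0 or e.radius_nm <= 0:
                raise ValueError("edge lengths and radii must be positive")
            arc = polyline_length(e.polyline_nm)
            if not np.isclose(arc, e.length_nm, rtol=1e-6):
                raise ValueError("edge length inconsistent with its polyline")
        for n in self.nodes:
            if n.node_class == ENDPOINT and degree[n.id] != 1:
                raise ValueError(f"endpoint {n.id} has degree {degree[n.id]}")
            if n.node_class == BRANCHPOINT and degree[n.id] < 3:
                raise ValueError(f"branchpoint {n.id} has degree {degree[n.id]}")


# Ground-truth graphs from the generator share this structure.
GroundTruthGraph = SkeletonGraph


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


@dataclass
class AreaFractions:
    """Tube-model surface areas of the endpoint and edge classes."""

    area_endpoint_nm2: float
    area_edge_nm2: float
    fraction_endpoint: float = field(init=False)
    fraction_edge: float = field(init=False)

    def __post_init__(self) -> None:
        total = self.area_endpoint_nm2 + self.area_edge_nm2
        if total <= 0:
            raise ValueError("total surface area must be positive")
        self.fraction_endpoint = self.area_endpoint_nm2 / total
        self.fraction_edge = self.area_edge_nm2 / total


def surface_areas(graph: SkeletonGraph,
                  fallback_radius_nm: float | None = None) -> AreaFractions:
    """Class surface areas: edges ``2*pi*r_bar*sum(l)``, endpoints ``n*2*pi*r_bar^2``.

    ``r_bar`` is the length-weighted mean radius over all edges (the network's
    average half-width).  ``fallback_radius_nm`` supplies the radius for the
    degenerate edgeless case (isolated caps).
    """
    n_end = graph.n_endpoints
    if not graph.edges and n_end == 0:
        raise ValueError("graph has neither edges nor endpoints")
    if graph.edges:
        r = graph.mean_radius_nm()
        total_l = graph.total_edge_length_nm
    else:
        if fallback_radius_nm is None:
            raise ValueError("edgeless graph needs fallback_radius_nm")
        r, total_l = float(fallback_radius_nm), 0.0
    area_end = n_end * 2.0 * np.pi * r**2
    area_edge = 2.0 * np.pi * r * total_l
    return AreaFractions(area_endpoint_nm2=area_end, area_edge_nm2=area_edge)


# ---------------------------------------------------------------------------
# mask -> skeleton graph
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_graph(mask: SegmentationMask,
                   prune_len_nm: float | None = None) -> SkeletonGraph:
    """Skeletonize a binary organelle mask and trace its node/edge graph.

    Skeleton pixels with one neighbour become endpoints; clusters of pixels
    with three or more neighbours become branchpoints; the chains between
    them become edges carrying their arc length and the mean tube radius
    read from the Euclidean distance transform along the chain (minus half
    a pixel for the raster boundary offset).  Terminal spurs shorter than
    ``prune_len_nm`` (default: the estimated tube radius) are removed.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if not m.any():
        raise ValueError("mask has no foreground")
    px = float(mask.pixel_size_nm)

    skel = skeletonize(m)
    edt = ndimage.distance_transform_edt(m)
    if not skel.any():
        warnings.warn("skeletonization produced no skeleton; degenerate mask")
        return SkeletonGraph(nodes=[], edges=[], pixel_size_nm=px)

    nodes_px, edges_px = _trace_skeleton(skel)

    if prune_len_nm is None:
        # tube radius estimate: median EDT over skeleton, half-pixel corrected
        prune_len_nm = max(float(np.median(edt[skel])) - 0.5, 0.5) * px

    nodes_px, edges_px = _prune_spurs(nodes_px, edges_px, prune_len_nm / px)

    if not edges_px:
        warnings.warn("no edges remain after spur pruning; degenerate graph")

    # smooth chains, estimate radii, correct endpoint retraction, go to nm
    degree: dict[int, int] = {nid: 0 for nid in nodes_px}
    for (u, v, _) in edges_px:
        degree[u] += 1
        degree[v] += 1

    node_pos: dict[int, np.ndarray] = {
        nid: np.asarray(pos_rc, dtype=float) for nid, (pos_rc, _c) in
        nodes_px.items()}
    edges: list[GraphEdge] = []
    for (u, v, chain) in edges_px:
        chain = _smooth_chain(np.asarray(chain, dtype=float))
        rr = np.clip(np.round(chain[:, 0]).astype(int), 0, m.shape[0] - 1)
        cc = np.clip(np.round(chain[:, 1]).astype(int), 0, m.shape[1] - 1)
        radius_px = max(float(np.mean(edt[rr, cc])) - 0.5, 0.5)
        # skeletonization retracts tube tips: push terminal ends out to one
        # radius short of the mask boundary (the cap center)
        if degree[u] == 1:
            chain = _extend_tip(chain[::-1], m, radius_px)[::-1]
            node_pos[u] = chain[0]
        if degree[v] == 1:
            chain = _extend_tip(chain, m, radius_px)
            node_pos[v] = chain[-1]
        poly = np.column_stack([chain[:, 1], chain[:, 0]]) * px
        length = polyline_length(poly)
        if length <= 0:
            continue
        edges.append(GraphEdge(u=u, v=v, polyline_nm=poly,
                               length_nm=length, radius_nm=radius_px * px))

    nodes: list[GraphNode] = []
    for nid, (_pos_rc, cls) in nodes_px.items():
        pos_rc = node_pos[nid]
        xy = np.array([pos_rc[1] * px, pos_rc[0] * px])
        nodes.append(GraphNode(id=nid, position_nm=xy, node_class=cls))
    h, w = m.shape
    return SkeletonGraph(nodes=nodes, edges=edges,
                         field_size_nm=(w * px, h * px), pixel_size_nm=px)


def _extend_tip(chain: np.ndarray, mask: np.ndarray,
                radius_px: float) -> np.ndarray:
    """Extend the terminal end of ``chain`` (its last point) along the local
    tube direction to one radius short of the mask boundary."""
    k = min(len(chain) - 1, 5)
    if k < 1:
        return chain
    d = chain[-1] - chain[-1 - k]
    norm = np.linalg.norm(d)
    if norm <= 0:
        return chain
    d = d / norm
    end = chain[-1]
    t, step, t_max = 0.0, 0.25, 3.0 * radius_px + 2.0
    while t < t_max:
        p = end + (t + step) * d
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) \
                or not mask[r, c]:
            break
        t += step
    shift = t - radius_px
    if shift <= 0:
        return chain
    return np.vstack([chain, end + shift * d])


def _smooth_chain(chain: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of a pixel chain (ends kept fixed).

    Removes the 8-connected staircase, whose raw arc length overestimates
    the underlying curve length by a few percent.
    """
    if len(chain) <= window:
        return chain
    kernel = np.ones(window) / window
    sm = chain.copy()
    for d in range(2):
        sm[:, d] = np.convolve(chain[:, d], kernel, mode="same")
    half = window // 2
    sm[:half] = chain[:half]
    sm[-half:] = chain[-half:]
    return sm


def _trace_skeleton(skel: np.ndarray):
    """Trace a skeleton raster into node pixels and edge chains.

    Returns (nodes, edges): ``nodes`` maps node id -> ((row, col), class),
    ``edges`` is a list of (u, v, chain-of-(row, col)).
    """
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbr_count = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    deg = np.where(skel, nbr_count, 0)

    junction_px = (deg >= 3)
    endpoint_px = (deg == 1)
    isolated_px = skel & (deg == 0)

    # cluster adjacent junction pixels into single branchpoint nodes
    jl, n_j = ndimage.label(junction_px, structure=np.ones((3, 3), dtype=int))
    node_of_pixel: dict[tuple[int, int], int] = {}
    nodes: dict[int, tuple[tuple[float, float], str]] = {}
    next_id = 0
    for j in range(1, n_j + 1):
        pix = np.argwhere(jl == j)
        centroid = tuple(pix.mean(axis=0))
        nodes[next_id] = (centroid, BRANCHPOINT)
        for (r, c) in pix:
            node_of_pixel[(int(r), int(c))] = next_id
        next_id += 1
    for (r, c) in np.argwhere(endpoint_px):
        nodes[next_id] = ((float(r), float(c)), ENDPOINT)
        node_of_pixel[(int(r), int(c))] = next_id
        next_id += 1
    # lone skeleton pixels: treat as degenerate, skip
    if isolated_px.any():
        warnings.warn("isolated skeleton pixels ignored")

    is_node = junction_px | endpoint_px
    visited = np.zeros_like(skel, dtype=bool)
    edges: list[tuple[int, int, list[tuple[int, int]]]] = []

    def neighbors(r: int, c: int):
        for dr, dc in _NEIGHBOR_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel[rr, cc]:
                yield rr, cc

    seen_node_pairs_direct: set[frozenset] = set()
    for (r0, c0) in np.argwhere(is_node):
        r0, c0 = int(r0), int(c0)
        u = node_of_pixel[(r0, c0)]
        for (r1, c1) in neighbors(r0, c0):
            if is_node[r1, c1]:
                v = node_of_pixel[(r1, c1)]
                if v != u:
                    key = frozenset(((r0, c0), (r1, c1)))
                    if key not in seen_node_pairs_direct:
                        seen_node_pairs_direct.add(key)
                        edges.append((u, v, [(r0, c0), (r1, c1)]))
                continue
            if visited[r1, c1]:
                continue
            # walk the degree-2 chain until the next node pixel
            chain = [(r0, c0), (r1, c1)]
            visited[r1, c1] = True
            prev, cur = (r0, c0), (r1, c1)
            while True:
                nxt = [(rr, cc) for (rr, cc) in neighbors(*cur)
                       if (rr, cc) != prev
                       and not (is_node[rr, cc] and (rr, cc) in
                                node_of_pixel and
                                node_of_pixel[(rr, cc)] == u and len(chain) == 2)]
                # prefer an unvisited chain pixel; else a node pixel
                node_next = [p for p in nxt if is_node[p]]
                chain_next = [p for p in nxt if not is_node[p] and not visited[p]]
                if node_next:
                    end = node_next[0]
                    chain.append(end)
                    edges.append((u, node_of_pixel[end], chain))
                    break
                if not chain_next:
                    # dead end without a node pixel (can happen on 8-conn
                    # artifacts); drop the fragment
                    break
                prev, cur = cur, chain_next[0]
                visited[cur] = True
                chain.append(cur)

    # cycle components with no node pixels are ignored (tree networks only)
    return nodes, edges


def _prune_spurs(nodes, edges, prune_len_px: float, max_rounds: int = 10):
    """Remove terminal spurs shorter than ``prune_len_px``; merge the
    degree-2 nodes this creates; reclassify node classes from final degrees."""
    for _ in range(max_rounds):
        degree: dict[int, int] = {nid: 0 for nid in nodes}
        for (u, v, _) in edges:
            degree[u] += 1
            degree[v] += 1
        removed = False
        kept = []
        for (u, v, chain) in edges:
            length = _chain_len(chain)
            is_spur = ((degree[u] == 1 or degree[v] == 1)
                       and not (degree[u] == 1 and degree[v] == 1)
                       and length < prune_len_px)
            if is_spur:
                removed = True
            else:
                kept.append((u, v, chain))
        edges = kept
        # merge degree-2 nodes created by pruning
        degree = {nid: 0 for nid in nodes}
        incident: dict[int, list[int]] = {nid: [] for nid in nodes}
        for i, (u, v, _) in enumerate(edges):
            degree[u] += 1
            degree[v] += 1
            incident[u].append(i)
            incident[v].append(i)
        merged = False
        for nid, d in degree.items():
            if d == 2 and nodes[nid][1] == BRANCHPOINT:
                i1, i2 = incident[nid]
                if i1 == i2:
                    continue  # self-loop through the node; leave as is
                e1, e2 = edges[i1], edges[i2]
                new_edge = _merge_edges(e1, e2, nid)
                if new_edge is None:
                    continue
                edges = [e for k, e in enumerate(edges) if k not in (i1, i2)]
                edges.append(new_edge)
                merged = True
                break  # indices stale; restart round
        if not removed and not merged:
            break

    degree = {nid: 0 for nid in nodes}
    for (u, v, _) in edges:
        degree[u] += 1
        degree[v] += 1
    out_nodes = {}
    for nid, (pos, _cls) in nodes.items():
        d = degree.get(nid, 0)
        if d == 0:
            continue
        out_nodes[nid] = (pos, ENDPOINT if d == 1 else BRANCHPOINT)
    # drop edges touching nodes that vanished (shouldn't happen, guard)
    edges = [e for e in edges if e[0] in out_nodes and e[1] in out_nodes]
    return out_nodes, edges


def _chain_len(chain) -> float:
    arr = np.asarray(chain, dtype=float)
    if len(arr) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))


def _merge_edges(e1, e2, nid):
    u1, v1, c1 = e1
    u2, v2, c2 = e2
    c1 = list(c1)
    c2 = list(c2)
    if u1 == nid:
        c1 = c1[::-1]
        far1 = v1
    elif v1 == nid:
        far1 = u1
    else:
        return None
    if u2 == nid:
        far2 = v2
    elif v2 == nid:
        c2 = c2[::-1]
        far2 = u2
    else:
        return None
    return (far1, far2, c1 + c2[1:])


# ---------------------------------------------------------------------------
# location assignment
# ---------------------------------------------------------------------------

def _spot_positions_nm(spots) -> np.ndarray:
    """Accept an (N, 2) array of nm positions, or objects with
    ``centroid_nm`` (SpotRecord) or ``position_nm`` (SpotTruth)."""
    if isinstance(spots, np.ndarray):
        return spots.reshape(-1, 2).astype(float)
    pts = []
    for s in spots:
        if hasattr(s, "centroid_nm"):
            pts.append(np.asarray(s.centroid_nm, dtype=float))
        elif hasattr(s, "position_nm"):
            pts.append(np.asarray(s.position_nm, dtype=float))
        else:
            pts.append(np.asarray(s, dtype=float))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def assign_spot_locations(spots, graph: SkeletonGraph, mask: SegmentationMask,
                          assignment_radius_factor: float = 1.0,
                          mask_dilation_nm: float = 135.0):
    """Label each spot endpoint / branchpoint / edge / free.

    A spot whose position lies farther than ``mask_dilation_nm`` outside the
    organelle mask is free.  Otherwise, if it lies within
    ``assignment_radius_factor`` tube radii of an endpoint or branchpoint
    node it takes that node's class (the nearer node; an exact tie goes to
    endpoint); otherwise it is on an edge.

    Returns ``(LocationCounts, labels)``.
    """
    from .stats import LocationCounts  # local import avoids a cycle

    pos = _spot_positions_nm(spots)
    px = float(mask.pixel_size_nm)
    m = np.asarray(mask.mask, dtype=bool)
    # distance (in px) from any pixel to the mask
    dist_out = ndimage.distance_transform_edt(~m)

    on_mask = np.zeros(len(pos), dtype=bool)
    for i, (x, y) in enumerate(pos):
        r = int(np.clip(round(y / px), 0, m.shape[0] - 1))
        c = int(np.clip(round(x / px), 0, m.shape[1] - 1))
        on_mask[i] = dist_out[r, c] * px <= mask_dilation_nm

    if on_mask.any() and not graph.nodes and not graph.edges:
        raise ValueError("spots fall on the mask but the graph is empty")

    r_tube = graph.mean_radius_nm() if graph.edges else float(mask_dilation_nm)
    cap = assignment_radius_factor * r_tube
    ends = graph.node_positions(ENDPOINT)
    branches = graph.node_positions(BRANCHPOINT)

    labels: list[str] = []
    for i, p in enumerate(pos):
        if not on_mask[i]:
            labels.append(FREE)
            continue
        d_end = np.min(np.linalg.norm(ends - p, axis=1)) if len(ends) else np.inf
        d_br = (np.min(np.linalg.norm(branches - p, axis=1))
                if len(branches) else np.inf)
        if d_end <= cap and d_end <= d_br:
            labels.append(ENDPOINT)  # tie at d_end == d_br goes to endpoint
        elif d_br <= cap:
            labels.append(BRANCHPOINT)
        else:
            labels.append(EDGE)

    counts = LocationCounts(
        n_endpoint=labels.count(ENDPOINT),
        n_branchpoint=labels.count(BRANCHPOINT),
        n_edge=labels.count(EDGE),
        n_free=labels.count(FREE),
    )
    return counts, labels
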