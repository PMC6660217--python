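"""Tree morphologies: SWC I/O, annotation, simplification, surgery, statistics.

A :class:`Morphology` is a rooted tree of nodes with 3-D positions (um),
radii (um) and an anatomical region label per node (``soma``, ``AL``, ``LH``,
``contralateral`` or ``other``).  All geometric quantities used by the cable
model -- branch lengths, membrane areas, axial resistances -- derive from it.

SWC dialect
-----------
Standard 7 whitespace-separated columns ``id type x y z radius parent``;
column 6 is the *radius* in um (not the diameter); ids are positive integers;
the root has parent ``-1``; comment lines start with ``#``.  Regions are
encoded in the structure-type column using the mapping

====================  =====
region                label
====================  =====
soma                  1
AL                    2
LH                    3
contralateral         4
other                 5
====================  =====

and may alternatively be supplied via a two-column sidecar file
(``node_id region_name``), which takes precedence over the structure label.

Edge lengths default to the Euclidean distance between endpoint positions.
:func:`simplify` resamples interior nodes along arc length and records the
exact arc length of each new edge as a per-node override, so total path
length is preserved exactly even on bent branches; :func:`write_swc` emits
only positions, hence round-trips are lossless for geometry-backed
morphologies but drop arc-length overrides of simplified ones.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGIONS",
    "MorphNode",
    "Morphology",
    "SectionStats",
    "read_swc",
    "write_swc",
    "radius_from_measures",
    "simplify",
    "section_stats",
    "capacitance_from_area",
    "conductance_from_area",
    "sever",
    "label_regions",
]

REGIONS = ("soma", "AL", "LH", "contralateral", "other")

REGION_TO_LABEL = {"soma": 1, "AL": 2, "LH": 3, "contralateral": 4, "other": 5}
LABEL_TO_REGION = {v: k for k, v in REGION_TO_LABEL.items()}


class SWCError(ValueError):
    """Malformed SWC content (bad field count, orphan parent, cycle...)."""


@dataclass
class MorphNode:
    """One point of the reconstruction.

    Attributes
    ----------
    id : int
        Positive, unique within the morphology.
    parent_id : int
        Id of the parent node, ``-1`` for the root.
    position : ndarray shape (3,)
        x, y, z in um.
    radius : float
        Neurite radius in um, strictly positive.
    structure_label : int
        SWC structure-type column.
    region : str
        One of :data:`REGIONS`.
    """

    id: int
    parent_id: int
    position: np.ndarray
    radius: float
    structure_label: int = 5
    region: str = "other"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")
        if not self.radius > 0:
            raise ValueError(f"node {self.id}: radius must be > 0, got {self.radius}")
        if self.region not in REGIONS:
            raise ValueError(f"node {self.id}: unknown region {self.region!r}")


class Morphology:
    """Rooted tree of :class:`MorphNode` in topological order.

    Parameters
    ----------
    nodes : sequence of MorphNode
        Parent must precede child; exactly one root (``parent_id == -1``).
    edge_lengths : dict, optional
        Per-child-id arc-length override (um) for the incoming edge.  Used by
        :func:`simplify` to keep path lengths exact after resampling.
    """

    def __init__(self, nodes, edge_lengths: dict[int, float] | None = None):
        self.nodes: list[MorphNode] = list(nodes)
        self.edge_lengths: dict[int, float] = dict(edge_lengths or {})
        self._index: dict[int, int] = {}
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()
        roots = 0
        for i, node in enumerate(self.nodes):
            if node.id in seen:
                raise SWCError(f"duplicate node id {node.id}")
            if node.id <= 0:
                raise SWCError(f"node ids must be positive, got {node.id}")
            if node.parent_id == -1:
                roots += 1
            elif node.parent_id not in seen:
                raise SWCError(
                    f"node {node.id} references parent {node.parent_id} "
                    "which does not precede it (orphan or cycle)"
                )
            seen.add(node.id)
            self._index[node.id] = i
        if self.nodes and roots != 1:
            raise SWCError(f"expected exactly one root, found {roots}")
        for child_id in self.edge_lengths:
            if child_id not in seen:
                raise SWCError(f"edge-length override for unknown node {child_id}")

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> MorphNode:
        return self.nodes[self._index[node_id]]

    @property
    def root(self) -> MorphNode:
        if not self.nodes:
            raise ValueError("empty morphology has no root")
        return self.nodes[0]

    def children(self) -> dict[int, list[int]]:
        """Map node id -> list of child ids (topological order)."""
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                out[n.parent_id].append(n.id)
        return out

    def edges(self):
        """Yield (parent_id, child_id) for every edge, topological order."""
        for n in self.nodes:
            if n.parent_id != -1:
                yield (n.parent_id, n.id)

    def edge_length(self, child_id: int) -> float:
        """Arc length (um) of the edge ending at ``child_id``."""
        if child_id in self.edge_lengths:
            return self.edge_lengths[child_id]
        child = self.node(child_id)
        parent = self.node(child.parent_id)
        return float(np.linalg.norm(child.position - parent.position))

    def total_length(self) -> float:
        return sum(self.edge_length(c) for _, c in self.edges())

    def region_nodes(self, region: str) -> list[int]:
        return [n.id for n in self.nodes if n.region == region]

    def copy(self) -> "Morphology":
        return Morphology(
            [replace(n, position=n.position.copy()) for n in self.nodes],
            dict(self.edge_lengths),
        )

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.node(path[-1]).parent_id != -1:
            path.append(self.node(path[-1]).parent_id)
        return path


# -- I/O -------------------------------------------------------------------


def read_swc(source, region_sidecar=None) -> Morphology:
    """Parse SWC text into a :class:`Morphology`.

    Parameters
    ----------
    source : str or path or file-like
        SWC text itself (if it contains a newline), a path, or a stream.
    region_sidecar : str or path or file-like, optional
        Two-column text (node id, region name) overriding the structure-label
        region mapping.

    Raises
    ------
    SWCError
        On malformed lines, orphan parent references or multiple roots.

    Notes
    -----
    Zero-length edges (coincident parent/child positions) are collapsed onto
    the parent with a warning; the child's children are re-attached to the
    parent.  This mirrors contracting a multi-point soma to one node.
    """
    text = _as_text(source)
    raw: list[tuple[int, int, np.ndarray, float, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 7:
            raise SWCError(f"line {lineno}: expected 7 fields, got {len(fields)}")
        try:
            nid = int(fields[0])
            label = int(fields[1])
            pos = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
            radius = float(fields[5])
            parent = int(fields[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from exc
        raw.append((nid, parent, pos, radius, label))

    ids = {r[0] for r in raw}
    for nid, parent, *_ in raw:
        if parent != -1 and parent not in ids:
            raise SWCError(f"node {nid} references missing parent {parent}")

    raw = _topological_sort(raw)

    # collapse zero-length edges onto the parent
    remap: dict[int, int] = {}
    kept: list[tuple[int, int, np.ndarray, float, int]] = []
    positions: dict[int, np.ndarray] = {}
    n_collapsed = 0
    for nid, parent, pos, radius, label in raw:
        parent = remap.get(parent, parent)
        if parent != -1 and np.linalg.norm(pos - positions[parent]) == 0.0:
            remap[nid] = parent
            n_collapsed += 1
            continue
        positions[nid] = pos
        kept.append((nid, parent, pos, radius, label))
    if n_collapsed:
        warnings.warn(f"collapsed {n_collapsed} zero-length edge(s) on read")

    regions = _read_sidecar(region_sidecar) if region_sidecar is not None else {}
    nodes = [
        MorphNode(
            id=nid,
            parent_id=parent,
            position=pos,
            radius=radius,
            structure_label=label,
            region=regions.get(nid, LABEL_TO_REGION.get(label, "other")),
        )
        for nid, parent, pos, radius, label in kept
    ]
    return Morphology(nodes)


def write_swc(morphology: Morphology) -> str:
    """Serialize to canonical SWC text (topological node order).

    The region of each node is encoded in the structure-type column via the
    module-level mapping; arc-length overrides of simplified morphologies are
    not representable and are dropped.
    """
    lines = ["# id type x y z radius parent"]
    for n in morphology.nodes:
        x, y, z = n.position
        lines.append(
            f"{n.id} {REGION_TO_LABEL[n.region]} {x:.6f} {y:.6f} {z:.6f} "
            f"{n.radius:.6f} {n.parent_id}"
        )
    return "\n".join(lines) + "\n"


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" in s:
        return s
    with io.open(s, "r") as fh:
        return fh.read()


def _read_sidecar(source) -> dict[int, str]:
    text = _as_text(source)
    out: dict[int, str] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        nid, region = stripped.split()
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r} in sidecar")
        out[int(nid)] = region
    return out


def _topological_sort(raw):
    by_id = {r[0]: r for r in raw}
    children: dict[int, list[int]] = {r[0]: [] for r in raw}
    roots = []
    for nid, parent, *_ in raw:
        if parent == -1:
            roots.append(nid)
        else:
            children[parent].append(nid)
    if len(roots) != 1 and raw:
        raise SWCError(f"expected exactly one root, found {len(roots)}")
    order, stack, visited = [], list(roots), set()
    while stack:
        nid = stack.pop()
        if nid in visited:
            raise SWCError(f"cycle detected at node {nid}")
        visited.add(nid)
        order.append(by_id[nid])
        stack.extend(reversed(children[nid]))
    if len(order) != len(raw):
        missing = sorted(set(by_id) - visited)
        raise SWCError(f"cycle detected: nodes {missing} unreachable from root")
    return order


# -- measurement aggregation ----------------------------------------------


def radius_from_measures(measures) -> float:
    """Aggregate repeated radius measurements (um) from consecutive sections.

    The estimator is the arithmetic mean.  Raises ``ValueError`` on an empty
    list or non-positive measures.
    """
    arr = np.asarray(list(measures), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one radius measure is required")
    if np.any(arr <= 0):
        raise ValueError("radius measures must be positive")
    return float(arr.mean())


# -- simplification --------------------------------------------------------


def simplify(morphology: Morphology, max_segment_length: float) -> Morphology:
    """Resample interior nodes so no inter-node arc exceeds ``max_segment_length``.

    Branch points, the root and terminal tips are preserved exactly.  Each
    unbranched run is resampled at equal arc-length spacing ``L/n`` with
    ``n = ceil(L / max_segment_length)``; new node positions are interpolated
    on the original polyline, radii linearly in arc length, and the exact arc
    length ``L/n`` is recorded as an edge-length override.  Total path length
    is therefore preserved exactly; membrane area is preserved to within 1%
    (trapezoidal resampling of a linearly tapering diameter).  Runs already
    at or below the target spacing are left untouched, so coarsening never
    increases the node count (refining below the original spacing does) and
    the operation is idempotent at fixed spacing.
    """
    if not max_segment_length > 0:
        raise ValueError("max_segment_length must be positive")
    if len(morphology) == 0:
        return Morphology([])

    children = morphology.children()
    keep = {
        n.id
        for n in morphology.nodes
        if n.parent_id == -1 or len(children[n.id]) != 1
    }

    new_nodes: list[MorphNode] = []
    overrides: dict[int, float] = {}
    next_id = max(n.id for n in morphology.nodes) + 1

    root = morphology.root
    new_nodes.append(replace(root, position=root.position.copy()))

    # walk each unbranched run from a kept node to the next kept node
    stack = [root.id]
    while stack:
        start = stack.pop()
        for child in reversed(children[start]):
            run = [start, child]
            while run[-1] not in keep:
                run.append(children[run[-1]][0])
            end = run[-1]
            stack.append(end)

            seg_len = [morphology.edge_length(c) for c in run[1:]]
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            L = cum[-1]
            n_seg = max(1, math.ceil(L / max_segment_length - 1e-12))
            if n_seg == 1 and len(seg_len) > 1:
                # collapsing to one edge loses area unless the taper is
                # linear; keep one interior node whenever it is not
                orig_area = sum(
                    edge_geometry(morphology, c)[0]
                    * edge_geometry(morphology, c)[1]
                    for c in run[1:]
                )
                r0 = morphology.node(run[0]).radius
                rn = morphology.node(end).radius
                if abs((r0 + rn) * L - orig_area) > 1e-9 * max(orig_area, 1e-12):
                    n_seg = 2
            if n_seg >= len(seg_len) and max(seg_len) <= max_segment_length + 1e-12:
                # already fine enough: keep the run as-is
                for c in run[1:]:
                    node = morphology.node(c)
                    new_nodes.append(replace(node, position=node.position.copy()))
                    if c in morphology.edge_lengths:
                        overrides[c] = morphology.edge_lengths[c]
                continue

            resampled: list[MorphNode] = []
            prev_id = start
            for k in range(1, n_seg + 1):
                s = L * k / n_seg
                if k == n_seg:
                    node = morphology.node(end)
                    nid = end
                    pos, radius = node.position.copy(), node.radius
                    label, region = node.structure_label, node.region
                else:
                    nid = next_id
                    next_id += 1
                    pos, radius, label, region = _interp_on_run(morphology, run, cum, s)
                resampled.append(
                    MorphNode(
                        id=nid,
                        parent_id=prev_id,
                        position=pos,
                        radius=radius,
                        structure_label=label,
                        region=region,
                    )
                )
                overrides[nid] = L / n_seg
                prev_id = nid
            _rescale_run_area(morphology, run, resampled, L / n_seg)
            new_nodes.extend(resampled)

    return Morphology(new_nodes, overrides)


def _rescale_run_area(morphology, run, resampled, h):
    """Scale the interior radii of a resampled run to preserve its area.

    The run's membrane area is linear in the interior radii (trapezoid of
    the diameter over uniform spacing ``h``), so a single scale factor
    restores the original edge-sum area exactly whenever interior nodes
    exist; endpoints (branch points / tips) are never altered.
    """
    if len(resampled) < 2:
        return
    orig_area = 0.0
    for c in run[1:]:
        length, dbar = edge_geometry(morphology, c)
        orig_area += math.pi * dbar * length
    r_start = morphology.node(run[0]).radius
    r_end = resampled[-1].radius
    interior_sum = sum(n.radius for n in resampled[:-1])
    target = orig_area / (2.0 * math.pi * h) - (r_start + r_end) / 2.0
    if interior_sum <= 0 or target <= 0:
        return
    gamma = target / interior_sum
    if 0.2 < gamma < 5.0:
        for n in resampled[:-1]:
            n.radius *= gamma


def _interp_on_run(morphology, run, cum, s):
    """Point at arc length ``s`` along the polyline through ``run``."""
    j = int(np.searchsorted(cum, s, side="right") - 1)
    j = min(j, len(run) - 2)
    a, b = morphology.node(run[j]), morphology.node(run[j + 1])
    span = cum[j + 1] - cum[j]
    t = 0.0 if span == 0 else (s - cum[j]) / span
    pos = a.position + t * (b.position - a.position)
    radius = a.radius + t * (b.radius - a.radius)
    return pos, radius, b.structure_label, b.region


# -- section statistics ----------------------------------------------------


@dataclass
class SectionStats:
    """Per-region morphometry and passive totals (cf. whole-cell tables).

    L um; Diam um (length-weighted); Area um^2; Ri MOhm (axial resistance
    from the region's origin to the length-midpoint of its longest path);
    Cm_total pF; gpas_total nS.
    """

    region: str
    L: float
    Diam: float
    Area: float
    Ri: float
    Cm_total: float
    gpas_total: float


def capacitance_from_area(area_um2: float, specific_cm: float) -> float:
    """Total membrane capacitance in pF from area (um^2) and c_m (uF/cm^2)."""
    # 1 uF/cm^2 == 1e-2 pF/um^2
    return area_um2 * specific_cm * 1e-2


def conductance_from_area(area_um2: float, specific_gpas: float) -> float:
    """Total leak conductance in nS from area (um^2) and g_pas (S/cm^2)."""
    # 1 S/cm^2 == 10 nS/um^2
    return area_um2 * specific_gpas * 10.0


def edge_geometry(morphology: Morphology, child_id: int):
    """(length um, mean endpoint diameter um) of the edge ending at child."""
    child = morphology.node(child_id)
    parent = morphology.node(child.parent_id)
    length = morphology.edge_length(child_id)
    dbar = child.radius + parent.radius  # mean of the two diameters
    return length, dbar


def axial_resistance_mohm(length_um, diam_um, Ra_ohm_cm) -> float:
    """Axial resistance (MOhm) of a cylinder: 4*Ra*l / (pi*d^2)."""
    # Ohm*cm * um / um^2 = Ohm*cm/um = 1e4 Ohm = 1e-2 MOhm
    return 4.0 * Ra_ohm_cm * length_um / (math.pi * diam_um**2) * 1e-2


def section_stats(
    morphology: Morphology,
    region: str,
    specific_cm: float = 1.0,
    specific_gpas: float = 2.64e-4,
    axial_resistivity: float = 150.0,
) -> SectionStats:
    """Morphometric and passive totals for one region.

    Every edge is attributed to the region of its *child* node.  Edge
    membrane area uses a cylinder with the mean of the endpoint diameters
    (additive across any partition of the region's edges).  ``Ri`` is the
    summed axial resistance along the path from the region's origin (the
    first node, in root-first order, belonging to the region) to the
    length-midpoint of the longest within-region path from that origin.

    Parameters are the specific membrane capacitance (uF/cm^2), specific
    leak conductance (S/cm^2) and axial resistivity (Ohm*cm).

    An empty region yields zeroed stats with a warning.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if len(morphology) == 0 or not morphology.region_nodes(region):
        warnings.warn(f"region {region!r} is empty; returning zeroed stats")
        return SectionStats(region, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    edges = [
        (p, c) for p, c in morphology.edges() if morphology.node(c).region == region
    ]

    L = 0.0
    area = 0.0
    dl = 0.0
    for _, c in edges:
        length, dbar = edge_geometry(morphology, c)
        L += length
        dl += dbar * length
        area += math.pi * dbar * length
    diam = dl / L if L > 0 else 0.0

    ri = _region_ri(morphology, region, edges, axial_resistivity)

    return SectionStats(
        region=region,
        L=L,
        Diam=diam,
        Area=area,
        Ri=ri,
        Cm_total=capacitance_from_area(area, specific_cm),
        gpas_total=conductance_from_area(area, specific_gpas),
    )


def _region_ri(morphology, region, edges, Ra) -> float:
    """Axial resistance origin -> length-midpoint of the longest region path."""
    if not edges:
        return 0.0
    origin = next(n.id for n in morphology.nodes if n.region == region)
    in_region = {c for _, c in edges}
    children = morphology.children()
    # farthest region node from origin, walking only region edges
    dist = {origin: 0.0}
    stack = [origin]
    far, far_d = origin, 0.0
    while stack:
        nid = stack.pop()
        for c in children[nid]:
            if c in in_region:
                length, _ = edge_geometry(morphology, c)
                dist[c] = dist[nid] + length
                if dist[c] > far_d:
                    far, far_d = c, dist[c]
                stack.append(c)
    if far_d == 0.0:
        return 0.0
    # path origin -> far
    path = []
    nid = far
    while nid != origin:
        path.append(nid)
        nid = morphology.node(nid).parent_id
    path.reverse()
    target = far_d / 2.0
    ri, walked = 0.0, 0.0
    for c in path:
        length, dbar = edge_geometry(morphology, c)
        if walked + length >= target:
            frac = (target - walked) / length
            ri += axial_resistance_mohm(length * frac, dbar, Ra)
            break
        ri += axial_resistance_mohm(length, dbar, Ra)
        walked += length
    return ri


# -- surgery ---------------------------------------------------------------


def sever(morphology: Morphology, edge: tuple[int, int]):
    """Cut one edge, returning ``(proximal, distal)`` morphologies.

    The distal tree is re-rooted at the child node of the cut edge.  Node
    ids, regions and edge-length overrides are preserved; no node is lost or
    duplicated.
    """
    parent_id, child_id = edge
    if child_id not in morphology._index:
        raise ValueError(f"no node {child_id}")
    child = morphology.node(child_id)
    if child.parent_id == -1:
        raise ValueError("the root has no incoming edge to sever")
    if child.parent_id != parent_id:
        raise ValueError(f"no edge ({parent_id}, {child_id}) in morphology")

    distal_ids = {child_id}
    children = morphology.children()
    stack = [child_id]
    while stack:
        for c in children[stack.pop()]:
            distal_ids.add(c)
            stack.append(c)

    proximal_nodes, distal_nodes = [], []
    for n in morphology.nodes:
        copy = replace(n, position=n.position.copy())
        if n.id in distal_ids:
            if n.id == child_id:
                copy.parent_id = -1
            distal_nodes.append(copy)
        else:
            proximal_nodes.append(copy)
    prox_ov = {
        k: v
        for k, v in morphology.edge_lengths.items()
        if k not in distal_ids
    }
    dist_ov = {
        k: v
        for k, v in morphology.edge_lengths.items()
        if k in distal_ids and k != child_id
    }
    return Morphology(proximal_nodes, prox_ov), Morphology(distal_nodes, dist_ov)


# -- region labelling ------------------------------------------------------


def label_regions(morphology: Morphology, region_spec: dict) -> Morphology:
    """Assign regions from spatial boxes or explicit node-id sets.

    ``region_spec`` maps a region name to either a set/list of node ids or an
    axis-aligned box ``((xmin, ymin, zmin), (xmax, ymax, zmax))`` (inclusive).
    Every node is assigned exactly one region; nodes matched by no entry
    become ``other``, except the root which defaults to ``soma``.  A node
    matched by more than one entry raises ``ValueError`` listing the
    conflicted ids.
    """
    assignments: dict[int, str] = {}
    conflicts: list[int] = []
    for region, entry in region_spec.items():
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        for n in morphology.nodes:
            if _matches(n, entry):
                if n.id in assignments and assignments[n.id] != region:
                    conflicts.append(n.id)
                else:
                    assignments[n.id] = region
    if conflicts:
        raise ValueError(
            f"overlapping region specs for node ids {sorted(set(conflicts))}"
        )

    new_nodes = []
    for n in morphology.nodes:
        region = assignments.get(n.id)
        if region is None:
            region = "soma" if n.parent_id == -1 else "other"
        new_nodes.append(
            replace(
                n,
                position=n.position.copy(),
                region=region,
                structure_label=REGION_TO_LABEL[region],
            )
        )
    return Morphology(new_nodes, dict(morphology.edge_lengths))


def _matches(node: MorphNode, entry) -> bool:
    if isinstance(entry, (set, frozenset, list, tuple)) and all(
        isinstance(x, (int, np.integer)) for x in entry
    ):
        return node.id in set(entry)
    (lo, hi) = entry
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return bool(np.all(node.position >= lo) and np.all(node.position <= hi))
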