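"""Vascular network domain types, validation, and the TSV network format.

A network is a rooted directed tree: one inlet node feeds a hierarchy of
vessel segments (order 1 = largest feeding artery, order 5 = terminal
arterioles).  Each terminal arteriole drains into a chain of lumped
compartments (capillaries, small venules, large venules), each compartment
being a set of identical parallel vessels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Node",
    "VesselSegment",
    "VascularNetwork",
    "CompartmentChain",
    "NetworkFormatError",
    "NetworkTopologyError",
    "read_network",
    "write_network",
    "validate_network",
    "read_chains",
    "write_chains",
]

#: reference arteriolar diameters by branching order, µm
DEFAULT_ORDER_DIAMETERS = {1: 117.0, 2: 73.0, 3: 44.0, 4: 32.0, 5: 22.0}


class NetworkFormatError(ValueError):
    """Malformed network file."""


class NetworkTopologyError(ValueError):
    """Graph is not a single-inlet rooted tree."""


@dataclass
class Node:
    id: int
    position: np.ndarray  # (3,) µm
    pressure: float | None = None  # mmHg, assigned by the flow solver

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")


@dataclass
class VesselSegment:
    id: int
    from_node: int
    to_node: int
    diameter: float  # µm
    length: float  # µm
    order: int
    is_terminal: bool = False
    flow: float = math.nan  # nl/min, positive from -> to
    hematocrit: float = math.nan  # discharge hematocrit
    viscosity: float = math.nan  # cP
    wall_shear: float = math.nan  # dyn/cm2
    passive_diameter: float = math.nan  # D0, µm
    control_diameter: float = math.nan  # Dc, µm
    control_tension: float = math.nan  # Tc, dyn/cm


@dataclass
class CompartmentChain:
    """Capillary -> small-venule -> large-venule chain fed by one terminal."""

    terminal_id: int
    n_capillaries: int
    capillary_length: float  # µm
    capillary_radius: float = 3.0  # µm (6 µm diameter)
    n_small_venules: int = 1
    small_venule_length: float = 500.0  # µm
    small_venule_radius: float = 10.0  # µm
    n_large_venules: int = 1
    large_venule_length: float = 1500.0  # µm
    large_venule_radius: float = 30.0  # µm
    inflow: float = math.nan  # nl/min
    inflow_pressure: float = math.nan  # mmHg


@dataclass
class VascularNetwork:
    nodes: list[Node]
    segments: list[VesselSegment]
    inlet_node: int
    inlet_pressure: float = 40.0  # mmHg
    outlet_pressure: float = 24.0  # mmHg
    order_diameters: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_DIAMETERS)
    )

    # ---- lookups -------------------------------------------------------
    def node_map(self) -> dict[int, Node]:
        return {n.id: n for n in self.nodes}

    def segment_map(self) -> dict[int, VesselSegment]:
        return {s.id: s for s in self.segments}

    def out_segments(self) -> dict[int, list[VesselSegment]]:
        out: dict[int, list[VesselSegment]] = {n.id: [] for n in self.nodes}
        for s in self.segments:
            out[s.from_node].append(s)
        return out

    def terminal_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.is_terminal]

    def topological_segments(self) -> list[VesselSegment]:
        """Segments ordered root-first (every parent before its children)."""
        out = self.out_segments()
        ordered: list[VesselSegment] = []
        stack = list(reversed(out[self.inlet_node]))
        while stack:
            s = stack.pop()
            ordered.append(s)
            stack.extend(reversed(out[s.to_node]))
        return ordered

    def parent_segment(self) -> dict[int, int | None]:
        """Map segment id -> parent segment id (None for the root segment)."""
        into: dict[int, int] = {}
        for s in self.segments:
            into[s.to_node] = s.id
        return {
            s.id: into.get(s.from_node) for s in self.segments
        }

    def root_to_terminal_paths(self) -> dict[int, list[int]]:
        """Terminal segment id -> list of segment ids from root to terminal."""
        parent = self.parent_segment()
        paths = {}
        for t in self.terminal_segments():
            path = [t.id]
            while parent[path[-1]] is not None:
                path.append(parent[path[-1]])
            paths[t.id] = list(reversed(path))
        return paths

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            nodes=[replace(n, position=n.position.copy()) for n in self.nodes],
            segments=[replace(s) for s in self.segments],
            inlet_node=self.inlet_node,
            inlet_pressure=self.inlet_pressure,
            outlet_pressure=self.outlet_pressure,
            order_diameters=dict(self.order_diameters),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(net: VascularNetwork) -> list[str]:
    """Check all structural invariants; return a list of violations.

    An empty list means the network is valid.  Violations are data, not
    exceptions, so callers can report all problems at once.
    """
    violations: list[str] = []
    node_ids = [n.id for n in net.nodes]
    if len(set(node_ids)) != len(node_ids):
        violations.append("nodes: duplicate ids")
    seg_ids = [s.id for s in net.segments]
    if len(set(seg_ids)) != len(seg_ids):
        violations.append("segments: duplicate ids")
    nm = set(node_ids)
    if net.inlet_node not in nm:
        violations.append(f"inlet node {net.inlet_node} not present")
    for n in net.nodes:
        if not np.all(np.isfinite(n.position)):
            violations.append(f"node {n.id}: non-finite position")
    pos = {n.id: n.position for n in net.nodes}
    for s in net.segments:
        if s.diameter <= 0:
            violations.append(f"segment {s.id}: diameter must be > 0")
        if s.length <= 0:
            violations.append(f"segment {s.id}: length must be > 0")
        if s.order not in (1, 2, 3, 4, 5):
            violations.append(f"segment {s.id}: order {s.order} outside 1-5")
        if not (math.isnan(s.hematocrit) or 0.0 <= s.hematocrit <= 1.0):
            violations.append(f"segment {s.id}: hematocrit outside [0, 1]")
        if s.from_node not in nm or s.to_node not in nm:
            violations.append(f"segment {s.id}: references unknown node")
            continue
        euclid = float(np.linalg.norm(pos[s.to_node] - pos[s.from_node]))
        if s.length < euclid - 1e-6:
            violations.append(
                f"segment {s.id}: stored length {s.length:.3f} µm shorter "
                f"than node distance {euclid:.3f} µm"
            )

    # topology: connected rooted tree with a single inlet and no cycles
    g = nx.DiGraph()
    g.add_nodes_from(node_ids)
    g.add_edges_from((s.from_node, s.to_node) for s in net.segments)
    if not nx.is_directed_acyclic_graph(g):
        violations.append("topology: graph contains a cycle")
    else:
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if roots != [net.inlet_node] and set(roots) != {net.inlet_node}:
            violations.append(
                f"topology: expected single inlet {net.inlet_node}, "
                f"found roots {sorted(roots)}"
            )
        for n in g.nodes:
            if g.in_degree(n) > 1:
                violations.append(f"topology: node {n} has multiple parents")
        und = g.to_undirected()
        if g.number_of_nodes() and not nx.is_connected(und):
            for comp in nx.connected_components(und):
                if net.inlet_node not in comp:
                    violations.append(
                        f"topology: disconnected nodes {sorted(comp)}"
                    )
    if net.segments and len(net.segments) != len(net.nodes) - 1:
        violations.append(
            "topology: segment count must equal node count - 1 in a tree"
        )
    # leaves must be terminal and terminals must be leaves
    has_child = {s.from_node for s in net.segments}
    for s in net.segments:
        is_leaf = s.to_node not in has_child
        if is_leaf and not s.is_terminal:
            violations.append(f"segment {s.id}: leaf segment not marked terminal")
        if s.is_terminal and not is_leaf:
            violations.append(f"segment {s.id}: terminal segment has children")
    return violations


def _require_valid(net: VascularNetwork) -> None:
    violations = validate_network(net)
    if violations:
        topo = [v for v in violations if v.startswith("topology")]
        if topo:
            raise NetworkTopologyError("; ".join(violations))
        raise NetworkFormatError("; ".join(violations))


# ---------------------------------------------------------------------------
# TSV format
# ---------------------------------------------------------------------------

_NODE_COLS = ["id", "x_um", "y_um", "z_um"]
_SEG_COLS = ["id", "from", "to", "order", "diameter_um", "length_um", "terminal"]
_SEG_RESULT_COLS = ["flow_nl_min", "hd", "visc_cP"]


def write_network(net: VascularNetwork, path: str | Path) -> None:
    """Write a network as a two-section UTF-8 TSV file.

    Numeric text uses repr-exact formatting so a read/write round trip is
    bit-identical.  Solved flows/hematocrits/viscosities are written as
    optional result columns when any segment carries them.
    """
    if not net.segments:
        raise NetworkFormatError("refusing to write a network with no segments")
    path = Path(path)
    with_results = any(not math.isnan(s.flow) for s in net.segments)
    lines = []
    lines.append(f"# inlet_node\t{net.inlet_node}")
    lines.append(f"# inlet_pressure_mmHg\t{net.inlet_pressure!r}")
    lines.append(f"# outlet_pressure_mmHg\t{net.outlet_pressure!r}")
    od = ",".join(f"{k}:{v!r}" for k, v in sorted(net.order_diameters.items()))
    lines.append(f"# order_diameters_um\t{od}")
    lines.append("#nodes")
    lines.append("\t".join(_NODE_COLS))
    for n in net.nodes:
        x, y, z = (float(v) for v in n.position)
        lines.append(f"{n.id}\t{x!r}\t{y!r}\t{z!r}")
    lines.append("#segments")
    cols = _SEG_COLS + (_SEG_RESULT_COLS if with_results else [])
    lines.append("\t".join(cols))
    for s in net.segments:
        row = [
            str(s.id), str(s.from_node), str(s.to_node), str(s.order),
            repr(float(s.diameter)), repr(float(s.length)),
            str(int(s.is_terminal)),
        ]
        if with_results:
            row += [repr(float(s.flow)), repr(float(s.hematocrit)),
                    repr(float(s.viscosity))]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_network(path: str | Path) -> VascularNetwork:
    """Read and validate a network from the two-section TSV format."""
    path = Path(path)
    meta: dict[str, str] = {}
    nodes: list[Node] = []
    segments: list[VesselSegment] = []
    section = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line == "#nodes":
            section = "nodes"
            continue
        if line == "#segments":
            section = "segments"
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0].strip()] = parts[1].strip()
            continue
        fields_ = line.split("\t")
        if fields_[0] == "id":  # header row
            continue
        try:
            if section == "nodes":
                nid, x, y, z = fields_[:4]
                nodes.append(Node(int(nid), np.array([float(x), float(y), float(z)])))
            elif section == "segments":
                seg = VesselSegment(
                    id=int(fields_[0]),
                    from_node=int(fields_[1]),
                    to_node=int(fields_[2]),
                    order=int(fields_[3]),
                    diameter=float(fields_[4]),
                    length=float(fields_[5]),
                    is_terminal=bool(int(fields_[6])),
                )
                if len(fields_) >= 10:
                    seg.flow = float(fields_[7])
                    seg.hematocrit = float(fields_[8])
                    seg.viscosity = float(fields_[9])
                segments.append(seg)
            else:
                raise NetworkFormatError(
                    f"{path}:{lineno}: data row before a section marker"
                )
        except (ValueError, IndexError) as exc:
            if isinstance(exc, NetworkFormatError):
                raise
            raise NetworkFormatError(f"{path}:{lineno}: malformed row: {raw!r}") from exc

    order_diameters = dict(DEFAULT_ORDER_DIAMETERS)
    if "order_diameters_um" in meta:
        order_diameters = {
            int(k): float(v)
            for k, v in (p.split(":") for p in meta["order_diameters_um"].split(","))
        }
    net = VascularNetwork(
        nodes=nodes,
        segments=segments,
        inlet_node=int(meta.get("inlet_node", nodes[0].id if nodes else 0)),
        inlet_pressure=float(meta.get("inlet_pressure_mmHg", 40.0)),
        outlet_pressure=float(meta.get("outlet_pressure_mmHg", 24.0)),
        order_diameters=order_diameters,
    )
    _require_valid(net)
    return net


_CHAIN_COLS = [
    "terminal_id", "n_C", "L_C_um", "r_C_um",
    "n_SV", "L_SV_um", "r_SV_um", "n_LV", "L_LV_um", "r_LV_um",
]


def write_chains(chains: Iterable[CompartmentChain], path: str | Path) -> None:
    lines = ["\t".join(_CHAIN_COLS)]
    for c in chains:
        lines.append("\t".join([
            str(c.terminal_id), str(c.n_capillaries),
            repr(float(c.capillary_length)), repr(float(c.capillary_radius)),
            str(c.n_small_venules), repr(float(c.small_venule_length)),
            repr(float(c.small_venule_radius)),
            str(c.n_large_venules), repr(float(c.large_venule_length)),
            repr(float(c.large_venule_radius)),
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_chains(path: str | Path) -> list[CompartmentChain]:
    chains = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("terminal_id"):
            continue
        f = line.split("\t")
        try:
            chains.append(CompartmentChain(
                terminal_id=int(f[0]), n_capillaries=int(f[1]),
                capillary_length=float(f[2]), capillary_radius=float(f[3]),
                n_small_venules=int(f[4]), small_venule_length=float(f[5]),
                small_venule_radius=float(f[6]),
                n_large_venules=int(f[7]), large_venule_length=float(f[8]),
                large_venule_radius=float(f[9]),
            ))
        except (ValueError, IndexError) as exc:
            raise NetworkFormatError(f"{path}:{lineno}: malformed row") from exc
    return chains
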