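"""Seeded generator of heterogeneous arteriolar trees and compartment chains.

The generator emulates the statistical structure of experimentally observed
retinal arteriolar branches: a single feeding artery (order 1, 117 µm)
ramifies through four to five orders of arterioles of fixed per-order
diameter (117/73/44/32/22 µm) but variable per-order length and pathway
depth, ending in terminal arterioles that each feed a chain of capillary and
venular compartments.  Heterogeneity arises from two branching motifs: a
symmetric bifurcation (both children one order deeper) and an asymmetric
side branch (one child one order deeper while the parent continues at its
own order), chosen at random with probability ``asymmetry``.  Terminal
arterioles reached through short, low-resistance pathways carry much more
flow than deep ones, which produces the right-skewed distribution of
capillaries per compartment seen in real branches.

Per-order length statistics of the reference branches were never reported;
the lognormal defaults here are calibration choices documented in the
methods note, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .hemodynamics import single_capillary_flow
from .network import (
    CompartmentChain,
    DEFAULT_ORDER_DIAMETERS,
    Node,
    VascularNetwork,
    validate_network,
)

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "generate_arteriolar_tree",
    "attach_compartments",
    "summarize_capillary_distribution",
    "branch1_like_config",
    "branch2_like_config",
]


class GenerationError(RuntimeError):
    pass


def _default_length_means():
    return {1: 700.0, 2: 550.0, 3: 450.0, 4: 350.0, 5: 300.0}


def _default_length_cvs():
    return {1: 0.3, 2: 0.35, 3: 0.4, 4: 0.4, 5: 0.4}


@dataclass
class GeneratorConfig:
    seed: int
    n_terminals: int = 64
    max_order: int = 5
    order_diameters: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ORDER_DIAMETERS)
    )
    order_length_mean: dict[int, float] = field(default_factory=_default_length_means)
    order_length_cv: dict[int, float] = field(default_factory=_default_length_cvs)
    #: probability that a growth event is an asymmetric side branch
    asymmetry: float = 0.55
    domain_extent: tuple[float, float, float] = (9000.0, 9000.0, 240.0)
    z_jitter: float = 15.0  # µm, quasi-planar embedding
    #: length multiplier for single-terminal side pathways shed directly
    #: off the arcades (orders 1-2); these serve nearby territory
    short_path_scale: float = 0.35
    #: per-chain capillary lengths, lognormal
    capillary_length_mean: float = 400.0  # µm
    capillary_length_cv: float = 0.3
    inlet_pressure: float = 40.0  # mmHg
    outlet_pressure: float = 24.0  # mmHg

    def __post_init__(self):
        if self.n_terminals < 1:
            raise ValueError("n_terminals must be >= 1")
        if self.max_order not in (4, 5):
            raise ValueError("max_order must be 4 or 5")
        diams = [self.order_diameters[o] for o in sorted(self.order_diameters)]
        if any(b >= a for a, b in zip(diams, diams[1:])):
            raise ValueError("order_diameters must be strictly decreasing")
        if not (0.0 <= self.asymmetry <= 1.0):
            raise ValueError("asymmetry must lie in [0, 1]")


_FULL_SCALE_LENGTHS = {1: 1700.0, 2: 1400.0, 3: 1300.0, 4: 1100.0, 5: 850.0}


def branch1_like_config(seed: int) -> GeneratorConfig:
    """Full-scale preset emulating the denser reference branch.

    About 280 terminal pathways with shorter capillaries; downstream
    capillary totals come out near 7e4 with per-compartment medians of a
    few hundred.
    """
    return GeneratorConfig(
        seed=seed, n_terminals=280, asymmetry=0.6,
        order_length_mean=dict(_FULL_SCALE_LENGTHS),
        domain_extent=(40000.0, 40000.0, 240.0),
        capillary_length_mean=400.0,
    )


def branch2_like_config(seed: int) -> GeneratorConfig:
    """Full-scale preset emulating the sparser reference branch.

    Fewer terminal pathways than ``branch1_like_config`` but longer
    capillaries, hence higher extraction per pathway.
    """
    return GeneratorConfig(
        seed=seed, n_terminals=170, asymmetry=0.6,
        order_length_mean=dict(_FULL_SCALE_LENGTHS),
        domain_extent=(40000.0, 40000.0, 240.0),
        capillary_length_mean=500.0,
    )


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def _draw_length(rng, cfg, order):
    """Lognormal length, truncated to [0.2, 5] x mean to keep it embeddable."""
    mean = cfg.order_length_mean[order]
    cv = cfg.order_length_cv[order]
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    for _ in range(100):
        val = rng.lognormal(mu, math.sqrt(sigma2))
        if 0.2 * mean <= val <= 5.0 * mean:
            return val
    return mean


def _min_clearance(builder, start, end, radius, skip_node):
    """Smallest surface-to-surface distance between the candidate segment
    and previously placed segments (µm); segments incident to the start
    node are excluded, as are near-start sample points."""
    if not builder["seg_a"]:
        return math.inf
    a = np.asarray(builder["seg_a"])
    b = np.asarray(builder["seg_b"])
    r = np.asarray(builder["seg_r"])
    touch = np.asarray(builder["seg_from"]) == skip_node
    touch |= np.asarray(builder["seg_to"]) == skip_node
    best = math.inf
    for t in (0.25, 0.5, 0.75, 1.0):
        p = start + (end - start) * t
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        tt = np.clip(np.einsum("ij,ij->i", p - a, ab)
                     / np.maximum(denom, 1e-12), 0.0, 1.0)
        proj = a + tt[:, None] * ab
        d = np.linalg.norm(p - proj, axis=1) - r - radius
        d[touch] = math.inf
        best = min(best, float(d.min()))
    return best


def _place(rng, cfg, start, theta, length, radius, from_node, builder):
    """End position of a straight segment: planar heading with z jitter,
    kept inside the domain box and clear of previously placed vessels
    (bounded retries; the least-overlapping candidate wins otherwise)."""
    ex, ey, ez = cfg.domain_extent
    best = None
    for attempt in range(25):
        jitter = 0.0 if attempt == 0 else rng.normal(0.0, 0.12 + 0.03 * attempt)
        th = theta + jitter
        z = start[2] + rng.normal(0.0, cfg.z_jitter)
        z = min(max(z, -ez / 2), ez / 2)
        dxy = math.sqrt(max(length**2 - (z - start[2]) ** 2, 1e-6))
        end = np.array([start[0] + dxy * math.cos(th),
                        start[1] + dxy * math.sin(th), z])
        in_box = abs(end[0]) <= ex / 2 and abs(end[1]) <= ey / 2
        clearance = _min_clearance(builder, start, end, radius, from_node)
        score = clearance if in_box else clearance - 1e6
        if best is None or score > best[0]:
            best = (score, end, th)
        if in_box and clearance > 4.0:
            return end, th
        builder["overflow"] += 1
    return best[1], best[2]


def generate_arteriolar_tree(cfg: GeneratorConfig) -> VascularNetwork:
    """Grow a rooted arteriolar tree with exactly ``cfg.n_terminals`` leaves.

    The construction is quota-driven: each subtree is asked to deliver a
    fixed number of terminals, so the terminal count is exact while pathway
    depth and per-order chain lengths vary stochastically.  Identical
    configs (including the seed) yield bit-identical networks.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes: list[Node] = []
    segments: list[dict] = []
    builder = {"overflow": 0, "seg_a": [], "seg_b": [], "seg_r": [],
               "seg_from": [], "seg_to": []}

    def new_node(pos):
        nid = len(nodes)
        nodes.append(Node(nid, np.asarray(pos, dtype=float)))
        return nid

    ex = cfg.domain_extent[0]
    root_node = new_node([-ex / 2 * 0.9, 0.0, 0.0])

    def add_segment(from_node, order, theta, quota, length_scale=1.0):
        """Create one segment at ``order`` heading ``theta`` whose subtree
        must contain exactly ``quota`` terminals."""
        length = length_scale * _draw_length(rng, cfg, order)
        start = nodes[from_node].position
        diameter = cfg.order_diameters[order]
        end, th = _place(rng, cfg, start, theta, length, diameter / 2.0,
                         from_node, builder)
        to_node = new_node(end)
        seg = {
            "id": len(segments), "from_node": from_node, "to_node": to_node,
            "order": order, "diameter": diameter,
            "length": float(np.linalg.norm(end - start)),
            "is_terminal": order == cfg.max_order,
        }
        segments.append(seg)
        builder["seg_a"].append(start)
        builder["seg_b"].append(end)
        builder["seg_r"].append(diameter / 2.0)
        builder["seg_from"].append(from_node)
        builder["seg_to"].append(to_node)
        if order == cfg.max_order:
            if quota != 1:
                raise GenerationError("terminal segment asked for quota != 1")
            return
        if quota == 1:
            # single pathway continues straight down the hierarchy
            add_segment(to_node, order + 1, th + rng.normal(0, 0.15), 1,
                        length_scale)
            return
        deepest = order == cfg.max_order - 1  # children would be terminal
        # the feeding artery and first-order arterioles run as arcades that
        # shed side branches; symmetric bifurcations occur deeper in the tree
        p_side = 1.0 if order <= 2 else cfg.asymmetry
        if rng.random() < p_side or (deepest and quota > 2):
            # side branch: child one order deeper, parent order continues
            q_side = 1
            if not deepest and quota > 2:
                # side branches subtend small subtrees; most of the quota
                # continues along the parent pathway.  Arcade-level side
                # branches (orders 1-2) carry larger sub-territories.
                p_quota = 0.3 if order <= 2 else 0.15
                q_side = 1 + int(rng.binomial(quota - 2, p_quota))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            # single-terminal side branches off the arcades feed nearby
            # territory through anatomically short pathways; these carry
            # the high-flow tail of the capillary-count distribution
            side_scale = (cfg.short_path_scale
                          if (order <= 2 and q_side == 1) else length_scale)
            add_segment(to_node, order + 1,
                        th + sign * rng.uniform(0.7, 1.2), q_side, side_scale)
            # arcades curve: the continuation heading drifts
            add_segment(to_node, order,
                        th + rng.normal(0, 0.15) + rng.uniform(-0.25, 0.25),
                        quota - q_side, length_scale)
        else:
            # symmetric bifurcation: both children one order deeper
            q_a = int(rng.binomial(quota, 0.5))
            q_a = min(max(q_a, 1), quota - 1)
            delta = rng.uniform(0.3, 0.6)
            add_segment(to_node, order + 1, th + delta, q_a, length_scale)
            add_segment(to_node, order + 1, th - delta, quota - q_a,
                        length_scale)

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * cfg.n_terminals + 1000))
    try:
        add_segment(root_node, 1, 0.0, cfg.n_terminals)
    finally:
        sys.setrecursionlimit(old_limit)

    if builder["overflow"] > 60 * cfg.n_terminals:
        raise GenerationError(
            "domain_extent too small to embed the requested tree"
        )
    from .network import VesselSegment

    net = VascularNetwork(
        nodes=nodes,
        segments=[VesselSegment(**s) for s in segments],
        inlet_node=root_node,
        inlet_pressure=cfg.inlet_pressure,
        outlet_pressure=cfg.outlet_pressure,
        order_diameters=dict(cfg.order_diameters),
    )
    violations = validate_network(net)
    if violations:
        raise GenerationError("generated network invalid: " + "; ".join(violations))
    return net


# ---------------------------------------------------------------------------
# compartment chains
# ---------------------------------------------------------------------------

def attach_compartments(
    net: VascularNetwork,
    q_capillary: float | None = None,
    cfg: GeneratorConfig | None = None,
    compartment_dims: dict | None = None,
) -> list[CompartmentChain]:
    """Build one compartment chain per terminal arteriole.

    The capillary count of chain i is n_C,i = max(1, round(Q_TA,i / Q_C))
    where Q_TA,i is the solved flow through terminal arteriole i and Q_C the
    reference single-capillary flow.  Capillary lengths are drawn per chain
    (seeded by ``cfg``); venule compartment dimensions are configurable
    defaults, since no reference values exist for them.
    """
    if q_capillary is None:
        q_capillary = single_capillary_flow()
    if q_capillary <= 0:
        raise ValueError("q_capillary must be > 0")
    dims = dict(compartment_dims or {})
    rng = np.random.default_rng(cfg.seed + 7_654_321) if cfg is not None else None
    chains = []
    for t in net.terminal_segments():
        if not math.isfinite(t.flow):
            raise RuntimeError("flows must be solved before attaching compartments")
        n_c = max(1, round(t.flow / q_capillary))
        if rng is not None:
            mean = cfg.capillary_length_mean
            cv = cfg.capillary_length_cv
            sigma2 = math.log(1 + cv * cv)
            l_c = float(np.clip(
                rng.lognormal(math.log(mean) - sigma2 / 2, math.sqrt(sigma2)),
                0.2 * mean, 5 * mean,
            ))
        else:
            l_c = dims.get("capillary_length", 400.0)
        chains.append(CompartmentChain(
            terminal_id=t.id,
            n_capillaries=int(n_c),
            capillary_length=l_c,
            capillary_radius=dims.get("capillary_radius", 3.0),
            n_small_venules=max(1, round(n_c / dims.get("sv_per_capillary_inv", 10.0))),
            small_venule_length=dims.get("small_venule_length", 500.0),
            small_venule_radius=dims.get("small_venule_radius", 10.0),
            n_large_venules=max(1, round(n_c / dims.get("lv_per_capillary_inv", 50.0))),
            large_venule_length=dims.get("large_venule_length", 1500.0),
            large_venule_radius=dims.get("large_venule_radius", 30.0),
            inflow=t.flow,
        ))
    return chains


def summarize_capillary_distribution(chains: list[CompartmentChain],
                                     bin_edges=None) -> dict:
    """Total, median, mean and histogram of capillaries per compartment."""
    if not chains:
        raise ValueError("no chains to summarize")
    counts = np.array([c.n_capillaries for c in chains])
    if bin_edges is None:
        bin_edges = np.arange(0, max(3000, counts.max() + 250), 250)
    hist, edges = np.histogram(counts, bins=bin_edges)
    return {
        "total": int(counts.sum()),
        "median": float(np.median(counts)),
        "mean": float(counts.mean()),
        "max": int(counts.max()),
        "histogram": hist,
        "bin_edges": np.asarray(edges, dtype=float),
    }
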