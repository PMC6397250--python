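"""Synthetic vascular networks with exact ground truth.

Emulates Cldn5-eGFP retinal flatmounts: a bright, interconnected,
curvilinear vessel network radiating from a central point (the
optic-nerve-head analogue), optionally layered into three plexuses at
distinct depths, rasterized with background noise and uneven illumination.

The growth model is deliberately simple — iterative tip advance with a
fixed step, heading jitter from a wrapped normal, stochastic side
branching, and anastomosis by tip capture — because it yields an exact
geometric graph (nodes, polyline edges, radii) whose total length,
junction count and radial extent are known exactly, which is what the
downstream measurement chain is validated against. It makes no attempt at
biophysical realism (no VEGF gradients, no astrocyte template, no
remodeling dynamics).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from vesselmetrics.images import CalibratedImage, ParameterError


@dataclass
class SynthParams:
    """Generator knobs; the seed fully determines the output.

    Units: µm everywhere; ``branch_rate`` is per µm of grown vessel,
    ``noise_sd`` is in 8-bit intensity units.
    """

    field_size: float = 1200.0
    outgrowth_fraction: float = 0.95
    branch_rate: float = 0.02
    branch_dispersion: float = 1.0  # relative sd of inter-branch distance (1 irregular, ~0.2 regular)
    anastomosis_probability: float = 0.7
    capture_radius: float = 2.0
    capture_jitter: float = 0.0  # per-tip fractional sd of the capture radius
    patchiness: float = 0.0  # lognormal sd of a smooth spatial capture-scale field
    min_junction_separation: float = 0.0  # µm; enforce spacing between junction nodes
    vessel_radius_range: tuple[float, float] = (2.5, 4.5)
    n_initial_tips: int = 8
    step_um: float = 10.0
    heading_jitter: float = 0.3  # rad, sd of per-step wrapped-normal heading change
    branch_angle: float = 0.7  # rad, mean deviation of a new branch
    n_layers: int = 1
    layer_z_positions: tuple[float, ...] = (10.0, 30.0, 50.0)
    layer_sigma_z: float = 2.5
    noise_sd: float = 5.0
    illumination_gradient: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.field_size <= 0:
            raise ParameterError("field_size must be positive")
        if not 0.0 <= self.outgrowth_fraction <= 1.0:
            raise ParameterError("outgrowth_fraction must be in [0, 1]")
        if self.branch_rate < 0:
            raise ParameterError("branch_rate must be >= 0")
        if self.branch_dispersion < 0:
            raise ParameterError("branch_dispersion must be >= 0")
        if not 0.0 <= self.anastomosis_probability <= 1.0:
            raise ParameterError("anastomosis_probability must be in [0, 1]")
        if self.capture_radius < 0:
            raise ParameterError("capture_radius must be >= 0")
        if self.capture_jitter < 0:
            raise ParameterError("capture_jitter must be >= 0")
        if self.patchiness < 0:
            raise ParameterError("patchiness must be >= 0")
        if self.min_junction_separation < 0:
            raise ParameterError("min_junction_separation must be >= 0")
        lo, hi = self.vessel_radius_range
        if lo <= 0 or hi < lo:
            raise ParameterError("vessel_radius_range must be 0 < lo <= hi")
        if self.n_initial_tips < 1:
            raise ParameterError("need at least one initial tip")
        if self.step_um <= 0:
            raise ParameterError("step_um must be positive")
        if self.n_layers not in (1, 3):
            raise ParameterError("n_layers must be 1 or 3")
        if self.n_layers == 3:
            zs = self.layer_z_positions
            if len(zs) != 3 or not all(b > a for a, b in zip(zs, zs[1:])):
                raise ParameterError("layer_z_positions must be 3 strictly increasing values")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class Edge:
    """Polyline vessel between two nodes; points include both node positions."""

    a: int
    b: int
    points: np.ndarray  # (n, 2) float µm, columns (x, y)
    radius: float

    def length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


@dataclass
class VesselGraph:
    """Ground-truth geometric graph of a synthetic vascular network."""

    nodes: list[np.ndarray]  # (x, y) µm
    edges: list[Edge]
    center: np.ndarray  # (x, y) µm
    field_size: float

    def total_length(self) -> float:
        """Sum of polyline chord lengths in µm."""
        return sum(e.length() for e in self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.nodes), dtype=int)
        for e in self.edges:
            deg[e.a] += 1
            deg[e.b] += 1
        return deg

    def junction_nodes(self) -> list[int]:
        """Nodes where >= 3 vessels meet."""
        return [i for i, d in enumerate(self.degrees()) if d >= 3]

    def junction_count(self) -> int:
        return len(self.junction_nodes())

    def min_junction_separation(self) -> float:
        """Smallest pairwise distance between junction nodes, µm (inf if < 2)."""
        pos = np.array([self.nodes[i] for i in self.junction_nodes()])
        if len(pos) < 2:
            return math.inf
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for i, p in enumerate(self.nodes):
            g.add_node(i, pos=tuple(p))
        for k, e in enumerate(self.edges):
            g.add_edge(e.a, e.b, key=k, length=e.length(), radius=e.radius)
        return g

    def to_dict(self) -> dict:
        return {
            "nodes": [list(map(float, p)) for p in self.nodes],
            "edges": [
                {
                    "a": e.a,
                    "b": e.b,
                    "points": np.asarray(e.points, dtype=float).tolist(),
                    "radius": float(e.radius),
                }
                for e in self.edges
            ],
            "center": list(map(float, self.center)),
            "field_size": float(self.field_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselGraph":
        return cls(
            nodes=[np.asarray(p, dtype=float) for p in d["nodes"]],
            edges=[
                Edge(e["a"], e["b"], np.asarray(e["points"], dtype=float), e["radius"])
                for e in d["edges"]
            ],
            center=np.asarray(d["center"], dtype=float),
            field_size=float(d["field_size"]),
        )

    def check(self) -> None:
        """Assert the structural invariants."""
        for e in self.edges:
            assert np.allclose(e.points[0], self.nodes[e.a]), "polyline must start at node a"
            assert np.allclose(e.points[-1], self.nodes[e.b]), "polyline must end at node b"
        for p in self.nodes:
            assert np.all(p >= 0) and np.all(p <= self.field_size), "node outside field"
        for e in self.edges:
            pts = np.asarray(e.points)
            assert np.all(pts >= 0) and np.all(pts <= self.field_size), "vessel outside field"
        if self.edges:
            assert self.total_length() > 0


class _Tip:
    """One actively growing vessel tip with its own random stream."""

    __slots__ = (
        "tip_id", "start_node", "start_pos", "pos", "heading", "radius",
        "points", "rng", "capture_scale", "next_branch_dist", "dist_since_branch",
    )

    def __init__(self, tip_id, start_node, pos, heading, radius, seed, capture_jitter=0.0):
        self.tip_id = tip_id
        self.start_node = start_node
        self.start_pos = np.asarray(pos, dtype=float).copy()
        self.pos = np.asarray(pos, dtype=float).copy()
        self.heading = float(heading)
        self.radius = float(radius)
        self.points = [self.pos.copy()]
        # independent stream per tip so a parent's trajectory does not
        # depend on how many children it spawns
        self.rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tip_id,)))
        # heterogeneous stopping distances give an irregular (immature-like)
        # spacing distribution; 0 jitter gives a regular (adult-like) one
        self.capture_scale = max(0.2, 1.0 + self.rng.normal(0.0, capture_jitter))
        self.next_branch_dist = math.inf
        self.dist_since_branch = 0.0


class _SegmentIndex:
    """Exact nearest-vessel queries against all finalized polyline segments.

    Rebuilt lazily from the edge list whenever it changes; queries are a
    single vectorized point-to-segment distance over every segment.
    """

    def __init__(self, edges: list[Edge]):
        self.edges = edges
        self.dirty = True
        self._blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def invalidate(self) -> None:
        """Edge indices changed (a split): rebuild everything on next query."""
        self.dirty = True
        self._cache = None

    @staticmethod
    def _block(e_idx: int, e: Edge):
        pts = np.asarray(e.points)
        ref = np.stack([np.full(len(pts) - 1, e_idx), np.arange(len(pts) - 1)], axis=1)
        return pts[:-1], pts[1:], ref

    def append(self, e_idx: int) -> None:
        """A new edge was finalized; geometry of old edges is unchanged."""
        if self.dirty:
            return
        e = self.edges[e_idx]
        if len(e.points) >= 2:
            self._blocks.append(self._block(e_idx, e))
            self._cache = None

    def _arrays(self):
        if self.dirty:
            self._blocks = [
                self._block(ei, e) for ei, e in enumerate(self.edges) if len(e.points) >= 2
            ]
            self.dirty = False
            self._cache = None
        if self._cache is None:
            if self._blocks:
                self._cache = tuple(
                    np.concatenate([blk[k] for blk in self._blocks]) for k in range(3)
                )
            else:
                empty = np.empty((0, 2))
                self._cache = (empty, empty, np.empty((0, 2), dtype=int))
        return self._cache

    def nearest(self, point: np.ndarray, exclude_near: np.ndarray, exclude_radius: float):
        """Nearest segment to ``point``; segments whose closest approach lies
        within ``exclude_radius`` of ``exclude_near`` are ignored.

        Returns ``(distance, edge_idx, start_vertex_idx, t, foot_point)`` or
        ``None`` when there are no eligible segments.
        """
        a, b, ref = self._arrays()
        if len(a) == 0:
            return None
        v = b - a
        vv = (v**2).sum(axis=1)
        vv[vv == 0] = 1e-12
        t = np.clip(((point - a) * v).sum(axis=1) / vv, 0.0, 1.0)
        foot = a + t[:, None] * v
        d2 = ((foot - point) ** 2).sum(axis=1)
        excl = ((foot - exclude_near) ** 2).sum(axis=1) < exclude_radius**2
        d2[excl] = np.inf
        i = int(np.argmin(d2))
        if not np.isfinite(d2[i]):
            return None
        return (math.sqrt(d2[i]), int(ref[i, 0]), int(ref[i, 1]), float(t[i]), foot[i])


def _grow_network(params: SynthParams, salt: int) -> VesselGraph:
    """One growth attempt; ``salt`` varies the streams between retries.

    Tips advance by ``step_um`` per round with wrapped-normal heading
    jitter; each step branches with probability ``branch_rate * step_um``
    (a side tip deviating by about ``branch_angle``). A tip stepping
    within ``capture_radius`` of an existing vessel either fuses to it
    (probability ``anastomosis_probability``), creating a loop and a
    recorded junction, or terminates as a blind ending — either way tips
    die in crowded territory, which is what keeps the network density
    self-limiting and the raster geometry consistent with the graph
    (vessels never cross without a recorded junction when
    ``capture_radius`` exceeds the vessel width). Growth stops at
    ``outgrowth_fraction`` times the field radius, so no vessel point lies
    farther than that from the center.
    """
    fs = params.field_size
    center = np.array([fs / 2.0, fs / 2.0])
    max_r = params.outgrowth_fraction * fs / 2.0
    seed = (params.seed, salt)

    nodes: list[np.ndarray] = [center.copy()]
    edges: list[Edge] = []
    index = _SegmentIndex(edges)

    # junction bookkeeping for the optional minimum-separation constraint
    junction_positions: list[np.ndarray] = []
    if params.n_initial_tips >= 3:
        junction_positions.append(center.copy())
    junction_id_by_pos: dict[int, int] = {}  # position index -> node id
    if params.n_initial_tips >= 3:
        junction_id_by_pos[0] = 0

    def nearest_junction(pos: np.ndarray) -> tuple[int, float]:
        """(index into junction_positions, distance); (-1, inf) when none."""
        if not junction_positions:
            return -1, math.inf
        arr = np.asarray(junction_positions)
        d = np.sqrt(((arr - pos) ** 2).sum(axis=1))
        i = int(np.argmin(d))
        return i, float(d[i])

    def register_junction(node_id: int) -> None:
        junction_id_by_pos[len(junction_positions)] = node_id
        junction_positions.append(nodes[node_id].copy())

    tip_counter = 0
    tips: list[_Tip] = []

    def draw_branch_dist(tip: _Tip) -> float:
        """Distance a tip grows before its next side branch.

        Mean 1/branch_rate; ``branch_dispersion`` sets the relative spread,
        separating irregular immature-like branching (about 1) from the
        regular spacing of a pruned adult network (about 0.2).
        """
        if params.branch_rate <= 0:
            return math.inf
        base = 1.0 + params.branch_dispersion * tip.rng.normal()
        return max(0.5 * params.step_um, base / params.branch_rate)

    root_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2**31,)))
    radii = root_rng.uniform(*params.vessel_radius_range, size=params.n_initial_tips)
    for i in range(params.n_initial_tips):
        heading = 2.0 * math.pi * i / params.n_initial_tips + root_rng.normal(
            0.0, params.heading_jitter
        )
        tip = _Tip(tip_counter, 0, center, heading, radii[i], seed, params.capture_jitter)
        tip.next_branch_dist = draw_branch_dist(tip)
        tips.append(tip)
        tip_counter += 1

    exclude_radius = 1.5 * params.step_um

    # smooth spatial modulation of the stopping distance: immature networks
    # are patchy, with fine-meshed regions next to large gaps
    if params.patchiness > 0:
        patch_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2**31 + 1,))
        )
        n_grid = 6
        # two-level field: a fixed fraction of sparse cells (wide spacing,
        # isolated crossing vessels) amid dense mesh. Sparse cells are
        # drawn only from cells inside the vascularized disk and outside
        # the uniformly dense center, with their count fixed, so the
        # realized sparse area is the same for every seed; extremes are
        # clipped so no region suppresses growth entirely
        sparse_fraction = 0.45
        hi = min(math.exp(params.patchiness), 5.0)
        lo = max(math.exp(-params.patchiness * sparse_fraction / (1.0 - sparse_fraction)), 0.7)
        cell_xy = (np.arange(n_grid) + 0.5) / n_grid * fs
        gx, gy = np.meshgrid(cell_xy, cell_xy)
        r_cell = np.sqrt((gx - center[0]) ** 2 + (gy - center[1]) ** 2)
        eligible = np.argwhere((r_cell <= max_r) & (r_cell >= 0.35 * max_r))
        patch_rng.shuffle(eligible)
        n_hi = int(round(sparse_fraction * len(eligible)))
        patch_grid = np.full((n_grid, n_grid), lo)
        for iy, ix in eligible[:n_hi]:
            patch_grid[iy, ix] = hi

        def patch_factor(pos: np.ndarray) -> float:
            gx = np.clip(pos[0] / fs * (n_grid - 1), 0, n_grid - 1 - 1e-9)
            gy = np.clip(pos[1] / fs * (n_grid - 1), 0, n_grid - 1 - 1e-9)
            ix, iy = int(gx), int(gy)
            tx, ty = gx - ix, gy - iy
            raw = float(
                patch_grid[iy, ix] * (1 - tx) * (1 - ty)
                + patch_grid[iy, ix + 1] * tx * (1 - ty)
                + patch_grid[iy + 1, ix] * (1 - tx) * ty
                + patch_grid[iy + 1, ix + 1] * tx * ty
            )
            # the central zone vascularizes first and stays uniformly dense;
            # patchiness is a mid-peripheral remodeling feature
            r_frac = float(np.linalg.norm(pos - center)) / max(max_r, 1e-9)
            w = np.clip((r_frac - 0.35) / 0.15, 0.0, 1.0)
            return 1.0 + w * (raw - 1.0)

    else:

        def patch_factor(pos: np.ndarray) -> float:
            return 1.0

    def add_node(pos: np.ndarray) -> int:
        # clamp away float fuzz at the rim so coordinates stay in the field
        nodes.append(np.clip(np.asarray(pos, dtype=float), 0.0, fs))
        return len(nodes) - 1

    def finalize(tip: _Tip, end_node: int) -> None:
        pts = np.asarray(tip.points + [nodes[end_node]], dtype=float)
        # drop a duplicated final vertex (termination exactly on the last point)
        if len(pts) >= 2 and np.allclose(pts[-1], pts[-2]):
            pts = pts[:-1]
        if len(pts) < 2:
            return
        pts[0] = nodes[tip.start_node]
        pts[-1] = nodes[end_node]
        pts = np.clip(pts, 0.0, fs)
        edges.append(Edge(tip.start_node, end_node, pts, tip.radius))
        index.append(len(edges) - 1)

    def split_edge_at(e_idx: int, v_idx: int) -> int:
        """Create a node at an interior vertex of an edge; returns the node id."""
        e = edges[e_idx]
        pts = np.asarray(e.points)
        if v_idx <= 0:
            return e.a
        if v_idx >= len(pts) - 1:
            return e.b
        n_new = add_node(pts[v_idx])
        edges[e_idx] = Edge(e.a, n_new, pts[: v_idx + 1].copy(), e.radius)
        edges.append(Edge(n_new, e.b, pts[v_idx:].copy(), e.radius))
        index.invalidate()
        return n_new

    def fuse_at(e_idx: int, v_idx: int, t: float, foot: np.ndarray) -> int:
        """Create (or reuse) a node at the capture point on a segment.

        Snaps to the edge's own end node when the capture point lies within
        one step of it, so a fusion never creates a sub-step stub edge that
        the raster could not resolve.
        """
        e = edges[e_idx]
        pts = np.asarray(e.points)
        steps = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        arc_foot = cum[v_idx] + t * steps[v_idx]
        if arc_foot <= params.step_um:
            return e.a
        if cum[-1] - arc_foot <= params.step_um:
            return e.b
        if t < 0.25:
            return split_edge_at(e_idx, v_idx)
        if t > 0.75:
            return split_edge_at(e_idx, v_idx + 1)
        edges[e_idx] = Edge(
            e.a, e.b, np.insert(pts, v_idx + 1, foot, axis=0), e.radius
        )
        index.invalidate()
        return split_edge_at(e_idx, v_idx + 1)

    def fuse_with_separation(e_idx: int, v_idx: int, t: float, foot: np.ndarray) -> int:
        """Fuse at a capture point, honoring the junction-separation constraint."""
        sep = params.min_junction_separation
        ji, jd = nearest_junction(foot) if sep > 0 else (-1, math.inf)
        if jd < sep:
            # merge into the nearby junction instead of creating a new one
            # closer than the separation constraint
            return junction_id_by_pos[ji]
        end_node = fuse_at(e_idx, v_idx, t, foot)
        register_junction(end_node)
        return end_node

    # deferred anastomoses onto trails of still-active tips: resolved into
    # connector edges once the target trail has been finalized
    pending_fusions: list[tuple[int, np.ndarray, float]] = []

    max_rounds = int(6 * max(max_r, params.step_um) / params.step_um) + 50
    for _ in range(max_rounds):
        if not tips:
            break
        # trails of active tips, so two concurrently growing vessels cannot
        # cross each other unnoticed (stale by at most one round, which the
        # capture margin covers)
        t_blocks = [
            (np.asarray(t.points)[:-1], np.asarray(t.points)[1:],
             np.full(len(t.points) - 1, t.tip_id))
            for t in tips
            if len(t.points) >= 2
        ]
        if t_blocks:
            trail_a = np.concatenate([b[0] for b in t_blocks])
            trail_b = np.concatenate([b[1] for b in t_blocks])
            trail_owner = np.concatenate([b[2] for b in t_blocks])
        else:
            trail_a = trail_b = np.empty((0, 2))
            trail_owner = np.empty(0, dtype=int)
        # segments laid by tips earlier in this same round
        fresh = np.empty((len(tips), 5))
        fresh_n = 0

        def _seg_nearest(point, start_pos, a, b, owner, own_id):
            v = b - a
            vv = (v**2).sum(axis=1)
            vv[vv == 0] = 1e-12
            t = np.clip(((point - a) * v).sum(axis=1) / vv, 0.0, 1.0)
            foot = a + t[:, None] * v
            d2 = ((foot - point) ** 2).sum(axis=1)
            d2[owner == own_id] = np.inf
            d2[((foot - start_pos) ** 2).sum(axis=1) < exclude_radius**2] = np.inf
            i = int(np.argmin(d2))
            if not np.isfinite(d2[i]):
                return None
            return (math.sqrt(d2[i]), foot[i])

        def trail_nearest(point: np.ndarray, own_id: int, start_pos: np.ndarray):
            best = None
            if len(trail_a):
                best = _seg_nearest(point, start_pos, trail_a, trail_b, trail_owner, own_id)
            if fresh_n:
                f = fresh[:fresh_n]
                cand = _seg_nearest(point, start_pos, f[:, 0:2], f[:, 2:4], f[:, 4], own_id)
                if cand is not None and (best is None or cand[0] < best[0]):
                    best = cand
            return best

        new_tips: list[_Tip] = []
        survivors: list[_Tip] = []
        for tip in tips:
            jitter = tip.rng.normal(0.0, params.heading_jitter)
            tip.heading += jitter
            direction = np.array([math.cos(tip.heading), math.sin(tip.heading)])
            new_pos = tip.pos + params.step_um * direction

            r_new = float(np.linalg.norm(new_pos - center))

            # capture by an existing vessel: fuse (anastomosis) or stall.
            # Checked before the outgrowth boundary so rim-terminating tips
            # fuse with vessels already at the rim instead of piling up
            # against them. Without a separation constraint, no capture in
            # the central zone: radial vessels leaving the optic-nerve-head
            # analogue run close and parallel without fusing. In
            # separation-constrained (consistency-grade) networks every
            # close approach must be resolved, so the zone is disabled.
            in_center_zone = (
                params.min_junction_separation <= 0
                and r_new < 4.0 * params.step_um
            )
            hit = (
                index.nearest(new_pos, tip.start_pos, exclude_radius)
                if params.capture_radius > 0 and not in_center_zone
                else None
            )
            # capped so stacked modulations can never strangle growth outright
            capture_eff = min(
                params.capture_radius * tip.capture_scale * patch_factor(new_pos), 60.0
            )
            t_hit = (
                trail_nearest(new_pos, tip.tip_id, tip.start_pos)
                if params.capture_radius > 0 and not in_center_zone
                else None
            )
            trail_cap = tip.radius + params.vessel_radius_range[1] + 2.0
            trail_hit = t_hit is not None and t_hit[0] <= trail_cap
            if hit is not None and hit[0] <= capture_eff and (
                not trail_hit or hit[0] <= t_hit[0]
            ):
                _, e_idx, v_idx, t, foot = hit
                sep = params.min_junction_separation
                too_close = sep > 0 and nearest_junction(foot)[1] < sep
                if too_close:
                    # fusing here would land within the separation constraint
                    # of an existing junction (a degree-4 pile-up): stall,
                    # retracting one step so the blind end keeps clearance
                    # from the vessel that captured it
                    if len(tip.points) >= 2:
                        tip.points.pop()
                    end_node = add_node(tip.points[-1])
                elif tip.rng.uniform() < params.anastomosis_probability:
                    end_node = fuse_with_separation(e_idx, v_idx, t, foot)
                else:
                    end_node = add_node(tip.pos)
                finalize(tip, end_node)
                continue
            # a still-growing neighbor does not yet perfuse tissue, so it
            # only interacts at contact scale: fuse when strokes would
            # touch (the connection is made once the trail became an edge);
            # without fusion the sprout simply keeps growing
            if trail_hit and tip.rng.uniform() < params.anastomosis_probability:
                end_node = add_node(new_pos)
                pending_fusions.append((end_node, t_hit[1].copy(), tip.radius))
                finalize(tip, end_node)
                continue

            # outgrowth boundary: terminate exactly on the circle
            if r_new > max_r:
                v = new_pos - tip.pos
                a = float(v @ v)
                b = 2.0 * float((tip.pos - center) @ v)
                c = float((tip.pos - center) @ (tip.pos - center)) - max_r**2
                disc = max(b * b - 4 * a * c, 0.0)
                t = (-b + math.sqrt(disc)) / (2 * a) if a > 0 else 0.0
                end_pos = tip.pos + np.clip(t, 0.0, 1.0) * v
                end_node = add_node(end_pos)
                finalize(tip, end_node)
                continue

            fresh[fresh_n] = (*tip.pos, *new_pos, tip.tip_id)
            fresh_n += 1
            tip.pos = new_pos
            tip.points.append(new_pos.copy())
            tip.dist_since_branch += params.step_um

            if tip.dist_since_branch >= tip.next_branch_dist:
                sep = params.min_junction_separation
                if sep > 0 and nearest_junction(new_pos)[1] < sep:
                    # too close to an existing junction: retry a step later
                    tip.next_branch_dist = tip.dist_since_branch + params.step_um
                    survivors.append(tip)
                    continue
                branch_node = add_node(new_pos)
                register_junction(branch_node)
                finalize(tip, branch_node)
                child = _Tip(
                    tip_counter,
                    branch_node,
                    new_pos,
                    0.0,
                    float(tip.rng.uniform(*params.vessel_radius_range)),
                    seed,
                    params.capture_jitter,
                )
                sign = 1.0 if child.rng.uniform() < 0.5 else -1.0
                child.heading = tip.heading + sign * abs(
                    child.rng.normal(params.branch_angle, 0.2)
                )
                child.next_branch_dist = draw_branch_dist(child)
                tip_counter += 1
                new_tips.append(child)
                # parent continues as a fresh edge from the branch node
                tip.start_node = branch_node
                tip.start_pos = new_pos.copy()
                tip.points = [new_pos.copy()]
                tip.dist_since_branch = 0.0
                tip.next_branch_dist = draw_branch_dist(tip)
            survivors.append(tip)
        tips = survivors + new_tips

    # anything still growing at the round cap terminates where it stands
    for tip in tips:
        if len(tip.points) >= 2:
            end_node = add_node(tip.pos)
            finalize(tip, end_node)

    def truncate_edge_to(end_node: int) -> None:
        """Pull the edge ending at ``end_node`` back by one vertex for clearance."""
        refs = sum((e.a == end_node) + (e.b == end_node) for e in edges)
        if refs != 1:
            return  # another vessel already attaches here; leave it alone
        for k in range(len(edges) - 1, -1, -1):
            e = edges[k]
            if e.b == end_node:
                if len(e.points) >= 3:
                    pts = np.asarray(e.points)[:-1].copy()
                    nodes[end_node] = pts[-1].copy()
                    edges[k] = Edge(e.a, end_node, pts, e.radius)
                else:
                    # single-step stub: nothing left after retraction
                    del edges[k]
                index.invalidate()
                return

    # resolve deferred anastomoses now that every trail is an edge
    for end_node, foot, radius in pending_fusions:
        hit = index.nearest(foot, foot, 0.0)
        if hit is None:
            continue
        _, e_idx, v_idx, t, foot2 = hit
        sep = params.min_junction_separation
        if sep > 0 and nearest_junction(foot2)[1] < sep:
            # connecting here would pile onto an existing junction: leave a
            # blind ending, pulled back a step so the strokes stay separate
            truncate_edge_to(end_node)
            continue
        target = fuse_with_separation(e_idx, v_idx, t, foot2)
        if target == end_node:
            continue
        gap = float(np.linalg.norm(nodes[target] - nodes[end_node]))
        if gap <= 1e-9:
            continue
        if gap < 0.5 * params.step_um:
            # too short for a resolvable connector edge: re-target the
            # pending tip's own edge to end at the fusion node instead
            for k in range(len(edges) - 1, -1, -1):
                if edges[k].b == end_node:
                    e = edges[k]
                    pts = np.vstack([e.points, nodes[target]])
                    edges[k] = Edge(e.a, target, pts, e.radius)
                    index.invalidate()
                    break
            continue
        pts = np.array([nodes[end_node], nodes[target]], dtype=float)
        edges.append(Edge(end_node, target, pts, radius))
        index.append(len(edges) - 1)

    # in consistency-grade networks, a blind ending that touches another
    # vessel would merge with it in the raster and fake a junction: retract
    # such endings step by step until they keep clearance, deleting
    # single-step stubs outright
    if params.min_junction_separation > 0:
        merge_clearance = 2.0 * params.vessel_radius_range[1] + 3.0
        for _ in range(4):
            deg = np.zeros(len(nodes), dtype=int)
            for e in edges:
                deg[e.a] += 1
                deg[e.b] += 1
            changed_any = False
            for k in range(len(edges) - 1, -1, -1):
                e = edges[k]
                for node_id, at_end in ((e.b, True), (e.a, False)):
                    if deg[node_id] != 1:
                        continue
                    pos = nodes[node_id]
                    too_close = False
                    for m, e2 in enumerate(edges):
                        if m == k:
                            continue
                        pts = np.asarray(e2.points)
                        v = pts[1:] - pts[:-1]
                        vv = (v**2).sum(axis=1)
                        vv[vv == 0] = 1e-12
                        t = np.clip(((pos - pts[:-1]) * v).sum(axis=1) / vv, 0, 1)
                        foot = pts[:-1] + t[:, None] * v
                        if (((foot - pos) ** 2).sum(axis=1) < merge_clearance**2).any():
                            too_close = True
                            break
                    if not too_close:
                        continue
                    pts = np.asarray(e.points)
                    if len(pts) >= 3:
                        pts = pts[:-1] if at_end else pts[1:]
                        nodes[node_id] = (pts[-1] if at_end else pts[0]).copy()
                        edges[k] = Edge(e.a, e.b, pts.copy(), e.radius)
                    else:
                        del edges[k]
                    changed_any = True
                    break
            if not changed_any:
                break

    # contract edges shorter than the raster can resolve; their two end
    # nodes are geometrically one point at any realistic pixel size
    min_len = 2.0
    changed = True
    while changed:
        changed = False
        for k, e in enumerate(edges):
            if e.a != e.b and e.length() < min_len:
                keep, drop = (e.a, e.b) if e.a <= e.b else (e.b, e.a)
                del edges[k]
                for m, e2 in enumerate(edges):
                    a2 = keep if e2.a == drop else e2.a
                    b2 = keep if e2.b == drop else e2.b
                    if a2 != e2.a or b2 != e2.b:
                        pts = np.asarray(e2.points).copy()
                        if e2.a == drop:
                            pts[0] = nodes[keep]
                        if e2.b == drop:
                            pts[-1] = nodes[keep]
                        edges[m] = Edge(a2, b2, pts, e2.radius)
                changed = True
                break

    graph = VesselGraph(nodes=nodes, edges=edges, center=center, field_size=fs)
    graph.check()
    return graph


def _has_unresolvable_contact(graph: VesselGraph, clearance: float) -> bool:
    """True when two vessels approach within ``clearance`` away from a
    junction they legitimately share — geometry the raster would merge into
    a junction that does not exist in the graph."""
    from scipy.spatial import cKDTree

    pts_list, eids, arcs = [], [], []
    edge_len = []
    for ei, e in enumerate(graph.edges):
        P = np.asarray(e.points)
        arc = 0.0
        for a, b in zip(P[:-1], P[1:]):
            L = float(np.linalg.norm(b - a))
            n = max(int(L / 2.0), 1)
            ts = np.linspace(0.0, 1.0, n, endpoint=False)
            pts_list.append(a + ts[:, None] * (b - a))
            eids.append(np.full(n, ei))
            arcs.append(arc + ts * L)
            arc += L
        pts_list.append(P[-1:])
        eids.append(np.array([ei]))
        arcs.append(np.array([arc]))
        edge_len.append(arc)
    if not pts_list:
        return False
    pts = np.concatenate(pts_list)
    eid = np.concatenate(eids)
    arc_pos = np.concatenate(arcs)

    def arc_to_node(k: int, node: int) -> float:
        """Arc distance from sample k to a node of its edge (inf otherwise)."""
        e = graph.edges[eid[k]]
        d = math.inf
        if e.a == node:
            d = arc_pos[k]
        if e.b == node:
            d = min(d, edge_len[eid[k]] - arc_pos[k])
        return d

    junction_pos = np.array([graph.nodes[i] for i in graph.junction_nodes()])
    pairs = cKDTree(pts).query_pairs(r=clearance, output_type="ndarray")
    for i, j in pairs:
        if eid[i] == eid[j]:
            continue
        ea, eb = graph.edges[eid[i]], graph.edges[eid[j]]
        shared = {ea.a, ea.b} & {eb.a, eb.b}
        # contact is legitimate only close (along each vessel) to a node the
        # two edges share; Euclidean closeness is not enough, since an edge
        # can curve back and graze its partner before terminating on it
        allowed = any(
            arc_to_node(i, s) < 1.0 * clearance and arc_to_node(j, s) < 1.0 * clearance
            for s in shared
        )
        if not allowed and len(junction_pos):
            dji = np.sqrt(((junction_pos - pts[i]) ** 2).sum(axis=1)).min()
            djj = np.sqrt(((junction_pos - pts[j]) ** 2).sum(axis=1)).min()
            if dji < 1.0 * clearance and djj < 1.0 * clearance:
                allowed = True
        if not allowed:
            return True
    return False


def generate_network(params: SynthParams) -> VesselGraph:
    """Grow a vascular network radially from the field center.

    Tips advance by ``step_um`` per round with wrapped-normal heading
    jitter, branch at distance intervals drawn around ``1/branch_rate``,
    and fuse with (or stall at) existing vessels they approach within the
    capture radius; growth stops at ``outgrowth_fraction`` times the field
    radius. The seed fully determines the output.

    When ``min_junction_separation`` is set, the network is additionally
    required to be *raster-consistent*: no two vessels approach within
    merge distance away from a recorded junction. Growth attempts that
    violate this are discarded and regrown with a different internal
    stream (deterministically, so a given seed always yields the same
    network).
    """
    params.validate()
    if params.min_junction_separation <= 0:
        return _grow_network(params, 0)
    clearance = 2.0 * params.vessel_radius_range[1] + 2.0
    graph = _grow_network(params, 0)
    for salt in range(1, 10):
        if not _has_unresolvable_contact(graph, clearance):
            break
        graph = _grow_network(params, salt)
    return graph


def _stroke_mask(
    graph: VesselGraph, pixel_size: float, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Exact hard-stroke rasterization: pixel center within one radius of a polyline.

    No anti-aliasing, so an analytic point-to-segment distance test over all
    pixels reproduces this mask bit for bit.
    """
    if shape is None:
        n = int(math.floor(graph.field_size / pixel_size)) + 1
        shape = (n, n)
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for e in graph.edges:
        pts_px = np.asarray(e.points, dtype=float) / pixel_size  # (x, y)
        r_px = e.radius / pixel_size
        for p, q in zip(pts_px[:-1], pts_px[1:]):
            x0 = max(int(math.floor(min(p[0], q[0]) - r_px)) - 1, 0)
            x1 = min(int(math.ceil(max(p[0], q[0]) + r_px)) + 1, w - 1)
            y0 = max(int(math.floor(min(p[1], q[1]) - r_px)) - 1, 0)
            y1 = min(int(math.ceil(max(p[1], q[1]) + r_px)) + 1, h - 1)
            if x1 < x0 or y1 < y0:
                continue
            xs = np.arange(x0, x1 + 1)
            ys = np.arange(y0, y1 + 1)
            gx, gy = np.meshgrid(xs, ys)
            v = q - p
            vv = float(v @ v)
            if vv == 0:
                d2 = (gx - p[0]) ** 2 + (gy - p[1]) ** 2
            else:
                t = ((gx - p[0]) * v[0] + (gy - p[1]) * v[1]) / vv
                t = np.clip(t, 0.0, 1.0)
                d2 = (gx - (p[0] + t * v[0])) ** 2 + (gy - (p[1] + t * v[1])) ** 2
            mask[y0 : y1 + 1, x0 : x1 + 1] |= d2 <= r_px**2
    return mask


_FG_LEVEL = 200.0  # 8-bit units
_BG_LEVEL = 25.0


def _finish_image(
    raw: np.ndarray,
    bit_depth: int,
    noise_sd: float,
    illumination_gradient: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply illumination ramp + noise and quantize. ``raw`` is in 8-bit units."""
    if bit_depth not in (8, 16):
        raise ParameterError(f"bit_depth must be 8 or 16, got {bit_depth}")
    w = raw.shape[-1]
    if illumination_gradient != 0 and w > 1:
        ramp = 1.0 + illumination_gradient * (np.arange(w) / (w - 1) - 0.5)
        raw = raw * ramp
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=raw.shape)
    scale = 1.0 if bit_depth == 8 else 257.0
    maxval = 255 if bit_depth == 8 else 65535
    out = np.clip(np.round(raw * scale), 0, maxval)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)


def rasterize(
    graph: VesselGraph,
    pixel_size: float = 1.0,
    bit_depth: int = 8,
    noise_sd: float = 0.0,
    illumination_gradient: float = 0.0,
    seed: int = 0,
) -> CalibratedImage:
    """Rasterize a network into a retina-like 2D grayscale image.

    Each polyline is drawn as a hard stroke of width twice its radius
    (pixel centers at integer coordinates, no anti-aliasing); vessel
    foreground is bright over a dim background, with an optional
    multiplicative left-to-right illumination ramp of the given fractional
    amplitude and additive Gaussian noise.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    mask = _stroke_mask(graph, pixel_size)
    metadata: dict = {"warnings": []}
    if graph.edges:
        min_width_px = 2.0 * min(e.radius for e in graph.edges) / pixel_size
        if min_width_px < 1.0:
            metadata["warnings"].append(
                f"thinnest vessel is {min_width_px:.2f} px wide at pixel_size={pixel_size}; "
                "vessels may vanish"
            )
    raw = np.where(mask, _FG_LEVEL, _BG_LEVEL)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    pixels = _finish_image(raw, bit_depth, noise_sd, illumination_gradient, rng)
    return CalibratedImage(
        pixels,
        pixel_size,
        center=(float(graph.center[0] / pixel_size), float(graph.center[1] / pixel_size)),
        metadata=metadata,
    )


def rasterize_stack(
    graph_per_layer: list[VesselGraph],
    pixel_size: float = 1.0,
    pixel_size_z: float = 1.0,
    layer_z_positions: tuple[float, ...] = (10.0, 30.0, 50.0),
    layer_sigma_z: float = 2.5,
    bit_depth: int = 8,
    noise_sd: float = 0.0,
    illumination_gradient: float = 0.0,
    seed: int = 0,
) -> CalibratedImage:
    """Rasterize three layered networks into a (z, y, x) stack.

    Each layer's vessels occupy a Gaussian-weighted z-band centered on its
    nominal depth, so the per-slice foreground profile has three local
    maxima at (approximately) the stated positions — the structure the
    plexus-separation stage relies on.
    """
    if len(graph_per_layer) != len(layer_z_positions):
        raise ParameterError("one z position per layer is required")
    zs = list(layer_z_positions)
    if not all(b > a for a, b in zip(zs, zs[1:])):
        raise ParameterError("layer_z_positions must be strictly increasing")
    gaps = [b - a for a, b in zip(zs, zs[1:])]
    warn_list = []
    if gaps and min(gaps) < 4.0 * layer_sigma_z:
        warn_list.append(
            f"layer z-bands overlap: min gap {min(gaps):.1f} µm < 4 sigma_z "
            f"({4 * layer_sigma_z:.1f} µm)"
        )
        warnings.warn(warn_list[-1], UserWarning, stacklevel=2)

    fs = max(g.field_size for g in graph_per_layer)
    n_xy = int(math.floor(fs / pixel_size)) + 1
    masks = [_stroke_mask(g, pixel_size, (n_xy, n_xy)) for g in graph_per_layer]

    z_max = zs[-1] + 3.0 * layer_sigma_z
    n_z = int(math.floor(z_max / pixel_size_z)) + 1
    raw = np.full((n_z, n_xy, n_xy), _BG_LEVEL, dtype=float)
    for k in range(n_z):
        z = k * pixel_size_z
        for m, z_l in zip(masks, zs):
            wgt = math.exp(-((z - z_l) ** 2) / (2.0 * layer_sigma_z**2))
            if wgt < 0.02:
                continue
            level = _BG_LEVEL + (_FG_LEVEL - _BG_LEVEL) * wgt
            raw[k] = np.where(m, np.maximum(raw[k], level), raw[k])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    pixels = _finish_image(raw, bit_depth, noise_sd, illumination_gradient, rng)
    g0 = graph_per_layer[0]
    return CalibratedImage(
        pixels,
        (pixel_size_z, pixel_size, pixel_size),
        center=(float(g0.center[0] / pixel_size), float(g0.center[1] / pixel_size)),
        metadata={"warnings": warn_list, "layer_z_positions": zs},
    )


def generate_dataset(params: SynthParams):
    """Generate graphs (one per layer) and the matching image or stack."""
    params.validate()
    if params.n_layers == 1:
        graph = generate_network(params)
        image = rasterize(
            graph,
            pixel_size=1.0,
            noise_sd=params.noise_sd,
            illumination_gradient=params.illumination_gradient,
            seed=params.seed,
        )
        return [graph], image
    graphs = [
        generate_network(replace(params, seed=params.seed + 1000 * layer))
        for layer in range(3)
    ]
    image = rasterize_stack(
        graphs,
        pixel_size=1.0,
        pixel_size_z=1.0,
        layer_z_positions=params.layer_z_positions,
        layer_sigma_z=params.layer_sigma_z,
        noise_sd=params.noise_sd,
        illumination_gradient=params.illumination_gradient,
        seed=params.seed,
    )
    return graphs, image


def write_synthetic(out_dir, params: SynthParams):
    """Write the rasterized TIFF plus a JSON ground-truth sidecar."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    graphs, image = generate_dataset(params)
    tif_path = out_dir / "synthetic.tif"
    tifffile.imwrite(tif_path, image.pixels)
    sidecar = {
        "params": asdict(params),
        "pixel_size": image.pixel_size
        if np.isscalar(image.pixel_size)
        else list(image.pixel_size),
        "center_px": list(image.center) if image.center else None,
        "layers": [
            {
                "total_length_um": g.total_length(),
                "junction_count": g.junction_count(),
                "graph": g.to_dict(),
            }
            for g in graphs
        ],
    }
    json_path = out_dir / "synthetic_truth.json"
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh)
    return tif_path, json_path


# Study-condition presets: an early, dense, irregular network (around the
# p10 remodeling peak) versus a pruned, regular adult-like network (p60+).
PRESETS: dict[str, SynthParams] = {
    "p10": SynthParams(
        field_size=800.0,
        outgrowth_fraction=0.94,
        branch_rate=0.05,
        branch_dispersion=1.0,
        anastomosis_probability=0.55,
        capture_radius=12.0,
        capture_jitter=0.6,
        patchiness=1.5,
        vessel_radius_range=(2.5, 3.5),
        n_initial_tips=8,
        heading_jitter=0.45,
        noise_sd=5.0,
        illumination_gradient=0.1,
    ),
    "p60": SynthParams(
        field_size=800.0,
        outgrowth_fraction=1.0,
        branch_rate=0.025,
        branch_dispersion=0.1,
        anastomosis_probability=0.98,
        capture_radius=14.0,
        vessel_radius_range=(1.8, 2.6),
        n_initial_tips=8,
        heading_jitter=0.05,
        noise_sd=5.0,
        illumination_gradient=0.1,
    ),
}
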