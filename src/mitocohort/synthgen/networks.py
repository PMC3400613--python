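"""Random tubular-network ground truth for single-cell mitochondrial images.

A network is stored as a vector graph (node coordinates + edge list) drawn
inside a circular cell of radius ``cell_radius_px``.  Each requested fragment
is grown as its own curvature-limited self-avoiding random walk; side branches
are spawned from interior (degree-2) nodes so that fragment count and
branch-point density stay independently controllable.  The walk keeps a
clearance of one tube diameter from material laid by other fragments (and by
its own distant past), so the rasterized tubes of distinct fragments never
touch; this is verified against the final raster before returning.

All quantities are in pixel units; coordinates are (row, col) offsets from the
cell centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation, label as _cc_label
from skimage.draw import line as _bresenham
from skimage.morphology import disk as _disk_footprint


class InfeasibleNetworkError(ValueError):
    """Requested network cannot be packed into the cell at the demanded density."""


# branches shorter than this are retracted: after the point-spread function
# and thresholding they would rasterize to stubs below the resolution of
# skeleton-based branch detection
_MIN_BRANCH_LEN = 12


@dataclass(frozen=True)
class NetworkGroundTruth:
    """Vector ground truth paired with every rendered cell image.

    node_coords : (n, 2) float array, (row, col) offsets from the cell centre
    edges       : (m, 2) int array of node indices
    """

    node_coords: np.ndarray
    edges: np.ndarray
    n_fragments: int
    n_branch_nodes: int
    tube_radius_px: int
    target_vv_pct: float
    achieved_vv_pct: float
    cell_radius_px: float
    total_length_px: float

    def degrees(self) -> np.ndarray:
        return graph_degrees(len(self.node_coords), self.edges)


def graph_degrees(n_nodes: int, edges: np.ndarray) -> np.ndarray:
    deg = np.zeros(n_nodes, dtype=int)
    if len(edges):
        np.add.at(deg, np.asarray(edges).ravel(), 1)
    return deg


def count_components(n_nodes: int, edges: np.ndarray) -> int:
    """Connected components among nodes that carry at least one edge (union-find)."""
    parent = np.arange(n_nodes)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    used = np.zeros(n_nodes, dtype=bool)
    for a, b in np.asarray(edges, dtype=int):
        used[a] = used[b] = True
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(i) for i in range(n_nodes) if used[i]}
    return len(roots)


def cell_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def rasterize_network(
    truth: NetworkGroundTruth, shape: tuple[int, int], center: tuple[float, float]
) -> np.ndarray:
    """Binary tube mask: Bresenham polylines dilated by a disk of the tube radius."""
    canvas = np.zeros(shape, dtype=bool)
    coords = truth.node_coords
    for a, b in truth.edges:
        r0 = int(round(coords[a, 0] + center[0]))
        c0 = int(round(coords[a, 1] + center[1]))
        r1 = int(round(coords[b, 0] + center[0]))
        c1 = int(round(coords[b, 1] + center[1]))
        rr, cc = _bresenham(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[ok], cc[ok]] = True
    if truth.tube_radius_px > 0:
        canvas = binary_dilation(canvas, structure=_disk_footprint(truth.tube_radius_px))
    return canvas


class _Grower:
    """Incremental self-avoiding walk machinery on a pixel grid local to one cell.

    Every polyline pixel is stamped with a monotone counter; a candidate step is
    rejected when its clearance disk contains a stamp that is neither the walk's
    own recent trail nor the chronological neighbourhood of its start node.
    Bumping the counter between fragments therefore makes the clearance rule
    strict across fragments.
    """

    _FAN = (0.0, 0.45, -0.45, 0.9, -0.9, 1.4, -1.4, 2.0, -2.0)

    def __init__(self, radius: float, tube: int, rng: np.random.Generator):
        self.R = float(radius)
        self.tube = int(tube)
        self.rng = rng
        margin = self.tube + 3
        self.size = int(2 * math.ceil(self.R) + 2 * margin + 1)
        self.c0 = self.size // 2
        self.occ = np.full((self.size, self.size), -1, dtype=np.int64)
        self.raster = np.zeros((self.size, self.size), dtype=bool)
        self.cellmask = cell_mask((self.size, self.size), (self.c0, self.c0), self.R)
        self.cell_area = int(self.cellmask.sum())
        self.area = 0
        # strands of distinct fragments must stay resolvable after a ~1 px PSF,
        # so keep two extra pixels beyond the bare tube-separation minimum
        self.clearance = 2 * self.tube + 4
        yy, xx = np.ogrid[-self.clearance : self.clearance + 1,
                          -self.clearance : self.clearance + 1]
        self._cl_disk = yy**2 + xx**2 <= self.clearance**2
        # hard no-contact zone: tubes may never touch, whatever the exemptions
        self.contact = 2 * self.tube + 1
        cy, cx = np.ogrid[-self.contact : self.contact + 1, -self.contact : self.contact + 1]
        self._contact_disk = cy**2 + cx**2 <= self.contact**2
        fp = _disk_footprint(self.tube).astype(bool)
        self.fp_off = np.argwhere(fp) - self.tube
        self.nodes: list[tuple[float, float]] = []
        self.node_stamp: list[int] = []
        self.edges: list[tuple[int, int]] = []
        self.deg: list[int] = []        # incremental node degrees
        self.parent: list[int] = []     # node each node grew from (-1 for starts)
        self.pix_counter = 0
        self.age = 2 * (self.clearance + 1) + 4

    # -- geometry helpers -------------------------------------------------
    def _pix(self, p: tuple[float, float]) -> tuple[int, int]:
        return int(round(p[0] + self.c0)), int(round(p[1] + self.c0))

    def inside(self, p: tuple[float, float]) -> bool:
        return math.hypot(p[0], p[1]) <= self.R - self.tube - 1.0

    def collision(self, p: tuple[float, float], origin_stamp: int) -> bool:
        r, c = self._pix(p)
        cl = self.clearance
        win = self.occ[r - cl : r + cl + 1, c - cl : c + cl + 1]
        occupied = win >= 0
        stamps = win[self._cl_disk & occupied]
        if len(stamps):
            recent = stamps >= self.pix_counter - self.age
            near_origin = np.abs(stamps - origin_stamp) <= self.age
            if (~recent & ~near_origin).any():
                return True
        # inner zone: contact is forbidden even for the walk's own trail and
        # its branch origin, save for the few pixels just laid behind the head
        k = cl - self.contact
        inner = win[k : k + 2 * self.contact + 1, k : k + 2 * self.contact + 1]
        istamps = inner[self._contact_disk & (inner >= 0)]
        if len(istamps):
            immediate = istamps >= self.pix_counter - (2 * self.contact + 2)
            at_origin = np.abs(istamps - origin_stamp) <= 2 * self.contact + 2
            if (~immediate & ~at_origin).any():
                return True
        return False

    def free_point(self, max_radius_frac: float = 0.8, tries: int = 400) -> tuple[float, float]:
        """A start point with full clearance from everything already laid."""
        for _ in range(tries):
            r = self.R * max_radius_frac * math.sqrt(self.rng.uniform())
            t = self.rng.uniform(0, 2 * math.pi)
            p = (r * math.sin(t), r * math.cos(t))
            if self.inside(p) and not self.collision(p, origin_stamp=-(10**9)):
                return p
        raise InfeasibleNetworkError("no room left to start a new fragment")

    def _paint(self, p_from: tuple[float, float], p_to: tuple[float, float]) -> None:
        """Stamp the Bresenham pixels of one step and grow the tube raster."""
        r0, c0 = self._pix(p_from)
        r1, c1 = self._pix(p_to)
        rr, cc = _bresenham(r0, c0, r1, c1)
        for r, c in zip(rr, cc):
            if self.occ[r, c] < 0:
                self.occ[r, c] = self.pix_counter
            self.pix_counter += 1
            fr = self.fp_off[:, 0] + r
            fc = self.fp_off[:, 1] + c
            fresh = ~self.raster[fr, fc]
            self.raster[fr[fresh], fc[fresh]] = True
            self.area += int(fresh.sum())

    def add_start(self, p: tuple[float, float]) -> int:
        self.nodes.append(p)
        self.node_stamp.append(self.pix_counter)
        self.deg.append(0)
        self.parent.append(-1)
        self._paint(p, p)
        return len(self.nodes) - 1

    def bump_epoch(self) -> None:
        """Advance the stamp counter so subsequent walks treat everything laid
        so far as foreign material (full clearance enforced)."""
        self.pix_counter += self.age + 1

    # -- checkpointing ------------------------------------------------------
    def checkpoint(self) -> tuple:
        """Snapshot for rolling back a walk that turns out too short to keep
        (sub-resolution branch stubs are retracted, not stored as truth)."""
        return (self.occ.copy(), self.raster.copy(), self.area, self.pix_counter,
                len(self.nodes), len(self.edges), self.deg.copy())

    def restore(self, chk: tuple) -> None:
        occ, raster, area, pix, n_nodes, n_edges, deg = chk
        self.occ = occ
        self.raster = raster
        self.area = area
        self.pix_counter = pix
        del self.nodes[n_nodes:]
        del self.node_stamp[n_nodes:]
        del self.edges[n_edges:]
        del self.parent[n_nodes:]
        self.deg = deg

    def _reflect(self, p: tuple[float, float], h: float) -> float:
        """Specular reflection of heading ``h`` off the circular cell boundary."""
        nr, nc = p
        norm = math.hypot(nr, nc)
        if norm == 0:
            return h
        nr, nc = nr / norm, nc / norm
        dr, dc = math.sin(h), math.cos(h)
        dot = dr * nr + dc * nc
        return math.atan2(dr - 2 * dot * nr, dc - 2 * dot * nc)

    # -- growth -----------------------------------------------------------
    def grow_walk(
        self,
        start_idx: int,
        heading: float,
        target_area: float,
        max_steps: int = 100000,
        straight_steps: int = 0,
    ) -> int:
        """Grow unit steps from ``start_idx`` until the raster area reaches
        ``target_area`` or the walk jams.  Returns the number of edges added.

        The first ``straight_steps`` steps are taken without curvature or
        avoidance deviations, which gives branch junctions a reproducible
        local geometry."""
        p = self.nodes[start_idx]
        prev = start_idx
        added = 0
        origin_stamp = self.node_stamp[start_idx]
        while added < max_steps and self.area < target_area:
            committed = False
            if added < straight_steps:
                drift = 0.0
                fan = (0.0,)
            else:
                drift = float(np.clip(self.rng.normal(0.0, 0.08), -0.3, 0.3))
                fan = self._FAN
            for delta in fan:
                h = heading + drift + delta
                q = (p[0] + math.sin(h), p[1] + math.cos(h))
                if not self.inside(q):
                    h = self._reflect(p, h) + self.rng.normal(0.0, 0.1)
                    q = (p[0] + math.sin(h), p[1] + math.cos(h))
                    if not self.inside(q):
                        continue
                if self.occ[self._pix(q)] >= 0:  # never retrace laid pixels
                    continue
                if self.collision(q, origin_stamp):
                    continue
                # round sharp avoidance turns: pull the previous node to the
                # chord midpoint so the rasterized tube has no hard corner
                # (corners thin into spurious >=3-neighbour skeleton pixels)
                if (
                    added >= 2
                    and abs(delta) >= 0.9
                    and prev > start_idx
                    and self.deg[prev] == 1
                ):
                    pp = self.nodes[self.parent[prev]]
                    self.nodes[prev] = ((pp[0] + q[0]) / 2.0, (pp[1] + q[1]) / 2.0)
                self.nodes.append(q)
                self.node_stamp.append(self.pix_counter)
                idx = len(self.nodes) - 1
                self.edges.append((prev, idx))
                self.deg[prev] += 1
                self.deg.append(1)
                self.parent.append(prev)
                self._paint(p, q)
                p, prev, heading = q, idx, h
                added += 1
                committed = True
                break
            if not committed:
                break
        return added

    def local_free(self, idx: int) -> int:
        """Free pixels in the clearance window around a node (frontier score)."""
        r, c = self._pix(self.nodes[idx])
        cl = self.clearance
        win = self.occ[r - cl : r + cl + 1, c - cl : c + cl + 1]
        return int((win < 0).sum())

    def leaf_heading(self, leaf: int) -> float:
        other = self.parent[leaf]
        if other < 0:
            return float(self.rng.uniform(0, 2 * math.pi))
        d = (self.nodes[leaf][0] - self.nodes[other][0],
             self.nodes[leaf][1] - self.nodes[other][1])
        return math.atan2(d[0], d[1])

    def branch_heading(self, origin: int) -> float:
        """Heading perpendicular to the local strand direction, so the junction
        renders as a detectable branch point rather than a smooth
        continuation."""
        other = self.parent[origin]
        if other < 0:
            return float(self.rng.uniform(0, 2 * math.pi))
        d = (self.nodes[origin][0] - self.nodes[other][0],
             self.nodes[origin][1] - self.nodes[other][1])
        along = math.atan2(d[0], d[1])
        side = self.rng.choice((-1.0, 1.0))
        return along + side * math.pi / 2


def generate_network(
    cell_radius_px: float,
    target_vv_pct: float,
    n_fragments: int,
    branch_density: float,
    tube_radius_px: int = 2,
    seed: int = 0,
) -> NetworkGroundTruth:
    """Draw a random mitochondrial network with controlled volume density,
    fragment count and branch-point density.

    Parameters
    ----------
    cell_radius_px : radius of the circular cell, pixels.
    target_vv_pct : intended tube-raster area as a percentage of cell area,
        in (0, 60].
    n_fragments : requested number of connected components (>= 1).
    branch_density : expected branch nodes per pixel of skeleton length; the
        realized count is Poisson around ``branch_density * length``.
    tube_radius_px : dilation radius used when rasterizing.
    seed : RNG seed; the result is a pure function of the arguments.

    Raises
    ------
    InfeasibleNetworkError
        When the demanded area cannot be packed into the cell, or the walk
        cannot realize the requested fragment count / density.
    """
    if not 0 < target_vv_pct <= 60:
        raise ValueError("target_vv_pct must lie in (0, 60]")
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if branch_density < 0:
        raise ValueError("branch_density must be >= 0")
    tube = int(tube_radius_px)
    width = 2 * tube + 1
    # packing bound: parallel tubes of width w at the enforced centreline spacing
    max_cover = 0.75 * width / (width + 3.0)
    if target_vv_pct / 100.0 > max_cover:
        raise InfeasibleNetworkError(
            f"target_vv_pct={target_vv_pct} with tube radius {tube} demands more "
            "area than can be packed into the cell"
        )
    last_err: Exception | None = None
    for attempt in range(5):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        try:
            return _generate_once(
                cell_radius_px, target_vv_pct, n_fragments, branch_density, tube, rng
            )
        except InfeasibleNetworkError as err:
            last_err = err
    raise InfeasibleNetworkError(
        f"failed after 5 attempts: {last_err}"
    )


def _generate_once(
    cell_radius_px: float,
    target_vv_pct: float,
    n_fragments: int,
    branch_density: float,
    tube: int,
    rng: np.random.Generator,
) -> NetworkGroundTruth:
    width = 2 * tube + 1
    grower = _Grower(cell_radius_px, tube, rng)
    target_area = target_vv_pct / 100.0 * grower.cell_area
    length_est = target_area / width
    n_branch_total = int(rng.poisson(branch_density * length_est))

    # area budget per fragment, then per trunk/branch inside a fragment
    frag_shares = rng.dirichlet(np.full(n_fragments, 6.0))
    frag_marks = np.cumsum(frag_shares) * target_area
    branch_alloc = rng.multinomial(n_branch_total, frag_shares)

    prev_mark = 0.0
    min_branch_area = (_MIN_BRANCH_LEN + 2) * width
    for f in range(n_fragments):
        p0 = grower.free_point()
        idx0 = grower.add_start(p0)
        frag_budget = frag_marks[f] - prev_mark
        # every scheduled branch needs enough area to reach a resolvable
        # length, otherwise it would only be retracted again
        k = min(int(branch_alloc[f]),
                max(0, int((0.6 * frag_budget) // min_branch_area)))
        shares = rng.dirichlet(np.full(k + 1, 4.0))
        sizes = shares * (frag_budget - k * min_branch_area)
        sizes[1:] += min_branch_area
        marks = prev_mark + np.cumsum(sizes)
        first_node = len(grower.nodes) - 1
        grower.grow_walk(idx0, rng.uniform(0, 2 * math.pi), marks[0])
        # spawn branches until the scheduled count is realized; a branch that
        # cannot reach a resolvable length is rolled back (the stored truth
        # never holds sub-resolution stubs) and another origin is tried
        realized = 0
        attempts = 0
        while realized < k and attempts < 10 * k:
            attempts += 1
            if frag_marks[f] - grower.area < min_branch_area:
                break
            deg_frag = np.asarray(grower.deg[first_node:])
            interior = np.flatnonzero(deg_frag == 2) + first_node
            if not len(interior):
                break
            cand = rng.choice(interior, size=min(8, len(interior)), replace=False)
            origin = int(max(cand, key=grower.local_free))
            chk = grower.checkpoint()
            target = min(frag_marks[f], grower.area + float(sizes[1 + realized]))
            added = grower.grow_walk(
                origin, grower.branch_heading(origin), target, straight_steps=5,
            )
            if added >= _MIN_BRANCH_LEN:
                realized += 1
            elif added > 0:
                grower.restore(chk)
        _extend_to(grower, frag_marks[f], rng, first_node, strict=False)
        prev_mark = frag_marks[f]
        grower.bump_epoch()
    # any residual area deficit may be filled from every fragment, not just the last
    _extend_to(grower, target_area, rng, first_node=0, strict=True)

    nodes_arr = np.array(grower.nodes, dtype=float)
    edges = np.array(grower.edges, dtype=int)
    deg = graph_degrees(len(nodes_arr), edges)
    n_frag = count_components(len(nodes_arr), edges)
    if n_frag != n_fragments:
        raise InfeasibleNetworkError(
            f"realized {n_frag} fragments instead of {n_fragments}"
        )
    seg = nodes_arr[edges[:, 0]] - nodes_arr[edges[:, 1]] if len(edges) else np.zeros((0, 2))
    total_len = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    truth = NetworkGroundTruth(
        node_coords=nodes_arr,
        edges=edges,
        n_fragments=n_frag,
        n_branch_nodes=int((deg >= 3).sum()),
        tube_radius_px=tube,
        target_vv_pct=float(target_vv_pct),
        achieved_vv_pct=0.0,
        cell_radius_px=float(cell_radius_px),
        total_length_px=total_len,
    )
    # verify against the raster actually produced downstream (corner rounding
    # nudges node coordinates after painting, so rasterize afresh)
    final = rasterize_network(truth, grower.occ.shape, (grower.c0, grower.c0))
    _, n_cc = _cc_label(final, structure=np.ones((3, 3), dtype=int))
    if n_cc != n_fragments:
        raise InfeasibleNetworkError(
            "rasterized fragments touch; regenerating with a fresh layout"
        )
    achieved_vv = 100.0 * int(final.sum()) / grower.cell_area
    if abs(achieved_vv - target_vv_pct) > 1.0:
        raise InfeasibleNetworkError(
            f"achieved Vv {achieved_vv:.2f}% is more than 1 point from target {target_vv_pct}%"
        )
    return replace(truth, achieved_vv_pct=float(achieved_vv))


def _extend_to(
    grower: _Grower,
    target_area: float,
    rng: np.random.Generator,
    first_node: int,
    strict: bool = True,
) -> None:
    """Top up raster area by continuing from leaves at or after ``first_node``;
    when every leaf is jammed, rescue by branching from an interior node (which
    adds a branch point, recorded faithfully in the returned ground truth).
    With ``strict`` a residual deficit raises; otherwise it is left for a later
    pass over the whole network."""
    fails = 0
    max_fails = 150 + int(max(0.0, target_area - grower.area) / 25.0)
    while grower.area < target_area and fails < max_fails:
        deg_frag = np.asarray(grower.deg[first_node:])
        leaves = np.flatnonzero(deg_frag == 1) + first_node
        if fails < 2 * len(leaves) + 4 and len(leaves):
            start = int(rng.choice(leaves))
            heading = grower.leaf_heading(start)
        else:
            interior = np.flatnonzero(deg_frag == 2) + first_node
            if not len(interior):
                break
            # prefer origins on the free-space frontier so rescues succeed
            cand = rng.choice(interior, size=min(8, len(interior)), replace=False)
            start = int(max(cand, key=grower.local_free))
            chk = grower.checkpoint()
            added = grower.grow_walk(
                start, grower.branch_heading(start), target_area, max_steps=400,
                straight_steps=5,
            )
            if 0 < added < _MIN_BRANCH_LEN:
                grower.restore(chk)  # rescue stub: retract, try elsewhere
                added = 0
            fails = fails + 1 if added < 5 else 0
            continue
        added = grower.grow_walk(start, heading, target_area, max_steps=400)
        fails = fails + 1 if added < 5 else 0
    if strict and grower.area < target_area - 0.008 * grower.cell_area:
        raise InfeasibleNetworkError(
            "walk jammed before reaching the requested volume density"
        )
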