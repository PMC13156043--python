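"""D8 overland flow routing and downstream mass transport.

Each cell drains to its steepest-descent neighbour among the eight adjacent
cells (drop divided by centre distance, diagonals √2 longer). Ties are
broken by a fixed neighbour order (N, NE, E, SE, S, SW, W, NW — first wins),
making the field deterministic. Flat cells are resolved by breadth-first
assignment toward the nearest equal-elevation neighbour that already drains;
local minima and unresolvable flats become sinks. The resulting directions
form a forest, so mass can be propagated to sinks in topological order with
exact conservation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FlowField", "flow_directions", "route_mass", "offsite_extent",
           "D8_OFFSETS"]

# direction codes 1..8 = N, NE, E, SE, S, SW, W, NW; 0 = sink
D8_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2)] * 2)

SINK = 0


@dataclass
class FlowField:
    """Per-cell D8 direction codes (0 = sink, 1..8 = N..NW clockwise)."""

    direction: np.ndarray  # int8
    is_sink: np.ndarray  # bool

    @property
    def shape(self):
        return self.direction.shape

    def downstream_index(self, r: int, c: int) -> tuple[int, int] | None:
        code = self.direction[r, c]
        if code == SINK:
            return None
        dr, dc = D8_OFFSETS[code - 1]
        return r + dr, c + dc


def flow_directions(elevation: np.ndarray) -> FlowField:
    """Steepest-descent D8 directions for a (pre-filled) elevation grid."""
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2:
        raise ValueError("elevation must be 2-D")
    if np.all(np.isnan(z)):
        raise ValueError("all-nodata elevation grid")
    n, m = z.shape
    direction = np.zeros((n, m), dtype=np.int8)
    assigned = np.zeros((n, m), dtype=bool)

    # Pass 1: strict steepest descent.
    for r in range(n):
        for c in range(m):
            best_slope = 0.0
            best_code = SINK
            zc = z[r, c]
            for k, (dr, dc) in enumerate(D8_OFFSETS):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n and 0 <= cc < m):
                    continue
                drop = zc - z[rr, cc]
                if drop <= 0:
                    continue
                slope = drop / _DIST[k]
                if slope > best_slope:  # strict: first in order wins ties
                    best_slope = slope
                    best_code = k + 1
            if best_code != SINK:
                direction[r, c] = best_code
                assigned[r, c] = True

    # Pass 2: flats — BFS from draining cells across equal elevation.
    queue = deque((r, c) for r in range(n) for c in range(m) if assigned[r, c])
    while queue:
        r, c = queue.popleft()
        zc = z[r, c]
        for k, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n and 0 <= cc < m):
                continue
            if assigned[rr, cc] or z[rr, cc] != zc:
                continue
            # (rr, cc) is a flat neighbour at the same level: drain toward (r, c)
            back = (k + 4) % 8  # opposite direction code index
            direction[rr, cc] = back + 1
            assigned[rr, cc] = True
            queue.append((rr, cc))

    # Remaining unassigned cells are sinks (code 0 already).
    return FlowField(direction=direction, is_sink=direction == SINK)


def _topological_order(flow: FlowField) -> np.ndarray:
    """Kahn's algorithm over the flow forest; raises on a cycle."""
    n, m = flow.shape
    size = n * m
    target = np.full(size, -1, dtype=np.int64)
    indeg = np.zeros(size, dtype=np.int64)
    dirs = flow.direction.ravel()
    rows, cols = np.divmod(np.arange(size), m)
    for code in range(1, 9):
        sel = dirs == code
        dr, dc = D8_OFFSETS[code - 1]
        tr, tc = rows[sel] + dr, cols[sel] + dc
        if np.any((tr < 0) | (tr >= n) | (tc < 0) | (tc >= m)):
            raise ValueError("flow direction points outside the grid")
        t = tr * m + tc
        target[sel] = t
        np.add.at(indeg, t, 1)
    order = np.empty(size, dtype=np.int64)
    queue = deque(np.flatnonzero(indeg == 0).tolist())
    k = 0
    while queue:
        i = queue.popleft()
        order[k] = i
        k += 1
        t = target[i]
        if t >= 0:
            indeg[t] -= 1
            if indeg[t] == 0:
                queue.append(t)
    if k != size:
        raise ValueError("cycle detected in flow field")
    return order, target


def route_mass(loss: np.ndarray, flow: FlowField,
               transfer_frac: float = 0.5) -> np.ndarray:
    """Propagate mobile load downslope; returns the deposition grid.

    At every non-sink cell a fraction ``transfer_frac`` of the arriving load
    moves to the downstream neighbour and the rest deposits locally; sinks
    retain everything. Total deposited mass equals total input mass exactly
    (the split is a partition at every step). NaN input cells contribute 0.
    """
    if not 0 <= transfer_frac <= 1:
        raise ValueError("transfer_frac must lie in [0, 1]")
    loss = np.asarray(loss, dtype=float)
    if loss.shape != flow.shape:
        raise ValueError("loss and flow shapes differ")
    order, target = _topological_order(flow)
    arriving = np.nan_to_num(loss, nan=0.0).ravel().copy()
    deposited = np.zeros_like(arriving)
    for i in order:
        t = target[i]
        if t < 0:
            deposited[i] += arriving[i]
        else:
            deposited[i] += (1.0 - transfer_frac) * arriving[i]
            arriving[t] += transfer_frac * arriving[i]
    return deposited.reshape(flow.shape)


def offsite_extent(deposited: np.ndarray, source_mask: np.ndarray,
                   threshold: float, cell_size_m: float = 100.0) -> float:
    """Maximum distance (km) from any source cell at which deposition exceeds
    ``threshold``, measured as Euclidean distance to the nearest source.

    Returns 0 when no supra-threshold cell lies outside the source mask.
    """
    source_mask = np.asarray(source_mask, dtype=bool)
    if not source_mask.any():
        raise ValueError("empty source mask")
    deposited = np.asarray(deposited, dtype=float)
    dist_m = ndimage.distance_transform_edt(~source_mask,
                                            sampling=cell_size_m)
    outside = ~source_mask & (deposited > threshold)
    if not outside.any():
        return 0.0
    return float(dist_m[outside].max() / 1000.0)
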