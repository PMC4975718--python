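"""Dendritic stream networks: topology, flow, hydrologic distance and sampling.

A stream network is represented as a rooted tree of *segments* (stretches of
stream between confluences), directed towards a single outlet.  Every
non-terminal segment has exactly two upstream children (binary, dendritic
branching; no braided or diverging channels).  Each segment carries a length,
an additive flow value and a planar embedding of its two endpoints.

Positions on the network are addressed by ``(segment_id, updist)`` where
``updist`` is the along-stream distance from the network outlet.  Two points
are *flow-connected* when water flows from one to the other, i.e. when one
point's segment lies in the other's upstream set; only flow-connected pairs
receive non-zero covariance under the tail-up model (see
:mod:`streamnet.covariance`).

The geometry needed by the spatial models — pairwise stream distances, the
flow-connectivity mask and the confluence-weight products ``pi_ij`` — is
computed in vectorized form by :meth:`StreamNetwork.pairwise_geometry` and
cached per point-set pair.
"""

from __future__ import annotations

import io
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "StreamNetwork",
    "NetworkPoint",
    "NetworkPointSet",
    "PairGeometry",
    "generate_network",
    "flow_connected",
    "stream_distance",
    "connection_weight",
    "sample_points",
    "max_separation",
]

_BRANCH_ANGLE = np.deg2rad(35.0)  # half-angle between sibling branches


@dataclass
class Segment:
    """One stream segment (stretch between confluences).

    ``downstream_id`` is ``None`` exactly for the outlet segment.  ``flow``
    is the additive flow value ``f_i`` used for confluence weights; here it
    equals the number of headwater segments upstream of (and including) the
    segment, which satisfies mass balance ``f_c = f_a + f_b`` exactly.
    ``(x0, y0)`` is the downstream endpoint, ``(x1, y1)`` the upstream one.
    """

    id: int
    downstream_id: int | None
    length: float
    flow: float = 1.0
    x0: float = 0.0
    y0: float = 0.0
    x1: float = 0.0
    y1: float = 0.0


@dataclass(frozen=True)
class NetworkPoint:
    """A single location on the network: segment plus distance from outlet."""

    segment_id: int
    updist: float
    cx: float = 0.0
    cy: float = 0.0


class NetworkPointSet:
    """Ordered set of network locations backing rows/columns of matrices.

    The ordering is stable: every matrix built from a point set (distance,
    connectivity, covariance, design) indexes its rows by this order.
    """

    _counter = itertools.count()

    def __init__(self, segment_ids, updist, cx, cy, role: str = "observation"):
        self.segment_ids = np.asarray(segment_ids, dtype=np.int64)
        self.updist = np.asarray(updist, dtype=float)
        self.cx = np.asarray(cx, dtype=float)
        self.cy = np.asarray(cy, dtype=float)
        if not (len(self.segment_ids) == len(self.updist) == len(self.cx) == len(self.cy)):
            raise ValueError("point-set field lengths differ")
        self.role = role
        # token identifies the point set for geometry caching
        self._token = next(NetworkPointSet._counter)

    def __len__(self) -> int:
        return len(self.segment_ids)

    def __getitem__(self, i: int) -> NetworkPoint:
        return NetworkPoint(
            int(self.segment_ids[i]), float(self.updist[i]),
            float(self.cx[i]), float(self.cy[i]),
        )

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) Cartesian coordinates."""
        return np.column_stack([self.cx, self.cy])

    @classmethod
    def from_points(cls, points, role: str = "observation") -> "NetworkPointSet":
        pts = list(points)
        return cls(
            [p.segment_id for p in pts],
            [p.updist for p in pts],
            [p.cx for p in pts],
            [p.cy for p in pts],
            role=role,
        )

    @classmethod
    def concat(cls, a: "NetworkPointSet", b: "NetworkPointSet",
               role: str = "observation") -> "NetworkPointSet":
        return cls(
            np.concatenate([a.segment_ids, b.segment_ids]),
            np.concatenate([a.updist, b.updist]),
            np.concatenate([a.cx, b.cx]),
            np.concatenate([a.cy, b.cy]),
            role=role,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "point_id": np.arange(len(self)),
            "segment_id": self.segment_ids,
            "updist": self.updist,
            "cx": self.cx,
            "cy": self.cy,
            "role": self.role,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NetworkPointSet":
        role = str(df["role"].iloc[0]) if "role" in df and len(df) else "observation"
        return cls(df["segment_id"], df["updist"], df["cx"], df["cy"], role=role)

    @classmethod
    def from_csv(cls, path) -> "NetworkPointSet":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class PairGeometry:
    """Pairwise network geometry between two point sets.

    ``dist[i, j]`` is the stream distance, ``connected[i, j]`` the
    flow-connectivity indicator and ``pij[i, j]`` the product of confluence
    weights (zero where flow-unconnected).
    """

    dist: np.ndarray
    connected: np.ndarray
    pij: np.ndarray
    euclid: np.ndarray = field(default=None, repr=False)


class StreamNetwork:
    """A dendritic (binary-branching) stream network rooted at one outlet.

    Parameters
    ----------
    segments : iterable of Segment
        Tree of segments; exactly one must have ``downstream_id is None``.
    use_sqrt_weights : bool
        Confluence-weight convention for ``pi_ij``.  The default (``False``)
        takes the plain product of flow ratios ``omega_k = f_k / f_c``; the
        alternative uses ``sqrt(omega_k)``, the convention that keeps the
        tail-up marginal variance constant across confluences.
    """

    def __init__(self, segments, use_sqrt_weights: bool = False):
        segs = sorted(segments, key=lambda s: s.id)
        self.segments = {s.id: s for s in segs}
        self.n_seg = len(segs)
        if sorted(self.segments) != list(range(1, self.n_seg + 1)):
            raise ValueError("segment ids must be 1..n_seg")
        self.use_sqrt_weights = use_sqrt_weights
        self._geom_cache: dict[tuple[int, int], PairGeometry] = {}
        self._build_index()
        self._validate()

    # ------------------------------------------------------------------ build
    def _build_index(self) -> None:
        n = self.n_seg
        ids = np.arange(1, n + 1)
        self.lengths = np.array([self.segments[i].length for i in ids])
        self.flows = np.array([self.segments[i].flow for i in ids])
        # parent in 0-based indexing; outlet points at itself
        parent = np.empty(n, dtype=np.int64)
        outlet = None
        children: list[list[int]] = [[] for _ in range(n)]
        for i in ids:
            d = self.segments[i].downstream_id
            if d is None:
                if outlet is not None:
                    raise ValueError("more than one outlet segment")
                outlet = i - 1
                parent[i - 1] = i - 1
            else:
                parent[i - 1] = d - 1
                children[d - 1].append(i - 1)
        if outlet is None:
            raise ValueError("no outlet segment (downstream_id None missing)")
        self.outlet_index = outlet
        self.parent = parent
        self.children = children

        # iterative DFS from the outlet: depths, Euler intervals, updists,
        # cumulative log confluence weights down to the outlet
        depth = np.zeros(n, dtype=np.int64)
        tin = np.zeros(n, dtype=np.int64)
        tout = np.zeros(n, dtype=np.int64)
        base_updist = np.zeros(n)  # updist of the downstream end l_i
        logw = np.zeros(n)  # log prod of omega on the path to the outlet
        timer = 0
        order = []
        stack = [outlet]
        visited = np.zeros(n, dtype=bool)
        while stack:
            v = stack.pop()
            if visited[v]:
                continue
            visited[v] = True
            order.append(v)
            tin[v] = timer
            timer += 1
            for c in children[v]:
                depth[c] = depth[v] + 1
                base_updist[c] = base_updist[v] + self.lengths[v]
                w = self.flows[c] / self.flows[v]
                if self.use_sqrt_weights:
                    w = np.sqrt(w)
                logw[c] = logw[v] + np.log(w)
                stack.append(c)
        if not visited.all():
            raise ValueError("downstream_id relation is not a tree reaching the outlet")
        # subtree intervals: tout = max tin over subtree (preorder property)
        tout[:] = tin
        for v in reversed(order):
            for c in children[v]:
                tout[v] = max(tout[v], tout[c])
        self.depth = depth
        self.tin = tin
        self.tout = tout
        self.base_updist = base_updist
        self.top_updist = base_updist + self.lengths
        self.logw = logw
        self.dfs_order = order

        # binary-lifting table for vectorized LCA
        maxk = max(1, int(np.ceil(np.log2(max(2, depth.max() + 1)))) + 1)
        up = np.empty((maxk, n), dtype=np.int64)
        up[0] = parent
        for k in range(1, maxk):
            up[k] = up[k - 1][up[k - 1]]
        self._lift = up

    def _validate(self) -> None:
        if np.any(self.lengths <= 0):
            raise ValueError("segment lengths must be positive")
        if np.any(self.flows <= 0):
            raise ValueError("flow values must be positive")
        for v in range(self.n_seg):
            kids = self.children[v]
            if len(kids) not in (0, 2):
                raise ValueError("dendritic network requires 0 or 2 upstream children")
            if kids:
                if not np.isclose(self.flows[v], sum(self.flows[c] for c in kids)):
                    raise ValueError("flow mass balance violated at a confluence")

    # -------------------------------------------------------------- topology
    @property
    def outlet_id(self) -> int:
        return self.outlet_index + 1

    def headwater_ids(self) -> list[int]:
        return [v + 1 for v in range(self.n_seg) if not self.children[v]]

    def confluence_triplets(self) -> list[tuple[int, int, int]]:
        """(child_a, child_b, downstream) segment-id triplets, one per confluence."""
        out = []
        for v in range(self.n_seg):
            if self.children[v]:
                a, b = sorted(self.children[v])
                out.append((a + 1, b + 1, v + 1))
        return out

    def n_confluences(self) -> int:
        return len(self.confluence_triplets())

    def is_ancestor(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """True where segment ``i`` is downstream of (or equal to) ``j`` (0-based)."""
        return (self.tin[i] <= self.tin[j]) & (self.tout[j] <= self.tout[i])

    def _lca(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Vectorized lowest common ancestor of 0-based segment arrays."""
        a = np.array(a, dtype=np.int64, copy=True)
        b = np.array(b, dtype=np.int64, copy=True)
        da, db = self.depth[a], self.depth[b]
        # lift the deeper one up to equal depth
        diff = da - db
        swap = diff < 0
        a[swap], b[swap] = b[swap], a[swap].copy()
        diff = np.abs(diff)
        for k in range(self._lift.shape[0]):
            m = (diff >> k) & 1 == 1
            if m.any():
                a[m] = self._lift[k][a[m]]
        neq = a != b
        for k in range(self._lift.shape[0] - 1, -1, -1):
            m = neq & (self._lift[k][a] != self._lift[k][b])
            if m.any():
                a[m] = self._lift[k][a[m]]
                b[m] = self._lift[k][b[m]]
        a[neq] = self.parent[a[neq]]
        return a

    # -------------------------------------------------------------- geometry
    def pairwise_geometry(self, pts_a: NetworkPointSet,
                          pts_b: NetworkPointSet) -> PairGeometry:
        """Stream distance, connectivity and confluence-weight matrices.

        Results are cached per ordered point-set pair; the flow-connectivity
        mask and weights are computed once and reused by every covariance
        evaluation on the same locations.
        """
        key = (pts_a._token, pts_b._token)
        hit = self._geom_cache.get(key)
        if hit is not None:
            return hit
        sa = pts_a.segment_ids - 1
        sb = pts_b.segment_ids - 1
        ua = pts_a.updist[:, None]
        ub = pts_b.updist[None, :]

        A = sa[:, None]
        B = sb[None, :]
        a_down = self.is_ancestor(A, B)  # a's segment downstream of b's
        b_down = self.is_ancestor(B, A)
        connected = a_down | b_down

        # pi_ij from cumulative log weights: ratio along the downstream path
        pij = np.where(connected,
                       np.exp(-np.abs(self.logw[sa][:, None] - self.logw[sb][None, :])),
                       0.0)

        dist = np.abs(ua - ub)
        if not connected.all():
            lca = self._lca(np.broadcast_to(A, connected.shape).ravel(),
                            np.broadcast_to(B, connected.shape).ravel()).reshape(connected.shape)
            junction = self.top_updist[lca]
            dist = np.where(connected, dist, ua + ub - 2.0 * junction)

        dx = pts_a.cx[:, None] - pts_b.cx[None, :]
        dy = pts_a.cy[:, None] - pts_b.cy[None, :]
        geom = PairGeometry(dist=dist, connected=connected, pij=pij,
                            euclid=np.hypot(dx, dy))
        self._geom_cache[key] = geom
        return geom

    # -------------------------------------------------------------- sampling
    def sample_points(self, n: int, seed: int, role: str = "observation") -> NetworkPointSet:
        """Draw ``n`` locations, segments length-weighted, positions uniform."""
        if n < 1:
            raise ValueError("need n >= 1 points")
        rng = np.random.default_rng(seed)
        p = self.lengths / self.lengths.sum()
        seg0 = rng.choice(self.n_seg, size=n, p=p)
        frac = rng.uniform(0.0, 1.0, size=n)
        pos = frac * self.lengths[seg0]
        updist = self.base_updist[seg0] + pos
        x0 = np.array([self.segments[i + 1].x0 for i in seg0])
        y0 = np.array([self.segments[i + 1].y0 for i in seg0])
        x1 = np.array([self.segments[i + 1].x1 for i in seg0])
        y1 = np.array([self.segments[i + 1].y1 for i in seg0])
        cx = x0 + frac * (x1 - x0)
        cy = y0 + frac * (y1 - y0)
        return NetworkPointSet(seg0 + 1, updist, cx, cy, role=role)

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "n_seg": self.n_seg,
            "use_sqrt_weights": self.use_sqrt_weights,
            "segments": [
                {
                    "id": s.id,
                    "downstream_id": s.downstream_id,
                    "length": s.length,
                    "flow": s.flow,
                    "x0": s.x0, "y0": s.y0, "x1": s.x1, "y1": s.y1,
                }
                for s in (self.segments[i] for i in sorted(self.segments))
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "StreamNetwork":
        segs = [Segment(**{k: rec[k] for k in
                           ("id", "downstream_id", "length", "flow",
                            "x0", "y0", "x1", "y1")})
                for rec in d["segments"]]
        return cls(segs, use_sqrt_weights=d.get("use_sqrt_weights", False))

    @classmethod
    def from_json(cls, source) -> "StreamNetwork":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            return cls.from_dict(json.loads(source))
        with open(source) as fh:
            return cls.from_dict(json.load(fh))

    def to_edge_csv(self, path=None) -> str:
        df = pd.DataFrame(self.to_dict()["segments"])
        if path is not None:
            df.to_csv(path, index=False)
            return ""
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_edge_csv(cls, path) -> "StreamNetwork":
        df = pd.read_csv(path)
        segs = []
        for rec in df.to_dict("records"):
            d = rec["downstream_id"]
            segs.append(Segment(
                id=int(rec["id"]),
                downstream_id=None if pd.isna(d) else int(d),
                length=float(rec["length"]), flow=float(rec["flow"]),
                x0=float(rec["x0"]), y0=float(rec["y0"]),
                x1=float(rec["x1"]), y1=float(rec["y1"]),
            ))
        return cls(segs)


# ---------------------------------------------------------------- generation
def generate_network(n_seg: int, seed: int, mean_length: float = 1.0,
                     use_sqrt_weights: bool = False) -> StreamNetwork:
    """Grow a random dendritic network with ``n_seg`` segments.

    Growth starts from a single outlet segment; a uniformly random terminal
    segment is repeatedly split at its upstream end into two children until
    ``n_seg`` segments exist (so ``n_seg`` must be odd: ``2k + 1`` segments
    for ``k`` confluences).  Segment lengths are iid exponential with the
    given mean.  Flow values count the headwater segments upstream of each
    segment, which satisfies mass balance at every confluence.  The planar
    embedding bisects branch directions at +/-35 degrees and is used only to
    supply Cartesian coordinates; crossings are possible and harmless.
    """
    if n_seg < 1 or n_seg % 2 == 0:
        raise ValueError("invalid segment count for binary dendritic tree")
    rng = np.random.default_rng(seed)
    lengths = {1: rng.exponential(mean_length)}
    downstream: dict[int, int | None] = {1: None}
    children: dict[int, list[int]] = {1: []}
    terminals = [1]
    next_id = 2
    while next_id <= n_seg:
        t = terminals.pop(rng.integers(len(terminals)))
        for _ in range(2):
            lengths[next_id] = rng.exponential(mean_length)
            downstream[next_id] = t
            children[next_id] = []
            children[t].append(next_id)
            terminals.append(next_id)
            next_id += 1

    # flows: headwater counts, accumulated leaves-to-root
    flow: dict[int, float] = {}

    def _flow(i: int) -> float:
        stack, post = [i], []
        while stack:
            v = stack.pop()
            post.append(v)
            stack.extend(children[v])
        for v in reversed(post):
            flow[v] = sum(flow[c] for c in children[v]) if children[v] else 1.0
        return flow[i]

    _flow(1)

    # embedding: outlet points straight up; children split +/-35 degrees
    coords: dict[int, tuple[float, float, float, float]] = {}
    angle: dict[int, float] = {1: np.pi / 2}
    start: dict[int, tuple[float, float]] = {1: (0.0, 0.0)}
    stack = [1]
    while stack:
        v = stack.pop()
        x0, y0 = start[v]
        th = angle[v]
        x1 = x0 + lengths[v] * np.cos(th)
        y1 = y0 + lengths[v] * np.sin(th)
        coords[v] = (x0, y0, x1, y1)
        kids = children[v]
        for c, da in zip(kids, (+_BRANCH_ANGLE, -_BRANCH_ANGLE)):
            angle[c] = th + da
            start[c] = (x1, y1)
            stack.append(c)

    segs = [Segment(id=i, downstream_id=downstream[i], length=lengths[i],
                    flow=flow[i], x0=coords[i][0], y0=coords[i][1],
                    x1=coords[i][2], y1=coords[i][3])
            for i in range(1, n_seg + 1)]
    return StreamNetwork(segs, use_sqrt_weights=use_sqrt_weights)


# ------------------------------------------------------- point-pair queries
def _singleton(p: NetworkPoint) -> NetworkPointSet:
    return NetworkPointSet([p.segment_id], [p.updist], [p.cx], [p.cy])


def flow_connected(p: NetworkPoint, q: NetworkPoint, net: StreamNetwork) -> str:
    """``"connected"`` if water flows between p and q, else ``"unconnected"``."""
    i, j = np.array([p.segment_id - 1]), np.array([q.segment_id - 1])
    conn = net.is_ancestor(i, j)[0] or net.is_ancestor(j, i)[0]
    return "connected" if conn else "unconnected"


def stream_distance(p: NetworkPoint, q: NetworkPoint, net: StreamNetwork) -> float:
    """Along-stream separation of two locations (any pair, via their junction)."""
    g = net.pairwise_geometry(_singleton(p), _singleton(q))
    return float(g.dist[0, 0])


def connection_weight(p: NetworkPoint, q: NetworkPoint, net: StreamNetwork) -> float:
    """Product of confluence weights ``pi`` between a flow-connected pair."""
    if flow_connected(p, q, net) != "connected":
        raise ValueError("weight undefined for flow-unconnected pair")
    g = net.pairwise_geometry(_singleton(p), _singleton(q))
    return float(g.pij[0, 0])


def sample_points(net: StreamNetwork, n: int, seed: int,
                  role: str = "observation") -> NetworkPointSet:
    """Length-weighted random locations on the network (see the method)."""
    return net.sample_points(n, seed, role=role)


def max_separation(points: NetworkPointSet, net: StreamNetwork) -> float:
    """Maximum pairwise stream distance ``v`` over a point set."""
    if len(points) < 2:
        raise ValueError("max_separation needs at least 2 points")
    g = net.pairwise_geometry(points, points)
    return float(g.dist.max())
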