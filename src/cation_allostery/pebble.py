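"""(6,6) pebble game on body-bar multigraphs.

Atoms (or abstract rigid bodies) carry six degrees of freedom each; a bond of
multiplicity m is processed as m independent bar insertions.  A bar is accepted
only when seven pebbles can be gathered on its two endpoints, which is exactly
the independence test of the (6,6)-sparsity matroid that characterises generic
body-bar rigidity in three dimensions (Tay's theorem).  The engine provides

* :func:`free_dof` — the number of pebbles collectable on an arbitrary body
  set, equal to the dimension of the projection of the framework's
  infinitesimal-motion space onto that set's coordinates;
* :func:`decompose` — rigid-cluster decomposition;
* :func:`oracle_dof` — an independent dense-linear-algebra oracle built from a
  generic rigidity matrix, used to verify the combinatorial engine.

All searches are deterministic: bodies are processed in ascending id and the
pebble search is depth-first with ascending neighbour order, so cluster labels
and DOF counts are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

K = 6  # pebbles per body
L = 6  # sparsity offset; a bar needs L+1 pebbles on its endpoints

Edge = Tuple[int, int, int]  # (u, v, multiplicity)


@dataclass
class RigidDecomposition:
    """Rigid-cluster labelling of a body-bar framework."""

    labels: Dict[int, int]
    n_clusters: int
    total_dof: int

    def clusters(self) -> Dict[int, List[int]]:
        out: Dict[int, List[int]] = {}
        for body, lab in self.labels.items():
            out.setdefault(lab, []).append(body)
        for members in out.values():
            members.sort()
        return out


class PebbleGame:
    """Mutable pebble-game state for one framework.

    Parameters
    ----------
    bodies:
        Iterable of integer body ids (need not be contiguous).
    edges:
        ``(u, v, multiplicity)`` triples; multiplicities in 1..6.
    """

    def __init__(self, bodies: Iterable[int], edges: Sequence[Edge]):
        self.bodies = sorted(set(bodies))
        if not self.bodies:
            raise ValueError("framework must contain at least one body")
        self._index = {b: i for i, b in enumerate(self.bodies)}
        n = len(self.bodies)
        self.pebbles = [K] * n
        # directed multigraph: out[u][v] = number of bars oriented u -> v
        self.out: List[Dict[int, int]] = [dict() for _ in range(n)]
        self.redundant = 0
        self.n_bars = 0
        for u, v, mult in sorted(
            ((min(a, b), max(a, b), m) for a, b, m in edges)
        ):
            if u == v:
                raise ValueError(f"self-edge on body {u}")
            if not 1 <= mult <= 6:
                raise ValueError(f"bar multiplicity {mult} outside 1..6")
            iu, iv = self._index[u], self._index[v]
            for _ in range(mult):
                self._insert_bar(iu, iv)

    # -- internal machinery -------------------------------------------------

    def _find_pebble(self, start: int, forbidden: frozenset) -> List[int] | None:
        """DFS from `start` along directed bars to a vertex outside
        `forbidden` holding a free pebble; returns the path or None."""
        stack = [start]
        parent = {start: -1}
        while stack:
            v = stack.pop()
            if v != start and v not in forbidden and self.pebbles[v] > 0:
                path = [v]
                while parent[path[-1]] != -1:
                    path.append(parent[path[-1]])
                path.reverse()
                return path  # start ... v
            for w in sorted(self.out[v], reverse=True):
                if w not in parent:
                    parent[w] = v
                    stack.append(w)
        return None

    def _move_pebble(self, path: List[int]) -> None:
        """Bring the free pebble at path[-1] to path[0], reversing bars."""
        for a, b in zip(path, path[1:]):
            # one bar a -> b gets reversed to b -> a
            self.out[a][b] -= 1
            if self.out[a][b] == 0:
                del self.out[a][b]
            self.out[b][a] = self.out[b].get(a, 0) + 1
        self.pebbles[path[-1]] -= 1
        self.pebbles[path[0]] += 1

    def _gather_pair(self, iu: int, iv: int, want: int) -> bool:
        forbidden = frozenset((iu, iv))
        while self.pebbles[iu] + self.pebbles[iv] < want:
            path = None
            if self.pebbles[iu] < K:
                path = self._find_pebble(iu, forbidden)
            if path is None and self.pebbles[iv] < K:
                path = self._find_pebble(iv, forbidden)
            if path is None:
                return False
            self._move_pebble(path)
        return True

    def _insert_bar(self, iu: int, iv: int) -> None:
        if self._gather_pair(iu, iv, L + 1):
            payer = iu if self.pebbles[iu] > 0 else iv
            other = iv if payer == iu else iu
            self.pebbles[payer] -= 1
            self.out[payer][other] = self.out[payer].get(other, 0) + 1
            self.n_bars += 1
        else:
            self.redundant += 1

    # -- queries ------------------------------------------------------------

    def copy(self) -> "PebbleGame":
        clone = object.__new__(PebbleGame)
        clone.bodies = self.bodies
        clone._index = self._index
        clone.pebbles = list(self.pebbles)
        clone.out = [dict(d) for d in self.out]
        clone.redundant = self.redundant
        clone.n_bars = self.n_bars
        return clone

    def collect_on(self, site: Sequence[int], stop_at: int | None = None) -> int:
        """Maximum number of pebbles collectable on `site` (mutates state).

        Pebbles already on site bodies count; further pebbles are retrieved
        from outside the site only.  `stop_at` allows early exit (used for the
        7-pebble co-rigidity test).
        """
        idx = []
        for b in site:
            if b not in self._index:
                raise KeyError(f"unknown body id {b}")
            idx.append(self._index[b])
        idx = sorted(set(idx))
        forbidden = frozenset(idx)
        total = sum(self.pebbles[i] for i in idx)
        progress = True
        while progress and (stop_at is None or total < stop_at):
            progress = False
            for i in idx:
                if stop_at is not None and total >= stop_at:
                    break
                while self.pebbles[i] < K:
                    path = self._find_pebble(i, forbidden)
                    if path is None:
                        break
                    self._move_pebble(path)
                    total += 1
                    progress = True
                    if stop_at is not None and total >= stop_at:
                        break
        return total

    def total_dof(self) -> int:
        return K * len(self.bodies) - self.n_bars


def _as_graph(network) -> Tuple[List[int], List[Edge]]:
    """Accept either (bodies, edges) raw data or an object exposing
    `.body_bar()` (e.g. structure_io.ConstraintNetwork)."""
    if hasattr(network, "body_bar"):
        return network.body_bar()
    bodies, edges = network
    return list(bodies), list(edges)


def build_game(network) -> PebbleGame:
    bodies, edges = _as_graph(network)
    return PebbleGame(bodies, edges)


def free_dof(network, site: Sequence[int]) -> int:
    """Conformational degrees of freedom available to `site`.

    Equals the dimension of the projection of the framework's infinitesimal
    motion space onto the site bodies' 6-per-body coordinates.  For any site
    in a connected framework this is at least 6 (rigid-body motions).
    """
    if not site:
        raise ValueError("site must be non-empty")
    game = build_game(network)
    return game.collect_on(site)


def decompose(network) -> RigidDecomposition:
    """Rigid-cluster decomposition.

    Two bodies are co-rigid when at most six pebbles can be gathered on the
    pair after all bars are inserted.  In the (6,6) matroid, rigid components
    are vertex-disjoint, connected subgraphs, so union-find over co-rigid
    *adjacent* pairs recovers the full decomposition; this is verified against
    the dense oracle in the test suite.
    """
    bodies, edges = _as_graph(network)
    game = PebbleGame(bodies, edges)

    parent = {b: b for b in bodies}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seen = set()
    for u, v, _ in edges:
        a, b = min(u, v), max(u, v)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        if find(a) == find(b):
            continue
        probe = game.copy()
        if probe.collect_on((a, b), stop_at=L + 1) <= L:
            parent[find(a)] = find(b)

    labels: Dict[int, int] = {}
    next_label = 0
    for b in sorted(bodies):
        root = find(b)
        if root not in labels:
            labels[root] = next_label
            next_label += 1
    return RigidDecomposition(
        labels={b: labels[find(b)] for b in bodies},
        n_clusters=next_label,
        total_dof=game.total_dof(),
    )


# ---------------------------------------------------------------------------
# Independent oracle: generic rigidity matrix + null-space projection
# ---------------------------------------------------------------------------

def _rigidity_matrix(bodies, edges, rng) -> np.ndarray:
    """Generic body-bar rigidity matrix.

    Each bar attaches at random generic points a (on u) and b (on v); the row
    enforces d·(v_a − v_b) = 0 with d = a − b, where the velocity of a point p
    on body u with motion (t_u, ω_u) is t_u + ω_u × p.
    """
    index = {b: i for i, b in enumerate(bodies)}
    n = len(bodies)
    rows = []
    for u, v, mult in edges:
        iu, iv = index[u], index[v]
        for _ in range(mult):
            a = rng.uniform(-1.0, 1.0, 3)
            b = rng.uniform(-1.0, 1.0, 3)
            d = a - b
            row = np.zeros(6 * n)
            row[6 * iu : 6 * iu + 3] = d
            row[6 * iu + 3 : 6 * iu + 6] = np.cross(a, d)
            row[6 * iv : 6 * iv + 3] = -d
            row[6 * iv + 3 : 6 * iv + 6] = -np.cross(b, d)
            rows.append(row)
    if not rows:
        return np.zeros((0, 6 * n))
    return np.asarray(rows)


def _oracle_once(bodies, edges, site, rng) -> int:
    from scipy.linalg import null_space

    n = len(bodies)
    R = _rigidity_matrix(bodies, edges, rng)
    if R.shape[0] == 0:
        N = np.eye(6 * n)
    else:
        N = null_space(R, rcond=1e-10)
    index = {b: i for i, b in enumerate(bodies)}
    rows = []
    for b in sorted(set(site)):
        i = index[b]
        rows.extend(range(6 * i, 6 * i + 6))
    P = N[rows, :]
    if P.size == 0:
        return 0
    return int(np.linalg.matrix_rank(P, tol=1e-8))


def oracle_dof(network, site: Sequence[int], seed: int = 0) -> int:
    """Dense-algebra DOF count for `site` (verification oracle).

    Builds three independent generic realizations of the bar framework,
    computes each null space's projection rank onto the site's coordinate
    block, and returns the majority value (guards against accidental
    non-generic rank drops).  Intended for frameworks of ≲60 bodies.
    """
    bodies, edges = _as_graph(network)
    vals = []
    for k in range(3):
        rng = np.random.default_rng(seed * 1000 + 17 * k + 1)
        vals.append(_oracle_once(bodies, edges, site, rng))
    vals.sort()
    return vals[1]


def oracle_total_dof(network, seed: int = 0) -> int:
    bodies, _ = _as_graph(network)
    return oracle_dof(network, bodies, seed=seed)
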