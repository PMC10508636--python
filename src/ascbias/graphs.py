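"""Admixture graphs: representation, exhaustive enumeration, prediction, fitting.

An admixture graph is a rooted DAG whose leaves are populations, whose
ordinary ("drift") edges carry lengths in f2 units, and whose admixture nodes
have exactly two parents with mixing proportions alpha and 1 - alpha (the two
in-edges of an admixture node carry no drift).  Expected f2 between two
leaves A, B is

    f2(A, B) = sum over drift edges e of len(e) * (wA(e) - wB(e))^2

where wX(e) is the probability that a lineage sampled in X traverses e
(products of mixing proportions summed over paths).  Graphs are fitted to
observed block-f2 data by minimising the quadratic form

    q(theta) = (f_obs - f_exp(theta))' Q^{-1} (f_obs - f_exp(theta))

over a full-rank basis of f3-statistics anchored at a reference population,
with Q the block-jackknife covariance of the basis (ridge-regularised).  The
reported fit quality is the minimised q ("LL score") and the worst residual
WR: the largest |observed - fitted| f4 deviation in jackknife-SE units,
scanned over *all* f4-statistics including their f2/f3 specialisations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize, nnls

from .fstats import F2Blocks, jackknife_cov

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureGraph:
    """Leaf-labeled admixture graph with optional parameters.

    ``edges`` is a list of (parent, child) pairs.  A node with two in-edges
    is an admixture node; ``alphas`` maps an admixture node to the mixing
    proportion of its *first* listed parent.  ``lengths`` maps edges to
    f2-unit drift lengths (every edge may carry drift, see ``drift_edges``).
    """

    edges: list[tuple[str, str]]
    lengths: dict[tuple[str, str], float] = field(default_factory=dict)
    alphas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [tuple(e) for e in self.edges]
        self._parents: dict[str, list[str]] = {}
        self._children: dict[str, list[str]] = {}
        for p, c in self.edges:
            self._parents.setdefault(c, []).append(p)
            self._children.setdefault(p, []).append(c)
            self._parents.setdefault(p, [])
            self._children.setdefault(c, [])
        roots = [n for n, ps in self._parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {roots}")
        self._root = roots[0]
        for n, ps in self._parents.items():
            if len(ps) > 2:
                raise ValueError(f"node {n} has {len(ps)} parents")
        if self._has_cycle():
            raise ValueError("graph is cyclic")

    def _has_cycle(self) -> bool:
        state: dict[str, int] = {}
        for start in self._children:
            if state.get(start):
                continue
            stack = [(start, iter(self._children.get(start, ())))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if state.get(nxt) == 1:
                        return True
                    if not state.get(nxt):
                        state[nxt] = 1
                        stack.append((nxt, iter(self._children.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    stack.pop()
        return False

    # -- structure -------------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> list[str]:
        return sorted(self._parents)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n, cs in self._children.items() if not cs)

    @property
    def admixture_nodes(self) -> list[str]:
        return sorted(n for n, ps in self._parents.items() if len(ps) == 2)

    @property
    def n_admixture(self) -> int:
        return len(self.admixture_nodes)

    def parents(self, node: str) -> list[str]:
        return list(self._parents[node])

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    @property
    def drift_edges(self) -> list[tuple[str, str]]:
        """Edges that carry drift.

        Every edge carries a length, including the in-edges of admixture
        nodes: drift accumulated on a parent lineage between its attachment
        point and the admixture event lives on that in-edge.  (This is
        equivalent to the zero-length-admixture-edge convention with explicit
        pre-admixture parent nodes, with fewer bookkeeping nodes.)
        """
        return list(self.edges)

    def topological_order(self) -> list[str]:
        order, seen = [], set()
        def visit(n):
            if n in seen:
                return
            seen.add(n)
            for p in self._parents[n]:
                visit(p)
            order.append(n)
        for n in sorted(self._parents):
            visit(n)
        return order

    # -- parameters ------------------------------------------------------

    def with_parameters(self, lengths: dict, alphas: dict) -> "AdmixtureGraph":
        return AdmixtureGraph(list(self.edges), dict(lengths), dict(alphas))

    def require_parameters(self) -> None:
        for e in self.drift_edges:
            if e not in self.lengths:
                raise ValueError(f"unset length for drift edge {e}")
        for m in self.admixture_nodes:
            if m not in self.alphas:
                raise ValueError(f"unset mixing proportion for {m}")

    # -- canonical form --------------------------------------------------

    def canonical_key(self, leaf_order: list[str] | None = None):
        return _canon_key(self.edges, leaf_order or self.leaves)

    # -- traversal weights and expected f2 -------------------------------

    def path_weights(self, leaf: str) -> dict[tuple[str, str], float]:
        """wX(e): probability a lineage from ``leaf`` traverses each edge."""
        prob = {n: 0.0 for n in self._parents}
        prob[leaf] = 1.0
        w: dict[tuple[str, str], float] = {}
        # propagate upward in reverse topological order (leaves first)
        order = self.topological_order()
        for n in reversed(order):
            ps = self._parents[n]
            if not ps:
                continue
            if len(ps) == 1:
                w[(ps[0], n)] = w.get((ps[0], n), 0.0) + prob[n]
                prob[ps[0]] += prob[n]
            else:
                a = self.alphas.get(n)
                if a is None:
                    raise ValueError(f"unset mixing proportion for {n}")
                shares = (a, 1.0 - a)
                for p, s in zip(ps, shares):
                    w[(p, n)] = w.get((p, n), 0.0) + s * prob[n]
                    prob[p] += s * prob[n]
        return w

    def expected_f2(self, a: str, b: str) -> float:
        wa = self.path_weights(a)
        wb = self.path_weights(b)
        total = 0.0
        for e in self.drift_edges:
            diff = wa.get(e, 0.0) - wb.get(e, 0.0)
            if diff:
                total += self.lengths[e] * diff * diff
        return total

    def expected_f2_matrix(self, leaves: list[str] | None = None) -> np.ndarray:
        """Pairwise expected f2 among ``leaves`` (default: all leaves)."""
        self.require_parameters()
        lv = leaves or self.leaves
        ws = {x: self.path_weights(x) for x in lv}
        de = self.drift_edges
        lens = np.array([self.lengths[e] for e in de])
        W = np.array([[ws[x].get(e, 0.0) for e in de] for x in lv])
        diff = W[:, None, :] - W[None, :, :]
        return np.einsum("ijk,k->ij", diff ** 2, lens)

    # -- text format -----------------------------------------------------

    def to_text(self) -> str:
        adm = set(self.admixture_nodes)
        lines = []
        for p, c in self.edges:
            if c in adm:
                ps = self._parents[c]
                a = self.alphas.get(c)
                w = "" if a is None else (f"\t{a:.6g}" if ps[0] == p else f"\t{1-a:.6g}")
                lines.append(f"{p}\t{c}\tadmix{w}")
            else:
                ln = self.lengths.get((p, c))
                w = "" if ln is None else f"\t{ln:.8g}"
                lines.append(f"{p}\t{c}\tdrift{w}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AdmixtureGraph":
        edges, lengths, alphas = [], {}, {}
        admix_first: dict[str, str] = {}
        for line in text.strip().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            p, c, kind = parts[0], parts[1], parts[2]
            edges.append((p, c))
            if kind == "drift" and len(parts) > 3:
                lengths[(p, c)] = float(parts[3])
            elif kind == "admix" and len(parts) > 3 and c not in admix_first:
                admix_first[c] = p
                alphas[c] = float(parts[3])
        return cls(edges, lengths, alphas)

    @classmethod
    def from_qpgraph(cls, text: str) -> "AdmixtureGraph":
        """Read the common qpGraph text layout (root/label/edge/admix lines)."""
        edges, lengths, alphas = [], {}, {}
        for line in text.strip().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "edge":
                _, _, p, c = parts[:4]
                edges.append((p, c))
                if len(parts) > 4:
                    lengths[(p, c)] = float(parts[4])
            elif parts[0] == "admix":
                c, p1, p2 = parts[1:4]
                edges.append((p1, c))
                edges.append((p2, c))
                if len(parts) > 4:
                    w = float(parts[4])
                    alphas[c] = w / 100.0 if w > 1 else w
        return cls(edges, lengths, alphas)


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

def _canon_key(edges, leaf_labels):
    """Canonical form of a directed graph with leaf colors fixed (BLISS)."""
    nodes = sorted({x for e in edges for x in e}, key=str)
    idx = {n: k for k, n in enumerate(nodes)}
    label_ix = {lab: i for i, lab in enumerate(leaf_labels)}
    colors = [1 + label_ix[n] if n in label_ix else 0 for n in nodes]
    g = ig.Graph(directed=True)
    g.add_vertices(len(nodes))
    g.add_edges([(idx[p], idx[c]) for p, c in edges])
    perm = g.canonical_permutation(color=colors)
    g2 = g.permute_vertices(perm)
    cols = [0] * len(nodes)
    for n, k in idx.items():
        cols[perm[k]] = colors[k]
    return (tuple(sorted(g2.get_edgelist())), tuple(cols))


# ---------------------------------------------------------------------------
# exhaustive topology enumeration
# ---------------------------------------------------------------------------

@dataclass
class TopologyCatalog:
    """Deduplicated catalog of admixture graph topologies."""

    n_leaves: int
    n_admix: int
    graphs: list[AdmixtureGraph]
    convention: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)

    def __getitem__(self, i):
        return self.graphs[i]


def _rooted_trees(labels):
    """All rooted binary leaf-labeled trees (edge lists); (2n-3)!! of them."""
    trees = [[("R", labels[0]), ("R", labels[1])]]
    for step, lab in enumerate(labels[2:]):
        nxt = []
        for t in trees:
            children = {c for _, c in t}
            cur_root = next(p for p, _ in t if p not in children)
            for i, (p, c) in enumerate(t):
                nid = f"n{step}_{i}"
                nxt.append([e for j, e in enumerate(t) if j != i]
                           + [(p, nid), (nid, c), (nid, lab)])
            nid = f"n{step}_r"
            nxt.append([(nid, cur_root), (nid, lab)] + list(t))
        trees = nxt
    return trees


def _descendants(edges):
    adj: dict[str, list[str]] = {}
    for p, c in edges:
        adj.setdefault(p, []).append(c)
    memo: dict[str, set] = {}
    def desc(x):
        if x not in memo:
            out = set()
            for y in adj.get(x, ()):
                out.add(y)
                out |= desc(y)
            memo[x] = out
        return memo[x]
    return desc


def _admixture_insertions(edges, leaves, tag, source_attachment="node"):
    """All single-admixture-event insertions into a graph.

    ``node`` attachment: a new admixture node subdivides a destination edge
    and receives its second in-edge from an existing internal node.
    ``edge`` attachment: the source is a new node subdividing a source edge
    (finer convention; kept as a knob).
    """
    out = []
    desc = _descendants(edges)
    leafset = set(leaves)
    if source_attachment == "node":
        internal = sorted({x for e in edges for x in e} - leafset, key=str)
        for j, (p2, c2) in enumerate(edges):
            for s in internal:
                # s below the new admixture node would create a cycle
                if s == p2 or s == c2 or s in desc(c2):
                    continue
                m = f"m{tag}"
                ne = [e for k, e in enumerate(edges) if k != j]
                ne += [(p2, m), (m, c2), (s, m)]
                out.append(ne)
    elif source_attachment == "edge":
        n = len(edges)
        for i, j in itertools.permutations(range(n), 2):
            p1, c1 = edges[i]
            p2, c2 = edges[j]
            if c2 == p1 or p1 in desc(c2):
                continue
            u, v = f"u{tag}", f"v{tag}"
            ne = [e for k, e in enumerate(edges) if k not in (i, j)]
            ne += [(p1, u), (u, c1), (p2, v), (v, c2), (u, v)]
            out.append(ne)
    else:
        raise ValueError(source_attachment)
    return out


def _has_duplicate_admixture(edges) -> bool:
    """Two admixture nodes drawing from an identical, non-adjacent parent pair.

    Such "double admixture" between the same pair of ancestor lineages spans
    the same model space as a chained configuration and is not counted as a
    distinct topology (parents joined by a drift edge are exempt: there the
    two events tap genuinely different points of the genealogy).
    """
    parents: dict[str, list[str]] = {}
    for p, c in edges:
        parents.setdefault(c, []).append(p)
    admix = [n for n, ps in parents.items() if len(ps) == 2]
    eset = set(edges)
    for a, b in itertools.combinations(admix, 2):
        if set(parents[a]) == set(parents[b]):
            x, y = parents[a]
            if (x, y) not in eset and (y, x) not in eset:
                return True
    return False


def enumerate_topologies(n_leaves: int, n_admix: int,
                         labels: list[str] | None = None,
                         source_attachment: str = "node",
                         exclude_duplicate_admixture: bool = True,
                         max_graphs: int = 2_000_000) -> TopologyCatalog:
    """Exhaustively enumerate admixture graph topologies, deduplicated.

    Graphs are generated from all rooted binary leaf-labeled trees by
    repeatedly inserting admixture events, and deduplicated by color-aware
    directed-graph isomorphism with leaf labels fixed.  The default
    convention (node-attached sources, duplicate admixture events between an
    identical parent pair counted once) reproduces the published exhaustive
    catalog size of 32,745 for five leaves and two admixture events.

    Intended for small problems (<= 6 leaves, <= 2 admixture events).
    """
    if labels is None:
        labels = [f"P{i+1}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")
    if n_leaves < 2:
        raise ValueError("need at least two leaves")

    seen = set()
    level = []
    for t in _rooted_trees(labels):
        k = _canon_key(t, labels)
        if k not in seen:
            seen.add(k)
            level.append(t)
    for a in range(n_admix):
        seen = set()
        nxt = []
        for g in level:
            for ng in _admixture_insertions(g, labels, a, source_attachment):
                if exclude_duplicate_admixture and _has_duplicate_admixture(ng):
                    continue
                k = _canon_key(ng, labels)
                if k not in seen:
                    seen.add(k)
                    nxt.append(ng)
                    if len(nxt) > max_graphs:
                        raise RuntimeError("combinatorial limit exceeded")
        level = nxt
        logger.info("enumeration: %d graphs after %d admixture events",
                    len(level), a + 1)

    # deterministic ordering by canonical key
    keyed = sorted((( _canon_key(g, labels), g) for g in level), key=lambda x: x[0])
    graphs = [AdmixtureGraph(g) for _, g in keyed]
    return TopologyCatalog(
        n_leaves=n_leaves, n_admix=n_admix, graphs=graphs,
        convention={"source_attachment": source_attachment,
                    "exclude_duplicate_admixture": exclude_duplicate_admixture,
                    "dedup": "bliss-canonical-leaf-colored"})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GraphFit:
    """Result of fitting one topology to block-f2 data."""

    graph: AdmixtureGraph
    ll: float
    wr: float
    worst_f4: tuple | None
    lengths: dict
    alphas: dict
    n_restarts: int
    converged: bool

    def summary(self) -> dict:
        return {"ll": self.ll, "wr": self.wr,
                "worst_f4": self.worst_f4, "converged": self.converged}


def _f3_basis(pops: list[str], ref: str):
    others = [p for p in pops if p != ref]
    return [(ref, a, b) for i, a in enumerate(others) for b in others[i:]]


def _basis_blocks(f2b: F2Blocks, basis) -> np.ndarray:
    cols = []
    for ref, a, b in basis:
        cols.append(0.5 * (f2b.block_f2(ref, a) + f2b.block_f2(ref, b)
                           - f2b.block_f2(a, b)))
    return np.stack(cols, axis=1)


def _expected_basis_design(graph: AdmixtureGraph, basis, alphas: dict):
    """Design matrix mapping drift-edge lengths to expected basis f3 values."""
    g = graph.with_parameters({e: 0.0 for e in graph.drift_edges}, alphas)
    de = g.drift_edges
    leaves = g.leaves
    ws = {x: g.path_weights(x) for x in leaves}
    W = {x: np.array([ws[x].get(e, 0.0) for e in de]) for x in leaves}
    rows = []
    for ref, a, b in basis:
        rows.append((W[ref] - W[a]) * (W[ref] - W[b]))
    return np.vstack(rows), de


def fit_graph(graph: AdmixtureGraph, f2b: F2Blocks, numstart: int = 100,
              diag: float = 0.0001, seed: int = 0,
              diag_absolute: bool = False,
              cov_mode: str = "auto",
              compute_wr: bool = True,
              starts: np.ndarray | None = None) -> GraphFit:
    """Fit drift lengths and mixing proportions of a topology to f2 data.

    The objective is the inverse-covariance-weighted quadratic form over the
    f3 basis anchored at the first fitted population; drift lengths are
    solved by non-negative least squares given the mixing proportions, and
    proportions are optimised from ``numstart`` random restarts.  ``diag``
    ridge-regularises the jackknife covariance (relative to its mean
    diagonal by default).

    ``cov_mode`` selects the weighting: "full" uses the complete jackknife
    covariance, "diagonal" only its diagonal (per-statistic variances), and
    "auto" (default) falls back to the diagonal when there are too few
    blocks to estimate a full-rank covariance (n_blocks < n_stats + 3).
    """
    pops = [p for p in f2b.populations if p in set(graph.leaves)]
    missing = set(graph.leaves) - set(pops)
    if missing:
        raise ValueError(f"populations missing from f2 data: {sorted(missing)}")
    ref = pops[0]
    basis = _f3_basis(pops, ref)
    Y = _basis_blocks(f2b, basis)
    w = f2b.weights
    y = (w @ Y) / w.sum()
    Q = jackknife_cov(Y, w)
    if cov_mode == "auto":
        cov_mode = "full" if f2b.n_blocks >= len(basis) + 3 else "diagonal"
    if cov_mode == "diagonal":
        Q = np.diag(np.diag(Q))
    elif cov_mode != "full":
        raise ValueError(f"unknown cov_mode: {cov_mode}")
    if diag_absolute:
        ridge = diag
    else:
        mean_diag = float(np.mean(np.diag(Q)))
        scale = float(np.mean(y ** 2))
        # degenerate (noise-free) covariance: fall back to the data scale
        if mean_diag <= 1e-12 * max(scale, 1e-300):
            mean_diag = max(scale, 1e-12)
        ridge = diag * mean_diag
    Q = Q + ridge * np.eye(len(basis))
    L = cholesky(Q, lower=True)
    y_w = solve_triangular(L, y, lower=True)

    admix = graph.admixture_nodes
    k = len(admix)
    rng = np.random.default_rng(seed)

    def objective(alpha_vec):
        alphas = dict(zip(admix, np.clip(alpha_vec, 1e-4, 1 - 1e-4)))
        X, de = _expected_basis_design(graph, basis, alphas)
        A = solve_triangular(L, X, lower=True)
        try:
            b, rnorm = nnls(A, y_w)
        except RuntimeError:  # pragma: no cover - nnls non-convergence
            return np.inf, None, None
        return rnorm ** 2, dict(zip(de, b)), alphas

    best = (np.inf, None, None)
    converged = True
    if k == 0:
        best = objective(np.empty(0))
        n_try = 1
    else:
        start_list = None if starts is None else np.atleast_2d(starts)
        n_try = len(start_list) if start_list is not None else max(1, numstart)
        for t in range(n_try):
            a0 = (start_list[t] if start_list is not None
                  else rng.uniform(0.05, 0.95, size=k))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = minimize(lambda a: objective(a)[0], a0, method="L-BFGS-B",
                               bounds=[(1e-4, 1 - 1e-4)] * k,
                               options={"maxiter": 200})
            val, lens, alphas = objective(res.x)
            if val < best[0]:
                best = (val, lens, alphas)
        if not np.isfinite(best[0]):
            converged = False

    ll, lengths, alphas = best
    fitted = graph.with_parameters(lengths or {}, alphas or {})

    wr, worst = np.nan, None
    if compute_wr and lengths is not None:
        wr, worst = worst_residual(fitted, f2b, pops)
    return GraphFit(graph=fitted, ll=float(ll), wr=float(wr), worst_f4=worst,
                    lengths=lengths or {}, alphas=alphas or {},
                    n_restarts=n_try, converged=converged)


def _jack_many(values: np.ndarray, weights: np.ndarray):
    """Vectorised weighted jackknife over many statistics (shared weights)."""
    ok = weights > 0
    V, w = values[ok], weights[ok].astype(float)
    g = len(w)
    n = w.sum()
    total = w @ V
    est = total / n
    loo = (total[None, :] - V * w[:, None]) / (n - w)[:, None]
    h = n / w
    theta_j = g * est - np.sum((1.0 - w / n)[:, None] * loo, axis=0)
    tau = h[:, None] * est[None, :] - (h - 1.0)[:, None] * loo
    var = np.sum((tau - theta_j[None, :]) ** 2 / (h - 1.0)[:, None], axis=0) / g
    return est, np.sqrt(var)


def all_f4_quadruples(pops: list[str]):
    """All distinct f4 statistics up to symmetry, incl. f2/f3 specialisations.

    Quadruples (a, b; c, d) with four distinct populations (three pairings
    per 4-subset), f3-type (t, a; t, b), and f2-type (a, b; a, b).
    """
    quads = []
    for four in itertools.combinations(pops, 4):
        a, b, c, d = four
        quads += [(a, b, c, d), (a, c, b, d), (a, d, b, c)]
    for t, a, b in ((t, a, b) for t in pops
                    for a, b in itertools.combinations([p for p in pops if p != t], 2)):
        quads.append((t, a, t, b))
    for a, b in itertools.combinations(pops, 2):
        quads.append((a, b, a, b))
    return quads


def worst_residual(fitted: AdmixtureGraph, f2b: F2Blocks, pops: list[str]):
    """Largest |observed - fitted| f4 deviation in jackknife-SE units."""
    quads = all_f4_quadruples(pops)
    lv = list(pops)
    exp_f2 = fitted.expected_f2_matrix(lv)
    ix = {p: i for i, p in enumerate(lv)}

    obs_blocks = np.stack([f2b.block_f4(*q) for q in quads], axis=1)
    est, se = _jack_many(obs_blocks, f2b.weights)
    pred = np.array([
        0.5 * (exp_f2[ix[a], ix[d]] + exp_f2[ix[b], ix[c]]
               - exp_f2[ix[a], ix[c]] - exp_f2[ix[b], ix[d]])
        for a, b, c, d in quads
    ])
    # floor the SE at numerical precision so that noise-free data do not
    # turn rounding residuals into huge Z-scores
    floor = 1e-7 * max(float(np.max(np.abs(est))), 1e-300)
    se_eff = np.maximum(se, floor)
    z = np.abs(est - pred) / se_eff
    i = int(np.nanargmax(z))
    return float(z[i]), quads[i]


def alpha_jackknife(graph: AdmixtureGraph, f2b: F2Blocks, node: str,
                    numstart: int = 10, diag: float = 0.0001,
                    seed: int = 0) -> tuple[float, float]:
    """Block-jackknife estimate and SE of one mixing proportion.

    Fits the full data, then refits each leave-one-block-out dataset
    warm-started at the full-data optimum; the weighted jackknife over the
    leave-one-out alphas gives the SE.
    """
    full = fit_graph(graph, f2b, numstart=numstart, diag=diag, seed=seed,
                     compute_wr=False)
    admix = graph.admixture_nodes
    a_hat = np.array([full.alphas[m] for m in admix])
    loo = []
    for j in range(f2b.n_blocks):
        sub = f2b.drop_block(j)
        refit = fit_graph(graph, sub, diag=diag, seed=seed, compute_wr=False,
                          starts=a_hat)
        loo.append(refit.alphas[node])
    loo = np.array(loo)
    w = f2b.weights.astype(float)
    g = len(w)
    n = w.sum()
    est = float(full.alphas[node])
    h = n / w
    theta_j = g * est - np.sum((1.0 - w / n) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return est, float(np.sqrt(var))


def sample_incorrect_graphs(catalog: TopologyCatalog, lls: np.ndarray,
                            ll_range=(70.0, 300.0), k: int = 100,
                            seed: int = 0) -> list[int]:
    """Pick k topologies whose (unascertained) LL lies in ``ll_range``.

    Stands in for a heuristic-search-derived set of plausible-but-wrong
    graphs; returns catalog indices.  If fewer than k qualify, all are
    returned with a warning.
    """
    lls = np.asarray(lls, dtype=float)
    lo, hi = ll_range
    pool = np.flatnonzero((lls >= lo) & (lls <= hi))
    if pool.size == 0:
        logger.warning("no graphs with LL in [%g, %g]", lo, hi)
        return []
    if pool.size <= k:
        if pool.size < k:
            logger.warning("only %d graphs in LL range (requested %d)",
                           pool.size, k)
        return [int(i) for i in pool]
    rng = np.random.default_rng(seed)
    return [int(i) for i in rng.choice(pool, size=k, replace=False)]
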