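"""Felsenstein pruning likelihoods, discrete-gamma rate classes, and
distance-based trees.

The pruning pass is vectorised over alignment columns: partial likelihoods
are (n_columns, n_states) arrays per node, rescaled per column with the log
scale factors tracked separately, so deep trees and many columns never
underflow.  Gaps and ambiguity codes enter as all-ones partial vectors
(missing data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .alignment import AnnotatedAlignment
from .substitution import ReversibleModel, transition_probabilities
from .tree import CompiledTree, Phylogeny

__all__ = [
    "RateClassModel",
    "discrete_gamma_rates",
    "column_log_likelihood",
    "alignment_log_likelihood",
    "per_column_log_likelihoods",
    "fit_gamma_shape",
    "assign_rate_classes",
    "total_log_likelihood",
    "pairwise_ml_distance",
    "distance_matrix",
    "write_distance_tsv",
    "read_distance_tsv",
    "build_ls_tree",
    "optimize_branch_lengths",
]

MAX_DISTANCE = 20.0


@dataclass(eq=False)
class RateClassModel:
    """Discrete-gamma rate classes with per-column assignments.

    ``class_rates`` are the means of k equal-probability gamma categories
    (shape ``alpha``, mean 1), renormalized to average exactly 1;
    ``column_assignment`` holds the most probable class per column.
    """

    n_classes: int
    shape: float
    class_rates: np.ndarray
    column_assignment: np.ndarray
    soft: bool = False  # integrate over classes instead of conditioning

    def subset(self, column_idx: np.ndarray) -> "RateClassModel":
        return RateClassModel(
            n_classes=self.n_classes,
            shape=self.shape,
            class_rates=self.class_rates,
            column_assignment=self.column_assignment[column_idx],
            soft=self.soft,
        )


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Category means of the k equal-probability discrete-gamma classes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    # X ~ Gamma(shape=alpha, scale=1/alpha); category mean over quantile bins
    edges = stats.gamma.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    upper = special.gammainc(alpha + 1, edges[1:] * alpha)
    lower = special.gammainc(alpha + 1, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# pruning


def _leaf_partials(codes: np.ndarray, n_states: int) -> np.ndarray:
    """(n_cols, n_states) partials for one row: one-hot, or ones if missing."""
    ncols = codes.shape[0]
    L = np.zeros((ncols, n_states))
    observed = codes >= 0
    L[observed, codes[observed].astype(int)] = 1.0
    L[~observed] = 1.0  # gap or ambiguity: missing data
    return L


def _branch_matrices(
    ct: CompiledTree, model: ReversibleModel, rate: float
) -> list[np.ndarray | None]:
    P: list[np.ndarray | None] = [None] * ct.n_nodes
    for v in range(ct.n_nodes):
        if ct.parent[v] >= 0:
            P[v] = transition_probabilities(model, ct.lengths[v] * rate)
    return P


def _down_pass(
    ct: CompiledTree,
    P: list[np.ndarray | None],
    leaf_L: dict[int, np.ndarray],
    n_states: int,
):
    """Postorder partial likelihoods with per-column log-scale tracking.

    Returns (partials, scales): lists indexed by node id; partials[v] is
    (n_cols, n_states), scales[v] is (n_cols,) accumulated log factors.
    """
    some = next(iter(leaf_L.values()))
    ncols = some.shape[0]
    partials: list[np.ndarray] = [None] * ct.n_nodes
    scales: list[np.ndarray] = [None] * ct.n_nodes
    for v in ct.postorder:
        v = int(v)
        if not ct.children[v]:
            partials[v] = leaf_L[v]
            scales[v] = np.zeros(ncols)
            continue
        L = np.ones((ncols, n_states))
        sc = np.zeros(ncols)
        for c in ct.children[v]:
            L = L * (partials[c] @ P[c].T)
            sc = sc + scales[c]
        m = L.max(axis=1)
        m[m <= 0] = 1.0
        L = L / m[:, None]
        partials[v] = L
        scales[v] = sc + np.log(m)
    return partials, scales


def _root_log_likelihoods(
    ct: CompiledTree, partials, scales, pi: np.ndarray
) -> np.ndarray:
    r = ct.root
    lik = partials[r] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + scales[r]


def _up_pass(ct: CompiledTree, P, partials, scales, pi: np.ndarray):
    """Preorder 'outside' vectors: out[v](a) is the likelihood of all data
    outside v's subtree as a function of the state at v's *parent* end,
    with the root prior folded in.  Scaled like the down pass."""
    ncols, n_states = partials[ct.root].shape
    out: list[np.ndarray] = [None] * ct.n_nodes
    oscales: list[np.ndarray] = [None] * ct.n_nodes
    out[ct.root] = np.broadcast_to(pi, (ncols, n_states)).copy()
    oscales[ct.root] = np.zeros(ncols)
    for v in ct.postorder[::-1]:
        v = int(v)
        kids = ct.children[v]
        if not kids:
            continue
        # outside likelihood as a function of the state AT v: propagate the
        # parent-side vector through v's own branch (prior already folded in
        # at the root)
        base = out[v] @ P[v] if ct.parent[v] >= 0 else out[v]
        for c in kids:
            G = base.copy()
            sc = oscales[v].copy()
            for s in kids:
                if s == c:
                    continue
                G = G * (partials[s] @ P[s].T)
                sc = sc + scales[s]
            m = G.max(axis=1)
            m[m <= 0] = 1.0
            G = G / m[:, None]
            out[c] = G
            oscales[c] = sc + np.log(m)
    return out, oscales


def _leaf_partial_map(
    ct: CompiledTree, aln: AnnotatedAlignment, column_idx: np.ndarray
) -> dict[int, np.ndarray]:
    n_states = aln.alphabet.size
    leaf_L = {}
    for name, node in ct.leaf_index.items():
        if name not in aln.names:
            raise ValueError(f"tree leaf {name!r} has no alignment row")
        leaf_L[node] = _leaf_partials(aln.row(name)[column_idx], n_states)
    return leaf_L


def per_column_log_likelihoods(
    aln: AnnotatedAlignment,
    tree: Phylogeny,
    model: ReversibleModel,
    rates: np.ndarray,
) -> np.ndarray:
    """(n_cols, len(rates)) pruning log-likelihoods, one column batch per rate."""
    ct = tree.compiled()
    all_cols = np.arange(aln.n_cols)
    leaf_L = _leaf_partial_map(ct, aln, all_cols)
    n_states = aln.alphabet.size
    out = np.empty((aln.n_cols, len(rates)))
    for c, rate in enumerate(np.asarray(rates, dtype=float)):
        P = _branch_matrices(ct, model, rate)
        partials, scales = _down_pass(ct, P, leaf_L, n_states)
        out[:, c] = _root_log_likelihoods(ct, partials, scales, model.pi)
    return out


def column_log_likelihood(
    column: dict[str, str] | np.ndarray,
    tree: Phylogeny,
    model: ReversibleModel,
    rate: float = 1.0,
    aln_names: list[str] | None = None,
) -> float:
    """Pruning log-likelihood of a single column.

    ``column`` maps leaf name -> one-letter symbol, or is a code array
    parallel to ``aln_names``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    ct = tree.compiled()
    n_states = model.alphabet.size
    if isinstance(column, dict):
        get = lambda name: model.alphabet.index(column[name])
    else:
        codes = np.asarray(column)
        get = lambda name: int(codes[aln_names.index(name)])
    leaf_L = {}
    for name, node in ct.leaf_index.items():
        leaf_L[node] = _leaf_partials(np.array([get(name)], dtype=np.int8), n_states)
    P = _branch_matrices(ct, model, rate)
    partials, scales = _down_pass(ct, P, leaf_L, n_states)
    return float(_root_log_likelihoods(ct, partials, scales, model.pi)[0])


def alignment_log_likelihood(
    aln: AnnotatedAlignment,
    tree: Phylogeny,
    model: ReversibleModel,
    rate_model: RateClassModel | None = None,
) -> float:
    """Total log-likelihood over columns.

    Hard rate models condition each column on its assigned class; soft rate
    models average the equal-probability class mixture.
    """
    if rate_model is None or rate_model.n_classes == 1:
        ll = per_column_log_likelihoods(aln, tree, model, np.ones(1))[:, 0]
        return float(ll.sum())
    ll = per_column_log_likelihoods(aln, tree, model, rate_model.class_rates)
    if rate_model.soft:
        k = rate_model.n_classes
        return float(special.logsumexp(ll - np.log(k), axis=1).sum())
    return float(ll[np.arange(aln.n_cols), rate_model.column_assignment].sum())


def total_log_likelihood(
    alns, trees, model, rate_models=None
) -> float:
    if rate_models is None:
        rate_models = [None] * len(alns)
    return sum(
        alignment_log_likelihood(a, t, model, rm)
        for a, t, rm in zip(alns, trees, rate_models)
    )


# ---------------------------------------------------------------------------
# discrete-gamma rate classes


def fit_gamma_shape(
    aln: AnnotatedAlignment,
    tree: Phylogeny,
    model: ReversibleModel,
    k: int,
    bounds: tuple[float, float] = (0.05, 50.0),
) -> float:
    """ML gamma shape under the k-class equal-probability mixture."""
    if k == 1:
        return np.inf

    def neg_mix_loglik(log_alpha: float) -> float:
        rates = discrete_gamma_rates(float(np.exp(log_alpha)), k)
        ll = per_column_log_likelihoods(aln, tree, model, rates)
        return -float(special.logsumexp(ll - np.log(k), axis=1).sum())

    res = optimize.minimize_scalar(
        neg_mix_loglik,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-3},
    )
    if not res.success:
        raise RuntimeError(f"gamma-shape optimization failed: {res.message}")
    return float(np.exp(res.x))


def assign_rate_classes(
    aln: AnnotatedAlignment,
    tree: Phylogeny,
    model: ReversibleModel,
    k: int,
    soft: bool = False,
) -> RateClassModel:
    """Fit the gamma shape and assign each column to its most probable class.

    Posterior over classes is proportional to (1/k) L(column | rate_c);
    ties resolve to the lower class index (np.argmax convention).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return RateClassModel(
            n_classes=1,
            shape=np.inf,
            class_rates=np.ones(1),
            column_assignment=np.zeros(aln.n_cols, dtype=int),
        )
    alpha = fit_gamma_shape(aln, tree, model, k)
    rates = discrete_gamma_rates(alpha, k)
    ll = per_column_log_likelihoods(aln, tree, model, rates)
    assignment = np.argmax(ll, axis=1)
    return RateClassModel(
        n_classes=k, shape=alpha, class_rates=rates,
        column_assignment=assignment, soft=soft,
    )


# ---------------------------------------------------------------------------
# pairwise distances and least-squares trees


def pairwise_ml_distance(
    row_a: np.ndarray, row_b: np.ndarray, model: ReversibleModel
) -> float:
    """ML evolutionary distance between two sequences under the model.

    Maximizes sum over shared non-missing sites of log(pi_a P(t)_{ab}) on
    t in [1e-6, 20]; saturated pairs are capped at 20 with a warning.
    """
    usable = (row_a >= 0) & (row_b >= 0)
    if int(usable.sum()) < 2:
        raise ValueError("fewer than 2 overlapping non-missing sites")
    n = model.size
    pair_counts = np.zeros((n, n))
    np.add.at(pair_counts, (row_a[usable].astype(int), row_b[usable].astype(int)), 1.0)
    log_pi = np.log(model.pi)

    def neg_loglik(t: float) -> float:
        P = transition_probabilities(model, t)
        with np.errstate(divide="ignore"):
            logP = np.where(P > 0, np.log(np.maximum(P, 1e-300)), -np.inf)
        return -float(np.sum(pair_counts * (log_pi[:, None] + logP)))

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(1e-6, MAX_DISTANCE), method="bounded",
        options={"xatol": 1e-8},
    )
    t = float(res.x)
    if t > MAX_DISTANCE * 0.999:
        warnings.warn("saturated pair: distance capped at 20")
        t = MAX_DISTANCE
    return t


def distance_matrix(
    aln: AnnotatedAlignment, model: ReversibleModel
) -> np.ndarray:
    d = np.zeros((aln.n_rows, aln.n_rows))
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            d[i, j] = d[j, i] = pairwise_ml_distance(
                aln.codes[i], aln.codes[j], model
            )
    return d


def write_distance_tsv(dist: np.ndarray, names: list[str], path=None) -> str:
    """Square distance matrix as TSV with a header row and name column."""
    lines = ["\t" + "\t".join(names)]
    for name, row in zip(names, np.asarray(dist, dtype=float)):
        lines.append(name + "\t" + "\t".join(f"{v:.10g}" for v in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        from pathlib import Path

        Path(path).write_text(text)
    return text


def read_distance_tsv(path_or_text) -> tuple[np.ndarray, list[str]]:
    from ._util import path_or_text as _pot

    rows = [ln.split("\t") for ln in _pot(path_or_text).splitlines() if ln.strip()]
    names = rows[0][1:]
    n = len(names)
    d = np.zeros((n, n))
    for i, row in enumerate(rows[1:]):
        if row[0] != names[i]:
            raise ValueError(f"row label {row[0]!r} != column label {names[i]!r}")
        d[i] = [float(v) for v in row[1:]]
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    return d, names


def _leaf_bitsets(ct: CompiledTree, leaf_order: list[str]) -> list[int]:
    pos = {ct.leaf_index[name]: k for k, name in enumerate(leaf_order)}
    bits = [0] * ct.n_nodes
    for v in ct.postorder:
        v = int(v)
        if not ct.children[v]:
            bits[v] = 1 << pos[v]
        else:
            b = 0
            for c in ct.children[v]:
                b |= bits[c]
            bits[v] = b
    return bits


def ols_branch_lengths(tree: Phylogeny, dist: np.ndarray, names: list[str]) -> Phylogeny:
    """Ordinary-least-squares branch lengths on a fixed topology.

    Solves ``A l = d`` over leaf pairs, where A indicates which edges lie on
    each pairwise path; negative solutions are clamped to 0.
    """
    ct = tree.compiled()
    bits = _leaf_bitsets(ct, names)
    edges = [v for v in range(ct.n_nodes) if ct.parent[v] >= 0]
    n = len(names)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(edges)))
    for col, v in enumerate(edges):
        below = bits[v]
        for rowk, (i, j) in enumerate(pairs):
            in_i = bool(below & (1 << i))
            in_j = bool(below & (1 << j))
            if in_i != in_j:
                A[rowk, col] = 1.0
    d = np.array([dist[i, j] for i, j in pairs])
    lengths, *_ = np.linalg.lstsq(A, d, rcond=None)
    lengths = np.maximum(lengths, 0.0)
    # write back through newick round-trip to keep Phylogeny immutable-ish
    nodes = list(tree._tree.postorder_node_iter())
    for v, ln in zip(edges, lengths):
        nodes[v].edge.length = float(ln)
    return Phylogeny.from_newick(tree.to_newick(digits=17))


def build_ls_tree(dist: np.ndarray, names: list[str]) -> Phylogeny:
    """Neighbor-joining topology + OLS branch lengths, negatives clamped."""
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = dist[0, 1] / 2.0
        return Phylogeny.from_newick(f"({names[0]}:{half:.17g},{names[1]}:{half:.17g});")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    import io as _io

    topo = nj(DistanceMatrix(dist, ids=names))
    buf = _io.StringIO()
    topo.write(buf, format="newick")
    tree = Phylogeny.from_newick(buf.getvalue())
    return ols_branch_lengths(tree, dist, names)


# ---------------------------------------------------------------------------
# ML branch lengths on a fixed topology (shared_topology rate mode)


def optimize_branch_lengths(
    aln: AnnotatedAlignment,
    tree: Phylogeny,
    model: ReversibleModel,
    rate_model: RateClassModel | None = None,
    max_sweeps: int = 5,
    tol: float = 1e-4,
) -> Phylogeny:
    """Coordinate-ascent ML branch lengths on the given topology."""
    work = Phylogeny.from_newick(tree.to_newick(digits=17))
    nodes = [
        nd for nd in work._tree.postorder_node_iter() if nd.parent_node is not None
    ]
    last = alignment_log_likelihood(aln, work, model, rate_model)
    for _ in range(max_sweeps):
        for nd in nodes:
            def neg(t: float, nd=nd) -> float:
                nd.edge.length = t
                work._compiled = None
                return -alignment_log_likelihood(aln, work, model, rate_model)

            res = optimize.minimize_scalar(
                neg, bounds=(0.0, MAX_DISTANCE), method="bounded",
                options={"xatol": 1e-6},
            )
            nd.edge.length = float(res.x)
            work._compiled = None
        now = alignment_log_likelihood(aln, work, model, rate_model)
        if now - last < tol:
            break
        last = now
    return work
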