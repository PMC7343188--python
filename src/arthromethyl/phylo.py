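"""Trees, Brownian-motion ancestral state reconstruction and phylogenetic
generalized least squares.

The ancestral estimate at an internal node is the GLS root estimate of the
tree re-rooted at that node, computed here through path-length algebra:
with t_i the node-to-tip path lengths and d_ij the (root-independent)
patristic distances, the re-rooted tip covariance is
V[i,j] = (t_i + t_j - d_ij) / 2, and the estimate is the inverse-variance
weighted mean (1'V^-1 1)^-1 1'V^-1 x.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class _Node:
    index: int
    label: str
    parent: int | None
    edge_length: float | None
    is_tip: bool
    children: tuple[int, ...]


class PhyloTree:
    """Rooted tree with strictly positive branch lengths and unique tips."""

    def __init__(self, dtree: dendropy.Tree) -> None:
        self._dtree = dtree
        nodes: list[_Node] = []
        index_of: dict[int, int] = {}
        n_internal = 0
        for nd in dtree.preorder_node_iter():
            idx = len(nodes)
            index_of[id(nd)] = idx
            parent = index_of[id(nd.parent_node)] if nd.parent_node is not None else None
            is_tip = nd.is_leaf()
            if is_tip:
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeError("tip without label")
                label = nd.taxon.label
            else:
                label = nd.label if nd.label else f"node{n_internal}"
                n_internal += 1
            length = nd.edge.length
            if parent is not None:
                if length is None:
                    raise TreeError(f"missing branch length above {label!r}")
                if length <= 0:
                    raise TreeError(f"non-positive branch length above {label!r}")
            nodes.append(_Node(idx, label, parent, length, is_tip, ()))
        # fill children
        kids: dict[int, list[int]] = {n.index: [] for n in nodes}
        for n in nodes:
            if n.parent is not None:
                kids[n.parent].append(n.index)
        self.nodes = [
            _Node(n.index, n.label, n.parent, n.edge_length, n.is_tip, tuple(kids[n.index]))
            for n in nodes
        ]
        self.tip_indices = [n.index for n in self.nodes if n.is_tip]
        self.tip_labels = [self.nodes[i].label for i in self.tip_indices]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("duplicate tip labels")
        self.internal_indices = [n.index for n in self.nodes if not n.is_tip]
        self._depths: np.ndarray | None = None
        self._dist: np.ndarray | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            if "uplicate" in str(exc):
                raise TreeError("duplicate tip labels") from exc
            raise TreeError(f"invalid newick: {exc}") from exc
        return cls(dtree)

    def to_newick(self, node_labels: dict[str, str] | None = None) -> str:
        """Newick string; ``node_labels`` overrides internal node labels."""
        labels = {n.index: n.label for n in self.nodes if not n.is_tip}
        if node_labels:
            for idx, lab in labels.items():
                if lab in node_labels:
                    labels[idx] = node_labels[lab]

        def _fmt(idx: int) -> str:
            n = self.nodes[idx]
            if n.is_tip:
                core = n.label.replace(" ", "_")
            else:
                core = "(" + ",".join(_fmt(c) for c in n.children) + ")" + labels[idx]
            if n.parent is not None:
                core += f":{n.edge_length:.10g}"
            return core

        root = next(n.index for n in self.nodes if n.parent is None)
        return _fmt(root) + ";"

    # -- geometry -----------------------------------------------------------

    def _all_distances(self) -> np.ndarray:
        """Pairwise path lengths between all nodes (undirected)."""
        if self._dist is not None:
            return self._dist
        m = len(self.nodes)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(m)]
        for n in self.nodes:
            if n.parent is not None:
                adj[n.parent].append((n.index, n.edge_length))
                adj[n.index].append((n.parent, n.edge_length))
        dist = np.zeros((m, m))
        for src in range(m):
            seen = np.zeros(m, bool)
            seen[src] = True
            stack = [(src, 0.0)]
            while stack:
                u, du = stack.pop()
                for v, w in adj[u]:
                    if not seen[v]:
                        seen[v] = True
                        dist[src, v] = du + w
                        stack.append((v, du + w))
        self._dist = dist
        return dist

    def depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        if self._depths is None:
            root = next(n.index for n in self.nodes if n.parent is None)
            self._depths = self._all_distances()[root]
        return self._depths

    def tip_covariance(self, root_index: int | None = None) -> np.ndarray:
        """BM tip covariance structure (shared path length from the root, or
        from an arbitrary node when ``root_index`` is given)."""
        dist = self._all_distances()
        tips = np.array(self.tip_indices)
        if root_index is None:
            root_index = next(n.index for n in self.nodes if n.parent is None)
        t = dist[root_index, tips]
        dij = dist[np.ix_(tips, tips)]
        v = (t[:, None] + t[None, :] - dij) / 2.0
        return v

    def n_tips(self) -> int:
        return len(self.tip_indices)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_newick(tree: PhyloTree, path, node_labels: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(node_labels) + "\n")


# ---------------------------------------------------------------------------
# Ancestral state reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralEstimate:
    """Per internal node: ML state, variance and 95% CI, plus the rate."""

    table: pd.DataFrame  # index: node label; columns: estimate, variance, ci_low, ci_high
    sigma2: float

    def estimate(self, node: str) -> float:
        return float(self.table.loc[node, "estimate"])

    @property
    def root(self) -> str:
        return str(self.table.index[0])


def _order_values(tree: PhyloTree, values) -> np.ndarray:
    if isinstance(values, pd.Series):
        values = values.to_dict()
    missing = [t for t in tree.tip_labels if t not in values]
    if missing:
        raise TreeError(f"missing tip values for {missing}")
    return np.array([float(values[t]) for t in tree.tip_labels])


def asr_bm(tree: PhyloTree, tip_values, method: str = "ml") -> AncestralEstimate:
    """Maximum-likelihood Brownian-motion ancestral states.

    ``method`` selects the rate estimator: ``ml`` divides the GLS quadratic
    form by n, ``reml`` by n-1.  The per-node variance is
    sigma2 / (1'V^-1 1) on the covariance re-rooted at that node.
    """
    if tree.n_tips() < 2:
        raise TreeError("need at least 2 tips")
    if method not in ("ml", "reml"):
        raise TreeError(f"unknown method {method!r}")
    x = _order_values(tree, tip_values)
    n = len(x)
    c = tree.tip_covariance()
    cinv_1 = np.linalg.solve(c, np.ones(n))
    a_root = float(cinv_1 @ x / cinv_1.sum())
    resid = x - a_root
    quad = float(resid @ np.linalg.solve(c, resid))
    sigma2 = quad / (n if method == "ml" else n - 1)

    rows = []
    for idx in tree.internal_indices:
        v = tree.tip_covariance(root_index=idx)
        vinv_1 = np.linalg.solve(v, np.ones(n))
        denom = float(vinv_1.sum())
        est = float(vinv_1 @ x / denom)
        var = sigma2 / denom
        half = 1.96 * np.sqrt(var)
        rows.append((tree.nodes[idx].label, est, var, est - half, est + half))
    table = pd.DataFrame(
        rows, columns=["node", "estimate", "variance", "ci_low", "ci_high"]
    ).set_index("node")
    return AncestralEstimate(table, float(sigma2))


# ---------------------------------------------------------------------------
# Phylogenetic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PglsResult:
    table: pd.DataFrame  # index: term; columns: coef, se, t, p
    sigma2: float
    df_resid: int

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def pgls(tree: PhyloTree, response, predictors: pd.DataFrame | None = None) -> PglsResult:
    """GLS regression with BM residual covariance V = sigma2 * shared-path
    matrix; coefficient t-tests on n-k residual degrees of freedom."""
    y = _order_values(tree, response)
    n = len(y)
    if predictors is None:
        x = np.ones((n, 1))
        terms = ["intercept"]
    else:
        missing = [t for t in tree.tip_labels if t not in predictors.index]
        if missing:
            raise TreeError(f"predictors missing tips {missing}")
        aligned = predictors.loc[tree.tip_labels]
        x = np.column_stack([np.ones(n), aligned.to_numpy(float)])
        terms = ["intercept"] + list(aligned.columns)
    k = x.shape[1]
    if np.linalg.matrix_rank(x) < k:
        raise TreeError("design matrix is rank deficient")
    if n <= k:
        raise TreeError("not enough tips for the number of predictors")
    c = tree.tip_covariance()
    cinv_x = np.linalg.solve(c, x)
    cinv_y = np.linalg.solve(c, y)
    xtcx = x.T @ cinv_x
    beta = np.linalg.solve(xtcx, x.T @ cinv_y)
    resid = y - x @ beta
    sigma2 = float(resid @ np.linalg.solve(c, resid)) / (n - k)
    cov_beta = sigma2 * np.linalg.inv(xtcx)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), n - k)
    table = pd.DataFrame(
        {"coef": beta, "se": se, "t": t, "p": p}, index=pd.Index(terms, name="term")
    )
    return PglsResult(table, sigma2, n - k)
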