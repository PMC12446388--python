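"""Tree construction and likelihood machinery.

Topology comes from deterministic neighbor joining on an ML distance matrix;
branch lengths are then refitted by maximizing the Felsenstein-pruning
log-likelihood one branch at a time (round-robin coordinate ascent).  Trees
are dendropy objects throughout, so Newick I/O, midpoint rooting and
patristic distances ride on that library.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .errors import TreeError, ValidationError
from .io import Alignment
from .substitution import (
    N_STATES,
    T_MAX,
    DistanceMatrix,
    SubstitutionModel,
    encode,
)

_BL_XATOL = 1e-7
_MIN_BL = 1e-9


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dmat: DistanceMatrix, allow_saturated: bool = False) -> dendropy.Tree:
    """Classical NJ agglomeration; deterministic given the matrix.

    Ties in the Q criterion break on the smallest (row, column) index pair.
    Negative intermediate branch lengths are clamped to zero with the deficit
    transferred to the sibling branch, and the clamp count is recorded on the
    returned tree as ``nj_negative_branches``.
    """
    n = len(dmat)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dmat.values)):
        raise ValidationError("distance matrix contains non-finite entries")
    if dmat.saturated.any() and not allow_saturated:
        pairs = [
            (dmat.taxa[i], dmat.taxa[j])
            for i, j in zip(*np.nonzero(np.triu(dmat.saturated)))
        ]
        raise ValidationError(
            f"saturated distances present for pairs {pairs}; "
            "pass allow_saturated=True to proceed"
        )

    taxon_namespace = dendropy.TaxonNamespace(dmat.taxa)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: list[dendropy.Node] = []
    for name in dmat.taxa:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(name)
        nodes.append(node)

    D = dmat.values.copy()
    active = list(range(n))
    clamped = 0

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qc = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        # deterministic arg-min with lexicographic tie-break
        flat = np.argmin(Qc)
        ii, jj = divmod(int(flat), m)
        if ii > jj:
            ii, jj = jj, ii
        i, j = active[ii], active[jj]

        dij = D[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp-and-transfer for negative lengths
        if li < 0:
            lj += -li
            li = 0.0
            clamped += 1
        if lj < 0:
            li += -lj
            lj = 0.0
            clamped += 1

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)

        # distances from the new node to the remaining actives
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    # join the last two clusters on a single edge; make the seed trifurcating
    # when possible so the tree reads as unrooted
    i, j = active
    last = D[i, j]
    a, b = nodes[i], nodes[j]
    if a.is_leaf() and b.is_leaf():
        root = dendropy.Node()
        root.add_child(a)
        root.add_child(b)
        a.edge.length = last / 2.0
        b.edge.length = last / 2.0
    else:
        if a.is_leaf():
            a, b = b, a
        b.edge.length = float(max(last, 0.0))
        a.add_child(b)
        root = a
    tree.seed_node = root
    tree.is_rooted = False
    tree.nj_negative_branches = clamped  # type: ignore[attr-defined]
    return tree


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class _Pruner:
    """Pattern-compressed Felsenstein pruning over a fixed topology."""

    def __init__(self, tree: dendropy.Tree, alignment: Alignment, model: SubstitutionModel):
        leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        aln_names = set(alignment.taxa)
        if leaf_names != aln_names:
            missing = sorted(leaf_names ^ aln_names)
            raise TreeError(f"tree/alignment taxa mismatch: {missing}")
        self.model = model
        self.tree = tree

        enc = np.array([encode(alignment[leaf].residues) for leaf in sorted(aln_names)])
        self._leaf_order = sorted(aln_names)
        patterns, weights = np.unique(enc, axis=1, return_counts=True)
        self.patterns = patterns  # (n_leaves, n_patterns)
        self.weights = weights.astype(float)
        self.n_patterns = patterns.shape[1]

        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): k for k, nd in enumerate(self.nodes)}
        # leaf partials: identity columns, ones for gap/unknown (missing data)
        self._leaf_partials: dict[int, np.ndarray] = {}
        for nd in self.nodes:
            if nd.is_leaf():
                states = patterns[self._leaf_order.index(nd.taxon.label)]
                part = np.zeros((self.n_patterns, N_STATES))
                miss = states < 0
                part[miss, :] = 1.0
                idx = np.nonzero(~miss)[0]
                part[idx, states[idx]] = 1.0
                self._leaf_partials[id(nd)] = part

    # -- downward (subtree) partials -------------------------------------
    def down_partials(self) -> dict[int, np.ndarray]:
        D: dict[int, np.ndarray] = {}
        for nd in self.nodes:
            if nd.is_leaf():
                D[id(nd)] = self._leaf_partials[id(nd)]
            else:
                part = np.ones((self.n_patterns, N_STATES))
                for child in nd.child_nodes():
                    P = self.model.transition_matrix(_edge_len(child))
                    part *= D[id(child)] @ P.T
                D[id(nd)] = part
        return D

    def log_likelihood(self, D: dict[int, np.ndarray] | None = None) -> float:
        if D is None:
            D = self.down_partials()
        site = D[id(self.tree.seed_node)] @ self.model.pi
        return float(np.sum(self.weights * np.log(np.clip(site, 1e-300, None))))

    # -- outside partials for single-branch optimization ------------------
    def outside_partials(self, D: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
        """F[v]: likelihood of all data outside subtree(v), given the state at
        v's parent (pi excluded)."""
        F: dict[int, np.ndarray] = {}
        G: dict[int, np.ndarray] = {id(self.tree.seed_node): np.ones((self.n_patterns, N_STATES))}
        for nd in self.tree.preorder_node_iter():
            children = nd.child_nodes()
            if not children:
                continue
            contribs = [
                D[id(c)] @ self.model.transition_matrix(_edge_len(c)).T for c in children
            ]
            total = G[id(nd)]
            for k, child in enumerate(children):
                f = total.copy()
                for k2, contrib in enumerate(contribs):
                    if k2 != k:
                        f *= contrib
                F[id(child)] = f
                G[id(child)] = f @ self.model.transition_matrix(_edge_len(child))
        return F

    def branch_loglik_fn(self, node: dendropy.Node, D, F):
        """Log-likelihood as a function of the length of node's parent edge."""
        d_v = D[id(node)]
        f_v = F[id(node)]
        w = self.weights
        pi = self.model.pi

        def fn(t: float) -> float:
            P = self.model.transition_matrix(t)
            site = np.einsum("pa,a,pa->p", f_v, pi, d_v @ P.T)
            return float(np.sum(w * np.log(np.clip(site, 1e-300, None))))

        return fn


def _edge_len(node: dendropy.Node) -> float:
    length = node.edge.length
    return float(length) if length is not None else 0.0


def tree_log_likelihood(
    tree: dendropy.Tree, alignment: Alignment, model: SubstitutionModel
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree."""
    return _Pruner(tree, alignment, model).log_likelihood()


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> dendropy.Tree:
    """Round-robin ML optimization of every branch length.

    Returns a new tree (the input is not modified) with ``converged`` and
    ``log_likelihood`` attributes.  The log-likelihood is non-decreasing
    across sweeps by construction.
    """
    tree = tree.clone(depth=1)
    pruner = _Pruner(tree, alignment, model)
    branch_nodes = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    prev_ll = pruner.log_likelihood()
    converged = False
    for _sweep in range(max_sweeps):
        for nd in branch_nodes:
            D = pruner.down_partials()
            F = pruner.outside_partials(D)
            fn = pruner.branch_loglik_fn(nd, D, F)
            res = minimize_scalar(
                lambda t: -fn(t),
                bounds=(_MIN_BL, T_MAX),
                method="bounded",
                options={"xatol": _BL_XATOL},
            )
            if fn(float(res.x)) >= fn(_edge_len(nd)):
                nd.edge.length = float(res.x)
        ll = pruner.log_likelihood()
        if ll - prev_ll < tol:
            prev_ll = max(ll, prev_ll)
            converged = True
            break
        prev_ll = ll
    tree.log_likelihood = prev_ll  # type: ignore[attr-defined]
    tree.converged = converged  # type: ignore[attr-defined]
    return tree


# ---------------------------------------------------------------------------
# distances on trees
# ---------------------------------------------------------------------------

def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between all leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    lookup = {t.label: t for t in tree.taxon_namespace if t.label in set(taxa)}
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Rooted copy of the tree, rooted at the midpoint of the longest path."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    rooted = tree.clone(depth=1)
    node = rooted.find_node_with_taxon_label(outgroup)
    if node is None:
        raise TreeError(f"outgroup taxon {outgroup!r} not in tree")
    rooted.to_outgroup_position(node, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def is_rooted(tree: dendropy.Tree) -> bool:
    return len(tree.seed_node.child_nodes()) == 2


def root_to_tip(tree: dendropy.Tree) -> Mapping[str, float]:
    """Path length from the root to every leaf; requires a rooted tree."""
    if not is_rooted(tree):
        raise TreeError(
            "root-to-tip distances require a rooted tree; apply midpoint_root "
            "(or root_with_outgroup) first"
        )
    out: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        dist = 0.0
        nd = leaf
        while nd.parent_node is not None:
            dist += _edge_len(nd)
            nd = nd.parent_node
        out[leaf.taxon.label] = dist
    return out


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted symmetric (Robinson-Foulds) distance between topologies."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    tb = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"),
        schema="newick",
        taxon_namespace=tns,
        preserve_underscores=True,
    )
    for t in (ta, tb):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
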