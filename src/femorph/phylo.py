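"""Phylogenetic comparative statistics for shape data.

Trees are handled through dendropy; all branch lengths default to 1 (the
topology-only convention used when divergence times are unavailable). Under
Brownian motion the expected covariance of a trait between two tips equals
the shared root-to-ancestor path length, giving the matrix C that underlies
everything here:

* ``kmult_test`` — the multivariate extension of Blomberg's K. K compares the
  observed ratio of among-tip to phylogenetically-corrected variation with
  its Brownian-motion expectation; K = 1 is the BM baseline, K > 1 means
  variation concentrated between clades, K < 1 within clades. Significance by
  permutation of tip rows.
* ``pgls_fit`` — phylogenetic generalized least squares of shape on size and
  locomotor mode with sequential (Type I) sums of squares and residual-
  randomization permutation tests.
* ``ancestral_continuous`` — squared-change-parsimony ancestral states (the
  BM maximum-likelihood states), used to draw phylomorphospace branches.
* ``fitch_states`` — minimal-change discrete ancestral-state sets for the
  bipedal/quadrupedal character, exact on polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.linalg


@dataclass
class Phylogeny:
    """A rooted, tip-labelled tree (polytomies allowed)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick")

    def set_unit_lengths(self) -> "Phylogeny":
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is not self.tree.seed_node:
                edge.length = 1.0
            else:
                edge.length = None
        return self

    def validate_tips(self, labels) -> None:
        tips = set(self.tip_labels)
        missing = sorted(set(labels) - tips)
        extra = sorted(tips - set(labels))
        if missing or extra:
            raise ValueError(
                f"tip/data mismatch: data rows without tips {missing[:5]}, "
                f"tips without data {extra[:5]}"
            )


def read_newick(path_or_string, unit_lengths: bool = True) -> Phylogeny:
    """Read a rooted Newick tree; by default overwrite all branch lengths to 1."""
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except Exception as exc:  # dendropy raises its own parse errors
        raise ValueError(f"malformed Newick input: {exc}") from exc
    phy = Phylogeny(tree=tree)
    if unit_lengths:
        phy.set_unit_lengths()
    else:
        for edge in tree.preorder_edge_iter():
            if edge.length is None and edge.head_node is not tree.seed_node:
                edge.length = 1.0
    return phy


# backwards-friendly alias matching the pipeline stage name
def read_newick_unit_lengths(path) -> Phylogeny:
    return read_newick(path, unit_lengths=True)


def expand_tree_to_specimens(phy: Phylogeny,
                             specimens_by_species: dict[str, list[str]]) -> Phylogeny:
    """Attach conspecific specimens as a unit-length terminal polytomy.

    Comparative statistics run per femur while the tree is species-level:
    each species tip with more than one specimen becomes an internal node
    carrying one unit-length terminal branch per specimen (a single specimen
    simply renames the tip). Species missing from the mapping keep their tip.
    """
    tree = dendropy.Tree(phy.tree)
    taxa = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        species = leaf.taxon.label
        ids = specimens_by_species.get(species)
        if not ids:
            continue
        if len(ids) == 1:
            leaf.taxon = taxa.require_taxon(label=ids[0])
            continue
        leaf.taxon = None
        for sid in ids:
            child = dendropy.Node(taxon=taxa.require_taxon(label=sid))
            child.edge.length = 1.0
            leaf.add_child(child)
    return Phylogeny(tree=tree)


def bm_covariance(phy: Phylogeny, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: C[i, j] = depth of the MRCA of tips i, j.

    Returns the matrix and the tip order used. ``order`` (if given) must match
    the tree's tip labels one-to-one.
    """
    tree = phy.tree
    labels = phy.tip_labels
    if order is not None:
        phy.validate_tips(order)
        labels = list(order)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    C = np.zeros((n, n))
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            C[i, i] = depth[node]
        else:
            children = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = depth[node]
            tipsets[node] = [i for ch in children for i in ch]
    return C, labels


@dataclass
class PhyloSignalResult:
    k_mult: float
    p_value: float
    n_permutations: int
    seed: int | None
    null_distribution: np.ndarray | None = None


def _kmult_statistic(Y: np.ndarray, Cinv: np.ndarray, expected: float) -> float:
    n = Y.shape[0]
    ones = np.ones(n)
    w = Cinv @ ones
    ahat = (w @ Y) / (ones @ w)
    R = Y - ahat[None, :]
    num = float(np.einsum("ij,ij->", R, R))
    den = float(np.einsum("ij,ik,kj->", R, Cinv, R))
    return (num / den) / expected


def kmult_test(data: np.ndarray, phy: Phylogeny, tip_labels: list[str],
               n_perm: int = 999, seed: int | None = None) -> PhyloSignalResult:
    """Multivariate phylogenetic signal K with a permutation test.

    ``data`` rows (n x p scores or residuals) must correspond to
    ``tip_labels``. The p-value is the proportion of row permutations whose K
    is >= the observed one, the observed case included in numerator and
    denominator.
    """
    Y = np.atleast_2d(np.asarray(data, float))
    if Y.shape[0] == len(tip_labels) or Y.ndim == 2:
        if Y.shape[0] != len(tip_labels) and Y.shape[1] == len(tip_labels):
            Y = Y.T
    if Y.shape[0] != len(tip_labels):
        raise ValueError("data rows must match tip labels")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    C, _ = bm_covariance(phy, order=list(tip_labels))
    n = C.shape[0]
    try:
        Cinv = scipy.linalg.inv(C)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance: {exc}") from exc
    ones = np.ones(n)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)

    observed = _kmult_statistic(Y, Cinv, expected)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    count = 1  # observed included
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = _kmult_statistic(Y[perm], Cinv, expected)
        if null[b] >= observed:
            count += 1
    p = count / (n_perm + 1)
    return PhyloSignalResult(k_mult=float(observed), p_value=float(p),
                             n_permutations=n_perm, seed=seed,
                             null_distribution=null)


# ---------------------------------------------------------------------------
# PGLS with residual randomization
# ---------------------------------------------------------------------------

@dataclass
class PGLSTerm:
    name: str
    df: int
    ss: float
    r_squared: float
    f_statistic: float
    p_value: float


@dataclass
class PGLSResult:
    terms: list[PGLSTerm]
    ss_total: float
    ss_residual: float
    n_permutations: int
    seed: int | None

    def term(self, name: str) -> PGLSTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _inv_sqrt(C: np.ndarray, clip: float = 1e-12) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(C)
    vals = np.clip(vals, clip, None)
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def pgls_fit(shape: np.ndarray, size: np.ndarray, mode: list[str],
             phy: Phylogeny, tip_labels: list[str],
             interaction: bool = True, n_perm: int = 999,
             seed: int | None = None) -> PGLSResult:
    """PGLS of shape on log size and locomotor mode under Brownian motion.

    Data and design are whitened by the symmetric inverse square root of the
    BM covariance; terms enter sequentially as size, mode, size x mode, with
    per-term r-squared = SS_term / SS_total and significance assessed by
    residual randomization of the reduced model (RRPP).
    """
    Y = np.atleast_2d(np.asarray(shape, float))
    if Y.shape[0] != len(tip_labels):
        raise ValueError("shape rows must match tip labels")
    size = np.asarray(size, float)
    mode = list(mode)
    n = Y.shape[0]
    C, _ = bm_covariance(phy, order=list(tip_labels))
    T = _inv_sqrt(C)
    Z = T @ Y

    levels = sorted(set(mode))
    dummies = np.stack([[1.0 if m == lev else 0.0 for m in mode]
                        for lev in levels[1:]], axis=1) if len(levels) > 1 else np.empty((n, 0))
    blocks: list[tuple[str, np.ndarray]] = [("size", size[:, None])]
    if dummies.shape[1]:
        blocks.append(("mode", dummies))
        if interaction:
            blocks.append(("size:mode", size[:, None] * dummies))

    intercept = np.ones((n, 1))
    designs = [intercept]
    names = []
    for name, cols in blocks:
        designs.append(np.hstack([designs[-1], cols]))
        names.append(name)
    full = designs[-1]
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(f"collinear design among terms {names}")

    Xw = [T @ X for X in designs]
    hats = [_hat(X) for X in Xw]
    rss = [float(((Z - H @ Z) ** 2).sum()) for H in hats]
    ss_total = rss[0]
    ss_resid = rss[-1]
    if ss_total <= 1e-12 * max(1.0, float(np.abs(Z).max()) ** 2) * n:
        terms = [PGLSTerm(name=name,
                          df=designs[i + 1].shape[1] - designs[i].shape[1],
                          ss=0.0, r_squared=0.0, f_statistic=0.0, p_value=1.0)
                 for i, name in enumerate(names)]
        return PGLSResult(terms=terms, ss_total=0.0, ss_residual=0.0,
                          n_permutations=n_perm, seed=seed)
    df_full = full.shape[1]
    ms_resid = ss_resid / max(n - df_full, 1)

    rng = np.random.default_rng(seed)
    terms: list[PGLSTerm] = []
    for t_idx, name in enumerate(names):
        df_t = designs[t_idx + 1].shape[1] - designs[t_idx].shape[1]
        ss_t = rss[t_idx] - rss[t_idx + 1]
        f_obs = (ss_t / df_t) / ms_resid if ms_resid > 0 else np.inf
        H_red = hats[t_idx]
        H_cur = hats[t_idx + 1]
        fitted = H_red @ Z
        resid = Z - fitted
        count = 1
        for _ in range(n_perm):
            Zb = fitted + resid[rng.permutation(n)]
            rss_red = float(((Zb - H_red @ Zb) ** 2).sum())
            rss_cur = float(((Zb - H_cur @ Zb) ** 2).sum())
            rss_full_b = float(((Zb - hats[-1] @ Zb) ** 2).sum())
            ms_b = rss_full_b / max(n - df_full, 1)
            f_b = ((rss_red - rss_cur) / df_t) / ms_b if ms_b > 0 else np.inf
            if f_b >= f_obs:
                count += 1
        terms.append(PGLSTerm(
            name=name, df=df_t, ss=ss_t,
            r_squared=ss_t / ss_total if ss_total > 0 else 0.0,
            f_statistic=f_obs,
            p_value=count / (n_perm + 1),
        ))
    return PGLSResult(terms=terms, ss_total=ss_total, ss_residual=ss_resid,
                      n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------

def ancestral_continuous(scores: np.ndarray, phy: Phylogeny,
                         tip_labels: list[str]) -> dict:
    """Squared-change-parsimony ancestral values for continuous traits.

    Internal-node values minimize the sum over edges of
    ``||x_parent - x_child||^2 / length`` — the stationarity conditions form a
    sparse linear system whose solution equals the BM maximum-likelihood
    ancestral states. Returns ``{"nodes": internal x m array, "node_ids":
    labels, "tree": phy}`` with nodes in preorder.
    """
    Y = np.atleast_2d(np.asarray(scores, float))
    if Y.shape[0] != len(tip_labels):
        raise ValueError("score rows must match tip labels")
    phy.validate_tips(tip_labels)
    tree = phy.tree
    tip_vals = {lab: Y[i] for i, lab in enumerate(tip_labels)}

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {nd: i for i, nd in enumerate(internal)}
    m = Y.shape[1]
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros((len(internal), m))
    for nd in internal:
        i = idx[nd]
        neighbors = list(nd.child_nodes())
        if nd.parent_node is not None:
            neighbors.append(nd.parent_node)
        for nb in neighbors:
            edge = nb.edge if nb in nd.child_nodes() else nd.edge
            w = 1.0 / (edge.length or 1.0)
            A[i, i] += w
            if nb.is_leaf():
                b[i] += w * tip_vals[nb.taxon.label]
            else:
                A[i, idx[nb]] -= w
    X = np.linalg.solve(A, b)
    node_ids = [f"node{i}" for i in range(len(internal))]
    for nd, lab in zip(internal, node_ids):
        nd.label = nd.label or lab
    return {"nodes": X, "node_ids": [nd.label for nd in internal],
            "internal_nodes": internal, "tree": phy}


def squared_change_objective(phy: Phylogeny, tip_labels: list[str],
                             tip_values: np.ndarray,
                             internal_values: np.ndarray) -> float:
    """Sum over edges of squared change / branch length (diagnostic)."""
    tree = phy.tree
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {nd: i for i, nd in enumerate(internal)}
    tip_vals = {lab: np.atleast_1d(v) for lab, v in zip(tip_labels, np.atleast_2d(tip_values))}

    def value(nd):
        return tip_vals[nd.taxon.label] if nd.is_leaf() else internal_values[idx[nd]]

    total = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        diff = value(nd) - value(nd.parent_node)
        total += float((diff ** 2).sum()) / (nd.edge.length or 1.0)
    return total


# ---------------------------------------------------------------------------
# discrete parsimony
# ---------------------------------------------------------------------------

def fitch_states(tip_modes: dict[str, str], phy: Phylogeny,
                 states: tuple[str, ...] = ("B", "Q"),
                 indeterminate: str = "free") -> dict:
    """Minimal-change ancestral state sets for a discrete character.

    ``tip_modes`` maps tip labels to a state or ``"I"``; indeterminate tips
    are either treated as free (any state, ``"free"``, the default) or pruned
    (``"exclude"``). Implemented as a min-change dynamic program (unit
    substitution cost), which on binary trees reproduces the classic
    intersection/union two-pass sets and on polytomies still attains the
    exhaustive minimum. Nodes whose set has both states are "ambiguous".

    Returns ``{"node_sets": {node label or id: frozenset}, "changes": int}``.
    """
    tree = dendropy.Tree(phy.tree)  # deep copy
    scored = {t: m for t, m in tip_modes.items() if m in states}
    if len(scored) < 2:
        raise ValueError("need at least 2 tips with scored states")
    if indeterminate == "exclude":
        keep = [leaf.taxon for leaf in tree.leaf_node_iter()
                if tip_modes.get(leaf.taxon.label) in states]
        tree.retain_taxa(keep)
        tree.suppress_unifurcations()

    INF = float("inf")
    down: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            mode = tip_modes.get(nd.taxon.label)
            if mode in states:
                down[nd] = {s: (0.0 if s == mode else INF) for s in states}
            else:
                down[nd] = {s: 0.0 for s in states}
        else:
            cost = {s: 0.0 for s in states}
            for child in nd.child_nodes():
                for s in states:
                    cost[s] += min(down[child][t] + (0.0 if s == t else 1.0)
                                   for t in states)
            down[nd] = cost

    root = tree.seed_node
    changes = int(min(down[root].values()))

    up: dict = {root: {s: 0.0 for s in states}}
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        children = nd.child_nodes()
        for child in children:
            sib_cost = {s: sum(min(down[sib][t] + (0.0 if s == t else 1.0)
                                   for t in states)
                               for sib in children if sib is not child)
                        for s in states}
            up[child] = {t: min(up[nd][s] + sib_cost[s] + (0.0 if s == t else 1.0)
                                for s in states)
                         for t in states}

    node_sets: dict = {}
    counter = 0
    for nd in tree.preorder_node_iter():
        total = {s: down[nd][s] + up[nd][s] for s in states}
        best = min(total.values())
        sset = frozenset(s for s in states if total[s] <= best + 1e-9)
        if nd.is_leaf():
            key = nd.taxon.label
        else:
            key = nd.label or f"node{counter}"
            counter += 1
        node_sets[key] = sset
    return {"node_sets": node_sets, "changes": changes, "tree": Phylogeny(tree)}
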