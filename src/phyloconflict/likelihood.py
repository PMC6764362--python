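"""GTR+Gamma pruning likelihood, branch-length optimization,
constraint-respecting topology search, and the gene-wise edge test.

The engine scores *hypotheses about a single contentious edge*: each
hypothesis is a (possibly multifurcating) constraint tree whose resolved
splits must appear in any topology scored under it.  Every gene is free
to resolve the rest of its topology however its data prefer, so the
summed score for a hypothesis reflects only the focal relationship and
is robust to conflict elsewhere in the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc, logsumexp

from .alignments import Alignment
from .trees import Bipartition, Node, PhyloTree, TreeError, extract_bipartitions

__all__ = [
    "SubstModel",
    "ConstraintHypothesis",
    "EdgeTestResult",
    "log_likelihood",
    "optimize_branch_lengths",
    "constrained_search",
    "edge_test",
    "estimate_model",
]

NT_ORDER = "ACGT"
#: IUPAC nucleotide codes -> conditional-likelihood rows
AMBIG = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "T": (0, 0, 0, 1),
    "U": (0, 0, 0, 1),
    "R": (1, 0, 1, 0),
    "Y": (0, 1, 0, 1),
    "S": (0, 1, 1, 0),
    "W": (1, 0, 0, 1),
    "K": (0, 0, 1, 1),
    "M": (1, 1, 0, 0),
    "B": (0, 1, 1, 1),
    "D": (1, 0, 1, 1),
    "H": (1, 1, 0, 1),
    "V": (1, 1, 1, 0),
    "N": (1, 1, 1, 1),
    "?": (1, 1, 1, 1),
    "-": (1, 1, 1, 1),
    "X": (1, 1, 1, 1),
}

MIN_BL = 1e-8
MAX_BL = 10.0


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean-normalized discrete-Gamma category rates (equal-probability bins,
    category rate = conditional mean within the bin)."""
    if ncat == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # conditional mean of Gamma(alpha, 1/alpha) within [a, b]:
    # ncat * (I(alpha+1, b*alpha) - I(alpha+1, a*alpha)) with regularized I
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = ncat * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstModel:
    """GTR+Gamma nucleotide substitution model.

    ``exch`` holds the six exchangeabilities in the order
    AC, AG, AT, CG, CT, GT (GT conventionally 1); the rate matrix is
    normalized to one expected substitution per unit branch length, and
    the discrete-Gamma category rates average to 1.
    """

    freqs: np.ndarray
    exch: np.ndarray
    gamma_alpha: float = 1.0
    n_rate_categories: int = 1

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exch = np.asarray(self.exch, dtype=float)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("freqs must be 4 positive reals")
        if abs(self.freqs.sum() - 1) > 1e-8:
            raise ValueError("freqs must sum to 1")
        if self.exch.shape != (6,) or np.any(self.exch <= 0):
            raise ValueError("exch must be 6 positive reals")
        if self.gamma_alpha <= 0 or self.n_rate_categories < 1:
            raise ValueError("invalid gamma parameters")
        self._build()

    def _build(self) -> None:
        pi = self.freqs
        s = self.exch
        Q = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(pairs, s):
            Q[i, j] = x * pi[j]
            Q[j, i] = x * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        # symmetrize for a stable eigendecomposition
        rt = np.sqrt(pi)
        B = (rt[:, None] * Q) / rt[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eval = w
        self._right = V / rt[:, None] * 1.0
        self._left = (V * rt[:, None]).T
        self.category_rates = discrete_gamma_rates(self.gamma_alpha, self.n_rate_categories)
        self._pcache: dict[float, np.ndarray] = {}

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        e = np.exp(self._eval * (t * rate))
        P = (self._right * e[None, :]) @ self._left
        return np.clip(P, 0.0, None)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(ncat, 4, 4) stack over the Gamma categories (memoized on t)."""
        cached = self._pcache.get(t)
        if cached is not None:
            return cached
        e = np.exp(np.outer(self.category_rates * t, self._eval))  # (ncat, 4)
        P = np.einsum("ij,cj,jk->cik", self._right, e, self._left)
        np.clip(P, 0.0, None, out=P)
        if len(self._pcache) > 8192:
            self._pcache.clear()
        self._pcache[t] = P
        return P

    @classmethod
    def jc(cls, n_rate_categories: int = 1, gamma_alpha: float = 1.0) -> "SubstModel":
        return cls(np.full(4, 0.25), np.ones(6), gamma_alpha, n_rate_categories)

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        exch: Optional[Sequence[float]] = None,
        gamma_alpha: float = 1.0,
        n_rate_categories: int = 4,
    ) -> "SubstModel":
        """Model with empirical base frequencies from the alignment."""
        counts = np.zeros(4)
        for seq in aln.sequences.values():
            for i, b in enumerate(NT_ORDER):
                counts[i] += seq.upper().count(b)
        if counts.sum() == 0:
            raise ValueError("no unambiguous bases in alignment")
        freqs = (counts + 0.5) / (counts.sum() + 2.0)
        return cls(freqs / freqs.sum(), np.ones(6) if exch is None else exch,
                   gamma_alpha, n_rate_categories)

    def to_dict(self) -> dict:
        return {
            "freqs": self.freqs.tolist(),
            "exch": self.exch.tolist(),
            "gamma_alpha": self.gamma_alpha,
            "n_rate_categories": self.n_rate_categories,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstModel":
        return cls(
            np.asarray(d["freqs"], dtype=float),
            np.asarray(d["exch"], dtype=float),
            float(d.get("gamma_alpha", 1.0)),
            int(d.get("n_rate_categories", 1)),
        )


# ----------------------------------------------------------------------
# array representation of a tree for pruning


class _ArrTree:
    """Postorder array form of a tree over an alignment's tip data."""

    def __init__(self, tree: PhyloTree, aln: Alignment):
        self.tree = tree
        order = list(tree.postorder())
        self.nodes = order
        self.index = {id(n): i for i, n in enumerate(order)}
        self.children = [[self.index[id(c)] for c in n.children] for n in order]
        self.parent = np.full(len(order), -1, dtype=int)
        for i, n in enumerate(order):
            for c in self.children[i]:
                self.parent[c] = i
        self.lengths = np.array(
            [n.length if n.length is not None else np.nan for n in order]
        )
        self.root = len(order) - 1
        self.leaf_rows: dict[int, np.ndarray] = {}
        for i, n in enumerate(order):
            if n.is_leaf:
                if n.label not in aln.sequences:
                    raise TreeError(f"leaf {n.label!r} has no sequence")
                seq = aln.sequences[n.label].upper()
                self.leaf_rows[i] = np.array(
                    [AMBIG.get(c, AMBIG["N"]) for c in seq], dtype=float
                )
        bad = [
            order[i].label or "internal"
            for i in range(len(order))
            if i != self.root and not np.isfinite(self.lengths[i])
        ]
        if bad:
            raise TreeError(f"non-finite branch length on: {bad}")

    @property
    def nsites(self) -> int:
        return next(iter(self.leaf_rows.values())).shape[0]

    def write_lengths_back(self) -> None:
        for i, n in enumerate(self.nodes):
            if i != self.root:
                n.length = float(self.lengths[i])


def _lowers(at: _ArrTree, model: SubstModel):
    """Lower conditional likelihoods per node: (ncat, nsites, 4) + log-scalers."""
    ncat = model.n_rate_categories
    ns = at.nsites
    L: list[Optional[np.ndarray]] = [None] * len(at.nodes)
    scale: list[Optional[np.ndarray]] = [None] * len(at.nodes)
    for i in range(len(at.nodes)):
        if not at.children[i]:
            L[i] = np.broadcast_to(at.leaf_rows[i], (ncat, ns, 4)).copy()
            scale[i] = np.zeros((ncat, ns))
            continue
        acc = np.ones((ncat, ns, 4))
        sc = np.zeros((ncat, ns))
        for c in at.children[i]:
            P = model.transition_matrices(at.lengths[c])
            acc = acc * np.einsum("cij,csj->csi", P, L[c])
            sc = sc + scale[c]
        m = acc.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        acc /= m[:, :, None]
        sc = sc + np.log(m)
        L[i] = acc
        scale[i] = sc
    return L, scale


def _root_loglik(at: _ArrTree, model: SubstModel, L, scale) -> float:
    site = np.einsum("j,csj->cs", model.freqs, L[at.root])
    logs = np.log(np.clip(site, 1e-300, None)) + scale[at.root]
    return float(logsumexp(logs, axis=0).sum() - at.nsites * math.log(model.n_rate_categories))


def log_likelihood(aln: Alignment, tree: PhyloTree, model: SubstModel) -> float:
    """Felsenstein pruning log-likelihood with a discrete-Gamma mixture.

    Gaps and ambiguity codes are fully/partially ambiguous tip states.
    The value is invariant to root placement for this reversible model.
    """
    at = _ArrTree(tree, aln)
    L, scale = _lowers(at, model)
    return _root_loglik(at, model, L, scale)


# ----------------------------------------------------------------------
# branch-length optimization


def _branch_kernel(at: _ArrTree, model: SubstModel, L, scale, v: int):
    """Upper message for node v's branch: T(x_parent) with its log-scaler.

    T multiplies the root prior, all subtrees hanging off the root-to-v
    path, and the transition matrices along that path; combined with the
    lower partials of v it gives the exact likelihood as a function of
    v's branch length alone.
    """
    ncat, ns = model.n_rate_categories, at.nsites
    path = []
    node = v
    while node != at.root:
        node = at.parent[node]
        path.append(node)
    path.reverse()  # root ... parent(v)
    T = np.broadcast_to(model.freqs, (ncat, ns, 4)).copy()
    Ts = np.zeros((ncat, ns))
    for k, u in enumerate(path):
        nxt = path[k + 1] if k + 1 < len(path) else v
        for c in at.children[u]:
            if c == nxt:
                continue
            P = model.transition_matrices(at.lengths[c])
            T = T * np.einsum("cij,csj->csi", P, L[c])
            Ts = Ts + scale[c]
        if nxt != v:
            P = model.transition_matrices(at.lengths[nxt])
            T = np.einsum("cij,csi->csj", P, T)
        m = T.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        T /= m[:, :, None]
        Ts += np.log(m)
    return T, Ts


def _branch_loglik(T, Ts, Lv, Lvs, model: SubstModel, t: float) -> float:
    P = model.transition_matrices(t)
    msg = np.einsum("cij,csj->csi", P, Lv)
    site = np.einsum("csi,csi->cs", T, msg)
    logs = np.log(np.clip(site, 1e-300, None)) + Ts + Lvs
    return float(logsumexp(logs, axis=0).sum() - Lv.shape[1] * math.log(model.n_rate_categories))


def _eigen_kernel(T, Lv, model: SubstModel):
    """Project the branch kernel onto the model's eigenbasis.

    site_lik(t) = sum_k V[c,s,k] * exp(lambda_k * r_c * t), so each trial
    branch length costs only an exponential and one contraction.
    """
    A = T @ model._right          # (ncat, nsites, 4)
    B = Lv @ model._left.T        # (ncat, nsites, 4)
    return A * B


def _eigen_loglik(V, scales, model: SubstModel, t: float) -> float:
    e = np.exp(np.outer(model.category_rates * t, model._eval))  # (ncat, 4)
    site = np.matmul(V, e[:, :, None])[:, :, 0]
    logs = np.log(np.maximum(site, 1e-300)) + scales
    m = logs.max(axis=0)
    tot = m + np.log(np.exp(logs - m).sum(axis=0))
    return float(tot.sum() - V.shape[1] * math.log(model.n_rate_categories))


def optimize_branch_lengths(
    aln: Alignment,
    tree: PhyloTree,
    model: SubstModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
    warn: bool = True,
) -> tuple[PhyloTree, float]:
    """Coordinate-wise branch-length optimization (bracketed scalar search).

    Sweeps over all branches until the log-likelihood improves by less
    than ``tol`` or ``max_sweeps`` is reached; each branch is optimized
    exactly given the others, so the likelihood never decreases.  Lengths
    are bounded to [1e-8, 10].
    """
    t = tree.copy()
    at = _ArrTree(t, aln)
    ll = _optimize_arr(at, model, tol, max_sweeps, warn)
    at.write_lengths_back()
    return t, ll


def _optimize_arr(
    at: _ArrTree,
    model: SubstModel,
    tol: float,
    max_sweeps: int,
    warn: bool = False,
    nodes: Optional[Sequence[int]] = None,
    xatol: float = 1e-8,
) -> float:
    targets = [v for v in (nodes if nodes is not None else range(len(at.nodes)))
               if v != at.root]
    L, scale = _lowers(at, model)
    ll = _root_loglik(at, model, L, scale)
    for _sweep in range(max_sweeps):
        start = ll
        for v in targets:
            T, Ts = _branch_kernel(at, model, L, scale, v)
            V = _eigen_kernel(T, L[v], model)
            scales = Ts + scale[v]

            def neg(x):
                return -_eigen_loglik(V, scales, model, x)

            res = minimize_scalar(neg, bounds=(MIN_BL, MAX_BL), method="bounded",
                                  options={"xatol": xatol})
            if -res.fun > ll + 1e-12:
                at.lengths[v] = float(res.x)
                ll = -res.fun
                # refresh ancestors' lower partials
                u = at.parent[v]
                while u != -1:
                    acc = np.ones_like(L[u])
                    sc = np.zeros_like(scale[u])
                    for c in at.children[u]:
                        P = model.transition_matrices(at.lengths[c])
                        acc = acc * np.einsum("cij,csj->csi", P, L[c])
                        sc = sc + scale[c]
                    m = acc.max(axis=2)
                    m = np.where(m > 0, m, 1.0)
                    L[u] = acc / m[:, :, None]
                    scale[u] = sc + np.log(m)
                    u = at.parent[u]
        if ll - start < tol:
            break
    else:
        if warn:
            import warnings

            warnings.warn("branch-length optimization hit max sweeps", RuntimeWarning)
    return ll


# ----------------------------------------------------------------------
# constraints and topology search


@dataclass
class ConstraintHypothesis:
    """A named constraint: every resolved split of ``constraint_tree``
    must appear in any accepted topology."""

    name: str
    constraint_tree: PhyloTree

    def splits(self, taxa: Optional[Iterable[str]] = None) -> frozenset[Bipartition]:
        """Constraint splits, optionally restricted to an analysis taxon set."""
        ctaxa = self.constraint_tree.leaf_labels()
        if len(ctaxa) < 4:
            return frozenset()
        raw = extract_bipartitions(self.constraint_tree)
        if taxa is None:
            return frozenset(raw)
        taxa = frozenset(taxa)
        out = set()
        for bp in raw:
            r = bp.restrict(taxa & bp.taxon_set)
            if r is not None:
                out.add(r)
        return frozenset(out)

    @classmethod
    def from_split(
        cls, name: str, split: Bipartition, taxa: Iterable[str]
    ) -> "ConstraintHypothesis":
        """Constraint tree forcing a single split: one resolved clade in
        an otherwise unresolved polytomy."""
        taxa = frozenset(taxa)
        root = Node()
        clade = Node()
        for t in sorted(split.side_a):
            clade.add_child(Node(label=t))
        root.add_child(clade)
        for t in sorted(taxa - split.side_a):
            root.add_child(Node(label=t))
        return cls(name, PhyloTree(root, rooted=False))


def _check_satisfiable(splits: Iterable[Bipartition]) -> None:
    splits = list(splits)
    for i, a in enumerate(splits):
        for b in splits[i + 1 :]:
            if a.conflicts_with(b):
                raise TreeError(f"unsatisfiable constraint: {a} vs {b}")


def _tree_satisfies(tree: PhyloTree, splits: Iterable[Bipartition]) -> bool:
    taxa = tree.leaf_labels()
    have = None
    for bp in splits:
        r = bp.restrict(taxa & bp.taxon_set)
        if r is None:
            continue
        if have is None:
            from .trees import restricted_splits

            have = set(restricted_splits(tree, taxa))
        if r not in have:
            return False
    return True


def _fitch_score(tree: PhyloTree, aln: Alignment) -> int:
    """Fitch parsimony score over all sites (bitmask state sets)."""
    code = {}
    for ch, row in AMBIG.items():
        code[ch] = sum(1 << i for i, v in enumerate(row) if v)
    score = 0
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            seq = aln.sequences[node.label].upper()
            sets[id(node)] = np.array([code.get(c, 15) for c in seq], dtype=np.int8)
            continue
        acc = None
        for c in node.children:
            s = sets[id(c)]
            if acc is None:
                acc = s
                continue
            inter = acc & s
            union = acc | s
            miss = inter == 0
            score += int(miss.sum())
            acc = np.where(miss, union, inter)
        sets[id(node)] = acc
    return score


def _insert_leaf(tree: PhyloTree, target: Node, label: str, bl: float = 0.1) -> Node:
    """Split the branch above ``target`` and attach a new leaf there."""
    parent = target.parent
    mid = Node(length=bl)
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add_child(target)
    target.length = bl
    leaf = Node(label=label, length=bl)
    mid.add_child(leaf)
    return leaf


def _stepwise_parsimony(
    taxa: Sequence[str], aln: Alignment, constraint_splits: frozenset[Bipartition]
) -> PhyloTree:
    """Deterministic constraint-respecting stepwise-addition start tree."""
    taxa = sorted(taxa)
    root = Node()
    for t in taxa[:3]:
        root.add_child(Node(label=t, length=0.1))
    tree = PhyloTree(root, rooted=False)
    for label in taxa[3:]:
        sub = aln.subset([n.label for n in tree.leaves()] + [label])
        best = None
        current = frozenset(tree.leaf_labels() | {label})
        for target in list(tree.postorder()):
            if target is tree.root:
                continue
            leaf = _insert_leaf(tree, target, label)
            ok = _tree_satisfies(tree, constraint_splits)
            if ok:
                s = _fitch_score(tree, sub)
                if best is None or s < best[0]:
                    best = (s, target)
            # undo insertion
            mid = leaf.parent
            parent = mid.parent
            mid.remove_child(leaf)
            kept = mid.children[0]
            idx = parent.children.index(mid)
            parent.children[idx] = kept
            kept.parent = parent
        if best is None:
            raise TreeError("unsatisfiable constraint: no valid placement for " + label)
        _insert_leaf(tree, best[1], label)
    return tree


def _nni_moves(tree: PhyloTree):
    """Yield (edge_node, swap_index) for the two NNIs at each internal edge."""
    for v in tree.internal_nodes(exclude_root=True):
        if len(v.children) != 2:
            continue
        u = v.parent
        sibs = [c for c in u.children if c is not v]
        if not sibs:
            continue
        yield v, 0
        yield v, 1


def _apply_nni(tree: PhyloTree, v: Node, which: int) -> None:
    """Swap v's child ``which`` with v's first sibling (in place)."""
    u = v.parent
    s = next(c for c in u.children if c is not v)
    c = v.children[which]
    iu = u.children.index(s)
    iv = v.children.index(c)
    u.children[iu] = c
    c.parent = u
    v.children[iv] = s
    s.parent = v
    # the edge (u, v) keeps its length; supports are meaningless mid-search


def constrained_search(
    aln: Alignment,
    constraint: ConstraintHypothesis,
    model: SubstModel,
    starting_tree: Optional[PhyloTree] = None,
    tol: float = 1e-6,
    quick_sweeps: int = 1,
) -> tuple[PhyloTree, float]:
    """Maximum-likelihood topology under a constraint.

    Stepwise parsimony addition (respecting the constraint) seeds the
    search; NNI moves that preserve every resolved constraint split then
    hill-climb on the optimized log-likelihood.  Deterministic for a
    given alignment/constraint/model.
    """
    taxa = sorted(aln.taxa)
    csplits = constraint.splits(taxa)
    _check_satisfiable(csplits)
    if starting_tree is not None:
        tree = starting_tree.unrooted_copy()
        if not _tree_satisfies(tree, csplits):
            raise TreeError("starting tree violates the constraint")
    else:
        tree = _stepwise_parsimony(taxa, aln, csplits)
    for n in tree.postorder():
        if n is not tree.root and (n.length is None or not np.isfinite(n.length)):
            n.length = 0.1
    # coarse tolerance while searching; a final polish runs at ``tol``
    search_tol = max(tol, 1e-3)
    tree, ll = optimize_branch_lengths(aln, tree, model, tol=search_tol, warn=False)
    n_taxa = len(taxa)
    for _round in range(4 * n_taxa):
        best: Optional[tuple[float, PhyloTree]] = None
        for v, which in list(_nni_moves(tree)):
            cand = tree.copy()
            # map v onto the copy by postorder position
            pos = list(tree.postorder()).index(v)
            cv = list(cand.postorder())[pos]
            _apply_nni(cand, cv, which)
            if not _tree_satisfies(cand, csplits):
                continue
            # cheap local score: re-optimize only the branches around the
            # rearranged edge; the survivor gets a full optimization below
            at = _ArrTree(cand, aln)
            iv = at.index[id(cv)]
            local = {iv, at.parent[iv], *at.children[iv]}
            if at.parent[iv] != -1:
                local.update(at.children[at.parent[iv]])
            local.discard(-1)
            cll = _optimize_arr(
                at, model, tol=search_tol, max_sweeps=quick_sweeps,
                nodes=sorted(local), xatol=1e-5,
            )
            at.write_lengths_back()
            if best is None or cll > best[0]:
                best = (cll, cand)
        if best is None or best[0] <= ll + search_tol:
            break
        tree, ll = optimize_branch_lengths(aln, best[1], model, tol=search_tol, warn=False)
    tree, ll = optimize_branch_lengths(aln, tree, model, tol=tol, warn=False)
    return tree, ll


def score_fixed_topology(
    aln: Alignment, tree: PhyloTree, model: SubstModel, tol: float = 1e-6
) -> float:
    """Branch-length-optimized log-likelihood of a fixed topology."""
    _, ll = optimize_branch_lengths(aln, tree, model, tol=tol, warn=False)
    return ll


# ----------------------------------------------------------------------
# model estimation


def estimate_model(
    aln: Alignment,
    tree: Optional[PhyloTree] = None,
    n_rate_categories: int = 4,
    maxiter: int = 60,
) -> SubstModel:
    """Per-gene GTR+Gamma parameters by ML on a starting tree.

    Base frequencies are empirical; exchangeabilities (GT fixed at 1)
    and the Gamma shape are optimized on the starting topology (stepwise
    parsimony if none given) with branch lengths re-optimized once.
    """
    base = SubstModel.from_alignment(aln, gamma_alpha=0.5,
                                     n_rate_categories=n_rate_categories)
    if tree is None:
        tree = _stepwise_parsimony(sorted(aln.taxa), aln, frozenset())
        for n in tree.postorder():
            if n is not tree.root and n.length is None:
                n.length = 0.1
    tree, _ = optimize_branch_lengths(aln, tree, base, warn=False)

    def build(theta: np.ndarray) -> SubstModel:
        ex = np.append(np.exp(theta[:5]), 1.0)
        return SubstModel(base.freqs, ex, float(np.exp(theta[5])), n_rate_categories)

    def neg(theta: np.ndarray) -> float:
        try:
            return -log_likelihood(aln, tree, build(theta))
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = np.zeros(6)
    x0[5] = math.log(0.5)
    res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": maxiter})
    return build(res.x)


# ----------------------------------------------------------------------
# the edge test


@dataclass
class EdgeTestResult:
    """Per-gene and summed constrained log-likelihoods per hypothesis."""

    table: pd.DataFrame  # genes x hypotheses, full precision
    flagged_genes: list[str]
    trees: dict[tuple[str, str], PhyloTree] = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def best_hypothesis(self) -> str:
        totals = self.totals
        best = totals.max()
        return sorted(totals.index[totals == best])[0]

    @property
    def per_gene_best(self) -> pd.Series:
        return self.table.idxmax(axis=1)

    def rounded_totals(self) -> pd.Series:
        """Display form: log-likelihood totals rounded to whole numbers."""
        return self.totals.round(0).astype(int)


def edge_test(
    genes: Sequence[tuple[str, Alignment]],
    hypotheses: Sequence[ConstraintHypothesis],
    model: Union[SubstModel, Mapping[str, SubstModel], None] = None,
    keep_trees: bool = False,
    tol: float = 1e-6,
) -> EdgeTestResult:
    """Gene-wise edge test over alternative constraint hypotheses.

    For every gene and hypothesis the constrained maximum log-likelihood
    is computed; per-hypothesis totals are the column sums and the best
    hypothesis attains the maximum total.  A gene whose sampled taxa
    cannot distinguish the hypotheses (all restricted constraints
    identical) is scored unconstrained once, contributes that score to
    every hypothesis, and is flagged.  Model parameters are fixed per
    gene: supplied directly, per gene by name, or estimated when None.
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least 2 hypotheses")
    names = [h.name for h in hypotheses]
    if len(set(names)) != len(names):
        raise ValueError("duplicate hypothesis names")
    rows = {}
    flagged = []
    trees: dict[tuple[str, str], PhyloTree] = {}
    for gene, aln in genes:
        if isinstance(model, SubstModel):
            m = model
        elif model is None:
            m = estimate_model(aln)
        else:
            m = model[gene]
        taxa = frozenset(aln.taxa)
        restricted = [h.splits(taxa) for h in hypotheses]
        if len(set(restricted)) == 1:
            star = ConstraintHypothesis(
                "unconstrained", _star_tree(sorted(taxa))
            )
            t, ll = constrained_search(aln, star, m, tol=tol)
            rows[gene] = {h.name: ll for h in hypotheses}
            flagged.append(gene)
            if keep_trees:
                for h in hypotheses:
                    trees[(gene, h.name)] = t
            continue
        scores = {}
        for h in hypotheses:
            t, ll = constrained_search(aln, h, m, tol=tol)
            scores[h.name] = ll
            if keep_trees:
                trees[(gene, h.name)] = t
        rows[gene] = scores
    table = pd.DataFrame.from_dict(rows, orient="index")[names]
    table.index.name = "gene"
    return EdgeTestResult(table=table, flagged_genes=flagged, trees=trees)


def _star_tree(taxa: Sequence[str]) -> PhyloTree:
    root = Node()
    for t in taxa:
        root.add_child(Node(label=t))
    return PhyloTree(root, rooted=False)
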