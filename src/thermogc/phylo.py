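"""Tree handling and phylogenetic covariance construction.

A rooted tree with branch lengths is the coordinate system for every
comparative analysis in this package: the phylogenetic covariance of a
Brownian trait between two tips is the length of their shared root-to-MRCA
path, and all four trait-evolution models (BM, Pagel's lambda, OU with the
ancestral state estimated at the root, early burst) are expressed as
transforms of that base matrix.

Trees are stored as thin wrappers around :class:`dendropy.Tree`; dendropy
does the Newick parsing and writing, while covariance math, Brownian trait
simulation and GLS ancestral-state reconstruction live here.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

MODELS = ("BM", "OU_fixed_root", "lambda", "EB")

#: Diagonal jitter factor applied when a covariance matrix with duplicate
#: rows (zero-length terminal branches) fails its Cholesky factorization.
JITTER = 1e-10


class NewickError(ValueError):
    """Malformed Newick input (syntax, duplicate labels, missing lengths)."""


@dataclass
class ModelParams:
    """Parameters of one of the four trait-evolution models.

    Only the parameters of the named model are meaningful: ``lam`` for the
    Pagel's-lambda model (in [0, 1]), ``alpha`` (> 0) for the fixed-root OU
    model, ``r`` (any sign) for the early-burst rate exponent.  ``sigma2``
    is the Brownian rate common to all models.
    """

    model: str = "BM"
    sigma2: float = 1.0
    lam: float = 1.0
    alpha: float = 1.0
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.model == "lambda" and not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        if self.model == "OU_fixed_root" and self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class PhyloCovariance:
    """Base phylogenetic covariance for a tip subset.

    ``C[i, j]`` is the shared root-to-MRCA path length of tips ``i`` and
    ``j``; the diagonal holds total root-to-tip distances.  Patristic
    distance is recoverable as ``C[i,i] + C[j,j] - 2 C[i,j]``.
    """

    tip_order: list[str]
    C: np.ndarray

    def patristic(self) -> np.ndarray:
        d = np.diag(self.C)
        return d[:, None] + d[None, :] - 2.0 * self.C


class Branch:
    """One branch, identified by its child node, with its descendant tips."""

    __slots__ = ("id", "length", "tip_indices", "child_is_tip", "parent_id")

    def __init__(self, id: str, length: float, tip_indices: np.ndarray,
                 child_is_tip: bool, parent_id: str) -> None:
        self.id = id
        self.length = length
        self.tip_indices = tip_indices
        self.child_is_tip = child_is_tip
        self.parent_id = parent_id


class PhyloTree:
    """Rooted tree with branch lengths, unique tip labels, single root.

    Polytomies are accepted throughout; no analysis here requires a binary
    resolution.  Zero-length branches are legal — downstream matrix solves
    add a logged diagonal jitter when they make the covariance singular.
    """

    def __init__(self, dtree: dendropy.Tree) -> None:
        self._tree = dtree
        self._index_nodes()

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    # ------------------------------------------------------------- indexing
    def _index_nodes(self) -> None:
        tree = self._tree
        seen: set[str] = set()
        self.tip_labels: list[str] = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickError("tip without a label")
            lab = leaf.taxon.label
            if lab in seen:
                raise NewickError(f"duplicate tip label {lab!r}")
            seen.add(lab)
            self.tip_labels.append(lab)
        if len(self.tip_labels) < 2:
            raise NewickError("tree must have at least 2 tips")
        # Stable ids for internal nodes: existing label, else node<k> in preorder.
        k = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd._tgc_id = nd.taxon.label
            elif nd.label:
                nd._tgc_id = nd.label
            else:
                nd._tgc_id = f"node{k}"
            k += 1
        root = tree.seed_node
        root._tgc_depth = 0.0
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above {nd._tgc_id!r}")
            if nd.edge.length < 0:
                raise NewickError(f"negative branch length above {nd._tgc_id!r}")
            nd._tgc_depth = nd.parent_node._tgc_depth + nd.edge.length
        tipidx = {lab: i for i, lab in enumerate(self.tip_labels)}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd._tgc_tips = np.array([tipidx[nd.taxon.label]], dtype=np.intp)
            else:
                nd._tgc_tips = np.concatenate([c._tgc_tips for c in nd.child_nodes()])

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-node distance for every node (tips and internals)."""
        return {nd._tgc_id: nd._tgc_depth for nd in self._tree.preorder_node_iter()}

    def total_length(self) -> float:
        return sum(nd.edge.length for nd in self._tree.preorder_node_iter()
                   if nd.parent_node is not None)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = [nd._tgc_depth for nd in self._tree.leaf_node_iter()]
        return max(d) - min(d) <= tol * max(max(d), 1.0)

    def branches(self) -> list[Branch]:
        """All non-root branches in preorder, with descendant-tip index sets."""
        out = []
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            out.append(Branch(nd._tgc_id, float(nd.edge.length), nd._tgc_tips,
                              nd.is_leaf(), nd.parent_node._tgc_id))
        return out

    # ------------------------------------------------------------- pruning
    def prune_to(self, tips: Sequence[str]) -> "PhyloTree":
        """Subtree induced by ``tips`` (root-to-tip depths preserved)."""
        want = set(tips)
        unknown = want - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in want]
        clone.retain_taxa(taxa)
        # retain_taxa may leave the root with a single child; keep as is —
        # covariance math only uses depths, which are preserved.
        return PhyloTree(clone)

    # ---------------------------------------------------------- covariance
    def covariance(self, tips: Sequence[str] | None = None) -> PhyloCovariance:
        """Base matrix of shared root-to-MRCA path lengths for ``tips``."""
        order = list(tips) if tips is not None else list(self.tip_labels)
        if not order:
            raise ValueError("tip subset must be non-empty")
        unknown = set(order) - set(self.tip_labels)
        if unknown:
            raise KeyError(f"unknown tip label(s): {sorted(unknown)}")
        full_idx = {lab: i for i, lab in enumerate(self.tip_labels)}
        n_all = self.n_tips
        Cfull = np.zeros((n_all, n_all))
        # For every internal node at depth t, tip pairs whose MRCA is that
        # node get C_ij = t; assign by overwriting from root downward so the
        # deepest common ancestor wins.
        for nd in self._tree.preorder_node_iter():
            ix = nd._tgc_tips
            Cfull[np.ix_(ix, ix)] = nd._tgc_depth
        for nd in self._tree.leaf_node_iter():
            i = full_idx[nd.taxon.label]
            Cfull[i, i] = nd._tgc_depth
        sel = np.array([full_idx[lab] for lab in order], dtype=np.intp)
        return PhyloCovariance(order, Cfull[np.ix_(sel, sel)])


# -------------------------------------------------------------------- I/O

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Raises :class:`NewickError` naming the offending token for malformed
    strings, duplicate tip labels or missing branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    return PhyloTree(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths (repr precision, round-trip safe)."""
    s = tree._tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return s.strip() + "\n"


# ------------------------------------------------------- model covariance

def _chol_with_jitter(V: np.ndarray, context: str = "covariance"):
    """Cholesky factor, retrying once with logged diagonal jitter."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        eps = JITTER * float(np.mean(np.diag(V)))
        logger.warning("%s not positive definite; adding diagonal jitter %.3e",
                       context, eps)
        try:
            return linalg.cholesky(V + eps * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"{context} is singular even after jitter") from exc


def model_covariance(cov: PhyloCovariance, params: ModelParams) -> np.ndarray:
    """Trait covariance among tips under one of the four models.

    BM: ``sigma2 * C``.  lambda: off-diagonals scaled by lambda.  OU (fixed
    root): stationary-variance form ``sigma2/(2 alpha) (1 - exp(-2 alpha
    t_ij)) exp(-alpha d_ij)`` with ``t_ij`` the shared path and ``d_ij``
    the patristic distance.  EB: ``sigma2 (exp(r t_ij) - 1)/r`` with the
    ``r -> 0`` limit ``sigma2 t_ij``.
    """
    C = cov.C
    s2 = params.sigma2
    if params.model == "BM":
        return s2 * C
    if params.model == "lambda":
        V = params.lam * C
        np.fill_diagonal(V, np.diag(C))
        return s2 * V
    if params.model == "OU_fixed_root":
        a = params.alpha
        d = cov.patristic()
        return s2 / (2.0 * a) * (1.0 - np.exp(-2.0 * a * C)) * np.exp(-a * d)
    if params.model == "EB":
        r = params.r
        if abs(r) < 1e-9:
            return s2 * C
        return s2 * np.expm1(r * C) / r
    raise ValueError(params.model)  # pragma: no cover


# --------------------------------------------------------- trait simulation

def simulate_traits(tree: PhyloTree, Sigma: np.ndarray,
                    roots: Sequence[float] = (0.0, 0.0),
                    seed: int | np.random.Generator = 0,
                    n_rep: int = 1) -> np.ndarray:
    """Simulate correlated bivariate Brownian traits at the tips.

    Draws from the exact matrix-normal implied by bivariate BM with
    evolutionary (per-unit-time) covariance ``Sigma`` (2x2, symmetric PSD)
    and root states ``roots``: vec-covariance is ``Sigma (x) C``.

    Returns an array of shape ``(n_rep, n_tips, 2)`` (``n_rep=1`` still
    keeps the leading axis; callers index ``[0]``).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape != (2, 2) or not np.allclose(Sigma, Sigma.T):
        raise ValueError("Sigma must be a symmetric 2x2 matrix")
    evals = np.linalg.eigvalsh(Sigma)
    if evals.min() < -1e-12 * max(evals.max(), 1.0):
        raise ValueError("Sigma must be positive semidefinite")
    rng = np.random.default_rng(seed)
    C = tree.covariance().C
    Lc = _chol_with_jitter(C + 1e-12 * np.mean(np.diag(C)) * np.eye(len(C)),
                           "tree covariance")
    # PSD-safe factor of Sigma (allows perfectly correlated traits).
    w, U = np.linalg.eigh(Sigma)
    Ls = U * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((n_rep, C.shape[0], 2))
    X = np.einsum("ij,rjk,lk->ril", Lc, Z, Ls)
    return X + np.asarray(roots, dtype=float)


# --------------------------------------------------- ancestral reconstruction

def ancestral_states(tree: PhyloTree, x: dict[str, float] | Sequence[float]) -> dict[str, float]:
    """ML (GLS) ancestral states under Brownian motion.

    The root estimate is the GLS mean ``(1' C^-1 1)^-1 1' C^-1 x``; every
    internal node is its conditional expectation given the tips, using
    shared-path covariances between the node and each tip.
    """
    labels = tree.tip_labels
    if isinstance(x, dict):
        xv = np.array([x[lab] for lab in labels], dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (len(labels),):
            raise ValueError("x must have one value per tip")
    C = tree.covariance().C
    if float(np.max(np.diag(C))) <= 0:
        raise ValueError("degenerate tree: zero total depth")
    L = _chol_with_jitter(C, "tree covariance")
    one = np.ones(len(xv))
    Ci1 = linalg.cho_solve((L, True), one)
    mu = float(one @ linalg.cho_solve((L, True), xv) / (one @ Ci1))
    w = linalg.cho_solve((L, True), xv - mu * one)
    tipidx = {lab: i for i, lab in enumerate(labels)}
    # cov(node v, tip i) = depth(v) if tip descends from v, else the shared
    # depth of any descendant tip of v with tip i.
    out: dict[str, float] = {}
    for nd in tree._tree.preorder_node_iter():
        if nd.is_leaf():
            out[nd._tgc_id] = float(xv[tipidx[nd.taxon.label]])
            continue
        cv = np.empty(len(xv))
        rep = nd._tgc_tips[0]
        cv[:] = C[rep, :]
        cv[nd._tgc_tips] = nd._tgc_depth
        out[nd._tgc_id] = mu + float(cv @ w)
    root_id = tree._tree.seed_node._tgc_id
    out[root_id] = mu
    return out
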