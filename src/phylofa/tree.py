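"""Rooted-tree handling for phylogenetic comparative analysis.

A :class:`Phylogeny` wraps a rooted ``dendropy`` tree with branch lengths and
exposes the quantities the comparative methods need: the phylogenetic
covariance matrix ``C`` (shared root-to-MRCA path lengths under Brownian
motion), Pagel's λ branch-length transform, the largest admissible λ for an
ultrametric tree, pruning to a taxon subset, and seeded Brownian-motion trait
simulation.

Taxon order is canonical everywhere: tip labels sorted lexicographically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "TreeStructureError",
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "read_newick",
    "write_newick",
    "is_ultrametric",
    "phylo_covariance",
    "lambda_transform",
    "lambda_max",
    "simulate_bm",
    "prune_to_taxa",
    "normalize_label",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or missing labels, absent branch lengths)."""


class TreeStructureError(ValueError):
    """Tree violates a structural precondition (e.g. non-ultrametric where required)."""


def normalize_label(label: str) -> str:
    """Canonical taxon label: trimmed, underscores mapped to single spaces.

    Applied on both the tree and trait-table side before any join, so
    ``"Isotoma_viridis"`` and ``" Isotoma viridis "`` reconcile.
    """
    return " ".join(label.replace("_", " ").split())


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths.

    Wraps a :class:`dendropy.Tree`; tip labels are normalized and unique.
    """

    _tree: dendropy.Tree
    tip_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [normalize_label(leaf.taxon.label) for leaf in self._tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickError(f"duplicate tip labels: {sorted(dupes)}")
        if any(not l for l in labels):
            raise NewickError("empty tip label")
        for leaf, l in zip(self._tree.leaf_node_iter(), labels):
            leaf.taxon.label = l
        root = self._tree.seed_node
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "(internal node)"
                raise NewickError(f"missing branch length on edge leading to {name!r}")
            if edge.length < 0:
                raise NewickError(f"negative branch length {edge.length}")
        self.tip_names = sorted(labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        depths: dict[str, float] = {}
        for node, d in self._node_depths().items():
            if node.is_leaf():
                depths[node.taxon.label] = d
        return depths

    def _node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = float(node.edge.length or 0.0)
            else:
                depths[node] = depths[node.parent_node] + float(node.edge.length)
        return depths

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def to_newick(self) -> str:
        # .17g keeps branch lengths exact through write/parse round trips
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".17g"
        )
        return s.strip()

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance structure of a rooted tree.

    ``C[i, j]`` is the root-to-MRCA path length of taxa ``i`` and ``j``;
    the diagonal holds root-to-tip depths. Rows/columns follow ``taxa``
    (sorted tip labels).
    """

    C: np.ndarray
    taxa: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.taxa)

    def submatrix(self, names: list[str]) -> "PhyloCovariance":
        order = sorted(names)
        missing = [t for t in order if t not in self.taxa]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = [self.taxa.index(t) for t in order]
        return PhyloCovariance(self.C[np.ix_(idx, idx)], tuple(order))


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Internal node labels and support values are tolerated and ignored;
    every non-root edge must carry a branch length.
    """
    if text.count("(") != text.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"newick parse failure: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    s = tree.to_newick()
    if not s.endswith(";"):
        s += ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def is_ultrametric(tree: Phylogeny, rtol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within ``rtol`` of tree height."""
    depths = np.array(list(tree.tip_depths().values()))
    h = depths.max()
    if h == 0:
        return True
    return bool(np.all(np.abs(depths - h) <= rtol * h))


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Shared-path-length matrix C of a rooted tree, taxa in sorted order."""
    taxa = tuple(tree.tip_names)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    depths = tree._node_depths()
    # For every internal node, tip pairs whose MRCA is that node are those
    # drawn from two different child subtrees; their C entry is its depth.
    tipsets: dict[dendropy.Node, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            C[i, i] = depths[node]
        else:
            d = depths[node]
            kids = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
            tipsets[node] = [i for k in kids for i in k]
    return PhyloCovariance(C, taxa)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's λ transform: off-diagonal entries scaled by ``lam``, diagonal kept."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(C, cov.taxa)


def lambda_max(tree: Phylogeny, rtol: float = 1e-6) -> float:
    """Largest λ whose transform still corresponds to a valid ultrametric tree.

    Equals tree height divided by the depth of the deepest internal node
    other than the root; 1.0 for a star tree (no such node).
    """
    if not is_ultrametric(tree, rtol=rtol):
        raise TreeStructureError("lambda_max requires an ultrametric tree")
    depths = tree._node_depths()
    h = tree.height
    internal = [
        d
        for node, d in depths.items()
        if not node.is_leaf() and node.parent_node is not None and d > 0
    ]
    if not internal:
        return 1.0
    return h / max(internal)


def _mvn_factor(C: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix, tolerant of zero eigenvalues."""
    w, U = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def simulate_bm(
    tree: Phylogeny,
    sigma2: float = 1.0,
    n_traits: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate Brownian-motion traits at the tips.

    Returns an ``(n_tips, n_traits)`` array, one column per independent draw
    from N(0, sigma2·C); rows follow the canonical (sorted) taxon order.
    """
    if n_traits <= 0:
        raise ValueError("n_traits must be positive")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cov = phylo_covariance(tree)
    L = _mvn_factor(sigma2 * cov.C)
    Z = rng.standard_normal((cov.n, n_traits))
    return L @ Z


def prune_to_taxa(tree: Phylogeny, names) -> Phylogeny:
    """Induced subtree on ``names``; unifurcations collapsed, lengths summed."""
    wanted = {normalize_label(n) for n in names}
    unknown = sorted(wanted - set(tree.tip_names))
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    clone = tree._tree.clone(depth=1)
    clone.retain_taxa_with_labels(list(wanted))
    clone.purge_taxon_namespace()
    return Phylogeny(clone)
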