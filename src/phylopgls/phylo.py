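"""Phylogenies and the covariance/correlation matrices PGLS needs.

A :class:`Phylogeny` is a thin wrapper around a rooted :class:`dendropy.Tree`
with non-negative branch lengths.  It is the single source of covariance
structure for the regression machinery: under Brownian motion the covariance
between two species is the depth of their most recent common ancestor (the
branch length their root-to-tip paths share); Pagel's lambda shrinks the
off-diagonal shared paths toward zero; the Ornstein-Uhlenbeck structure is a
correlation decaying exponentially with patristic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CovarianceModel",
    "CovMatrix",
    "read_tree",
    "prune_tip",
    "bm_covariance",
    "patristic_distances",
    "apply_structure",
]

STRUCTURES = ("brownian", "pagel", "ou")


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


def normalize_label(label: str) -> str:
    """Unify whitespace and underscores in a species label.

    Newick files (10kTrees among them) write ``Pan_troglodytes`` while trait
    tables often write ``Pan troglodytes``; both normalize to the underscore
    form.  Matching is case-sensitive after normalization.
    """
    return "_".join(str(label).split())


@dataclass(frozen=True)
class CovarianceModel:
    """An evolutionary correlation family plus its scalar parameter.

    kind
        One of ``brownian`` (no parameter), ``pagel`` (lambda in [0, 1]) or
        ``ou`` (alpha > 0).
    parameter
        lambda or alpha; must be None for ``brownian``.
    """

    kind: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in STRUCTURES:
            raise ValueError(
                f"unknown correlation structure {self.kind!r}; expected one of {STRUCTURES}"
            )
        if self.kind == "brownian":
            if self.parameter is not None:
                raise ValueError("brownian structure takes no parameter")
        elif self.kind == "pagel":
            if self.parameter is None or not 0.0 <= self.parameter <= 1.0:
                raise ValueError(f"Pagel's lambda must lie in [0, 1], got {self.parameter}")
        elif self.kind == "ou":
            if self.parameter is None or self.parameter <= 0.0:
                raise ValueError(f"OU alpha must be > 0, got {self.parameter}")


@dataclass
class CovMatrix:
    """A symmetric matrix labeled by species, in a fixed species order."""

    species_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species_order)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match species_order length")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_order, columns=self.species_order)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")

    def reorder(self, species: list[str]) -> "CovMatrix":
        idx = [self.species_order.index(s) for s in species]
        return CovMatrix(list(species), self.values[np.ix_(idx, idx)])


class Phylogeny:
    """A rooted tree with labeled tips and non-negative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeError("every tip must carry a non-empty label")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dups = {x for x in labels if labels.count(x) > 1}
        if dups:
            raise TreeError(f"duplicate tip labels: {sorted(dups)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise TreeError(
                    f"missing branch length on the edge above "
                    f"{self._describe_node(edge.head_node)}"
                )
            if edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")
        self._tips = labels

    @staticmethod
    def _describe_node(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return f"tip {node.taxon.label!r}"
        some = [l.taxon.label for l in node.leaf_iter()][:3]
        return f"internal node above {some}"

    # -- basic accessors ---------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels, in the tree's leaf-iteration order."""
        return list(self._tips)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (treat as read-only)."""
        return self._tree

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        return {
            leaf.taxon.label: leaf.distance_from_root() for leaf in self._tree.leaf_node_iter()
        }

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self.depths().values())

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:
        return f"Phylogeny(n_tips={self.n_tips}, depth={self.depth:.4g})"

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def prune(self, species: str | list[str]) -> "Phylogeny":
        """Remove one or more tips, fusing the freed edges.

        Path lengths among the surviving tips are unchanged: when a removal
        leaves a degree-two node, its two incident edges are merged and their
        lengths summed.
        """
        drop = [species] if isinstance(species, str) else list(species)
        drop = [normalize_label(s) for s in drop]
        missing = [s for s in drop if s not in self._tips]
        if missing:
            raise TreeError(
                f"unknown tip(s) {missing}; available tips: {sorted(self._tips)}"
            )
        if len(self._tips) - len(drop) < 1:
            raise TreeError("cannot prune away every tip")
        tree = self._tree.clone(depth=1)
        # detach from the shared taxon namespace before pruning so the
        # original tree is untouched
        tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
        tree.prune_taxa_with_labels(drop, suppress_unifurcations=True)
        tree.purge_taxon_namespace()
        return Phylogeny(tree)

    # -- matrices ----------------------------------------------------------

    def _tip_nodes(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    def bm_covariance(self) -> CovMatrix:
        """Brownian-motion covariance: V[i, j] = depth of MRCA(i, j).

        The diagonal is each tip's root-to-tip depth.  Computed by a single
        postorder sweep: an internal node at depth d sets V[i, j] = d for
        every tip pair split between two of its child subtrees.
        """
        if self.n_tips < 2:
            raise TreeError("covariance needs at least 2 tips")
        tip_index = {label: i for i, label in enumerate(self._tips)}
        n = self.n_tips
        V = np.zeros((n, n))
        node_depth: dict[int, float] = {}
        below: dict[int, list[int]] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            d = 0.0 if parent is None else node_depth[id(parent)] + (node.edge.length or 0.0)
            node_depth[id(node)] = d
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = tip_index[node.taxon.label]
                below[id(node)] = [i]
                V[i, i] = node_depth[id(node)]
                continue
            child_sets = [below[id(c)] for c in node.child_nodes()]
            d = node_depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            V[i, j] = V[j, i] = d
            below[id(node)] = [i for s in child_sets for i in s]
        return CovMatrix(self.tips, V)

    def patristic_distances(self) -> CovMatrix:
        """Tip-to-tip path lengths: d_ij = depth_i + depth_j - 2 depth_MRCA."""
        V = self.bm_covariance()
        diag = np.diag(V.values)
        D = diag[:, None] + diag[None, :] - 2.0 * V.values
        np.fill_diagonal(D, 0.0)
        return CovMatrix(V.species_order, D)


# -- module-level functional API ------------------------------------------


def read_tree(text: str, schema: str | None = None) -> Phylogeny:
    """Parse a single rooted tree from a Newick or NEXUS string or file path.

    Tip labels are normalized (whitespace and underscores unified); branch
    lengths are required on every non-root edge.
    """
    if "\n" not in text and not text.strip().endswith(";"):
        try:
            with open(text) as fh:
                text = fh.read()
        except OSError as exc:
            raise TreeError(f"input is neither a tree string nor a readable file: {exc}")
    if schema is None:
        schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text, schema=schema, preserve_underscores=True, rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises assorted parse error classes
        raise TreeError(f"could not parse {schema} tree: {exc}") from exc
    return Phylogeny(tree)


def prune_tip(tree: Phylogeny, species: str) -> Phylogeny:
    """Remove one tip; patristic distances among survivors are preserved."""
    return tree.prune(species)


def bm_covariance(tree: Phylogeny) -> CovMatrix:
    return tree.bm_covariance()


def patristic_distances(tree: Phylogeny) -> CovMatrix:
    return tree.patristic_distances()


def apply_structure(tree: Phylogeny, model: CovarianceModel) -> CovMatrix:
    """Build the (co)variance matrix implied by a correlation structure.

    brownian
        Raw BM covariance (shared root-to-MRCA path lengths).
    pagel
        BM covariance with every off-diagonal multiplied by lambda; the
        diagonal is untouched, so lambda=1 is exactly Brownian and lambda=0
        is a diagonal (phylogeny-free) matrix.
    ou
        Correlation exp(-alpha * d_ij) of the patristic distance d_ij, with a
        unit diagonal; large alpha approaches independence.
    """
    if model.kind == "brownian":
        return tree.bm_covariance()
    if model.kind == "pagel":
        V = tree.bm_covariance()
        lam = float(model.parameter)
        out = V.values * lam
        np.fill_diagonal(out, np.diag(V.values))
        return CovMatrix(V.species_order, out)
    D = tree.patristic_distances()
    out = np.exp(-float(model.parameter) * D.values)
    np.fill_diagonal(out, 1.0)
    return CovMatrix(D.species_order, out)
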