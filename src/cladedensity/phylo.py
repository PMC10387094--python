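"""Tree I/O, phylogenetic variance-covariance matrices, and tip speciation rates.

The two quantities computed here are the inputs to the clade-density
statistic and to the ES-sim test:

* the phylogenetic variance-covariance matrix C, whose entry ``C[i, j]`` is
  the depth (distance from the root) of the most recent common ancestor of
  tips i and j — the amount of shared evolutionary history, which under
  Brownian motion is the trait covariance of the two tips;
* the DR statistic, a per-tip speciation-rate estimator defined as the
  inverse of the "equal splits" measure
  ``ES_i = sum_j l_j * 2**-(j-1)`` over the root-to-tip edges of tip i,
  with the pendant edge first (j = 1).  Recent, short branches dominate,
  so lambda_DR tracks speciation rather than net diversification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloError",
    "PhyloTree",
    "TreeEnsemble",
    "VcvMatrix",
    "TipRateTable",
    "read_newick",
    "vcv",
    "dr_statistic",
    "restrict_rates",
]


class PhyloError(ValueError):
    """Raised for malformed trees or invalid tree-level requests."""


class PhyloTree:
    """A rooted, branch-length-bearing tree with uniquely labelled tips.

    Wraps a :class:`dendropy.Tree`, validating on construction that every
    tip carries a unique label, every non-root edge carries a branch
    length, and lengths are strictly positive (zero lengths only with
    ``allow_zero_lengths=True``).  Polytomies are rejected unless
    ``resolve_polytomies`` supplies a seed, in which case they are resolved
    randomly with zero-length internal edges.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        allow_zero_lengths: bool = False,
        resolve_polytomies: int | None = None,
    ) -> None:
        if resolve_polytomies is not None:
            rng = __import__("random").Random(resolve_polytomies)
            tree.resolve_polytomies(limit=2, update_bipartitions=False, rng=rng)
            for nd in tree.preorder_node_iter():
                if nd.edge.length is None and nd.parent_node is not None:
                    nd.edge.length = 0.0
            allow_zero_lengths = True
        self._tree = tree
        self._validate(allow_zero_lengths)
        self._tip_labels = tuple(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        self._depths: dict[dendropy.Node, float] | None = None

    # -- validation ----------------------------------------------------

    def _validate(self, allow_zero: bool) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise PhyloError("tree contains an unlabeled tip")
            if leaf.taxon.label in seen:
                raise PhyloError(f"duplicate tip label: {leaf.taxon.label!r}")
            seen.add(leaf.taxon.label)
        if len(seen) < 2:
            raise PhyloError("tree must have at least 2 tips")
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            length = nd.edge.length
            if length is None:
                raise PhyloError(
                    "missing branch length on edge above "
                    f"{_node_name(nd)!r} (pass default_edge_length to read_newick "
                    "to substitute a value)"
                )
            if length < 0 or (length == 0 and not allow_zero):
                raise PhyloError(
                    f"non-positive branch length {length} above {_node_name(nd)!r}"
                )
            nkids = len(nd.child_nodes())
            if nkids > 2:
                raise PhyloError(
                    f"polytomy ({nkids} children) at {_node_name(nd)!r}; pass "
                    "resolve_polytomies=<seed> to resolve randomly"
                )
        if len(self._tree.seed_node.child_nodes()) > 2:
            raise PhyloError(
                "polytomy at the root; pass resolve_polytomies=<seed>"
            )

    # -- accessors -----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance from the root to every node (root depth 0; any root
        edge length is ignored)."""
        if self._depths is None:
            depths: dict[dendropy.Node, float] = {self._tree.seed_node: 0.0}
            for nd in self._tree.preorder_node_iter():
                if nd.parent_node is not None:
                    depths[nd] = depths[nd.parent_node] + nd.edge.length
            self._depths = depths
        return self._depths

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance."""
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self._tree.leaf_node_iter())

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        depths = self.node_depths()
        tip_depths = [depths[leaf] for leaf in self._tree.leaf_node_iter()]
        span = max(tip_depths) - min(tip_depths)
        return span <= rel_tol * max(max(tip_depths), 1.0)

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, **kwargs) -> "PhyloTree":
        tree = _parse_one_newick(source)
        return cls(tree, **kwargs)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        ).strip()

    def write_newick(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, depth={self.depth:.4g})"


@dataclass(frozen=True)
class TreeEnsemble:
    """An ordered set of alternative topologies over one tip-label universe,
    used to propagate phylogenetic uncertainty through an analysis."""

    trees: tuple[PhyloTree, ...]

    def __post_init__(self) -> None:
        if not self.trees:
            raise PhyloError("empty tree ensemble")
        universe = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != universe:
                extra = set(t.tip_labels) ^ universe
                raise PhyloError(
                    f"tree {k} does not share the tip-label universe "
                    f"(mismatched labels: {sorted(extra)[:5]} ...)"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.trees[0].tip_labels


def _node_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None:
        return nd.taxon.label
    return nd.label or "<internal>"


def _parse_one_newick(source: str) -> dendropy.Tree:
    data = source
    if "(" not in source:  # looks like a path, not a newick string
        with open(source) as fh:
            data = fh.read()
    elif os.path.exists(source):
        with open(source) as fh:
            data = fh.read()
    try:
        return dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise PhyloError(f"could not parse newick: {exc}") from exc


def read_newick(
    source: str | os.PathLike,
    *,
    ensemble: bool = False,
    default_edge_length: float | None = None,
    allow_zero_lengths: bool = False,
    resolve_polytomies: int | None = None,
) -> PhyloTree | TreeEnsemble:
    """Read a newick tree (or, with ``ensemble=True``, one tree per line).

    Labels are preserved verbatim (underscores included) and branch lengths
    are read at full precision.  Missing branch lengths are an error unless
    ``default_edge_length`` supplies a substitute.
    """
    source = os.fspath(source) if not isinstance(source, str) else source
    kwargs = dict(
        allow_zero_lengths=allow_zero_lengths,
        resolve_polytomies=resolve_polytomies,
    )
    if not ensemble:
        tree = _parse_one_newick(source)
        _fill_missing_lengths(tree, default_edge_length)
        return PhyloTree(tree, **kwargs)
    if "(" in source and not os.path.exists(source):
        lines = [ln.strip() for ln in source.splitlines() if ln.strip()]
    else:
        with open(source) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    trees = []
    for ln in lines:
        tree = _parse_one_newick(ln)
        _fill_missing_lengths(tree, default_edge_length)
        trees.append(PhyloTree(tree, **kwargs))
    return TreeEnsemble(tuple(trees))


def _fill_missing_lengths(tree: dendropy.Tree, default: float | None) -> None:
    if default is None:
        return
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = default


# ---------------------------------------------------------------------
# Phylogenetic variance-covariance
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class VcvMatrix:
    """Phylogenetic variance-covariance matrix: C[i, j] = depth of the MRCA
    of tips i and j; C[i, i] = root-to-tip distance of tip i."""

    species: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise PhyloError("VCV shape does not match species list")
        if not np.allclose(m, m.T, rtol=0, atol=1e-10 * max(1.0, np.abs(m).max())):
            raise PhyloError("VCV must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.species), columns=list(self.species))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


def vcv(tree: PhyloTree, *, normalize_depth: bool = False) -> VcvMatrix:
    """Compute the phylogenetic VCV from branch lengths.

    ``C[i, j]`` is the shared root-path length of tips i and j, i.e. the
    depth of their MRCA; it is 0 exactly when the MRCA is the root.  By
    default raw branch-length units are kept; ``normalize_depth=True``
    rescales so the maximum tip depth is 1.
    """
    labels = tree.tip_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depths = tree.node_depths()
    tipsets: dict[dendropy.Node, np.ndarray] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            i = idx[nd.taxon.label]
            C[i, i] = depths[nd]
            tipsets[nd] = np.array([i])
        else:
            groups = [tipsets.pop(ch) for ch in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    C[np.ix_(groups[a], groups[b])] = d
                    C[np.ix_(groups[b], groups[a])] = d
            tipsets[nd] = np.concatenate(groups)
    if normalize_depth:
        C = C / C.diagonal().max()
    return VcvMatrix(labels, C)


# ---------------------------------------------------------------------
# DR statistic (equal splits)
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class TipRateTable:
    """Per-tip equal-splits measure ES and speciation rate lambda_DR = 1/ES.

    ``computed_on_full_tree`` records that values came from the complete
    phylogeny; :func:`restrict_rates` subsets without recomputation, so
    dropping tips with no geography never biases the rates downward.
    """

    species: tuple[str, ...]
    es: np.ndarray = field(repr=False)
    lambda_dr: np.ndarray = field(repr=False)
    computed_on_full_tree: bool = True

    def __post_init__(self) -> None:
        es = np.asarray(self.es, dtype=float)
        lam = np.asarray(self.lambda_dr, dtype=float)
        if not (np.all(es > 0) and np.all(lam > 0)):
            raise PhyloError("ES and lambda_DR must be strictly positive")
        object.__setattr__(self, "es", es)
        object.__setattr__(self, "lambda_dr", lam)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"es": self.es, "lambda_dr": self.lambda_dr},
            index=pd.Index(list(self.species), name="species"),
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def series(self) -> pd.Series:
        return pd.Series(self.lambda_dr, index=list(self.species), name="lambda_dr")


def dr_statistic(tree: PhyloTree) -> TipRateTable:
    """Equal-splits ES and lambda_DR for every tip.

    For tip i with root-to-tip edges ordered pendant-first
    (j = 1 pendant, ..., N_i root-adjacent):
    ``ES_i = sum_j l_j * 2**-(j-1)`` and ``lambda_DR_i = 1 / ES_i``.
    Halving the weight at each split means the pendant branch dominates,
    which is what makes the statistic sensitive to recent speciation.
    """
    labels = tree.tip_labels
    es = np.empty(len(labels))
    pos = {lab: i for i, lab in enumerate(labels)}
    for leaf in tree.tree.leaf_node_iter():
        total = 0.0
        w = 1.0
        nd = leaf
        while nd.parent_node is not None:
            total += nd.edge.length * w
            w *= 0.5
            nd = nd.parent_node
        if total <= 0:
            raise PhyloError(
                f"zero-length root-to-tip path for {leaf.taxon.label!r}; "
                "lambda_DR is undefined"
            )
        es[pos[leaf.taxon.label]] = total
    return TipRateTable(labels, es, 1.0 / es, computed_on_full_tree=True)


def restrict_rates(table: TipRateTable, keep: list[str] | tuple[str, ...]) -> TipRateTable:
    """Subset a rate table to ``keep`` without recomputing.

    Rates stay those of the full tree: recomputing on a pruned tree would
    collapse internal nodes into longer edges and bias lambda_DR downward.
    """
    keep = list(keep)
    pos = {lab: i for i, lab in enumerate(table.species)}
    unknown = [s for s in keep if s not in pos]
    if unknown:
        raise PhyloError(f"species not in rate table: {unknown}")
    sel = np.array([pos[s] for s in keep])
    return TipRateTable(
        tuple(keep),
        table.es[sel],
        table.lambda_dr[sel],
        computed_on_full_tree=table.computed_on_full_tree,
    )
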