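"""Phylogenetic trees as points in Billera-Holmes-Vogtmann (BHV) tree space.

A rooted phylogenetic tree on leaves ``0, 1, ..., N`` (the root is the leaf
labelled 0 by convention) is encoded as a set of *splits* -- bipartitions of
the leaf set induced by cutting a single edge -- together with a strictly
positive length for each split.  Tree space :math:`\\mathcal{T}_N` is the
union of Euclidean orthants, one per tree topology, glued along shared
boundary topologies; a tree is a point in this space and its internal edge
lengths are its orthant coordinates.

Splits are stored canonically as the set of leaves *not* containing the root,
encoded as an integer bitmask: leaf ``i`` (for non-root leaves, indexed
``1..N`` in the tree's taxon ordering) corresponds to bit ``i-1``.  Pendant
splits are singletons, the root edge is the full non-root set, and internal
splits have between 2 and N-1 leaves.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "Split",
    "Topology",
    "PhyloTree",
    "split_compatible",
    "validate_topology",
    "parse_newick",
    "parse_newick_list",
    "write_newick",
    "tree_norm",
    "trees_to_tsv",
]


class Split:
    """A bipartition of the leaf set, keyed by the side away from the root.

    Parameters
    ----------
    mask:
        Bitmask over the non-root leaves; bit ``i-1`` set means taxon at
        index ``i`` of the tree's taxon ordering lies on the far side of the
        edge from the root.
    nleaves:
        The number N of non-root leaves.
    """

    __slots__ = ("mask", "nleaves", "_hash")

    def __init__(self, mask: int, nleaves: int):
        full = (1 << nleaves) - 1
        if not 0 < mask <= full:
            raise ValueError(f"split mask {mask:#x} out of range for N={nleaves}")
        self.mask = mask
        self.nleaves = nleaves
        self._hash = hash((mask, nleaves))

    @classmethod
    def from_indices(cls, indices: Iterable[int], nleaves: int) -> "Split":
        """Build a split from 1-based non-root leaf indices."""
        mask = 0
        for i in indices:
            if not 1 <= i <= nleaves:
                raise ValueError(f"leaf index {i} outside 1..{nleaves}")
            mask |= 1 << (i - 1)
        return cls(mask, nleaves)

    def indices(self) -> frozenset[int]:
        """The 1-based leaf indices on the side away from the root."""
        return frozenset(
            i + 1 for i in range(self.nleaves) if self.mask >> i & 1
        )

    def leaves(self, taxa: tuple[str, ...]) -> frozenset[str]:
        """Leaf labels on the side away from the root, given a taxon order."""
        return frozenset(taxa[i] for i in self.indices())

    @property
    def size(self) -> int:
        return self.mask.bit_count()

    @property
    def is_pendant(self) -> bool:
        """True for pendant splits: singletons and the root edge."""
        return self.size == 1 or self.size == self.nleaves

    @property
    def is_internal(self) -> bool:
        return 2 <= self.size <= self.nleaves - 1

    def compatible_with(self, other: "Split") -> bool:
        if self.nleaves != other.nleaves:
            raise ValueError("splits defined over different leaf sets")
        a, b = self.mask, other.mask
        # The root-containing sides always intersect, so the four-intersection
        # rule reduces to: away-sides disjoint or nested.
        return (a & b) == 0 or (a | b) == a or (a | b) == b

    def __eq__(self, other):
        return (
            isinstance(other, Split)
            and self.mask == other.mask
            and self.nleaves == other.nleaves
        )

    def __hash__(self):
        return self._hash

    def __repr__(self):
        return f"Split({sorted(self.indices())}, N={self.nleaves})"


def split_compatible(a: Split, b: Split) -> bool:
    """Whether two splits can occur in the same tree (four-intersection rule)."""
    return a.compatible_with(b)


def _masks_compatible(a: int, b: int) -> bool:
    ab = a & b
    return ab == 0 or ab == a or ab == b


def validate_topology(splits: Iterable[Split]) -> bool:
    """True iff the splits are pairwise compatible with at most N-2 internal ones.

    An empty collection is a valid (star tree) topology.
    """
    splits = list(splits)
    if not splits:
        return True
    n = splits[0].nleaves
    internal = 0
    for s in splits:
        if s.nleaves != n:
            raise ValueError("splits defined over different leaf sets")
        if s.is_internal:
            internal += 1
    if internal > n - 2:
        return False
    masks = [s.mask for s in splits]
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if not _masks_compatible(a, b):
                return False
    return True


class Topology:
    """A tree topology: the set of internal splits, identifying an orthant."""

    __slots__ = ("splits", "_hash")

    def __init__(self, splits: Iterable[Split]):
        self.splits = frozenset(s for s in splits if s.is_internal)
        self._hash = hash(self.splits)

    def __eq__(self, other):
        return isinstance(other, Topology) and self.splits == other.splits

    def __hash__(self):
        return self._hash

    def __len__(self):
        return len(self.splits)

    def __repr__(self):
        return f"Topology({sorted(tuple(sorted(s.indices())) for s in self.splits)})"


class PhyloTree:
    """A phylogenetic tree: compatible splits with positive lengths.

    Attributes
    ----------
    taxa:
        Tuple of leaf labels; ``taxa[0]`` is the root leaf.
    edges:
        Mapping ``Split -> length``.  Looking up an absent split via
        :meth:`length_of` returns 0 by convention.

    A tree need not carry pendant edges: analyses in this package default to
    ignoring pendant edge lengths, and trees on orthant boundaries
    (unresolved topologies) are represented simply by the absence of the
    contracted splits.
    """

    __slots__ = ("taxa", "edges")

    def __init__(
        self,
        taxa: tuple[str, ...],
        edges: Mapping[Split, float],
        validate: bool = True,
    ):
        self.taxa = tuple(taxa)
        n = len(self.taxa) - 1
        cleaned: dict[Split, float] = {}
        for s, length in edges.items():
            length = float(length)
            if length < 0:
                raise ValueError(f"negative edge length {length} for {s}")
            if length == 0.0:
                continue  # boundary trees are represented by split absence
            cleaned[s] = length
        self.edges = cleaned
        if validate:
            if n < 2:
                raise ValueError("need at least 2 non-root leaves")
            if len(set(self.taxa)) != len(self.taxa):
                raise ValueError("duplicate taxon labels")
            for s in cleaned:
                if s.nleaves != n:
                    raise ValueError("split leaf count does not match taxa")
            if not validate_topology(cleaned.keys()):
                raise ValueError("splits are not pairwise compatible")

    # -- basic accessors -------------------------------------------------

    @property
    def n_leaves(self) -> int:
        """N: the number of non-root leaves."""
        return len(self.taxa) - 1

    def length_of(self, split: Split) -> float:
        return self.edges.get(split, 0.0)

    def internal_edges(self) -> dict[Split, float]:
        return {s: l for s, l in self.edges.items() if s.is_internal}

    def pendant_edges(self) -> dict[Split, float]:
        return {s: l for s, l in self.edges.items() if s.is_pendant}

    @property
    def topology(self) -> Topology:
        return Topology(self.edges.keys())

    @property
    def is_fully_resolved(self) -> bool:
        return len(self.internal_edges()) == self.n_leaves - 2

    def norm(self, internal_only: bool = True) -> float:
        """Euclidean norm of the edge-length vector (Eq. for ||x||)."""
        total = 0.0
        for s, l in self.edges.items():
            if internal_only and not s.is_internal:
                continue
            total += l * l
        return total ** 0.5

    def total_internal_length(self) -> float:
        return sum(self.internal_edges().values())

    # -- mask-level views used by the geodesic engine --------------------

    def _mask_edges(self, internal_only: bool = True) -> dict[int, float]:
        if internal_only:
            return {s.mask: l for s, l in self.edges.items() if s.is_internal}
        return {s.mask: l for s, l in self.edges.items()}

    @classmethod
    def _from_masks(
        cls,
        taxa: tuple[str, ...],
        mask_edges: Mapping[int, float],
        validate: bool = False,
    ) -> "PhyloTree":
        n = len(taxa) - 1
        return cls(
            taxa,
            {Split(m, n): l for m, l in mask_edges.items()},
            validate=validate,
        )

    # -- comparisons -----------------------------------------------------

    def __eq__(self, other):
        return (
            isinstance(other, PhyloTree)
            and self.taxa == other.taxa
            and self.edges == other.edges
        )

    def approx_equal(self, other: "PhyloTree", tol: float = 1e-9) -> bool:
        if self.taxa != other.taxa:
            return False
        keys = set(self.edges) | set(other.edges)
        return all(
            abs(self.length_of(s) - other.length_of(s)) <= tol for s in keys
        )

    def __repr__(self):
        return f"PhyloTree({self.to_newick()!r})"

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_newick(
        cls, text: str, root_label: str | None = None
    ) -> "PhyloTree":
        return parse_newick(text, root_label=root_label)

    def to_newick(self, precision: int = 12) -> str:
        return write_newick(self, precision=precision)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _dendropy_to_tree(dt: dendropy.Tree, root_label: str | None) -> PhyloTree:
    dt.suppress_unifurcations()  # degree-2 vertices: lengths are summed
    leaves = [lf.taxon.label for lf in dt.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels in Newick input")
    if root_label is None:
        root_label = "0" if "0" in leaves else leaves[0]
    if root_label not in leaves:
        raise ValueError(f"root label {root_label!r} not among leaves {leaves}")
    # numeric labels sort numerically so taxon "10" follows "9", not "1"
    others = sorted(
        (lf for lf in leaves if lf != root_label),
        key=lambda s: (0, int(s)) if s.isdigit() else (1, 0, s),
    )
    taxa = (root_label,) + tuple(others)
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa) - 1
    full = (1 << n) - 1

    # Accumulate mask -> length for every edge, treating the tree as unrooted.
    mask_edges: dict[int, float] = {}

    def leafset_mask(node) -> int:
        m = 0
        for lf in node.leaf_iter():
            i = index[lf.taxon.label]
            if i > 0:
                m |= 1 << (i - 1)
            else:
                m |= 1 << n  # sentinel bit for the root leaf
        return m

    seed = dt.seed_node
    for node in dt.preorder_node_iter():
        if node is seed:
            continue
        length = node.edge.length
        if length is None:
            raise ValueError(
                "missing branch length on edge above "
                f"{node.taxon.label if node.taxon else 'internal node'}"
            )
        m = leafset_mask(node)
        if m >> n & 1:  # side contains the root leaf: store the complement
            m = full & ~(m & full)
        if m == 0 or m > full:
            continue
        mask_edges[m] = mask_edges.get(m, 0.0) + float(length)

    splits = {Split(m, n): l for m, l in mask_edges.items() if l > 0.0}
    return PhyloTree(taxa, splits, validate=True)


def parse_newick(text: str, root_label: str | None = None) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    The designated root leaf (default the taxon labelled ``"0"``, else the
    first leaf) fixes the canonical orientation of every split.  Branch
    lengths are mandatory; zero-length internal edges are contracted, moving
    the tree to the orthant boundary.  Malformed input raises ``ValueError``
    with the parser's position information.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises DataError subclasses
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _dendropy_to_tree(dt, root_label)


def parse_newick_list(
    text: str, root_label: str | None = None
) -> list[PhyloTree]:
    """Parse a multi-tree file: one Newick per line, or a NEXUS tree block."""
    stripped = text.lstrip()
    if stripped[:6].upper() == "#NEXUS":
        tl = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True
        )
        return [_dendropy_to_tree(t, root_label) for t in tl]
    trees = []
    for line in io.StringIO(text):
        line = line.strip()
        if line and not line.startswith("#"):
            trees.append(parse_newick(line, root_label=root_label))
    return trees


def write_newick(tree: PhyloTree, precision: int = 12) -> str:
    """Serialize a tree to rooted Newick, root leaf written last at the base.

    Trees without pendant edges (the common case when pendant lengths are
    ignored) are written with zero pendant lengths.
    """
    n = tree.n_leaves
    full = (1 << n) - 1
    fmt = f"%.{precision}g"
    internal = sorted(
        ((s.mask, l) for s, l in tree.internal_edges().items()),
        key=lambda ml: ml[0].bit_count(),
    )
    pendants = {s.mask: l for s, l in tree.pendant_edges().items()}

    def build(mask: int, members: list[tuple[int, float]]) -> str:
        # members: internal splits strictly inside `mask`, largest placed first
        children: list[str] = []
        used = 0
        rest = list(members)
        while rest:
            cm, cl = rest.pop()  # largest remaining
            inside = [(m, l) for m, l in rest if m & cm == m]
            rest = [(m, l) for m, l in rest if m & cm != m]
            children.append(f"{build(cm, inside)}:{fmt % cl}")
            used |= cm
        for i in range(n):
            bit = 1 << i
            if mask & bit and not used & bit:
                label = tree.taxa[i + 1]
                children.append(f"{label}:{fmt % pendants.get(bit, 0.0)}")
        return "(" + ",".join(children) + ")"

    root_len = pendants.get(full, 0.0)
    body = build(full, internal)
    return f"({body[1:-1]},{tree.taxa[0]}:{fmt % root_len});"


def tree_norm(x: PhyloTree, internal_only: bool = True) -> float:
    """Square root of the sum of squared edge lengths of the selected edges."""
    return x.norm(internal_only=internal_only)


def trees_to_tsv(trees: Iterable[PhyloTree]) -> str:
    """Sparse split-length records: tree_id, sorted leaf labels, length."""
    lines = ["tree_id\tsplit\tlength"]
    for i, t in enumerate(trees):
        for s in sorted(t.edges, key=lambda s: (s.size, s.mask)):
            leaves = ",".join(
                sorted(s.leaves(t.taxa), key=lambda x: (len(x), x))
            )
            lines.append(f"{i}\t{leaves}\t{t.edges[s]:.12g}")
    return "\n".join(lines) + "\n"
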