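"""Tree and trait-table I/O for phylogenetic comparative analyses.

Trees are rooted, with branch lengths in time units (chronograms). Parsing and
serialisation go through :mod:`dendropy`; in memory a tree is held as a compact
:class:`PhyloTree` (parent/child arrays) so the comparative machinery can walk
it without touching the I/O layer.

Trait tables are pandas DataFrames indexed by species label, with caste sizes
in mm (columns ``worker_mm``, ``male_mm``, ``queen_mm``), an optional ``genus``
column and a per-row ``source`` tag.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("worker_mm", "male_mm", "queen_mm")


class TreeParseError(ValueError):
    """Malformed tree text (bad parentheses, missing semicolon, ...)."""


class TreeValidationError(ValueError):
    """Structurally valid text that violates tree invariants."""


class TraitTableError(ValueError):
    """Trait table violates its invariants."""


def normalize_label(label: str) -> str:
    """Canonical form used to match taxa between tree and table.

    Case-insensitive; underscores and runs of whitespace are equivalent to a
    single space; surrounding whitespace is ignored.
    """
    return re.sub(r"[\s_]+", " ", label.strip()).lower()


@dataclass
class PhyloTree:
    """Rooted phylogeny as parent/child index arrays.

    Node 0 is always the root. ``parent[i]`` is -1 for the root;
    ``edge_length[i]`` is the length of the branch above node ``i`` (NaN for
    the root). Children of every node are kept sorted by the lexicographically
    smallest tip label below them, which fixes a deterministic traversal (and
    hence a stable sign convention for contrasts) independent of input order.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    children: list[list[int]]
    labels: list[str | None]

    root: int = 0
    _postorder: list[int] | None = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        self._sort_children()
        self.validate()

    def _min_tip_labels(self) -> list[str]:
        out = [""] * self.n_nodes
        for i in self.postorder():
            if self.is_tip(i):
                out[i] = self.labels[i] or ""
            else:
                out[i] = min(out[c] for c in self.children[i])
        return out

    def _sort_children(self) -> None:
        # postorder needed before labels exist for internal nodes; build an
        # unsorted traversal first, then re-sort and invalidate the cache
        self._postorder = None
        ranks = self._min_tip_labels()
        for kids in self.children:
            kids.sort(key=lambda c: ranks[c])
        self._postorder = None

    def validate(self) -> None:
        n = self.n_nodes
        if not (len(self.children) == len(self.labels) == len(self.edge_length) == n):
            raise TreeValidationError("inconsistent array lengths")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != self.root:
            raise TreeValidationError("tree must have exactly one root at index 0")
        if len(self.postorder()) != n:
            raise TreeValidationError("tree is not connected/acyclic")
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        nonroot = np.arange(n) != self.root
        if np.any(self.edge_length[nonroot] < 0) or np.any(
            ~np.isfinite(self.edge_length[nonroot])
        ):
            raise TreeValidationError("all non-root branch lengths must be finite and >= 0")

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in self.postorder() if self.is_tip(i)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] or "" for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def is_binary(self) -> bool:
        return all(
            len(self.children[i]) in (0, 2) for i in range(self.n_nodes)
        ) and len(self.children[self.root]) == 2

    def postorder(self) -> list[int]:
        """Children-before-parent node ordering (deterministic)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for c in reversed(self.children[node]):
                        stack.append((c, False))
            self._postorder = order
        return self._postorder

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for i in reversed(self.postorder()):
            if i != self.root:
                d[i] = d[self.parent[i]] + self.edge_length[i]
        return d

    def tip_depths(self) -> dict[str, float]:
        d = self.depths()
        return {self.labels[i]: d[i] for i in self.tip_indices}

    def n_descendant_tips(self) -> np.ndarray:
        out = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder():
            out[i] = 1 if self.is_tip(i) else sum(out[c] for c in self.children[i])
        return out

    def tips_below(self, node: int) -> list[str]:
        acc: list[str] = []
        stack = [node]
        while stack:
            i = stack.pop()
            if self.is_tip(i):
                acc.append(self.labels[i] or "")
            else:
                stack.extend(reversed(self.children[i]))
        return acc

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            edge_length=self.edge_length.copy(),
            children=[list(k) for k in self.children],
            labels=list(self.labels),
        )

    # -- conversion --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        length = np.full(n, np.nan)
        children: list[list[int]] = [[] for _ in range(n)]
        labels: list[str | None] = [None] * n
        for nd in nodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                labels[i] = str(nd.taxon.label)
            elif nd.label is not None:
                labels[i] = str(nd.label)
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                length[i] = 0.0 if nd.edge.length is None else float(nd.edge.length)
        return cls(parent=parent, edge_length=length, children=children, labels=labels)

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for i in self.postorder():
            lab = _quote_label(self.labels[i]) if self.labels[i] else ""
            if self.is_tip(i):
                body = lab
            else:
                body = "(" + ",".join(parts.pop(c) for c in self.children[i]) + ")" + lab
            if i == self.root:
                parts[i] = body
            else:
                parts[i] = f"{body}:{np.format_float_positional(self.edge_length[i], trim='-')}"
        return parts[self.root] + ";"


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- parsing ----------------------------------------------------------------


def parse_tree(text: str, dialect: str = "newick") -> PhyloTree:
    """Parse a Newick string or a NEXUS TREES block into a :class:`PhyloTree`.

    Quoted and underscore-escaped labels are normalised to plain strings
    (unquoted underscores become spaces, per the Newick convention). NEXUS
    support is read-only: the first tree of the TREES block, honouring a
    TRANSLATE table; all other blocks are ignored.
    """
    if dialect not in ("newick", "nexus"):
        raise ValueError(f"dialect must be 'newick' or 'nexus', got {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=dialect,
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = ""
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if line is not None:
            pos = f" (line {line}, column {col})"
        raise TreeParseError(f"could not parse {dialect} tree{pos}: {exc}") from exc
    tree = PhyloTree.from_dendropy(dtree)
    return tree


def write_tree(tree: PhyloTree, path=None) -> str:
    """Serialise to Newick; optionally write to ``path``. Returns the string."""
    text = tree.to_newick() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- validation and surgery --------------------------------------------------


def check_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """Test whether all tips are equidistant from the root.

    Returns ``(flag, max_relative_deviation)`` where the deviation is
    ``max_tips |depth - mean depth| / mean depth``. Chronograms from dating
    software carry rounding noise, hence the relative tolerance (default 1e-6).
    """
    if tree.n_tips < 2:
        raise TreeValidationError("ultrametricity needs >= 2 tips")
    depths = np.array([d for d in (tree.depths()[i] for i in tree.tip_indices)])
    mean = depths.mean()
    if mean <= 0:
        raise TreeValidationError("zero-depth tree")
    dev = float(np.max(np.abs(depths - mean)) / mean)
    return dev <= rel_tol, dev


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    """Induced subtree on ``taxa``; unbranched nodes are suppressed with their
    branch lengths summed, so tip-to-tip path lengths are conserved exactly."""
    keep = set(taxa)
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise TreeValidationError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise TreeValidationError("need at least 2 taxa to prune to")

    # keep_flag per node, then rebuild top-down skipping suppressed nodes
    keep_flag = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.postorder():
        if tree.is_tip(i):
            keep_flag[i] = (tree.labels[i] or "") in keep
        else:
            keep_flag[i] = any(keep_flag[c] for c in tree.children[i])

    parent: list[int] = []
    length: list[float] = []
    children: list[list[int]] = []
    labels: list[str | None] = []

    def add_node(label, par, ln):
        idx = len(parent)
        parent.append(par)
        length.append(ln)
        children.append([])
        labels.append(label)
        if par >= 0:
            children[par].append(idx)
        return idx

    def kept_kids(i):
        return [c for c in tree.children[i] if keep_flag[c]]

    def build(i, par, extra):
        kids = kept_kids(i)
        if not tree.is_tip(i) and len(kids) == 1:
            # suppress unary node: fold its branch into the child's
            child = kids[0]
            build(child, par, extra + tree.edge_length[child])
            return
        ln = np.nan if par < 0 else extra
        idx = add_node(tree.labels[i], par, ln)
        for c in kids:
            build(c, idx, tree.edge_length[c])

    # find the new root: deepest node on the path from the old root that still
    # has >= 2 kept children (root-side unary chain is dropped entirely)
    node = tree.root
    while not tree.is_tip(node) and len(kept_kids(node)) == 1:
        node = kept_kids(node)[0]
    build(node, -1, np.nan)
    return PhyloTree(
        parent=np.array(parent),
        edge_length=np.array(length),
        children=children,
        labels=labels,
    )


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Arbitrarily break polytomies with zero-length branches.

    Multifurcations (e.g. from Bayesian consensus trees) are resolved by
    repeatedly joining a random pair of children under a new zero-length node,
    using ``seed`` for reproducibility. The result is binary and has identical
    tip-to-tip path lengths.
    """
    rng = np.random.default_rng(seed)
    parent = list(tree.parent)
    length = list(tree.edge_length)
    children = [list(k) for k in tree.children]
    labels: list[str | None] = list(tree.labels)
    changed = False
    for i in list(range(len(children))):
        while len(children[i]) > 2:
            changed = True
            pick = sorted(rng.choice(len(children[i]), size=2, replace=False))
            a, b = children[i][pick[0]], children[i][pick[1]]
            new = len(parent)
            parent.append(i)
            length.append(0.0)
            children.append([a, b])
            labels.append(None)
            parent[a] = parent[b] = new
            children[i] = [c for c in children[i] if c not in (a, b)] + [new]
    if changed:
        logger.info("resolved polytomies with zero-length branches (seed=%d)", seed)
    # re-index so the root is node 0 and arrays are preorder-compact
    return _reindex(np.array(parent), np.array(length), children, labels)


def _reindex(parent, length, children, labels) -> PhyloTree:
    root = int(np.flatnonzero(parent < 0)[0])
    order = []
    stack = [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    remap = {old: new for new, old in enumerate(order)}
    n = len(order)
    new_parent = np.full(n, -1, dtype=int)
    new_length = np.full(n, np.nan)
    new_children: list[list[int]] = [[] for _ in range(n)]
    new_labels: list[str | None] = [None] * n
    for old in order:
        new = remap[old]
        new_labels[new] = labels[old]
        if parent[old] >= 0:
            new_parent[new] = remap[parent[old]]
            new_length[new] = length[old]
            new_children[remap[parent[old]]].append(new)
    return PhyloTree(
        parent=new_parent, edge_length=new_length, children=new_children, labels=new_labels
    )


# -- trait tables ------------------------------------------------------------


def read_trait_table(path_or_buffer) -> pd.DataFrame:
    """Read a caste trait table (CSV, header ``species,worker_mm,male_mm,
    queen_mm[,genus,source,...]``) into a species-indexed DataFrame.

    Empty cells and "NA" are missing. Validates: unique species labels, every
    non-missing size > 0, and at least one of male/queen present per row.
    """
    df = pd.read_csv(path_or_buffer, na_values=["NA"], keep_default_na=True, skipinitialspace=True)
    if "species" not in df.columns:
        raise TraitTableError("trait table must have a 'species' column")
    missing_cols = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TraitTableError(f"trait table missing columns: {missing_cols}")
    df["species"] = df["species"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise TraitTableError(f"duplicate species labels: {dupes}")
    for col in TRAIT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
        bad = df.loc[df[col].notna() & (df[col] <= 0), "species"]
        if len(bad):
            raise TraitTableError(f"non-positive {col} for: {sorted(bad)}")
    no_repro = df.loc[df["male_mm"].isna() & df["queen_mm"].isna(), "species"]
    if len(no_repro):
        raise TraitTableError(f"rows missing both male and queen sizes: {sorted(no_repro)}")
    return df.set_index("species")


def match_taxa(tree: PhyloTree, table: pd.DataFrame) -> tuple[PhyloTree, pd.DataFrame]:
    """Intersect tree tips and table rows (case-insensitive, underscore/space
    equivalent). Unmatched tips/rows are dropped with a logged warning, and the
    table is re-keyed to the tree's tip spelling."""
    tip_norm = {normalize_label(t): t for t in tree.tip_labels}
    row_norm = {normalize_label(s): s for s in table.index}
    common = sorted(set(tip_norm) & set(row_norm))
    dropped_tips = sorted(set(tip_norm) - set(row_norm))
    dropped_rows = sorted(set(row_norm) - set(tip_norm))
    if dropped_tips:
        logger.warning("dropping %d tree tips without trait data: %s", len(dropped_tips), dropped_tips)
    if dropped_rows:
        logger.warning("dropping %d trait rows not in tree: %s", len(dropped_rows), dropped_rows)
    if len(common) < 2:
        raise TreeValidationError("fewer than 2 taxa shared between tree and trait table")
    pruned = prune_to_taxa(tree, [tip_norm[k] for k in common])
    sub = table.loc[[row_norm[k] for k in common]].copy()
    sub.index = pd.Index([tip_norm[k] for k in common], name="species")
    return pruned, sub


def load_tree(path, dialect: str | None = None) -> PhyloTree:
    """Read a tree file, inferring the dialect from the extension if needed."""
    p = str(path)
    if dialect is None:
        dialect = "nexus" if p.lower().endswith((".nex", ".nexus", ".tre.nex")) else "newick"
    with open(p) as fh:
        return parse_tree(fh.read(), dialect=dialect)
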