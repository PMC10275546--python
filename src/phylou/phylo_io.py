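"""Phylogeny I/O, regime paintings, lineage histories, and species tables.

Trees are read with :mod:`dendropy` (Newick/NEXUS) and converted to a light
internal representation with explicit parent/child pointers.  A
:class:`RegimePainting` assigns a sequence of ``(regime, length)`` segments to
every edge, identified by the edge's child node.  Paintings plus the tree
yield per-tip :class:`LineageHistory` objects (ordered regime epochs from the
root), which are the raw material for the adaptation design matrices in
:mod:`phylou.ou_engine`.
"""

from __future__ import annotations

import io
import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloError",
    "Node",
    "Phylogeny",
    "RegimePainting",
    "LineageHistory",
    "SpeciesTable",
    "DietFlags",
    "read_tree",
    "scale_to_unit_height",
    "paint_from_node_states",
    "cross_paintings",
    "lineage_epochs",
    "phylo_matrices",
    "classify_diet",
    "bin_group_size",
    "load_species_table",
    "GROUP_SIZE_BINS",
]


class PhyloError(ValueError):
    """Raised for malformed trees, paintings, or species tables."""


class Node:
    """A node in a rooted tree. ``length`` is the edge above the node."""

    __slots__ = ("index", "label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.index: int = -1
        self.label = label
        self.length = float(length)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label or self.index}, len={self.length:g})"


class Phylogeny:
    """Rooted tree with branch lengths in time units.

    Attributes
    ----------
    nodes : list[Node]
        All nodes in postorder; ``nodes[i].index == i``.
    tips : list[Node]
        Tip nodes in postorder.  This order fixes the row/column order of all
        matrices derived from the tree.
    original_height : float
        Root-to-tip height before any rescaling (time units, e.g. myr).
    scaled : bool
        True once the tree has been rescaled to unit height.
    """

    def __init__(self, root: Node, original_height: float | None = None,
                 scaled: bool = False):
        self.root = root
        self._index()
        self._validate()
        self.scaled = scaled
        self.original_height = (float(original_height)
                                if original_height is not None
                                else self.height())

    # ------------------------------------------------------------------
    def _index(self) -> None:
        nodes: list[Node] = []

        def post(n: Node) -> None:
            for c in n.children:
                c.parent = n
                post(c)
            n.index = len(nodes)
            nodes.append(n)

        self.root.parent = None
        post(self.root)
        self.nodes = nodes
        self.tips = [n for n in nodes if n.is_tip]
        self.tip_labels = [t.label for t in self.tips]

    def _validate(self) -> None:
        labels = [t.label for t in self.tips]
        if any(lb is None or lb == "" for lb in labels):
            raise PhyloError("all tips must be labelled")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise PhyloError(f"duplicate tip labels: {sorted(dupes)}")
        for n in self.nodes:
            if n is self.root:
                continue
            if n.length is None or math.isnan(n.length):
                raise PhyloError(f"missing branch length above {n!r}")
            if n.length < 0:
                raise PhyloError(f"negative branch length above {n!r}")

    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def tip(self, label: str) -> Node:
        try:
            return self.tips[self.tip_labels.index(label)]
        except ValueError:
            raise PhyloError(f"unknown tip {label!r}") from None

    def depths(self) -> np.ndarray:
        """Root-to-node distance for every node, indexed by node index."""
        out = np.zeros(len(self.nodes))
        stack = [self.root]
        while stack:
            n = stack.pop()
            for c in n.children:
                out[c.index] = out[n.index] + c.length
                stack.append(c)
        return out

    def tip_depths(self) -> np.ndarray:
        d = self.depths()
        return np.array([d[t.index] for t in self.tips])

    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        td = self.tip_depths()
        h = td.max()
        return bool(h == 0 or (td.max() - td.min()) <= rel_tol * h)

    def total_branch_length(self) -> float:
        return float(sum(n.length for n in self.nodes if n is not self.root))

    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.children = [clone(c) for c in n.children]
            return m

        return Phylogeny(clone(self.root), self.original_height, self.scaled)

    def path_to_tip(self, label: str) -> list[Node]:
        """Nodes from (just below) the root down to the tip, excluding root."""
        node = self.tip(label)
        path = []
        while node is not None and node is not self.root:
            path.append(node)
            node = node.parent
        return path[::-1]

    def mrca(self, labels: Sequence[str]) -> Node:
        paths = [set(id(n) for n in [self.root] + self.path_to_tip(lb))
                 for lb in labels]
        common = set.intersection(*paths)
        node = self.tip(labels[0])
        while id(node) not in common:
            node = node.parent
        return node

    def extract_subtree(self, labels: Sequence[str]) -> "Phylogeny":
        """Clade spanned by ``labels`` (MRCA and everything below it).

        All tips below the MRCA are kept.  Heights are recomputed, so the
        returned tree is unscaled even if the parent tree was.
        """
        anc = self.mrca(list(labels))

        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.children = [clone(c) for c in n.children]
            return m

        root = clone(anc)
        root.length = 0.0
        return Phylogeny(root)

    # ------------------------------------------------------------------
    def to_newick(self, precision: int = 10) -> str:
        def render(n: Node) -> str:
            if n.is_tip:
                core = _quote_label(n.label)
            else:
                core = "(" + ",".join(render(c) for c in n.children) + ")"
            if n is self.root:
                return core
            return f"{core}:{n.length:.{precision}g}"

        return render(self.root) + ";"

    def write(self, path: str | os.PathLike, format: str = "newick") -> None:
        text = self.to_newick()
        if format == "nexus":
            taxa = " ".join(_quote_label(lb) for lb in self.tip_labels)
            text = ("#NEXUS\nBEGIN TAXA;\n"
                    f"  DIMENSIONS NTAX={self.n_tips};\n"
                    f"  TAXLABELS {taxa};\nEND;\n"
                    "BEGIN TREES;\n  TREE tree1 = " + text + "\nEND;\n")
        elif format != "newick":
            raise PhyloError(f"unknown tree format {format!r}")
        with open(path, "w") as fh:
            fh.write(text + ("\n" if not text.endswith("\n") else ""))

    def __repr__(self):  # pragma: no cover
        return (f"Phylogeny(n_tips={self.n_tips}, height={self.height():.4g}, "
                f"scaled={self.scaled})")


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ----------------------------------------------------------------------
# reading / scaling
# ----------------------------------------------------------------------

def read_tree(source, format: str = "newick") -> Phylogeny:
    """Read a rooted tree with branch lengths from Newick or NEXUS.

    ``source`` may be a path, a file-like object, or a string containing the
    tree itself.  Branch lengths are mandatory on every non-root edge.
    """
    if format not in ("newick", "nexus"):
        raise PhyloError(f"unknown tree format {format!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        looks_like_data = ("(" in s and ";" in s) or s.lstrip().startswith("#NEXUS")
        if not looks_like_data and os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        elif looks_like_data:
            text = s
        elif os.path.exists(s):
            with open(s) as fh:
                text = fh.read()
        else:
            raise PhyloError(f"no such tree file: {s}")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=format,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise PhyloError(f"could not parse {format} tree: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        n = Node(label=label, length=0.0)
        kids = dnode.child_nodes()
        if kids:
            n.children = [convert(c) for c in kids]
        if dnode.parent_node is not None:
            if dnode.edge.length is None:
                raise PhyloError(
                    f"missing branch length above {label or 'internal node'}")
            n.length = float(dnode.edge.length)
        return n

    root = convert(dtree.seed_node)
    if not root.children:
        raise PhyloError("tree has no branching structure")
    return Phylogeny(root)


def scale_to_unit_height(tree: Phylogeny, rel_tol: float = 1e-6) -> Phylogeny:
    """Return a copy rescaled so every root-to-tip distance equals 1.

    The original height is preserved on the result for unit conversion.
    Raises for trees that are not ultrametric within ``rel_tol`` (relative
    to tree height).
    """
    if not tree.is_ultrametric(rel_tol):
        td = tree.tip_depths()
        raise PhyloError(
            "tree is not ultrametric: tip depths span "
            f"[{td.min():.6g}, {td.max():.6g}]")
    h = tree.height()
    if h <= 0:
        raise PhyloError("tree height must be positive")
    out = tree.copy()
    for n in out.nodes:
        if n is not out.root:
            n.length /= h
    # exact unit depths: stretch terminal edges to absorb rounding noise
    depths = out.depths()
    for t in out.tips:
        t.length += 1.0 - depths[t.index]
    result = Phylogeny(out.root,
                       original_height=tree.original_height if tree.scaled
                       else h,
                       scaled=True)
    return result


# ----------------------------------------------------------------------
# paintings and lineage histories
# ----------------------------------------------------------------------

@dataclass
class RegimePainting:
    """Per-edge regime segments, keyed by the child node's index.

    Segment lists run from the parent end of the edge toward the child and
    their lengths sum to the edge length.  ``regimes`` is the declared label
    set (sorted tuple).
    """

    segments: dict[int, list[tuple[str, float]]]
    regimes: tuple[str, ...]

    def validate(self, tree: Phylogeny, tol: float = 1e-9) -> None:
        for n in tree.nodes:
            if n is tree.root:
                continue
            segs = self.segments.get(n.index)
            if segs is None:
                raise PhyloError(f"painting missing edge above node {n.index}")
            total = sum(l for _, l in segs)
            if abs(total - n.length) > tol * max(1.0, n.length):
                raise PhyloError(
                    f"segments on edge above node {n.index} sum to {total}, "
                    f"expected {n.length}")
            for r, l in segs:
                if r not in self.regimes:
                    raise PhyloError(f"unknown regime label {r!r}")
                if l < 0:
                    raise PhyloError("negative segment length")

    def relabel(self, mapping: Mapping[str, str]) -> "RegimePainting":
        segs = {i: [(mapping.get(r, r), l) for r, l in ss]
                for i, ss in self.segments.items()}
        regs = tuple(sorted({mapping.get(r, r) for r in self.regimes}))
        return RegimePainting(segs, regs)

    # -- exports -------------------------------------------------------
    def to_edge_table(self, tree: Phylogeny) -> pd.DataFrame:
        rows = []
        for n in tree.nodes:
            if n is tree.root:
                continue
            for k, (r, l) in enumerate(self.segments[n.index]):
                rows.append({"child_node": n.index,
                             "child_label": n.label if n.is_tip else "",
                             "segment": k, "regime": r, "length": l})
        return pd.DataFrame(rows)

    def to_simmap_newick(self, tree: Phylogeny, precision: int = 10) -> str:
        """SIMMAP-style annotated Newick; segments listed parent-to-child."""

        def annot(n: Node) -> str:
            segs = self.segments[n.index]
            body = ":".join(f"{r},{l:.{precision}g}" for r, l in segs)
            return "{" + body + "}"

        def render(n: Node) -> str:
            if n.is_tip:
                core = _quote_label(n.label)
            else:
                core = "(" + ",".join(render(c) for c in n.children) + ")"
            if n is tree.root:
                return core
            return f"{core}:{annot(n)}"

        return render(tree.root) + ";"


@dataclass
class LineageHistory:
    """Ordered regime epochs along one root-to-tip lineage.

    Epochs are ``(regime, start, end)`` with times measured from the root;
    they are contiguous and cover ``[0, total_time]``.
    """

    tip: str
    epochs: list[tuple[str, float, float]]
    total_time: float

    def time_in_regime(self, regime: str) -> float:
        return sum(e - s for r, s, e in self.epochs if r == regime)

    @property
    def root_regime(self) -> str:
        return self.epochs[0][0]

    def validate(self, tol: float = 1e-9) -> None:
        t = 0.0
        for r, s, e in self.epochs:
            if abs(s - t) > tol or e <= s:
                raise PhyloError(f"epochs of {self.tip} are not contiguous")
            t = e
        if abs(t - self.total_time) > tol:
            raise PhyloError(
                f"epochs of {self.tip} cover {t}, expected {self.total_time}")


def paint_from_node_states(tree: Phylogeny,
                           node_states: Mapping) -> RegimePainting:
    """Paint each edge with its *child* node's state.

    ``node_states`` maps node indices (and/or tip labels) to regime labels
    and must cover every node including the root.  Shifts implied by a
    parent/child state disagreement are placed at the parent end of the
    edge, so the whole edge carries the child's state.
    """
    states: dict[int, str] = {}
    for key, val in node_states.items():
        if isinstance(key, str):
            states[tree.tip(key).index] = str(val)
        else:
            states[int(key)] = str(val)
    missing = [n.index for n in tree.nodes if n.index not in states]
    if missing:
        raise PhyloError(f"missing node states for nodes {missing}")
    regimes = tuple(sorted(set(states.values())))
    segments = {n.index: [(states[n.index], n.length)]
                for n in tree.nodes if n is not tree.root}
    return RegimePainting(segments, regimes)


def cross_paintings(p1: RegimePainting, p2: RegimePainting,
                    tree: Phylogeny, sep: str = ":") -> RegimePainting:
    """Cross two paintings of the same tree into one combined factor.

    Only level combinations actually realized somewhere on the tree appear
    in the combined regime set.
    """
    def regime_at(segs: list[tuple[str, float]], t: float) -> str:
        acc = 0.0
        for r, l in segs:
            acc += l
            if t < acc:
                return r
        return segs[-1][0]

    segments: dict[int, list[tuple[str, float]]] = {}
    realized: set[str] = set()
    for n in tree.nodes:
        if n is tree.root:
            continue
        s1 = p1.segments[n.index]
        s2 = p2.segments[n.index]
        # union of segment breakpoints along the edge
        cuts = {0.0, n.length}
        for segs in (s1, s2):
            acc = 0.0
            for _, l in segs[:-1]:
                acc += l
                cuts.add(min(acc, n.length))
        pts = sorted(cuts)
        merged: list[tuple[str, float]] = []
        for a, b in zip(pts[:-1], pts[1:]):
            if b - a <= 0:
                continue
            mid = 0.5 * (a + b)
            label = f"{regime_at(s1, mid)}{sep}{regime_at(s2, mid)}"
            realized.add(label)
            if merged and merged[-1][0] == label:
                merged[-1] = (label, merged[-1][1] + (b - a))
            else:
                merged.append((label, b - a))
        if not merged:  # zero-length edge
            label = f"{s1[0][0]}{sep}{s2[0][0]}"
            realized.add(label)
            merged = [(label, 0.0)]
        segments[n.index] = merged
    return RegimePainting(segments, tuple(sorted(realized)))


def lineage_epochs(tree: Phylogeny, painting: RegimePainting,
                   tip: str) -> LineageHistory:
    """Regime epochs from the root to ``tip`` implied by a painting.

    Adjacent epochs with the same regime are merged.
    """
    path = tree.path_to_tip(tip)
    epochs: list[tuple[str, float, float]] = []
    t = 0.0
    for node in path:
        for regime, length in painting.segments[node.index]:
            if length <= 0:
                continue
            if epochs and epochs[-1][0] == regime:
                r, s, _ = epochs[-1]
                epochs[-1] = (r, s, t + length)
            else:
                epochs.append((regime, t, t + length))
            t += length
    return LineageHistory(tip=tip, epochs=epochs, total_time=t)


def phylo_matrices(tree: Phylogeny):
    """Shared-time matrix ``s``, distance matrix ``d``, and depth vector ``T``.

    ``s[i, j]`` is the root-to-MRCA time of tips i and j (tip order is
    ``tree.tip_labels``); ``d = T_i + T_j - 2 s`` and ``s[i, i] = T_i``.
    """
    n = tree.n_tips
    depths = tree.depths()
    tip_pos = {t.index: k for k, t in enumerate(tree.tips)}
    s = np.zeros((n, n))
    # descendant tip sets, postorder
    desc: dict[int, list[int]] = {}
    for node in tree.nodes:
        if node.is_tip:
            desc[node.index] = [tip_pos[node.index]]
            s[tip_pos[node.index], tip_pos[node.index]] = depths[node.index]
        else:
            sets = [desc[c.index] for c in node.children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            s[i, j] = s[j, i] = depths[node.index]
            desc[node.index] = [i for ss in sets for i in ss]
    T = np.diag(s).copy()
    d = T[:, None] + T[None, :] - 2.0 * s
    return s, d, T


# ----------------------------------------------------------------------
# species-level data
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DietFlags:
    frugivorous: bool
    folivorous: bool
    strict_folivorous: bool


DIET_CATEGORIES = ("pct_fauna", "pct_plant_repro", "pct_plant_veg",
                   "pct_exudate")


def classify_diet(percentages: Mapping[str, float] | Sequence[float],
                  on_strict_list: bool = False) -> DietFlags:
    """Two-way diet coding from percent feeding time in four categories.

    A species is frugivorous if plant reproductive parts occupy a strictly
    larger share than every other category, folivorous if plant vegetative
    parts do.  Ties are classified as neither, with a warning.  The strict
    folivore flag additionally requires membership on a user-supplied list
    of species with physiological adaptations for folivory.
    """
    if isinstance(percentages, Mapping):
        vals = [float(percentages[k]) for k in DIET_CATEGORIES]
    else:
        vals = [float(v) for v in percentages]
        if len(vals) != 4:
            raise PhyloError("expected four diet percentages")
    if any(v < 0 for v in vals):
        raise PhyloError("diet percentages must be non-negative")
    if all(v == 0 for v in vals):
        raise PhyloError("all-zero diet percentages")
    fauna, repro, veg, exud = vals
    top = max(vals)
    winners = [k for k, v in zip(DIET_CATEGORIES, vals) if v == top]
    if len(winners) > 1:
        if "pct_plant_repro" in winners or "pct_plant_veg" in winners:
            warnings.warn("diet percentage tie; classifying as neither "
                          "frugivorous nor folivorous", stacklevel=2)
        return DietFlags(False, False, False)
    frug = winners[0] == "pct_plant_repro"
    foli = winners[0] == "pct_plant_veg"
    return DietFlags(frug, foli, foli and bool(on_strict_list))


GROUP_SIZE_BINS = ("1-5", "6-10", "11-25", "26-50", ">50")


def bin_group_size(avg_group_size: float) -> str:
    """Five ordered group-size categories; values rounded half-up first."""
    if not (avg_group_size > 0):
        raise PhyloError(f"average group size must be positive, "
                         f"got {avg_group_size}")
    n = math.floor(avg_group_size + 0.5)
    if n <= 5:
        return "1-5"
    if n <= 10:
        return "6-10"
    if n <= 25:
        return "11-25"
    if n <= 50:
        return "26-50"
    return ">50"


#: canonical species-table columns (all optional except species and response)
SPECIES_COLUMNS = [
    "species",
    "log_ecv", "log_ecv_var",
    "log_mass", "log_mass_var",
    "log_group_size",
    "pct_fauna", "pct_plant_repro", "pct_plant_veg", "pct_exudate",
    "mating_system", "social_system", "group_size_category",
    "activity_period", "strict_folivore",
]


class SpeciesTable:
    """Species means, observation variances, and predictors.

    Wraps a :class:`pandas.DataFrame` indexed by species name.  Derived
    columns (``frugivorous``, ``folivorous``, ``strict_folivorous``,
    ``group_size_category``) are filled in from the raw diet percentages and
    group sizes when possible; cathemeral activity is recoded as diurnal.
    """

    def __init__(self, data: pd.DataFrame, strict_list: Iterable[str] = ()):
        df = data.copy()
        if "species" in df.columns:
            df = df.set_index("species")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise PhyloError("duplicate species in table")
        strict = set(strict_list)
        for col in ("log_ecv_var", "log_mass_var"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise PhyloError(f"{col} contains negative variances")
        for col in DIET_CATEGORIES:
            if col in df.columns:
                bad = df[col].dropna()
                if ((bad < 0) | (bad > 100)).any():
                    raise PhyloError(f"{col} outside [0, 100]")
        if all(c in df.columns for c in DIET_CATEGORIES):
            flags = [classify_diet({c: row[c] for c in DIET_CATEGORIES},
                                   sp in strict or
                                   bool(row.get("strict_folivore", False)))
                     if not row[list(DIET_CATEGORIES)].isna().any()
                     else DietFlags(False, False, False)
                     for sp, row in df.iterrows()]
            df["frugivorous"] = [f.frugivorous for f in flags]
            df["folivorous"] = [f.folivorous for f in flags]
            df["strict_folivorous"] = [f.strict_folivorous for f in flags]
        if ("group_size_category" not in df.columns
                and "log_group_size" in df.columns):
            df["group_size_category"] = [
                bin_group_size(math.exp(g)) if pd.notna(g) else None
                for g in df["log_group_size"]]
        if "activity_period" in df.columns:
            df["activity_period"] = df["activity_period"].replace(
                {"cathemeral": "diurnal"})
        self.data = df

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, species: Sequence[str]) -> "SpeciesTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise PhyloError(f"species not in table: {missing}")
        out = SpeciesTable.__new__(SpeciesTable)
        out.data = self.data.loc[list(species)].copy()
        return out

    def check_against_tree(self, tree: Phylogeny) -> None:
        extra = sorted(set(self.data.index) - set(tree.tip_labels))
        if extra:
            raise PhyloError(
                f"species present in data but absent from tree: {extra}")

    def to_csv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, index_label="species")


def load_species_table(source, strict_list: Iterable[str] = ()) -> SpeciesTable:
    """Load a species table from CSV (path, file-like, or text)."""
    if isinstance(source, pd.DataFrame):
        return SpeciesTable(source, strict_list)
    if hasattr(source, "read"):
        df = pd.read_csv(source)
    elif isinstance(source, str) and "\n" in source:
        df = pd.read_csv(io.StringIO(source))
    else:
        df = pd.read_csv(source)
    return SpeciesTable(df, strict_list)
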