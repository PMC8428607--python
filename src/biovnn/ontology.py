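"""Pathway ontology parsing, filtering and the layered DAG used as an
architecture template.

A pathway hierarchy is a rooted directed acyclic graph: child pathways are
components of parent pathways, and there is a single root.  Gene sets come
from a GMT file, parent-child relations from a two-column TSV and reactions
(finer gene groups inside pathways, used only for validation of feature
importances) from a reaction TSV.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConfigurationError, GmtParseError, OntologyError

logger = logging.getLogger(__name__)

#: id given to the virtual root created when the relation file has several
#: top-level pathways (as Reactome's does).
VIRTUAL_ROOT = "ROOT"


@dataclass
class Pathway:
    """One pathway: gene members plus its position in the hierarchy."""

    id: str
    name: str = ""
    genes: set[str] = field(default_factory=set)
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)


@dataclass
class PathwayHierarchy:
    """Rooted DAG of pathways with longest-path-from-leaves level numbers.

    Levels start at 1 for leaf (childless) pathways; ``level(child) <
    level(parent)`` always holds and the root sits at ``n_levels``.
    """

    pathways: dict[str, Pathway]
    root: str
    levels: dict[str, int]
    n_levels: int

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if self.root not in self.pathways:
            raise OntologyError(f"root {self.root!r} is not a pathway")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"hierarchy contains a cycle: {cycle}")
        roots = [p for p in self.pathways.values() if not p.parents]
        if [r.id for r in roots] != [self.root] and {r.id for r in roots} != {self.root}:
            raise OntologyError(
                f"expected a single root {self.root!r}, found parentless "
                f"pathways {sorted(r.id for r in roots)}"
            )
        for p in self.pathways.values():
            if p.id != self.root and not nx.has_path(g, p.id, self.root):
                raise OntologyError(f"pathway {p.id!r} cannot reach the root")
            for parent in p.parents:
                if self.levels[p.id] >= self.levels[parent]:
                    raise OntologyError(
                        f"level({p.id})={self.levels[p.id]} not below "
                        f"level({parent})={self.levels[parent]}"
                    )
        if self.levels[self.root] != self.n_levels:
            raise OntologyError("root level must equal n_levels")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.pathways)
        for p in self.pathways.values():
            for parent in p.parents:
                g.add_edge(p.id, parent)
        return g

    # -- queries -----------------------------------------------------------

    def leaves(self) -> list[str]:
        return [p.id for p in self.pathways.values() if not p.children]

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways.values():
            out |= p.genes
        return out

    def pathways_of_gene(self, gene: str) -> list[str]:
        gene = gene.upper()
        return [p.id for p in self.pathways.values() if gene in p.genes]

    def subtree(self, pathway_id: str) -> set[str]:
        """All descendants of a pathway, itself included."""
        out = {pathway_id}
        stack = [pathway_id]
        while stack:
            for c in self.pathways[stack.pop()].children:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    def closure_genes(self, pathway_id: str) -> set[str]:
        """Union of gene members over the pathway's subtree."""
        out: set[str] = set()
        for t in self.subtree(pathway_id):
            out |= self.pathways[t].genes
        return out

    def by_level(self) -> list[list[str]]:
        """Pathway ids grouped by level, index 0 = level 1 (leaves deepest)."""
        out: list[list[str]] = [[] for _ in range(self.n_levels)]
        for pid, lvl in self.levels.items():
            out[lvl - 1].append(pid)
        for group in out:
            group.sort()
        return out

    def topological_order(self) -> list[str]:
        """Children before parents, deterministic (level then id)."""
        return sorted(self.pathways, key=lambda p: (self.levels[p], p))

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for pid in sorted(self.pathways):
            p = self.pathways[pid]
            h.update(pid.encode())
            h.update(",".join(sorted(p.genes)).encode())
            h.update(",".join(sorted(p.parents)).encode())
        return h.hexdigest()


@dataclass
class ReactionSet:
    """Reaction id -> member genes. Reactions are finer than pathways and are
    never used to build the network; they validate feature importances."""

    reactions: dict[str, set[str]]

    def partners(self, gene: str) -> set[str]:
        """Union of co-members of ``gene`` over every reaction containing it."""
        gene = gene.upper()
        out: set[str] = set()
        for members in self.reactions.values():
            if gene in members:
                out |= members
        out.discard(gene)
        return out


# ---------------------------------------------------------------------------
# parsing


def _clean_gene(token: str) -> str:
    return token.strip().upper()


def parse_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file into ``{pathway id: gene set}``.

    Each line is ``id<TAB>description<TAB>gene...``; gene symbols are
    uppercased and deduplicated.
    """
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid = fields[0].strip()
            genes = {_clean_gene(g) for g in fields[2:] if g.strip()}
            out[pid] = genes
    return out


def parse_gmt_names(path: str | Path) -> dict[str, str]:
    """Pathway id -> description (second GMT column)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2 and fields[0].strip():
                out[fields[0].strip()] = fields[1].strip()
    return out


def write_gmt(path: str | Path, gene_sets: Mapping[str, Iterable[str]],
              names: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for pid in gene_sets:
            name = (names or {}).get(pid, pid)
            genes = sorted({_clean_gene(g) for g in gene_sets[pid]})
            fh.write("\t".join([pid, name, *genes]) + "\n")


def parse_hierarchy(path: str | Path) -> set[tuple[str, str]]:
    """Parse a two-column (child TAB parent) relation file into directed edges."""
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise GmtParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            child, parent = fields[0].strip(), fields[1].strip()
            if child == parent:
                raise OntologyError(f"{path}:{lineno}: self-edge on {child!r}")
            edges.add((child, parent))
    return edges


def write_hierarchy(path: str | Path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for child, parent in sorted(edges):
            fh.write(f"{child}\t{parent}\n")


def parse_reactions(path: str | Path, min_genes: int = 2) -> ReactionSet:
    """Parse a reaction TSV (reaction id TAB gene...).

    Reactions with fewer than ``min_genes`` members carry no pairwise
    relationship and are dropped with a warning.
    """
    reactions: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0].strip():
                continue
            rid = fields[0].strip()
            genes = {_clean_gene(g) for g in fields[1:] if g.strip()}
            if len(genes) < min_genes:
                logger.warning("reaction %s has <%d genes; dropped", rid, min_genes)
                continue
            reactions[rid] = genes
    return ReactionSet(reactions)


def write_reactions(path: str | Path, reactions: ReactionSet) -> None:
    with open(path, "w") as fh:
        for rid in sorted(reactions.reactions):
            fh.write("\t".join([rid, *sorted(reactions.reactions[rid])]) + "\n")


# ---------------------------------------------------------------------------
# hierarchy construction


def _compute_levels(pathways: dict[str, Pathway]) -> dict[str, int]:
    """Longest path from the leaf side: leaves are level 1 and a parent sits
    strictly above its deepest child."""
    g = nx.DiGraph()
    g.add_nodes_from(pathways)
    for p in pathways.values():
        for c in p.children:
            g.add_edge(c, p.id)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        raise OntologyError(f"hierarchy contains a cycle: {nx.find_cycle(g)}")
    levels: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        levels[node] = 1 if not preds else 1 + max(levels[c] for c in preds)
    return levels


def build_hierarchy(gene_sets: Mapping[str, set[str]],
                    edges: Iterable[tuple[str, str]],
                    names: Mapping[str, str] | None = None) -> PathwayHierarchy:
    """Assemble a validated hierarchy from gene sets and child->parent edges.

    If the edge set leaves several pathways parentless (Reactome's top-level
    pathways), a virtual root containing the union of all genes is created
    and the parentless pathways are attached to it.
    """
    names = names or {}
    pathways = {
        pid: Pathway(id=pid, name=names.get(pid, pid), genes=set(genes))
        for pid, genes in gene_sets.items()
    }
    for child, parent in edges:
        if child not in pathways or parent not in pathways:
            # relations referring to filtered-out pathways are simply dropped
            continue
        pathways[child].parents.add(parent)
        pathways[parent].children.add(child)

    parentless = [p.id for p in pathways.values() if not p.parents]
    if not pathways:
        raise ConfigurationError("no pathways supplied")
    if len(parentless) == 1:
        root = parentless[0]
    else:
        root = VIRTUAL_ROOT
        if root in pathways:
            raise OntologyError(f"pathway id {root!r} collides with the virtual root")
        universe: set[str] = set()
        for p in pathways.values():
            universe |= p.genes
        pathways[root] = Pathway(id=root, name="root", genes=universe)
        for pid in parentless:
            pathways[pid].parents.add(root)
            pathways[root].children.add(pid)

    levels = _compute_levels(pathways)
    return PathwayHierarchy(pathways=pathways, root=root, levels=levels,
                            n_levels=levels[root])


def filter_pathways(raw: Mapping[str, set[str]],
                    edges: Iterable[tuple[str, str]],
                    relevant_genes: set[str],
                    min_genes: int = 5,
                    names: Mapping[str, str] | None = None) -> PathwayHierarchy:
    """Keep pathways with at least ``min_genes`` relevant members and rebuild
    the rooted hierarchy.

    ``relevant_genes`` is the union of feature genes (expression inputs) and
    target genes (dependency outputs).  Gene sets are restricted to that
    universe, since only those genes can wire into the network.  The root is
    always retained; surviving pathways whose parents were all filtered away
    are re-attached to the root so their signal can still reach the output.
    """
    relevant = {g.upper() for g in relevant_genes}
    full = build_hierarchy(dict(raw), edges, names=names)

    kept: dict[str, set[str]] = {}
    for pid, p in full.pathways.items():
        inter = p.genes & relevant
        if pid == full.root or len(inter) >= min_genes:
            kept[pid] = inter
    if full.root in kept and not kept[full.root]:
        # virtual root gets the union of surviving genes
        universe: set[str] = set()
        for genes in kept.values():
            universe |= genes
        kept[full.root] = universe
    non_root = [pid for pid in kept if pid != full.root and kept[pid]]
    if not non_root:
        raise ConfigurationError(
            f"no pathway has >= {min_genes} relevant genes; hierarchy is empty"
        )
    # drop a root with no surviving genes at all
    if not kept[full.root]:
        raise ConfigurationError("root pathway has no relevant genes")

    surviving_edges = {
        (c, par)
        for c, par in ((p.id, parent) for p in full.pathways.values()
                       for parent in p.parents)
        if c in kept and par in kept
    }
    # orphaned survivors (all parents filtered away) re-attach to the root
    has_parent = {c for c, _ in surviving_edges}
    for pid in kept:
        if pid != full.root and pid not in has_parent:
            surviving_edges.add((pid, full.root))
    return build_hierarchy(
        kept, surviving_edges,
        names={pid: full.pathways[pid].name for pid in kept},
    )
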