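"""Haplotype collapsing and tree-derived haplotype genealogies.

A haplotype genealogy is obtained by transforming the bifurcating tree rather
than by network heuristics: substitutions are first optimised onto the tree
by the same deterministic Fitch resolution used for barcoding diagnostics,
tips carrying identical sequences are merged, branches on which no
substitution was placed are contracted, and internal nodes that remain
unsampled become size-0 connector nodes (spliced away when they merely
subdivide an edge).  Node size is the number of sequence records; edge weight
is the number of substitution events on the contracted path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx

from .cbb import fitch_optimize
from .io import Alignment, IUPAC_CODES, PhyloTree

__all__ = [
    "Haplotype",
    "HaplotypeSet",
    "collapse_haplotypes",
    "build_genealogy",
    "export_genealogy",
    "genealogy_from_json",
]

_MISSING = frozenset("ACGT")  # gap / N / ambiguity treated as uninformative


@dataclass
class Haplotype:
    name: str
    sequence: str          # representative sequence
    members: list          # sample ids
    count: int


class HaplotypeSet:
    """Partition of the samples into identical-sequence classes, ordered by
    descending count then smallest member id."""

    def __init__(self, haplotypes: list):
        self.haplotypes = haplotypes
        self._by_member = {
            m: h for h in haplotypes for m in h.members
        }

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def of_sample(self, sid: str) -> Haplotype:
        return self._by_member[sid]

    @property
    def n_samples(self) -> int:
        return sum(h.count for h in self.haplotypes)


def _compatible(a: str, b: str) -> bool:
    """Equal at every site where both carry a determined base."""
    for x, y in zip(a, b):
        sx, sy = IUPAC_CODES[x], IUPAC_CODES[y]
        if sx is _MISSING or sy is _MISSING or len(sx) > 1 or len(sy) > 1:
            continue
        if x != y:
            return False
    return True


def collapse_haplotypes(alignment: Alignment, policy: str = "strict") -> HaplotypeSet:
    """Collapse identical sequences into haplotypes.

    ``strict`` merges only character-by-character identical sequences.
    ``ignore-missing`` additionally skips sites where either sequence carries
    a gap, 'N' or ambiguity code; because that relation is not transitive,
    groups are merged greedily in descending count order and a warning is
    emitted when a group is compatible with more than one cluster.
    """
    if policy not in ("strict", "ignore-missing"):
        raise ValueError(f"unknown haplotype policy: {policy}")

    groups: dict[str, list] = {}
    for sid, seq in alignment.items():
        groups.setdefault(seq, []).append(sid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))

    if policy == "ignore-missing":
        clusters: list[tuple[str, list]] = []  # (representative, members)
        for seq, members in ordered:
            hits = [i for i, (rep, _) in enumerate(clusters) if _compatible(seq, rep)]
            if not hits:
                clusters.append((seq, list(members)))
                continue
            if len(hits) > 1:
                warnings.warn(
                    "ignore-missing collapsing is ambiguous for a group "
                    f"containing {members[0]!r}; merged into the largest "
                    "compatible cluster",
                    stacklevel=2,
                )
            rep, mem = clusters[hits[0]]
            mem.extend(members)
        ordered = sorted(
            ((rep, mem) for rep, mem in clusters),
            key=lambda kv: (-len(kv[1]), min(kv[1])),
        )

    haplotypes = [
        Haplotype(name=f"H{i + 1}", sequence=seq, members=list(members),
                  count=len(members))
        for i, (seq, members) in enumerate(ordered)
    ]
    return HaplotypeSet(haplotypes)


def build_genealogy(
    tree: PhyloTree,
    alignment: Alignment,
    haplotypes: HaplotypeSet,
) -> nx.Graph:
    """Transform the bifurcating tree into a haplotype genealogy.

    Per-site substitutions come from the deterministic Fitch optimisation;
    zero-substitution branches are contracted, same-haplotype tips merged,
    unsampled degree-2 connector nodes spliced (including a size-0 root,
    giving unrooted-network semantics).  Returns an undirected
    :class:`networkx.Graph` whose nodes carry ``size``, ``members`` and
    ``haplotype`` attributes and whose edges carry integer ``weight`` >= 1.
    """
    submap = fitch_optimize(tree, alignment)
    ids = submap.branch_ids

    g = nx.Graph()
    members: dict[str, list] = {}
    for node in tree.tree.postorder_node_iter():
        nid = ids[node]
        members[nid] = [node.taxon.label] if node.is_leaf() else []
        g.add_node(nid)
        if node.parent_node is not None:
            w = len(submap.events_on(nid))
            g.add_edge(ids[node.parent_node], nid, weight=w)

    def merge(keep: str, drop: str) -> None:
        members[keep].extend(members.pop(drop))
        for nb in list(g.neighbors(drop)):
            if nb == keep:
                continue
            w = g[drop][nb]["weight"]
            if g.has_edge(keep, nb):
                # parallel paths between the same haplotypes carry cancelling
                # homoplasies; keep the lighter connection
                g[keep][nb]["weight"] = min(g[keep][nb]["weight"], w)
            else:
                g.add_edge(keep, nb, weight=w)
        g.remove_node(drop)

    # contract zero-weight edges
    changed = True
    while changed:
        changed = False
        for u, v, _ in list(g.edges(data="weight")):
            if g.has_edge(u, v) and g[u][v]["weight"] == 0:
                merge(u, v)
                changed = True

    # merge any same-haplotype tips still apart (possible only under
    # homoplasy or the ignore-missing policy): absorb the connecting path
    for h in haplotypes:
        nodes = {n for n in g.nodes if set(members[n]) & set(h.members)}
        while len(nodes) > 1:
            nodes = sorted(nodes)
            try:
                path = nx.shortest_path(g, nodes[0], nodes[1])
            except nx.NetworkXNoPath:  # pragma: no cover - genealogy is connected
                break
            for mid in path[1:]:
                merge(path[0], mid)
            nodes = {n for n in g.nodes if set(members[n]) & set(h.members)}

    # splice unsampled degree-2 connectors (root included)
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if members[n]:
                continue
            nbrs = list(g.neighbors(n))
            if len(nbrs) == 2:
                w = g[n][nbrs[0]]["weight"] + g[n][nbrs[1]]["weight"]
                g.remove_node(n)
                members.pop(n)
                if g.has_edge(nbrs[0], nbrs[1]):
                    g[nbrs[0]][nbrs[1]]["weight"] = min(
                        g[nbrs[0]][nbrs[1]]["weight"], w
                    )
                else:
                    g.add_edge(nbrs[0], nbrs[1], weight=w)
                changed = True

    for n in g.nodes:
        mem = sorted(members[n])
        g.nodes[n]["members"] = mem
        g.nodes[n]["size"] = len(mem)
        g.nodes[n]["haplotype"] = (
            haplotypes.of_sample(mem[0]).name if mem else None
        )
    return g


def export_genealogy(genealogy: nx.Graph, format: str = "json", samples=None) -> str:
    """Serialise a genealogy as DOT (Graphviz) or JSON text.

    DOT nodes get an area proportional to size (width ∝ sqrt(size)); when a
    :class:`~haplodelim.io.SampleTable` is given, nodes are coloured by the
    majority clade label of their members.
    """
    if format == "json":
        data = {
            "nodes": [
                {
                    "id": n,
                    "size": genealogy.nodes[n]["size"],
                    "members": genealogy.nodes[n]["members"],
                    "haplotype": genealogy.nodes[n]["haplotype"],
                }
                for n in sorted(genealogy.nodes)
            ],
            "edges": [
                {"source": u, "target": v, "weight": int(w)}
                for u, v, w in sorted(genealogy.edges(data="weight"))
            ],
            "metadata": {
                "n_samples": sum(d["size"] for _, d in genealogy.nodes(data=True)),
                "total_substitutions": int(
                    sum(w for _, _, w in genealogy.edges(data="weight"))
                ),
            },
        }
        return json.dumps(data, indent=2)
    if format == "dot":
        palette = [
            "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
        ]
        clade_colors: dict[str, str] = {}
        lines = ["graph genealogy {", "  node [shape=circle, style=filled];"]
        for n in sorted(genealogy.nodes):
            d = genealogy.nodes[n]
            width = max(0.25, 0.35 * (d["size"] ** 0.5))
            color = "#dddddd"
            if samples is not None and d["members"]:
                counts: dict[str, int] = {}
                for m in d["members"]:
                    counts[samples[m].clade_label] = counts.get(samples[m].clade_label, 0) + 1
                clade = max(sorted(counts), key=lambda c: counts[c])
                color = clade_colors.setdefault(
                    clade, palette[len(clade_colors) % len(palette)]
                )
            label = d["haplotype"] or ""
            lines.append(
                f'  "{n}" [label="{label}", width={width:.2f}, '
                f'fillcolor="{color}", tooltip="size={d["size"]}"];'
            )
        for u, v, w in sorted(genealogy.edges(data="weight")):
            lines.append(f'  "{u}" -- "{v}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown export format: {format}")


def genealogy_from_json(text: str) -> nx.Graph:
    """Inverse of :func:`export_genealogy` for the JSON format."""
    data = json.loads(text)
    g = nx.Graph()
    for nd in data["nodes"]:
        g.add_node(
            nd["id"], size=nd["size"], members=list(nd["members"]),
            haplotype=nd["haplotype"],
        )
    for ed in data["edges"]:
        g.add_edge(ed["source"], ed["target"], weight=ed["weight"])
    return g
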