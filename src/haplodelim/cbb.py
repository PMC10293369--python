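"""Character-based barcoding (CBB) diagnostics.

Nucleotide substitutions are optimised onto a fixed bifurcating topology by
Fitch parsimony with a fully deterministic traceback, each clade's stem-branch
substitutions are extracted as its diagnostic characters, and each diagnostic
is classified by how exclusive it is:

``global``
    the (site, derived state) pair occurs on no other branch of the tree;
``ingroup``
    it recurs somewhere, but on no other branch inside the in-group subtree;
``combination``
    it recurs inside the in-group, so only the combination of characters is
    diagnostic.

The traceback is deterministic on purpose: the root takes the alphabetically
smallest member of its Fitch set and every child inherits the parent state
whenever possible, so event placement is bit-reproducible and identical to the
resolution used when building haplotype genealogies.  Gaps and 'N' contribute
the full state set {A,C,G,T} (missing data forces no event); IUPAC ambiguity
codes contribute their code's set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import Alignment, IUPAC_CODES, PhyloTree, PositionMap, SampleTable

__all__ = [
    "SubstitutionEvent",
    "SubstitutionMap",
    "Diagnostic",
    "DiagnosticSet",
    "fitch_optimize",
    "stem_diagnostics",
    "classify_exclusivity",
    "diagnose_all",
]

_NUCS = "ACGT"


@dataclass(frozen=True)
class SubstitutionEvent:
    site: int           # alignment coordinate, 1-based
    branch: str         # identifier of the child node of the branch
    from_state: str
    to_state: str


@dataclass
class SubstitutionMap:
    """All substitution events of a tree plus per-site Fitch lengths."""

    events: list[SubstitutionEvent]
    per_site_length: dict[int, int]
    total_score: int
    branch_ids: dict = field(repr=False, default_factory=dict)  # node -> id
    clades: dict = field(repr=False, default_factory=dict)      # id -> frozenset(tips)

    def events_on(self, branch: str) -> list[SubstitutionEvent]:
        return [ev for ev in self.events if ev.branch == branch]

    def events_at(self, site: int) -> list[SubstitutionEvent]:
        return [ev for ev in self.events if ev.site == site]


@dataclass
class Diagnostic:
    site: int                    # alignment coordinate
    position_label: str          # reference-numbered, or "aln:<site>"
    from_state: str
    to_state: str
    exclusivity: str             # global | ingroup | combination
    retained_by_all_members: bool


@dataclass
class DiagnosticSet:
    clade: str
    diagnostics: list[Diagnostic]

    @property
    def n_total(self) -> int:
        return len(self.diagnostics)

    @property
    def n_retained(self) -> int:
        return sum(d.retained_by_all_members for d in self.diagnostics)

    @property
    def n_global(self) -> int:
        return sum(d.exclusivity == "global" for d in self.diagnostics)

    @property
    def n_ingroup(self) -> int:
        return sum(d.exclusivity == "ingroup" for d in self.diagnostics)

    @property
    def n_exclusive_retained(self) -> int:
        return sum(
            d.retained_by_all_members and d.exclusivity in ("global", "ingroup")
            for d in self.diagnostics
        )


def _state_set(char: str) -> frozenset:
    return IUPAC_CODES.get(char, frozenset(_NUCS))


def _branch_ids(tree: PhyloTree) -> dict:
    """Stable node identifiers: leaf name for tips, n<k> in postorder."""
    ids = {}
    k = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"n{k}"
            k += 1
    return ids


def fitch_optimize(tree: PhyloTree, alignment: Alignment) -> SubstitutionMap:
    """Optimise per-site substitutions onto ``tree`` by Fitch parsimony.

    Bottom-up pass: a node's state set is the intersection of its children's
    sets when non-empty, else their union; each union adds one to the site's
    Fitch length.  Top-down pass (deterministic): the root takes the
    alphabetically smallest member of its set; each child keeps the parent
    state if possible, otherwise takes its own smallest member and an event is
    recorded on that branch.  The number of events per site equals the site's
    Fitch length.
    """
    leaves = set(tree.leaf_names)
    if leaves != set(alignment.ids):
        raise ValueError(
            "tree leaves and alignment ids differ: "
            f"only-in-tree={sorted(leaves - set(alignment.ids))[:5]}, "
            f"only-in-alignment={sorted(set(alignment.ids) - leaves)[:5]}"
        )
    for node in tree.tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ValueError("fitch_optimize requires a strictly bifurcating tree")

    ids = _branch_ids(tree)
    post = list(tree.tree.postorder_node_iter())
    pre = list(tree.tree.preorder_node_iter())
    events: list[SubstitutionEvent] = []
    per_site: dict[int, int] = {}

    for site in range(1, alignment.length + 1):
        column = alignment.site(site)
        # bottom-up
        sets: dict = {}
        length = 0
        for node in post:
            if node.is_leaf():
                sets[node] = _state_set(column[node.taxon.label])
            else:
                a, b = (sets[ch] for ch in node.child_nodes())
                inter = a & b
                if inter:
                    sets[node] = inter
                else:
                    sets[node] = a | b
                    length += 1
        if length == 0:
            per_site[site] = 0
            continue
        # top-down deterministic resolution
        states: dict = {}
        for node in pre:
            s = sets[node]
            if node.parent_node is None:
                states[node] = min(s)
            else:
                p = states[node.parent_node]
                if p in s:
                    states[node] = p
                else:
                    states[node] = min(s)
                    events.append(
                        SubstitutionEvent(site, ids[node], p, states[node])
                    )
        per_site[site] = length

    clades = {ids[n]: tree.leaves_under(n) for n in pre}
    return SubstitutionMap(
        events=events,
        per_site_length=per_site,
        total_score=sum(per_site.values()),
        branch_ids=ids,
        clades=clades,
    )


def stem_diagnostics(
    submap: SubstitutionMap,
    tree: PhyloTree,
    clade_tips: Iterable[str],
    alignment: Alignment,
    position_map: Optional[PositionMap] = None,
    clade_name: str = "clade",
    ingroup_tips: Optional[Iterable[str]] = None,
) -> DiagnosticSet:
    """Diagnostic substitutions on the stem branch of a clade.

    The stem is the branch subtending the MRCA of ``clade_tips``; its events
    are the clade's candidate diagnostics.  A diagnostic is retained when
    every clade member is compatible with the derived state at that site
    (missing data counts as compatible, i.e. no reversal is observed).
    """
    clade_tips = frozenset(clade_tips)
    mrca = tree.mrca(clade_tips)
    if tree.leaves_under(mrca) != clade_tips:
        raise ValueError(
            f"{clade_name}: tips are not monophyletic "
            "(see tree-based non-exclusivity handling)"
        )
    if mrca.parent_node is None:
        raise ValueError(f"{clade_name}: clade is the whole tree; no stem branch")

    branch = submap.branch_ids[mrca]
    ingroup_tips = frozenset(ingroup_tips) if ingroup_tips is not None else None
    diags = []
    for ev in submap.events_on(branch):
        column = alignment.site(ev.site)
        retained = all(ev.to_state in _state_set(column[t]) for t in clade_tips)
        diags.append(
            Diagnostic(
                site=ev.site,
                position_label=(
                    position_map.label(ev.site) if position_map else f"aln:{ev.site}"
                ),
                from_state=ev.from_state,
                to_state=ev.to_state,
                exclusivity=classify_exclusivity(submap, ev, ingroup_tips),
                retained_by_all_members=retained,
            )
        )
    diags.sort(key=lambda d: d.site)
    return DiagnosticSet(clade=clade_name, diagnostics=diags)


def classify_exclusivity(
    submap: SubstitutionMap,
    event: SubstitutionEvent,
    ingroup_tips: Optional[frozenset] = None,
) -> str:
    """Exclusivity of one substitution: global, ingroup or combination.

    Two events conflict only when they share both site and derived state on
    different branches; a parallel change to a *different* state at the same
    site does not break exclusivity.
    """
    others = [
        ev
        for ev in submap.events_at(event.site)
        if ev.branch != event.branch and ev.to_state == event.to_state
    ]
    if not others:
        return "global"
    if ingroup_tips is None:
        return "combination"
    inside = [
        ev for ev in others if submap.clades.get(ev.branch, frozenset()) <= ingroup_tips
    ]
    return "combination" if inside else "ingroup"


def diagnose_all(
    tree: PhyloTree,
    alignment: Alignment,
    samples: SampleTable,
    position_map: Optional[PositionMap] = None,
    min_diagnostics: int = 1,
    require_exclusive: bool = False,
    submap: Optional[SubstitutionMap] = None,
) -> dict:
    """CBB report for every a-priori species label and every named clade.

    Returns ``{name: {"set": DiagnosticSet | None, "applicable": bool,
    "delimited": bool, "kind": "species" | "clade"}}``.  A label whose tips
    are not monophyletic gets ``applicable=False`` (CBB cannot delimit a
    non-exclusive group).  A species is CBB-delimited when it has at least
    ``min_diagnostics`` retained diagnostics (retained *exclusive*
    diagnostics when ``require_exclusive`` is set).
    """
    if submap is None:
        submap = fitch_optimize(tree, alignment)
    ingroup = frozenset(samples.ingroup_ids())
    report: dict = {}

    def entry(name: str, tips: list, kind: str) -> None:
        tipset = frozenset(tips)
        try:
            dset = stem_diagnostics(
                submap, tree, tipset, alignment,
                position_map=position_map, clade_name=name, ingroup_tips=ingroup,
            )
        except ValueError:
            report[name] = {
                "set": None, "applicable": False, "delimited": False, "kind": kind,
            }
            return
        count = dset.n_exclusive_retained if require_exclusive else dset.n_retained
        report[name] = {
            "set": dset,
            "applicable": True,
            "delimited": count >= min_diagnostics,
            "kind": kind,
        }

    for label in samples.species_labels():
        entry(label, samples.tips_of_species(label), "species")
    for clade in samples.clade_labels():
        if clade in report:  # a clade named like a species label
            continue
        entry(clade, samples.tips_of_clade(clade), "clade")
    return report
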