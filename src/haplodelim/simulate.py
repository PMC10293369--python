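"""Synthetic single-locus data with ground-truth ledgers.

Two generators cover the two halves of the analysis:

:func:`simulate_structured`
    a clade-structured alignment + tree + metadata for the delimitation
    stages: each a-priori group gets a neutral within-group coalescent
    genealogy (parameter θ, coalescent units), grafted onto a fixed label
    topology, with an exact number of *planted* stem substitutions on each
    group's subtending branch.  In homoplasy-free mode (the default) every
    mutation hits a fresh site, so the generator's ledger — which branch got
    which (site, from, to) — is an exact oracle for Fitch optimisation,
    barcoding diagnostics and the haplotype genealogy.

:func:`simulate_demographic`
    a single-population coalescent sample for the mismatch/neutrality
    statistics, optionally with a sudden expansion: looking backwards, the
    coalescence rate is multiplied by ``f`` for times older than ``t``
    (the population was ``f``-fold smaller before the expansion).  Mutations
    are Poisson with mean (total tree length × θ0/2), placed uniformly on
    branches under an infinite-sites model over L sites.

All randomness for a run comes from one ``numpy`` Generator seeded
explicitly; the draw order is fixed (root sequence, then per group:
coalescent topology and times, stem sites and states, within-group
mutations), so identical seed + configuration gives byte-identical outputs.

:func:`make_demo_dataset` is a canned configuration shaped like a small
mitochondrial phylogeography study: six in-group labels of which three are
"good" species with planted stem diagnostics of sizes 2, 5 and 5, three
labels interdigitated inside them (synonym analogues), two out-group labels,
and supports of 1.0 everywhere except one 0.7 node whose sister is fully
supported — so the full pipeline exercises the sister-rescue and
single-haplotype rules and ends with exactly three valid species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .io import Alignment, PhyloTree, SampleInfo, SampleTable

__all__ = [
    "CladeSpec",
    "SimulationLedger",
    "simulate_structured",
    "simulate_demographic",
    "make_demo_dataset",
]

_NUCS = "ACGT"


@dataclass
class CladeSpec:
    """One a-priori group in a structured simulation.

    ``name`` must match a leaf of the label topology; ``label`` is the
    species label written to the sample table (defaults to ``name``; two
    specs may share a label to plant an interdigitated, non-exclusive
    group).
    """

    name: str
    n_samples: int
    theta: float = 0.0
    stem_substitutions: int = 0
    support: Optional[float] = None
    label: Optional[str] = None
    clade_label: str = "unassigned"
    ingroup: bool = True
    #: substitutions planted on terminal branches (one per tip, round-robin),
    #: guaranteeing within-group haplotype diversity regardless of theta
    tip_substitutions: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.theta < 0 or self.stem_substitutions < 0:
            raise ValueError("theta and stem_substitutions must be >= 0")
        if self.label is None:
            self.label = self.name


@dataclass
class SimulationLedger:
    """Ground truth of one simulation run."""

    seed: int
    params: dict
    tree_newick: str = ""
    #: list of {"site", "from", "to", "branch_tips"} with 1-based sites and
    #: branch_tips the sorted tips below the mutated branch
    mutations: list = field(default_factory=list)
    haplotype_partition: list = field(default_factory=list)
    n_variable_sites: int = 0

    @property
    def total_mutations(self) -> int:
        return len(self.mutations)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class _Node:
    __slots__ = ("name", "children", "length", "support", "muts", "tips")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[_Node] = []
        self.length = length
        self.support: Optional[float] = None
        self.muts: list = []          # (site, to_state)
        self.tips: list = []

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        sup = "" if self.support is None else format(self.support, "g")
        return f"({inner}){sup}:{self.length:.6f}"


def _fill_tips(node: _Node) -> list:
    if not node.children:
        node.tips = [node.name]
    else:
        node.tips = [t for c in node.children for t in _fill_tips(c)]
    return node.tips


def _coalescent_subtree(names: list, rng: np.random.Generator,
                        rate_change: Optional[tuple] = None) -> _Node:
    """Neutral coalescent over ``names``; waiting times Exp(C(k,2) · rate).

    ``rate_change=(t, f)`` multiplies the rate by f for times older than t.
    Returns the root; branch lengths are in coalescent units.
    """
    nodes = [_Node(nm) for nm in names]
    if len(nodes) == 1:
        return nodes[0]
    heights = {id(nd): 0.0 for nd in nodes}
    now = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        pair_rate = k * (k - 1) / 2.0
        rate = pair_rate
        if rate_change is not None and now >= rate_change[0]:
            rate = pair_rate * rate_change[1]
        w = rng.exponential(1.0 / rate)
        if rate_change is not None and now < rate_change[0] < now + w:
            now = rate_change[0]
            continue  # memoryless restart at the rate change
        now += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = _Node()
        parent.children = [a, b]
        a.length = now - heights[id(a)]
        b.length = now - heights[id(b)]
        heights[id(parent)] = now
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _parse_label_topology(newick: str) -> _Node:
    """Minimal Newick parser for the label topology (names only)."""
    text = newick.strip().rstrip(";")
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        node = _Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        name = text[start:pos].split(":")[0]
        if name:
            node.name = name
        return node

    root = parse()

    def check_binary(nd: _Node):
        if nd.children and len(nd.children) != 2:
            raise ValueError("label topology must be strictly bifurcating")
        for c in nd.children:
            check_binary(c)

    check_binary(root)
    return root


class _SitePool:
    """Draws distinct 1-based sites (infinite-sites bookkeeping)."""

    def __init__(self, L: int, rng: np.random.Generator):
        self._perm = [int(x) + 1 for x in rng.permutation(L)]
        self._next = 0

    def draw(self) -> int:
        if self._next >= len(self._perm):
            raise ValueError(
                "site exhaustion: more mutations than alignment sites in "
                "homoplasy-free mode; increase L or lower theta"
            )
        site = self._perm[self._next]
        self._next += 1
        return site


def _apply_mutations(root: _Node, root_seq: list, L: int) -> dict:
    """Propagate sequences from the root, applying each branch's mutations."""
    seqs: dict[str, str] = {}

    def walk(node: _Node, seq: list):
        seq = list(seq)
        for site, to in node.muts:
            seq[site - 1] = to
        if not node.children:
            seqs[node.name] = "".join(seq)
        for c in node.children:
            walk(c, seq)

    walk(root, root_seq)
    return seqs


def simulate_structured(
    specs: list,
    topology: str,
    L: int,
    seed: int,
    support_default: float = 1.0,
) -> tuple[Alignment, PhyloTree, SampleTable, SimulationLedger]:
    """Clade-structured alignment + tree + metadata + ground-truth ledger.

    ``topology`` is a Newick string whose leaves are the ``name`` fields of
    ``specs``.  Within each group a neutral coalescent genealogy is grafted
    onto the label topology; mutations are Poisson(branch length × θ/2)
    inside groups plus exactly ``stem_substitutions`` planted on each group's
    stem, all at distinct sites (homoplasy-free / infinite sites).  Internal
    nodes carry ``support_default`` except group roots, which carry their
    spec's ``support``.
    """
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("duplicate spec names")
    root = _parse_label_topology(topology)
    leaf_names = [t for t in _fill_tips(root)]
    if set(leaf_names) != set(by_name):
        raise ValueError(
            f"topology leaves {sorted(leaf_names)} do not match spec names "
            f"{sorted(by_name)}"
        )
    total_planted = sum(s.stem_substitutions for s in specs)
    if total_planted > L:
        raise ValueError("more planted stem substitutions than sites")

    rng = np.random.default_rng(seed)
    root_seq = [_NUCS[i] for i in rng.integers(0, 4, size=L)]
    pool = _SitePool(L, rng)
    ledger = SimulationLedger(
        seed=seed,
        params={
            "kind": "structured",
            "L": L,
            "topology": topology,
            "specs": [asdict(s) for s in specs],
        },
    )

    # replace each label leaf by its within-group coalescent subtree
    def expand(node: _Node):
        for i, child in enumerate(node.children):
            if child.children or child.name not in by_name:
                expand(child)
                if child.children and child.support is None:
                    child.support = support_default
                continue
            spec = by_name[child.name]
            names = [f"{spec.name}_{k + 1:02d}" for k in range(spec.n_samples)]
            sub = _coalescent_subtree(names, rng)
            sub.length = 1.0
            if sub.children:
                sub.support = (
                    spec.support if spec.support is not None else support_default
                )
            node.children[i] = sub

            # planted stem substitutions on the grafted branch
            for _ in range(spec.stem_substitutions):
                site = pool.draw()
                cur = root_seq[site - 1]
                to = _NUCS[(_NUCS.index(cur) + int(rng.integers(1, 4))) % 4]
                sub.muts.append((site, to))

            # planted tip substitutions (deterministic haplotype diversity)
            if spec.tip_substitutions:
                tips = []

                def find_tips(nd: _Node):
                    if not nd.children:
                        tips.append(nd)
                    for c in nd.children:
                        find_tips(c)

                find_tips(sub)
                tips.sort(key=lambda t: t.name)
                for k in range(spec.tip_substitutions):
                    site = pool.draw()
                    cur = root_seq[site - 1]
                    to = _NUCS[(_NUCS.index(cur) + int(rng.integers(1, 4))) % 4]
                    tips[k % len(tips)].muts.append((site, to))

            # within-group Poisson mutations
            if spec.theta > 0:
                def mutate_branch(nd: _Node):
                    for c in nd.children:
                        n_mut = int(rng.poisson(c.length * spec.theta / 2.0))
                        for _ in range(n_mut):
                            site = pool.draw()
                            cur = root_seq[site - 1]
                            to = _NUCS[
                                (_NUCS.index(cur) + int(rng.integers(1, 4))) % 4
                            ]
                            c.muts.append((site, to))
                        mutate_branch(c)
                mutate_branch(sub)

    if not root.children and root.name in by_name:
        # single-group topology: the whole tree is one within-group genealogy
        spec = by_name[root.name]
        names = [f"{spec.name}_{k + 1:02d}" for k in range(spec.n_samples)]
        root = _coalescent_subtree(names, rng)
        if spec.theta > 0:
            def mutate_branch(nd: _Node):
                for c in nd.children:
                    n_mut = int(rng.poisson(c.length * spec.theta / 2.0))
                    for _ in range(n_mut):
                        site = pool.draw()
                        cur = root_seq[site - 1]
                        to = _NUCS[(_NUCS.index(cur) + int(rng.integers(1, 4))) % 4]
                        c.muts.append((site, to))
                    mutate_branch(c)
            mutate_branch(root)
    else:
        expand(root)
    if root.support is None:
        root.support = support_default
    _fill_tips(root)

    # record the ledger in a deterministic preorder
    def record(node: _Node):
        for site, to in node.muts:
            ledger.mutations.append(
                {
                    "site": site,
                    "from": root_seq[site - 1],
                    "to": to,
                    "branch_tips": sorted(node.tips),
                }
            )
        for c in node.children:
            record(c)

    record(root)

    seqs = _apply_mutations(root, root_seq, L)
    order = [t for t in root.tips]
    alignment = Alignment((sid, seqs[sid]) for sid in order)
    tree = PhyloTree.from_newick(root.newick() + ";")
    ledger.tree_newick = tree.as_newick()

    rows = []
    name_to_spec = {}
    for spec in specs:
        for k in range(spec.n_samples):
            name_to_spec[f"{spec.name}_{k + 1:02d}"] = spec
    for sid in order:
        spec = name_to_spec[sid]
        rows.append(
            SampleInfo(
                sample_id=sid,
                species_label=spec.label,
                clade_label=spec.clade_label,
                ingroup=spec.ingroup,
            )
        )
    samples = SampleTable(rows)

    by_seq: dict[str, list] = {}
    for sid in order:
        by_seq.setdefault(seqs[sid], []).append(sid)
    ledger.haplotype_partition = sorted(
        (sorted(v) for v in by_seq.values()), key=lambda g: g[0]
    )
    ledger.n_variable_sites = len({m["site"] for m in ledger.mutations})
    return alignment, tree, samples, ledger


def simulate_demographic(
    n: int,
    theta0: float,
    expansion: Optional[tuple] = None,
    L: int = 1000,
    seed: int = 0,
) -> tuple[Alignment, SimulationLedger]:
    """Single-population coalescent sample, optionally with sudden expansion.

    ``expansion=(t, f)`` multiplies the coalescence rate by ``f`` for times
    older than ``t`` (an instantaneous ``f``-fold size change looking back).
    Mutations: Poisson(total tree length × θ0/2), uniform on branches,
    infinite sites over ``L`` positions.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if expansion is not None and expansion[1] <= 0:
        raise ValueError("expansion factor must be > 0")
    rng = np.random.default_rng(seed)
    root_seq = [_NUCS[i] for i in rng.integers(0, 4, size=L)]
    names = [f"s{k + 1:02d}" for k in range(n)]
    root = _coalescent_subtree(names, rng, rate_change=expansion)
    _fill_tips(root)

    branches = []

    def collect(nd: _Node):
        for c in nd.children:
            branches.append(c)
            collect(c)

    collect(root)
    total_len = sum(b.length for b in branches)
    n_mut = int(rng.poisson(total_len * theta0 / 2.0)) if theta0 > 0 else 0
    pool = _SitePool(L, rng)
    lens = np.array([b.length for b in branches])
    probs = lens / lens.sum() if total_len > 0 else None
    ledger = SimulationLedger(
        seed=seed,
        params={
            "kind": "demographic",
            "n": n,
            "theta0": theta0,
            "expansion": list(expansion) if expansion else None,
            "L": L,
            "total_tree_length": total_len,
        },
    )
    for _ in range(n_mut):
        b = branches[int(rng.choice(len(branches), p=probs))]
        site = pool.draw()
        cur = root_seq[site - 1]
        to = _NUCS[(_NUCS.index(cur) + int(rng.integers(1, 4))) % 4]
        b.muts.append((site, to))
        ledger.mutations.append(
            {"site": site, "from": cur, "to": to, "branch_tips": sorted(b.tips)}
        )

    seqs = _apply_mutations(root, root_seq, L)
    alignment = Alignment((sid, seqs[sid]) for sid in names)
    ledger.tree_newick = root.newick() + ";"
    by_seq: dict[str, list] = {}
    for sid in names:
        by_seq.setdefault(seqs[sid], []).append(sid)
    ledger.haplotype_partition = sorted(
        (sorted(v) for v in by_seq.values()), key=lambda g: g[0]
    )
    ledger.n_variable_sites = len({m["site"] for m in ledger.mutations})
    return alignment, ledger


#: Label topology of the canned fixture.  The three "good" species sit on
#: clearly subtended branches; the synonym analogues are split into two
#: same-labelled groups each, placed so their joint MRCA spans the good
#: species (non-exclusive by construction).  No stem substitution is planted
#: on a child-of-root branch, where parsimony placement is ambiguous.
DEMO_TOPOLOGY = (
    "(((synA1x,(synA1y,(synA2x,(spA,synA2y)))),"
    "((synB1x,(spB,synB1y)),spC)),(out1,out2));"
)


def demo_specs(
    stems: bool = True,
    uniform_support: Optional[float] = None,
) -> list:
    """CladeSpecs of the canned study-shaped fixture."""
    def sup(v):
        return v if uniform_support is None else uniform_support

    st = (lambda k: k) if stems else (lambda k: 0)
    ing = dict(clade_label="ingroup", ingroup=True)
    out = dict(clade_label="outgroup", ingroup=False)
    return [
        CladeSpec("synA1x", 1, 0.0, st(1), label="syn_A1", **ing),
        CladeSpec("synA1y", 1, 0.0, st(1), label="syn_A1", **ing),
        CladeSpec("synA2x", 1, 0.0, st(1), label="syn_A2", **ing),
        CladeSpec("spA", 8, 1.5, st(2), support=sup(0.7), label="species_A",
                  tip_substitutions=1, **ing),
        CladeSpec("synA2y", 2, 0.0, st(1), support=sup(1.0), label="syn_A2", **ing),
        CladeSpec("synB1x", 1, 0.0, st(1), label="syn_B1", **ing),
        CladeSpec("spB", 6, 0.5, st(5), support=sup(1.0), label="species_B", **ing),
        CladeSpec("synB1y", 1, 0.0, st(1), label="syn_B1", **ing),
        CladeSpec("spC", 4, 0.0, st(5), support=sup(1.0), label="species_C", **ing),
        CladeSpec("out1", 2, 0.0, st(3), support=sup(1.0), label="outgroup_1", **out),
        CladeSpec("out2", 2, 0.0, st(3), support=sup(1.0), label="outgroup_2", **out),
    ]


def make_demo_dataset(
    seed: int,
    L: int = 1039,
    stems: bool = True,
    uniform_support: Optional[float] = None,
):
    """The canned study-shaped fixture (see module docstring).

    ``stems=False`` removes all planted stem substitutions;
    ``uniform_support`` overrides every stamped support (backbone included).
    """
    sd = support_default = 1.0 if uniform_support is None else uniform_support
    return simulate_structured(
        demo_specs(stems=stems, uniform_support=uniform_support),
        DEMO_TOPOLOGY,
        L=L,
        seed=seed,
        support_default=sd,
    )
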