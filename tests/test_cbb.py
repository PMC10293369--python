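import numpy as np
import pytest

from haplodelim.cbb import (
    SubstitutionEvent,
    classify_exclusivity,
    diagnose_all,
    fitch_optimize,
    stem_diagnostics,
)
from haplodelim.io import Alignment, PhyloTree, SampleInfo, SampleTable
from haplodelim.simulate import CladeSpec, make_demo_dataset, simulate_structured

from oracles import fitch_length_enumerate, fitch_length_pure_python


def tree_as_children(tree):
    """PhyloTree -> {internal id: (child ids)} plus the tip name map."""
    ids = {}
    k = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"i{k}"
            k += 1
    children = {
        ids[n]: tuple(ids[c] for c in n.child_nodes())
        for n in tree.tree.postorder_node_iter()
        if not n.is_leaf()
    }
    return children


def random_tree(rng, leaves):
    """Random binary rooted tree over the given leaf names."""
    nodes = [f"{lv}" for lv in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return PhyloTree.from_newick(nodes[0] + ";")


class TestFitch:
    def test_invariant_site_no_events(self):
        aln = Alignment([(x, "A") for x in "ABCD"])
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        sm = fitch_optimize(tree, aln)
        assert sm.total_score == 0 and sm.events == []

    def test_single_informative_site_deterministic_placement(self):
        # root set {C,T} resolves alphabetically to C, so the event is the
        # T-derived change on the stem of (A,B)
        aln = Alignment([("A", "T"), ("B", "T"), ("C", "C"), ("D", "C")])
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        sm = fitch_optimize(tree, aln)
        assert sm.total_score == 1
        (ev,) = sm.events
        assert ev.from_state == "C" and ev.to_state == "T"
        assert sm.clades[ev.branch] == frozenset("AB")

    def test_missing_tip_contributes_full_set(self):
        aln = Alignment([("A", "N"), ("B", "T"), ("C", "C"), ("D", "-")])
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        sm = fitch_optimize(tree, aln)
        assert sm.total_score == 1  # only the T/C conflict costs a change

    def test_score_matches_enumeration_small_trees(self):
        rng = np.random.default_rng(23)
        for n_leaves in (4, 5, 6):
            leaves = [f"t{i}" for i in range(n_leaves)]
            tree = random_tree(rng, leaves)
            chars = np.array(list("ACGT"))
            aln = Alignment(
                [(lv, "".join(chars[rng.integers(0, 4, 12)])) for lv in leaves]
            )
            sm = fitch_optimize(tree, aln)
            children = tree_as_children(tree)
            for site in range(1, 13):
                column = aln.site(site)
                want = fitch_length_pure_python(children, column)
                assert sm.per_site_length[site] == want
            assert sm.total_score == sum(sm.per_site_length.values())

    def test_per_site_events_equal_fitch_length(self):
        aln, tree, _, _ = make_demo_dataset(seed=2)
        sm = fitch_optimize(tree, aln)
        from collections import Counter

        per_site = Counter(ev.site for ev in sm.events)
        for site, length in sm.per_site_length.items():
            assert per_site.get(site, 0) == length

    def test_planted_mutations_recovered_on_true_branches(self):
        for seed in (0, 1):
            aln, tree, _, ledger = make_demo_dataset(seed=seed)
            sm = fitch_optimize(tree, aln)
            got = sorted(
                (ev.site, ev.to_state, tuple(sorted(sm.clades[ev.branch])))
                for ev in sm.events
            )
            want = sorted(
                (m["site"], m["to"], tuple(m["branch_tips"]))
                for m in ledger.mutations
            )
            assert got == want

    def test_relabeling_permutes_but_preserves_counts(self):
        aln, tree, _, _ = make_demo_dataset(seed=4)
        sm = fitch_optimize(tree, aln)
        ren = {sid: f"x_{sid}" for sid in aln.ids}
        aln2 = Alignment((ren[sid], seq) for sid, seq in aln.items())
        nwk = tree.as_newick()
        for old, new in ren.items():
            nwk = nwk.replace(old, new)
        tree2 = PhyloTree.from_newick(nwk)
        sm2 = fitch_optimize(tree2, aln2)
        assert sm2.total_score == sm.total_score
        assert sm2.per_site_length == sm.per_site_length


class TestStemDiagnostics:
    @pytest.fixture
    def planted(self):
        specs = [
            CladeSpec("p", 3, 0.0, 3, clade_label="c"),
            CladeSpec("q", 3, 0.0, 2, clade_label="c"),
            CladeSpec("r", 2, 0.0, 5, clade_label="c"),
            CladeSpec("s", 2, 0.0, 1, clade_label="c"),
        ]
        return simulate_structured(specs, "((p,q),(r,s));", L=200, seed=12)

    def test_planted_stem_recovered(self, planted):
        aln, tree, samples, ledger = planted
        sm = fitch_optimize(tree, aln)
        dset = stem_diagnostics(sm, tree, samples.tips_of_species("p"), aln,
                                clade_name="p")
        assert dset.n_total == 3
        assert all(d.retained_by_all_members for d in dset.diagnostics)
        assert all(d.exclusivity == "global" for d in dset.diagnostics)

    def test_empty_stem(self):
        aln = Alignment([(x, "ACGT") for x in "ABCD"])
        tree = PhyloTree.from_newick("((A,B),(C,D));")
        sm = fitch_optimize(tree, aln)
        dset = stem_diagnostics(sm, tree, ["A", "B"], aln)
        assert dset.n_total == 0

    def test_non_monophyletic_rejected(self, planted):
        aln, tree, samples, _ = planted
        sm = fitch_optimize(tree, aln)
        mixed = samples.tips_of_species("p")[:1] + samples.tips_of_species("r")[:1]
        with pytest.raises(ValueError, match="not monophyletic"):
            stem_diagnostics(sm, tree, mixed, aln)

    def test_sister_pair_shares_joint_stem(self, planted):
        # the clade joining two planted groups reports its own joint stem
        aln, tree, samples, _ = planted
        sm = fitch_optimize(tree, aln)
        joint = samples.tips_of_species("p") + samples.tips_of_species("q")
        dset = stem_diagnostics(sm, tree, joint, aln, clade_name="pq")
        assert dset.n_total == 0  # nothing planted above the pair here


class TestExclusivity:
    def _eight_taxon_case(self):
        # hand-built: site 1 mutates A->T once (global); site 2 mutates A->G
        # on an in-group branch and again on an out-group branch (ingroup
        # exclusivity); site 3 mutates A->C in parallel on two in-group
        # terminal branches (combination).  Verified by listing every event
        # of the optimisation.
        seqs = {
            "i1": "TGC", "i2": "TGA", "i3": "TAC", "i4": "TAA",
            "o1": "AGA", "o2": "AGA", "o3": "AAA", "o4": "AAA",
        }
        aln = Alignment(list(seqs.items()))
        tree = PhyloTree.from_newick(
            "(((i1,i2),(i3,i4)),((o1,o2),(o3,o4)));"
        )
        sm = fitch_optimize(tree, aln)
        ingroup = frozenset(["i1", "i2", "i3", "i4"])
        return aln, tree, sm, ingroup

    def test_unique_event_is_global(self):
        _, _, sm, ingroup = self._eight_taxon_case()
        (ev,) = [e for e in sm.events if e.site == 1]
        assert classify_exclusivity(sm, ev, ingroup) == "global"

    def test_outgroup_recurrence_is_ingroup_exclusive(self):
        _, _, sm, ingroup = self._eight_taxon_case()
        evs = sm.events_at(2)
        assert len(evs) == 2
        inside = [e for e in evs if sm.clades[e.branch] <= ingroup]
        assert len(inside) == 1
        assert classify_exclusivity(sm, inside[0], ingroup) == "ingroup"

    def test_ingroup_recurrence_is_combination(self):
        _, _, sm, ingroup = self._eight_taxon_case()
        evs = [e for e in sm.events_at(3) if sm.clades[e.branch] <= ingroup]
        assert len(evs) == 2
        for ev in evs:
            assert classify_exclusivity(sm, ev, ingroup) == "combination"

    def test_adding_homoplasy_only_demotes(self):
        # monotonicity: appending a synthetic recurrent event can demote
        # global -> ingroup -> combination, never promote
        _, _, sm, ingroup = self._eight_taxon_case()
        (ev,) = [e for e in sm.events if e.site == 1]
        assert classify_exclusivity(sm, ev, ingroup) == "global"
        outgroup_branch = next(
            b for b, tips in sm.clades.items()
            if tips == frozenset(["o1", "o2"])
        )
        sm.events.append(SubstitutionEvent(1, outgroup_branch, "A", "T"))
        assert classify_exclusivity(sm, ev, ingroup) == "ingroup"
        ingroup_branch = next(
            b for b, tips in sm.clades.items()
            if tips == frozenset(["i3", "i4"])
        )
        sm.events.append(SubstitutionEvent(1, ingroup_branch, "A", "T"))
        assert classify_exclusivity(sm, ev, ingroup) == "combination"


class TestDiagnoseAll:
    def test_planted_counts_reported(self):
        specs = [
            CladeSpec("a", 3, 0.0, 2, clade_label="in"),
            CladeSpec("b", 3, 0.0, 5, clade_label="in"),
            CladeSpec("c", 3, 0.0, 5, clade_label="in"),
            CladeSpec("d", 2, 0.0, 1, clade_label="out", ingroup=False),
        ]
        aln, tree, samples, _ = simulate_structured(
            specs, "((a,(b,c)),d);", L=300, seed=6
        )
        report = diagnose_all(tree, aln, samples)
        counts = {
            lbl: report[lbl]["set"].n_total for lbl in ("a", "b", "c")
        }
        assert counts == {"a": 2, "b": 5, "c": 5}
        assert all(report[lbl]["delimited"] for lbl in ("a", "b", "c"))

    def test_empty_stem_not_delimited(self):
        specs = [
            CladeSpec("a", 3, 0.0, 0),
            CladeSpec("b", 3, 0.0, 4),
            CladeSpec("c", 2, 0.0, 2),
        ]
        aln, tree, samples, _ = simulate_structured(
            specs, "((a,b),c);", L=100, seed=8
        )
        report = diagnose_all(tree, aln, samples)
        assert report["a"]["applicable"] and not report["a"]["delimited"]

    def test_non_monophyletic_label_not_applicable(self, demo):
        aln, tree, samples, _ = demo
        report = diagnose_all(tree, aln, samples)
        assert not report["syn_A1"]["applicable"]
        assert not report["syn_A1"]["delimited"]

    def test_require_exclusive_flag(self, demo):
        aln, tree, samples, _ = demo
        strict = diagnose_all(tree, aln, samples, require_exclusive=True)
        assert strict["species_A"]["delimited"]  # planted stems are exclusive
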