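import pytest

from haplodelim.cbb import diagnose_all
from haplodelim.haplotypes import collapse_haplotypes
from haplodelim.io import Alignment, PhyloTree, SampleInfo, SampleTable
from haplodelim.simulate import CladeSpec, make_demo_dataset, simulate_structured
from haplodelim.wp import (
    assess_exclusivity,
    consensus_delimit,
    summarize,
    wp_delimit,
)


def build_case(newick, seqs, labels):
    aln = Alignment(list(seqs.items()))
    tree = PhyloTree.from_newick(newick)
    samples = SampleTable(
        [SampleInfo(sid, lab) for sid, lab in labels.items()]
    )
    return aln, tree, samples, collapse_haplotypes(aln)


class TestExclusivity:
    def test_pure_clade_is_exclusive(self):
        aln, tree, samples, haps = build_case(
            "(((a1,a2)0.99,a3)0.99,(b1,b2)0.99);",
            {"a1": "AAAA", "a2": "AAAT", "a3": "AATT",
             "b1": "TTAA", "b2": "TTAT"},
            {"a1": "spA", "a2": "spA", "a3": "spA", "b1": "spB", "b2": "spB"},
        )
        assert assess_exclusivity(tree, samples, "spA", haps) == ("exclusive", [])

    def test_interdigitated_label_reports_partner(self):
        aln, tree, samples, haps = build_case(
            "((a1,(b1,a2)0.9)0.9,(b2,b3)0.9);",
            {"a1": "AAAA", "a2": "AAAT", "b1": "AATT",
             "b2": "TTAA", "b3": "TTAT"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "b3": "spB"},
        )
        exc, partners = assess_exclusivity(tree, samples, "spA", haps)
        assert exc == "non-exclusive" and partners == ["spB"]

    def test_single_haplotype_label(self):
        aln, tree, samples, haps = build_case(
            "((a1,a2)1.0,(b1,b2)1.0);",
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"},
        )
        assert assess_exclusivity(tree, samples, "spA", haps)[0] == "single-haplotype"

    def test_unknown_label_raises(self):
        aln, tree, samples, haps = build_case(
            "(a1,b1);", {"a1": "AA", "b1": "AT"}, {"a1": "spA", "b1": "spB"}
        )
        with pytest.raises(ValueError, match="no samples"):
            assess_exclusivity(tree, samples, "ghost", haps)


class TestWPRules:
    def _verdict(self, verdicts, label):
        return next(v for v in verdicts if v.species_label == label)

    def case(self, support_a):
        return build_case(
            f"(((a1,a2){support_a},(c1,c2)1.0)1.0,(b1,b2)1.0);",
            {"a1": "AAAA", "a2": "AAAT", "c1": "CCCC", "c2": "CCCA",
             "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "c1": "spC", "c2": "spC",
             "b1": "spB", "b2": "spB"},
        )

    def test_exclusive_supported_delimited(self):
        aln, tree, samples, haps = self.case(1.0)
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.decision == "delimited" and v.rule == "exclusive, supported"

    def test_sister_rescue(self):
        # weak own support (0.7) but a well-supported sister clade
        aln, tree, samples, haps = self.case(0.7)
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.decision == "delimited" and "sister-rescue" in v.rule
        assert v.own_support == 0.7 and v.sister_support == 1.0

    def test_both_unsupported_ambiguous(self):
        aln, tree, samples, haps = build_case(
            "(((a1,a2)0.7,(c1,c2)0.8)0.9,(b1,b2)1.0);",
            {"a1": "AAAA", "a2": "AAAT", "c1": "CCCC", "c2": "CCCA",
             "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "c1": "spC", "c2": "spC",
             "b1": "spB", "b2": "spB"},
        )
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.decision == "ambiguous"

    def test_single_haplotype_with_supported_sister_delimited(self):
        aln, tree, samples, haps = build_case(
            "((a1,a2)0.5,(b1,b2)1.0);",
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"},
        )
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.exclusivity == "single-haplotype"
        assert v.decision == "delimited"

    def test_single_haplotype_unsupported_sister_ambiguous(self):
        aln, tree, samples, haps = build_case(
            "((a1,a2)0.5,(b1,b2)0.5);",
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"},
        )
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.decision == "ambiguous"

    def test_non_exclusive_not_delimited_with_partner(self):
        aln, tree, samples, haps = build_case(
            "((a1,(b1,a2)1.0)1.0,(b2,b3)1.0);",
            {"a1": "AAAA", "a2": "AAAT", "b1": "AATT",
             "b2": "TTAA", "b3": "TTAT"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB", "b3": "spB"},
        )
        v = self._verdict(wp_delimit(tree, samples, haps), "spA")
        assert v.decision == "not-delimited"
        assert v.lump_partners == ["spB"]

    def test_threshold_is_strict_greater_than(self):
        # support exactly at the threshold does not pass ("higher than")
        aln, tree, samples, haps = self.case(0.95)
        verdicts = wp_delimit(tree, samples, haps, support_threshold=0.95)
        v = self._verdict(verdicts, "spA")
        assert v.rule != "exclusive, supported"

    def test_raising_threshold_never_delimits_more(self):
        aln, tree, samples, haps = self.case(0.7)
        lo = wp_delimit(tree, samples, haps, support_threshold=0.5)
        hi = wp_delimit(tree, samples, haps, support_threshold=0.99)
        for vlo, vhi in zip(lo, hi):
            if vhi.decision == "delimited":
                assert vlo.decision == "delimited"

    def test_absent_support_treated_as_zero(self):
        aln, tree, samples, haps = build_case(
            "((a1,a2),(b1,b2));",
            {"a1": "AAAA", "a2": "AAAT", "b1": "TTTT", "b2": "TTTA"},
            {"a1": "spA", "a2": "spA", "b1": "spB", "b2": "spB"},
        )
        for v in wp_delimit(tree, samples, haps):
            assert v.decision == "ambiguous"


class TestConsensus:
    def test_both_methods_required(self, demo):
        aln, tree, samples, _ = demo
        haps = collapse_haplotypes(aln)
        verdicts = wp_delimit(tree, samples, haps)
        report = diagnose_all(tree, aln, samples)
        decisions = consensus_delimit(verdicts, report)
        s = summarize(decisions)
        assert s["n_valid_species"] == 3
        assert s["valid_species"] == ["species_A", "species_B", "species_C"]
        assert s["synonym_candidates"] == ["syn_A1", "syn_A2", "syn_B1"]
        by_label = {d.species_label: d for d in decisions}
        assert by_label["syn_A2"].final == "possible-junior-synonym-of species_A"
        assert by_label["syn_B1"].final == "possible-junior-synonym-of species_B"

    def test_wp_without_cbb_is_unresolved(self):
        # stems removed: WP can still delimit but CBB finds no diagnostics
        aln, tree, samples, _ = make_demo_dataset(seed=7, stems=False)
        haps = collapse_haplotypes(aln)
        verdicts = wp_delimit(tree, samples, haps)
        report = diagnose_all(tree, aln, samples)
        s = summarize(consensus_delimit(verdicts, report))
        assert s["n_valid_species"] == 0

    def test_low_supports_give_no_valid_species(self):
        aln, tree, samples, _ = make_demo_dataset(seed=7, uniform_support=0.5)
        haps = collapse_haplotypes(aln)
        verdicts = wp_delimit(tree, samples, haps)
        report = diagnose_all(tree, aln, samples)
        s = summarize(consensus_delimit(verdicts, report))
        assert s["n_valid_species"] == 0

    def test_outgroup_excluded_from_summary(self, demo):
        aln, tree, samples, _ = demo
        haps = collapse_haplotypes(aln)
        decisions = consensus_delimit(
            wp_delimit(tree, samples, haps), diagnose_all(tree, aln, samples)
        )
        s = summarize(decisions)
        assert "outgroup_1" not in s["valid_species"]

    def test_planted_species_recovered_and_shuffle_breaks_exclusivity(self):
        specs = [
            CladeSpec("x", 4, 0.0, 2, support=1.0, tip_substitutions=1),
            CladeSpec("y", 4, 0.0, 3, support=1.0, tip_substitutions=1),
            CladeSpec("z", 3, 0.0, 2, support=1.0, tip_substitutions=1),
        ]
        for seed in (1, 2, 3):
            aln, tree, samples, _ = simulate_structured(
                specs, "((x,y),z);", L=150, seed=seed
            )
            haps = collapse_haplotypes(aln)
            verdicts = wp_delimit(tree, samples, haps)
            assert all(v.decision == "delimited" for v in verdicts)
            # shuffling labels across clades destroys exclusivity
            rows = samples.rows()
            labels = [r.species_label for r in rows]
            shuffled = SampleTable(
                [
                    SampleInfo(r.sample_id, labels[(i + 1) % len(labels)])
                    for i, r in enumerate(rows)
                ]
            )
            verdicts2 = wp_delimit(tree, shuffled, collapse_haplotypes(aln))
            assert any(v.exclusivity == "non-exclusive" for v in verdicts2)
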