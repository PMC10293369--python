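"""Tree-based species delimitation and the consensus with barcoding.

Implements the Wiens–Penkrot (WP) protocol over a-priori species labels on a
rooted tree with node supports, plus the consensus rule that a species is
valid only when both the tree-based and the character-based method delimit
it.

Decision rules per label (support comparisons are strict ``>`` against the
threshold, default 0.95 posterior probability):

1. exclusive haplotypes and the label's own clade well supported → delimited;
2. exclusive but weakly supported, sister group well supported → delimited
   (sister-rescue);
3. exclusive, neither supported → ambiguous;
4. all sequences one haplotype: delimited when the sister lineage is well
   supported, else ambiguous;
5. non-exclusive (interdigitated with other labels) → not delimited; the
   interdigitated labels are reported as lump partners (potential senior
   synonyms).

Out-group labels receive verdicts but never count toward the valid-species
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .haplotypes import HaplotypeSet
from .io import PhyloTree, SampleTable

__all__ = [
    "WPVerdict",
    "DelimitationDecision",
    "assess_exclusivity",
    "wp_delimit",
    "consensus_delimit",
]


@dataclass
class WPVerdict:
    species_label: str
    exclusivity: str                     # exclusive | non-exclusive | single-haplotype
    own_support: Optional[float]
    sister_support: Optional[float]
    decision: str                        # delimited | not-delimited | ambiguous
    lump_partners: list = field(default_factory=list)
    rule: str = ""
    ingroup: bool = True


@dataclass
class DelimitationDecision:
    species_label: str
    wp: WPVerdict
    cbb_delimited: bool
    cbb_total: int
    cbb_exclusive: int
    final: str                           # valid | possible-junior-synonym-of X | unresolved


def _support(value: Optional[float]) -> float:
    """Absent support counts as 0: an unsupported node never passes."""
    return 0.0 if value is None else value


def assess_exclusivity(
    tree: PhyloTree,
    samples: SampleTable,
    label: str,
    haplotypes: HaplotypeSet,
) -> tuple[str, list]:
    """Classify a label as single-haplotype, exclusive or non-exclusive.

    Returns ``(exclusivity, interdigitated_labels)``; the second element is
    non-empty only for non-exclusive labels and lists the other labels found
    inside the MRCA of this label's tips.
    """
    tips = samples.tips_of_species(label)
    if not tips:
        raise ValueError(f"label {label!r} has no samples")
    haps = {haplotypes.of_sample(t).name for t in tips}
    if len(haps) == 1:
        return "single-haplotype", []
    mrca = tree.mrca(tips)
    under = tree.leaves_under(mrca)
    if under == frozenset(tips):
        return "exclusive", []
    partners = sorted(
        {samples[t].species_label for t in under} - {label}
    )
    return "non-exclusive", partners


def _sister_support(tree: PhyloTree, node) -> Optional[float]:
    """Support of the sister clade's own node; for a single-tip sister the
    parent node's support is substituted (the tip has no node of its own)."""
    sister = tree.sister_of(node)
    if sister is None:
        return None
    if sister.is_leaf():
        return tree.support_of(node.parent_node)
    return tree.support_of(sister)


def wp_delimit(
    tree: PhyloTree,
    samples: SampleTable,
    haplotypes: HaplotypeSet,
    support_threshold: float = 0.95,
) -> list[WPVerdict]:
    """Apply the WP decision table to every a-priori species label."""
    if not 0 < support_threshold <= 1:
        raise ValueError("support threshold must lie in (0, 1]")
    verdicts = []
    for label in samples.species_labels():
        tips = samples.tips_of_species(label)
        exclusivity, partners = assess_exclusivity(tree, samples, label, haplotypes)
        mrca = tree.mrca(tips)
        own = tree.support_of(mrca) if not mrca.is_leaf() else None
        sis = _sister_support(tree, mrca)
        ingroup = samples.is_ingroup_species(label)

        if exclusivity == "non-exclusive":
            decision, rule = "not-delimited", "non-exclusive"
        elif exclusivity == "single-haplotype":
            if _support(sis) > support_threshold:
                decision, rule = "delimited", "single-haplotype, sister supported"
            else:
                decision, rule = "ambiguous", "single-haplotype, sister unsupported"
        else:  # exclusive
            if _support(own) > support_threshold:
                decision, rule = "delimited", "exclusive, supported"
            elif _support(sis) > support_threshold:
                decision, rule = "delimited", "exclusive, sister-rescue"
            else:
                decision, rule = "ambiguous", "exclusive, unsupported"

        verdicts.append(
            WPVerdict(
                species_label=label,
                exclusivity=exclusivity,
                own_support=own,
                sister_support=sis,
                decision=decision,
                lump_partners=partners,
                rule=rule,
                ingroup=ingroup,
            )
        )
    return verdicts


def consensus_delimit(verdicts: list, cbb_report: dict) -> list[DelimitationDecision]:
    """Combine WP verdicts with the CBB report.

    A species is ``valid`` only when WP delimits it *and* it has the required
    barcoding diagnostics.  A non-exclusive label becomes a possible junior
    synonym of the valid label(s) it interdigitates with; everything else is
    ``unresolved``.
    """
    valid = set()
    for v in verdicts:
        cbb = cbb_report.get(v.species_label, {})
        if v.decision == "delimited" and cbb.get("delimited"):
            valid.add(v.species_label)

    decisions = []
    for v in verdicts:
        cbb = cbb_report.get(v.species_label, {})
        dset = cbb.get("set")
        cbb_delim = bool(cbb.get("delimited"))
        if v.species_label in valid:
            final = "valid"
        elif v.exclusivity == "non-exclusive":
            seniors = [p for p in v.lump_partners if p in valid]
            if seniors:
                final = f"possible-junior-synonym-of {'/'.join(seniors)}"
            else:
                final = "unresolved"
        else:
            final = "unresolved"
        decisions.append(
            DelimitationDecision(
                species_label=v.species_label,
                wp=v,
                cbb_delimited=cbb_delim,
                cbb_total=dset.n_total if dset else 0,
                cbb_exclusive=(dset.n_global + dset.n_ingroup) if dset else 0,
                final=final,
            )
        )
    return decisions


def summarize(decisions: list) -> dict:
    """Counts of in-group valid species and synonym candidates."""
    n_valid = sum(d.final == "valid" and d.wp.ingroup for d in decisions)
    synonyms = [
        d.species_label
        for d in decisions
        if d.final.startswith("possible-junior-synonym") and d.wp.ingroup
    ]
    return {
        "n_valid_species": n_valid,
        "valid_species": [
            d.species_label for d in decisions if d.final == "valid" and d.wp.ingroup
        ],
        "n_synonym_candidates": len(synonyms),
        "synonym_candidates": synonyms,
    }
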