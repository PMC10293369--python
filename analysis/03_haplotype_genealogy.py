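#!/usr/bin/env python
"""Build the haplotype genealogy from the bifurcating tree.

Collapses identical sequences into haplotypes, optimises substitutions onto
the tree, contracts substitution-free branches and writes the resulting
genealogy (node size = number of sequence records, edge weight = number of
substitutions) as DOT and JSON under ``results/``.
"""

from pathlib import Path

from haplodelim.haplotypes import build_genealogy, collapse_haplotypes, export_genealogy
from haplodelim.io import read_alignment, read_samples, read_tree

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    aln = read_alignment(ROOT / "dataset" / "alignment.fasta")
    tree = read_tree(ROOT / "dataset" / "tree.nwk")
    samples = read_samples(ROOT / "dataset" / "samples.tsv")

    haps = collapse_haplotypes(aln)
    g = build_genealogy(tree, aln, haps)
    (ROOT / "genealogy.dot").write_text(export_genealogy(g, "dot", samples=samples))
    (ROOT / "genealogy.json").write_text(export_genealogy(g, "json"))

    sampled = [d for _, d in g.nodes(data=True) if d["size"] > 0]
    total_w = sum(w for *_, w in g.edges(data="weight"))
    print(f"{aln.n} sequences collapse to {len(haps)} haplotypes")
    print(
        f"genealogy: {g.number_of_nodes()} nodes "
        f"({len(sampled)} sampled, {g.number_of_nodes() - len(sampled)} inferred), "
        f"{g.number_of_edges()} edges, {total_w} substitutions in total"
    )
    biggest = max(sampled, key=lambda d: d["size"])
    print(
        f"largest haplotype node: {biggest['haplotype']} with "
        f"{biggest['size']} records ({', '.join(biggest['members'][:4])}...)"
    )
    print(f"wrote {ROOT/'genealogy.dot'} and {ROOT/'genealogy.json'}")


if __name__ == "__main__":
    main()
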