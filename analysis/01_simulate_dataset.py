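#!/usr/bin/env python
"""Generate the synthetic study dataset used by the downstream analyses.

Writes a clade-structured cyt-b-like alignment (1,039 bp, 29 samples, eight
a-priori species labels, two of them out-groups), the true tree with node
supports, the sample metadata table and the ground-truth mutation ledger to
``results/dataset/``.
"""

from pathlib import Path

from haplodelim.io import write_alignment, write_samples, write_tree
from haplodelim.simulate import make_demo_dataset

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    aln, tree, samples, ledger = make_demo_dataset(seed=SEED)
    write_alignment(aln, OUT / "alignment.fasta")
    write_tree(tree, OUT / "tree.nwk")
    write_samples(samples, OUT / "samples.tsv")
    (OUT / "ledger.json").write_text(ledger.to_json())

    n_planted = sum(
        s["stem_substitutions"] + s.get("tip_substitutions", 0)
        for s in ledger.params["specs"]
    )
    print(f"wrote {aln.n} samples x {aln.length} bp to {OUT}")
    print(
        f"true mutations: {ledger.total_mutations} "
        f"({n_planted} planted, {ledger.total_mutations - n_planted} coalescent)"
    )
    print(f"true haplotypes: {len(ledger.haplotype_partition)}")


if __name__ == "__main__":
    main()
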