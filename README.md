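# haplodelim

Single-locus phylogeography and species delimitation for small
mitochondrial datasets — the analysis a systematist runs after sequencing a
cyt *b* (or similar) fragment from a handful of candidate species: collapse
sequences into haplotypes, transform the inference tree into a haplotype
genealogy, characterise each group's demographic history from its mismatch
distribution, and decide which a-priori species labels hold up under two
independent delimitation criteria.

## What it computes

**Haplotype genealogy.** Instead of a network heuristic, the genealogy is
derived from the bifurcating tree: per-site substitutions are optimised onto
the fixed topology by Fitch parsimony, identical sequences are merged,
substitution-free branches are contracted, and unsampled connector nodes are
spliced. Node size = number of sequence records; edge weight = number of
substitutions.

**Mismatch / neutrality statistics** per group (complete deletion per
group, so each group reports its own effective length *L*eff):

- segregating sites *S*, mean pairwise differences *k̄*, nucleotide
  diversity π = *k̄*/*L*eff;
- Tajima's *D* = (*k̄* − *S*/*a*₁) / √(*e*₁*S* + *e*₂*S*(*S*−1)), negative
  under recent expansion;
- Ramos-Onsins & Rozas *R*₂ = √(n⁻¹ Σᵢ(*U*ᵢ − *k̄*/2)²) / *S*, with *U*ᵢ the
  singleton count of sequence *i*;
- Harpending's raggedness *r* = Σ(*x*ᵢ − *x*ᵢ₋₁)² over mismatch classes,
  low for the smooth unimodal spectra of expanding populations;
- observed mismatch spectra with expected curves under constant size
  (*e*ᵢ = θ̂ⁱ/(θ̂+1)ⁱ⁺¹) or a simulated sudden expansion.

**Character-based barcoding (CBB).** Fitch-parsimony substitution events on
each species' stem branch are its diagnostic characters, classified as
globally exclusive (that site/state change occurs on no other branch),
in-group exclusive, or combination-only.

**Tree-based delimitation (Wiens–Penkrot).** Per a-priori label: delimited
when its haplotypes are exclusive and its node support exceeds 0.95
posterior probability, with two special cases — a weakly supported species
is rescued by a well-supported sister group, and a single-haplotype species
is delimited when its sister lineage is well supported. Interdigitated
labels are flagged as possible junior synonyms.

**Consensus.** A species is *valid* only when both methods delimit it.

A seeded synthetic-data generator (`haplodelim.simulate`) produces
clade-structured alignments with planted stem substitutions and a complete
ground-truth ledger, plus single-population coalescent samples with optional
sudden expansion, so every stage is testable without any downloads.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_mismatch_statistics.py
python analysis/03_haplotype_genealogy.py
python analysis/04_species_delimitation.py
```

The first script writes a 29-sample, 1,039-bp synthetic dataset with eight
a-priori labels (three good species, three synonym analogues nested inside
them, two out-groups). The last prints:

```
WP verdicts:
  syn_A1       non-exclusive    own=1.00 -> not-delimited (non-exclusive)
  species_A    exclusive        own=0.70 -> delimited (exclusive, sister-rescue)
  species_C    single-haplotype own=1.00 -> delimited (single-haplotype, sister supported)
  ...
valid species: 3 (species_A, species_B, species_C); synonym candidates: 3 (syn_A1, syn_A2, syn_B1)
```

`species_A` shows the sister-rescue rule (own support 0.70 < 0.95, sister
fully supported), `species_C` the single-haplotype rule; the three nested
labels are returned as possible junior synonyms of the species whose clades
absorb them. The demographic contrast in script 02 prints mean Tajima's
*D* ≈ −0.1 and raggedness ≈ 0.08 for a constant-size population versus
*D* ≈ −2.0 and raggedness ≈ 0.02 for a recent 100-fold expansion at matched
*k̄* — the signature by which unimodal mismatch distributions indicate
recent expansion.

The same stages are available as subcommands of the `haplodelim` CLI
(`simulate`, `stats`, `genealogy`, `diagnose`, `delimit`, `pipeline`) for
use on real FASTA/Newick/TSV inputs.

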