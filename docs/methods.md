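# Methods

This note documents the models, conventions and numerical choices behind
`haplodelim`, in the order the pipeline runs them.

## Data model and coordinates

All stages share one `Alignment` (equal-length nucleotide sequences over
the IUPAC alphabet plus `-`), one rooted, strictly bifurcating `PhyloTree`
with per-node supports normalised to [0, 1], and one `SampleTable` mapping
each sequence to an a-priori species label, a named clade and an in-group
flag. Coordinates are 1-based and closed everywhere: positions are
reported to humans (barcoding tables, figure legends), never sliced.

Polytomies are rejected by default because both the parsimony optimisation
and the tree-based delimitation rules presuppose a binary tree; an explicit
flag resolves them deterministically (left-branching in input order).
Support values above 1 anywhere mark the file as percent-scaled and all
supports are divided by 100; a node without support counts as 0 in every
threshold comparison, so absence of evidence never passes a support test.

Reference-based position numbering aligns the alignment's majority-rule
consensus to a reference sequence (e.g. a complete mitochondrial genome)
with global Needleman–Wunsch at fixed scores — match +1, mismatch −1, gap
−2, linear. The scores are deliberately a documented constant rather than
an option: the mapping must be reproducible, and the test suite certifies
it against an independent aligner on cases whose optimum is provably unique
(co-optimal global alignments are counted by dynamic programming, and only
unique-optimum cases are used as oracles, since two correct aligners may
legitimately disagree on tie-broken paths). Columns opposite reference
gaps are reported with an `aln:` prefix instead of a number.

## Fitch optimisation and the deterministic traceback

Per site, ancestral state sets follow Fitch's procedure (intersection when
non-empty, else union; each union adds one to the site's length). The
traceback is fully deterministic: the root takes the alphabetically
smallest member of its set, and every child keeps the parent state when
possible, otherwise takes its own smallest member, recording a substitution
event on that branch. This replaces the ACCTRAN/DELTRAN choice of classic
parsimony software with a bit-reproducible rule; the same resolution drives
both the barcoding diagnostics and the haplotype genealogy, so the two
outputs can never disagree about where a substitution sits. The number of
events per site always equals the site's Fitch length (tested against
exhaustive enumeration of all ancestral assignments on trees up to ten
leaves).

Missing data (`-`, `N`) contributes the full state set {A,C,G,T}; gaps are
treated as missing rather than as a fifth state — indel coding is out of
scope for a single mitochondrial fragment. IUPAC ambiguity codes
contribute their code's set.

One placement ambiguity is inherent and worth knowing: for a site whose
only change lies on a child-of-root branch, any parsimony method may place
the event on either root branch (rerooting ambiguity). The synthetic
generator therefore never plants stem substitutions on root-adjacent
branches of its canned fixture, which keeps ledger-exact recovery
well-defined.

## Haplotype genealogy

Identical sequences are collapsed into haplotypes (`strict` policy by
default; `ignore-missing` additionally skips sites where either sequence is
missing — that relation is not transitive, so groups merge greedily in
descending count order with a warning on ambiguity). The genealogy is then
the tree itself after three reductions: contract every branch that carries
no optimised substitution, merge tips of the same haplotype, and splice
unsampled degree-2 connector nodes (the root included, giving unrooted
network semantics). Edge weight is the substitution count of the
contracted path. Invariants: node sizes sum to the number of sequences;
edge weights sum to the parsimony score; on homoplasy-free data the
weighted path length between any two haplotype nodes equals their pairwise
difference count.

## Mismatch statistics

The default site policy is complete deletion per group — any column with a
gap, `N` or ambiguity code in any sequence of the group is excluded, and
the group's effective length is reported with every statistic. This is
the convention of the standard desktop tools and explains why groups over
the same matrix can have slightly different site counts. Pairwise deletion
is available behind the same interface.

Tajima's D uses the standard coefficients a₁…e₂ and is reported as an
explicit `undefined` (with reason) when S = 0 or n < 4; R2 when S = 0;
everything when n = 1. The implementation is tested to 1e-9 against an
exact rational-arithmetic evaluation of the closed forms and cross-checked
against an independent phylogenetics library.

Raggedness is r = Σᵢ₌₁^{d+1} (xᵢ − xᵢ₋₁)² over mismatch classes 0..d with
a terminal step x_{d+1} := 0, where d is the largest observed difference.
Under this convention a spectrum with all mass at class 0 has r = 1 and a
uniform spectrum has r = 1/(d+1)²; other software may use a different
terminal convention, which would shift absolute values but not the
expansion-versus-constant contrast the statistic is used for here.

The expected mismatch curve under constant size is the equilibrium
geometric form eᵢ = θ̂ⁱ/(θ̂+1)ⁱ⁺¹ with θ̂ = k̄. The expansion expectation
is simulation-based (mean spectrum over seeded coalescent replicates)
rather than a closed form: the replicate count, parameters and seed are
recorded in the model descriptor. When parameters are not supplied they
are moment-fitted: θ₀ from Watterson's estimator and the expansion time t
solved from k̄ = θ₀[(1 − e^(−t)) + e^(−t)/f] at fixed fold-change f = 100.

## Tree-based delimitation and consensus

Per a-priori label the verdict is one of: *single-haplotype* (all its
sequences collapse to one haplotype), *exclusive* (its tips form a clade
containing no other label), or *non-exclusive* (the labels interdigitated
inside its MRCA are reported). Decision rules, with all comparisons strict
`>` against the threshold (default 0.95 posterior probability — "higher
than 0.95", so exactly 0.95 does not pass):

1. exclusive and own clade supported → delimited;
2. exclusive, own clade weak, sister group supported → delimited;
3. exclusive, neither supported → ambiguous;
4. single-haplotype with supported sister → delimited, else ambiguous;
5. non-exclusive → not delimited, partners reported.

"Sister group support" is the support of the sister clade's own node; when
the sister is a single tip (which has no node), the parent's support is
substituted. Out-group labels receive verdicts but are excluded from the
valid-species summary. Ambiguous verdicts propagate to the consensus as
*unresolved* rather than *not delimited*, since lack of support is not
evidence of conspecificity.

CBB delimits a species when it has at least one retained diagnostic
(`min_diagnostics` configurable; `require_exclusive` restricts the count to
globally or in-group exclusive diagnostics). A diagnostic is *retained*
when every clade member is compatible with the derived state — whether
reversed stem characters should still count cannot be settled from
published barcoding tables, so both countings (total and retained) are
reported. Consensus: valid iff both methods delimit; a non-exclusive
label becomes a possible junior synonym of the valid label(s) it
interdigitates with.

## Synthetic data

The generator is the test bed's ground truth, not a full evolutionary
simulator. `simulate_structured` grafts neutral within-group coalescent
genealogies (parameter θ in coalescent units; no effective-size
bookkeeping, since only relative signatures matter) onto a fixed label
topology and plants an exact number of stem substitutions per group, all
at distinct sites (infinite sites / homoplasy-free), each derived state
differing from the root state. Planted sites are excluded from the
within-group mutable pool so the ledger is exact. One numpy generator,
seeded explicitly, drives every draw in a documented order (root sequence,
then per group: coalescent topology and times, stem sites/states, tip
substitutions, within-group Poisson mutations), so identical seed and
configuration give byte-identical files.

`simulate_demographic` simulates a single population with exponential
waiting times at rate C(k,2), optionally multiplying the rate by f for
times older than t (a sudden f-fold size change looking back), and places
Poisson(total length × θ₀/2) mutations uniformly on branches.

The canned fixture (`make_demo_dataset`) mirrors a small mitochondrial
phylogeography study: 29 samples, 1,039 bp, eight labels — three good
species with planted stems of 2, 5 and 5 substitutions, three synonym
analogues each split into two same-labelled groups placed so their joint
MRCA spans a good species (non-exclusive by construction), two out-groups
— and supports of 1.0 except one 0.7 node with a fully supported sister.
Each synonym subgroup carries one planted substitution so no label
accidentally collapses to a single haplotype, and the 0.7-support species
carries one planted tip substitution so it always has multiple haplotypes
and exercises the sister-rescue rule rather than the single-haplotype rule.
θ values (1.5 / 0.5 / 0) were chosen to span multi-haplotype,
low-diversity and monomorphic species at these sample sizes.

What the generator does *not* emulate: homoplasy (unless infinite sites is
switched off by exhausting L), rate heterogeneity, indels, recombination,
migration, selection, and the estimation error of a real tree inference —
the "inference" tree handed to the pipeline is the true tree with stamped
supports. Passing tests therefore demonstrate that the transformations
and decision rules are implemented exactly, not that the upstream tree or
its supports would be this clean on real data.

## Problem sizes and tolerances

The statistical checks run at n = 25, θ = 5 with 500 constant-size and 200
expansion replicates (alignment length 1,500), sizes at which the
Monte-Carlo standard error of mean Tajima's D is well below the 0.2
acceptance band and a full run stays in the tens of seconds. The
expansion condition (θ₀ = 50, t = 0.1, f = 100) is matched to the
constant-size condition at mean pairwise differences ≈ 5 so the raggedness
comparison contrasts shape, not scale. Exact oracles (rational
arithmetic, exhaustive enumeration, ledger recovery) use tolerance 1e-9 or
strict equality.

## Known limitations

- The genealogy transformation assumes the input tree is reasonably close
  to a parsimony-consistent history; heavily homoplastic data can force
  merges of identical tips across the network, which are resolved by
  absorbing the connecting path (rare at single-locus desk scale, logged
  in code comments).
- Coalescent p-values for D and R2 (and Fu's Fs) are not computed; the
  statistics are reported for comparison across groups.
- Delimitation operates strictly on a-priori labels; it never proposes
  unlabelled species (no discovery mode).
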