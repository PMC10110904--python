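# Methods

This note documents the models, algorithms and numerical conventions behind
`panchol`, the assumptions they rest on, and the design choices made where
several defensible options existed.

## Pairwise protein alignment

The similarity engine is classic dynamic-programming alignment —
Smith–Waterman (local, the default) or Needleman–Wunsch (global) — with a
named substitution matrix (default BLOSUM62) and affine gap penalties,
computed by Biopython's `PairwiseAligner`. The gap cost convention is
BLAST-like: a gap of length *k* costs `gap_open + k * gap_extend`, with
defaults 11/1. The implementation is validated against an independent
brute-force DP oracle (explicit H/E/F state matrices, written first) in the
test suite, including the textbook `HEAGAWGHEE`/`PAWHEAE` pair (local,
BLOSUM62, gap 10/1, score 17).

Reported statistics follow BLAST conventions:

- **identity** = 100 × identical columns / aligned columns (gapped columns
  count in the denominator; pairwise alignments have no gap–gap columns);
- **query/subject coverage** = 100 × alignment span on that sequence / its
  length.

Ties among optimal tracebacks are resolved deterministically: the pair is
aligned in a canonical (lexicographic) orientation and the engine's first
enumerated traceback is used, which makes identity and coverage exactly
symmetric in the two arguments. E-value statistics are deliberately out of
scope; screens are expressed purely through identity/coverage thresholds.

`all_vs_all` applies a shared k-mer prefilter (default: ≥1 shared 4-mer,
counted through one sparse matrix product) before aligning cross-strain
pairs — a recall-oriented choice: in the divergence regime orthologs occupy
(≥70% identity over ≥150 residues) the expected shared-4-mer count is in the
dozens, so the prefilter discards essentially no true pair while skipping the
~60% of unrelated pairs that share no 4-mer. With `stats="best"` the
(substantially slower) traceback statistics are computed only for each
protein's best-scoring hit per partner strain — exactly the rows RBH
inference consults; `stats="full"` computes them for every stored pair and is
the mode the oracle-equivalence tests exercise.

## Orthogroup inference

A **reciprocal best hit** (RBH) joins proteins *p* (strain A) and *q*
(strain B) when each is the other's highest-scoring match within the partner
strain; ties break toward higher identity, then the lexicographically smaller
id. Edges must additionally reach ≥30% identity and ≥50% coverage (both
configurable) to guard against spurious single-domain links. Orthogroups are
the connected components of the RBH graph.

Two follow-up passes handle gene duplication, which pure cross-strain RBH
cannot represent:

1. **Paralog attachment.** An unassigned protein joins a component when its
   alignment score to any member reaches 0.9 × that member's weakest
   cross-strain RBH edge score. The fractional slack matters: a duplicated
   copy carrying an above-average mutation load scores systematically below
   *every* member's weakest edge (its own mutations enter every comparison),
   so a strict ≥-weakest rule detaches roughly one duplicate in six at 2%
   divergence. Scores against non-homologous proteins sit an order of
   magnitude lower (~50 vs ~880 at typical lengths), so the slack costs no
   specificity. Candidate pairs are gated by ≥5 shared 4-mers so only
   plausibly homologous pairs are aligned.
2. **Within-strain duplicate grouping.** A family private to one strain with
   two copies produces no cross-strain hit at all, so neither RBH components
   nor attachment can see it; leftover same-strain pairs passing the RBH
   identity/coverage gate are therefore joined before the remainder become
   singletons.

With both passes the pipeline recovers 100% of simulated families exactly at
substitution rates 0–0.05 (5 strains, 321 families, seed-fixed), and the
partition category counts match the generator truth exactly.

Orthogroup ids (`OG0000001`…) are assigned by sorted smallest member id, so
identical inputs give byte-identical outputs. The consensus COG class of an
orthogroup is the modal member class; ties go to the lexicographically
smallest letter; fully unannotated groups carry none.

## Pan-proteome partition

With *n* strains, an orthogroup present in all *n* is **core**, in exactly
one **unique**, otherwise **accessory** — presence, not copy number, drives
the label, so a one-strain family with two copies is still unique. Protein
counts per category are sums of copy numbers over the category's
orthogroups; the per-strain "strain-specific" count sums copy numbers of the
unique orthogroups private to that strain, and core orthogroups split into
single-copy (copy number 1 in every strain) and multi-copy. Percentages are
rounded half-up to one decimal (`decimal.Decimal`, not banker's rounding), so
1,807/3,741 → 48.3%, 863/3,741 → 23.1% (23% at integer rounding) and
1,070/3,741 → 28.6%.

## COG abundance and group contrasts

Abundance of a COG class in a scope is 100 × (class count) / (annotated
proteins in scope). A scope is either a partition category or a strain group,
optionally restricted to one category (e.g. "accessory proteins of the
hypocholesterolemic strains" — both conventions are computed and labelled
explicitly, since group-level abundance over accessory proteins and over
whole proteomes answer different questions). The abundance definition found
in comparative-genomics servers divides instead by the class's total count in
an external database; that denominator is irreproducible outside the server,
so the default here is the self-contained within-scope total, with a
`family_total` mode (class total across the analyzed proteomes) available.
Fold-abundance ratios between two scopes are invariant to any per-class-
constant denominator, so contrasts like 3%/0.7% = 4.29-fold survive this
substitution unchanged.

`group_exclusive(A, B)` returns orthogroups present in every A strain and
absent from every B strain; strains outside both groups are ignored. The
operation is anti-monotone in both groups (adding a strain to either can only
shrink the result) and the two directions are disjoint by construction.

## Marker screening

Each panel marker is locally aligned against every proteome protein; the
best-scoring hit is evaluated at identity > threshold (default 85%, strict
inequality) and query coverage ≥ threshold. "Full" coverage defaults to
≥99.5% rather than exactly 100%: the optimal local alignment always trims a
mismatching terminal residue, so a single substituted terminus would
otherwise mask an unambiguous homolog; an `exact_coverage` flag restores the
strict interpretation. Raising either threshold can only flip markers from
present to absent.

## ANI, divergence, neighbor joining

ANI between genomes follows the fragment convention: the query genome is cut
into non-overlapping 1,000 bp fragments (terminal remainders discarded,
fragments >10% N skipped), each fragment is aligned semi-globally against the
subject genome with edlib, and fragment identity is edit-distance based:
100 × (1 − distance / fragment length). Fragments below the 70% identity
floor are dropped; the one-way ANI is the mean identity of retained
fragments, and the reported ANI averages the two directions, making the
matrix exactly symmetric. Semi-global alignment consumes the whole fragment,
so fragment coverage is complete by construction and the minimum-coverage
parameter is honored trivially. A pair in which either direction retains no
fragment (unrelated sequences sit near 25% identity, far below the floor)
yields NaN with a warning rather than a misleading number; the divergence
transform refuses NaN pairs explicitly. Edit-distance identity equals
substitution-based identity exactly under the no-indel genome model below and
differs negligibly for real close genomes; MinHash-style estimation is out of
scope.

Divergence is 100 − ANI (percentage points), with ANI = 100 − divergence as
the exact inverse. Neighbor joining is the classic Saitou–Nei agglomeration:
join the pair minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch lengths
from the standard two-point formulas, new distances by the reduction formula.
Ties break toward the lexicographically smallest label pair; negative limbs
are clamped to zero with the deficit moved to the sibling branch (logged);
two-leaf input splits the single edge evenly. On additive matrices the tree
reproduces every pairwise distance to ≤1e−9 (validated against random trees
and cross-checked against scikit-bio's implementation). Divergence is used as
the NJ distance directly, with no further transform. Newick output quotes
labels containing whitespace or structural characters and prints branch
lengths to six decimals.

## Synthetic pangenome generator

The generator emulates a five-strain probiotic comparison with two
phenotype groups (cholesterol-assimilating: LR13, WEFA23; general: T110,
170M39, SP15). Defaults: 150 core families, 90 accessory families
(presence sets rejection-sampled at inclusion probability 0.5 conditioned on
2 ≤ presence ≤ n−1), 12 unique families per strain, and 21 group-marker
families present in every strain of the first group and absent from the
second — the contrast the pipeline is designed to detect. Accessory sampling
additionally rejects the exact marker presence pattern, so the marker
families are by construction the only group-exclusive families and the
ground truth stays unambiguous; a single-strain marker group is rejected as
infeasible alongside unique families for the same reason.

Protein lengths are drawn Normal(240, 70) truncated at 60 — desk-scale but
in the bacterial range; each family gets a random ancestral sequence, each
carrying strain an independently point-mutated copy (per-residue substitution
probability *r*, default 0.02, substitutions uniform over the other 19
letters), and with probability 0.05 a strain receives a second mutated copy
(duplication). There are no indels: expected pairwise identity between family
members stays analytic, (1−r)² + r²/19 per site, and the alignment stage
still exercises gaps through its own fixtures. COG classes are drawn from a
configurable distribution over one-letter categories, weighted toward
carbohydrate metabolism (G), translation (J) and amino-acid transport (E) as
in lactic-acid bacteria, with 14% of families left unannotated (the
"hypothetical protein" fraction).

Nucleotide genomes (default 50 kb — scaled from the ~2.7 Mb originals to keep
all-pairs fragment alignment interactive) evolve from a random root along the
fixed tree ((LR13,WEFA23),((T110,170M39),SP15)) at 0.005 substitutions per
site per branch. The recorded expected divergence between leaves uses the
exact 4-state uniform-substitution chain: identity probability
1/4 + 3/4 · Π(1 − 4p_b/3) over branches *b* on the connecting path — the raw
(uncorrected) quantity that fragment ANI estimates.

A single `numpy` Generator seeded from the config drives all proteome draws
in a documented order (families in listed order: length, ancestral sequence,
COG class, presence set, per-strain duplication coin and copies); genome
evolution uses an independent stream (seed+1). Outputs are bit-reproducible
from (config, seed).

What the generator does **not** model — and what passing tests therefore do
not certify about real data: indels and rearrangements, horizontal transfer
and chimeric families, codon/GC structure, domain-level homology (real
single-domain links are why the RBH quality gate exists), annotation errors,
and fragmented assemblies. The generator validates the machinery, not the
biology.

## Problem sizes and runtime

The study-scale validation runs use 5 strains × 321 families (~1,150
proteins, ~145k aligned candidate pairs, about two minutes each) and 50 kb
genomes; the standard test suite completes in a few minutes, with the
remaining tests on deliberately small fixtures. `scripts/acceptance.py`
re-runs one study-scale simulation plus the arithmetic worked examples.

## Known limitations

- RBH + connected components is a deliberately transparent stand-in for
  graph-inflation orthology tools; it has no duplication/loss reconciliation
  and no gene trees, and transitive chaining through components can in
  principle merge families bridged by a promiscuous protein.
- The abundance denominator differs from external-database conventions (see
  above); absolute abundances are comparable within this package only,
  though fold contrasts transfer.
- Fragment ANI is exact only under the no-indel model; for indel-rich genome
  pairs edit-distance identity under-counts matches relative to
  alignment-column identity.
- The marker screen is protein-vs-protein; six-frame nucleotide search is out
  of scope.
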