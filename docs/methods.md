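# Methods

## Scope and data model

The unit of analysis is a strain's PKS/NRPS cluster inventory: a list of
biosynthetic gene clusters, each a list of ORFs whose catalytic domains
are given as a domain-organization string.  Inventories are inputs — the
package does not detect clusters from genomic sequence (no antiSMASH-style
scanning, no HMM domain calling) and does not compute dDDH or ANI from
genomes; those values enter as annotations.  Two reference inventories
are packaged (`TP-A0598`, 9 clusters; `NBRC3934`, 13 clusters), together
with the published homology-based conservation map between them
(5 pairs).

## Domain-organization grammar

Domains within a module are separated by `/`, modules by `-`.  The
canonical substrate dialect is `A(leu)`; the Markdown-escaped `A_(leu)_`
form seen in typeset tables is accepted on input (the underscores are
typesetting artifacts).  Type II PKS subunits are stored as
`KSalpha`/`KSbeta_CLF` and serialized `KSa`/`KSb(CLF)`; `KSα`,
`KSβ (CLF)` and similar spellings parse.  `...` (or `…`) is a GAP token
for undetermined domains.  A substrate subscript occasionally appears on
a T token (`A/T(thr)-C`); it is stored on the T token and used as the
module's substrate, since the module's residue identity is what it
encodes.  `>N` sizes set a lower-bound flag; sizes are descriptive
metadata only and never compared.  Module boundaries are taken exactly
as printed — no re-segmentation at parse time; interpretation happens in
classification.

Parsing and canonical serialization are mutually inverse: parse →
serialize → parse is a fixed point, property-tested over grammar-sampled
strings.

## Module and cluster classification

A module is classified from its domain set alone: any KS-family domain →
PKS extension; CoL → PKS loading; A+T with C → NRPS extension, without
C → NRPS loading; C+T without A → A-less NRPS module; only TE/TD →
termination; anything else (lone A, lone ACP, AT/KR/ACP remnants) is a
fragment.  A cluster is typed from its content: dissociated
KSalpha+KSbeta subunits → type II PKS; a single standalone-KS ORF →
type III PKS; both PKS and NRPS modules → hybrid; NRPS modules only →
NRPS; otherwise type I PKS.  A declared type that disagrees with the
derived one triggers a warning, not an error — declared metadata may
encode judgment the domain content cannot.

## Backbone prediction

Assembly lines are walked ORF by ORF, module by module.  Emission rules:
substrate-annotated NRPS module → that residue (capitalized); A domain
without a call → `x`, or `mx` when the module carries an MT domain
(methyl-amino acid); C/T module without A → `y`; PKS extension module →
`pk`; epimerization (E) domains never alter the emitted token; loading
CoL modules and termination domains emit nothing.  A lone A-domain ORF
*with* a substrate call contributes its residue when walked in order —
required for clusters whose A domain acts in trans on a downstream T
domain.  TE or TD closes the current chain; residues emitted afterwards
open a new chain (so one cluster can yield two peptides).  The final
chain is flagged partial — serialized with a trailing `-` — when it was
not closed by TE/TD and the cluster contains a scaffold-truncated ORF.

Walk order defaults to file order; the reference tables list ORFs in
assembly order for all but two hybrid clusters, which carry an explicit
`assembly_order` in the fixture (an expert call recorded as data — a
heuristic reordering is available but deliberately not the default,
since no robust ordering rule exists for fragmented clusters).
Prediction is refused for type II/III PKS clusters (no colinear line)
and is not attempted for clusters with identified products.

## Cluster similarity and conservation inference

Similarity between two clusters of the same type is a global alignment
over their module-signature sequences (signature = module class + sorted
domain kinds + substrate): 1 per identical signature, 0.25 per aligned
same-class pair differing in signature, gaps free, normalized by the
longer module count.  Two special rules sit in front of the alignment:
clusters of different types score 0, and when *both* clusters carry
known-product annotations, product identity decides (1 or 0).  The
latter is essential: the dissociated type-II PKS systems for spore
pigment, oxytetracycline and trioxacarcin are architecturally almost
identical (KSα/KSβ/ACP), and only the product annotation carries the
homology evidence that separates them.

Conservation is inferred by maximum-total-similarity one-to-one
assignment (Hungarian algorithm; a brute-force permutation search is
kept as an independent oracle in the tests) over pairs at or above a
similarity threshold.  The default threshold is **0.6**: it must sit
below 0.625 — the score of a conserved type-I PKS pair in the reference
strains that differs by a single DH domain — and above 0.25, the highest
score of any non-conserved cross-strain pair; 0.6 splits that margin
conservatively.  With it, architecture-based inference alone reproduces
the published 5-cluster conserved set.  A user-supplied map
(`source="given"`) always overrides inference: published conserved calls
are expert data.

## RC and the concordance analysis

RC (%) = 2·C_ab/(A+B)·100 is computed with exact rational arithmetic;
integer-percent values use half-up rounding (the convention of printed
tables: 45.45 → 45, 61.54 → 62).  Per-strain shared/specific fractions
are reported the same way.  Species calls on strain pairs use dDDH ≥ 70%
(boundary inclusive), with ANI ≥ 95% as the fallback when dDDH is
absent; with neither measure the call is undetermined.  Regressions are
ordinary least squares on complete cases (records missing either
variable are dropped; ≥ 3 required).  The regression direction does not
affect R².

## 16S identity

Identity = matches / compared positions, where a compared position is an
aligned column with an unambiguous base in both sequences (gap and N
columns excluded from the denominator — the convention under which one
substitution in a 1451-position alignment prints as 1450/1451 = 99.93%).
Percentages round half-up at the second decimal.  U is read as T.  The
pre-aligned path is authoritative; for unaligned input a global
Needleman–Wunsch alignment (match +2, mismatch −1, gap open −5, extend
−2) is computed first, but alignment parameters of external services
vary, so tests pin only the pre-aligned arithmetic.

## Synthetic generator

`generate_pair` emulates the statistical structure of the reference
pair: defaults of 9 + 13 clusters with 5 shared, a type mix of ~27%
t1pks / 18% t2pks / 9% t3pks / 28% nrps / 18% hybrid, module counts from
a shifted Poisson (mean 4, min 1, matching the 1–10 modules seen in real
tables), and a 0.4 probability that an A domain lacks a substrate call.
Shared clusters are drawn once and copied into both strains; the second
copy is mutated per module at rate `divergence` (substrate swap,
E/DH/KR gain or loss, module duplication/deletion), always preserving
cluster type — conservation is a within-type notion.  Strain-specific
clusters are independent draws, rejection-sampled until their similarity
to every cluster already placed in the pair is below 0.5; this is what
makes the planted map the identifiable ground truth (a type III PKS
cluster is always exactly `[KS]`, so without the guard both strains
would routinely contain indistinguishable "specific" clusters and no
inference method could be scored against the truth).  Everything is
driven by one `numpy` generator seeded from the config, so identical
configs give identical inventories.

What the generator does **not** emulate: nucleotide/protein sequences
(no sequence-level homology, so inference quality against real
sequence-divergence patterns is not measured), gene rearrangements
within clusters beyond module indels, and cross-type evolutionary
transitions.  Passing recovery tests therefore show that the assignment
machinery is correct and well-calibrated for architecture-level
divergence, not that the 0.6 threshold is optimal for any particular
real genus.

## Problem sizes and numerical choices

The property suites run at small scale chosen to keep the full test
suite fast while still exercising the combinatorics: brute-force
assignment cross-checks on 5×5 instances (120 permutations), 1,000
grammar-sampled round-trip strings, 100 random configurations for
zero-divergence recovery, and 20 replicates per divergence level for the
recovery curve.  Exact rationals (`fractions.Fraction`) are used for RC
so that equality assertions are exact rather than float-tolerant;
half-up rounding is implemented explicitly (Python's `round` is
banker's).  Assignment ties are broken deterministically by
lexicographic cluster id.

## Known limitations

* Architecture-based similarity cannot separate same-type clusters with
  identical module signatures but unrelated sequences; known-product
  annotations (or a user-supplied map) are required in such cases.
* The backbone predictor does not model tailoring enzymes,
  stereochemistry, macrocyclization, starter-unit identity for PKS
  loading modules, or trans-AT complementation; `pk` tokens are emitted
  one per PKS extension module by convention.
* The walk order of heavily fragmented clusters (many scaffold-truncated
  ORFs) is not reconstructable from domain strings; such clusters are
  left to explicit ordering or known-product annotation.
* Fitted R² values on synthetic concordance tables characterize the
  generator scenario, not any published strain collection.
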