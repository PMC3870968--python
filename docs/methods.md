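# Methods

`plpmine` re-implements, as a reusable tested pipeline, a proteome-mining
analysis that discovers fold type I pyridoxal-5′-phosphate (PLP)-dependent
enzymatic domains embedded in multidomain NRPS/PKS assembly-line proteins,
classifies them into four families, and reports the domain architectures of
the parent proteins.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## The profile HMM and its seed

Fold type I PLP enzymes share as little as ~10% pairwise sequence identity,
so the family profile is anchored on a *structure-based* alignment: 13
structurally conserved regions (SCRs) totalling 108 columns across 31
reference structures, with the long inter-SCR insertions/deletions kept in
the alignment.  The packaged seed alignment is a synthetic reconstruction
of that object (`data/seed_plp_type1.synthetic.afa`): 31 rows labelled by
the source PDB entries, 13 SCR blocks of total width 108, kept indel
regions, and the two invariant catalytic residues — the aspartate that
contacts the cofactor pyridine nitrogen at SCR position 69 and the
Schiff-base lysine at SCR position 85.  `scripts/build_fixtures.py`
regenerates it deterministically; real seed alignments can be substituted
through the same aligned-FASTA + SCR-TSV (or Stockholm-like) interface.

The reconstruction draws every row from a common master sequence under the
JTT substitution model with three site-rate classes: SCR columns evolve at
0.3× the nominal rate, flanking core columns at 0.6×, variable (indel)
regions at 1×, with unrelated background content in the indel regions.
The rates were chosen so the reconstructed profile behaves like the
original: it must still recover embedded domains whose overall identity to
the reference enzymes is only ~25–40%, the range reported for the real
discoveries.  Nominal row divergence from the master is 0.5; the four
family masters sit at 0.35 from the master, family seed rows at 0.25, and
the labelled reference sequences at 0.20.

Two match-state masks are built from the same seed:

* the **SCR profile** — exactly the 108 SCR columns (the profile whose
  printed constants are 31 rows / 13 SCRs / 108 match states);
* the **search profile** — the SCR columns plus every inter-SCR column
  with gap fraction ≤ 0.5 (156 match states for the packaged seed).  This
  mirrors what an HMM builder does when the indel-kept alignment is handed
  to it, and it is the profile the mining cascade scans with: the
  cascade's coverage threshold of 110 match states exceeds 108, so it is
  only satisfiable — and only meaningful as "the SCR core was matched" —
  against the longer search profile.

Profile estimation uses uniform row weights, single-parameter
background-mixture pseudocounts (default weight 1.0, Robinson–Robinson
background, overridable), and Laplace-smoothed transition counts of each
row's match/insert/delete path through the mask.  Transitions with no
Plan7 counterpart (I→D, D→I) are dropped from the counts.

## The alignment engine

The model is Plan7-like and strictly local: uniform entry 1/K into any
match state, free exit from any match state, no multi-hit wing retraction,
and a background null model that cancels the unaligned flanks.  Scores are
log2 odds (bits).  Viterbi ties break deterministically with state
preference M > D > I; delete chains are computed with running-scan
recurrences so the inner loop is vectorised over states.  Forward and
Viterbi agree with an exhaustive path-enumeration oracle to 1e-9 bits on
toy instances (this is a graded test).  Reproducing HMMER3 bit scores
numerically is a non-goal; the engine is self-consistent and oracle-exact
under its own model.

E-values: the score law of random background sequences is fitted with a
Gumbel distribution (default calibration: 1000 i.i.d. background sequences
of length 400, seeded).  A hit is reported when its per-sequence tail
probability is ≤ 0.01 — the original analysis states no reporting
threshold, only the post-hoc length/coverage filters, so this default is a
declared choice of this package.

## The mining cascade

1. **Scan** the database with the search profile; one best hit per
   sequence at p ≤ 0.01.
2. **Pass 1**: keep hits in sequences *longer than* 1000 residues whose
   optimal path visits *at least* 110 match states (strict / inclusive
   boundaries, following the stated rules literally).  The length
   threshold removes stand-alone ~400-residue PLP enzymes; coverage
   ensures the SCR core is present.
3. **Domain annotation** with a packaged mini-profile library (CP
   carrier-protein with the conserved-serine phosphopantetheine motif,
   KS, AT, C, A, KR, TE) replacing the external Pfam dependency; users can
   substitute real Pfam-derived profiles through the profile-JSON
   interface.  Candidate hits per profile come from iterated Viterbi with
   envelope masking; a hit must cover ≥ 50% of its profile's match states
   (this suppresses leftover fragments of an already-called domain — the
   counterpart of Pfam's internal competition, about which the source
   analysis is silent); calls are then assigned greedily by bit score with
   ≤ 10 residues of tolerated overlap.  Only sequences with at least one
   CP call co-occurring with a PLP type I call continue.
4. **Excision and specialisation**: the PLP domains of the survivors are
   excised at their envelope coordinates, Viterbi-aligned back to the
   search profile, and a new profile with the same number of match states
   is re-estimated from the stacked paths (the hmmalign-then-rebuild
   step).  Re-estimation keeps the base profile in the rare case it does
   not improve the mean training self-score, so specialisation never
   degrades recognition of its own training set.  A free re-alignment of
   the excised set is deliberately not implemented.
5. **Pass 2**: rescan everything with the specialised profile; keep
   sequences *longer than* 500 residues (the approximate combined length
   of a CP domain plus a type I enzyme) with coverage ≥ 110 and CP/PLP
   co-occurrence.  Because pass 2 deliberately lowers the length
   threshold, its count may exceed the pass-1 count; the monotone funnel
   is scanned ≥ hits ≥ pass1 ≥ CP-co-occurrence and excised ≥
   non-redundant.

Architecture strings join the ordered calls with an en dash; PLP calls
render as PLP1–PLP4 for Aminotran_3, Aminotran_1_2, Beta_elim_lyase and
Pyridoxal_deC respectively, and PLP? when unassigned.

## Classification

**Redundancy pruning.** Pairwise identity is computed on one optimal
global alignment (BLOSUM62, gap open −10, extend −0.5) with the full
alignment length (gap columns included) as denominator; sequences sharing
more than 70% identity are pruned greedily, discarding the shorter member
(ties: the later one in input order).  The exact elimination order of the
EMBOSS routine this emulates is internal to EMBOSS; the retained-set size,
not its membership, is the meaningful quantity.

**Distances and trees.** Excised domains (and the labelled references)
are implicitly aligned by stacking their Viterbi match-column rows.  After
complete deletion of every column containing a gap, each pair's distance
is the maximum-likelihood scaling of the JTT rate matrix
(eigendecomposition of the published exchangeabilities; 1-D bounded
likelihood optimisation; saturation capped at 10 substitutions/site and
flagged).  Trees follow the minimum-evolution criterion: neighbor-joining
start, ordinary-least-squares branch lengths (negative estimates clamped
to zero and flagged), and first-improvement NNI hill climbing with a fixed
edge order.  Bootstrap resamples the gap-free columns with replacement;
supports are bipartition percentages and the consensus is majority-rule,
with supports above 50 displayed in the Newick output.  Version-specific
tie-breaking of the original desktop software is unknowable, so
cross-checks are topological (the four family clades), not branch-exact.

**Family assignment.**  Two modes: *profile competition* (default in the
pipeline; best Forward bit score among the four family profiles,
unassigned when the margin over the runner-up is below 1 bit) and *clade*
(the family of the references in the domain's smallest surrounding clade
of the tree; a clade mixing families yields an explicit unassigned
verdict, which is a legal output).  The key-residue check reports the
residues aligned to the annotated catalytic Asp and Schiff-base Lys
columns, flagging deletions — natural exceptions exist (Thr or Val in
place of the lysine), so the report is descriptive, not a filter.

## The synthetic benchmark

The generator emulates the study's target proteins: multidomain
assemblies (roughly 800–2500 aa here) with ordered domains drawn from
published layouts (e.g. KS–CP–PLP, A–CP–PLP, CP–PLP–C, A–CP–KS–AT–CP–PLP),
low-complexity A/G/P/S/T-biased linkers of 10–40 aa, and a PLP type I
domain planted at a controlled overall divergence from one of the four
family consensuses (JTT conditionals, site rates as above, indel rate 0.01
per position; auxiliary domains diverge at 0.2).  Domain length ranges:
CP 70–90, KS 400–440, AT 290–320, C 430–460, A 480–520, KR 170–190,
PLP 380–440 aa.  Three decoy classes accompany the positives: stand-alone
~400 aa PLP enzymes (must fail the pass-1 length rule), CP-less
multidomain PLP proteins (must fail co-occurrence), and non-PLP
multidomain proteins (must produce no PLP hit at p ≤ 0.01).  Truth tables
carry exact planted coordinates; a positive counts as recovered iff its
sequence is pass2-kept, a PLP call overlaps the planted interval by at
least half the planted length, and the assigned family (when assigned)
matches.

The graded benchmark uses 50 sequences per class over divergences
0.1/0.2/0.3/0.4 (200 positives + 150 decoys, generator seed 7) — chosen as
the package's standard problem size.  What passing shows: the cascade's
filters, coordinates, specialisation and classifiers behave correctly
under the package's own generative model, whose divergence process matches
the classifier's evolutionary model.  What it does not show: performance
on real proteomes, where domain boundaries are fuzzier, compositional
biases stronger, the family structure less balanced, and where profile
competition with real Pfam families (trans-AT PKS idiosyncrasies,
DUF-containing layouts) matters.  Absolute hit counts of the original
database-version-bound survey are likewise out of reach by construction.

## Degenerate inputs and edge cases

Empty databases yield empty results, not errors.  Fewer than two excised
training domains skip specialisation (the base profile rescans).  Profiles
with a single match state have no insert/delete machinery.  Saturated
distances are capped and flagged; all-gap column sets after complete
deletion are an error.  Duplicate FASTA identifiers are a hard error.
Calibration requires ≥ 100 random sequences and non-degenerate score
variance.  Bootstrap with one replicate returns that replicate's topology
with all supports at 100.
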