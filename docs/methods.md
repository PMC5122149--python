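# Methods

This note records the models, defaults and design choices behind
`chsphylo`, and what the simulation-based validation does and does not
establish.

## Simulator

**Species tree.** `sample_species_tree` draws an ultrametric rooted binary
tree of exact depth *d* (expected substitutions per site root-to-leaf).
With one taxon group the topology comes from sequential random joins at
sorted uniform ages. With two groups the taxa are split evenly and each
group becomes its own subtree, the two stems meeting at the root; group
subtrees use a cherry-rich balanced shape (leaves paired into cherries,
cherries joined in a balanced arrangement) with node ages shrinking by a
uniform(0.4, 0.8) factor per level. The balanced, cherry-rich shape mimics
a curated reference phylogeny in which every taxon has a close relative; it
also guarantees that several donor lineages have disjoint local clades, so
independently planted transfers do not contaminate each other's
phylogenetic neighborhood. Group subtrees coalesce within 70% of the total
depth.

**Family process.** `evolve_family` runs a birth–death–transfer process
top-down along the species tree; rates are per lineage per unit branch
length. Duplications split a lineage in place; losses terminate it; a
transfer copies the lineage onto a uniformly chosen contemporaneous branch
of a different species, the donor continuing (additive acquisition, the
pattern seen for bacterial operon gains; replacing transfer is not
modeled). Deterministically planted transfers are supported for fixtures:
donors are chosen so no donor sits in another donor's sibling subtree
(events then have clean, single-transfer neighborhoods), and the transfer
time is the midpoint of the feasible interval on the two terminal branches.
An all-copies-lost outcome returns an empty gene tree plus the log, not an
error. The event log is replayable: an independent interpreter reproduces
the gene tree's leaf multiset exactly, and the test suite asserts this
under all rate combinations.

**Sequences.** Substitutions follow a per-site Poisson process at rate *r*
per unit branch length, each event replacing the residue with a uniform
random distinct amino acid. This 20-state uniform-jump chain has the
closed-form expected p-distance (19/20)(1 − e^(−20rt/19)) between sequences
separated by path length *t*, which the suite checks by simulation at 2000
sites. No rate matrix, no across-site heterogeneity: none of the downstream
inference depends on a specific replacement model, and the closed form
keeps the process independently checkable. Indels are single-column
insertions/deletions at rate `indel_rate` per site (no affine length
model). True homology columns are tracked through a global column order, so
the simulator emits the exact alignment. Planted motif anchors (three D
positions, QXXRW, QXXXY — 13 residues) are immutable and indel-protected
unless motif decay is requested; `decay_motifs` destroys every QXXRW
occurrence to manufacture guaranteed "dubious" proteins.

**Composition.** Coding sequences come from codon back-translation under
the standard genetic code. Synonymous choice is the only G+C knob: codons
are sampled with weights ∝ exp(β·GC(codon)) where β is solved by bisection
so the expected CDS G+C hits the target (clamped to the range achievable
for the protein's composition). `apply_composition_shift` resamples all
codons (protein fixed) toward donor_gc·(1 − a) + host_gc·a for amelioration
*a*; fixtures use a = 0 for recent transfers and 0.8 for ancient ones —
conventions, not empirical claims. At 3000 nt the realized G+C is within
±0.03 of target, at 30 000 nt within ±0.01 (tested). Default group targets
are 0.35 and 0.60, roughly spanning real microbial genome G+C; genomic
background contexts (5000 nt by default) are i.i.d. sequences at the host
target.

**Chimeras and neighborhoods.** `make_recombinant` fuses the N-terminal
part of one gene through its QXXXY occurrence to the C-terminal part of
another from its occurrence, duplicating the motif; the aligned variant
inserts duplicate columns (gap in all references) exactly as an aligner
would place a tandem duplication, so the ungapped chimera equals the
sequence-level fusion. Neighborhood tables give vertical genes
genome-private flanking families; every HGT donor's focal gene carries a
conserved operon (default DUF1800, DUF1501, SE — the bacterial co-transfer
pattern), and the transferred copy arrives with the donor's neighborhood
intact.

**What the simulator does not emulate.** Alignment error (the true
alignment is exact), rate heterogeneity, codon-model effects, gene
conversion, partial transfers, genome rearrangements beyond the focal
neighborhood, and compositional drift within a genome. Passing tests
therefore demonstrate correctness of the inference logic under clean,
known-truth conditions — not robustness to aligner artifacts or model
misspecification on real data.

## Screening

The PSSM is a per-column log2-odds profile, score(a) =
log2(((count + pc·bg_a)/(n + pc))/bg_a) with uniform background and
pseudocount 1; columns with ≥ 50% gaps are dropped. Since a raw score has
no E-value, the hit threshold is calibrated empirically: the 0.99 quantile
of best-window scores over 1000 seeded shuffles of a length-matched
sequence, keeping the screen permissive (a lenient cutoff deliberately
admits relatives; the motif filter and trees do the discrimination). The
catalytic filter requires an ordered assignment D < D < D < QXXRW with a
configurable minimum D separation (default 10 residues; the literature
specifies only the motif set, not spacing). QXXXY duplication uses
leftmost non-overlapping matching. The transmembrane scanner is a
Kyte–Doolittle window mean (window 19, cutoff 1.6, standard conventions);
a segment is the residue span covered by a maximal run of qualifying
windows.

## Trimming

Two column scores in [0, 1]: entropy mode 1 − H/log2(20), and similarity
mode (mean pairwise substitution-matrix score over non-gap pairs, min–max
normalized by the matrix value range; BLOSUM62 by default, any matrix
loadable). Columns are kept when the smoothed score (window 3) passes the
cutoff (default 0.5) and the gap fraction does not exceed its cutoff.
Selection is **iterated to a fixpoint**: one-pass smoothing is not
idempotent (a weak column can be propped up by a high-scoring neighbor
that itself gets removed), and iterating makes trim(trim(x)) = trim(x) by
construction. Note a calibration asymmetry: with min–max normalization an
18/20-conserved column scores ≈ 0.48, so similarity mode at cutoff 0.5 is
extremely strict on diverged alignments; the pipeline therefore defaults
to entropy mode, where cutoff 0.5 keeps 62–100% of honestly aligned
simulated columns while removing 100% of injected random columns (maximum
noise score observed 0.28). Users of similarity mode should lower the
cutoff to ≈ 0.3.

## Trees

Distances are p (mismatch fraction over shared non-gap columns) or Poisson
(−ln(1 − p)); a pair with no shared columns, or p ≥ 1 under Poisson, is an
explicit error naming the pair. Neighbor joining uses the standard Q
criterion with two reproducibility rules: ties within 1e-12 merge the
lexicographically smallest cluster pair (a cluster is labeled by its
smallest member), and negative branch lengths are clamped to zero with the
deficit moved to the sister so the joined path length is preserved.
Bootstrap supports are percentages of valid replicate NJ trees containing
the bipartition, computed per replicate by column resampling; replicates
hitting an undefined distance are discarded and counted, never imputed.
Supports live in a bipartition → support map carried on the tree, so
rerooting re-annotates rather than migrating labels. Outgroup rooting
requires the outgroup to be monophyletic in the unrooted tree (refusal
lists the intruding leaves) and roots at the midpoint of the separating
edge. Long branches are flagged at k× the median terminal branch (k = 4).
Full ML and Bayesian inference are deliberately out of scope; the
"two independent settings" concordance requirement is realized as NJ under
the two distance corrections with independent bootstraps, which preserves
the concordance logic at desk scale.

## Classification, HGT, chimeras

A class is accepted iff monophyletic with support ≥ 60 (the one
conventionally printed support threshold; configurable) in **both** trees;
rejection reasons name the failing tree and criterion. Query assignment
walks to the first ancestor containing a reference leaf and assigns only
if all its references belong to one class and the edge support passes —
an abstaining (never guessing) rule; leave-one-out on simulated classes
misassigns nothing and recovers ≥ 90%.

Incongruence: a leaf is called when the smallest clade with support ≥ 60
containing it and ≥ 2 other (non-ignored) leaves has all those others in a
single foreign group. This leaf-level rule deliberately avoids full
duplication–transfer–loss reconciliation. Composition: region G+C z-score
against the genomic background's window values (window 1000, step 30);
|z| ≥ 2 flags, with a documented fallback (absolute difference ≥ 0.05) for
zero-variance backgrounds; the z ≥ 2 rule is this package's
operationalization of "different G+C content" and is configurable.
Synteny: genome pairs from different taxon groups with neighborhood
Jaccard ≥ 0.5 (strand-insensitive; strand can be encoded into labels) form
co-transfer components. Combination: strong ⇔ ≥ 2 evidence lines, weak ⇔
exactly 1. Note the donor genome's own operon makes the donor gene a
legitimate weak synteny-only call; only recipients accumulate two or more
lines. A transfer whose donor lineage later went extinct keeps only its
composition line and is reported weak — visible in the README example and
a real sensitivity limit of the approach.

Chimera diagnosis splits the alignment at the midpoint between two QXXXY
copies and compares fragment placements at support ≥ 60, with fragments
under 50 columns refused. The default breakpoint rule takes the first two
motif matches; because chance QXXXY matches occur (~1 expected per 300
residues), the pipeline uses the `closest` pair rule — the most tightly
spaced adjacent copies, i.e. the tandem-duplication junction signature —
which is robust to stray matches. Every positive verdict carries the
caveat that a transient elevated evolutionary rate can mimic discordant
placements; the package reports, it does not adjudicate.

## Validation conditions and problem sizes

All validation runs on simulated data; sizes were chosen to exercise the
methods at desk scale. NJ recovery: 100 random trees of 4–12 taxa, branch
lengths U(0.05, 1.0). NJ vs exhaustive OLS: 100 six-taxon matrices formed
as tree distances plus uniform ±0.02 noise — inside the NJ l∞ consistency
radius (half the minimum branch length, 0.025); outside that regime NJ and
minimum-OLS genuinely diverge and no equivalence should be expected.
HGT recovery: 20 replicates of the 12-taxon two-group fixture, 3 planted
recent transfers each (amelioration 0, donor G+C 0.35 vs host 0.60,
co-transferred 3-gene operon), tree depth 0.8, substitution rate 1.0,
300-residue proteins, 100 bootstrap replicates, thresholds at their
defaults (support 60, z 2.0, Jaccard 0.5). Class concordance: 20
replicates, 3 classes of 12 members, within-class tree depth 0.05 and
between-class stems 0.2 (≥ 0.4 between, ≤ 0.1 within divergence). Chimera
recovery: one two-family dataset at within-family depth 0.1 — deeper than
the class fixture because fragment-level placement needs within-family
variation exceeding bootstrap resampling noise (at depth 0.05 references
are near-identical over a ~155-column fragment and assignments abstain) —
with 10 fusions and 10 controls. Determinism: the full default pipeline
run twice, all artifacts byte-compared. The reproduction script
(`scripts/acceptance.py`) recomputes all of these from fresh simulations
under a user-supplied seed.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open in every file written. NJ tie
tolerance 1e-12; distance-matrix symmetry tolerance 1e-12; species trees
are ultrametric to 1e-9. Empty profiles (sequence shorter than the G+C
window), proteins shorter than the PSSM width, and all-lost gene families
return empty results rather than errors; malformed files, ragged
alignments, duplicate ids, unknown labels, non-monophyletic outgroups and
undefined distances raise typed errors naming the offender. Every
stochastic function takes one integer seed and is bit-reproducible;
derived seeds stay below 2^31.

## Known limitations

No ML/Bayesian inference, no DTL reconciliation, no codon-usage (CAI)
analysis or composition HMMs, no breakpoint optimization by likelihood, no
automatic de-novo class discovery (class proposals embed taxonomic
knowledge the algorithm cannot infer, so they come from the user or from
simulation truth). Incongruence detection weakens when the donor lineage
is extinct or multiple transfers share a phylogenetic neighborhood;
composition evidence fades with amelioration; chimera detection needs
enough within-family divergence for fragment placements to be decisive.
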