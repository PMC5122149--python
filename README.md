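# chsphylo

Chitin synthases (CHS) are processive family-2 glycosyltransferases (GT2)
that polymerize UDP-GlcNAc into chitin. The family — which also contains
hyaluronan synthases (HAS), cellulose synthases and bacterial NodC — has a
long history of duplications, losses and, more surprisingly, horizontal
gene transfers (HGT), including transfers of eukaryotic *chs* genes into
bacterial genomes and an ancient chimeric ("recCHS"-like) lineage formed by
recombination between two GT2 ancestors. `chsphylo` implements the full
inference chain needed to study such a family, for anyone working on
gene-family evolution in proteomes:

1. **Candidate screening** — PSSM similarity search plus the catalytic-motif
   functionality filter: a CHS must carry three aspartate anchors followed
   by the QXXRW motif (D, D, D, QXXRW, in order); proteins lacking them are
   *dubious* and excluded. A duplicated QXXXY motif marks chimera suspects,
   and a Kyte–Doolittle hydropathy scanner sketches transmembrane segments.
2. **Alignment trimming** — removal of ambiguously aligned / highly
   variable columns (entropy or substitution-matrix scoring, smoothed,
   iterated to a fixpoint) before tree inference.
3. **Trees** — neighbor-joining on p- and Poisson-corrected distances with
   nonparametric bootstrap (100 replicates by default, supports in
   [0, 100]), outgroup rooting (HAS/NodC-like references), Robinson–Foulds
   comparison, and long-branch flagging for LBA control.
4. **Classification** — a *class* is a set of sequences forming a
   monophyletic group with bootstrap support ≥ 60 in the trees from **both**
   distance settings; queries are assigned by smallest-including-clade
   logic.
5. **HGT detection** — three combined evidence lines: phylogenetic
   incongruence (a leaf nested in a well-supported clade of a foreign taxon
   group), G+C composition anomaly (sliding windows of 1000 bp at a 30 bp
   step; |z| ≥ 2 against the genomic background), and gene-neighborhood
   co-transfer (conserved operon context shared across distant genomes,
   Jaccard ≥ 0.5). Two or more lines make a *strong* call, one a *weak*
   call.
6. **Chimera diagnosis** — split the alignment at the duplicated-QXXXY
   breakpoint, infer trees for the N- and C-fragments independently, and
   call a chimera when the two fragments place the query in different
   reference groups with support ≥ 60 on both sides.

Because real proteome-scale inputs are enormous and accession-less, the
package ships a first-class **gene-family evolution simulator**
(`chsphylo.simulate`): an ultrametric species tree, a
duplication–loss–transfer process along it, protein sequences with planted
immutable motifs and a tracked true alignment, codon back-translation with
steerable G+C (so HGT recipients retain donor composition under tunable
amelioration), chimeric fusions, and co-transferred neighborhoods — giving
every stage exact ground truth.

## Worked example

Run the whole chain on a simulated dataset (12 species in two groups,
duplications and losses, two planted transfers with donor G+C and a
co-transferred operon, one planted chimera, three motif-decayed genes,
plus an HAS-like outgroup pair):

```sh
chsphylo run-all --out-dir demo --seed 5
```

prints

```
[simulate] genes=23, events=7, hgt_events=2
[scan] scanned=21, kept=18, dubious=3, pssm_threshold=-41.493
[trim] sequences=20, outgroup=2, excluded=0, columns_in=331, columns_kept=228
[tree] corrections=['p', 'poisson'], bootstrap_reps=100, long_branch_flags=[], discarded_replicates={'p': 0, 'poisson': 0}
[classify] proposed=2, accepted=1, rejected=[{'class': 'D2', 'reason': 'not monophyletic (tree1)'}]
[hgt] calls_strong=1, calls_weak=4, evaluated=17
[recomb] queries=13, chimeric=1
```

Reading the numbers: the three motif-decayed genes are exactly the three
*dubious* ones the scan discards. Trimming keeps 228 of 331 alignment
columns. Of the two planted transfers, `t09|g3` is called **strong** on all
three evidence lines (nested in the donor group with support 100, composition
z = −16.0, operon shared between genomes t05 and t09); the second transfer's
donor lineage was subsequently lost, so only its composition anomaly
(z = −22.2) survives and it is honestly reported **weak**. The recomb stage
screens 13 sequences with ≥ 2 QXXXY matches but convicts only the planted
fusion `rec1|chim1` (N-side group g1, C-side g2, both supports 100). Division
D2 is initially rejected because that chimera nests inside it — the classic
reason chimeric sequences are excluded from phylogenetic analyses. Re-running
with the flagged sequence excluded:

```sh
chsphylo run-all --out-dir demo2 --seed 5   # plus exclude: [rec1|chim1] in a YAML config
```

accepts both divisions (`proposed=2, accepted=2`).

Each stage writes standard formats into the output directory (FASTA,
newick with integer supports, TSV tables with 0-based half-open
coordinates) plus a `run_report.json` whose per-stage counts reconcile.
Stages can also be run individually (`chsphylo scan|trim|tree|classify|
hgt|recomb`) on your own files, and the library API mirrors the CLI
one-to-one.

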