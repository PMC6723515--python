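# stopswitch

Detection and phylogenetic analysis of **stop-codon readthrough length
polymorphisms** in mitochondrial genes, built around the best-documented
case: the ND6 gene of camarodont sea urchins, which segregates a short (S)
and a long (L) protein variant in the same populations.

## The biology, briefly

In sea urchin mitochondrial genomes the *ND5* gene (H-strand) and the
*ND6* gene (L-strand) abut on opposite strands. *ND6* occurs in two forms:

* **S variant** — 489 bp, a 162-residue protein ending at a TAG stop;
* **L variant** — 498 bp, 165 residues: a single substitution at gene
  position 488 (the middle base of the stop codon, `488A>G`) turns TAG
  into the tryptophan codon TGG, and translation reads through the 9-nt
  downstream segment `TTATGATAA`, appending **Trp-Leu-Trp** before the
  next in-frame stop (TAA). Because that segment lies inside the *ND5*
  terminus on the other strand, the realized L coding region overlaps
  *ND5* by exactly 9 bp, while the S forms do not overlap at all.

The third residue of the tail is encoded by TGA — tryptophan under the
echinoderm mitochondrial genetic code (NCBI translation table 9, shipped
as the default), a detail the whole mechanism depends on.

Both alleles segregate within several related species. That pattern —
the same two allelic lineages shared across species boundaries — is the
signature of a **trans-species polymorphism (TSP)** maintained since a
polymorphic common ancestor, as opposed to convergent re-invention of the
L allele in each species. The package quantifies the distinction by
parsimony on a species tree and tests the mechanistic alternatives (RNA
editing, stop-codon reassignment) by comparing transcripts with genomic
DNA.

It is written for molecular evolution researchers working with annotated
mitochondrial genomes (GenBank flat files), orthologous gene sets (FASTA),
transcript read sets (FASTQ/FASTA), and phylogenies (Newick).

## What the package computes

| Step | Method |
|---|---|
| S/L classification | conceptual translation (table 9 by default) against the cohort's S reference length; truncated / stop-less sequences flagged, not dropped |
| stop-switch localization | the unique position whose substitution converts a stop to a sense codon, reported 1-based from the gene start (488 in the canonical geometry) |
| overlap geometry | interval intersection of the realized (extended) coding region with the opposite-strand neighbor, circular-aware |
| tree building | Saitou–Nei neighbor joining on p or Jukes–Cantor distances (or a user-supplied Newick, which takes precedence); outgroup or midpoint rooting |
| character mapping | generalized Fitch parsimony with polymorphic tips as state sets (`min_changes`) |
| TSP assessment | allele-presence parsimony over node states {S}, {L}, {S,L}: every allele gain or loss costs one event; the data are TSP-consistent when ≥ 2 taxa are polymorphic and a single ancestral origin of L attains the minimum event count |
| divergence | Nei's D<sub>xy</sub> (uncorrected and JC), with a per-site binomial SD for single-genome comparisons |
| protein features | amino-acid composition, Kyte–Doolittle hydrophobicity, Grantham distances recomputed from his published formula, a Schneider–Wrede-style physicochemical distance, Wilcoxon tests (exact to n = 25) |
| transcript check | exact k-mer seed + ungapped-extension read mapping, consensus RNA–DNA difference calling, and S/L allele support counts at the focal site |

A first-class synthetic-data generator (`stopswitch.synth`) regenerates the
canonical gene geometry with known ground truth — trees, evolved cohorts
with the polymorphism maintained under a *persistence* or *convergence*
scenario, two-gene GenBank genomes, and transcript reads — and backs most
of the test suite.

## Worked example

Simulate a dataset at the default (canonical) geometry and scan it:

```sh
$ stopswitch simulate --seed 1 --outdir demo
$ stopswitch scan demo/genomes.gbk --out demo/variants.tsv
classified 11 sequences: L=3, S=8
states: T4:{S}, T6:{S}, T5:{L,S}, T2:{L,S}, T8:{L,S}, T7:{S}, T3:{S}, T1:{S}
```

The report's first lines:

```
taxon  sequence_id  variant_class  protein_length_aa  cds_length_nt  stop_switch_site  ref_allele  alt_allele  extension_aa  overlap_bp
T4     T4           S              162                489            488               A           G                         0
T5     T5_S         S              162                489            488               A           G                         0
T5     T5_L         L              165                498            488               A           G           WLW           9
```

Reading the numbers: every S sequence is 489 bp / 162 aa and leaves the
neighbor gene untouched (overlap 0); every L sequence is 498 bp / 165 aa,
carries the A→G change at position 488, appends Trp-Leu-Trp, and overlaps
the neighbor by 9 bp. Mapping the character on the phylogeny:

```sh
$ stopswitch tsp demo/genomes.gbk --out demo/tsp.tsv
3 polymorphic taxa (T2, T5, T8); a single ancestral origin of L explains
the data at the minimum event count (1): consistent with a trans-species
polymorphism maintained across speciation.
```

The same steps run on real data: point `scan`/`tsp` at GenBank flat files
(or `scan --fasta` at pre-extracted gene regions), `transcripts` at a gene
plus an SRA read set, `dxy` at two FASTA groups. `stopswitch --help` lists
all subcommands; everything is also importable (`from stopswitch import
scan_cohort, assess_tsp, ...`).

## Custom genetic codes

Code tables are plain text, one codon per line:

```
# comment lines start with '#'
TTT	F	-
ATG	M	M
TAA	*	-
```

columns: codon, one-letter amino acid (`*` = stop), and `M` for initiation
codons. `load_code()` accepts a shipped name (`echinoderm_mt`, `standard`,
`invertebrate_mt`) or a path to such a file; all 64 codons must be present.

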