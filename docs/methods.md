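# Methods

This note documents the models and procedures `stopswitch` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Coordinates and formats

Internally all intervals are 0-based half-open on the forward strand;
every user-facing report is 1-based inclusive, matching the convention in
which the canonical stop-switch site is "position 488 from the gene
start". GenBank locations (1-based inclusive, `complement(...)`,
`join(...)` across the origin of a circular genome) are converted on
input; a join across the origin sets `wraps_origin` and the feature's
interval is read as `[start, N) + [0, end)`. Only `gene` and `CDS`
features are ingested (a gene annotated as both collapses to one feature,
preferring the CDS); other keys are ignored with a logged notice. Gene
labels pass through an editable synonym table because submitters name the
same gene "ND6", "NAD6", "NADH6" or by its product string. N bases are
preserved throughout and never translated silently.

## Translation

Genetic codes are data, not logic: shipped plain-text tables for the
echinoderm mitochondrial code (NCBI table 9 — TGA=Trp, AGA/AGG=Ser,
AAA=Asn, stops {TAA, TAG}), the standard code, and the invertebrate
mitochondrial code, all validated for 64-codon totality at load time. The
translator works in frame 1 and supports three stop policies: `halt`
(default), `readthrough_once` (the first stop decodes as a caller-supplied
residue — the mechanism under study substitutes Trp — and translation
continues to the next stop), and `translate_through`. Codons containing N
decode to `X` unless all resolutions agree on one residue; 1–2 trailing
bases are reported as an incomplete terminal codon, never dropped. An
annotated CDS with no in-frame stop is flagged `no-stop` rather than
raising, since polyadenylation-completed stops and truncated deposits both
occur in real mitochondrial annotation.

## S/L classification

A cohort of orthologous gene regions (each extracted with downstream
genomic context, default 30 nt, so readthrough can reach its realized
stop) is classified against a reference S protein length:

* equal to the reference → **S**;
* longer, with the first stop downstream of the reference stop → **L**;
  the extension is the nucleotide segment after the reference stop up to
  and including the realized stop (9 nt in the canonical geometry) and the
  residues beyond the reference length (Trp-Leu-Trp);
* shorter → **other/truncated**; no stop at all → **other/no-stop**. Both
  are excluded from the character map, mirroring how truncated deposits
  are excluded from phylogenetic mapping.

When no reference is supplied the cohort defines it: *the smallest protein
length observed in more than one sequence* (falling back to the overall
smallest). Requiring replication keeps a single aberrant truncation from
dragging the reference down, while L-majority cohorts (observed in real
samples at 14 L : 2 S) still anchor on the short form; a plain mode would
misassign those. Ties resolve toward the shorter length, consistent with
the short variant being ancestral. L calls whose extension differs from
the cohort's modal extension length are flagged `extra-length` (the
+2-residue Asn-Asp-type variant); body indels are not resolved — there is
deliberately no multiple alignment in the scanner.

The stop-switch site is localized by comparing an S and an L exemplar over
their shared prefix: the unique position where substituting the S base
with the L base converts a stop codon into a sense codon. Zero or several
candidates raise an ambiguity error listing them. Overlap with the
opposite-strand neighbor is the circular-aware interval intersection of
the *realized* (extended) coding region with the neighbor's annotation.

## Trees and character mapping

Distances are p-distances or Jukes–Cantor, with gap/N sites excluded
pairwise (not listwise); JC distances at p ≥ 0.75 are saturated and set to
a documented sentinel (10.0) with a warning. Neighbor joining is the
standard Saitou–Nei agglomeration with deterministic index-based
tie-breaking; negative branch-length estimates are clamped to zero and
logged. On additive matrices NJ provably recovers the generating topology,
which the tests exercise; an independently implemented NJ (dendropy's) is
used as a cross-check oracle, never as the implementation. ML and Bayesian
tree search are out of scope: a user-supplied Newick always takes
precedence over the built-in NJ, because the S/L mapping logic is
indifferent to how the topology was obtained. Input trees are rooted on a
named outgroup when given, otherwise at the midpoint of the longest
leaf-to-leaf path (implemented directly; logged).

Two parsimony layers answer two different questions:

* **`min_changes`** — classical Fitch with polymorphic tips entered as
  state sets and treated as ambiguity. An alternative encoding that splits
  each polymorphic tip into an S leaf and an L leaf is provided; it counts
  each tip's polymorphism as one forced change, so its cost equals the
  set-encoding cost plus the number of polymorphic tips — an identity the
  tests assert. The two encodings are *not* interchangeable statistics.
* **TSP assessment** — allele-presence parsimony over node states {S},
  {L}, {S,L}, edge cost = number of alleles gained plus alleles lost, with
  a virtual root edge from the ancestral state {S}. A polymorphic ancestor
  transmits both alleles at zero cost, which is precisely what
  "trans-species polymorphism" asserts; allele loss costs one event, so a
  deep origin followed by many losses is *not* free and convergent gains
  can win. The report is `tsp_consistent` when at least two tips are
  polymorphic and some minimum-cost reconstruction places a single gain of
  L on an edge ancestral to every L-bearing tip; otherwise the minimum
  number of independent origins among minimum-cost reconstructions is
  reported. Minimum cost and minimum origins come from a Sankoff-style
  dynamic program (exact); the single-origin test evaluates each candidate
  ancestral edge with a constrained version of the same DP. Both are
  verified against exhaustive enumeration on small trees.

D<sub>xy</sub> is the mean pairwise between-group distance (uncorrected
and JC both reported, since field usage varies). Its SD is the sample SD
over cross pairs; when each group is a single sequence it degenerates to
the per-site binomial SD √(p(1−p)/m) over the m compared sites (delta-
method scaled under JC). No equivalence with any particular program's
uncertainty definition is claimed. A set compared against itself excludes
identical-index pairs, so it equals the within-set mean distance.

Pairwise global alignment is Needleman–Wunsch with linear gap penalty and
deterministic traceback (diagonal over up over left). It substitutes for a
full MSA in pairwise gene and protein comparisons only.

## Protein features

Composition is the frequency vector over the 20 residues (X excluded from
the denominator, count reported separately). Hydrophobicity uses named
per-residue scales (default Kyte–Doolittle). The Grantham matrix is
recomputed at runtime from his published side-chain composition, polarity
and volume values and formula, normalized so the mean over the 190 pairs
is 100; recomputed entries match the published integers to within the
rounding unit. The Schneider–Wrede-style matrix is a **constructed
stand-in** (the 1994 matrix is not redistributed): z-scored Euclidean
distance over three shipped published scales (Kyte–Doolittle hydropathy,
Hopp–Woods hydrophilicity, Zamyatnin residue volume), max-normalized to
[0, 1]. It preserves the role of the matrix, not its exact entries, and is
labelled accordingly in the API.

The S-vs-L comparison pairs the two 20-component composition vectors in a
paired Wilcoxon signed-rank test (the only construction available for two
single proteins), uses a rank-sum test for the per-residue hydrophobicity
profiles, and reports distance-profile totals over the aligned shared
positions (zero when the variants differ only in the tail). Wilcoxon
tests: zeros discarded, exact null enumeration for n ≤ 25 informative
pairs (a documented threshold balancing runtime and fidelity), continuity-
corrected normal approximation beyond, mid-ranks for ties; all-zero
differences return the degenerate p = 1 with a note. The p-values an
upstream feature server once produced for this contrast are not
reproducible from its publication and are not targets; the package's own
tests check structural properties of the comparison instead.

## Transcript concordance

Reads are mapped by exact k-mer seeding (default k = 15; both orientations
tried) and ungapped extension; the placement with most seed votes, then
best identity, wins, and reads under 90% identity over their overlap are
discarded and tallied. No gapped or spliced alignment is attempted — the
question is presence/absence concordance, not alignment statistics. An
RNA–DNA difference (RDD) is a position with depth ≥ 5 whose modal read
base differs from the genomic base at ≥ 0.8 fraction (consensus calling,
so the threshold must exceed 0.5 — an allelic 50/50 mix at the focal site
is *not* an RDD). Verdicts: `concordant` (no RDD, focal site covered),
`discordant`, or `insufficient` (focal depth below threshold). Reads are
assigned S or L solely by their base at the focal site; downstream
extension content is corroborating. All thresholds are overridable and
logged; verdicts are explicitly threshold-relative.

## Synthetic data

The generator emulates the study system with known ground truth. Defaults
regenerate the canonical geometry exactly: a 162-codon stop-free gene body,
TAG as codon 163 (switch site 3·162+2 = 488), downstream segment
`TTATGATAA`, an ND5-like 200-codon neighbor whose terminus is the reverse
complement of that segment (so the L-form overlap is exactly 9 bp), and a
150-nt freely evolving spacer — about 1.24 kb per genome, a deliberately
scaled-down stand-in for a 15.7-kb mitochondrial genome that still gives
the distance-based tree builder genome-scale signal. Trees are Yule (birth
rate 1) over 8 taxa by default, or caterpillars, or user-fixed. Evolution
is Jukes–Cantor along branches at 0.05 substitutions/site per branch-length
unit (within the range of congeneric-to-confamilial mitochondrial
divergence); proposals creating an in-frame stop inside a coding body are
re-drawn — a deliberate departure from a free JC process so that length
classification is never confounded by incidental nonsense mutations. The
focal codon, the extension and the gene junction are held invariant,
mirroring the strong conservation of this terminus in real genomes.

Scenarios: *persistence* plants one S→L origin on the branch ancestral to
a clade of designated polymorphic taxa, each of which then emits both an S
and an L sequence; *convergence* plants independent origins on the
terminal branches of two taxa chosen so that at least two other lineages
separate them (guaranteeing a single ancestral origin is not a
minimum-event explanation on the true tree). Reads are drawn with uniform
coverage including template ends (starts range over the clipped window),
from both strands, with per-base error (default 10⁻³) and optional
site-level edits at configurable fractions. One RNG, seeded once per run,
is threaded through everything; same seed, same dataset, byte for byte.
Every dataset self-validates against its planted truth at generation time.

What the generator does *not* emulate: indels, rate heterogeneity among
sites or lineages, base-composition bias, selection, recombination,
sequencing-error structure beyond a uniform rate. Passing tests therefore
demonstrate correctness of the detection and mapping machinery under
clean, known conditions — not robustness to every artifact of real data.

## Problem sizes and determinism

The randomized suites run at sizes chosen to exercise the exhaustive
oracles meaningfully while keeping the whole test run fast: parsimony vs
brute force on 500 random trees of ≤ 8 leaves, NJ recovery on 100 additive
matrices, stop-switch localization vs brute force on 500 synthetic pairs,
100 end-to-end pipeline runs per evolutionary scenario (labels: ≥ 95% of
persistence runs TSP-consistent, ≤ 5% of convergence runs — the rare
misses come from NJ topology error on very short terminal branches), 1,000
zero-error read-mapping trials, and exact-Wilcoxon enumeration to n = 10.
All suites use fixed seeds.

## Known limitations

* The scanner assumes frame-1 translation and no frameshifts; frameshift
  length variants are out of scope by design.
* Stop-switch coordinates are per-sequence; they are never projected
  across species with upstream indels.
* The TSP assessment is a parsimony statement, not a likelihood one: it
  weighs allele gains and losses equally and cannot incorporate branch
  lengths or population-genetic persistence probabilities.
* Recombination as an explanation for shared polymorphism is not assessed
  (reports say so explicitly).
* Origin-wrapping genes are parsed and extracted, but downstream-context
  extraction for a wrapped gene is not supported.
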