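"""Classification of stop-codon readthrough (S/L) length variants.

The central observation this package operationalises: in camarodont sea
urchin mitochondrial genomes the ND6 gene segregates two length variants —
a short form (S) terminating at an in-frame TAG, and a long form (L) in
which a single substitution inside that stop codon (488A>G, turning TAG
into the tryptophan codon TGG) lets translation read through into the
adjacent sequence until the next in-frame stop.  The readthrough extension
(TTATGATAA in the reported genomes) adds Trp-Leu-Trp to the protein and
creates a 9-bp overlap with the opposite-strand ND5 gene.

This module classifies orthologous coding sequences into S/L/other against
a reference S length, localizes the stop-switch substitution by comparing
S and L exemplars, measures the resulting opposite-strand gene overlap, and
aggregates per-taxon S/L character states for phylogenetic mapping.

All user-facing coordinates are 1-based from the gene's first base on the
reading strand; internally everything is 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import GeneFeature
from .mito_translate import GeneticCode, translate

#: TSV columns of the variant report, in order
VARIANT_REPORT_COLUMNS = (
    "taxon",
    "sequence_id",
    "variant_class",
    "protein_length_aa",
    "cds_length_nt",
    "stop_switch_site",
    "ref_allele",
    "alt_allele",
    "extension_aa",
    "overlap_bp",
    "notes",
)


class AmbiguityError(ValueError):
    """Zero or several candidate stop-switch sites were found."""

    def __init__(self, message: str, candidates: list | None = None) -> None:
        super().__init__(message)
        self.candidates = candidates or []


@dataclass
class VariantCall:
    """Classification of one coding sequence against the cohort's S reference."""

    taxon: str = ""
    sequence_id: str = ""
    variant_class: str = "other"  # S | L | other
    cds_length_nt: int | None = None  # including the stop codon
    protein_length_aa: int | None = None
    stop_switch_site: int | None = None  # 1-based within the gene
    ref_allele: str | None = None
    alt_allele: str | None = None
    extension_nt: str = ""
    extension_aa: str = ""
    overlap_bp: int = 0
    notes: tuple[str, ...] = ()

    def with_notes(self, *extra: str) -> "VariantCall":
        self.notes = tuple(dict.fromkeys(self.notes + extra))
        return self


@dataclass
class CharacterStateMap:
    """Per-taxon S/L character states: each taxon maps to {S}, {L} or {S,L}."""

    states: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, st in self.states.items():
            st = frozenset(st)
            if not st or not st <= {"S", "L"}:
                raise ValueError(f"taxon {taxon!r}: state must be a non-empty subset of {{S, L}}")
            self.states[taxon] = st

    def polymorphic_taxa(self) -> list[str]:
        return [t for t, st in self.states.items() if st == {"S", "L"}]

    def __getitem__(self, taxon: str) -> frozenset[str]:
        return self.states[taxon]

    def __iter__(self):
        return iter(self.states)


def classify_variant(
    cds: str,
    code: GeneticCode,
    reference_protein_length: int | None = None,
) -> VariantCall:
    """Classify one reading-orientation coding sequence as S, L or other.

    ``cds`` should include downstream genomic context past the annotated
    stop (see ``extract_gene_region``) so that readthrough variants can run
    to their realized stop.  With a reference length R (the cohort's S
    protein length): a protein of exactly R residues is S; longer proteins
    whose first stop lies downstream of the reference stop are L; shorter
    ones are flagged truncated.  A sequence with no in-frame stop is
    flagged ``no-stop`` rather than raising.
    """
    if len(cds) < 6:
        raise ValueError(f"CDS too short to classify: {len(cds)} nt")
    cds = cds.upper()
    result = translate(cds, code, stop_policy="halt")
    call = VariantCall(
        protein_length_aa=len(result.protein),
        cds_length_nt=result.cds_length_nt,
    )
    if not result.found_stop:
        call.variant_class = "other"
        call.protein_length_aa = None
        call.cds_length_nt = None
        return call.with_notes("no-stop")
    ref = reference_protein_length
    if ref is None:
        return call  # class assigned at cohort level
    if "N" in cds[3 * ref : 3 * ref + 3]:
        call.with_notes("ambiguous")
    plen = len(result.protein)
    if plen == ref:
        call.variant_class = "S"
    elif plen > ref:
        call.variant_class = "L"
        call.extension_nt = cds[3 * ref + 3 : 3 * plen + 3]
        call.extension_aa = result.protein[ref:]
    else:
        call.variant_class = "other"
        call.with_notes("truncated")
    return call


def localize_stop_switch(
    cds_s: str, cds_l: str, code: GeneticCode
) -> tuple[int, str, str]:
    """Locate the substitution that converts a stop codon into a sense codon.

    Compares the shared prefix of an S and an L coding sequence codon by
    codon and returns ``(site, ref_allele, alt_allele)`` where ``site`` is
    1-based from the gene's first base.  Exactly one such position must
    exist; zero or several raise :class:`AmbiguityError` listing the
    candidates.
    """
    cds_s, cds_l = cds_s.upper(), cds_l.upper()
    shared = min(len(cds_s), len(cds_l))
    shared -= shared % 3
    candidates: list[tuple[int, str, str]] = []
    for i in range(shared):
        if cds_s[i] == cds_l[i]:
            continue
        c0 = i - i % 3
        codon_s = cds_s[c0 : c0 + 3]
        switched = codon_s[: i - c0] + cds_l[i] + codon_s[i - c0 + 1 :]
        if code.is_stop(codon_s) and not code.is_stop(switched):
            candidates.append((i + 1, cds_s[i], cds_l[i]))
    if len(candidates) != 1:
        raise AmbiguityError(
            f"expected exactly one stop-switch site, found {len(candidates)}: "
            f"{[c[0] for c in candidates]}",
            candidates,
        )
    return candidates[0]


def _interval_set(start: int, end: int, wraps: bool, n: int) -> list[tuple[int, int]]:
    if wraps:
        return [(start, n), (0, end)]
    return [(start, end)]


def compute_overlap(
    gene_a: GeneFeature,
    gene_b: GeneFeature,
    genome_length: int,
    topology: str = "linear",
) -> int:
    """Length in bp of the intersection of two gene intervals.

    Strand-agnostic and aware of circular genomes: intervals wrapping the
    origin are split into their two forward-strand segments first.
    ``gene_a`` is normally the realized (possibly extended) coding region.
    """
    if topology != "circular" and (gene_a.wraps_origin or gene_b.wraps_origin):
        raise ValueError("origin-wrapping features on a linear genome")
    total = 0
    for a0, a1 in _interval_set(gene_a.start, gene_a.end, gene_a.wraps_origin, genome_length):
        for b0, b1 in _interval_set(gene_b.start, gene_b.end, gene_b.wraps_origin, genome_length):
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


def realized_feature(feature: GeneFeature, extension_nt: int, genome_length: int) -> GeneFeature:
    """Extend an annotated gene at its 3' end (in reading orientation) by
    ``extension_nt`` forward-strand bases, wrapping the origin if needed."""
    if extension_nt == 0:
        return feature
    if feature.strand == 1:
        end = feature.end + extension_nt
        wraps = feature.wraps_origin or end > genome_length
        return GeneFeature(
            feature.gene_name, feature.start, end % genome_length if end > genome_length else end,
            1, wraps, feature.feature_key,
        )
    start = feature.start - extension_nt
    wraps = feature.wraps_origin or start < 0
    return GeneFeature(
        feature.gene_name, start % genome_length, feature.end, -1, wraps, feature.feature_key
    )


def _reference_s_length(protein_lengths: Sequence[int]) -> int:
    """The cohort's S reference: the shortest well-formed protein length
    supported by more than one sequence, falling back to the overall
    shortest.  Requiring replication keeps a single aberrant truncation
    (an *Eucidaris tribuloides*-style deletion) from dragging the reference
    down; ties resolve toward the shorter length, matching the inferred
    ancestral state of the short variant."""
    counts = Counter(protein_lengths)
    replicated = sorted(l for l, c in counts.items() if c > 1)
    if replicated:
        return replicated[0]
    return min(protein_lengths)


def scan_cohort(
    cds_by_taxon: Mapping[str, str | Sequence[str]],
    code: GeneticCode,
    reference_protein_length: int | None = None,
) -> tuple[list[VariantCall], CharacterStateMap]:
    """Classify a cohort of orthologous gene sequences and build the
    per-taxon S/L character map.

    Each taxon may contribute one sequence or a list (an intraspecific
    sample).  The S reference length is taken from the cohort when not
    supplied.  Taxa whose sequences include both classes map to {S, L};
    sequences classified ``other`` (truncated / no stop) are excluded from
    the character map, mirroring their exclusion from phylogenetic mapping.
    """
    if len(cds_by_taxon) < 2:
        raise ValueError("cohort needs at least two taxa")
    flat: list[tuple[str, str, str]] = []  # (taxon, seq_id, cds)
    for taxon, seqs in cds_by_taxon.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        for i, s in enumerate(seqs):
            sid = taxon if len(seqs) == 1 else f"{taxon}.{i + 1}"
            flat.append((taxon, sid, s.upper()))

    prelim = {sid: classify_variant(cds, code) for taxon, sid, cds in flat}
    lengths = [c.protein_length_aa for c in prelim.values() if c.protein_length_aa is not None]
    if not lengths:
        raise ValueError("no sequence in the cohort has a well-formed in-frame stop")
    ref = reference_protein_length if reference_protein_length is not None else _reference_s_length(lengths)

    calls: list[VariantCall] = []
    s_exemplar: str | None = None
    l_exemplar: str | None = None
    for taxon, sid, cds in flat:
        call = classify_variant(cds, code, reference_protein_length=ref)
        call.taxon = taxon
        call.sequence_id = sid
        calls.append(call)
        if call.variant_class == "S" and s_exemplar is None:
            s_exemplar = cds
        elif call.variant_class == "L" and l_exemplar is None:
            l_exemplar = cds

    # modal L extension length: longer L calls are flagged, mirroring the
    # AB863103.1-style +2-residue variant
    ext_lengths = Counter(
        len(c.extension_aa) for c in calls if c.variant_class == "L" and c.extension_aa
    )
    if ext_lengths:
        modal_ext = ext_lengths.most_common(1)[0][0]
        for c in calls:
            if c.variant_class == "L" and len(c.extension_aa) != modal_ext:
                c.with_notes("extra-length")

    # localize the stop switch from one S/L exemplar pair and annotate calls
    if s_exemplar is not None and l_exemplar is not None:
        try:
            site, ref_allele, alt_allele = localize_stop_switch(s_exemplar, l_exemplar, code)
        except AmbiguityError:
            site = ref_allele = alt_allele = None
        if site is not None:
            for c in calls:
                if c.variant_class in ("S", "L"):
                    c.stop_switch_site = site
                    c.ref_allele = ref_allele
                    c.alt_allele = alt_allele

    states: dict[str, frozenset[str]] = {}
    for c in calls:
        if c.variant_class in ("S", "L"):
            states.setdefault(c.taxon, frozenset())
            states[c.taxon] = states[c.taxon] | {c.variant_class}
    return calls, CharacterStateMap({t: st for t, st in states.items() if st})


def class_counts(calls: Sequence[VariantCall]) -> Counter:
    """Cohort-wide counts of each variant class."""
    return Counter(c.variant_class for c in calls)


def variant_report_rows(calls: Sequence[VariantCall]) -> list[dict]:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "taxon": c.taxon,
                "sequence_id": c.sequence_id or f"seq{i + 1}",
                "variant_class": c.variant_class,
                "protein_length_aa": c.protein_length_aa,
                "cds_length_nt": c.cds_length_nt,
                "stop_switch_site": c.stop_switch_site,
                "ref_allele": c.ref_allele,
                "alt_allele": c.alt_allele,
                "extension_aa": c.extension_aa,
                "overlap_bp": c.overlap_bp,
                "notes": ";".join(c.notes),
            }
        )
    return rows
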