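"""Readers/writers for the standard formats the pipeline touches.

GenBank flat files, FASTA and FASTQ are parsed with Biopython; Newick trees
with dendropy.  External 1-based inclusive coordinates (GenBank) are
converted on input to the internal convention — 0-based half-open intervals
on the forward strand — and converted back to 1-based in user-facing
reports.

Gene naming in deposited mitochondrial records is inconsistent ("ND6",
"NAD6", "NADH6", "NADH dehydrogenase subunit 6", ...); lookups go through a
user-editable synonym table (:data:`DEFAULT_GENE_SYNONYMS`).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .mito_translate import reverse_complement, validate_dna

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input text violates the expected file format."""


class GeneLookupError(LookupError):
    """Zero or several features match a requested gene name."""


#: canonical gene name -> accepted synonyms (matched case-insensitively,
#: ignoring spaces, hyphens and underscores).  Extend or replace per dataset.
DEFAULT_GENE_SYNONYMS: dict[str, tuple[str, ...]] = {
    "ND5": ("ND5", "NAD5", "NADH5", "MT-ND5", "NADH dehydrogenase subunit 5"),
    "ND6": ("ND6", "NAD6", "NADH6", "MT-ND6", "NADH dehydrogenase subunit 6"),
}


def _normalize_name(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch not in " -_")


def canonical_gene_name(raw: str, synonyms: Mapping[str, Sequence[str]] | None = None) -> str | None:
    """Map a raw annotation label to its canonical gene name, or None."""
    table = DEFAULT_GENE_SYNONYMS if synonyms is None else synonyms
    key = _normalize_name(raw)
    for canonical, alts in table.items():
        if key == _normalize_name(canonical) or key in {_normalize_name(a) for a in alts}:
            return canonical
    return None


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene annotation on the forward strand of a genome.

    ``[start, end)`` is 0-based half-open.  When ``wraps_origin`` is true
    (a join across the origin of a circular genome) the interval is
    ``[start, genome_length) + [0, end)`` and ``start >= end``.
    """

    gene_name: str
    start: int
    end: int
    strand: int
    wraps_origin: bool = False
    feature_key: str = "gene"

    def __post_init__(self) -> None:
        if not self.gene_name:
            raise ValueError("gene_name must be non-empty")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if not self.wraps_origin and not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A genome sequence plus its gene annotations."""

    identifier: str
    sequence: str
    topology: str = "linear"
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("identifier must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        self.sequence = self.sequence.upper()
        validate_dna(self.sequence)
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            hi = max(f.start, f.end)
            if hi > n or (f.wraps_origin and self.topology != "circular"):
                raise ValueError(f"feature {f.gene_name} exceeds genome of length {n}")

    def slice(self, start: int, end: int, wraps_origin: bool = False) -> str:
        """Forward-strand slice, concatenating across the origin when wrapped."""
        if wraps_origin:
            return self.sequence[start:] + self.sequence[:end]
        return self.sequence[start:end]


@dataclass
class ReadSet:
    """Sequencing reads: (read_id, sequence, optional quality string)."""

    reads: list[tuple[str, str, str | None]]

    def __post_init__(self) -> None:
        for rid, seq, qual in self.reads:
            validate_dna(seq.upper())
            if qual is not None and len(qual) != len(seq):
                raise FormatError(f"read {rid!r}: quality length {len(qual)} != read length {len(seq)}")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# GenBank


def _feature_from_location(feat: SeqFeature, name: str, genome_length: int) -> GeneFeature:
    loc = feat.location
    if loc is None:
        raise FormatError(f"feature {name!r} has a malformed or missing location")
    strand = -1 if loc.strand == -1 else 1
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    starts = [int(p.start) for p in parts]
    ends = [int(p.end) for p in parts]
    if len(parts) == 1:
        return GeneFeature(name, starts[0], ends[0], strand, False, feat.type)
    # join across the origin: one part ends at the sequence end, another starts at 0
    ordered = sorted(zip(starts, ends))
    if ordered[0][0] == 0 and ordered[-1][1] == genome_length and len(parts) == 2:
        return GeneFeature(name, ordered[-1][0], ordered[0][1], strand, True, feat.type)
    # contiguous multi-part joins collapse to their span; anything else is malformed
    if all(ordered[i][1] == ordered[i + 1][0] for i in range(len(ordered) - 1)):
        return GeneFeature(name, ordered[0][0], ordered[-1][1], strand, False, feat.type)
    raise FormatError(f"feature {name!r}: unsupported compound location {loc}")


def parse_genbank(
    text: str, synonyms: Mapping[str, Sequence[str]] | None = None
) -> GenomeRecord:
    """Parse one GenBank flat-file record into a :class:`GenomeRecord`.

    Only ``gene`` and ``CDS`` features are ingested; other keys are ignored
    with a logged notice.  Gene labels are canonicalised through the synonym
    table when they match; unmatched labels are kept verbatim.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # Biopython raises plain ValueError subclasses
        raise FormatError(f"cannot parse GenBank record: {exc}") from exc
    try:
        seq = str(rec.seq)
    except Exception as exc:
        raise FormatError("GenBank record lacks an ORIGIN sequence") from exc
    if not seq or set(seq) == {"?"}:
        raise FormatError("GenBank record lacks an ORIGIN sequence")
    topology = rec.annotations.get("topology", "linear")
    features: list[GeneFeature] = []
    skipped: set[str] = set()
    for feat in rec.features:
        if feat.type not in ("gene", "CDS"):
            if feat.type != "source":
                skipped.add(feat.type)
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or [None])[0]
        if raw is None:
            continue
        name = canonical_gene_name(raw, synonyms) or raw
        features.append(_feature_from_location(feat, name, len(seq)))
    if skipped:
        logger.info("ignored feature keys in %s: %s", rec.id, ", ".join(sorted(skipped)))
    return GenomeRecord(
        identifier=rec.id or rec.name,
        sequence=seq.upper(),
        topology=topology if topology in ("linear", "circular") else "linear",
        features=features,
    )


def read_genbank(path: str | Path, synonyms=None) -> list[GenomeRecord]:
    """Read all records from a GenBank flat file."""
    text = Path(path).read_text()
    chunks = [c for c in text.split("//\n") if c.strip()]
    return [parse_genbank(c.rstrip("\n") + "\n//\n", synonyms) for c in chunks]


def write_genbank(record: GenomeRecord, handle_or_path) -> None:
    """Write a GenomeRecord as GenBank flat-file text."""
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier.split(".")[0][:16],
        description="synthetic mitochondrial region",
        annotations={"molecule_type": "DNA", "topology": record.topology},
    )
    n = len(record.sequence)
    for f in record.features:
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start, n, strand=f.strand), SimpleLocation(0, f.end, strand=f.strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand=f.strand)
        rec.features.append(SeqFeature(loc, type=f.feature_key, qualifiers={"gene": [f.gene_name]}))
    if hasattr(handle_or_path, "write"):
        SeqIO.write(rec, handle_or_path, "genbank")
    else:
        with open(handle_or_path, "w") as fh:
            SeqIO.write(rec, fh, "genbank")


# ---------------------------------------------------------------------------
# gene extraction


def _matching_features(
    record: GenomeRecord, gene_name: str, synonyms=None
) -> list[GeneFeature]:
    want = canonical_gene_name(gene_name, synonyms) or gene_name
    hits = [
        f
        for f in record.features
        if (canonical_gene_name(f.gene_name, synonyms) or f.gene_name) == want
    ]
    # a gene is typically annotated both as `gene` and `CDS` over the same
    # interval; collapse identical intervals, preferring the CDS entry
    by_interval: dict[tuple, GeneFeature] = {}
    for f in sorted(hits, key=lambda f: f.feature_key != "CDS"):
        by_interval.setdefault((f.start, f.end, f.strand, f.wraps_origin), f)
    return list(by_interval.values())


def find_gene(record: GenomeRecord, gene_name: str, synonyms=None) -> GeneFeature:
    hits = _matching_features(record, gene_name, synonyms)
    if len(hits) != 1:
        listing = [f"{f.gene_name}[{f.start}:{f.end}]({f.strand:+d})" for f in hits]
        raise GeneLookupError(
            f"{record.identifier}: expected exactly one feature for {gene_name!r}, "
            f"found {len(hits)}: {listing}"
        )
    return hits[0]


def extract_gene_cds(record: GenomeRecord, gene_name: str, synonyms=None) -> str:
    """Return the reading-strand sequence of a uniquely named gene."""
    f = find_gene(record, gene_name, synonyms)
    raw = record.slice(f.start, f.end, f.wraps_origin)
    return reverse_complement(raw) if f.strand == -1 else raw


def extract_gene_region(
    record: GenomeRecord, gene_name: str, downstream_nt: int = 30, synonyms=None
) -> str:
    """Reading-strand gene sequence extended ``downstream_nt`` bases past its 3' end.

    Readthrough variants translate beyond the annotated stop, so the scanner
    needs downstream genomic context.  On linear genomes the extension is
    clamped at the sequence boundary; on circular genomes it wraps.
    """
    f = find_gene(record, gene_name, synonyms)
    n = len(record.sequence)
    if f.wraps_origin:
        raise NotImplementedError("downstream context for origin-wrapping genes is not supported")
    if f.strand == 1:
        end = f.end + downstream_nt
        if record.topology == "circular" and end > n:
            return record.sequence[f.start :] + record.sequence[: end - n]
        return record.sequence[f.start : min(end, n)]
    start = f.start - downstream_nt
    if record.topology == "circular" and start < 0:
        raw = record.sequence[start % n :] + record.sequence[: f.end]
    else:
        raw = record.sequence[max(start, 0) : f.end]
    return reverse_complement(raw)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

FASTA_LINE_WIDTH = 70


def read_fasta(path_or_handle) -> dict[str, str]:
    """Read a FASTA file into an ordered {identifier: sequence} map.

    Identifiers are the token up to the first whitespace; duplicates are an
    error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path_or_handle) -> None:
    def _write(fh) -> None:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i : i + FASTA_LINE_WIDTH] + "\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def read_fastq(path_or_handle) -> ReadSet:
    reads: list[tuple[str, str, str | None]] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(path_or_handle, "fastq"):
            if rec.id in seen:
                raise FormatError(f"duplicate FASTQ identifier {rec.id!r}")
            seen.add(rec.id)
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append((rec.id, str(rec.seq).upper(), qual))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse FASTQ: {exc}") from exc
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path_or_handle) -> None:
    def _write(fh) -> None:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)
    else:
        with open(path_or_handle, "w") as fh:
            _write(fh)


def read_reads(path: str | Path) -> ReadSet:
    """Read transcript reads from FASTQ or FASTA, by extension."""
    path = Path(path)
    if path.suffix.lower() in (".fq", ".fastq"):
        return read_fastq(path)
    return ReadSet([(rid, seq, None) for rid, seq in read_fasta(str(path)).items()])


# ---------------------------------------------------------------------------
# Newick


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a string or path; leaf labels must be unique."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels in tree: {dup}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# tabular reports


def write_report_tsv(
    rows: Iterable[Mapping[str, object]], columns: Sequence[str], path_or_handle
) -> None:
    """Write a stable-column TSV report (missing fields become empty cells)."""
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path_or_handle, sep="\t", index=False)
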