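"""Orchestration of the analysis stages.

The library functions here wire the modules together the way the original
study flows: annotated genomes (or a gene FASTA) -> S/L variant scan and
overlap geometry -> tree building (NJ, or a user-supplied Newick) -> S/L
character mapping and the trans-species polymorphism assessment -> the
DNA-vs-transcript concordance check.  The thin ``cli`` module exposes the
same steps as subcommands.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import dendropy

from . import io_formats, phylo, scan, transcripts
from .io_formats import GenomeRecord
from .mito_translate import load_code
from .scan import CharacterStateMap, VariantCall
from .synth import SimulationConfig, SyntheticDataset, generate_dataset
from .transcripts import ConcordanceReport

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Defaults for a pipeline run; every field is CLI-overridable."""

    gene: str = "ND6"
    neighbor_gene: str = "ND5"
    code_name: str = "echinoderm_mt"
    outgroup: str | None = None
    downstream_nt: int = 30
    distance_model: str = "jc"
    k: int = transcripts.DEFAULT_K
    min_identity: float = transcripts.DEFAULT_MIN_IDENTITY
    min_depth: int = transcripts.DEFAULT_MIN_DEPTH
    min_alt_fraction: float = transcripts.DEFAULT_MIN_ALT_FRACTION
    seed: int = 0
    synonyms: dict | None = None


def taxon_of(identifier: str) -> str:
    """Strip a trailing _S/_L allele suffix from a record identifier."""
    if "_" in identifier:
        stem, suffix = identifier.rsplit("_", 1)
        if suffix in ("S", "L"):
            return stem
    return identifier


def scan_genomes(
    records: list[GenomeRecord], cfg: RunConfig | None = None
) -> tuple[list[VariantCall], CharacterStateMap]:
    """Scan annotated genomes for S/L variants of the focal gene, including
    the overlap of each realized coding region with the neighbor gene."""
    cfg = cfg or RunConfig()
    code = load_code(cfg.code_name)
    cds_by_taxon: dict[str, list[str]] = {}
    recs_flat: list[GenomeRecord] = []
    for rec in records:
        taxon = taxon_of(rec.identifier)
        region = io_formats.extract_gene_region(rec, cfg.gene, cfg.downstream_nt, cfg.synonyms)
        cds_by_taxon.setdefault(taxon, []).append(region)
        recs_flat.append(rec)
    calls, states = scan.scan_cohort(cds_by_taxon, code)
    # scan_cohort flattens cds_by_taxon in insertion order, so calls align
    # with recs_flat grouped the same way
    order: list[GenomeRecord] = []
    by_taxon: dict[str, list[GenomeRecord]] = {}
    for rec in recs_flat:
        by_taxon.setdefault(taxon_of(rec.identifier), []).append(rec)
    for taxon in cds_by_taxon:
        order.extend(by_taxon[taxon])
    for call, rec in zip(calls, order):
        call.sequence_id = rec.identifier
        try:
            gene_feat = io_formats.find_gene(rec, cfg.gene, cfg.synonyms)
            nb_feat = io_formats.find_gene(rec, cfg.neighbor_gene, cfg.synonyms)
        except io_formats.GeneLookupError:
            continue
        ext_len = len(call.extension_nt) if call.variant_class == "L" else 0
        realized = scan.realized_feature(gene_feat, ext_len, len(rec.sequence))
        call.overlap_bp = scan.compute_overlap(realized, nb_feat, len(rec.sequence), rec.topology)
    return calls, states


def scan_gene_fasta(
    seqs: dict[str, str], cfg: RunConfig | None = None
) -> tuple[list[VariantCall], CharacterStateMap]:
    """Scan pre-extracted gene regions (reading orientation) from a FASTA map."""
    cfg = cfg or RunConfig()
    code = load_code(cfg.code_name)
    cds_by_taxon: dict[str, list[str]] = {}
    for ident, seq in seqs.items():
        cds_by_taxon.setdefault(taxon_of(ident), []).append(seq)
    return scan.scan_cohort(cds_by_taxon, code)


def build_tree(
    genome_seqs: dict[str, str], cfg: RunConfig | None = None
) -> dendropy.Tree:
    """Neighbor-joining tree from equal-length genome sequences, rooted on
    the configured outgroup (midpoint when absent)."""
    cfg = cfg or RunConfig()
    dm = phylo.distance_matrix(genome_seqs, model=cfg.distance_model)
    tree = phylo.nj_tree(dm)
    return phylo.root_on_outgroup(tree, cfg.outgroup)


def assess_tsp_pipeline(
    records: list[GenomeRecord],
    cfg: RunConfig | None = None,
    tree: dendropy.Tree | None = None,
) -> tuple[phylo.TspReport, list[VariantCall]]:
    """Genomes -> variant scan -> tree (NJ unless supplied) -> TSP report.

    A user-supplied tree takes precedence over the built-in NJ builder.
    """
    cfg = cfg or RunConfig()
    calls, states = scan_genomes(records, cfg)
    if tree is None:
        # one genome per taxon for distances: prefer the S-allele record
        seqs: dict[str, str] = {}
        for rec in records:
            taxon = taxon_of(rec.identifier)
            if taxon not in seqs or rec.identifier.endswith("_S"):
                seqs[taxon] = rec.sequence
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("genomes differ in length; supply a tree or a pre-aligned set")
        tree = build_tree(seqs, cfg)
    else:
        tree = phylo.root_on_outgroup(tree, cfg.outgroup)
    report = phylo.assess_tsp(tree, states)
    return report, calls


def run_synthetic_tsp(
    config: SimulationConfig, cfg: RunConfig | None = None
) -> phylo.TspReport:
    """End-to-end on one synthetic dataset: assemble genomes, serialize to
    GenBank text, re-parse, extract, scan, build the NJ tree, assess TSP."""
    dataset = generate_dataset(config)
    buf = io.StringIO()
    for rec in dataset.genomes:
        io_formats.write_genbank(rec, buf)
    text = buf.getvalue()
    records = []
    for chunk in text.split("//\n"):
        if chunk.strip():
            records.append(io_formats.parse_genbank(chunk.rstrip("\n") + "\n//\n"))
    report, _ = assess_tsp_pipeline(records, cfg)
    return report


def transcript_concordance(
    gene_region: str,
    readset,
    cfg: RunConfig | None = None,
    focal_site: int | None = None,
    s_allele: str | None = None,
    l_allele: str | None = None,
) -> ConcordanceReport:
    """Map transcript reads to the gene DNA and call RNA-DNA differences;
    when the focal stop-switch site and alleles are given, count S- and
    L-supporting reads there."""
    cfg = cfg or RunConfig()
    pileup = transcripts.map_reads(gene_region, readset, k=cfg.k, min_identity=cfg.min_identity)
    report = transcripts.call_rdd(
        pileup, min_depth=cfg.min_depth, min_alt_fraction=cfg.min_alt_fraction,
        focal_site=focal_site,
    )
    if focal_site is not None and s_allele and l_allele:
        report.s_support, report.l_support = transcripts.count_allele_support(
            pileup, focal_site, s_allele, l_allele
        )
    return report
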