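"""DNA-vs-transcript concordance: the RNA-editing / codon-reassignment test.

If the S/L length polymorphism were an artifact of RNA editing or of a
reassigned stop codon, transcripts would differ from the genomic sequence
at (or around) the stop-switch site.  This module maps transcript reads
onto the gene DNA with a deterministic exact-k-mer seed + ungapped
extension mapper, builds a per-position pileup, calls RNA-DNA differences
(RDD) by consensus, and counts reads supporting each allele at the focal
site.  Zero RDD sites with the focal site covered means the transcripts
match the DNA: editing and reassignment are not supported.

Default thresholds (k = 15, identity >= 0.9, min_depth = 5,
min_alt_fraction = 0.8) are deliberately conservative and all overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ReadSet
from .mito_translate import reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

DEFAULT_K = 15
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_ALT_FRACTION = 0.8


@dataclass
class Pileup:
    """Per-position base counts over a gene: counts[i, b] for base b at
    0-based gene position i."""

    gene: str
    counts: np.ndarray  # (len(gene), 4) int
    mapped_reads: int = 0
    discarded_reads: int = 0

    def depth(self, pos0: int) -> int:
        return int(self.counts[pos0].sum())

    def consensus(self, pos0: int) -> str | None:
        col = self.counts[pos0]
        if col.sum() == 0:
            return None
        return _BASES[int(col.argmax())]


@dataclass
class RddSite:
    position: int  # 1-based within the gene
    dna_base: str
    rna_consensus_base: str
    depth: int
    alt_fraction: float


@dataclass
class ConcordanceReport:
    covered_positions: int
    rdd_sites: list[RddSite] = field(default_factory=list)
    s_support: int = 0
    l_support: int = 0
    verdict: str = "insufficient"  # concordant | discordant | insufficient
    focal_site: int | None = None
    mapped_reads: int = 0
    discarded_reads: int = 0


def _seed_candidates(index: dict[str, list[int]], read: str, k: int) -> dict[int, int]:
    """Vote for candidate gene offsets (gene_pos - read_pos) from exact k-mer hits."""
    votes: dict[int, int] = {}
    for rpos in range(len(read) - k + 1):
        for gpos in index.get(read[rpos : rpos + k], ()):
            off = gpos - rpos
            votes[off] = votes.get(off, 0) + 1
    return votes


def _ungapped_identity(gene: str, read: str, offset: int) -> tuple[float, int, int]:
    """Identity of the read against the gene at a fixed offset, over the
    overlapping region only; returns (identity, g_start, g_end)."""
    g_start = max(0, offset)
    g_end = min(len(gene), offset + len(read))
    if g_end <= g_start:
        return 0.0, 0, 0
    matches = sum(
        1 for g in range(g_start, g_end) if gene[g] == read[g - offset]
    )
    return matches / (g_end - g_start), g_start, g_end


def map_reads(
    gene: str,
    reads: ReadSet,
    k: int = DEFAULT_K,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Pileup:
    """Map reads onto a gene by exact k-mer seeding and ungapped extension.

    Both read orientations are tried; the placement with the most seed
    votes (then the better identity) wins.  Reads whose best placement
    falls below ``min_identity`` over the overlapping region are discarded
    and tallied.  No gapped alignment is attempted.
    """
    if k < 11:
        raise ValueError("k must be >= 11 to keep seeds specific")
    gene = gene.upper()
    if len(gene) < k:
        raise ValueError(f"gene ({len(gene)} nt) shorter than k = {k}")
    index: dict[str, list[int]] = {}
    for i in range(len(gene) - k + 1):
        index.setdefault(gene[i : i + k], []).append(i)

    counts = np.zeros((len(gene), 4), dtype=np.int64)
    mapped = discarded = 0
    for _, seq, _ in reads.reads:
        seq = seq.upper()
        best = None  # (votes, identity, oriented_read, offset, span)
        for oriented in (seq, reverse_complement(seq)):
            if len(oriented) < k:
                continue
            for off, votes in _seed_candidates(index, oriented, k).items():
                ident, g0, g1 = _ungapped_identity(gene, oriented, off)
                key = (votes, ident)
                if best is None or key > best[0]:
                    best = (key, oriented, off, g0, g1)
        if best is None or best[0][1] < min_identity:
            discarded += 1
            continue
        _, oriented, off, g0, g1 = best
        mapped += 1
        for g in range(g0, g1):
            b = oriented[g - off]
            if b in _BASE_INDEX:
                counts[g, _BASE_INDEX[b]] += 1
    return Pileup(gene=gene, counts=counts, mapped_reads=mapped, discarded_reads=discarded)


def call_rdd(
    pileup: Pileup,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt_fraction: float = DEFAULT_MIN_ALT_FRACTION,
    focal_site: int | None = None,
) -> ConcordanceReport:
    """Call RNA-DNA difference sites from a pileup.

    A position is an RDD site when its depth reaches ``min_depth`` and the
    modal read base differs from the genomic base with fraction at least
    ``min_alt_fraction`` (consensus-style calling, so the fraction
    threshold must exceed 0.5).  The verdict is ``concordant`` when no RDD
    site exists and the focal site (if given) is adequately covered,
    ``insufficient`` when it is not, and ``discordant`` otherwise.
    """
    if min_depth <= 0 or not 0.5 < min_alt_fraction <= 1.0:
        raise ValueError("min_depth must be positive and min_alt_fraction in (0.5, 1]")
    depths = pileup.counts.sum(axis=1)
    covered = int((depths > 0).sum())
    sites: list[RddSite] = []
    for pos0 in np.nonzero(depths >= min_depth)[0]:
        col = pileup.counts[pos0]
        total = int(col.sum())
        top = int(col.argmax())
        frac = col[top] / total
        if _BASES[top] != pileup.gene[pos0] and frac >= min_alt_fraction:
            sites.append(
                RddSite(int(pos0) + 1, pileup.gene[pos0], _BASES[top], total, float(frac))
            )
    report = ConcordanceReport(
        covered_positions=covered,
        rdd_sites=sites,
        focal_site=focal_site,
        mapped_reads=pileup.mapped_reads,
        discarded_reads=pileup.discarded_reads,
    )
    if focal_site is not None and pileup.depth(focal_site - 1) < min_depth:
        report.verdict = "insufficient"
    elif sites:
        report.verdict = "discordant"
    else:
        report.verdict = "concordant"
    return report


def count_allele_support(
    pileup: Pileup, focal_site: int, s_allele: str, l_allele: str
) -> tuple[int, int]:
    """Read counts carrying the S and the L allele at the 1-based focal site."""
    if not 1 <= focal_site <= len(pileup.gene):
        raise ValueError(f"focal site {focal_site} outside gene of length {len(pileup.gene)}")
    s_allele, l_allele = s_allele.upper(), l_allele.upper()
    if s_allele == l_allele or len(s_allele) != 1 or len(l_allele) != 1:
        raise ValueError("alleles must be two distinct single bases")
    col = pileup.counts[focal_site - 1]
    return int(col[_BASE_INDEX[s_allele]]), int(col[_BASE_INDEX[l_allele]])
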