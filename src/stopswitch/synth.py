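"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: a species tree, a
two-gene mitochondrial region with the characteristic geometry (an
ND5-like gene on the forward/H strand abutting an ND6-like gene on the
reverse/L strand, with a 9-nt readthrough extension of ND6 lying inside
the ND5 terminus), gene sequences evolved along the tree with the focal
stop-switch polymorphism maintained, and transcript read sets.

Defaults regenerate the reported gene geometry exactly: a 162-codon short
protein, the stop codon TAG as codon 163 (so the stop-switch site is
position 488, middle base of the stop), and the downstream segment
TTATGATAA whose readthrough appends Trp-Leu-Trp before the realized TAA.

Two evolutionary scenarios are simulated for the S/L polymorphism:

``persistence``
    one S-to-L origin on the branch ancestral to all designated polymorphic
    taxa; both alleles are transmitted through the subsequent speciations,
    so every polymorphic taxon carries both (the trans-species pattern);
``convergence``
    independent S-to-L origins on the terminal branches of each designated
    polymorphic taxon, chosen far enough apart that a single ancestral
    origin is not a minimum-event explanation.

Substitution is Jukes-Cantor along branches, with proposals that would
create an in-frame stop inside a coding body re-drawn (stop codons in gene
bodies would confound length classification; the deliberate departure from
a free JC process is documented).  The focal stop codon, the readthrough
extension and the ND5/ND6 junction are held invariant, mirroring the
strong conservation of this terminus in real genomes.  One RNG, seeded
once per run, is threaded through all operations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .io_formats import GeneFeature, GenomeRecord, ReadSet, write_fasta, write_genbank, write_newick
from .mito_translate import GeneticCode, load_code, reverse_complement, translate
from .scan import localize_stop_switch

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_B2I = {65: 0, 67: 1, 71: 2, 84: 3}


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of a synthetic dataset; defaults regenerate the worked
    sea urchin ND6 geometry."""

    seed: int = 0
    n_taxa: int = 8
    tree_shape: str = "yule"  # yule | caterpillar | a fixed newick string
    birth_rate: float = 1.0
    subst_rate: float = 0.05  # substitutions per site per branch-length unit
    gene_length_codons: int = 162  # S protein length
    stop_codon: str = "TAG"
    extension_nt: str = "TTATGATAA"
    nd5_length_codons: int = 200
    spacer_length: int = 150
    scenario: str = "persistence"  # persistence | convergence
    polymorphic_taxa: tuple[str, ...] | None = None
    code_name: str = "echinoderm_mt"
    read_depth: int = 50
    read_length: int = 70
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ConfigError("n_taxa must be >= 3")
        if self.scenario not in ("persistence", "convergence"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if len(self.extension_nt) % 3 != 0 or len(self.extension_nt) < 3:
            raise ConfigError("extension_nt must be a non-empty whole number of codons")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")

    @property
    def focal_codon_index(self) -> int:
        """1-based codon index of the stop codon (163 by default)."""
        return self.gene_length_codons + 1

    @property
    def stop_switch_site(self) -> int:
        """1-based gene position of the focal substitution: the middle base
        of the stop codon, 3*(focal_codon-1)+2 = 488 by default."""
        return 3 * self.gene_length_codons + 2

    @property
    def gene_region_length(self) -> int:
        return 3 * self.gene_length_codons + 3 + len(self.extension_nt)


@dataclass
class GroundTruth:
    """Planted truth emitted next to every dataset."""

    tree_newick: str
    states: dict[str, tuple[str, ...]]  # taxon -> ("S",) / ("S", "L")
    stop_switch_site: int
    ref_allele: str
    alt_allele: str
    extension_nt: str
    extension_aa: str
    scenario: str
    planted_edits: dict[int, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["states"] = {k: sorted(v) for k, v in self.states.items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    cds_by_taxon: dict[str, list[str]]  # ND6 gene regions (incl. downstream)
    genome_alignment: dict[str, str]  # one S-allele genome per taxon, equal length
    genomes: list[GenomeRecord]  # one record per emitted allele
    truth: GroundTruth


# ---------------------------------------------------------------------------
# trees


def simulate_tree(config: SimulationConfig, rng: np.random.Generator) -> dendropy.Tree:
    """A seeded random tree: pure-birth (Yule), pectinate caterpillar with
    unit branches, or a fixed user newick."""
    n = config.n_taxa
    labels = [f"T{i + 1}" for i in range(n)]
    if config.tree_shape == "caterpillar":
        newick = labels[0]
        for lab in labels[1:]:
            newick = f"({newick}:1.0,{lab}:1.0)"
        newick += ";"
    elif config.tree_shape == "yule":
        newick = _yule_newick(labels, config.birth_rate, rng)
    else:
        newick = config.tree_shape  # fixed newick text
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _yule_newick(labels: list[str], birth_rate: float, rng: np.random.Generator) -> str:
    class _N:
        __slots__ = ("children", "bl", "label")

        def __init__(self):
            self.children, self.bl, self.label = [], 0.0, None

    root = _N()
    active = [root]
    while len(active) < len(labels):
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.bl += dt
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        kids = [_N(), _N()]
        parent.children = kids
        active.extend(kids)
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.bl += dt
    order = list(rng.permutation(len(labels)))
    leaves = [n for n in _postorder(root) if not n.children]
    for leaf, k in zip(leaves, order):
        leaf.label = labels[k]

    def emit(node) -> str:
        if not node.children:
            return f"{node.label}:{node.bl:.8f}"
        return "(" + ",".join(emit(c) for c in node.children) + f"):{node.bl:.8f}"

    return emit(root) + ";"


def _postorder(node):
    for c in node.children:
        yield from _postorder(c)
    yield node


# ---------------------------------------------------------------------------
# sequence evolution


def _random_sense_codons(n: int, code: GeneticCode, rng: np.random.Generator) -> str:
    sense = sorted(c for c in code.codon_to_aa if code.codon_to_aa[c] != "*")
    return "".join(rng.choice(sense) for _ in range(n))


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.array([_B2I[b] for b in seq.encode()], dtype=np.uint8)


def _arr_to_seq(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _evolve_segment(
    arr: np.ndarray,
    branch_length: float,
    rate: float,
    rng: np.random.Generator,
    code: GeneticCode | None,
) -> np.ndarray:
    """JC evolution of one segment; when ``code`` is given the segment is a
    coding body and proposals creating a stop codon are re-drawn."""
    out = arr.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * branch_length))
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    if hits.size == 0:
        return out
    out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    if code is None:
        return out
    for _ in range(10):
        bad = _stop_codon_starts(out, code)
        if not bad:
            return out
        for c0 in bad:
            mutated = [i for i in range(c0, c0 + 3) if out[i] != arr[i]]
            for i in mutated:  # re-draw among the non-parental bases
                out[i] = (arr[i] + rng.integers(1, 4)) % 4
    # pathological draw: revert the offending codons to the parent state
    for c0 in _stop_codon_starts(out, code):
        out[c0 : c0 + 3] = arr[c0 : c0 + 3]
    return out


def _stop_codon_starts(arr: np.ndarray, code: GeneticCode) -> list[int]:
    seq = _arr_to_seq(arr)
    return [i for i in range(0, len(seq) - 2, 3) if code.is_stop(seq[i : i + 3])]


def _pick_persistence_clade(tree: dendropy.Tree, rng: np.random.Generator) -> list[str]:
    internal = [
        n
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
        and 2 <= len(n.leaf_nodes()) < len(tree.leaf_nodes())
    ]
    if not internal:
        raise ConfigError("tree has no proper internal clade for a persistence scenario")
    node = internal[int(rng.integers(len(internal)))]
    return [leaf.taxon.label for leaf in node.leaf_nodes()]


def _separating_subtrees(tree: dendropy.Tree, a: str, b: str) -> int:
    """Number of maximal subtrees hanging off the path a..b (excluding a, b)."""
    na = tree.find_node_with_taxon_label(a)
    nb = tree.find_node_with_taxon_label(b)
    mrca = tree.mrca(taxa=[na.taxon, nb.taxon])
    path_nodes = set()
    for tip in (na, nb):
        node = tip
        while node is not mrca:
            path_nodes.add(node)
            node = node.parent_node
    path_nodes.add(mrca)
    count = 0
    for node in path_nodes:
        for child in node.child_nodes():
            if child not in path_nodes and child not in (na, nb):
                count += 1
    return count


def _pick_convergence_pair(tree: dendropy.Tree, rng: np.random.Generator) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    pairs = [
        (a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
        if _separating_subtrees(tree, a, b) >= 2
    ]
    if not pairs:
        raise ConfigError(
            "no leaf pair is separated by >= 2 other lineages; use more taxa "
            "for a convergence scenario"
        )
    return list(pairs[int(rng.integers(len(pairs)))])


def evolve_alignment(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, str], dict[str, tuple[str, ...]]]:
    """Evolve the two-gene region along the tree.

    Returns ``(cds_by_taxon, genome_parts_by_taxon, states)`` where
    ``cds_by_taxon[taxon]`` holds the taxon's ND6 gene regions (one per
    allele carried, S first), ``genome_parts_by_taxon`` holds the taxon's
    S-allele forward-strand genome sequence, and ``states`` is the planted
    per-taxon character state.
    """
    code = load_code(config.code_name)
    nd5_tail = reverse_complement(config.extension_nt)
    if code.is_stop(config.stop_codon) is False:
        raise ConfigError(f"{config.stop_codon} is not a stop codon of {code.name}")
    if not code.is_stop(nd5_tail[-3:]):
        raise ConfigError(
            "the reverse complement of extension_nt must end with a stop codon "
            "(it doubles as the ND5 terminus)"
        )

    if config.polymorphic_taxa is not None:
        poly = list(config.polymorphic_taxa)
        if not poly:
            raise ConfigError(f"{config.scenario} scenario requires polymorphic taxa")
    elif config.scenario == "persistence":
        poly = _pick_persistence_clade(tree, rng)
    else:
        poly = _pick_convergence_pair(tree, rng)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not set(poly) <= labels:
        raise ConfigError(f"polymorphic taxa {sorted(set(poly) - labels)} not in the tree")

    # root state: evolving bodies + invariant junction/stop/extension
    nd6_body = _seq_to_arr(_random_sense_codons(config.gene_length_codons, code, rng))
    nd5_body = _seq_to_arr(_random_sense_codons(config.nd5_length_codons - 3, code, rng))
    spacer = rng.integers(0, 4, size=config.spacer_length).astype(np.uint8)

    if config.scenario == "persistence":
        origin = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t) for t in poly])
    else:
        origin = None

    seqs: dict = {}  # node -> (nd6_body, nd5_body, spacer)
    carries_l: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = (nd6_body, nd5_body, spacer)
            carries_l[node] = False
            continue
        bl = node.edge.length or 0.0
        p6, p5, psp = seqs[node.parent_node]
        seqs[node] = (
            _evolve_segment(p6, bl, config.subst_rate, rng, code),
            _evolve_segment(p5, bl, config.subst_rate, rng, code),
            _evolve_segment(psp, bl, config.subst_rate, rng, None),
        )
        carries_l[node] = carries_l[node.parent_node] or node is origin

    cds_by_taxon: dict[str, list[str]] = {}
    genome_parts: dict[str, str] = {}
    states: dict[str, tuple[str, ...]] = {}
    stop = config.stop_codon
    sw_off = config.stop_switch_site - 3 * config.gene_length_codons - 1  # offset in stop codon
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        b6, b5, sp = seqs[leaf]
        body = _arr_to_seq(b6)
        s_region = body + stop + config.extension_nt
        is_poly = taxon in poly and (config.scenario == "convergence" or carries_l[leaf])
        if taxon in poly and config.scenario == "persistence" and not carries_l[leaf]:
            raise ConfigError(
                f"taxon {taxon} was designated polymorphic but is not a descendant "
                "of the planted origin; for persistence the polymorphic taxa must form a clade"
            )
        if is_poly:
            l_stop = stop[:sw_off] + "G" + stop[sw_off + 1 :]
            l_region = body + l_stop + config.extension_nt
            cds_by_taxon[taxon] = [s_region, l_region]
            states[taxon] = ("S", "L")
        else:
            cds_by_taxon[taxon] = [s_region]
            states[taxon] = ("S",)
        genome_parts[taxon] = _arr_to_seq(b5) + reverse_complement(config.extension_nt)
        genome_parts[taxon] = (
            genome_parts[taxon]
            + reverse_complement(s_region[: 3 * config.gene_length_codons + 3])
            + _arr_to_seq(sp)
        )
    return cds_by_taxon, genome_parts, states


# ---------------------------------------------------------------------------
# genome assembly


def assemble_genome(
    cds_by_gene: dict[str, str],
    config: SimulationConfig,
    identifier: str = "SYN1",
    spacer: str | None = None,
) -> GenomeRecord:
    """Assemble a circular two-gene genome with the characteristic geometry.

    ``cds_by_gene`` maps ``"ND5"`` to a forward-strand CDS whose final bases
    must equal the reverse complement of the ND6 extension (the shared
    junction), and ``"ND6"`` to the gene region in reading orientation
    (body + stop-or-switched codon [+ extension, optional]).  The emitted
    record annotates the S-form intervals: ND5 ``[0, L5)`` on strand +1 and
    ND6 abutting it on strand -1, so the S forms do not overlap while the
    realized L-form CDS overlaps ND5 by exactly the extension length.
    """
    nd5 = cds_by_gene["ND5"].upper()
    nd6 = cds_by_gene["ND6"].upper()
    ext = config.extension_nt
    if not nd5.endswith(reverse_complement(ext)):
        raise ConfigError(
            "ND5 must end with the reverse complement of the ND6 extension; "
            "the extension lies inside the ND5 terminus"
        )
    s_len = 3 * config.gene_length_codons + 3
    nd6_annot = nd6[:s_len]
    if len(nd6_annot) != s_len:
        raise ConfigError(f"ND6 region shorter than the S form ({s_len} nt)")
    if spacer is None:
        spacer = "T" * config.spacer_length
    sequence = nd5 + reverse_complement(nd6_annot) + spacer
    features = [
        GeneFeature("ND5", 0, len(nd5), 1, feature_key="CDS"),
        GeneFeature("ND6", len(nd5), len(nd5) + s_len, -1, feature_key="CDS"),
    ]
    return GenomeRecord(identifier, sequence, "circular", features)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    templates: str | list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    edits: dict[int, tuple[str, float]] | None = None,
    weights: list[float] | None = None,
) -> ReadSet:
    """Uniform-coverage reads from one or more templates (e.g. the S and L
    transcripts), from both strands, with per-base error and optional
    site-level editing.

    ``edits`` maps 1-based template positions to ``(new_base, fraction)``:
    each read covering the site carries the edit with that probability
    (emulating partial RNA editing).  Same seed, same read set.
    """
    if isinstance(templates, str):
        templates = [templates]
    templates = [t.upper() for t in templates]
    if weights is None:
        weights = [1.0 / len(templates)] * len(templates)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    rl = config.read_length
    if any(rl > len(t) for t in templates):
        raise ConfigError("read_length exceeds a template length")
    # read starts range over [-(rl-1), len-1] with clipping at the template
    # bounds, so every position (including the ends) sees ~read_depth coverage
    tlen = len(templates[0])
    n_reads = int(np.ceil(config.read_depth * (tlen + rl - 1) / rl))
    reads: list[tuple[str, str, str | None]] = []
    for i in range(n_reads):
        t = templates[int(rng.choice(len(templates), p=weights))]
        start = int(rng.integers(-(rl - 1), len(t)))
        lo = max(0, start)
        frag = list(t[lo : start + rl])
        if edits:
            for pos1, (base, fraction) in edits.items():
                idx = pos1 - 1 - lo
                if 0 <= idx < len(frag) and rng.random() < fraction:
                    frag[idx] = base
        if config.error_rate > 0:
            err = np.nonzero(rng.random(len(frag)) < config.error_rate)[0]
            for j in err:
                frag[j] = "ACGT"[(_B2I[ord(frag[j])] + int(rng.integers(1, 4))) % 4]
        seq = "".join(frag)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"read{i + 1}", seq, "I" * len(seq)))
    return ReadSet(reads)


# ---------------------------------------------------------------------------
# whole datasets


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete, self-validated dataset from one seeded config."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    cds_by_taxon, genome_parts, states = evolve_alignment(tree, config, rng)
    code = load_code(config.code_name)

    genomes: list[GenomeRecord] = []
    for taxon, regions in cds_by_taxon.items():
        nd5 = genome_parts[taxon][: 3 * config.nd5_length_codons]
        s_len = 3 * config.gene_length_codons + 3
        spacer = genome_parts[taxon][3 * config.nd5_length_codons + s_len :]
        for allele, region in zip(("S", "L"), regions):
            ident = taxon if len(regions) == 1 else f"{taxon}_{allele}"
            genomes.append(
                assemble_genome({"ND5": nd5, "ND6": region}, config, identifier=ident, spacer=spacer)
            )

    # generation-time self-validation against the planted truth
    ref_len = config.gene_length_codons
    ext_aa = None
    for taxon, regions in cds_by_taxon.items():
        s_res = translate(regions[0], code)
        if len(s_res.protein) != ref_len:
            raise ConfigError(f"self-check failed: S protein of {taxon} has {len(s_res.protein)} aa")
        if len(regions) == 2:
            l_res = translate(regions[1], code)
            ext_aa = l_res.protein[ref_len:]
            site, ref_allele, alt_allele = localize_stop_switch(regions[0], regions[1], code)
            if site != config.stop_switch_site:
                raise ConfigError(f"self-check failed: stop switch at {site}, planted {config.stop_switch_site}")
    sw = config.stop_switch_site
    stop = config.stop_codon
    truth = GroundTruth(
        tree_newick=write_newick(tree).strip(),
        states=states,
        stop_switch_site=sw,
        ref_allele=stop[(sw - 1) % 3],
        alt_allele="G",
        extension_nt=config.extension_nt,
        extension_aa=ext_aa or "",
        scenario=config.scenario,
    )
    return SyntheticDataset(
        config=config,
        tree=tree,
        cds_by_taxon=cds_by_taxon,
        genome_alignment={t: genome_parts[t] for t in cds_by_taxon},
        genomes=genomes,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset to disk: GenBank genomes, ND6 FASTA, the true tree,
    and a ground-truth JSON sidecar (schema: the fields of GroundTruth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gbk = outdir / "genomes.gbk"
    with open(gbk, "w") as fh:
        for rec in dataset.genomes:
            write_genbank(rec, fh)
    paths["genomes"] = gbk
    fasta = outdir / "nd6_regions.fasta"
    seqs = {}
    for taxon, regions in dataset.cds_by_taxon.items():
        for allele, region in zip(("S", "L"), regions):
            seqs[taxon if len(regions) == 1 else f"{taxon}_{allele}"] = region
    write_fasta(seqs, fasta)
    paths["nd6_fasta"] = fasta
    nwk = outdir / "true_tree.nwk"
    nwk.write_text(dataset.truth.tree_newick + "\n")
    paths["tree"] = nwk
    gt = outdir / "ground_truth.json"
    gt.write_text(dataset.truth.to_json() + "\n")
    paths["ground_truth"] = gt
    return paths
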