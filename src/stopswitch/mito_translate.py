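"""Genetic-code tables and conceptual translation.

Mitochondrial genomes use non-standard genetic codes; in the echinoderm
mitochondrial code (NCBI translation table 9) TGA encodes tryptophan,
AGA/AGG encode serine, AAA encodes asparagine, and only TAA/TAG terminate
translation.  Because a stop-switch substitution extends translation into
downstream sequence, the translator supports, besides the ordinary halting
policy, a forced-readthrough policy in which the first stop codon is
decoded as a caller-supplied amino acid and translation continues to the
next in-frame stop.

Code tables are shipped as plain-text data files (one ``CODON<TAB>AA`` line
per codon, ``*`` marking stops) so that users can supply their own; see
:func:`load_code`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
CODONS = tuple("".join(c) for c in itertools.product(_BASES, repeat=3))

#: names of the code tables shipped with the package
SHIPPED_CODES = ("echinoderm_mt", "standard", "invertebrate_mt")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T,N}."""


class CodeTableError(ValueError):
    """A genetic-code table is unknown, incomplete, or malformed."""


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to amino acids, with an explicit stop set."""

    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = [c for c in CODONS if c not in self.codon_to_aa]
        if missing:
            raise CodeTableError(
                f"code table {self.name!r} is incomplete: missing {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        extra = set(self.codon_to_aa) - set(CODONS)
        if extra:
            raise CodeTableError(f"code table {self.name!r} has non-codon keys: {sorted(extra)}")
        if not self.stop_codons:
            raise CodeTableError(f"code table {self.name!r} has an empty stop set")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == "*"

    def decode(self, codon: str) -> str:
        """Decode one codon; codons containing N give 'X' unless all resolutions agree."""
        if codon in self.codon_to_aa:
            return self.codon_to_aa[codon]
        validate_dna(codon)
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        residues = {self.codon_to_aa[c] for c in _resolve_ambiguous(codon)}
        return residues.pop() if len(residues) == 1 else "X"


@dataclass(frozen=True)
class TranslationResult:
    """Outcome of conceptual translation of a CDS in frame 1.

    ``stop_position_nt`` is the 1-based position of the realized stop
    codon's first base within the CDS (so the coding length including the
    stop codon is ``stop_position_nt + 2``).  ``trailing_partial`` counts
    the 0-2 leftover bases of an incomplete terminal codon; they are never
    silently dropped.
    """

    protein: str
    stop_codon: str | None
    stop_position_nt: int | None
    trailing_partial: int = 0

    @property
    def found_stop(self) -> bool:
        return self.stop_codon is not None

    @property
    def cds_length_nt(self) -> int | None:
        """Coding length in nucleotides including the stop codon, when a stop was found."""
        return None if self.stop_position_nt is None else self.stop_position_nt + 2


def validate_dna(seq: str) -> str:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, with N complementing to N."""
    validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _resolve_ambiguous(codon: str) -> Iterable[str]:
    options = [_BASES if b == "N" else b for b in codon]
    for combo in itertools.product(*options):
        yield "".join(combo)


def translate(
    cds: str,
    code: GeneticCode,
    stop_policy: str = "halt",
    readthrough_aa: str = "W",
) -> TranslationResult:
    """Conceptually translate ``cds`` in frame 1 under ``code``.

    stop_policy
        ``"halt"`` stops at the first in-frame stop codon;
        ``"readthrough_once"`` decodes the first stop as ``readthrough_aa``
        and continues to the next stop; ``"translate_through"`` decodes
        every stop as ``readthrough_aa`` and runs to the sequence end.
    """
    validate_dna(cds)
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: length {len(cds)}")
    if stop_policy not in ("halt", "readthrough_once", "translate_through"):
        raise ValueError(f"unknown stop policy {stop_policy!r}")

    protein: list[str] = []
    stops_passed = 0
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = code.decode(codon)
        if aa == "*":
            if stop_policy == "halt" or (stop_policy == "readthrough_once" and stops_passed >= 1):
                return TranslationResult(
                    protein="".join(protein),
                    stop_codon=codon,
                    stop_position_nt=i + 1,
                    trailing_partial=0,
                )
            stops_passed += 1
            protein.append(readthrough_aa)
        else:
            protein.append(aa)
    return TranslationResult(
        protein="".join(protein),
        stop_codon=None,
        stop_position_nt=None,
        trailing_partial=len(cds) % 3,
    )


def _parse_code_lines(name: str, lines: Iterable[str]) -> GeneticCode:
    table: dict[str, str] = {}
    starts: set[str] = set()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CodeTableError(f"malformed code-table line in {name!r}: {line!r}")
        codon, aa = parts[0].upper(), parts[1]
        if codon not in CODONS:
            raise CodeTableError(f"not a codon in {name!r}: {codon!r}")
        if len(aa) != 1:
            raise CodeTableError(f"amino acid field must be one letter or '*': {aa!r}")
        table[codon] = aa
        if len(parts) >= 3 and parts[2] == "M":
            starts.add(codon)
    return GeneticCode(name=name, codon_to_aa=table, start_codons=frozenset(starts))


def load_code(name_or_file: str | Path) -> GeneticCode:
    """Load a genetic code by shipped name or from a code-table file."""
    name = str(name_or_file)
    if name in SHIPPED_CODES:
        text = (
            resources.files("stopswitch.data.codes").joinpath(f"{name}.tsv").read_text()
        )
        return _parse_code_lines(name, text.splitlines())
    path = Path(name_or_file)
    if path.exists():
        return _parse_code_lines(path.stem, path.read_text().splitlines())
    raise CodeTableError(
        f"unknown genetic code {name!r}; shipped codes are {', '.join(SHIPPED_CODES)}"
    )
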