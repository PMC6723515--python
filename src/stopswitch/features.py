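"""Physicochemical comparison of protein variants.

The S and L forms of a readthrough-polymorphic protein share their whole
body and differ only in a short C-terminal tail, so composition,
hydrophobicity and pairwise residue-distance profiles localise the
physicochemical consequences of readthrough to the extension.  Distances
come in two flavours: the Grantham (1974) chemical distance, recomputed
here from his published side-chain composition/polarity/volume values and
formula, and a Schneider-Wrede-style physicochemical distance constructed
from per-residue hydropathy, hydrophilicity and residue-volume scales (the
original 1994 matrix is not redistributed; see :func:`sw_matrix`).

Wilcoxon tests use exact null enumeration up to n = 25 paired observations
and the continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
EXACT_WILCOXON_MAX_N = 25

#: Grantham's formula constants (alpha, beta, gamma) and normalisation target
_GRANTHAM_ALPHA, _GRANTHAM_BETA, _GRANTHAM_GAMMA = 1.833, 0.1018, 0.000399


class ScaleLookupError(KeyError):
    """Unknown residue scale name."""


@dataclass(frozen=True)
class FeatureVector:
    kind: str  # composition | hydrophobicity | grantham_profile | sw_profile
    values: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels differ in length")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # exact | normal-approximation | degenerate
    n: tuple[int, ...]
    note: str = ""


def _read_scale(name: str) -> dict[str, tuple[float, ...]]:
    try:
        text = resources.files("stopswitch.data.scales").joinpath(f"{name}.tsv").read_text()
    except FileNotFoundError as exc:
        raise ScaleLookupError(name) from exc
    out: dict[str, tuple[float, ...]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = tuple(float(x) for x in parts[1:])
    return out


@functools.lru_cache(maxsize=None)
def residue_scale(name: str = "kyte_doolittle") -> dict[str, float]:
    """A named per-residue scale as {amino acid: value}."""
    if name not in ("kyte_doolittle", "hopp_woods", "residue_volume"):
        raise ScaleLookupError(f"unknown scale {name!r}")
    return {aa: v[0] for aa, v in _read_scale(name).items()}


def aa_composition(protein: str) -> FeatureVector:
    """Amino-acid frequency vector over the 20 residues in fixed order.

    ``X`` residues (ambiguous translations) are excluded from the
    denominator; their count is appended to the vector's labels metadata
    only through :func:`composition_excluded`.
    """
    protein = protein.upper()
    counted = [aa for aa in protein if aa in AA_ORDER]
    if not counted:
        raise ValueError("empty protein (or no unambiguous residues)")
    bad = set(protein) - set(AA_ORDER) - {"X"}
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    n = len(counted)
    freqs = tuple(counted.count(aa) / n for aa in AA_ORDER)
    return FeatureVector("composition", freqs, tuple(AA_ORDER))


def composition_excluded(protein: str) -> int:
    """Number of X residues excluded from the composition denominator."""
    return protein.upper().count("X")


def hydrophobicity_profile(protein: str, scale: str = "kyte_doolittle") -> FeatureVector:
    """Per-residue hydrophobicity values under a named scale (default
    Kyte-Doolittle hydropathy)."""
    table = residue_scale(scale)
    protein = protein.upper()
    values = []
    for aa in protein:
        if aa == "X":
            values.append(float("nan"))
        elif aa in table:
            values.append(table[aa])
        else:
            raise ValueError(f"invalid residue {aa!r}")
    labels = tuple(str(i + 1) for i in range(len(protein)))
    return FeatureVector("hydrophobicity", tuple(values), labels)


@functools.lru_cache(maxsize=None)
def grantham_matrix() -> dict[tuple[str, str], float]:
    """The Grantham chemical-distance matrix recomputed from his published
    side-chain composition (c), polarity (p) and volume (v) values:

        D(i,j) = k * sqrt(alpha (c_i-c_j)^2 + beta (p_i-p_j)^2 + gamma (v_i-v_j)^2)

    with k chosen so the mean over the 190 unordered pairs is 100 (matching
    the published normalisation; published entries are rounded integers).
    """
    props = _read_scale("grantham_properties")
    raw: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(AA_ORDER, 2):
        ca, pa, va = props[a]
        cb, pb, vb = props[b]
        raw[(a, b)] = math.sqrt(
            _GRANTHAM_ALPHA * (ca - cb) ** 2
            + _GRANTHAM_BETA * (pa - pb) ** 2
            + _GRANTHAM_GAMMA * (va - vb) ** 2
        )
    k = 100.0 / (sum(raw.values()) / len(raw))
    out: dict[tuple[str, str], float] = {}
    for (a, b), v in raw.items():
        out[(a, b)] = out[(b, a)] = k * v
    for a in AA_ORDER:
        out[(a, a)] = 0.0
    return out


@functools.lru_cache(maxsize=None)
def sw_matrix() -> dict[tuple[str, str], float]:
    """A Schneider-Wrede-style physicochemical distance matrix.

    Constructed (not copied) from three shipped per-residue scales —
    Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity and Zamyatnin
    residue volume — by z-scoring each scale over the 20 residues and
    taking Euclidean distance, normalised so the maximum pair distance is
    1.  A synthetic stand-in for the Schneider & Wrede (1994) matrix, which
    this package does not redistribute; it preserves the matrix's role (a
    polarity/volume-driven residue distance) rather than its exact entries.
    """
    scales = [residue_scale(n) for n in ("kyte_doolittle", "hopp_woods", "residue_volume")]
    z = []
    for table in scales:
        v = np.array([table[a] for a in AA_ORDER])
        z.append((v - v.mean()) / v.std())
    z = np.stack(z, axis=1)  # 20 x 3
    out: dict[tuple[str, str], float] = {}
    maxd = 0.0
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            d = float(np.linalg.norm(z[i] - z[j]))
            out[(a, b)] = d
            maxd = max(maxd, d)
    return {k: v / maxd for k, v in out.items()}


def _distance_profile(
    kind: str,
    matrix: dict[tuple[str, str], float],
    protein_a: str,
    protein_b: str,
    alignment: tuple[str, str] | None = None,
) -> FeatureVector:
    if alignment is not None:
        a, b = alignment
    else:
        a, b = protein_a.upper(), protein_b.upper()
    if len(a) != len(b):
        raise ValueError("profiles need equal-length (aligned) proteins; pass an alignment")
    values: list[float] = []
    labels: list[str] = []
    for i, (x, y) in enumerate(zip(a.upper(), b.upper())):
        if x == "-" or y == "-" or x == "X" or y == "X":
            continue  # gap/ambiguous positions are excluded, not scored
        values.append(matrix[(x, y)])
        labels.append(str(i + 1))
    return FeatureVector(kind, tuple(values), tuple(labels))


def grantham_profile(protein_a: str, protein_b: str, alignment=None) -> FeatureVector:
    """Per-aligned-position Grantham distances (0 at identities; gaps excluded)."""
    return _distance_profile("grantham_profile", grantham_matrix(), protein_a, protein_b, alignment)


def schneider_wrede_profile(protein_a: str, protein_b: str, alignment=None) -> FeatureVector:
    """Per-aligned-position Schneider-Wrede-style distances (see :func:`sw_matrix`)."""
    return _distance_profile("sw_profile", sw_matrix(), protein_a, protein_b, alignment)


def wilcoxon(
    x, y, paired: bool = False, alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon test between two numeric vectors.

    Paired: signed-rank with zero differences discarded, exact enumeration
    for n <= 25 informative pairs, normal approximation with continuity
    correction beyond.  Unpaired: rank-sum (Mann-Whitney) with mid-ranks
    for ties.  All-zero paired differences give the degenerate p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length vectors")
        diffs = x - y
        n_nonzero = int(np.count_nonzero(diffs))
        if n_nonzero == 0:
            return TestResult(0.0, 1.0, "degenerate", (len(x), len(y)),
                              note="all paired differences are zero")
        if n_nonzero < 3:
            note = "fewer than 3 non-zero differences; p is coarse"
        else:
            note = ""
        method = "exact" if n_nonzero <= EXACT_WILCOXON_MAX_N else "approx"
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=(method == "approx"),
            alternative=alternative, method=("exact" if method == "exact" else "approx"),
        )
        return TestResult(
            float(res.statistic), float(res.pvalue),
            "exact" if method == "exact" else "normal-approximation",
            (len(x), len(y)), note,
        )
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return TestResult(float(res.statistic), float(res.pvalue), "rank-sum", (len(x), len(y)))


def compare_variant_proteins(protein_s: str, protein_l: str) -> dict:
    """Feature comparison of two protein variants (typically S vs L).

    Returns composition vectors and their paired Wilcoxon test over the 20
    residue categories, mean hydrophobicity with a rank-sum test over the
    per-residue profiles, and summed Grantham / Schneider-Wrede-style
    distances over the aligned shared positions.
    """
    comp_s, comp_l = aa_composition(protein_s), aa_composition(protein_l)
    comp_test = wilcoxon(comp_s.values, comp_l.values, paired=True)
    hyd_s = hydrophobicity_profile(protein_s)
    hyd_l = hydrophobicity_profile(protein_l)
    hyd_test = wilcoxon(hyd_s.values, hyd_l.values, paired=False)
    n = min(len(protein_s), len(protein_l))
    gran = grantham_profile(protein_s[:n], protein_l[:n])
    sw = schneider_wrede_profile(protein_s[:n], protein_l[:n])
    return {
        "composition_s": comp_s,
        "composition_l": comp_l,
        "composition_test": comp_test,
        "hydrophobicity_mean_s": hyd_s.mean,
        "hydrophobicity_mean_l": hyd_l.mean,
        "hydrophobicity_test": hyd_test,
        "grantham_profile": gran,
        "grantham_total": float(np.sum(gran.values)),
        "sw_profile": sw,
        "sw_total": float(np.sum(sw.values)),
    }
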