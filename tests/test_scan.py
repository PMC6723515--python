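"""S/L variant classification, stop-switch localization, overlap geometry."""

import numpy as np
import pytest

from stopswitch.io_formats import GeneFeature
from stopswitch.mito_translate import translate
from stopswitch.scan import (
    AmbiguityError,
    classify_variant,
    class_counts,
    compute_overlap,
    localize_stop_switch,
    scan_cohort,
)
from conftest import make_sl_pair


def brute_force_stop_switch(cds_s: str, cds_l: str, code):
    """Independent oracle: a site is a stop switch iff substituting the S
    base with the L base strictly extends the halted translation."""
    base_len = len(translate(cds_s, code).protein)
    shared = min(len(cds_s), len(cds_l))
    out = []
    for i in range(shared):
        if cds_s[i] == cds_l[i]:
            continue
        mod = cds_s[:i] + cds_l[i] + cds_s[i + 1 :]
        res = translate(mod, code)
        if res.found_stop and len(res.protein) > base_len:
            out.append(i + 1)
        if not res.found_stop and len(res.protein) > base_len:
            out.append(i + 1)
    return out


class TestClassifyVariant:
    def test_s_form_geometry(self, echinoderm, sl_pair):
        s_region, _ = sl_pair
        call = classify_variant(s_region, echinoderm, reference_protein_length=162)
        assert call.variant_class == "S"
        assert call.protein_length_aa == 162
        assert call.cds_length_nt == 489
        assert call.extension_nt == "" and call.extension_aa == ""

    def test_l_form_geometry(self, echinoderm, sl_pair):
        _, l_region = sl_pair
        call = classify_variant(l_region, echinoderm, reference_protein_length=162)
        assert call.variant_class == "L"
        assert call.protein_length_aa == 165
        assert call.cds_length_nt == 498
        assert call.extension_aa == "WLW"
        assert call.extension_nt == "TTATGATAA"
        # the extension re-translated ends in exactly one stop codon
        assert echinoderm.is_stop(call.extension_nt[-3:])
        res = translate(call.extension_nt, echinoderm)
        assert res.stop_position_nt == len(call.extension_nt) - 2

    def test_premature_stop_is_truncated_other(self, echinoderm, sl_pair):
        s_region, _ = sl_pair
        truncated = s_region[:30] + "TAA" + s_region[33:]
        call = classify_variant(truncated, echinoderm, reference_protein_length=162)
        assert call.variant_class == "other"
        assert "truncated" in call.notes

    def test_no_stop_flagged_not_raised(self, echinoderm):
        call = classify_variant("ATG" * 20, echinoderm, reference_protein_length=5)
        assert call.variant_class == "other"
        assert "no-stop" in call.notes

    def test_protein_length_difference_equals_extension(self, echinoderm):
        for seed in range(10):
            s, l = make_sl_pair(seed=seed, subst_rate=0.05)
            cs = classify_variant(s, echinoderm, 162)
            cl = classify_variant(l, echinoderm, 162)
            assert cl.protein_length_aa - cs.protein_length_aa == len(cl.extension_aa)


class TestLocalizeStopSwitch:
    def test_default_pair_gives_site_488_a_to_g(self, echinoderm, sl_pair):
        s, l = sl_pair
        site, ref, alt = localize_stop_switch(s, l, echinoderm)
        assert (site, ref, alt) == (488, "A", "G")
        assert site == 3 * 162 + 2  # middle base of stop codon 163

    def test_identical_sequences_ambiguous(self, echinoderm, sl_pair):
        s, _ = sl_pair
        with pytest.raises(AmbiguityError):
            localize_stop_switch(s, s, echinoderm)

    def test_two_planted_switches_listed(self, echinoderm):
        # two in-frame stops, both switched: candidates at both positions
        s = "ATGTAGAAATAGCCC"
        l = "ATGTGGAAATGGCCC"
        with pytest.raises(AmbiguityError) as err:
            localize_stop_switch(s, l, echinoderm)
        assert sorted(c[0] for c in err.value.candidates) == [5, 11]

    def test_matches_brute_force_on_random_pairs(self, echinoderm, rng):
        for _ in range(100):
            s, l = make_sl_pair(seed=int(rng.integers(2**31)))
            # sprinkle extra sense<->sense noise into the shared body
            l = list(l)
            for _ in range(3):
                i = int(rng.integers(0, 480))
                c0 = i - i % 3
                codon = "".join(l[c0 : c0 + 3])
                alt = "ACGT"[int(rng.integers(4))]
                cand = codon[: i - c0] + alt + codon[i - c0 + 1 :]
                if not echinoderm.is_stop(cand):
                    l[i] = alt
            l = "".join(l)
            oracle = brute_force_stop_switch(s, l, echinoderm)
            if len(oracle) == 1:
                site, _, _ = localize_stop_switch(s, l, echinoderm)
                assert site == oracle[0]
            else:
                with pytest.raises(AmbiguityError):
                    localize_stop_switch(s, l, echinoderm)


class TestComputeOverlap:
    def test_interval_intersection(self):
        a = GeneFeature("a", 100, 200, 1)
        b = GeneFeature("b", 150, 250, -1)
        assert compute_overlap(a, b, 1000) == 50

    def test_disjoint_is_zero(self):
        a = GeneFeature("a", 0, 100, 1)
        b = GeneFeature("b", 100, 200, -1)
        assert compute_overlap(a, b, 1000) == 0

    def test_symmetry_and_circular_shift_invariance(self, rng):
        n = 500
        for _ in range(50):
            s1, s2 = sorted(rng.integers(0, n, size=2))
            e1 = int(rng.integers(s1 + 1, n + 1))
            e2 = int(rng.integers(s2 + 1, n + 1))
            a = GeneFeature("a", int(s1), e1, 1)
            b = GeneFeature("b", int(s2), e2, 1)
            ov = compute_overlap(a, b, n, "circular")
            assert ov == compute_overlap(b, a, n, "circular")
            shift = int(rng.integers(1, n))

            def shifted(f):
                s, e = (f.start + shift) % n, (f.end - 1 + shift) % n + 1
                if s >= e:
                    return GeneFeature(f.gene_name, s, e % n, f.strand, True)
                return GeneFeature(f.gene_name, s, e, f.strand)

            assert compute_overlap(shifted(a), shifted(b), n, "circular") == ov


class TestScanCohort:
    def _cohort(self, n_s, n_l, echinoderm, seed=3, extra=None):
        s, l = make_sl_pair(seed=seed)
        seqs = [s] * n_s + [l] * n_l + (extra or [])
        return {"taxonA": seqs, "taxonB": [s]}

    def test_five_s_four_l(self, echinoderm):
        calls, states = scan_cohort(self._cohort(5, 4, echinoderm), echinoderm)
        counts = class_counts(calls)
        assert counts["S"] == 6 and counts["L"] == 4  # taxonB adds one S
        assert states["taxonA"] == {"S", "L"}
        assert states["taxonB"] == {"S"}

    def test_l_majority_cohort_keeps_short_reference(self, echinoderm):
        # 2 S vs 14 L: the S reference must remain the shorter form even
        # though the long form is modal
        calls, states = scan_cohort(self._cohort(2, 14, echinoderm), echinoderm)
        counts = class_counts(calls)
        assert counts["S"] == 3 and counts["L"] == 14
        lengths = {c.variant_class: c.protein_length_aa for c in calls}
        assert lengths["S"] == 162 and lengths["L"] == 165

    def test_extra_length_variant_flagged(self, echinoderm):
        s, l = make_sl_pair(seed=3)
        # an L variant two codons longer: the realized TAA is pushed 6 nt
        # downstream (extension codons 4-5 become sense before a new TAA)
        longer = l[:489] + "TTATGAAATGATTAA"
        cohort = {"taxonA": [s, l, l, longer], "taxonB": [s]}
        calls, _ = scan_cohort(cohort, echinoderm)
        flagged = [c for c in calls if "extra-length" in c.notes]
        assert len(flagged) == 1
        assert flagged[0].variant_class == "L"
        assert flagged[0].protein_length_aa == 167

    def test_all_identical_single_class(self, echinoderm):
        s, _ = make_sl_pair(seed=4)
        calls, states = scan_cohort({"a": [s, s], "b": [s]}, echinoderm)
        assert class_counts(calls) == {"S": 3}
        assert states["a"] == {"S"} and states["b"] == {"S"}

    def test_cohort_without_any_stop_raises(self, echinoderm):
        with pytest.raises(ValueError, match="well-formed"):
            scan_cohort({"a": "ATG" * 10, "b": "ATG" * 10}, echinoderm)

    def test_calls_annotated_with_shared_switch_site(self, echinoderm):
        calls, _ = scan_cohort(self._cohort(2, 2, echinoderm), echinoderm)
        for c in calls:
            if c.variant_class in "SL":
                assert c.stop_switch_site == 488
                assert (c.ref_allele, c.alt_allele) == ("A", "G")
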