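"""Variant/ASDP matching, the residual-variant algebra and region calls."""

import numpy as np
import pytest

from _oracles import symmetric_difference_oracle
from altloci.asdp_discovery import SMALL, SNV, SV, Asdp
from altloci.diplotype import (
    ALT_HET,
    ALT_HOM,
    REF_HOM,
    InferenceConfig,
    infer_region_genotype,
    match_variants_to_asdps,
    normalize_variant,
    residual_variants,
)
from altloci.io_formats import HET, HOM_ALT, MISSING, VariantCall


def _variant(pos, ref="A", alt="G", gt=HOM_ALT, chrom="chr7"):
    return VariantCall(chrom, pos, ref, alt, gt)


def _asdp(pos, ref="A", alt="G", chrom="chr7", locus="ACC_1", size_class=SMALL):
    return Asdp(chrom, pos, ref, alt, SNV, len(alt), size_class, locus, region_id="R1")


class TestNormalization:
    def test_suffix_and_prefix_trimming(self):
        assert normalize_variant("c", 100, "CAT", "CAG") == ("c", 102, "T", "G")
        assert normalize_variant("c", 100, "CT", "AT") == ("c", 100, "C", "A")

    def test_left_shift_through_anchor(self):
        #            123456789
        seq = "GGCATTTGG"
        # the same deletion of one A..T written right-anchored and left-anchored
        right = normalize_variant("c", 4, "AT", "T", seq=seq, seq_start=1)
        left = normalize_variant("c", 3, "CA", "C", seq=seq, seq_start=1)
        assert right == left

    def test_haplotype_equivalence_oracle(self):
        """Two representations normalize together iff applying them to the
        reference yields the same haplotype string."""
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        for _ in range(200):
            pos = int(rng.integers(5, 50))
            length = int(rng.integers(1, 4))
            deleted = seq[pos : pos + length]
            # canonical: (pos, anchor+deleted, anchor)
            a = (pos, seq[pos - 1] + deleted, seq[pos - 1])
            # right-shifted rewriting of the same deletion
            b = (pos + 1, deleted + seq[pos + length], seq[pos + length])

            def apply(p, ref, alt):
                assert seq[p - 1 : p - 1 + len(ref)] == ref
                return seq[: p - 1] + alt + seq[p - 1 + len(ref) :]

            if apply(*a) == apply(*b):
                na = normalize_variant("c", *a, seq=seq, seq_start=1)
                nb = normalize_variant("c", *b, seq=seq, seq_start=1)
                assert na == nb


class TestMatching:
    def test_exact_allele_match(self):
        matched = match_variants_to_asdps([_variant(1000)], [_asdp(1000)])
        assert len(matched) == 1

    def test_allele_mismatch_modes(self):
        R = [_variant(1000, "A", "G")]
        A = [_asdp(1000, "A", "T")]
        assert match_variants_to_asdps(R, A, "allele_exact") == []
        assert len(match_variants_to_asdps(R, A, "position_only")) == 1

    def test_one_to_one_matching(self):
        R = [_variant(1000), _variant(1000)]
        A = [_asdp(1000)]
        assert len(match_variants_to_asdps(R, A)) == 1

    def test_differently_anchored_indels_match(self):
        seq = "GGCATTTGG"
        R = [_variant(3, "CA", "C", gt=HET, chrom="c")]
        A = [_asdp(4, "AT", "T", chrom="c")]
        assert match_variants_to_asdps(R, A, seq=seq, seq_start=1)


class TestResidualVariants:
    def test_worked_eight_six_five_example(self):
        """|R| = 8, |A| = 6, 5 matched -> |RV| = 8 + 6 - 2*5 = 4."""
        shared_pos = [1000, 1100, 1200, 1300, 1400]
        R = [_variant(p) for p in shared_pos] + [
            _variant(2000), _variant(2100, "C", "T"), _variant(2200)
        ]
        A = [_asdp(p) for p in shared_pos] + [_asdp(3000)]
        rv = residual_variants(R, A)
        assert (rv.n_R, rv.n_A, rv.n_shared) == (8, 6, 5)
        assert rv.n_RV == 4
        assert rv.n_RV == rv.n_R + rv.n_A - 2 * rv.n_shared

    def test_empty_asdp_set_returns_all_calls(self):
        R = [_variant(1000), _variant(2000)]
        rv = residual_variants(R, [])
        assert rv.n_RV == 2 and rv.residual_asdps == []

    def test_fully_matched_sets_cancel(self):
        R = [_variant(1000), _variant(2000)]
        A = [_asdp(1000), _asdp(2000)]
        assert residual_variants(R, A).n_RV == 0

    def test_identity_against_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            pos_space = rng.integers(1, 40, size=rng.integers(0, 25))
            r_keys = [(int(p), "A", "G") for p in pos_space]
            a_keys = [
                (int(p), "A", "G")
                for p in rng.integers(1, 40, size=rng.integers(0, 25))
            ]
            R = [_variant(p, r, a) for p, r, a in r_keys]
            A = [_asdp(p, r, a) for p, r, a in a_keys]
            rv = residual_variants(R, A)
            shared, n_rv, _ = symmetric_difference_oracle(
                [("chr7",) + k for k in r_keys], [("chr7",) + k for k in a_keys]
            )
            assert rv.n_shared == shared
            assert rv.n_RV == n_rv == rv.n_R + rv.n_A - 2 * rv.n_shared

    def test_matching_monotonicity(self):
        A = [_asdp(1000), _asdp(2000)]
        R = [_variant(1000)]
        base = residual_variants(R, A).n_RV
        # adding a variant matching an unmatched ASDP lowers |RV| by one
        assert residual_variants(R + [_variant(2000)], A).n_RV == base - 1
        # adding a non-matching variant raises it by one
        assert residual_variants(R + [_variant(5000)], A).n_RV == base + 1


class TestGenotypeInference:
    def test_alt_present_when_rv_below_r(self):
        shared = [_variant(p) for p in (1, 2, 3, 4, 5)]
        R = shared + [_variant(10, "C", "A"), _variant(11, "C", "A"), _variant(12, "C", "A")]
        A = {"ACC_1": [_asdp(p) for p in (1, 2, 3, 4, 5, 9)]}
        gt = infer_region_genotype(R, A)
        assert gt.n_RV == 4 and gt.n_R == 8
        assert gt.call in (ALT_HET, ALT_HOM)
        assert gt.chosen_alt == "ACC_1"

    def test_no_matches_means_ref_hom(self):
        R = [_variant(100, "C", "A"), _variant(200, "C", "A")]
        A = {"ACC_1": [_asdp(500), _asdp(600)]}
        gt = infer_region_genotype(R, A)
        assert gt.call == REF_HOM and gt.chosen_alt is None
        assert gt.n_RV >= gt.n_R

    def test_decision_branches_are_exclusive(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n_shared = int(rng.integers(0, 8))
            n_r_only = int(rng.integers(0, 8))
            n_a_only = int(rng.integers(0, 8))
            R = [_variant(i) for i in range(1, n_shared + 1)] + [
                _variant(100 + i, "C", "T") for i in range(n_r_only)
            ]
            A = {"ACC_1": [_asdp(i) for i in range(1, n_shared + 1)]
                 + [_asdp(500 + i) for i in range(n_a_only)]}
            if not R and not A["ACC_1"]:
                continue
            gt = infer_region_genotype(R, A)
            if gt.n_R == 0:
                assert gt.call == REF_HOM and gt.low_evidence
            elif gt.call == REF_HOM:
                assert gt.n_RV >= gt.n_R
            else:
                assert gt.n_RV < gt.n_R

    def test_homozygosity_threshold_strict(self):
        # 10 matched variants, 9 homozygous: fraction 0.9 is NOT > 0.9
        R = [_variant(i, gt=HOM_ALT) for i in range(1, 10)] + [_variant(10, gt=HET)]
        A = {"ACC_1": [_asdp(i) for i in range(1, 11)]}
        assert infer_region_genotype(R, A).call == ALT_HET
        # all homozygous -> ALT_HOM
        R = [_variant(i, gt=HOM_ALT) for i in range(1, 11)]
        gt = infer_region_genotype(R, A)
        assert gt.call == ALT_HOM and gt.hom_fraction == 1.0

    def test_missing_genotypes_excluded_from_fraction(self):
        R = [_variant(1, gt=HOM_ALT), _variant(2, gt=MISSING), _variant(3, gt=HOM_ALT)]
        A = {"ACC_1": [_asdp(1), _asdp(2), _asdp(3)]}
        gt = infer_region_genotype(R, A)
        assert gt.call == ALT_HOM and gt.hom_fraction == 1.0

    def test_minimum_rv_locus_selected(self):
        R = [_variant(p) for p in (1, 2, 3, 4, 5)]
        A = {
            "ACC_B": [_asdp(p, locus="ACC_B") for p in (1, 2, 3, 4)],  # RV 1
            "ACC_A": [_asdp(p, locus="ACC_A") for p in (1, 9, 10, 11)],  # RV 7
        }
        gt = infer_region_genotype(R, A)
        assert gt.chosen_alt == "ACC_B"
        assert gt.n_RV == 1  # |R|=5, |A|=4, shared=4

    def test_locus_tie_broken_deterministically(self):
        R = [_variant(1), _variant(2)]
        A = {
            "ACC_Z": [_asdp(1, locus="ACC_Z"), _asdp(2, locus="ACC_Z")],
            "ACC_A": [_asdp(1, locus="ACC_A"), _asdp(2, locus="ACC_A")],
        }
        assert infer_region_genotype(R, A).chosen_alt == "ACC_A"

    def test_sv_asdps_excluded_by_default(self):
        R = [_variant(1)]
        sv = _asdp(50, "A", "G", size_class=SV)
        A = {"ACC_1": [_asdp(1), sv]}
        gt = infer_region_genotype(R, A)
        assert gt.n_A == 1  # SV removed from the inference set
        gt_sv = infer_region_genotype(R, A, InferenceConfig(include_sv=True))
        assert gt_sv.n_A == 2

    def test_zero_variant_region_low_evidence(self):
        A = {"ACC_1": [_asdp(1), _asdp(2)]}
        gt = infer_region_genotype([], A)
        assert gt.call == REF_HOM and gt.low_evidence and gt.n_RV == 2

    def test_region_without_loci_rejected(self):
        with pytest.raises(ValueError):
            infer_region_genotype([_variant(1)], {})
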