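"""Candidate event calling, the sliding-window filter, and VCF output."""

import numpy as np
import pytest

from _oracles import window_filter_oracle
from altloci.align_refine import PairwiseAlignment, trim_to_variable_region
from altloci.asdp_discovery import (
    BLOCK_SUBSTITUTION,
    DELETION,
    INSERTION,
    SNV,
    SMALL,
    SV,
    Asdp,
    asdps_to_vcf,
    call_candidate_asdps,
    discover_asdps,
    high_confidence_filter,
    read_asdp_vcf,
)
from altloci.diplotype import normalize_variant
from altloci.io_formats import RegionInfo
from altloci.synth import SimSpec, generate_region_pair

GAP = None


def _region(length=10000, start=1, chrom="chr7"):
    return RegionInfo("R1", chrom, start, start + length - 1, ["ACC_1"], {"ACC_1": "+"})


def _aln(cols, ref_offset=0):
    return PairwiseAlignment(columns=cols, ref_offset=ref_offset)


class TestCandidateCalling:
    def test_single_mismatch_is_snv(self):
        cols = [("A", "A")] * 7 + [("A", "G")] + [("C", "C")] * 5
        # trimmed input starts at the first difference
        trimmed = trim_to_variable_region(_aln(cols, ref_offset=0))
        asdps = call_candidate_asdps(trimmed, _region(start=100), "ACC_1")
        assert len(asdps) == 1
        a = asdps[0]
        assert (a.pos, a.ref_allele, a.alt_allele) == (107, "A", "G")
        assert a.category == SNV and a.size_class == SMALL and a.event_size == 1

    def test_deletion_gets_anchor_base(self):
        cols = (
            [("T", "G")]  # leading difference so the alignment is trimmed-form
            + [("C", "C")] * 4
            + [("A", GAP), ("G", GAP), ("T", GAP)]
            + [("C", "C")] * 3
            + [("T", "A")]
        )
        asdps = call_candidate_asdps(_aln(cols), _region(), "ACC_1")
        deletion = asdps[1]
        assert deletion.category == DELETION
        assert len(deletion.ref_allele) == 4 and deletion.alt_allele == "C"
        assert deletion.event_size == 3
        assert deletion.pos == 5  # anchor = last matching base before the run

    def test_sixty_base_insertion_is_sv_class(self):
        cols = [("G", "C")] + [("A", "A")] * 4 + [(GAP, "T")] * 60 + [("C", "G")]
        asdps = call_candidate_asdps(_aln(cols), _region(), "ACC_1")
        ins = asdps[1]
        assert ins.category == INSERTION
        assert ins.event_size == 60 and ins.size_class == SV

    def test_two_adjacent_mismatches_are_block_substitution(self):
        cols = [("A", "C"), ("G", "T")] + [("A", "A")] * 3
        asdps = call_candidate_asdps(_aln(cols), _region(), "ACC_1")
        assert len(asdps) == 1
        a = asdps[0]
        assert a.category == BLOCK_SUBSTITUTION
        assert (a.ref_allele, a.alt_allele, a.event_size) == ("AG", "CT", 2)

    def test_leading_indel_uses_following_anchor(self):
        cols = [(GAP, "T"), (GAP, "T")] + [("A", "A")] * 5 + [("G", "C")]
        asdps = call_candidate_asdps(_aln(cols), _region(), "ACC_1")
        ins = asdps[0]
        assert ins.category == INSERTION
        assert ins.ref_allele == "A" and ins.alt_allele == "TTA"

    def test_mixed_run_classified_by_allele_lengths(self):
        cols = [("A", "C"), ("G", GAP), ("T", GAP)] + [("A", "A")] * 3
        asdps = call_candidate_asdps(_aln(cols), _region(), "ACC_1")
        assert len(asdps) == 1
        a = asdps[0]
        assert a.category == DELETION  # ref side longer
        assert (a.ref_allele, a.alt_allele) == ("AGT", "C")

    def test_alignment_beyond_region_rejected(self):
        cols = [("A", "C")] * 100
        with pytest.raises(ValueError):
            call_candidate_asdps(_aln(cols), _region(length=50), "ACC_1")


def _random_alignment(rng, n):
    """Random column list with clustered discrepancies."""
    cols = []
    i = 0
    while i < n:
        if rng.random() < 0.1:
            burst = int(rng.integers(1, 20))
            for _ in range(min(burst, n - i)):
                r = rng.random()
                if r < 0.4:
                    cols.append(("A", "G"))
                elif r < 0.7:
                    cols.append(("A", GAP))
                else:
                    cols.append((GAP, "C"))
                i += 1
        else:
            cols.append(("T", "T"))
            i += 1
    return cols


def _runs(cols):
    runs, i = [], 0
    while i < len(cols):
        r, a = cols[i]
        if r is None or a is None or r != a:
            s = i
            while i < len(cols) and (cols[i][0] is None or cols[i][1] is None or cols[i][0] != cols[i][1]):
                i += 1
            runs.append((s, i))
        else:
            i += 1
    return runs


class TestWindowFilter:
    def test_isolated_mismatch_kept(self):
        cols = [("A", "A")] * 100
        cols[50] = ("A", "G")
        aln = _aln(cols)
        cand = [Asdp("c", 51, "A", "G", SNV, 1, SMALL, "x", columns=(50, 51))]
        kept = high_confidence_filter(cand, aln)
        assert kept == cand and cand[0].high_confidence

    def test_dense_cluster_fully_excluded(self):
        cols = [("A", "A")] * 200
        positions = list(range(80, 110, 3)) + [82]  # 11 mismatches in 30 columns
        for p in positions:
            cols[p] = ("A", "G")
        aln = _aln(cols)
        cand = [
            Asdp("c", p + 1, "A", "G", SNV, 1, SMALL, "x", columns=(p, p + 1))
            for p in sorted(set(positions))
        ]
        kept = high_confidence_filter(cand, aln)
        assert kept == []
        assert all(not c.high_confidence for c in cand)

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(20, 2000))
            cols = _random_alignment(rng, n)
            runs = _runs(cols)
            cand = [
                Asdp("c", s + 1, "N", "M", SNV, 1, SMALL, "x", columns=(s, e))
                for s, e in runs
            ]
            kept = high_confidence_filter(cand, _aln(cols))
            disc = [r is None or a is None or r != a for r, a in cols]
            expected = window_filter_oracle(runs, disc, 50, 10)
            assert [c.high_confidence for c in cand] == expected
            assert kept == [c for c, keep in zip(cand, expected) if keep]

    def test_anti_monotone_in_max_disc(self):
        rng = np.random.default_rng(7)
        cols = _random_alignment(rng, 800)
        runs = _runs(cols)
        previous = None
        for max_disc in range(0, 25, 4):
            cand = [
                Asdp("c", s + 1, "N", "M", SNV, 1, SMALL, "x", columns=(s, e))
                for s, e in runs
            ]
            kept = {c.columns for c in high_confidence_filter(cand, _aln(cols), 50, max_disc)}
            if previous is not None:
                assert previous <= kept  # raising the budget never removes an ASDP
            previous = kept

    def test_short_alignment_single_window(self):
        cols = [("A", "G")] * 12 + [("C", "C")] * 10  # 12 > 10 in the only window
        cand = [Asdp("c", 1, "N", "M", SNV, 1, SMALL, "x", columns=(0, 12))]
        assert high_confidence_filter(cand, _aln(cols)) == []


class TestVcfOutput:
    def test_round_trip_with_info_keys(self, tmp_path, default_region):
        sim = default_region
        asdps = discover_asdps(
            sim.ref_seq, sim.alt_seq, sim.blocks, sim.region, sim.region.alt_accessions[0]
        )
        path = tmp_path / "asdps.vcf"
        asdps_to_vcf(asdps, {sim.region.chrom: sim.ref_seq}, path)
        back = read_asdp_vcf(path)
        assert [(a.pos, a.ref_allele, a.alt_allele, a.category, a.high_confidence) for a in back] == [
            (a.pos, a.ref_allele, a.alt_allele, a.category, a.high_confidence)
            for a in sorted(asdps, key=lambda a: a.pos)
        ]

    def test_same_position_two_loci_kept_separate(self, tmp_path):
        asdps = [
            Asdp("chr7", 5, "A", "G", SNV, 1, SMALL, "ACC_1", region_id="R1"),
            Asdp("chr7", 5, "A", "T", SNV, 1, SMALL, "ACC_2", region_id="R1"),
        ]
        path = tmp_path / "two.vcf"
        asdps_to_vcf(asdps, {"chr7": "CCCCATTTT"}, path)
        back = read_asdp_vcf(path)
        assert len(back) == 2
        assert {a.alt_locus for a in back} == {"ACC_1", "ACC_2"}
        assert len({a.pos for a in back}) == 1

    def test_reference_mismatch_names_position(self, tmp_path):
        asdps = [Asdp("chr7", 5, "A", "G", SNV, 1, SMALL, "ACC_1")]
        with pytest.raises(ValueError, match="chr7:5"):
            asdps_to_vcf(asdps, {"chr7": "CCCCCTTTT"}, tmp_path / "bad.vcf")

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        asdps_to_vcf([], {"chr7": "ACGT"}, path)
        assert read_asdp_vcf(path) == []


class TestEndToEndDiscovery:
    def test_recovers_planted_events_exactly(self):
        """Well-spaced small events are recovered with position, allele and
        category intact (after left-normalization of the representation)."""
        for seed in (3, 4, 5):
            sim = generate_region_pair(SimSpec(rng_seed=seed))
            found = discover_asdps(
                sim.ref_seq,
                sim.alt_seq,
                sim.blocks,
                sim.region,
                sim.region.alt_accessions[0],
            )
            hc = [a for a in found if a.high_confidence]

            def norm(a):
                return normalize_variant(
                    a.chrom, a.pos, a.ref_allele, a.alt_allele, sim.ref_seq, 1
                )

            assert sorted(norm(a) for a in hc) == sorted(norm(t) for t in sim.truth)
            assert {a.category for a in hc} == {t.category for t in sim.truth}

    def test_category_counts_partition_total(self, sv_region):
        sim = sv_region
        found = discover_asdps(
            sim.ref_seq, sim.alt_seq, sim.blocks, sim.region, sim.region.alt_accessions[0]
        )
        by_cat = {}
        for a in found:
            by_cat[a.category] = by_cat.get(a.category, 0) + 1
        assert sum(by_cat.values()) == len(found)
        assert set(by_cat) <= {SNV, DELETION, INSERTION, BLOCK_SUBSTITUTION}
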