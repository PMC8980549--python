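import itertools

import numpy as np
import pytest

from founderage import (
    MISSING,
    block_theta,
    derive_family_events,
    find_shared_core,
    infer_founder,
    partition_blocks,
    segment_lengths,
    sharing_counts,
)
from founderage.haplotype import collapse_families

from conftest import make_map, make_matrix

# expected study structure (block label -> (n_markers, theta, sharing))
STUDY_BLOCKS = [
    ("rs12403629", 10, 0.01242, 4),
    ("rs345292", 13, 0.01068, 6),
    ("rs17020437", 6, 0.01009, 8),
    ("rs12034547", 8, 0.00858, 10),
    ("rs1333130", 24, 0.00130, 14),
    ("CLCC1-MUTATION", 9, 0.0, 18),
    ("rs587727", 2, 0.00192, 16),
    ("rs17014495", 17, 0.00221, 12),
    ("rs12239350", 4, 0.00828, 6),
    ("rs11102121", 2, 0.01522, 2),
]


class TestSharedCore:
    def test_study_core_is_nine_markers(self, study):
        marker_map, matrix = study
        core = find_shared_core(matrix, marker_map)
        assert len(core) == 9
        assert marker_map.rsids[core.start] == "rs10857972"
        assert marker_map.rsids[core.stop - 1] == "rs570812"
        assert marker_map.focal_index in core

    def test_widening_core_breaks_identity(self, study):
        marker_map, matrix = study
        core = find_shared_core(matrix, marker_map)
        for edge in (core.start - 1, core.stop):
            seen = {a for a in matrix.alleles[:, edge] if a != MISSING}
            assert len(seen) > 1

    def test_identical_matrix_gives_full_range(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "ATG"})
        assert find_shared_core(matrix, mm) == range(0, 3)

    def test_discordant_flanks_give_singleton_core(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "CTA"})
        assert find_shared_core(matrix, mm) == range(1, 2)

    def test_missing_is_compatible(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "-T-"})
        assert find_shared_core(matrix, mm) == range(0, 3)


def brute_force_founders(matrix, marker_map):
    """Oracle: all founder assignments (over alleles seen per column)
    minimizing the total number of recombination events, where a family
    needs one event per side on which it mismatches the founder."""
    fams = collapse_families(matrix)
    focal = marker_map.focal_index
    n = matrix.n_markers
    choices = []
    for i in range(n):
        seen = sorted({a for a in matrix.alleles[:, i] if a != MISSING})
        choices.append(seen or ["N"])

    def events(founder):
        total = 0
        for hap in fams.alleles:
            mism = [
                i
                for i in range(n)
                if hap[i] != MISSING and hap[i] != founder[i]
            ]
            total += any(i < focal for i in mism) + any(
                i > focal for i in mism
            )
        return total

    best, best_set = None, []
    for cand in itertools.product(*choices):
        e = events(cand)
        if best is None or e < best:
            best, best_set = e, [cand]
        elif e == best:
            best_set.append(cand)
    return best, best_set


class TestInferFounder:
    def test_unanimous_column_full_support(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "ATG", "F3": "ATG"})
        founder = infer_founder(matrix, mm)
        assert founder.alleles == ["A", "T", "G"]
        assert (founder.support == 6).all()

    def test_study_support_at_rs17014495(self, study, study_founder):
        marker_map, _ = study
        _, founder = study_founder
        i = marker_map.index_of("rs17014495")
        assert founder.allele(i) == "C"
        assert founder.support[i] == 12

    def test_support_non_increasing_outward(self, study, study_founder):
        marker_map, _ = study
        core, founder = study_founder
        left = founder.support[: core.start + 1]
        right = founder.support[core.stop - 1 :]
        assert (np.diff(left) >= 0).all()  # increases toward the core
        assert (np.diff(right) <= 0).all()
        assert (founder.support[core.start : core.stop] == 18).all()

    def test_recovers_planted_founder_minimizing_events(self):
        # three families, one planted recombination each, 7 markers;
        # brute-force enumeration is the independent oracle
        mm = make_map([100 + 1000 * i for i in range(7)], focal_pos=3100)
        planted = "ACGTACG"
        matrix = make_matrix(
            {
                "F1": "TTGTACG",  # left event before marker 2
                "F2": "ACGTAAT",  # right event after marker 4
                "F3": "ACGTACG",  # no event... keep founder
            }
        )
        best, best_set = brute_force_founders(matrix, mm)
        founder = infer_founder(matrix, mm)
        assert tuple(founder.alleles) in best_set
        assert "".join(founder.alleles) == planted

    def test_minimal_events_matches_brute_force_on_toys(self):
        # 4-marker toys: total events of the inferred founder equals the
        # brute-force minimum
        mm = make_map([100, 1100, 2100, 3100], focal_pos=1100)
        for haps in (
            {"F1": "ACGT", "F2": "TCGA", "F3": "ACAT"},
            {"F1": "ACGT", "F2": "TCAT", "F3": "TCAT"},
            {"F1": "GCTT", "F2": "GCTA", "F3": "ACTT"},
        ):
            matrix = make_matrix(haps)
            best, _ = brute_force_founders(matrix, mm)
            founder = infer_founder(matrix, mm)
            total = sum(
                d.n_events for d in derive_family_events(matrix, founder, mm)
            )
            assert total == best

    def test_study_tie_markers_flagged(self, study, study_founder):
        marker_map, _ = study
        _, founder = study_founder
        # the 6-6 split at rs12239350 is a genuine plurality tie resolved
        # by the distinct-lineage rule
        assert marker_map.index_of("rs12239350") in founder.tie_indices


class TestPartition:
    def test_study_block_structure(self, study, study_partition):
        marker_map, _ = study
        got = [
            (b.label_rsid, b.n_markers, round(b.theta, 5), b.shared_chromosomes)
            for b in study_partition.blocks
        ]
        assert got == STUDY_BLOCKS

    def test_study_tail_markers(self, study, study_partition):
        marker_map, _ = study
        tails = [marker_map.rsids[i] for i in study_partition.tail_indices]
        assert tails == [
            "rs11102065",
            "rs752653894",
            "rs61787370",
            "rs1030926216",
        ]

    def test_theta_from_positions(self, study, study_partition):
        marker_map, _ = study
        b = study_partition.by_label("rs1333130")
        assert b.theta == pytest.approx((108_950_376 - 108_820_610) * 1e-8)
        assert block_theta(b, marker_map) == b.theta

    def test_single_chromosome_single_block(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG"})
        founder = infer_founder(matrix, mm)
        partition = partition_blocks(matrix, mm, founder)
        assert len(partition.blocks) == 1
        assert partition.blocks[0].member_markers == range(0, 3)

    def test_planted_breakpoints_set_boundaries(self):
        # founder AAAA...; F2 diverges left of marker 1, F3 right of
        # marker 5; boundaries must fall at the planted intervals
        mm = make_map([100 + 1000 * i for i in range(7)], focal_pos=3100)
        matrix = make_matrix(
            {
                "F1": "AAAAAAA",
                "F2": "CCAAAAA",
                "F3": "AAAAACC",
                "F4": "AAAAAAA",
                "F5": "AAAAAAA",
            }
        )
        founder = infer_founder(matrix, mm)
        partition = partition_blocks(matrix, mm, founder)
        spans = sorted(
            (b.start, b.stop) for b in partition.blocks
        )
        assert spans == [(0, 1), (2, 4), (5, 6)]


class TestSharing:
    def test_study_counts(self, study, study_founder, study_partition):
        marker_map, matrix = study
        _, founder = study_founder
        counts = sharing_counts(matrix, founder, study_partition, marker_map)
        assert counts == [4, 6, 8, 10, 14, 18, 16, 12, 6, 2]

    def test_focal_block_equals_total(self, study, study_partition):
        assert study_partition.focal_block.shared_chromosomes == 18

    def test_non_increasing_outward(self, study, study_partition):
        focal_i = next(
            i for i, b in enumerate(study_partition.blocks) if b.is_focal
        )
        counts = [b.shared_chromosomes for b in study_partition.blocks]
        assert counts[: focal_i + 1] == sorted(counts[: focal_i + 1])
        assert counts[focal_i:] == sorted(counts[focal_i:], reverse=True)


class TestFamilyEvents:
    def test_study_event_counts(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        events = {
            d.family_id: d.n_events
            for d in derive_family_events(matrix, founder, marker_map)
        }
        assert events["61224"] == 0
        assert events["61244"] == 1
        assert max(events.values()) <= 2
        # 7 families with two events, one with one, one with none
        assert sorted(events.values()) == [0, 1] + [2] * 7

    def test_study_shared_ancestor_groups(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        derivs = derive_family_events(matrix, founder, marker_map)
        groups = {}
        for d in derivs:
            if d.shared_ancestor_group:
                groups.setdefault(d.shared_ancestor_group, set()).add(
                    d.family_id
                )
        assert sorted(groups.values(), key=sorted) == [
            {"61030", "61334"},
            {"61031", "61328"},
            {"FAM2", "FAM3"},
        ]

    def test_n_events_counts_breakpoints(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        for d in derive_family_events(matrix, founder, marker_map):
            assert d.n_events == (d.left_breakpoint is not None) + (
                d.right_breakpoint is not None
            )
            assert d.level == d.n_events

    def test_focal_mismatch_raises(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "ATG"})
        founder = infer_founder(matrix, mm)
        founder.alleles[1] = "C"  # corrupt the focal allele
        with pytest.raises(ValueError, match="focal"):
            derive_family_events(matrix, founder, mm)

    def test_within_family_discordance_reported(self):
        mm = make_map([100, 200, 300], focal_pos=200)
        matrix = make_matrix({"F1": "ATG", "F2": "ATG"})
        matrix.alleles[1, 0] = "G"  # F1-b disagrees with F1-a at marker 0
        founder = infer_founder(matrix, mm)
        derivs = derive_family_events(matrix, founder, mm)
        errors = {d.family_id: d.data_errors for d in derivs}
        assert errors["F1"] == ["m0"]


class TestSegmentLengths:
    def test_family_61224_censored_both_sides(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        seg = segment_lengths(matrix, founder, marker_map)
        k = matrix.chromosome_labels.index("61224-a")
        assert seg.left_censored[k] and seg.right_censored[k]
        # censored at the outermost genotyped markers
        assert seg.left[k] == pytest.approx(
            (108_950_376 - 107_600_949) * 1e-8
        )
        assert seg.right[k] == pytest.approx(
            (111_136_919 - 108_950_376) * 1e-8
        )

    def test_flanking_divergence_gives_half_intervals(self):
        mm = make_map([100, 1_000_100, 2_000_100], focal_pos=1_000_100)
        matrix = make_matrix({"F1": "ATG", "F2": "ATG", "F3": "CTA"})
        founder = infer_founder(matrix, mm)
        assert founder.alleles == ["A", "T", "G"]
        seg = segment_lengths(matrix, founder, mm)
        diverged = ~(seg.left_censored | seg.right_censored)
        assert diverged.sum() == 2  # the two F3 chromosomes
        for k in np.nonzero(diverged)[0]:
            assert seg.left[k] == pytest.approx(0.005)  # half of 1 cM
            assert seg.right[k] == pytest.approx(0.005)

    def test_censoring_conventions_ordered(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        mid = segment_lengths(matrix, founder, marker_map, "midpoint")
        last = segment_lengths(matrix, founder, marker_map, "last-match")
        first = segment_lengths(matrix, founder, marker_map, "first-mismatch")
        unc = ~mid.censored
        assert (last.lengths[unc] <= mid.lengths[unc] + 1e-15).all()
        assert (mid.lengths[unc] <= first.lengths[unc] + 1e-15).all()

    def test_unknown_convention_rejected(self, study, study_founder):
        marker_map, matrix = study
        _, founder = study_founder
        with pytest.raises(ValueError):
            segment_lengths(matrix, founder, marker_map, "nearest")
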