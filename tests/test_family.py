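"""Motif parsing/scanning, local-alignment identity, and family calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapkkk.family import (
    SUBFAMILY_PATTERNS,
    FamilyAssignment,
    FamilyCallParams,
    MotifParseError,
    align_identity,
    chromosome_distribution,
    classify_subfamily,
    identify_family,
    pairwise_identity,
    parse_motif_pattern,
    scan_motif,
)

from oracles import gotoh_identities, gotoh_local, naive_motif_scan

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


class TestMotifParsing:
    def test_zik_pattern_structure(self):
        pat = parse_motif_pattern("GTPEFMAPE (L/V) (Y/F)", label="ZIK")
        assert len(pat) == 11
        assert [len(e) for e in pat.elements[:9]] == [1] * 9
        assert pat.elements[9] == frozenset("LV")
        assert pat.elements[10] == frozenset("YF")

    def test_raf_pattern_wildcards(self):
        pat = parse_motif_pattern("GTxx (W/Y) MAPE")
        assert len(pat) == 9
        assert pat.elements[2] is None and pat.elements[3] is None
        assert pat.elements[4] == frozenset("WY")

    def test_round_trip_to_canonical_text(self):
        for text in ["GTPEFMAPE(L/V)(Y/F)", "G(T/S)Px(W/F)MAPEV", "GTxx(W/Y)MAPE"]:
            pat = parse_motif_pattern(text)
            again = parse_motif_pattern(pat.to_text())
            assert again.elements == pat.elements

    @pytest.mark.parametrize(
        "bad", ["G(T/)PX", "G(TS", "G)T", "G(/T)P", "GT1PE", "G(T/S"]
    )
    def test_malformed_patterns_rejected_with_position(self, bad):
        with pytest.raises(MotifParseError, match="position"):
            parse_motif_pattern(bad)


class TestMotifScan:
    def test_raf_literal_instantiation(self):
        raf = next(p for p in SUBFAMILY_PATTERNS if p.label == "Raf")
        assert scan_motif("MGTQKWMAPEL", raf) == [1]

    def test_zik_alternative_membership(self):
        zik = next(p for p in SUBFAMILY_PATTERNS if p.label == "ZIK")
        assert scan_motif("GTPEFMAPELY", zik) == [0]
        assert scan_motif("GTPEFMAPEKY", zik) == []

    def test_mekk_alternatives_satisfied(self):
        mekk = next(p for p in SUBFAMILY_PATTERNS if p.label == "MEKK")
        assert scan_motif("GSPAFMAPEV", mekk) == [0]

    def test_sequence_shorter_than_pattern_gives_no_hits(self):
        assert scan_motif("GTP", SUBFAMILY_PATTERNS[0]) == []

    def test_agrees_with_naive_matcher_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = random_protein(rng, 60)
            pat = SUBFAMILY_PATTERNS[int(rng.integers(3))]
            assert scan_motif(seq, pat) == naive_motif_scan(seq, pat.elements)


class TestClassifySubfamily:
    def test_planted_motif_classifies(self):
        rng = np.random.default_rng(2)
        base = random_protein(rng, 80)
        seq = base[:30] + "GSPAFMAPEV" + base[40:]
        assert classify_subfamily(seq) == {"MEKK"}

    def test_motif_free_sequence_unclassified(self):
        # poly-A cannot contain any signature motif
        assert classify_subfamily("A" * 100) == set()


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0

    def test_no_positive_alignment_gives_zero(self):
        # A/C scores 0 in BLOSUM62: optimal local alignment is empty
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKT")

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(20, 60)))
            b = random_protein(rng, int(rng.integers(20, 60)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_matches_dp_oracle_on_random_pairs(self):
        """Score equals an independent Gotoh DP; identity is attained by a
        co-optimal alignment of that DP."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(25, 50)))
            b = random_protein(rng, int(rng.integers(25, 50)))
            ident, span = align_identity(a, b)
            # canonical ordering used by the implementation
            x, y = (a, b) if a <= b else (b, a)
            best, _ = gotoh_local(x, y)
            options = gotoh_identities(x, y)
            assert (
                best <= 0
                and (ident, span) == (0.0, 0)
                or any(
                    length == span and matches / length == ident
                    for matches, length in options
                    if length
                )
            )


class TestIdentifyFamily:
    def test_candidate_identical_to_queries_is_member(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        queries = {f"q{i}": seq for i in range(6)}
        res = identify_family({"c": seq}, queries)
        assert res[0].qualifying_hit_count == 6
        assert res[0].is_member

    def test_four_hits_below_min_five_not_member(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        rng = np.random.default_rng(3)
        queries = {f"q{i}": seq for i in range(4)}
        queries["far"] = "".join(
            rng.choice(list("ACDE"), size=len(seq))
        )  # unrelated composition
        res = identify_family({"c": seq}, queries)
        assert res[0].qualifying_hit_count == 4
        assert not res[0].is_member

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(9)
        base = random_protein(rng, 120)
        queries = {f"q{i}": random_protein(rng, 120) for i in range(3)}
        queries["near"] = base[:100] + random_protein(rng, 20)
        lo = identify_family({"c": base}, queries, FamilyCallParams(0.2, 1))
        hi = identify_family({"c": base}, queries, FamilyCallParams(0.6, 1))
        assert hi[0].qualifying_hit_count <= lo[0].qualifying_hit_count

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            identify_family({"c": "MKT"}, {})


class TestChromosomeDistribution:
    def test_empty_input(self):
        assert chromosome_distribution([]) == {}

    def test_counts_members_only_and_unknown_bucket(self):
        assigns = [
            FamilyAssignment("a", 5, True, set(), "1"),
            FamilyAssignment("b", 5, True, set(), "1"),
            FamilyAssignment("c", 6, True, set(), "1"),
            FamilyAssignment("d", 5, True, set(), "unknown"),
            FamilyAssignment("e", 0, False, set(), "2"),
        ]
        assert chromosome_distribution(assigns) == {"1": 3, "unknown": 1}

    @given(
        st.lists(
            st.tuples(st.booleans(), st.sampled_from(["1", "2", "3", "unknown"])),
            max_size=30,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_counts_sum_to_member_total(self, flags):
        assigns = [
            FamilyAssignment(f"c{i}", 5 if m else 0, m, set(), chrom)
            for i, (m, chrom) in enumerate(flags)
        ]
        dist = chromosome_distribution(assigns)
        assert sum(dist.values()) == sum(m for m, _ in flags)
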