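"""Center-star alignment, homogeneity grouping and primer construction."""

import itertools

import numpy as np
import pytest

from trna_anchor.consensus import (
    GROUP1_CONSENSUS,
    GROUP2_CONSENSUS,
    M13_TAIL,
    PCOF1_CORE,
    TRWF1_RESOLUTION,
    AlignedBlock,
    PrimerSpec,
    center_star_msa,
    degenerate_consensus,
    derive_rescue_primer,
    design_primer,
    partition_groups,
    primer_tm,
    trwf1,
    trwf2,
)
from trna_anchor.iupac import degeneracy, expansions

from conftest import expand_uniform, random_iupac


def _edit_distance_oracle(a: str, b: str) -> int:
    """Plain DP edit distance, independent of the alignment code."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestCenterStar:
    def test_identical_pair_gap_free(self):
        block = center_star_msa(["ACGTACGT", "ACGTACGT"])
        assert block.rows == ["ACGTACGT", "ACGTACGT"]

    def test_single_gap_alignment_matches_dp_oracle(self):
        block = center_star_msa(["ACGT", "AGT"])
        assert block.n_columns == 4
        gaps = sum(r.count("-") for r in block.rows)
        assert gaps == _edit_distance_oracle("ACGT", "AGT") == 1
        matches = sum(
            a == b and a != "-" for a, b in zip(block.rows[0], block.rows[1])
        )
        assert matches == 3

    def test_equal_length_expansions_align_gap_free(self):
        rng = np.random.default_rng(5)
        seqs = [expand_uniform(GROUP1_CONSENSUS, rng) for _ in range(30)]
        block = center_star_msa(seqs)
        assert block.n_columns == 19
        assert all("-" not in r for r in block.rows)

    def test_alignment_preserves_sequences(self):
        rng = np.random.default_rng(6)
        seqs = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, size=rng.integers(20, 40)))
            for _ in range(10)
        ]
        block = center_star_msa(seqs)
        assert [r.replace("-", "") for r in block.rows] == seqs

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            center_star_msa(["ACGT"])


class TestPartition:
    def test_planted_two_group_split_92_28(self):
        rng = np.random.default_rng(9)
        seqs = [expand_uniform(GROUP1_CONSENSUS, rng) for _ in range(92)]
        seqs += [expand_uniform(GROUP2_CONSENSUS, rng) for _ in range(28)]
        ids = [f"g1_{i}" for i in range(92)] + [f"g2_{i}" for i in range(28)]
        block = center_star_msa(seqs, ids)
        groups = partition_groups(block, identity_threshold=0.75)
        assert [len(g.member_ids) for g in groups] == [92, 28]
        assert set(groups[0].member_ids) == {f"g1_{i}" for i in range(92)}
        assert set(groups[1].member_ids) == {f"g2_{i}" for i in range(28)}

    def test_identical_rows_single_group(self):
        block = AlignedBlock(["a", "b", "c"], ["ACGTACGTACGTACGTACG"] * 3)
        groups = partition_groups(block)
        assert len(groups) == 1
        assert sorted(groups[0].member_ids) == ["a", "b", "c"]

    def test_threshold_one_with_variation_gives_singletons(self):
        rows = ["AAAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAAT", "AAAAAAAAAAAAAAAAATT"]
        groups = partition_groups(
            AlignedBlock(["a", "b", "c"], rows), identity_threshold=1.0
        )
        assert [len(g.member_ids) for g in groups] == [1, 1, 1]

    def test_partition_is_order_invariant_partition(self):
        rng = np.random.default_rng(13)
        seqs = [expand_uniform(GROUP1_CONSENSUS, rng) for _ in range(12)]
        seqs += [expand_uniform(GROUP2_CONSENSUS, rng) for _ in range(6)]
        ids = [f"s{i}" for i in range(18)]
        block = center_star_msa(seqs, ids)
        base = partition_groups(block)
        seen = [m for g in base for m in g.member_ids]
        assert sorted(seen) == sorted(ids)  # a partition: each id exactly once
        perm = list(rng.permutation(18))
        block2 = center_star_msa([seqs[i] for i in perm], [ids[i] for i in perm])
        shuffled = partition_groups(block2)
        assert {frozenset(g.member_ids) for g in base} == {
            frozenset(g.member_ids) for g in shuffled
        }

    def test_empty_window_rejected(self):
        block = AlignedBlock(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            partition_groups(block, window=(2, 2))


class TestDegenerateConsensus:
    def test_roundtrip_uniform_expansion_of_printed_consensus(self):
        rows = list(expansions(GROUP1_CONSENSUS))
        cons = degenerate_consensus(rows, min_freq=0.0)
        assert cons.iupac == GROUP1_CONSENSUS

    def test_roundtrip_200_random_iupac_strings(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            s = random_iupac(rng, int(rng.integers(1, 31)), max_degeneracy=256)
            assert degenerate_consensus(list(expansions(s)), min_freq=0.0).iupac == s

    def test_identical_rows_return_that_sequence(self):
        assert degenerate_consensus(["ACGT", "ACGT"]).iupac == "ACGT"

    def test_two_rows_differing_a_g_give_r(self):
        assert degenerate_consensus(["AAG", "AGG"], min_freq=0.0).iupac == "ARG"

    def test_n_counts_quarter_toward_each_base(self):
        # N + three A rows: A freq 0.8125, others 0.0625; min_freq 0.1 -> A
        cons = degenerate_consensus(["N", "A", "A", "A"], min_freq=0.1)
        assert cons.iupac == "A"
        assert cons.freq[0]["A"] == pytest.approx(0.8125)

    def test_all_gap_column_raises(self):
        with pytest.raises(ValueError, match="column 1"):
            degenerate_consensus(["A-A", "A-A"], min_freq=0.0)

    def test_min_freq_drops_rare_base(self):
        rows = ["A"] * 19 + ["G"]
        assert degenerate_consensus(rows, min_freq=0.1).iupac == "A"
        assert degenerate_consensus(rows, min_freq=0.0).iupac == "R"


class TestDesignPrimer:
    def test_trwf1_reproduced_from_group1_consensus(self):
        p = trwf1()
        assert p.core == "AAACTAATARCCTTCAAAG"
        assert p.tail == M13_TAIL
        assert p.degeneracy == 2
        assert p.three_prime_base == "G"
        assert p.full_oligo == M13_TAIL + "AAACTAATARCCTTCAAAG"

    def test_trwf2_reproduced_with_3prime_extension(self):
        p = trwf2()
        assert p.core == "AAACTAATAATYTTCAAAATTA"
        assert p.degeneracy == 2

    def test_degeneracies_by_brute_force_expansion(self):
        for core in (trwf1().core, trwf2().core, PCOF1_CORE):
            assert len(list(expansions(core))) == 2

    def test_non_degenerate_consensus_verbatim(self):
        p = design_primer("ACGTACGTAA", prefer_3prime_GC=False)
        assert p.core == "ACGTACGTAA"
        assert p.degeneracy == 1

    def test_gc_3prime_trims_to_rightmost_strong_base(self):
        p = design_primer("ACGTACGTAA", prefer_3prime_GC=True)
        assert p.core == "ACGTACG"
        assert p.three_prime_base == "G"

    def test_resolution_base_must_belong_to_code(self):
        with pytest.raises(ValueError, match="not in code"):
            design_primer(GROUP1_CONSENSUS, resolution_map={7: "G"})  # W = {A,T}

    def test_degeneracy_matches_brute_force_for_random_consensi(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            s = random_iupac(rng, int(rng.integers(5, 15)), max_degeneracy=128)
            p = design_primer(s, prefer_3prime_GC=False)
            assert p.degeneracy == len(set(expansions(s))) == degeneracy(s)


class TestRescuePrimer:
    def test_recovers_pcof1_from_expansions_of_its_own_string(self):
        templates = [
            "ACGTAC" + e + "GGGTTT" for e in expansions(PCOF1_CORE)
        ] * 3
        p = derive_rescue_primer(templates, (6, 6 + len(PCOF1_CORE)), min_freq=0.0)
        assert p.core == PCOF1_CORE
        assert p.direction == "forward"

    def test_identical_templates_verbatim_window(self):
        t = "AAACCCGGGTTTAAACCCGGG"
        p = derive_rescue_primer([t, t, t], (3, 12))
        assert p.core == t[3:12]

    def test_window_not_covered_lists_offenders(self):
        with pytest.raises(ValueError, match="short1"):
            derive_rescue_primer(
                ["A" * 30, "A" * 10],
                (0, 20),
                ids=["ok", "short1"],
            )

    def test_planted_g_to_a_transition_yields_r_or_a(self):
        base = "CCTGCAACTAATCATAAAAATATTAG"
        mutated = base[:3] + "A" + base[4:]  # G->A at position 3
        templates = [base] * 7 + [mutated] * 3
        p0 = derive_rescue_primer(templates, (0, len(base)), min_freq=0.0)
        assert p0.core[3] == "R"
        p1 = derive_rescue_primer(templates, (0, len(base)), min_freq=0.4)
        assert p1.core[3] == "G"


class TestPrimerTm:
    def test_non_degenerate_min_equals_max(self):
        assert primer_tm(PrimerSpec("p", "ACGTACGTAC")) == (30.0, 30.0)

    def test_trwf1_range_spans_one_r(self):
        tmin, tmax = primer_tm(trwf1())
        assert tmax - tmin == 2
        # oracle: Wallace rule on the two concrete expansions
        wallace = lambda s: sum(4 if c in "GC" else 2 for c in s)
        temps = sorted(wallace(e) for e in expansions(trwf1().core))
        assert (tmin, tmax) == (temps[0], temps[-1])

    def test_all_n_tenmer_spans_20_40(self):
        assert primer_tm(PrimerSpec("p", "N" * 10)) == (20.0, 40.0)

    def test_short_core_rejected(self):
        with pytest.raises(ValueError):
            primer_tm(PrimerSpec("p", "ACGTACGTA"))
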