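"""Seed grouping, flag-aware binary comparison, IUPAC consensus merging."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from hypothesis import given, settings, strategies as st

import dealkit as dk
from dealkit._alphabet import CODE_TO_MASK, decode, encode
from dealkit.deal import ClusterRecord, FlaggedRead


def fread(bases, flags=None, rid="r"):
    f = np.zeros(len(bases), bool) if flags is None else np.asarray(flags, bool)
    return FlaggedRead(rid, encode(bases), f)


def cluster(bases, flags=None):
    return ClusterRecord.from_read(fread(bases, flags))


def test_iupac_masks_match_reference_table():
    """Bit-mask union reproduces the IUPAC ambiguity table (oracle: Biopython)."""
    for code, mask in CODE_TO_MASK.items():
        expected = set(ambiguous_dna_values[code])
        got = {b for b in "ACGT" if CODE_TO_MASK[b] & mask}
        assert got == expected, code


def test_extract_seed_lengths():
    read = "A" * 540
    assert len(dk.extract_seed(read, dk.SeedSpec.scfv())) == 40  # 20 + 20
    assert len(dk.extract_seed(read, dk.SeedSpec(((280, 300),)))) == 20
    # region covering the whole read degenerates to exact dedup on the read
    assert dk.extract_seed("ACGT", dk.SeedSpec(((1, 5),))) == "ACGT"
    assert dk.extract_seed("A" * 100, dk.SeedSpec.scfv()) is None  # too short


def test_group_by_seed_equals_dict_partition():
    rng = np.random.default_rng(3)
    spec = dk.SeedSpec(((3, 7),))
    reads = [fread("".join("ACGT"[i] for i in rng.integers(0, 4, 10)), rid=f"r{k}")
             for k in range(300)]
    groups, excluded = dk.group_by_seed(reads, spec)
    oracle: dict[str, list[int]] = {}
    for i, r in enumerate(reads):
        oracle.setdefault(r.bases[2:6], []).append(i)
    assert groups == oracle and not excluded


class TestMergeScenarios:
    """The three binary-comparison outcomes, verbatim."""

    def test_one_flag_resolves_to_reliable_base(self):
        c = cluster("ACGT")
        merged = dk.merge_pair(c, fread("ACTT", flags=[0, 0, 1, 0]))
        assert merged is not None
        assert merged.consensus == "ACGT"
        assert not merged.flags.any()  # resolved position is unflagged
        assert merged.cardinality == 2

    def test_both_flagged_yields_iupac_union_still_flagged(self):
        c = cluster("G", flags=[1])
        merged = dk.merge_pair(c, fread("T", flags=[1]))
        assert merged is not None
        assert merged.consensus == "K"  # G ∪ T
        assert merged.flags.tolist() == [True]

    def test_unflagged_difference_is_mismatch(self):
        assert dk.merge_pair(cluster("ACGT"), fread("ACTT")) is None

    def test_reliable_cluster_base_resolves_flagged_read(self):
        c = cluster("ACGT")
        merged = dk.merge_pair(c, fread("ANGT", flags=[0, 1, 0, 0]))
        assert merged.consensus == "ACGT" and not merged.flags.any()

    def test_three_flagged_bases_accumulate_union(self):
        c = cluster("A", flags=[1])
        c = dk.merge_pair(c, fread("G", flags=[1]))
        assert c.consensus == "R"
        c = dk.merge_pair(c, fread("T", flags=[1]))
        assert c.consensus == "D"  # A ∪ G ∪ T
        assert c.flags.tolist() == [True]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dk.merge_pair(cluster("ACGT"), fread("ACG"))


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.data())
def test_merge_match_is_monotone_in_flags(data):
    """Flagging additional positions never turns a MATCH into a MISMATCH."""
    n = data.draw(st.integers(4, 12))
    b1 = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    b2 = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    f1 = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    f2 = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    extra = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
    base = dk.merge_pair(cluster(b1, f1), fread(b2, f2))
    more = dk.merge_pair(cluster(b1, f1 | extra), fread(b2, f2 | extra))
    if base is not None:
        assert more is not None
    # and a MISMATCH always has an unflagged discordant position
    if base is None:
        disc = np.array([x != y for x, y in zip(b1, b2)])
        assert (disc & ~f1 & ~f2).any()


def test_cluster_group_without_flags_is_exact_dedup():
    rng = np.random.default_rng(4)
    variants = ["".join("ACGT"[i] for i in rng.integers(0, 4, 30)) for _ in range(40)]
    reads = [fread(variants[rng.integers(0, 40)], rid=f"r{k}") for k in range(500)]
    clusters = dk.cluster_group(reads)
    assert len(clusters) == len({r.bases for r in reads})
    assert sum(c.cardinality for c in clusters) == 500  # conservation
    # each cluster holds exactly the reads with its consensus
    for c in clusters:
        assert all(reads[int(m[1:])].bases == c.consensus for m in c.members)


def test_cluster_group_two_distinct_variants():
    reads = [fread("ACGTACGT", rid="a"), fread("ACGTACGT", rid="b"),
             fread("ACGTACTT", rid="c")]
    clusters = dk.cluster_group(reads)
    assert [c.cardinality for c in clusters] == [2, 1]


def test_run_deal_error_free_equals_truth(scfv_clean):
    run, pseudo = scfv_clean["run"], scfv_clean["pseudo"]
    result = dk.run_deal(pseudo, dk.SeedSpec.scfv(), profile=dk.ErrorProfile.flat(0.0))
    assert result.complexity == run.truth["source_id"].nunique()
    assert result.complexity == dk.naive_complexity(pseudo)
    assert sum(c.cardinality for c in result.clusters) == len(pseudo)


def test_run_deal_compensates_flagged_errors(vh_flagged):
    """Errors confined to flagged cycles collapse back onto the truth."""
    run, pseudo, profile = vh_flagged["run"], vh_flagged["pseudo"], vh_flagged["profile"]
    result = dk.run_deal(pseudo, dk.SeedSpec.vh(), profile=profile)
    assert result.complexity == run.truth["source_id"].nunique() == 600
    assert dk.naive_complexity(pseudo) > result.complexity


def test_reads_in_different_seed_groups_never_share_cluster(vh_flagged):
    pseudo, profile = vh_flagged["pseudo"], vh_flagged["profile"]
    result = dk.run_deal(pseudo, dk.SeedSpec.vh(), profile=profile)
    by_id = {p.id: p for p in pseudo}
    spec = dk.SeedSpec.vh()
    for c in result.clusters[:100]:
        seeds = {dk.extract_seed(by_id[m].bases, spec) for m in c.members}
        assert len(seeds) == 1


def test_run_deal_empty_input():
    result = dk.run_deal([], dk.SeedSpec.vh())
    assert result.complexity == 0 and result.clusters == []


def test_run_deal_order_deterministic(scfv_clean):
    pseudo = scfv_clean["pseudo"][:500]
    r1 = dk.run_deal(pseudo, dk.SeedSpec.scfv(), profile=dk.ErrorProfile.flat(0.0))
    r2 = dk.run_deal(pseudo, dk.SeedSpec.scfv(), profile=dk.ErrorProfile.flat(0.0))
    assert [c.members for c in r1.clusters] == [c.members for c in r2.clusters]
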