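"""Trimming, filtering, pairing and joining of raw reads."""

from __future__ import annotations

import numpy as np
import pytest

import dealkit as dk
from dealkit.preprocess import UnknownIndexError, median_phred

Q = lambda n, q=38: np.full(n, q, dtype=np.int16)  # noqa: E731


def mk(bases, mate="R1", index="i1", quals=None, rid="x"):
    return dk.SequenceRead(rid, bases, Q(len(bases)) if quals is None else np.asarray(quals),
                           mate, index_label=index)


# independent reverse-complement oracle used to check the library's
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc_oracle(s):
    return "".join(COMP[b] for b in reversed(s))


@pytest.mark.parametrize("mate,index,offset", [
    ("R1", "i1", 0), ("R1", "i2", 1), ("R1", "i3", 7), ("R1", "i4", 8),
    ("R2", "i1", 13), ("R2", "i2", 12), ("R2", "i3", 11), ("R2", "i4", 10),
])
def test_trim_shifter_offsets(mate, index, offset):
    read = mk("ACGTACGTACGTACGTACGT", mate=mate, index=index)
    out = dk.trim_shifter(read, dk.RunConfig())
    assert out.bases == read.bases[offset:]
    assert out.cycle_start == 1 + offset  # cycle provenance preserved


def test_trim_shifter_unknown_index():
    with pytest.raises(UnknownIndexError):
        dk.trim_shifter(mk("ACGT", index="i9"), dk.RunConfig())


@pytest.mark.parametrize("quals,keep", [
    ([40] * 8, True),
    ([31] * 8, False),
    ([30, 32, 32, 40], True),   # even length: lower middle value = 32
    ([30, 31, 33, 40], False),  # lower middle = 31 < 32
])
def test_median_quality_filter(quals, keep):
    read = mk("A" * len(quals), quals=quals)
    assert dk.filter_median_quality(read, 32) is keep


def test_median_is_lower_middle():
    assert median_phred(np.array([30, 32, 32, 40])) == 32
    assert median_phred(np.array([10, 20, 30, 40])) == 20


def test_trim_fixed():
    assert len(dk.trim_fixed(mk("A" * 350), 320)) == 320
    assert len(dk.trim_fixed(mk("A" * 250), 220)) == 220
    assert dk.trim_fixed(mk("A" * 210), 220) is None


def test_sync_pairs():
    s1 = [mk("AA", rid=i) for i in "abc"]
    s2 = [mk("AA", mate="R2", rid=i) for i in "bcd"]
    pairs, orphans = dk.sync_pairs(s1, s2)
    assert [p[0].id for p in pairs] == ["b", "c"]
    assert orphans == 2
    assert dk.sync_pairs(s1, [mk("AA", rid="z")])[0] == []
    pairs_all, _ = dk.sync_pairs(s1, [mk("AA", mate="R2", rid=i) for i in "abc"])
    assert len(pairs_all) == 3
    with pytest.raises(ValueError):
        dk.sync_pairs(s1 + [mk("AA", rid="a")], s2)


def test_join_pseudo_read_geometry_and_cycles():
    cfg = dk.RunConfig(trim_r1=6, trim_r2=4)
    r1 = mk("ACGTAC", rid="p")
    r2 = dk.SequenceRead("p", "ACGT", np.array([10, 20, 30, 40]), "R2", "i1")
    p = dk.join_pseudo_read(r1, r2, cfg)
    assert len(p) == 10
    assert p.bases[6:] == rc_oracle("ACGT")
    assert list(p.quals[6:]) == [40, 30, 20, 10]  # qualities reversed with the bases
    # first base of the reverse block is the mate's last sequencing cycle
    assert p.cycle_map[6] == ("R2", 4)
    assert p.cycle_map[0] == ("R1", 1)


def test_join_full_length_is_540():
    cfg = dk.RunConfig()
    r1 = mk("A" * 320, rid="p")
    r2 = mk("C" * 220, mate="R2", rid="p")
    p = dk.join_pseudo_read(r1, r2, cfg)
    assert len(p) == 540
    assert p.cycle_map[320] == ("R2", 220)
    with pytest.raises(ValueError):
        dk.join_pseudo_read(mk("A" * 319, rid="p"), r2, cfg)


class TestMergeOverlapping:
    def _pair(self, construct, n1, n2, q1=38, q2=38):
        r1 = dk.SequenceRead("m", construct[:n1], Q(n1, q1), "R1", "i1")
        r2 = dk.SequenceRead("m", rc_oracle(construct[-n2:]), Q(n2, q2), "R2", "i1")
        return r1, r2

    def test_exact_overlap_length(self):
        rng = np.random.default_rng(0)
        construct = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        r1, r2 = self._pair(construct, 60, 70)  # overlap 30
        p = dk.merge_overlapping(r1, r2, min_overlap=30)
        assert p is not None and len(p) == 100
        assert p.bases == construct

    def test_discordant_takes_higher_quality(self):
        rng = np.random.default_rng(1)
        construct = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        r1, r2 = self._pair(construct, 60, 70)
        # corrupt R1 inside the overlap with low quality
        bases = list(r1.bases)
        bases[45] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[45]]
        quals = r1.quals.copy()
        quals[45] = 20
        r1 = dk.SequenceRead("m", "".join(bases), quals, "R1", "i1")
        p = dk.merge_overlapping(r1, r2, min_overlap=30)
        assert p.bases == construct        # Q38 base beat the Q20 base
        assert p.quals[45] == 38
        assert p.cycle_map[45][0] == "R2"  # provenance follows the kept base

    def test_discordant_tie_keeps_forward_base_min_quality(self):
        rng = np.random.default_rng(2)
        construct = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        r1, r2 = self._pair(construct, 60, 70, q1=35, q2=35)
        bases = list(r1.bases)
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[45]]
        bases[45] = wrong
        r1 = dk.SequenceRead("m", "".join(bases), r1.quals, "R1", "i1")
        p = dk.merge_overlapping(r1, r2, min_overlap=30)
        assert p.bases[45] == wrong  # forward base wins the tie
        assert p.quals[45] == 35

    def test_no_overlap_returns_none(self):
        r1 = mk("A" * 50, rid="m")
        r2 = dk.SequenceRead("m", "C" * 50, Q(50), "R2", "i1")
        assert dk.merge_overlapping(r1, r2, min_overlap=30) is None


def test_pipeline_conserves_reads():
    cfg = dk.SimulationConfig(
        n_unique=100, n_reads=800, construct="scfv", rng_seed=21,
        low_quality_read_fraction=0.1,
        error_spec=dk.ErrorSpec(baseline=0.0, spikes=()),
    )
    rep = dk.generate_repertoire(cfg)
    run = dk.simulate_reads(rep, cfg)
    for idx, (r1s, r2s) in run.reads_by_index.items():
        res = dk.preprocess_pairs(r1s, r2s, dk.RunConfig(), mode="scfv")
        d = res.drops
        per_read_drops = (d["unclassified_index"] + d["adapter_dimer"]
                          + d["low_median_quality"] + d["too_short"])
        assert 2 * len(r1s) == 2 * res.n_kept + per_read_drops + d["orphan"]
        assert d["low_median_quality"] > 0  # the low-quality reads were caught


def test_zero_error_pseudo_reads_match_truth(scfv_clean):
    rep, run, pseudo = scfv_clean["rep"], scfv_clean["run"], scfv_clean["pseudo"]
    seqs = {s.id: s.sequence for s in rep.sequences}
    truth = run.truth.set_index("read_id")
    assert len(pseudo) == run.n_pairs
    for p in pseudo[:200]:
        src = seqs[truth.loc[p.id, "source_id"]]
        assert p.bases == src[:320] + src[-220:]
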