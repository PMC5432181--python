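"""In-silico translation: frames, ambiguous stop codons, protein clusters."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

import dealkit as dk
from dealkit._alphabet import encode
from dealkit.deal import ClusterRecord
from dealkit.protein import aggregate_protein_clusters, translate_ambiguous


def test_frame_classification():
    assert dk.frame_classify(369) == "in_frame"  # 369 mod 3 = 0
    assert dk.frame_classify(370) == "+1"
    assert dk.frame_classify(371) == "+2"
    assert dk.frame_classify(372, anchor_offset=2) == "+1"
    with pytest.raises(ValueError):
        dk.frame_classify(2, anchor_offset=3)


def codon_status_oracle(codon: str) -> str:
    """Enumerate all IUPAC expansions and translate with Biopython."""
    aas = {
        str(Seq("".join(bases)).translate())
        for bases in product(*(ambiguous_dna_values[b] for b in codon))
    }
    if aas == {"*"}:
        return "definite"
    return "possible" if "*" in aas else "none"


@pytest.mark.parametrize("codon,expected", [
    ("TAA", "definite"),
    ("TRA", "definite"),   # R = A/G: TAA and TGA are both stops
    ("TAY", "none"),       # TAC/TAT both encode Tyr
    ("TAM", "possible"),   # M = A/C: TAA stop, TAC Tyr
    ("TRR", "possible"),   # TAA/TAG/TGA stops but TGG = Trp
    ("NNN", "possible"),
    ("TGG", "none"),
])
def test_stop_scan_against_codon_table_oracle(codon, expected):
    assert codon_status_oracle(codon) == expected  # oracle agrees with label
    assert dk.scan_stops(codon) == expected


def test_translate_ambiguous_sequences():
    aa, status = translate_ambiguous("ATGGCC")
    assert (aa, status) == ("MA", "none")
    aa, status = translate_ambiguous("ATGTAAGCC")
    assert aa == "M*A" and status == "definite"
    # synonymous wobble stays a concrete residue; disagreement becomes X
    aa, _ = translate_ambiguous("GGR")  # GGA/GGG both Gly
    assert aa == "G"
    aa, _ = translate_ambiguous("RAT")  # AAT Asn / GAT Asp
    assert aa == "X"


def test_translation_respects_anchor_and_cds_end():
    aa, status = translate_ambiguous("GTAAATGGCC", anchor_offset=4)
    assert aa == "MA"
    assert translate_ambiguous("ATGTAA", cds_end=3)[1] == "none"


def nt_cluster(seq, card=1, flags=None):
    f = np.zeros(len(seq), bool) if flags is None else np.asarray(flags, bool)
    return ClusterRecord(encode(seq), f, [f"m{i}" for i in range(card)])


def test_synonymous_clusters_collapse():
    a = nt_cluster("ATGGGA", card=2)  # Met-Gly
    b = nt_cluster("ATGGGG", card=3)  # Met-Gly (wobble)
    report = dk.protein_clusters([a, b])
    assert report.total_protein_clusters == 1
    assert report.minimal_protein == 1  # merged cardinality 5


def test_stop_clusters_excluded_from_functional_bounds():
    ok = nt_cluster("ATGGCA", card=2)
    definite = nt_cluster("ATGTAA", card=2)
    # different length, so the possible-stop group stands alone
    possible = nt_cluster("ATGGCATAM", card=2, flags=[0] * 8 + [1])
    report = dk.protein_clusters([ok, definite, possible])
    assert report.total_protein_clusters == 3
    # lower bound drops possible+definite, upper bound drops definite only
    assert report.functional_clusters == (1, 2)
    assert report.pct_no_stop == pytest.approx((100 / 3, 200 / 3))


def test_possible_stop_synonym_of_clean_member_stays_functional():
    """A translation whose only uncertainty is an error-flagged codon joins
    the clean synonym group and the group remains certainly functional."""
    ok = nt_cluster("ATGGCA", card=2)            # MA
    uncertain = nt_cluster("ATGTAM", card=1, flags=[0, 0, 0, 0, 0, 1])  # MX
    report = dk.protein_clusters([ok, uncertain])
    assert report.total_protein_clusters == 1
    assert report.functional_clusters == (1, 1)


def test_wildcard_x_matches_any_residue():
    merged = aggregate_protein_clusters(
        [("MAX", "possible", 1), ("MAK", "none", 2)], wildcard=True
    )
    assert len(merged) == 1
    assert merged[0].aa == "MAK"  # concrete residue replaces the wildcard
    assert merged[0].stop_status == "none"  # one member is certainly stop-free
    strict = aggregate_protein_clusters(
        [("MAX", "possible", 1), ("MAK", "none", 2)], wildcard=False
    )
    assert len(strict) == 2


def test_protein_bounds_ordering(vh_flagged):
    pseudo, profile = vh_flagged["pseudo"], vh_flagged["profile"]
    result = dk.run_deal(pseudo, dk.SeedSpec.vh(), profile=profile)
    report = dk.protein_clusters(result.clusters)
    assert report.total_protein_clusters <= result.complexity
    lo, hi = report.functional_clusters
    assert lo <= hi <= report.total_protein_clusters
    assert report.minimal_protein <= report.total_protein_clusters


def test_simulated_frame_and_stop_fractions_recovered():
    cfg = dk.SimulationConfig(
        n_unique=600, n_reads=2400, construct="vh", coverage="exact",
        frameshift_fraction=0.134, stop_fraction=0.10, rng_seed=41,
        error_spec=dk.ErrorSpec(baseline=0.0, spikes=()),
    )
    rep = dk.generate_repertoire(cfg)
    run = dk.simulate_reads(rep, cfg)
    from conftest import preprocess_run

    pseudo, _ = preprocess_run(run, "vh")
    result = dk.run_deal(pseudo, dk.SeedSpec.vh(), profile=dk.ErrorProfile.flat(0.0))
    report = dk.protein_clusters(result.clusters)
    n = result.complexity
    sd_frame = 100 * np.sqrt(0.866 * 0.134 / n)
    assert report.pct_in_frame == pytest.approx(86.6, abs=3 * sd_frame + 0.5)
    n_if = report.n_in_frame
    sd_stop = 100 * np.sqrt(0.9 * 0.1 / n_if)
    assert report.pct_no_stop[1] == pytest.approx(90.0, abs=3 * sd_stop + 0.5)
    # error-free consensi carry no ambiguity, so the bounds coincide
    assert report.pct_no_stop[0] == report.pct_no_stop[1]


def test_two_chain_functional_projection():
    ok = nt_cluster("ATGGCA", card=2)
    report = dk.protein_clusters([ok])
    # single-chain full-CDS fraction f ⇒ scFv projection f² (independence)
    assert report.pct_full_cds == (100.0, 100.0)
    assert report.scfv_functional_pct == (100.0, 100.0)
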