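"""Protein-level diversity from in-silico translation of DEAL clusters.

Functional library quality is set by the fraction of members that code
for a full-length domain: the reading frame must be preserved (length
≡ 0 mod 3 relative to the coding anchor) and the CDS must be free of
stop codons.  Because consensus sequences may carry IUPAC ambiguity codes
at error-flagged positions, a codon can be a *definite* stop (every
expansion is a stop), a *possible* stop (some expansions are stops), or
stop-free; the functional complexity is therefore reported as a range,
with possible stops excluded only at the conservative end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._alphabet import CODE_TO_MASK, MASK_TO_CODE
from .deal import ClusterRecord

_STOPS = frozenset(standard_dna_table.stop_codons)
_BASES_OF = {code: frozenset(
    b for b in "ACGT" if CODE_TO_MASK[b] & mask
) for code, mask in CODE_TO_MASK.items()}

FRAME_CLASSES = ("in_frame", "+1", "+2")


def frame_classify(seq_or_len, anchor_offset: int = 0) -> str:
    """Reading-frame class from length modulo 3 past the coding anchor."""
    n = seq_or_len if isinstance(seq_or_len, int) else len(seq_or_len)
    if n <= anchor_offset:
        raise ValueError("sequence does not extend past the coding anchor")
    return FRAME_CLASSES[(n - anchor_offset) % 3]


def _codon_aminoacids(codon: str) -> set[str]:
    """Amino acids (with '*' for stop) over all IUPAC expansions of a codon."""
    aas = set()
    for expansion in product(*(_BASES_OF[b] for b in codon)):
        c = "".join(expansion)
        aas.add("*" if c in _STOPS else standard_dna_table.forward_table[c])
    return aas


def translate_ambiguous(
    seq: str, anchor_offset: int = 0, cds_end: int | None = None
) -> tuple[str, str]:
    """Translate an IUPAC consensus; returns ``(aa_sequence, stop_status)``.

    Codons whose expansions disagree at the amino-acid level become
    ``X``; an all-stop codon becomes ``*``.  ``stop_status`` is
    ``"definite"`` if any codon is unavoidably a stop, ``"possible"`` if
    some codon *may* be a stop, else ``"none"``.  Only complete codons in
    ``[anchor_offset, cds_end)`` are scanned.
    """
    end = len(seq) if cds_end is None else min(cds_end, len(seq))
    aa = []
    status = "none"
    for i in range(anchor_offset, end - 2, 3):
        aas = _codon_aminoacids(seq[i:i + 3])
        if aas == {"*"}:
            aa.append("*")
            status = "definite"
        elif "*" in aas:
            aa.append("X")
            if status == "none":
                status = "possible"
        elif len(aas) == 1:
            aa.append(next(iter(aas)))
        else:
            aa.append("X")
    return "".join(aa), status


def scan_stops(seq: str, anchor_offset: int = 0, cds_end: int | None = None) -> str:
    """Stop-codon status of an in-frame consensus: none/possible/definite."""
    return translate_ambiguous(seq, anchor_offset, cds_end)[1]


@dataclass
class ProteinCluster:
    """Protein-level cluster: representative amino-acid string (X allowed)."""

    aa: str
    cardinality: int
    nt_cluster_count: int
    stop_status: str  # worst status over merged members


def _aa_compatible(a: str, b: str) -> bool:
    """X matches any residue, but never a stop — a stop is not a residue."""
    if len(a) != len(b):
        return False
    return all(
        x == y or (x == "X" and y != "*") or (y == "X" and x != "*")
        for x, y in zip(a, b)
    )


def _aa_merge(a: str, b: str) -> str:
    return "".join(y if x == "X" else x for x, y in zip(a, b))


_STATUS_RANK = {"none": 0, "possible": 1, "definite": 2}


def aggregate_protein_clusters(
    translations: list[tuple[str, str, int]], wildcard: bool = True
) -> list[ProteinCluster]:
    """Greedy collapse of (aa, stop_status, cardinality) records.

    With ``wildcard=True`` an ``X`` matches any single residue, mirroring
    the flag-tolerant nucleotide merge; strict mode requires exact
    amino-acid identity.  A group's stop status is the most optimistic
    one among its members: if any member certainly encodes the protein
    without a stop, the group is stop-free.  (A definite-stop translation
    carries a literal ``*`` that only matches other definite stops, so
    definite groups never absorb clean members.)
    """
    clusters: list[ProteinCluster] = []
    for aa, status, card in translations:
        for pc in clusters:
            match = _aa_compatible(pc.aa, aa) if wildcard else pc.aa == aa
            if match:
                pc.aa = _aa_merge(pc.aa, aa) if wildcard else pc.aa
                pc.cardinality += card
                pc.nt_cluster_count += 1
                if _STATUS_RANK[status] < _STATUS_RANK[pc.stop_status]:
                    pc.stop_status = status
                break
        else:
            clusters.append(ProteinCluster(aa, card, 1, status))
    return clusters


@dataclass
class ProteinReport:
    """Protein-complexity report (percentages on the 0–100 scale).

    Range-valued fields are ``(lower, upper)``: the lower bound also
    excludes *possible* stop codons in error-flagged sequences, the upper
    bound excludes only definite ones.
    """

    total_reads: int
    n_nt_clusters: int
    n_in_frame: int
    pct_in_frame: float
    pct_no_stop: tuple[float, float]
    pct_full_cds: tuple[float, float]
    total_protein_clusters: int
    functional_clusters: tuple[int, int]
    minimal_protein: int
    minimal_functional: tuple[int, int]
    scfv_functional_pct: tuple[float, float]

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def protein_clusters(
    nt_clusters: list[ClusterRecord],
    anchor_offset: int = 0,
    wildcard: bool = True,
) -> ProteinReport:
    """Translate DEAL clusters and summarise protein-level diversity.

    In-frame clusters are translated and synonym-collapsed; out-of-frame
    clusters cannot be translated and each remains its own protein-level
    group.  Percent-in-frame is computed over nt clusters, percent
    without stop over in-frame clusters, and full-CDS as their product.
    The last line projects a two-chain (scFv) functional fraction as the
    square of the single-chain full-CDS fraction — an explicit
    independence assumption between the two chains.
    """
    in_frame: list[tuple[str, str, int]] = []
    out_frame: list[ClusterRecord] = []
    for c in nt_clusters:
        if frame_classify(len(c.masks), anchor_offset) == "in_frame":
            aa, status = translate_ambiguous(c.consensus, anchor_offset)
            in_frame.append((aa, status, c.cardinality))
        else:
            out_frame.append(c)
    n_nt = len(nt_clusters)
    n_if = len(in_frame)
    pct_in_frame = 100.0 * n_if / n_nt if n_nt else float("nan")

    n_definite = sum(1 for _, s, _ in in_frame if s == "definite")
    n_possible = sum(1 for _, s, _ in in_frame if s == "possible")
    if n_if:
        no_stop = (100.0 * (n_if - n_definite - n_possible) / n_if,
                   100.0 * (n_if - n_definite) / n_if)
    else:
        no_stop = (float("nan"), float("nan"))
    full_cds = tuple(pct_in_frame * v / 100.0 for v in no_stop)

    pclusters = aggregate_protein_clusters(in_frame, wildcard=wildcard)
    total_protein = len(pclusters) + len(out_frame)
    func_lower = sum(1 for pc in pclusters if pc.stop_status == "none")
    func_upper = sum(1 for pc in pclusters if pc.stop_status != "definite")
    minimal = (sum(1 for pc in pclusters if pc.cardinality >= 2)
               + sum(1 for c in out_frame if c.cardinality >= 2))
    min_func_lower = sum(1 for pc in pclusters
                         if pc.cardinality >= 2 and pc.stop_status == "none")
    min_func_upper = sum(1 for pc in pclusters
                         if pc.cardinality >= 2 and pc.stop_status != "definite")
    return ProteinReport(
        total_reads=sum(c.cardinality for c in nt_clusters),
        n_nt_clusters=n_nt,
        n_in_frame=n_if,
        pct_in_frame=pct_in_frame,
        pct_no_stop=no_stop,
        pct_full_cds=full_cds,  # type: ignore[arg-type]
        total_protein_clusters=total_protein,
        functional_clusters=(func_lower, func_upper),
        minimal_protein=minimal,
        minimal_functional=(min_func_lower, min_func_upper),
        scfv_functional_pct=tuple(v * v / 100.0 for v in full_cds),  # type: ignore[arg-type]
    )
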