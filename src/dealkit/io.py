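"""File formats: FASTQ/FASTA via Biopython, TSV for derived artefacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import encode
from .deal import ClusterRecord
from .preprocess import PseudoRead, SequenceRead


def read_fastq(path, mate: str | None = None, index_label: str | None = None) -> list[SequenceRead]:
    """Read a Sanger (Phred+33) FASTQ file into SequenceRead objects."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(SequenceRead(
            rec.id, str(rec.seq),
            np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            mate or "R1", index_label=index_label,
        ))
    return reads


def write_fastq(reads: list[SequenceRead], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries],
        str(path), "fasta",
    )


def write_pseudo_tsv(reads: list[PseudoRead], path) -> None:
    """Pseudo-reads with their quality and cycle provenance, one row each."""
    rows = [
        (
            p.id, p.bases,
            ",".join(map(str, p.quals)),
            "".join("1" if m == 1 else "2" for m in p.cycle_mates),
            ",".join(map(str, p.cycle_numbers)),
        )
        for p in reads
    ]
    pd.DataFrame(rows, columns=["id", "bases", "quals", "mates", "cycles"]).to_csv(
        path, sep="\t", index=False
    )


def read_pseudo_tsv(path) -> list[PseudoRead]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(PseudoRead(
            row.id, row.bases,
            np.array(row.quals.split(","), dtype=np.int16),
            np.frombuffer(row.mates.encode(), dtype=np.uint8) - ord("0"),
            np.array(row.cycles.split(","), dtype=np.int32),
            source_ids=(row.id,),
        ))
    return out


def write_clusters_tsv(clusters: list[ClusterRecord], path, members_path=None) -> None:
    """Cluster table: consensus, cardinality, flagged positions (1-based)."""
    rows = [
        (
            i, c.consensus, c.cardinality,
            ",".join(map(str, (np.nonzero(c.flags)[0] + 1))),
        )
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(rows, columns=["cluster_id", "consensus", "cardinality",
                                "flagged_positions"]).to_csv(path, sep="\t", index=False)
    if members_path is not None:
        member_rows = [
            (i, member) for i, c in enumerate(clusters) for member in c.members
        ]
        pd.DataFrame(member_rows, columns=["cluster_id", "read_id"]).to_csv(
            members_path, sep="\t", index=False
        )


def read_clusters_tsv(path, members_path=None) -> list[ClusterRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"consensus": str, "flagged_positions": str})
    members: dict[int, list[str]] = {}
    if members_path is not None:
        mdf = pd.read_csv(members_path, sep="\t", dtype={"read_id": str})
        for cid, grp in mdf.groupby("cluster_id"):
            members[int(cid)] = list(grp["read_id"])
    clusters = []
    for row in df.itertuples(index=False):
        masks = encode(row.consensus)
        flags = np.zeros(len(masks), dtype=bool)
        if isinstance(row.flagged_positions, str) and row.flagged_positions:
            flags[np.array(row.flagged_positions.split(","), dtype=int) - 1] = True
        ids = members.get(
            int(row.cluster_id),
            [f"member{j}" for j in range(int(row.cardinality))],
        )
        clusters.append(ClusterRecord(masks, flags, ids))
    return clusters
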