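"""Raw paired-end FASTQ to pseudo-reads.

The sequencing construct carries per-index "shifter" bases of different
lengths between the sequencing primer and the antibody insert; removing
them re-aligns all reads on the insert while de-phasing systematic
per-cycle errors across insert positions.  After shifter removal, reads
are median-quality filtered, cropped to fixed lengths, re-paired, and
either concatenated into fixed-length pseudo-reads (scFv constructs,
whose two reads do not overlap) or overlap-merged (VH constructs, short
enough that the reads cover the insert twice in the middle).

Every pseudo-read keeps a per-position map back to the original
sequencing cycle of the base that was kept, so that downstream flagging
can consult the per-cycle control error profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._alphabet import decode, encode, revcomp

#: index barcodes of the four sequencing adapters
DEFAULT_INDEX_BARCODES = {"i1": "TCAGCG", "i2": "GATCAC", "i3": "CTGAGA", "i4": "AGCTTT"}
#: number of shifter bases to discard from the start of each read
DEFAULT_SHIFTER_R1 = {"i1": 0, "i2": 1, "i3": 7, "i4": 8}
DEFAULT_SHIFTER_R2 = {"i1": 13, "i2": 12, "i3": 11, "i4": 10}


@dataclass
class SequenceRead:
    """One read with per-base Phred qualities.

    ``cycle_start`` is the sequencing cycle (1-based) of the first stored
    base; shifter trimming advances it so cycle provenance survives.
    """

    id: str
    bases: str
    quals: np.ndarray
    mate: str  # "R1" | "R2"
    index_label: str | None = None
    tile: str | None = None
    cycle_start: int = 1

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class PseudoRead:
    """A joined or overlap-merged read pair.

    ``cycle_mates``/``cycle_numbers`` record, per position, which mate and
    which original sequencing cycle produced the base that was kept.
    """

    id: str
    bases: str
    quals: np.ndarray
    cycle_mates: np.ndarray   # uint8: 1 = R1, 2 = R2
    cycle_numbers: np.ndarray  # int32, 1-based cycles
    source_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        self.cycle_mates = np.asarray(self.cycle_mates, dtype=np.uint8)
        self.cycle_numbers = np.asarray(self.cycle_numbers, dtype=np.int32)
        n = len(self.bases)
        if not (len(self.quals) == len(self.cycle_mates) == len(self.cycle_numbers) == n):
            raise ValueError(f"pseudo-read {self.id}: inconsistent field lengths")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def cycle_map(self) -> list[tuple[str, int]]:
        return [
            ("R1" if m == 1 else "R2", int(c))
            for m, c in zip(self.cycle_mates, self.cycle_numbers)
        ]


@dataclass
class RunConfig:
    """Run geometry and filter thresholds (defaults: MiSeq 350+250 protocol)."""

    index_barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_INDEX_BARCODES))
    shifter_offsets_r1: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SHIFTER_R1))
    shifter_offsets_r2: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SHIFTER_R2))
    trim_r1: int = 320
    trim_r2: int = 220
    min_median_phred: int = 32
    # adapter-dimer purge: drop reads whose first bases match the mate
    # adapter; disabled unless adapter sequences are provided
    adapter_r1: str | None = None
    adapter_r2: str | None = None
    adapter_probe_len: int = 12
    adapter_max_mismatch: int = 1


class UnknownIndexError(KeyError):
    """Read carries an index label with no configured shifter offset."""


def trim_shifter(read: SequenceRead, cfg: RunConfig) -> SequenceRead:
    """Drop the per-index shifter bases from the start of a read.

    Cycle provenance is preserved: position ``p`` after trimming maps to
    sequencing cycle ``p + offset + 1``.
    """
    offsets = cfg.shifter_offsets_r1 if read.mate == "R1" else cfg.shifter_offsets_r2
    if read.index_label not in offsets:
        raise UnknownIndexError(read.index_label)
    k = offsets[read.index_label]
    return replace(read, bases=read.bases[k:], quals=read.quals[k:],
                   cycle_start=read.cycle_start + k)


def median_phred(quals: np.ndarray) -> int:
    """Median quality; for even-length reads the *lower* middle value."""
    q = np.sort(np.asarray(quals))
    return int(q[(len(q) - 1) // 2])


def filter_median_quality(read: SequenceRead, min_median: int) -> bool:
    """Keep (True) iff the median Phred score reaches ``min_median``."""
    return median_phred(read.quals) >= min_median


def is_adapter_dimer(read: SequenceRead, cfg: RunConfig) -> bool:
    """Heuristic adapter-dimer test: read starts with the mate adapter."""
    adapter = cfg.adapter_r2 if read.mate == "R1" else cfg.adapter_r1
    if adapter is None:
        return False
    n = min(cfg.adapter_probe_len, len(adapter), len(read.bases))
    if n < cfg.adapter_probe_len:
        return False
    a = np.frombuffer(adapter[:n].encode(), dtype=np.uint8)
    b = np.frombuffer(read.bases[:n].encode(), dtype=np.uint8)
    return int((a != b).sum()) <= cfg.adapter_max_mismatch


def trim_fixed(read: SequenceRead, length: int) -> SequenceRead | None:
    """Crop to the first ``length`` bases; ``None`` if the read is shorter."""
    if len(read) < length:
        return None
    return replace(read, bases=read.bases[:length], quals=read.quals[:length])


def sync_pairs(
    stream1: list[SequenceRead], stream2: list[SequenceRead]
) -> tuple[list[tuple[SequenceRead, SequenceRead]], int]:
    """Re-pair two filtered streams by read id, dropping orphans.

    Output order follows ``stream1``.  Returns (pairs, n_orphans).
    Duplicate ids within one stream are an error.
    """
    by_id: dict[str, SequenceRead] = {}
    for r in stream2:
        if r.id in by_id:
            raise ValueError(f"duplicate read id in stream: {r.id}")
        by_id[r.id] = r
    seen: set[str] = set()
    pairs = []
    for r in stream1:
        if r.id in seen:
            raise ValueError(f"duplicate read id in stream: {r.id}")
        seen.add(r.id)
        mate = by_id.get(r.id)
        if mate is not None:
            pairs.append((r, mate))
    n_orphans = (len(stream1) - len(pairs)) + (len(stream2) - len(pairs))
    return pairs, n_orphans


def join_pseudo_read(r1: SequenceRead, r2: SequenceRead, cfg: RunConfig) -> PseudoRead:
    """Concatenate R1 with the reverse complement of R2 (scFv mode).

    The resulting pseudo-read has length ``trim_r1 + trim_r2`` (540 by
    default).  Reverse-complementing reverses cycle order, so the first
    base of the R2 block is the mate's *last* retained sequencing cycle.
    """
    if len(r1) != cfg.trim_r1 or len(r2) != cfg.trim_r2:
        raise ValueError(
            f"pair {r1.id}: lengths {len(r1)}/{len(r2)} differ from "
            f"configured {cfg.trim_r1}/{cfg.trim_r2}"
        )
    n1, n2 = len(r1), len(r2)
    bases = r1.bases + revcomp(r2.bases)
    quals = np.concatenate([r1.quals, r2.quals[::-1]])
    mates = np.concatenate([np.full(n1, 1, np.uint8), np.full(n2, 2, np.uint8)])
    cyc1 = r1.cycle_start + np.arange(n1, dtype=np.int32)
    cyc2 = r2.cycle_start + n2 - 1 - np.arange(n2, dtype=np.int32)
    cycles = np.concatenate([cyc1, cyc2])
    return PseudoRead(r1.id, bases, quals, mates, cycles, source_ids=(r1.id,))


def merge_overlapping(
    r1: SequenceRead,
    r2: SequenceRead,
    min_overlap: int = 30,
    max_mismatch_rate: float = 0.1,
) -> PseudoRead | None:
    """Overlap-merge a VH read pair into one full-length read.

    The reverse read is reverse-complemented and slid along the forward
    read (ungapped); the offset maximising matches − mismatches wins,
    provided the overlap reaches ``min_overlap`` and its mismatch rate is
    below ``max_mismatch_rate``.  Inside the overlap a concordant position
    keeps the base with the higher of the two qualities; a discordant
    position keeps the higher-quality base with its quality; a discordant
    tie keeps the forward base and demotes the position to the lower
    quality so it is likely flagged downstream.  Returns ``None`` when no
    acceptable overlap exists.
    """
    n1, n2 = len(r1), len(r2)
    a1 = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    r2c = revcomp(r2.bases)
    a2 = np.frombuffer(r2c.encode(), dtype=np.uint8)
    q2 = r2.quals[::-1]
    cyc2 = r2.cycle_start + n2 - 1 - np.arange(n2, dtype=np.int32)

    def evaluate(offset: int) -> tuple[int, int, int] | None:
        ov = min(n1 - offset, n2)
        if ov < min_overlap:
            return None
        mism = int((a1[offset:offset + ov] != a2[:ov]).sum())
        if mism > max_mismatch_rate * ov:
            return None
        return (ov - 2 * mism, ov, mism)

    # probe k-mers of the reverse-complemented mate located in the forward
    # read give candidate offsets cheaply; fall back to a full scan
    k = 16
    candidates: set[int] = set()
    for j in (0, n2 // 4, n2 // 2, 3 * n2 // 4):
        if j + k > n2:
            continue
        probe = r2c[j:j + k]
        start = 0
        while True:
            hit = r1.bases.find(probe, start)
            if hit < 0:
                break
            if hit - j >= 0:
                candidates.add(hit - j)
            start = hit + 1
    best: tuple[int, int] | None = None  # (score, offset)
    for off in sorted(candidates):
        ev = evaluate(off)
        if ev and (best is None or ev[0] > best[0]):
            best = (ev[0], off)
    if best is None:
        for off in range(0, n1 - min_overlap + 1):
            ev = evaluate(off)
            if ev and (best is None or ev[0] > best[0]):
                best = (ev[0], off)
    if best is None:
        return None

    offset = best[1]
    ov = min(n1 - offset, n2)
    # prefix from R1
    bases = [r1.bases[:offset]]
    quals = [r1.quals[:offset]]
    mates = [np.full(offset, 1, np.uint8)]
    cycles = [r1.cycle_start + np.arange(offset, dtype=np.int32)]
    # overlap consensus
    b1 = a1[offset:offset + ov]
    b2 = a2[:ov]
    qa = r1.quals[offset:offset + ov]
    qb = q2[:ov]
    concord = b1 == b2
    take_r1 = qa >= qb  # discordant tie -> forward-read base
    ov_bases = np.where(take_r1, b1, b2)
    ov_quals = np.where(concord, np.maximum(qa, qb),
                        np.where(qa == qb, np.minimum(qa, qb),
                                 np.maximum(qa, qb)))
    ov_mates = np.where(take_r1, 1, 2).astype(np.uint8)
    ov_cycles = np.where(take_r1,
                         r1.cycle_start + offset + np.arange(ov, dtype=np.int32),
                         cyc2[:ov])
    bases.append(ov_bases.tobytes().decode())
    quals.append(ov_quals.astype(np.int16))
    mates.append(ov_mates)
    cycles.append(ov_cycles.astype(np.int32))
    # suffix from R2 (if the mate extends past the forward read)
    if ov < n2:
        bases.append(r2c[ov:])
        quals.append(q2[ov:])
        mates.append(np.full(n2 - ov, 2, np.uint8))
        cycles.append(cyc2[ov:])
    return PseudoRead(
        r1.id,
        "".join(bases),
        np.concatenate(quals),
        np.concatenate(mates),
        np.concatenate(cycles),
        source_ids=(r1.id,),
    )


@dataclass
class PreprocessResult:
    pseudo_reads: list[PseudoRead]
    drops: dict[str, int]

    @property
    def n_kept(self) -> int:
        return len(self.pseudo_reads)


def preprocess_pairs(
    r1_reads: list[SequenceRead],
    r2_reads: list[SequenceRead],
    cfg: RunConfig | None = None,
    mode: str = "scfv",
    min_overlap: int = 30,
    max_mismatch_rate: float = 0.1,
) -> PreprocessResult:
    """Full preprocessing pipeline for one demultiplexed index.

    Stages: shifter trimming → adapter-dimer purge → median-quality filter
    → fixed-length crop → re-pairing → join (scFv) or overlap merge (VH).
    ``drops`` accounts for every removed read so that
    input pairs = kept + Σ drop reasons.
    """
    if cfg is None:
        cfg = RunConfig()
    if mode not in ("scfv", "vh"):
        raise ValueError(f"unknown mode {mode!r}")
    drops = {
        "unclassified_index": 0, "adapter_dimer": 0, "low_median_quality": 0,
        "too_short": 0, "orphan": 0, "merge_failed": 0,
    }

    def survive(reads: list[SequenceRead], trim_len: int) -> list[SequenceRead]:
        out = []
        for read in reads:
            try:
                read = trim_shifter(read, cfg)
            except UnknownIndexError:
                drops["unclassified_index"] += 1
                continue
            if is_adapter_dimer(read, cfg):
                drops["adapter_dimer"] += 1
                continue
            if not filter_median_quality(read, cfg.min_median_phred):
                drops["low_median_quality"] += 1
                continue
            trimmed = trim_fixed(read, trim_len)
            if trimmed is None:
                drops["too_short"] += 1
                continue
            out.append(trimmed)
        return out

    s1 = survive(r1_reads, cfg.trim_r1)
    s2 = survive(r2_reads, cfg.trim_r2)
    pairs, n_orphans = sync_pairs(s1, s2)
    drops["orphan"] = n_orphans

    pseudo: list[PseudoRead] = []
    for r1, r2 in pairs:
        if mode == "scfv":
            pseudo.append(join_pseudo_read(r1, r2, cfg))
        else:
            merged = merge_overlapping(r1, r2, min_overlap, max_mismatch_rate)
            if merged is None:
                drops["merge_failed"] += 1
            else:
                pseudo.append(merged)
    return PreprocessResult(pseudo, drops)
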