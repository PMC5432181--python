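"""Quality-aware sequence-identity collapse (DEAL).

Reads are first partitioned by an exact-match "seed" cut from the most
variable stretch of the construct (the CDR3s), which turns the all-vs-all
comparison into many small independent sub-problems.  Within a seed
group, each read is compared against the consensus of every previously
formed cluster, position by position:

* both bases reliable and different  -> the reads are genuinely distinct
  (MISMATCH, no grouping);
* exactly one side flagged unreliable -> the reliable base wins and the
  position becomes unflagged;
* both sides flagged -> the merged base is the IUPAC code for the union
  of the two base sets and the position stays flagged.

The number of clusters that survive this collapse is the library
complexity estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import decode, encode, is_concrete
from .errors import ErrorProfile, FlagThresholds, flag_unreliable
from .preprocess import PseudoRead


@dataclass(frozen=True)
class SeedSpec:
    """Seed regions as 1-based, end-exclusive intervals on the pseudo-read.

    The default scFv seed concatenates 20 nt from each CDR3
    (positions 280–300 of the forward block and 470–490 of the reverse
    block); the VH seed uses the single CDR3 window.
    """

    regions: tuple[tuple[int, int], ...] = ((280, 300), (470, 490))

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.regions:
            if not (1 <= start < end):
                raise ValueError(f"bad seed interval ({start}, {end})")
            if start < prev_end:
                raise ValueError("seed intervals must be ordered and non-overlapping")
            prev_end = end

    @classmethod
    def scfv(cls) -> "SeedSpec":
        return cls(((280, 300), (470, 490)))

    @classmethod
    def vh(cls) -> "SeedSpec":
        return cls(((280, 300),))

    @property
    def max_end(self) -> int:
        return max(end for _, end in self.regions) - 1


def extract_seed(p: "PseudoRead | str", spec: SeedSpec) -> str | None:
    """Concatenated seed-region substrings; ``None`` if the read is short."""
    bases = p if isinstance(p, str) else p.bases
    if len(bases) < spec.max_end:
        return None
    return "".join(bases[start - 1:end - 1] for start, end in spec.regions)


@dataclass
class FlaggedRead:
    """A pseudo-read ready for clustering: bit-mask bases + flag mask."""

    id: str
    masks: np.ndarray
    flags: np.ndarray

    @classmethod
    def from_pseudo(cls, p: PseudoRead, flags: np.ndarray) -> "FlaggedRead":
        return cls(p.id, encode(p.bases), np.asarray(flags, dtype=bool))

    @property
    def bases(self) -> str:
        return decode(self.masks)

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class ClusterRecord:
    """A DEAL cluster: IUPAC consensus, per-position flags, members."""

    masks: np.ndarray
    flags: np.ndarray
    members: list[str] = field(default_factory=list)

    @property
    def consensus(self) -> str:
        return decode(self.masks)

    @property
    def cardinality(self) -> int:
        return len(self.members)

    @classmethod
    def from_read(cls, read: FlaggedRead) -> "ClusterRecord":
        return cls(read.masks.copy(), read.flags.copy(), [read.id])


def merge_pair(cluster: ClusterRecord, read: FlaggedRead) -> ClusterRecord | None:
    """Try to merge a read into a cluster; ``None`` means MISMATCH.

    Implements the three comparison scenarios (see module docstring).
    Only a position where *both* sides are reliable and disagree
    separates two sequences; the returned record is a new object.
    """
    if len(cluster.masks) != len(read.masks):
        raise ValueError("merge_pair requires equal-length sequences")
    cf, rf = cluster.flags, read.flags
    cm, rm = cluster.masks, read.masks
    both_ok = ~cf & ~rf
    if np.any(both_ok & (cm != rm)):
        return None
    merged = np.where(cf & ~rf, rm, cm)            # (ii) reliable read base wins
    both_flagged = cf & rf
    merged = np.where(both_flagged, cm | rm, merged)  # (iii) union of base sets
    flags = both_flagged.copy()
    return ClusterRecord(merged, flags, cluster.members + [read.id])


def group_by_seed(reads: list[FlaggedRead], spec: SeedSpec) -> tuple[dict[str, list[int]], list[int]]:
    """Partition read indices by exact seed identity.

    Returns (groups, excluded) where ``excluded`` lists indices of reads
    too short to cover the seed regions.
    """
    groups: dict[str, list[int]] = {}
    excluded: list[int] = []
    for i, read in enumerate(reads):
        seed = extract_seed(read.bases, spec)
        if seed is None:
            excluded.append(i)
        else:
            groups.setdefault(seed, []).append(i)
    return groups, excluded


def cluster_group(reads: list[FlaggedRead]) -> list[ClusterRecord]:
    """Greedy sequential collapse of one seed group.

    Each read is tried against existing clusters in creation order and
    joins the first match, otherwise founds a new cluster.  Reads of
    unequal length never match (variable-length input is allowed).
    """
    clusters: list[ClusterRecord] = []
    for read in reads:
        for i, cluster in enumerate(clusters):
            if len(cluster.masks) != len(read.masks):
                continue
            merged = merge_pair(cluster, read)
            if merged is not None:
                clusters[i] = merged
                break
        else:
            clusters.append(ClusterRecord.from_read(read))
    return clusters


@dataclass
class DealResult:
    clusters: list[ClusterRecord]
    complexity: int
    seed_complexity: int
    n_reads: int
    n_excluded_short: int
    group_sizes: list[int]

    @property
    def cardinality_counts(self) -> Counter:
        return Counter(c.cardinality for c in self.clusters)

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_excluded_short": self.n_excluded_short,
            "seed_complexity": self.seed_complexity,
            "complexity": self.complexity,
            "max_cardinality": max((c.cardinality for c in self.clusters), default=0),
        }


def run_deal(
    reads: list[PseudoRead],
    spec: SeedSpec | None = None,
    thresholds: FlagThresholds | None = None,
    profile: ErrorProfile | None = None,
    flags: list[np.ndarray] | None = None,
) -> DealResult:
    """Seed-group and collapse a stream of pseudo-reads.

    ``flags`` may carry precomputed unreliability masks; otherwise they
    are derived from ``profile``/``thresholds`` via
    :func:`dealkit.errors.flag_unreliable`.  Input order is part of the
    contract: the greedy collapse is deterministic given the read order,
    which is preserved from the input.
    """
    spec = spec or SeedSpec.scfv()
    thresholds = thresholds or FlagThresholds()
    if not reads:
        import warnings

        warnings.warn("run_deal called with no reads; complexity is 0", stacklevel=2)
    flagged: list[FlaggedRead] = []
    for i, p in enumerate(reads):
        f = flags[i] if flags is not None else flag_unreliable(p, profile, thresholds)
        flagged.append(FlaggedRead(p.id, encode(p.bases), np.asarray(f, dtype=bool)))

    groups, excluded = group_by_seed(flagged, spec)
    clusters: list[ClusterRecord] = []
    group_sizes: list[int] = []
    for seed in groups:  # insertion order = input order of first occurrence
        idx = groups[seed]
        group_sizes.append(len(idx))
        clusters.extend(cluster_group([flagged[i] for i in idx]))
    return DealResult(
        clusters=clusters,
        complexity=len(clusters),
        seed_complexity=len(groups),
        n_reads=len(reads),
        n_excluded_short=len(excluded),
        group_sizes=group_sizes,
    )


def naive_complexity(reads: list[PseudoRead]) -> int:
    """Exact string deduplication count — the error-naive baseline."""
    return len({p.bases for p in reads})
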