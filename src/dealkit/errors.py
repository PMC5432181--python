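"""Empirical per-cycle error rates and per-position reliability flags.

The sequencer's own Phred scores and the empirical mismatch rate of a
spiked-in control phage measure different things and disagree in both
scale and shape — in particular the reported quality of the earliest
cycles is a poor predictor of the true mismatch rate.  A base is
therefore considered unreliable when *either* descriptor fails: reported
quality below ``min_phred`` or control mismatch rate of its sequencing
cycle above ``max_cycle_error``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import encode, is_concrete, revcomp
from .preprocess import PseudoRead, SequenceRead


def phred_error(q) -> float | np.ndarray:
    """Error probability encoded by a Phred score: ``10**(-q/10)``."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0) if np.ndim(q) else 10.0 ** (-float(q) / 10.0)


@dataclass
class FlagThresholds:
    """Reliability thresholds: Phred floor and control-error ceiling (%)."""

    min_phred: float = 32.0
    max_cycle_error: float = 1.0  # percent

    def __post_init__(self) -> None:
        if self.min_phred < 0 or self.max_cycle_error < 0:
            raise ValueError("thresholds must be non-negative")


class ErrorProfile:
    """Per-(mate, cycle) empirical mismatch percentage from control reads.

    Cycles never observed hold NaN (absent), never an optimistic zero.
    """

    def __init__(self, mismatch_pct: dict[str, np.ndarray], n_obs: dict[str, np.ndarray]):
        self.mismatch_pct = {m: np.asarray(v, dtype=float) for m, v in mismatch_pct.items()}
        self.n_obs = {m: np.asarray(v, dtype=np.int64) for m, v in n_obs.items()}
        for mate, pct in self.mismatch_pct.items():
            obs = self.n_obs[mate]
            if pct.shape != obs.shape:
                raise ValueError("profile arrays inconsistent")
            if np.nanmin(pct, initial=0.0) < 0 or np.nanmax(pct, initial=0.0) > 100:
                raise ValueError("mismatch percentages must lie in [0, 100]")

    @classmethod
    def flat(cls, pct: float, n_cycles: dict[str, int] | None = None,
             n_obs: int = 1000) -> "ErrorProfile":
        """Uniform profile, mostly for tests and precomputed-rate input."""
        n_cycles = n_cycles or {"R1": 350, "R2": 250}
        return cls(
            {m: np.full(n, pct, dtype=float) for m, n in n_cycles.items()},
            {m: np.full(n, n_obs, dtype=np.int64) for m, n in n_cycles.items()},
        )

    def rate(self, mate: str, cycle: int) -> float:
        """Mismatch % at a 1-based cycle; NaN if absent/never observed."""
        arr = self.mismatch_pct.get(mate)
        if arr is None or not (1 <= cycle <= len(arr)):
            return float("nan")
        return float(arr[cycle - 1])

    def rates_for(self, mates: np.ndarray, cycles: np.ndarray) -> np.ndarray:
        """Vectorised lookup for a pseudo-read's cycle map."""
        out = np.full(len(cycles), np.nan)
        for code, mate in ((1, "R1"), (2, "R2")):
            arr = self.mismatch_pct.get(mate)
            if arr is None:
                continue
            sel = mates == code
            cyc = cycles[sel]
            valid = (cyc >= 1) & (cyc <= len(arr))
            vals = np.full(len(cyc), np.nan)
            vals[valid] = arr[cyc[valid] - 1]
            out[sel] = vals
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mate in sorted(self.mismatch_pct):
            pct, obs = self.mismatch_pct[mate], self.n_obs[mate]
            for i in range(len(pct)):
                rows.append((mate, i + 1, pct[i], int(obs[i])))
        return pd.DataFrame(rows, columns=["mate", "cycle", "pct_mismatch", "n"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ErrorProfile":
        df = pd.read_csv(path, sep="\t")
        pct: dict[str, np.ndarray] = {}
        obs: dict[str, np.ndarray] = {}
        for mate, grp in df.groupby("mate"):
            n = int(grp["cycle"].max())
            p = np.full(n, np.nan)
            o = np.zeros(n, dtype=np.int64)
            p[grp["cycle"].to_numpy() - 1] = grp["pct_mismatch"].to_numpy()
            o[grp["cycle"].to_numpy() - 1] = grp["n"].to_numpy()
            pct[str(mate)], obs[str(mate)] = p, o
        return cls(pct, obs)


def _kmer_index(reference: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i:i + k], []).append(i)
    return index


def compute_phix_profile(
    reads: list[SequenceRead],
    reference: str,
    min_identity: float = 0.7,
    k: int = 20,
) -> ErrorProfile:
    """Measure per-cycle mismatch rates from control-phage reads.

    Each read is placed at its best ungapped offset on the reference
    (both strands, found via exact k-mer probes with a full-scan
    fallback); reads whose best identity is below ``min_identity`` are
    excluded as non-control.  Indels are not modelled.
    """
    if not reads:
        raise ValueError(
            "no control reads supplied; provide control FASTQ or a "
            "precomputed per-cycle profile (ErrorProfile.from_tsv)"
        )
    ref_fwd = np.frombuffer(reference.encode(), dtype=np.uint8)
    ref_rev = np.frombuffer(revcomp(reference).encode(), dtype=np.uint8)
    refs = {"+": (reference, ref_fwd), "-": (revcomp(reference), ref_rev)}
    indexes = {s: _kmer_index(refs[s][0], k) for s in refs}
    L = len(reference)

    lengths = {r.mate: max(len(x) for x in reads if x.mate == r.mate) for r in reads}
    mism = {m: np.zeros(n, dtype=np.int64) for m, n in lengths.items()}
    nobs = {m: np.zeros(n, dtype=np.int64) for m, n in lengths.items()}
    n_excluded = 0

    for read in reads:
        arr = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        n = len(arr)
        best: tuple[int, np.ndarray] | None = None  # (n_mismatch, mask)
        probe_sets = ([0, n // 3, 2 * n // 3], list(range(0, n - k + 1, k)))
        for probes in probe_sets:  # cheap probes first, dense fallback after
            for strand, (_, ref_arr) in refs.items():
                candidates: set[int] = set()
                for j in probes:
                    if j + k > n:
                        continue
                    for pos in indexes[strand].get(read.bases[j:j + k], ()):
                        start = pos - j
                        if 0 <= start <= L - n:
                            candidates.add(start)
                for start in candidates:
                    mask = arr != ref_arr[start:start + n]
                    nm = int(mask.sum())
                    if best is None or nm < best[0]:
                        best = (nm, mask)
            if best is not None:
                break
        if best is None or best[0] > (1.0 - min_identity) * n:
            n_excluded += 1
            continue
        cyc0 = read.cycle_start - 1
        mism[read.mate][cyc0:cyc0 + n] += best[1]
        nobs[read.mate][cyc0:cyc0 + n] += 1

    pct = {}
    for m in mism:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct[m] = np.where(nobs[m] > 0, 100.0 * mism[m] / np.maximum(nobs[m], 1), np.nan)
    profile = ErrorProfile(pct, nobs)
    profile.n_excluded = n_excluded  # type: ignore[attr-defined]
    return profile


def flag_unreliable(
    p: PseudoRead,
    profile: ErrorProfile | None,
    t: FlagThresholds | None = None,
) -> np.ndarray:
    """Boolean unreliability mask for a pseudo-read.

    A position is flagged when its reported quality is below
    ``min_phred``, or the control mismatch rate of its sequencing cycle
    exceeds ``max_cycle_error`` percent, or its base is N/ambiguous.
    Cycles absent from the profile are flagged (fail-unsafe), since the
    whole point of the control is that Phred alone cannot be trusted.
    With ``profile=None`` only the Phred and ambiguity checks apply.
    """
    t = t or FlagThresholds()
    flags = p.quals < t.min_phred
    flags |= ~is_concrete(encode(p.bases))
    if profile is not None:
        rates = profile.rates_for(p.cycle_mates, p.cycle_numbers)
        flags |= np.isnan(rates) | (rates > t.max_cycle_error)
    return flags
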