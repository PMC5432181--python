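"""Primer-class assignment and chain/VDJ assortment diagnostics.

Each library sequence starts with one forward-primer scaffold and ends
with one reverse-primer scaffold.  Counting the (forward, reverse) class
pairs and comparing the observed joint frequencies against the product
of the marginals measures whether the two ends assorted independently —
a skew here points to amplification bias during library construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._alphabet import CODE_TO_MASK, encode

UNCLASSIFIED = "UC"


@dataclass
class PrimerLibrary:
    """Recognition sequences per class, stored in sense-strand orientation."""

    forward: dict[str, str]
    reverse: dict[str, str]
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for table in (self.forward, self.reverse):
            for name, seq in table.items():
                if not seq:
                    raise ValueError(f"empty recognition sequence for {name}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, max_mismatch: int = 2) -> "PrimerLibrary":
        fwd = {r["class"]: r["sequence"] for _, r in df.iterrows() if r["end"] == "5prime"}
        rev = {r["class"]: r["sequence"] for _, r in df.iterrows() if r["end"] == "3prime"}
        return cls(fwd, rev, max_mismatch)

    def to_frame(self) -> pd.DataFrame:
        rows = [("5prime", c, s) for c, s in self.forward.items()]
        rows += [("3prime", c, s) for c, s in self.reverse.items()]
        return pd.DataFrame(rows, columns=["end", "class", "sequence"])


def _mismatches(window: str, primer: str) -> int:
    """IUPAC-aware mismatch count; a degenerate primer base matches any
    of its expansions."""
    w = encode(window)
    p = encode(primer)
    return int(((w & p) == 0).sum())


def assign_primer(sequence: str, lib: PrimerLibrary, end: str) -> str:
    """Best primer class at the 5' or 3' end; ties and poor matches → UC."""
    table = lib.forward if end == "5prime" else lib.reverse
    best_class, best_mm, tied = UNCLASSIFIED, None, False
    for name, primer in table.items():
        if len(sequence) < len(primer):
            continue
        window = sequence[:len(primer)] if end == "5prime" else sequence[-len(primer):]
        mm = _mismatches(window, primer)
        if best_mm is None or mm < best_mm:
            best_class, best_mm, tied = name, mm, False
        elif mm == best_mm:
            tied = True
    if best_mm is None or best_mm > lib.max_mismatch or tied:
        return UNCLASSIFIED
    return best_class


@dataclass
class AssortmentTable:
    """Observed vs expected (forward, reverse) class pair frequencies.

    ``observed`` includes the UC row/column and sums to 1 over all
    pairs; ``expected`` is the outer product of the classified marginals
    and sums to 1 over classified pairs.  ``log2_ratio`` is
    ``log2(observed / expected)`` over classified pairs (the heatmap).
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    log2_ratio: pd.DataFrame
    chi2: float
    n_pairs: int
    n_classified: int


def assortment(assignments: list[tuple[str, str]]) -> AssortmentTable:
    """Build the observed/expected assortment table from class pairs."""
    if not assignments:
        raise ValueError("no primer assignments supplied")
    counts = Counter(assignments)
    fwd_names = sorted({f for f, _ in assignments if f != UNCLASSIFIED})
    rev_names = sorted({r for _, r in assignments if r != UNCLASSIFIED})
    n = len(assignments)

    obs = pd.DataFrame(
        0.0, index=fwd_names + [UNCLASSIFIED], columns=rev_names + [UNCLASSIFIED]
    )
    for (f, r), c in counts.items():
        obs.loc[f, r] += c / n

    classified = {(f, r): c for (f, r), c in counts.items()
                  if f != UNCLASSIFIED and r != UNCLASSIFIED}
    n_cl = sum(classified.values())
    if n_cl == 0:
        raise ValueError("every pair is unclassified; cannot form marginals")
    fmarg = pd.Series(0.0, index=fwd_names)
    rmarg = pd.Series(0.0, index=rev_names)
    for (f, r), c in classified.items():
        fmarg[f] += c / n_cl
        rmarg[r] += c / n_cl
    expected = pd.DataFrame(np.outer(fmarg, rmarg), index=fwd_names, columns=rev_names)

    obs_cl = pd.DataFrame(0.0, index=fwd_names, columns=rev_names)
    for (f, r), c in classified.items():
        obs_cl.loc[f, r] = c / n_cl
    with np.errstate(divide="ignore"):
        log2_ratio = np.log2(obs_cl.where(obs_cl > 0) / expected.where(expected > 0))

    table = (obs_cl * n_cl).to_numpy()
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    chi2 = float(chi2_contingency(table[np.ix_(keep_r, keep_c)])[0]) \
        if keep_r.sum() > 1 and keep_c.sum() > 1 else 0.0
    return AssortmentTable(obs, expected, log2_ratio, chi2, n, n_cl)


def assign_pairs(
    sequences: list[str], lib: PrimerLibrary
) -> list[tuple[str, str]]:
    """Classify both ends of every sequence."""
    return [
        (assign_primer(s, lib, "5prime"), assign_primer(s, lib, "3prime"))
        for s in sequences
    ]
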