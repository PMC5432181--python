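"""Complexity bounds and truncated negative-binomial complexity estimation.

The cluster-cardinality histogram carries the sampling signature of the
library: a repertoire sampled far below saturation piles up in
low-cardinality clusters.  Three numbers summarise it:

* the observed cluster count (the direct diversity estimate);
* the *minimal* complexity — clusters of cardinality ≥ 2 only, since the
  singleton class also absorbs every read whose errors escaped flagging;
* the *theoretical* complexity C from fitting
  ``Nseq(x) ≈ C · NB(x; p, s)`` over cardinalities ``x ≥ x_min``, where
  the untruncated negative-binomial mass lets C extrapolate to the
  unobserved zero class (library members never sampled).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import nbinom

from .deal import ClusterRecord


@dataclass
class CardinalityHistogram:
    """Counts of clusters per cardinality: ``x -> Nseq(x)``."""

    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x, n in self.counts.items():
            if x < 1 or n < 0:
                raise ValueError("cardinalities must be >= 1 with counts >= 0")

    @property
    def total_clusters(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return sum(x * n for x, n in self.counts.items())

    def without(self, cardinalities) -> "CardinalityHistogram":
        """Copy with specific cardinality cells decremented/removed."""
        counts = dict(self.counts)
        for x in cardinalities:
            counts[x] = counts.get(x, 0) - 1
            if counts[x] <= 0:
                del counts[x]
        return CardinalityHistogram(counts)


def cardinality_histogram(clusters: list[ClusterRecord]) -> CardinalityHistogram:
    """Exact histogram of cluster cardinalities."""
    return CardinalityHistogram(dict(Counter(c.cardinality for c in clusters)))


def minimal_complexity(h: CardinalityHistogram) -> int:
    """Clusters of cardinality ≥ 2 — the lower bound on library complexity."""
    return sum(n for x, n in h.counts.items() if x >= 2)


@dataclass
class Outlier:
    cluster_index: int
    cardinality: int
    backbone_match: bool


def _best_identity(query: str, target: str, k: int = 21) -> float:
    """Best ungapped-placement identity of ``query`` against ``target``."""
    n, L = len(query), len(target)
    if n == 0 or L == 0:
        return 0.0
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    ta = np.frombuffer(target.encode(), dtype=np.uint8)
    candidates: set[int] = set()
    for j in range(0, max(n - k, 0) + 1, max(k, 1)):
        probe = query[j:j + k]
        start = 0
        while True:
            hit = target.find(probe, start)
            if hit < 0:
                break
            candidates.add(hit - j)
            start = hit + 1
    if not candidates:
        candidates = set(range(-n + 1, L))  # exhaustive fallback for tiny inputs
    best = 0.0
    for off in candidates:
        q0, t0 = max(0, -off), max(0, off)
        span = min(n - q0, L - t0)
        if span <= 0:
            continue
        ident = float((qa[q0:q0 + span] == ta[t0:t0 + span]).sum()) / n
        best = max(best, ident)
    return best


def detect_outliers(
    clusters: list[ClusterRecord],
    backbone: str | None = None,
    z_cut: float = 3.5,
    min_identity: float = 0.9,
    join_point: int | None = None,
) -> list[Outlier]:
    """Flag abnormally deep clusters (e.g. undigested vector backbone).

    A cluster is an outlier when its log-cardinality exceeds
    ``median + z_cut · MAD`` of the log-cardinality distribution.  When
    the vector backbone sequence is supplied, outliers are annotated by a
    ≥ ``min_identity`` ungapped substring match to it.  For pseudo-reads
    built by concatenating two non-overlapping reads, pass the
    concatenation position as ``join_point`` so each block is matched
    separately (length-weighted).  A high outlier count indicates an
    unbalanced library.
    """
    if not clusters:
        raise ValueError("no clusters to analyse")

    def identity(consensus: str) -> float:
        if join_point is not None and 0 < join_point < len(consensus):
            parts = (consensus[:join_point], consensus[join_point:])
            return sum(_best_identity(p, backbone) * len(p) for p in parts) / len(consensus)
        return _best_identity(consensus, backbone)

    cards = np.array([c.cardinality for c in clusters], dtype=float)
    logc = np.log(cards)
    med = np.median(logc)
    mad = np.median(np.abs(logc - med))
    cut = med + z_cut * max(mad, 1e-12)
    out = []
    for i in np.nonzero(logc > cut)[0]:
        cluster = clusters[int(i)]
        matched = backbone is not None and identity(cluster.consensus) >= min_identity
        out.append(Outlier(int(i), cluster.cardinality, matched))
    return out


@dataclass
class NegBinFit:
    """Result of the truncated negative-binomial regression.

    ``C`` is the estimated total complexity (including the unseen zero
    class); ``p``/``s`` the probability and size parameters.
    """

    p: float
    s: float
    C: float
    fit_range: tuple[int, int]
    sse: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not (0 < self.p < 1) or self.s <= 0 or self.C <= 0:
            raise ValueError("invalid negative-binomial fit parameters")


def fit_truncated_negbin(
    h: CardinalityHistogram,
    x_min: int = 2,
    x_max: int | None = None,
) -> NegBinFit:
    """Least-squares fit of ``Nseq(x) = C · NB(x; p, s)`` on ``x ≥ x_min``.

    The probability mass is the *untruncated* negative binomial, so the
    scale coefficient C estimates the total complexity including members
    with zero sampled reads.  Singletons are excluded by default
    (``x_min = 2``) because the cardinality-1 class is inflated by
    uncorrectable errors.  A coarse (p, s) grid (with the optimal C in
    closed form at each node) seeds a bounded nonlinear least-squares
    refinement.
    """
    xs = np.array(sorted(x for x in h.counts if x >= x_min
                         and (x_max is None or x <= x_max)), dtype=float)
    if len(xs) < 3:
        raise ValueError("need at least 3 distinct cardinality values in fit range")
    ys = np.array([h.counts[int(x)] for x in xs], dtype=float)

    def pmf(p: float, s: float) -> np.ndarray:
        return nbinom.pmf(xs, s, p)

    # grid search: for fixed (p, s) the optimal C is the weighted
    # projection  C* = Σ y·f / Σ f²
    starts = []
    for p0 in np.linspace(0.05, 0.95, 13):
        for s0 in np.geomspace(0.2, 12.0, 13):
            f = pmf(p0, s0)
            denom = float(f @ f)
            if denom <= 0 or not np.isfinite(denom):
                continue
            c0 = float(ys @ f) / denom
            if c0 <= 0:
                continue
            sse = float(((ys - c0 * f) ** 2).sum())
            starts.append((sse, p0, s0, c0))
    if not starts:
        raise RuntimeError("negative-binomial grid search found no viable start")
    starts.sort()

    def residuals(theta: np.ndarray) -> np.ndarray:
        p0, s0, logc = theta
        return ys - np.exp(logc) * nbinom.pmf(xs, s0, p0)

    best = None
    for sse0, p0, s0, c0 in starts[:4]:
        try:
            sol = optimize.least_squares(
                residuals,
                x0=[p0, s0, np.log(c0)],
                bounds=([1e-6, 1e-4, -5.0], [1 - 1e-6, 1e4, 60.0]),
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float((sol.fun ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError(
            f"negative-binomial fit failed to converge; best grid SSE {starts[0][0]:.3g} "
            f"at p={starts[0][1]:.3g}, s={starts[0][2]:.3g}"
        )
    sse, sol = best
    p_hat, s_hat, logc_hat = sol.x
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")
    return NegBinFit(
        p=float(p_hat), s=float(s_hat), C=float(np.exp(logc_hat)),
        fit_range=(int(xs[0]), int(xs[-1])), sse=sse, r_squared=r2,
        n_points=len(xs),
    )


@dataclass
class ComplexitySummary:
    """Five-column complexity report for one library."""

    total_reads: int
    maximal_complexity: int | None  # transformant count, user-supplied
    deal_clusters: int
    minimal: int
    theoretical: float | None

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "maximal_complexity": self.maximal_complexity,
            "deal_clusters": self.deal_clusters,
            "minimal_complexity": self.minimal,
            "theoretical_complexity": self.theoretical,
        }


def summarize_complexity(
    clusters: list[ClusterRecord],
    transformants: int | None = None,
    backbone: str | None = None,
    x_min: int = 2,
    exclude_outliers: bool = True,
    join_point: int | None = None,
) -> ComplexitySummary:
    """End-to-end complexity summary from DEAL clusters.

    Outlier clusters (vector backbone and other over-represented
    contaminants) are removed from the histogram before fitting: they are
    not library diversity.
    """
    h = cardinality_histogram(clusters)
    if exclude_outliers and clusters:
        outliers = detect_outliers(clusters, backbone=backbone, join_point=join_point)
        h_fit = h.without([o.cardinality for o in outliers])
    else:
        h_fit = h
    try:
        theoretical: float | None = fit_truncated_negbin(h_fit, x_min=x_min).C
    except (ValueError, RuntimeError):
        theoretical = None
    return ComplexitySummary(
        total_reads=h.total_reads,
        maximal_complexity=transformants,
        deal_clusters=h.total_clusters,
        minimal=minimal_complexity(h),
        theoretical=theoretical,
    )
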