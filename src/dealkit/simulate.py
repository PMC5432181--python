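"""Synthetic antibody-library sequencing runs with full truth tables.

The generator emulates, at the sequence level, a paired-end Illumina run
over a library of known distinct antibody constructs:

* each construct carries a forward-primer scaffold, framework segments,
  one (VH) or two (scFv) hypervariable CDR3 stretches covering the
  clustering seed regions, and a reverse-primer scaffold;
* per-index barcode/shifter bases of different lengths are prepended so
  that a systematic error in one sequencing cycle lands on different
  construct positions in different indexes;
* substitution errors are injected with cycle-indexed rates (baseline
  plus configurable spikes) and the reported Phred score follows a
  calibration map with a miscalibrated early-cycle window, where the
  quality no longer predicts the true error rate;
* a control-phage spike-in read set is drawn from a fixed synthetic
  reference with the same cycle-indexed error process, so the measured
  per-cycle profile estimates the injected one.

Indels are not simulated (their proportion in Illumina data is
negligible for this purpose), and everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import revcomp
from .preprocess import (
    DEFAULT_INDEX_BARCODES,
    DEFAULT_SHIFTER_R1,
    DEFAULT_SHIFTER_R2,
    SequenceRead,
)
from .primers import PrimerLibrary

#: forward (V-class) recognition scaffolds, 21 nt, stop-free in frame 0
DEFAULT_V_PRIMERS = {
    "VH1": "ATGGCCCCATTTAGCCGCGGC",
    "VH2": "ATGGCCAATACATCGGAGACG",
    "VH3": "ATGGCCCCTGCCAATTTCGAA",
    "VH4": "ATGGCCATCAAGACCCGTCGG",
    "VH5": "ATGGCCAATTCGGCAACTTTT",
    "VH6": "ATGGCCATGGGAGGAGCCTTT",
}
#: reverse (J-class) recognition scaffolds in sense-strand orientation
DEFAULT_J_PRIMERS = {
    "J1": "AATGCAGCCCGCAATATGAAG",
    "J2": "GATTGCAGACAGCGGAGCGAG",
    "J3": "ACTGCACATGATTCGGGTAGT",
    "J4": "ACGGCCGCAGGAATACCTACG",
    "J5": "GATGTCACAGCAAATGCTATC",
}

#: shifter bases prepended per index (lengths match the shifter offsets)
SHIFTER_SEQ_R1 = {"i1": "", "i2": "T", "i3": "GACTGAC", "i4": "ACGTACGT"}
SHIFTER_SEQ_R2 = {
    "i1": "TCGATCAGTCGAT",
    "i2": "CGATCAGTCGAT",
    "i3": "GATCAGTCGAT",
    "i4": "ATCAGTCGAT",
}

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASE_CHARS = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHAR_TO_BASE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CHAR_TO_BASE[ord(_b)] = _i
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)


def default_primer_library(max_mismatch: int = 2) -> PrimerLibrary:
    return PrimerLibrary(dict(DEFAULT_V_PRIMERS), dict(DEFAULT_J_PRIMERS), max_mismatch)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """A stop-free random coding stretch of ``n`` codons."""
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def control_reference(length: int = 5386) -> str:
    """Fixed synthetic control-phage reference (deterministic)."""
    rng = np.random.default_rng(5386)
    return _BASE_CHARS[rng.integers(0, 4, size=length)].tobytes().decode()


# constant 3'/5' run-off sequences read when a read extends past the insert
_ADAPTER_TAIL_3 = _BASE_CHARS[
    np.random.default_rng(97).integers(0, 4, size=420)
].tobytes().decode()
_ADAPTER_TAIL_5 = _BASE_CHARS[
    np.random.default_rng(98).integers(0, 4, size=420)
].tobytes().decode()


@dataclass(frozen=True)
class ErrorSpec:
    """Cycle-indexed substitution rates: baseline plus spike windows.

    ``spikes`` are (first_cycle, last_cycle, rate) with 1-based inclusive
    cycle bounds; within a spike the rate replaces the baseline.  The
    same spec applies to both mates (cycles count per mate).
    """

    baseline: float = 0.0005
    spikes: tuple[tuple[int, int, float], ...] = ((12, 24, 0.02),)

    def __post_init__(self) -> None:
        rates = [self.baseline] + [r for _, _, r in self.spikes]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("substitution rates must lie in [0, 1]")

    def rates(self, n_cycles: int) -> np.ndarray:
        arr = np.full(n_cycles, self.baseline, dtype=float)
        for a, b, r in self.spikes:
            arr[max(a - 1, 0):b] = r
        return arr


@dataclass(frozen=True)
class PhredSpec:
    """Map from true per-cycle error rate to reported Phred score.

    Outside the miscalibration window the reported score is the
    calibrated value ``-10·log10(rate)`` (clipped to [2, 41], with
    ``q_good`` for error-free cycles).  Inside the window —
    covering the early cycles where reported quality fails to predict
    the mismatch rate — the score is ``miscal_q`` regardless of the true
    rate, so only the control-phage profile can reveal those errors.
    """

    q_good: int = 38
    miscal_window: tuple[int, int] | None = (1, 40)
    miscal_q: int = 38
    low_read_q: int = 20

    def reported(self, rates: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            q = np.where(
                rates > 0,
                np.clip(np.round(-10.0 * np.log10(np.maximum(rates, 1e-12))), 2, 41),
                float(self.q_good),
            )
        if self.miscal_window is not None:
            a, b = self.miscal_window
            q[max(a - 1, 0):b] = self.miscal_q
        return q.astype(np.int16)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated run."""

    n_unique: int = 5000
    n_reads: int | None = 30000
    construct: str = "scfv"  # "scfv" | "vh"
    scfv_length: int = 750
    abundance_model: str = "uniform"  # uniform | negative_binomial | lognormal
    abundance_params: dict = field(default_factory=dict)
    coverage: str = "multinomial"  # multinomial | exact
    frameshift_fraction: float = 0.0
    stop_fraction: float = 0.0
    backbone_copies: int = 0
    vj_coupling: float = 0.0
    low_quality_read_fraction: float = 0.0
    error_spec: ErrorSpec = field(default_factory=ErrorSpec)
    phred_spec: PhredSpec = field(default_factory=PhredSpec)
    read_len_r1: int = 350
    read_len_r2: int = 250
    indexes: tuple[str, ...] = ("i1", "i2", "i3", "i4")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError("n_unique must be >= 1")
        for name in ("frameshift_fraction", "stop_fraction", "vj_coupling",
                     "low_quality_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.construct not in ("scfv", "vh"):
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.coverage not in ("multinomial", "exact"):
            raise ValueError(f"unknown coverage mode {self.coverage!r}")


@dataclass
class RepertoireSequence:
    id: str
    sequence: str
    v_class: str
    j_class: str
    in_frame: bool
    has_stop: bool
    weight: float


@dataclass
class TrueRepertoire:
    sequences: list[RepertoireSequence]
    backbone: str | None
    anchor_offset: int = 0
    copy_numbers: np.ndarray | None = None  # NB copy-number model only

    def __len__(self) -> int:
        return len(self.sequences)


class CapacityError(ValueError):
    """Requested diversity exceeds the combinatorial CDR design space."""


def _abundance_weights(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-sequence weights; also raw copy numbers for the NB model."""
    n = cfg.n_unique
    if cfg.abundance_model == "uniform":
        return np.full(n, 1.0 / n), None
    if cfg.abundance_model == "negative_binomial":
        p = cfg.abundance_params.get("p", 0.3)
        s = cfg.abundance_params.get("s", 1.5)
        copies = rng.negative_binomial(s, p, size=n).astype(np.int64)
        total = copies.sum()
        if total == 0:
            return np.full(n, 1.0 / n), copies
        return copies / total, copies
    if cfg.abundance_model == "lognormal":
        mu = cfg.abundance_params.get("mu", 0.0)
        sigma = cfg.abundance_params.get("sigma", 1.0)
        w = rng.lognormal(mu, sigma, size=n)
        return w / w.sum(), None
    raise ValueError(f"unknown abundance model {cfg.abundance_model!r}")


def generate_repertoire(cfg: SimulationConfig) -> TrueRepertoire:
    """Draw ``n_unique`` distinct constructs with attached truth.

    Construct geometry (positions relative to the coding anchor at 0,
    all segment boundaries codon-aligned):

    * VH:   primer(21) FR1(39) VAR1(30) FR2-3(180) CDR3(30–48, step 3)
            tail(39) J-primer(21); total 360–378 nt.
    * scFv: primer(21) FR1(39) VAR1(30) FR2-3(180) CDR3-H(42)
            middle(L−402) CDR3-L(42) tail(27) J-primer(21); total L
            (default 750) so that all variability falls inside the two
            sequenced windows of the 540 nt pseudo-read.

    Frameshifted members get 1–2 extra bases inserted in CDR3(-H);
    stop-bearing in-frame members get a random CDR3 codon replaced by a
    stop.  All random coding stretches are drawn stop-free, so stop
    codons occur exactly where the truth table says.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_unique
    n_var_codons = 10 + 10  # VAR1 + minimum CDR3 codons
    capacity = len(_NONSTOP_CODONS) ** n_var_codons
    if n > capacity // 100:
        raise CapacityError(
            f"n_unique={n} exceeds the safe combinatorial capacity of the CDR design"
        )

    fr1 = _random_codons(rng, 13)
    fr23 = _random_codons(rng, 60)
    v_names = list(DEFAULT_V_PRIMERS)
    j_names = list(DEFAULT_J_PRIMERS)
    if cfg.construct == "vh":
        tail = _random_codons(rng, 13)
        middle = None
        tail_l = None
    else:
        if cfg.scfv_length % 3 or cfg.scfv_length < 560:
            raise ValueError("scfv_length must be a multiple of 3 and >= 560")
        middle = _random_codons(rng, (cfg.scfv_length - 402) // 3)
        tail_l = _random_codons(rng, 9)

    n_fs = int(round(cfg.frameshift_fraction * n))
    order = rng.permutation(n)
    frameshifted = np.zeros(n, dtype=bool)
    frameshifted[order[:n_fs]] = True
    in_frame_idx = order[n_fs:]
    n_stop = int(round(cfg.stop_fraction * len(in_frame_idx)))
    stopped = np.zeros(n, dtype=bool)
    stopped[in_frame_idx[:n_stop]] = True

    weights, copy_numbers = _abundance_weights(cfg, rng)

    v_idx = rng.integers(0, len(v_names), size=n)
    j_idx = rng.integers(0, len(j_names), size=n)
    if cfg.vj_coupling > 0:
        forced = rng.random(n) < cfg.vj_coupling
        j_idx[forced] = v_idx[forced] % len(j_names)

    sequences: list[RepertoireSequence] = []
    seen: set[str] = set()
    for i in range(n):
        vp = DEFAULT_V_PRIMERS[v_names[v_idx[i]]]
        jp = DEFAULT_J_PRIMERS[j_names[j_idx[i]]]
        for _attempt in range(200):
            var1 = _random_codons(rng, 10)
            if cfg.construct == "vh":
                cdr3_codons = int(rng.integers(10, 17))  # 30..48 nt
                cdr3 = _random_codons(rng, cdr3_codons)
                if stopped[i]:
                    j = int(rng.integers(0, cdr3_codons))
                    cdr3 = cdr3[:3 * j] + _STOP_CODONS[rng.integers(0, 3)] + cdr3[3 * j + 3:]
                if frameshifted[i]:
                    d = int(rng.integers(1, 3))
                    pos = int(rng.integers(0, len(cdr3)))
                    ins = _BASE_CHARS[rng.integers(0, 4, size=d)].tobytes().decode()
                    cdr3 = cdr3[:pos] + ins + cdr3[pos:]
                seq = vp + fr1 + var1 + fr23 + cdr3 + tail + jp
            else:
                cdr3h = _random_codons(rng, 14)
                cdr3l = _random_codons(rng, 14)
                if stopped[i]:
                    j = int(rng.integers(0, 14))
                    cdr3h = cdr3h[:3 * j] + _STOP_CODONS[rng.integers(0, 3)] + cdr3h[3 * j + 3:]
                if frameshifted[i]:
                    d = int(rng.integers(1, 3))
                    pos = int(rng.integers(0, len(cdr3h)))
                    ins = _BASE_CHARS[rng.integers(0, 4, size=d)].tobytes().decode()
                    cdr3h = cdr3h[:pos] + ins + cdr3h[pos:]
                seq = vp + fr1 + var1 + fr23 + cdr3h + middle + cdr3l + tail_l + jp
            if seq not in seen:
                seen.add(seq)
                break
        else:
            raise CapacityError("could not generate a distinct sequence; design space exhausted")
        sequences.append(RepertoireSequence(
            id=f"seq{i:06d}", sequence=seq,
            v_class=v_names[v_idx[i]], j_class=j_names[j_idx[i]],
            in_frame=not frameshifted[i], has_stop=bool(stopped[i]),
            weight=float(weights[i]),
        ))

    backbone = None
    if cfg.backbone_copies > 0:
        bb_len = cfg.scfv_length if cfg.construct == "scfv" else 366
        backbone = _BASE_CHARS[rng.integers(0, 4, size=bb_len)].tobytes().decode()
    return TrueRepertoire(sequences, backbone, copy_numbers=copy_numbers)


@dataclass
class SimulatedRun:
    """Reads per demultiplexed index, plus the truth table."""

    reads_by_index: dict[str, tuple[list[SequenceRead], list[SequenceRead]]]
    truth: pd.DataFrame
    repertoire: TrueRepertoire

    @property
    def n_pairs(self) -> int:
        return len(self.truth)

    def write(self, out_dir) -> None:
        from .io import write_fastq

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for idx, (r1s, r2s) in sorted(self.reads_by_index.items()):
            write_fastq(r1s, out / f"{idx}_R1.fastq")
            write_fastq(r2s, out / f"{idx}_R2.fastq")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def _inject_errors(
    raws: list[str], rates: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Vectorised substitution errors on equal-length raw reads.

    Returns the mutated base matrix (uint8 char codes) and, per read,
    the 1-based cycles where a substitution was injected.
    """
    m, n = len(raws), len(raws[0])
    mat = np.frombuffer("".join(raws).encode(), dtype=np.uint8).reshape(m, n).copy()
    mask = rng.random((m, n)) < rates[None, :]
    rows, cols = np.nonzero(mask)
    if len(rows):
        codes = _CHAR_TO_BASE[mat[rows, cols]]
        new = (codes + rng.integers(1, 4, size=len(rows))) % 4
        mat[rows, cols] = _BASE_CHARS[new]
    boundaries = np.searchsorted(rows, np.arange(m + 1))
    per_read = [cols[boundaries[i]:boundaries[i + 1]] + 1 for i in range(m)]
    return mat, per_read


def simulate_reads(repertoire: TrueRepertoire, cfg: SimulationConfig) -> SimulatedRun:
    """Simulate a demultiplexed paired-end run over a repertoire."""
    rng = np.random.default_rng(cfg.rng_seed + 1)
    n = len(repertoire.sequences)
    weights = np.array([s.weight for s in repertoire.sequences])
    weights = weights / weights.sum()

    if cfg.n_reads is None:
        if repertoire.copy_numbers is None:
            raise ValueError("n_reads=None requires the negative_binomial copy-number model")
        counts = np.asarray(repertoire.copy_numbers, dtype=np.int64)
    elif cfg.coverage == "multinomial":
        counts = rng.multinomial(cfg.n_reads, weights)
    else:  # exact: deterministic counts proportional to the weights
        base = np.floor(cfg.n_reads * weights).astype(np.int64)
        remainder = cfg.n_reads - base.sum()
        frac = cfg.n_reads * weights - base
        extra = np.argsort(-frac, kind="stable")[:remainder]
        base[extra] += 1
        counts = base

    source_idx = np.repeat(np.arange(n), counts)
    seqs = [s.sequence for s in repertoire.sequences]
    ids = [s.id for s in repertoire.sequences]
    if cfg.backbone_copies > 0:
        if repertoire.backbone is None:
            raise ValueError("backbone_copies > 0 but repertoire has no backbone")
        source_idx = np.concatenate([source_idx, np.full(cfg.backbone_copies, n)])
        seqs.append(repertoire.backbone)
        ids.append("backbone")
    source_idx = rng.permutation(source_idx)
    m_total = len(source_idx)
    index_choice = rng.integers(0, len(cfg.indexes), size=m_total)

    rc_cache = {i: revcomp(seqs[i]) for i in np.unique(source_idx)}
    e1 = cfg.error_spec.rates(cfg.read_len_r1)
    e2 = cfg.error_spec.rates(cfg.read_len_r2)
    q1 = cfg.phred_spec.reported(e1)
    q2 = cfg.phred_spec.reported(e2)

    reads_by_index: dict[str, tuple[list[SequenceRead], list[SequenceRead]]] = {}
    truth_rows = []
    for ii, index in enumerate(cfg.indexes):
        sel = np.nonzero(index_choice == ii)[0]
        if len(sel) == 0:
            reads_by_index[index] = ([], [])
            continue
        k1 = DEFAULT_SHIFTER_R1[index]
        k2 = DEFAULT_SHIFTER_R2[index]
        s1 = SHIFTER_SEQ_R1[index]
        s2 = SHIFTER_SEQ_R2[index]
        raw1 = [s1 + (seqs[source_idx[g]] + _ADAPTER_TAIL_3)[: cfg.read_len_r1 - k1]
                for g in sel]
        raw2 = [s2 + (rc_cache[source_idx[g]] + _ADAPTER_TAIL_5)[: cfg.read_len_r2 - k2]
                for g in sel]
        mat1, err1 = _inject_errors(raw1, e1, rng)
        mat2, err2 = _inject_errors(raw2, e2, rng)
        low = rng.random(len(sel)) < cfg.low_quality_read_fraction
        r1s, r2s = [], []
        for row, g in enumerate(sel):
            rid = f"r{g:07d}"
            if low[row]:
                qa = np.full(cfg.read_len_r1, cfg.phred_spec.low_read_q, np.int16)
                qb = np.full(cfg.read_len_r2, cfg.phred_spec.low_read_q, np.int16)
            else:
                qa, qb = q1.copy(), q2.copy()
            r1s.append(SequenceRead(rid, mat1[row].tobytes().decode(), qa,
                                    "R1", index_label=index))
            r2s.append(SequenceRead(rid, mat2[row].tobytes().decode(), qb,
                                    "R2", index_label=index))
            src = source_idx[g]
            truth_rows.append((
                rid, ids[src], index,
                ",".join(map(str, err1[row])), ",".join(map(str, err2[row])),
                repertoire.sequences[src].v_class if src < n else "",
                repertoire.sequences[src].j_class if src < n else "",
                repertoire.sequences[src].in_frame if src < n else False,
                repertoire.sequences[src].has_stop if src < n else False,
            ))
        reads_by_index[index] = (r1s, r2s)

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source_id", "index", "error_cycles_r1",
                 "error_cycles_r2", "v_class", "j_class", "in_frame", "has_stop"],
    ).sort_values("read_id", kind="stable").reset_index(drop=True)
    return SimulatedRun(reads_by_index, truth, repertoire)


@dataclass
class ControlRun:
    """Simulated control-phage spike-in reads plus their reference."""

    reads: list[SequenceRead]
    reference: str
    injected_cycles: list[np.ndarray]


def simulate_phix(cfg: SimulationConfig, n_reads: int) -> ControlRun:
    """Control-phage reads sharing the library's cycle-indexed error process."""
    rng = np.random.default_rng(cfg.rng_seed + 2)
    reference = control_reference()
    L = len(reference)
    ref_rc = revcomp(reference)
    reads: list[SequenceRead] = []
    injected: list[np.ndarray] = []
    for mate, read_len, rates in (("R1", cfg.read_len_r1, cfg.error_spec.rates(cfg.read_len_r1)),
                                  ("R2", cfg.read_len_r2, cfg.error_spec.rates(cfg.read_len_r2))):
        m = n_reads // 2 if mate == "R1" else n_reads - n_reads // 2
        if m == 0:
            continue
        starts = rng.integers(0, L - read_len + 1, size=m)
        strands = rng.random(m) < 0.5
        raws = [
            (reference if fwd else ref_rc)[s:s + read_len]
            for s, fwd in zip(starts, strands)
        ]
        mat, errs = _inject_errors(raws, rates, rng)
        quals = cfg.phred_spec.reported(rates)
        for row in range(m):
            reads.append(SequenceRead(
                f"phix_{mate}_{row:06d}", mat[row].tobytes().decode(),
                quals.copy(), mate,
            ))
            injected.append(errs[row])
    return ControlRun(reads, reference, injected)
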