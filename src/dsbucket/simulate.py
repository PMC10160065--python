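"""Synthetic data generation and evaluation.

Generators for (i) jointly simulated HMM sequence-pair databases and
(ii) a uniform-random genome with long reads carrying substitution and
indel errors at a controlled total rate, plus the sensitivity /
false-positive bookkeeping used to score search output against the
simulated ground truth.

The read generator applies independent per-base errors (substitution,
insertion, deletion) — a simplification of real long-read error profiles
(no homopolymer bias, no quality model); all evaluation here is relative
to the generator's own recorded truth, not to any external simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsb_sa import Hit, reverse_complement
from .models import HMMParams, sample_hmm_pair

__all__ = [
    "ReadTruth",
    "EvalReport",
    "make_hmm_dataset",
    "make_genome_reads",
    "evaluate_hits",
    "verifiable_truth",
]

DNA = "ACGT"


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    ref_id: str
    true_start: int  # 0-based half-open origin on the reference
    true_end: int
    strand: str
    error_rate_applied: float


@dataclass(frozen=True)
class EvalReport:
    sensitivity: float
    n_true: int
    n_recovered: int
    n_false_positive: int


def make_hmm_dataset(
    eps_error: float,
    delta: float,
    T: int,
    N: int,
    rng_seed,
) -> tuple[list[str], list[str], list[tuple[int, int]]]:
    """N jointly simulated pairs from the two-state binary model; the
    x-sides form the database, the y-sides the queries, and the truth is
    the index pairing (database i partners query i)."""
    if not 0 <= eps_error < 0.5:
        raise ValueError("eps_error must be in [0, 0.5)")
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    params = HMMParams.symmetric_binary(eps_error, delta)
    rng = np.random.default_rng(rng_seed)
    database, queries, truth = [], [], []
    for i in range(N):
        pair = sample_hmm_pair(params, T, rng)
        database.append(pair.x)
        queries.append(pair.y)
        truth.append((i, i))
    return database, queries, truth


def make_genome_reads(
    genome_len: int,
    n_reads: int,
    mean_len: int,
    total_error: float,
    indel_frac: float,
    rng_seed,
    with_rc: bool = True,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[ReadTruth]]:
    """Uniform-random genome plus reads with per-base errors.

    Each template base is substituted with probability
    ``total_error * (1 - indel_frac)``, and an insertion or a deletion each
    occur with probability ``total_error * indel_frac / 2``.  Read lengths
    jitter uniformly within +-20% of ``mean_len``; origins are uniform;
    half the reads are reverse-complemented when ``with_rc``.
    """
    if mean_len >= genome_len:
        raise ValueError("mean_len must be < genome_len")
    if not 0 <= total_error < 1:
        raise ValueError("total_error must be in [0, 1)")
    if not 0 <= indel_frac <= 1:
        raise ValueError("indel_frac must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    genome = "".join(DNA[b] for b in rng.integers(0, 4, size=genome_len))
    p_sub = total_error * (1 - indel_frac)
    p_ins = p_del = total_error * indel_frac / 2

    reads: list[tuple[str, str]] = []
    truth: list[ReadTruth] = []
    for i in range(n_reads):
        tlen = int(rng.integers(int(0.8 * mean_len), int(1.2 * mean_len) + 1))
        tlen = min(tlen, genome_len)
        start = int(rng.integers(0, genome_len - tlen + 1))
        template = genome[start : start + tlen]
        out = []
        n_err = 0
        for ch in template:
            u = rng.random()
            if u < p_del:
                n_err += 1
                continue
            if u < p_del + p_ins:
                out.append(DNA[rng.integers(0, 4)])
                n_err += 1
            if rng.random() < p_sub:
                choices = [c for c in DNA if c != ch]
                out.append(choices[rng.integers(0, 3)])
                n_err += 1
            else:
                out.append(ch)
        seq = "".join(out)
        strand = "+"
        if with_rc and rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        rid = f"read{i}"
        reads.append((rid, seq))
        truth.append(
            ReadTruth(
                read_id=rid,
                ref_id="ref0",
                true_start=start,
                true_end=start + tlen,
                strand=strand,
                error_rate_applied=n_err / max(1, tlen),
            )
        )
    return [("ref0", genome)], reads, truth


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def evaluate_hits(
    hits: list[Hit], truth: list[ReadTruth], overlap_frac: float = 0.5
) -> EvalReport:
    """Sensitivity and false positives against simulated truth.

    A truth row is recovered when some hit for its read, on the same
    reference and strand, overlaps the true interval by at least
    ``overlap_frac`` of the true length.  Hits recovering no truth row at
    that threshold are false positives.
    """
    if not truth:
        raise ValueError("empty truth table")
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    by_read: dict[str, list[ReadTruth]] = {}
    for t in truth:
        by_read.setdefault(t.read_id, []).append(t)

    recovered: set[int] = set()
    n_fp = 0
    truth_ids = {(t.read_id, t.true_start, t.true_end, t.strand): i for i, t in enumerate(truth)}
    for h in hits:
        matched = False
        for t in by_read.get(h.query_id, ()):
            if t.ref_id != h.ref_id or t.strand != h.strand:
                continue
            need = overlap_frac * (t.true_end - t.true_start)
            if _overlap(h.ref_start, h.ref_end, t.true_start, t.true_end) >= need:
                recovered.add(truth_ids[(t.read_id, t.true_start, t.true_end, t.strand)])
                matched = True
        if not matched:
            n_fp += 1
    n_true = len(truth)
    n_rec = len(recovered)
    return EvalReport(
        sensitivity=n_rec / n_true,
        n_true=n_true,
        n_recovered=n_rec,
        n_false_positive=n_fp,
    )


def verifiable_truth(
    reference: list[tuple[str, str]],
    reads: list[tuple[str, str]],
    truth: list[ReadTruth],
    params,
    llr_threshold: float = 0.0,
    window_pad: float = 0.25,
) -> list[ReadTruth]:
    """Truth rows that full-DP window verification can recover at all.

    Only a window overlapping a read's true origin can count toward
    recovering that truth row, so the exhaustive-verification reference is
    computed by running the full log-likelihood-ratio DP on each read's
    padded true window; rows scoring below the threshold are unrecoverable
    by any verification-based method and are excluded from the relative
    sensitivity denominator.
    """
    from .dsb_sa import encode_dna, sa_llr_window

    ref_map = dict(reference)
    read_map = dict(reads)
    out: list[ReadTruth] = []
    for t in truth:
        ref_seq = ref_map[t.ref_id]
        seq = read_map[t.read_id]
        if t.strand == "-":
            seq = reverse_complement(seq)
        pad = int(window_pad * len(seq))
        w0 = max(0, t.true_start - pad)
        w1 = min(len(ref_seq), t.true_end + pad)
        score = sa_llr_window(params, encode_dna(ref_seq[w0:w1]), encode_dna(seq))
        if score >= llr_threshold:
            out.append(t)
    return out
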