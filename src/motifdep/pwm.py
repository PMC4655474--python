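"""Position weight matrix, first-order Markov background, and genome scanning.

A motif of width ``L`` is summarized as an ``L x 4`` probability matrix
(columns A, C, G, T).  Candidate windows are scored as the log-odds between
the PWM product probability and a first-order Markov background estimated
from the genome being scanned:

    score(w) = sum_p log probs[p][w_p]  -  log P_bg(w),
    P_bg(w)  = initial(w_1) * prod_p transition(w_p | w_{p-1}).

Scores are in natural-log units internally; BED export reports bits
(log base 2).  Both strands are scanned; a minus-strand hit stores the
reverse-complemented window and its offset on the forward strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqs import (
    ALPHABET,
    AlphabetError,
    BindingSiteSet,
    Genome,
    encode,
    reverse_complement,
)

__all__ = [
    "CountMatrix",
    "PWM",
    "MarkovBackground",
    "ScanHit",
    "estimate_background",
    "build_pwm",
    "score_window",
    "scan_genome",
    "unique_hit_sequences",
    "permute_columns",
    "information_content",
    "hits_to_bed",
]


@dataclass(frozen=True)
class CountMatrix:
    """Per-position base counts of an aligned site set (columns A,C,G,T)."""

    counts: np.ndarray  # (L, 4) ints
    n_sites: int

    @classmethod
    def from_sites(cls, sites: BindingSiteSet) -> "CountMatrix":
        arr = sites.as_array()
        counts = np.stack([(arr == b).sum(axis=0) for b in range(4)], axis=1)
        return cls(counts=counts, n_sites=len(sites))

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix; every row sums to 1."""

    probs: np.ndarray  # (L, 4)
    pseudocount: float = 1.0
    name: str = "pwm"

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    def to_tsv(self) -> str:
        """JASPAR-like 4 x L tab-separated matrix (rows A, C, G, T)."""
        lines = [">" + self.name]
        for b, base in enumerate(ALPHABET):
            lines.append(base + "\t" + "\t".join(f"{p:.6g}" for p in self.probs[:, b]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PWM":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        name = lines[0][1:].strip() if lines[0].startswith(">") else "pwm"
        rows = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows[parts[0]] = [float(x) for x in parts[1:]]
        probs = np.array([rows[b] for b in ALPHABET]).T
        return cls(probs=probs, name=name)


@dataclass(frozen=True)
class MarkovBackground:
    """First-order Markov genomic background (Laplace-smoothed)."""

    initial: np.ndarray  # (4,)
    transition: np.ndarray  # (4, 4), row-stochastic

    def log_window_prob(self, window_idx: np.ndarray) -> float:
        return float(
            np.log(self.initial[window_idx[0]])
            + np.log(self.transition[window_idx[:-1], window_idx[1:]]).sum()
        )


@dataclass(frozen=True)
class ScanHit:
    """A scored genome window. ``offset`` is 0-based on the forward strand;
    for strand '-' the stored window is the reverse complement of the slice."""

    offset: int
    strand: str
    window: str
    score: float


def estimate_background(genome: Genome) -> MarkovBackground:
    """Estimate the first-order background from all adjacent non-N pairs
    on the given strand, with +1 (Laplace) smoothing."""
    arr = genome.as_array()
    usable = arr >= 0
    if usable.sum() < 2:
        raise ValueError("genome has fewer than 2 non-N bases")
    mono = np.array([(arr == b).sum() for b in range(4)], dtype=float)
    initial = (mono + 1.0) / (mono.sum() + 4.0)
    a, b = arr[:-1], arr[1:]
    ok = (a >= 0) & (b >= 0)
    trans = np.ones((4, 4))  # +1 smoothing
    np.add.at(trans, (a[ok], b[ok]), 1.0)
    transition = trans / trans.sum(axis=1, keepdims=True)
    return MarkovBackground(initial=initial, transition=transition)


def build_pwm(sites: BindingSiteSet, pseudocount: float = 1.0, name: str | None = None) -> PWM:
    """probs[p][b] = (count[p][b] + pseudocount) / (n + 4 * pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    cm = CountMatrix.from_sites(sites)
    probs = (cm.counts + pseudocount) / (cm.n_sites + 4.0 * pseudocount)
    return PWM(probs=probs, pseudocount=pseudocount, name=name or sites.tf_name)


def score_window(pwm: PWM, bg: MarkovBackground, window: str) -> float:
    """Log-odds score (natural log) of one window."""
    idx = encode(window.upper())
    if len(idx) != pwm.length:
        raise ValueError(f"window length {len(idx)} != motif width {pwm.length}")
    if (idx < 0).any():
        raise AlphabetError("window contains N or non-ACGT characters; not scoreable")
    idx = idx.astype(np.intp)
    fg = float(pwm.log_probs()[np.arange(pwm.length), idx].sum())
    return fg - bg.log_window_prob(idx)


def _strand_scores(
    arr: np.ndarray, pwm: PWM, bg: MarkovBackground
) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all N-free windows of one strand array.

    Returns (window start indices in *arr*, scores)."""
    L = pwm.length
    if len(arr) < L:
        return np.empty(0, dtype=np.intp), np.empty(0)
    W = sliding_window_view(arr, L)
    valid = (W >= 0).all(axis=1)
    starts = np.flatnonzero(valid)
    Wv = W[starts].astype(np.intp)
    lp = pwm.log_probs()
    fg = lp[np.arange(L), Wv].sum(axis=1)
    bgs = np.log(bg.initial[Wv[:, 0]]) + np.log(
        bg.transition[Wv[:, :-1], Wv[:, 1:]]
    ).sum(axis=1)
    return starts, fg - bgs


def scan_genome(
    pwm: PWM,
    bg: MarkovBackground,
    genome: Genome,
    min_score: float,
    max_score: float = np.inf,
    min_inclusive: bool = False,
    max_inclusive: bool = False,
) -> list[ScanHit]:
    """Scan both strands; keep windows whose score lies in the requested band.

    The default band is open at both ends (``min_score < score < max_score``),
    matching a strict "greater than zero" retention rule; the low-scoring
    negative pool uses the closed lower bound ``-2 <= score < 0`` via
    ``min_inclusive=True``.
    Hits are sorted by offset, then strand ('+' before '-').
    """
    L = pwm.length
    n = len(genome)
    if L > n:
        raise ValueError("motif wider than genome")
    arr = genome.as_array()
    rc = np.where(arr >= 0, 3 - arr, -1)[::-1].astype(np.int8)

    def keep(scores: np.ndarray) -> np.ndarray:
        lo = scores >= min_score if min_inclusive else scores > min_score
        hi = scores <= max_score if max_inclusive else scores < max_score
        return lo & hi

    hits: list[ScanHit] = []
    seq = genome.sequence
    starts, scores = _strand_scores(arr, pwm, bg)
    sel = keep(scores)
    for i, s in zip(starts[sel], scores[sel]):
        hits.append(ScanHit(int(i), "+", seq[i : i + L], float(s)))
    starts, scores = _strand_scores(rc, pwm, bg)
    sel = keep(scores)
    for j, s in zip(starts[sel], scores[sel]):
        off = n - int(j) - L
        hits.append(ScanHit(off, "-", reverse_complement(seq[off : off + L]), float(s)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def unique_hit_sequences(hits, collapse_revcomp: bool = False) -> list[str]:
    """Deduplicated window strings in first-occurrence order.

    With ``collapse_revcomp`` a window and its reverse complement count as
    one (the first one seen is kept)."""
    seen: set[str] = set()
    out: list[str] = []
    for h in hits:
        key = h.window
        if key in seen:
            continue
        if collapse_revcomp and reverse_complement(key) in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


def permute_columns(pwm: PWM, seed: int) -> PWM:
    """Permute motif positions (rows of ``probs``) uniformly at random;
    the identity permutation is resampled away (guaranteed for L >= 2)."""
    L = pwm.length
    if L < 2:
        raise ValueError("need at least 2 positions to permute")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(L)
        if not np.array_equal(perm, np.arange(L)):
            break
    return PWM(probs=pwm.probs[perm], pseudocount=pwm.pseudocount, name=pwm.name + "_permuted")


def information_content(counts_or_pwm) -> tuple[list[float], float]:
    """Per-position information content in bits and its width-normalized mean.

    IC_p = 2 + sum_b f_pb log2 f_pb with 0*log0 = 0; frequencies are raw
    column frequencies (counts / n) for a CountMatrix or site set, or the
    stored probabilities for a PWM.  Uses a uniform reference (no background
    correction).
    """
    if isinstance(counts_or_pwm, BindingSiteSet):
        counts_or_pwm = CountMatrix.from_sites(counts_or_pwm)
    if isinstance(counts_or_pwm, CountMatrix):
        freqs = counts_or_pwm.counts / counts_or_pwm.n_sites
    elif isinstance(counts_or_pwm, PWM):
        freqs = counts_or_pwm.probs
    else:
        freqs = np.asarray(counts_or_pwm, dtype=float)
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    per_pos = 2.0 + plogp.sum(axis=1)
    return [float(x) for x in per_pos], float(per_pos.mean())


def hits_to_bed(hits, genome: Genome, name_prefix: str = "hit") -> str:
    """BED6 (0-based half-open) with the score column in bits."""
    lines = []
    L = len(hits[0].window) if hits else 0
    for k, h in enumerate(hits):
        rec_id, rec_start = genome.id, 0
        for rid, lo, hi in genome.record_bounds:
            if lo <= h.offset < hi:
                rec_id, rec_start = rid, lo
                break
        lines.append(
            "\t".join(
                [
                    rec_id,
                    str(h.offset - rec_start),
                    str(h.offset - rec_start + len(h.window)),
                    f"{name_prefix}{k+1}",
                    f"{h.score / np.log(2):.4f}",
                    h.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
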