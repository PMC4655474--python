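"""Labeled training matrix: dummy-coded bases, binary association features,
and the 30:1 negative set.

Each position of a width-L sequence contributes three coded single-base
features using a sum-to-zero dummy coding:

    A -> ( 1, 0, 0)    C -> (0, 1, 0)    G -> (0, 0, 1)    T -> (-1,-1,-1)

laid out at coded indices n = 3(p-1)+1 .. 3(p-1)+3.  Each association
feature contributes one binary column: 1 iff every member base is present.

Negatives come from three procedures, 10 per positive each: windows of a
column-permuted PWM scanning above 0, random sequences GC-matched to the
positive set, and genome windows scoring in [-2, 0).  The pooled negatives
are deduplicated, purged of positive strings, and reported with provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mining import AssociationFeature
from .pwm import PWM, MarkovBackground, permute_columns, scan_genome, unique_hit_sequences
from .seqs import ALPHABET, BASE_INDEX, AlphabetError, BindingSiteSet, Genome, encode

__all__ = [
    "BASE_CODES",
    "dummy_code",
    "dummy_decode",
    "coded_feature_names",
    "association_code",
    "negatives_permuted",
    "negatives_gc_random",
    "negatives_low_score",
    "assemble_design",
    "DesignMatrix",
]

log = logging.getLogger(__name__)

BASE_CODES = {
    "A": (1, 0, 0),
    "C": (0, 1, 0),
    "G": (0, 0, 1),
    "T": (-1, -1, -1),
}
_CODE_MATRIX = np.array([BASE_CODES[b] for b in ALPHABET], dtype=float)  # (4, 3)


def dummy_code(sequence: str) -> np.ndarray:
    """Code a length-L sequence into its 3L vector of coded features."""
    seq = sequence.upper()
    if any(c not in BASE_CODES for c in seq):
        raise AlphabetError(f"cannot dummy-code non-ACGT sequence {sequence!r}")
    idx = [BASE_INDEX[c] for c in seq]
    return _CODE_MATRIX[idx].reshape(-1)


def dummy_decode(z: np.ndarray) -> str:
    """Inverse of :func:`dummy_code` (the coding is injective)."""
    z = np.asarray(z, dtype=float)
    if z.size % 3:
        raise ValueError("coded vector length must be a multiple of 3")
    out = []
    for block in z.reshape(-1, 3):
        match = [b for b, code in BASE_CODES.items() if np.array_equal(block, code)]
        if not match:
            raise ValueError(f"block {block} is not a valid base code")
        out.append(match[0])
    return "".join(out)


def coded_feature_names(L: int) -> list[str]:
    """Z column names: Z{n}({base}{p}) with n = 3(p-1)+i, i = 1..3 for A,C,G."""
    names = []
    for p in range(1, L + 1):
        for i, base in enumerate("ACG"):
            names.append(f"Z{3 * (p - 1) + i + 1}({base}{p})")
    return names


def association_code(sequence: str, features: list[AssociationFeature]) -> np.ndarray:
    """Binary vector: a_j = 1 iff every member item of feature j is present."""
    seq = sequence.upper()
    out = np.zeros(len(features))
    for j, f in enumerate(features):
        if all(seq[item.pos - 1] == item.base for item in f.members):
            out[j] = 1.0
    return out


def _draw_unique(pool: list[str], need: int, rng, what: str, exclude=frozenset()) -> list[str]:
    pool = [s for s in pool if s not in exclude]
    if len(pool) < need:
        warnings.warn(
            f"{what}: only {len(pool)} unique sequences available, needed {need}",
            stacklevel=3,
        )
        return list(pool)
    picked = rng.choice(len(pool), size=need, replace=False)
    return [pool[i] for i in sorted(picked)]


def negatives_permuted(
    pwm: PWM,
    bg: MarkovBackground,
    genome: Genome,
    n_pos: int,
    X: int = 10,
    seed: int = 0,
    exclude=frozenset(),
) -> list[str]:
    """X * n_pos unique windows of a column-permuted PWM scoring above 0.

    ``exclude`` removes already-used strings (positives, earlier pools) so
    the pooled negative set stays non-redundant."""
    rng = np.random.default_rng(seed)
    perm = permute_columns(pwm, seed=int(rng.integers(2**31 - 1)))
    hits = scan_genome(perm, bg, genome, min_score=0.0)
    pool = unique_hit_sequences(hits)
    return _draw_unique(pool, X * n_pos, rng, "permuted-PWM negatives", exclude)


def negatives_gc_random(
    positives: BindingSiteSet, X: int = 10, seed: int = 0, exclude=frozenset()
) -> list[str]:
    """X * n_pos distinct random sequences GC-matched to the pooled
    positive set (i.i.d. per base; duplicate or excluded draws redrawn)."""
    rng = np.random.default_rng(seed)
    g = positives.gc_fraction
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]  # A C G T
    need = X * len(positives)
    out: list[str] = []
    seen: set[str] = set()
    for _attempt in range(60):
        draws = rng.choice(4, size=(need, positives.length), p=probs)
        for row in draws:
            s = "".join(ALPHABET[b] for b in row)
            if s in seen or s in exclude:
                continue
            seen.add(s)
            out.append(s)
            if len(out) == need:
                return out
    warnings.warn(
        f"GC-matched negatives: only {len(out)} distinct sequences drawn, "
        f"needed {need}",
        stacklevel=2,
    )
    return out


def negatives_low_score(
    pwm: PWM,
    bg: MarkovBackground,
    genome: Genome,
    n_pos: int,
    X: int = 10,
    seed: int = 0,
    exclude=frozenset(),
) -> list[str]:
    """X * n_pos unique genome windows with -2 <= score < 0."""
    rng = np.random.default_rng(seed)
    hits = scan_genome(
        pwm, bg, genome, min_score=-2.0, max_score=0.0, min_inclusive=True
    )
    pool = unique_hit_sequences(hits)
    return _draw_unique(pool, X * n_pos, rng, "low-score negatives", exclude)


@dataclass
class DesignMatrix:
    """Rows = labeled sequences; columns = 3L coded + K association features."""

    X: np.ndarray  # (n, 3L + K)
    y: np.ndarray  # (n,) of 0/1
    sequences: list[str]
    provenance: list[str]  # per row: positive | permuted | gc-random | low-score
    feature_names: list[str]
    features: list[AssociationFeature]
    L: int
    shortfalls: dict = field(default_factory=dict)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return int((1 - self.y).sum())

    @property
    def K(self) -> int:
        return len(self.features)

    def to_tsv(self) -> str:
        header = "sequence\tlabel\tprovenance\t" + "\t".join(self.feature_names)
        lines = [header]
        for i in range(len(self.y)):
            vals = "\t".join(f"{v:g}" for v in self.X[i])
            lines.append(
                f"{self.sequences[i]}\t{int(self.y[i])}\t{self.provenance[i]}\t{vals}"
            )
        return "\n".join(lines) + "\n"


def assemble_design(
    positives: BindingSiteSet,
    features: list[AssociationFeature],
    neg_pools: dict[str, list[str]],
) -> DesignMatrix:
    """Assemble the labeled design matrix from positives and negative pools.

    Negatives are pooled in the given pool order, deduplicated by exact
    string, and purged of any sequence identical to a positive; shortfalls
    against the nominal pool sizes are recorded (and logged), never fatal.
    Positives keep duplicates (identical sites at different loci), which is
    logged when it happens.
    """
    L = positives.length
    pos_set = set(positives.sequences)
    if len(pos_set) < len(positives):
        log.info(
            "positive set has %d duplicate sequences (kept)",
            len(positives) - len(pos_set),
        )
    sequences: list[str] = list(positives.sequences)
    provenance: list[str] = ["positive"] * len(positives)
    seen: set[str] = set()
    shortfalls: dict[str, int] = {}
    for pool_name, pool in neg_pools.items():
        kept = 0
        for s in pool:
            s = s.upper()
            if s in pos_set or s in seen:
                continue
            if len(s) != L:
                raise ValueError(f"negative of length {len(s)} != motif width {L}")
            seen.add(s)
            sequences.append(s)
            provenance.append(pool_name)
            kept += 1
        if kept < len(pool):
            shortfalls[pool_name] = len(pool) - kept
            log.info(
                "negative pool %r: %d of %d sequences dropped as redundant",
                pool_name,
                len(pool) - kept,
                len(pool),
            )
    n_neg = len(sequences) - len(positives)
    if n_neg == 0:
        raise ValueError("no negatives left after deduplication")
    y = np.array([1] * len(positives) + [0] * n_neg, dtype=float)
    arr = np.vstack([encode(s) for s in sequences]).astype(np.intp)
    Z = _CODE_MATRIX[arr].reshape(len(sequences), 3 * L)
    if features:
        A = np.empty((len(sequences), len(features)))
        for j, f in enumerate(features):
            mask = np.ones(len(sequences), dtype=bool)
            for item in f.members:
                mask &= arr[:, item.pos - 1] == BASE_INDEX[item.base]
            A[:, j] = mask
        Xmat = np.hstack([Z, A])
    else:
        Xmat = Z
    names = coded_feature_names(L) + [f.id for f in features]
    return DesignMatrix(
        X=Xmat,
        y=y,
        sequences=sequences,
        provenance=provenance,
        feature_names=names,
        features=list(features),
        L=L,
        shortfalls=shortfalls,
    )
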