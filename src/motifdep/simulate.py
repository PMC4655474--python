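"""Synthetic genomes and motif sets with planted within-motif dependence.

The generator emulates the statistical structure the modeling pipeline
assumes: a genomic background (i.i.d. or first-order Markov), a set of
aligned binding sites whose independent positions follow per-position
marginals of a chosen information content, and one or more position groups
whose bases are drawn jointly from a user-specified distribution (for
example an inverted-repeat pair constrained to {CG, AT}).  Every planted
site is inserted into the genome at a known, non-overlapping offset on a
known strand, so downstream scanning, mining and model fitting can be
checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .seqs import ALPHABET, BASE_INDEX, BindingSiteSet, Genome, decode, reverse_complement

__all__ = [
    "DependencyGroup",
    "SyntheticTruth",
    "generate_synthetic_case",
    "consensus_prob_for_ic",
    "paired_dependency",
    "dependence_recovery_case",
]


@dataclass(frozen=True)
class DependencyGroup:
    """A group of motif positions with a joint base distribution.

    ``positions`` are 1-based motif positions; ``joint`` maps base strings
    (one base per position, in the order of ``positions``) to probabilities
    summing to 1.
    """

    positions: tuple[int, ...]
    joint: dict[str, float]

    def __post_init__(self) -> None:
        k = len(self.positions)
        if k < 2:
            raise ValueError("a dependency group needs at least 2 positions")
        if len(set(self.positions)) != k:
            raise ValueError("dependency group positions must be distinct")
        total = 0.0
        for pat, p in self.joint.items():
            if len(pat) != k or any(b not in BASE_INDEX for b in pat):
                raise ValueError(f"pattern {pat!r} does not match positions {self.positions}")
            if p < 0:
                raise ValueError("joint probabilities must be nonnegative")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"joint distribution sums to {total}, not 1")


def paired_dependency(pos_a: int, pos_b: int, patterns=("CG", "AT"), probs=None) -> DependencyGroup:
    """Convenience constructor for a two-position joint dependence."""
    if probs is None:
        probs = [1.0 / len(patterns)] * len(patterns)
    return DependencyGroup((pos_a, pos_b), dict(zip(patterns, probs)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic case: where sites were planted and from
    which distributions they were drawn."""

    planted_positions: tuple[tuple[int, str], ...]  # (0-based offset, "+"/"-")
    dependency_spec: tuple[DependencyGroup, ...]
    marginals: tuple[tuple[float, float, float, float], ...]  # L x 4, A C G T

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_positions": [[o, s] for o, s in self.planted_positions],
                "dependency_spec": [
                    {"positions": list(g.positions), "joint": g.joint}
                    for g in self.dependency_spec
                ],
                "marginals": [list(row) for row in self.marginals],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_positions=tuple((int(o), s) for o, s in d["planted_positions"]),
            dependency_spec=tuple(
                DependencyGroup(tuple(g["positions"]), dict(g["joint"]))
                for g in d["dependency_spec"]
            ),
            marginals=tuple(tuple(row) for row in d["marginals"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def consensus_prob_for_ic(target: float) -> float:
    """Probability of the consensus base giving a column information content
    of ``target`` bits when the three other bases share the remainder.

    IC(c) = 2 + c*log2(c) + (1-c)*log2((1-c)/3), monotone on c in [1/4, 1].
    """
    if not 0.0 <= target <= 2.0:
        raise ValueError("information content per position must be in [0, 2]")
    if target == 0.0:
        return 0.25
    if target >= 2.0 - 1e-12:
        return 1.0

    def ic(c: float) -> float:
        rest = (1.0 - c) / 3.0
        h = -c * np.log2(c)
        if rest > 0:
            h -= 3 * rest * np.log2(rest)
        return 2.0 - h - target

    return float(brentq(ic, 0.25 + 1e-12, 1.0 - 1e-12))


def _sample_markov(n: int, initial: np.ndarray, transition: np.ndarray, rng) -> np.ndarray:
    """Sample a length-n base-index sequence from a first-order chain."""
    out = np.empty(n, dtype=np.int8)
    cum_init = np.cumsum(initial)
    cum_trans = np.cumsum(transition, axis=1)
    u = rng.random(n)
    out[0] = np.searchsorted(cum_init, u[0])
    for i in range(1, n):
        out[i] = np.searchsorted(cum_trans[out[i - 1]], u[i])
    return out


def generate_synthetic_case(
    width: int,
    n_sites: int,
    genome_len: int,
    dependency_spec=(),
    info_content_target=1.5,
    seed: int = 0,
    background_order: int = 1,
    tf_name: str = "synthetic",
    background_concentration: float = 30.0,
    marginal_overrides: dict | None = None,
) -> tuple[Genome, BindingSiteSet, SyntheticTruth]:
    """Generate a genome with planted motif instances and return the truth.

    Parameters
    ----------
    width : motif width L (>= 2).
    n_sites : number of planted instances (also the positive set size).
    genome_len : background genome length before planting.
    dependency_spec : iterable of :class:`DependencyGroup`; groups must be
        disjoint.  Positions not covered by any group are drawn independently
        from a consensus-biased marginal at ``info_content_target`` bits.
    info_content_target : information content (bits, 0..2) of the
        independent positions; either one value for all of them or a
        sequence of per-position values of length ``width`` (entries at
        dependency-group positions are ignored).  Real motifs are
        heterogeneous -- a conserved core plus variable flanks -- so
        per-position profiles give the most faithful fixtures.
    background_order : 0 for i.i.d. background, 1 for a first-order Markov
        chain whose rows are drawn from a Dirichlet around uniform.
    background_concentration : Dirichlet concentration of the background
        distribution(s); larger means closer to uniform.
    marginal_overrides : optional {1-based position: (pA, pC, pG, pT)}
        replacing the consensus-based marginal at selected independent
        positions -- e.g. a degenerate two-base (IUPAC R/Y/W/S style)
        column as ``{4: (0.5, 0, 0, 0.5)}``.

    Deterministic given identical parameters and seed.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    groups = tuple(dependency_spec)
    covered: set[int] = set()
    for g in groups:
        if not all(1 <= p <= width for p in g.positions):
            raise ValueError(f"dependency positions {g.positions} outside 1..{width}")
        if covered & set(g.positions):
            raise ValueError("dependency groups must be disjoint")
        covered |= set(g.positions)
    if genome_len < 2 * n_sites * width + width:
        raise ValueError(
            f"genome of length {genome_len} too short to place {n_sites} "
            f"non-overlapping sites of width {width}"
        )

    rng = np.random.default_rng(seed)

    # --- background model ----------------------------------------------
    if background_order == 0:
        initial = rng.dirichlet([background_concentration] * 4)
        transition = np.tile(initial, (4, 1))
    elif background_order == 1:
        initial = rng.dirichlet([background_concentration] * 4)
        transition = rng.dirichlet([background_concentration] * 4, size=4)
    else:
        raise ValueError("background_order must be 0 or 1")
    genome_arr = _sample_markov(genome_len, initial, transition, rng)

    # --- per-position marginals ----------------------------------------
    ic_targets = np.broadcast_to(
        np.asarray(info_content_target, dtype=float), (width,)
    )
    consensus = rng.integers(0, 4, size=width)
    marginals = np.empty((width, 4))
    for p in range(width):
        c = consensus_prob_for_ic(float(ic_targets[p]))
        marginals[p] = (1.0 - c) / 3.0
        marginals[p, consensus[p]] = c
    for pos, dist in (marginal_overrides or {}).items():
        if not 1 <= pos <= width:
            raise ValueError(f"override position {pos} outside 1..{width}")
        dist = np.asarray(dist, dtype=float)
        if dist.shape != (4,) or abs(dist.sum() - 1.0) > 1e-9 or (dist < 0).any():
            raise ValueError(f"override at position {pos} is not a distribution")
        marginals[pos - 1] = dist
    # positions inside dependency groups follow the group's induced marginal
    for g in groups:
        for k, pos in enumerate(g.positions):
            m = np.zeros(4)
            for pat, p in g.joint.items():
                m[BASE_INDEX[pat[k]]] += p
            marginals[pos - 1] = m

    # --- draw sites ------------------------------------------------------
    sites = np.empty((n_sites, width), dtype=np.int8)
    for p in range(width):
        sites[:, p] = rng.choice(4, size=n_sites, p=marginals[p])
    for g in groups:
        patterns = list(g.joint)
        probs = np.array([g.joint[p] for p in patterns])
        choice = rng.choice(len(patterns), size=n_sites, p=probs)
        for k, pos in enumerate(g.positions):
            bases = np.array([BASE_INDEX[pat[k]] for pat in patterns], dtype=np.int8)
            sites[:, pos - 1] = bases[choice]
    site_strings = tuple(decode(row) for row in sites)

    # --- plant sites without overlap -------------------------------------
    taken: list[tuple[int, int]] = []
    planted: list[tuple[int, str]] = []
    max_attempts = 200 * n_sites + 200
    attempts = 0
    for i in range(n_sites):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError("genome too short to place sites without overlap")
            off = int(rng.integers(0, genome_len - width + 1))
            if all(off + width <= a or off >= b for a, b in taken):
                break
        taken.append((off, off + width))
        strand = "+" if rng.random() < 0.5 else "-"
        s = site_strings[i] if strand == "+" else reverse_complement(site_strings[i])
        genome_arr[off : off + width] = np.frombuffer(
            bytes(BASE_INDEX[ch] for ch in s), dtype=np.int8
        )
        planted.append((off, strand))

    genome = Genome(id=f"{tf_name}_genome", sequence=decode(genome_arr))
    positives = BindingSiteSet(tf_name, site_strings)
    truth = SyntheticTruth(
        planted_positions=tuple(planted),
        dependency_spec=groups,
        marginals=tuple(tuple(float(x) for x in row) for row in marginals),
    )
    return genome, positives, truth


def dependence_recovery_case(
    seed: int,
    width: int = 12,
    n_sites: int = 200,
    genome_len: int = 100_000,
    pair: tuple[int, int] = (2, 5),
    patterns: tuple[str, str] = ("CG", "AT"),
) -> tuple[Genome, BindingSiteSet, SyntheticTruth]:
    """The standard planted-dependence fixture: a specific TF motif of
    width 12 with one jointly-varying position pair.

    The independent positions mimic how specific TF motifs actually look in
    sequence logos: a handful of invariant core positions (2 bits, here
    positions 1, 3, 7 and 11) surrounded by degenerate two-base columns
    (IUPAC R/Y/W/S style, 1 bit, equiprobable).  The degenerate columns keep
    the planted instances diverse enough to survive hit deduplication while
    the invariant core keeps partial-match background windows rare -- both
    are needed for the planted joint dependence to remain visible among the
    unique candidate windows the mining stage sees.
    """
    core = [p for p in (1, 3, 7, 11) if p <= width and p not in pair]
    profile = np.full(width, 0.7)
    profile[[p - 1 for p in core]] = 2.0
    two_base = {"CG": (0.0, 0.5, 0.5, 0.0), "AT": (0.5, 0.0, 0.0, 0.5)}
    overrides = {
        p: two_base["CG" if i % 2 == 0 else "AT"]
        for i, p in enumerate(
            q for q in range(1, width + 1) if q not in core and q not in pair
        )
    }
    return generate_synthetic_case(
        width=width,
        n_sites=n_sites,
        genome_len=genome_len,
        dependency_spec=[DependencyGroup(pair, {patterns[0]: 0.5, patterns[1]: 0.5})],
        info_content_target=profile,
        seed=seed,
        marginal_overrides=overrides,
        tf_name=f"planted_{seed}",
    )
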