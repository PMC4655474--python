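"""Association-feature mining over motif positions.

Candidate sequences (genome windows scoring above zero) are turned into
transactions of single-base items -- "C2" meaning cytosine at motif position
2 -- and mined for frequent itemsets with the Apriori algorithm.  Valid
positive and negative association rules are derived from every bipartition
of each frequent itemset, filtered by minimum confidence ``mc`` and minimum
correlation strength ``MCS`` (a phi coefficient), and finally integrated
into association features: one feature per distinct base itemset.

Because every transaction carries exactly one item per position, itemsets
mixing two bases at one position can never be frequent and are pruned during
candidate generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .seqs import ALPHABET, BASE_INDEX, AlphabetError, validate_equal_length

__all__ = [
    "Item",
    "parse_item",
    "TransactionDB",
    "FrequentItemset",
    "AssociationRule",
    "AssociationFeature",
    "POLARITIES",
    "itemize",
    "support",
    "apriori",
    "rule_measures",
    "derive_rules",
    "integrate_features",
    "rules_to_tsv",
]

#: rule polarities; "!" marks a complemented (absent) itemset
POLARITIES = ("A->B", "A->!B", "!A->B", "!A->!B")


class Item(NamedTuple):
    """A single-base feature: *base* at 1-based motif position *pos*."""

    base: str
    pos: int

    def __str__(self) -> str:
        return f"{self.base}{self.pos}"

    @property
    def code(self) -> int:
        return (self.pos - 1) * 4 + BASE_INDEX[self.base]


def parse_item(text: str) -> Item:
    base, pos = text[0], text[1:]
    if base not in BASE_INDEX or not pos.isdigit():
        raise ValueError(f"cannot parse item {text!r}")
    return Item(base, int(pos))


def _item_from_code(code: int) -> Item:
    return Item(ALPHABET[code % 4], code // 4 + 1)


class TransactionDB:
    """Transactions of single-base items, one item per motif position.

    Stored as an (n, L) int8 matrix of base indices; multiplicity is kept."""

    def __init__(self, array: np.ndarray):
        if array.ndim != 2 or array.shape[0] == 0 or array.shape[1] == 0:
            raise ValueError("transaction database must be a nonempty (n, L) matrix")
        self.array = array
        self.n, self.length = array.shape
        # one boolean column per item code, used for fast support counting
        self._onehot = np.zeros((self.n, 4 * self.length), dtype=bool)
        for b in range(4):
            self._onehot[:, b::4] = array == b

    def itemset_mask(self, codes: Sequence[int]) -> np.ndarray:
        m = self._onehot[:, codes[0]].copy()
        for c in codes[1:]:
            m &= self._onehot[:, c]
        return m


class FrequentItemset(NamedTuple):
    items: frozenset
    support: float


@dataclass(frozen=True)
class AssociationRule:
    """A -> B (or a complemented polarity) over a frequent base itemset X = A u B."""

    antecedent: frozenset
    consequent: frozenset
    polarity: str
    confidence: float
    correlation: float
    support_x: float
    support_a: float
    support_b: float

    @property
    def base_itemset(self) -> frozenset:
        return self.antecedent | self.consequent

    def __str__(self) -> str:
        a = ",".join(str(i) for i in sorted(self.antecedent, key=lambda x: (x.pos, x.base)))
        b = ",".join(str(i) for i in sorted(self.consequent, key=lambda x: (x.pos, x.base)))
        return self.polarity.replace("A", "{" + a + "}", 1).replace("B", "{" + b + "}", 1)


def feature_id(members: Iterable[Item]) -> str:
    return ":".join(str(i) for i in sorted(members, key=lambda x: (x.pos, x.base)))


@dataclass(frozen=True)
class AssociationFeature:
    """A set of >= 2 single-base features integrated from valid rules that
    share one base itemset.  Encoded downstream as a binary all-members-present
    indicator."""

    members: frozenset
    source_rules: tuple = ()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an association feature needs at least 2 members")

    @property
    def id(self) -> str:
        return feature_id(self.members)

    @property
    def positions(self) -> frozenset:
        return frozenset(i.pos for i in self.members)

    def __str__(self) -> str:
        return self.id


def itemize(sequences: Sequence[str]) -> TransactionDB:
    """Convert equal-length ACGT sequences into transactions (one item per
    position); multiplicity is preserved."""
    if not sequences:
        raise ValueError("no sequences to itemize")
    L = validate_equal_length(sequences)
    if L == 0:
        raise ValueError("cannot itemize empty sequences")
    arr = np.empty((len(sequences), L), dtype=np.int8)
    for i, s in enumerate(sequences):
        s = s.upper()
        if any(c not in BASE_INDEX for c in s):
            raise AlphabetError(f"sequence {i} contains non-ACGT characters")
        arr[i] = [BASE_INDEX[c] for c in s]
    return TransactionDB(arr)


def support(itemset: Iterable[Item], db: TransactionDB) -> float:
    """Fraction of transactions containing every item of *itemset*."""
    codes = [i.code for i in itemset]
    if not codes:
        raise ValueError("support of an empty itemset is undefined")
    return float(db.itemset_mask(codes).mean())


def apriori(
    db: TransactionDB, min_support: float, max_itemset_size: int = 6
) -> list[FrequentItemset]:
    """All itemsets of size <= max_itemset_size with support >= min_support.

    Levelwise candidate generation by (k-1)-prefix join with anti-monotone
    pruning; candidates holding two items at one position are pruned a
    priori.  A warning is emitted if the size cap may have truncated the
    lattice.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    if max_itemset_size < 2:
        raise ValueError("max_itemset_size must be >= 2")
    n = db.n
    sup1 = db._onehot.mean(axis=0)
    level = {}
    out: list[FrequentItemset] = []
    for code in np.flatnonzero(sup1 >= min_support):
        t = (int(code),)
        level[t] = db._onehot[:, code]
        out.append(FrequentItemset(frozenset([_item_from_code(code)]), float(sup1[code])))

    k = 1
    frequent_keys = set(level)
    while level and k < max_itemset_size:
        keys = sorted(level)
        nxt = {}
        for a_i in range(len(keys)):
            ta = keys[a_i]
            for b_i in range(a_i + 1, len(keys)):
                tb = keys[b_i]
                if ta[:-1] != tb[:-1]:
                    break  # sorted: prefixes no longer match
                last_a, last_b = ta[-1], tb[-1]
                if last_a // 4 == last_b // 4:
                    continue  # two bases at one position never co-occur
                cand = ta + (last_b,)
                # anti-monotone prune: every (k)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent_keys
                    for j in range(len(cand) - 1)
                ):
                    continue
                mask = level[ta] & db._onehot[:, last_b]
                s = mask.sum() / n
                if s >= min_support:
                    nxt[cand] = mask
                    out.append(
                        FrequentItemset(
                            frozenset(_item_from_code(c) for c in cand), float(s)
                        )
                    )
        frequent_keys = set(nxt)
        level = nxt
        k += 1
    if level and k == max_itemset_size and max_itemset_size < db.length:
        warnings.warn(
            f"frequent itemsets reached the size cap ({max_itemset_size}); "
            "larger dependencies may have been truncated",
            stacklevel=2,
        )
    return out


def _phi(sup_a: float, sup_b: float, sup_x: float) -> float:
    denom = sup_a * (1.0 - sup_a) * sup_b * (1.0 - sup_b)
    if denom <= 0.0:
        return 0.0
    return (sup_x - sup_a * sup_b) / float(np.sqrt(denom))


def rule_measures(A: Iterable[Item], B: Iterable[Item], db: TransactionDB) -> tuple[float, float]:
    """Confidence P(B|A) and phi correlation of the rule A -> B.

    correlation = (sup(AuB) - sup(A)sup(B)) / sqrt(sup(A)(1-sup(A))sup(B)(1-sup(B))),
    defined as 0 when either marginal support is 0 or 1.
    """
    A, B = frozenset(A), frozenset(B)
    if not A or not B:
        raise ValueError("A and B must be nonempty")
    if A & B:
        raise ValueError("A and B must be disjoint")
    sup_a = support(A, db)
    if sup_a == 0.0:
        raise ZeroDivisionError("confidence undefined: sup(A) = 0")
    sup_b = support(B, db)
    sup_x = support(A | B, db)
    return sup_x / sup_a, _phi(sup_a, sup_b, sup_x)


def _polarity_measures(
    polarity: str, sup_a: float, sup_b: float, sup_x: float
) -> tuple[float, float] | None:
    """(confidence, signed correlation) of one polarity, or None if the
    conditioning event has probability 0."""
    phi = _phi(sup_a, sup_b, sup_x)
    if polarity == "A->B":
        if sup_a == 0.0:
            return None
        return sup_x / sup_a, phi
    if polarity == "A->!B":
        if sup_a == 0.0:
            return None
        return (sup_a - sup_x) / sup_a, -phi
    if polarity == "!A->B":
        if sup_a == 1.0:
            return None
        return (sup_b - sup_x) / (1.0 - sup_a), -phi
    if polarity == "!A->!B":
        if sup_a == 1.0:
            return None
        return (1.0 - sup_a - sup_b + sup_x) / (1.0 - sup_a), phi
    raise ValueError(f"unknown polarity {polarity!r}")


def derive_rules(
    frequents: Sequence[FrequentItemset],
    db: TransactionDB,
    mc: float,
    MCS: float,
    polarities: Iterable[str] = POLARITIES,
) -> list[AssociationRule]:
    """Valid rules from every ordered bipartition (A, B) of every frequent
    itemset X with |X| >= 2, across the requested polarities.

    A rule is valid iff confidence >= mc and |correlation| >= MCS; the
    correlation magnitude is the phi coefficient of (A, B), with a sign per
    polarity (negated when exactly one side is complemented).
    """
    if not 0.0 < mc <= 1.0:
        raise ValueError("mc must be in (0, 1]")
    if not 0.0 <= MCS <= 1.0:
        raise ValueError("MCS must be in [0, 1]")
    polarities = tuple(polarities)
    for p in polarities:
        if p not in POLARITIES:
            raise ValueError(f"unknown polarity {p!r}")
    sup_map = {fs.items: fs.support for fs in frequents}
    rules: list[AssociationRule] = []
    for fs in frequents:
        X = fs.items
        if len(X) < 2:
            continue
        items = sorted(X, key=lambda i: i.code)
        m = len(items)
        for mask in range(1, 2**m - 1):
            A = frozenset(items[j] for j in range(m) if mask >> j & 1)
            B = X - A
            sup_a = sup_map.get(A)
            sup_b = sup_map.get(B)
            if sup_a is None:
                sup_a = support(A, db)
            if sup_b is None:
                sup_b = support(B, db)
            for pol in polarities:
                res = _polarity_measures(pol, sup_a, sup_b, fs.support)
                if res is None:
                    continue
                conf, corr = res
                if conf >= mc and abs(corr) >= MCS:
                    rules.append(
                        AssociationRule(
                            antecedent=A,
                            consequent=B,
                            polarity=pol,
                            confidence=conf,
                            correlation=corr,
                            support_x=fs.support,
                            support_a=sup_a,
                            support_b=sup_b,
                        )
                    )
    return rules


def integrate_features(rules: Sequence[AssociationRule]) -> list[AssociationFeature]:
    """One association feature per distinct base itemset X among the valid
    rules, regardless of rule polarity or direction."""
    by_x: dict[frozenset, list[AssociationRule]] = {}
    for r in rules:
        by_x.setdefault(r.base_itemset, []).append(r)
    feats = [
        AssociationFeature(members=x, source_rules=tuple(rs)) for x, rs in by_x.items()
    ]
    feats.sort(key=lambda f: f.id)
    return feats


def rules_to_tsv(rules: Sequence[AssociationRule]) -> str:
    header = "rule\tpolarity\tsupport_x\tconfidence\tcorrelation"
    lines = [header]
    for r in rules:
        lines.append(
            f"{r}\t{r.polarity}\t{r.support_x:.6g}\t{r.confidence:.6g}\t{r.correlation:.6g}"
        )
    return "\n".join(lines) + "\n"
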