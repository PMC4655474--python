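"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the definitions, not the
package internals: itemsets are Python frozensets, supports are counted by
subset tests over explicit transaction sets, and rule measures are computed
from directly counted probabilities.
"""

from itertools import combinations, product

from motifdep.mining import Item


def transactions_from_sequences(sequences):
    """Each sequence becomes a frozenset of (base, 1-based position) items."""
    return [
        frozenset(Item(b, p + 1) for p, b in enumerate(s)) for s in sequences
    ]


def brute_support(itemset, transactions):
    return sum(1 for t in transactions if itemset <= t) / len(transactions)


def brute_frequent_itemsets(sequences, min_support, max_size):
    """Exhaustive enumeration of all itemsets with at most one item per
    position, sizes 1..max_size."""
    transactions = transactions_from_sequences(sequences)
    L = len(sequences[0])
    out = {}
    for k in range(1, max_size + 1):
        for positions in combinations(range(1, L + 1), k):
            for bases in product("ACGT", repeat=k):
                itemset = frozenset(Item(b, p) for b, p in zip(bases, positions))
                s = brute_support(itemset, transactions)
                if s >= min_support:
                    out[itemset] = s
    return out


def brute_phi(sup_a, sup_b, sup_x):
    denom = sup_a * (1 - sup_a) * sup_b * (1 - sup_b)
    if denom <= 0:
        return 0.0
    return (sup_x - sup_a * sup_b) / denom**0.5


def brute_rules(sequences, min_support, mc, mcs, max_size):
    """All valid rules over all bipartitions of all frequent itemsets, every
    polarity, with measures computed from directly counted event
    probabilities (not support identities)."""
    transactions = transactions_from_sequences(sequences)
    n = len(transactions)
    frequents = brute_frequent_itemsets(sequences, min_support, max_size)
    rules = {}
    for X in frequents:
        if len(X) < 2:
            continue
        items = sorted(X, key=lambda i: (i.pos, i.base))
        for k in range(1, len(items)):
            for A_items in combinations(items, k):
                A = frozenset(A_items)
                B = X - A
                in_a = [A <= t for t in transactions]
                in_b = [B <= t for t in transactions]
                p_a = sum(in_a) / n
                p_b = sum(in_b) / n
                p_ab = sum(a and b for a, b in zip(in_a, in_b)) / n
                phi = brute_phi(p_a, p_b, p_ab)
                cands = []
                if p_a > 0:
                    p_b_given_a = sum(
                        a and b for a, b in zip(in_a, in_b)
                    ) / sum(in_a)
                    cands.append(("A->B", p_b_given_a, phi))
                    p_notb_given_a = sum(
                        a and not b for a, b in zip(in_a, in_b)
                    ) / sum(in_a)
                    cands.append(("A->!B", p_notb_given_a, -phi))
                if p_a < 1:
                    n_nota = n - sum(in_a)
                    p_b_given_nota = sum(
                        (not a) and b for a, b in zip(in_a, in_b)
                    ) / n_nota
                    cands.append(("!A->B", p_b_given_nota, -phi))
                    p_notb_given_nota = sum(
                        (not a) and (not b) for a, b in zip(in_a, in_b)
                    ) / n_nota
                    cands.append(("!A->!B", p_notb_given_nota, phi))
                for pol, conf, corr in cands:
                    if conf >= mc and abs(corr) >= mcs:
                        rules[(A, B, pol)] = (conf, corr)
    return rules
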