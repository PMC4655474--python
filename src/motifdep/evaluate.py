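"""Model assessment: cross-validation, AUC, threshold screening, and the
binding-configuration graph.

Cross-validation adapts to the positive-set size: leave-one-out over the
positives when there are ten or fewer of them (prokaryotic TFs often have
single-digit numbers of curated sites), ten-fold otherwise.  The whole
pipeline -- PWM, scanning, mining,
negative-set construction, fitting -- is re-run inside each training fold,
so held-out positives can never influence the trained fold model.  Held-out
positives are scored together with fold-local negatives (30 per held-out
positive, drawn by the same three procedures from fold-specific seeds) and
all out-of-fold scores are pooled into a single rank-based AUC.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy import stats

from .design import assemble_design
from .elrm import ELRMModel, FitConfig, fit_elrm, predict_probability, select_features
from .mining import FrequentItemset, apriori, itemize
from .pipeline import MiningThresholds, _negative_pools, mine_features
from .pwm import build_pwm, estimate_background, scan_genome, unique_hit_sequences
from .seqs import ALPHABET, BindingSiteSet, Genome

__all__ = [
    "CVResult",
    "ThresholdGrids",
    "ScreeningResult",
    "ModelGraph",
    "auc",
    "fold_count",
    "cross_validate",
    "screen_thresholds",
    "specificity_correlation",
    "readout_overlap",
    "detect_multi_config",
    "export_graph",
]


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    AUC = (sum of positive midranks - n_pos(n_pos+1)/2) / (n_pos * n_neg);
    exact (1.0) on separable inputs, unlike trapezoid summation.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def fold_count(n_pos: int) -> int:
    """Leave-one-out for ten or fewer positives, ten-fold otherwise."""
    return n_pos if n_pos <= 10 else 10


@dataclass
class CVResult:
    """Pooled out-of-fold scores; every sample is scored exactly once."""

    fold_assignments: np.ndarray  # fold index per pooled sample
    labels: np.ndarray
    scores: np.ndarray
    auc: float
    n_folds: int


@dataclass
class _FoldContext:
    """Everything a training fold needs, independent of mining thresholds."""

    fold: int
    train_sites: BindingSiteSet
    test_pos: list[str]
    test_neg: list[str]
    db: object  # TransactionDB | None
    neg_pools: dict
    fit_seed: int
    base_frequents: list[FrequentItemset] | None = None


def _make_fold_contexts(
    positives: BindingSiteSet,
    genome: Genome,
    seed: int,
    X_neg: int = 10,
    base_min_support: float | None = None,
    max_itemset_size: int = 6,
    collapse_revcomp: bool = False,
) -> list[_FoldContext]:
    n_pos = len(positives)
    if n_pos < 2:
        raise ValueError("cross-validation needs at least 2 positives")
    n_folds = fold_count(n_pos)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pos)
    fold_of = np.empty(n_pos, dtype=int)
    for i, idx in enumerate(order):
        fold_of[idx] = i % n_folds

    contexts: list[_FoldContext] = []
    for k in range(n_folds):
        test_idx = np.flatnonzero(fold_of == k)
        train_idx = np.flatnonzero(fold_of != k)
        train_sites = BindingSiteSet(
            positives.tf_name, tuple(positives.sequences[i] for i in train_idx)
        )
        frng = np.random.default_rng([seed, k])
        train_neg_seed, eval_neg_seed, fit_seed = (
            int(x) for x in frng.integers(2**31 - 1, size=3)
        )
        pwm = build_pwm(train_sites)
        bg = estimate_background(genome)
        hits = scan_genome(pwm, bg, genome, min_score=0.0)
        windows = unique_hit_sequences(hits, collapse_revcomp=collapse_revcomp)
        db = itemize(windows) if windows else None
        base_freq = (
            apriori(db, base_min_support, max_itemset_size=max_itemset_size)
            if db is not None and base_min_support is not None
            else None
        )
        pools = _negative_pools(pwm, bg, genome, train_sites, X_neg, train_neg_seed)
        # fold-local evaluation negatives: 3 * X_neg per held-out positive
        n_test = len(test_idx)
        eval_sites = BindingSiteSet(
            positives.tf_name,
            tuple(positives.sequences[i] for i in test_idx) * 2
            if n_test == 1
            else tuple(positives.sequences[i] for i in test_idx),
        )
        eval_pools = _negative_pools(pwm, bg, genome, eval_sites, X_neg, eval_neg_seed)
        test_neg: list[str] = []
        seen: set[str] = set()
        budget = 3 * X_neg * n_test
        for pool in eval_pools.values():
            for s in pool:
                if s not in seen:
                    seen.add(s)
                    test_neg.append(s)
                if len(test_neg) >= budget:
                    break
            if len(test_neg) >= budget:
                break
        contexts.append(
            _FoldContext(
                fold=k,
                train_sites=train_sites,
                test_pos=[positives.sequences[i] for i in test_idx],
                test_neg=test_neg,
                db=db,
                neg_pools=pools,
                fit_seed=fit_seed,
                base_frequents=base_freq,
            )
        )
    return contexts


def _evaluate_contexts(
    contexts: list[_FoldContext],
    thresholds: MiningThresholds,
    fit_config: FitConfig,
) -> CVResult:
    all_scores: list[float] = []
    all_labels: list[int] = []
    fold_assign: list[int] = []
    for ctx in contexts:
        features, _ = mine_features(ctx.db, thresholds, ctx.base_frequents)
        design = assemble_design(ctx.train_sites, features, ctx.neg_pools)
        model = fit_elrm(design, replace(fit_config, seed=ctx.fit_seed))
        for s in ctx.test_pos:
            all_scores.append(predict_probability(model, s))
            all_labels.append(1)
            fold_assign.append(ctx.fold)
        for s in ctx.test_neg:
            all_scores.append(predict_probability(model, s))
            all_labels.append(0)
            fold_assign.append(ctx.fold)
    labels = np.array(all_labels)
    scores = np.array(all_scores)
    return CVResult(
        fold_assignments=np.array(fold_assign),
        labels=labels,
        scores=scores,
        auc=auc(labels, scores),
        n_folds=len(contexts),
    )


def cross_validate(
    positives: BindingSiteSet,
    genome: Genome,
    thresholds: MiningThresholds = MiningThresholds(),
    fit_config: FitConfig = FitConfig(),
    seed: int = 0,
    X_neg: int = 10,
) -> CVResult:
    """Pooled out-of-fold AUC with the full pipeline re-run per fold."""
    contexts = _make_fold_contexts(
        positives,
        genome,
        seed,
        X_neg=X_neg,
        max_itemset_size=thresholds.max_itemset_size,
        collapse_revcomp=thresholds.collapse_revcomp,
    )
    return _evaluate_contexts(contexts, thresholds, fit_config)


@dataclass(frozen=True)
class ThresholdGrids:
    """The screening grid: 3 supports x 4 confidences x 4 correlation
    strengths = 48 settings."""

    supports: tuple = (0.1, 0.15, 0.2)
    confidences: tuple = (0.5, 0.6, 0.7, 0.8)
    correlations: tuple = (0.05, 0.1, 0.15, 0.2)

    def settings(self) -> list[tuple[float, float, float]]:
        return list(product(self.supports, self.confidences, self.correlations))


@dataclass
class ScreeningResult:
    settings: list[tuple[float, float, float]]  # (min_support, mc, MCS)
    aucs: np.ndarray  # (n_settings, n_cases)
    stable: np.ndarray  # bool per setting
    outlier_budget: int
    optimal_index: int | None

    @property
    def optimal(self) -> tuple[float, float, float] | None:
        return None if self.optimal_index is None else self.settings[self.optimal_index]


def _tukey_low_outliers(values: np.ndarray) -> int:
    q1, q3 = np.percentile(values, [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    return int((values < fence).sum())


def screen_thresholds(
    cases: list[tuple[BindingSiteSet, Genome]],
    grids: ThresholdGrids = ThresholdGrids(),
    fit_config: FitConfig = FitConfig(),
    seed: int = 0,
    X_neg: int = 10,
    min_worst_auc: float = 0.8,
    outlier_budget: int | None = None,
    thresholds_template: MiningThresholds = MiningThresholds(),
) -> ScreeningResult:
    """Evaluate every grid setting by cross-validated AUC across the cases.

    A setting is *stable* when its per-case AUC distribution has at most
    ``outlier_budget`` low outliers (Tukey's rule, below Q1 - 1.5 IQR;
    budget defaults to ceil(6/86 * n_cases)) and its worst-case AUC exceeds
    ``min_worst_auc``.  The optimum is the stable setting with the smallest
    AUC standard deviation, ties broken by the larger mean AUC.

    The fold split, the negative sets and the scan results are fixed per
    (case, seed) and shared across all settings, so the comparison isolates
    the mining thresholds.
    """
    if not cases:
        raise ValueError("need at least one case")
    settings = grids.settings()
    if outlier_budget is None:
        outlier_budget = math.ceil(6 / 86 * len(cases))
    base_support = min(grids.supports)
    case_contexts = [
        _make_fold_contexts(
            pos,
            gen,
            seed=int(np.random.default_rng([seed, ci]).integers(2**31 - 1)),
            X_neg=X_neg,
            base_min_support=base_support,
            max_itemset_size=thresholds_template.max_itemset_size,
            collapse_revcomp=thresholds_template.collapse_revcomp,
        )
        for ci, (pos, gen) in enumerate(cases)
    ]
    aucs = np.zeros((len(settings), len(cases)))
    for si, (ms, mc, mcs) in enumerate(settings):
        th = replace(thresholds_template, min_support=ms, mc=mc, MCS=mcs)
        for ci, contexts in enumerate(case_contexts):
            aucs[si, ci] = _evaluate_contexts(contexts, th, fit_config).auc
    stable = np.array(
        [
            _tukey_low_outliers(aucs[si]) <= outlier_budget
            and aucs[si].min() > min_worst_auc
            for si in range(len(settings))
        ]
    )
    optimal_index: int | None = None
    if stable.any():
        sds = aucs.std(axis=1, ddof=1) if len(cases) > 1 else aucs.std(axis=1)
        means = aucs.mean(axis=1)
        candidates = np.flatnonzero(stable)
        # smallest SD, ties broken by the largest mean
        best = min(candidates, key=lambda i: (round(sds[i], 12), -round(means[i], 12)))
        optimal_index = int(best)
    return ScreeningResult(
        settings=settings,
        aucs=aucs,
        stable=stable,
        outlier_budget=outlier_budget,
        optimal_index=optimal_index,
    )


def specificity_correlation(pairs) -> float:
    """Pearson correlation between association-feature ratio and
    width-normalized information content across models."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (ratio, IC) pairs")
    if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
        warnings.warn("zero variance in one variable; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(arr[:, 0], arr[:, 1])[0])


def _assoc_positions(model: ELRMModel, tolerance: float = 0.0) -> set[int]:
    _, assoc = select_features(model, tolerance)
    selected_ids = {fid for fid, _ in assoc}
    out: set[int] = set()
    for f in model.features:
        if f.id in selected_ids:
            out |= {i.pos for i in f.members}
    return out


def readout_overlap(
    model: ELRMModel, readout_positions: set[int], tolerance: float = 0.0
) -> tuple[float, float]:
    """Overlap between base-readout positions and the positions covered by
    the selected association features.

    Returns (fraction of readout positions inside association features,
    fraction of association-feature positions that are readout).  The second
    fraction is 0 (with a warning) when no association feature survived.
    """
    readout = set(readout_positions)
    if any(p < 1 or p > model.L for p in readout):
        raise ValueError("readout positions must lie in 1..L")
    assoc = _assoc_positions(model, tolerance)
    frac_readout = len(readout & assoc) / len(readout) if readout else 0.0
    if not assoc:
        warnings.warn("no selected association features; readout fraction set to 0")
        return frac_readout, 0.0
    return frac_readout, len(assoc & readout) / len(assoc)


def detect_multi_config(
    model: ELRMModel, tolerance: float = 0.0
) -> list[tuple[int, list[str]]]:
    """Positions that participate in the selected association features with
    two or more different bases -- i.e. positions admitting more than one
    binding configuration.  Returns (position, sorted bases), ascending."""
    _, assoc = select_features(model, tolerance)
    selected_ids = {fid for fid, _ in assoc}
    bases_at: dict[int, set[str]] = {}
    for f in model.features:
        if f.id in selected_ids:
            for item in f.members:
                bases_at.setdefault(item.pos, set()).add(item.base)
    return [(p, sorted(bs)) for p, bs in sorted(bases_at.items()) if len(bs) >= 2]


@dataclass
class ModelGraph:
    """Graph view of a fitted model: single-base features are nodes,
    association features are hyperedges among them."""

    nodes: list[dict]  # {id, base, pos, coefficient, associated}
    hyperedges: list[dict]  # {id, members, coefficient}

    def validate(self) -> None:
        ids = {n["id"] for n in self.nodes}
        for e in self.hyperedges:
            missing = set(e["members"]) - ids
            if missing:
                raise ValueError(f"hyperedge {e['id']} has dangling endpoints {missing}")
            if not all(np.isfinite(n["coefficient"]) for n in self.nodes):
                raise ValueError("non-finite node coefficient")

    def to_json(self) -> str:
        return json.dumps({"nodes": self.nodes, "hyperedges": self.hyperedges}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelGraph":
        d = json.loads(text)
        return cls(nodes=d["nodes"], hyperedges=d["hyperedges"])

    def to_dot(self) -> str:
        """DOT serialization; hyperedges with more than two endpoints are
        expanded through a point-shaped star node."""
        lines = ["graph elrm {"]
        for n in self.nodes:
            rank = "top" if n["associated"] else "bottom"
            lines.append(
                f'  "{n["id"]}" [shape=box,label="{n["id"]}\\n{n["coefficient"]:.3g}",group="{rank}"];'
            )
        for k, e in enumerate(self.hyperedges):
            if len(e["members"]) == 2:
                a, b = e["members"]
                lines.append(f'  "{a}" -- "{b}" [label="{e["coefficient"]:.3g}"];')
            else:
                star = f"assoc_{k}"
                lines.append(f'  "{star}" [shape=point,label=""];')
                for m in e["members"]:
                    lines.append(f'  "{star}" -- "{m}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


def export_graph(model: ELRMModel, tolerance: float = 0.0) -> ModelGraph:
    """Build the binding-configuration graph of a fitted model.

    Nodes are the selected single-base features plus every member of a
    selected association feature (with its decoded coefficient, which may be
    zero); hyperedges are the selected association features.
    """
    singles, assoc = select_features(model, tolerance)
    selected_ids = {fid for fid, _ in assoc}
    node_ids: dict[str, dict] = {}
    associated: set[str] = set()
    edges: list[dict] = []
    base_col = {b: i for i, b in enumerate(ALPHABET)}
    for f, coef in zip(model.features, model.beta_a):
        if f.id not in selected_ids:
            continue
        members = sorted((str(i) for i in f.members), key=lambda s: (int(s[1:]), s[0]))
        edges.append({"id": f.id, "members": members, "coefficient": float(coef)})
        for item in f.members:
            nid = str(item)
            associated.add(nid)
            if nid not in node_ids:
                node_ids[nid] = {
                    "id": nid,
                    "base": item.base,
                    "pos": item.pos,
                    "coefficient": float(model.decoded[item.pos - 1, base_col[item.base]]),
                    "associated": True,
                }
    for pos, base, coef in singles:
        nid = f"{base}{pos}"
        if nid not in node_ids:
            node_ids[nid] = {
                "id": nid,
                "base": base,
                "pos": pos,
                "coefficient": float(coef),
                "associated": False,
            }
    for nid in associated:
        node_ids[nid]["associated"] = True
    graph = ModelGraph(
        nodes=sorted(node_ids.values(), key=lambda n: (n["pos"], n["base"])),
        hyperedges=edges,
    )
    graph.validate()
    return graph
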