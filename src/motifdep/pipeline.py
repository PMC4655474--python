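"""End-to-end model construction for one TF.

Workflow: build the PWM from the positive set, estimate the first-order
background from the genome, scan both strands, mine association features
from the unique windows scoring above zero, draw the three 10-per-positive
negative pools, assemble the coded design matrix, and fit the elastic-net
logistic model with cross-validated lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .design import (
    DesignMatrix,
    assemble_design,
    negatives_gc_random,
    negatives_low_score,
    negatives_permuted,
)
from .elrm import ELRMModel, FitConfig, fit_elrm
from .mining import (
    POLARITIES,
    AssociationFeature,
    AssociationRule,
    TransactionDB,
    apriori,
    derive_rules,
    integrate_features,
    itemize,
)
from .pwm import (
    PWM,
    MarkovBackground,
    build_pwm,
    estimate_background,
    scan_genome,
    unique_hit_sequences,
)
from .seqs import BindingSiteSet, Genome

__all__ = ["MiningThresholds", "TrainResult", "mine_features", "train_model"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MiningThresholds:
    """Mining knobs; the defaults are the screening optimum (support 0.2,
    confidence 0.6, correlation strength 0.1)."""

    min_support: float = 0.2
    mc: float = 0.6
    MCS: float = 0.1
    max_itemset_size: int = 6
    polarities: tuple = POLARITIES
    collapse_revcomp: bool = False


@dataclass
class TrainResult:
    model: ELRMModel
    design: DesignMatrix
    pwm: PWM
    background: MarkovBackground
    features: list[AssociationFeature]
    rules: list[AssociationRule]
    n_hits: int
    n_transactions: int


def mine_features(
    db: TransactionDB | None,
    thresholds: MiningThresholds,
    base_frequents=None,
) -> tuple[list[AssociationFeature], list[AssociationRule]]:
    """Mine association features from a transaction database.

    ``base_frequents`` may carry a frequent-itemset list mined at a lower
    support threshold; it is then filtered instead of re-mined (the frequent
    lattice at a higher support is exactly the filtered one).
    """
    if db is None:
        return [], []
    if base_frequents is not None:
        frequents = [f for f in base_frequents if f.support >= thresholds.min_support]
    else:
        frequents = apriori(
            db, thresholds.min_support, max_itemset_size=thresholds.max_itemset_size
        )
    rules = derive_rules(
        frequents, db, thresholds.mc, thresholds.MCS, thresholds.polarities
    )
    return integrate_features(rules), rules


def _negative_pools(
    pwm: PWM,
    bg: MarkovBackground,
    genome: Genome,
    positives: BindingSiteSet,
    X_neg: int,
    seed: int,
) -> dict[str, list[str]]:
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(2**31 - 1, size=3))
    # each pool excludes the positives and all earlier pools, so the union
    # is non-redundant by construction (exactly 30 per positive when ample)
    exclude = set(positives.sequences)
    permuted = negatives_permuted(
        pwm, bg, genome, len(positives), X=X_neg, seed=s1, exclude=frozenset(exclude)
    )
    exclude.update(permuted)
    gc_random = negatives_gc_random(
        positives, X=X_neg, seed=s2, exclude=frozenset(exclude)
    )
    exclude.update(gc_random)
    low_score = negatives_low_score(
        pwm, bg, genome, len(positives), X=X_neg, seed=s3, exclude=frozenset(exclude)
    )
    return {"permuted": permuted, "gc-random": gc_random, "low-score": low_score}


def train_model(
    positives: BindingSiteSet,
    genome: Genome,
    thresholds: MiningThresholds = MiningThresholds(),
    fit_config: FitConfig = FitConfig(),
    seed: int = 0,
    X_neg: int = 10,
) -> TrainResult:
    """Run the whole pipeline for one TF; deterministic given *seed*."""
    rng = np.random.default_rng(seed)
    neg_seed, fit_seed = (int(x) for x in rng.integers(2**31 - 1, size=2))

    pwm = build_pwm(positives)
    bg = estimate_background(genome)
    hits = scan_genome(pwm, bg, genome, min_score=0.0)
    windows = unique_hit_sequences(hits, collapse_revcomp=thresholds.collapse_revcomp)
    db = itemize(windows) if windows else None
    features, rules = mine_features(db, thresholds)
    log.info(
        "%s: %d hits, %d unique windows, %d rules, %d association features",
        positives.tf_name,
        len(hits),
        len(windows),
        len(rules),
        len(features),
    )

    pools = _negative_pools(pwm, bg, genome, positives, X_neg, neg_seed)
    design = assemble_design(positives, features, pools)
    model = fit_elrm(design, replace(fit_config, seed=fit_seed))
    log.info(
        "%s: %d/%d rows, %d columns, lambda_opt=%.4g, %d single + %d association selected",
        positives.tf_name,
        design.n_pos,
        design.n_neg,
        design.X.shape[1],
        model.lambda_opt,
        len(model.selected_single),
        len(model.selected_assoc),
    )
    return TrainResult(
        model=model,
        design=design,
        pwm=pwm,
        background=bg,
        features=features,
        rules=rules,
        n_hits=len(hits),
        n_transactions=len(windows),
    )
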