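"""Cross-validation, AUC, screening, overlap metrics, graph export."""

import numpy as np
import pytest

import motifdep as md
from motifdep.elrm import FitConfig
from motifdep.evaluate import ModelGraph, _make_fold_contexts, _evaluate_contexts
from motifdep.mining import AssociationFeature, Item
from motifdep.pipeline import MiningThresholds

from .test_elrm import _manual_model


def _brute_auc(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_examples():
    assert md.auc([0, 0, 1, 1], [1, 2, 3, 4]) == 1.0
    assert md.auc([0, 1, 0, 1], [1, 2, 3, 4]) == 0.75
    with pytest.raises(ValueError):
        md.auc([1, 1], [0.2, 0.3])


def test_auc_matches_concordant_pair_count():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=n)  # with ties
        assert md.auc(labels, scores) == pytest.approx(_brute_auc(labels, scores))


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, size=10_000)
    scores = rng.random(10_000)
    assert md.auc(labels, scores) == pytest.approx(0.5, abs=0.02)


@pytest.mark.parametrize("n_pos,expected", [(4, 4), (10, 10), (11, 10), (50, 10)])
def test_fold_count_rule(n_pos, expected):
    assert md.fold_count(n_pos) == expected


@pytest.fixture(scope="module")
def perfect_case():
    """Fully conserved motif: every positive is the same string."""
    return md.generate_synthetic_case(
        width=8, n_sites=5, genome_len=10_000, info_content_target=2.0, seed=33
    )


def test_cross_validate_loo_structure_and_perfect_auc(perfect_case, quick_fit_config):
    genome, sites, _ = perfect_case
    cv = md.cross_validate(sites, genome, fit_config=quick_fit_config, seed=2)
    assert cv.n_folds == 5  # LOO for <= 10 positives
    # every sample scored exactly once, one positive per fold
    for k in range(cv.n_folds):
        fold_labels = cv.labels[cv.fold_assignments == k]
        assert fold_labels.sum() == 1
    assert cv.auc == 1.0


def test_cross_validate_switches_to_ten_fold(small_case, quick_fit_config):
    genome, sites, _ = small_case  # 30 positives
    contexts = _make_fold_contexts(sites, genome, seed=0)
    assert len(contexts) == 10
    sizes = [len(c.test_pos) for c in contexts]
    assert sum(sizes) == len(sites)


def test_heldout_positives_cannot_influence_fold_model(small_case, quick_fit_config):
    """Poisoning a held-out positive with a sentinel leaves the trained fold
    model bit-identical (no leakage through mining, negatives, or fitting)."""
    genome, sites, _ = small_case
    contexts = _make_fold_contexts(sites, genome, seed=4)
    # pick a held-out sequence that occurs exactly once in the site set so
    # replacing it by value touches only the held-out slot
    target = next(
        s
        for c in contexts
        for s in c.test_pos
        if sites.sequences.count(s) == 1
    )
    sentinel = "ACGTACGT"[: sites.length]
    assert sentinel != target
    poisoned_seqs = tuple(
        sentinel if s == target else s for s in sites.sequences
    )
    poisoned = md.BindingSiteSet(sites.tf_name, poisoned_seqs)
    contexts_p = _make_fold_contexts(poisoned, genome, seed=4)
    # find the fold holding out the poisoned index in the new split
    k = next(
        i for i, c in enumerate(contexts_p) if sentinel in c.test_pos
    )
    assert contexts[k].train_sites.sequences == contexts_p[k].train_sites.sequences
    assert contexts[k].neg_pools == contexts_p[k].neg_pools
    th = MiningThresholds()
    fc = FitConfig(n_lambda=8, lambda_min_ratio=0.01, cv_folds=4)
    from motifdep.design import assemble_design
    from motifdep.pipeline import mine_features

    models = []
    for ctx in (contexts[k], contexts_p[k]):
        features, _ = mine_features(ctx.db, th)
        design = assemble_design(ctx.train_sites, features, ctx.neg_pools)
        fc_fold = FitConfig(
            n_lambda=8, lambda_min_ratio=0.01, cv_folds=4, seed=ctx.fit_seed
        )
        models.append(md.fit_elrm(design, fc_fold))
    m1, m2 = models
    assert m1.intercept == m2.intercept
    assert np.array_equal(m1.beta_z, m2.beta_z)
    assert np.array_equal(m1.beta_a, m2.beta_a)
    assert [f.id for f in m1.features] == [f.id for f in m2.features]


def test_default_grid_has_48_settings():
    assert len(md.ThresholdGrids().settings()) == 48


def test_screen_single_setting_trivially_optimal(small_case, quick_fit_config):
    genome, sites, _ = small_case
    grids = md.ThresholdGrids(supports=(0.2,), confidences=(0.6,), correlations=(0.1,))
    res = md.screen_thresholds(
        [(sites, genome)], grids, fit_config=quick_fit_config, seed=1
    )
    assert len(res.settings) == 1
    if res.stable[0]:
        assert res.optimal == (0.2, 0.6, 0.1)
    else:
        assert res.optimal is None


def test_screen_reverifies_its_own_predicates(small_case, perfect_case, quick_fit_config):
    g1, s1, _ = small_case
    g2, s2, _ = perfect_case
    grids = md.ThresholdGrids(
        supports=(0.1, 0.2), confidences=(0.6, 0.8), correlations=(0.1,)
    )
    res = md.screen_thresholds(
        [(s1, g1), (s2, g2)], grids, fit_config=quick_fit_config, seed=3
    )
    assert res.aucs.shape == (4, 2)
    if res.optimal_index is not None:
        i = res.optimal_index
        assert res.stable[i]
        assert res.aucs[i].min() > 0.8
        sds = res.aucs.std(axis=1, ddof=1)
        assert all(
            sds[i] <= sds[j] + 1e-12 for j in np.flatnonzero(res.stable)
        )


def test_specificity_correlation():
    pairs = [(0.1, 0.5), (0.5, 1.2), (0.9, 1.9)]
    assert md.specificity_correlation(pairs) == pytest.approx(1.0)
    with pytest.warns(UserWarning):
        assert np.isnan(md.specificity_correlation([(0.5, 1.0)] * 4))
    with pytest.raises(ValueError):
        md.specificity_correlation([(0.1, 0.5), (0.2, 0.6)])


def test_readout_overlap():
    model = _manual_model(
        np.zeros((10, 4)), beta_a=np.array([1.0, 0.5]),
        features=["A2:C5", "C5:G7"],
    )
    fr, fa = md.readout_overlap(model, {2, 5, 9})
    assert fr == pytest.approx(2 / 3)  # 2 and 5 in features, 9 not
    assert fa == pytest.approx(2 / 3)  # of {2,5,7}, readout are {2,5}
    exact = md.readout_overlap(model, {2, 5, 7})
    assert exact == (1.0, 1.0)
    no_assoc = _manual_model(np.zeros((10, 4)), beta_a=np.zeros(0), features=[])
    with pytest.warns(UserWarning):
        assert md.readout_overlap(no_assoc, {2}) == (0.0, 0.0)
    with pytest.raises(ValueError):
        md.readout_overlap(model, {11})


def test_detect_multi_config():
    model = _manual_model(
        np.zeros((9, 4)),
        beta_a=np.array([6.8, 3.48, 3.05]),
        features=["T7:A8", "T7:T8", "C7:A8"],
    )
    assert md.detect_multi_config(model) == [(7, ["C", "T"]), (8, ["A", "T"])]
    one_per_pos = _manual_model(
        np.zeros((9, 4)), beta_a=np.array([1.0]), features=["A2:C5"]
    )
    assert md.detect_multi_config(one_per_pos) == []
    empty = _manual_model(np.zeros((9, 4)), beta_a=np.zeros(0), features=[])
    assert md.detect_multi_config(empty) == []


def test_export_graph_structure():
    decoded = np.zeros((9, 4))
    decoded[8] = [0.0, 0.0, 0.4, -0.4]  # G9 positive, T9 negative
    model = _manual_model(decoded, beta_a=np.array([1.2]), features=["A2:C5"])
    graph = md.export_graph(model)
    ids = {n["id"] for n in graph.nodes}
    assert ids == {"A2", "C5", "G9", "T9"}
    assert len(graph.hyperedges) == 1
    edge = graph.hyperedges[0]
    assert edge["members"] == ["A2", "C5"]
    assert edge["coefficient"] == pytest.approx(1.2)
    assoc_flags = {n["id"]: n["associated"] for n in graph.nodes}
    assert assoc_flags["A2"] and assoc_flags["C5"]
    assert not assoc_flags["G9"]


def test_export_graph_empty_model():
    model = _manual_model(np.zeros((4, 4)), beta_a=np.zeros(0), features=[])
    graph = md.export_graph(model)
    assert graph.nodes == [] and graph.hyperedges == []


def test_graph_json_roundtrip_and_dot():
    decoded = np.zeros((9, 4))
    model = _manual_model(
        decoded, beta_a=np.array([1.0, 2.0]), features=["A2:C5", "A2:C5:G7"]
    )
    graph = md.export_graph(model)
    back = ModelGraph.from_json(graph.to_json())
    assert back.to_json() == graph.to_json()
    dot = graph.to_dot()
    assert '"A2" -- "C5"' in dot
    assert "assoc_" in dot  # 3-member hyperedge expands through a star node
    back.validate()


def test_graph_validate_catches_dangling_edge():
    bad = ModelGraph(
        nodes=[{"id": "A2", "base": "A", "pos": 2, "coefficient": 0.1, "associated": True}],
        hyperedges=[{"id": "A2:C5", "members": ["A2", "C5"], "coefficient": 1.0}],
    )
    with pytest.raises(ValueError, match="dangling"):
        bad.validate()
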