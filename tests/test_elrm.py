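"""Elastic-net logistic fitting, decoding, selection, prediction."""

import subprocess
import textwrap

import numpy as np
import pytest

import motifdep as md
from motifdep._cd import enet_logistic_path, lambda_grid
from motifdep.elrm import ELRMModel, FitConfig, decode_coefficients
from motifdep.mining import AssociationFeature, Item


def _logistic_data(seed, n=300, p=12, sparse_truth=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:sparse_truth] = rng.choice([-2.0, 1.5, 2.0], size=sparse_truth)
    eta = X @ beta + 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def _toy_design(X, y, L, features=()):
    """Wrap a raw matrix as a DesignMatrix for fit_elrm."""
    from motifdep.design import DesignMatrix, coded_feature_names

    return DesignMatrix(
        X=X,
        y=y,
        sequences=[f"s{i}" for i in range(len(y))],
        provenance=["positive" if v else "neg" for v in y],
        feature_names=coded_feature_names(L) + [f.id for f in features],
        features=list(features),
        L=L,
    )


def test_path_matches_r_glmnet(tmp_path):
    """Independent oracle: coefficients along a shared lambda sequence agree
    with R glmnet (binomial, alpha = 0.5, no standardization)."""
    X, y = _logistic_data(0)
    lams = lambda_grid(X, y, 0.5, n_lambda=25, lambda_min_ratio=1e-3)
    b0s, betas = enet_logistic_path(
        X, y, lams, alpha=0.5, tol=1e-10, max_irls=50, dev_ratio_stop=1.0
    )
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    np.savetxt(tmp_path / "lams.csv", lams, delimiter=",")
    script = tmp_path / "oracle.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("X.csv", header=FALSE))
            y <- scan("y.csv", quiet=TRUE)
            lams <- scan("lams.csv", quiet=TRUE)
            fit <- glmnet(X, y, family="binomial", alpha=0.5, lambda=lams,
                          standardize=FALSE, thresh=1e-12)
            write.table(t(as.matrix(coef(fit))), "coefs.csv", sep=",",
                        row.names=FALSE, col.names=FALSE)
            """
        )
    )
    subprocess.run(
        ["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True
    )
    oracle = np.loadtxt(tmp_path / "coefs.csv", delimiter=",")
    ours = np.column_stack([b0s, betas])
    assert np.abs(ours - oracle).max() < 5e-4


def test_infinite_penalty_gives_null_model():
    X, y = _logistic_data(1)
    b0s, betas = enet_logistic_path(X, y, np.array([1e6]), alpha=0.5)
    assert np.all(betas == 0.0)
    prev = y.mean()
    assert b0s[0] == pytest.approx(np.log(prev / (1 - prev)), abs=1e-8)


def _duplicated_pair_data(seed=2, n=400):
    """A design whose only predictors are one signal column and its exact
    duplicate -- the clean setting in which the lasso concentrates weight on
    a single representative while ridge shares it."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-2.0 * x))).astype(float)
    return np.column_stack([x, x]), y


def test_lasso_picks_one_of_duplicated_columns():
    X, y = _duplicated_pair_data()
    lams = lambda_grid(X, y, 1.0, n_lambda=20, lambda_min_ratio=1e-2)
    _, betas = enet_logistic_path(X, y, lams, alpha=1.0)
    dup_active = (np.abs(betas) > 1e-8).sum(axis=1)
    assert dup_active.max() <= 1


def test_ridge_splits_duplicated_columns():
    X, y = _duplicated_pair_data()
    lams = lambda_grid(X, y, 0.0, n_lambda=10, lambda_min_ratio=1e-2)
    _, betas = enet_logistic_path(X, y, lams, alpha=0.0)
    last = betas[-1]
    assert last[0] != 0 and last[1] != 0
    assert last[0] == pytest.approx(last[1], rel=1e-3)


def test_decode_examples():
    decoded = decode_coefficients(np.array([1.0, 0, 0]))
    assert decoded.tolist() == [[1.0, 0.0, 0.0, -1.0]]
    assert decode_coefficients(np.zeros(3)).tolist() == [[0, 0, 0, 0]]
    assert decode_coefficients(np.array([1.0, 1, 1])).tolist() == [[1, 1, 1, -3]]


def test_decode_rows_sum_to_zero_exactly():
    rng = np.random.default_rng(4)
    decoded = decode_coefficients(rng.standard_normal(3 * 50))
    assert np.all(decoded.sum(axis=1) == 0.0)


def test_fit_elrm_validates_input():
    X, y = _logistic_data(5, n=60, p=6)
    with pytest.raises(ValueError, match="both labels"):
        md.fit_elrm(_toy_design(X, np.ones_like(y), 2))
    with pytest.raises(ValueError, match="no variation"):
        md.fit_elrm(_toy_design(np.zeros_like(X), y, 2))


def test_fit_elrm_selects_planted_signal():
    """The coded columns carrying the signal receive nonzero coefficients;
    pure-noise columns are mostly dropped."""
    rng = np.random.default_rng(6)
    n = 400
    X = rng.choice([-1.0, 0.0, 1.0], size=(n, 12))
    eta = 2.5 * X[:, 0] - 2.5 * X[:, 4] - 1.0
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    model = md.fit_elrm(_toy_design(X, y, 4), FitConfig(n_lambda=30, seed=0))
    assert model.beta_z[0] > 0.1
    assert model.beta_z[4] < -0.1
    assert model.path_nnz[0] == 0  # at lambda_max nothing is selected


def test_permuted_labels_select_almost_nothing():
    """Null sparsity: with labels shuffled, the CV-selected model keeps at
    most a few percent of the columns on average."""
    rng = np.random.default_rng(7)
    n, p = 600, 42
    X = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
    y = np.array([1.0] * 100 + [0.0] * (n - 100))
    rates = []
    for seed in range(20):
        perm = np.random.default_rng(seed).permutation(n)
        model = md.fit_elrm(
            _toy_design(X, y[perm], p // 3),
            FitConfig(n_lambda=15, seed=seed),
        )
        rates.append(np.mean(model.beta_z != 0))
    assert np.mean(rates) <= 0.05


def test_lambda_path_nnz_monotone():
    X, y = _logistic_data(8, n=500, p=15)
    model = md.fit_elrm(_toy_design(X, y, 5), FitConfig(n_lambda=40, seed=1))
    nnz = model.path_nnz
    # lambda decreases along the path, so nnz must not decrease
    assert np.all(np.diff(nnz) >= 0)


def test_select_features_tolerance():
    decoded = decode_coefficients(np.array([0.5, 0, 0, 0, 0, 0]))
    model = _manual_model(decoded, beta_a=np.array([0.2]), features=["A1:C2"])
    singles, assoc = md.select_features(model)
    assert {(p, b) for p, b, _ in singles} == {(1, "A"), (1, "T")}
    assert assoc == [("A1:C2", 0.2)]
    assert md.select_features(model, tolerance=np.inf) == ([], [])
    zero = _manual_model(np.zeros((2, 4)), beta_a=np.zeros(1), features=["A1:C2"])
    assert md.select_features(zero) == ([], [])


def _manual_model(decoded, beta_a, features, intercept=0.0):
    L = decoded.shape[0]
    beta_z = decoded[:, :3].reshape(-1)
    feats = [
        AssociationFeature(
            frozenset(Item(t[0], int(t[1:])) for t in fid.split(":"))
        )
        for fid in features
    ]
    return ELRMModel(
        intercept=intercept,
        beta_z=beta_z,
        beta_a=np.asarray(beta_a, dtype=float),
        decoded=decoded,
        features=feats,
        L=L,
        alpha=0.5,
        lambda_opt=0.1,
        lambda_path=np.array([0.1]),
        cv_mean_deviance=np.array([1.0]),
        path_nnz=np.array([0]),
        config=FitConfig(),
    )


def test_predict_probability_zero_model_is_half():
    model = _manual_model(np.zeros((3, 4)), beta_a=np.zeros(0), features=[])
    assert md.predict_probability(model, "ACG") == pytest.approx(0.5)
    with pytest.raises(ValueError):
        md.predict_probability(model, "ACGT")


def test_mutating_association_member_drops_probability():
    """Breaking a strongly positive association feature lowers the
    predicted probability (the A19->G19 style experiment)."""
    decoded = np.zeros((4, 4))
    model = _manual_model(
        decoded, beta_a=np.array([6.0]), features=["A2:C4"], intercept=-3.0
    )
    intact = md.predict_probability(model, "TACC")
    broken = md.predict_probability(model, "TGCC")
    assert intact > 0.9
    assert broken < 0.1


def test_prediction_depends_only_on_selected_positions():
    decoded = decode_coefficients(np.array([1.0, 0, 0] + [0.0] * 9))
    model = _manual_model(decoded, beta_a=np.zeros(0), features=[])
    assert md.predict_probability(model, "ACGT") == md.predict_probability(model, "ATTT")


def test_feature_ratio_arithmetic():
    # 25 association, 0 single-base
    m = _manual_model(
        np.zeros((30, 4)),
        beta_a=np.ones(25),
        features=[f"A{i}:C{i + 1}" for i in range(1, 26)],
    )
    assert md.feature_ratio(m) == 1.0
    # 83 single-base, 3 association: 20 rows of (1,1,1,-3) and one (1,1,-2,0)
    decoded = np.vstack(
        [np.tile([1.0, 1.0, 1.0, -3.0], (20, 1)), [[1.0, 1.0, -2.0, 0.0]]]
    )
    m2 = _manual_model(
        decoded, beta_a=np.ones(3), features=["A1:C2", "A2:C3", "A3:C4"]
    )
    assert len(md.select_features(m2)[0]) == 83
    assert md.feature_ratio(m2) == pytest.approx(3 / 86)
    empty = _manual_model(np.zeros((2, 4)), beta_a=np.zeros(0), features=[])
    assert md.feature_ratio(empty) == 0.0


def test_feature_reduction_vs_pwm_denominators():
    decoded = np.tile([1.0, 0.0, 0.0, -1.0], (10, 1))  # 20 selected singles
    m = _manual_model(decoded, beta_a=np.ones(1), features=["A1:C2"])
    assert md.feature_reduction_vs_pwm(m, "4L") == pytest.approx(21 / 40)
    assert md.feature_reduction_vs_pwm(m, "3L") == pytest.approx(21 / 30)
    with pytest.raises(ValueError):
        md.feature_reduction_vs_pwm(m, "2L")


def test_model_json_roundtrip(small_trained):
    model = small_trained.model
    back = ELRMModel.from_json(model.to_json())
    assert back.intercept == pytest.approx(model.intercept)
    assert np.allclose(back.beta_z, model.beta_z)
    assert np.allclose(back.beta_a, model.beta_a)
    assert [f.id for f in back.features] == [f.id for f in model.features]
    s = small_trained.design.sequences[0]
    assert md.predict_probability(back, s) == pytest.approx(
        md.predict_probability(model, s)
    )


def test_trained_model_separates_fixture(small_trained):
    """Held-in sanity: positives score higher than assembled negatives."""
    design = small_trained.design
    probs = np.array(
        [md.predict_probability(small_trained.model, s) for s in design.sequences]
    )
    assert probs[design.y == 1].mean() > probs[design.y == 0].mean() + 0.2
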