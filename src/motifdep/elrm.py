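"""Elastic-net regularized logistic regression over coded motif features.

The binding model is

    logit P(Y=1) = beta0 + sum_{i=1..3L} beta_i Z_i + sum_{j=1..K} gamma_j A_j

with Z the sum-to-zero dummy coding of the bases and A the binary
association-feature indicators.  The penalty mixes ridge and lasso,
lambda * [ alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2 ], with alpha = 0.5
by default so that correlated groups of features are retained together.
lambda is chosen as the value minimizing mean 10-fold cross-validated
binomial deviance on a descending geometric grid; ties resolve to the
larger lambda (the sparser model).

Coded coefficients are decoded per position back to the four bases:
a_A, a_C, a_G are the three coded coefficients and a_T = -(a_A + a_C + a_G),
the inner product of each base's code with the position's coefficients, so
decoded rows sum to zero exactly.  Features with zero coefficients are
discarded; the surviving association features are the within-motif
dependence the model reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from ._cd import enet_logistic_path, lambda_grid
from .design import DesignMatrix, association_code, dummy_code
from .mining import AssociationFeature, Item, parse_item
from .seqs import ALPHABET

__all__ = [
    "FitConfig",
    "ELRMModel",
    "fit_elrm",
    "decode_coefficients",
    "select_features",
    "predict_probability",
    "feature_ratio",
    "feature_reduction_vs_pwm",
]


@dataclass(frozen=True)
class FitConfig:
    """Fitting knobs.

    alpha : elastic-net mixing (1 = lasso, 0 = ridge); 0.5 by default.
    n_lambda, lambda_min_ratio : geometric lambda grid; the ratio defaults
        to 1e-4 (1e-2 when columns outnumber rows).
    cv_folds : folds for the lambda-selection cross-validation (default 10).
    lambda_rule : "min" (minimum mean CV deviance) or "1se".
    standardize : standardize predictors internally; coefficients are
        always reported on the original coding scale.
    """

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    cv_folds: int = 10
    seed: int = 0
    standardize: bool = True
    lambda_rule: str = "min"
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class ELRMModel:
    """A fitted binding model: intercept, coded/association coefficients,
    the decoded per-base coefficient table, and the surviving features."""

    intercept: float
    beta_z: np.ndarray  # (3L,)
    beta_a: np.ndarray  # (K,)
    decoded: np.ndarray  # (L, 4), rows sum to 0 exactly
    features: list[AssociationFeature]
    L: int
    alpha: float
    lambda_opt: float
    lambda_path: np.ndarray
    cv_mean_deviance: np.ndarray
    path_nnz: np.ndarray  # nonzero penalized coefficients at each lambda
    config: FitConfig
    provenance_hash: str = ""

    @property
    def selected_single(self) -> list[tuple[int, str, float]]:
        return select_features(self)[0]

    @property
    def selected_assoc(self) -> list[tuple[str, float]]:
        return select_features(self)[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "beta_z": list(self.beta_z),
                "beta_a": list(self.beta_a),
                "decoded": [list(r) for r in self.decoded],
                "features": [f.id for f in self.features],
                "L": self.L,
                "alpha": self.alpha,
                "lambda_opt": self.lambda_opt,
                "lambda_path": list(self.lambda_path),
                "cv_mean_deviance": list(self.cv_mean_deviance),
                "path_nnz": [int(x) for x in self.path_nnz],
                "config": {
                    "alpha": self.config.alpha,
                    "n_lambda": self.config.n_lambda,
                    "lambda_min_ratio": self.config.lambda_min_ratio,
                    "cv_folds": self.config.cv_folds,
                    "seed": self.config.seed,
                    "standardize": self.config.standardize,
                    "lambda_rule": self.config.lambda_rule,
                },
                "provenance_hash": self.provenance_hash,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ELRMModel":
        d = json.loads(text)
        features = [
            AssociationFeature(frozenset(parse_item(t) for t in fid.split(":")))
            for fid in d["features"]
        ]
        return cls(
            intercept=d["intercept"],
            beta_z=np.array(d["beta_z"]),
            beta_a=np.array(d["beta_a"]),
            decoded=np.array(d["decoded"]),
            features=features,
            L=d["L"],
            alpha=d["alpha"],
            lambda_opt=d["lambda_opt"],
            lambda_path=np.array(d["lambda_path"]),
            cv_mean_deviance=np.array(d["cv_mean_deviance"]),
            path_nnz=np.array(d["path_nnz"], dtype=int),
            config=FitConfig(**d["config"]),
            provenance_hash=d.get("provenance_hash", ""),
        )

    def coefficients_tsv(self) -> str:
        lines = ["feature\tcoefficient"]
        for p in range(self.L):
            for b, base in enumerate(ALPHABET):
                lines.append(f"{base}{p + 1}\t{self.decoded[p, b]:.6g}")
        for f, c in zip(self.features, self.beta_a):
            lines.append(f"{f.id}\t{c:.6g}")
        return "\n".join(lines) + "\n"


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def decode_coefficients(beta_z: np.ndarray) -> np.ndarray:
    """Per-position (A, C, G, T) coefficients from the 3L coded vector.

    a_T is the inner product of T's code (-1,-1,-1) with the position's
    coefficients; each decoded row sums to zero exactly.
    """
    beta_z = np.asarray(beta_z, dtype=float)
    if beta_z.size % 3:
        raise ValueError("coded coefficient vector length must be a multiple of 3")
    b = beta_z.reshape(-1, 3)
    s = b[:, 0] + b[:, 1] + b[:, 2]
    return np.column_stack([b[:, 0], b[:, 1], b[:, 2], -s])


def fit_elrm(design: DesignMatrix, config: FitConfig = FitConfig()) -> ELRMModel:
    """Fit the elastic-net logistic model and select lambda by CV.

    Deterministic given the design and ``config.seed``.
    """
    X = np.asarray(design.X, dtype=float)
    y = np.asarray(design.y, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("both labels must be present")
    if np.all(X == X[0]):
        raise ValueError("design matrix has no variation")

    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd_safe
    else:
        mu = np.zeros(X.shape[1])
        sd_safe = np.ones(X.shape[1])
        Xs = X

    lambdas = lambda_grid(
        Xs, y, config.alpha, n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio
    )

    # stratified folds need at least one minority-class sample per fold
    n_splits = max(2, min(config.cv_folds, int(y.sum()), int((1 - y).sum())))
    skf = StratifiedKFold(
        n_splits=n_splits, shuffle=True, random_state=config.seed % (2**31)
    )
    dev = np.zeros((n_splits, len(lambdas)))
    for k, (tr, te) in enumerate(skf.split(Xs, y)):
        if np.unique(y[tr]).size < 2:  # pragma: no cover - stratified folds
            raise ValueError("a CV fold lost one class; too few samples per class")
        b0s, betas = enet_logistic_path(
            Xs[tr], y[tr], lambdas, alpha=config.alpha, tol=config.tol
        )
        eta = b0s[:, None] + betas @ Xs[te].T  # (n_lambda, n_test)
        probs = expit(eta)
        for li in range(len(lambdas)):
            dev[k, li] = _binomial_deviance(y[te], probs[li])
    mean_dev = dev.mean(axis=0)
    if config.lambda_rule == "min":
        i_opt = int(np.argmin(mean_dev))  # first index = largest lambda on ties
    else:
        i_min = int(np.argmin(mean_dev))
        se = dev[:, i_min].std(ddof=1) / np.sqrt(n_splits)
        i_opt = int(np.argmax(mean_dev <= mean_dev[i_min] + se))

    b0s, betas = enet_logistic_path(Xs, y, lambdas, alpha=config.alpha, tol=config.tol)
    path_nnz = (betas != 0).sum(axis=1)
    beta_s = betas[i_opt]
    # back to the original coding scale
    beta = beta_s / sd_safe
    intercept = float(b0s[i_opt] - np.dot(beta_s, mu / sd_safe))

    L = design.L
    beta_z = beta[: 3 * L]
    beta_a = beta[3 * L :]
    return ELRMModel(
        intercept=intercept,
        beta_z=beta_z,
        beta_a=beta_a,
        decoded=decode_coefficients(beta_z),
        features=list(design.features),
        L=L,
        alpha=config.alpha,
        lambda_opt=float(lambdas[i_opt]),
        lambda_path=lambdas,
        cv_mean_deviance=mean_dev,
        path_nnz=path_nnz,
        config=config,
        provenance_hash=hashlib.sha256(
            "\n".join(design.sequences).encode()
        ).hexdigest()[:16],
    )


def select_features(
    model: ELRMModel, tolerance: float = 0.0
) -> tuple[list[tuple[int, str, float]], list[tuple[str, float]]]:
    """Surviving features: decoded single-base coefficients and association
    coefficients with magnitude strictly above *tolerance*."""
    singles: list[tuple[int, str, float]] = []
    for p in range(model.L):
        for b, base in enumerate(ALPHABET):
            c = model.decoded[p, b]
            if abs(c) > tolerance:
                singles.append((p + 1, base, float(c)))
    assoc = [
        (f.id, float(c))
        for f, c in zip(model.features, model.beta_a)
        if abs(c) > tolerance
    ]
    return singles, assoc


def predict_probability(model: ELRMModel, sequence: str) -> float:
    """Binding probability of one width-L sequence under the fitted model."""
    if len(sequence) != model.L:
        raise ValueError(f"sequence length {len(sequence)} != motif width {model.L}")
    z = dummy_code(sequence)
    a = association_code(sequence, model.features)
    eta = model.intercept + float(z @ model.beta_z) + float(a @ model.beta_a)
    return float(expit(eta))


def feature_reduction_vs_pwm(
    model: ELRMModel, denominator: str = "4L", tolerance: float = 0.0
) -> float:
    """Selected-feature count relative to the PWM's feature count.

    The PWM reference can be counted as 4L (one probability per base and
    position) or 3L (free parameters per position); both conventions are
    supported since either is defensible.
    """
    if denominator not in ("3L", "4L"):
        raise ValueError("denominator must be '3L' or '4L'")
    singles, assoc = select_features(model, tolerance)
    denom = (4 if denominator == "4L" else 3) * model.L
    return (len(singles) + len(assoc)) / denom


def feature_ratio(model: ELRMModel, tolerance: float = 0.0) -> float:
    """Share of association features among all selected features; 0 when
    nothing is selected."""
    singles, assoc = select_features(model, tolerance)
    total = len(singles) + len(assoc)
    if total == 0:
        return 0.0
    return len(assoc) / total
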