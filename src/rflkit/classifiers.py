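"""Downstream classifiers and the native probability formulas.

Four classifier families consume either the raw 9 sensor channels or the
transfer features: Random Forest, decision tree, multinomial logistic
regression, and Gaussian naive Bayes.  Fitting delegates to
scikit-learn; the per-feature Gaussian likelihood and the logistic
probability are additionally implemented natively here so the formulas
themselves are directly testable, and a native log-space GNB scorer
cross-checks the delegated backend.

Default hyperparameters are the tuned values of the reference study:
RF(n_estimators=10, max_depth=10, criterion='entropy', random_state=0),
DT(max_leaf_nodes=None, min_impurity_decrease=0.0),
LR(random_state=0, max_iter=200, C=1.0, multinomial softmax),
GNB(priors=None, var_smoothing=1e-9).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

VALID_KINDS = ("rf", "dt", "lr", "gnb")

_DEFAULTS: dict[str, dict] = {
    "rf": {"n_estimators": 10, "max_depth": 10, "criterion": "entropy"},
    "dt": {"max_leaf_nodes": None, "min_impurity_decrease": 0.0},
    "lr": {"max_iter": 200, "C": 1.0},
    "gnb": {"priors": None, "var_smoothing": 1e-9},
}

_ALLOWED: dict[str, set] = {
    "rf": {"n_estimators", "max_depth", "criterion", "min_samples_leaf"},
    "dt": {"max_depth", "max_leaf_nodes", "min_impurity_decrease", "criterion"},
    "lr": {"max_iter", "C", "tol"},
    "gnb": {"priors", "var_smoothing"},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to build and with which hyperparameters."""

    kind: str = "rf"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        object.__setattr__(self, "kind", kind)
        if kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
        unknown = set(self.hyperparameters) - _ALLOWED[kind]
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {kind!r}: {sorted(unknown)}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(_DEFAULTS[self.kind])
        params.update(self.hyperparameters)
        return params

    def to_dict(self) -> dict:
        return {"kind": self.kind, "hyperparameters": dict(self.hyperparameters),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        unknown = set(d) - {"kind", "hyperparameters", "seed"}
        if unknown:
            raise ValueError(f"unknown ClassifierSpec keys: {sorted(unknown)}")
        return cls(kind=d.get("kind", "rf"),
                   hyperparameters=d.get("hyperparameters", {}),
                   seed=d.get("seed", 0))


def make_classifier(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn estimator for a spec."""
    p = spec.resolved_hyperparameters()
    if spec.kind == "rf":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.kind == "dt":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.kind == "lr":
        # softmax (multinomial) with L2 at the given C — the modern default
        return LogisticRegression(random_state=spec.seed, **p)
    return GaussianNB(**p)


def train_classifier(spec: ClassifierSpec, X, y):
    """Fit the spec's estimator; requires at least two classes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty matrix")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    model = make_classifier(spec)
    model.fit(X, y)
    return model


def predict(model, X) -> np.ndarray:
    """Argmax of class probabilities; ties go to the lowest class index."""
    proba = predict_proba(model, X)
    return model.classes_[np.argmax(proba, axis=1)]


def predict_proba(model, X) -> np.ndarray:
    if not hasattr(model, "classes_"):
        raise RuntimeError("model is not fitted")
    return model.predict_proba(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Native formulas (oracle implementations)
# ---------------------------------------------------------------------------

def gnb_feature_likelihood(x_i: float, mu: float, var: float) -> float:
    """Gaussian per-feature likelihood
    ``P(x_i|C) = exp(-(x_i - mu)^2 / (2 var)) / sqrt(2 pi var)``."""
    if var <= 0:
        raise ValueError("variance must be positive")
    return float(
        np.exp(-((x_i - mu) ** 2) / (2.0 * var)) / np.sqrt(2.0 * np.pi * var)
    )


def lr_probability(x, beta0: float, beta) -> float:
    """Binary logistic probability
    ``P(y=1|x) = 1 / (1 + exp(-(beta0 + beta . x)))``."""
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape != beta.shape:
        raise ValueError(
            f"x has shape {x.shape} but coefficients have shape {beta.shape}"
        )
    z = beta0 + float(beta @ x) if x.size else beta0
    # numerically stable logistic
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


@dataclass
class GNBParams:
    """Moments of a Gaussian naive Bayes model (post-smoothing variances)."""

    priors: np.ndarray          # (K,)
    means: np.ndarray           # (K, d)
    variances: np.ndarray       # (K, d), smoothing already added
    classes: np.ndarray         # (K,)


def gnb_fit_params(X, y, var_smoothing: float = 1e-9) -> GNBParams:
    """Estimate per-class moments; smoothing ``eps = var_smoothing *
    max_f Var(x_f)`` is added to every variance (the standard stabiliser)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    variances = np.vstack([X[y == c].var(axis=0) for c in classes])
    eps = var_smoothing * X.var(axis=0).max()
    variances = variances + eps
    if np.any(variances <= 0):
        raise ValueError("variances must be strictly positive after smoothing")
    priors = np.array([(y == c).mean() for c in classes])
    return GNBParams(priors=priors, means=means, variances=variances,
                     classes=classes)


def gnb_predict_proba(params: GNBParams, X) -> np.ndarray:
    """Posterior class probabilities from the native formulas, in log space.

    ``log P(C|x) ∝ log P(C) + sum_i log P(x_i|C)`` with the Gaussian
    per-feature likelihood; normalised per row.
    """
    X = np.asarray(X, dtype=float)
    log_prior = np.log(params.priors)
    # (n, K): sum over features of log N(x_i; mu, var)
    diff = X[:, None, :] - params.means[None, :, :]
    log_lik = -0.5 * np.sum(
        np.log(2.0 * np.pi * params.variances)[None, :, :]
        + diff ** 2 / params.variances[None, :, :],
        axis=2,
    )
    joint = log_prior[None, :] + log_lik
    joint -= joint.max(axis=1, keepdims=True)
    p = np.exp(joint)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

FORMAT_VERSION = 1


def save_model(model, spec: ClassifierSpec, path) -> None:
    """Persist a fitted model with its spec and a format version."""
    payload = {"version": FORMAT_VERSION, "spec": spec.to_dict(), "model": model}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path):
    """Load a persisted model; returns ``(model, spec)``."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('version')}")
    return payload["model"], ClassifierSpec.from_dict(payload["spec"])
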