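"""Per-residue logistic-regression confidence scores.

Two independent classifiers estimate the probability that a modeled residue
is correct: the C-alpha model uses the classifier's C-alpha probability as
its single feature; the amino-acid model uses the HMM emission probability
at the aligned position, the C-alpha probability, and a one-hot encoding of
the assigned type (22 features).  Training labels come from 3-A one-to-one
matching against a reference structure.  No pretrained coefficients are
shipped: fit on data with a reference available, then apply.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .constants import AA_ALPHABET, AA_INDEX
from .evaluation import DEFAULT_CUTOFF, match_ca
from .io_formats import StructureModel

CA_FEATURES = ("ca_prob",)
AA_FEATURES = ("emission_prob", "ca_prob") + tuple(
    f"is_{a}" for a in AA_ALPHABET)


@dataclass
class LogisticModel:
    """Fitted logistic classifier: sigmoid(beta0 + beta . x)."""

    intercept: float
    coef: np.ndarray
    feature_schema: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float).reshape(-1)
        if self.feature_schema and len(self.feature_schema) != len(self.coef):
            raise ValueError("feature schema length != coefficient count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"intercept": self.intercept,
                       "coef": self.coef.tolist(),
                       "feature_schema": list(self.feature_schema)}, fh)

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(intercept=d["intercept"], coef=np.array(d["coef"]),
                   feature_schema=tuple(d["feature_schema"]))


def logistic_score(model: LogisticModel, features: np.ndarray) -> np.ndarray:
    """Sigmoid of the linear predictor; accepts (p,) or (n, p) input."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != len(model.coef):
        raise ValueError(f"expected {len(model.coef)} features, "
                         f"got {x.shape[1]}")
    z = model.intercept + x @ model.coef
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out[0]) if np.asarray(features).ndim == 1 else out


def make_ca_features(model: StructureModel) -> np.ndarray:
    """(n_residues, 1): the classifier C-alpha probability."""
    return np.array([[r.ca_prob] for r in model.all_residues()])


def make_aa_features(model: StructureModel) -> np.ndarray:
    """(n_residues, 22): emission, C-alpha probability, one-hot type."""
    rows = []
    for r in model.all_residues():
        onehot = np.zeros(20)
        onehot[AA_INDEX[r.aa]] = 1.0
        rows.append(np.concatenate([[r.emission_prob, r.ca_prob], onehot]))
    return np.stack(rows)


def make_labels(model: StructureModel, reference: StructureModel,
                cutoff: float = DEFAULT_CUTOFF
                ) -> tuple[np.ndarray, np.ndarray]:
    """Binary (ca_label, aa_label) per model residue via 3-A matching.

    ca_label = 1 for residues with a one-to-one reference partner within
    the cutoff; aa_label = 1 only for matched residues whose amino-acid
    type equals the partner's.
    """
    match = match_ca(model, reference, cutoff)
    mres = model.all_residues()
    rres = reference.all_residues()
    ca = np.zeros(len(mres), dtype=int)
    aa = np.zeros(len(mres), dtype=int)
    for mi, ri, _ in match.pairs:
        ca[mi] = 1
        if mres[mi].aa == rres[ri].aa:
            aa[mi] = 1
    return ca, aa


def fit_confidence(features: np.ndarray, labels: np.ndarray,
                   schema: tuple[str, ...] = (),
                   ridge: float = 1e-6) -> LogisticModel:
    """Maximum-likelihood logistic fit (tiny L2 ridge for separable data)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; cannot fit a "
                         "logistic model")
    clf = LogisticRegression(C=1.0 / max(ridge, 1e-12), solver="lbfgs",
                             tol=1e-10, max_iter=5000)
    clf.fit(features, labels)
    return LogisticModel(intercept=float(clf.intercept_[0]),
                         coef=clf.coef_[0],
                         feature_schema=schema or tuple(
                             f"x{i}" for i in range(features.shape[1])))


@dataclass
class ConfidenceAnnotation:
    ca_confidences: np.ndarray
    aa_confidences: np.ndarray

    @property
    def mean_ca_confidence(self) -> float:
        return float(self.ca_confidences.mean())

    @property
    def mean_aa_confidence(self) -> float:
        return float(self.aa_confidences.mean())


def apply_confidence(model: StructureModel, ca_model: LogisticModel,
                     aa_model: LogisticModel) -> ConfidenceAnnotation:
    """Score every residue in place and return the annotation summary."""
    ca_scores = np.atleast_1d(logistic_score(ca_model,
                                             make_ca_features(model)))
    aa_scores = np.atleast_1d(logistic_score(aa_model,
                                             make_aa_features(model)))
    for r, cs, as_ in zip(model.all_residues(), ca_scores, aa_scores):
        r.ca_confidence = float(cs)
        r.aa_confidence = float(as_)
    return ConfidenceAnnotation(ca_confidences=ca_scores,
                                aa_confidences=aa_scores)
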