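"""Logistic classification of splice sites as well- vs less-supported.

The model predicts the probability that a site exhibits a MANE-like
conservation pattern from (i) the number of genomes conserving the canonical
dinucleotide jointly and (ii) one conservation count per surrounding position
(the "full" variant), or from the joint count alone (the
"dinucleotide_only" variant).  Donor and acceptor models are trained
separately, on MANE-like sites as positives and random intronic sites as
negatives, with a stratified hold-out test split.

:class:`SpliceSiteClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``predict_proba``, fitted attributes with trailing
underscores) and composes with sklearn model selection; the module-level
functions are thin wrappers used by the pipeline and CLI.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    auc,
    f1_score,
    precision_score,
    recall_score,
    roc_curve,
)
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .catalogs import Catalog
from .conservation import SHIFTS, ConservationProfile, features_matrix

WELL_SUPPORTED = "well_supported"
LESS_SUPPORTED = "less_supported"

#: feature layout: column 0 = joint dinucleotide count, then SHIFTS order
N_FEATURES = 1 + len(SHIFTS)


class ConvergenceError(RuntimeError):
    """Raised when the logistic solver fails to converge."""


class SpliceSiteClassifier(BaseEstimator, ClassifierMixin):
    """Logistic model over conservation-count features.

    Parameters
    ----------
    variant
        ``"full"`` uses the joint dinucleotide count plus the 60 positional
        counts; ``"dinucleotide_only"`` uses the joint count alone (the
        positional columns, if present in X, are ignored).
    C
        Inverse L2 regularisation strength (sklearn convention); mild
        regularisation by default.
    threshold
        Probability cut-off for the well-supported label; ties at the
        threshold label well-supported.
    """

    def __init__(
        self,
        variant: str = "full",
        C: float = 1.0,
        threshold: float = 0.5,
        max_iter: int = 2000,
    ) -> None:
        self.variant = variant
        self.C = C
        self.threshold = threshold
        self.max_iter = max_iter

    def _slice(self, X: np.ndarray) -> np.ndarray:
        if self.variant == "dinucleotide_only":
            return X[:, :1]
        if self.variant != "full":
            raise ValueError(f"unknown variant {self.variant!r}")
        if X.shape[1] != N_FEATURES:
            raise ValueError(
                f"full variant expects {N_FEATURES} features "
                f"(joint count + {len(SHIFTS)} positional counts), "
                f"got {X.shape[1]}"
            )
        return X

    def fit(self, X, y) -> "SpliceSiteClassifier":
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("training data must contain both classes")
        Xv = self._slice(X)
        model = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=self.max_iter
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(Xv, y)
            except ConvergenceWarning as w:
                raise ConvergenceError(
                    f"logistic fit did not converge within {self.max_iter} "
                    f"iterations: {w}"
                ) from w
        self.model_ = model
        self.n_features_in_ = X.shape[1]
        self.alpha0_ = float(model.intercept_[0])
        self.alpha1_ = float(model.coef_[0][0])
        self.alpha_l_: Dict[int, float] = (
            {}
            if self.variant == "dinucleotide_only"
            else {l: float(c) for l, c in zip(SHIFTS, model.coef_[0][1:])}
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.decision_function(self._slice(X))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        return self.model_.predict_proba(self._slice(X))

    def predict(self, X) -> np.ndarray:
        """1 (well-supported) iff predicted probability >= threshold."""
        proba = self.predict_proba(X)[:, 1]
        return (proba >= self.threshold).astype(int)

    # -- serialisation ----------------------------------------------------

    def to_json(self, path: Optional[str | os.PathLike] = None) -> str:
        check_is_fitted(self, "model_")
        payload = {
            "variant": self.variant,
            "C": self.C,
            "threshold": self.threshold,
            "alpha0": self.alpha0_,
            "alpha1": self.alpha1_,
            "alpha_l": {str(l): c for l, c in self.alpha_l_.items()},
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | os.PathLike) -> "SpliceSiteClassifier":
        if os.path.exists(source):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        est = cls(
            variant=payload["variant"],
            C=payload["C"],
            threshold=payload["threshold"],
        )
        model = LogisticRegression(C=est.C, solver="lbfgs")
        alpha_l = {int(k): v for k, v in payload["alpha_l"].items()}
        if est.variant == "dinucleotide_only":
            coef = np.array([[payload["alpha1"]]])
        else:
            coef = np.array([[payload["alpha1"]] + [alpha_l[l] for l in SHIFTS]])
        model.coef_ = coef
        model.intercept_ = np.array([payload["alpha0"]])
        model.classes_ = np.array([0, 1])
        est.model_ = model
        est.classes_ = model.classes_
        est.n_features_in_ = 1 if est.variant == "dinucleotide_only" else N_FEATURES
        est.alpha0_ = payload["alpha0"]
        est.alpha1_ = payload["alpha1"]
        est.alpha_l_ = alpha_l
        return est


# ---------------------------------------------------------------------------
# pipeline wrappers


@dataclass
class TrainTestSplit:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class ModelMetrics:
    auc: float
    f_score: float
    precision: float
    recall: float
    roc_points: np.ndarray = field(repr=False)


def assemble_training_set(
    mane_profiles: Sequence[ConservationProfile],
    random_profiles: Sequence[ConservationProfile],
    kind: str,
    split: float = 0.2,
    seed: int = 0,
) -> TrainTestSplit:
    """Stratified train/test split of positive (MANE-like) vs negative
    (random) profiles of one site kind."""
    pos = [p for p in mane_profiles if p.site.kind == kind]
    neg = [p for p in random_profiles if p.site.kind == kind]
    if not pos or not neg:
        raise ValueError(f"empty class for kind={kind!r}")
    if not (0 < split < 1):
        raise ValueError("split fraction must be in (0, 1)")
    X = features_matrix(list(pos) + list(neg))
    y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=split, random_state=seed, stratify=y
    )
    return TrainTestSplit(X_train, y_train, X_test, y_test)


def fit_model(
    train: TrainTestSplit,
    variant: str = "full",
    regularization: float = 1.0,
    threshold: float = 0.5,
) -> SpliceSiteClassifier:
    return SpliceSiteClassifier(
        variant=variant, C=regularization, threshold=threshold
    ).fit(train.X_train, train.y_train)


def classify(
    profile: ConservationProfile | np.ndarray, model: SpliceSiteClassifier
) -> tuple[float, str]:
    """(probability, label) for a single site."""
    vec = profile.vector() if isinstance(profile, ConservationProfile) else profile
    p = float(model.predict_proba(vec.reshape(1, -1))[0, 1])
    return p, WELL_SUPPORTED if p >= model.threshold else LESS_SUPPORTED


def evaluate(
    model: SpliceSiteClassifier, X_test: np.ndarray, y_test: np.ndarray
) -> ModelMetrics:
    """ROC/AUC by threshold sweep plus F-score at the model threshold."""
    if len(np.unique(y_test)) < 2:
        raise ValueError("AUC undefined on a single-class test set")
    proba = model.predict_proba(X_test)[:, 1]
    fpr, tpr, _ = roc_curve(y_test, proba)
    pred = model.predict(X_test)
    return ModelMetrics(
        auc=float(auc(fpr, tpr)),
        f_score=float(f1_score(y_test, pred)),
        precision=float(precision_score(y_test, pred)),
        recall=float(recall_score(y_test, pred)),
        roc_points=np.column_stack([fpr, tpr]),
    )


def well_supported_transcripts(
    catalog: Catalog,
    mane: Catalog,
    labels: Dict[tuple, bool],
) -> tuple[list[str], dict]:
    """Transcripts whose every splice site is either shared with MANE or
    labelled well-supported.

    ``labels`` maps site identity -> bool (well-supported).  Transcripts
    without introns are ignored; an unlabelled non-MANE site is an error.
    """
    kept: list[str] = []
    n_considered = 0
    for tid, tr in catalog.transcripts.items():
        idents = catalog.transcript_sites.get(tid, [])
        if tr.n_introns < 1 or not idents:
            continue
        n_considered += 1
        ok = True
        for ident in idents:
            if ident in mane.site_index:
                continue
            if ident not in labels:
                raise ValueError(f"site {ident} of {tid} has no label")
            if not labels[ident]:
                ok = False
                break
        if ok:
            kept.append(tid)
    summary = {
        "dataset": catalog.name,
        "transcripts": n_considered,
        "well_supported_transcripts": len(kept),
    }
    return kept, summary
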