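"""Subtype-restricted linear signature classifiers for BRCA-likeness.

A signature model is a linear decision rule on a fixed gene list — weights,
an intercept, and the subtype it applies to (e.g. a basal-restricted
BRCA1-like signature, a LumB-restricted BRCA2-like signature).  Models are
typically loaded as data; :func:`train_signature_model` fits one by a linear
support-vector machine for synthetic experiments.

Scoring is restricted by subtype: only samples whose assigned intrinsic
subtype matches the model's ``applicable_subtype`` are scored.  A sample is
called positive (BRCA-like) iff its decision score is strictly positive;
a score exactly on the boundary is called sporadic-like.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = ["SignatureModel", "BrcaLikeCall", "train_signature_model", "predict_brca_like"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureModel:
    """Linear decision rule on a signature gene list.

    ``decision_score(x) = weights . x[genes] + intercept``; positive scores
    mean ``positive_class`` (BRCA-like), nonpositive ``negative_class``.
    Any preprocessing (e.g. per-gene standardization at training time) is
    folded into the weights and intercept, so the rule applies directly to
    raw log-scale expression.
    """

    signature_gene_ids: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float
    positive_class: str
    negative_class: str
    applicable_subtype: str

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.signature_gene_ids):
            raise ValueError("one weight per signature gene required")
        if not any(w != 0 for w in self.weights):
            raise ValueError("all signature weights are zero")
        if self.positive_class == self.negative_class:
            raise ValueError("class labels must differ")

    def decision_score(self, profile: pd.Series) -> float:
        missing = [g for g in self.signature_gene_ids if g not in profile.index]
        if missing:
            raise ValueError(f"profile is missing signature genes: {missing[:10]}")
        x = profile.loc[list(self.signature_gene_ids)].to_numpy(float)
        return float(np.dot(self.weights, x) + self.intercept)


@dataclass(frozen=True)
class BrcaLikeCall:
    sample_id: str
    decision_score: float
    predicted_class: str


def train_signature_model(
    matrix: pd.DataFrame,
    class_of: Mapping[str, str],
    signature_gene_ids: Sequence[str],
    applicable_subtype: str,
    positive_class: str,
    negative_class: str | None = None,
    C: float = 1.0,
    standardize: bool = True,
) -> SignatureModel:
    """Fit a maximum-margin linear rule on the signature-gene subspace.

    Training samples are the keys of ``class_of`` (values: class labels, one
    of which is ``positive_class``).  Genes are z-scored with training
    statistics when ``standardize`` is true; the scaling is folded into the
    returned weights/intercept.  Soft margin with regularization constant
    ``C`` (default 1).
    """
    missing = [g for g in signature_gene_ids if g not in matrix.index]
    if missing:
        raise ValueError(f"signature genes absent from matrix: {missing[:10]}")
    samples = list(class_of)
    labels = {class_of[s] for s in samples}
    if positive_class not in labels:
        raise ValueError(f"no training sample with class {positive_class!r}")
    others = sorted(labels - {positive_class})
    if len(others) != 1:
        raise ValueError(f"need exactly two classes, got {sorted(labels)}")
    if negative_class is None:
        negative_class = others[0]
    y = np.array([1 if class_of[s] == positive_class else 0 for s in samples])
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 training samples per class")

    X = matrix.loc[list(signature_gene_ids), samples].to_numpy(float).T
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
        Xs = X

    svm = SVC(kernel="linear", C=C, tol=1e-6)
    svm.fit(Xs, y)
    w_std = svm.coef_.ravel()
    b_std = float(svm.intercept_[0])
    # fold the z-scoring into the rule: w.(x-mu)/sd + b
    w = w_std / sd
    b = b_std - float(np.dot(w_std, mu / sd))
    return SignatureModel(
        signature_gene_ids=tuple(str(g) for g in signature_gene_ids),
        weights=tuple(float(v) for v in w),
        intercept=b,
        positive_class=positive_class,
        negative_class=negative_class,
        applicable_subtype=applicable_subtype,
    )


def predict_brca_like(
    model: SignatureModel,
    matrix: pd.DataFrame,
    calls: Iterable,
) -> list[BrcaLikeCall]:
    """Score the samples whose assigned subtype matches the model's.

    ``calls`` are subtype calls (anything with ``sample_id`` and
    ``assigned_subtype``).  Samples of other subtypes are omitted with a log
    line; an empty eligible set yields an empty list with a warning.
    """
    out: list[BrcaLikeCall] = []
    n_skipped = 0
    for c in calls:
        if c.assigned_subtype != model.applicable_subtype:
            n_skipped += 1
            logger.debug(
                "sample %s skipped: subtype %s, model applies to %s",
                c.sample_id, c.assigned_subtype, model.applicable_subtype,
            )
            continue
        if c.sample_id not in matrix.columns:
            raise ValueError(f"sample {c.sample_id!r} not in expression matrix")
        score = model.decision_score(matrix[c.sample_id])
        cls = model.positive_class if score > 0 else model.negative_class
        out.append(BrcaLikeCall(c.sample_id, score, cls))
    if n_skipped:
        logger.info("skipped %d samples outside subtype %r",
                    n_skipped, model.applicable_subtype)
    if not out:
        logger.warning("no samples eligible for subtype %r", model.applicable_subtype)
    return out
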