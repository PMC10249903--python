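"""Class likelihoods, posterior probabilities and the reliability score.

The classifier is a generative averaged one-dependence estimator: for a
class, the likelihood of an instance is the sum over present attributes j of

    f(x_j | class) * prod_{i != j, present} f(x_i | x_j, class)

where the marginal f(x_j|class) and the conditionals (derived from pairwise
joint mixtures) come from the trained model.  Posterior probabilities are
prior-weighted, normalized likelihoods.

The reliability score (SRS) is the base-10 log of the *maximum* class
likelihood.  It deliberately ignores priors and normalization: posteriors
say which trained class fits best *relatively*, while the SRS says how well
the instance fits any trained class at all.  Instances resembling no class
get a low SRS even when one class wins the posterior by a landslide.

Missing attributes shrink both the outer sum and the inner products to the
set of present attributes; no imputation happens anywhere.  All arithmetic
is done in log space so extreme likelihood ratios remain stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densities import GMM1D, GMM2D, log10_density_1d, log10_density_2d
from .errors import MissingDataError, SchemaError, ValidationError
from .io import AttributeTable
from .model import TrainedModel

__all__ = [
    "ClassificationRecord",
    "class_log10_likelihood",
    "posterior_probabilities",
    "srs",
    "classify_table",
]

_LN10 = np.log(10.0)


@dataclass
class ClassificationRecord:
    """Per-instance output: posterior vector, reliability score, bookkeeping.

    ``posteriors`` is None when the instance could not be scored (no present
    attributes or total underflow); ``abstained`` is also set when the SRS
    falls below a user-supplied threshold, in which case the posteriors are
    still reported.
    """

    posteriors: np.ndarray | None
    srs: float | None
    n_present: int
    abstained: bool
    class_labels: list
    model_fingerprint: str = ""

    def posterior(self, label: str) -> float:
        if self.posteriors is None:
            raise MissingDataError("record has no posteriors (abstained row)")
        return float(self.posteriors[self.class_labels.index(label)])


def _instance_to_row(model: TrainedModel, instance) -> np.ndarray:
    """Normalize an instance (mapping or sequence) to a 1 x p float row."""
    names = model.attribute_names
    if isinstance(instance, dict):
        unknown = set(instance) - set(names)
        if unknown:
            raise SchemaError(f"unknown attribute(s): {sorted(unknown)}")
        row = np.array([float(instance.get(n, np.nan)) for n in names])
    else:
        row = np.asarray(instance, dtype=float).ravel()
        if row.size != len(names):
            raise SchemaError(
                f"instance has {row.size} values, model expects {len(names)}"
            )
    if np.any(np.isinf(row)):
        raise ValidationError("present attribute values must be finite")
    return row[None, :]


def _pattern_loglik10(model: TrainedModel, X: np.ndarray, present: np.ndarray) -> np.ndarray:
    """log10 class likelihoods for rows sharing one missingness pattern.

    X is (n, p) standardized values; ``present`` a boolean length-p mask.
    Returns (n, n_classes).  Rows must actually match the pattern.
    """
    names = model.attribute_names
    S = np.flatnonzero(present)
    n = X.shape[0]
    out = np.empty((n, len(model.classes)))
    for ci, cm in enumerate(model.classes):
        # per-attribute marginal log10 densities
        logmarg = {j: log10_density_1d(cm.marginals[names[j]], X[:, j]) for j in S}
        # terms[:, t] accumulates the j = S[t] summand of the outer sum
        terms = np.zeros((n, len(S)))
        for t, j in enumerate(S):
            terms[:, t] = logmarg[j]
        for a_idx in range(len(S)):
            for b_idx in range(a_idx + 1, len(S)):
                i, j = S[a_idx], S[b_idx]
                joint = cm.joints[(names[i], names[j])]
                lj = np.atleast_1d(log10_density_2d(joint, X[:, i], X[:, j]))
                # conditioning on coordinate i (joint coord 0) and on j (coord 1)
                lm_i = np.atleast_1d(log10_density_1d(joint.marginal(0), X[:, i]))
                lm_j = np.atleast_1d(log10_density_1d(joint.marginal(1), X[:, j]))
                # f(x_j | x_i): contributes to the outer term j' = i
                terms[:, a_idx] += lj - lm_i
                # f(x_i | x_j): contributes to the outer term j' = j
                terms[:, b_idx] += lj - lm_j
        ln_terms = terms * _LN10
        hi = ln_terms.max(axis=1)
        with np.errstate(invalid="ignore"):
            ln_sum = hi + np.log(np.exp(ln_terms - hi[:, None]).sum(axis=1))
        ln_sum = np.where(np.isfinite(hi), ln_sum, -np.inf)
        out[:, ci] = ln_sum / _LN10
    return out


def _loglik10_table(model: TrainedModel, X: np.ndarray):
    """(n, n_classes) log10 likelihood matrix plus per-row present counts.

    Rows are grouped by missingness pattern so each pattern's densities are
    evaluated vectorized across rows; rows with nothing present get -inf.
    """
    n = X.shape[0]
    mask = ~np.isnan(X)
    n_present = mask.sum(axis=1)
    loglik = np.full((n, len(model.classes)), -np.inf)
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    for pi, pattern in enumerate(patterns):
        rows = np.flatnonzero(inverse == pi)
        if not pattern.any():
            continue
        loglik[rows] = _pattern_loglik10(model, X[rows], pattern)
    return loglik, n_present


def _resolve_priors(model: TrainedModel, priors) -> np.ndarray:
    if priors is None:
        return model.priors
    if isinstance(priors, dict):
        missing = set(model.class_labels) - set(priors)
        if missing:
            raise ValidationError(f"priors missing class(es): {sorted(missing)}")
        arr = np.array([float(priors[c]) for c in model.class_labels])
    else:
        arr = np.asarray(priors, dtype=float)
        if arr.size != len(model.classes):
            raise ValidationError("one prior per class required")
    if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
        raise ValidationError("priors must be non-negative and sum to 1")
    return arr


def class_log10_likelihood(model: TrainedModel, instance, class_label) -> float:
    """log10 AODE likelihood of ``instance`` under one class.

    With a single present attribute j the inner product is empty and the
    value reduces to ``log10 f(x_j | class)``.
    """
    row = model.standardize_values(_instance_to_row(model, instance))
    if not np.any(~np.isnan(row)):
        raise MissingDataError("instance has no present attributes")
    ci = model.class_labels.index(class_label)  # raises ValueError for unknown label
    loglik, _ = _loglik10_table(model, row)
    return float(loglik[0, ci])


def posterior_probabilities(model: TrainedModel, instance, priors=None) -> np.ndarray:
    """Posterior class probabilities (prior-weighted normalized likelihoods).

    Computed in log space and normalized, so extreme likelihood ratios give
    clean 0/1 posteriors instead of NaNs.  Order follows
    ``model.class_labels``.
    """
    if len(model.classes) < 2:
        raise ValidationError("posterior probabilities need at least two classes")
    pri = _resolve_priors(model, priors)
    row = model.standardize_values(_instance_to_row(model, instance))
    if not np.any(~np.isnan(row)):
        raise MissingDataError("instance has no present attributes")
    loglik, _ = _loglik10_table(model, row)
    return _posterior_from_loglik(loglik, pri)[0]


def _posterior_from_loglik(loglik10: np.ndarray, priors: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        ln_post = loglik10 * _LN10 + np.log(priors)[None, :]
    hi = ln_post.max(axis=1, keepdims=True)
    w = np.exp(ln_post - hi)
    return w / w.sum(axis=1, keepdims=True)


def srs(model: TrainedModel, instance) -> float:
    """Reliability score: max over classes of the log10 AODE likelihood.

    Priors play no role; with a single attribute this is the max of the
    per-class log10 marginal densities.
    """
    row = model.standardize_values(_instance_to_row(model, instance))
    if not np.any(~np.isnan(row)):
        raise MissingDataError("instance has no present attributes")
    loglik, _ = _loglik10_table(model, row)
    return float(loglik[0].max())


def classify_table(
    model: TrainedModel,
    table: AttributeTable,
    priors=None,
    srs_threshold: float | None = None,
):
    """Score every row of a table; one record per row, input order.

    Rows with zero present attributes are abstained with no posteriors.
    If ``srs_threshold`` is given, rows whose SRS falls below it are flagged
    abstained as well (their posteriors are still reported).
    """
    if table.attribute_names != list(model.attribute_names):
        raise SchemaError(
            "table attributes do not match the model: "
            f"{table.attribute_names} vs {list(model.attribute_names)}"
        )
    pri = _resolve_priors(model, priors)
    X = model.standardize_values(table.data.to_numpy())
    loglik, n_present = _loglik10_table(model, X)
    fingerprint = model.fingerprint()
    labels = list(model.class_labels)

    records = []
    for r in range(X.shape[0]):
        if n_present[r] == 0 or not np.any(np.isfinite(loglik[r])):
            records.append(
                ClassificationRecord(
                    posteriors=None,
                    srs=None if n_present[r] == 0 else float("-inf"),
                    n_present=int(n_present[r]),
                    abstained=True,
                    class_labels=labels,
                    model_fingerprint=fingerprint,
                )
            )
            continue
        post = _posterior_from_loglik(loglik[r : r + 1], pri)[0]
        row_srs = float(loglik[r].max())
        abstained = srs_threshold is not None and not (row_srs >= srs_threshold)
        records.append(
            ClassificationRecord(
                posteriors=post,
                srs=row_srs,
                n_present=int(n_present[r]),
                abstained=abstained,
                class_labels=labels,
                model_fingerprint=fingerprint,
            )
        )
    return records
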