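"""SRS-based diagnostic workflows.

Three workflows, all reading nothing but classification records produced
under one trained model:

* **unknown-class detection** — instances from a class absent at training
  time concentrate at low SRS; quantified with ROC/AUC against known-class
  instances (:func:`srs_roc_auc`).
* **distribution-shift testing** — the SRS acts as a 1-D reduction of the
  attribute space; a two-sample test on SRS values of two cohorts scored
  under the same model flags systemic training/application mismatch
  (:func:`srs_shift_test`).
* **missingness profiling** — grouping rows by their exact missing-attribute
  set shows which attributes' absence drags the SRS down, separating
  informative from expendable attributes (:func:`missingness_profile`).

Abstention (:func:`apply_abstention`) flags records below a user-chosen SRS
threshold; no default threshold exists on purpose, since workable values
are application-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    ComparabilityError,
    DegenerateDataError,
    ValidationError,
)
from .io import AttributeTable

__all__ = [
    "ShiftReport",
    "RocResult",
    "MissingnessReport",
    "mann_whitney_u",
    "welch_t",
    "srs_shift_test",
    "srs_roc_auc",
    "missingness_profile",
    "apply_abstention",
]

#: Below this product of sample sizes the Mann-Whitney p-value is computed
#: by exact enumeration of the permutation distribution (ties included).
EXACT_MW_LIMIT = 200


@dataclass
class ShiftReport:
    """Outcome of a two-sample comparison between cohorts a and b."""

    method: str
    statistic: float
    p_value: float
    group_sizes: tuple
    mean_srs: tuple
    direction: str  # "a_lower", "b_lower" or "equal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class RocResult:
    """ROC of separating known-class from unknown-class instances by SRS."""

    thresholds: np.ndarray
    tpr: np.ndarray  # fraction of known-class scores >= threshold
    fpr: np.ndarray  # fraction of unknown-class scores >= threshold
    auc: float


@dataclass
class MissingnessReport:
    """SRS statistics grouped by exact missing-attribute set.

    ``groups`` is a list of dicts (missing_set, count, mean_srs, sd_srs)
    ordered by mean SRS ascending; ``per_attribute`` maps each attribute to
    its mean SRS when absent vs when present.
    """

    groups: list
    per_attribute: dict
    n_rows: int


def _clean_samples(sample_a, sample_b):
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    return a, b


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_a < mean_b:
        return "a_lower"
    if mean_b < mean_a:
        return "b_lower"
    return "equal"


def _exact_mw_p(a: np.ndarray, b: np.ndarray, u_a: float) -> float:
    """Two-sided exact p over the permutation distribution of U, with ties.

    Midranks are doubled to integers and a dynamic program counts, for every
    achievable rank sum of the smaller sample, the number of ways to realize
    it.  Counts stay below 2**53 for every size this branch handles, so the
    arithmetic is exact.
    """
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    # DP over the smaller sample for speed; U is symmetric between samples
    k = min(n_a, n_b)
    total = ranks2.sum()
    max_sum = int(np.sort(ranks2)[-k:].sum())
    dp = np.zeros((k + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in ranks2:
        # iterate sizes downward so each item is used at most once
        for c in range(k, 0, -1):
            dp[c, r:] += dp[c - 1, : max_sum + 1 - r]
    # doubled rank sum of the smaller sample <-> doubled U for that sample
    # U_small = Rsum_small - n_small(n_small+1)/2 ; work in doubled units
    offset = k * (k + 1)  # doubled
    nm = n_a * n_b
    u_small = u_a if n_a <= n_b else nm - u_a
    dev = abs(2.0 * u_small - nm)  # doubled distance from the mean nm/2
    counts = dp[k]
    sums2 = np.arange(max_sum + 1)
    u2 = sums2 - offset  # doubled U for each achievable rank sum
    keep = np.abs(u2 - nm) >= dev - 1e-9
    hits = counts[keep].sum()
    total_ways = counts.sum()
    return float(hits / total_ways)


def mann_whitney_u(sample_a, sample_b) -> ShiftReport:
    """Two-sided Mann-Whitney U test (ties counted half).

    The p-value is an exact enumeration over the permutation distribution
    whenever ``n*m <= 200`` (exactness at the sample sizes where it is
    affordable and matters), and a tie- and continuity-corrected normal
    approximation otherwise.  The reported statistic is U for sample a.
    """
    a, b = _clean_samples(sample_a, sample_b)
    # U_a: pairs where a > b, plus half the ties
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u_a = float(r_a - a.size * (a.size + 1) / 2.0)
    if a.size * b.size <= EXACT_MW_LIMIT:
        p = _exact_mw_p(a, b, u_a)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return ShiftReport(
        method="mann_whitney",
        statistic=u_a,
        p_value=min(p, 1.0),
        group_sizes=(a.size, b.size),
        mean_srs=(float(a.mean()), float(b.mean())),
        direction=_direction(a.mean(), b.mean()),
    )


def welch_t(sample_a, sample_b) -> ShiftReport:
    """Two-sided Welch t-test (unequal variances, Welch-Satterthwaite df)."""
    a, b = _clean_samples(sample_a, sample_b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateDataError("both samples have zero variance")
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ShiftReport(
        method="welch_t",
        statistic=float(t),
        p_value=float(min(p, 1.0)),
        group_sizes=(a.size, b.size),
        mean_srs=(float(a.mean()), float(b.mean())),
        direction=_direction(a.mean(), b.mean()),
    )


def _srs_values(records) -> np.ndarray:
    vals = [r.srs for r in records if r.srs is not None and np.isfinite(r.srs)]
    return np.asarray(vals, dtype=float)


def srs_shift_test(records_a, records_b, method: str = "welch_t") -> ShiftReport:
    """Two-sample test on the SRS values of two scored cohorts.

    Both record sets must have been produced by the same trained model
    (fingerprints are compared); SRS values are only comparable within one
    model, so mixing models raises :class:`ComparabilityError`.
    """
    records_a, records_b = list(records_a), list(records_b)
    fps = {r.model_fingerprint for r in records_a} | {
        r.model_fingerprint for r in records_b
    }
    if len(fps) != 1:
        raise ComparabilityError(
            "records were scored under different models; SRS values are only "
            "comparable within a single trained model"
        )
    a, b = _srs_values(records_a), _srs_values(records_b)
    if method == "welch_t":
        return welch_t(a, b)
    if method == "mann_whitney":
        return mann_whitney_u(a, b)
    raise ValidationError(f"unknown method {method!r}")


def srs_roc_auc(srs_known, srs_unknown) -> RocResult:
    """ROC curve and AUC for picking out known-class instances by SRS.

    A threshold sweeps over all distinct scores; the true-positive rate is
    the fraction of known-class scores at or above the threshold, the
    false-positive rate the same fraction among unknown-class scores.  The
    trapezoid AUC satisfies the rank identity ``AUC = U/(n*m)`` with the
    Mann-Whitney U of known vs unknown (ties counted half); the identity is
    asserted internally on every call.
    """
    known = np.asarray(srs_known, dtype=float).ravel()
    unknown = np.asarray(srs_unknown, dtype=float).ravel()
    if known.size == 0 or unknown.size == 0:
        raise ValidationError("both score sets must be non-empty")

    thresholds = np.concatenate([[np.inf], np.unique(np.concatenate([known, unknown]))[::-1]])
    tpr = np.array([(known >= t).mean() for t in thresholds])
    fpr = np.array([(unknown >= t).mean() for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))

    # rank-based identity (also the probability a known outranks an unknown)
    ranks = stats.rankdata(np.concatenate([known, unknown]))
    u_known = ranks[: known.size].sum() - known.size * (known.size + 1) / 2.0
    auc_rank = float(u_known / (known.size * unknown.size))
    assert abs(auc - auc_rank) <= 1e-9, "ROC trapezoid violated the U identity"
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def missingness_profile(table: AttributeTable, records) -> MissingnessReport:
    """Group rows by exact missing-attribute set and profile the SRS.

    Groups are ordered by mean SRS ascending, so the patterns that hurt
    reliability most come first.  The per-attribute view contrasts the mean
    SRS of rows missing the attribute with rows where it is present.
    """
    records = list(records)
    if len(records) != table.n_rows:
        raise ValidationError("records are not aligned to the table rows")
    names = table.attribute_names
    mask = ~table.present_mask()  # True where missing
    srs_vals = np.array(
        [np.nan if r.srs is None else r.srs for r in records], dtype=float
    )

    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    groups = []
    for pi, pattern in enumerate(patterns):
        rows = np.flatnonzero(inverse == pi)
        vals = srs_vals[rows]
        finite = vals[np.isfinite(vals)]
        groups.append(
            {
                "missing_set": tuple(np.asarray(names)[pattern]),
                "count": int(rows.size),
                "mean_srs": float(finite.mean()) if finite.size else float("nan"),
                "sd_srs": float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
            }
        )
    groups.sort(key=lambda g: (np.isnan(g["mean_srs"]), g["mean_srs"]))

    per_attribute = {}
    for j, name in enumerate(names):
        absent = srs_vals[mask[:, j]]
        present = srs_vals[~mask[:, j]]
        absent = absent[np.isfinite(absent)]
        present = present[np.isfinite(present)]
        per_attribute[name] = {
            "mean_srs_absent": float(absent.mean()) if absent.size else float("nan"),
            "mean_srs_present": float(present.mean()) if present.size else float("nan"),
        }
    return MissingnessReport(groups=groups, per_attribute=per_attribute, n_rows=table.n_rows)


def apply_abstention(records, srs_threshold: float):
    """Return records with abstention flags updated against a threshold.

    A record abstains iff it already abstained or its SRS is below the
    threshold.  Returns ``(new_records, n_newly_abstained)``.
    """
    if srs_threshold is None or np.isnan(srs_threshold):
        raise ValidationError("srs_threshold must be a number (+/-inf allowed)")
    out = []
    newly = 0
    for r in records:
        flag = r.abstained or (r.srs is not None and r.srs < srs_threshold)
        if flag and not r.abstained:
            newly += 1
        out.append(
            type(r)(
                posteriors=r.posteriors,
                srs=r.srs,
                n_present=r.n_present,
                abstained=flag,
                class_labels=r.class_labels,
                model_fingerprint=r.model_fingerprint,
            )
        )
    return out, newly
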