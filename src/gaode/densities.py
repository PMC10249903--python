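"""One- and two-dimensional Gaussian-mixture densities.

These are the probabilistic building blocks of the classifier: for every
class, each attribute gets a univariate Gaussian mixture (its marginal) and
each attribute pair gets a bivariate Gaussian mixture (its joint).
Conditional densities are derived from the joints by dividing out the
joint's own implied marginal, so each conditional integrates to one.

All public density evaluations return base-10 logarithms and are computed
in log space throughout (log-sum-exp over components), so they stay finite
far into the tails instead of underflowing to zero.

Mixture fitting uses EM (scikit-learn) with the number of components chosen
by BIC over ``1..max_components``; fits are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import DegenerateDataError, TrainingDataError, ValidationError

__all__ = [
    "GMM1D",
    "GMM2D",
    "fit_gmm_1d",
    "fit_gmm_2d",
    "log10_density_1d",
    "log10_density_2d",
    "log10_conditional_density",
]

_LN10 = np.log(10.0)
_LOG_2PI = np.log(2.0 * np.pi)

#: Minimum number of observations required for any mixture fit.
DEFAULT_MIN_SAMPLES = 10

#: Variance floor, as a fraction of the squared data range.
DEFAULT_VARIANCE_FLOOR = 1e-8

#: EM restarts per candidate component count (k >= 2).
_N_INIT = 3

#: Diagonal regularization passed to EM.
_REG_COVAR = 1e-6


def _check_weights(weights: np.ndarray) -> None:
    if weights.ndim != 1 or weights.size < 1:
        raise ValidationError("weights must be a non-empty 1-D array")
    if np.any(weights <= 0):
        raise ValidationError("mixture weights must be strictly positive")
    if abs(weights.sum() - 1.0) > 1e-12:
        raise ValidationError(
            f"mixture weights must sum to 1 (got {weights.sum()!r})"
        )


@dataclass(frozen=True)
class GMM1D:
    """Univariate Gaussian mixture with strictly positive weights.

    Parameters are stored as plain arrays (one entry per component) so the
    model is trivially serializable and evaluation is vectorizable.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        _check_weights(self.weights)
        if not (self.weights.shape == self.means.shape == self.variances.shape):
            raise ValidationError("weights, means and variances must have equal length")
        if np.any(self.variances <= 0):
            raise ValidationError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class GMM2D:
    """Bivariate Gaussian mixture over an ordered attribute pair.

    ``covariances`` holds one symmetric positive-definite 2x2 matrix per
    component.  ``attribute_pair`` records which attributes the two
    coordinates refer to (in order).
    """

    weights: np.ndarray
    means: np.ndarray  # shape (k, 2)
    covariances: np.ndarray  # shape (k, 2, 2)
    attribute_pair: tuple[str, str] = ("x0", "x1")

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(
            self, "covariances", np.asarray(self.covariances, dtype=float)
        )
        _check_weights(self.weights)
        k = self.weights.size
        if self.means.shape != (k, 2):
            raise ValidationError("means must have shape (k, 2)")
        if self.covariances.shape != (k, 2, 2):
            raise ValidationError("covariances must have shape (k, 2, 2)")
        for c in self.covariances:
            if not np.allclose(c, c.T, atol=1e-12):
                raise ValidationError("covariance matrices must be symmetric")
            eigvals = np.linalg.eigvalsh(c)
            if eigvals.min() <= 0:
                raise ValidationError("covariance matrices must be positive definite")

    @property
    def n_components(self) -> int:
        return self.weights.size

    def marginal(self, coord: int) -> GMM1D:
        """The 1-D marginal implied by this joint in coordinate ``coord``.

        It is the mixture of the components' own univariate marginals, with
        the same weights.  This (not a separately fitted marginal) is the
        denominator used when conditioning, which makes the conditional a
        proper density.
        """
        if coord not in (0, 1):
            raise ValidationError("coord must be 0 or 1")
        return GMM1D(
            weights=self.weights,
            means=self.means[:, coord],
            variances=self.covariances[:, coord, coord],
        )

    def transposed(self) -> "GMM2D":
        """The same joint with coordinates swapped."""
        swap = self.covariances[:, ::-1, :][:, :, ::-1]
        return GMM2D(
            weights=self.weights,
            means=self.means[:, ::-1],
            covariances=swap,
            attribute_pair=(self.attribute_pair[1], self.attribute_pair[0]),
        )


def _as_finite_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite")
    return arr


def log10_density_1d(model: GMM1D, x) -> np.ndarray | float:
    """log10 of the mixture density at ``x`` (scalar or array).

    Computed as a log-sum-exp over components; finite for any finite ``x``
    whose exponent is representable in double precision.
    """
    arr = _as_finite_array(x, "x")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    # (n, k) component log densities in natural log
    z = (arr[:, None] - model.means[None, :]) ** 2 / model.variances[None, :]
    comp = -0.5 * (_LOG_2PI + np.log(model.variances[None, :]) + z)
    comp += np.log(model.weights[None, :])
    hi = comp.max(axis=1)
    out = (hi + np.log(np.exp(comp - hi[:, None]).sum(axis=1))) / _LN10
    return float(out[0]) if scalar else out


def _bivariate_component_logpdfs(model: GMM2D, xy: np.ndarray) -> np.ndarray:
    """Natural-log pdfs of each component at each point; shape (n, k)."""
    n = xy.shape[0]
    k = model.n_components
    out = np.empty((n, k))
    for c in range(k):
        cov = model.covariances[c]
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
        d = xy - model.means[c]
        quad = (
            inv[0, 0] * d[:, 0] ** 2
            + 2.0 * inv[0, 1] * d[:, 0] * d[:, 1]
            + inv[1, 1] * d[:, 1] ** 2
        )
        out[:, c] = -0.5 * (2.0 * _LOG_2PI + np.log(det) + quad)
    return out


def log10_density_2d(model: GMM2D, x, y) -> np.ndarray | float:
    """log10 of the bivariate mixture density at ``(x, y)``."""
    xa = _as_finite_array(x, "x")
    ya = _as_finite_array(y, "y")
    scalar = xa.ndim == 0 and ya.ndim == 0
    xa, ya = np.atleast_1d(xa), np.atleast_1d(ya)
    xa, ya = np.broadcast_arrays(xa, ya)
    xy = np.column_stack([xa, ya])
    comp = _bivariate_component_logpdfs(model, xy) + np.log(model.weights[None, :])
    hi = comp.max(axis=1)
    out = (hi + np.log(np.exp(comp - hi[:, None]).sum(axis=1))) / _LN10
    return float(out[0]) if scalar else out


def log10_conditional_density(joint: GMM2D, x_i, x_j) -> np.ndarray | float:
    """log10 of f(x_i | x_j) derived from the joint model.

    Equal to ``log10 f(x_i, x_j) - log10 f_j(x_j)`` where ``f_j`` is the
    joint's own implied marginal in the conditioning (second) coordinate.
    By construction the conditional integrates to one over ``x_i``.
    """
    return log10_density_2d(joint, x_i, x_j) - log10_density_1d(
        joint.marginal(1), x_j
    )


def _seed_for(seed: int, k: int) -> int:
    # one deterministic child stream per candidate component count
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, k]).generate_state(1)[0] % (2**31))


def fit_gmm_1d(
    values,
    max_components: int = 5,
    seed: int = 0,
    *,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> GMM1D:
    """Fit a univariate Gaussian mixture by EM with BIC model selection.

    Component counts ``1..max_components`` are fitted (three seeded EM
    restarts each for k >= 2) and the fit minimizing BIC is returned.
    Variances are clipped from below at ``variance_floor`` times the squared
    data range, which prevents degenerate spikes on near-duplicate values.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(vals)):
        raise ValidationError("training values must be finite")
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    if vals.size < min_samples:
        raise TrainingDataError(
            f"need at least {min_samples} values to fit a 1-D mixture, got {vals.size}"
        )
    rng_range = vals.max() - vals.min()
    if rng_range == 0.0:
        raise DegenerateDataError("all training values are identical (zero variance)")
    floor = variance_floor * rng_range**2

    X = vals[:, None]
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        if k > vals.size:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=1 if k == 1 else _N_INIT,
            reg_covar=_REG_COVAR,
            random_state=_seed_for(seed, k),
        )
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    w = best.weights_ / best.weights_.sum()
    variances = np.maximum(best.covariances_[:, 0, 0], floor)
    return GMM1D(weights=w, means=best.means_[:, 0], variances=variances)


def fit_gmm_2d(
    pairs,
    max_components: int = 5,
    seed: int = 0,
    *,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    attribute_pair: tuple[str, str] = ("x0", "x1"),
) -> GMM2D:
    """Fit a bivariate Gaussian mixture by EM with BIC model selection.

    Rows containing non-finite entries must be removed by the caller; the
    fit requires at least ``min_samples`` complete pairs.  Each component's
    covariance is regularized to keep its smallest eigenvalue at or above
    the variance floor.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("training pairs must be finite")
    if max_components < 1:
        raise ValidationError("max_components must be >= 1")
    if arr.shape[0] < min_samples:
        raise TrainingDataError(
            f"need at least {min_samples} complete pairs to fit a joint mixture, "
            f"got {arr.shape[0]}"
        )
    ranges = arr.max(axis=0) - arr.min(axis=0)
    if np.any(ranges == 0.0):
        raise DegenerateDataError("an attribute has zero variance in the pair data")
    floor = variance_floor * float(ranges.max()) ** 2

    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        if k > arr.shape[0]:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=1 if k == 1 else _N_INIT,
            reg_covar=_REG_COVAR,
            random_state=_seed_for(seed, k),
        )
        gm.fit(arr)
        bic = gm.bic(arr)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    covs = best.covariances_.copy()
    for c in range(covs.shape[0]):
        covs[c] = 0.5 * (covs[c] + covs[c].T)
        lo = np.linalg.eigvalsh(covs[c]).min()
        if lo < floor:
            covs[c] += (floor - lo) * np.eye(2)
    w = best.weights_ / best.weights_.sum()
    return GMM2D(
        weights=w,
        means=best.means_,
        covariances=covs,
        attribute_pair=attribute_pair,
    )
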