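"""Seeded synthetic data generators.

Each generator emulates the statistical structure of one benchmark
scenario used to exercise the classifier and its diagnostics:

* a two-class single-attribute problem with well-separated narrow
  Gaussians, N(-1, 0.2^2) vs N(+1, 0.2^2);
* two-attribute class pairs with contrasting correlation structure;
* a three-class, seven-attribute morphology-style table (correlated traits,
  one class intermediate between the other two) for leave-one-class-out
  unknown-class experiments;
* binary-class, 22-attribute cohorts for training/application shift
  experiments (translation of the application cohort, or shrinkage of its
  between-class separation);
* a two-class table mixing informative attributes (class-dependent, tight)
  with pure noise attributes (class-independent, broad), plus controlled
  missingness injection.

All generators are pure functions of their parameters and seed: the same
call yields a bitwise-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import AttributeTable

__all__ = [
    "ScenarioSpec",
    "gen_1d_two_class",
    "gen_2d_classes",
    "preset_2d",
    "uniform_grid_sample",
    "gen_multiclass_unknown",
    "gen_cohort_shift",
    "gen_informative_noise",
    "inject_missingness",
    "split_train_test",
]

#: Trait names used for the 7-attribute morphology-style generator.
_MORPHOLOGY_NAMES = [
    "area",
    "perimeter",
    "compactness",
    "kernel_length",
    "kernel_width",
    "asymmetry",
    "groove_length",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_1d_two_class(
    n_per_class: int = 1000,
    means: tuple = (-1.0, 1.0),
    sd: float = 0.2,
    seed: int = 0,
) -> AttributeTable:
    """Two classes, one attribute, equal-sd Gaussians.

    Defaults draw 1000 instances per class from N(-1, 0.2^2) (class1) and
    N(+1, 0.2^2) (class2): narrow, well-separated classes whose midpoint is
    25 within-class standard deviations from either mean.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    if not sd > 0:
        raise ValidationError("sd must be positive")
    rng = _rng(seed)
    x1 = rng.normal(means[0], sd, n_per_class)
    x2 = rng.normal(means[1], sd, n_per_class)
    data = pd.DataFrame({"x": np.concatenate([x1, x2])})
    labels = pd.Series(["class1"] * n_per_class + ["class2"] * n_per_class, name="class")
    return AttributeTable(data=data, labels=labels)


@dataclass(frozen=True)
class ScenarioSpec:
    """Explicit per-class bivariate mixture parameters for 2-D scenarios.

    ``classes`` maps a class label to a list of components, each a tuple
    ``(weight, mean, cov)`` with ``mean`` length-2 and ``cov`` 2x2.
    """

    classes: dict
    n_per_class: int = 1000
    attribute_names: tuple = ("x", "y")

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        for label, comps in self.classes.items():
            w = np.array([c[0] for c in comps], dtype=float)
            if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError(f"class {label!r}: weights must be positive and sum to 1")
            for _, mean, cov in comps:
                cov = np.asarray(cov, dtype=float)
                if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                    raise ValidationError(f"class {label!r}: covariance must be symmetric 2x2")
                if np.linalg.eigvalsh(cov).min() <= 0:
                    raise ValidationError(f"class {label!r}: covariance must be positive definite")


def preset_2d(name: str, n_per_class: int = 1000) -> ScenarioSpec:
    """Built-in two-attribute scenarios with contrasting correlation structure.

    ``"X-like"``: two independent, diagonally separated round classes.
    ``"Y-like"``: two overlapping classes with opposite strong correlations.
    ``"Z-like"``: a bimodal class against a single broad class.
    """
    r = 0.9
    presets = {
        "X-like": {
            "class1": [(1.0, (-1.0, -1.0), ((0.09, 0.0), (0.0, 0.09)))],
            "class2": [(1.0, (1.0, 1.0), ((0.09, 0.0), (0.0, 0.09)))],
        },
        "Y-like": {
            "class1": [(1.0, (0.0, 0.0), ((1.0, r), (r, 1.0)))],
            "class2": [(1.0, (0.0, 0.0), ((1.0, -r), (-r, 1.0)))],
        },
        "Z-like": {
            "class1": [
                (0.5, (-1.0, 1.0), ((0.04, 0.0), (0.0, 0.04))),
                (0.5, (1.0, -1.0), ((0.04, 0.0), (0.0, 0.04))),
            ],
            "class2": [(1.0, (0.0, 0.0), ((0.5, 0.35), (0.35, 0.5)))],
        },
    }
    if name not in presets:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return ScenarioSpec(classes=presets[name], n_per_class=n_per_class)


def gen_2d_classes(spec: ScenarioSpec, seed: int = 0) -> AttributeTable:
    """Draw labeled samples from per-class bivariate Gaussian mixtures."""
    rng = _rng(seed)
    frames, labels = [], []
    for label in sorted(spec.classes):
        comps = spec.classes[label]
        weights = np.array([c[0] for c in comps])
        counts = rng.multinomial(spec.n_per_class, weights)
        draws = []
        for (w, mean, cov), k in zip(comps, counts):
            if k:
                draws.append(rng.multivariate_normal(np.asarray(mean, float), np.asarray(cov, float), size=k))
        xy = np.vstack(draws)
        rng.shuffle(xy, axis=0)
        frames.append(xy)
        labels.extend([label] * spec.n_per_class)
    data = pd.DataFrame(np.vstack(frames), columns=list(spec.attribute_names))
    return AttributeTable(data=data, labels=pd.Series(labels, name="class"))


def uniform_grid_sample(
    bounds=((-2.0, 2.0), (-2.0, 2.0)),
    n: int = 2000,
    seed: int = 0,
    attribute_names: tuple | None = None,
) -> AttributeTable:
    """Uniform draws over an axis-aligned box, for probability/SRS heat maps."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    lo, hi = [], []
    for b in bounds:
        if not (np.isfinite(b[0]) and np.isfinite(b[1])) or b[0] >= b[1]:
            raise ValidationError(f"invalid bounds {b!r}")
        lo.append(b[0])
        hi.append(b[1])
    rng = _rng(seed)
    vals = rng.uniform(lo, hi, size=(n, len(bounds)))
    if attribute_names is None:
        attribute_names = ["x", "y", "z"][: len(bounds)] if len(bounds) <= 3 else [
            f"x{i}" for i in range(len(bounds))
        ]
    return AttributeTable(data=pd.DataFrame(vals, columns=list(attribute_names)))


def gen_multiclass_unknown(
    n_per_class: int = 70,
    n_attributes: int = 7,
    seed: int = 0,
    spacing: float = 1.0,
) -> AttributeTable:
    """Three classes of correlated traits with class1 intermediate.

    Traits follow a one-factor model within each class: a shared latent
    factor (loading 0.3 per trait) plus independent noise (sd 0.2), giving
    strong pairwise trait correlations like real morphology measurements.
    Class means sit at ``-spacing * u`` (class2), ``0`` (class1) and
    ``+spacing * u`` (class3) along a fixed positive direction ``u``, so
    class1 is componentwise intermediate between the other two.
    """
    if n_per_class < 10:
        raise ValidationError("n_per_class must be >= 10")
    if n_attributes < 2:
        raise ValidationError("n_attributes must be >= 2")
    rng = _rng(seed)
    base_u = np.array([1.0, 1.0, 0.8, 1.2, 0.9, 1.1, 1.0])
    u = np.resize(base_u, n_attributes)
    loading = np.full(n_attributes, 0.3)
    noise_sd = 0.2

    if n_attributes == 7:
        names = list(_MORPHOLOGY_NAMES)
    else:
        names = [f"trait{i + 1}" for i in range(n_attributes)]

    offsets = {"class1": 0.0, "class2": -spacing, "class3": +spacing}
    frames, labels = [], []
    for label in sorted(offsets):
        mu = offsets[label] * u
        z = rng.normal(size=(n_per_class, 1))
        eps = rng.normal(scale=noise_sd, size=(n_per_class, n_attributes))
        frames.append(mu[None, :] + z * loading[None, :] + eps)
        labels.extend([label] * n_per_class)
    data = pd.DataFrame(np.vstack(frames), columns=names)
    return AttributeTable(data=data, labels=pd.Series(labels, name="class"))


def _random_correlation(rng: np.random.Generator, p: int, rank: int = 5) -> np.ndarray:
    """A fixed-per-seed random correlation matrix with moderate off-diagonals."""
    A = rng.normal(size=(p, rank)) * 0.45
    C = A @ A.T + np.eye(p)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def gen_cohort_shift(
    n_per_cohort: int = 800,
    shift=None,
    separation_scale: float = 1.0,
    seed: int = 0,
    n_attributes: int = 22,
):
    """Binary-class multivariate-normal cohorts for shift experiments.

    Returns ``(train, matched, mismatched)`` tables.  The training table
    holds ``n_per_cohort`` rows per class; each test cohort holds
    ``n_per_cohort`` rows split evenly between the classes.  The matched
    cohort is drawn from the training distribution.  The mismatched cohort
    is translated by ``shift`` (default 0.35 on every attribute, a systemic
    cohort-wide offset) and its between-class mean gap is multiplied by
    ``separation_scale`` (values < 1 shrink the class separation, the
    second failure mode of interest).

    Attributes share a random correlation matrix fixed by the seed; the two
    classes differ in mean on the first 8 attributes (gap 0.8 sd each).
    """
    if n_per_cohort < 10:
        raise ValidationError("n_per_cohort must be >= 10")
    if not separation_scale >= 0:
        raise ValidationError("separation_scale must be >= 0")
    if shift is None:
        shift = np.full(n_attributes, 0.35)
    else:
        shift = np.broadcast_to(np.asarray(shift, dtype=float), (n_attributes,)).copy()
    rng = _rng(seed)
    corr = _random_correlation(rng, n_attributes)
    gap = np.zeros(n_attributes)
    gap[: min(8, n_attributes)] = 0.8
    names = [f"attr{i + 1}" for i in range(n_attributes)]

    def draw(n_per_class, center, scale):
        frames, labels = [], []
        for label, sign in (("elevated", +0.5), ("normal", -0.5)):
            mu = center + sign * scale * gap
            frames.append(rng.multivariate_normal(mu, corr, size=n_per_class))
            labels.extend([label] * n_per_class)
        data = pd.DataFrame(np.vstack(frames), columns=names)
        return AttributeTable(data=data, labels=pd.Series(labels, name="class"))

    zero = np.zeros(n_attributes)
    train = draw(n_per_cohort, zero, 1.0)
    matched = draw(n_per_cohort // 2, zero, 1.0)
    mismatched = draw(n_per_cohort // 2, shift, separation_scale)
    return train, matched, mismatched


def gen_informative_noise(
    n_per_class: int = 500,
    n_informative: int = 5,
    n_noise: int = 3,
    seed: int = 0,
    separation: float = 1.0,
    informative_sd: float = 0.4,
) -> AttributeTable:
    """Two classes with informative and pure-noise attributes.

    Informative attributes are tight per-class Gaussians (sd 0.4) whose
    means differ between classes by ``separation``; noise attributes are
    N(0, 1) identically for both classes and carry no class signal.  The
    contrast in per-class concentration is what lets the reliability score
    tell a missing informative attribute from a missing noise attribute.
    """
    if n_per_class < 1 or n_informative < 1 or n_noise < 1:
        raise ValidationError("counts must be >= 1")
    rng = _rng(seed)
    names = [f"inf{i + 1}" for i in range(n_informative)] + [
        f"noise{i + 1}" for i in range(n_noise)
    ]
    frames, labels = [], []
    for label, sign in (("classA", -0.5), ("classB", +0.5)):
        inf = rng.normal(
            loc=sign * separation, scale=informative_sd, size=(n_per_class, n_informative)
        )
        noise = rng.normal(size=(n_per_class, n_noise))
        frames.append(np.hstack([inf, noise]))
        labels.extend([label] * n_per_class)
    data = pd.DataFrame(np.vstack(frames), columns=names)
    return AttributeTable(data=data, labels=pd.Series(labels, name="class"))


def inject_missingness(
    table: AttributeTable,
    remove=None,
    rate: float | None = None,
    seed: int = 0,
) -> AttributeTable:
    """Return a copy of the table with cells blanked out.

    Exactly one mode must be chosen:

    * ``remove=[names...]`` blanks those attributes in every row;
    * ``remove=(k, [candidates...])`` blanks ``k`` randomly chosen
      candidates per row (a fresh draw per row);
    * ``rate=p`` blanks each cell independently with probability ``p``.

    A row that would lose all its attributes raises a validation error.
    """
    if (remove is None) == (rate is None):
        raise ValidationError("specify exactly one of remove= or rate=")
    names = table.attribute_names
    values = table.data.to_numpy().copy()
    rng = _rng(seed)

    if rate is not None:
        if not 0.0 <= rate < 1.0:
            raise ValidationError("rate must be in [0, 1)")
        blank = rng.random(values.shape) < rate
    else:
        blank = np.zeros(values.shape, dtype=bool)
        if isinstance(remove, tuple) and len(remove) == 2 and isinstance(remove[0], (int, np.integer)):
            k, candidates = remove
            idx = [names.index(c) for c in candidates]
            if not 1 <= k <= len(idx):
                raise ValidationError("k must be between 1 and the number of candidates")
            for r in range(values.shape[0]):
                chosen = rng.choice(idx, size=k, replace=False)
                blank[r, chosen] = True
        else:
            idx = [names.index(c) for c in remove]
            blank[:, idx] = True

    new_missing = blank | np.isnan(values)
    if np.any(new_missing.all(axis=1)):
        bad = int(np.flatnonzero(new_missing.all(axis=1))[0])
        raise ValidationError(f"row {bad} would be left with zero present attributes")
    values[blank] = np.nan
    return AttributeTable(
        data=pd.DataFrame(values, columns=names),
        labels=None if table.labels is None else table.labels.copy(),
        ids=None if table.ids is None else table.ids.copy(),
    )


def split_train_test(table: AttributeTable, train_fraction: float = 0.5, seed: int = 0):
    """Random stratified split into (train, test) tables.

    Splits each class separately so both halves keep the class proportions;
    with the 70-per-class default of the three-class generator this yields
    the 35/35 per-class design.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    rng = _rng(seed)
    n = table.n_rows
    train_mask = np.zeros(n, dtype=bool)
    if table.labels is None:
        perm = rng.permutation(n)
        cut = int(round(train_fraction * n))
        train_mask[perm[:cut]] = True
    else:
        for label in table.class_labels():
            rows = np.flatnonzero((table.labels == label).to_numpy())
            perm = rng.permutation(rows)
            cut = int(round(train_fraction * rows.size))
            train_mask[perm[:cut]] = True
    return table.subset(train_mask), table.subset(~train_mask)
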