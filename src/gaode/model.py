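"""Training, construction and persistence of the full per-class model.

A trained model holds, for every class, one univariate Gaussian mixture per
attribute (the marginals) and one bivariate Gaussian mixture per unordered
attribute pair (the joints), plus class priors and optional standardization
parameters.  Classification and the reliability score both read exclusively
from this object, which is what makes the score interpretable: it is
computed from the very densities the classifier uses.

Models serialize to a single versioned JSON document; the SHA-256 hash of
the canonical serialization acts as a fingerprint that result files carry,
so scores from different models can never be compared silently.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .densities import (
    DEFAULT_MIN_SAMPLES,
    DEFAULT_VARIANCE_FLOOR,
    GMM1D,
    GMM2D,
    fit_gmm_1d,
    fit_gmm_2d,
)
from .errors import FormatError, TrainingDataError, ValidationError
from .io import AttributeTable

__all__ = [
    "TrainingConfig",
    "ClassModel",
    "TrainedModel",
    "train_model",
    "build_model_from_parameters",
    "save_model",
    "load_model",
]

FORMAT_VERSION = "gaode-model-1"


@dataclass(frozen=True)
class TrainingConfig:
    """Settings for model training.

    max_components:
        Upper bound on mixture components per density; BIC chooses within
        ``1..max_components``.
    min_samples:
        Minimum rows (per class, and per pairwise-complete subset) for any fit.
    seed:
        Seed for all EM restarts; recorded in the model for provenance.
    standardize:
        If True, attributes are centered/scaled using training means and
        standard deviations (computed over present values only); the
        parameters are stored so application data is transformed identically.
    variance_floor:
        Variance floor as a fraction of the squared per-fit data range.
    """

    max_components: int = 5
    min_samples: int = DEFAULT_MIN_SAMPLES
    seed: int = 0
    standardize: bool = False
    variance_floor: float = DEFAULT_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if self.max_components < 1 or self.min_samples < 1:
            raise ValidationError("max_components and min_samples must be >= 1")


@dataclass
class ClassModel:
    """Density bank for one class: marginals per attribute, joints per pair."""

    class_label: str
    marginals: dict  # attribute name -> GMM1D
    joints: dict  # (name_i, name_j) with i<j in attribute order -> GMM2D


@dataclass
class TrainedModel:
    """The complete generative model all scoring reads from."""

    attribute_names: list
    classes: list  # of ClassModel
    priors: np.ndarray
    standardization: dict | None = None  # name -> (mean, sd)
    config: TrainingConfig | None = None

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        if np.any(self.priors <= 0) or abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValidationError("priors must be strictly positive and sum to 1")
        if len(self.priors) != len(self.classes):
            raise ValidationError("one prior per class required")
        n = len(self.attribute_names)
        expected_pairs = n * (n - 1) // 2
        for cm in self.classes:
            if set(cm.marginals) != set(self.attribute_names):
                raise ValidationError(
                    f"class {cm.class_label!r}: marginals must cover every attribute"
                )
            if len(cm.joints) != expected_pairs:
                raise ValidationError(
                    f"class {cm.class_label!r}: expected {expected_pairs} joints, "
                    f"got {len(cm.joints)}"
                )

    @property
    def class_labels(self) -> list:
        return [c.class_label for c in self.classes]

    def class_model(self, label: str) -> ClassModel:
        for cm in self.classes:
            if cm.class_label == label:
                return cm
        raise KeyError(f"unknown class label {label!r}")

    def standardize_values(self, data: np.ndarray) -> np.ndarray:
        """Apply stored standardization to an (n, p) value array (NaN-safe)."""
        if self.standardization is None:
            return data
        out = data.astype(float).copy()
        for j, name in enumerate(self.attribute_names):
            m, s = self.standardization[name]
            out[:, j] = (out[:, j] - m) / s
        return out

    def fingerprint(self) -> str:
        """SHA-256 hash of the canonical serialization."""
        doc = _serialize(self)
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()


def _pairs(names) -> list:
    return list(itertools.combinations(names, 2))


def train_model(table: AttributeTable, config: TrainingConfig | None = None) -> TrainedModel:
    """Fit per-class marginal and pairwise-joint mixtures from labeled data.

    Marginal fits use the rows where that attribute is present; joint fits
    use pairwise-complete rows (both members present).  No imputation is
    performed anywhere.  Priors default to uniform; they can be overridden
    at classification time.
    """
    config = config or TrainingConfig()
    if table.labels is None:
        raise TrainingDataError("training table must carry class labels")
    names = table.attribute_names
    if len(names) < 1:
        raise TrainingDataError("at least one attribute required")
    labels = table.class_labels()

    values = table.data.to_numpy()
    if config.standardize:
        standardization = {}
        for j, name in enumerate(names):
            col = values[:, j]
            present = col[~np.isnan(col)]
            sd = float(present.std(ddof=0))
            if sd == 0.0:
                raise TrainingDataError(f"attribute {name!r} has zero variance")
            standardization[name] = (float(present.mean()), sd)
        work = values.copy()
        for j, name in enumerate(names):
            m, s = standardization[name]
            work[:, j] = (work[:, j] - m) / s
    else:
        standardization = None
        work = values

    fit_kwargs = dict(
        min_samples=config.min_samples, variance_floor=config.variance_floor
    )
    class_models = []
    for label in labels:
        mask = (table.labels == label).to_numpy()
        if mask.sum() < config.min_samples:
            raise TrainingDataError(
                f"class {label!r} has only {int(mask.sum())} rows "
                f"(minimum {config.min_samples})"
            )
        sub = work[mask]
        marginals = {}
        for j, name in enumerate(names):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                raise TrainingDataError(
                    f"attribute {name!r} entirely missing for class {label!r}"
                )
            marginals[name] = fit_gmm_1d(
                col, config.max_components, config.seed, **fit_kwargs
            )
        joints = {}
        for a, b in _pairs(names):
            ja, jb = names.index(a), names.index(b)
            cols = sub[:, [ja, jb]]
            complete = cols[~np.isnan(cols).any(axis=1)]
            joints[(a, b)] = fit_gmm_2d(
                complete,
                config.max_components,
                config.seed,
                attribute_pair=(a, b),
                **fit_kwargs,
            )
        class_models.append(ClassModel(class_label=label, marginals=marginals, joints=joints))

    priors = np.full(len(labels), 1.0 / len(labels))
    return TrainedModel(
        attribute_names=names,
        classes=class_models,
        priors=priors,
        standardization=standardization,
        config=config,
    )


def build_model_from_parameters(spec: dict) -> TrainedModel:
    """Construct a model from explicit component parameters (no fitting).

    Intended for closed-form work: the resulting model evaluates densities
    exactly equal to the specified mixtures.

    ``spec`` layout::

        {
          "attributes": ["x", "y"],
          "classes": {
            "class1": {
              "marginals": {"x": {"weights": [...], "means": [...], "variances": [...]}, ...},
              "joints": {("x", "y"): {"weights": [...], "means": [[..]], "covariances": [[[..]]]}},
            },
            ...
          },
          "priors": {"class1": 0.5, ...}   # optional, uniform if absent
        }
    """
    names = list(spec["attributes"])
    class_specs = spec["classes"]
    labels = sorted(class_specs)
    class_models = []
    for label in labels:
        cs = class_specs[label]
        marginals = {
            name: GMM1D(**params) for name, params in cs.get("marginals", {}).items()
        }
        joints = {}
        for pair, params in cs.get("joints", {}).items():
            pair = tuple(pair)
            joints[pair] = GMM2D(attribute_pair=pair, **params)
        class_models.append(ClassModel(class_label=label, marginals=marginals, joints=joints))
    if "priors" in spec:
        priors = np.array([float(spec["priors"][label]) for label in labels])
    else:
        priors = np.full(len(labels), 1.0 / len(labels))
    return TrainedModel(attribute_names=names, classes=class_models, priors=priors)


# --- persistence ---------------------------------------------------------


def _serialize(model: TrainedModel) -> dict:
    def gmm1d(m: GMM1D) -> dict:
        return {
            "weights": m.weights.tolist(),
            "means": m.means.tolist(),
            "variances": m.variances.tolist(),
        }

    def gmm2d(m: GMM2D) -> dict:
        return {
            "weights": m.weights.tolist(),
            "means": m.means.tolist(),
            "covariances": m.covariances.tolist(),
        }

    doc = {
        "format_version": FORMAT_VERSION,
        "attribute_names": list(model.attribute_names),
        "priors": model.priors.tolist(),
        "standardization": None
        if model.standardization is None
        else {k: list(v) for k, v in model.standardization.items()},
        "config": None
        if model.config is None
        else {
            "max_components": model.config.max_components,
            "min_samples": model.config.min_samples,
            "seed": model.config.seed,
            "standardize": model.config.standardize,
            "variance_floor": model.config.variance_floor,
        },
        "classes": [
            {
                "class_label": cm.class_label,
                "marginals": {name: gmm1d(m) for name, m in cm.marginals.items()},
                "joints": {
                    "\t".join(pair): gmm2d(m) for pair, m in cm.joints.items()
                },
            }
            for cm in model.classes
        ],
    }
    return doc


def save_model(model: TrainedModel, path) -> None:
    """Write the model as a versioned JSON document (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_serialize(model), fh, sort_keys=True)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format_version") != FORMAT_VERSION:
        raise FormatError(
            f"{path}: unknown model format version {doc.get('format_version')!r}"
            if isinstance(doc, dict)
            else f"{path}: malformed model file"
        )
    classes = []
    for cdoc in doc["classes"]:
        marginals = {
            name: GMM1D(
                weights=np.array(m["weights"]),
                means=np.array(m["means"]),
                variances=np.array(m["variances"]),
            )
            for name, m in cdoc["marginals"].items()
        }
        joints = {}
        for key, m in cdoc["joints"].items():
            pair = tuple(key.split("\t"))
            joints[pair] = GMM2D(
                weights=np.array(m["weights"]),
                means=np.array(m["means"]),
                covariances=np.array(m["covariances"]),
                attribute_pair=pair,
            )
        classes.append(
            ClassModel(class_label=cdoc["class_label"], marginals=marginals, joints=joints)
        )
    config = None
    if doc.get("config"):
        config = TrainingConfig(**doc["config"])
    standardization = None
    if doc.get("standardization"):
        standardization = {k: tuple(v) for k, v in doc["standardization"].items()}
    return TrainedModel(
        attribute_names=list(doc["attribute_names"]),
        classes=classes,
        priors=np.array(doc["priors"]),
        standardization=standardization,
        config=config,
    )
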