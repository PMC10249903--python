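"""Shared fixtures: exact (closed-form) models and small trained models."""

import numpy as np
import pandas as pd
import pytest

import gaode as g

STD_NORMAL_1D = {"weights": [1.0], "means": [0.0], "variances": [1.0]}


def gmm1(mean, var):
    return {"weights": [1.0], "means": [mean], "variances": [var]}


def joint2(mean, cov):
    return {"weights": [1.0], "means": [mean], "covariances": [cov]}


@pytest.fixture(scope="session")
def fig1a_exact_model():
    """Two single-Gaussian classes N(-1, 0.2^2) and N(+1, 0.2^2), one attribute."""
    return g.build_model_from_parameters(
        {
            "attributes": ["x"],
            "classes": {
                "class1": {"marginals": {"x": gmm1(-1.0, 0.04)}, "joints": {}},
                "class2": {"marginals": {"x": gmm1(1.0, 0.04)}, "joints": {}},
            },
        }
    )


@pytest.fixture(scope="session")
def independent_2d_model():
    """One class, two independent standard-normal attributes."""
    return g.build_model_from_parameters(
        {
            "attributes": ["x", "y"],
            "classes": {
                "c1": {
                    "marginals": {"x": STD_NORMAL_1D, "y": STD_NORMAL_1D},
                    "joints": {("x", "y"): joint2([0.0, 0.0], [[1.0, 0.0], [0.0, 1.0]])},
                }
            },
        }
    )


@pytest.fixture(scope="session")
def correlated_2d_model():
    """One class, standard bivariate normal joint with rho = 0.9."""
    return g.build_model_from_parameters(
        {
            "attributes": ["x", "y"],
            "classes": {
                "c1": {
                    "marginals": {"x": STD_NORMAL_1D, "y": STD_NORMAL_1D},
                    "joints": {("x", "y"): joint2([0.0, 0.0], [[1.0, 0.9], [0.9, 1.0]])},
                }
            },
        }
    )


@pytest.fixture(scope="session")
def two_class_2d_model():
    """Two classes of independent Gaussians in 2-D, zero-correlation joints.

    Class means (-1,-1) and (+1,+1), all variances 0.25: an exact model for
    checking the reduction to Naive Bayes when the joints carry no
    correlation.
    """
    def cls(mu):
        return {
            "marginals": {"x": gmm1(mu, 0.25), "y": gmm1(mu, 0.25)},
            "joints": {
                ("x", "y"): joint2([mu, mu], [[0.25, 0.0], [0.0, 0.25]])
            },
        }

    return g.build_model_from_parameters(
        {"attributes": ["x", "y"], "classes": {"a": cls(-1.0), "b": cls(1.0)}}
    )


@pytest.fixture(scope="session")
def wheat_like_model_and_tables():
    """A trained three-class morphology-style model with its train/test split."""
    table = g.gen_multiclass_unknown(seed=7)
    train, test = g.split_train_test(table, 0.5, seed=7)
    model = g.train_model(train, g.TrainingConfig(seed=7, max_components=2))
    return model, train, test


def unlabeled(table):
    """Strip labels so a table can be scored against any model."""
    return g.AttributeTable(data=table.data.copy())
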